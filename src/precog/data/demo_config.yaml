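# Packaged demonstration configuration — SYNTHETIC data.
#
# The shape mimics a multi-site OSCE: test takers nested within 6 sites,
# crossed with 4 exam forms and 18 stations, 30 examinees per site.  The
# true variance components are illustrative values chosen so the plug-in
# dependability coefficient of the current plan lands near 0.80; they are
# NOT estimates from any real examination.
design: "p:s x f x st"
error_type: absolute

simulation:
  sizes: {p: 30, s: 6, f: 4, st: 18}
  grand_mean: 70.0
  seed: 20220901
  components:
    "p:s": 0.35        # examinee (object of measurement)
    "s": 0.03          # site main effect
    "f": 0.03          # form difficulty
    "st": 1.05         # station difficulty (dominant facet effect)
    "s·f": 0.01
    "s·st": 0.02
    "f·st": 0.05
    "s·f·st": 0.01
    "p·f:s": 0.10      # examinee × form, within site
    "p·st:s": 0.90     # examinee × station, within site
    "p·f·st:s": 1.20   # residual

plans:
  - {label: current,  sizes: {s: 6, f: 4, st: 18}}
  - {label: proposed, sizes: {s: 5, f: 3, st: 17}}

cost_schedule:
  currency: "£"
  fixed_cost: 0
  unit_costs: {s: 15896, f: 6677, st: 4843}

cea:
  base: current
  intervention: proposed
  rescale_unit: 0.01
  n_draws: 10000
  seed: 20221017
  uncertainty:
    delta_effectiveness: {kind: normal, sd: auto}
    delta_cost: {kind: normal, cv: 0.05}
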