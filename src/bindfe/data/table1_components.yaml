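# Printed free-energy decomposition of crizotinib binding (kcal/mol, Å-based
# units) for the wild-type and G2032R-mutated ROS1 kinase: the eight restraint
# components, S* (Å²), I* (Å), the separation PMF depth, and the published
# totals used to verify the assembly arithmetic.
temperature: 310.0
systems:
  WT-ROS1:
    conf_site: 0.073
    conf_bulk: 1.639
    orient_alpha: 0.410
    orient_beta: 0.892
    orient_gamma: 0.210
    orient_bulk: 7.135
    trans_theta: 0.355
    trans_Theta: 0.162
    separation_pmf: -24.96
    s_star: 9.834
    i_star: 1.98e+17
    printed:
      k_bind: 3.85e+13
      dg_bind_us: -14.70
      dg_off: 12.10
      dg_bind_meta: -10.14
  G2032R-ROS1:
    conf_site: 0.323
    conf_bulk: 1.772
    orient_alpha: 0.617
    orient_beta: 0.520
    orient_gamma: 0.389
    orient_bulk: 7.230
    trans_theta: 0.214
    trans_Theta: 0.165
    separation_pmf: -18.32
    s_star: 8.950
    i_star: 4.44e+12
    printed:
      k_bind: 6.64e+08
      dg_bind_us: -7.95
      dg_off: 5.53
      dg_bind_meta: -5.91
printed_ddg:
  dg_bind_us: -6.75
  dg_off: 6.57
  dg_bind_meta: -4.23
  separation_pmf: -6.64
tolerances:
  k_bind_rel: 0.02
  dg_bind_us_abs: 0.02
  ddg_abs: 0.03
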