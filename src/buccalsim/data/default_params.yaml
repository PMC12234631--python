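time_scale: 1.02
control_dt: 0.01
anatomy:
  R: 1.0
  theta_H: 4.71238898038469
  theta_f: 0.6
  H_lumen: 2.0
  L_head: 3.0
  mm_per_unit: 6.0
  eso_anchor:
  - -2.5
  - 2.0
  e6_anchor_rel_head:
  - -1.0
  - 2.0
damping:
  scale: 0.02
  rel:
    x_h: 1.0
    x_d: 1.0
    x_v: 1.0
    x_g: 1.0
    y_g: 1.0
    theta_g: 1.0
penalty:
  k_pen: 10.0
  k_W: 10.0
friction:
  mu_s_g: 1.05
  mu_k_g: 0.7
  mu_s_j: 1.2
  mu_k_j: 1.0
head_spring:
  k: 2.0
  x_rest: 0.0
muscles:
  I2:
    T_max: 1.0
    tau: 1.0
    tau_act: 1.0
    tau_relax: 1.8
    L_0: 4.9
    L_max: 6.2
    passive_law: piecewise
  I3:
    T_max: 4.5
    tau: 0.8
    passive_law: none
  I3a:
    T_max: 1.0
    tau: 0.3
    passive_law: none
  I4:
    T_max: 1.5
    tau: 0.5
    passive_law: none
  hinge:
    T_max: 3.0
    tau: 0.7
    L_0: 0.45
    L_max: 1.2
    passive_law: piecewise
  I1d:
    T_max: 1.0
    tau: 0.8
    L_0: 2.0
    L_max: 2.6
    passive_law: linear
  I1v:
    T_max: 1.0
    tau: 0.8
    L_0: 2.0
    L_max: 2.6
    passive_law: linear
  E1:
    T_max: 0.4
    tau: 0.8
    L_0: 2.9
    L_max: 3.9
    passive_law: piecewise
  E2:
    T_max: 0.45
    tau: 0.8
    L_0: 2.9
    L_max: 3.9
    passive_law: piecewise
  E6:
    T_max: 0.3
    tau: 0.8
    L_0: 2.2
    L_max: 3.0
    passive_law: piecewise
  esophagus:
    T_max: 0.8
    tau: 1.0
    L_0: 3.5
    L_max: 4.5
    passive_law: piecewise
initial_state:
  x_h: 0.0
  x_d: 1.0
  x_v: 1.0
  x_g: 0.7
  theta_g: 0.1
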