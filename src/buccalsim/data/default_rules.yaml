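sensory:
  prot_bite:
    signal: xhat
    direction: greater
    threshold: 0.93
    target: B64
  ret_bite:
    signal: xhat
    direction: less
    threshold: 0.27
    target: B64
  prot_swallow:
    signal: xhat
    direction: greater
    threshold: 0.92
    target: B64
  ret_swallow:
    signal: xhat
    direction: less
    threshold: 0.2
    target: B64
  prot_reject:
    signal: xhat
    direction: greater
    threshold: 0.9
    target: B64
  ret_reject:
    signal: xhat
    direction: less
    threshold: 0.2
    target: B64
  i2_off_bite:
    signal: xhat
    direction: greater
    threshold: 0.88
    target: B31B32
  i2_off_swallow:
    signal: xhat
    direction: greater
    threshold: 0.55
    target: B31B32
  i2_off_reject:
    signal: xhat
    direction: greater
    threshold: 0.85
    target: B31B32
  hinge_stretch:
    signal: xhat
    direction: greater
    threshold: 0.7
    target: B7
  grasper_closed:
    signal: Pg_norm
    direction: greater
    threshold: 0.5
    target: B8ab
  reject_i3_gate:
    signal: xhat
    direction: less
    threshold: 0.77
    target: B3B6B9
  i2_off_loaded:
    signal: xhat
    direction: greater
    threshold: 0.42
    target: B31B32
derived:
  BITE: mech_lips and chem_lips and not mech_grasper
  SWALLOW: mech_grasper and chem_lips
  REJECT: mech_grasper and not chem_lips
  UNLOADED: SWALLOW and not seaweed_fixed
  LOADED: SWALLOW and seaweed_fixed
  ANY_BEHAVIOR: BITE or SWALLOW or REJECT
  PROT_DONE: (BITE and prot_bite) or (SWALLOW and prot_swallow) or (REJECT and prot_reject)
  RET_DONE: (BITE and ret_bite) or (SWALLOW and ret_swallow) or (REJECT and ret_reject)
  I2_OFF: (BITE and i2_off_bite) or (UNLOADED and i2_off_swallow) or (LOADED and i2_off_loaded)
    or (REJECT and i2_off_reject)
neurons:
  CBI2: ANY_BEHAVIOR and not B64
  CBI3: chem_lips and mech_lips
  CBI4: mech_grasper
  B64: PROT_DONE or (B64 and not RET_DONE)
  B20: REJECT and not B64
  B40B30: CBI2 and not B64
  B4B5: 1 if (CBI4 and B64 and not REJECT) else 0
  B31B32: ANY_BEHAVIOR and not B64 and not I2_OFF
  B8ab: B20 or ((BITE or SWALLOW) and B64 and not (B4B5 >= 2))
  B38: (BITE or SWALLOW) and not B64
  B3B6B9: B64 and not (B4B5 >= 2) and (not REJECT or reject_i3_gate)
  B7: B64
  B82: (CBI2 or CBI4) and not B64
  CE1: ANY_BEHAVIOR and not B64
  CE2: B64 and (not REJECT or reject_i3_gate)
  CE6: ANY_BEHAVIOR and not B64
motor_map:
  I2: B31B32
  I4: B8ab
  I3: B3B6B9
  I3a: B38
  hinge: B7
  I1d: B82
  I1v: B82
  E1: CE1
  E2: CE2
  E6: CE6
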