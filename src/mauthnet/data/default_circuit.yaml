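# Default circuit configuration (the parameter table the model is built
# from).  Conductances in nS (chemical g_peak / gap g_gap), HH channel
# densities in mS/cm^2, areas in um^2, times in ms, potentials in mV.
variant: biased_bilateral_mutual
ablations: []
config:
  lif:
    M:
      Rm: 10.0
      Erest: -79.0
      ECl: -75.0
      Espike: -61.0
      tau_m: 23.0
      t_refractory: 2.0
      n_per_side: 1
    FF:
      Rm: 400.0
      Erest: -77.0
      ECl: -75.0
      Espike: -61.0
      tau_m: 10.0
      t_refractory: 2.0
      n_per_side: 30
  hh:
    auditory:
      El: -79.0
      EK: -90.0
      ENa: 50.0
      gl: 0.05
      gNa: 100.0
      gK: 200.0
      n_per_side: 30
      area_min: 2000.0
      area_max: 20000.0
      v_rest_target: -79.0
  synapses:
    ff_ipsi_m: {g_peak: 25.0, delay: 0.3, tau_decay: 2.0}
    ff_contra_m_ratio: 2.5
    ff_contra_ff: {g_peak: 12.0, delay: 0.3, tau_decay: 2.0}
    aud_m_glut: {g_peak: 12.0, delay: 0.7, tau_decay: 2.0}
  gaps:
    # aud_m is the compound (lumped) electrical conductance of the afferent
    # pool onto one M-cell; aud_ff is per afferent/FF pair.
    aud_m: {g_gap: 15.0, dendritic_tau: 0.4, lumped: true}
    aud_ff: {g_gap: 10.0}
  sim:
    dt: 0.01
    glutamate_E_rev: 0.0
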