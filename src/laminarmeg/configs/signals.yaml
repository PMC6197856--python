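# The six standard frequency-band / epoch-window contrasts used for laminar
# discrimination.  Windows are seconds relative to the alignment event.
signals:
  - name: visual_alpha_rdk
    band: [7, 13]
    event: rdk
    woi: [0.0, 2.0]
    baseline_woi: [-1.0, -0.5]
    hypothesis: deep
  - name: visual_gamma_rdk
    band: [60, 90]
    event: rdk
    woi: [0.25, 0.5]
    baseline_woi: [-0.5, -0.25]
    hypothesis: superficial
  - name: visual_gamma_cue
    band: [60, 90]
    event: cue
    woi: [0.1, 0.5]
    baseline_woi: [-0.5, -0.1]
    hypothesis: superficial
  - name: motor_beta_rdk
    band: [15, 30]
    event: rdk
    woi: [0.0, 2.0]
    baseline_woi: [-0.5, 0.0]
    hypothesis: deep
  - name: motor_beta_rebound
    band: [15, 30]
    event: response
    woi: [0.5, 1.0]
    baseline_woi: [-0.25, 0.25]
    hypothesis: deep
  - name: motor_gamma_response
    band: [60, 90]
    event: response
    woi: [-0.1, 0.2]
    baseline_woi: [-1.5, -1.0]
    hypothesis: superficial
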