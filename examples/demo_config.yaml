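seed: 1
stages:
- ecog
- lesion
- evansblue
- stats
groups:
- name: sham
  n_animals: 4
  ecog:
    duration_s: 300.0
    events_per_recording: 0
    event_duration_s: 3.0
    event_amplitude: 5.0
  lesion:
    loss_fraction: 0.0
    loss_jitter_sd: 0.03
    n_sections: 6
  evansblue:
    fraction: 0.0
    fraction_jitter_sd: 0.02
    threshold: 120.0
- name: rb
  n_animals: 4
  ecog:
    duration_s: 300.0
    events_per_recording: 4
    event_duration_s: 3.0
    event_amplitude: 5.0
  lesion:
    loss_fraction: 0.371
    loss_jitter_sd: 0.03
    n_sections: 6
  evansblue:
    fraction: 0.25
    fraction_jitter_sd: 0.02
    threshold: 120.0
- name: rb_spg_15min
  n_animals: 4
  ecog:
    duration_s: 300.0
    events_per_recording: 0
    event_duration_s: 3.0
    event_amplitude: 5.0
  lesion:
    loss_fraction: 0.206
    loss_jitter_sd: 0.03
    n_sections: 6
  evansblue:
    fraction: 0.1
    fraction_jitter_sd: 0.02
    threshold: 120.0
- name: rb_spg_24h
  n_animals: 4
  ecog:
    duration_s: 300.0
    events_per_recording: 0
    event_duration_s: 3.0
    event_amplitude: 5.0
  lesion:
    loss_fraction: 0.179
    loss_jitter_sd: 0.03
    n_sections: 6
  evansblue:
    fraction: 0.1
    fraction_jitter_sd: 0.02
    threshold: 120.0
compare:
- - rb
  - sham
- - rb
  - rb_spg_15min
- - rb
  - rb_spg_24h
parameters:
  ecog:
    baseline_duration_s: 120.0
    rms_uv: 50.0
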