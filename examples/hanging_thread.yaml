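# A 30-element thread with a spiral rest shape, pinned at its upper end and
# hanging under gravity. Lengths may use _m / _cm / _mm suffixed keys.
schema_version: 1
seed: 0
duration: 1.0
sim:
  dt: 0.0041666666666666666  # 1/240 s
  iterations: 10
  use_ddc: true
  collision_enabled: false
rods:
  - name: thread
    shape:
      type: spiral
      helix_radius_mm: 4
      pitch_mm: 8
      axis: [0, -1, 0]
    n_elements: 30
    total_length_cm: 5
    radius_mm: 0.833
boundaries:
  - type: pin
    rod: 0
    particle: 0
output:
  trajectory: true
  every: 12
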