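# Configuration file schema

`RunConfig` is read from a YAML (or JSON) mapping. All keys are optional;
defaults are shown. Unknown keys are rejected.

```yaml
seed: 0                      # int, top-level seed; all sub-generators derive from it
mode: aggregation            # "aggregation" | "disaggregation"
dilution_factor: null        # float; null -> 1e5 (aggregation) or 1e3 (disaggregation)
stability_factors:           # dilution-stability correction per oligomer type
  A: 3.0
  B: 1.5
m_tot_uM: 70.0               # total monomer concentration of the bulk incubation, uM
p_donor: 0.5                 # donor fraction of the labeling mix

instrument:
  bin_width_ms: 1.0          # photon binning, ms
  donor_threshold: 20.0      # burst threshold, photons/bin
  acceptor_threshold: 10.0   # burst threshold, photons/bin
  gamma: 0.26                # detection/quantum-yield correction, (0, 1]
  monomer_donor_brightness: 30.0    # photons/bin of one donor at focus
  background_rate_donor: 2.0        # mean background, photons/bin
  background_rate_acceptor: 1.0     # mean background, photons/bin
  coincidence_detection_efficiency: 0.25   # (0, 1]
  probe_volume_fl: 4.0       # confocal probe volume, fL
  scan_speed_um_s: 200.0     # stage scan speed, um/s
```

Validation rules (raise `ValueError` on load): thresholds must exceed the
corresponding background rates; `gamma` and
`coincidence_detection_efficiency` in (0, 1]; positive geometry and
brightness; `p_donor` in [0, 1]; `mode` one of the two values above.

## Trace file format

TSV with a comment header and three required integer columns:

```
# bin_width_ms=1.0
# seed=7
bin_index	donor_counts	acceptor_counts
0	3	1
1	25	12
...
```

Missing columns, negative or non-integer counts raise a `SchemaError`
naming the offending column and row.
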