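# Expected values for the packaged-fixture reproduction report.
# Each key names a check computed by karyosynth.report.run_reproduction.
total_markers: 86
newly_mapped: 80
focal_cloned_probes: 18
origin_counts:
  GHO: 24
  LAG: 30
  LRE: 31
  EQU: 1
conserved_macro_chromosomes: ["1", "2", "3", "4", "6", "7", "8", "13", "14", "15"]
hit_unit_count: 11
lag_macro_count: 8
marker_counts:
  "1": 9
  "3": 7
  "6": 5
  "7": 6
  "13": 6
gho7_gga4q_support: 6
micro_composed: ["5", "9", "10", "11"]
partitions_identical: false
required_events:
  - ["centric_fusion", ["proto-GHO13", "proto-GHO15"], "Toxicofera"]
  - ["centric_fusion", ["proto-GHO3", "proto-GHO6"], "Toxicofera"]
  - ["centric_fusion", ["proto-GHO8", "proto-GHO12"], "Toxicofera"]
  - ["centric_fusion", ["proto-GHO7", "proto-GHO14q"], "Toxicofera"]
  - ["centric_fusion", ["proto-GHOZ", "proto-GHO1q"], "Toxicofera"]
  - ["centric_fusion", ["proto-GHO1p", "proto-GHO1q"], "Gekkota"]
  - ["centric_fusion", ["proto-GHO2q", "proto-LAG1"], "Gekkota"]
  - ["tandem_fusion", ["GHO14p", "proto-GHO14q"], "Gekkota"]
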