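# Default parameter sets for the five rule-based glaucomatous-field
# criteria, expressed through the generic cluster-rule engine
# (vfstack.criteria).  These are editable reconstructions of the
# published criteria; levels name probability-map categories.
#
# Fields: map_kind (TD|PD), cluster_min_size, cluster_level, anchor_level,
# non_edge_only, same_hemifield, require_ght_outside, require_psd_abnormal,
# psd_percentile, confirmation_tests.
LoGTS:
  map_kind: TD
  cluster_min_size: 3
  cluster_level: "p<5%"
  anchor_level: "p<5%"
  non_edge_only: false
  same_hemifield: false
  require_ght_outside: false
  require_psd_abnormal: false
  psd_percentile: 0.05
  confirmation_tests: 1
UKGTS:
  map_kind: TD
  cluster_min_size: 3
  cluster_level: "p<5%"
  anchor_level: "p<1%"
  non_edge_only: false
  same_hemifield: true
  require_ght_outside: false
  require_psd_abnormal: false
  psd_percentile: 0.05
  confirmation_tests: 1
Kang:
  map_kind: TD
  cluster_min_size: 3
  cluster_level: "p<5%"
  anchor_level: "p<1%"
  non_edge_only: true
  same_hemifield: true
  require_ght_outside: false
  require_psd_abnormal: false
  psd_percentile: 0.05
  confirmation_tests: 1
HAP2_p1:
  map_kind: PD
  cluster_min_size: 3
  cluster_level: "p<5%"
  anchor_level: "p<1%"
  non_edge_only: true
  same_hemifield: true
  require_ght_outside: false
  require_psd_abnormal: false
  psd_percentile: 0.05
  confirmation_tests: 1
Foster:
  map_kind: PD
  cluster_min_size: 3
  cluster_level: "p<5%"
  anchor_level: "p<1%"
  non_edge_only: false
  same_hemifield: false
  require_ght_outside: true
  require_psd_abnormal: false
  psd_percentile: 0.05
  confirmation_tests: 1
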