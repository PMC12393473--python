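# Demo configuration for `autopod run-all --config configs/demo.yaml`.
# Any key omitted here falls back to the built-in defaults.
seed: 1
simulate:
  trio:
    chrom_length: 310000
    n_target_fixed: 400
    n_sister_fixed: 300
    n_shared_polymorphic: 150
    indel_blocks: [[120000, 400], [250000, 250]]
    blacklist_regions: [[60000, 61000]]
  atlas:
    n_elements: 300
    element_length: 500
    spacing: 1000
  features:
    n_per_class: 40
    length: 200
  score_track:
    shift: 1.0
    noise_sd: 0.5
divergence:
  standard_length: 500
  maf_threshold: 0.05
  min_identity: 0.25
  identity_rule: and
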