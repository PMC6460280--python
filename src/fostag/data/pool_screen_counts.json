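{
  "description": "Summary counts reported for a 40-clone pooled soil fosmid sequencing screen; inputs for the worked-example arithmetic.",
  "n_clones": 40,
  "raw_reads": 135103,
  "mean_read_length_nt": 369,
  "cleaned_reads": 85745,
  "assembly": {
    "n_contigs": 3811,
    "total_nt": 2853727,
    "longest_nt": 37904,
    "n_gt_1kb": 343,
    "n_gt_10kb": 37,
    "n50_nt": 1006,
    "l50_count": 337
  },
  "clones_full_tagged": 18,
  "clones_partial_tagged": 15,
  "orf_predictions": 105773,
  "clusters": 97317,
  "seed_mean_aa": 136,
  "seed_sd_aa": 120,
  "seed_max_aa": 1536,
  "peptides_with_domain_hit": 2202,
  "distinct_domain_families": 1175,
  "assigned_fosmid_predictions": 451,
  "protease_genes_on_assigned_fosmids": 14,
  "lipase_esterase_genes_on_assigned_fosmids": 12,
  "assumed_fosmid_length_nt": 44000
}
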