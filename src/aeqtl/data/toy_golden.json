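{
  "comment": "Hand-computed expected outputs for make_toy_fixture(); every number derived by hand from the fixture's count and genotype tables.",
  "regions": {
    "geneA": {"txsnp_ids": ["tx1", "tx4"], "span": [5000, 15000]},
    "geneB": {"txsnp_ids": ["tx3"], "span": [120000, 130000]}
  },
  "txsnps_in_no_region": ["tx2"],
  "pairs": [
    {"risk_snp_id": "rs_toy", "region_id": "geneA", "distance": 4001, "distance_rank": 1},
    {"risk_snp_id": "rs_toy", "region_id": "geneB", "distance": 119001, "distance_rank": 2}
  ],
  "funnels": {
    "geneA": {
      "n_candidates": 15,
      "n_unphased_txsnp": 0,
      "n_fail_reads": 1,
      "n_fail_minor": 1,
      "n_pass": 13,
      "n_usable_samples": 12,
      "group_n": [5, 2, 5],
      "testable": true
    },
    "geneB": {
      "n_candidates": 5,
      "n_unphased_txsnp": 0,
      "n_fail_reads": 1,
      "n_fail_minor": 1,
      "n_pass": 4,
      "n_usable_samples": 4,
      "group_n": [2, 0, 2],
      "testable": false
    }
  },
  "fractions": {
    "geneA": {
      "S01": {"fraction_p1": 0.6, "n_txsnps": 2, "total_reads": 80, "group": 0},
      "S02": {"fraction_p1": 0.6, "n_txsnps": 1, "total_reads": 40, "group": 0},
      "S03": {"fraction_p1": 0.75, "n_txsnps": 1, "total_reads": 40, "group": 0},
      "S04": {"fraction_p1": 0.7, "n_txsnps": 1, "total_reads": 40, "group": 0},
      "S05": {"fraction_p1": 0.65, "n_txsnps": 1, "total_reads": 40, "group": 0},
      "S06": {"fraction_p1": 0.5, "n_txsnps": 1, "total_reads": 40, "group": 1},
      "S07": {"fraction_p1": 0.475, "n_txsnps": 1, "total_reads": 40, "group": 1},
      "S08": {"fraction_p1": 0.3, "n_txsnps": 1, "total_reads": 40, "group": 2},
      "S09": {"fraction_p1": 0.3, "n_txsnps": 1, "total_reads": 40, "group": 2},
      "S10": {"fraction_p1": 0.35, "n_txsnps": 1, "total_reads": 40, "group": 2},
      "S11": {"fraction_p1": 0.25, "n_txsnps": 1, "total_reads": 40, "group": 2},
      "S12": {"fraction_p1": 0.325, "n_txsnps": 1, "total_reads": 40, "group": 2}
    },
    "geneB": {
      "S01": {"fraction_p1": 0.5, "n_txsnps": 1, "total_reads": 40, "group": 0},
      "S02": {"fraction_p1": 0.5, "n_txsnps": 1, "total_reads": 30, "group": 0},
      "S08": {"fraction_p1": 0.55, "n_txsnps": 1, "total_reads": 40, "group": 2},
      "S09": {"fraction_p1": 0.7142857142857143, "n_txsnps": 1, "total_reads": 42, "group": 2}
    }
  }
}
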