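{
  "description": "Published reference values from the original multicenter lymphoma study this package reimplements: the five simplified marker panels (split into markers inherited from ancestor tasks and task-specific additions) and, per cohort, the record count of each terminal subtype leaf together with the mean number of markers actually measured in the clinic at each hierarchy level. Shipped so that panel-reuse arithmetic and the cost comparison can be reproduced without any patient-level data.",
  "simplified_panels": {
    "t_hl_nhl": {
      "inherited": [],
      "added": ["CD15", "CD5", "LCA", "CD30"]
    },
    "t_nhl_sub": {
      "inherited": ["CD30", "CD5"],
      "added": ["CD56", "CD10", "EBERs", "CD20", "TIA1"]
    },
    "t_b_sub": {
      "inherited": ["CD30", "CD5", "EBERs", "CD20", "CD10"],
      "added": ["TdT", "CD23", "CyD1"]
    },
    "t_t_sub": {
      "inherited": ["CD30", "CD5", "CD56", "CD10", "EBERs", "TIA1"],
      "added": ["TdT", "ALK", "CXCL-13"]
    },
    "t_dlbcl_coo": {
      "inherited": ["CD10"],
      "added": ["MUM-1"]
    }
  },
  "cohorts": {
    "internal_primary": {
      "leaf_counts": {
        "HL": 347, "NK-NHL": 343,
        "FL": 449, "MZL": 451, "MCL": 126, "BL": 151, "SLL": 86,
        "PMLBCL": 52, "B-LBL/ALL": 38, "Others": 35,
        "non-GCB": 519, "GCB": 327,
        "ALCL": 132, "AITL": 102, "TLBL": 137, "PTCL-U": 77
      },
      "clinical_means": {
        "t_hl_nhl": 13.58, "t_nhl_sub": 12.35, "t_b_sub": 12.42,
        "t_dlbcl_coo": 14.94, "t_t_sub": 13.5
      },
      "reported": {
        "weighted_required_mean": 11.12, "clinical_mean": 13.31,
        "overall_saving_pct": 16.45, "hl_level_saving_pct": 70.54
      }
    },
    "internal_later": {
      "leaf_counts": {
        "HL": 345, "NK-NHL": 329,
        "FL": 399, "MZL": 524, "MCL": 119, "BL": 88, "SLL": 62,
        "PMLBCL": 34, "B-LBL/ALL": 31, "Others": 27,
        "non-GCB": 390, "GCB": 228,
        "ALCL": 129, "AITL": 131, "TLBL": 93, "PTCL-U": 50
      },
      "clinical_means": {
        "t_hl_nhl": 13.65, "t_nhl_sub": 13.59, "t_b_sub": 12.78,
        "t_dlbcl_coo": 15.59, "t_t_sub": 15.98
      },
      "reported": {
        "weighted_required_mean": 10.95, "clinical_mean": 13.99,
        "overall_saving_pct": 21.73
      }
    },
    "external": {
      "leaf_counts": {
        "HL": 690, "NK-NHL": 293,
        "FL": 797, "MZL": 529, "MCL": 242, "BL": 48, "SLL": 81,
        "PMLBCL": 57, "B-LBL/ALL": 31, "Others": 20,
        "non-GCB": 728, "GCB": 314,
        "ALCL": 140, "AITL": 176, "TLBL": 134, "PTCL-U": 69
      },
      "clinical_means": {
        "t_hl_nhl": 9.96, "t_nhl_sub": 9.59, "t_b_sub": 10.92,
        "t_dlbcl_coo": 12.6, "t_t_sub": 11.76
      },
      "reported": {
        "weighted_required_mean": 10.77, "clinical_mean": 11.18,
        "overall_saving_pct": 3.67
      }
    }
  },
  "cumulative_required": {
    "t_hl_nhl": 4, "t_nhl_sub": 9, "t_b_sub": 12,
    "t_dlbcl_coo": 13, "t_t_sub": 12
  }
}
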