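# Default five-task configuration of the hierarchical lymphoma classifier.
# Class labels and candidate ("full") marker panels follow the 4th revised
# WHO classification as used by the original multicenter study; the
# minimum-required expressions gate task eligibility on marker availability.
tasks:
  - task_id: t_hl_nhl
    display_name: HL and NHL differentiation
    class_labels: [HL, NHL]
    min_required: CD30
    auc_retention: 0.99
    full_panel: [CD15, CD30, CD5, LCA, CD3, CD20, CD79, EBERs]
  - task_id: t_nhl_sub
    display_name: NHL subtypes differentiation
    class_labels: [B-NHL, T-NHL, NK-NHL]
    min_required: CD3 AND CD20
    auc_retention: 0.99
    full_panel: [CD56, CD20, EBERs, CD3, CD4, CD10, TIA1, MUM-1, CD30, GrB,
                 CD2, Perf, CD7, Pax-5, CD79, CD8, CD21, CD5]
  - task_id: t_b_sub
    display_name: B-cell lymphoma subtypes differentiation
    class_labels: [DLBCL, FL, MZL, MCL, BL, SLL, PMLBCL, B-LBL/ALL, Others]
    min_required: CD20 AND CD10 AND CyD1 AND (CD5 OR Bcl-2)
    auc_retention: 0.95
    full_panel: [CyD1, TdT, CD23, CD30, CD20, EBERs, Bcl-6, MUM-1, CD138,
                 CD10, CD21, CD38, CD5, CD43, Ki67, C-myc, Pax-5, Bcl-2, ALK]
  - task_id: t_t_sub
    display_name: T-cell lymphoma subtypes differentiation
    class_labels: [ALCL, AITL, TLBL, PTCL-U]
    min_required: CD3 OR CD8 OR CD30 OR ALK
    auc_retention: 0.99
    full_panel: [TdT, CXCL-13, ALK, CD30, CD10, CD3, EBERs, CD56, GrB, CD4,
                 TIA1, Ki67, Bcl-6, CD2, CD7, CD43, CD5, Bcl-2, CD8]
  - task_id: t_dlbcl_coo
    display_name: DLBCL subtypes differentiation
    class_labels: [GCB, non-GCB]
    min_required: CD10 AND MUM-1
    auc_retention: 0.99
    full_panel: [CD10, MUM-1, Bcl-6]

hierarchy:
  task: t_hl_nhl
  children:
    HL: {leaf: HL}
    NHL:
      task: t_nhl_sub
      children:
        B-NHL:
          task: t_b_sub
          children:
            DLBCL:
              task: t_dlbcl_coo
              children:
                GCB: {leaf: GCB}
                non-GCB: {leaf: non-GCB}
            FL: {leaf: FL}
            MZL: {leaf: MZL}
            MCL: {leaf: MCL}
            BL: {leaf: BL}
            SLL: {leaf: SLL}
            PMLBCL: {leaf: PMLBCL}
            B-LBL/ALL: {leaf: B-LBL/ALL}
            Others: {leaf: Others}
        T-NHL:
          task: t_t_sub
          children:
            ALCL: {leaf: ALCL}
            AITL: {leaf: AITL}
            TLBL: {leaf: TLBL}
            PTCL-U: {leaf: PTCL-U}
        NK-NHL: {leaf: NK-NHL}
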