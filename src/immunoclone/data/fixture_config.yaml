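# Bundled synthetic fixture: 2 patients x 2 compartments x 500 cells = 2000 cells.
seed: 7
simulate:
  n_patients: 2
  cells_per_sample: 500
  shared_clone_prob: 0.3
  cross_subset_prob: 0.15
  shm_rate: 1.0
  expr_fractions:
    B_naive: {CD19: 0.9, CXCL13: 0.3, CD86: 0.4, CD28: 0.0, CCR4: 0.1,
              CCL22: 0.1, PDCD1: 0.0, CD274: 0.2}
    B_memory: {CD19: 0.9, CD27: 0.8, CD86: 0.6, CD28: 0.0, CCL22: 0.2,
               CCR4: 0.1, PDCD1: 0.1, CD274: 0.2}
    CD4_naive: {CD3E: 0.9, CD28: 0.7, CCR4: 0.2, CXCL13: 0.0, CD86: 0.0,
                CCL22: 0.0, PDCD1: 0.1, CD274: 0.0}
    CD4_Treg: {CD3E: 0.9, CD28: 0.8, CCR4: 0.7, CCL22: 0.1, CD86: 0.1,
               CXCL13: 0.0, PDCD1: 0.3, CD274: 0.1}
    CD8_naive: {CD3E: 0.9, CD28: 0.6, CCR4: 0.1, CD86: 0.0, CCL22: 0.0,
                CXCL13: 0.0, PDCD1: 0.1, CD274: 0.0}
    CD8_EM: {CD3E: 0.9, CD28: 0.4, GZMB: 0.6, PDCD1: 0.4, CD86: 0.0,
             CCL22: 0.1, CCR4: 0.1, CD274: 0.1}
clonality:
  reps: 100
interactions:
  min_cells: 3
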