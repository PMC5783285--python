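"""Pipeline-wide default constants.

These mirror the published protocol: 82 externally computed physicochemical
descriptor columns plus 9 cluster-size columns (single-linkage cutoffs
3.0-7.0 A in 0.5 A steps) give the 91-column feature schema; decoy lists are
truncated to the top 500 poses of the docking engine's own ordering; model
selection scores clusters obtained at a 3.5 A cutoff; the metaparameter grid
is 50 log-spaced regularization constants c in [1e-4, 1e3] crossed with
ensemble sizes n = 1..50.
"""

# Feature schema
N_DESCRIPTOR_SLOTS = 82
CLUSTER_SIZE_CUTOFFS = (3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0)
N_FEATURES = N_DESCRIPTOR_SLOTS + len(CLUSTER_SIZE_CUTOFFS)  # 91

# Decoy-list truncation (docking engine's original ordering)
DEFAULT_DECOY_LIMIT = 500

# Single-linkage cutoff used when scoring models (cluster-rank score)
DEFAULT_SCORING_CUTOFF = 3.5

# Metaparameter grid
GRID_C_MIN = 1e-4
GRID_C_MAX = 1e3
GRID_N_C = 50
GRID_N_MAX = 50
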