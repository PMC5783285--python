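"""Aggregate several model rankings into one Schulze consensus.

Each trained model is a ballot over one complex's decoys; the consensus
ranks decoy a above b when the strongest preference path a -> b beats the
one b -> a.
"""

import numpy as np

from irappa.rsvm import build_pairs, rank_by_projection, train
from irappa.schulze import build_preference_graph, schulze_consensus, strongest_paths
from irappa.synthetic import SyntheticSpec, generate

spec = SyntheticSpec(n_complexes=6, decoys_per_complex=30, noise_sigma=0.2, seed=8)
sets = generate(spec)
target = sets[0]

# an ensemble of three models trained on different complex subsets
models = [train(build_pairs(sets[i : i + 3]), c=0.01) for i in (1, 2, 3)]
rankings = [rank_by_projection(m, target) for m in models]

W = build_preference_graph(rankings)
P = strongest_paths(W)
consensus = schulze_consensus(rankings, initial_ranks=target.initial_ranks)

a, b = int(consensus[0]), int(consensus[1])
print(f"ensemble of {len(rankings)} ballots over {target.n_decoys} decoys")
print(f"top decoy: {target.decoy_ids[a]} "
      f"(ranked above runner-up in {W[a, b]}/{len(rankings)} ballots; "
      f"strongest paths {P[a, b]:.0f} vs {P[b, a]:.0f})")
pos = np.empty(target.n_decoys, dtype=int)
pos[consensus] = np.arange(1, target.n_decoys + 1)
nn = target.near_native_mask
print(f"best near-native: consensus rank {pos[nn].min()}, "
      f"engine rank {target.initial_ranks[nn].min()}")
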