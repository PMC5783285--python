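"""Generate a synthetic decoy benchmark and inspect what the engine gives us.

Each complex gets a feature table (planted linear quality signal + noise),
CAPRI labels, an imperfect engine ordering, and clustered ligand poses.
"""

import numpy as np

from irappa.synthetic import SyntheticSpec, generate

spec = SyntheticSpec(n_complexes=10, decoys_per_complex=100, seed=1)
sets = generate(spec)

print(f"{len(sets)} complexes x {sets[0].n_decoys} decoys, {sets[0].n_features} features")
for dset in sets[:3]:
    counts = {cat.name.lower(): int((dset.label_codes == int(cat)).sum())
              for cat in set(dset.labels)}
    print(f"  {dset.complex_id}: {counts}")

# How good is the simulated docking engine's own ordering?
hits = sum(
    1 for s in sets if s.has_near_native and s.initial_ranks[s.near_native_mask].min() <= 10
)
have = sum(1 for s in sets if s.has_near_native)
print(f"engine top-10 retrieval: {hits}/{have} complexes "
      "(fraction of complexes with a sampled near-native whose best one is in the top 10)")
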