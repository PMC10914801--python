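"""Narrow a generated sequence pool to a heterogeneous, blinded candidate
set.

Starting from a pool with deliberate near-duplicates, this removes
everything too close (>= 60 % identity, cd-hit convention) to a chosen
"wild type", clusters the survivors greedily at 60 % identity, samples one
representative per cluster and double-blinds the result, so downstream
experiments cannot know the computational ranking.
"""

import numpy as np

from minescreen.io import SequenceRecord
from minescreen.selection import (
    blind_variants, exclude_by_wildtype, greedy_cluster, needle_metrics,
    sample_representatives,
)

rng = np.random.default_rng(0)
aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
wildtype = "".join(rng.choice(aa, size=60))


def mutate(seq, n_mut):
    s = list(seq)
    for j in rng.choice(len(s), size=n_mut, replace=False):
        s[j] = rng.choice(aa)
    return "".join(s)


pool = (
    [SequenceRecord(id=f"near{i}", residues=mutate(wildtype, 6))
     for i in range(5)]                                   # ~90% to wild type
    + [SequenceRecord(id=f"far{i}", residues=mutate(wildtype, 40))
       for i in range(12)]                                # distant homologs
)
print(f"pool: {len(pool)} generated sequences")

survivors = exclude_by_wildtype(pool, wildtype, threshold=0.60)
print(f"{len(pool) - len(survivors)} sequences >= 60% identical to the "
      f"wild type excluded, {len(survivors)} remain")

clusters = greedy_cluster(survivors, threshold=0.60)
picks = sample_representatives(clusters, seed=0)
print(f"greedy clustering at 60% identity: {len(clusters.clusters)} clusters")

chosen = [r for r in survivors if r.id in set(picks)]
blinded, key = blind_variants(chosen, seed=0)
print(f"blinded candidate set: {', '.join(r.id for r in blinded[:5])}, ...")
ident, simil = needle_metrics(wildtype, blinded[0].residues)
print(f"{blinded[0].id} vs wild type: {ident:.1f}% identity, "
      f"{simil:.1f}% similarity (global alignment)")
print("(the blinding key maps synMinEv* names back to pool ids; it is kept "
      "apart from the scored outputs)")
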