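"""Post-generation narrowing of candidate sequences.

Generated sequences too close to the E. coli wild type are excluded, the
rest are clustered greedily at a 60 % identity threshold (cd-hit style:
identity = identical aligned residues / length of the shorter sequence,
here computed from an exact global alignment instead of cd-hit's word
heuristics), one representative is sampled per cluster, and the final
candidates are double-blinded by a seeded renaming.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import SequenceRecord


@dataclass(frozen=True)
class ClusterSet:
    clusters: tuple[tuple[str, tuple[str, ...]], ...]  # (representative id, member ids)
    threshold: float = 0.60
    identity_convention: str = "cdhit"

    def representative_ids(self) -> list[str]:
        return [rep for rep, _ in self.clusters]


@dataclass(frozen=True)
class BlindingKey:
    mapping: tuple[tuple[str, str], ...]  # (blinded name, original id)
    seed: int

    def unblind(self, blinded_name: str) -> str:
        for b, orig in self.mapping:
            if b == blinded_name:
                return orig
        raise KeyError(blinded_name)


def _free_end_gaps(aligner: Align.PairwiseAligner) -> None:
    """Zero the end-gap scores (attribute names changed across Biopython)."""
    new_names = ("open_end_insertion_score", "extend_end_insertion_score",
                 "open_end_deletion_score", "extend_end_deletion_score")
    old_names = ("target_end_open_gap_score", "target_end_extend_gap_score",
                 "query_end_open_gap_score", "query_end_extend_gap_score")
    names = new_names if hasattr(aligner, new_names[0]) else old_names
    for name in names:
        setattr(aligner, name, 0.0)


def _identity_aligner() -> Align.PairwiseAligner:
    """Global aligner maximizing identities (match 1, mismatch/gap 0, free
    end gaps) for the cd-hit identity convention."""
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = -0.01   # tiny cost so gaps are not inserted for free
    a.extend_gap_score = -0.01
    _free_end_gaps(a)
    return a


def _needle_aligner() -> Align.PairwiseAligner:
    """EMBOSS-Needle-equivalent global aligner: BLOSUM62, gap open 10,
    gap extend 0.5 (a length-k gap costs 10 + 0.5k, hence the -10.5 open
    score under the open+(k-1)*extend convention), end gaps unpenalized."""
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -10.5
    a.extend_gap_score = -0.5
    _free_end_gaps(a)
    return a


def _aligned_columns(alignment) -> list[tuple[str, str]]:
    """Column pairs (including gap columns) of the best alignment."""
    s1, s2 = alignment[0], alignment[1]
    return list(zip(str(s1), str(s2)))


def identity_cdhit(a: str, b: str) -> float:
    """cd-hit identity convention: identical aligned residues divided by
    the length of the shorter sequence, from a global alignment."""
    if not a or not b:
        raise ValueError("empty sequence")
    if a == b:
        return 1.0
    aligner = _identity_aligner()
    aln = aligner.align(a, b)[0]
    matches = sum(1 for x, y in _aligned_columns(aln) if x == y and x != "-")
    return matches / min(len(a), len(b))


def needle_metrics(a: str, b: str) -> tuple[float, float]:
    """Percent identity and percent similarity from an EMBOSS-Needle-style
    global alignment.  Identity counts identical columns, similarity counts
    columns with a positive BLOSUM62 score; both are divided by the full
    alignment length (gap columns included)."""
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = _needle_aligner()
    aln = aligner.align(a, b)[0]
    blosum = substitution_matrices.load("BLOSUM62")
    columns = _aligned_columns(aln)
    n_cols = len(columns)
    ident = sum(1 for x, y in columns if x == y and x != "-")
    simil = sum(
        1 for x, y in columns
        if x != "-" and y != "-" and blosum[x, y] > 0
    )
    return 100.0 * ident / n_cols, 100.0 * simil / n_cols


def exclude_by_wildtype(
    sequences: list[SequenceRecord], wildtype: str, threshold: float = 0.60
) -> list[SequenceRecord]:
    """Drop every sequence with identity >= threshold to the wild type
    (cd-hit convention); a sequence at exactly the threshold is excluded."""
    return [
        r for r in sequences if identity_cdhit(r.ungapped, wildtype) < threshold
    ]


def greedy_cluster(
    sequences: list[SequenceRecord], threshold: float = 0.60
) -> ClusterSet:
    """cd-hit-style greedy incremental clustering: sequences are visited by
    decreasing length (ties by id); each joins the first existing cluster
    whose *representative* it matches at >= threshold identity, otherwise
    it founds a new cluster."""
    if not sequences:
        raise ValueError("no sequences to cluster")
    ordered = sorted(sequences, key=lambda r: (-len(r.ungapped), r.id))
    reps: list[SequenceRecord] = []
    members: list[list[str]] = []
    for rec in ordered:
        for ci, rep in enumerate(reps):
            if identity_cdhit(rec.ungapped, rep.ungapped) >= threshold:
                members[ci].append(rec.id)
                break
        else:
            reps.append(rec)
            members.append([rec.id])
    return ClusterSet(
        clusters=tuple(
            (rep.id, tuple(mem)) for rep, mem in zip(reps, members)
        ),
        threshold=threshold,
    )


def sample_representatives(clusters: ClusterSet, seed: int = 0) -> list[str]:
    """Seeded uniform choice of one member id per cluster."""
    rng = np.random.default_rng(seed)
    picks = []
    for _, member_ids in clusters.clusters:
        picks.append(member_ids[int(rng.integers(len(member_ids)))])
    return picks


def blind_variants(
    sequences: list[SequenceRecord], seed: int = 0, prefix: str = "synMinEv"
) -> tuple[list[SequenceRecord], BlindingKey]:
    """Rename sequences to ``{prefix}1..{prefix}K`` in a seeded random
    order; the bijective key is returned separately so experimenters never
    see the computational ordering."""
    if len(sequences) > 9999:
        raise ValueError("too many sequences to blind")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(sequences))
    renamed = []
    mapping = []
    for new_idx, orig_idx in enumerate(perm, start=1):
        rec = sequences[int(orig_idx)]
        name = f"{prefix}{new_idx}"
        renamed.append(SequenceRecord(id=name, residues=rec.residues))
        mapping.append((name, rec.id))
    return renamed, BlindingKey(mapping=tuple(mapping), seed=seed)
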