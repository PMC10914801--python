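"""Training-set construction from raw homolog sequences.

The pipeline is: length/composition filter -> exact deduplication ->
gap-column trimming of the alignment -> one-hot encoding over the fixed
21-letter alphabet (20 amino acids + gap) -> seeded 80/20 train/validation
split.  A test split is deliberately absent: the final evaluation of
generated sequences is experimental, not held-out reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GAP, STANDARD_AA, SequenceRecord

#: canonical alphabet: ACDEFGHIKLMNPQRSTVWY then gap at index 20
ALPHABET = STANDARD_AA + GAP
ALPHABET_INDEX = {c: i for i, c in enumerate(ALPHABET)}


@dataclass
class MsaDataset:
    """Aligned, trimmed, encoded homolog set ready for VAE training."""

    sequences: list[str]
    kept_columns: np.ndarray          # bool mask over original columns
    encoded: np.ndarray               # (n, width, 21) float32 one-hot
    split: np.ndarray                 # array of "train" / "validation"
    seed: int
    ids: list[str] | None = None
    alphabet: str = ALPHABET

    @property
    def width(self) -> int:
        return self.encoded.shape[1]

    def subset(self, which: str) -> np.ndarray:
        return self.encoded[self.split == which]


def filter_sequences(
    records: list[SequenceRecord], min_len: int = 20, max_len: int = 200
) -> list[SequenceRecord]:
    """Keep records whose ungapped length is within [min_len, max_len] and
    whose residues are all standard amino acids; order preserved."""
    standard = set(STANDARD_AA)
    kept = []
    for r in records:
        seq = r.ungapped
        if not (min_len <= len(seq) <= max_len):
            continue
        if set(seq) - standard:
            continue
        kept.append(r)
    return kept


def dedup_identical(records: list[SequenceRecord]) -> list[SequenceRecord]:
    """Drop exact duplicates (ungapped residue string, case already
    normalized at parse time); first occurrence wins — the behaviour of a
    100 %-identity cd-hit pass."""
    seen: set[str] = set()
    out = []
    for r in records:
        key = r.ungapped
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def trim_gap_columns(
    aligned: list[str], max_gap_fraction: float = 0.98
) -> tuple[list[str], np.ndarray]:
    """Drop columns whose gap fraction is strictly greater than
    ``max_gap_fraction`` (a 49/50 = 0.98 column survives).  Returns the
    trimmed rows and the boolean keep-mask over original columns."""
    if not aligned:
        raise ValueError("empty alignment")
    width = len(aligned[0])
    if any(len(s) != width for s in aligned):
        raise ValueError("ragged alignment")
    arr = np.frombuffer("".join(aligned).encode("ascii"), dtype="S1").reshape(
        len(aligned), width
    )
    gap_fraction = (arr == GAP.encode()).mean(axis=0)
    keep = gap_fraction <= max_gap_fraction
    trimmed = [
        arr[i, keep].tobytes().decode("ascii") for i in range(len(aligned))
    ]
    return trimmed, keep


def one_hot_encode(alignment: list[str], alphabet: str = ALPHABET) -> np.ndarray:
    """Encode aligned rows to a (n, width, |alphabet|) one-hot tensor."""
    index = {c: i for i, c in enumerate(alphabet)}
    n = len(alignment)
    width = len(alignment[0]) if alignment else 0
    out = np.zeros((n, width, len(alphabet)), dtype=np.float32)
    for i, row in enumerate(alignment):
        for j, c in enumerate(row):
            try:
                out[i, j, index[c]] = 1.0
            except KeyError:
                raise ValueError(
                    f"symbol {c!r} at row {i}, column {j} not in alphabet"
                ) from None
    return out


def one_hot_decode(encoded: np.ndarray, alphabet: str = ALPHABET) -> list[str]:
    idx = np.asarray(encoded).argmax(axis=-1)
    lookup = np.array(list(alphabet))
    return ["".join(lookup[row]) for row in idx]


def split_dataset(n: int, fraction: float = 0.8, seed: int = 0) -> np.ndarray:
    """Seeded uniform permutation split; floor(fraction*n) sequences train,
    the remainder validate."""
    if n < 2:
        raise ValueError("need at least 2 sequences to split")
    rng = np.random.default_rng(seed)
    n_train = int(np.floor(fraction * n))
    labels = np.array(["validation"] * n, dtype=object)
    labels[rng.permutation(n)[:n_train]] = "train"
    return labels


def build_dataset(
    aligned_records: list[SequenceRecord],
    max_gap_fraction: float = 0.98,
    split_fraction: float = 0.8,
    seed: int = 0,
) -> MsaDataset:
    """Trim, encode and split an already filtered/deduplicated alignment."""
    rows = [r.residues for r in aligned_records]
    trimmed, keep = trim_gap_columns(rows, max_gap_fraction)
    encoded = one_hot_encode(trimmed)
    split = split_dataset(len(trimmed), split_fraction, seed)
    return MsaDataset(
        sequences=trimmed,
        kept_columns=keep,
        encoded=encoded,
        split=split,
        seed=seed,
        ids=[r.id for r in aligned_records],
    )
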