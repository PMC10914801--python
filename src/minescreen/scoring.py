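"""Divide-and-conquer in silico function score.

The emergent function screened for (MinDE pattern formation) is estimated
indirectly from four sub-functions per candidate:

* membrane binding  — mean hydrophobicity over the N-terminal helix (or,
  if the N-terminus is unstructured, over the whole N-terminal region up
  to the MinD-binding helix);
* MinD interaction  — mean inter-chain predicted aligned error (PAE)
  between the candidate's MinD-binding helix and structured MinD residues
  in the predicted heterodimer (low PAE = confident interface);
* dimerization      — mean inter-chain PAE between structured residues of
  the two copies in the predicted homodimer;
* solubility        — external per-sequence predictor value in [0, 1].

Each sub-score is min-max normalized across the candidate set, the two
PAE-based scores are orientation-flipped (1 - normalized, since small PAE
is good), and the four normalized scores are summed with unit weights into
a function score in [0, 4].  The post-hoc "improved" score keeps only the
MinD-interaction and membrane (N-terminal hydrophobicity) terms, in [0, 2].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import StructureFile

logger = logging.getLogger("minescreen")

#: polar + charged residues used by the synthetic solubility proxy
_POLAR = set("DEKRHSTNQ")


@dataclass(frozen=True)
class ChainAnnotation:
    """Per-chain secondary structure and the named regions scoring needs.

    Regions are half-open 0-based ``(start, stop)`` ranges.
    """

    chain_id: str
    ss: str                                  # per-residue H|E|C
    regions: dict = field(default_factory=dict)

    @property
    def structured_mask(self) -> np.ndarray:
        return np.array([c in "HE" for c in self.ss])

    def helices(self) -> list[tuple[int, int]]:
        """Maximal runs of H as half-open (start, stop) ranges."""
        runs = []
        start = None
        for i, c in enumerate(self.ss + "$"):
            if c == "H" and start is None:
                start = i
            elif c != "H" and start is not None:
                runs.append((start, i))
                start = None
        return runs


@dataclass(frozen=True)
class PaeMatrix:
    """PAE matrix over a complex, with the residue→chain partition."""

    matrix: np.ndarray
    chain_offsets: dict           # chain_id -> (start, length) in global indices

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("PAE matrix must be square")
        if np.any(m < 0):
            raise ValueError("PAE entries must be >= 0")
        covered = sum(length for _, length in self.chain_offsets.values())
        if covered != m.shape[0]:
            raise ValueError("chain offsets do not partition the matrix")
        object.__setattr__(self, "matrix", m)

    def global_indices(self, chain_id: str, local_indices) -> np.ndarray:
        start, length = self.chain_offsets[chain_id]
        idx = np.asarray(local_indices, dtype=int)
        if np.any(idx < 0) or np.any(idx >= length):
            raise IndexError(f"residue index out of range for chain {chain_id}")
        return start + idx


# ---------------------------------------------------------------------------
# secondary structure from Cα geometry

# P-SEA-style inter-Cα distance windows (Å), fixed from ideal geometry:
# α-helix (1.5 Å rise, ~100°/residue): d(i,i+2)≈5.4, d(i,i+3)≈5.1, d(i,i+4)≈6.2
# extended strand (~3.35 Å rise):      d(i,i+2)≈6.7, d(i,i+3)≈10.1
_HELIX_D2 = (4.9, 6.0)
_HELIX_D3 = (4.3, 5.7)
_HELIX_D4 = (5.4, 6.9)
_STRAND_D2 = (6.3, 7.2)
_STRAND_D3 = (9.0, 10.8)


def assign_secondary_structure(coords: np.ndarray) -> str:
    """Assign H/E/C per residue from Cα coordinates alone using distance
    windows on d(i,i+2..4).  Chains shorter than the window come back all
    coil; H wins over E where windows overlap."""
    xyz = np.asarray(coords, dtype=float)
    n = xyz.shape[0]
    labels = np.full(n, "C", dtype="U1")
    if n < 4:
        return "".join(labels)

    def d(i, j):
        return float(np.linalg.norm(xyz[i] - xyz[j]))

    is_e = np.zeros(n, bool)
    for i in range(n - 3):
        if _STRAND_D2[0] <= d(i, i + 2) <= _STRAND_D2[1] and \
           _STRAND_D3[0] <= d(i, i + 3) <= _STRAND_D3[1]:
            is_e[i : i + 4] = True
    labels[is_e] = "E"
    is_h = np.zeros(n, bool)
    for i in range(n - 4):
        if _HELIX_D2[0] <= d(i, i + 2) <= _HELIX_D2[1] and \
           _HELIX_D3[0] <= d(i, i + 3) <= _HELIX_D3[1] and \
           _HELIX_D4[0] <= d(i, i + 4) <= _HELIX_D4[1]:
            is_h[i : i + 5] = True
    labels[is_h] = "H"
    return "".join(labels)


def annotate_structure(structure: StructureFile,
                       ss_override: dict | None = None) -> dict:
    """Annotate every chain of a structure; ``ss_override`` may map a
    chain id to an externally computed H/E/C string."""
    out = {}
    for cid, _ in structure.chains:
        if ss_override and cid in ss_override:
            ss = ss_override[cid]
        else:
            ss = assign_secondary_structure(structure.ca_coords(cid))
        out[cid] = ChainAnnotation(chain_id=cid, ss=ss)
    return out


# ---------------------------------------------------------------------------
# sub-scores


def interchain_pae_mean(pae: PaeMatrix, indices_a: np.ndarray,
                        indices_b: np.ndarray) -> float:
    """Mean PAE over both off-diagonal blocks between two global residue
    sets (PAE is asymmetric; both directions are averaged)."""
    a = np.asarray(indices_a, dtype=int)
    b = np.asarray(indices_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty residue set")
    block_ab = pae.matrix[np.ix_(a, b)]
    block_ba = pae.matrix[np.ix_(b, a)]
    return float((block_ab.sum() + block_ba.sum()) / (2 * a.size * b.size))


def locate_mind_binding_helix(
    variant_ann: ChainAnnotation,
    pae: PaeMatrix,
    partner_ann: ChainAnnotation,
) -> tuple[int, int] | None:
    """Pick, among the variant's helices, the one with the lowest mean
    inter-chain PAE to the partner's structured residues (ties: lower start
    index).  Returns None — the flagged worst case — if the variant has no
    helix or the partner no structured residue."""
    helices = variant_ann.helices()
    partner_structured = np.flatnonzero(partner_ann.structured_mask)
    if not helices or partner_structured.size == 0:
        logger.warning("chain %s: no binding helix located (helices=%d, "
                       "partner structured=%d)", variant_ann.chain_id,
                       len(helices), partner_structured.size)
        return None
    partner_idx = pae.global_indices(partner_ann.chain_id, partner_structured)
    best = None
    best_mean = np.inf
    for start, stop in helices:
        idx = pae.global_indices(variant_ann.chain_id, np.arange(start, stop))
        m = interchain_pae_mean(pae, idx, partner_idx)
        if m < best_mean - 1e-12:
            best, best_mean = (start, stop), m
    return best


def annotate_variant_regions(
    variant_ann: ChainAnnotation,
    pae: PaeMatrix,
    partner_ann: ChainAnnotation,
    helix_override: tuple[int, int] | None = None,
) -> ChainAnnotation:
    """Fill in the named regions scoring needs: the MinD-binding helix
    (PAE-located unless overridden), the N-terminal region (from residue 0
    up to, excluding, that helix) and — when the N-terminus is structured —
    the N-terminal helix itself."""
    helix = helix_override or locate_mind_binding_helix(variant_ann, pae,
                                                        partner_ann)
    regions = dict(variant_ann.regions)
    if helix is not None:
        regions["mind_binding_helix"] = helix
        regions["nterminal_region"] = (0, helix[0])
        nterm_helices = [h for h in variant_ann.helices()
                         if h[1] <= helix[0]]
        if nterm_helices:
            regions["nterminal_helix"] = nterm_helices[0]
    else:
        regions["nterminal_region"] = (0, len(variant_ann.ss))
    return ChainAnnotation(chain_id=variant_ann.chain_id,
                           ss=variant_ann.ss, regions=regions)


def membrane_binding_score(hydro_track: np.ndarray,
                           annotation: ChainAnnotation) -> float:
    """Mean hydrophobicity over the N-terminal helix; if the N-terminus is
    unstructured, the mean over the full N-terminal region (up to the
    MinD-binding helix) is used instead."""
    track = np.asarray(hydro_track, dtype=float)
    if track.size != len(annotation.ss):
        raise ValueError("hydrophobicity track length != chain length")
    region = annotation.regions.get("nterminal_helix") \
        or annotation.regions.get("nterminal_region")
    if region is None:
        raise ValueError("annotation lacks an N-terminal region")
    start, stop = region
    if stop <= start:
        raise ValueError("degenerate N-terminal region")
    return float(track[start:stop].mean())


def mind_interaction_score(pae: PaeMatrix, variant_ann: ChainAnnotation,
                           mind_ann: ChainAnnotation) -> float:
    """Mean inter-chain PAE between the variant's MinD-binding helix and
    structured MinD residues; the rest of the variant is ignored.  Variants
    without a locatable helix get the matrix maximum (worst case)."""
    helix = variant_ann.regions.get("mind_binding_helix")
    if helix is None:
        helix = locate_mind_binding_helix(variant_ann, pae, mind_ann)
    if helix is None:
        return float(pae.matrix.max())
    start, stop = helix
    v_idx = pae.global_indices(variant_ann.chain_id, np.arange(start, stop))
    m_idx = pae.global_indices(
        mind_ann.chain_id, np.flatnonzero(mind_ann.structured_mask)
    )
    return interchain_pae_mean(pae, v_idx, m_idx)


def dimerization_score(pae: PaeMatrix, ann_a: ChainAnnotation,
                       ann_b: ChainAnnotation) -> float:
    """Mean inter-chain PAE between structured residues (helices and
    strands) of the two copies in the homodimer."""
    sa = np.flatnonzero(ann_a.structured_mask)
    sb = np.flatnonzero(ann_b.structured_mask)
    if sa.size == 0 or sb.size == 0:
        logger.warning("dimerization: chain without structured residues; "
                       "worst-case PAE used")
        return float(pae.matrix.max())
    return interchain_pae_mean(
        pae,
        pae.global_indices(ann_a.chain_id, sa),
        pae.global_indices(ann_b.chain_id, sb),
    )


def solubility_score(value: float | None = None,
                     sequence: str | None = None) -> float:
    """Pass through an external solubility predictor value in [0, 1]
    (values above 0.7 indicate a likely-soluble protein).  When only a
    sequence is given, a *synthetic proxy* — the polar/charged residue
    fraction — is returned instead; it is NOT equivalent to the published
    predictor and exists for fixture-driven testing only."""
    if value is not None:
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"solubility value {value} outside [0, 1]")
        if value > 0.7:
            logger.info("solubility %.3f: likely soluble (>0.7)", value)
        return float(value)
    if sequence is None:
        raise ValueError("need an external value or a sequence (proxy mode)")
    logger.warning("solubility: using synthetic composition proxy, not the "
                   "published predictor")
    return sum(1 for c in sequence if c in _POLAR) / len(sequence)


# ---------------------------------------------------------------------------
# normalization, combination, ranking


def minmax_normalize(values, flip: bool = False) -> np.ndarray:
    """Map values to [0, 1] by (v - min)/(max - min); ``flip`` then takes
    1 - value (for scores where small raw values are good).  An all-equal
    input maps to 0.5 everywhere (logged) so downstream sums stay defined."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("min-max normalization needs at least 2 values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        logger.warning("min-max normalization of an all-equal list; "
                       "returning 0.5 for all %d values", v.size)
        out = np.full_like(v, 0.5)
    else:
        out = (v - lo) / (hi - lo)
    return 1.0 - out if flip else out


def combine_scores(raw: pd.DataFrame) -> pd.DataFrame:
    """Normalize the four raw sub-scores across variants and combine.

    Expects columns ``variant_id, membrane_raw, mind_raw, dimer_raw,
    solubility_raw``.  Adds the four ``*_norm`` columns (PAE-based scores
    flipped), ``function_score`` = sum of all four in [0, 4] and
    ``improved_score`` = mind_norm + membrane_norm in [0, 2].
    """
    required = ["membrane_raw", "mind_raw", "dimer_raw", "solubility_raw"]
    for col in required:
        if col not in raw.columns:
            raise ValueError(f"missing sub-score column {col!r}")
        if raw[col].isna().any():
            bad = raw.loc[raw[col].isna(), "variant_id"].tolist()
            raise ValueError(f"missing {col} for variant(s) {bad}")
    table = raw.copy()
    table["membrane_norm"] = minmax_normalize(table["membrane_raw"])
    table["mind_norm"] = minmax_normalize(table["mind_raw"], flip=True)
    table["dimer_norm"] = minmax_normalize(table["dimer_raw"], flip=True)
    table["solubility_norm"] = minmax_normalize(table["solubility_raw"])
    table["function_score"] = (
        table["membrane_norm"] + table["mind_norm"]
        + table["dimer_norm"] + table["solubility_norm"]
    )
    table["improved_score"] = table["mind_norm"] + table["membrane_norm"]
    return table


def rank_and_select(table: pd.DataFrame, k_top: int = 24,
                    k_bottom: int = 24) -> pd.DataFrame:
    """Sort by descending function score (ties broken by variant id for a
    stable order), assign 1-based ranks, and label the ``k_top`` best as
    'high' and the ``k_bottom`` worst as 'low' for experimental follow-up."""
    n = len(table)
    if n < k_top + k_bottom:
        raise ValueError(
            f"need at least {k_top + k_bottom} variants, have {n}"
        )
    out = table.sort_values(
        ["function_score", "variant_id"], ascending=[False, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, n + 1)
    selection = np.array([""] * n, dtype=object)
    selection[:k_top] = "high"
    if k_bottom:
        selection[-k_bottom:] = "low"
    out["selection"] = selection
    return out
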