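"""Seeded generators for every input the pipeline consumes.

Each generator returns its ground truth alongside the data, so downstream
modules can be tested end to end with no external files: clustered MSAs
with conserved columns, block-structured PAE matrices with a controllable
inter-chain confidence, idealized Cα geometry for helix/strand/coil
layouts, noisy sinusoidal kymograph signals, lognormal cell-length mixtures
with a minicell component, and SEC standards on a known log-linear line.

Noise is Gaussian throughout, truncated at zero wherever the quantity must
stay non-negative (PAE, elution volumes).
"""

from __future__ import annotations

import numpy as np

from .io import PaeFile, Residue, SequenceRecord, StructureFile
from .msa import ALPHABET
from .assays import SEC_STANDARD_MASSES

_HELIX_RADIUS = 2.3       # Å
_HELIX_RISE = 1.5         # Å per residue
_HELIX_TURN = np.deg2rad(100.0)
_STRAND_RISE = 3.35       # Å per residue
_STRAND_ZIGZAG = 0.9      # Å lateral alternation
_COIL_STEP = 3.8          # Å Cα-Cα


def synth_msa(
    n_seqs: int = 500,
    n_cols: int = 100,
    n_clusters: int = 3,
    conservation: float = 5.0,
    gap_rate: float = 0.05,
    seed: int = 0,
) -> tuple[list[SequenceRecord], np.ndarray]:
    """Aligned records with phylogenetic cluster structure.

    Per cluster, each column gets an amino-acid profile drawn from a flat
    Dirichlet and sharpened as p_i ∝ p_i**conservation — at conservation=0
    columns are uniform, as conservation→∞ every column becomes one-hot and
    all sequences within a cluster identical (up to gaps).  ``gap_rate`` is
    the per-position gap probability.  Returns (records, cluster labels).
    """
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    rng = np.random.default_rng(seed)
    aa = np.array(list(ALPHABET[:20]))
    profiles = np.empty((n_clusters, n_cols, 20))
    for c in range(n_clusters):
        base = rng.dirichlet(np.ones(20), size=n_cols)
        if conservation == 0:
            sharp = np.ones_like(base)
        else:
            # rescale by the column max first so huge exponents stay finite
            sharp = (base / base.max(axis=1, keepdims=True)) ** conservation
        profiles[c] = sharp / sharp.sum(axis=1, keepdims=True)
    labels = np.arange(n_seqs) % n_clusters
    cdf = np.cumsum(profiles, axis=2)
    u = rng.random((n_seqs, n_cols, 1))
    idx = (u > cdf[labels]).sum(axis=2)
    rows = aa[idx]
    if gap_rate > 0:
        rows[rng.random((n_seqs, n_cols)) < gap_rate] = "-"
    records = [
        SequenceRecord(id=f"seq{i}", residues="".join(rows[i]))
        for i in range(n_seqs)
    ]
    return records, labels


def synth_helix_coords(
    layout: list[tuple[str, int]], seed: int = 0, origin=(0.0, 0.0, 0.0)
) -> np.ndarray:
    """Cα coordinates realizing a secondary-structure layout: ideal α-helix
    geometry (2.3 Å radius, 1.5 Å rise, 100°/residue), extended strand
    (3.35 Å rise with a 0.9 Å zigzag), and a seeded 3.8 Å random walk for
    coil.  Segments continue from the previous endpoint along +z."""
    rng = np.random.default_rng(seed)
    coords: list[np.ndarray] = []
    pos = np.asarray(origin, dtype=float)
    k_global = 0
    for ss, length in layout:
        for k in range(length):
            if ss == "H":
                theta = k * _HELIX_TURN
                point = pos + np.array([
                    _HELIX_RADIUS * np.cos(theta),
                    _HELIX_RADIUS * np.sin(theta),
                    k * _HELIX_RISE,
                ])
            elif ss == "E":
                point = pos + np.array([
                    0.0,
                    _STRAND_ZIGZAG * (1 if k % 2 else -1),
                    k * _STRAND_RISE,
                ])
            elif ss == "C":
                if coords and k == 0:
                    point = pos
                else:
                    step = rng.standard_normal(3)
                    step *= _COIL_STEP / np.linalg.norm(step)
                    point = (coords[-1] + step) if coords else pos
            else:
                raise ValueError(f"unknown ss label {ss!r}")
            coords.append(point)
            k_global += 1
        # restart the next segment past the current endpoint
        pos = coords[-1] + np.array([0.0, 0.0, 4.5])
    return np.array(coords)


def _structure_from_layouts(
    chain_layouts: dict, seed: int = 0
) -> tuple[StructureFile, dict]:
    """Build a multi-chain Cα structure from per-chain layouts; chains are
    laterally offset so they do not overlap.  Returns the structure and the
    ground-truth SS string per chain."""
    chains = []
    truth = {}
    for ci, (cid, layout) in enumerate(chain_layouts.items()):
        coords = synth_helix_coords(layout, seed=seed + ci,
                                    origin=(30.0 * ci, 0.0, 0.0))
        residues = tuple(
            Residue(key=str(i + 1), name="A", ca=tuple(c))
            for i, c in enumerate(coords)
        )
        chains.append((cid, residues))
        truth[cid] = "".join(ss * length for ss, length in layout)
    return StructureFile(chains=tuple(chains), source_dialect="PDB"), truth


#: default chain layout for PAE fixtures: short N-terminal helix, coil
#: linker, long (binding) helix, coil tail
DEFAULT_CHAIN_LAYOUT = [("C", 2), ("H", 8), ("C", 5), ("H", 12), ("C", 3)]


def synth_pae(
    chain_lengths: tuple[int, int] | None = None,
    intra_mean: float = 4.0,
    inter_mean: float = 8.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    chain_layouts: dict | None = None,
) -> tuple[PaeFile, StructureFile, dict]:
    """Block-structured PAE matrix plus a companion two-chain structure.

    Intra-chain blocks have mean ``intra_mean``, inter-chain blocks mean
    ``inter_mean`` (low = confident interface); Gaussian noise is truncated
    at zero.  Returns (PaeFile, StructureFile, ground truth dict with the
    SS string per chain and the block means)."""
    if chain_layouts is None:
        chain_layouts = {"A": list(DEFAULT_CHAIN_LAYOUT),
                         "B": list(DEFAULT_CHAIN_LAYOUT)}
        if chain_lengths is not None:
            na, nb = chain_lengths
            chain_layouts = {"A": _layout_of_length(na),
                             "B": _layout_of_length(nb)}
    if intra_mean < 0 or inter_mean < 0:
        raise ValueError("PAE means must be >= 0")
    structure, ss_truth = _structure_from_layouts(chain_layouts, seed=seed)
    lengths = [len(ss_truth[cid]) for cid, _ in structure.chains]
    n = sum(lengths)
    rng = np.random.default_rng(seed)
    matrix = np.full((n, n), intra_mean)
    na = lengths[0]
    matrix[:na, na:] = inter_mean
    matrix[na:, :na] = inter_mean
    if noise_sd > 0:
        matrix = matrix + rng.normal(0.0, noise_sd, size=matrix.shape)
    matrix = np.maximum(matrix, 0.0)
    truth = {"ss": ss_truth, "intra_mean": intra_mean,
             "inter_mean": inter_mean,
             "chain_lengths": tuple(lengths)}
    return PaeFile(matrix=matrix, n_residues=n), structure, truth


def _layout_of_length(n: int) -> list[tuple[str, int]]:
    """Shrink/grow the default layout to an exact residue count."""
    layout = [list(seg) for seg in DEFAULT_CHAIN_LAYOUT]
    total = sum(length for _, length in layout)
    layout[-1][1] += n - total
    if layout[-1][1] < 0:
        # fall back to one long helix with a coil tail for tiny chains
        return [("H", max(n - 2, 0)), ("C", min(n, 2))]
    return [tuple(seg) for seg in layout]


def synth_hydro_track(
    n_res: int, nterm_mean: float = 0.6, body_mean: float = 0.3,
    nterm_len: int = 10, noise_sd: float = 0.02, seed: int = 0
) -> np.ndarray:
    """Per-residue hydrophobicity track with a controllable N-terminal
    mean — variants meant to bind the membrane get a hydrophobic
    N-terminus."""
    rng = np.random.default_rng(seed)
    track = np.full(n_res, body_mean)
    track[: min(nterm_len, n_res)] = nterm_mean
    return np.clip(track + rng.normal(0.0, noise_sd, size=n_res), 0.0, 1.0)


def synth_kymograph(
    period_s: float = 42.0,
    dt: float = 5.0,
    n_frames: int = 60,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    phase: float = 0.3,
    offset: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """A*sin(2πt/T + φ) + c sampled at dt with seeded Gaussian noise;
    the true period is the ground truth.  Aliasing (T ≤ 2·dt) is refused."""
    if period_s <= 2 * dt:
        raise ValueError("period must exceed 2*dt (Nyquist)")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * dt
    y = amplitude * np.sin(2 * np.pi * t / period_s + phase) + offset
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_frames)
    return y, dt


def synth_cell_lengths(
    n: int = 1000,
    log_mean: float = np.log(3.5),
    log_sd: float = 0.35,
    minicell_frac: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Lognormal cell-length body (default median 3.5 µm, the wild-type
    median) plus a sub-µm minicell component at the stated fraction."""
    if not 0.0 <= minicell_frac <= 1.0:
        raise ValueError("minicell_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lengths = rng.lognormal(log_mean, log_sd, size=n)
    is_mini = rng.random(n) < minicell_frac
    lengths[is_mini] = rng.uniform(0.3, 0.95, size=is_mini.sum())
    return lengths


def synth_sec_standards(
    slope: float = -0.35,
    intercept: float = 1.1,
    noise_sd: float = 0.0,
    vo: float = 8.0,
    vc: float = 23.5,
    seed: int = 0,
    masses: list[tuple[str, float]] | None = None,
) -> list[tuple[str, float, float]]:
    """SEC standards (name, mass kDa, Ve mL) generated by inverting
    Kav = slope*log10(mass) + intercept; the default masses are the usual
    gel-filtration standard set."""
    if vc <= vo:
        raise ValueError("vc must exceed vo")
    rng = np.random.default_rng(seed)
    if masses is None:
        masses = list(SEC_STANDARD_MASSES)
    out = []
    for name, mass in masses:
        k = slope * np.log10(mass) + intercept
        ve = vo + k * (vc - vo)
        if noise_sd > 0:
            ve += rng.normal(0.0, noise_sd)
        out.append((name, mass, float(max(ve, 0.0))))
    return out
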