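"""Readers and writers for the external formats the pipeline touches.

Sequences travel as :class:`SequenceRecord`, AlphaFold-style predicted
aligned error (PAE) matrices as :class:`PaeFile`, and predicted complex
structures (Cα only) as :class:`StructureFile`.  Residue indices are
0-based everywhere inside the package and 1-based in user-facing reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("minescreen")

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: non-standard residue names mapped to their nearest standard parent
NONSTANDARD_PARENT = {
    "MSE": "M", "SEC": "C", "PYL": "K", "HYP": "P", "SEP": "S",
    "TPO": "T", "PTR": "Y", "CSO": "C", "MLY": "K", "FME": "M",
}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein sequence, possibly gapped ('-')."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ParseError("sequence record with empty id")
        if not self.residues:
            raise ParseError(f"sequence {self.id!r} has empty residues")

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class PaeFile:
    """Square predicted-aligned-error matrix in Ångström."""

    matrix: np.ndarray
    n_residues: int

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ParseError(f"PAE matrix is not square: shape {m.shape}")
        if m.shape[0] != self.n_residues:
            raise ParseError("n_residues does not match matrix side")
        if np.any(m < 0):
            raise ParseError("PAE matrix contains negative entries")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class Residue:
    """One residue reduced to its Cα position; ``key`` keeps author
    numbering plus insertion code for reports."""

    key: str
    name: str          # one-letter code; 'X' for unknown
    ca: tuple[float, float, float]


@dataclass(frozen=True)
class StructureFile:
    chains: tuple[tuple[str, tuple[Residue, ...]], ...]
    source_dialect: str = "PDB"

    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    def chain(self, chain_id: str) -> tuple[Residue, ...]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise KeyError(chain_id)

    def ca_coords(self, chain_id: str) -> np.ndarray:
        return np.array([r.ca for r in self.chain(chain_id)], dtype=float)


# ---------------------------------------------------------------------------
# sequences


def _validate_residues(seq: str, record_id: str, lineno: int | None = None) -> str:
    seq = seq.upper()
    allowed = set(STANDARD_AA) | set("BJOUXZ") | {GAP, "."}
    bad = set(seq) - allowed
    if bad:
        where = f" (line {lineno})" if lineno is not None else ""
        raise ParseError(
            f"illegal character(s) {sorted(bad)} in sequence {record_id!r}{where}"
        )
    return seq.replace(".", GAP)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly empty) FASTA file; residue case is normalized to
    upper.  Malformed records raise :class:`ParseError` naming the line."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        header: str | None = None
        chunks: list[str] = []
        header_line = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append(_finish_record(header, chunks, header_line, seen))
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"empty FASTA header at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(f"sequence data before first header at line {lineno}")
                chunks.append(line.strip())
        if header is not None:
            records.append(_finish_record(header, chunks, header_line, seen))
    return records


def _finish_record(header: str, chunks: list[str], lineno: int, seen: set[str]) -> SequenceRecord:
    parts = header.split(None, 1)
    rid = parts[0]
    desc = parts[1] if len(parts) > 1 else ""
    if rid in seen:
        raise ParseError(f"duplicate sequence id {rid!r} (line {lineno})")
    seen.add(rid)
    seq = _validate_residues("".join(chunks), rid, lineno)
    if not seq:
        raise ParseError(f"record {rid!r} has no residues (line {lineno})")
    return SequenceRecord(id=rid, residues=seq, description=desc)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_alignment(path: str | Path, dialect: str = "fasta") -> list[SequenceRecord]:
    """Read an alignment (``fasta`` or ``stockholm``); all rows must share
    one aligned length, otherwise the offending sequence id is reported."""
    dialect = {"aligned-fasta": "fasta", "fasta": "fasta", "stockholm": "stockholm"}[dialect]
    if dialect == "fasta":
        records = read_fasta(path)
    else:
        aln = AlignIO.read(str(path), "stockholm")
        records = [
            SequenceRecord(
                id=r.id,
                residues=_validate_residues(str(r.seq), r.id),
                description=r.description if r.description != "<unknown description>" else "",
            )
            for r in aln
        ]
    if not records:
        return records
    width = len(records[0].residues)
    for r in records:
        if len(r.residues) != width:
            raise ParseError(
                f"ragged alignment: sequence {r.id!r} has length "
                f"{len(r.residues)}, expected {width}"
            )
    return records


# ---------------------------------------------------------------------------
# PAE JSON (both public AlphaFold dialects)


def read_pae_json(path: str | Path) -> PaeFile:
    """Read an AlphaFold PAE JSON in either the nested-list dialect
    (``predicted_aligned_error`` / ``pae``) or the flat triplet dialect
    (``residue1``/``residue2``/``distance``)."""
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, list):
        if not payload:
            raise ParseError(f"{path}: empty PAE JSON")
        payload = payload[0]
    if not isinstance(payload, dict):
        raise ParseError(f"{path}: unrecognized PAE JSON layout")

    if "residue1" in payload and "residue2" in payload:
        r1 = np.asarray(payload["residue1"], dtype=int)
        r2 = np.asarray(payload["residue2"], dtype=int)
        d = np.asarray(payload["distance"], dtype=float)
        n = int(max(r1.max(), r2.max()))
        matrix = np.full((n, n), np.nan)
        matrix[r1 - 1, r2 - 1] = d          # triplets are 1-based
        if np.isnan(matrix).any():
            raise ParseError(f"{path}: flat PAE dialect does not cover the full matrix")
    else:
        for key in ("predicted_aligned_error", "pae", "distance_matrix"):
            if key in payload:
                matrix = np.asarray(payload[key], dtype=float)
                break
        else:
            raise ParseError(f"{path}: no PAE matrix key found")
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ParseError(f"{path}: PAE matrix not square (shape {matrix.shape})")
    if np.any(matrix < 0):
        raise ParseError(f"{path}: PAE matrix has negative entries")
    return PaeFile(matrix=matrix, n_residues=matrix.shape[0])


def write_pae_json(pae: PaeFile, path: str | Path, dialect: str = "nested") -> None:
    if dialect == "nested":
        payload = {"predicted_aligned_error": pae.matrix.tolist(),
                   "max_predicted_aligned_error": float(pae.matrix.max())}
    elif dialect == "flat":
        n = pae.n_residues
        r1, r2 = np.meshgrid(np.arange(1, n + 1), np.arange(1, n + 1), indexing="ij")
        payload = {"residue1": r1.ravel().tolist(),
                   "residue2": r2.ravel().tolist(),
                   "distance": pae.matrix.ravel().tolist()}
    else:
        raise ValueError(f"unknown PAE dialect {dialect!r}")
    with open(path, "w") as fh:
        json.dump([payload], fh)


# ---------------------------------------------------------------------------
# structures (Cα only)

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F", "GLY": "G",
    "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L", "MET": "M", "ASN": "N",
    "PRO": "P", "GLN": "Q", "ARG": "R", "SER": "S", "THR": "T", "VAL": "V",
    "TRP": "W", "TYR": "Y",
}


def _one_letter(resname: str) -> str:
    if resname in _THREE_TO_ONE:
        return _THREE_TO_ONE[resname]
    if resname in NONSTANDARD_PARENT:
        return NONSTANDARD_PARENT[resname]
    return "X"


def read_structure(path: str | Path) -> StructureFile:
    """Read Cα coordinates from a PDB or mmCIF file (dialect by extension,
    with mmCIF fallback).  Residues lacking a Cα are skipped with a logged
    warning; order follows author numbering within each chain."""
    path = Path(path)
    st = gemmi.read_structure(str(path))
    dialect = "mmCIF" if path.suffix.lower() in {".cif", ".mmcif"} else "PDB"
    st.setup_entities()
    model = st[0]
    chains = []
    skipped = 0
    for chain in model:
        residues = []
        for res in chain:
            ca = res.find_atom("CA", "*")
            if ca is None:
                skipped += 1
                logger.warning("%s: residue %s %s in chain %s has no CA; skipped",
                               path.name, res.name, res.seqid, chain.name)
                continue
            icode = res.seqid.icode.strip()
            key = f"{res.seqid.num}{icode}"
            residues.append(Residue(key=key, name=_one_letter(res.name),
                                    ca=(ca.pos.x, ca.pos.y, ca.pos.z)))
        if residues:
            chains.append((chain.name, tuple(residues)))
    if not chains:
        raise ParseError(f"{path}: no chain with CA atoms")
    if skipped:
        logger.info("%s: skipped %d residue(s) without CA", path.name, skipped)
    ids = [c for c, _ in chains]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate chain ids {ids}")
    return StructureFile(chains=tuple(chains), source_dialect=dialect)


def write_structure_pdb(structure: StructureFile, path: str | Path) -> None:
    """Write a minimal Cα-only PDB (fixtures and round-trips)."""
    one_to_three = {v: k for k, v in _THREE_TO_ONE.items()}
    serial = 1
    with open(path, "w") as fh:
        for cid, residues in structure.chains:
            for i, res in enumerate(residues, start=1):
                resname = one_to_three.get(res.name, "UNK")
                x, y, z = res.ca
                fh.write(
                    f"ATOM  {serial:5d}  CA  {resname:<3s} {cid:1s}{i:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
                serial += 1
            fh.write("TER\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# score tables

#: stable column order for screen tables (subset used when absent)
SCORE_COLUMNS = [
    "variant_id", "blinded_name",
    "membrane_raw", "mind_raw", "dimer_raw", "solubility_raw",
    "membrane_norm", "mind_norm", "dimer_norm", "solubility_norm",
    "function_score", "improved_score", "elbo_score", "hmm_score",
    "identity_wt", "similarity_wt", "identity_closest",
    "rank", "selection",
    "in_vitro_positive", "in_vivo_oscillation", "phenotype", "wave_occurrence",
]


def write_score_table(table: pd.DataFrame, path: str | Path, blinded: bool = False) -> None:
    """Write a ScreenTable CSV with a stable column order and floats at six
    significant digits.  ``blinded=True`` drops rank/selection columns so
    experimenters cannot see the computational ordering."""
    cols = [c for c in SCORE_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    if blinded:
        cols = [c for c in cols if c not in {"rank", "selection", "function_score",
                                             "improved_score"}]
    table[cols].to_csv(path, index=False, float_format="%.6g")


def read_score_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
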