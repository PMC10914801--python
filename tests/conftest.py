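"""Shared fixtures: every external-format input is generated at test time
through the synthetic module and the package's own writers, so the I/O
layer is exercised in passing."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pytest

from minescreen import io as msio
from minescreen import synthetic


@pytest.fixture
def two_chain_fixture():
    """Noise-free block PAE + companion structure (30+30 residues)."""
    return synthetic.synth_pae(intra_mean=4.0, inter_mean=8.0, noise_sd=0.0,
                               seed=0)


def write_variant_dir(tmp_path, variant_specs, seed=0):
    """Write per-variant heterodimer/homodimer structure + PAE files plus
    hydrophobicity and solubility CSVs, as the ``score`` stage expects.

    ``variant_specs``: list of (variant_id, het_inter_mean, hydro_nterm,
    solubility) tuples; lower het_inter_mean = more confident interface.
    """
    vdir = tmp_path / "variants"
    vdir.mkdir(exist_ok=True)
    hydro_rows = []
    sol_rows = []
    for i, (vid, inter_mean, nterm_hydro, sol) in enumerate(variant_specs):
        for tag, inter in (("het", inter_mean), ("hom", 0.8 * inter_mean)):
            pae, structure, truth = synthetic.synth_pae(
                intra_mean=4.0, inter_mean=inter, noise_sd=0.0,
                seed=seed,  # identical geometry across variants
            )
            msio.write_structure_pdb(structure, vdir / f"{vid}.{tag}.pdb")
            msio.write_pae_json(pae, vdir / f"{vid}.{tag}.pae.json")
        n_res = truth["chain_lengths"][0]
        track = synthetic.synth_hydro_track(
            n_res, nterm_mean=nterm_hydro, noise_sd=0.0, seed=seed + i
        )
        hydro_rows += [
            {"variant_id": vid, "residue_index": j, "value": v}
            for j, v in enumerate(track)
        ]
        sol_rows.append({"variant_id": vid, "value": sol})
    pd.DataFrame(hydro_rows).to_csv(tmp_path / "hydro.csv", index=False)
    pd.DataFrame(sol_rows).to_csv(tmp_path / "solubility.csv", index=False)
    return vdir, tmp_path / "hydro.csv", tmp_path / "solubility.csv"
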