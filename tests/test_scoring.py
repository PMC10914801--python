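"""Divide-and-conquer scoring: secondary structure, PAE block means,
region annotation, normalization, combination and ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from minescreen.scoring import (
    ChainAnnotation, PaeMatrix, annotate_variant_regions,
    assign_secondary_structure, combine_scores, dimerization_score,
    interchain_pae_mean, locate_mind_binding_helix, membrane_binding_score,
    mind_interaction_score, minmax_normalize, rank_and_select,
    solubility_score,
)
from minescreen.synthetic import synth_helix_coords, synth_pae


def make_pae(matrix, n_a):
    n = matrix.shape[0]
    return PaeMatrix(matrix=matrix,
                     chain_offsets={"A": (0, n_a), "B": (n_a, n - n_a)})


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_h(self):
        ss = assign_secondary_structure(synth_helix_coords([("H", 12)]))
        assert set(ss[2:-2]) == {"H"}

    def test_extended_strand_interior_is_e(self):
        ss = assign_secondary_structure(synth_helix_coords([("E", 8)]))
        assert set(ss[1:-1]) == {"E"}

    def test_three_residue_chain_all_coil(self):
        coords = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
        assert assign_secondary_structure(coords) == "CCC"

    def test_random_walk_mostly_coil(self):
        ss = assign_secondary_structure(synth_helix_coords([("C", 40)], seed=11))
        assert ss.count("C") / len(ss) > 0.7


class TestInterchainPaeMean:
    def test_constant_block(self):
        m = np.full((4, 4), 5.0)
        assert interchain_pae_mean(make_pae(m, 2), [0, 1], [2, 3]) == 5.0

    def test_asymmetric_blocks_symmetrized(self):
        m = np.zeros((4, 4))
        m[:2, 2:] = 4.0
        m[2:, :2] = 6.0
        assert interchain_pae_mean(make_pae(m, 2), [0, 1], [2, 3]) == 5.0

    def test_single_pair(self):
        m = np.zeros((2, 2))
        m[0, 1], m[1, 0] = 2.0, 4.0
        assert interchain_pae_mean(make_pae(m, 1), [0], [1]) == 3.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n_a, n_b = rng.integers(2, 6, size=2)
            m = rng.random((n_a + n_b, n_a + n_b)) * 30
            a = rng.choice(n_a, size=rng.integers(1, n_a + 1), replace=False)
            b = n_a + rng.choice(n_b, size=rng.integers(1, n_b + 1), replace=False)
            total, count = 0.0, 0
            for i in a:
                for j in b:
                    total += m[i, j] + m[j, i]
                    count += 2
            got = interchain_pae_mean(make_pae(m, n_a), a, b)
            np.testing.assert_allclose(got, total / count, atol=1e-10)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            interchain_pae_mean(make_pae(np.zeros((2, 2)), 1), [], [0])


class TestBindingHelix:
    def ann(self, ss, chain="A"):
        return ChainAnnotation(chain_id=chain, ss=ss)

    def test_low_pae_helix_wins(self):
        # chain A: two helices (0-4, 8-12); only the second has a
        # low-PAE block to chain B
        ss_a = "HHHHCCCCHHHH"
        m = np.full((16, 16), 20.0)
        m[8:12, 12:] = 2.0
        m[12:, 8:12] = 2.0
        pae = make_pae(m, 12)
        helix = locate_mind_binding_helix(self.ann(ss_a), pae,
                                          self.ann("HHHH", "B"))
        assert helix == (8, 12)

    def test_equal_means_tie_breaks_to_lower_start(self):
        ss_a = "HHHHCCCCHHHH"
        m = np.full((16, 16), 7.0)
        pae = make_pae(m, 12)
        helix = locate_mind_binding_helix(self.ann(ss_a), pae,
                                          self.ann("HHHH", "B"))
        assert helix == (0, 4)

    def test_all_coil_chain_flagged(self):
        pae = make_pae(np.full((8, 8), 6.0), 4)
        assert locate_mind_binding_helix(self.ann("CCCC"), pae,
                                         self.ann("HHHH", "B")) is None

    def test_no_helix_scores_worst_case(self):
        m = np.full((8, 8), 6.0)
        m[0, 1] = 31.0
        pae = make_pae(m, 4)
        raw = mind_interaction_score(pae, self.ann("CCCC"),
                                     self.ann("HHHH", "B"))
        assert raw == 31.0


class TestMembraneScore:
    def test_constant_track(self):
        ann = ChainAnnotation(chain_id="A", ss="HHHHCCHHHH",
                              regions={"nterminal_helix": (0, 4)})
        assert membrane_binding_score(np.full(10, 0.42), ann) == pytest.approx(0.42)

    def test_mean_of_helix_values(self):
        ann = ChainAnnotation(chain_id="A", ss="HHHCCC",
                              regions={"nterminal_helix": (0, 3)})
        track = np.array([0.2, 0.4, 0.6, 9.0, 9.0, 9.0])
        assert membrane_binding_score(track, ann) == pytest.approx(0.4)

    def test_unstructured_nterminus_falls_back_to_region(self):
        ann = ChainAnnotation(chain_id="A", ss="CCCCHHHH",
                              regions={"nterminal_region": (0, 4)})
        track = np.array([1.0, 1.0, 0.0, 0.0, 5.0, 5.0, 5.0, 5.0])
        assert membrane_binding_score(track, ann) == pytest.approx(0.5)

    def test_degenerate_region_rejected(self):
        ann = ChainAnnotation(chain_id="A", ss="HHHH",
                              regions={"nterminal_region": (0, 0)})
        with pytest.raises(ValueError, match="degenerate"):
            membrane_binding_score(np.ones(4), ann)


class TestDimerization:
    def test_constant_inter_block(self, two_chain_fixture):
        pae_file, structure, truth = two_chain_fixture
        n_a = truth["chain_lengths"][0]
        pae = make_pae(pae_file.matrix, n_a)
        ann_a = ChainAnnotation(chain_id="A", ss=truth["ss"]["A"])
        ann_b = ChainAnnotation(chain_id="B", ss=truth["ss"]["B"])
        assert dimerization_score(pae, ann_a, ann_b) == pytest.approx(
            truth["inter_mean"]
        )

    def test_all_coil_worst_case(self):
        m = np.full((8, 8), 3.0)
        m[0, 5] = 28.5
        pae = make_pae(m, 4)
        coil = ChainAnnotation(chain_id="A", ss="CCCC")
        other = ChainAnnotation(chain_id="B", ss="HHHH")
        assert dimerization_score(pae, coil, other) == 28.5


class TestSolubility:
    def test_external_passthrough_and_flag(self):
        assert solubility_score(0.71) == 0.71
        assert solubility_score(0.0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            solubility_score(1.2)

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40))
    @settings(deadline=None, max_examples=30)
    def test_proxy_bounded(self, seq):
        assert 0.0 <= solubility_score(sequence=seq) <= 1.0


class TestNormalizeCombineRank:
    def test_minmax_examples(self):
        np.testing.assert_allclose(minmax_normalize([1, 3, 5]), [0, 0.5, 1])
        np.testing.assert_allclose(minmax_normalize([1, 3, 5], flip=True),
                                   [1, 0.5, 0])
        np.testing.assert_allclose(minmax_normalize([2, 2, 2]), [0.5] * 3)

    def test_minmax_needs_two_values(self):
        with pytest.raises(ValueError):
            minmax_normalize([1.0])

    @staticmethod
    def raw_table():
        return pd.DataFrame({
            "variant_id": ["v1", "v2", "v3"],
            "membrane_raw": [0.9, 0.5, 0.1],
            "mind_raw": [3.0, 6.0, 9.0],      # low is good
            "dimer_raw": [2.0, 5.0, 8.0],     # low is good
            "solubility_raw": [0.9, 0.5, 0.1],
        })

    def test_best_in_all_reaches_four(self):
        table = combine_scores(self.raw_table())
        best = table.set_index("variant_id").loc["v1"]
        assert best["function_score"] == pytest.approx(4.0)
        assert best["improved_score"] == pytest.approx(2.0)
        worst = table.set_index("variant_id").loc["v3"]
        assert worst["function_score"] == pytest.approx(0.0)

    def test_middle_variant_sums(self):
        table = combine_scores(self.raw_table()).set_index("variant_id")
        assert table.loc["v2", "function_score"] == pytest.approx(2.0)
        assert table.loc["v2", "improved_score"] == pytest.approx(1.0)

    def test_missing_subscore_names_column(self):
        bad = self.raw_table().drop(columns=["dimer_raw"])
        with pytest.raises(ValueError, match="dimer_raw"):
            combine_scores(bad)

    def test_bounds_hold_on_random_tables(self):
        rng = np.random.default_rng(8)
        raw = pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(20)],
            "membrane_raw": rng.random(20),
            "mind_raw": rng.random(20) * 30,
            "dimer_raw": rng.random(20) * 30,
            "solubility_raw": rng.random(20),
        })
        table = combine_scores(raw)
        assert table["function_score"].between(0, 4).all()
        assert table["improved_score"].between(0, 2).all()

    def test_affine_rescaling_invariance(self):
        raw = self.raw_table()
        rescaled = raw.copy()
        rescaled["mind_raw"] = raw["mind_raw"] * 7.0 + 3.0
        np.testing.assert_allclose(
            combine_scores(raw)["function_score"],
            combine_scores(rescaled)["function_score"],
        )

    def test_rank_and_select_counts_and_ties(self):
        raw = pd.DataFrame({
            "variant_id": [f"v{i:02d}" for i in range(6)],
            "membrane_raw": [0.9, 0.5, 0.5, 0.5, 0.5, 0.1],
            "mind_raw": [3, 6, 6, 6, 6, 9],
            "dimer_raw": [2, 5, 5, 5, 5, 8],
            "solubility_raw": [0.9, 0.5, 0.5, 0.5, 0.5, 0.1],
        })
        table = rank_and_select(combine_scores(raw), k_top=2, k_bottom=2)
        assert list(table["rank"]) == [1, 2, 3, 4, 5, 6]
        # ties resolved by id, stable across runs
        tied = table[table["function_score"] == 2.0]["variant_id"].tolist()
        assert tied == sorted(tied)
        assert (table["selection"] == "high").sum() == 2
        assert (table["selection"] == "low").sum() == 2

    def test_bottom_only_selection(self):
        table = rank_and_select(combine_scores(self.raw_table()),
                                k_top=0, k_bottom=2)
        assert (table["selection"] == "high").sum() == 0
        assert (table["selection"] == "low").sum() == 2

    def test_insufficient_variants_rejected(self):
        with pytest.raises(ValueError):
            rank_and_select(combine_scores(self.raw_table()), 24, 24)


def test_lower_interchain_pae_ranks_higher():
    """Two fixtures identical except for the inter-chain PAE mean: the
    more confident interface must win both the normalized score and the
    rank."""
    rows = []
    for vid, inter in (("vlow", 3.0), ("vhigh", 9.0)):
        pae_file, structure, truth = synth_pae(
            intra_mean=4.0, inter_mean=inter, noise_sd=0.0, seed=0
        )
        n_a = truth["chain_lengths"][0]
        pae = make_pae(pae_file.matrix, n_a)
        ann_a = ChainAnnotation(chain_id="A", ss=truth["ss"]["A"])
        ann_b = ChainAnnotation(chain_id="B", ss=truth["ss"]["B"])
        va = annotate_variant_regions(ann_a, pae, ann_b)
        rows.append({
            "variant_id": vid,
            "membrane_raw": 0.5,
            "mind_raw": mind_interaction_score(pae, va, ann_b),
            "dimer_raw": dimerization_score(pae, ann_a, ann_b),
            "solubility_raw": 0.5,
        })
    table = rank_and_select(combine_scores(pd.DataFrame(rows)),
                            k_top=1, k_bottom=1)
    assert table.iloc[0]["variant_id"] == "vlow"
    t = table.set_index("variant_id")
    assert t.loc["vlow", "mind_norm"] > t.loc["vhigh", "mind_norm"]
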