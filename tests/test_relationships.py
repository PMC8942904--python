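"""Marker QC and NOIA / VanRaden relationship matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import epinoia as ep
from epinoia.errors import DegeneratePanelError, EmptyPanelError, InputError


def frame(columns: dict) -> pd.DataFrame:
    df = pd.DataFrame(columns, dtype=float)
    df.index = [f"L{i}" for i in range(len(df))]
    return df


def reference_noia_G(genotypes: np.ndarray) -> np.ndarray:
    """Independent NOIA coding oracle: per-genotype coefficient lookup."""
    n, m = genotypes.shape
    Ha = np.zeros_like(genotypes, dtype=float)
    for j in range(m):
        col = genotypes[:, j]
        p_Aa = np.mean(col == 1)
        p_aa = np.mean(col == 2)
        lookup = {0: p_Aa + 2 * p_aa, 1: p_Aa + 2 * p_aa - 1, 2: p_Aa + 2 * p_aa - 2}
        Ha[:, j] = [lookup[int(g)] for g in col]
    M = Ha @ Ha.T
    return M / (np.trace(M) / n)


def reference_vanraden_G(genotypes: np.ndarray) -> np.ndarray:
    """Independent VanRaden oracle, trace-normalized."""
    p = genotypes.mean(axis=0) / 2.0
    W = genotypes - 2.0 * p
    M = W @ W.T
    return M / (np.trace(M) / genotypes.shape[0])


class TestQC:
    def test_filters_by_maf_and_call_rate(self):
        geno = frame({"A": [0, 0, 0, 2], "B": [0, 0, 0, 0],
                      "C": [0, np.nan, 2, 2]})
        out, report = ep.qc_filter(geno)
        assert list(out.columns) == ["A"]
        reasons = dict(zip(report.removed["marker"], report.removed["reason"]))
        assert reasons == {"B": "maf", "C": "call_rate"}

    def test_boundary_maf_is_retained(self):
        # MAF exactly 0.05 on 20 hard calls survives the strict inequality
        col = [2.0] + [0.0] * 19
        geno = frame({"A": col, "B": [0, 2] * 10})
        out, _ = ep.qc_filter(geno)
        assert "A" in out.columns

    def test_clean_panel_passes_unchanged(self, random_panel):
        geno = random_panel(seed=1)
        maf = np.minimum(geno.mean() / 2, 1 - geno.mean() / 2)
        clean = geno.loc[:, maf >= 0.1]  # clearly polymorphic, fully called
        out, report = ep.qc_filter(clean)
        pd.testing.assert_frame_equal(out, clean)
        assert report.removed.empty

    def test_idempotent(self, random_panel):
        geno = random_panel(seed=2, missing=0.05)
        once, _ = ep.qc_filter(geno)
        twice, rep = ep.qc_filter(once)
        pd.testing.assert_frame_equal(once, twice)
        assert rep.removed.empty

    def test_all_markers_removed_raises(self):
        geno = frame({"A": [0, 0, 0, 0], "B": [2, 2, 2, 2]})
        with pytest.raises(EmptyPanelError):
            ep.qc_filter(geno)


class TestImputation:
    def test_mean_fills_missing(self):
        geno = frame({"A": [0, 2, np.nan, 2]})
        out = ep.impute_missing_mean(geno)
        assert out.loc["L2", "A"] == pytest.approx(4 / 3)

    def test_identity_without_missing(self, random_panel):
        geno = random_panel(seed=3)
        pd.testing.assert_frame_equal(ep.impute_missing_mean(geno), geno)

    def test_column_means_preserved(self, random_panel):
        geno = random_panel(n=80, m=40, seed=4, missing=0.013)
        out = ep.impute_missing_mean(geno)
        assert not out.isna().any().any()
        np.testing.assert_allclose(out.mean(), geno.mean(), atol=1e-12)

    def test_fully_missing_marker_refers_to_qc(self):
        geno = frame({"A": [np.nan, np.nan], "B": [0, 2]})
        with pytest.raises(InputError, match="qc_filter"):
            ep.impute_missing_mean(geno)


class TestFrequencies:
    @pytest.mark.parametrize("col,expected", [
        ([0, 1, 2, 1], (0.25, 0.5, 0.25)),
        ([1, 1, 1], (0.0, 1.0, 0.0)),
        ([0, 0, 2, np.nan], (2 / 3, 0.0, 1 / 3)),
    ])
    def test_counting_rule(self, col, expected):
        freqs = ep.genotype_frequencies(frame({"A": col}))
        assert tuple(freqs.loc["A"]) == pytest.approx(expected)

    def test_fractional_calls_are_excluded(self):
        freqs = ep.genotype_frequencies(frame({"A": [0, 2, 1.5, 0.7]}))
        assert tuple(freqs.loc["A"]) == pytest.approx((0.5, 0, 0.5))

    def test_rows_sum_to_one(self, random_panel):
        freqs = ep.genotype_frequencies(random_panel(seed=5, missing=0.1))
        np.testing.assert_allclose(freqs.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_hard_calls_raise(self):
        with pytest.raises(InputError):
            ep.genotype_frequencies(frame({"A": [0.5, 1.5]}))


class TestNoiaCoefficients:
    def test_symmetric_frequencies_give_unit_coefficients(self):
        geno = frame({"A": [0, 1, 2, 1]})
        coeffs = ep.noia_additive_coefficients(geno, ep.genotype_frequencies(geno))
        assert list(coeffs["A"]) == pytest.approx([1.0, 0.0, -1.0, 0.0])

    def test_all_heterozygous_centers_to_zero(self):
        geno = frame({"A": [1, 1, 1]})
        coeffs = ep.noia_additive_coefficients(geno, ep.genotype_frequencies(geno))
        assert (coeffs["A"] == 0.0).all()

    def test_columns_center_to_zero(self, random_panel):
        geno = random_panel(n=40, m=30, seed=6)
        coeffs = ep.noia_additive_coefficients(geno, ep.genotype_frequencies(geno))
        np.testing.assert_allclose(coeffs.sum(axis=0), 0.0, atol=1e-9)

    def test_dimension_mismatch_raises(self, random_panel):
        geno = random_panel(seed=7)
        freqs = ep.genotype_frequencies(geno.iloc[:, :-1])
        with pytest.raises(InputError):
            ep.noia_additive_coefficients(geno, freqs)


class TestRelationshipMatrices:
    def test_two_line_hand_example(self):
        geno = frame({"A": [0, 2]})
        G = ep.build_G_noia(
            ep.noia_additive_coefficients(geno, ep.genotype_frequencies(geno)))
        np.testing.assert_allclose(G, [[1, -1], [-1, 1]], atol=1e-12)

    def test_identical_lines_are_fully_related(self, random_panel):
        one = random_panel(n=1, m=30, seed=8)
        geno = pd.concat([one] * 3)
        geno.index = ["L0", "L1", "L2"]
        # identical lines: sample frequencies degenerate, use external freqs
        freqs = pd.DataFrame({"p_AA": 0.25, "p_Aa": 0.5, "p_aa": 0.25},
                             index=geno.columns)
        G = ep.build_G_noia(ep.noia_additive_coefficients(geno, freqs))
        assert np.allclose(G, 1.0)

    def test_mean_diagonal_is_one(self, random_panel):
        geno = random_panel(n=30, m=80, seed=9)
        G = ep.build_G_noia(
            ep.noia_additive_coefficients(geno, ep.genotype_frequencies(geno)))
        H = ep.build_H_noia(G)
        assert np.diag(G).mean() == pytest.approx(1.0, abs=1e-12)
        assert np.diag(H).mean() == pytest.approx(1.0, abs=1e-12)

    def test_hadamard_square_hand_example(self):
        G = pd.DataFrame([[1.0, -1.0], [-1.0, 1.0]], index=["a", "b"],
                         columns=["a", "b"])
        H = ep.build_H_noia(G)
        np.testing.assert_allclose(H, [[1, 1], [1, 1]], atol=1e-12)
        I = pd.DataFrame(np.eye(3))
        np.testing.assert_allclose(ep.build_H_noia(I), np.eye(3), atol=1e-12)

    def test_epistatic_entries_are_squared_additive_up_to_scalar(self, random_panel):
        geno = random_panel(n=25, m=60, seed=10)
        G = ep.build_G_noia(
            ep.noia_additive_coefficients(geno, ep.genotype_frequencies(geno)))
        H = ep.build_H_noia(G)
        ratio = H.to_numpy() / (G.to_numpy() ** 2)
        assert (H.to_numpy() >= 0).all()
        assert np.allclose(ratio, ratio[0, 0])

    def test_positive_semidefinite(self, random_panel):
        geno = random_panel(n=30, m=50, seed=11)
        G = ep.build_G_noia(
            ep.noia_additive_coefficients(geno, ep.genotype_frequencies(geno)))
        H = ep.build_H_noia(G)
        assert np.linalg.eigvalsh(G.to_numpy()).min() >= -1e-8
        assert np.linalg.eigvalsh(H.to_numpy()).min() >= -1e-8

    def test_degenerate_panel_raises(self):
        geno = frame({"A": [1, 1, 1]})
        coeffs = ep.noia_additive_coefficients(geno, ep.genotype_frequencies(geno))
        with pytest.raises(DegeneratePanelError):
            ep.build_G_noia(coeffs)


class TestVanRadenEquivalence:
    def test_classic_scale_hand_example(self):
        geno = frame({"A": [0, 2]})
        G = ep.build_G_vanraden(geno)
        np.testing.assert_allclose(G, [[2, -2], [-2, 2]], atol=1e-12)
        Gn = ep.build_G_vanraden(geno, normalize_trace=True)
        np.testing.assert_allclose(Gn, [[1, -1], [-1, 1]], atol=1e-12)

    def test_monomorphic_panel_raises(self):
        with pytest.raises(DegeneratePanelError):
            ep.build_G_vanraden(frame({"A": [2.0, 2.0]}))

    @pytest.mark.parametrize("seed", range(50))
    def test_noia_equals_trace_normalized_vanraden(self, random_panel, seed):
        geno = random_panel(n=20, m=50, seed=seed)
        G_noia = ep.build_G_noia(
            ep.noia_additive_coefficients(geno, ep.genotype_frequencies(geno)))
        G_vr = ep.build_G_vanraden(geno, normalize_trace=True)
        np.testing.assert_allclose(G_noia.to_numpy(), G_vr.to_numpy(), atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_both_codings_match_independent_oracles(self, random_panel, seed):
        geno = random_panel(n=20, m=50, seed=100 + seed)
        vals = geno.to_numpy()
        G_noia = ep.build_G_noia(
            ep.noia_additive_coefficients(geno, ep.genotype_frequencies(geno)))
        np.testing.assert_allclose(G_noia.to_numpy(), reference_noia_G(vals),
                                   atol=1e-10)
        G_vr = ep.build_G_vanraden(geno, normalize_trace=True)
        np.testing.assert_allclose(G_vr.to_numpy(), reference_vanraden_G(vals),
                                   atol=1e-10)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000), flip_seed=st.integers(0, 10_000))
    def test_orientation_invariance(self, seed, flip_seed):
        """Flipping which allele is counted at any subset of markers leaves
        the NOIA relationship matrix unchanged."""
        from conftest import make_panel
        geno = make_panel(n=15, m=30, seed=seed)
        r = np.random.default_rng(flip_seed)
        flip = r.random(geno.shape[1]) < 0.5
        flipped = geno.copy()
        flipped.loc[:, flip] = 2.0 - flipped.loc[:, flip]
        G1 = ep.build_G_noia(
            ep.noia_additive_coefficients(geno, ep.genotype_frequencies(geno)))
        G2 = ep.build_G_noia(
            ep.noia_additive_coefficients(flipped, ep.genotype_frequencies(flipped)))
        np.testing.assert_allclose(G1.to_numpy(), G2.to_numpy(), atol=1e-10)


def test_relationship_matrix_tsv_roundtrip(tmp_path, random_panel):
    geno = random_panel(seed=12)
    G = ep.build_G_noia(
        ep.noia_additive_coefficients(geno, ep.genotype_frequencies(geno)))
    path = tmp_path / "G.tsv"
    ep.write_relationship_matrix(G, path)
    back = ep.read_relationship_matrix(path)
    np.testing.assert_allclose(back.to_numpy(), G.to_numpy(), atol=1e-12)
    assert list(back.index) == list(G.index)
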