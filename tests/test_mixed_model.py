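"""Spatial design, AI-REML estimation, and mixed-model-equation solutions."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import epinoia as ep
from epinoia.errors import ConvergenceError, IdMismatchError, InputError
from epinoia.mixed_model import ModelBundle, RandomTerm

from conftest import make_program


def grid_plots(nx, ny, trial="T1"):
    rows = [{"trial": trial, "x": x, "y": y, "line_id": f"L{x}{y}",
             "is_check": False, "yield_kg": 0.0}
            for x in range(1, nx + 1) for y in range(1, ny + 1)]
    return pd.DataFrame(rows)


def one_term_bundle(y, Z, K=None, levels=None, X=None, name="additive"):
    n = len(y)
    levels = levels if levels is not None else pd.RangeIndex(Z.shape[1])
    X = X if X is not None else np.ones((n, 1))
    return ModelBundle(
        spec=ep.ModelSpec("I+GA"), y=np.asarray(y, float), X=X,
        fixed_levels=pd.Index([f"b{i}" for i in range(X.shape[1])]),
        terms=[RandomTerm(name, sp.csr_matrix(Z), K, levels)],
        plots=None, spatial=None)


class TestSpatialDesign:
    def test_two_by_two_grid(self):
        design = ep.build_spatial_design(grid_plots(2, 2))
        assert design.n_positions == 16
        assert design.is_virtual.sum() == 12
        assert design.incidence.shape == (4, 9)
        for row in design.incidence:
            assert len(set(row)) == 9

    def test_single_plot_grid(self):
        design = ep.build_spatial_design(grid_plots(1, 1))
        assert design.n_positions == 9
        assert design.is_virtual.sum() == 8

    def test_adjacent_plots_share_six_positions(self):
        plots = grid_plots(3, 3)
        design = ep.build_spatial_design(plots)
        a = plots.index[(plots.x == 1) & (plots.y == 1)][0]
        b = plots.index[(plots.x == 1) & (plots.y == 2)][0]
        shared = set(design.incidence[a]) & set(design.incidence[b])
        assert len(shared) == 6

    def test_duplicate_coordinates_raise(self):
        plots = pd.concat([grid_plots(2, 2)] * 2, ignore_index=True)
        with pytest.raises(InputError, match="duplicate"):
            ep.build_spatial_design(plots)

    def test_virtual_positions_referenced_only_from_borders(self):
        plots = grid_plots(4, 5)
        design = ep.build_spatial_design(plots)
        border = ((plots.x.isin([1, 4])) | (plots.y.isin([1, 5]))).to_numpy()
        interior_refs = set(design.incidence[~border].ravel())
        assert not any(design.is_virtual[i] for i in interior_refs)

    def test_trials_do_not_share_positions(self):
        plots = pd.concat([grid_plots(2, 2, "T1"), grid_plots(2, 2, "T2")],
                          ignore_index=True)
        design = ep.build_spatial_design(plots)
        t1 = set(design.incidence[:4].ravel())
        t2 = set(design.incidence[4:].ravel())
        assert t1 & t2 == set()


class TestAssembly:
    def test_model_terms_follow_spec(self, demo_program, demo_matrices):
        G, H = demo_matrices
        bundle_I = ep.assemble_model(demo_program.plots, ep.ModelSpec("I"))
        assert [t.name for t in bundle_I.terms] == ["line", "gxe", "spatial"]
        bundle_AA = ep.assemble_model(demo_program.plots,
                                      ep.ModelSpec("I+GA+GAA"), G=G, H=H)
        assert [t.name for t in bundle_AA.terms] == \
            ["line", "additive", "epistatic", "gxe", "spatial"]

    def test_spatial_incidence_has_nine_entries_per_observation(self, demo_program):
        bundle = ep.assemble_model(demo_program.plots, ep.ModelSpec("I"))
        Z = bundle.term("spatial").Z
        assert Z.nnz == 9 * bundle.n_obs

    def test_missing_lines_in_G_are_reported(self, demo_program, demo_matrices):
        G, _ = demo_matrices
        truncated = G.iloc[:-3, :-3]
        dropped = set(G.index[-3:]) & set(demo_program.plots["line_id"])
        with pytest.raises(IdMismatchError) as err:
            ep.assemble_model(demo_program.plots, ep.ModelSpec("I+GA"), G=truncated)
        assert dropped <= set(err.value.missing)

    def test_checks_can_be_left_out_of_genomic_terms(self, demo_program, demo_matrices):
        G, _ = demo_matrices
        checks = demo_program.line_info.index[demo_program.line_info["is_check"]]
        no_checks = G.drop(index=checks, columns=checks)
        spec = ep.ModelSpec("I+GA", include_checks_in_genomic=False)
        bundle = ep.assemble_model(demo_program.plots, spec, G=no_checks)
        Z = bundle.term("additive").Z
        check_rows = bundle.plots["is_check"].to_numpy(bool)
        assert Z[check_rows].nnz == 0
        assert Z[~check_rows].nnz == (~check_rows).sum()


class TestAIReml:
    def test_matches_balanced_anova_closed_form(self):
        rng = np.random.default_rng(7)
        g, r = 10, 5
        y = np.repeat(rng.normal(0, 2, g), r) + rng.normal(0, 1, g * r)
        Z = sp.csr_matrix((np.ones(g * r),
                           (np.arange(g * r), np.repeat(np.arange(g), r))))
        vc = ep.ai_reml_estimate(one_term_bundle(y, Z, name="group"))
        gm = y.reshape(g, r).mean(axis=1)
        msb = r * ((gm - gm.mean()) ** 2).sum() / (g - 1)
        msw = ((y.reshape(g, r) - gm[:, None]) ** 2).sum() / (g * (r - 1))
        assert vc.sigma2["group"] == pytest.approx((msb - msw) / r, abs=1e-6)
        assert vc.sigma2["error"] == pytest.approx(msw, abs=1e-6)

    def test_pure_noise_leaves_no_structure_variance(self):
        res = make_program(seed=21, locations_per_year=3, blocks_per_trial=4,
                           lines_per_block=10, n_crosses=6, lines_per_cross=15)
        plots = res.plots.copy()
        rng = np.random.default_rng(3)
        plots["yield_kg"] = rng.normal(0.0, 1.0, len(plots))
        vc = ep.ai_reml_estimate(ep.assemble_model(plots, ep.ModelSpec("I")))
        # structure components collapse toward the floor; a residual of a few
        # percent of the noise variance is within REML sampling error
        assert vc.sigma2["line"] <= 0.02
        assert 9 * vc.sigma2["spatial"] <= 0.05
        assert vc.sigma2["error"] == pytest.approx(1.0, rel=0.1)

    def test_loglik_nondecreasing_over_accepted_iterations(self, demo_fit):
        lls = [step["loglik"] for step in demo_fit["vc"].trace]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_shift_in_y_changes_only_fixed_effects(self, demo_program, demo_matrices):
        G, _ = demo_matrices
        spec = ep.ModelSpec("I+GA")
        b1 = ep.assemble_model(demo_program.plots, spec, G=G)
        shifted = demo_program.plots.copy()
        shifted["yield_kg"] += 7.5
        b2 = ep.assemble_model(shifted, spec, G=G)
        vc1, vc2 = ep.ai_reml_estimate(b1), ep.ai_reml_estimate(b2)
        for name in vc1.sigma2:
            assert vc2.sigma2[name] == pytest.approx(vc1.sigma2[name],
                                                     rel=1e-8, abs=1e-12)
        s1, s2 = ep.solve_mme(b1, vc1), ep.solve_mme(b2, vc2)
        np.testing.assert_allclose(s2.fixed_effects - s1.fixed_effects, 7.5,
                                   atol=1e-6)

    def test_reports_se_and_sampling_correlations(self, demo_fit):
        vc = demo_fit["vc"]
        assert set(vc.se) == set(vc.sigma2)
        assert all(se >= 0 for se in vc.se.values())
        corr = vc.corr
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-12)

    def test_nonconvergence_carries_trace(self, demo_program):
        bundle = ep.assemble_model(demo_program.plots, ep.ModelSpec("I"))
        with pytest.raises(ConvergenceError) as err:
            ep.ai_reml_estimate(bundle, max_iter=2)
        assert len(err.value.trace) == 2


class TestSolveMME:
    def test_zero_additive_variance_gives_zero_gebv(self, demo_program, demo_matrices):
        G, _ = demo_matrices
        bundle = ep.assemble_model(demo_program.plots, ep.ModelSpec("I+GA"), G=G)
        vc = ep.VarianceComponents(model="I+GA", sigma2={
            "line": 0.1, "additive": 0.0, "gxe": 0.1, "spatial": 0.01,
            "error": 0.2})
        sol = ep.solve_mme(bundle, vc)
        assert (sol.gebv == 0.0).all()

    def test_single_record_identity_blup_shrinks_by_half(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 10)
        ids = pd.Index([f"L{i}" for i in range(10)])
        bundle = one_term_bundle(y, sp.identity(10), K=np.eye(10), levels=ids)
        vc = ep.VarianceComponents(model="I+GA",
                                   sigma2={"additive": 1.0, "error": 1.0})
        sol = ep.solve_mme(bundle, vc)
        np.testing.assert_allclose(sol.gebv, 0.5 * (y - y.mean()), atol=1e-8)

    def test_mme_agrees_with_gls_solver(self):
        # dual-route check: Henderson equations vs direct GLS/BLUP formulas
        rng = np.random.default_rng(5)
        n, q = 40, 12
        codes = rng.integers(0, q, n)
        Z = sp.csr_matrix((np.ones(n), (np.arange(n), codes)), shape=(n, q))
        Araw = rng.normal(size=(q, 2 * q))
        K = Araw @ Araw.T / (2 * q) + 0.5 * np.eye(q)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(0, 1, n)
        sg2, se2 = 0.7, 1.3
        bundle = one_term_bundle(y, Z, K=K, levels=pd.RangeIndex(q), X=X)
        vc = ep.VarianceComponents(model="I+GA",
                                   sigma2={"additive": sg2, "error": se2})
        sol = ep.solve_mme(bundle, vc)
        Zd = Z.toarray()
        V = sg2 * Zd @ K @ Zd.T + se2 * np.eye(n)
        Vinv = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
        u = sg2 * K @ Zd.T @ Vinv @ (y - X @ beta)
        np.testing.assert_allclose(sol.fixed_effects.to_numpy(), beta, atol=1e-6)
        np.testing.assert_allclose(sol.gebv.to_numpy(), u, atol=1e-6)


class TestNonorthogonalityReport:
    def test_identical_fits_report_zero_change(self):
        vc = ep.VarianceComponents.from_plot_totals(
            "I+GA", line=0.05, additive=0.05, spatial_total=0.04, gxe=0.1,
            error=0.06)
        vc2 = ep.VarianceComponents.from_plot_totals(
            "I+GA+GAA", line=0.05, additive=0.05, epistatic=0.01,
            spatial_total=0.04, gxe=0.1, error=0.06)
        report = ep.vc_nonorthogonality_report(vc, vc2)
        assert report["additive_relative_reduction"] == 0.0

    def test_tabulated_additive_reduction(self):
        # additive variance drops 0.051 -> 0.020 when epistasis enters:
        # a ~61% reduction on the rounded components (58.4% unrounded)
        fit_A = ep.VarianceComponents.from_plot_totals(
            "I+GA", line=0.053, additive=0.051, spatial_total=0.044,
            gxe=0.131, error=0.057)
        fit_AA = ep.VarianceComponents.from_plot_totals(
            "I+GA+GAA", line=0.014, additive=0.020, epistatic=0.064,
            spatial_total=0.044, gxe=0.131, error=0.057)
        report = ep.vc_nonorthogonality_report(fit_A, fit_AA)
        assert report["additive_relative_reduction"] == pytest.approx(0.608, abs=0.002)

    def test_collinear_terms_show_negative_sampling_correlation(
            self, demo_program, demo_matrices):
        # near-duplicate covariance structures compete for the same variance
        G, _ = demo_matrices
        H_dup = 0.999 * G + 0.001 * pd.DataFrame(
            np.eye(len(G)), index=G.index, columns=G.columns)
        bundle = ep.assemble_model(demo_program.plots, ep.ModelSpec("I+GA+GAA"),
                                   G=G, H=H_dup)
        vc = ep.ai_reml_estimate(bundle)
        assert vc.corr.loc["additive", "epistatic"] < -0.3
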