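"""Cross-validation of genomic predictions.

Two schemes:

* leave-one-line-out (LOO): every line's plots are masked in turn and its
  GEBV (and GEEV under the epistatic model) predicted from all other lines;
* leave-one-cycle-out (LSO): all phenotypes of one breeding cycle are masked
  and predicted from the remaining cycles — the scenario a breeder actually
  faces with new material.

Predictive ability (PA) is the Pearson correlation between the pooled partial
predictions and the fixed-effect-corrected line means. Under the default
variance-component policy the components are estimated once on the full data
and reused in every fold; the LOO folds are then solved exactly by low-rank
downdates (Woodbury identity) of the full-data mixed-model-equation
factorization, which is algebraically identical to re-solving the equations
with the line's rows removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import stats

from .errors import InputError, UndefinedStatisticError
from .mixed_model import (ModelBundle, ModelSpec, VarianceComponents,
                          ai_reml_estimate, assemble_model, build_mme,
                          solve_mme, MixedModelSolution)

logger = logging.getLogger(__name__)

__all__ = [
    "CorrectedLineMeans",
    "CVPredictions",
    "BootstrapComparison",
    "corrected_line_means",
    "run_loo_cv",
    "run_lso_cv",
    "predictive_ability",
    "bootstrap_compare",
    "relative_difference",
    "max_potential_pa",
]


# ---------------------------------------------------------------------------
# Corrected line means
# ---------------------------------------------------------------------------

@dataclass
class CorrectedLineMeans:
    """Per-line means of (phenotype - fitted fixed effect), and repetition counts."""

    means: pd.Series
    n_reps: pd.Series
    n_bar: float


def corrected_line_means(plots: pd.DataFrame, full_fit: MixedModelSolution,
                         include_checks: bool = False) -> CorrectedLineMeans:
    """Average each line's plot phenotypes after removing the fixed effects.

    The fixed effects must come from a fit on the complete phenotype data;
    the same corrected means serve as the validation target for every
    cross-validation fold.
    """
    sub = plots if include_checks else plots[~plots["is_check"].astype(bool)]
    if sub.empty:
        raise InputError("no candidate plots after excluding checks")
    fitted = full_fit.fitted_fixed(sub)
    corrected = sub["yield_kg"].to_numpy(dtype=float) - fitted.to_numpy(dtype=float)
    df = pd.DataFrame({"line_id": sub["line_id"].to_numpy(), "value": corrected})
    grouped = df.groupby("line_id")["value"]
    means = grouped.mean()
    n_reps = grouped.size().astype(float)
    return CorrectedLineMeans(means=means, n_reps=n_reps,
                              n_bar=float(n_reps.sum() / len(n_reps)))


# ---------------------------------------------------------------------------
# Cross-validation schemes
# ---------------------------------------------------------------------------

@dataclass
class CVPredictions:
    """Partial-information predictions, one row per validated line."""

    scheme: str
    model: str
    predictions: pd.DataFrame      # columns: gebv, geev, total
    n_folds: int
    vc: VarianceComponents | None = None
    failures: list = field(default_factory=list)


def _prediction_frame(rows: dict, model: str) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "line_id"
    if "geev" not in df.columns:
        df["geev"] = 0.0
    df["total"] = df["gebv"] + df["geev"]
    return df


def run_loo_cv(plots: pd.DataFrame, spec: ModelSpec,
               G: pd.DataFrame | None = None, H: pd.DataFrame | None = None,
               vc: VarianceComponents | None = None,
               vc_policy: str = "fixed",
               candidates: list[str] | None = None,
               reml_kwargs: dict | None = None) -> CVPredictions:
    """Leave-one-line-out cross-validation.

    With ``vc_policy='fixed'`` (default) the given variance components — or
    components estimated once on the full data — are reused in every fold and
    each fold is solved by an exact Woodbury downdate of the full-data MME.
    ``vc_policy='per_fold'`` re-estimates REML within every fold (expensive;
    intended for small data).
    """
    if vc_policy not in ("fixed", "per_fold"):
        raise InputError(f"unknown vc_policy {vc_policy!r}")
    if "additive" not in spec.random_terms:
        raise InputError("LOO cross-validation requires a genomic model")
    bundle = assemble_model(plots, spec, G=G, H=H)
    if candidates is None:
        mask = ~bundle.plots["is_check"].astype(bool)
        candidates = sorted(bundle.plots.loc[mask, "line_id"].unique())
    if len(candidates) < 3:
        raise InputError("LOO needs at least 3 candidate lines")
    if vc is None:
        vc = ai_reml_estimate(bundle, **(reml_kwargs or {}))

    rows: dict[str, dict] = {}
    failures: list[str] = []

    if vc_policy == "per_fold":
        for lid in candidates:
            keep = bundle.plots["line_id"] != lid
            sub = bundle.plots[keep]
            fold_bundle = assemble_model(sub, spec, G=G, H=H)
            fold_vc = ai_reml_estimate(fold_bundle, **(reml_kwargs or {}))
            sol = solve_mme(fold_bundle, fold_vc)
            rows[lid] = {"gebv": float(sol.gebv.get(lid, 0.0))}
            if sol.geev is not None:
                rows[lid]["geev"] = float(sol.geev.get(lid, 0.0))
        return CVPredictions("LOO", spec.model, _prediction_frame(rows, spec.model),
                             n_folds=len(candidates), vc=None, failures=failures)

    system = build_mme(bundle, vc)
    A = system.A.tocsr()
    sigma_e2 = system.sigma_e2
    line_ids = bundle.plots["line_id"].to_numpy()
    add_start, _ = system.offsets["additive"]
    add_levels = bundle.term("additive").levels
    if "epistatic" in system.offsets:
        epi_start, _ = system.offsets["epistatic"]
        epi_levels = bundle.term("epistatic").levels
    else:
        epi_start = None

    for lid in candidates:
        fold_rows = np.flatnonzero(line_ids == lid)
        assert fold_rows.size > 0 and (line_ids[fold_rows] == lid).all()
        Ai = A[fold_rows].toarray()                       # k x m
        yi = system.y[fold_rows]
        try:
            U = sla.cho_solve(system.chol, Ai.T, check_finite=False)   # m x k
            S = sigma_e2 * np.eye(fold_rows.size) - Ai @ U
            d = system.theta_hat - U @ (yi / sigma_e2)
            theta_i = d + U @ np.linalg.solve(S, Ai @ d)
        except np.linalg.LinAlgError:
            logger.warning("LOO fold for line %s is singular; skipped", lid)
            failures.append(lid)
            continue
        j = add_levels.get_loc(lid)
        rows[lid] = {"gebv": float(theta_i[add_start + j])}
        if epi_start is not None:
            rows[lid]["geev"] = float(theta_i[epi_start + epi_levels.get_loc(lid)])

    return CVPredictions("LOO", spec.model, _prediction_frame(rows, spec.model),
                         n_folds=len(candidates), vc=vc, failures=failures)


def run_lso_cv(plots: pd.DataFrame, spec: ModelSpec,
               G: pd.DataFrame | None = None, H: pd.DataFrame | None = None,
               vc: VarianceComponents | None = None,
               vc_policy: str = "fixed",
               reml_kwargs: dict | None = None) -> CVPredictions:
    """Leave-one-breeding-cycle-out cross-validation."""
    if vc_policy not in ("fixed", "per_fold"):
        raise InputError(f"unknown vc_policy {vc_policy!r}")
    if "additive" not in spec.random_terms:
        raise InputError("LSO cross-validation requires a genomic model")
    cycles = sorted(plots["cycle"].unique())
    if len(cycles) < 2:
        raise InputError("LSO needs at least 2 breeding cycles")
    if vc is None and vc_policy == "fixed":
        bundle = assemble_model(plots, spec, G=G, H=H)
        vc = ai_reml_estimate(bundle, **(reml_kwargs or {}))

    rows: dict[str, dict] = {}
    failures: list = []
    for cycle in cycles:
        train = plots[plots["cycle"] != cycle]
        held = plots[(plots["cycle"] == cycle) & (~plots["is_check"].astype(bool))]
        if train.empty:
            raise InputError(f"cycle {cycle!r} contains all observations; LSO undefined")
        fold_bundle = assemble_model(train, spec, G=G, H=H)
        fold_vc = vc if vc_policy == "fixed" else \
            ai_reml_estimate(fold_bundle, **(reml_kwargs or {}))
        sol = solve_mme(fold_bundle, fold_vc)
        for lid in sorted(held["line_id"].unique()):
            rows[lid] = {"gebv": float(sol.gebv.get(lid, np.nan))}
            if sol.geev is not None:
                rows[lid]["geev"] = float(sol.geev.get(lid, np.nan))
    return CVPredictions("LSO", spec.model, _prediction_frame(rows, spec.model),
                         n_folds=len(cycles), vc=vc, failures=failures)


# ---------------------------------------------------------------------------
# Predictive ability and model comparison
# ---------------------------------------------------------------------------

def predictive_ability(predictions: pd.Series, means: CorrectedLineMeans | pd.Series) -> float:
    """Pearson correlation between pooled predictions and corrected line means."""
    target = means.means if isinstance(means, CorrectedLineMeans) else means
    common = predictions.index.intersection(target.index)
    if len(common) < 3:
        raise InputError("predictive ability needs at least 3 aligned lines")
    a = predictions.loc[common].to_numpy(dtype=float)
    b = target.loc[common].to_numpy(dtype=float)
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise UndefinedStatisticError("zero variance; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class BootstrapComparison:
    """Paired nonparametric bootstrap contrast of two models' PA."""

    pa_a: float
    pa_b: float
    boot_mean_a: float
    boot_mean_b: float
    boot_se_a: float
    boot_se_b: float
    mean_difference: float
    t_statistic: float
    p_value: float
    n_boot: int
    n_redrawn: int
    alpha: float = 0.01

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("pa_a", "pa_b", "boot_mean_a", "boot_mean_b", "boot_se_a",
                 "boot_se_b", "mean_difference", "t_statistic", "p_value",
                 "n_boot", "n_redrawn", "alpha")} | {"significant": self.significant}


def bootstrap_compare(pred_a: pd.Series, pred_b: pd.Series,
                      means: CorrectedLineMeans | pd.Series,
                      n_boot: int = 10_000, seed: int = 0,
                      alpha: float = 0.01) -> BootstrapComparison:
    """Ordinary bootstrap with replacement at full sample size, paired across
    models (both PAs are computed on the same resampled lines), summarized by
    bootstrap SEs and a two-tailed paired t-test over the replicate PA pairs.
    """
    target = means.means if isinstance(means, CorrectedLineMeans) else means
    common = pred_a.index.intersection(pred_b.index).intersection(target.index)
    if len(common) < 3:
        raise InputError("bootstrap comparison needs at least 3 aligned lines")
    a = pred_a.loc[common].to_numpy(dtype=float)
    b = pred_b.loc[common].to_numpy(dtype=float)
    m = target.loc[common].to_numpy(dtype=float)
    n = len(common)
    rng = np.random.default_rng(seed)

    pas_a = np.empty(n_boot)
    pas_b = np.empty(n_boot)
    n_redrawn = 0
    for r in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            ar, br, mr = a[idx], b[idx], m[idx]
            if np.std(ar) > 0 and np.std(br) > 0 and np.std(mr) > 0:
                break
            n_redrawn += 1
        pas_a[r] = np.corrcoef(ar, mr)[0, 1]
        pas_b[r] = np.corrcoef(br, mr)[0, 1]

    diff = pas_a - pas_b
    if np.std(diff, ddof=1) == 0.0:
        t_stat, p_value = 0.0, 1.0
    else:
        t_stat, p_value = stats.ttest_rel(pas_a, pas_b)
    return BootstrapComparison(
        pa_a=float(np.corrcoef(a, m)[0, 1]), pa_b=float(np.corrcoef(b, m)[0, 1]),
        boot_mean_a=float(pas_a.mean()), boot_mean_b=float(pas_b.mean()),
        boot_se_a=float(pas_a.std(ddof=1)), boot_se_b=float(pas_b.std(ddof=1)),
        mean_difference=float(diff.mean()), t_statistic=float(t_stat),
        p_value=float(p_value), n_boot=n_boot, n_redrawn=n_redrawn, alpha=alpha)


def relative_difference(pa_aa: float, pa_a: float) -> float:
    """RD = (PA_epistatic - PA_additive) / PA_additive on unrounded PAs."""
    if pa_a == 0.0:
        raise UndefinedStatisticError("reference PA is zero; relative difference undefined")
    return (pa_aa - pa_a) / pa_a


def max_potential_pa(h2_like: float, n_bar: float) -> float:
    """Theoretical ceiling sqrt(n h^2 / (1 + (n-1) h^2)) for PA against means
    of n repeated plots; for total-merit predictions pass the additive plus
    epistatic variance proportion in place of h^2."""
    if not (0.0 <= h2_like <= 1.0):
        raise InputError(f"heritability-like proportion must be in [0, 1], got {h2_like}")
    if n_bar < 1.0:
        raise InputError(f"average repetitions must be >= 1, got {n_bar}")
    denom = 1.0 + (n_bar - 1.0) * h2_like
    return float(np.sqrt(n_bar * h2_like / denom)) if h2_like > 0 else 0.0
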