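"""Spatial mixed models with genomic covariance structures.

Implements the three plot-level models for inbred-line yield trials:

* ``I``          : y = Xb + Z l + Z f + sum_9 Z s + e   (identity covariances)
* ``I+GA``       : adds an additive genomic effect g ~ N(0, G sigma_g^2)
* ``I+GA+GAA``   : adds an additive-by-additive effect h ~ N(0, H sigma_h^2)

with b fixed trial effects (nested within year x location x cycle), l an
uncorrelated line effect, f the line-by-environment interaction, and s spatial
position effects: every plot is covered by the 9 positions of the 3x3 square
centered on it, with a one-deep ring of virtual border positions per trial so
border plots also have 9 covering positions.

Variance components are estimated by average-information REML on the
observation-level covariance V = sum_k sigma_k^2 Z_k K_k Z_k' + sigma_e^2 I,
with EM fallback steps whenever an AI update would leave the parameter space
or decrease the restricted likelihood, so accepted iterations are
non-decreasing in REML log-likelihood. BLUE/BLUP solutions come from the
mixed-model equations at the estimated components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from .errors import (ConvergenceError, IdMismatchError, InputError,
                     SingularSystemError)

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_TERMS",
    "SpatialDesign",
    "ModelSpec",
    "RandomTerm",
    "ModelBundle",
    "VarianceComponents",
    "MixedModelSolution",
    "build_spatial_design",
    "assemble_model",
    "ai_reml_estimate",
    "solve_mme",
    "vc_nonorthogonality_report",
]

#: Random terms per model (the residual "error" is always present).
MODEL_TERMS = {
    "I": ("line", "gxe", "spatial"),
    "I+GA": ("line", "additive", "gxe", "spatial"),
    "I+GA+GAA": ("line", "additive", "epistatic", "gxe", "spatial"),
}


# ---------------------------------------------------------------------------
# Spatial design
# ---------------------------------------------------------------------------

@dataclass
class SpatialDesign:
    """Position bookkeeping for the 9-plot spatial effect."""

    n_positions: int
    incidence: np.ndarray          # (n_obs, 9) int position indices
    is_virtual: np.ndarray         # (n_positions,) True if never observed
    positions: pd.DataFrame        # trial, x, y per position index

    def incidence_matrix(self) -> sp.csr_matrix:
        n_obs = self.incidence.shape[0]
        rows = np.repeat(np.arange(n_obs), 9)
        cols = self.incidence.ravel()
        data = np.ones(rows.size)
        return sp.csr_matrix((data, (rows, cols)), shape=(n_obs, self.n_positions))


def build_spatial_design(plots: pd.DataFrame) -> SpatialDesign:
    """Enumerate per-trial grid positions (real + virtual ring) and map each
    observation to the 9 positions of its 3x3 window."""
    required = {"trial", "x", "y"}
    if not required.issubset(plots.columns):
        raise InputError(f"plot table must contain columns {sorted(required)}")
    if plots.duplicated(subset=["trial", "x", "y"]).any():
        dup = plots[plots.duplicated(subset=["trial", "x", "y"], keep=False)]
        raise InputError(
            f"duplicate (trial, x, y) coordinates, e.g. {dup[['trial', 'x', 'y']].iloc[0].tolist()}")

    pos_records = []
    index_of: dict[tuple, int] = {}
    incidence = np.zeros((len(plots), 9), dtype=np.int64)
    observed: set[int] = set()

    for trial, sub in plots.groupby("trial", sort=True):
        xs, ys = sub["x"].astype(int), sub["y"].astype(int)
        x0, x1 = xs.min() - 1, xs.max() + 1
        y0, y1 = ys.min() - 1, ys.max() + 1
        for x in range(x0, x1 + 1):
            for y in range(y0, y1 + 1):
                index_of[(trial, x, y)] = len(pos_records)
                pos_records.append((trial, x, y))
        for row, x, y in zip(sub.index, xs, ys):
            k = 0
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    idx = index_of[(trial, x + dx, y + dy)]
                    incidence[plots.index.get_loc(row), k] = idx
                    k += 1
            observed.add(index_of[(trial, x, y)])

    n_pos = len(pos_records)
    is_virtual = np.ones(n_pos, dtype=bool)
    is_virtual[list(observed)] = False
    positions = pd.DataFrame(pos_records, columns=["trial", "x", "y"])
    return SpatialDesign(n_positions=n_pos, incidence=incidence,
                         is_virtual=is_virtual, positions=positions)


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Which model to fit and how check plots enter the genomic terms."""

    model: str = "I+GA"
    include_checks_in_genomic: bool = True

    def __post_init__(self):
        if self.model not in MODEL_TERMS:
            raise InputError(f"unknown model {self.model!r}; choose from {list(MODEL_TERMS)}")

    @property
    def random_terms(self) -> tuple[str, ...]:
        return MODEL_TERMS[self.model]


@dataclass
class RandomTerm:
    name: str
    Z: sp.csr_matrix
    K: np.ndarray | None          # None means identity
    levels: pd.Index

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    def ZKZt(self) -> np.ndarray:
        Zd = self.Z.toarray()
        if self.K is None:
            return Zd @ Zd.T
        return Zd @ self.K @ Zd.T


@dataclass
class ModelBundle:
    spec: ModelSpec
    y: np.ndarray
    X: np.ndarray
    fixed_levels: pd.Index
    terms: list[RandomTerm]
    plots: pd.DataFrame
    spatial: SpatialDesign

    @property
    def n_obs(self) -> int:
        return self.y.size

    def term(self, name: str) -> RandomTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _factor_matrix(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    n = codes.size
    keep = codes >= 0
    rows = np.arange(n)[keep]
    return sp.csr_matrix((np.ones(keep.sum()), (rows, codes[keep])),
                         shape=(n, n_levels))


def assemble_model(plots: pd.DataFrame, spec: ModelSpec,
                   G: pd.DataFrame | None = None,
                   H: pd.DataFrame | None = None) -> ModelBundle:
    """Build y, the fixed trial design, and all random-term incidences.

    Genomic terms require a relationship matrix covering every line in the
    plot table (checks may be exempted via the spec flag; their rows in the
    genomic incidence are then zero).
    """
    plots = plots.reset_index(drop=True).copy()
    if "env" not in plots.columns:
        plots["env"] = plots["year"].astype(str) + "_" + plots["location"].astype(str)
    if plots["yield_kg"].isna().any():
        raise InputError("plot table contains missing phenotypes; drop those rows first")
    y = plots["yield_kg"].to_numpy(dtype=float)

    trial_cat = pd.Categorical(plots["trial"])
    X = _factor_matrix(trial_cat.codes.astype(np.int64), len(trial_cat.categories)).toarray()
    fixed_levels = pd.Index(trial_cat.categories, name="trial")

    is_check = plots["is_check"].to_numpy(dtype=bool) if "is_check" in plots.columns \
        else np.zeros(len(plots), dtype=bool)

    terms: list[RandomTerm] = []
    for name in spec.random_terms:
        if name == "line":
            cat = pd.Categorical(plots["line_id"])
            Z = _factor_matrix(cat.codes.astype(np.int64), len(cat.categories))
            terms.append(RandomTerm("line", Z, None, pd.Index(cat.categories)))
        elif name in ("additive", "epistatic"):
            M = G if name == "additive" else H
            if M is None:
                raise InputError(f"model {spec.model} requires a matrix for the {name} term")
            levels = pd.Index(M.index.astype(str))
            line_ids = plots["line_id"].astype(str)
            mask = ~is_check if not spec.include_checks_in_genomic else np.ones(len(plots), bool)
            missing = sorted(set(line_ids[mask]) - set(levels))
            if missing:
                raise IdMismatchError(
                    f"{len(missing)} line(s) in plots absent from the {name} matrix, "
                    f"e.g. {missing[:5]}", missing=missing)
            codes = levels.get_indexer(line_ids)
            codes[~mask] = -1
            Z = _factor_matrix(codes, len(levels))
            K = M.to_numpy(dtype=float)
            terms.append(RandomTerm(name, Z, K, levels))
        elif name == "gxe":
            combo = plots["line_id"].astype(str) + "|" + plots["env"].astype(str)
            cat = pd.Categorical(combo)
            Z = _factor_matrix(cat.codes.astype(np.int64), len(cat.categories))
            terms.append(RandomTerm("gxe", Z, None, pd.Index(cat.categories)))
        elif name == "spatial":
            spatial = build_spatial_design(plots)
            terms.append(RandomTerm("spatial", spatial.incidence_matrix(), None,
                                    pd.RangeIndex(spatial.n_positions)))
        else:  # pragma: no cover
            raise InputError(f"unknown random term {name!r}")

    return ModelBundle(spec=spec, y=y, X=X, fixed_levels=fixed_levels,
                       terms=terms, plots=plots,
                       spatial=spatial if "spatial" in spec.random_terms else None)


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """REML estimates on the plot scale (kg^2 / plot^2).

    ``sigma2['spatial']`` is the per-position variance; the plot-level spatial
    contribution to phenotypic variance is nine times it
    (``spatial_plot_total``).
    """

    model: str
    sigma2: dict[str, float]
    se: dict[str, float] | None = None
    corr: pd.DataFrame | None = None
    loglik: float | None = None
    n_iter: int = 0
    converged: bool = True
    final_update_norm: float = 0.0
    floored: list[str] = field(default_factory=list)
    trace: list[dict] = field(default_factory=list)

    @property
    def spatial_plot_total(self) -> float:
        return 9.0 * self.sigma2.get("spatial", 0.0)

    def __getitem__(self, name: str) -> float:
        return self.sigma2[name]

    @classmethod
    def from_plot_totals(cls, model: str, *, line: float | None = None,
                         additive: float | None = None,
                         epistatic: float | None = None,
                         spatial_total: float | None = None,
                         gxe: float | None = None,
                         error: float | None = None,
                         se: dict | None = None) -> "VarianceComponents":
        """Build from tabulated plot-level totals (spatial given as the
        9-plot total, as printed in variance-component tables)."""
        sigma2 = {}
        for name, value in (("line", line), ("additive", additive),
                            ("epistatic", epistatic), ("gxe", gxe), ("error", error)):
            if value is not None:
                sigma2[name] = float(value)
        if spatial_total is not None:
            sigma2["spatial"] = float(spatial_total) / 9.0
        return cls(model=model, sigma2=sigma2, se=se)

    def to_dict(self) -> dict:
        out = {"model": self.model, "sigma2": dict(self.sigma2),
               "spatial_plot_total": self.spatial_plot_total,
               "loglik": self.loglik, "n_iter": self.n_iter,
               "converged": self.converged, "floored": list(self.floored)}
        if self.se is not None:
            out["se"] = dict(self.se)
        if self.corr is not None:
            out["sampling_correlations"] = self.corr.round(10).to_dict()
        return out


def _reml_loglik(theta: np.ndarray, Vks: list[np.ndarray], y: np.ndarray,
                 X: np.ndarray) -> float:
    n = y.size
    V = theta[-1] * np.eye(n)
    for t, Vk in zip(theta[:-1], Vks):
        V += t * Vk
    c, low = sla.cho_factor(V, lower=True, check_finite=False)
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv_y = sla.cho_solve((c, low), y, check_finite=False)
    Vinv_X = sla.cho_solve((c, low), X, check_finite=False)
    XtVinvX = X.T @ Vinv_X
    sign, logdetXVX = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        raise SingularSystemError("X'V^-1 X is singular; fixed part is rank deficient")
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
    yPy = y @ Vinv_y - (X.T @ Vinv_y) @ beta
    return -0.5 * (logdetV + logdetXVX + yPy)


def ai_reml_estimate(bundle: ModelBundle,
                     start: dict[str, float] | None = None,
                     max_iter: int = 100,
                     tol: float = 1e-8,
                     floor_frac: float = 1e-8,
                     compute_se: bool = True) -> VarianceComponents:
    """Average-information REML with EM fallback.

    Starting values split the phenotypic variance equally across all
    components unless ``start`` is given. AI (Newton) updates are proposed
    first; whenever a proposal leaves the parameter space or would decrease
    the restricted log-likelihood, a guaranteed-ascent EM step is taken
    instead (with step-halving as a last resort against round-off). Estimates
    are clamped at a variance floor of ``floor_frac`` times the phenotypic
    variance. Standard errors and sampling correlations of the estimates come
    from the inverse average-information matrix at convergence.
    """
    y, X = bundle.y, bundle.X
    n, p = y.size, X.shape[1]
    names = [t.name for t in bundle.terms] + ["error"]
    K = len(names)
    if n <= p + K:
        raise InputError(
            f"{n} observations cannot identify {p} fixed effects plus {K} variance components")

    Vks = [t.ZKZt() for t in bundle.terms]
    qs = np.array([t.q for t in bundle.terms] + [n], dtype=float)

    vary = float(np.var(y, ddof=1))
    floor = floor_frac * vary
    if start is None:
        theta = np.full(K, vary / K)
    else:
        theta = np.array([max(start.get(nm, vary / K), floor) for nm in names])

    def aux(theta):
        """Full P-based quantities at theta."""
        V = theta[-1] * np.eye(n)
        for t, Vk in zip(theta[:-1], Vks):
            V += t * Vk
        c, low = sla.cho_factor(V, lower=True, check_finite=False)
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        Vinv = sla.cho_solve((c, low), np.eye(n), check_finite=False)
        VinvX = Vinv @ X
        XtVinvX = X.T @ VinvX
        sign, logdetXVX = np.linalg.slogdet(XtVinvX)
        if sign <= 0:
            raise SingularSystemError("X'V^-1 X is singular; fixed part is rank deficient")
        P = Vinv - VinvX @ np.linalg.solve(XtVinvX, VinvX.T)
        P = (P + P.T) / 2.0
        Py = P @ y
        ll = -0.5 * (logdetV + logdetXVX + y @ Py)
        return P, Py, ll

    P, Py, ll = aux(theta)
    trace = []
    converged = False
    update_norm = np.inf

    for it in range(1, max_iter + 1):
        T = np.empty((n, K))
        trPV = np.empty(K)
        for k, Vk in enumerate(Vks):
            T[:, k] = Vk @ Py
            trPV[k] = np.sum(P * Vk)
        T[:, -1] = Py
        trPV[-1] = np.trace(P)
        yPVPy = Py @ T                      # y' P V_k P y per component
        score = -0.5 * (trPV - yPVPy)
        AI = 0.5 * (T.T @ P @ T)
        AI = (AI + AI.T) / 2.0

        step_kind = "AI"
        theta_new = None
        # Newton step in the AI metric, solved in the subspace of components
        # not pinned at the floor with an outward gradient; the step is
        # clipped at the floor and damped until it ascends. Clipped
        # components are free to re-enter on later iterations.
        pinned = (theta <= floor * (1 + 1e-9)) & (score < 0)
        free = ~pinned
        try:
            if free.any():
                delta = np.zeros(K)
                delta[free] = np.linalg.solve(AI[np.ix_(free, free)], score[free])
                for damp in (1.0, 0.5, 0.25, 0.1):
                    cand = np.maximum(theta + damp * delta, floor)
                    cand[pinned] = floor
                    ll_cand = _reml_loglik(cand, Vks, y, X)
                    if np.isfinite(ll_cand) and ll_cand >= ll - 1e-10:
                        theta_new, ll_new = cand, ll_cand
                        break
        except np.linalg.LinAlgError:
            pass

        if theta_new is None:
            step_kind = "EM"
            logger.debug("iteration %d: AI update rejected, taking EM step", it)
            cand = np.maximum(theta + theta ** 2 * (yPVPy - trPV) / qs, floor)
            ll_cand = _reml_loglik(cand, Vks, y, X)
            halvings = 0
            while (not np.isfinite(ll_cand) or ll_cand < ll - 1e-10) and halvings < 20:
                cand = (cand + theta) / 2.0
                ll_cand = _reml_loglik(cand, Vks, y, X)
                halvings += 1
            if not np.isfinite(ll_cand) or ll_cand < ll - 1e-10:
                raise ConvergenceError(
                    f"no ascent step found at iteration {it}", trace=trace)
            theta_new, ll_new = cand, ll_cand

        update_norm = float(np.max(np.abs(theta_new - theta) / np.maximum(theta, floor)))
        ll_change = abs(ll_new - ll) / (1.0 + abs(ll))
        trace.append({"iteration": it, "loglik": float(ll_new), "step": step_kind,
                      "theta": {nm: float(v) for nm, v in zip(names, theta_new)},
                      "update_norm": update_norm})
        theta = theta_new
        P, Py, ll = aux(theta)  # refresh at accepted point
        if update_norm < tol and ll_change < 1e-10:
            converged = True
            break

    if not converged:
        raise ConvergenceError(
            f"AI-REML did not converge in {max_iter} iterations "
            f"(last update norm {update_norm:.3g})", trace=trace)

    floored = [nm for nm, v in zip(names, theta) if v <= floor * (1 + 1e-12)]

    se = corr = None
    if compute_se:
        T = np.empty((n, K))
        for k, Vk in enumerate(Vks):
            T[:, k] = Vk @ Py
        T[:, -1] = Py
        AI = 0.5 * (T.T @ P @ T)
        AI = (AI + AI.T) / 2.0
        try:
            cov = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            raise SingularSystemError(
                "average-information matrix is singular at the optimum; "
                "consider simplifying the model") from None
        d = np.sqrt(np.maximum(np.diag(cov), 0.0))
        se = {nm: float(v) for nm, v in zip(names, d)}
        with np.errstate(divide="ignore", invalid="ignore"):
            cm = cov / np.outer(d, d)
        np.fill_diagonal(cm, 1.0)
        corr = pd.DataFrame(cm, index=names, columns=names)

    return VarianceComponents(
        model=bundle.spec.model,
        sigma2={nm: float(v) for nm, v in zip(names, theta)},
        se=se, corr=corr, loglik=float(ll), n_iter=len(trace),
        converged=converged, final_update_norm=update_norm,
        floored=floored, trace=trace)


# ---------------------------------------------------------------------------
# Mixed-model equations
# ---------------------------------------------------------------------------

def _psd_inverse(K: np.ndarray, what: str, rel_eps: float = 1e-8) -> np.ndarray:
    """Invert a covariance matrix, clipping near-null eigenvalues.

    Relationship matrices from finite marker panels are often numerically
    rank deficient; eigenvalues below ``rel_eps`` times the largest are
    clipped before inversion, which heavily shrinks the corresponding
    directions while keeping the result positive definite.
    """
    w, V = np.linalg.eigh((K + K.T) / 2.0)
    eps = rel_eps * w[-1]
    if w[-1] <= 0:
        raise SingularSystemError(f"{what} has no positive eigenvalue")
    n_clipped = int((w < eps).sum())
    if n_clipped:
        logger.debug("%s: clipped %d near-null eigenvalue(s)", what, n_clipped)
    w = np.maximum(w, eps)
    return (V / w) @ V.T


@dataclass
class MMESystem:
    """Factorized Henderson mixed-model equations (reused by cross-validation)."""

    A: sp.csr_matrix               # [X  Z_1 ... Z_k], observation rows
    chol: tuple                    # cho_factor of the coefficient matrix
    theta_hat: np.ndarray          # full solution vector
    offsets: dict[str, tuple[int, int]]   # block name -> (start, stop)
    y: np.ndarray
    sigma_e2: float
    active_terms: list[str]

    def block(self, name: str) -> np.ndarray:
        start, stop = self.offsets[name]
        return self.theta_hat[start:stop]


@dataclass
class MixedModelSolution:
    """BLUEs and BLUPs at given variance components."""

    fixed_effects: pd.Series
    random_effects: dict[str, pd.Series]
    vc: VarianceComponents
    system: MMESystem | None = None

    @property
    def gebv(self) -> pd.Series | None:
        return self.random_effects.get("additive")

    @property
    def geev(self) -> pd.Series | None:
        return self.random_effects.get("epistatic")

    def fitted_fixed(self, plots: pd.DataFrame) -> pd.Series:
        """Fitted fixed effect x'b for each plot row."""
        return plots["trial"].map(self.fixed_effects).astype(float)


def build_mme(bundle: ModelBundle, vc: VarianceComponents) -> MMESystem:
    """Assemble and factorize Henderson's mixed-model equations.

    Terms with exactly zero variance are excluded (their predictions are
    zero by infinite shrinkage).
    """
    sigma_e2 = vc.sigma2.get("error")
    if sigma_e2 is None or sigma_e2 <= 0:
        raise InputError("error variance must be positive to solve the MME")
    active = [t for t in bundle.terms if vc.sigma2.get(t.name, 0.0) > 0.0]

    blocks = [sp.csr_matrix(bundle.X)] + [t.Z for t in active]
    A = sp.hstack(blocks, format="csr")
    C = (A.T @ A).toarray() / sigma_e2
    offsets = {}
    pos = bundle.X.shape[1]
    offsets["fixed"] = (0, pos)
    for t in active:
        offsets[t.name] = (pos, pos + t.q)
        lam = 1.0 / vc.sigma2[t.name]
        if t.K is None:
            C[pos:pos + t.q, pos:pos + t.q] += lam * np.eye(t.q)
        else:
            C[pos:pos + t.q, pos:pos + t.q] += lam * _psd_inverse(t.K, f"{t.name} covariance")
        pos += t.q
    r = (A.T @ bundle.y) / sigma_e2
    try:
        chol = sla.cho_factor(C, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise SingularSystemError(f"mixed-model equations are singular: {exc}") from None
    theta_hat = sla.cho_solve(chol, r, check_finite=False)
    return MMESystem(A=A, chol=chol, theta_hat=theta_hat, offsets=offsets,
                     y=bundle.y, sigma_e2=sigma_e2,
                     active_terms=[t.name for t in active])


def solve_mme(bundle: ModelBundle, vc: VarianceComponents,
              keep_system: bool = False) -> MixedModelSolution:
    """Solve the MME at the given variance components and label the solutions."""
    system = build_mme(bundle, vc)
    fixed = pd.Series(system.block("fixed"), index=bundle.fixed_levels, name="blue")
    random: dict[str, pd.Series] = {}
    for t in bundle.terms:
        if t.name in system.offsets:
            random[t.name] = pd.Series(system.block(t.name), index=t.levels, name=t.name)
        else:
            random[t.name] = pd.Series(np.zeros(t.q), index=t.levels, name=t.name)
    return MixedModelSolution(fixed_effects=fixed, random_effects=random, vc=vc,
                              system=system if keep_system else None)


def vc_nonorthogonality_report(fit_A: VarianceComponents,
                               fit_AA: VarianceComponents) -> dict:
    """Describe how the additive variance moves when epistasis enters the model.

    A large drop in the additive estimate, together with a negative sampling
    correlation between the additive and epistatic estimates, signals a
    non-orthogonal partition of genetic variance.
    """
    for fit, need in ((fit_A, "additive"), (fit_AA, "epistatic")):
        if need not in fit.sigma2:
            raise InputError(f"fit of model {fit.model!r} lacks the {need!r} component")
    g_A = fit_A.sigma2["additive"]
    g_AA = fit_AA.sigma2["additive"]
    report = {
        "additive_change": g_AA - g_A,
        "additive_relative_reduction": (1.0 - g_AA / g_A) if g_A != 0 else np.nan,
    }
    if fit_AA.corr is not None:
        report["additive_epistatic_correlation"] = float(
            fit_AA.corr.loc["additive", "epistatic"])
        report["line_epistatic_correlation"] = float(
            fit_AA.corr.loc["line", "epistatic"])
    if fit_A.corr is not None:
        report["line_additive_correlation"] = float(
            fit_A.corr.loc["line", "additive"])
    return report
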