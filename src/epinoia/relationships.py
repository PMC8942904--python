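"""Marker QC and genomic relationship matrices.

Builds the NOIA additive relationship matrix G (trace-normalized cross-product
of the frequency-centered additive coefficient matrix), its Hadamard-square
epistatic counterpart H, and the classic VanRaden matrix used for the
EG-BLUP equivalence check.

Notes on the coding
-------------------
Allele counts tally the second ("a") allele: AA = 0, Aa = 1, aa = 2. The NOIA
additive coefficient for a line with allele count x at a marker is

    coef(x) = (p_Aa + 2 p_aa) - x,

i.e. the negated deviation of the count from its observed mean, so every
column of the coefficient matrix sums to zero. (Some presentations print the
homozygote coefficient with the inner sign flipped, which does not center the
column; the centered form is the one that makes trace normalization behave and
reproduces the VanRaden identity.) Genotypic frequencies are counted on hard
calls {0, 1, 2}; the coefficient map is affine in x, so applying it to
fractional mean-imputed counts is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegeneratePanelError, EmptyPanelError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "QCReport",
    "qc_filter",
    "impute_missing_mean",
    "genotype_frequencies",
    "noia_additive_coefficients",
    "build_G_noia",
    "build_H_noia",
    "build_G_vanraden",
    "read_genotypes",
    "write_relationship_matrix",
    "read_relationship_matrix",
]


@dataclass
class QCReport:
    """Markers removed by quality control and why."""

    n_input: int
    n_retained: int
    removed: pd.DataFrame = field(default_factory=pd.DataFrame)  # marker, reason, value


def _check_genotypes(genotypes: pd.DataFrame) -> None:
    if genotypes.shape[0] < 1 or genotypes.shape[1] < 1:
        raise InputError("genotype matrix must have at least one line and one marker")
    if genotypes.index.has_duplicates or genotypes.columns.has_duplicates:
        raise InputError("line and marker ids must be unique")
    vals = genotypes.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (vals < 0) | (vals > 2)
    if np.nansum(bad):
        raise InputError("genotype entries must lie in [0, 2] or be missing")


def qc_filter(genotypes: pd.DataFrame, maf_min: float = 0.05,
              call_rate_min: float = 0.90) -> tuple[pd.DataFrame, QCReport]:
    """Remove markers with MAF < ``maf_min`` or call rate < ``call_rate_min``.

    Both thresholds are strict, so boundary markers (MAF exactly 0.05, call
    rate exactly 0.90) are retained. MAF is computed from observed calls only.
    """
    _check_genotypes(genotypes)
    vals = genotypes.to_numpy(dtype=float)
    observed = ~np.isnan(vals)
    call_rate = observed.mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(vals, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)

    removed = []
    for j, marker in enumerate(genotypes.columns):
        if call_rate[j] < call_rate_min:
            removed.append((marker, "call_rate", call_rate[j]))
        elif maf[j] < maf_min:
            removed.append((marker, "maf", maf[j]))
    removed_df = pd.DataFrame(removed, columns=["marker", "reason", "value"])
    keep = genotypes.columns.difference(removed_df["marker"], sort=False)
    out = genotypes[keep]
    if out.shape[1] == 0:
        raise EmptyPanelError(
            f"quality control removed all {genotypes.shape[1]} markers; "
            "relationship matrices are undefined")
    report = QCReport(n_input=genotypes.shape[1], n_retained=out.shape[1],
                      removed=removed_df)
    return out, report


def impute_missing_mean(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Replace each missing call by its marker's mean observed allele count."""
    _check_genotypes(genotypes)
    vals = genotypes.to_numpy(dtype=float)
    if np.isnan(vals).all(axis=0).any():
        fully = genotypes.columns[np.isnan(vals).all(axis=0)]
        raise InputError(
            f"marker(s) with no observed calls: {list(fully[:5])}; "
            "run qc_filter before imputation")
    if not np.isnan(vals).any():
        return genotypes.copy()
    col_means = np.nanmean(vals, axis=0)
    filled = np.where(np.isnan(vals), col_means[None, :], vals)
    return pd.DataFrame(filled, index=genotypes.index, columns=genotypes.columns)


def genotype_frequencies(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-marker proportions of hard calls {0, 1, 2} among observed calls.

    Fractional (imputed) entries are excluded from the counting. Returns a
    DataFrame indexed by marker with columns ``p_AA``, ``p_Aa``, ``p_aa``.
    """
    _check_genotypes(genotypes)
    vals = genotypes.to_numpy(dtype=float)
    counts = np.zeros((genotypes.shape[1], 3))
    for g, col in zip((0.0, 1.0, 2.0), range(3)):
        counts[:, col] = (vals == g).sum(axis=0)
    total = counts.sum(axis=1)
    if (total == 0).any():
        bad = genotypes.columns[total == 0]
        raise InputError(f"marker(s) with zero hard calls: {list(bad[:5])}")
    freqs = counts / total[:, None]
    return pd.DataFrame(freqs, index=genotypes.columns,
                        columns=["p_AA", "p_Aa", "p_aa"])


def noia_additive_coefficients(genotypes: pd.DataFrame,
                               freqs: pd.DataFrame) -> pd.DataFrame:
    """NOIA additive coefficient matrix H_a: coef = (p_Aa + 2 p_aa) - x."""
    if not genotypes.columns.equals(freqs.index):
        raise InputError("genotypes and frequencies cover different markers")
    vals = genotypes.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise InputError("impute missing genotypes before computing coefficients")
    mean_count = (freqs["p_Aa"] + 2.0 * freqs["p_aa"]).to_numpy()
    coeffs = mean_count[None, :] - vals
    return pd.DataFrame(coeffs, index=genotypes.index, columns=genotypes.columns)


def _trace_normalize(M: np.ndarray, what: str) -> np.ndarray:
    n = M.shape[0]
    denom = np.trace(M) / n
    if denom <= 0.0:
        raise DegeneratePanelError(
            f"{what} has zero trace: the marker panel carries no variation")
    return M / denom


def build_G_noia(coeffs: pd.DataFrame) -> pd.DataFrame:
    """G = H_a H_a' / (tr(H_a H_a') / n); mean diagonal exactly one."""
    Ha = coeffs.to_numpy(dtype=float)
    M = Ha @ Ha.T
    G = _trace_normalize(M, "H_a H_a'")
    G = (G + G.T) / 2.0
    return pd.DataFrame(G, index=coeffs.index, columns=coeffs.index)


def build_H_noia(G: pd.DataFrame) -> pd.DataFrame:
    """Epistatic matrix H = (G .* G) / (tr(G .* G) / n)."""
    vals = G.to_numpy(dtype=float)
    if vals.shape[0] != vals.shape[1]:
        raise InputError("relationship matrix must be square")
    M = vals * vals
    H = _trace_normalize(M, "G .* G")
    H = (H + H.T) / 2.0
    return pd.DataFrame(H, index=G.index, columns=G.columns)


def build_G_vanraden(genotypes: pd.DataFrame,
                     normalize_trace: bool = False) -> pd.DataFrame:
    """VanRaden genomic relationship matrix.

    Allele counts are centered by twice the allele frequency; the
    cross-product is scaled by 2 sum p(1-p) (classic scale) or
    trace-normalized when ``normalize_trace`` is set.
    """
    vals = genotypes.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise InputError("impute missing genotypes before building G")
    p = vals.mean(axis=0) / 2.0
    W = vals - 2.0 * p[None, :]
    M = W @ W.T
    if normalize_trace:
        G = _trace_normalize(M, "W W'")
    else:
        denom = 2.0 * np.sum(p * (1.0 - p))
        if denom <= 0.0:
            raise DegeneratePanelError("all markers are monomorphic; VanRaden scale undefined")
        G = M / denom
    G = (G + G.T) / 2.0
    return pd.DataFrame(G, index=genotypes.index, columns=genotypes.index)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a lines x markers CSV/TSV with 0/1/2/NA entries."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)


def write_relationship_matrix(G: pd.DataFrame, path: str | Path) -> None:
    G.to_csv(path, sep="\t", index_label="line_id")


def read_relationship_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df
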