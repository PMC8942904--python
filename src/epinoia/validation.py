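"""LR-method validation of genomic predictions and between-model agreement.

The LR method contrasts predictions computed with "whole" information (a fit
on the complete phenotype data) against "partial" predictions (from a
cross-validation where each line's — or cycle's — own phenotypes were
masked):

* bias       mu_wp = mean(u_hat_partial) - mean(u_hat_whole), expectation 0
  for unbiased prediction;
* dispersion b_wp = cov(u_hat_whole, u_hat_partial) / var(u_hat_partial),
  the slope of the regression of whole on partial, expectation 1 when
  predictions are neither under- nor over-dispersed (b_wp < 1 flags
  inflation of the partial predictions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedStatisticError

__all__ = ["LRStatistics", "lr_bias", "lr_dispersion", "lr_statistics",
           "prediction_agreement"]


def _aligned(whole: pd.Series, partial: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    common = whole.index.intersection(partial.index)
    if len(common) == 0:
        raise InputError("whole and partial predictions share no line ids")
    return (whole.loc[common].to_numpy(dtype=float),
            partial.loc[common].to_numpy(dtype=float))


def lr_bias(whole: pd.Series, partial: pd.Series) -> float:
    """mu_wp = mean(partial) - mean(whole), in prediction units."""
    w, p = _aligned(whole, partial)
    return float(p.mean() - w.mean())


def lr_dispersion(whole: pd.Series, partial: pd.Series) -> float:
    """b_wp = cov(whole, partial) / var(partial)."""
    w, p = _aligned(whole, partial)
    var_p = p.var(ddof=1)
    if var_p == 0.0:
        raise UndefinedStatisticError("partial predictions have zero variance; b_wp undefined")
    cov = np.cov(w, p, ddof=1)[0, 1]
    return float(cov / var_p)


@dataclass
class LRStatistics:
    mu_wp: float
    b_wp: float
    prediction_type: str = ""
    scheme: str = ""

    def to_dict(self) -> dict:
        return {"mu_wp": self.mu_wp, "b_wp": self.b_wp,
                "prediction_type": self.prediction_type, "scheme": self.scheme}


def lr_statistics(whole: pd.Series, partial: pd.Series,
                  prediction_type: str = "", scheme: str = "") -> LRStatistics:
    return LRStatistics(mu_wp=lr_bias(whole, partial),
                        b_wp=lr_dispersion(whole, partial),
                        prediction_type=prediction_type, scheme=scheme)


def prediction_agreement(pred_x: pd.Series, pred_y: pd.Series,
                         k: int = 10) -> tuple[float | None, int]:
    """Pearson correlation of two prediction vectors plus top-k overlap.

    The overlap counts lines common to both vectors' top-k rankings; it is
    returned even when the correlation is undefined (zero variance).
    """
    common = pred_x.index.intersection(pred_y.index)
    if len(common) == 0:
        raise InputError("prediction vectors share no line ids")
    if k > len(common):
        raise InputError(f"k = {k} exceeds the {len(common)} shared lines")
    x = pred_x.loc[common]
    y = pred_y.loc[common]
    top_x = set(x.sort_values(ascending=False).index[:k])
    top_y = set(y.sort_values(ascending=False).index[:k])
    overlap = len(top_x & top_y)
    if x.std(ddof=0) == 0.0 or y.std(ddof=0) == 0.0:
        return None, overlap
    corr = float(np.corrcoef(x.to_numpy(float), y.to_numpy(float))[0, 1])
    return corr, overlap
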