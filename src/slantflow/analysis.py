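"""Results-level computations: sqrt(def) regressions and model diagnostics.

The central empirical claim being tested is that perceived slant-tangent is
proportional to sqrt(def) with no dependence on head-translation velocity
beyond the one def itself carries.  Three computations capture it:

* a no-intercept regression of response on sqrt(def) (the condition slope k);
* a velocity-effect test — does a regime indicator improve on sqrt(def)
  alone? — with a subject-level permutation p-value;
* an observed-vs-predicted regression of responses on ``k*sqrt(def)``
  (slope ~ 1, intercept ~ 0 when the square-root law holds).

Inference here is fixed-effects regression plus permutation tests rather
than mixed-effects MCMC: the scientific contrasts (the sqrt(def) slope and
the regime effect) are preserved while keeping the pipeline self-contained.
Goodness of fit is a model-concordance (agreement) coefficient rather than
a classical R^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bayes_core import closed_form_retinal_estimate

__all__ = [
    "RegressionResult",
    "no_intercept_slope",
    "agreement_statistic",
    "velocity_effect_test",
    "observed_vs_predicted",
]


@dataclass(frozen=True)
class RegressionResult:
    """Container for the regression outputs reported by this module."""

    slope: float
    intercept: Optional[float] = None
    slope_stderr: Optional[float] = None
    regime_coef: Optional[float] = None
    agreement_r2: Optional[float] = None
    p_value: Optional[float] = None
    conf_int: Optional[tuple] = None
    n: int = 0

    def to_dict(self) -> dict:
        return {
            k: v
            for k, v in self.__dict__.items()
            if v is not None
        }


def agreement_statistic(observed, predicted) -> float:
    """Model-concordance coefficient between observations and predictions.

    Implemented as::

        1 - sum((o - p)**2) / (sum((o - m)**2) + sum((p - m)**2))

    where ``m`` is the grand mean of both vectors pooled (their shared
    mean).  Equals 1 iff observed == predicted; drops to <= 0 when the
    predictions do no better than that shared mean; and is invariant under
    a common affine change applied to both vectors.  This is a concordance-
    type agreement measure, not a classical proportion of variance
    explained.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1 or len(o) < 2:
        raise ValueError("observed and predicted must be equal-length vectors (n >= 2)")
    m = np.mean(np.concatenate([o, p]))
    denom = np.sum((o - m) ** 2) + np.sum((p - m) ** 2)
    if denom == 0:
        raise ValueError("agreement undefined: all values identical")
    return float(1.0 - np.sum((o - p) ** 2) / denom)


def no_intercept_slope(response_tan, sqrt_def) -> RegressionResult:
    """Least-squares slope of response on sqrt(def) through the origin.

    slope = sum(x*y) / sum(x*x); the attached agreement statistic compares
    responses with the fitted values.
    """
    y = np.asarray(response_tan, dtype=float)
    x = np.asarray(sqrt_def, dtype=float)
    if y.shape != x.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("inputs must be equal-length vectors (n >= 2)")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("predictor is identically zero")
    slope = float(np.sum(x * y) / sxx)
    resid = y - slope * x
    dof = max(len(y) - 1, 1)
    stderr = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    try:
        agree = agreement_statistic(y, slope * x)
    except ValueError:
        agree = None
    return RegressionResult(
        slope=slope, slope_stderr=stderr, agreement_r2=agree, n=len(y)
    )


def _regime_indicator(regime: pd.Series) -> np.ndarray:
    levels = sorted(regime.unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two velocity regimes required, got {levels}")
    return (regime.to_numpy() == levels[0]).astype(float)


def velocity_effect_test(
    table: pd.DataFrame, n_permutations: int = 1000, seed: int = 0
) -> RegressionResult:
    """Does head-translation velocity add anything beyond sqrt(def)?

    Fits ``response_tan ~ 1 + sqrt(def_max) + regime`` where the regime
    indicator is 1 for the first regime level in sorted order, so
    ``regime_coef`` estimates that regime's additive offset.  The reported
    ``slope`` is the paper-style no-intercept sqrt(def) slope on the same
    rows.

    The p-value uses Freedman-Lane residual permutation: residuals of the
    reduced (intercept + sqrt(def)) fit are permuted and added back to its
    fitted values, keeping the regime/def covariate structure fixed — naive
    label shuffling is anticonservative here because the regimes occupy
    different parts of the def range.  Residuals are permuted in
    subject-sized blocks when block sizes are equal (regimes are
    between-subject), row-wise otherwise.
    """
    for col in ("response_tan", "def_max", "regime", "subject_id"):
        if col not in table.columns:
            raise ValueError(f"trial table lacks column {col!r}")
    y = table["response_tan"].to_numpy(dtype=float)
    x = np.sqrt(table["def_max"].to_numpy(dtype=float))
    ind = _regime_indicator(table["regime"])
    ones = np.ones_like(x)
    X = np.column_stack([ones, x, ind])

    def fit_coef(yy: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
        return float(beta[2])

    coef = fit_coef(y)

    p_value = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        X0 = np.column_stack([ones, x])
        beta0, *_ = np.linalg.lstsq(X0, y, rcond=None)
        fitted0 = X0 @ beta0
        resid0 = y - fitted0
        # subject-block permutation preserves any within-subject correlation
        subj = table["subject_id"].to_numpy()
        subjects = pd.unique(subj)
        blocks = [np.flatnonzero(subj == s) for s in subjects]
        sizes = {len(b) for b in blocks}
        count = 0
        for _ in range(n_permutations):
            if len(sizes) == 1 and len(blocks) > 1:
                order = rng.permutation(len(blocks))
                perm_idx = np.concatenate([blocks[i] for i in order])
                r_perm = np.empty_like(resid0)
                r_perm[np.concatenate(blocks)] = resid0[perm_idx]
            else:
                r_perm = resid0[rng.permutation(len(resid0))]
            if abs(fit_coef(fitted0 + r_perm)) >= abs(coef) - 1e-15:
                count += 1
        p_value = (count + 1) / (n_permutations + 1)

    return RegressionResult(
        slope=float(np.sum(x * y) / np.sum(x * x)),
        regime_coef=coef,
        p_value=p_value,
        n=len(table),
    )


def observed_vs_predicted(
    table: pd.DataFrame, k_by_condition: Dict[str, float]
) -> RegressionResult:
    """OLS of responses on the square-root-law predictions ``k_c * sqrt(def)``.

    Slope near 1 and intercept near 0 indicate the condition-wise square-root
    law accounts for the judgments.  Reports the 95% confidence interval of
    the slope and the agreement statistic.
    """
    missing = set(table["condition"].unique()) - set(k_by_condition)
    if missing:
        raise ValueError(f"no k for condition(s): {sorted(missing)}")
    pred = closed_form_retinal_estimate(
        table["def_max"].to_numpy(dtype=float), 1.0
    ) * table["condition"].map(k_by_condition).to_numpy(dtype=float)
    y = table["response_tan"].to_numpy(dtype=float)
    model = sm.OLS(y, sm.add_constant(pred)).fit()
    ci = model.conf_int()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_stderr=float(model.bse[1]),
        agreement_r2=agreement_statistic(y, model.fittedvalues),
        conf_int=(float(ci[1][0]), float(ci[1][1])),
        n=len(y),
    )
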