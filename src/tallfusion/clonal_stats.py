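"""Limiting-dilution frequency estimation and 2x2 co-occurrence statistics.

The limiting-dilution fit is the single-hit Poisson model: a graft of d
cells responds (engrafts disease) with probability 1 - exp(-d*f), where f
is the frequency of disease-initiating cells. The log-likelihood over dose
groups (d_i, n_i tested, r_i responding) is

    l(f) = sum_i [ r_i * log(1 - exp(-d_i f)) - (n_i - r_i) * d_i f ]

maximized by a bounded 1-D search on log f; for a single dose group the MLE
has the closed form f = -log(1 - r/n) / d. The default confidence interval
is Wald on log f (+/- 1.96 SE from the observed information); a
profile-likelihood interval is available for small samples. Frequencies of
two conditions are compared with a likelihood-ratio test against chi2(1).

Co-occurrence of two binary lesions (e.g. fusion status vs NRAS mutation)
is summarized by the odds ratio with a two-sided Fisher exact p-value; the
Haldane-Anscombe 0.5 correction is applied to the OR only when a zero cell
exists.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .somatic_filter import fisher_exact_two_sided

logger = logging.getLogger(__name__)

_LOG_F_LO = math.log(1e-9)
_LOG_F_HI = math.log(1 - 1e-9)


@dataclass(frozen=True)
class LDAEstimate:
    """Single-hit frequency MLE with a 95% CI (built on the log-f scale)."""

    f_hat: float
    ci_low: float
    ci_high: float
    log_likelihood: float
    se_log_f: float
    ci_method: str = "wald"

    @property
    def one_in(self) -> float:
        return 1.0 / self.f_hat

    @property
    def one_in_interval(self) -> tuple[float, float]:
        return (1.0 / self.ci_high, 1.0 / self.ci_low)


@dataclass(frozen=True)
class ORResult:
    odds_ratio: float
    p_value: float
    corrected: bool  # Haldane-Anscombe 0.5 applied to the OR


def _validate_table(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    dose = table["dose"].to_numpy(dtype=float)
    n = table["tested"].to_numpy(dtype=int)
    r = table["responding"].to_numpy(dtype=int)
    if (dose <= 0).any():
        raise ValueError("doses must be positive")
    if ((r < 0) | (r > n)).any():
        raise ValueError("responding must satisfy 0 <= responding <= tested")
    return dose, n, r


def _log_likelihood(log_f: float, dose: np.ndarray, n: np.ndarray, r: np.ndarray) -> float:
    f = math.exp(log_f)
    df = dose * f
    # log(1 - exp(-x)) computed stably for both small and large x
    with np.errstate(divide="ignore"):
        log_p = np.where(df < 1e-10, np.log(np.maximum(df, 1e-300)), np.log(-np.expm1(-df)))
    return float((r * log_p - (n - r) * df).sum())


def fit_single_hit(table: pd.DataFrame, ci_method: str = "wald") -> LDAEstimate:
    """Maximum-likelihood single-hit frequency from a dose-response table.

    Requires an informative table: saturated tables (every animal responds)
    leave f unbounded above and raise; all-negative tables drive f to 0 and
    raise. For a single dose group the closed form -log(1 - r/n)/d is
    reproduced to optimizer precision.
    """
    dose, n, r = _validate_table(table)
    if (r == n).all():
        raise ValueError("saturated: all tested animals responded; f unbounded above")
    if (r == 0).all():
        raise ValueError("no responses: f_hat tends to 0")

    neg = lambda log_f: -_log_likelihood(log_f, dose, n, r)
    res = optimize.minimize_scalar(
        neg, bounds=(_LOG_F_LO, _LOG_F_HI), method="bounded",
        options={"xatol": 1e-12},
    )
    log_f = float(res.x)
    ll = -float(res.fun)

    # expected Fisher information on the log-f scale (the standard Wald SE
    # for the complementary log-log parameterization of the single-hit model)
    # since 1 - p = exp(-d f), the per-dose term n (df e^{-df})^2 / (p(1-p))
    # simplifies to n (df)^2 e^{-df} / p, which is stable at saturating doses
    f = math.exp(log_f)
    df = dose * f
    p = -np.expm1(-df)
    per_dose = n * df**2 * np.exp(-df) / p
    info = float(per_dose.sum())
    se = 1.0 / math.sqrt(info) if info > 0 else float("inf")

    if ci_method == "wald":
        ci_low = math.exp(log_f - 1.96 * se)
        ci_high = min(math.exp(log_f + 1.96 * se), 1.0)
    elif ci_method == "profile":
        target = ll - stats.chi2.ppf(0.95, df=1) / 2.0
        drop = lambda x: _log_likelihood(x, dose, n, r) - target
        lo = log_f
        step = max(se, 0.1)
        while drop(lo) > 0 and lo > _LOG_F_LO:
            lo = max(lo - step, _LOG_F_LO)
        ci_low = math.exp(optimize.brentq(drop, lo, log_f)) if drop(lo) < 0 else math.exp(_LOG_F_LO)
        hi = log_f
        while drop(hi) > 0 and hi < _LOG_F_HI:
            hi = min(hi + step, _LOG_F_HI)
        ci_high = math.exp(optimize.brentq(drop, log_f, hi)) if drop(hi) < 0 else 1.0
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return LDAEstimate(
        f_hat=math.exp(log_f), ci_low=ci_low, ci_high=ci_high,
        log_likelihood=ll, se_log_f=se, ci_method=ci_method,
    )


def compare_frequencies(table_a: pd.DataFrame, table_b: pd.DataFrame) -> tuple[float, float]:
    """Likelihood-ratio test of equal single-hit frequency in two tables.

    Returns (LR statistic, p-value vs chi2 with 1 df)."""
    fit_a = fit_single_hit(table_a)
    fit_b = fit_single_hit(table_b)
    pooled = pd.concat([table_a, table_b], ignore_index=True)
    fit_pooled = fit_single_hit(pooled)
    lr = 2.0 * (fit_a.log_likelihood + fit_b.log_likelihood - fit_pooled.log_likelihood)
    lr = max(lr, 0.0)
    return lr, float(stats.chi2.sf(lr, df=1))


def odds_ratio_test(table) -> ORResult:
    """Odds ratio and two-sided Fisher exact p for a 2x2 table [[a,b],[c,d]].

    OR = (a*d)/(b*c); when any cell is zero the Haldane-Anscombe 0.5
    correction is applied to the OR (flagged), while the Fisher p-value
    always uses the uncorrected counts. Two zero cells in one margin leave
    the OR undefined and raise.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    a, b = arr[0]
    c, d = arr[1]
    margins = [(a, b), (c, d), (a, c), (b, d)]
    if any(x == 0 and y == 0 for x, y in margins):
        raise ValueError("two zero cells in one margin: odds ratio undefined")
    corrected = bool((arr == 0).any())
    if corrected:
        logger.info("odds_ratio_test: zero cell present, Haldane-Anscombe 0.5 applied")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    p = fisher_exact_two_sided(int(arr[0, 0]), int(arr[0, 1]), int(arr[1, 0]), int(arr[1, 1]))
    return ORResult(odds_ratio=float(odds), p_value=p, corrected=corrected)
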