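"""Group-level and brain-behavior statistics.

One-sample t-tests against chance (25% for four classes) with Bonferroni
correction over the 8 regions, paired t-tests with Cohen's d, the
distance / shared-button confusion model, and the correlation suite
(Pearson, Spearman, Kendall tau-b with one- and two-tailed p-values plus
default Bayes factors).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bayes import kendall_bf, pearson_bf
from .decoding import ConfusionMatrix

CHANCE_4CLASS = 0.25
N_ROI_COMPARISONS = 8

#: Compare-task response mapping: 2 and 4 share the "less than 5" button,
#: 6 and 8 share the "more than 5" button.
COMPARE_BUTTON_MAP = {2: 0, 4: 0, 6: 1, 8: 1}


@dataclass(frozen=True)
class GroupStatResult:
    t: float
    df: int
    p_uncorrected: float
    p_bonferroni: float
    cohen_d: float
    mu0: float
    tails: int
    m_comparisons: int


@dataclass(frozen=True)
class DistanceEffectResult:
    """Group summary of the per-participant distance / button regressions."""

    coefficients: pd.DataFrame  # participant, intercept, distance, button
    distance_t: float
    distance_p: float
    button_t: float
    button_p: float
    df: int


@dataclass(frozen=True)
class CorrelationReport:
    pearson_r: float
    spearman_rho: float
    kendall_tau: float
    p_two_pearson: float
    p_one_pearson: float
    p_two_spearman: float
    p_one_spearman: float
    p_two_kendall: float
    p_one_kendall: float
    bf10: float
    bf01: float
    bf_minus0: float
    bf_plus0: float
    bf10_kendall: float
    bf_minus0_kendall: float
    kappa: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def one_sample_t(
    values: np.ndarray,
    mu0: float = CHANCE_4CLASS,
    tails: int = 2,
    m_comparisons: int = N_ROI_COMPARISONS,
) -> GroupStatResult:
    """One-sample t-test against a reference (chance decoding by default).

    Bonferroni correction multiplies the uncorrected p by the number of
    comparisons (8 regions by default), capped at 1.  Cohen's d is
    ``(mean - mu0) / SD``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: t is undefined")
    mean = x.mean()
    t = (mean - mu0) / (sd / np.sqrt(n))
    df = n - 1
    if tails == 2:
        p = 2.0 * sps.t.sf(abs(t), df)
    elif tails == 1:
        p = sps.t.sf(t, df)
    else:
        raise ValueError("tails must be 1 or 2")
    return GroupStatResult(
        t=float(t), df=df, p_uncorrected=float(p),
        p_bonferroni=float(min(1.0, m_comparisons * p)),
        cohen_d=float((mean - mu0) / sd), mu0=mu0, tails=tails,
        m_comparisons=m_comparisons,
    )


def paired_t_cohend(
    a: np.ndarray, b: np.ndarray, m_comparisons: int = 1
) -> GroupStatResult:
    """Paired t-test on a - b with Cohen's d of the differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, mu0=0.0, tails=2, m_comparisons=m_comparisons)


def _confusion_predictors(
    cm: ConfusionMatrix, targets: tuple[int, ...] = (4, 6),
    button_map: dict[int, int] = COMPARE_BUTTON_MAP,
) -> pd.DataFrame:
    """Off-diagonal prediction rates for the checked targets, with distance
    and shared-button predictors."""
    labels = [int(v) for v in cm.labels]
    rates = cm.rates
    rows = []
    for tgt in targets:
        ti = labels.index(tgt)
        for pj, pred in enumerate(labels):
            if pred == tgt:
                continue
            rows.append(dict(
                target=tgt, predicted=pred, rate=rates[ti, pj],
                distance=abs(pred - tgt),
                shared_button=int(button_map[pred] == button_map[tgt]),
            ))
    return pd.DataFrame(rows)


def distance_button_model(
    confusions: dict[str, ConfusionMatrix],
    button_map: dict[int, int] | None = None,
    targets: tuple[int, ...] = (4, 6),
) -> DistanceEffectResult:
    """Numerical-distance vs shared-button account of classifier confusions.

    For each participant, regresses the off-diagonal prediction rates for
    targets 4 and 6 on numerical distance and a shared-button indicator
    (ordinary least squares), then tests each coefficient across
    participants with a one-sample t (df = n - 1), approximating the
    random-intercept/random-slope mixed model.  A distance effect without a
    button effect indicates the decoder read numerical information rather
    than motor plans.
    """
    button_map = COMPARE_BUTTON_MAP if button_map is None else button_map
    coef_rows = []
    for pid, cm in sorted(confusions.items()):
        tbl = _confusion_predictors(cm, targets, button_map)
        if len(tbl) < 3:
            raise ValueError(
                f"{pid}: need at least 3 usable off-diagonal predictions"
            )
        X = np.column_stack([
            np.ones(len(tbl)), tbl["distance"], tbl["shared_button"],
        ])
        beta, *_ = np.linalg.lstsq(X, tbl["rate"].to_numpy(), rcond=None)
        coef_rows.append(dict(participant=pid, intercept=beta[0],
                              distance=beta[1], button=beta[2]))
    coefs = pd.DataFrame(coef_rows)
    if len(coefs) < 2:
        raise ValueError("need at least 2 participants for the group test")
    dist = one_sample_t(coefs["distance"], mu0=0.0, m_comparisons=1)
    butt = one_sample_t(coefs["button"], mu0=0.0, m_comparisons=1)
    return DistanceEffectResult(
        coefficients=coefs,
        distance_t=dist.t, distance_p=dist.p_uncorrected,
        button_t=butt.t, button_p=butt.p_uncorrected,
        df=len(coefs) - 1,
    )


def _one_sided_p(stat_sign: float, p_two: float, alternative: str) -> float:
    """Convert a two-sided p to one-sided given the observed sign."""
    half = p_two / 2.0
    if alternative == "negative":
        return half if stat_sign <= 0 else 1.0 - half
    return half if stat_sign >= 0 else 1.0 - half


def correlation_suite(
    brain_metric: np.ndarray,
    behavior_metric: np.ndarray,
    kappa: float = 1.0,
    alternative: str = "negative",
) -> CorrelationReport:
    """Frequentist and Bayesian correlations for one brain x behavior pair.

    Pearson r, Spearman rho (average ranks for ties, t approximation for
    p), and Kendall tau-b (normal approximation); one-tailed p-values in
    the stated ``alternative`` direction; default Bayes factors for r
    (exact integration) and tau (yoked normal approximation).
    """
    x = np.asarray(brain_metric, dtype=float)
    y = np.asarray(behavior_metric, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be paired 1-D arrays")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")

    r, p_r = sps.pearsonr(x, y)
    rho_res = sps.spearmanr(x, y)
    rho, p_rho = float(rho_res.statistic), float(rho_res.pvalue)
    if np.isnan(rho):
        raise ValueError("ties degenerate the rank correlation")
    tau_res = sps.kendalltau(x, y, variant="b")
    tau, p_tau = float(tau_res.statistic), float(tau_res.pvalue)

    sign = {"negative": -1.0, "positive": 1.0}[alternative]
    bf10 = pearson_bf(r, n, kappa, side="two")
    return CorrelationReport(
        pearson_r=float(r),
        spearman_rho=rho,
        kendall_tau=tau,
        p_two_pearson=float(p_r),
        p_one_pearson=_one_sided_p(np.sign(r) * sign, p_r, "positive"),
        p_two_spearman=p_rho,
        p_one_spearman=_one_sided_p(np.sign(rho) * sign, p_rho, "positive"),
        p_two_kendall=p_tau,
        p_one_kendall=_one_sided_p(np.sign(tau) * sign, p_tau, "positive"),
        bf10=bf10,
        bf01=1.0 / bf10,
        bf_minus0=pearson_bf(r, n, kappa, side="negative"),
        bf_plus0=pearson_bf(r, n, kappa, side="positive"),
        bf10_kendall=kendall_bf(tau, n, kappa, side="two"),
        bf_minus0_kendall=kendall_bf(tau, n, kappa, side="negative"),
        kappa=kappa,
        n=n,
    )
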