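"""Behavioral summaries: the performance metric P, the Weber-fraction model,
and the math-score transform.

The number-comparison session is summarized two ways.  The performance
metric ``P = RT * (1 + 2 * ER)`` folds the error rate into the mean correct
response time, so errorless performance leaves RT unchanged and chance
performance (50% errors on a two-choice task) doubles it.  The Weber
fraction ``w`` is the single noise parameter of the approximate-number
comparison model: the predicted error rate for comparing n1 and n2 is

    0.5 * erfc( |n1 - n2| / (sqrt(2) * w * sqrt(n1**2 + n2**2)) )

Math achievement standard scores arrive with a negative skew; squaring the
scores is the normalizing transform used before correlational analyses, and
``transform_math_scores`` reports skewness and Shapiro-Wilk diagnostics for
both the raw and squared scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats


@dataclass
class ComparisonTrial:
    n1: int
    n2: int
    correct: bool
    rt_ms: float


@dataclass
class BehavioralSession:
    """One participant's number-comparison session."""

    trials: list[ComparisonTrial]
    format: str = "nonsymbolic"
    participant_id: str = "sub-00"

    def __post_init__(self) -> None:
        for i, tr in enumerate(self.trials):
            if tr.n1 == tr.n2:
                raise ValueError(f"trial {i}: comparison pair must differ")
            if tr.rt_ms <= 0:
                raise ValueError(f"trial {i}: rt_ms must be positive")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def per_ratio_accuracy(self) -> dict[tuple[int, int], float]:
        """Observed proportion correct per comparison pair (smaller, larger)."""
        acc: dict[tuple[int, int], list[int]] = {}
        for tr in self.trials:
            key = (min(tr.n1, tr.n2), max(tr.n1, tr.n2))
            acc.setdefault(key, []).append(int(tr.correct))
        return {k: float(np.mean(v)) for k, v in sorted(acc.items())}


@dataclass(frozen=True)
class BehavioralSummary:
    ER: float
    RT: float
    P: float
    n_trials: int
    n_correct: int
    n_trimmed: int


@dataclass(frozen=True)
class ScoreTransform:
    raw: np.ndarray
    squared: np.ndarray
    skew_raw: float
    skew_squared: float
    shapiro_raw: tuple[float, float]
    shapiro_squared: tuple[float, float]


def performance_metric(
    session: BehavioralSession, sd_cutoff: float = 3.0
) -> BehavioralSummary:
    """Combined speed-accuracy performance score P = RT * (1 + 2 * ER).

    The error rate uses all trials.  Mean RT uses correct trials only,
    after a single pass removing trials beyond ``sd_cutoff`` sample
    standard deviations from the participant's mean correct RT.
    Higher P means worse performance.
    """
    correct_rts = np.array(
        [tr.rt_ms for tr in session.trials if tr.correct], dtype=float
    )
    if correct_rts.size == 0:
        raise ValueError(
            "no correct trials: mean RT (and hence P) is undefined"
        )
    er = 1.0 - correct_rts.size / session.n_trials
    mu = correct_rts.mean()
    sd = correct_rts.std(ddof=1) if correct_rts.size > 1 else 0.0
    keep = np.abs(correct_rts - mu) <= sd_cutoff * sd if sd > 0 else \
        np.ones_like(correct_rts, dtype=bool)
    rt = float(correct_rts[keep].mean())
    return BehavioralSummary(
        ER=float(er),
        RT=rt,
        P=rt * (1.0 + 2.0 * er),
        n_trials=session.n_trials,
        n_correct=int(correct_rts.size),
        n_trimmed=int((~keep).sum()),
    )


def weber_error(
    n1: int | np.ndarray,
    n2: int | np.ndarray,
    w: float,
    printed_form: bool = False,
) -> float | np.ndarray:
    """Predicted comparison error rate under the Weber model.

    Returns ``0.5 * erfc(|n1 - n2| / (sqrt(2) * w * sqrt(n1^2 + n2^2)))``,
    which lies in [0, 0.5].  ``printed_form=True`` switches the denominator
    to ``sqrt(n1^2 + n1^2)`` for comparison against sources that print the
    model that way; the standard form is the default.
    """
    if w <= 0:
        raise ValueError("Weber fraction w must be positive")
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise ValueError("numerosities must be >= 1")
    denom_sq = n1**2 + (n1**2 if printed_form else n2**2)
    z = np.abs(n1 - n2) / (np.sqrt(2.0) * w * np.sqrt(denom_sq))
    out = 0.5 * special.erfc(z)
    return float(out) if out.ndim == 0 else out


W_BOUNDS = (0.01, 2.0)


@dataclass(frozen=True)
class WeberFit:
    w: float
    sse: float
    at_boundary: bool
    method: str

    def __float__(self) -> float:
        return self.w


def fit_weber(
    data: BehavioralSession | dict[tuple[int, int], float],
    method: str = "ls",
    trial_counts: dict[tuple[int, int], int] | None = None,
) -> WeberFit:
    """Fit the single-parameter Weber model to per-ratio accuracies.

    ``data`` is either a session (accuracies computed per comparison pair)
    or a mapping ``(n1, n2) -> proportion correct``.  The default objective
    is least squares on proportion correct against ``1 - weber_error``; a
    Bernoulli maximum-likelihood objective is available with
    ``method="mle"`` (requires per-pair trial counts for sessions built by
    hand).  The search is bounded to w in [0.01, 2] with a coarse grid scan
    followed by bounded scalar minimization (tolerance 1e-4).  All-perfect
    accuracy pins w at the lower bound and sets ``at_boundary``.
    """
    if isinstance(data, BehavioralSession):
        acc = data.per_ratio_accuracy()
        counts: dict[tuple[int, int], int] = {}
        for tr in data.trials:
            key = (min(tr.n1, tr.n2), max(tr.n1, tr.n2))
            counts[key] = counts.get(key, 0) + 1
    else:
        acc = {(min(a, b), max(a, b)): p for (a, b), p in data.items()}
        counts = trial_counts or {k: 1 for k in acc}
    if len(acc) < 2:
        raise ValueError("need accuracies for at least 2 distinct ratios")
    pairs = np.array(sorted(acc), dtype=float)
    obs = np.array([acc[tuple(int(v) for v in p)] for p in pairs])
    wts = np.array([counts[tuple(int(v) for v in p)] for p in pairs], float)

    if method == "ls":
        def objective(w: float) -> float:
            pred = 1.0 - weber_error(pairs[:, 0], pairs[:, 1], w)
            return float(np.sum(wts * (obs - pred) ** 2))
    elif method == "mle":
        eps = 1e-9
        def objective(w: float) -> float:
            pe = np.clip(weber_error(pairs[:, 0], pairs[:, 1], w), eps, 1 - eps)
            return float(-np.sum(
                wts * (obs * np.log1p(-pe) + (1 - obs) * np.log(pe))
            ))
    else:
        raise ValueError(f"unknown method {method!r}")

    lo, hi = W_BOUNDS
    grid = np.linspace(lo, hi, 200)
    w0 = grid[int(np.argmin([objective(w) for w in grid]))]
    bracket = (max(lo, w0 - 0.02), min(hi, w0 + 0.02))
    res = optimize.minimize_scalar(
        objective, bounds=bracket, method="bounded",
        options={"xatol": 1e-5},
    )
    w_hat = float(res.x)
    at_boundary = w_hat <= lo + 1e-3 or w_hat >= hi - 1e-3
    return WeberFit(w=w_hat, sse=float(res.fun), at_boundary=at_boundary,
                    method=method)


def transform_math_scores(scores: np.ndarray) -> ScoreTransform:
    """Square standard scores and report normality diagnostics.

    Reports the adjusted Fisher-Pearson sample skewness and the
    Shapiro-Wilk statistic/p for both raw and squared scores.  Squaring is
    the variance-raising transform that counteracts a negative skew in
    achievement standard scores.
    """
    raw = np.asarray(scores, dtype=float)
    if raw.size < 3:
        raise ValueError("need at least 3 scores")
    if np.ptp(raw) == 0:
        raise ValueError("constant scores: normality is undefined")
    squared = raw**2
    return ScoreTransform(
        raw=raw,
        squared=squared,
        skew_raw=float(stats.skew(raw, bias=False)),
        skew_squared=float(stats.skew(squared, bias=False)),
        shapiro_raw=tuple(map(float, stats.shapiro(raw))),
        shapiro_squared=tuple(map(float, stats.shapiro(squared))),
    )
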