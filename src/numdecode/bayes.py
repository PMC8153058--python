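"""Default Bayes factors for correlations.

The two-sided test places a stretched beta prior on the population
correlation rho -- a Beta(1/kappa, 1/kappa) density rescaled to (-1, 1),
which at the default width kappa = 1 is uniform -- and integrates the exact
sampling distribution of the observed Pearson r against it:

    BF10 = int_-1^1 f(r | rho, n) pi(rho) drho / f(r | 0, n)

where f(r | rho, n) is the exact density of the sample correlation under a
bivariate normal (hypergeometric-function form; constant factors cancel in
the ratio).  One-sided variants integrate the truncated, renormalized prior
over (-1, 0) or (0, 1).  The Bayes factor depends on the data only through
(r, n).

The Kendall-tau Bayes factor uses the parametric-yoking normal
approximation: the sampling distribution of tau-b is treated as normal with
variance 2(2n + 5) / (9 n (n - 1)), and the prior on tau is induced from
the stretched beta on rho through the bivariate-normal relation
``tau = (2 / pi) * arcsin(rho)``.  It is a documented approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special


class BayesFactorError(RuntimeError):
    """Numeric integration failed to converge."""


def _likelihood_ratio(rho: float, r: float, n: int) -> float:
    """f(r | rho, n) / f(r | 0, n) from the exact density of Pearson r."""
    a = (1.0 - rho**2) ** ((n - 1) / 2.0)
    b = (1.0 - rho * r) ** (-(n - 1.5))
    h = special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0)
    h0 = special.hyp2f1(0.5, 0.5, n - 0.5, 0.5)
    return a * b * h / h0


def _prior(rho: float, kappa: float) -> float:
    a = 1.0 / kappa
    return (1.0 - rho**2) ** (a - 1.0) / special.beta(a, a) / 2 ** (2 * a - 1)


def pearson_bf(r: float, n: int, kappa: float = 1.0,
               side: str = "two") -> float:
    """BF10-style Bayes factor for a Pearson correlation.

    ``side``: "two" for any-direction alternative (BF10), "negative" for
    rho < 0 (BF-0), "positive" for rho > 0 (BF+0).  The null is always
    rho = 0; BF01 is the reciprocal of the two-sided value.
    """
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie strictly inside (-1, 1)")
    if n < 3:
        raise ValueError("n must be >= 3")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if side == "two":
        lo, hi, renorm = -1.0, 1.0, 1.0
    elif side == "negative":
        lo, hi, renorm = -1.0, 0.0, 2.0
    elif side == "positive":
        lo, hi, renorm = 0.0, 1.0, 2.0
    else:
        raise ValueError(f"unknown side {side!r}")

    def integrand(rho: float) -> float:
        return _likelihood_ratio(rho, r, n) * _prior(rho, kappa) * renorm

    val, err = integrate.quad(integrand, lo, hi, limit=300)
    if not np.isfinite(val) or (val > 0 and err / val > 1e-4):
        raise BayesFactorError(
            f"quadrature did not converge (value={val}, abs err={err})"
        )
    return float(val)


@dataclass(frozen=True)
class PearsonBFReport:
    r: float
    n: int
    kappa: float
    bf10: float
    bf01: float
    bf_minus0: float
    bf_plus0: float


def pearson_bf_report(r: float, n: int, kappa: float = 1.0) -> PearsonBFReport:
    """Two-sided and both one-sided default Bayes factors for one (r, n)."""
    bf10 = pearson_bf(r, n, kappa, side="two")
    return PearsonBFReport(
        r=r, n=n, kappa=kappa, bf10=bf10, bf01=1.0 / bf10,
        bf_minus0=pearson_bf(r, n, kappa, side="negative"),
        bf_plus0=pearson_bf(r, n, kappa, side="positive"),
    )


def kendall_bf(tau: float, n: int, kappa: float = 1.0,
               side: str = "two") -> float:
    """Approximate default Bayes factor for Kendall's tau.

    Normal approximation to the sampling distribution of tau-b with the
    null variance 2(2n + 5) / (9 n (n - 1)); prior on tau induced from the
    stretched beta on rho via tau = (2/pi) arcsin(rho).  Marked approximate:
    adequate for moderate n and |tau| well inside (-1, 1).
    """
    if not -1.0 < tau < 1.0:
        raise ValueError("tau must lie strictly inside (-1, 1)")
    if n < 3:
        raise ValueError("n must be >= 3")
    var = 2.0 * (2 * n + 5) / (9.0 * n * (n - 1))
    if side == "two":
        lo, hi, renorm = -1.0, 1.0, 1.0
    elif side == "negative":
        lo, hi, renorm = -1.0, 0.0, 2.0
    elif side == "positive":
        lo, hi, renorm = 0.0, 1.0, 2.0
    else:
        raise ValueError(f"unknown side {side!r}")

    def integrand(rho: float) -> float:
        tau_pop = 2.0 / np.pi * np.arcsin(rho)
        like = np.exp(-((tau - tau_pop) ** 2) / (2 * var))
        return like * _prior(rho, kappa) * renorm

    num, _ = integrate.quad(integrand, lo, hi, limit=300)
    den = np.exp(-(tau**2) / (2 * var))
    return float(num / den)
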