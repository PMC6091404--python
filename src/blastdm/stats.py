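"""Bayesian statistics for behavioral comparisons.

JZS Bayes-factor t tests (Cauchy effect-size prior, default scale
r = 0.707, the JASP default), Bayes-factor Pearson correlations
(stretched-beta prior on rho, default width 1), and posterior "Bayesian p
values" — two-sided tail probabilities that one fitted group-level
posterior exceeds another, the conventional reading of posterior-based
t-test reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate, stats
from scipy.special import betaln, hyp2f1

QUAD_TOL = 1e-8


@dataclass
class BayesFactorResult:
    bf10: float
    test: str
    n: int
    statistic: float          # t for t tests, r for correlations
    prior_scale: float

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def _jzs_bf_from_t(t: float, df: float, n_eff: float, r_scale: float) -> float:
    """BF10 by integrating the noncentral-t likelihood over the Cauchy
    effect-size prior: BF10 = int Cauchy(d; 0, r) p(t | d sqrt(N)) dd / p(t | 0)."""
    null = stats.t.pdf(t, df)

    def integrand(d):
        return stats.cauchy.pdf(d, scale=r_scale) * \
            stats.nct.pdf(t, df, d * math.sqrt(n_eff))

    alt, _ = integrate.quad(integrand, -np.inf, np.inf,
                            epsabs=QUAD_TOL, epsrel=QUAD_TOL, limit=200)
    return alt / null


def jzs_ttest_bf(x=None, y=None, t: Optional[float] = None,
                 n: Optional[int] = None, n2: Optional[int] = None,
                 paired: bool = False, r_scale: float = 0.707
                 ) -> BayesFactorResult:
    """JZS Bayes factor for a one-sample/paired or two-sample t test.

    Give either raw vectors (x alone, or x and y) or summary statistics
    (t plus sample sizes). For paired input the difference x - y is tested.
    """
    if x is not None:
        x = np.asarray(x, dtype=float)
        if y is not None and paired:
            if len(x) != len(y):
                raise ValueError("paired samples must have equal length")
            x, y = x - np.asarray(y, dtype=float), None
        if y is None:
            if len(x) < 2:
                raise ValueError("need n >= 2")
            if np.std(x, ddof=1) == 0:
                raise ValueError("zero variance")
            n = len(x)
            t = float(np.mean(x) / (np.std(x, ddof=1) / math.sqrt(n)))
            df, n_eff, label = n - 1, n, "paired" if paired else "one-sample"
        else:
            y = np.asarray(y, dtype=float)
            if len(x) < 2 or len(y) < 2:
                raise ValueError("need n >= 2 per group")
            n, n2 = len(x), len(y)
            sp = math.sqrt(((n - 1) * np.var(x, ddof=1)
                            + (n2 - 1) * np.var(y, ddof=1)) / (n + n2 - 2))
            if sp == 0:
                raise ValueError("zero variance")
            t = float((np.mean(x) - np.mean(y))
                      / (sp * math.sqrt(1 / n + 1 / n2)))
            df, n_eff, label = n + n2 - 2, n * n2 / (n + n2), "two-sample"
    else:
        if t is None or n is None:
            raise ValueError("give raw data or (t, n)")
        if n2 is None:
            df, n_eff = n - 1, n
            label = "paired" if paired else "one-sample"
        else:
            df, n_eff, label = n + n2 - 2, n * n2 / (n + n2), "two-sample"
    bf = _jzs_bf_from_t(t, df, n_eff, r_scale)
    return BayesFactorResult(bf10=float(bf), test=f"jzs-t ({label})",
                             n=int(n), statistic=float(t),
                             prior_scale=r_scale)


def _corr_loglik_ratio(rho: float, r: float, n: int) -> float:
    """log p(r | rho, n) - log p(r | 0, n) for the Pearson sampling density."""
    if abs(rho) >= 1:
        return -np.inf
    lr = (n - 1) / 2.0 * math.log1p(-rho * rho) \
        - (n - 1.5) * math.log1p(-rho * r) \
        + math.log(hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2.0)) \
        - math.log(hyp2f1(0.5, 0.5, n - 0.5, (0 + 1) / 2.0))
    return lr


def pearson_bf(x, y, kappa: float = 1.0) -> BayesFactorResult:
    """Bayes factor for a Pearson correlation, stretched-beta prior on rho
    with width kappa (kappa = 1 gives the uniform prior; the JASP default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    # |r| = 1 exactly makes the sampling density degenerate; back off a hair
    r_int = float(np.clip(r, -1 + 1e-7, 1 - 1e-7))
    a = 1.0 / kappa

    def integrand(rho):
        logprior = (a - 1) * (math.log1p(rho) + math.log1p(-rho)) \
            - (2 * a - 1) * math.log(2.0) - betaln(a, a)
        return math.exp(logprior + _corr_loglik_ratio(rho, r_int, n))

    with np.errstate(over="ignore"):
        bf, _ = integrate.quad(integrand, -1, 1, epsabs=QUAD_TOL,
                               epsrel=QUAD_TOL, limit=200,
                               points=[r_int])
    return BayesFactorResult(bf10=float(bf), test="pearson", n=n,
                             statistic=r, prior_scale=kappa)


def posterior_p(draws_a, draws_b):
    """Two-sided posterior probability that two fitted quantities differ:
    p = 2 min(P(A - B > 0), P(A - B < 0)), with its Monte-Carlo SE.

    Draws may be paired (equal length, differenced directly) or independent
    posterior samples (cross-differenced via truncation to the shorter)."""
    a = np.asarray(draws_a, dtype=float).ravel()
    b = np.asarray(draws_b, dtype=float).ravel()
    m = min(len(a), len(b))
    if m < 100:
        import warnings
        warnings.warn("fewer than 100 draws; posterior p is unstable")
    diff = a[:m] - b[:m]
    p_pos = float(np.mean(diff > 0))
    p = 2.0 * min(p_pos, 1.0 - p_pos)
    se = 2.0 * math.sqrt(max(p_pos * (1 - p_pos), 1e-12) / m)
    return p, se
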