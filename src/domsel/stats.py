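"""Significance tests and the nearly-neutral omega(S) map.

Contains the G-test of independence used for radical-vs-conservative
contrasts, Pearson correlation with its t-based p-value, the
nearly-neutral relation omega = S / (1 - e^-S) with S = 4*Ne*s and its
numerical inverse, and the species-level correlation of accumulation
metrics against effective population size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

METRICS = ("ratio_omega", "ratio_radical", "ratio_conservative")


@dataclass
class NeRecord:
    """Species-level effective population size at the most recent epoch."""

    species: str
    ne_recent: float

    def __post_init__(self):
        if not (math.isfinite(self.ne_recent) and self.ne_recent > 0):
            raise ValueError(
                f"{self.species}: ne_recent must be finite and positive, "
                f"got {self.ne_recent}")


@dataclass
class CorrelationReport:
    metric: str
    n: int
    r: float
    p: float
    dropped_species: tuple = ()


def g_test(table, williams: bool = False) -> tuple:
    """Log-likelihood-ratio (G) test of independence on a 2x2 table.

    Returns (G, p) with p from the chi-square(1) upper tail; no
    continuity correction.  The optional Williams correction divides G
    by the standard q factor.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValueError("negative count in contingency table")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = obs.sum()
    if n <= 0 or (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin: G-test undefined")
    expected = np.outer(rows, cols) / n
    mask = obs > 0
    g = 2.0 * (obs[mask] * np.log(obs[mask] / expected[mask])).sum()
    if williams:
        q = 1.0 + ((n / rows).sum() - 1.0) * ((n / cols).sum() - 1.0) / (6.0 * n)
        g /= q
    g = max(g, 0.0)
    return float(g), float(stats.chi2.sf(g, df=1))


def pearson_with_p(x, y) -> tuple:
    """Sample Pearson r and its two-sided t-test p-value (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError(f"need n >= 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def omega_from_S(S):
    """Nearly-neutral fixation-rate ratio omega(S) = S / (1 - e^-S).

    S = 4*Ne*s is the population-scaled selection coefficient; the map
    is continuous through S = 0 where omega = 1.
    """
    S = np.asarray(S, dtype=float)
    out = np.empty_like(S)
    small = np.abs(S) < 1e-8
    # second-order expansion around 0: S/(1-e^-S) = 1 + S/2 + S^2/12 + ...
    out[small] = 1.0 + S[small] / 2.0 + S[small] ** 2 / 12.0
    with np.errstate(over="ignore"):
        out[~small] = S[~small] / (-np.expm1(-S[~small]))
    return out if out.ndim else float(out)


def S_from_omega(omega) -> float:
    """Numerical inverse of :func:`omega_from_S` (scalar), |error| < 1e-10."""
    omega = float(omega)
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega}")
    if abs(omega - 1.0) < 1e-12:
        return 0.0
    # omega(S) is strictly increasing; bracket and bisect with brentq
    lo, hi = -1.0, 1.0
    while omega_from_S(lo) > omega:
        lo *= 2.0
        if lo < -1e6:
            raise ValueError(f"omega={omega} out of invertible range")
    while omega_from_S(hi) < omega:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError(f"omega={omega} out of invertible range")
    return float(optimize.brentq(lambda s: omega_from_S(s) - omega, lo, hi,
                                 xtol=1e-12, rtol=8.9e-16))


def correlate_metrics(summaries: list, ne_records: list,
                      log10_ne: bool = False, strict: bool = True) -> list:
    """Correlate each accumulation metric with Ne across species.

    Species are joined by exact name; species with an undefined metric
    are dropped pairwise (and logged).  A metric with fewer than 3
    remaining species raises, or is skipped with a warning when
    ``strict`` is false.
    """
    ne_by_species = {}
    for rec in ne_records:
        if rec.species in ne_by_species:
            raise ValueError(f"duplicate species {rec.species!r} in Ne table")
        ne_by_species[rec.species] = rec.ne_recent

    reports = []
    for metric in METRICS:
        xs, ys, dropped = [], [], []
        for s in summaries:
            if s.species not in ne_by_species:
                dropped.append(s.species)
                continue
            value = s.metric(metric)
            if not math.isfinite(value):
                dropped.append(s.species)
                continue
            ne = ne_by_species[s.species]
            xs.append(math.log10(ne) if log10_ne else ne)
            ys.append(value)
        if dropped:
            logger.info("correlate %s: dropped species %s", metric, dropped)
        if len(xs) < 3:
            msg = (f"{metric}: only {len(xs)} species with defined values "
                   f"(need >= 3)")
            if strict:
                raise ValueError(msg)
            logger.warning("skipping correlation: %s", msg)
            continue
        r, p = pearson_with_p(xs, ys)
        reports.append(CorrelationReport(metric=metric, n=len(xs), r=r, p=p,
                                         dropped_species=tuple(dropped)))
    return reports
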