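"""Bayesian mapping from read counts to peptide frequency.

For a peptide observed ``c`` times in ``N`` reads, the posterior over its
true library frequency ``f`` combines a binomial sampling likelihood with
an exponential abundance prior (rate ``lambda``, fitted from the observed
frequency spectrum):

    P(f | c, N)  propto  Binomial(c; N, f) * lambda * exp(-lambda * f)

The posterior maximum solves ``c/f - (N - c)/(1 - f) - lambda = 0``, a
quadratic in ``f`` whose physical root has the closed form

    f_hat = 2 c / ( (N + lambda) + sqrt((N + lambda)^2 - 4 lambda c) )

which reduces to ``c / N`` as the prior flattens (lambda -> 0).  The
``calibrate_count_cutoff`` diagnostic reports where the map from counts to
f_hat becomes linear with the ideal slope 1/N; the production pipeline
uses the fixed conservative cutoff of six counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln

from .reads import DEFAULT_MIN_COUNT, CountTable

GRID_FLOOR = 1e-12


@dataclass(frozen=True)
class FrequencyPrior:
    """Exponential abundance prior; ``rate`` is in inverse-frequency units."""

    rate: float
    fit_range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("prior rate must be non-negative")


@dataclass
class PosteriorCurve:
    grid: np.ndarray
    density: np.ndarray  # normalized so trapezoid integral over grid is 1
    mle_f: float

    def interval_mass(self, lo: float, hi: float) -> float:
        mask = (self.grid >= lo) & (self.grid <= hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(self.density[mask], self.grid[mask]))


def fit_exponential_prior(
    table: CountTable, min_count: int = DEFAULT_MIN_COUNT
) -> FrequencyPrior:
    """Maximum-likelihood exponential rate on measurable frequencies.

    Frequencies ``c/N`` of peptides at or above the count cutoff define
    the measurable range; the exponential MLE is the inverse mean.
    Duplicate-scaling a table leaves frequencies, hence the rate, unchanged.
    """
    if not table.counts:
        raise ValueError("cannot fit a prior to an empty count table")
    n = table.depth
    if n == 0:
        raise ValueError("cannot fit a prior to an all-zero count table")
    freqs = np.array(
        [c / n for c in table.counts.values() if c >= min_count], dtype=float
    )
    if freqs.size == 0:
        raise ValueError("no peptides at or above the count cutoff")
    rate = 1.0 / float(freqs.mean())
    return FrequencyPrior(rate=rate, fit_range=(float(freqs.min()), float(freqs.max())))


def _log_posterior(f: np.ndarray, c: int, n: int, rate: float) -> np.ndarray:
    # Binomial log-likelihood (up to the c-only normalizer) plus log prior.
    log_binom = -betaln(c + 1, n - c + 1) - np.log(n + 1)
    return (
        log_binom
        + c * np.log(f)
        + (n - c) * np.log1p(-f)
        - rate * f
        + (np.log(rate) if rate > 0 else 0.0)
    )


def map_frequency(c: int, n: int, rate: float) -> float:
    """Posterior-maximum frequency from the stationary condition (closed form)."""
    if n <= 0:
        raise ValueError("N must be positive")
    if not 0 <= c <= n:
        raise ValueError("count must satisfy 0 <= c <= N")
    if c == 0:
        return 0.0
    s = n + rate
    disc = s * s - 4.0 * rate * c
    return 2.0 * c / (s + np.sqrt(disc))


def posterior_frequency(
    c: int,
    n: int,
    prior: FrequencyPrior,
    grid_size: int = 4000,
) -> PosteriorCurve:
    """Normalized posterior density of ``f`` on a log-spaced grid."""
    if n <= 0:
        raise ValueError("N must be positive")
    if not 0 <= c <= n:
        raise ValueError("count must satisfy 0 <= c <= N")
    grid = np.geomspace(GRID_FLOOR, 1.0 - GRID_FLOOR, grid_size)
    logp = _log_posterior(grid, c, n, prior.rate)
    logp -= logp.max()
    dens = np.exp(logp)
    dens /= np.trapezoid(dens, grid)
    return PosteriorCurve(grid=grid, density=dens, mle_f=map_frequency(c, n, prior.rate))


def mle_curve(prior: FrequencyPrior, n: int, max_count: int = 100) -> pd.DataFrame:
    counts = np.arange(0, max_count + 1)
    f_hat = np.array([map_frequency(int(c), n, prior.rate) for c in counts])
    return pd.DataFrame({"count": counts, "mle_f": f_hat})


def calibrate_count_cutoff(
    prior: FrequencyPrior,
    n: int,
    tolerance: float = 0.05,
    max_count: int = 100,
) -> tuple[int, pd.DataFrame]:
    """Smallest count from which the count -> f_hat map is linear.

    Linearity is judged by successive differences: from the returned count
    onward, every step ``f_hat(c+1) - f_hat(c)`` stays within ``tolerance``
    (relative) of the ideal binomial slope ``1/N``.  Raises when no such
    regime exists below ``max_count`` (a very steep prior).
    """
    if n <= 0:
        raise ValueError("N must be positive")
    curve = mle_curve(prior, n, max_count)
    f_hat = curve["mle_f"].to_numpy()
    diffs = np.diff(f_hat)  # diffs[c] = f_hat(c+1) - f_hat(c)
    ok = np.abs(diffs * n - 1.0) < tolerance
    # find the smallest c >= 1 such that every step at or beyond c is linear
    onset = None
    for c in range(1, max_count):
        if ok[c:].all():
            onset = c
            break
    if onset is None:
        raise ValueError(
            f"no linear regime found below count {max_count}; "
            f"prior rate {prior.rate:.3g} is too steep relative to N={n}"
        )
    return onset, curve
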