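"""Two-Gaussian classification of the enrichment distribution.

The E distribution of a panning experiment decomposes into a narrow
"unresponsive" component centered near zero (peptides whose frequency is
unchanged by competitor; the spread is counting noise) and a broad
"responsive" component shifted negative (peptides the competitor
depletes).  After fitting both components, a peptide's posterior
probability of being unresponsive is taken as the unweighted density
ratio

    p_posterior(E) = pdf_u(E) / (pdf_r(E) + pdf_u(E))

and the classification cutoff E* is the most negative solution of
``p_posterior(E*) = p_star`` (default 0.05): peptides with E <= E* are
called responsive binders.  The same responsive component extrapolates
the total number of competitor-depleted (E < 0) peptides from the number
observed below the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

DEFAULT_P_STAR = 0.05


class MixtureFitError(RuntimeError):
    """Raised when the two-component structure cannot be established."""


class CutoffError(RuntimeError):
    """Raised when the posterior never crosses p_star on the negative side.

    Carries the diagnostic posterior curve in ``curve``.
    """

    def __init__(self, message: str, curve: pd.DataFrame | None = None):
        super().__init__(message)
        self.curve = curve


@dataclass(frozen=True)
class Component:
    mean: float
    sd: float
    weight: float


class EnrichmentMixture(BaseEstimator):
    """Responsive/unresponsive Gaussian mixture over enrichment values.

    Parameters
    ----------
    n_restarts : EM restarts with random initialization; best kept.
    method : ``"em"`` fits raw values by EM; ``"histogram"`` least-squares
        fits the two-Gaussian density to a histogram (fidelity check
        against fitting a binned distribution).
    max_mu_unresponsive : sanity bound on |mean| of the unresponsive
        component; labeling conflicts raise rather than guess.
    random_state : seed for EM initialization.

    Fitted attributes: ``responsive_`` and ``unresponsive_`` components,
    ``log_likelihood_``, ``cutoff_`` (E* at ``p_star``; None when the
    posterior has no crossing).
    """

    def __init__(
        self,
        n_restarts: int = 10,
        method: str = "em",
        p_star: float = DEFAULT_P_STAR,
        max_mu_unresponsive: float = 0.5,
        n_bins: int = 100,
        random_state: int | None = None,
    ):
        self.n_restarts = n_restarts
        self.method = method
        self.p_star = p_star
        self.max_mu_unresponsive = max_mu_unresponsive
        self.n_bins = n_bins
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y=None):
        e = np.asarray(X, dtype=float).ravel()
        e = e[np.isfinite(e)]
        if e.size < 100:
            raise ValueError(f"need at least 100 enrichment values, got {e.size}")
        if self.method == "em":
            params = self._fit_em(e)
        elif self.method == "histogram":
            params = self._fit_histogram(e)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self._label_components(*params)
        self.n_ = int(e.size)
        try:
            self.cutoff_ = self.solve_cutoff(self.p_star)
        except CutoffError:
            self.cutoff_ = None
        return self

    def _fit_em(self, e: np.ndarray):
        gm = GaussianMixture(
            n_components=2,
            n_init=self.n_restarts,
            covariance_type="full",
            reg_covar=1e-8,
            random_state=self.random_state,
        ).fit(e[:, None])
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        weights = gm.weights_.ravel()
        self.log_likelihood_ = float(gm.score(e[:, None]) * e.size)
        self.converged_ = bool(gm.converged_)
        return means, sds, weights

    def _fit_histogram(self, e: np.ndarray):
        density, edges = np.histogram(e, bins=self.n_bins, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])

        def model(x, w, m1, s1, m2, s2):
            return w * stats.norm.pdf(x, m1, abs(s1)) + (1 - w) * stats.norm.pdf(
                x, m2, abs(s2)
            )

        p0 = [0.2, np.percentile(e, 10), e.std(), np.median(e), e.std() / 4]
        popt, _ = optimize.curve_fit(
            model, centers, density, p0=p0, bounds=([0, -np.inf, 1e-6, -np.inf, 1e-6],
                                                   [1, np.inf, np.inf, np.inf, np.inf]),
            maxfev=50000,
        )
        w, m1, s1, m2, s2 = popt
        means = np.array([m1, m2])
        sds = np.abs([s1, s2])
        weights = np.array([w, 1 - w])
        self.log_likelihood_ = float(
            np.sum(np.log(model(e, *popt) + 1e-300))
        )
        self.converged_ = True
        return means, sds, weights

    def _label_components(self, means, sds, weights):
        if np.min(weights) < 0.02:
            raise MixtureFitError(
                f"vanishing component weight {np.min(weights):.4f}: the E "
                "distribution does not support two components"
            )
        if np.max(sds) / np.min(sds) < 1.05:
            raise MixtureFitError(
                "component widths are indistinguishable; no responsive/"
                "unresponsive structure"
            )
        u = int(np.argmin(sds))  # unresponsive: the narrow component
        r = 1 - u
        if abs(means[u]) > self.max_mu_unresponsive:
            raise MixtureFitError(
                f"narrow component mean {means[u]:.3f} is far from zero; "
                "labeling criteria conflict"
            )
        if abs(means[u]) >= abs(means[r]):
            raise MixtureFitError(
                "narrow component is further from zero than the broad one; "
                "labeling criteria conflict"
            )
        self.unresponsive_ = Component(float(means[u]), float(sds[u]), float(weights[u]))
        self.responsive_ = Component(float(means[r]), float(sds[r]), float(weights[r]))

    # -------------------------------------------------------------- queries
    def _check_fitted(self):
        if not hasattr(self, "responsive_"):
            raise RuntimeError("model is not fitted")

    def pdf_responsive(self, e):
        self._check_fitted()
        return stats.norm.pdf(e, self.responsive_.mean, self.responsive_.sd)

    def pdf_unresponsive(self, e):
        self._check_fitted()
        return stats.norm.pdf(e, self.unresponsive_.mean, self.unresponsive_.sd)

    def posterior_unresponsive(self, e):
        """Unweighted density ratio pdf_u / (pdf_r + pdf_u).

        Computed from log densities so that the deep tails return the
        correct 0/1 limits instead of 0/0.
        """
        self._check_fitted()
        e = np.asarray(e, dtype=float)
        log_u = stats.norm.logpdf(e, self.unresponsive_.mean, self.unresponsive_.sd)
        log_r = stats.norm.logpdf(e, self.responsive_.mean, self.responsive_.sd)
        with np.errstate(over="ignore"):
            out = 1.0 / (1.0 + np.exp(log_r - log_u))
        return float(out) if out.ndim == 0 else out

    def solve_cutoff(self, p_star: float = DEFAULT_P_STAR) -> float:
        """Most negative root of ``p_posterior(E) = p_star``."""
        self._check_fitted()
        if not 0 < p_star < 1:
            raise ValueError("p_star must lie in (0, 1)")
        lo = self.responsive_.mean - 10 * self.responsive_.sd
        hi = self.unresponsive_.mean
        grid = np.linspace(lo, hi, 2000)
        post = self.posterior_unresponsive(grid)
        above = post - p_star
        crossings = np.nonzero(np.diff(np.sign(above)) != 0)[0]
        if crossings.size == 0:
            curve = pd.DataFrame({"E": grid, "p_posterior": post})
            raise CutoffError(
                f"posterior never crosses p_star={p_star}; components may be "
                "too similar",
                curve=curve,
            )
        i = int(crossings[0])
        root = optimize.brentq(
            lambda e: self.posterior_unresponsive(e) - p_star,
            grid[i],
            grid[i + 1],
            xtol=1e-10,
            rtol=1e-12,
        )
        return float(root)

    def predict(self, X):
        """1 where E <= fitted cutoff (responsive call), else 0."""
        self._check_fitted()
        if self.cutoff_ is None:
            raise CutoffError("no cutoff available; posterior had no crossing")
        e = np.asarray(X, dtype=float).ravel()
        return (e <= self.cutoff_).astype(int)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def fit_mixture(
    e_values,
    n_restarts: int = 10,
    seed: int | None = None,
    method: str = "em",
) -> EnrichmentMixture:
    return EnrichmentMixture(
        n_restarts=n_restarts, method=method, random_state=seed
    ).fit(e_values)


def posterior_unresponsive(e, model: EnrichmentMixture):
    return model.posterior_unresponsive(e)


def solve_cutoff(model: EnrichmentMixture, p_star: float = DEFAULT_P_STAR) -> float:
    return model.solve_cutoff(p_star)


def classify(table: pd.DataFrame, e_star: float) -> set[str]:
    """Responsive peptide set: E at or below the cutoff (inclusive)."""
    if table.empty:
        return set()
    hits = table.loc[table["E"] <= e_star, "peptide"]
    return set(hits)


def estimate_total_negative(model, n_below: int, e_star: float) -> float:
    """Extrapolate the total number of E < 0 peptides.

    Scales the observed count below the cutoff by the responsive
    component's probability ratio ``P(E < 0) / P(E <= E*)``.  ``model``
    may be a fitted mixture or a ``(mu_r, sigma_r)`` pair.
    """
    if hasattr(model, "responsive_"):
        mu, sd = model.responsive_.mean, model.responsive_.sd
    else:
        mu, sd = model
    if sd <= 0:
        raise ValueError("responsive sd must be positive")
    denom = stats.norm.cdf(e_star, mu, sd)
    if denom == 0:
        raise ValueError("responsive component has no mass below the cutoff")
    ratio = stats.norm.cdf(0.0, mu, sd) / denom
    return float(n_below * ratio)
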