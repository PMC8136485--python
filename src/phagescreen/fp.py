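"""Fluorescence-polarization binding analysis.

A fluorescein-labelled probe peptide reports on occupancy of the S100
peptide-binding cleft: bound probe rotates slowly and polarization R is
high; displacing it with an unlabelled competitor peptide lowers R.  The
module covers the full quantitative chain:

* channel pairs -> polarization, ``R = (v_v - G v_h) / (v_v + 2 G v_h)``;
* probe titration fit to the single-site model
  ``P = dPmax * [M] / ([M] + KD_probe) + P0``;
* probe/protein complex concentration [MX] from the exact mass-action
  quadratic;
* conversion of competition curves to fractional saturation
  ``theta = (R - P0) / dP_predicted`` with the max(theta) >= 0.5 validity
  gate;
* displacement fit ``1 - theta = [competitor]/([competitor] + KD_apparent)``;
* correction of KD_apparent for probe depletion,
  ``KD_peptide = KD_apparent / (1 + [X]T (1 - d/2)/KD_probe + d/(1-d))``
  with ``d = [MX]/[X]T``.

Curve fits are exposed both as plain functions and as scikit-learn style
estimators (`ProbeBindingModel`, `CompetitionBindingModel`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

#: Signal change at full probe saturation, from the initial probe fits.
DEFAULT_DPMAX = 0.135

_MAD_SCALE = 1.4826  # makes the MAD a consistent sigma estimate for normals


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries residual diagnostics."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


@dataclass
class FPTitration:
    """One titration: concentration series with replicate polarization reads."""

    concentrations: np.ndarray
    readings: np.ndarray  # shape (n_conc, n_replicates)
    probe_total: float | None = None  # [X]T, uM
    protein_total: float | None = None  # [M]T, uM
    g_factor: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.readings = np.atleast_2d(np.asarray(self.readings, dtype=float))
        if self.readings.shape[0] != self.concentrations.size:
            self.readings = self.readings.T
        if self.readings.shape[0] != self.concentrations.size:
            raise ValueError("readings do not align with concentrations")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")

    def mean_readings(self, clean: bool = True) -> np.ndarray:
        rows = []
        for row in self.readings:
            vals = row[np.isfinite(row)]
            if clean and vals.size >= 2:
                vals = remove_outliers(vals)
            rows.append(float(np.mean(vals)))
        return np.asarray(rows)

    def write_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.readings,
            columns=[f"rep{i + 1}" for i in range(self.readings.shape[1])],
        )
        df.insert(0, "concentration", self.concentrations)
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, **kwargs) -> "FPTitration":
        df = pd.read_csv(path)
        reps = [c for c in df.columns if c != "concentration"]
        return cls(df["concentration"].to_numpy(), df[reps].to_numpy(), **kwargs)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def polarization(v_v, v_h, g: float = 1.0):
    """Polarization from vertical/horizontal channel intensities."""
    v_v = np.asarray(v_v, dtype=float)
    v_h = np.asarray(v_h, dtype=float)
    denom = v_v + 2.0 * g * v_h
    if np.any(denom <= 0):
        raise ValueError("v_v + 2 G v_h must be positive")
    out = (v_v - g * v_h) / denom
    return float(out) if out.ndim == 0 else out


def remove_outliers(readings, n_mad: float = 3.0) -> np.ndarray:
    """Drop technical replicates beyond ``n_mad`` scaled MADs from the median.

    Never drops below two readings: if the rule would, the two readings
    closest to the median are kept.  Idempotent on already-clean data.
    """
    x = np.asarray(readings, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 technical replicates")
    med = np.median(x)
    dev = np.abs(x - med)
    mad = _MAD_SCALE * np.median(dev)
    keep = dev <= n_mad * mad
    if keep.sum() < 2:
        keep = np.zeros_like(keep)
        keep[np.argsort(dev, kind="stable")[:2]] = True
    return x[keep]


def complex_concentration(xt: float, mt: float, kd: float) -> float:
    """[MX] from total probe XT, total protein MT and KD (mass action).

    The physical (minus) root of the quadratic is taken; it satisfies
    ``[MX] <= min(XT, MT)``.
    """
    if xt < 0 or mt < 0:
        raise ValueError("total concentrations must be non-negative")
    if kd <= 0:
        raise ValueError("KD must be positive")
    b = xt + mt + kd
    disc = b * b - 4.0 * xt * mt
    if disc < 0:
        raise ValueError("negative discriminant: inconsistent inputs")
    return (b - np.sqrt(disc)) / 2.0


def predicted_delta(dpmax: float, xt: float, mx: float) -> float:
    """Expected polarization change for the competition experiment."""
    if xt <= 0:
        raise ValueError("total probe concentration must be positive")
    return dpmax * mx / xt


def to_saturation(readings, p0: float, dp_predicted: float):
    """Baseline-subtract and scale to fractional saturation theta.

    Returns ``(theta, valid)``; ``valid`` is False when ``max(theta) < 0.5``,
    in which case a downstream competition fit is refused.
    """
    if dp_predicted <= 0:
        raise ValueError("dP_predicted must be positive")
    theta = (np.asarray(readings, dtype=float) - p0) / dp_predicted
    return theta, bool(np.max(theta) >= 0.5)


def correct_kd(kd_apparent: float, xt: float, kd_probe: float, delta: float) -> float:
    """Correct an apparent competition KD for probe and complex effects."""
    if not 0 <= delta < 1:
        raise ValueError("delta = [MX]/[X]T must lie in [0, 1)")
    if kd_probe <= 0:
        raise ValueError("KD_probe must be positive")
    factor = 1.0 + xt * (1.0 - delta / 2.0) / kd_probe + delta / (1.0 - delta)
    return kd_apparent / factor


def apparent_from_peptide_kd(
    kd_peptide: float, xt: float, kd_probe: float, delta: float
) -> float:
    """Inverse of :func:`correct_kd`; used to lay out simulated experiments."""
    if not 0 <= delta < 1:
        raise ValueError("delta = [MX]/[X]T must lie in [0, 1)")
    factor = 1.0 + xt * (1.0 - delta / 2.0) / kd_probe + delta / (1.0 - delta)
    return kd_peptide * factor


# ---------------------------------------------------------------------------
# Curve fits
# ---------------------------------------------------------------------------

def _single_site(conc, dpmax, kd, p0):
    return dpmax * conc / (conc + kd) + p0


def _displacement(conc, kd, p0_theta=None):  # pragma: no cover - thin helper
    return 1.0 - conc / (conc + kd)


class ProbeBindingModel(BaseEstimator):
    """Single-site fit of a probe titration.

    Fitted attributes: ``p0_``, ``dpmax_``, ``kd_`` (uM) and their standard
    errors in ``stderr_``.
    """

    def __init__(self, min_points: int = 5):
        self.min_points = min_points

    def fit(self, concentrations, readings):
        conc = np.asarray(concentrations, dtype=float)
        y = np.asarray(readings, dtype=float)
        if conc.size < self.min_points:
            raise ValueError(f"need at least {self.min_points} concentrations")
        span = np.ptp(y)
        p0_guess = float(y[np.argmin(conc)])
        kd_guess = float(np.median(conc[conc > 0])) if np.any(conc > 0) else 1.0
        try:
            popt, pcov = optimize.curve_fit(
                _single_site,
                conc,
                y,
                p0=[span if span > 0 else 0.1, kd_guess, p0_guess],
                maxfev=20000,
            )
        except RuntimeError as exc:
            raise FitError(f"probe fit did not converge: {exc}", residuals=y) from exc
        if popt[1] <= 0:
            raise FitError("probe fit returned non-positive KD", residuals=y)
        self.dpmax_, self.kd_, self.p0_ = map(float, popt)
        err = np.sqrt(np.diag(pcov))
        self.stderr_ = {"dpmax": err[0], "kd": err[1], "p0": err[2]}
        self.residuals_ = y - self.predict(conc)
        return self

    def predict(self, concentrations):
        conc = np.asarray(concentrations, dtype=float)
        return _single_site(conc, self.dpmax_, self.kd_, self.p0_)


class CompetitionBindingModel(BaseEstimator):
    """Competition (displacement) fit on fractional saturation.

    ``fit`` takes competitor concentrations and raw polarization readings;
    it estimates the baseline P0 by a decreasing single-site pre-fit,
    converts to theta with the supplied ``dp_predicted``, enforces the
    ``max(theta) >= 0.5`` gate, and fits the displacement isotherm.

    Fitted attributes: ``p0_``, ``theta_``, ``valid_``, ``kd_apparent_``.
    """

    def __init__(self, dp_predicted: float, min_points: int = 5, fit_baseline: bool = True):
        self.dp_predicted = dp_predicted
        self.min_points = min_points
        self.fit_baseline = fit_baseline

    def fit(self, concentrations, readings, p0: float | None = None):
        conc = np.asarray(concentrations, dtype=float)
        y = np.asarray(readings, dtype=float)
        if conc.size < self.min_points:
            raise ValueError(f"need at least {self.min_points} concentrations")
        if p0 is None:
            if not self.fit_baseline:
                raise ValueError("p0 required when fit_baseline=False")
            # Decreasing single-site pre-fit for the baseline.  The
            # amplitude is pinned to dp_predicted — that quantity is known
            # by construction, and letting it float creates a
            # baseline/amplitude degeneracy on curves that do not reach
            # their plateau.
            dp = self.dp_predicted

            def _decreasing(c, kd, p0_):
                return dp * kd / (c + kd) + p0_

            try:
                popt, _ = optimize.curve_fit(
                    _decreasing,
                    conc,
                    y,
                    p0=[np.median(conc[conc > 0]), float(np.min(y))],
                    maxfev=20000,
                )
            except RuntimeError as exc:
                raise FitError(f"baseline pre-fit did not converge: {exc}") from exc
            p0 = float(popt[1])
        self.p0_ = float(p0)
        theta, valid = to_saturation(y, self.p0_, self.dp_predicted)
        self.theta_ = theta
        self.valid_ = valid
        if not valid:
            raise FitError(
                f"max(theta) = {np.max(theta):.3f} < 0.5: signal too weak to fit",
                residuals=theta,
            )
        self.kd_apparent_ = fit_competition(conc, theta, min_points=self.min_points)
        return self

    def predict(self, concentrations):
        conc = np.asarray(concentrations, dtype=float)
        return 1.0 - conc / (conc + self.kd_apparent_)

    def corrected_kd(self, xt: float, kd_probe: float, mt: float) -> float:
        mx = complex_concentration(xt, mt, kd_probe)
        return correct_kd(self.kd_apparent_, xt, kd_probe, mx / xt)


def fit_probe(titration: FPTitration, clean: bool = True) -> ProbeBindingModel:
    return ProbeBindingModel().fit(titration.concentrations, titration.mean_readings(clean))


def fit_competition(concentrations, theta, min_points: int = 5) -> float:
    """Fit the displacement isotherm to a theta series; returns KD_apparent."""
    conc = np.asarray(concentrations, dtype=float)
    th = np.asarray(theta, dtype=float)
    if conc.size < min_points:
        raise ValueError(f"need at least {min_points} concentrations")

    def model(c, kd):
        return 1.0 - c / (c + kd)

    try:
        popt, _ = optimize.curve_fit(
            model, conc, th, p0=[np.median(conc[conc > 0])], maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"competition fit did not converge: {exc}") from exc
    kd = float(popt[0])
    if kd <= 0:
        raise FitError("competition fit returned non-positive KD")
    return kd


# ---------------------------------------------------------------------------
# Contingency statistics (E class vs detectable binding)
# ---------------------------------------------------------------------------

def contingency_stats(table, correction: bool = False) -> dict:
    """Pearson chi-squared (1 df) and phi coefficient for a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=correction)
    (a, b), (c, d) = t
    phi = (a * d - b * c) / np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    return {"chi2": float(chi2), "p_value": float(p), "phi": float(phi), "dof": int(dof)}
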