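"""Forster calibration against dsDNA rulers and efficiency-to-distance inversion.

The transfer efficiency of a donor/acceptor pair at separation R follows

    E(R) = 1 / (1 + (R / R_eff)^6),

where the effective Forster radius ``R_eff = R0 * gamma^(1/6)`` folds the
spectroscopic Forster radius R0 together with the instrument detection factor
gamma.  R0 and gamma are not separately identifiable from (R, E) data, so the
calibration is parameterised directly in R_eff: a one-parameter weighted
nonlinear regression of measured mean efficiencies on the known ruler
separations (0.34 nm per base pair, optionally plus the dye-linker length).

The uncertainty of the dye-linker length enters as an abscissa error and is
folded into the fit by the effective-variance method,

    sigma_eff^2 = sigma_E^2 + (dE/dR)^2 * sigma_R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import (
    LINKER_REL_UNCERTAINTY,
    LINKER_TOTAL_NM,
    RISE_PER_BP_NM,
)

__all__ = [
    "RulerGeometry",
    "CalibrationModel",
    "FoersterCalibration",
    "ruler_separation",
    "forster_efficiency",
    "efficiency_from_distance",
    "distance_from_efficiency",
    "fit_calibration",
]


@dataclass(frozen=True)
class RulerGeometry:
    """Geometry of the dsDNA calibration rulers and dye linkers.

    Parameters
    ----------
    rise_per_bp : float
        Helical rise of dsDNA in nm per base pair.
    include_linker_in_abscissa : bool
        Whether the ruler abscissa (the "separation of the fluorophores")
        includes the total dye-linker length on top of the duplex length.
    linker_total : float
        Total effective linker contribution in nm when the dyes point in
        opposite directions.
    linker_rel_uncertainty : float
        Relative uncertainty of the linker length; propagated into the
        calibration fit as an abscissa error.
    """

    rise_per_bp: float = RISE_PER_BP_NM
    include_linker_in_abscissa: bool = False
    linker_total: float = LINKER_TOTAL_NM
    linker_rel_uncertainty: float = LINKER_REL_UNCERTAINTY

    def __post_init__(self) -> None:
        if self.rise_per_bp <= 0:
            raise ValueError(f"rise_per_bp must be > 0, got {self.rise_per_bp}")
        if not 0.0 <= self.linker_rel_uncertainty < 1.0:
            raise ValueError(
                "linker_rel_uncertainty must be in [0, 1), got "
                f"{self.linker_rel_uncertainty}"
            )
        if self.linker_total < 0:
            raise ValueError(f"linker_total must be >= 0, got {self.linker_total}")

    @property
    def sigma_abscissa(self) -> float:
        """Absolute abscissa uncertainty (nm) from the linker length."""
        return self.linker_rel_uncertainty * self.linker_total


@dataclass
class CalibrationModel:
    """A fitted effective-Forster-radius calibration.

    Attributes
    ----------
    r_eff : float
        Effective Forster radius in nm (distance of 50% transfer).
    sigma_r_eff : float
        1-sigma uncertainty of ``r_eff`` in nm.
    points : pandas.DataFrame or None
        The (R_nm, E, sigma_E) ruler points that produced the fit.
    geometry : RulerGeometry
    metadata : dict
        Optional extras; R0 and gamma are unidentifiable and, if known from
        elsewhere, live only here.
    """

    r_eff: float
    sigma_r_eff: float = 0.0
    points: pd.DataFrame | None = None
    geometry: RulerGeometry = field(default_factory=RulerGeometry)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.r_eff <= 0:
            raise ValueError(f"r_eff must be > 0, got {self.r_eff}")
        if self.sigma_r_eff < 0:
            raise ValueError(f"sigma_r_eff must be >= 0, got {self.sigma_r_eff}")


def ruler_separation(bp: int, geometry: RulerGeometry | None = None) -> float:
    """Fluorophore separation (nm) of a dsDNA ruler of ``bp`` base pairs."""
    geometry = geometry or RulerGeometry()
    if bp <= 0:
        raise ValueError(f"ruler length must be a positive bp count, got {bp}")
    sep = bp * geometry.rise_per_bp
    if geometry.include_linker_in_abscissa:
        sep += geometry.linker_total
    return sep


def forster_efficiency(r, r_eff: float):
    """Transfer efficiency E = 1/(1 + (r/r_eff)^6) at separation ``r`` (nm).

    Vectorised over ``r``; r = 0 gives 1 and r -> inf gives 0.
    """
    if r_eff <= 0:
        raise ValueError(f"r_eff must be > 0, got {r_eff}")
    r = np.asarray(r, dtype=float)
    with np.errstate(over="ignore"):
        e = 1.0 / (1.0 + (r / r_eff) ** 6)
    return e if e.ndim else float(e)


def efficiency_from_distance(R, model: CalibrationModel | float):
    """Predicted efficiency at separation ``R`` (nm) under a calibration."""
    r_eff = model.r_eff if isinstance(model, CalibrationModel) else float(model)
    if np.any(np.asarray(R) < 0):
        raise ValueError("separation R must be >= 0")
    return forster_efficiency(R, r_eff)


def _dE_dR(R, r_eff: float):
    """Derivative of the Forster curve with respect to separation (0 at R=0)."""
    R = np.asarray(R, dtype=float)
    Rsafe = np.where(R > 0, R, np.nan)
    u = (Rsafe / r_eff) ** 6
    with np.errstate(invalid="ignore"):
        d = -6.0 * u / (Rsafe * (1.0 + u) ** 2)
    return np.where(R > 0, d, 0.0)


def distance_from_efficiency(
    E, sigma_E=0.0, model: CalibrationModel | float | None = None
):
    """Invert a mean efficiency to an inter-dye distance with uncertainty.

    Parameters
    ----------
    E : float or array
        Mean transfer efficiency, strictly inside (0, 1).
    sigma_E : float or array
        1-sigma uncertainty of E.
    model : CalibrationModel or float
        Fitted calibration (or a bare r_eff, taken as exact).

    Returns
    -------
    (R, sigma_R) : tuple of floats or arrays
        Distance in nm and its 1-sigma uncertainty from first-order
        propagation of sigma_E and sigma_r_eff in quadrature.
    """
    if model is None:
        raise ValueError("a CalibrationModel (or r_eff) is required")
    if isinstance(model, CalibrationModel):
        r_eff, s_reff = model.r_eff, model.sigma_r_eff
    else:
        r_eff, s_reff = float(model), 0.0
    E = np.asarray(E, dtype=float)
    sigma_E = np.broadcast_to(np.asarray(sigma_E, dtype=float), E.shape)
    if np.any((E <= 0.0) | (E >= 1.0)):
        bad = E[(E <= 0.0) | (E >= 1.0)]
        raise ValueError(
            f"cannot invert efficiency outside (0, 1): got {np.atleast_1d(bad)[0]!r}"
        )
    R = r_eff * (1.0 / E - 1.0) ** (1.0 / 6.0)
    # |dR/dE| = r_eff/6 * (1/E - 1)^(-5/6) / E^2
    dRdE = r_eff / 6.0 * (1.0 / E - 1.0) ** (-5.0 / 6.0) / E**2
    sigma_R = np.sqrt((dRdE * sigma_E) ** 2 + (R / r_eff * s_reff) ** 2)
    if R.ndim == 0:
        return float(R), float(sigma_R)
    return R, sigma_R


class FoersterCalibration(RegressorMixin, BaseEstimator):
    """One-parameter Forster-curve regression of efficiency on separation.

    Fits ``E(R) = 1/(1 + (R/r_eff)^6)`` to ruler points by weighted nonlinear
    least squares.  Ordinate errors ``sigma_E`` and the linker-length abscissa
    uncertainty are combined by the effective-variance method, iterating the
    weights a few times because dE/dR depends on the fitted r_eff.

    Parameters
    ----------
    rise_per_bp, include_linker_in_abscissa, linker_total,
    linker_rel_uncertainty : see :class:`RulerGeometry`.
    r_eff_init : float
        Starting value for the optimiser (nm).
    n_variance_iter : int
        Effective-variance reweighting iterations.

    Attributes
    ----------
    r_eff_ : float
        Fitted effective Forster radius (nm).
    sigma_r_eff_ : float
        Its 1-sigma uncertainty (nm).
    points_ : pandas.DataFrame
        The fitted (R_nm, E, sigma_E) points.
    """

    def __init__(
        self,
        rise_per_bp: float = RISE_PER_BP_NM,
        include_linker_in_abscissa: bool = False,
        linker_total: float = LINKER_TOTAL_NM,
        linker_rel_uncertainty: float = LINKER_REL_UNCERTAINTY,
        r_eff_init: float = 8.0,
        n_variance_iter: int = 3,
    ):
        self.rise_per_bp = rise_per_bp
        self.include_linker_in_abscissa = include_linker_in_abscissa
        self.linker_total = linker_total
        self.linker_rel_uncertainty = linker_rel_uncertainty
        self.r_eff_init = r_eff_init
        self.n_variance_iter = n_variance_iter

    @property
    def geometry(self) -> RulerGeometry:
        return RulerGeometry(
            rise_per_bp=self.rise_per_bp,
            include_linker_in_abscissa=self.include_linker_in_abscissa,
            linker_total=self.linker_total,
            linker_rel_uncertainty=self.linker_rel_uncertainty,
        )

    def fit(self, X, y, sigma_E=None):
        """Fit r_eff to separations ``X`` (nm) and mean efficiencies ``y``."""
        R = np.asarray(X, dtype=float).reshape(-1)
        E = np.asarray(y, dtype=float).reshape(-1)
        if R.size != E.size:
            raise ValueError("X and y must have the same length")
        if R.size == 0:
            raise ValueError("cannot calibrate on an empty point set")
        if np.ptp(R) == 0 and R.size > 1:
            raise ValueError("all ruler separations identical; r_eff not identifiable")
        if R.size < 3:
            warnings.warn(
                f"calibration with {R.size} point(s) is exactly determined or "
                "under-constrained; r_eff uncertainty is unreliable",
                UserWarning,
                stacklevel=2,
            )
        geometry = self.geometry
        if sigma_E is None:
            sE = np.zeros_like(E)
        else:
            sE = np.broadcast_to(np.asarray(sigma_E, dtype=float), E.shape).copy()
            if np.any(sE < 0):
                raise ValueError("sigma_E must be >= 0")

        def model(r, r_eff):
            return forster_efficiency(r, r_eff)

        sigma_R = geometry.sigma_abscissa
        r_eff = float(self.r_eff_init)
        have_weights = np.any(sE > 0) or sigma_R > 0
        n_iter = self.n_variance_iter if have_weights else 1
        pcov = np.array([[0.0]])
        for _ in range(max(1, n_iter)):
            if have_weights:
                slope = np.abs(_dE_dR(np.maximum(R, 1e-12), r_eff))
                sigma_eff = np.sqrt(sE**2 + (slope * sigma_R) ** 2)
                # guard against zero weights on individual points
                floor = max(1e-12, 1e-6 * (sigma_eff.max() or 1.0))
                sigma_eff = np.maximum(sigma_eff, floor)
            else:
                sigma_eff = None
            try:
                popt, pcov = curve_fit(
                    model,
                    R,
                    E,
                    p0=[r_eff],
                    sigma=sigma_eff,
                    absolute_sigma=have_weights,
                    maxfev=10000,
                )
            except RuntimeError as exc:  # pragma: no cover - pathological input
                raise RuntimeError(f"calibration fit did not converge: {exc}") from exc
            r_eff = float(popt[0])
        self.r_eff_ = r_eff
        self.sigma_r_eff_ = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else 0.0
        self.points_ = pd.DataFrame({"R_nm": R, "E": E, "sigma_E": sE})
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Predicted efficiencies at separations ``X`` (nm)."""
        R = np.asarray(X, dtype=float).reshape(-1)
        return forster_efficiency(R, self.r_eff_)

    def to_model(self) -> CalibrationModel:
        """Export the fitted state as a :class:`CalibrationModel`."""
        return CalibrationModel(
            r_eff=self.r_eff_,
            sigma_r_eff=self.sigma_r_eff_,
            points=self.points_,
            geometry=self.geometry,
        )


def fit_calibration(
    points: Iterable[Sequence[float]] | pd.DataFrame,
    geometry: RulerGeometry | None = None,
) -> CalibrationModel:
    """Fit the effective Forster radius to ruler points.

    Parameters
    ----------
    points : iterable of (R_nm, E, sigma_E) or DataFrame with those columns.
    geometry : RulerGeometry, optional

    Returns
    -------
    CalibrationModel
    """
    geometry = geometry or RulerGeometry()
    if isinstance(points, pd.DataFrame):
        R = points["R_nm"].to_numpy(dtype=float)
        E = points["E"].to_numpy(dtype=float) if "E" in points else points[
            "E_mean"
        ].to_numpy(dtype=float)
        col = "sigma_E" if "sigma_E" in points else ("E_sigma" if "E_sigma" in points else None)
        sE = points[col].to_numpy(dtype=float) if col else None
    else:
        arr = np.asarray([tuple(p) for p in points], dtype=float)
        if arr.size == 0:
            raise ValueError("cannot calibrate on an empty point set")
        R, E = arr[:, 0], arr[:, 1]
        sE = arr[:, 2] if arr.shape[1] > 2 else None
    est = FoersterCalibration(
        rise_per_bp=geometry.rise_per_bp,
        include_linker_in_abscissa=geometry.include_linker_in_abscissa,
        linker_total=geometry.linker_total,
        linker_rel_uncertainty=geometry.linker_rel_uncertainty,
    )
    est.fit(R, E, sigma_E=sE)
    return est.to_model()
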