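"""Single-molecule burst selection and FRET efficiency histogram statistics.

A freely diffusing, doubly-labelled molecule transiting the confocal volume
produces a photon burst: a 1 ms bin whose total (donor + acceptor) count
stands above the background.  For each selected bin the transfer efficiency

    E_i = I_A^i / (I_A^i + I_D^i)

is computed from background-subtracted counts, the efficiencies are
histogrammed, and the histogram is fitted with a Gaussian to extract the mean
efficiency and its full width at half maximum (FWHM).

The minimum width a FRET histogram can have comes from binomial partitioning
of a finite photon count ("shot noise"), sigma = sqrt(E (1-E) / N); the ratio
of the observed to the shot-noise-limited width measures the extra broadening
contributed by linker motion and chain fluctuation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import FWHM_FACTOR

logger = logging.getLogger(__name__)

__all__ = [
    "EfficiencyHistogram",
    "select_bursts",
    "compute_efficiencies",
    "fit_histogram",
    "shot_noise_sigma",
    "shot_noise_fwhm",
    "width_excess",
]

DEFAULT_N_BINS = 40
DEFAULT_HIST_RANGE = (-0.1, 1.1)
DEFAULT_MIN_SAMPLES = 50


@dataclass
class EfficiencyHistogram:
    """A Gaussian-fitted FRET efficiency histogram.

    ``mean_E``/``sigma_E``/``amplitude`` are the least-squares Gaussian
    parameters of the binned counts; ``sample_mean``/``sample_sd`` are the
    plain moments of the underlying efficiency samples (logged alongside the
    fit for comparison).
    """

    samples: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    mean_E: float
    sigma_E: float
    amplitude: float
    covariance: np.ndarray
    sample_mean: float
    sample_sd: float
    metadata: dict = field(default_factory=dict)

    @property
    def fwhm(self) -> float:
        return FWHM_FACTOR * self.sigma_E

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


def _totals(trace) -> np.ndarray:
    return np.asarray(trace.donor_counts) + np.asarray(trace.acceptor_counts)


def select_bursts(trace, threshold: float) -> np.ndarray:
    """Indices of bins whose raw total count strictly exceeds ``threshold``.

    Raw (not background-subtracted) totals are thresholded; the selection is
    order-preserving and idempotent, and raising the threshold can only
    remove bins.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    return np.flatnonzero(_totals(trace) > threshold)


def compute_efficiencies(trace, burst_bins) -> pd.DataFrame:
    """Per-burst-bin efficiencies from background-subtracted counts.

    The mean background rate of each channel is subtracted (expected-value
    subtraction); bins whose subtracted total is <= 0 are dropped and
    counted in a log message.  E is deliberately not clamped to [0, 1] so
    background leakage stays visible in the histogram tails.

    Returns a DataFrame with columns ``bin_index, I_D, I_A, E``.
    """
    burst_bins = np.asarray(burst_bins, dtype=int)
    n = len(trace.donor_counts)
    if burst_bins.size and (burst_bins.min() < 0 or burst_bins.max() >= n):
        raise IndexError(
            f"burst bin indices out of range for a trace of {n} bins"
        )
    I_D = np.asarray(trace.donor_counts, dtype=float)[burst_bins] - trace.background_rate_donor
    I_A = (
        np.asarray(trace.acceptor_counts, dtype=float)[burst_bins]
        - trace.background_rate_acceptor
    )
    total = I_A + I_D
    keep = total > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropped %d of %d burst bins with non-positive subtracted totals",
            n_dropped,
            burst_bins.size,
        )
    return pd.DataFrame(
        {
            "bin_index": burst_bins[keep],
            "I_D": I_D[keep],
            "I_A": I_A[keep],
            "E": I_A[keep] / total[keep],
        }
    )


def _gaussian(x, amplitude, mean, sigma):
    return amplitude * np.exp(-0.5 * ((x - mean) / sigma) ** 2)


def fit_histogram(
    samples,
    n_bins: int = DEFAULT_N_BINS,
    hist_range: tuple[float, float] = DEFAULT_HIST_RANGE,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> EfficiencyHistogram:
    """Histogram efficiency samples and fit the counts with a Gaussian.

    Parameters
    ----------
    samples : array-like or DataFrame with an ``E`` column
    n_bins, hist_range : histogram binning (default 40 bins over [-0.1, 1.1])
    min_samples : minimum number of samples required for a meaningful fit

    Raises
    ------
    ValueError
        On too few samples or a degenerate (zero-width) sample set.
    RuntimeError
        If the least-squares fit does not converge (optimizer diagnostics
        included).
    """
    if isinstance(samples, pd.DataFrame):
        e = samples["E"].to_numpy(dtype=float)
    else:
        e = np.asarray(samples, dtype=float).reshape(-1)
    if e.size < min_samples:
        raise ValueError(
            f"histogram fit needs at least {min_samples} samples, got {e.size}"
        )
    sample_mean = float(e.mean())
    sample_sd = float(e.std(ddof=1))
    if sample_sd == 0.0:
        raise ValueError("all efficiency samples identical: zero-width histogram")
    counts, edges = np.histogram(e, bins=n_bins, range=hist_range)
    if np.count_nonzero(counts) < 4:
        raise ValueError(
            "histogram mass concentrated in fewer than 4 bins "
            f"(sample sd {sample_sd:.2e} vs bin width {(edges[1]-edges[0]):.2e}); "
            "a 3-parameter Gaussian fit is degenerate — use more bins"
        )
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(counts.max()), sample_mean, max(sample_sd, (edges[1] - edges[0]) / 2))
    try:
        popt, pcov = curve_fit(
            _gaussian,
            centers,
            counts.astype(float),
            p0=p0,
            bounds=([0.0, hist_range[0] - 1.0, 1e-6], [np.inf, hist_range[1] + 1.0, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"Gaussian histogram fit did not converge (n={e.size}, "
            f"sample mean={sample_mean:.4f}, sd={sample_sd:.4f}): {exc}"
        ) from exc
    amplitude, mean_E, sigma_E = (float(v) for v in popt)
    if not 0.0 <= mean_E <= 1.0:
        logger.warning("fitted mean efficiency %.4f outside [0, 1]", mean_E)
    logger.info(
        "histogram fit: mean=%.4f sigma=%.4f (sample mean=%.4f sd=%.4f, n=%d)",
        mean_E,
        sigma_E,
        sample_mean,
        sample_sd,
        e.size,
    )
    return EfficiencyHistogram(
        samples=e,
        bin_edges=edges,
        counts=counts,
        mean_E=mean_E,
        sigma_E=sigma_E,
        amplitude=amplitude,
        covariance=pcov,
        sample_mean=sample_mean,
        sample_sd=sample_sd,
    )


def shot_noise_sigma(mean_E: float, mean_total_photons: float) -> float:
    """Shot-noise-limited histogram width sqrt(E (1-E) / N)."""
    if not 0.0 < mean_E < 1.0:
        raise ValueError(f"mean_E must be strictly inside (0, 1), got {mean_E}")
    if mean_total_photons <= 0:
        raise ValueError(f"mean_total_photons must be > 0, got {mean_total_photons}")
    return float(np.sqrt(mean_E * (1.0 - mean_E) / mean_total_photons))


def shot_noise_fwhm(mean_E: float, mean_total_photons: float) -> float:
    """Shot-noise-limited FWHM, 2 sqrt(2 ln 2) * sigma."""
    return FWHM_FACTOR * shot_noise_sigma(mean_E, mean_total_photons)


def width_excess(observed_fwhm: float, shot_noise_fwhm: float) -> float:
    """Ratio of the observed histogram FWHM to the shot-noise limit."""
    if observed_fwhm <= 0 or shot_noise_fwhm <= 0:
        raise ValueError("both widths must be > 0")
    return observed_fwhm / shot_noise_fwhm
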