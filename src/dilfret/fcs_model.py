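"""Single-species FCS autocorrelation model, fitting, and burst statistics.

Fluorescence correlation spectroscopy (FCS) records intensity fluctuations as
fluorophores diffuse through a small confocal detection volume.  For a single
species undergoing 3-D Brownian diffusion the autocorrelation is

    G(tau) = (1/N) * (1 + tau/tau_d)^-1 * (1 + tau/(s^2 tau_d))^-1/2

with ``N`` the mean number of molecules in the volume, ``tau_d`` the
characteristic translational diffusion time, and ``s`` the structure factor
(lateral-to-axial aspect ratio of the detection volume).  Fits hold ``s``
fixed at the instrument-calibrated value (0.1 by default, determined on free
dye and then frozen).

When the diffusing species become too large and heterogeneous for the
single-species model (slow, intense, irregular bursts), traces are instead
characterised by burst counts: maximal runs of bins above a background-derived
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import lmfit
import numpy as np

__all__ = [
    "AutocorrelationCurve",
    "FCSFit",
    "PhotonTrace",
    "BurstStatistics",
    "FitFailureError",
    "autocorrelation_model",
    "fit_autocorrelation",
    "diffusion_coefficient",
    "burst_statistics",
]


class FitFailureError(RuntimeError):
    """Raised when a nonlinear fit fails to produce a usable result."""


@dataclass
class AutocorrelationCurve:
    """Measured (or synthetic) autocorrelation: lag times (s) vs G(tau)."""

    lags: np.ndarray
    G: np.ndarray
    repeats: int | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.lags.shape != self.G.shape or self.lags.ndim != 1:
            raise ValueError("lags and G must be 1-D arrays of equal length")
        if self.lags.size and (np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0)):
            raise ValueError("lags must be strictly increasing and positive")


@dataclass(frozen=True)
class FCSFit:
    """Fitted single-species diffusion parameters."""

    N_particles: float
    tau_d: float  # s
    s: float  # structure factor (held fixed during fitting)
    residual_norm: float = float("nan")

    def __post_init__(self) -> None:
        if self.N_particles <= 0 or self.tau_d <= 0:
            raise ValueError("N_particles and tau_d must be positive")
        if not (0 < self.s <= 1):
            raise ValueError("structure factor must lie in (0, 1]")


@dataclass
class PhotonTrace:
    """Binned photon-count time trace."""

    times: np.ndarray  # s, uniform bin centres
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape or self.times.ndim != 1:
            raise ValueError("times and counts must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise ValueError("trace is empty")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("times must be uniformly spaced and increasing")

    @property
    def bin_width(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else math.nan


@dataclass(frozen=True)
class BurstStatistics:
    """Summary of super-threshold photon bursts in a trace."""

    n_bursts: int
    durations: np.ndarray  # s, one entry per burst
    burst_fraction: float  # fraction of bins inside bursts
    threshold: float


def autocorrelation_model(tau, N_particles: float, tau_d: float, s: float):
    """G(tau) of one species in 3-D Brownian diffusion.

    Accepts scalar or array ``tau`` (s); ``G(0) = 1/N`` exactly and the curve
    decreases monotonically to 0.
    """
    if N_particles <= 0 or tau_d <= 0 or s <= 0:
        raise ValueError("N_particles, tau_d and s must be positive")
    t = np.asarray(tau, dtype=float)
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("tau must be finite and >= 0")
    g = (1.0 / N_particles) / (1.0 + t / tau_d) / np.sqrt(1.0 + t / (s**2 * tau_d))
    return float(g) if np.isscalar(tau) or t.ndim == 0 else g


def fit_autocorrelation(curve: AutocorrelationCurve, fix_s: float = 0.1) -> FCSFit:
    """Least-squares fit of the single-species model with the structure factor fixed.

    ``fix_s`` defaults to 0.1, the free-dye-calibrated value used for all
    fits.  Initial guesses come from the zero-lag amplitude (N ~ 1/G(0)) and
    the half-decay lag (tau_d).  Unweighted residuals.

    Raises
    ------
    FitFailureError
        On degenerate input (e.g. all-zero G) or a non-convergent fit, with
        diagnostics in the message.
    """
    if curve.lags.size < 10:
        raise FitFailureError("need at least 10 lag points spanning the decay")
    if not (0 < fix_s <= 1):
        raise ValueError("fix_s must lie in (0, 1]")
    g0 = float(curve.G[0])
    if not np.isfinite(g0) or g0 <= 0 or np.all(curve.G <= 0):
        raise FitFailureError(f"degenerate curve: zero-lag amplitude {g0!r}")
    n0 = 1.0 / g0
    half = 0.5 * g0
    below = np.nonzero(curve.G <= half)[0]
    tau_d0 = float(curve.lags[below[0]]) if below.size else float(curve.lags[-1])

    model = lmfit.Model(
        lambda tau, N_particles, tau_d: autocorrelation_model(
            tau, N_particles, tau_d, fix_s
        )
    )
    params = model.make_params(
        N_particles={"value": n0, "min": 1e-12},
        tau_d={"value": tau_d0, "min": 1e-15},
    )
    result = model.fit(curve.G, params, tau=curve.lags)
    if not result.success or not np.isfinite(result.chisqr):
        raise FitFailureError(f"fit did not converge: {result.message}")
    return FCSFit(
        N_particles=float(result.params["N_particles"].value),
        tau_d=float(result.params["tau_d"].value),
        s=fix_s,
        residual_norm=float(np.sqrt(result.chisqr)),
    )


def diffusion_coefficient(tau_d: float, beam_waist: float = 0.25) -> float:
    """Translational diffusion coefficient from the diffusion time.

    ``D = w^2 / (4 tau_d)`` with the lateral beam waist ``w`` in µm (an
    instrument calibration parameter; default 0.25 µm) and ``tau_d`` in s;
    returns µm²/s.
    """
    if tau_d <= 0 or beam_waist <= 0:
        raise ValueError("tau_d and beam_waist must be positive")
    return beam_waist**2 / (4.0 * tau_d)


def burst_statistics(
    trace: PhotonTrace, threshold: float | None = None
) -> BurstStatistics:
    """Count maximal super-threshold runs ("bursts") in a photon trace.

    The default threshold is (background level + 5 background SD).  The
    background level is the median count and its SD is the scaled median
    absolute deviation, floored by the shot-noise SD sqrt(median); both are
    robust to the bursts themselves.  Returns the burst count, per-burst
    durations (in s) and the fraction of bins inside bursts.
    """
    counts = trace.counts
    if threshold is None:
        level = float(np.median(counts))
        mad_sd = 1.4826 * float(np.median(np.abs(counts - level)))
        threshold = level + 5.0 * max(mad_sd, math.sqrt(max(level, 0.0)))
    above = counts > threshold
    # run-length encode the boolean mask
    padded = np.concatenate(([False], above, [False])).astype(int)
    edges = np.flatnonzero(np.diff(padded))
    starts, ends = edges[::2], edges[1::2]
    durations = (ends - starts) * (trace.bin_width if counts.size > 1 else 1.0)
    return BurstStatistics(
        n_bursts=len(starts),
        durations=np.asarray(durations, dtype=float),
        burst_fraction=float(above.mean()),
        threshold=float(threshold),
    )
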