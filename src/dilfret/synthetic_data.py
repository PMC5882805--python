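"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator is a pure function of its parameters and a seed, and its
output satisfies the preconditions of the module that consumes it:

* :func:`make_leakage_trace` — two-phase-with-lag lumen-intensity traces
  (defaults at the reported kinetics: 48% first-phase amplitude, 1400 s lag).
* :func:`make_fcs_curve` — single-species autocorrelation curves with
  per-repeat multiplicative noise averaged over sweeps.
* :func:`make_fret_scene` — three-channel images of membrane-rim puncta with
  known per-punctum FRET efficiency, bleed-through and gamma, plus matched
  donor-only / acceptor-only calibration images.
* :func:`make_eff_histogram` — Gaussian-mixture efficiency histograms at
  chosen peak positions.

Noise defaults are generic confocal statistics: Poisson shot noise on
expected counts plus Gaussian read noise (SD 2 counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fcs_model import AutocorrelationCurve, autocorrelation_model
from .leakage_model import LeakageTrace, TwoPhaseParams, two_phase_intensity
from .pixel_fret import BleedThrough, EffHistogram, ThreeChannelImage

__all__ = [
    "Punctum",
    "PunctaScene",
    "MixtureSpec",
    "FretSceneTruth",
    "make_leakage_trace",
    "make_fcs_curve",
    "make_fret_scene",
    "make_eff_histogram",
    "REPORTED_LEAKAGE_PARAMS",
    "REPORTED_GPMV_PEAKS",
]

# Reported study conditions used as generator defaults: first-phase amplitude
# 0.48, lag 1400 s, decay to baseline; printed rates are carried at 1e-3 of
# their printed magnitude so that the first phase (time constant ~30 s) is
# resolved on the minute-scale time axis the lag implies.
REPORTED_LEAKAGE_PARAMS = TwoPhaseParams(k1=0.033, A1=0.48, T_lag=1400.0, k2=0.049, B=0.0)

# Membrane-oligomer efficiency peaks (mean, SD) of the first leakage phase.
REPORTED_GPMV_PEAKS = ((0.21, 0.07), (0.36, 0.04), (0.41, 0.08), (0.58, 0.02))


@dataclass(frozen=True)
class Punctum:
    """One membrane-localised oligomer punctum on the vesicle rim."""

    angle: float  # radians along the rim
    radius_px: float = 3.0  # Gaussian spot SD
    true_E: float = 0.5
    donor_brightness: float = 800.0  # expected peak counts before FRET loss
    acceptor_brightness: float = 600.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_E <= 1.0):
            raise ValueError("true_E must lie in [0, 1]")


@dataclass(frozen=True)
class PunctaScene:
    """Ground-truth description of a synthetic GPMV imaging field.

    The vesicle is rendered as a circular rim (equatorial optical section);
    puncta sit on the rim at the given angles.
    """

    shape: tuple[int, int] = (192, 192)
    center: tuple[float, float] = (96.0, 96.0)
    gpmv_radius_px: float = 60.0
    puncta: tuple[Punctum, ...] = (
        Punctum(angle=0.3, true_E=0.36),
        Punctum(angle=2.4, true_E=0.62),
    )
    bleed_through: BleedThrough = field(
        default_factory=lambda: BleedThrough(beta_donor=0.2, beta_acceptor=0.1, gamma=1.0)
    )
    rim_brightness: float = 30.0
    baseline: float = 3.0  # uniform background counts
    poisson_noise: bool = True
    read_noise_sd: float = 2.0


@dataclass(frozen=True)
class MixtureSpec:
    """Gaussian-mixture specification for synthetic efficiency histograms."""

    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...] | None = None
    n_samples: int = 100_000
    n_bins: int = 50

    def __post_init__(self) -> None:
        k = len(self.means)
        if len(self.sds) != k:
            raise ValueError("means and sds must have equal length")
        if any(not 0 <= m <= 1 for m in self.means):
            raise ValueError("means must lie in [0, 1]")
        if self.weights is not None:
            if len(self.weights) != k:
                raise ValueError("weights must match means")
            if abs(sum(self.weights) - 1.0) > 1e-9:
                raise ValueError("weights must sum to 1")


@dataclass
class FretSceneTruth:
    """Ground truth accompanying a rendered FRET scene."""

    image: ThreeChannelImage
    donor_only: ThreeChannelImage
    acceptor_only: ThreeChannelImage
    true_E_map: np.ndarray  # NaN off-puncta
    punctum_masks: list  # boolean mask per punctum
    bleed_through: BleedThrough


def make_leakage_trace(
    params: TwoPhaseParams = REPORTED_LEAKAGE_PARAMS,
    dt: float = 2.0,
    duration: float = 4000.0,
    noise_sd: float = 0.01,
    seed: int | None = None,
) -> LeakageTrace:
    """Two-phase leakage trace: exact model curve plus additive Gaussian noise.

    A duration shorter than the lag produces a single-phase-only trace (a
    valid degenerate input for the fitter).
    """
    times = np.arange(0.0, duration + dt / 2, dt)
    clean = two_phase_intensity(times, params)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sd, size=times.shape) if noise_sd > 0 else clean
    # keep within the trace type's normalised-intensity tolerance
    noisy = np.clip(noisy, -0.1, 1.2)
    return LeakageTrace(times=times, intensity=noisy, noise_sd=noise_sd)


def make_fcs_curve(
    N_particles: float = 5.0,
    tau_d: float = 1e-3,
    s: float = 0.1,
    lags: np.ndarray | None = None,
    noise_sd: float = 0.01,
    repeats: int = 30,
    seed: int | None = None,
) -> AutocorrelationCurve:
    """Synthetic autocorrelation curve averaged over noisy repeat sweeps.

    Each repeat applies multiplicative Gaussian noise (SD ``noise_sd``) to
    the exact model curve; the returned curve is the mean over ``repeats``,
    so its residual SD shrinks as 1/sqrt(repeats).
    """
    if lags is None:
        lags = np.logspace(-6, 0, 120)
    g = autocorrelation_model(lags, N_particles, tau_d, s)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sweeps = g * (1.0 + rng.normal(0.0, noise_sd, size=(repeats, lags.size)))
        g = sweeps.mean(axis=0)
    return AutocorrelationCurve(lags=lags, G=g, repeats=repeats)


def _gaussian_spot(shape, center, sd):
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    return np.exp(-(((rows - center[0]) ** 2 + (cols - center[1]) ** 2) / (2 * sd**2)))


def make_fret_scene(scene: PunctaScene = PunctaScene(), seed: int | None = None) -> FretSceneTruth:
    """Render a synthetic three-channel FRET field with calibration images.

    Per-pixel expected counts: donor emission is scaled by (1 - E), the
    sensitized FRET emission by gamma * E; bleed-through adds
    ``beta_d * donor + beta_a * acceptor`` to the FRET channel.  Calibration
    fields re-render the same puncta with only one label present.
    """
    shape = scene.shape
    cy, cx = scene.center
    bt = scene.bleed_through
    donor_clean = np.full(shape, 0.0)
    acceptor_clean = np.full(shape, 0.0)
    sensitized = np.full(shape, 0.0)
    donor_cal = np.full(shape, 0.0)
    acceptor_cal = np.full(shape, 0.0)
    true_E = np.full(shape, np.nan)
    punctum_masks = []

    # faint unlabeled-membrane rim so the vesicle outline is visible
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    d = np.hypot(rows - cy, cols - cx)
    rim = scene.rim_brightness * np.exp(-((d - scene.gpmv_radius_px) ** 2) / (2 * 1.5**2))
    donor_clean += 0.05 * rim
    acceptor_clean += 0.05 * rim

    for p in scene.puncta:
        py = cy + scene.gpmv_radius_px * math.sin(p.angle)
        px = cx + scene.gpmv_radius_px * math.cos(p.angle)
        if not (0 <= py < shape[0] and 0 <= px < shape[1]):
            raise ValueError(f"punctum at angle {p.angle} falls off the canvas")
        spot = _gaussian_spot(shape, (py, px), p.radius_px)
        donor_clean += p.donor_brightness * (1.0 - p.true_E) * spot
        acceptor_clean += p.acceptor_brightness * spot
        sensitized += bt.gamma * p.donor_brightness * p.true_E * spot
        donor_cal += p.donor_brightness * spot
        acceptor_cal += p.acceptor_brightness * spot
        mask = spot > 0.25
        punctum_masks.append(mask)
        true_E[mask] = p.true_E

    def finalize(donor, acceptor, fret, rng):
        fret = fret + bt.beta_donor * donor + bt.beta_acceptor * acceptor
        out = []
        for ch in (donor, acceptor, fret):
            expected = ch + scene.baseline
            noisy = (
                rng.poisson(expected).astype(float) if scene.poisson_noise else expected
            )
            if scene.read_noise_sd > 0:
                noisy = noisy + rng.normal(0.0, scene.read_noise_sd, size=shape)
            out.append(np.clip(noisy, 0.0, None))
        return ThreeChannelImage(donor=out[0], acceptor=out[1], fret=out[2])

    rng = np.random.default_rng(seed)
    image = finalize(donor_clean, acceptor_clean, sensitized, rng)
    donor_only = finalize(donor_cal, np.zeros(shape), np.zeros(shape), rng)
    acceptor_only = finalize(np.zeros(shape), acceptor_cal, np.zeros(shape), rng)
    return FretSceneTruth(
        image=image,
        donor_only=donor_only,
        acceptor_only=acceptor_only,
        true_E_map=true_E,
        punctum_masks=punctum_masks,
        bleed_through=bt,
    )


def make_eff_histogram(spec: MixtureSpec, seed: int | None = None) -> tuple[EffHistogram, np.ndarray]:
    """Sample a Gaussian mixture of efficiencies and bin it over [0, 1].

    Returns the histogram together with the raw samples (the ground truth).
    The mixture is truncated to [0, 1] by rejection (out-of-range draws are
    redrawn from their component), so no artificial point mass accumulates
    at the boundaries.
    """
    rng = np.random.default_rng(seed)
    k = len(spec.means)
    weights = np.asarray(spec.weights if spec.weights is not None else [1.0 / k] * k)
    comp = rng.choice(k, size=spec.n_samples, p=weights)
    means_arr, sds_arr = np.asarray(spec.means), np.asarray(spec.sds)
    samples = rng.normal(means_arr[comp], sds_arr[comp])
    out = (samples < 0.0) | (samples > 1.0)
    while out.any():
        redraw = comp[out]
        samples[out] = rng.normal(means_arr[redraw], sds_arr[redraw])
        out = (samples < 0.0) | (samples > 1.0)
    counts, edges = np.histogram(samples, bins=spec.n_bins, range=(0.0, 1.0))
    return EffHistogram(bin_edges=edges, counts=counts, source_mask="synthetic-mixture"), samples
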