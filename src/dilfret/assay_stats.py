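"""Closed-form assay statistics: percent toxicity and detected-acceptor fraction."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "ViabilityPlate",
    "UndefinedScaleError",
    "percent_toxicity",
    "detected_acceptor_fraction",
]


class UndefinedScaleError(ValueError):
    """Raised when the positive and negative controls coincide."""


@dataclass(frozen=True)
class ViabilityPlate:
    """Mean viability-assay fluorescence of sample and controls (a.u.).

    The negative control (vehicle only) defines 0% toxicity and the positive
    control (e.g. 10% DMSO) defines 100%.
    """

    sample_mean: float
    negative_control_mean: float
    positive_control_mean: float
    n_sample: int = 1
    n_negative: int = 1
    n_positive: int = 1

    def __post_init__(self) -> None:
        if self.negative_control_mean == self.positive_control_mean:
            raise UndefinedScaleError(
                "negative and positive control means coincide; toxicity scale undefined"
            )


def percent_toxicity(plate: ViabilityPlate) -> float:
    """Percent toxicity of a sample relative to plate controls.

    ``100 - 100 * (<S> - <P>) / (<N> - <P>)``: 0% when the sample matches the
    negative control, 100% at the positive control.  Values outside [0, 100]
    (e.g. fluorescence above the negative control) are reported as-is with a
    warning rather than clamped.
    """
    s = plate.sample_mean
    n = plate.negative_control_mean
    p = plate.positive_control_mean
    tox = 100.0 - 100.0 * (s - p) / (n - p)
    if not (0.0 <= tox <= 100.0):
        warnings.warn(
            f"percent toxicity {tox:.1f} outside [0, 100]; sample lies beyond the controls",
            stacklevel=2,
        )
    return tox


def detected_acceptor_fraction(n_fret_pixels: int, n_acceptor_pixels: int) -> float:
    """Fraction of acceptor-positive pixels that also show FRET.

    Estimates the share of acceptor molecules participating in FRET-competent
    assemblies.
    """
    if n_acceptor_pixels <= 0:
        raise UndefinedScaleError("no acceptor pixels; fraction undefined")
    if n_fret_pixels < 0 or n_fret_pixels > n_acceptor_pixels:
        raise ValueError("n_fret_pixels must lie in [0, n_acceptor_pixels]")
    return n_fret_pixels / n_acceptor_pixels
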