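"""Pairwise and multi-acceptor Förster transfer efficiency.

The pairwise efficiency follows the standard Förster relation

    E(r) = R0^6 / (R0^6 + r^6),

where ``R0`` is the Förster distance (donor–acceptor separation giving 50%
transfer).  When a donor sees several acceptors, each donor–acceptor pair is
treated as an *independent* opportunity for resonance transfer, so the
probability that the donor transfers to at least one acceptor is

    E_multi = 1 - prod_j (1 - E(r_j)).

With three acceptors each at r = R0 this gives 1 - 0.5^3 = 0.875, which is
the combination rule used throughout this package (kinetic rate competition,
by contrast, would give 0.75 for the same geometry).  Donor–donor and
acceptor–acceptor couplings are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ForsterConstants",
    "FluorophoreConfiguration",
    "UndefinedEfficiencyError",
    "pair_efficiency",
    "donor_transfer_efficiency",
    "configuration_efficiency",
]


class UndefinedEfficiencyError(ValueError):
    """Raised when an efficiency is requested for a donor-free configuration."""


@dataclass(frozen=True)
class ForsterConstants:
    """Physical constants of the donor/acceptor pair.

    Parameters
    ----------
    R0 : float
        Förster distance in Å.  Default 52 Å (Alexa 488 / Atto 647 pair).
    """

    R0: float = 52.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.R0) or self.R0 <= 0:
            raise ValueError(f"R0 must be positive and finite, got {self.R0!r}")


@dataclass
class FluorophoreConfiguration:
    """Donor and acceptor coordinates (Å) of one oligomer snapshot.

    Either list may be empty.  Arrays are coerced to shape ``(k, 3)``.
    """

    donor_positions: np.ndarray
    acceptor_positions: np.ndarray

    def __post_init__(self) -> None:
        self.donor_positions = _as_coords(self.donor_positions, "donor_positions")
        self.acceptor_positions = _as_coords(
            self.acceptor_positions, "acceptor_positions"
        )


def _as_coords(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        return arr.reshape(0, 3)
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 3:
        raise ValueError(f"{name} must be an (k, 3) array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return arr


def pair_efficiency(r, constants: ForsterConstants = ForsterConstants()):
    """Transfer efficiency of a single donor–acceptor pair at distance ``r`` (Å).

    Accepts a scalar or array of distances; returns the same shape.
    ``E = 1 / (1 + (r/R0)^6)``, which equals 0.5 at ``r = R0``.
    """
    r_arr = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r_arr)) or np.any(r_arr < 0):
        raise ValueError("distances must be finite and non-negative")
    eff = 1.0 / (1.0 + (r_arr / constants.R0) ** 6)
    return float(eff) if np.isscalar(r) or r_arr.ndim == 0 else eff


def donor_transfer_efficiency(
    distances, constants: ForsterConstants = ForsterConstants()
) -> float:
    """Efficiency of one donor facing acceptors at the given distances (Å).

    Combines pairwise efficiencies as independent transfer opportunities:
    ``1 - prod(1 - E(r_j))``.  An empty list returns 0 (no acceptor, no
    transfer).  Order-invariant, and always at least the best single pair.
    """
    d = np.asarray(distances, dtype=float).ravel()
    if d.size == 0:
        return 0.0
    p = pair_efficiency(d, constants)
    return float(1.0 - np.prod(1.0 - np.atleast_1d(p)))


def configuration_efficiency(
    config: FluorophoreConfiguration,
    constants: ForsterConstants = ForsterConstants(),
) -> float:
    """Mean transfer efficiency over the donors of a configuration.

    Each donor combines all acceptors under the independent-probability rule;
    the configuration's efficiency is the unweighted mean over donors (the
    per-donor-photon expectation).  Donor–donor and acceptor–acceptor
    couplings are not considered.

    Raises
    ------
    UndefinedEfficiencyError
        If the configuration has no donors (no FRET-channel signal exists;
        callers must filter such configurations).
    """
    nd = len(config.donor_positions)
    if nd == 0:
        raise UndefinedEfficiencyError("configuration has no donors")
    if len(config.acceptor_positions) == 0:
        return 0.0
    dist = cdist(config.donor_positions, config.acceptor_positions)
    p = 1.0 / (1.0 + (dist / constants.R0) ** 6)
    per_donor = 1.0 - np.prod(1.0 - p, axis=1)
    return float(per_donor.mean())
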