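"""Monte-Carlo simulator of diluted intermolecular FRET in spherical oligomers.

An oligomer of N monomers is modelled as a sphere whose volume is
N × (volume per monomer), i.e. constant protein density.  At a doping ratio
d:a:X (donor-labelled : acceptor-labelled : unlabelled monomer), each monomer
independently carries a donor with probability d/(d+a+X), an acceptor with
probability a/(d+a+X), and no label otherwise.  Labelled monomers are placed
uniformly at random in the sphere, and the trial's FRET efficiency is the
multi-acceptor configuration efficiency from :mod:`dilfret.fret_core`.

Because labels are heavily diluted (typically 1:1:X with X of order 100–500),
only oligomers with N of order X or larger are likely to contain both a donor
and an acceptor — this is what makes the measurement selective for large
assemblies.  Trials are averaged until the running mean converges.

Averaging convention: trials with no donor produce no FRET-channel signal and
are excluded; donor-bearing trials with no acceptor contribute efficiency 0.
Positions are redrawn independently every trial, which represents the rapidly
equilibrating ("dynamic") oligomer regime by averaging over placements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fret_core import ForsterConstants

__all__ = [
    "DopingRatio",
    "OligomerSpec",
    "ConvergenceControl",
    "SimulationResult",
    "sphere_radius",
    "labeling_probability",
    "pair_fraction",
    "sample_label_counts",
    "sample_positions",
    "run_trial",
    "simulate_average_fret",
    "fret_vs_N_curve",
]

NO_SIGNAL = None  # marker returned by run_trial for donor-free oligomers


@dataclass(frozen=True)
class DopingRatio:
    """Donor : acceptor : unlabelled monomer stoichiometry (e.g. 1:1:500)."""

    donor: float = 1.0
    acceptor: float = 1.0
    unlabeled: float = 500.0

    def __post_init__(self) -> None:
        for name, v in (
            ("donor", self.donor),
            ("acceptor", self.acceptor),
            ("unlabeled", self.unlabeled),
        ):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"doping component {name} must be >= 0, got {v!r}")
        if self.donor + self.acceptor + self.unlabeled <= 0:
            raise ValueError("doping ratio must have a positive total")

    @property
    def probabilities(self) -> tuple[float, float, float]:
        """Per-monomer (donor, acceptor, unlabelled) probabilities."""
        total = self.donor + self.acceptor + self.unlabeled
        return (self.donor / total, self.acceptor / total, self.unlabeled / total)

    @classmethod
    def parse(cls, text: str) -> "DopingRatio":
        """Parse a 'd:a:X' string such as '1:1:500'."""
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"doping ratio must be 'd:a:X', got {text!r}")
        return cls(*(float(p) for p in parts))

    def __str__(self) -> str:
        def fmt(v: float) -> str:
            return str(int(v)) if float(v).is_integer() else str(v)

        return f"{fmt(self.donor)}:{fmt(self.acceptor)}:{fmt(self.unlabeled)}"


@dataclass(frozen=True)
class OligomerSpec:
    """Parameters of one diluted-FRET simulation condition."""

    N: int = 500
    doping: DopingRatio = field(default_factory=DopingRatio)
    volume_per_monomer: float = 4000.0  # Å³ per monomer (protein density)
    constants: ForsterConstants = field(default_factory=ForsterConstants)

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 1:
            raise ValueError(f"N must be an integer >= 1, got {self.N!r}")
        if not math.isfinite(self.volume_per_monomer) or self.volume_per_monomer <= 0:
            raise ValueError("volume_per_monomer must be positive")

    @property
    def radius(self) -> float:
        return sphere_radius(self.N, self.volume_per_monomer)


@dataclass(frozen=True)
class ConvergenceControl:
    """Stopping rule for the running-mean Monte Carlo average.

    The simulation stops once the running mean over donor-bearing trials has
    changed by less than ``tolerance`` across a window of ``window`` trials
    (checked after at least ``min_trials`` total trials), or at
    ``max_trials``.
    """

    min_trials: int = 10_000
    max_trials: int = 1_000_000
    tolerance: float = 1e-3
    window: int = 1_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.min_trials > self.max_trials:
            raise ValueError("min_trials must be <= max_trials")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass(frozen=True)
class SimulationResult:
    """Converged (or capped) Monte-Carlo average for one (doping, N) cell."""

    mean_fret: float
    std_err: float
    n_trials: int
    n_donor_trials: int
    n_fret_capable: int  # trials with >=1 donor AND >=1 acceptor
    converged: bool
    seed: int | None


def sphere_radius(N: int, volume_per_monomer: float = 4000.0) -> float:
    """Radius (Å) of a sphere holding ``N`` monomers at fixed density.

    ``R = (3 N v / 4π)^(1/3)`` — constant protein density, so R ∝ N^(1/3).
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N!r}")
    if volume_per_monomer <= 0:
        raise ValueError("volume_per_monomer must be positive")
    return (3.0 * N * volume_per_monomer / (4.0 * math.pi)) ** (1.0 / 3.0)


def labeling_probability(X: float) -> float:
    """Per-monomer probability of carrying any label at doping 1:1:X.

    Equals ``2 / (X + 2)``.
    """
    if not math.isfinite(X) or X < 0:
        raise ValueError(f"X must be >= 0, got {X!r}")
    return 2.0 / (X + 2.0)


def pair_fraction(N: int, X: float) -> float:
    """Fraction of N-mers carrying exactly one donor and one acceptor at 1:1:X.

    Binomial probability of exactly two labelled monomers, scaled by 0.5 for
    the chance that the two labels are one donor and one acceptor (rather
    than two of the same kind).  Returns 0 for N < 2, which cannot host a
    pair.
    """
    if N < 2:
        return 0.0
    p = labeling_probability(X)
    return 0.5 * math.comb(N, 2) * p**2 * (1.0 - p) ** (N - 2)


def sample_label_counts(
    N: int, doping: DopingRatio, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw (n_donors, n_acceptors) for one trial oligomer.

    Each monomer is independently donor / acceptor / unlabelled with the
    doping-ratio probabilities (a trinomial draw).
    """
    pd_, pa, pu = doping.probabilities
    n_d, n_a, _ = rng.multinomial(N, (pd_, pa, pu))
    return int(n_d), int(n_a)


def sample_positions(k: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """``k`` points uniform in the ball of the given radius (Å).

    Isotropic directions from normalised Gaussian deviates; radii from the
    inverse CDF ``r = R u^(1/3)`` so that P(r <= ρ) = (ρ/R)³.
    """
    if k == 0:
        return np.empty((0, 3))
    directions = rng.standard_normal((k, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = radius * rng.random(k) ** (1.0 / 3.0)
    return directions * radii[:, None]


def _trial(
    spec: OligomerSpec, rng: np.random.Generator, radius: float
) -> tuple[float | None, int, int]:
    """One trial; returns (efficiency-or-None, n_donors, n_acceptors)."""
    n_d, n_a = sample_label_counts(spec.N, spec.doping, rng)
    if n_d == 0:
        return NO_SIGNAL, n_d, n_a
    if n_a == 0:
        return 0.0, n_d, n_a
    donors = sample_positions(n_d, radius, rng)
    acceptors = sample_positions(n_a, radius, rng)
    # inlined configuration_efficiency (hot path)
    diff = donors[:, None, :] - acceptors[None, :, :]
    dist6 = (diff * diff).sum(axis=2) ** 3
    p = 1.0 / (1.0 + dist6 / spec.constants.R0**6)
    return float((1.0 - np.prod(1.0 - p, axis=1)).mean()), n_d, n_a


def run_trial(spec: OligomerSpec, rng: np.random.Generator) -> float | None:
    """One random oligomer: draw labels, place fluorophores, score FRET.

    Returns :data:`NO_SIGNAL` (``None``) when the trial has no donor, 0.0
    when donors are present without acceptors, otherwise the mean per-donor
    multi-acceptor efficiency.
    """
    eff, _, _ = _trial(spec, rng, spec.radius)
    return eff


def simulate_average_fret(
    spec: OligomerSpec, control: ConvergenceControl = ConvergenceControl()
) -> SimulationResult:
    """Average FRET efficiency of random oligomers until convergence.

    Donor-free trials are excluded from the average; donor-bearing trials
    without an acceptor contribute 0.  Deterministic for a given
    ``control.seed``.
    """
    if spec.doping.donor <= 0:
        raise ValueError("simulation requires a positive donor doping component")
    rng = np.random.default_rng(control.seed)
    radius = spec.radius
    total = 0.0
    total_sq = 0.0
    n_donor = 0
    n_capable = 0
    n_trials = 0
    last_mean = np.nan
    converged = False
    while n_trials < control.max_trials:
        eff, n_d, n_a = _trial(spec, rng, radius)
        n_trials += 1
        if eff is not None:
            total += eff
            total_sq += eff * eff
            n_donor += 1
            if n_a > 0:
                n_capable += 1
        if n_trials % control.window == 0 and n_trials >= control.min_trials:
            mean = total / n_donor if n_donor else 0.0
            if n_donor and not np.isnan(last_mean):
                if abs(mean - last_mean) < control.tolerance:
                    converged = True
                    break
            last_mean = mean
    mean = total / n_donor if n_donor else 0.0
    if n_donor > 1:
        var = max(total_sq / n_donor - mean * mean, 0.0)
        std_err = math.sqrt(var / n_donor)
    else:
        std_err = float("nan")
    return SimulationResult(
        mean_fret=mean,
        std_err=std_err,
        n_trials=n_trials,
        n_donor_trials=n_donor,
        n_fret_capable=n_capable,
        converged=converged,
        seed=control.seed,
    )


def fret_vs_N_curve(
    N_grid,
    dopings,
    volume_per_monomer: float = 4000.0,
    constants: ForsterConstants = ForsterConstants(),
    control: ConvergenceControl = ConvergenceControl(),
) -> pd.DataFrame:
    """Simulated average FRET efficiency over a grid of sizes and dopings.

    Returns a tidy table with one row per (doping ratio, N): columns
    ``ratio, N, mean_fret, std_err, n_trials, n_donor_trials, converged``.
    Each cell derives its RNG stream from ``control.seed`` and the cell
    index, so the table is reproducible as a whole.
    """
    N_grid = list(N_grid)
    dopings = list(dopings)
    if not N_grid or not dopings:
        raise ValueError("N_grid and dopings must be non-empty")
    rows = []
    for i, doping in enumerate(dopings):
        if isinstance(doping, str):
            doping = DopingRatio.parse(doping)
        for j, N in enumerate(N_grid):
            cell_seed = (
                None
                if control.seed is None
                else (control.seed + 100_003 * i + j) % (2**31 - 1)
            )
            cell_control = replace(control, seed=cell_seed)
            spec = OligomerSpec(
                N=int(N),
                doping=doping,
                volume_per_monomer=volume_per_monomer,
                constants=constants,
            )
            res = simulate_average_fret(spec, cell_control)
            rows.append(
                {
                    "ratio": str(doping),
                    "N": int(N),
                    "mean_fret": res.mean_fret,
                    "std_err": res.std_err,
                    "n_trials": res.n_trials,
                    "n_donor_trials": res.n_donor_trials,
                    "converged": res.converged,
                }
            )
    return pd.DataFrame(rows)
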