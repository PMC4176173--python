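"""Domain types for the stochastic transcription-elongation lattice model.

A gene is a one-dimensional lattice of ``L`` nucleotide sites (1-based,
site 1 is the transcription start).  Elongation complexes (RNAPs) occupy
``footprint`` consecutive sites, step downstream one site at a time, and at
a fixed set of pause sites may fall into a long-lived stalled (backtracked)
state.  The Gre transcript-cleavage factor is modelled purely through its
effect on the pause kinetics: a scenario mimicking its absence multiplies
the pause duration ``tau``, the pause frequency ``f``, or divides the
stepping rate ``epsilon``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GeneModel",
    "KineticParams",
    "Scenario",
    "SCENARIO_NAMES",
    "TimestepError",
    "build_gene",
    "apply_scenario",
]

#: Scenario names: wild type plus the three hypotheses for what the Gre
#: factor does (suppress pause duration, pause frequency, or speed stepping).
SCENARIO_NAMES = (
    "wildtype",
    "nogre_pause_duration",
    "nogre_pause_frequency",
    "nogre_stepping_rate",
)


class TimestepError(ValueError):
    """Raised when the fixed timestep is too coarse for the given rates."""


@dataclass(frozen=True)
class GeneModel:
    """A gene as a lattice with pause sites and two probe windows.

    Coordinates are 1-based closed intervals.  ``probe_early`` hybridises
    to the 5' end of the transcript, ``probe_late`` to the 3' end; a
    transcript carries a probe's full target once the active site has
    passed the window's 3' end.
    """

    length: int
    pause_sites: tuple[int, ...]
    probe_early: tuple[int, int]
    probe_late: tuple[int, int]
    seed: int = 0

    def __post_init__(self) -> None:
        L = self.length
        if L < 10:
            raise ValueError(f"gene length must be >= 10 sites, got {L}")
        sites = tuple(int(s) for s in self.pause_sites)
        if sites != tuple(sorted(set(sites))):
            raise ValueError("pause sites must be unique and sorted")
        if sites and (sites[0] < 1 or sites[-1] > L):
            raise ValueError("pause sites must lie within [1, L]")
        object.__setattr__(self, "pause_sites", sites)
        for name in ("probe_early", "probe_late"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi <= L):
                raise ValueError(f"{name}={lo, hi} outside [1, {L}]")
            object.__setattr__(self, name, (int(lo), int(hi)))
        if not self.probe_early[1] < self.probe_late[1]:
            raise ValueError("probe_early must end upstream of probe_late")

    @property
    def pause_mask(self) -> np.ndarray:
        """Boolean lattice mask, index = site (length ``L + 2``)."""
        mask = np.zeros(self.length + 2, dtype=np.bool_)
        if self.pause_sites:
            mask[np.asarray(self.pause_sites)] = True
        return mask

    @property
    def probe_distance(self) -> int:
        """Distance between the 3' ends of the two probe windows (nt)."""
        return self.probe_late[1] - self.probe_early[1]

    def to_dict(self) -> dict:
        return {
            "length": self.length,
            "pause_sites": list(self.pause_sites),
            "probe_early": list(self.probe_early),
            "probe_late": list(self.probe_late),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneModel":
        return cls(
            length=int(d["length"]),
            pause_sites=tuple(d["pause_sites"]),
            probe_early=tuple(d["probe_early"]),
            probe_late=tuple(d["probe_late"]),
            seed=int(d.get("seed", 0)),
        )


@dataclass(frozen=True)
class KineticParams:
    """Kinetic parameters of the elongation model.

    alpha
        Initiation attempt rate (1/s); an attempt succeeds only when the
        promoter region (sites ``1..footprint``) is free.
    epsilon
        Stepping rate (nt/s) of an active complex.
    f
        Stall rate (1/s) while the active site sits on a pause site.
    tau
        Mean stall duration (s); rescue rate is ``1/tau``.
    footprint
        Lattice sites occupied per elongation complex (nt); enforces the
        hard-core exclusion spacing.
    dt
        Fixed kinetic Monte Carlo timestep (s).
    """

    alpha: float
    epsilon: float
    f: float = 0.0
    tau: float = 1.0
    footprint: int = 35
    dt: float = 0.01

    def __post_init__(self) -> None:
        for name in ("alpha", "epsilon", "f"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.f > 0 and self.tau <= 0:
            raise ValueError("tau must be > 0 when f > 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.footprint < 1:
            raise ValueError("footprint must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def max_rate(self) -> float:
        rates = [self.alpha, self.epsilon, self.f]
        if self.tau > 0:
            rates.append(1.0 / self.tau)
        return max(rates)

    def check_dt(self, limit: float = 0.2) -> None:
        """Refuse timesteps where any per-step probability exceeds ``limit``.

        With per-event probabilities ``rate * dt`` the discrete chain only
        approximates the continuous-time process when those probabilities
        are small; 0.2 keeps discretisation bias at the percent level.
        """
        if self.dt * self.max_rate > limit + 1e-12:
            raise TimestepError(
                f"dt={self.dt} too coarse for max rate {self.max_rate:g} "
                f"(dt*rate={self.dt * self.max_rate:.3g} > {limit})"
            )

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "epsilon": self.epsilon,
            "f": self.f,
            "tau": self.tau,
            "footprint": self.footprint,
            "dt": self.dt,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "KineticParams":
        return cls(**{k: d[k] for k in ("alpha", "epsilon", "f", "tau", "footprint", "dt") if k in d})


@dataclass(frozen=True)
class Scenario:
    """One hypothesis for the kinetic effect of losing the Gre factor."""

    name: str
    factor: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(
                f"unknown scenario {self.name!r}; expected one of {SCENARIO_NAMES}"
            )
        if self.factor <= 0:
            raise ValueError("scenario factor must be > 0")


def apply_scenario(base: KineticParams, scenario: Scenario) -> KineticParams:
    """Return a new parameter set with the scenario applied to ``base``.

    Exactly one of ``tau`` (multiplied), ``f`` (multiplied) or ``epsilon``
    (divided) changes; ``wildtype`` returns the base unchanged.
    """
    if scenario.name == "wildtype":
        return base
    if scenario.name == "nogre_pause_duration":
        return replace(base, tau=base.tau * scenario.factor)
    if scenario.name == "nogre_pause_frequency":
        return replace(base, f=base.f * scenario.factor)
    if scenario.name == "nogre_stepping_rate":
        return replace(base, epsilon=base.epsilon / scenario.factor)
    raise ValueError(f"unknown scenario {scenario.name!r}")  # pragma: no cover


def build_gene(
    L: int,
    pause_density: float,
    seed: int,
    probe_layout: Sequence[float] = (500 / 2700, 500 / 2700),
) -> GeneModel:
    """Construct a gene with randomly placed pause sites.

    ``round(pause_density * L)`` pause sites are drawn uniformly without
    replacement from sites ``[2, L-1]`` using ``seed``; the draw is a pure
    function of ``(L, pause_density, seed)``.  ``probe_layout`` gives the
    early and late probe window lengths as fractions of ``L``: the early
    window starts at site 1, the late window ends at site ``L``.
    """
    if L < 10:
        raise ValueError(f"gene length must be >= 10, got {L}")
    if not 0.0 <= pause_density <= 0.2:
        raise ValueError(f"pause_density must lie in [0, 0.2], got {pause_density}")
    n_pauses = round(pause_density * L)
    candidates = L - 2  # sites 2..L-1
    if n_pauses > candidates:
        raise ValueError(f"cannot place {n_pauses} pause sites on {candidates} interior sites")
    rng = np.random.default_rng(seed)
    sites = rng.choice(np.arange(2, L), size=n_pauses, replace=False) if n_pauses else np.array([], int)
    early_len = max(1, round(probe_layout[0] * L))
    late_len = max(1, round(probe_layout[1] * L))
    return GeneModel(
        length=L,
        pause_sites=tuple(sorted(int(s) for s in sites)),
        probe_early=(1, early_len),
        probe_late=(L - late_len + 1, L),
        seed=seed,
    )
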