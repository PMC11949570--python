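"""Spatially explicit point-pattern communities in the unit square.

A community is a set of individuals with coordinates in [0, 1), integer
species labels and a survival flag (time-1 snapshot vs. time-2 snapshot).
Communities are generated in two stages:

1. a lognormal species-abundance distribution (SAD) whose unevenness is
   set by a single target coefficient of variation ``cv_n``, realized by
   multinomial assignment of ``n_tot`` individuals to ``s_tot`` species;
2. a Thomas cluster point process: one mother point per species, uniform
   in the unit square, with each individual Gaussian-displaced from its
   mother by sd ``sigma`` per axis and wrapped onto the unit torus.

The torus wrap keeps each species' regional abundance exact (no edge
thinning), at the cost of clusters that can straddle the region boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CommunitySpec",
    "PointCommunity",
    "derive_s_tot",
    "sim_sad",
    "sim_thomas",
    "simulate_community",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CommunitySpec:
    """Generator settings for one point-pattern community.

    n_tot  : total number of individuals in the region (>= 1)
    s_frac : species pool as a fraction of n_tot; s_tot = round(s_frac * n_tot)
    cv_n   : target coefficient of variation of the SAD (sd/mean of
             abundances); higher means a less even SAD
    sigma  : per-axis sd of offspring displacement from the mother point,
             in units of the region side length
    """

    n_tot: int
    s_frac: float
    cv_n: float
    sigma: float

    def __post_init__(self) -> None:
        if self.n_tot < 1:
            raise ValueError("n_tot must be >= 1")
        if not (0.0 < self.s_frac <= 1.0):
            raise ValueError("s_frac must lie in (0, 1]")
        if self.cv_n <= 0:
            raise ValueError("cv_n must be > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    @property
    def s_tot(self) -> int:
        return derive_s_tot(self.n_tot, self.s_frac)


@dataclass
class PointCommunity:
    """Individuals as labelled points in the unit square.

    x, y     : coordinates in [0, 1)
    species  : integer labels in {1..s_tot}
    alive_t2 : survival flags (all True until mortality is applied)
    """

    x: np.ndarray
    y: np.ndarray
    species: np.ndarray
    alive_t2: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.species = np.asarray(self.species, dtype=np.int64)
        if self.alive_t2 is None:
            self.alive_t2 = np.ones(self.x.size, dtype=bool)
        self.alive_t2 = np.asarray(self.alive_t2, dtype=bool)
        n = self.x.size
        if not (self.y.size == self.species.size == self.alive_t2.size == n):
            raise ValueError("x, y, species, alive_t2 must have equal length")
        # generated communities live on [0, 1); an exact 1.0 (e.g. from an
        # imported snapshot) is tolerated and clamped into the last grid cell
        if n and (
            self.x.min() < 0 or self.x.max() > 1
            or self.y.min() < 0 or self.y.max() > 1
        ):
            raise ValueError("coordinates must lie in the unit square")

    def __len__(self) -> int:
        return self.x.size

    @property
    def n_species(self) -> int:
        return int(np.unique(self.species).size)

    def abundances(self) -> pd.Series:
        """Regional abundance per species (time 1)."""
        return pd.Series(self.species).value_counts().sort_index()

    def with_survival(self, alive: np.ndarray) -> "PointCommunity":
        return PointCommunity(self.x, self.y, self.species, np.asarray(alive, bool))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "species": self.species,
                "alive_t2": self.alive_t2.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PointCommunity":
        df = pd.read_csv(path)
        required = {"x", "y", "species", "alive_t2"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"point snapshot CSV missing columns: {sorted(missing)}")
        return cls(
            df["x"].to_numpy(float),
            df["y"].to_numpy(float),
            df["species"].to_numpy(np.int64),
            df["alive_t2"].to_numpy(bool),
        )


def derive_s_tot(n_tot: int, s_frac: float) -> int:
    """Species pool implied by (n_tot, s_frac): round(s_frac * n_tot), min 1."""
    return max(1, int(np.rint(float(s_frac) * int(n_tot))))


def sim_sad(
    s_tot: int,
    n_tot: int,
    cv_n: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a realized species-abundance vector from a lognormal SAD.

    Relative abundances are lognormal with log-scale variance
    ln(1 + cv_n**2) — chosen so the underlying distribution's CV equals
    ``cv_n`` — normalized to probabilities, then ``n_tot`` individuals are
    assigned multinomially.  Every species is guaranteed at least one
    individual: each empty species receives one individual reassigned from
    the currently most abundant species, so all s_tot species are present
    at time 1.
    """
    if s_tot < 1:
        raise ValueError("s_tot must be >= 1")
    if cv_n <= 0:
        raise ValueError("cv_n must be > 0")
    if s_tot > n_tot:
        raise ValueError(
            f"cannot place >=1 individual in each of {s_tot} species "
            f"with only {n_tot} individuals"
        )
    log_sd = np.sqrt(np.log1p(cv_n**2))
    rel = rng.lognormal(mean=0.0, sigma=log_sd, size=s_tot)
    abund = rng.multinomial(n_tot, rel / rel.sum())

    empty = np.flatnonzero(abund == 0)
    if empty.size:
        logger.debug("repairing %d empty species (donating from richest)", empty.size)
    for sp in empty:
        donor = int(np.argmax(abund))
        abund[donor] -= 1
        abund[sp] += 1
    assert abund.sum() == n_tot and abund.min() >= 1
    return abund


def sim_thomas(
    abundances: np.ndarray,
    sigma: float,
    rng: np.random.Generator,
) -> PointCommunity:
    """Realize abundances as a Thomas cluster pattern on the unit torus.

    One mother point per species, uniform in the unit square; each
    individual sits at mother + (dx, dy), dx, dy ~ Normal(0, sigma),
    wrapped modulo 1.  Per-species point counts equal the abundances.
    """
    abund = np.asarray(abundances, dtype=np.int64)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if np.any(abund < 0):
        raise ValueError("abundances must be non-negative")
    s_tot = abund.size
    n_tot = int(abund.sum())

    mothers = rng.uniform(size=(s_tot, 2))
    species = np.repeat(np.arange(1, s_tot + 1), abund)
    centers = np.repeat(mothers, abund, axis=0)
    pts = np.mod(centers + rng.normal(0.0, sigma, size=(n_tot, 2)), 1.0)
    return PointCommunity(pts[:, 0], pts[:, 1], species)


def simulate_community(spec: CommunitySpec, rng: np.random.Generator) -> PointCommunity:
    """SAD draw + Thomas placement in one call."""
    abund = sim_sad(spec.s_tot, spec.n_tot, spec.cv_n, rng)
    return sim_thomas(abund, spec.sigma, rng)
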