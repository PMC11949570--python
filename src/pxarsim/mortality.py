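"""Density-dependent per-individual mortality.

The per-individual probability of death is a two-parameter logistic-type
function of the *regional* abundance ``N`` of the individual's species
(the total count in the whole region, not a local density):

.. math::

    P_{death}(N; \\alpha, \\beta) =
        \\frac{E}{\\frac{1-\\alpha}{\\alpha} + E},
    \\qquad E = \\exp\\!\\big(N \\cdot \\mathrm{sgn}(\\beta)
                             \\cdot e^{-1/\\beta}\\big)

with ``P_death = alpha`` for every ``N`` when ``beta = 0``.

``alpha`` (the "intercept", in (0, 1)) is the death probability at N = 0;
``beta`` controls the sign and steepness of the density dependence: a
negative ``beta`` makes mortality *decrease* with abundance (negative
density dependence, an Allee-like penalty on rarity), a positive ``beta``
makes it *increase* (positive density dependence, a Janzen–Connell-like
penalty on commonness).  Note that the signed ``beta`` enters the inner
exponential, so the magnitude of ``beta`` does not map monotonically onto
steepness; documentation and result labels therefore always talk about
negative/positive density dependence rather than the sign of ``beta``.

Mortality is applied to a community as independent Bernoulli trials per
individual, with N equal to the species' total regional count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import expit

__all__ = [
    "MortalityParams",
    "SpeciesMortalityTable",
    "p_death",
    "apply_mortality",
    "sample_alpha_per_species",
]

# Saturation guards: the logistic is evaluated in log-odds space, so the
# only failure modes are arguments beyond float range; results are clipped
# into the open interval (0, 1).
_P_LO = 1e-300
_P_HI = 1.0 - 1e-16


@dataclass(frozen=True)
class MortalityParams:
    """Parameters (alpha, beta) of the density-dependent mortality curve.

    alpha : death probability at N = 0, strictly inside (0, 1)
            (the curve divides by both alpha and 1 - alpha).
    beta  : any finite real; sign sets the direction of density dependence,
            0 switches density dependence off entirely.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 < float(self.alpha) < 1.0):
            raise ValueError(
                f"alpha must lie strictly in (0, 1), got {self.alpha!r}"
            )
        if not math.isfinite(float(self.beta)):
            raise ValueError(f"beta must be finite, got {self.beta!r}")


class SpeciesMortalityTable:
    """Mapping species_id -> MortalityParams covering a whole community.

    Supports the shared-parameters design (every species on the same
    curve) and the heterogeneous design where each species draws its own
    intercept alpha.
    """

    def __init__(self, params: Mapping[int, MortalityParams]):
        self._params = dict(params)

    def __getitem__(self, species_id: int) -> MortalityParams:
        try:
            return self._params[species_id]
        except KeyError:
            raise KeyError(
                f"species {species_id} has no mortality parameters"
            ) from None

    def __contains__(self, species_id: int) -> bool:
        return species_id in self._params

    def __len__(self) -> int:
        return len(self._params)

    def species_ids(self) -> list[int]:
        return sorted(self._params)

    @classmethod
    def shared(cls, species_ids, alpha: float, beta: float) -> "SpeciesMortalityTable":
        """Every species on one curve (the main-text design)."""
        p = MortalityParams(alpha, beta)
        return cls({int(s): p for s in species_ids})

    @classmethod
    def per_species_alpha(
        cls,
        species_ids,
        beta: float,
        rng: np.random.Generator,
        alpha_low: float = 0.01,
        alpha_high: float = 0.99,
    ) -> "SpeciesMortalityTable":
        """Shared beta, per-species alpha ~ Uniform(alpha_low, alpha_high)."""
        ids = [int(s) for s in species_ids]
        alphas = sample_alpha_per_species(len(ids), alpha_low, alpha_high, rng)
        return cls({s: MortalityParams(a, beta) for s, a in zip(ids, alphas)})


def _validate_counts(n) -> np.ndarray:
    arr = np.asarray(n)
    if arr.dtype.kind == "f":
        if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
            raise ValueError("N must be a non-negative integer count")
        arr = arr.astype(np.int64)
    elif arr.dtype.kind not in "iu":
        raise ValueError("N must be a non-negative integer count")
    if np.any(arr < 0):
        raise ValueError("N must be non-negative")
    return arr


def p_death(n, params: MortalityParams):
    """Per-individual death probability at regional abundance ``n``.

    ``n`` may be a scalar or array of non-negative integers.  Computed in
    log-odds space (log-odds = n * sgn(beta) * exp(-1/beta) + logit(alpha))
    so that no intermediate overflows; results saturate strictly inside
    (0, 1).  The beta = 0 branch and n = 0 return ``alpha`` exactly.
    """
    arr = _validate_counts(n)
    scalar = np.isscalar(n) or np.ndim(n) == 0
    alpha, beta = float(params.alpha), float(params.beta)

    if beta == 0.0:
        out = np.full(arr.shape, alpha, dtype=float)
        return float(out) if scalar else out

    # sgn(beta) * exp(-1/beta), with the signed beta inside the exponential;
    # |beta| near 0 on the negative side overflows exp, so saturate to inf
    # (the logistic then saturates for any N > 0)
    inner = -1.0 / beta
    rate = math.copysign(math.exp(inner) if inner < 700 else math.inf, beta)
    logodds = arr.astype(float) * rate + math.log(alpha / (1.0 - alpha))
    p = np.clip(expit(logodds), _P_LO, _P_HI)
    p = np.where(arr == 0, alpha, p)
    return float(p) if scalar else p


def sample_alpha_per_species(
    n_species: int,
    alpha_low: float,
    alpha_high: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one mortality intercept per species, Uniform(alpha_low, alpha_high)."""
    if n_species < 0:
        raise ValueError("n_species must be >= 0")
    if not (0.0 < alpha_low < alpha_high < 1.0):
        raise ValueError(
            "require 0 < alpha_low < alpha_high < 1, got "
            f"({alpha_low}, {alpha_high})"
        )
    return rng.uniform(alpha_low, alpha_high, size=int(n_species))


def apply_mortality(community, table: SpeciesMortalityTable, rng: np.random.Generator):
    """Kill individuals by independent Bernoulli trials.

    Each individual of species s dies with probability
    ``p_death(N_s, table[s])`` where N_s is the species' total count in
    the whole region.  Returns a new community with ``alive_t2`` set;
    coordinates and labels are untouched.
    """
    species = np.asarray(community.species)
    ids, counts = np.unique(species, return_counts=True)
    missing = [int(s) for s in ids if s not in table]
    if missing:
        raise KeyError(f"species missing from mortality table: {missing}")

    p_by_species = {
        int(s): p_death(int(c), table[int(s)]) for s, c in zip(ids, counts)
    }
    p = np.array([p_by_species[int(s)] for s in species])
    alive = rng.uniform(size=species.size) >= p
    return community.with_survival(alive)
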