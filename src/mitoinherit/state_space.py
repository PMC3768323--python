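"""Core probability machinery over mitochondrial states.

A cell with capacity ``C`` mitochondria is summarised by the count
``j in 0..C`` of mutant (or type-1) organelles, so a cell class is a
probability vector of length ``C + 1``.  This module builds the exact
transition matrices of the life cycle — mutation, selfish within-cell
resampling, meiotic segregation — and the fitness maps, all as dense
row-stochastic numpy arrays.  There is no random number generator anywhere:
the population is infinite and every "sampling" step enters as its exact
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy import stats

from .params import DegeneratePopulationError, FitnessSpec, InvalidParameterError

#: probabilities below this are clamped to zero (then renormalized) to avoid
#: denormal underflow accumulating over very long runs
PROB_FLOOR = 1e-300


@dataclass(frozen=True)
class MitoDistribution:
    """Distribution of mutant-mitochondria counts for one cell class.

    ``capacity`` is the number of organelles in the class (M for diploids,
    M/2 for gametes); ``probs[j]`` is the probability of carrying exactly
    ``j`` mutants.
    """

    capacity: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise InvalidParameterError("capacity must be positive")
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (self.capacity + 1,):
            raise InvalidParameterError(
                f"probs must have length capacity+1 = {self.capacity + 1}"
            )
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise InvalidParameterError("probs must be a probability vector")
        object.__setattr__(self, "probs", p)

    @classmethod
    def point_mass(cls, capacity: int, j: int) -> "MitoDistribution":
        p = np.zeros(capacity + 1)
        p[j] = 1.0
        return cls(capacity, p)

    @property
    def mean(self) -> float:
        return float(np.arange(self.capacity + 1) @ self.probs)

    @property
    def variance(self) -> float:
        j = np.arange(self.capacity + 1)
        m = self.mean
        return float(((j - m) ** 2) @ self.probs)


def _check_M(M: int) -> None:
    if M < 2 or M % 2 != 0:
        raise InvalidParameterError(f"M must be a positive even integer, got {M}")


def fitness_vector(spec: FitnessSpec, M: int) -> np.ndarray:
    """Fitness f(j) for j = 0..M under the given shape.

    Concave (default): f(j) = 1 - (j/M)^2 — a cell with few mutants pays
    almost nothing, and fitness falls off sharply as the load grows, matching
    the high mutant-load threshold seen in oxidative-phosphorylation defects.
    Convex: f(j) = (1 - j/M)^2 — the mirror image, with a sharp initial
    decline.  Both pass through f(0) = 1 and f(M) = 0.
    """
    _check_M(M)
    j = np.arange(M + 1) / M
    if spec.shape == "concave":
        return 1.0 - j**2
    if spec.shape == "convex":
        return (1.0 - j) ** 2
    raise InvalidParameterError(
        f"fitness_vector handles concave/convex shapes, got {spec.shape!r}"
    )


def mutation_matrix(M: int, mu: float, bidirectional: bool = False) -> np.ndarray:
    """(M+1)x(M+1) transition matrix of one round of organelle mutation.

    Unidirectional (default): each of the M - j wild-type organelles mutates
    independently with probability mu, so row j is the pmf of
    j + Binomial(M-j, mu).  Bidirectional (coadaptation mode): mutation acts
    0 <-> 1 symmetrically; row j is the pmf of j - L + G with
    L ~ Binomial(j, mu) losses and G ~ Binomial(M-j, mu) gains, independent.
    """
    if not (0.0 <= mu <= 1.0):
        raise InvalidParameterError(f"mu must lie in [0, 1], got {mu}")
    T = np.zeros((M + 1, M + 1))
    if not bidirectional:
        for j in range(M + 1):
            gains = stats.binom.pmf(np.arange(M - j + 1), M - j, mu)
            T[j, j:] = gains
        return T
    for j in range(M + 1):
        loss = stats.binom.pmf(np.arange(j + 1), j, mu)  # index l: j -> j - l
        gain = stats.binom.pmf(np.arange(M - j + 1), M - j, mu)
        # net count j - l + g: convolve over (g - l); build directly
        for l, pl in enumerate(loss):
            T[j, j - l : j - l + M - j + 1] += pl * gain
    return T


def selfish_resample_matrix(M: int, k: float) -> np.ndarray:
    """Within-cell resampling with a replicative advantage 1 + k for mutants.

    After mutation and before selection the M organelles are resampled with
    replacement; a cell with x mutants samples a mutant with probability
    q = x(1 + k) / (M + x k), so row x is the Binomial(M, q) pmf.  With
    k = 0 the resampling is neutral (q = x/M), and homoplasmic states
    (x = 0, x = M) are absorbing for any k.
    """
    if k < 0:
        raise InvalidParameterError(f"k must be >= 0, got {k}")
    x = np.arange(M + 1)
    q = x * (1.0 + k) / (M + x * k)
    q = np.clip(q, 0.0, 1.0)  # x = M gives q = 1 exactly; guard float overshoot
    return stats.binom.pmf(np.arange(M + 1)[None, :], M, q[:, None])


def meiosis_gamete_matrix(M: int) -> np.ndarray:
    """(M+1) x (M/2+1) matrix mapping diploid state j to gamete state g.

    The diploid's M organelles are duplicated exactly (j mutants -> 2j among
    2M) and then partitioned without replacement through two meiotic
    divisions into four gametes of M/2 each.  Two successive without-
    replacement splits compose to a single hypergeometric draw, so entry
    (j, g) is the Hypergeometric(N=2M, K=2j, n=M/2) pmf at g.
    """
    _check_M(M)
    half = M // 2
    j = np.arange(M + 1)
    g = np.arange(half + 1)
    return stats.hypergeom.pmf(g[None, :], 2 * M, 2 * j[:, None], half)


def apply_selection(
    joint: Dict[object, Tuple[float, np.ndarray]],
    fitness: Dict[object, np.ndarray] | np.ndarray,
) -> Tuple[Dict[object, Tuple[float, np.ndarray]], Dict[object, float], float]:
    """Reweight a genotype-by-mitostate joint distribution by fitness.

    ``joint`` maps genotype keys to ``(frequency, conditional mito pmf)``;
    ``fitness`` is either one fitness vector shared by all genotypes or a
    per-genotype mapping (mitonuclear mode).  Every (genotype, j) mass is
    multiplied by f(j) and the whole population renormalized by the global
    mean fitness, so genotype frequencies shift in proportion to their mean
    fitness.

    Returns ``(new_joint, per-genotype mean fitness, overall mean fitness)``,
    the means taken before renormalization.
    """
    mean_by_geno: Dict[object, float] = {}
    new_mass: Dict[object, np.ndarray] = {}
    total = 0.0
    for key, (freq, dist) in joint.items():
        f = fitness[key] if isinstance(fitness, dict) else fitness
        weighted = dist * f
        w = float(weighted.sum())
        mean_by_geno[key] = w
        mass = freq * weighted
        new_mass[key] = mass
        total += freq * w
    if total <= 0.0:
        raise DegeneratePopulationError("global mean fitness is zero")
    out = {}
    for key, mass in new_mass.items():
        m = float(mass.sum())
        freq = m / total
        dist = mass / m if m > 0 else mass
        out[key] = (freq, dist)
    return out, mean_by_geno, total


def floor_and_renormalize(v: np.ndarray) -> np.ndarray:
    """Clamp sub-underflow probabilities to zero and renormalize."""
    w = np.where(v < PROB_FLOOR, 0.0, v)
    s = w.sum()
    if s <= 0.0:
        raise DegeneratePopulationError("distribution vanished under the floor")
    return w / s


__all__ = [
    "MitoDistribution",
    "PROB_FLOOR",
    "apply_selection",
    "fitness_vector",
    "floor_and_renormalize",
    "meiosis_gamete_matrix",
    "mutation_matrix",
    "selfish_resample_matrix",
]
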