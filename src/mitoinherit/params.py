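"""Model parameters and validation.

All parameters of the deterministic life-cycle recursion live in a single
frozen :class:`ModelParams` object: the mitochondrial population size ``M``,
the per-organelle mutation probability ``mu``, the fitness shape, the selfish
replicative advantage ``k``, the rule for fusions between two uniparental
(``A``) gametes, mating-type settings, the nuclear mutation rate ``nu`` used
in mitonuclear-coadaptation mode, and solver settings (introduction frequency,
burn-in, convergence tolerance, generation cap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple


class InvalidParameterError(ValueError):
    """A model parameter is outside its admissible range."""


class DegeneratePopulationError(RuntimeError):
    """The population has zero mean fitness or no compatible matings."""


#: admissible fitness shapes
FITNESS_SHAPES = ("concave", "convex", "mitonuclear")

#: admissible rules for fusions between two A (uniparental) gametes
AXA_RULES = ("BPI", "inviable", "UPI_random")


@dataclass(frozen=True)
class FitnessSpec:
    """Shape of the map from mutant-mitochondria count to cell fitness.

    ``concave`` is the default quadratic 1 - (j/M)^2: few mutations have minor
    effects, decline sharpens with load.  ``convex`` is its mirror
    (1 - j/M)^2 with a sharp initial decline.  ``mitonuclear`` defers to the
    coadaptation fitness table (nuclear-genotype dependent).
    """

    shape: str = "concave"

    def __post_init__(self) -> None:
        if self.shape not in FITNESS_SHAPES:
            raise InvalidParameterError(
                f"fitness shape must be one of {FITNESS_SHAPES}, got {self.shape!r}"
            )


@dataclass(frozen=True)
class SwitchingSchedule:
    """Periodic environmental switching of the favoured mitonuclear state.

    Every ``period`` generations a multiplicative fitness penalty ``cost`` is
    moved onto the currently dominant nuclear homozygote, forcing the
    population to re-adapt to the opposite state.
    """

    period: int
    cost: float

    def __post_init__(self) -> None:
        if self.period < 1:
            raise InvalidParameterError("switching period must be >= 1")
        if not (0.0 < self.cost < 1.0):
            raise InvalidParameterError("switching cost must lie in (0, 1)")


@dataclass(frozen=True)
class ModelParams:
    """All parameters of one model configuration.

    Parameters
    ----------
    M : int
        Mitochondria per diploid cell; even, >= 2.  Gametes carry M/2.
    mu : float
        Per-mitochondrion mutation probability per generation.
    fitness : FitnessSpec
        Fitness shape (concave by default).
    k : float
        Replicative advantage of selfish mutant mitochondria; 0 disables the
        within-cell resampling step entirely.
    AxA_rule : str
        Mitochondrial inheritance rule for fusions between two A gametes:
        "BPI" (default), "inviable", or "UPI_random".
    upi_amplification : str
        How a uniparental zygote's organelles are restored from the
        transmitting gamete's M/2 to the diploid complement M: "resample"
        (default; M draws with replacement at the gamete's mutant fraction)
        or "duplicate" (exact doubling, g -> 2g).
    n_mating_types : int
        Number of indexed self-incompatible mating-type alleles (0 disables
        the mating-type locus).
    universal_wildtype : bool
        Whether the mating-type allele 0 (compatible with everything,
        including itself) is permitted in the population.
    recomb : float
        Recombination fraction r in [0, 0.5] between the inheritance locus
        and the mating-type locus.
    nu : float
        Nuclear mutation probability at the mitonuclear locus (coadaptation
        mode); defaults to mu/10 when left as None.
    bidirectional_mu : bool
        Mitochondrial mutation acts 0 <-> 1 symmetrically (coadaptation mode)
        instead of wild-type -> mutant only.
    switching : SwitchingSchedule, optional
        Environmental switching schedule (coadaptation mode only).
    p0 : float
        Introduction frequency of an invading haplotype.
    burn_in : int
        Resident-only generations before the invader is introduced.
    tol : float
        Convergence tolerance: L-infinity change of the full joint
        genotype-by-mitostate probability vector.
    tol_window : int
        Consecutive generations the tolerance must hold.
    max_gen : int
        Hard cap on post-introduction generations.
    """

    M: int = 50
    mu: float = 0.01
    fitness: FitnessSpec = field(default_factory=FitnessSpec)
    k: float = 0.0
    AxA_rule: str = "BPI"
    upi_amplification: str = "resample"
    n_mating_types: int = 0
    universal_wildtype: bool = False
    recomb: float = 0.0
    nu: Optional[float] = None
    bidirectional_mu: bool = False
    switching: Optional[SwitchingSchedule] = None
    p0: float = 0.01
    burn_in: int = 100
    tol: float = 1e-12
    tol_window: int = 10
    max_gen: int = 1_000_000

    def __post_init__(self) -> None:
        if self.M < 2 or self.M % 2 != 0:
            raise InvalidParameterError(f"M must be a positive even integer >= 2, got {self.M}")
        if not (0.0 <= self.mu <= 1.0):
            raise InvalidParameterError(f"mu must lie in [0, 1], got {self.mu}")
        if self.k < 0:
            raise InvalidParameterError(f"k must be >= 0, got {self.k}")
        if self.AxA_rule not in AXA_RULES:
            raise InvalidParameterError(
                f"AxA_rule must be one of {AXA_RULES}, got {self.AxA_rule!r}"
            )
        if self.upi_amplification not in ("resample", "duplicate"):
            raise InvalidParameterError(
                "upi_amplification must be 'resample' or 'duplicate', "
                f"got {self.upi_amplification!r}"
            )
        if self.n_mating_types < 0:
            raise InvalidParameterError("n_mating_types must be >= 0")
        if not (0.0 <= self.recomb <= 0.5):
            raise InvalidParameterError(f"recomb must lie in [0, 0.5], got {self.recomb}")
        if self.nu is not None:
            if not (0.0 <= self.nu <= 1.0):
                raise InvalidParameterError(f"nu must lie in [0, 1], got {self.nu}")
            if self.nu >= self.mu > 0:
                warnings.warn(
                    "nu >= mu: the coadaptation model assumes the nuclear mutation "
                    "rate is well below the mitochondrial rate",
                    stacklevel=2,
                )
        if not (0.0 <= self.p0 < 1.0):
            raise InvalidParameterError(f"p0 must lie in [0, 1), got {self.p0}")
        if self.burn_in < 0:
            raise InvalidParameterError("burn_in must be >= 0")
        if self.tol <= 0:
            raise InvalidParameterError("tol must be positive")
        if self.max_gen < 1:
            raise InvalidParameterError("max_gen must be >= 1")

    @property
    def half_M(self) -> int:
        return self.M // 2

    @property
    def nu_effective(self) -> float:
        """Nuclear mutation rate, defaulting to mu/10."""
        return self.mu / 10.0 if self.nu is None else self.nu

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with selected fields replaced."""
        return replace(self, **kwargs)


__all__ = [
    "AXA_RULES",
    "FITNESS_SHAPES",
    "DegeneratePopulationError",
    "FitnessSpec",
    "InvalidParameterError",
    "ModelParams",
    "SwitchingSchedule",
]
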