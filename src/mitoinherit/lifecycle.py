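"""One-generation life-cycle operator for the infinite diploid population.

The cycle is: organelle mutation -> (selfish within-cell resampling) ->
selection -> meiosis (hypergeometric segregation of organelles, Mendelian
segregation with optional recombination at the nuclear loci) -> random
fusion of gametes constrained by mating-type self-incompatibility, with
uniparental (UPI) or biparental (BPI) transmission of organelles decided by
the nuclear inheritance alleles of the two gametes.

Nuclear genotypes are tracked explicitly as unordered pairs of
:class:`Haplotype`; each diploid class carries its own conditional
distribution over mutant-organelle counts.  Everything is exact — the model
is a deterministic recursion on genotype frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, Optional, Tuple

import numpy as np

from . import coadaptation
from .params import (
    DegeneratePopulationError,
    InvalidParameterError,
    ModelParams,
)
from .state_space import (
    apply_selection,
    fitness_vector,
    floor_and_renormalize,
    meiosis_gamete_matrix,
    mutation_matrix,
    selfish_resample_matrix,
)


@dataclass(frozen=True, order=True)
class Haplotype:
    """A gamete's nuclear haplotype.

    ``inh``: inheritance allele — 'a' (biparental wild-type) or 'A'
    (uniparental mutant; excludes its partner's organelles when fusing with
    an 'a' gamete).  ``mt``: mating-type index; 0 is the universally
    compatible wild-type, indexed alleles 1..n are incompatible with self.
    ``nm``: optional mitonuclear allele (0/1) in coadaptation mode.
    """

    inh: str
    mt: int = 0
    nm: Optional[int] = None

    def __post_init__(self) -> None:
        if self.inh not in ("a", "A"):
            raise InvalidParameterError(f"inh allele must be 'a' or 'A', got {self.inh!r}")
        if self.mt < 0:
            raise InvalidParameterError("mt index must be >= 0")
        if self.nm not in (None, 0, 1):
            raise InvalidParameterError("nm allele must be None, 0 or 1")

    def label(self) -> str:
        s = self.inh
        if self.mt:
            s += str(self.mt)
        if self.nm is not None:
            s += f".{self.nm}"
        return s


DiploidKey = Tuple[Haplotype, Haplotype]


def diploid_key(h1: Haplotype, h2: Haplotype) -> DiploidKey:
    """Canonical (sorted) unordered pair."""
    return (h1, h2) if h1 <= h2 else (h2, h1)


@dataclass
class DiploidPopulation:
    """Frequencies plus conditional organelle distributions per diploid class."""

    M: int
    entries: Dict[DiploidKey, Tuple[float, np.ndarray]]

    def validate(self, tol: float = 1e-10) -> None:
        total = sum(f for f, _ in self.entries.values())
        if abs(total - 1.0) > tol:
            raise ValueError(f"diploid frequencies sum to {total}, not 1")
        for key, (f, d) in self.entries.items():
            if f < 0:
                raise ValueError(f"negative frequency for {key}")
            if d.shape != (self.M + 1,):
                raise ValueError(f"mito distribution for {key} has wrong length")
            if f > 0 and abs(d.sum() - 1.0) > tol:
                raise ValueError(f"mito distribution for {key} sums to {d.sum()}")

    def allele_freq(self, inh: str) -> float:
        """Frequency of an inheritance allele among diploid gene copies."""
        tot = 0.0
        for (h1, h2), (f, _) in self.entries.items():
            tot += f * ((h1.inh == inh) + (h2.inh == inh)) / 2.0
        return tot

    def haplotype_freqs(self) -> Dict[Haplotype, float]:
        out: Dict[Haplotype, float] = {}
        for (h1, h2), (f, _) in self.entries.items():
            out[h1] = out.get(h1, 0.0) + f / 2.0
            out[h2] = out.get(h2, 0.0) + f / 2.0
        return out

    def joint_vector(self, keys: Iterable[DiploidKey]) -> np.ndarray:
        """Concatenated freq-weighted state vector over a fixed key order."""
        parts = []
        zero = np.zeros(self.M + 1)
        for key in keys:
            f, d = self.entries.get(key, (0.0, zero))
            parts.append(f * d)
        return np.concatenate(parts) if parts else zero

    @classmethod
    def monomorphic(
        cls, M: int, haplotype: Haplotype, j: int = 0
    ) -> "DiploidPopulation":
        """Population fixed for one haplotype, organelles at a point mass."""
        d = np.zeros(M + 1)
        d[j] = 1.0
        return cls(M, {diploid_key(haplotype, haplotype): (1.0, d)})


@dataclass
class GametePool:
    """Haploid gamete classes with conditional organelle distributions (M/2)."""

    M: int
    entries: Dict[Haplotype, Tuple[float, np.ndarray]]

    def validate(self, tol: float = 1e-10) -> None:
        total = sum(f for f, _ in self.entries.values())
        if abs(total - 1.0) > tol:
            raise ValueError(f"gamete frequencies sum to {total}, not 1")


@dataclass
class GenerationStats:
    """Per-generation summary written into trajectories.

    ``mean_fitness`` holds the expected fitness of each inheritance genotype
    ('aa', 'Aa', 'AA') censused on its zygote (start-of-generation) organelle
    distribution; ``allele_fitness`` is the copy-weighted aggregate per
    inheritance allele at the same census.  Frequencies are zygote
    frequencies.
    """

    generation: int
    p_A: float
    genotype_freqs: Dict[str, float]
    mean_fitness: Dict[str, float]
    allele_fitness: Dict[str, float]
    mean_fitness_pop: float
    haplotype_freqs: Dict[str, float] = field(default_factory=dict)
    mt_freqs: Dict[int, float] = field(default_factory=dict)
    nm_freq: Optional[float] = None


class _Operators:
    """Transition matrices and fitness tables, built once per parameter set."""

    def __init__(self, params: ModelParams):
        M = params.M
        bidir = params.bidirectional_mu or params.fitness.shape == "mitonuclear"
        self.mutation = mutation_matrix(M, params.mu, bidirectional=bidir)
        self.selfish = selfish_resample_matrix(M, params.k) if params.k > 0 else None
        self.meiosis = meiosis_gamete_matrix(M)
        self.amplify = upi_amplification_matrix(M, params.upi_amplification)
        if params.fitness.shape == "mitonuclear":
            self.fitness_table = coadaptation.fitness_table(M)
            self.fitness = None
        else:
            self.fitness = fitness_vector(params.fitness, M)
            self.fitness_table = None


@lru_cache(maxsize=32)
def _operators(params: ModelParams) -> _Operators:
    return _Operators(params)


def _inh_genotype(key: DiploidKey) -> str:
    a, b = key[0].inh, key[1].inh
    return a + b if a <= b else b + a  # 'AA', 'Aa', 'aa'


def _nuclear_nm(key: DiploidKey) -> int:
    return (key[0].nm or 0) + (key[1].nm or 0)


def fitness_for(
    key: DiploidKey, params: ModelParams, ops: Optional[_Operators] = None
) -> np.ndarray:
    """Fitness vector (over organelle counts) for one diploid class."""
    ops = ops or _operators(params)
    if ops.fitness is not None:
        return ops.fitness
    return ops.fitness_table[_nuclear_nm(key)]


def _nuclear_mutation(
    pop: DiploidPopulation, nu: float
) -> DiploidPopulation:
    """Flip each mitonuclear allele copy with probability nu (0 <-> 1)."""
    if nu == 0.0:
        return pop
    out: Dict[DiploidKey, list] = {}
    for (h1, h2), (f, d) in pop.entries.items():
        for f1 in (False, True):
            for f2 in (False, True):
                p = (nu if f1 else 1 - nu) * (nu if f2 else 1 - nu)
                if p == 0.0:
                    continue
                g1 = Haplotype(h1.inh, h1.mt, 1 - h1.nm) if f1 else h1
                g2 = Haplotype(h2.inh, h2.mt, 1 - h2.nm) if f2 else h2
                key = diploid_key(g1, g2)
                slot = out.setdefault(key, [0.0, np.zeros(pop.M + 1)])
                slot[0] += f * p
                slot[1] += f * p * d
    entries = {}
    for key, (f, mass) in out.items():
        if f > 0:
            entries[key] = (f, mass / f)
    return DiploidPopulation(pop.M, entries)


def produce_gametes(pop: DiploidPopulation, params: ModelParams) -> GametePool:
    """Meiosis: organelle segregation plus nuclear segregation/recombination.

    Each diploid's organelle distribution is pushed through the
    hypergeometric meiosis matrix.  Nuclear loci segregate Mendelian 50/50;
    the mating-type allele travels with the inheritance allele with
    probability 1 - r (recombinants at r); the mitonuclear locus, when
    present, is unlinked (free recombination).
    """
    ops = _operators(params)
    r = params.recomb
    half = params.M // 2
    acc: Dict[Haplotype, list] = {}
    for (h1, h2), (f, d) in pop.entries.items():
        if f == 0.0:
            continue
        gdist = d @ ops.meiosis
        pair = (h1, h2)
        have_nm = h1.nm is not None
        for i in (0, 1):  # parent of the inheritance allele
            for q in (0, 1):  # parent of the mating-type allele
                w_iq = (1 - r) / 2 if q == i else r / 2
                nm_sources = ((0, 0.5), (1, 0.5)) if have_nm else ((i, 1.0),)
                for s, w_s in nm_sources:
                    g = Haplotype(pair[i].inh, pair[q].mt, pair[s].nm)
                    w = f * w_iq * w_s
                    if w == 0.0:
                        continue
                    slot = acc.setdefault(g, [0.0, np.zeros(half + 1)])
                    slot[0] += w
                    slot[1] += w * gdist
    entries = {}
    for g, (w, mass) in acc.items():
        entries[g] = (w, mass / w)
    pool = GametePool(params.M, entries)
    return pool


def upi_amplification_matrix(M: int, mode: str = "resample") -> np.ndarray:
    """(M/2+1) x (M+1) matrix restoring a uniparental zygote's organelles.

    The transmitting gamete contributes its M/2 organelles (the partner's
    are excluded) and the population is amplified back to the diploid
    complement M.  "resample": M draws with replacement at the gamete's
    mutant fraction g/(M/2), i.e. row g is Binomial(M, 2g/M) — amplification
    adds segregation-like noise.  "duplicate": exact doubling, a point mass
    at 2g.  Both preserve the expected mutant fraction and keep homoplasmic
    gametes homoplasmic.
    """
    half = M // 2
    if mode == "duplicate":
        T = np.zeros((half + 1, M + 1))
        T[np.arange(half + 1), 2 * np.arange(half + 1)] = 1.0
        return T
    if mode != "resample":
        raise InvalidParameterError(f"unknown amplification mode {mode!r}")
    from scipy import stats

    q = np.arange(half + 1) / half
    return stats.binom.pmf(np.arange(M + 1)[None, :], M, q[:, None])


def _compatible(x: Haplotype, y: Haplotype, params: ModelParams) -> bool:
    if params.n_mating_types == 0:
        return True
    return not (x.mt == y.mt and x.mt != 0)


def fuse_gametes(pool: GametePool, params: ModelParams) -> DiploidPopulation:
    """Mass-action random fusion over compatible gamete pairs.

    The renormalization by the total compatible mass Z is what gives
    self-incompatible alleles their mating-rate disadvantage.  Organelle
    transmission: A x a is uniparental from the A gamete (partner's
    organelles excluded, transmitter amplified back to M); a x a is
    biparental (convolution); A x A follows ``params.AxA_rule``.
    """
    M = params.M
    amp = _operators(params).amplify
    haps = sorted(pool.entries)
    acc: Dict[DiploidKey, list] = {}
    Z = 0.0
    for i, x in enumerate(haps):
        fx, dx = pool.entries[x]
        for y in haps[i:]:
            fy, dy = pool.entries[y]
            if not _compatible(x, y, params):
                continue
            w = fx * fy * (2.0 if x != y else 1.0)
            if w == 0.0:
                continue
            n_A = (x.inh == "A") + (y.inh == "A")
            if n_A == 2 and params.AxA_rule == "inviable":
                continue  # excluded from Z: these fusions never form
            if n_A == 0:
                zdist = np.convolve(dx, dy)
            elif n_A == 1:
                transmitter = dx if x.inh == "A" else dy
                zdist = transmitter @ amp
            elif params.AxA_rule == "UPI_random":
                # transmitting role assigned to either partner with equal weight
                zdist = (0.5 * (dx + dy)) @ amp
            else:  # BPI
                zdist = np.convolve(dx, dy)
            Z += w
            key = diploid_key(x, y)
            slot = acc.setdefault(key, [0.0, np.zeros(M + 1)])
            slot[0] += w
            slot[1] += w * zdist
    if Z <= 0.0:
        raise DegeneratePopulationError("no compatible matings with positive mass")
    entries = {}
    for key, (w, mass) in acc.items():
        entries[key] = (w / Z, mass / w)
    return DiploidPopulation(M, entries)


def step_generation(
    pop: DiploidPopulation,
    params: ModelParams,
    generation: int = 0,
    fitness_override: Optional[Dict[int, np.ndarray]] = None,
) -> Tuple[DiploidPopulation, GenerationStats]:
    """Advance the population by one full life cycle.

    Order: organelle mutation (nuclear mutation first in coadaptation mode),
    selfish resampling when k > 0, selection, meiosis, fusion.  Returns the
    next zygote population and the generation's summary statistics.

    ``fitness_override`` replaces the mitonuclear fitness table (keyed by
    nuclear 0/1/2 = count of '1' alleles) — used for environmental switching.
    """
    ops = _operators(params)
    coad = params.fitness.shape == "mitonuclear"

    if coad:
        pop = _nuclear_mutation(pop, params.nu_effective)

    # organelle mutation, then selfish resampling
    mutated: Dict[DiploidKey, Tuple[float, np.ndarray]] = {}
    for key, (f, d) in pop.entries.items():
        nd = d @ ops.mutation
        if ops.selfish is not None:
            nd = nd @ ops.selfish
        mutated[key] = (f, floor_and_renormalize(nd))

    # selection
    if coad:
        table = fitness_override if fitness_override is not None else ops.fitness_table
        fit = {key: table[_nuclear_nm(key)] for key in mutated}
    else:
        fit = ops.fitness
    selected, _, _ = apply_selection(mutated, fit)

    stats = _summarize(pop, fit, generation)

    sel_pop = DiploidPopulation(params.M, selected)
    pool = produce_gametes(sel_pop, params)
    next_pop = fuse_gametes(pool, params)
    return next_pop, stats


def _summarize(
    zygotes: DiploidPopulation,
    fitness: Dict[DiploidKey, np.ndarray] | np.ndarray,
    generation: int,
) -> GenerationStats:
    geno_freqs: Dict[str, float] = {}
    for key, (f, _) in zygotes.entries.items():
        lab = _inh_genotype(key)
        geno_freqs[lab] = geno_freqs.get(lab, 0.0) + f

    # mean fitness censused on the zygote (start-of-generation) distributions
    fit_w: Dict[str, float] = {}
    fit_wf: Dict[str, float] = {}
    allele_w = {"a": 0.0, "A": 0.0}
    allele_wf = {"a": 0.0, "A": 0.0}
    mean_pop = 0.0
    for key, (f, d) in zygotes.entries.items():
        lab = _inh_genotype(key)
        fvec = fitness[key] if isinstance(fitness, dict) else fitness
        fbar = float(d @ fvec)
        mean_pop += f * fbar
        fit_w[lab] = fit_w.get(lab, 0.0) + f
        fit_wf[lab] = fit_wf.get(lab, 0.0) + f * fbar
        for h in key:
            allele_w[h.inh] += f
            allele_wf[h.inh] += f * fbar
    mean_fitness = {lab: fit_wf[lab] / fit_w[lab] for lab in fit_w if fit_w[lab] > 0}
    allele_fitness = {
        al: allele_wf[al] / allele_w[al] for al in allele_w if allele_w[al] > 0
    }

    hap = zygotes.haplotype_freqs()
    mt_freqs: Dict[int, float] = {}
    nm_tot, nm_any = 0.0, False
    for h, f in hap.items():
        mt_freqs[h.mt] = mt_freqs.get(h.mt, 0.0) + f
        if h.nm is not None:
            nm_any = True
            nm_tot += f * h.nm
    return GenerationStats(
        generation=generation,
        p_A=zygotes.allele_freq("A"),
        genotype_freqs=geno_freqs,
        mean_fitness=mean_fitness,
        allele_fitness=allele_fitness,
        mean_fitness_pop=mean_pop,
        haplotype_freqs={h.label(): f for h, f in hap.items()},
        mt_freqs=mt_freqs,
        nm_freq=nm_tot if nm_any else None,
    )


__all__ = [
    "DiploidPopulation",
    "GametePool",
    "GenerationStats",
    "Haplotype",
    "diploid_key",
    "fitness_for",
    "fuse_gametes",
    "produce_gametes",
    "step_generation",
    "upi_amplification_matrix",
]
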