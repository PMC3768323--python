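"""Experiment layer: invasion runs, equilibria, stability, fitness curves.

These drivers reproduce the model's standard numerical experiments: invade a
uniparental-inheritance mutant into a biparental resident population, iterate
the deterministic recursion to convergence, classify the resulting
equilibrium (E1 polymorphism / merged E2 / fixation E3 / loss), probe its
stability by small frequency perturbations, hold the allele frequency fixed
to map out frequency-dependent fitness, and sweep parameter grids.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import coadaptation
from .lifecycle import (
    DiploidPopulation,
    GenerationStats,
    Haplotype,
    diploid_key,
    fuse_gametes,
    produce_gametes,
    step_generation,
)
from .params import DegeneratePopulationError, ModelParams
from .state_space import apply_selection, floor_and_renormalize
from .lifecycle import _operators, _inh_genotype, _nuclear_nm  # shared operators

#: classification band half-width around the anchor frequencies 0, 0.5, 1
DELTA = 1e-3

CLASSIFICATIONS = ("E1", "E2_merged", "E3", "fixed_loss", "other")


@dataclass
class Trajectory:
    """Per-generation records of one run, plus the final population."""

    records: List[GenerationStats]
    final_pop: DiploidPopulation
    converged: bool
    introduction_generation: Optional[int] = None

    @property
    def final_p_A(self) -> float:
        return self.final_pop.allele_freq("A")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.records:
            row = {
                "generation": s.generation,
                "p_A": s.p_A,
                "freq_aa": s.genotype_freqs.get("aa", 0.0),
                "freq_Aa": s.genotype_freqs.get("Aa", 0.0),
                "freq_AA": s.genotype_freqs.get("AA", 0.0),
                "Fbar_aa": s.mean_fitness.get("aa", np.nan),
                "Fbar_Aa": s.mean_fitness.get("Aa", np.nan),
                "Fbar_AA": s.mean_fitness.get("AA", np.nan),
                "Fbar_allele_a": s.allele_fitness.get("a", np.nan),
                "Fbar_allele_A": s.allele_fitness.get("A", np.nan),
                "Fbar_pop": s.mean_fitness_pop,
            }
            for lab, f in sorted(s.haplotype_freqs.items()):
                row[f"freq_hap_{lab}"] = f
            if s.nm_freq is not None:
                row["freq_nm1"] = s.nm_freq
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class EquilibriumReport:
    """Classified end state of a run."""

    p_A: float
    classification: str
    c: Optional[float]
    genotype_freqs: Dict[str, float]
    mean_fitness: Dict[str, float]
    mean_fitness_pop: float
    generations_to_converge: int
    converged: bool
    stable: Optional[bool] = None
    haplotype_freqs: Dict[str, float] = field(default_factory=dict)


FitnessHook = Callable[[int, DiploidPopulation], Optional[Dict[int, np.ndarray]]]


def _joint_map(pop: DiploidPopulation) -> Dict[tuple, np.ndarray]:
    return {k: f * d for k, (f, d) in pop.entries.items()}


def _linf(a: Dict[tuple, np.ndarray], b: Dict[tuple, np.ndarray], M: int) -> float:
    zero = np.zeros(M + 1)
    keys = set(a) | set(b)
    return max(
        float(np.max(np.abs(a.get(k, zero) - b.get(k, zero)))) for k in keys
    )


def iterate_to_convergence(
    pop: DiploidPopulation,
    params: ModelParams,
    start_generation: int = 0,
    max_gen: Optional[int] = None,
    record: bool = True,
    fitness_hook: Optional[FitnessHook] = None,
) -> Tuple[DiploidPopulation, List[GenerationStats], bool, int]:
    """Run the recursion until the full joint state stops moving.

    Convergence: L-infinity change of the concatenated genotype-by-state
    probability vector below ``params.tol`` for ``params.tol_window``
    consecutive generations.
    """
    max_gen = params.max_gen if max_gen is None else max_gen
    records: List[GenerationStats] = []
    prev = _joint_map(pop)
    streak = 0
    gen = start_generation
    for _ in range(max_gen):
        override = fitness_hook(gen, pop) if fitness_hook else None
        pop, stats = step_generation(pop, params, gen, fitness_override=override)
        if record:
            records.append(stats)
        cur = _joint_map(pop)
        if _linf(prev, cur, params.M) < params.tol:
            streak += 1
            if streak >= params.tol_window:
                return pop, records, True, gen + 1
        else:
            streak = 0
        prev = cur
        gen += 1
    return pop, records, False, gen


def run_generations(
    pop: DiploidPopulation,
    params: ModelParams,
    n: int,
    start_generation: int = 0,
    fitness_hook: Optional[FitnessHook] = None,
) -> Tuple[DiploidPopulation, List[GenerationStats]]:
    """Run exactly n generations, recording stats."""
    records = []
    for g in range(start_generation, start_generation + n):
        override = fitness_hook(g, pop) if fitness_hook else None
        pop, stats = step_generation(pop, params, g, fitness_override=override)
        records.append(stats)
    return pop, records


def _half_generation_pool(pop: DiploidPopulation, params: ModelParams):
    """Mutation -> (selfish) -> selection -> meiosis, returning the gamete pool."""
    ops = _operators(params)
    mutated = {}
    for key, (f, d) in pop.entries.items():
        nd = d @ ops.mutation
        if ops.selfish is not None:
            nd = nd @ ops.selfish
        mutated[key] = (f, floor_and_renormalize(nd))
    if ops.fitness is not None:
        fit = ops.fitness
    else:
        fit = {key: ops.fitness_table[_nuclear_nm(key)] for key in mutated}
    selected, _, _ = apply_selection(mutated, fit)
    return produce_gametes(DiploidPopulation(params.M, selected), params)


def _pool_average_dist(pool, select=None) -> np.ndarray:
    """Frequency-weighted organelle distribution, optionally over a subset."""
    mass = None
    tot = 0.0
    for h, (f, d) in pool.entries.items():
        if select is not None and not select(h):
            continue
        mass = f * d if mass is None else mass + f * d
        tot += f
    if mass is None or tot <= 0:
        raise DegeneratePopulationError("no gametes match the selection")
    return mass / tot


def introduce_invader(
    pop: DiploidPopulation,
    params: ModelParams,
    invader: Haplotype,
    p0: float,
) -> DiploidPopulation:
    """Splice a new haplotype into the gamete pool at frequency p0.

    The invader arises as a nuclear mutation on the resident cytoplasmic
    background: it carries the residents' current aggregate gamete organelle
    distribution.  The resident pool is rescaled to 1 - p0 and fusion
    proceeds as usual, so the return value is the next zygote population.
    """
    pool = _half_generation_pool(pop, params)
    resident_dist = _pool_average_dist(pool)
    entries = {h: (f * (1 - p0), d) for h, (f, d) in pool.entries.items()}
    if invader in entries:
        f, d = entries[invader]
        entries[invader] = (f + p0, (f * d + p0 * resident_dist) / (f + p0))
    else:
        entries[invader] = (p0, resident_dist)
    pool.entries = entries
    return fuse_gametes(pool, params)


def run_invasion(
    params: ModelParams,
    resident: Haplotype = Haplotype("a"),
    invader: Haplotype = Haplotype("A"),
    initial_pop: Optional[DiploidPopulation] = None,
    fitness_hook: Optional[FitnessHook] = None,
) -> Trajectory:
    """Burn in the resident, introduce the invader at p0, run to convergence.

    The resident population starts organelle-mutant-free and runs alone for
    ``params.burn_in`` generations (approaching mutation-selection balance);
    the invader then enters the gamete pool at frequency ``params.p0`` and
    the recursion is iterated until the joint state converges.
    """
    pop = initial_pop or DiploidPopulation.monomorphic(params.M, resident, 0)
    pop, records = run_generations(pop, params, params.burn_in, 0, fitness_hook)
    intro_gen = params.burn_in
    if params.p0 > 0:
        pop = introduce_invader(pop, params, invader, params.p0)
    pop, post, converged, end_gen = iterate_to_convergence(
        pop, params, intro_gen + 1, fitness_hook=fitness_hook
    )
    if not converged:
        warnings.warn(
            f"invasion run did not converge within {params.max_gen} generations",
            stacklevel=2,
        )
    return Trajectory(records + post, pop, converged, introduction_generation=intro_gen)


def classify_p_A(p_A: float, converged: bool = True) -> str:
    if not converged:
        return "other"
    if p_A < DELTA:
        return "fixed_loss"
    if abs(p_A - 0.5) <= DELTA:
        return "E2_merged"
    if p_A > 1 - DELTA:
        return "E3"
    if p_A < 0.5 - DELTA:
        return "E1"
    return "other"


def classify_equilibrium(traj: Trajectory, params: ModelParams) -> EquilibriumReport:
    """Classify a converged trajectory's end state.

    With band half-width 1e-3: loss of A below it, merged E1/E2 within it of
    0.5, fixation E3 above 1 - 1e-3, a genuine E1 polymorphism anywhere in
    between below 0.5, anything else "other".
    """
    p_A = traj.final_p_A
    cls = classify_p_A(p_A, traj.converged)
    last = traj.records[-1]
    return EquilibriumReport(
        p_A=p_A,
        classification=cls,
        c=p_A if cls == "E1" else None,
        genotype_freqs=dict(last.genotype_freqs),
        mean_fitness=dict(last.mean_fitness),
        mean_fitness_pop=last.mean_fitness_pop,
        generations_to_converge=last.generation,
        converged=traj.converged,
        haplotype_freqs=dict(last.haplotype_freqs),
    )


def _perturb_p_A(
    pop: DiploidPopulation, params: ModelParams, target: float
) -> DiploidPopulation:
    """Shift the inheritance-allele frequency in the gamete pool to ``target``."""
    pool = _half_generation_pool(pop, params)
    pA = sum(f for h, (f, _) in pool.entries.items() if h.inh == "A")
    avg = _pool_average_dist(pool)
    entries = dict(pool.entries)
    if target > 0 and pA == 0.0:
        entries[Haplotype("A")] = (0.0, avg)
        pA = 0.0
    if target < 1 and pA == 1.0:
        entries[Haplotype("a")] = (0.0, avg)
    new_entries = {}
    for h, (f, d) in entries.items():
        if h.inh == "A":
            nf = (f / pA if pA > 0 else 1.0) * target
        else:
            nf = (f / (1 - pA) if pA < 1 else 1.0) * (1 - target)
        d = d if f > 0 else avg
        new_entries[h] = (nf, d)
    pool.entries = new_entries
    return fuse_gametes(pool, params)


def probe_stability(
    params: ModelParams,
    equilibrium_pop: DiploidPopulation,
    epsilon: float = 1e-3,
) -> Dict[str, object]:
    """Perturb p_A by +/- epsilon and report where each direction settles.

    The equilibrium is stable iff every feasible direction returns to the
    starting classification (and, for a polymorphism, to the same frequency
    within 10 * epsilon).
    """
    p0 = equilibrium_pop.allele_freq("A")
    start_cls = classify_p_A(p0)
    verdicts: Dict[str, object] = {"start_p_A": p0, "start_classification": start_cls}
    outcomes = []
    for direction, delta in (("down", -epsilon), ("up", +epsilon)):
        target = p0 + delta
        if not (0.0 <= target <= 1.0):
            verdicts[direction] = None  # infeasible at the boundary
            continue
        pert = _perturb_p_A(equilibrium_pop, params, target)
        pop, _, converged, _ = iterate_to_convergence(pert, params, record=False)
        pA = pop.allele_freq("A")
        cls = classify_p_A(pA, converged)
        returned = cls == start_cls and (
            cls != "E1" or abs(pA - p0) <= 10 * epsilon
        )
        verdicts[direction] = {"p_A": pA, "classification": cls, "returned": returned}
        outcomes.append(returned)
    verdicts["stable"] = bool(outcomes) and all(outcomes)
    return verdicts


def _hw_rescale(pop: DiploidPopulation, p: float) -> DiploidPopulation:
    """Force Hardy-Weinberg genotype frequencies at allele frequency p,
    preserving each genotype's conditional organelle distribution."""
    targets = {"aa": (1 - p) ** 2, "Aa": 2 * p * (1 - p), "AA": p * p}
    entries = {}
    for key, (f, d) in pop.entries.items():
        lab = _inh_genotype(key)
        t = targets[lab]
        if t > 0:
            entries[key] = (t, d)
    return DiploidPopulation(pop.M, entries)


def _proportional_rescale(pop: DiploidPopulation, p: float) -> DiploidPopulation:
    """Reweight existing genotype classes by w**n_A to hit allele frequency p."""
    from scipy.optimize import brentq

    def pA_at(logw: float) -> float:
        w = np.exp(logw)
        tot, amt = 0.0, 0.0
        for key, (f, _) in pop.entries.items():
            nA = (key[0].inh == "A") + (key[1].inh == "A")
            m = f * w**nA
            tot += m
            amt += m * nA / 2.0
        return amt / tot - p

    logw = brentq(pA_at, -200, 200)
    w = np.exp(logw)
    raw = {}
    tot = 0.0
    for key, (f, d) in pop.entries.items():
        nA = (key[0].inh == "A") + (key[1].inh == "A")
        raw[key] = (f * w**nA, d)
        tot += f * w**nA
    return DiploidPopulation(pop.M, {k: (f / tot, d) for k, (f, d) in raw.items()})


def stationary_bpi_fitness(params: ModelParams) -> float:
    """Mean fitness of the pure-biparental (p_A = 0) population at balance."""
    pop = DiploidPopulation.monomorphic(params.M, Haplotype("a"), 0)
    pop, records, converged, _ = iterate_to_convergence(pop, params)
    if not converged:
        warnings.warn("BPI baseline did not converge", stacklevel=2)
    return records[-1].mean_fitness_pop


def forced_frequency_curves(
    params: ModelParams,
    pA_grid: Sequence[float],
    rescale: str = "hardy_weinberg",
) -> pd.DataFrame:
    """Stationary per-genotype/per-allele fitness at fixed p_A values.

    After every generation the nuclear genotype frequencies are reset to the
    target p_A (Hardy-Weinberg proportions by default, proportional
    reweighting of the existing classes with ``rescale='proportional'``)
    while organelles evolve freely.  All fitnesses are normalized by the
    stationary mean fitness of the pure-BPI population at the same (M, mu).
    """
    if rescale not in ("hardy_weinberg", "proportional"):
        raise ValueError(f"unknown rescale mode {rescale!r}")
    rescaler = _hw_rescale if rescale == "hardy_weinberg" else _proportional_rescale
    baseline = stationary_bpi_fitness(params)

    # common starting point: resident at mutation-selection balance
    resident = DiploidPopulation.monomorphic(params.M, Haplotype("a"), 0)
    resident, _, _, _ = iterate_to_convergence(resident, params)
    bal_dist = next(iter(resident.entries.values()))[1]

    rows = []
    for p in pA_grid:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"target p_A {p} outside [0, 1]")
        entries = {}
        for pair, freq in (
            (("a", "a"), (1 - p) ** 2),
            (("A", "a"), 2 * p * (1 - p)),
            (("A", "A"), p * p),
        ):
            if freq > 0:
                key = diploid_key(Haplotype(pair[0]), Haplotype(pair[1]))
                entries[key] = (freq, bal_dist.copy())
        pop = DiploidPopulation(params.M, entries)
        prev = _joint_map(pop)
        stats = None
        converged = False
        streak = 0
        for gen in range(params.max_gen):
            pop, stats = step_generation(pop, params, gen)
            pop = rescaler(pop, p)
            cur = _joint_map(pop)
            if _linf(prev, cur, params.M) < params.tol:
                streak += 1
                if streak >= params.tol_window:
                    converged = True
                    break
            else:
                streak = 0
            prev = cur
        rows.append(
            {
                "p_A": p,
                "Fbar_aa": stats.mean_fitness.get("aa", np.nan) / baseline,
                "Fbar_Aa": stats.mean_fitness.get("Aa", np.nan) / baseline,
                "Fbar_AA": stats.mean_fitness.get("AA", np.nan) / baseline,
                "Fbar_allele_a": stats.allele_fitness.get("a", np.nan) / baseline,
                "Fbar_allele_A": stats.allele_fitness.get("A", np.nan) / baseline,
                "converged": converged,
            }
        )
    return pd.DataFrame(rows)


def fitness_distribution(
    pop: DiploidPopulation,
    fitness: np.ndarray,
    bins: int | Sequence[float] = 20,
) -> pd.DataFrame:
    """Per-inheritance-genotype histogram over fitness values.

    Each organelle state j maps to fitness f(j); each genotype's conditional
    distribution is aggregated into fitness bins (normalized within
    genotype).  Returns tidy rows (genotype, bin_left, bin_right, mass).
    """
    edges = np.histogram_bin_edges(fitness, bins=bins, range=(0.0, 1.0))
    agg: Dict[str, np.ndarray] = {}
    wsum: Dict[str, float] = {}
    for key, (f, d) in pop.entries.items():
        if f == 0:
            continue
        lab = _inh_genotype(key)
        h, _ = np.histogram(fitness, bins=edges, weights=f * d)
        agg[lab] = agg.get(lab, 0) + h
        wsum[lab] = wsum.get(lab, 0.0) + f
    rows = []
    for lab in sorted(agg):
        masses = agg[lab] / wsum[lab]
        for left, right, m in zip(edges[:-1], edges[1:], masses):
            rows.append(
                {"genotype": lab, "bin_left": left, "bin_right": right, "mass": m}
            )
    return pd.DataFrame(rows)


def sweep(base: ModelParams, grid: Dict[str, Sequence]) -> pd.DataFrame:
    """One invasion + classification per point of a parameter grid.

    Per-point failures are recorded (classification "error") and the sweep
    continues.  Columns: the varied parameters, p_A, classification, c,
    mean fitnesses and convergence info.
    """
    names = list(grid)
    rows = []
    for values in itertools.product(*(grid[n] for n in names)):
        point = dict(zip(names, values))
        row = dict(point)
        try:
            params = base.with_(**point)
            traj = run_invasion(params)
            rep = classify_equilibrium(traj, params)
            row.update(
                p_A=rep.p_A,
                classification=rep.classification,
                c=rep.c,
                Fbar_aa=rep.mean_fitness.get("aa", np.nan),
                Fbar_Aa=rep.mean_fitness.get("Aa", np.nan),
                Fbar_AA=rep.mean_fitness.get("AA", np.nan),
                converged=rep.converged,
                generations=rep.generations_to_converge,
            )
        except Exception as exc:  # record and continue
            row.update(classification="error", error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


MATING_SCENARIOS = ("A1_into_a", "a2_into_E1", "A1_into_two_types", "A1_into_n_types")


def _mating_type_start(
    params: ModelParams, n_types: int
) -> DiploidPopulation:
    """Initial zygotes for n pre-existing indexed mating types at equal
    frequency, organelle-mutant-free."""
    half = params.M // 2
    d = np.zeros(half + 1)
    d[0] = 1.0
    entries = {
        Haplotype("a", m): (1.0 / n_types, d.copy()) for m in range(1, n_types + 1)
    }
    from .lifecycle import GametePool

    pool = GametePool(params.M, entries)
    return fuse_gametes(pool, params)


def mating_type_invasion(
    params: ModelParams, scenario: str, invader_max_gen: Optional[int] = None
) -> Tuple[Trajectory, EquilibriumReport]:
    """Run one of the standard mating-type invasion scenarios.

    - ``A1_into_a``: the UPI mutation linked to a self-incompatible
      mating-type allele (A1) invades a population fixed for the universally
      compatible wild-type a.
    - ``a2_into_E1``: a second self-incompatible BPI allele (a2) is
      introduced into the A1/a polymorphism at E1.
    - ``A1_into_two_types`` / ``A1_into_n_types``: A1 invades a population
      with 2 (or ``params.n_mating_types``) pre-existing indexed types.
    """
    if scenario not in MATING_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {MATING_SCENARIOS}")
    if scenario == "A1_into_a":
        p = params.with_(n_mating_types=max(params.n_mating_types, 1),
                         universal_wildtype=True)
        traj = run_invasion(p, resident=Haplotype("a", 0), invader=Haplotype("A", 1))
    elif scenario == "a2_into_E1":
        p = params.with_(n_mating_types=max(params.n_mating_types, 2),
                         universal_wildtype=True)
        base_traj = run_invasion(
            p, resident=Haplotype("a", 0), invader=Haplotype("A", 1)
        )
        pop = introduce_invader(base_traj.final_pop, p, Haplotype("a", 2), p.p0)
        g0 = base_traj.records[-1].generation + 1
        pop, post, converged, _ = iterate_to_convergence(
            pop, p, g0 + 1, max_gen=invader_max_gen
        )
        if not converged:
            warnings.warn(
                "a2 invasion phase stopped before full convergence", stacklevel=2
            )
        traj = Trajectory(base_traj.records + post, pop, converged, g0)
    else:
        n = 2 if scenario == "A1_into_two_types" else params.n_mating_types
        if n < 2:
            raise ValueError("A1_into_n_types needs n_mating_types >= 2")
        p = params.with_(n_mating_types=max(n, params.n_mating_types))
        start = _mating_type_start(p, n)
        traj = run_invasion(
            p, resident=Haplotype("a", 1), invader=Haplotype("A", 1),
            initial_pop=start,
        )
    rep = classify_equilibrium(traj, params)
    return traj, rep


class SwitchingController:
    """Stateful fitness hook implementing periodic environmental switching.

    At every switch epoch the penalized mitonuclear state becomes the
    currently dominant nuclear allele; cells homozygous for the penalized
    state pay a multiplicative cost until the next epoch.
    """

    def __init__(self, params: ModelParams):
        if params.switching is None:
            raise ValueError("params.switching must be set")
        self.schedule = params.switching
        self.table = coadaptation.fitness_table(params.M)
        self.penalized = 0

    def __call__(self, gen: int, pop: DiploidPopulation) -> Dict[int, np.ndarray]:
        nuc: Dict[int, float] = {}
        for key, (f, _) in pop.entries.items():
            i = _nuclear_nm(key)
            nuc[i] = nuc.get(i, 0.0) + f
        dom = coadaptation.dominant_state(nuc)
        table, self.penalized = coadaptation.apply_switching(
            self.table, dom, self.schedule, gen, self.penalized
        )
        return table


def run_coadaptation_invasion(params: ModelParams) -> Trajectory:
    """Invasion of the UPI allele under mitonuclear-coadaptation fitness.

    The resident is nuclear 00 with fully matched (type-0) organelles; the
    switching schedule, when present, is applied throughout the run.
    """
    from .params import FitnessSpec

    p = params.with_(fitness=FitnessSpec(shape="mitonuclear"))
    hook = SwitchingController(p) if p.switching is not None else None
    return run_invasion(
        p,
        resident=Haplotype("a", 0, 0),
        invader=Haplotype("A", 0, 0),
        fitness_hook=hook,
    )


__all__ = [
    "CLASSIFICATIONS",
    "DELTA",
    "EquilibriumReport",
    "MATING_SCENARIOS",
    "SwitchingController",
    "Trajectory",
    "classify_equilibrium",
    "classify_p_A",
    "fitness_distribution",
    "forced_frequency_curves",
    "introduce_invader",
    "iterate_to_convergence",
    "mating_type_invasion",
    "probe_stability",
    "run_coadaptation_invasion",
    "run_generations",
    "run_invasion",
    "stationary_bpi_fitness",
    "sweep",
]
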