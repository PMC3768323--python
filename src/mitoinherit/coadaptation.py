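"""Mitonuclear coadaptation: matched/unmatched organelles and switching.

In this model variant the two organelle states are not wild-type/mutant but
type 0 and type 1, judged against a biallelic nuclear locus: fitness depends
on how well the cell's organelle population matches its nuclear genotype.
Mutation is symmetric (0 <-> 1) at rate mu for organelles and nu for the
nuclear locus.  An optional environmental schedule periodically penalizes
the currently dominant nuclear homozygote, forcing the population to switch
its coadapted state.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .params import InvalidParameterError, SwitchingSchedule

#: nuclear genotype codes: count of '1' alleles (0 = 00, 1 = 01, 2 = 11)
NUCLEAR_GENOTYPES = (0, 1, 2)


def mitonuclear_fitness(i: int, j: int, M: int) -> float:
    """Fitness of a cell with nuclear genotype ``i`` and ``j`` type-1 organelles.

    The fitness is the concave quadratic 1 - (u/M)^2 in the number ``u`` of
    organelles unmatched to the nucleus: for the 00 homozygote u = j, for the
    11 homozygote u = M - j, and the 01 heterozygote is half-matched to both
    organelle types (u = M/2 regardless of j).  Maximal (1.0) when the
    organelles fully match a homozygous nucleus, and symmetric under the
    joint relabelling 0 <-> 1: F(00, j) = F(11, M - j).
    """
    if i not in NUCLEAR_GENOTYPES:
        raise InvalidParameterError(f"nuclear genotype must be 0, 1 or 2, got {i}")
    if not (0 <= j <= M):
        raise InvalidParameterError(f"organelle state j={j} outside 0..{M}")
    if i == 0:
        u = j
    elif i == 2:
        u = M - j
    else:
        u = M / 2.0
    return 1.0 - (u / M) ** 2


def fitness_table(M: int) -> Dict[int, np.ndarray]:
    """Fitness vectors over organelle states, keyed by nuclear genotype."""
    j = np.arange(M + 1)
    return {
        i: np.array([mitonuclear_fitness(i, jj, M) for jj in j])
        for i in NUCLEAR_GENOTYPES
    }


def apply_switching(
    table: Dict[int, np.ndarray],
    dominant: int,
    schedule: SwitchingSchedule,
    generation: int,
    penalized: int,
) -> tuple[Dict[int, np.ndarray], int]:
    """Return the fitness table in force this generation, plus the penalized state.

    Every ``schedule.period`` generations the penalty moves onto the nuclear
    homozygote of the currently dominant state (``dominant`` in {0, 1}); in
    between, the previously penalized state keeps paying.  Cells of the
    penalized homozygote have all fitness values multiplied by
    ``1 - schedule.cost``; the heterozygote is never penalized directly.
    """
    if generation % schedule.period == 0:
        penalized = dominant
    out = dict(table)
    geno = 0 if penalized == 0 else 2
    out[geno] = table[geno] * (1.0 - schedule.cost)
    return out, penalized


def dominant_state(nuclear_freqs: Dict[int, float]) -> int:
    """Majority allele (0 or 1) given nuclear genotype frequencies."""
    p1 = nuclear_freqs.get(1, 0.0) * 0.5 + nuclear_freqs.get(2, 0.0)
    return 1 if p1 > 0.5 else 0


__all__ = [
    "NUCLEAR_GENOTYPES",
    "apply_switching",
    "dominant_state",
    "fitness_table",
    "mitonuclear_fitness",
]
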