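"""Discrete-ladder diploid genomes for an age-structured evolutionary simulation.

Every agent carries two homologous chromosomes of 384 loci each.  A
chromosome is split into a male-expressed block and a female-expressed block
of 192 loci; within each block, 99 loci encode per-stage survival rates
(life stages 2-100) and 93 loci encode per-stage reproduction rates (stages
8-100).  Survival of unweaned dependent infants (stages 0-1) is a model
constant and is deliberately *not* on the chromosome, which is why the
survival block starts at stage 2.

Locus values are restricted to discrete, strictly increasing ladders; a
mutation moves a locus exactly one rung.  The survival ladder is unevenly
spaced (coarse rungs at low values, fine rungs near 1) so that a locus
released from purifying selection decays to zero quickly.  The
beneficial-to-deleterious ratio ``eta`` biases mutation downward: a mutating
locus steps down with probability 1/2, up with probability eta/2, and is
otherwise left unchanged.

Chromosomes are represented as ``uint8`` arrays of ladder *indices*, not
floats, so single-rung moves are exact.  All operators are vectorised over
arbitrary leading batch dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MALE = 0
FEMALE = 1
SEX_NAMES = {MALE: "male", FEMALE: "female"}
SEX_CODES = {"male": MALE, "female": FEMALE}

SURVIVAL = "survival"
REPRODUCTION = "reproduction"

#: first / last stage carried on the chromosome for each trait
SURVIVAL_STAGE_RANGE = (2, 100)
REPRODUCTION_STAGE_RANGE = (8, 100)
MAX_STAGE = 101  # agents at this stage always die; no locus encodes it

N_SURVIVAL_LOCI = SURVIVAL_STAGE_RANGE[1] - SURVIVAL_STAGE_RANGE[0] + 1   # 99
N_REPRODUCTION_LOCI = (
    REPRODUCTION_STAGE_RANGE[1] - REPRODUCTION_STAGE_RANGE[0] + 1
)  # 93
N_LOCI_PER_SEX = N_SURVIVAL_LOCI + N_REPRODUCTION_LOCI                    # 192
N_LOCI = 2 * N_LOCI_PER_SEX                                               # 384


@dataclass(frozen=True)
class ValueLadder:
    """Ordered set of admissible rate values for one trait."""

    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        lv = self.levels
        if len(lv) < 2:
            raise ValueError("ladder needs at least two levels")
        if lv[0] != 0.0:
            raise ValueError("ladder must start at 0")
        if lv[-1] > 1.0:
            raise ValueError("ladder must end at or below 1")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("ladder levels must be strictly increasing")

    def __len__(self) -> int:
        return len(self.levels)

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.levels, dtype=float)


# Survival rungs: coarse 0.2 steps up to 0.6, 0.02 steps across the 0.80s,
# 0.01 steps across the 0.90s, then 0.99 and 0.999.
SURVIVAL_LADDER = ValueLadder(
    (0.0, 0.2, 0.4, 0.6,
     0.80, 0.82, 0.84, 0.86, 0.88,
     0.90, 0.91, 0.92, 0.93, 0.94, 0.95, 0.96, 0.97, 0.98,
     0.99, 0.999)
)
REPRODUCTION_LADDER = ValueLadder(
    tuple(round(0.1 * k, 1) for k in range(11))
)

_SURV_VALUES = SURVIVAL_LADDER.values
_REPR_VALUES = REPRODUCTION_LADDER.values


def _build_locus_tables():
    """Static lookup tables shared by the map object and the fast engine."""
    surv_locus = np.full((2, MAX_STAGE + 1), -1, dtype=np.int16)
    repr_locus = np.full((2, MAX_STAGE + 1), -1, dtype=np.int16)
    is_survival = np.zeros(N_LOCI, dtype=bool)
    for sex in (MALE, FEMALE):
        base = sex * N_LOCI_PER_SEX
        for i in range(SURVIVAL_STAGE_RANGE[0], SURVIVAL_STAGE_RANGE[1] + 1):
            pos = base + (i - SURVIVAL_STAGE_RANGE[0])
            surv_locus[sex, i] = pos
            is_survival[pos] = True
        for i in range(REPRODUCTION_STAGE_RANGE[0], REPRODUCTION_STAGE_RANGE[1] + 1):
            pos = base + N_SURVIVAL_LOCI + (i - REPRODUCTION_STAGE_RANGE[0])
            repr_locus[sex, i] = pos
    return surv_locus, repr_locus, is_survival


SURV_LOCUS, REPR_LOCUS, IS_SURVIVAL_LOCUS = _build_locus_tables()

#: highest admissible ladder index at each chromosome position
MAX_LEVEL_INDEX = np.where(
    IS_SURVIVAL_LOCUS, len(SURVIVAL_LADDER) - 1, len(REPRODUCTION_LADDER) - 1
).astype(np.uint8)


class LocusMap:
    """Bijection between (sex, trait, stage) and chromosome position 0..383."""

    def index(self, sex: int, trait: str, stage: int) -> int:
        table = {SURVIVAL: SURV_LOCUS, REPRODUCTION: REPR_LOCUS}.get(trait)
        if table is None:
            raise ValueError(f"unknown trait {trait!r}")
        if sex not in (MALE, FEMALE):
            raise ValueError(f"unknown sex code {sex!r}")
        if not 0 <= stage <= MAX_STAGE or table[sex, stage] < 0:
            raise ValueError(f"no {trait} locus for stage {stage}")
        return int(table[sex, stage])

    def describe(self, locus: int) -> tuple[int, str, int]:
        """Inverse map: chromosome position -> (sex, trait, stage)."""
        if not 0 <= locus < N_LOCI:
            raise ValueError(f"locus {locus} out of range")
        sex, offset = divmod(locus, N_LOCI_PER_SEX)
        if offset < N_SURVIVAL_LOCI:
            return sex, SURVIVAL, SURVIVAL_STAGE_RANGE[0] + offset
        return sex, REPRODUCTION, (
            REPRODUCTION_STAGE_RANGE[0] + offset - N_SURVIVAL_LOCI
        )

    def ladder(self, locus: int) -> ValueLadder:
        return SURVIVAL_LADDER if IS_SURVIVAL_LOCUS[locus] else REPRODUCTION_LADDER


LOCUS_MAP = LocusMap()


@dataclass(frozen=True)
class MutationModel:
    """Per-locus one-rung mutation with a deleterious bias.

    Parameters
    ----------
    rate:
        Probability that a given locus mutates in one meiosis (default 0.025).
    eta:
        Ratio of beneficial to deleterious mutation.  A mutating locus steps
        down a rung with probability 0.5, up with probability 0.5*eta, and
        stays put with probability 0.5*(1 - eta).
    """

    rate: float = 0.025
    eta: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("mutation rate must be in [0, 1]")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must be in [0, 1]")


# level indices used for founder genomes
_FOUNDER_S_LEVEL = int(np.searchsorted(_SURV_VALUES, 0.97))      # -> 0.97
_FOUNDER_R_EARLY_LEVEL = int(np.searchsorted(_REPR_VALUES, 0.4))  # -> 0.4
_FOUNDER_R_LATE_LEVEL = int(np.searchsorted(_REPR_VALUES, 0.1))   # -> 0.1


def founder_chromosome() -> np.ndarray:
    """Uniform founder chromosome: s_i = 0.97, r_i = 0.4 (stages 8-16) / 0.1 (17+)."""
    levels = np.empty(N_LOCI, dtype=np.uint8)
    levels[IS_SURVIVAL_LOCUS] = _FOUNDER_S_LEVEL
    for sex in (MALE, FEMALE):
        for stage in range(REPRODUCTION_STAGE_RANGE[0], REPRODUCTION_STAGE_RANGE[1] + 1):
            pos = REPR_LOCUS[sex, stage]
            levels[pos] = (
                _FOUNDER_R_EARLY_LEVEL if stage <= 16 else _FOUNDER_R_LATE_LEVEL
            )
    return levels


@dataclass
class Genome:
    """Diploid genome: two homologous chromosomes stored as ladder indices."""

    levels: np.ndarray  # shape (2, 384), uint8

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.uint8)
        if self.levels.shape != (2, N_LOCI):
            raise ValueError(f"genome must have shape (2, {N_LOCI})")
        if np.any(self.levels > MAX_LEVEL_INDEX):
            raise ValueError("ladder index out of range for its locus")

    @property
    def chrom_a(self) -> np.ndarray:
        return self.levels[0]

    @property
    def chrom_b(self) -> np.ndarray:
        return self.levels[1]

    @classmethod
    def founder(cls) -> "Genome":
        chrom = founder_chromosome()
        return cls(np.stack([chrom, chrom.copy()]))

    def copy(self) -> "Genome":
        return Genome(self.levels.copy())

    def express(self, sex: int, trait: str, stage: int) -> float:
        return express(self, sex, trait, stage)


def express(genome: Genome, sex: int, trait: str, stage: int) -> float:
    """Expressed rate: arithmetic mean of the two homologous locus values.

    Only loci of the agent's own sex block are ever read; the opposite block
    is carried silently.  Stages outside the locus domain (infancy 0-1 for
    survival, pre-maturity for reproduction, and the terminal stage) raise,
    because their rates are model constants, not genome properties.
    """
    locus = LOCUS_MAP.index(sex, trait, stage)
    values = _SURV_VALUES if trait == SURVIVAL else _REPR_VALUES
    return float(values[genome.levels[:, locus]].mean())


def mutate(
    levels: np.ndarray, model: MutationModel, rng: np.random.Generator
) -> np.ndarray:
    """Mutate chromosome level arrays (any shape ``(..., 384)``), returning a copy.

    Each locus is independently selected with probability ``model.rate``; a
    selected locus steps down one rung with probability 0.5, up one rung with
    probability ``0.5 * eta``, else stays.  Moves past a ladder end are
    clamped (no redraw).
    """
    levels = np.asarray(levels)
    if levels.shape[-1] != N_LOCI:
        raise ValueError(f"last axis must have {N_LOCI} loci")
    out = levels.astype(np.int16, copy=True)
    if model.rate == 0.0:
        return out.astype(np.uint8)
    selected = rng.random(levels.shape) < model.rate
    n_sel = int(selected.sum())
    if n_sel:
        draw = rng.random(n_sel)
        delta = np.zeros(n_sel, dtype=np.int16)
        delta[draw < 0.5] = -1
        delta[(draw >= 0.5) & (draw < 0.5 + 0.5 * model.eta)] = 1
        out[selected] += delta
        np.clip(out, 0, MAX_LEVEL_INDEX, out=out)
    return out.astype(np.uint8)


def crossover(
    chrom_a: np.ndarray,
    chrom_b: np.ndarray,
    breakpoint_prob: float = 0.10,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Recombine two homologous chromosomes (batched over leading axes).

    Each of the 383 inter-locus positions is independently a break-point with
    probability ``breakpoint_prob``; the chromosomes exchange content on
    alternating segments.  At every position the unordered pair of levels is
    conserved.
    """
    a = np.asarray(chrom_a)
    b = np.asarray(chrom_b)
    if a.shape != b.shape or a.shape[-1] != N_LOCI:
        raise ValueError("chromosomes must share shape (..., 384)")
    if rng is None:
        rng = np.random.default_rng()
    bp = rng.random(a.shape[:-1] + (N_LOCI - 1,)) < breakpoint_prob
    swap = np.zeros(a.shape, dtype=bool)
    swap[..., 1:] = np.cumsum(bp, axis=-1) & 1
    out_a = np.where(swap, b, a)
    out_b = np.where(swap, a, b)
    return out_a, out_b


def genome_to_frame(genome: Genome) -> pd.DataFrame:
    """Tabular dump: one row per locus (sex, trait, stage, level_a, level_b)."""
    rows = []
    for locus in range(N_LOCI):
        sex, trait, stage = LOCUS_MAP.describe(locus)
        rows.append(
            (SEX_NAMES[sex], trait, stage,
             int(genome.levels[0, locus]), int(genome.levels[1, locus]))
        )
    return pd.DataFrame(
        rows, columns=["sex", "trait", "stage", "level_a", "level_b"]
    )


def genome_from_frame(frame: pd.DataFrame) -> Genome:
    """Inverse of :func:`genome_to_frame`; round-trips exactly."""
    levels = np.zeros((2, N_LOCI), dtype=np.uint8)
    for row in frame.itertuples(index=False):
        locus = LOCUS_MAP.index(SEX_CODES[row.sex], row.trait, int(row.stage))
        levels[0, locus] = row.level_a
        levels[1, locus] = row.level_b
    return Genome(levels)
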