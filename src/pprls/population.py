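"""Agent identity, kinship bookkeeping and offspring construction.

The population is stored structure-of-arrays for speed (ids, sexes, stages,
maternal links and the stacked genome levels of every living agent), but the
module also exposes an object view, :class:`Agent`, for inspection, tests
and small-scale use.  Kinship is matrilineal only: each agent records its
mother's id and its maternal grandmother's id at birth; paternity is not
tracked because no care channel flows through fathers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .genome import (
    FEMALE,
    MALE,
    N_LOCI,
    SEX_NAMES,
    Genome,
    MutationModel,
    crossover,
    founder_chromosome,
    mutate,
)

NO_KIN = -1  # sentinel id for absent maternal links (founders)


@dataclass
class Agent:
    """Object view of one agent; detached copy of the array state."""

    id: int
    sex: int  # MALE or FEMALE
    stage: int
    genome: Genome
    mother_id: Optional[int] = None
    maternal_grandmother_id: Optional[int] = None
    alive: bool = True

    @property
    def sex_name(self) -> str:
        return SEX_NAMES[self.sex]


class PopulationState:
    """Living agents plus run bookkeeping (step index, famine counter, RNG).

    Attributes
    ----------
    ids, sex, stage, mother, grandmother:
        Per-living-agent arrays; maternal links use ``NO_KIN`` for founders.
    levels:
        ``(n, 2, 384)`` uint8 array of ladder indices (two chromosomes each).
    t, T_f:
        Step index and the consecutive-famine duration counter.
    """

    def __init__(
        self,
        ids: np.ndarray,
        sex: np.ndarray,
        stage: np.ndarray,
        mother: np.ndarray,
        grandmother: np.ndarray,
        levels: np.ndarray,
        rng: np.random.Generator,
        t: int = 0,
        T_f: int = 0,
        next_id: int | None = None,
    ) -> None:
        self.ids = np.asarray(ids, dtype=np.int64)
        self.sex = np.asarray(sex, dtype=np.int8)
        self.stage = np.asarray(stage, dtype=np.int16)
        self.mother = np.asarray(mother, dtype=np.int64)
        self.grandmother = np.asarray(grandmother, dtype=np.int64)
        self.levels = np.asarray(levels, dtype=np.uint8)
        self.rng = rng
        self.t = int(t)
        self.T_f = int(T_f)
        self.next_id = int(next_id if next_id is not None else
                           (self.ids.max() + 1 if self.ids.size else 0))
        # alive-status bitmap indexed by agent id, grown on demand
        self._alive_by_id = np.zeros(max(self.next_id, 1), dtype=bool)
        if self.ids.size:
            self._alive_by_id[self.ids] = True

    # -- size / membership -------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.ids.size)

    def is_alive(self, agent_id: int) -> bool:
        return 0 <= agent_id < self._alive_by_id.size and bool(
            self._alive_by_id[agent_id]
        )

    def alive_lookup(self, id_array: np.ndarray) -> np.ndarray:
        """Vectorised liveness check; NO_KIN and unknown ids map to False."""
        out = np.zeros(id_array.shape, dtype=bool)
        valid = (id_array >= 0) & (id_array < self._alive_by_id.size)
        out[valid] = self._alive_by_id[id_array[valid]]
        return out

    # -- mutation of the living set (used by the dynamics engine) ---------
    def allocate_ids(self, k: int) -> np.ndarray:
        new = np.arange(self.next_id, self.next_id + k, dtype=np.int64)
        self.next_id += k
        return new

    def replace_living(
        self,
        ids: np.ndarray,
        sex: np.ndarray,
        stage: np.ndarray,
        mother: np.ndarray,
        grandmother: np.ndarray,
        levels: np.ndarray,
    ) -> None:
        self.ids, self.sex, self.stage = ids, sex, stage
        self.mother, self.grandmother, self.levels = mother, grandmother, levels
        if self.next_id > self._alive_by_id.size:
            grown = np.zeros(max(2 * self._alive_by_id.size, self.next_id), bool)
            grown[: self._alive_by_id.size] = False
            self._alive_by_id = grown
        self._alive_by_id[:] = False
        if ids.size:
            self._alive_by_id[ids] = True

    # -- object views ------------------------------------------------------
    def agent(self, index: int) -> Agent:
        """Agent view by *array position* (not id)."""
        mid = int(self.mother[index])
        gid = int(self.grandmother[index])
        return Agent(
            id=int(self.ids[index]),
            sex=int(self.sex[index]),
            stage=int(self.stage[index]),
            genome=Genome(self.levels[index].copy()),
            mother_id=None if mid == NO_KIN else mid,
            maternal_grandmother_id=None if gid == NO_KIN else gid,
            alive=True,
        )

    def agents(self) -> list[Agent]:
        return [self.agent(i) for i in range(self.n)]

    def snapshot_frame(self) -> pd.DataFrame:
        """One row per living agent: id, sex, stage, maternal links."""
        return pd.DataFrame(
            {
                "id": self.ids,
                "sex": [SEX_NAMES[s] for s in self.sex],
                "stage": self.stage,
                "mother_id": self.mother,
                "grandmother_id": self.grandmother,
            }
        )


def init_population(
    n: int = 1000, rng: np.random.Generator | int | None = None
) -> PopulationState:
    """Founder population: uniform genomes, random sex, stages uniform on 0-50."""
    if n < 2:
        raise ValueError("need at least 2 founders")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    chrom = founder_chromosome()
    levels = np.broadcast_to(chrom, (n, 2, N_LOCI)).copy()
    return PopulationState(
        ids=np.arange(n, dtype=np.int64),
        sex=rng.integers(0, 2, size=n).astype(np.int8),
        stage=rng.integers(0, 51, size=n).astype(np.int16),
        mother=np.full(n, NO_KIN, dtype=np.int64),
        grandmother=np.full(n, NO_KIN, dtype=np.int64),
        levels=levels,
        rng=rng,
    )


def spawn_offspring(
    mother: Agent,
    father: Agent,
    rng: np.random.Generator,
    mutation_model: MutationModel | None = None,
    breakpoint_prob: float = 0.10,
    child_id: int = 0,
) -> Agent:
    """Construct one newborn from a mature female/male pair.

    The newborn receives one uniformly chosen chromosome from each parent;
    the inherited pair then undergoes crossover and, afterwards, per-locus
    mutation of both chromosomes.  Sex is assigned uniformly at random and
    the matrilineal links are copied down one generation.
    """
    if mother.sex != FEMALE or mother.stage < 8:
        raise ValueError("mother must be a female at stage >= 8")
    if father.sex != MALE or father.stage < 8:
        raise ValueError("father must be a male at stage >= 8")
    if mutation_model is None:
        mutation_model = MutationModel()
    mat = mother.genome.levels[rng.integers(0, 2)]
    pat = father.genome.levels[rng.integers(0, 2)]
    chrom_a, chrom_b = crossover(mat, pat, breakpoint_prob, rng)
    levels = mutate(np.stack([chrom_a, chrom_b]), mutation_model, rng)
    return Agent(
        id=child_id,
        sex=int(rng.integers(0, 2)),
        stage=0,
        genome=Genome(levels),
        mother_id=mother.id,
        maternal_grandmother_id=mother.mother_id,
    )


def kin_alive(state: PopulationState, agent: Agent) -> tuple[bool, bool]:
    """(mother alive, maternal grandmother alive) at the current snapshot."""
    mother_alive = agent.mother_id is not None and state.is_alive(agent.mother_id)
    gm_alive = (
        agent.maternal_grandmother_id is not None
        and state.is_alive(agent.maternal_grandmother_id)
    )
    return mother_alive, gm_alive
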