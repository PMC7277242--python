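"""One simulation step and the full run loop.

A step, in order:

1. **Famine accounting** — famine holds whenever the head count at the start
   of the step exceeds the resource capacity; the consecutive-famine counter
   ``T_f`` increments under famine and resets to zero otherwise.
2. **Kin snapshot** — mother/grandmother liveness is frozen at the start of
   the step, so a carer dying in the same step still provides care
   (simultaneous-update semantics; outcomes do not depend on processing
   order).
3. **Survival phase** — every agent survives with its care-modified,
   famine-magnified survival rate.  Unweaned infants (stages 0-1) use the
   fixed intrinsic rate; agents at the terminal stage always die.
4. **Reproduction phase** (skipped entirely under famine) — each surviving
   mature female gives birth to at most one child with her care-modified
   reproduction rate; the father is drawn among surviving mature males
   with probability proportional to their (care-modified) reproduction
   rate.  Newborns enter at stage 0 and are first counted in the next
   step's census.
5. **Ageing** — all pre-existing survivors advance one life stage.

The engine is fully vectorised over agents and reproducible from
``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import events as ev
from .genome import (
    FEMALE,
    MALE,
    MAX_STAGE,
    REPR_LOCUS,
    SURV_LOCUS,
    MutationModel,
    crossover,
    mutate,
    _REPR_VALUES,
    _SURV_VALUES,
)
from .population import PopulationState, init_population

REPRODUCTION_START = 8


@dataclass(frozen=True)
class CareStrategySet:
    """Which intergenerational-investment channels are active.

    ``m``/``gm``: mother-care / maternal-grandmother-care — each divides an
    unweaned infant's (stage 0-1) death rate by ``death_reduction_factor``
    while the carer is alive; the two compound multiplicatively.
    ``ltr``: reproduction-enhancing long-term care — a living mother
    multiplies her independent offspring's (stage >= 8) reproduction rate by
    ``ltr_multiplier`` (clamped at 1).
    ``lts``: survival-enhancing long-term care — a living mother divides her
    independent offspring's (stage >= 2) death rate by
    ``death_reduction_factor``.
    Recipient filters implement the sex-limited sensitivity variants.
    """

    m: bool = False
    gm: bool = False
    ltr: bool = False
    lts: bool = False
    death_reduction_factor: float = 10.0
    ltr_multiplier: float = 2.0
    ltr_recipients: str = "all"  # "all" | "female_only"
    lts_recipients: str = "all"  # "all" | "male_only"

    def __post_init__(self) -> None:
        if self.death_reduction_factor < 1 or self.ltr_multiplier < 1:
            raise ValueError("care strength factors must be >= 1")
        if self.ltr_recipients not in ("all", "female_only"):
            raise ValueError("ltr_recipients must be 'all' or 'female_only'")
        if self.lts_recipients not in ("all", "male_only"):
            raise ValueError("lts_recipients must be 'all' or 'male_only'")


@dataclass(frozen=True)
class StepConfig:
    """All per-step model parameters.

    ``capacity`` resource units replenish each step and each agent consumes
    one; famine holds while the census exceeds capacity.  Famine magnifies
    death rates by ``famine_base ** T_f`` and zeroes reproduction.
    ``famine_on`` selects whether famine magnifies the care-modified death
    rate (default) or the intrinsic one, with care applied afterwards.
    """

    capacity: int = 1000
    famine_base: float = 3.0
    infant_survival: float = 0.9
    reproduction_start: int = REPRODUCTION_START
    max_stage: int = MAX_STAGE
    breakpoint_prob: float = 0.10
    mutation: MutationModel = field(default_factory=MutationModel)
    care: CareStrategySet = field(default_factory=CareStrategySet)
    famine_on: str = "cared"  # "cared" | "intrinsic"

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")
        if self.famine_base <= 1:
            raise ValueError("famine_base must be > 1")
        if not 0.0 <= self.infant_survival <= 1.0:
            raise ValueError("infant_survival must be in [0, 1]")
        if self.famine_on not in ("cared", "intrinsic"):
            raise ValueError("famine_on must be 'cared' or 'intrinsic'")


def intrinsic_survival(agent, config: StepConfig) -> float:
    """Intrinsic per-step survival rate of one agent at its current stage."""
    if agent.stage >= config.max_stage:
        return 0.0
    if agent.stage < 2:
        return config.infant_survival
    return agent.genome.express(agent.sex, "survival", agent.stage)


def effective_survival(
    intrinsic_s,
    care_channels=0,
    T_f: int = 0,
    config: StepConfig | None = None,
):
    """Care-modified, famine-magnified survival rate (scalar or array).

    ``care_channels`` counts the applicable 10-fold death-rate reductions
    (e.g. 2 for an infant whose mother and grandmother are both alive);
    reductions compound multiplicatively.  Famine multiplies the death rate
    by ``famine_base ** T_f``; the result is clamped to [0, 1].
    """
    if config is None:
        config = StepConfig()
    s = np.asarray(intrinsic_s, dtype=float)
    d = 1.0 - s
    reduction = np.power(config.care.death_reduction_factor,
                         np.asarray(care_channels, dtype=float))
    magnify = config.famine_base ** T_f
    if config.famine_on == "cared":
        d_final = magnify * (d / reduction)
    else:  # famine acts on the intrinsic death rate, care divides afterwards
        d_final = (magnify * d) / reduction
    out = np.clip(1.0 - d_final, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def effective_reproduction(
    intrinsic_r,
    ltr_applicable=False,
    famine: bool = False,
    config: StepConfig | None = None,
):
    """Care-modified reproduction rate; zero under famine (scalar or array)."""
    if config is None:
        config = StepConfig()
    r = np.asarray(intrinsic_r, dtype=float)
    if famine:
        out = np.zeros_like(r)
    else:
        boosted = np.minimum(1.0, config.care.ltr_multiplier * r)
        out = np.where(np.asarray(ltr_applicable, dtype=bool), boosted, r)
    return float(out) if out.ndim == 0 else out


def choose_father(males, rng: np.random.Generator, weights=None):
    """Draw one mature male with probability proportional to his weight.

    ``males`` is a sequence of :class:`~pprls.population.Agent`; the default
    weight is each male's expressed reproduction rate at his current stage
    (the engine passes care-modified weights instead).  Returns ``None``
    when no eligible male exists or all weights are zero, in which case the
    birth silently fails.
    """
    eligible = [m for m in males if m.sex == MALE and m.stage >= REPRODUCTION_START]
    if not eligible:
        return None
    if weights is None:
        w = np.array(
            [m.genome.express(MALE, "reproduction", min(m.stage, 100))
             for m in eligible],
            dtype=float,
        )
    else:
        w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        return None
    return eligible[_weighted_index(w, total, rng)]


def _weighted_index(w: np.ndarray, total: float, rng: np.random.Generator) -> int:
    return int(np.searchsorted(np.cumsum(w), rng.random() * total, side="right"))


# ----------------------------------------------------------------------
# vectorised expression helpers

def _expressed_survival(state: PopulationState, config: StepConfig) -> np.ndarray:
    s = np.empty(state.n, dtype=float)
    stage = state.stage
    infants = stage < 2
    terminal = stage >= config.max_stage
    s[infants] = config.infant_survival
    s[terminal] = 0.0
    mid = ~(infants | terminal)
    if np.any(mid):
        idx = np.nonzero(mid)[0]
        loc = SURV_LOCUS[state.sex[idx], stage[idx]]
        s[idx] = _SURV_VALUES[state.levels[idx, :, loc]].mean(axis=1)
    return s


def _expressed_reproduction(
    state: PopulationState, idx: np.ndarray
) -> np.ndarray:
    """Expressed reproduction rate for agents at array positions ``idx``."""
    stage = np.minimum(state.stage[idx], 100)
    loc = REPR_LOCUS[state.sex[idx], stage]
    return _REPR_VALUES[state.levels[idx, :, loc]].mean(axis=1)


@dataclass
class StepReport:
    """Per-step census bookkeeping and (optional) female stage tallies."""

    n_start: int
    famine: bool
    T_f: int
    deaths: int
    births: int
    female_exposures: Optional[np.ndarray] = None  # (102,) counts
    female_survivals: Optional[np.ndarray] = None
    female_births: Optional[np.ndarray] = None


def step(
    state: PopulationState,
    config: StepConfig,
    collect: bool = False,
    event_log: Optional[ev.EventLog] = None,
) -> StepReport:
    """Advance the population by one step in place; see the module docstring."""
    rng = state.rng
    n = state.n
    if n == 0:
        return StepReport(0, False, state.T_f, 0, 0)
    t = state.t
    stage = state.stage
    sex = state.sex

    # (1) famine accounting on the head count at step start
    famine = n > config.capacity
    state.T_f = state.T_f + 1 if famine else 0
    T_f = state.T_f

    # (2) kin-liveness snapshot
    mother_alive = state.alive_lookup(state.mother)
    gm_alive = state.alive_lookup(state.grandmother)

    # (3) survival phase
    s = _expressed_survival(state, config)
    care = config.care
    channels = np.zeros(n, dtype=np.int8)
    infants = stage < 2
    if care.m:
        channels += (infants & mother_alive).astype(np.int8)
    if care.gm:
        channels += (infants & gm_alive).astype(np.int8)
    if care.lts:
        lts_ok = (stage >= 2) & mother_alive
        if care.lts_recipients == "male_only":
            lts_ok &= sex == MALE
        channels += lts_ok.astype(np.int8)
    s_eff = effective_survival(s, channels, T_f, config)
    survived = rng.random(n) < s_eff
    n_deaths = int(n - survived.sum())

    want_tallies = collect or event_log is not None
    fem_expo = fem_surv = fem_births = None
    if want_tallies:
        fem = sex == FEMALE
        fem_expo = np.bincount(stage[fem], minlength=MAX_STAGE + 1)
        fem_surv = np.bincount(stage[fem & survived], minlength=MAX_STAGE + 1)
        fem_births = np.zeros(MAX_STAGE + 1, dtype=np.int64)
    if event_log is not None:
        if famine:
            event_log.append(t, ev.FAMINE, np.array([-1]), np.array([T_f]),
                             np.array([-1]))
        event_log.append(t, ev.SURVIVE, state.ids[survived], stage[survived],
                         sex[survived])
        event_log.append(t, ev.DEATH, state.ids[~survived], stage[~survived],
                         sex[~survived])

    # (4) reproduction phase (no births at all under famine)
    k = 0
    if not famine:
        mature = stage >= config.reproduction_start
        mothers_pool = np.nonzero(survived & (sex == FEMALE) & mature)[0]
        fathers_pool = np.nonzero(survived & (sex == MALE) & mature)[0]
        if mothers_pool.size and fathers_pool.size:
            r = _expressed_reproduction(state, mothers_pool)
            if care.ltr:
                ltr_ok = mother_alive[mothers_pool]
                # female recipients always qualify under both filters
                r = np.where(
                    ltr_ok, np.minimum(1.0, care.ltr_multiplier * r), r
                )
            gives_birth = rng.random(mothers_pool.size) < r
            mothers_idx = mothers_pool[gives_birth]
            k = int(mothers_idx.size)
            if k:
                w = _expressed_reproduction(state, fathers_pool)
                if care.ltr and care.ltr_recipients == "all":
                    ltr_ok_m = mother_alive[fathers_pool]
                    w = np.where(
                        ltr_ok_m, np.minimum(1.0, care.ltr_multiplier * w), w
                    )
                total_w = w.sum()
                if total_w <= 0:
                    k = 0  # no eligible father: births silently fail
                else:
                    cw = np.cumsum(w)
                    fathers_idx = fathers_pool[
                        np.searchsorted(cw, rng.random(k) * total_w,
                                        side="right")
                    ]
                    mat = state.levels[
                        mothers_idx, rng.integers(0, 2, size=k), :
                    ]
                    pat = state.levels[
                        fathers_idx, rng.integers(0, 2, size=k), :
                    ]
                    chrom_a, chrom_b = crossover(
                        mat, pat, config.breakpoint_prob, rng
                    )
                    child_levels = mutate(
                        np.stack([chrom_a, chrom_b], axis=1),
                        config.mutation, rng,
                    )
                    child_sex = rng.integers(0, 2, size=k).astype(np.int8)
                    child_ids = state.allocate_ids(k)
                    child_mother = state.ids[mothers_idx]
                    child_gm = state.mother[mothers_idx]
                    if want_tallies:
                        np.add.at(fem_births, stage[mothers_idx], 1)
                    if event_log is not None:
                        event_log.append(
                            t, ev.BIRTH, child_mother, stage[mothers_idx],
                            np.full(k, FEMALE, dtype=np.int8),
                        )

    # (5) ageing + assembly of the next living set
    new_stage = (stage[survived] + 1).astype(np.int16)
    if k:
        ids = np.concatenate([state.ids[survived], child_ids])
        sexes = np.concatenate([sex[survived], child_sex])
        stages = np.concatenate([new_stage,
                                 np.zeros(k, dtype=np.int16)])
        mothers = np.concatenate([state.mother[survived], child_mother])
        gms = np.concatenate([state.grandmother[survived], child_gm])
        levels = np.concatenate([state.levels[survived], child_levels])
    else:
        ids = state.ids[survived]
        sexes = sex[survived]
        stages = new_stage
        mothers = state.mother[survived]
        gms = state.grandmother[survived]
        levels = state.levels[survived]
    state.replace_living(ids, sexes, stages, mothers, gms, levels)
    state.t = t + 1
    return StepReport(
        n_start=n, famine=famine, T_f=T_f, deaths=n_deaths, births=k,
        female_exposures=fem_expo, female_survivals=fem_surv,
        female_births=fem_births,
    )


@dataclass
class StageTally:
    """Aggregated female stage counts over a sampling window."""

    exposures: np.ndarray = field(
        default_factory=lambda: np.zeros(MAX_STAGE + 1, dtype=np.int64))
    survivals: np.ndarray = field(
        default_factory=lambda: np.zeros(MAX_STAGE + 1, dtype=np.int64))
    births: np.ndarray = field(
        default_factory=lambda: np.zeros(MAX_STAGE + 1, dtype=np.int64))

    def add(self, report: StepReport) -> None:
        self.exposures += report.female_exposures
        self.survivals += report.female_survivals
        self.births += report.female_births

    def merged(self, other: "StageTally") -> "StageTally":
        return StageTally(
            self.exposures + other.exposures,
            self.survivals + other.survivals,
            self.births + other.births,
        )


@dataclass
class RunResult:
    """Time series, window tallies and final population of one run."""

    status: str  # "completed" | "extinct"
    steps_run: int
    n: np.ndarray
    T_f: np.ndarray
    births: np.ndarray
    deaths: np.ndarray
    famine: np.ndarray
    windows: tuple[tuple[int, int], ...]
    tallies: list[StageTally]
    final_state: Optional[PopulationState]
    events: Optional[ev.EventLog]

    @property
    def extinct(self) -> bool:
        return self.status == "extinct"

    def series_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": np.arange(self.steps_run),
                "N": self.n,
                "T_f": self.T_f,
                "births": self.births,
                "deaths": self.deaths,
                "famine": self.famine,
            }
        )


def run(
    config: StepConfig,
    n_steps: int,
    rng: np.random.Generator | int | None = None,
    n_founders: int = 1000,
    windows: Sequence[tuple[int, int]] = (),
    record_events: bool = False,
    keep_final_state: bool = True,
) -> RunResult:
    """Run ``n_steps`` simulation steps (or until extinction) from founders.

    ``windows`` is a sequence of half-open step intervals ``[start, end)``;
    female stage tallies (exposures, survivals, births) are accumulated over
    each window for life-table estimation.  Fully reproducible from
    ``(config, seed)``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    windows = tuple((int(a), int(b)) for a, b in windows)
    for a, b in windows:
        if not 0 <= a < b <= n_steps:
            raise ValueError(f"window ({a}, {b}) outside run of {n_steps} steps")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    state = init_population(n_founders, rng)
    tallies = [StageTally() for _ in windows]
    log = ev.EventLog() if record_events else None
    n_arr = np.zeros(n_steps, dtype=np.int64)
    tf_arr = np.zeros(n_steps, dtype=np.int32)
    b_arr = np.zeros(n_steps, dtype=np.int64)
    d_arr = np.zeros(n_steps, dtype=np.int64)
    f_arr = np.zeros(n_steps, dtype=bool)
    status = "completed"
    steps_run = 0
    for t in range(n_steps):
        active = [tal for (a, b), tal in zip(windows, tallies) if a <= t < b]
        report = step(state, config, collect=bool(active), event_log=log)
        n_arr[t] = report.n_start
        tf_arr[t] = report.T_f
        b_arr[t] = report.births
        d_arr[t] = report.deaths
        f_arr[t] = report.famine
        for tal in active:
            tal.add(report)
        steps_run = t + 1
        if state.n == 0:
            status = "extinct"
            break
    return RunResult(
        status=status,
        steps_run=steps_run,
        n=n_arr[:steps_run],
        T_f=tf_arr[:steps_run],
        births=b_arr[:steps_run],
        deaths=d_arr[:steps_run],
        famine=f_arr[:steps_run],
        windows=windows,
        tallies=tallies,
        final_state=state if keep_final_state else None,
        events=log,
    )
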