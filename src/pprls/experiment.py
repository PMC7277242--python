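"""Condition presets, the replicate protocol and cross-condition aggregation.

A *condition* is a named combination of care channels: ``NULL``, ``M``,
``GM``, ``M+GM``, ``LTr``, ``LTr+M``, ``LTr+GM``, ``LTr+M+GM``, ``LTs``,
``LTs+M``, ``LTs+GM`` and ``LTs+M+GM``, optionally perturbed by sex-limited
long-term care or a different beneficial-to-deleterious mutation ratio eta.

The reference protocol runs each condition five times for 200,000 steps and
samples the female life table every 20,000 steps from step 100,000, each
sample over the trailing 10,000-step window; the per-window PrR values of
all replicates are pooled into the condition's PrR distribution.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .demography import (
    LifeTable,
    PPRLSMetrics,
    PPRLS_CUTOFF,
    ScalingStats,
    genotype_summary,
    life_table_from_tally,
    pprls_metrics,
    scaling_stats,
)
from .dynamics import CareStrategySet, RunResult, StageTally, StepConfig, run
from .genome import MutationModel

CONDITION_NAMES = (
    "NULL", "M", "GM", "M+GM",
    "LTr", "LTr+M", "LTr+GM", "LTr+M+GM",
    "LTs", "LTs+M", "LTs+GM", "LTs+M+GM",
)
_TOKENS = {"M": "m", "GM": "gm", "LTr": "ltr", "LTs": "lts"}


@dataclass(frozen=True)
class ConditionPreset:
    """Named care-strategy combination plus its mutation model."""

    name: str
    care: CareStrategySet
    mutation: MutationModel = field(default_factory=MutationModel)

    @classmethod
    def from_name(
        cls,
        name: str,
        eta: float = 0.5,
        mutation_rate: float = 0.025,
        death_reduction_factor: float = 10.0,
        ltr_multiplier: float = 2.0,
        ltr_recipients: str = "all",
        lts_recipients: str = "all",
    ) -> "ConditionPreset":
        flags = {"m": False, "gm": False, "ltr": False, "lts": False}
        if name != "NULL":
            for token in name.split("+"):
                if token not in _TOKENS:
                    raise ValueError(
                        f"unknown condition token {token!r} in {name!r}; "
                        f"valid conditions: {', '.join(CONDITION_NAMES)}"
                    )
                if flags[_TOKENS[token]]:
                    raise ValueError(f"repeated token {token!r} in {name!r}")
                flags[_TOKENS[token]] = True
        care = CareStrategySet(
            death_reduction_factor=death_reduction_factor,
            ltr_multiplier=ltr_multiplier,
            ltr_recipients=ltr_recipients,
            lts_recipients=lts_recipients,
            **flags,
        )
        return cls(name=name, care=care,
                   mutation=MutationModel(rate=mutation_rate, eta=eta))

    @property
    def has_mother_care(self) -> bool:
        return self.care.m


@dataclass(frozen=True)
class Protocol:
    """Replicate and sampling schedule."""

    n_steps: int = 200_000
    n_replicates: int = 5
    sample_times: tuple[int, ...] = tuple(range(100_000, 200_001, 20_000))
    window_length: int = 10_000

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.n_replicates < 1:
            raise ValueError("n_steps and n_replicates must be >= 1")
        for t in self.sample_times:
            if not self.window_length <= t <= self.n_steps:
                raise ValueError(
                    f"sample time {t} with window {self.window_length} "
                    f"outside run of {self.n_steps} steps"
                )

    @property
    def windows(self) -> tuple[tuple[int, int], ...]:
        return tuple((t - self.window_length, t) for t in self.sample_times)


def make_config(preset: ConditionPreset, **overrides) -> StepConfig:
    return StepConfig(care=preset.care, mutation=preset.mutation, **overrides)


@dataclass
class ConditionSummary:
    """Pooled PrR distribution and diagnostics for one condition."""

    name: str
    prr_samples: pd.DataFrame  # replicate, t, PrR, PrT, B, E, m_tot, l2
    prr_mean: float
    prr_sd: float
    prr_replicate_means: dict[int, float]
    n_extinct: int
    extinct_replicates: list[int]
    pooled_life_table: Optional[LifeTable]
    pooled_metrics: Optional[PPRLSMetrics]
    genotype_means: Optional[pd.DataFrame]
    pprls_strict: bool     # mean - 1 sd above the cutoff
    pprls_majority: bool   # mean above cutoff and >= 75% of samples above
    sample_tables: list[LifeTable] = field(default_factory=list)
    cutoff: float = PPRLS_CUTOFF
    runs: Optional[list[RunResult]] = None

    def to_dict(self) -> dict:
        return {
            "condition": self.name,
            "prr_mean": self.prr_mean,
            "prr_sd": self.prr_sd,
            "n_samples": int(len(self.prr_samples)),
            "prr_samples": self.prr_samples["PrR"].tolist(),
            "prr_replicate_means": {
                str(k): v for k, v in self.prr_replicate_means.items()
            },
            "n_extinct": self.n_extinct,
            "pprls_strict": self.pprls_strict,
            "pprls_majority": self.pprls_majority,
            "cutoff": self.cutoff,
        }


def _as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _run_replicate(args) -> RunResult:
    preset, overrides, n_steps, windows, seed_seq = args
    config = make_config(preset, **overrides)
    rng = np.random.default_rng(seed_seq)
    return run(config, n_steps, rng, windows=windows, keep_final_state=True)


def run_condition(
    preset: ConditionPreset,
    protocol: Protocol,
    seed: int | None = None,
    n_jobs: int = 1,
    keep_runs: bool = False,
    **config_overrides,
) -> ConditionSummary:
    """Run a condition's replicates and pool the per-window PrR samples.

    Replicates use independent child seeds spawned from ``seed``; extinct
    replicates contribute no samples and are counted.  The pooled life table
    merges the stage tallies of every completed window, and the genotype
    summary averages the final populations of all surviving replicates.
    """
    seeds = _as_seed_sequence(seed).spawn(protocol.n_replicates)
    jobs = [
        (preset, config_overrides, protocol.n_steps, protocol.windows, s)
        for s in seeds
    ]
    if n_jobs > 1:
        with ProcessPoolExecutor(max_workers=n_jobs) as pool:
            results = list(pool.map(_run_replicate, jobs))
    else:
        results = [_run_replicate(j) for j in jobs]
    return summarize_condition(preset, protocol, results, keep_runs=keep_runs)


def summarize_condition(
    preset: ConditionPreset,
    protocol: Protocol,
    results: Sequence[RunResult],
    keep_runs: bool = False,
) -> ConditionSummary:
    rows = []
    tables: list[LifeTable] = []
    pooled: Optional[StageTally] = None
    final_states = []
    extinct_reps = []
    for rep, res in enumerate(results):
        if res.extinct:
            extinct_reps.append(rep)
            continue
        final_states.append(res.final_state)
        for (a, b), tally in zip(res.windows, res.tallies):
            lt = life_table_from_tally(tally, (a, b))
            met = pprls_metrics(lt)
            pooled = tally if pooled is None else pooled.merged(tally)
            tables.append(lt)
            rows.append(
                (rep, b, met.PrR, met.PrT, met.B, met.E, met.m_tot,
                 float(lt.l[2]))
            )
    frame = pd.DataFrame(
        rows, columns=["replicate", "t", "PrR", "PrT", "B", "E", "m_tot",
                       "l2"]
    )
    if len(frame):
        mean = float(frame["PrR"].mean())
        sd = float(frame["PrR"].std(ddof=1)) if len(frame) > 1 else 0.0
        rep_means = {
            int(r): float(g["PrR"].mean())
            for r, g in frame.groupby("replicate")
        }
        frac_above = float((frame["PrR"] > PPRLS_CUTOFF).mean())
        strict = mean - sd > PPRLS_CUTOFF
        majority = mean > PPRLS_CUTOFF and frac_above >= 0.75
        pooled_lt = life_table_from_tally(pooled)
        pooled_met = pprls_metrics(pooled_lt)
    else:
        mean = sd = float("nan")
        rep_means = {}
        strict = majority = False
        pooled_lt = pooled_met = None
    return ConditionSummary(
        name=preset.name,
        prr_samples=frame,
        prr_mean=mean,
        prr_sd=sd,
        prr_replicate_means=rep_means,
        n_extinct=len(extinct_reps),
        extinct_replicates=extinct_reps,
        pooled_life_table=pooled_lt,
        pooled_metrics=pooled_met,
        genotype_means=genotype_summary(final_states) if final_states else None,
        pprls_strict=strict,
        pprls_majority=majority,
        sample_tables=tables,
        runs=list(results) if keep_runs else None,
    )


@dataclass
class MatrixResult:
    """All condition summaries plus the cross-condition scaling analysis."""

    summaries: dict[str, ConditionSummary]
    scaling: Optional[ScalingStats]

    def to_dict(self) -> dict:
        out = {
            "conditions": {k: s.to_dict() for k, s in self.summaries.items()}
        }
        if self.scaling is not None:
            out["scaling"] = {
                "mean_product_no_mother_care":
                    self.scaling.mean_product_no_mother_care,
                "spearman_rho": self.scaling.spearman_rho,
                "spearman_p": self.scaling.spearman_p,
            }
        return out


def run_matrix(
    presets: Sequence[ConditionPreset],
    protocol: Protocol,
    seed: int | None = None,
    n_jobs: int = 1,
    **config_overrides,
) -> MatrixResult:
    """Run several conditions and pool the Fig-5-style scaling statistics.

    Each per-window sample contributes one ``(l_2, m_tot, E)`` point; the
    scaling constant (mean ``m_tot * l_2``) averages samples from conditions
    without mother-care, and the Spearman correlation relates fertility to
    reproductive longevity across all samples.  Samples are labelled
    ``pprls`` / ``mother_care`` / ``other`` for plotting.
    """
    child_seeds = _as_seed_sequence(seed).spawn(len(presets))
    summaries: dict[str, ConditionSummary] = {}
    tables: list[LifeTable] = []
    labels: list[str] = []
    mother_care: list[bool] = []
    for preset, child in zip(presets, child_seeds):
        summary = run_condition(
            preset, protocol, seed=child, n_jobs=n_jobs, **config_overrides,
        )
        summaries[preset.name] = summary
        tables.extend(summary.sample_tables)
        labels.extend([preset.name] * len(summary.sample_tables))
        mother_care.extend(
            [preset.has_mother_care] * len(summary.sample_tables)
        )
    scaling = scaling_stats(tables, labels, mother_care) if tables else None
    if scaling is not None:
        marker = []
        for lab in scaling.frame["label"]:
            s = summaries[lab]
            if s.pprls_strict or s.pprls_majority:
                marker.append("pprls")
            elif s.name.split("+").count("M"):
                marker.append("mother_care")
            else:
                marker.append("other")
        scaling.frame["marker"] = marker
    return MatrixResult(summaries=summaries, scaling=scaling)
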