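"""Female period life tables and post-reproductive lifespan statistics.

The simulator reports, for a sampling window of steps, the per-stage
exposures, survivals and births of female agents.  From these this module
estimates a period life table — survivorship ``l_i`` (probability for a
female newborn to survive to stage *i*) and fecundity ``m_i`` (probability
for a living stage-*i* female to give birth in a step) — and derives:

``e_i``          expected remaining lifespan at stage *i*;
``B`` / ``E``    beginning / end of reproduction: the smallest stages whose
                 cumulative fecundity reaches 5% / 95% of the lifetime total
                 (``E`` is the reproductive longevity);
``PrT = e_E``    post-reproduction time;
``PrR``          post-reproduction representation,
                 ``l_E e_E / (l_B e_B)`` — the statistically robust measure
                 of prolonged post-reproductive lifespan (PPRLS); values
                 above ~0.20 indicate PPRLS;
``c_i``          care-efficacy curves: the expected number of receivers a
                 stage-*i* female supplies for each investment strategy.

All sums truncate at the terminal stage (guaranteed death), i.e.
``l_102 = 0``, making every formula finite and exact.  Estimation is
period-style (one exposure per living female per step at her stage; famine
deaths and famine-suppressed births are included), which avoids the
right-truncation bias a cohort estimator would suffer inside a finite
window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import events as ev
from .dynamics import StageTally
from .genome import (
    FEMALE,
    MAX_STAGE,
    REPR_LOCUS,
    SURV_LOCUS,
    _REPR_VALUES,
    _SURV_VALUES,
)

N_STAGES = MAX_STAGE + 1  # 0..101
PPRLS_CUTOFF = 0.20


@dataclass
class LifeTable:
    """Per-stage female survivorship and fecundity over a sampling window."""

    l: np.ndarray  # (102,) survivorship, l[0] == 1
    m: np.ndarray  # (102,) fecundity, m[i] == 0 for i < 8
    window: tuple[int, int] | None = None
    exposures: Optional[np.ndarray] = None
    no_data: Optional[np.ndarray] = None  # stages with zero exposure

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        if self.l.shape != (N_STAGES,) or self.m.shape != (N_STAGES,):
            raise ValueError(f"life table needs {N_STAGES} stages")
        if self.l[0] != 1.0:
            raise ValueError("l[0] must be 1")
        if np.any(np.diff(self.l) > 1e-12):
            raise ValueError("survivorship must be non-increasing")
        if np.any((self.l < 0) | (self.l > 1) | (self.m < 0) | (self.m > 1)):
            raise ValueError("l and m must lie in [0, 1]")

    @property
    def m_tot(self) -> float:
        """Total lifetime fecundity, sum of m_i."""
        return float(self.m.sum())

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            {"stage": np.arange(N_STAGES), "l": self.l, "m": self.m}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "LifeTable":
        frame = pd.read_csv(path, sep="\t")
        return cls(frame["l"].to_numpy(float), frame["m"].to_numpy(float))


def life_table_from_tally(
    tally: StageTally, window: tuple[int, int] | None = None
) -> LifeTable:
    """Period life table from window-aggregated female stage counts.

    Realised survival ``q_i = survivals_i / exposures_i`` and fecundity
    ``m_i = births_i / exposures_i``; survivorship accumulates as
    ``l_0 = 1, l_{i+1} = l_i q_i``.  Stages never observed in the window get
    ``q = m = 0`` and are flagged, not interpolated.
    """
    expo = np.asarray(tally.exposures, dtype=float)
    if expo[0] <= 0:
        raise ValueError("window contains no stage-0 female exposures")
    no_data = expo <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(no_data, 0.0, tally.survivals / np.maximum(expo, 1))
        m = np.where(no_data, 0.0, tally.births / np.maximum(expo, 1))
    l = np.ones(N_STAGES)
    l[1:] = np.cumprod(q[:-1])
    return LifeTable(l=l, m=m, window=window, exposures=expo.astype(np.int64),
                     no_data=no_data)


def tally_from_events(log: ev.EventLog, window: tuple[int, int]) -> StageTally:
    """Aggregate female stage counts from an event log over ``[start, end)``."""
    a, b = window
    sel = (log.step >= a) & (log.step < b)
    if not np.any(sel):
        raise ValueError(f"no events in window [{a}, {b})")
    event = log.event[sel]
    stage = log.stage[sel]
    sex = log.sex[sel]
    fem = sex == FEMALE
    tally = StageTally()
    surv = fem & (event == ev.SURVIVE)
    died = fem & (event == ev.DEATH)
    born = fem & (event == ev.BIRTH)  # birth records carry the mother
    tally.survivals += np.bincount(stage[surv], minlength=N_STAGES)
    tally.exposures += (
        np.bincount(stage[surv], minlength=N_STAGES)
        + np.bincount(stage[died], minlength=N_STAGES)
    )
    tally.births += np.bincount(stage[born], minlength=N_STAGES)
    return tally


def estimate_life_table(
    log: ev.EventLog, window: tuple[int, int]
) -> LifeTable:
    """Estimate the female period life table from an event log window."""
    return life_table_from_tally(tally_from_events(log, window), window)


def remaining_lifespan(l: np.ndarray) -> np.ndarray:
    """Expected remaining lifespan ``e_i`` from survivorship.

    ``e_i = sum_k (k - i)(l_k - l_{k+1}) / sum_k (l_k - l_{k+1})`` with the
    sums truncated at the terminal stage (``l`` beyond it is 0).  Stages with
    ``l_i = 0`` are never reached; their ``e_i`` is NaN rather than
    fabricated.
    """
    l = np.asarray(l, dtype=float)
    l_ext = np.append(l, 0.0)
    deaths = l_ext[:-1] - l_ext[1:]  # deaths[k] between stages k and k+1
    k = np.arange(deaths.size, dtype=float)
    # reversed cumulative sums: sum_{k >= i} deaths_k  and  k * deaths_k
    tail_d = np.cumsum(deaths[::-1])[::-1]
    tail_kd = np.cumsum((k * deaths)[::-1])[::-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        e = (tail_kd - k * tail_d) / tail_d
    e[l <= 0] = np.nan
    return e


def reproduction_bounds(m: np.ndarray) -> tuple[int, int]:
    """Stages where cumulative fecundity first reaches 5% and 95% of total."""
    m = np.asarray(m, dtype=float)
    total = m.sum()
    if total <= 0:
        raise ValueError("reproduction bounds undefined for m_tot = 0")
    cum = np.cumsum(m)
    eps = 1e-12 * total
    B = int(np.argmax(cum >= 0.05 * total - eps))
    E = int(np.argmax(cum >= 0.95 * total - eps))
    return B, E


@dataclass
class PPRLSMetrics:
    """Post-reproductive lifespan summary of one life table."""

    e: np.ndarray
    B: int
    E: int
    PrT: float
    PrR: float
    m_tot: float
    product: float  # m_tot * l_2, the fertility-infant-survival product
    has_pprls: bool
    cutoff: float = PPRLS_CUTOFF

    def to_dict(self) -> dict:
        return {
            "B": self.B,
            "E": self.E,
            "PrT": self.PrT,
            "PrR": self.PrR,
            "m_tot": self.m_tot,
            "m_tot_l2": self.product,
            "has_pprls": self.has_pprls,
            "cutoff": self.cutoff,
            "e": [None if np.isnan(x) else x for x in self.e],
        }


def pprls_metrics(lt: LifeTable, cutoff: float = PPRLS_CUTOFF) -> PPRLSMetrics:
    """Assemble e, B, E, PrT, PrR and the fertility summaries for one table."""
    e = remaining_lifespan(lt.l)
    B, E = reproduction_bounds(lt.m)
    if lt.l[B] <= 0:
        raise ValueError("degenerate life table: no survivors at stage B")
    PrT = float(e[E])
    PrR = float((lt.l[E] * e[E]) / (lt.l[B] * e[B]))
    m_tot = lt.m_tot
    return PPRLSMetrics(
        e=e, B=B, E=E, PrT=PrT, PrR=PrR, m_tot=m_tot,
        product=float(m_tot * lt.l[2]),
        has_pprls=bool(PrR > cutoff), cutoff=cutoff,
    )


def write_metrics_json(metrics: PPRLSMetrics, path) -> None:
    Path(path).write_text(json.dumps(metrics.to_dict(), indent=2))


@dataclass
class EfficacyCurves:
    """Expected number of care-receivers per stage for each strategy."""

    c_m: np.ndarray
    c_ltr: np.ndarray
    c_lts: np.ndarray
    c_gm: np.ndarray


def care_efficacy(lt: LifeTable) -> EfficacyCurves:
    """Per-stage expected number of care-receivers for each strategy.

    For a female at stage *i*:

    - mother-care receivers are her unweaned infants:
      ``c^M_i = m_{i-2} l_1 + m_{i-1} l_0``;
    - long-term-care receivers are her surviving independent offspring,
      adults for LTr (``j <= i - 9``) and weaned infants onward for LTs
      (``j <= i - 2``): ``sum_j m_j l_{i-j-1}`` over births at her stage
      ``j >= 8``;
    - grandmother-care receivers are her daughters' unweaned infants; the
      factor 1/2 keeps only daughters among her offspring.

    Out-of-range indices contribute zero; all curves are cumulative except
    ``c^M``, which tracks current fecundity and vanishes in late life.
    """
    l, m = lt.l, lt.m
    c_m = np.zeros(N_STAGES)
    c_ltr = np.zeros(N_STAGES)
    c_lts = np.zeros(N_STAGES)
    c_gm = np.zeros(N_STAGES)

    def _m(i):
        return m[i] if 0 <= i < N_STAGES else 0.0

    def _l(i):
        return l[i] if 0 <= i < N_STAGES else 0.0

    for i in range(N_STAGES):
        c_m[i] = _m(i - 2) * l[1] + _m(i - 1) * l[0]
        js = np.arange(8, i - 1)  # j <= i - 2
        if js.size:
            terms = m[js] * l[i - js - 1]
            c_lts[i] = terms.sum()
            c_ltr[i] = terms[js <= i - 9].sum()
        # grand-offspring: daughter born at stage j (of the grandmother),
        # daughter now at stage k with an infant at stage 0 or 1
        for j in range(8, i):
            k1 = i - j - 3  # grandchild at stage 1
            if 0 <= k1 <= i - 1 and k1 < N_STAGES:
                c_gm[i] += 0.5 * m[j] * l[k1] * m[k1] * l[1]
            k0 = i - j - 2  # grandchild at stage 0
            if 0 <= k0 <= i - 1 and k0 < N_STAGES:
                c_gm[i] += 0.5 * m[j] * l[k0] * m[k0] * l[0]
    return EfficacyCurves(c_m=c_m, c_ltr=c_ltr, c_lts=c_lts, c_gm=c_gm)


@dataclass
class ScalingStats:
    """Cross-sample infant-survival / fertility scaling summary."""

    frame: pd.DataFrame  # per sample: label, l2, m_tot, product, B, E
    mean_product_no_mother_care: float
    spearman_rho: float
    spearman_p: float


def scaling_stats(
    tables: Sequence[LifeTable],
    labels: Sequence[str] | None = None,
    mother_care: Sequence[bool] | None = None,
) -> ScalingStats:
    """Summarise the fertility-vs-infant-survival scaling across samples.

    Reports per-sample ``(l_2, m_tot, m_tot * l_2, B, E)``, the mean product
    over samples from conditions *without* mother-care (the scaling
    constant), and the Spearman rank correlation between fertility
    ``m_tot`` and reproductive longevity ``E`` over all samples.
    """
    if not tables:
        raise ValueError("need at least one life table")
    n = len(tables)
    labels = list(labels) if labels is not None else [""] * n
    mc = list(mother_care) if mother_care is not None else [False] * n
    rows = []
    for lt, lab, has_mc in zip(tables, labels, mc):
        B, E = reproduction_bounds(lt.m)
        rows.append((lab, float(lt.l[2]), lt.m_tot,
                     float(lt.m_tot * lt.l[2]), B, E, bool(has_mc)))
    frame = pd.DataFrame(
        rows, columns=["label", "l2", "m_tot", "product", "B", "E",
                       "mother_care"]
    )
    no_mc = frame.loc[~frame["mother_care"], "product"]
    mean_product = float(no_mc.mean()) if len(no_mc) else float("nan")
    if frame["m_tot"].nunique() > 1 and frame["E"].nunique() > 1:
        rho, p = sps.spearmanr(frame["m_tot"], frame["E"])
    else:
        rho, p = float("nan"), float("nan")
    return ScalingStats(
        frame=frame,
        mean_product_no_mother_care=mean_product,
        spearman_rho=float(rho),
        spearman_p=float(p),
    )


def genotype_summary(states) -> pd.DataFrame:
    """Mean expressed female rates per stage, pooled over every chromosome.

    ``states`` is one population state or a list of them (e.g. the final
    populations of several replicates); every chromosome of every living
    agent contributes its female-block locus value.
    """
    if not isinstance(states, (list, tuple)):
        states = [states]
    all_levels = np.concatenate(
        [st.levels.reshape(-1, st.levels.shape[-1]) for st in states]
    )  # (total chromosomes, 384)
    stages = np.arange(N_STAGES)
    mean_s = np.full(N_STAGES, np.nan)
    mean_r = np.full(N_STAGES, np.nan)
    for i in stages:
        sl = SURV_LOCUS[FEMALE, i]
        if sl >= 0:
            mean_s[i] = _SURV_VALUES[all_levels[:, sl]].mean()
        rl = REPR_LOCUS[FEMALE, i]
        if rl >= 0:
            mean_r[i] = _REPR_VALUES[all_levels[:, rl]].mean()
    return pd.DataFrame({"stage": stages, "mean_s": mean_s, "mean_r": mean_r})
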