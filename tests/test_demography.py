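"""Life-table estimation and post-reproductive statistics vs brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pprls import (
    EventLog,
    LifeTable,
    StepConfig,
    MutationModel,
    care_efficacy,
    estimate_life_table,
    genotype_summary,
    pprls_metrics,
    remaining_lifespan,
    reproduction_bounds,
    run,
    scaling_stats,
)
from pprls.demography import N_STAGES, tally_from_events
from pprls.population import init_population
import pprls.events as ev
from oracles import (
    oracle_efficacy,
    oracle_metrics,
    oracle_remaining_lifespan,
    random_toy_table,
)


class TestLifeTableEstimation:
    def _cohort_log(self, rng, q=0.9, n_cohorts=300, cohort=30, m8=0.0):
        """Brute-force synthetic log: independent female cohorts with a
        constant per-stage survival probability q."""
        log = EventLog()
        next_id = 0
        for t0 in range(n_cohorts):
            ids = np.arange(next_id, next_id + cohort)
            next_id += cohort
            alive = np.ones(cohort, dtype=bool)
            for stage in range(0, 30):
                t = t0 + stage
                live_ids = ids[alive]
                if live_ids.size == 0:
                    break
                survives = rng.random(live_ids.size) < q
                log.append(t, ev.SURVIVE, live_ids[survives],
                           np.full(survives.sum(), stage),
                           np.full(survives.sum(), 1))
                log.append(t, ev.DEATH, live_ids[~survives],
                           np.full((~survives).sum(), stage),
                           np.full((~survives).sum(), 1))
                if m8 and stage == 8:
                    gives = rng.random(live_ids.size) < m8
                    log.append(t, ev.BIRTH, live_ids[gives],
                               np.full(gives.sum(), 8),
                               np.full(gives.sum(), 1))
                idx = np.searchsorted(ids, live_ids[~survives])
                alive[idx] = False
        return log

    def test_deathless_log_gives_unit_survivorship(self):
        rng = np.random.default_rng(0)
        log = self._cohort_log(rng, q=1.0, n_cohorts=50, cohort=10)
        lt = estimate_life_table(log, (0, 80))
        observed = ~lt.no_data
        assert np.all(lt.l[observed[:len(lt.l)]] == 1.0)

    def test_constant_survival_gives_geometric_survivorship(self):
        rng = np.random.default_rng(1)
        log = self._cohort_log(rng, q=0.9, n_cohorts=400, cohort=40)
        lt = estimate_life_table(log, (0, 500))
        for i in range(1, 15):
            # binomial error on q per stage, compounded into l
            assert lt.l[i] == pytest.approx(0.9 ** i, rel=0.08)

    def test_fecundity_ratio_definition(self):
        rng = np.random.default_rng(2)
        log = self._cohort_log(rng, q=1.0, n_cohorts=100, cohort=10, m8=0.4)
        lt = estimate_life_table(log, (0, 200))
        expo = lt.exposures[8]
        assert expo > 0
        assert lt.m[8] == pytest.approx(0.4, abs=4 * np.sqrt(0.4 * 0.6 / expo))
        assert lt.m[9] == 0.0

    def test_empty_window_raises(self):
        log = EventLog()
        with pytest.raises(ValueError):
            estimate_life_table(log, (0, 10))

    def test_event_log_and_engine_tallies_agree(self):
        """The compact engine tallies equal tallies rebuilt from the full
        event log of the same run."""
        cfg = StepConfig(mutation=MutationModel(rate=0.025))
        res = run(cfg, 400, rng=8, windows=[(200, 400)], record_events=True)
        from_log = tally_from_events(res.events, (200, 400))
        tal = res.tallies[0]
        np.testing.assert_array_equal(from_log.exposures, tal.exposures)
        np.testing.assert_array_equal(from_log.survivals, tal.survivals)
        np.testing.assert_array_equal(from_log.births, tal.births)

    def test_zero_exposure_stages_flagged(self):
        rng = np.random.default_rng(3)
        log = self._cohort_log(rng, q=0.5, n_cohorts=30, cohort=10)
        lt = estimate_life_table(log, (0, 60))
        assert lt.no_data is not None and lt.no_data[80]
        assert lt.l[81] == 0.0 and lt.m[80] == 0.0


class TestRemainingLifespan:
    def test_geometric_closed_form(self):
        """l_i = p^i gives e_i = p/(1-p) away from the truncation stage."""
        l = 0.9 ** np.arange(N_STAGES)
        e = remaining_lifespan(l)
        # truncated tail: e_i = 9 (1 - 0.9^(101-i)); near stage 0 the
        # correction is ~1e-5 and the closed form holds to 0.1%
        np.testing.assert_allclose(e[:30], 9.0, rtol=1e-3)
        np.testing.assert_allclose(
            e, 9.0 * (1 - 0.9 ** (101 - np.arange(N_STAGES))), rtol=1e-9
        )

    def test_all_death_between_one_and_two(self):
        l = np.zeros(N_STAGES)
        l[0] = l[1] = 1.0
        assert remaining_lifespan(l)[0] == pytest.approx(1.0)

    def test_immediate_death(self):
        l = np.zeros(N_STAGES)
        l[0] = 1.0
        e = remaining_lifespan(l)
        assert e[0] == pytest.approx(0.0)
        assert np.isnan(e[1])  # never reached, flagged not fabricated

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            lt = random_toy_table(rng)
            np.testing.assert_allclose(
                remaining_lifespan(lt.l), oracle_remaining_lifespan(lt.l),
                atol=1e-12, equal_nan=True,
            )


class TestReproductionBounds:
    def test_flat_block(self):
        m = np.zeros(N_STAGES)
        m[8:12] = 0.5
        assert reproduction_bounds(m) == (8, 11)

    def test_uniform_over_full_span(self):
        m = np.zeros(N_STAGES)
        m[8:101] = 0.2
        assert reproduction_bounds(m) == (12, 96)

    def test_single_stage(self):
        m = np.zeros(N_STAGES)
        m[20] = 0.3
        assert reproduction_bounds(m) == (20, 20)

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            reproduction_bounds(np.zeros(N_STAGES))


class TestPPRLSMetrics:
    def test_geometric_flat_e_toy_case(self):
        """With geometric l and a short fecundity block, e is flat so
        PrR = l_E / l_B = p^(E-B)."""
        l = 0.9 ** np.arange(N_STAGES)
        m = np.zeros(N_STAGES)
        m[8:12] = 0.5
        met = pprls_metrics(LifeTable(l=l, m=m))
        assert (met.B, met.E) == (8, 11)
        assert met.PrR == pytest.approx(0.9 ** 3, rel=1e-3)
        assert met.PrT == pytest.approx(9.0, rel=1e-3)

    def test_point_mass_reproduction(self):
        l = 0.95 ** np.arange(N_STAGES)
        m = np.zeros(N_STAGES)
        m[20] = 0.3
        met = pprls_metrics(LifeTable(l=l, m=m))
        assert met.B == met.E == 20
        assert met.PrR == pytest.approx(1.0)
        assert met.PrT == pytest.approx(remaining_lifespan(l)[20])

    def test_against_oracle_on_random_tables(self):
        """100 random toy tables: metrics equal direct-summation oracle."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            lt = random_toy_table(rng)
            met = pprls_metrics(lt)
            B, E, PrT, PrR = oracle_metrics(lt.l, lt.m)
            assert (met.B, met.E) == (B, E)
            assert met.PrT == pytest.approx(PrT, abs=1e-12)
            assert met.PrR == pytest.approx(PrR, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10 ** 6), scale=st.floats(0.05, 1.0))
    def test_prr_invariant_under_fecundity_rescaling(self, seed, scale):
        rng = np.random.default_rng(seed)
        lt = random_toy_table(rng)
        met = pprls_metrics(lt)
        scaled = pprls_metrics(LifeTable(l=lt.l, m=np.minimum(1, lt.m * scale)))
        assert (scaled.B, scaled.E) == (met.B, met.E)
        assert scaled.PrR == pytest.approx(met.PrR, rel=1e-9)


class TestCareEfficacy:
    def test_mother_care_tracks_fecundity(self):
        l = np.ones(N_STAGES)
        m = np.zeros(N_STAGES)
        m[8:] = 0.5
        lt = LifeTable(l=l, m=m)
        c = care_efficacy(lt)
        assert c.c_m[9] == pytest.approx(0.5)
        np.testing.assert_allclose(c.c_m[10:], 1.0)
        assert c.c_m[8] == pytest.approx(0.0)

    def test_ltr_single_term(self):
        l = np.ones(N_STAGES)
        l[1:] = 0.3  # l_8 = 0.3
        m = np.zeros(N_STAGES)
        m[8] = 0.5
        c = care_efficacy(LifeTable(l=l, m=m))
        assert c.c_ltr[17] == pytest.approx(0.5 * 0.3)
        assert c.c_ltr[16] == 0.0  # offspring still younger than stage 8

    def test_gm_zero_before_stage_18(self):
        rng = np.random.default_rng(6)
        lt = random_toy_table(rng)
        c = care_efficacy(lt)
        np.testing.assert_array_equal(c.c_gm[:18], 0.0)
        assert c.c_gm[18:].sum() > 0

    def test_against_exhaustive_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            lt = random_toy_table(rng)
            c = care_efficacy(lt)
            o_m, o_ltr, o_lts, o_gm = oracle_efficacy(lt.l, lt.m)
            np.testing.assert_allclose(c.c_m, o_m, atol=1e-12)
            np.testing.assert_allclose(c.c_ltr, o_ltr, atol=1e-12)
            np.testing.assert_allclose(c.c_lts, o_lts, atol=1e-12)
            np.testing.assert_allclose(c.c_gm, o_gm, atol=1e-12)

    def test_cumulative_curves_persist_after_menopause(self):
        """LT and GM efficacy stay positive after fecundity ends; mother-care
        efficacy vanishes."""
        l = 0.97 ** np.arange(N_STAGES)
        m = np.zeros(N_STAGES)
        m[8:30] = 0.4
        c = care_efficacy(LifeTable(l=l, m=m))
        assert c.c_m[40] == 0.0
        assert c.c_lts[40] > 0 and c.c_ltr[40] > 0 and c.c_gm[40] > 0


class TestScalingStats:
    def test_single_table_product(self):
        l = np.ones(N_STAGES)
        l[2:] = 0.5
        m = np.zeros(N_STAGES)
        m[8:16] = 0.5
        stats = scaling_stats([LifeTable(l=l, m=m)])
        assert stats.frame["product"].iloc[0] == pytest.approx(0.5 * 4.0)
        assert stats.mean_product_no_mother_care == pytest.approx(2.0)

    def test_mother_care_excluded_from_pooled_product(self):
        l = np.ones(N_STAGES)
        l[2:] = 0.5
        m = np.zeros(N_STAGES)
        m[8:16] = 0.5
        lt = LifeTable(l=l, m=m)
        m2 = m * 0.5
        lt2 = LifeTable(l=l, m=m2)
        stats = scaling_stats([lt, lt2], labels=["a", "b"],
                              mother_care=[False, True])
        assert stats.mean_product_no_mother_care == pytest.approx(2.0)

    def test_perfect_monotone_spearman(self):
        rng = np.random.default_rng(8)
        tables = []
        for hi in (20, 40, 60, 80):
            l = 0.97 ** np.arange(N_STAGES)
            m = np.zeros(N_STAGES)
            m[8:hi] = 0.3
            tables.append(LifeTable(l=l, m=m))
        stats = scaling_stats(tables)
        assert stats.spearman_rho == pytest.approx(1.0)


class TestGenotypeSummary:
    def test_founder_population_means(self):
        state = init_population(50, rng=0)
        frame = genotype_summary(state)
        s = frame.set_index("stage")
        assert s.loc[10, "mean_s"] == pytest.approx(0.97)
        assert s.loc[16, "mean_r"] == pytest.approx(0.4)
        assert s.loc[17, "mean_r"] == pytest.approx(0.1)
        assert np.isnan(s.loc[0, "mean_s"])  # infancy not on the chromosome

    def test_single_agent_population(self):
        state = init_population(2, rng=1)
        frame_all = genotype_summary(state)
        # founders are uniform, so any subset gives the same means
        sub = init_population(2, rng=2)
        frame_sub = genotype_summary(sub)
        np.testing.assert_allclose(
            frame_all["mean_s"], frame_sub["mean_s"], equal_nan=True
        )


def test_life_table_tsv_roundtrip(tmp_path):
    rng = np.random.default_rng(9)
    lt = random_toy_table(rng)
    path = tmp_path / "lt.tsv"
    lt.write_tsv(path)
    back = LifeTable.read_tsv(path)
    np.testing.assert_allclose(back.l, lt.l)
    np.testing.assert_allclose(back.m, lt.m)


def test_event_log_tsv_roundtrip(tmp_path):
    cfg = StepConfig(mutation=MutationModel(rate=0.025))
    res = run(cfg, 50, rng=10, record_events=True, n_founders=100)
    path = tmp_path / "events.tsv.gz"
    res.events.write_tsv(path)
    back = EventLog.read_tsv(path)
    assert len(back) == len(res.events)
    lt_a = estimate_life_table(res.events, (0, 50))
    lt_b = estimate_life_table(back, (0, 50))
    np.testing.assert_allclose(lt_a.l, lt_b.l)
    np.testing.assert_allclose(lt_a.m, lt_b.m)
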