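# Methods

## The model

`pprls` simulates a sexually reproducing, age-structured population of
agents in discrete time to study how intergenerational investment
("care") reshapes age-specific purifying selection, and when that produces
a prolonged post-reproductive lifespan (PPRLS) in females.

Each agent has a sex, a life stage `i` (0–101, incremented every step) and
a diploid genome of two 384-locus chromosomes.  A chromosome carries a
male-expressed and a female-expressed block of 192 loci: 99 survival loci
(stages 2–100) and 93 reproduction loci (stages 8–100).  The expressed
rate is the arithmetic mean of the two homologous locus values; the
opposite-sex block is carried silently.  Stages 0–1 are unweaned dependent
infancy with a fixed survival rate of 0.9 that is deliberately *not*
genetically encoded — it is the opening for care — and stage 101 is
obligate death.

Locus values live on discrete ladders: reproduction on 0.0, 0.1, …, 1.0;
survival on 0, 0.20, 0.40, 0.60, 0.80, 0.82, …, 0.88, 0.90, 0.91, …, 0.98,
0.99, 0.999 (20 rungs, coarse at the bottom and fine near 1, so an
unselected survival locus decays quickly — a roughly convex fitness
ladder).  Values are stored as ladder *indices* so that single-rung
mutation moves are exact.

A newborn receives one uniformly chosen chromosome from each parent; the
inherited pair then undergoes crossover (each of the 383 junctions is a
break-point independently with probability 0.10) followed by per-locus
mutation at rate 0.025.  A mutating locus steps down one rung with
probability 1/2 and up with probability η/2 (default η = 0.5); the
remaining mass is no change.  Moves past a ladder end are clamped to the
end rather than redrawn, which keeps the per-locus move probabilities
well-defined without redistributing mass.  This deleterious bias is what
drives unselected rates toward zero and makes the model suitable for
studying the age-wise decay of purifying selection — no a-priori
survival/fertility trade-off function is imposed.

## One step

1. **Famine.**  1000 resource units replenish each step (no carry-over)
   and each agent consumes one.  Famine holds when the head count at the
   start of the step exceeds capacity; the consecutive-famine counter
   `T_f` increments under famine (it is 1 on the first famine step) and
   resets to 0 otherwise.
2. **Kin snapshot.**  Mother/maternal-grandmother liveness is frozen at
   the start of the step, so care eligibility is simultaneous-update: a
   carer and an infant dying in the same step do not interact, and
   within-step outcomes are independent of agent processing order.
3. **Survival.**  Each applicable care channel divides the agent's death
   rate `d = 1 - s_i` by 10 (mother-care and grandmother-care for stages
   0–1, compounding; survival-enhancing long-term care, LTs, for stages
   ≥ 2); famine then multiplies the cared death rate by `3^T_f`, and the
   survival probability is `max(0, 1 - 3^T_f · d_cared)`.  The source
   model defines famine on the intrinsic death rate and care on "the"
   death rate without fixing the joint order; we default to care-first
   because it keeps care meaningful during famine, and expose
   `famine_on="intrinsic"` as a sensitivity switch (the two differ only
   through the clamp at zero).
4. **Reproduction** (skipped entirely under famine).  Each *surviving*
   female at stage ≥ 8 gives birth to at most one child with her expressed
   rate, doubled (clamped at 1) by reproduction-enhancing long-term care
   (LTr) when her mother is alive.  The father is drawn, with replacement,
   among surviving males at stage ≥ 8 with probability proportional to the
   male's care-modified reproduction rate; if no male has positive weight
   the birth silently fails.  Using the care-modified male rate is what
   makes LTr matter for sons (through mating success) and gives the
   female-only LTr sensitivity variant something to remove.
5. **Ageing.**  Pre-existing survivors advance one stage; newborns enter
   at stage 0, are first counted in the next step's census, and can
   neither die nor receive care in their birth step.  Stages 0 and 1 are
   therefore two full steps of dependent infancy.

Runs start from 1000 founders with uniform genomes (s_i = 0.97;
r_i = 0.4 for stages 8–16, 0.1 afterwards), random sex and stages uniform
on 0–50.  Founders have no maternal links, so their offspring can receive
mother-care but not grandmother-care; this transient is absorbed by the
relaxation period.  Extinction terminates a run and is reported, not
raised.

## Demography

Life tables are estimated *period-style* over a sampling window of steps:
every living female contributes one exposure per step at her current
stage; `q_i` = survivals/exposures, `l_0 = 1`, `l_{i+1} = l_i q_i`, and
`m_i` = births/exposures.  Famine deaths are real deaths and famine steps
count in the fecundity denominator (famine zeroes the realised birth
rate).  A cohort estimator inside a finite window would right-truncate
late-born cohorts; the period estimator avoids that.  Stages with zero
exposure are flagged and set to `q = m = 0`, never interpolated.

All downstream sums truncate at stage 101 with `l_102 = 0`:

- remaining lifespan `e_i = Σ_k (k-i)(l_k - l_{k+1}) / Σ_k (l_k - l_{k+1})`,
  undefined (NaN) where `l_i = 0`;
- `B` and `E` are the smallest stages whose cumulative fecundity reaches
  5% and 95% of the lifetime total `m_tot = Σ m_i`;
- post-reproduction time `PrT = e_E` and post-reproduction representation
  `PrR = l_E e_E / (l_B e_B)`, with PPRLS called at `PrR > 0.20`;
- care-efficacy curves `c_i` (the expected number of care-receivers of a
  stage-i female) for each strategy, e.g.
  `c^M_i = m_{i-2} l_1 + m_{i-1} l_0` for mother-care and the cumulative
  sums for LTr/LTs/GM, with the grandmother curve halved because only
  daughters' infants qualify.

The `B`/`E` thresholds use `cum ≥ frac · total − 1e-12 · total` so that
exact 5%/95% boundaries are not lost to floating-point rounding.

## Protocol and reported statistics

The reference protocol is 5 replicates × 200,000 steps per condition,
with the life table sampled every 20,000 steps from step 100,000, each
over the trailing 10,000-step window `[t - 10,000, t)`.  Windows are
pooled across replicates into the condition's PrR distribution; extinct
replicates contribute no samples and are counted.  "Mean PrR unambiguously
beyond 0.20" is informal, so it is operationalised both ways and both are
reported: strictly (mean − 1 sd > 0.20) and by majority (mean > 0.20 with
≥ 75% of samples above).  Replicate seeds are spawned from one master seed
(`numpy.random.SeedSequence`), so results are reproducible and independent
of whether replicates run sequentially or in parallel.

Cross-condition scaling pools one `(l_2, m_tot, E)` point per window: the
scaling constant is the mean `m_tot · l_2` over samples from conditions
without mother-care, and the fertility–longevity association is the
Spearman rank correlation between `m_tot` and `E` over all samples.

## Numerical and design notes

- Chromosome state is `uint8` ladder indices; the engine is vectorised
  over agents (structure-of-arrays), and kin lookups go through an
  id-indexed liveness bitmap, so a 100,000-step run with a ~1000-agent
  census takes a few minutes on one core.
- The first famine step magnifies death by `3^1`: famine "has lasted" one
  stage during the step in which it holds, and the source description has
  survival compromised as soon as famine occurs.
- Paternal kinship is not tracked: no care channel flows through fathers.
- A male can father several newborns in one step (sampling with
  replacement); a female bears at most one child per step.
- Famine is evaluated on the head count at step start; surplus resource
  never carries over.

## What the tests do and do not show

Unit and property tests pin the operator statistics (mutation direction
frequencies, crossover break-point counts and allele conservation), exact
census bookkeeping, the worked care/famine survival arithmetic, and the
demographic formulas against independent brute-force oracles on toy life
tables.  Reduced-scale simulations (hundreds to tens of thousands of
steps) verify bookkeeping, determinism and qualitative behaviour
(extinction under strongly deleterious mutation at η = 0.1; care channels
raising realised survival).  The full 12-condition × 5-replicate ×
200,000-step experiment takes hours on one core and is run via
`pprls matrix`, not in the test suite; reduced-scale runs exercise the
same code paths but their absolute PrR values are still relaxing and are
not compared against full-scale results.

The simulator is the study system itself, not a fit to data: agents,
resources and care interactions are stylised (population ≈ 1000, one
resource unit per agent, 10-fold care factors), so conclusions transfer
qualitatively — strategy orderings and the presence/absence of PPRLS —
rather than as calibrated demographic rates for any real species.

## Known limitations

- Equilibrium statistics are stochastic outcomes of long runs; windowed
  estimates at reduced scale drift until the relaxation (~60,000–100,000
  steps) completes.
- The census oscillates around capacity with famine on roughly half of
  the steps; consecutive famine rarely exceeds two steps in the NULL
  condition, so realised infant survivorship is sensitive to the famine
  bookkeeping conventions listed above.
- No pair bonds, paternal care, spatial structure, or density dependence
  beyond the famine rule; no evolvable menopause locus.
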