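# Methods

## Overview

`fluxshift` implements a three-stage constraint-based analysis for
nominating reaction knockouts that shift a metabolic system from a
*source* condition (e.g. diseased tissue) toward a *target* condition
(e.g. healthy tissue), using only a stoichiometric model and
gene-expression data for the two conditions:

1. **Expression integration (iMAT).**  Expression is rank-discretized
   per sample, consensus-labelled across samples, propagated to
   reactions through GPR rules, and integrated into the model by a MILP
   that finds a steady-state flux distribution maximizing the number of
   expression-consistent reactions.
2. **Flux-space characterization (ACHR).**  The expression-consistent
   flux polytope is sampled with artificially-centered hit-and-run; the
   per-reaction mean over the samples is the condition's *metabolic
   state*.
3. **Transformation screen (MTA).**  Every candidate reaction knockout
   is scored by its predicted ability to move the source metabolic
   state toward the target, where "toward" is defined by
   differential-expression-derived reaction sets.  Candidates are
   ranked by the transformation score and selected by a dual criterion;
   selections can be validated by hypergeometric enrichment against a
   reference gene list.

All linear and mixed-integer programs are solved with HiGHS through
`scipy.optimize.linprog` / `scipy.optimize.milp`, which is deterministic
for a fixed problem — the package's reproducibility contract (identical
config + seeds ⇒ identical outputs) rests on this and on seeded PCG64
generators for all sampling.

## Constraint-based model

A network of m metabolites and n reactions is held as the
stoichiometric matrix S (m × n), bounds `v_min ≤ v ≤ v_max` (arbitrary
flux units; conventionally ±1000 for unconstrained internal reactions),
GPR rules, and exchange flags.  Steady state means S·v = 0: each
metabolite produced exactly as fast as it is consumed.  Feasibility is
always checked at `tol_steady = 1e-6` (mass-balance residual, ∞-norm)
and `tol_bound = 1e-9`.

**Dead-end filter.**  A metabolite touched by fewer than two remaining
reactions can never be balanced at nonzero flux; all reactions touching
it are removed and the pruning repeats to a fixed point.  The result is
iteration-order independent.  The filter is purely topological — it
needs no solver, and anything it removes is provably flux-blocked.  It
is weaker than an FVA-based blocked-reaction test (loops and
directionality-blocked reactions survive), which we consider acceptable
for a candidate filter since a blocked candidate simply scores at the
null.  **Candidates** for the knockout screen are the non-dead-end,
GPR-mapped, non-exchange reactions.

## Expression integration

* **Discretization** is per sample and purely rank-based: exactly
  ⌊0.25·n_genes⌋ top-ranked genes get +1 (highly expressed) and
  ⌊0.25·n_genes⌋ bottom-ranked genes −1, the rest 0.  Ranks are stable
  with ties broken by input order, which guarantees the exact-count
  property and makes the labels invariant under any strictly monotone
  transform (so log-scale vs linear-scale input is irrelevant).
* **Consensus**: a gene is +1/−1 in the final input iff at least
  ⌈(2/3)·n_samples⌉ samples label it so ("in two-thirds of samples"
  read as *at least* two-thirds, over all samples of the condition).
  Above 1/2 the two labels are mutually exclusive.
* **GPR propagation**: AND → min, OR → max over the ordering
  −1 < 0 < +1; genes without data count 0.  This is the standard
  conservative lifting: an enzyme complex (AND) is only as available as
  its scarcest subunit; isozymes (OR) are as available as the best one.
* Duplicate gene rows are collapsed by per-sample mean (symmetric and
  scale-preserving).

## iMAT

With RH (reaction state +1) and RL (−1), the MILP is

    max  Σ_{i∈RH} (y⁺ᵢ + y⁻ᵢ) + Σ_{i∈RL} zᵢ
    s.t. S·v = 0,  v_min ≤ v ≤ v_max
         vᵢ ≥ v_min,i + y⁺ᵢ (ε_active − v_min,i)     i ∈ RH
         vᵢ ≤ v_max,i + y⁻ᵢ (−ε_active − v_max,i)    i ∈ RH, reversible
         y⁺ᵢ + y⁻ᵢ ≤ 1
         v_min,i(1−zᵢ) − ε_zero zᵢ ≤ vᵢ ≤ v_max,i(1−zᵢ) + ε_zero zᵢ,  i ∈ RL

i.e. the implication constraints use each reaction's own bounds as
big-M coefficients — the tightest linear relaxation the bounds allow.
Defaults: `epsilon_active = 1.0` (minimum |flux| to count as active,
chosen against the conventional ±1000 bounds), `epsilon_zero = 1e-4`,
time limit 300 s per instance.  RL satisfaction is a soft objective
term, never a hard constraint, so contradictory expression degrades the
objective instead of causing infeasibility.  If the base LP itself is
infeasible, an elastic relaxation names a metabolite whose mass balance
cannot be satisfied.

**Frozen flux space.**  The binaries of the single returned optimum are
frozen into hard constraints (activated ⇒ |v| ≥ ε_active as a tightened
bound; silenced ⇒ |v| ≤ ε_zero), yielding a convex polytope that
contains the optimum.  Alternate MILP optima are *not* enumerated; the
output metadata flags that sampling covers one frozen optimum.

## ACHR sampling

Warmup: `max(2n, 100)` LP solutions of ±unit-coordinate objectives.
Each chain step picks a uniformly random stored point, takes the
direction from the running center (updated incrementally,
`center ← (t·center + x)/(t+1)` — the "artificially centered" feature)
to that point, projects it onto null(S) (orthonormal basis computed
once per polytope, so samples stay on the steady-state subspace to
machine precision), intersects the line with the bound/inequality
constraints, and jumps to a uniform point of the chord.  Every 10th
point is emitted (thinning) until 2000 samples exist (both defaults are
config keys; 2000 matches the sampling depth the screen is designed
for).  Degenerate directions or empty chords are resampled; 100
consecutive failures abort.  The PRNG is a seeded
`numpy.random.default_rng` (PCG64), recorded in the metadata; there is
no global random state.

Standard-error checks in the tests use an effective sample size from
the initial-positive-sequence autocorrelation estimator; no multi-chain
diagnostics are attempted.

## MTA screen

**Change sets.**  Per mapped gene, a two-sided Mann–Whitney rank-sum
test compares source vs target samples (distribution-free; robust to
microarray/RNA-seq scale differences).  Genes with p < 0.05 are
*changed* with direction `sign(median(target) − median(source))`; the
rest are *constant*.  Reactions inherit verdicts through their GPR
genes: any significantly-up gene and none down ⇒ R_F (flux should
increase), the mirror ⇒ R_B, all rule genes constant-with-data ⇒ R_S
(steady), mixed directions ⇒ excluded and reported, partial data ⇒
unconstrained.

**Response model.**  Knocking out candidate r fixes v_r = 0 and asks
how the network redistributes flux.  The package models the response as
*minimal weighted rearrangement anchored at the source state*:

    max  b_bonus·Σ_{i∈R_F∪R_B} bᵢ − (1−α)·Σ_{i∈R_S} dᵢ − γ·Σ_{i∈R_F∪R_B} eᵢ
    s.t. S·v = 0, bounds, v_r = 0
         bᵢ = 1 ⇒ vᵢ ≥ v_s,i + εᵢ (R_F)   /   vᵢ ≤ v_s,i − εᵢ (R_B)
         dᵢ ≥ |vᵢ − v_s,i| (i ∈ R_S),   eᵢ ≥ |vᵢ − v_s,i| (i ∈ R_F∪R_B)

with εᵢ = 0.1·max(|v_s,i|, 1) (10% of the source flux, floored at 10%
of a unit flux), γ = 0.01 and b_bonus = 1e-6.  The weight ordering
(1−α) ≫ γ ≫ b_bonus expresses three things: disturbing reactions the
data call steady is expensive; moving reactions the data call changed
is cheap, so flux displaced by the knockout preferentially reroutes
along the desired directions; and the achievement binaries only break
ties toward the target — they can never *pay* for movement.  A direct
consequence is that the **null problem** (same optimization, no
knockout) has the source state itself as its optimum: an unperturbed
network has no driving force to rearrange, so the no-perturbation score
is essentially zero and a knockout scores exactly by the rearrangement
it forces.  (An earlier design with a large achievement reward α·Σb was
abandoned: it let the null "transform spontaneously", making the
no-perturbation score an upper bound that no knockout could beat.)
α (default 0.66) remains the steadiness dial: larger α tolerates more
steady-set disturbance.

**Transformation score.**  From the optimal v:

    ts = ( Σ_{achieved} |vᵢ − v_s,i| − Σ_{unachieved, i∈R_F∪R_B} |vᵢ − v_s,i| )
         / max( Σ_{i∈R_S} |vᵢ − v_s,i| , δ )

— realized movement of successfully shifted reactions, minus movement
of changed reactions that went nowhere or the wrong way, per unit of
collateral damage to the steady set.  δ (default 0.1 = one minimal
meaningful movement εᵢ of a unit-flux reaction) floors the denominator:
flooring at numerical zero instead would hand any exactly-steady
solution an unbounded score and let rounding noise decide ranks.  All
three components are reported per candidate so any monotone
recombination can be audited.  An infeasible knockout (the network
cannot carry any steady flux without the reaction) gets ts = −∞.

**Ranking and selection.**  Candidates are sorted by descending ts,
ties broken lexicographically by id; percentile = 100·rank/n.  The dual
criterion keeps candidates that (1) strictly beat the null score and
(2) fall in the top ⌊0.10·n⌋ of the ranking.  Gene-level knockout mode
is available: a gene set to absent knocks out every reaction whose GPR
then evaluates false (`GPR.evaluate_bool`).

**Enrichment.**  Selected reactions translate to genes via their GPRs;
the exact upper-tail hypergeometric probability P(X ≥ k) (inclusive of
the observed overlap) is computed against a reference list, with the
candidate genes — the only genes a prediction can come from — as the
default universe.

## Synthetic scenarios

The generator builds layered networks: one bounded uptake (10 flux
units — the capacity cap that makes flux rearrangement zero-sum), P
parallel pathways of length L (defaults P=4, L=5), a cross-link from
each pathway to its neighbour at (almost) every level (probability
0.9), and one secretion.  Every internal reaction carries a unique 1–2
gene GPR; exchanges carry none; by construction there are no dead ends.
Ground-truth states come from an LP maximizing a random positive reward
over internal reactions, which routes the uptake through a single
reward-maximal (generically unique) zig-zag path.  The *source*
("disease") state is the unperturbed route; the *target* ("healthy")
state is the re-solved route after forcing one admissible reaction to
zero — so the knockout reproduces the target state by construction,
mirroring a protective perturbation, and the screen runs source →
target.  A knockout is admissible if its reaction carries flux in the
source state and its removal changes at least one flux by ≥ 1 unit.

Expression is tiered by ground-truth activity: genes of flux-carrying
reactions at 6.0, genes of silent reactions at 2.0, plus 20% decoy
genes (absent from the model) at 4.0, with i.i.d. N(0, 0.3) noise per
sample (5 samples per condition).  The tier gap/noise ratio (2.0 / 0.3)
keeps cross-tier rank misclassification rare while leaving realistic
within-tier rank churn, so the 25% quantile tails cut *inside* tiers —
as they do in real data.  What the generator does **not** emulate:
count-based noise models, correlated genes, regulatory feedback,
realistic metabolism topology, or partially effective knockdowns.
Passing the recovery tests therefore shows the inference chain is sound
when its assumptions hold, not that it is robust to everything real
transcriptomes do.

The noiseless-recovery tests assert containment (every +1 gene is an
active-reaction gene, every −1 gene a silent one) rather than equality
of the tier partition: with exact-count tails the quantile boundary
falls inside a tier, so the marginal members of a tier legitimately
receive 0.

## Problem sizes and determinism

The test and acceptance workloads use toy networks of ~20–35 reactions,
two conditions × 5 samples, 2000 ACHR samples, 20 scenario seeds (1–20)
for the recovery property, and 50 random networks (≤20 reactions, ≤8
expression-flagged) for the iMAT-vs-enumeration check — sizes chosen so
every oracle remains exhaustively computable.  With fixed seeds the
entire pipeline is reproducible bit-for-bit in its ranking outputs.

## Known limitations

* No thermodynamic (loopless) constraints; iMAT can activate internal
  loops if the model admits them.
* Sampling covers one frozen iMAT optimum, not the union over alternate
  optima.
* The differential-expression rule (rank-sum, α = 0.05) is a default,
  not a claim about any particular published analysis; with the small
  sample sizes typical of tissue datasets the exact test is
  conservative.
* The transformation score depends on the fidelity of the sampled
  source state; reactions with no expression evidence keep wide bounds
  and their sampled mean flux is correspondingly diffuse.
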