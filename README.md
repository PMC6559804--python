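# fluxshift

Expression-constrained metabolic modeling and in-silico knockout
screening: given a stoichiometric metabolic model and gene-expression
data for a *source* (e.g. diseased) and a *target* (e.g. healthy)
condition, `fluxshift` predicts which reaction knockouts would shift
the source condition's metabolic state toward the target's.  It is
aimed at systems-biology analyses that nominate metabolic drug targets
from transcriptomes — the kind of screen that flags an enzyme whose
inhibition is predicted to revert a disease-associated flux state.

## What it computes

For a network with stoichiometric matrix **S**, flux vector **v** and
bounds, constraint-based modeling restricts predictions to the feasible
steady-state space

&nbsp;&nbsp;&nbsp;&nbsp;S·v = 0, &nbsp; v_min ≤ v ≤ v_max.

Three stages are chained:

1. **iMAT** — per-sample expression is rank-discretized (top 25% of
   genes → highly expressed, bottom 25% → lowly expressed), consensus
   labels require agreement in ≥ 2/3 of samples, and GPR rules
   (AND = min, OR = max) lift gene states to reaction states.  A MILP
   then finds a feasible flux distribution maximizing the number of
   reactions whose activity (|v| ≥ ε or |v| ≈ 0) matches their
   expression state.
2. **ACHR sampling** — the expression-consistent flux polytope (binaries
   frozen at the iMAT optimum) is explored with artificially-centered
   hit-and-run; the mean of 2000 sampled flux vectors is the
   condition's *metabolic state* v_s.
3. **MTA screen** — rank-sum differential expression between the
   conditions defines reactions whose flux should increase (R_F),
   decrease (R_B) or stay put (R_S).  Each candidate knockout (every
   GPR-mapped, non-dead-end reaction) is scored by the transformation
   score

   &nbsp;&nbsp;&nbsp;&nbsp;ts = (Σ_achieved |vᵢ−v_s,i| − Σ_unachieved |vᵢ−v_s,i|) / max(Σ_R_S |vᵢ−v_s,i|, δ),

   the flux movement it forces in the desired directions per unit of
   collateral movement of the steady set.  Selected candidates must
   beat the no-perturbation score **and** rank in the top decile;
   selections can be tested for enrichment against a reference gene
   list with an exact hypergeometric tail.

A synthetic-scenario generator builds toy networks with a known causal
knockout (the target state is *generated from* that knockout), so the
whole chain can be validated against ground truth without any external
data.  See `docs/methods.md` for the full model description and design
rationale.

## Worked example

```python
from fluxshift import make_scenario
from fluxshift.pipeline import screen_scenario

scenario = make_scenario(seed=1)      # toy network + two-condition expression
results = screen_scenario(scenario)   # iMAT -> ACHR -> MTA, disease -> healthy
print(results.summary())
print(results.to_frame().head(3))
print("true knockout:", scenario.true_knockout)
```

prints

```
MTA knockout screen
============================================
candidates screened:     30
R_F / R_B / R_S sizes:   6 / 7 / 17
null score (ts):         -1.35558e-12
best candidate:          C2_3 (ts = 261.886)
beat the null score:     17
top-decile size:         3
passing dual criterion:  3

               ts  rank  percentile  steady_deviation
candidate
C2_3      261.886     1       3.333             0.000
C1_3      219.266     2       6.667             0.121
C3_4       43.790     3      10.000             0.642

true knockout: C2_3
```

The screen ranked 30 candidate knockouts.  The causal knockout `C2_3`
— the perturbation that *generated* the target state — is recovered at
rank 1: forcing it to zero moves ~262 flux units' worth of
expression-changed reactions in the desired direction per unit of
disturbance to the steady set, while the no-perturbation (null) score
is ≈ 0 because an unperturbed network has no reason to rearrange.
Three candidates pass the dual criterion (beat the null **and** top
decile); they are the knockouts the screen would nominate.

The same run is available from the shell:

```sh
fluxshift simulate --out demo --seed 1            # scenario bundle + run.toml
fluxshift run demo/run.toml                       # full pipeline
column -t demo/results/ranking.tsv | head -4      # ranked candidates
```

`run` writes `ranking.tsv` (per-candidate ts, rank, percentile, score
components, criterion flags, with the null score in row `null`),
`selection.tsv`, `source_state.tsv` (the sampled mean metabolic state),
optional `enrichment.json`, and a `manifest.json` recording the
resolved configuration, per-stage wall time, solver statuses and
input/output checksums.  Subcommands `imat`, `sample`, `mta`, `select`,
`enrich` and `overlap` expose the individual stages; models are
accepted as native JSON (`--model-format json_tabular`) or SBML L3
FBC (`--model-format sbml`).

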