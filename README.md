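# mediaopt

Active-learning optimisation of fermentation media, with the metabolomics
analyses needed to interpret the result.

Microbial products with complex biosynthesis — lipopeptides such as
surfactin, assembled by non-ribosomal peptide synthetases — often resist
rational yield engineering, and exhaustive media screens are too
expensive when each condition costs a plate well and a mass-spectrometry
injection. `mediaopt` implements the data-efficient alternative: a closed
Design-Build-Test-Learn (DBTL) loop that learns the titre landscape over
a 2-D medium space (glucose % w/v × NH4Cl mM, against an M9 minimal
background) from a handful of replicated conditions per round and steers
the next batch toward the optimum. It is aimed at bioprocess and
synthetic-biology groups running microplate-scale optimisation with
flow-injection MS readouts — and, because such datasets are rarely
public, it ships a calibrated synthetic study generator so the whole
pipeline is testable end to end.

## The model

Relative titre y at composition **x** (scaled to the unit square) is
modelled as a heteroskedastic Gaussian process

> y_i = f(**x**_i) + ε_i,  f ~ GP(0, k),  ε_i ~ N(0, s_i²)

with k a Matérn-5/2 ARD kernel (per-axis lengthscales ℓ₁, ℓ₂, signal
variance σ_f²) plus a small white term, and s_i² the squared standard
error of condition i's replicate mean. Hyperparameters maximise the
prior-penalised log marginal likelihood (MAP-II, lognormal hyperpriors)
by seeded multi-start L-BFGS-B.

Each round proposes q = 7 new media by Monte-Carlo **q-noisy expected
improvement**: with joint posterior samples f̃ over observed and
candidate points,

> qNEI(X_cand) = E[ max(0, max_{x∈X_cand} f̃(x) − (max_{x∈X_obs} f̃(x) + ξ)) ],  ξ = 0.01,

optimised greedily over a Sobol candidate pool with pending-point
conditioning. Measurements flow through the standard flow-injection
chain — asymmetric-least-squares baseline, trapezoid peak integration,
median ± 1.5·IQR outlier removal per replicate group, and normalisation
by the per-batch M9-reference mean — so every value is a relative
abundance anchored at M9 = 1.0.

Post-loop, the package computes uncertainty maps (posterior sd on a
dense grid), the performance-cliff region (predicted titre < 0.5),
titre-vs-growth Pareto fronts, Spearman correlation structure with
hierarchical clustering, PCA, and directional "metabolic anisotropy"
profiles: the mean gradient of each signal along radial paths around the
titre optimum as a function of direction angle.

## Worked example

Run a full synthetic three-iteration loop (ground truth: maximum 2.6× M9
at 0.8 % glucose / 50 mM NH4Cl; 15 % replicate CV, 6 blocks):

```sh
$ mediaopt loop --seed 1 --iterations 3 --out state/
best improvement 189.2 % at 0.78 % glucose / 62.5 mM NH4Cl; cliff area fraction 0.11
```

The best *observed* condition improved titre by 189 % over M9 — the
true ceiling is 160 %, and replicate noise plus best-of-24 selection
bias accounts for the overshoot. The cliff fraction is the share of the
composition space predicted to yield less than half the M9 titre. The
saved state exposes the rest:

```python
>>> from mediaopt.dbtl_loop import LoopState
>>> state = LoopState.load("state/")
>>> [round(r.mean_sd, 3) for r in state.iterations]
[0.363, 0.351, 0.285]
>>> state.iterations[-1].grid.argmax_composition()
MediaComposition(glucose_pct=0.746, nh4cl_mM=47.55)
```

Mean grid uncertainty falls from 0.363 to 0.285 as the model learns, and
the predicted optimum lands within one lengthscale of the true
(0.8, 50). `mediaopt analyze --state state/ --out analysis/` then writes
the correlation matrix, clusters, PCA scores/loadings, Pareto front and
anisotropy profiles as CSV. The other subcommands (`design`, `simulate`,
`process`, `acquire`, `step`) expose the individual stages, with `step`
fitting the surrogate on an externally measured condition table and
emitting the next batch, so the tool can drive a real experiment.

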