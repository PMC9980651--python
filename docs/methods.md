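# Methods

## Model and estimation

A bulk methylation profile over M marker CpGs is treated as a convex-ish
mixture of N cell-type profiles, `B_j = Σ_k p_k C_{j,k}`, with `C` taken
from a reference panel of purified cell populations (the per-type mean over
replicate samples). Proportions are estimated by minimising
`Σ_j (B_j − Σ_k p_k C_{j,k})²` subject to `p ≥ 0`. The non-negative problem
is solved exactly with an active-set non-negative least-squares routine
(`scipy.optimize.nnls`); the optional `Σ p ≤ 1` variant first checks whether
the NNLS solution already satisfies the cap and otherwise solves the
quadratic program with SLSQP (analytic gradient, `ftol` 1e-14, started from
the normalised NNLS point). Proportions are never renormalised to sum to 1:
under noise or an incomplete panel the estimated sum falls below 1 and that
deficit is informative. Estimates are deterministic given the inputs.

When a bulk profile lacks some marker probes, the fit runs over the
intersection of model and bulk probes; a warning is raised below 80%
coverage (tunable), and the error score uses the intersection size as M. A
rank-deficient mean-profile matrix over the shared probes (e.g., duplicated
cell types) yields a warning and a flaggedly non-unique solution rather than
an error. Beta values outside [0, 1] in a bulk vector are accepted as-is
(simulated profiles under the additive noise option can exceed 1).

The per-sample error score is `CETYGO = sqrt(Σ_j (B_j − B̂_j)² / M)` with
`B̂` the profile implied by the estimated proportions. It is 0 exactly for a
perfect fit and is reported at full float precision.

## Marker selection

Candidate probes must have complete data across the training panel (any
missing beta excludes the probe before testing). A one-way fixed-effects
ANOVA across cell-type groups — computed vectorised on beta values, no
M-value transform — gates probes at p < 1e-8. For each cell type the gated
probes are ranked by the one-vs-rest mean difference (type mean minus the
mean over all other samples); the top 50 positive (hypermethylated) and top
50 negative (hypomethylated) are selected, i.e., 100 sites per type by
default. Ties break on smaller p-value, then lexicographic probe ID, making
selection byte-deterministic. The same probe may serve several cell types;
the model deduplicates probes when assembling its M × N matrix while the
marker table keeps every entry. If a direction's pool is smaller than the
quota the achieved count is recorded and a warning emitted — a short panel
is a degraded model, not a crash. Cell types are ordered by sorted label
everywhere so results do not depend on sample order.

The ranking criterion (ANOVA gate + one-vs-rest mean difference) follows the
convention of the widely used reference-based pipelines for methylation
arrays; ranking by ANOVA F alone would not assign a direction per cell type.

## Autosomal filtering

Models are intended to be trained on autosomal probes only, so donor sex
cannot leak into the reference profiles; `filter_autosomal` drops probes
annotated to X, Y or the mitochondrial genome (with or without the `chr`
prefix) and refuses to guess when annotation is missing.

## Reconstructed bulks and the noise model

Validation bulks are weighted sums of held-out per-cell-type test profiles
at a known composition. Noise is injected as a proportion `rho ∈ [0, 0.5]`
of the signal replaced by i.i.d. Uniform(0, 1) draws:

```
B_j = (1 − rho) · Σ_k p_k C_{j,k} + rho · ε_j        (default, "mixture")
B_j =            Σ_k p_k C_{j,k} + rho · ε_j        (option, "additive")
```

The mixture form is the default because it treats `rho` literally as the
fraction of noise in the sample and reproduces the empirically expected
behaviour that estimated proportion sums *decrease* with noise. The additive
form is kept as an option; note that adding mean-0.5 noise on top of an
intact signal provably biases the estimated proportion sum upward (by
`rho · 0.5 · 1ᵀ(CᵀC)⁻¹Cᵀ1`, which is positive for any realistic non-negative
reference matrix), so sums *increase* with noise under that form. With
`rho = 0` both forms coincide and no random numbers are drawn.

Compositions are enumerated in integer grid units (tenths by default) so
sums are exact; the standard grids are the 31-level noise grid (0–0.1 by
0.01, 0.12–0.5 by 0.02), the 41 panel subsets of size 3–5 from 6 types, the
126 compositions of six types in tenths with each type in [0.1, 0.5], and
the 9 omitted proportions 0.1–0.9 in the leave-one-out design. Each
experiment derives per-condition seeds from its top-level seed via
`numpy.random.SeedSequence`, so reports are byte-reproducible and conditions
are independently seeded; the uniform noise is redrawn per condition.

The default base composition is a granulocyte-dominant whole-blood-like
vector (Gran 0.58, CD4T 0.16, CD8T 0.09, Mono 0.08, B 0.06, NK 0.03) — a
plausible stand-in for mean leukocyte proportions, supplied as a default and
overridable; none of the framework's properties depend on its exact values.

## Synthetic reference panels

The generator emulates a flow-sorted reference panel. Each cell type owns a
disjoint block of hypermethylated and hypomethylated marker probes placed at
`(1 ± effect_size)/2` for the target type and the opposite level for all
others; background probes share a per-probe mean drawn Uniform(0.1, 0.9)
across all types. Replicates add Gaussian noise (sd `within_type_sd`)
clipped to [0, 1] — with sd 0.02 the clipping is negligible. Probe-to-role
assignment is permuted under the design seed, so two designs differing only
in seed plant markers at different probes: a panel from another seed acts as
a "wrong tissue" surrogate sharing the probe universe. A configurable
fraction of probes is annotated to chrX/chrY; these are carved out of the
background block so that autosomal filtering never destroys planted marker
structure. Test individuals are fresh draws from the same per-type
distributions under an independent seed stream, mirroring a
leave-one-individual-out design (a same-profiles mode is available simply by
passing the panel's own means where exactness is wanted).

Defaults — 6 cell types × 6 replicates, 150 hyper + 150 hypo planted
markers per type, 2000 background probes, effect size 0.8, sd 0.02 — mirror
a well-powered sorted-blood panel in which the 100-sites-per-type quota is
comfortably met. What the generator deliberately does not model: genome-wide
autocorrelation, probe-chemistry differences, bimodal background betas,
correlated cell lineages (e.g., the similarity of T-cell subsets), or batch
effects. Passing tests therefore demonstrate the correctness and the
qualitative behaviour of the machinery, not expected error magnitudes on
real arrays; in particular the empirical "blood < 0.1" score threshold is a
property of real data and is not asserted here.

## Numerical choices

* ANOVA sums of squares below 1e-20 are treated as zero (degenerate probes
  get p = 1, or p = 0 when between-group variance survives).
* The `Σ p ≤ 1` constraint is enforced to 1e-8 slack; NNLS is exact at
  machine precision.
* Model serialisation writes floats with `%.17g` and reads them with
  round-trip parsing, so save/load is lossless; result tables likewise.
* Composition sums are validated to 1e-9 (grid-built compositions are exact
  in integer units).
* Simulation experiment sizes used in the shipped tests — 10 replicate
  individuals for the noise/leave-one-out/subset suites, panels of 1000–3800
  probes — were chosen as the smallest sizes at which the mean curves are
  stable.

## Known limitations

* Reference-free and partially reference-free deconvolution are out of
  scope, as are raw-array (idat) processing and normalisation; inputs are
  beta matrices.
* The score is relative to the chosen reference panel: a wrong but
  internally consistent panel can fit well. The wrong-panel tests show
  separation in medians, not a universal threshold.
* With highly collinear reference profiles the projection is ill-conditioned;
  the package warns on rank deficiency but does not regularise.
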