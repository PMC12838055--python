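# Methods

`semlink` implements an anchor-based semantic measurement pipeline for
open-response descriptor terms, together with the psychometric evaluation
battery used to judge whether the resulting scores behave like trait
measures: reliability, network stability, person-level convergence with a
questionnaire instrument, and configuration-level alignment of the two
instruments' facet spaces. Because real cohorts of this kind are typically
proprietary, the package ships a first-class synthetic-cohort generator
with known ground truth, and every stage of the battery is validated
against it.

## Scoring model

Each facet f is defined by an anchor set A_f of short phrases. With a fixed
embedding e(·) mapping text to a shared vector space, a term t scores on
facet f as the mean cosine similarity to the facet's anchors:

    s_{t,f} = (1/|A_f|) Σ_{a∈A_f} cos(e_t, e_a),   s_{t,f} ∈ [−1, 1].

After QC, person i's raw composite is x_{if} = mean_{t∈T_i} s_{t,f} over
their retained terms, and z_{if} standardizes each facet column across
persons with the sample (n−1) standard deviation. Zero-variance columns are
flagged and zeroed rather than dropped so matrix shapes stay stable.

QC normalizes terms (lowercase, NFC, trim, collapse internal whitespace),
retains the first occurrence of each normalized term within a person, flags
later occurrences as duplicates, and flags stop-list matches
({"nan", "n/a", "", "lorem", "click here"} by default) as noise. Personal
and professional term categories are pooled for scoring (the composite
definition does not separate them); the category field is preserved.

Design choices made where the procedure was genuinely open: anchors are
pooled by the plain mean of cosines (not max or softmax pooling, which
would change the composite's meaning from "overall proximity to the facet's
language" to "proximity to the nearest anchor"); standardization uses the
n−1 sample standard deviation; persons with no retained terms are excluded
with a warning and listed in the composite matrix's exclusion set.

## Embedding backends

The embedding is a deterministic contract (same text ⇒ same finite vector),
not a model estimated from the sample. Three backends satisfy it:

- **geometric** — the synthetic space described below, reconstructed
  bit-for-bit from generator parameters;
- **hash** — a seeded-hash unit vector per string; structure-free fallback
  that keeps arbitrary text embeddable;
- **sentence-transformers** — optional plug-in for a real pretrained
  encoder; never required by tests or the battery.

## Synthetic cohort generator

The generator emulates the data-generating situation of an expressive
open-response assessment at the level that matters for the battery: the
term-emission layer, not drawings or motor behavior.

Geometry. Each of D domains (default 5) gets a random unit direction; facet
centroids are unit-normalized mixtures `w·u_domain + (1−w)·v_facet` with
w = `domain_cohesion` (default 0.8). Anchor phrases, a parallel set of
comparison-instrument descriptors, and the facet vocabulary are
unit-normalized `centroid + κ·noise` with κ = `anchor_concentration`
(default 0.25). At w ≥ 0.7 the five-block facet structure is recoverable by
community detection downstream; at w = 1 and κ → 0 all facets of a domain
collapse onto the domain direction.

Persons. Latent domain scores θ are standard normal; latent facet
F_f = a·θ_{d(f)} + √(1−a²)·ε with a = `facet_loading_a` (default 0.7). A
person emits `terms_per_person` (default 20, alternating personal /
professional tags) terms: with probability `noise_rate` a stop-list-like
token, with probability `dup_rate` a repeat of a uniformly chosen prior
term, otherwise a fresh draw — a facet sampled with probability
∝ exp(F/temperature), then an unused vocabulary word of that facet. Fresh
draws avoid vocabulary the person already used, so realized duplicates
track the dial; dup_rate = 0.13 with 20 slots yields ≈12.3% realized
duplicates and ≈87.7% retention, the regime the generator is meant to
emulate. With both rates zero a person never repeats a term.

Questionnaire scores. Observed facet j is
`c·F_j + √(1−c²)·(a_b·η_{d(j)} + √(1−a_b²)·ν)`, rescaled to a T-score
metric (mean 50, sd 10). c = `b5_convergence_c` is the convergence dial:
corr(observed facet, latent facet) = c by construction, and the matched-
domain correlation between the two instruments rises monotonically in c.
a_b = `b5_structure_loading` (default 0.7) gives the instrument's unique
part its own within-domain structure; without it the questionnaire network
would be nearly empty at moderate c, which no real facet battery shows.

Ratings. `simulate_ratings` draws rating = clamp(round(true + rater bias +
error), 1, 5) and returns the latent true scores, so ICC recovery can be
checked against the analytic σ²_t/(σ²_t+σ²_b+σ²_e). Note that rounding to
the 1–5 integer grid adds roughly 1/12 of error variance and clamping
truncates the tails, so recovered ICCs sit ≈0.05 below the continuous-scale
analytic value at true_sd = 1 — an attenuation inherent to the ordinal
scale, not an estimator bias (the estimator is unbiased on the continuous
ratings).

What the generator does **not** emulate: zero-inflated or floor-affected
composite distributions, non-English tokens, rater drift over time, and any
image/drawing layer. Passing tests therefore show that the battery's
machinery is correct and calibrated under a clean five-domain world, not
that real expressive data will reach the same stability figures. One
consequence worth knowing: because every term scores on every facet and
within-domain anchor sets are geometrically close at the default cohesion,
within-domain facet composites are strongly collinear, and domain-level ω
saturates near 1 on synthetic cohorts — higher than the 0.71–0.94 range
typical of real semantic composites.

## Reliability battery

ω_total comes from a minimum-residual (ULS) one-factor solution of the
indicator Pearson correlation matrix: ω = (Σλ)² / ((Σλ)² + Σψ). The
hierarchical variant uses a Schmid–Leiman orthogonalization: minres
extraction of the group factors, varimax-then-promax oblique rotation, a
single higher-order factor fitted to the factor correlation matrix
(symmetric √φ convention when there are exactly two group factors), and the
standard distribution of loadings into a general part g = Λγ and
orthogonalized group parts Λ·diag(√(1−γ²)). Then
ω_t = [(Σg)² + Σ_s(Σλ_s)²] / [... + Σψ] and ω_h replaces the numerator with
(Σg)² alone. Degenerate cases are handled explicitly: with fewer than two
viable group factors (a factor with no appreciable loadings), all common
variance is assigned to the general factor, so a one-factor world gives
ω_h ≈ ω_t; requesting fewer than two groups is refused. For exchangeable
indicators ω equals standardized alpha to numerical precision — used as a
closed-form cross-check.

Rotation note: promax (power 4) over a varimax start was chosen rather than
direct oblimin; it is the classic oblique rotation, needs no gradient-
projection machinery, and on the block-structured matrices this battery
meets it lands in the same oblique solutions.

Percentile bootstrap CIs resample persons with replacement; each resample's
RNG seed is derived from (master seed, counter), so results are independent
of execution order and parallelizable. Failing resamples are dropped and
counted; more than 10% failures is an error. Corrected indicator–total
correlations r_it and leave-one-out Δω complete the indicator diagnostics.

ICC for absolute agreement uses the two-way random-effects mean squares:
ICC(A,1) = (MS_t − MS_e)/(MS_t + (k−1)MS_e + (k/n)(MS_r − MS_e)), with
ICC(A,k) for rater averages; both are reported because the single/average
choice is often left unstated in applied reports. The implementation is the
ANOVA formula itself; `pingouin` serves as an independent oracle in tests.

## Network battery

Networks are estimated on Spearman rank correlations (rank-then-Pearson
with average-rank ties; rank-based to blunt zero inflation), repaired to
positive definite by iterated eigenvalue clipping (floor 1e-6) with unit
diagonal, then fed to a graphical lasso over a log-spaced λ path from
λ_max (the largest absolute correlation — the smallest λ with an empty
graph) down to 0.01·λ_max. EBIC(λ) = −2·loglik + E·log n + 4·E·γ·log p
selects the model, with γ = 0.5 (the standard EBIC-glasso convention). An
opt-in patience parameter can stop the scan early when EBIC stagnates, but
it is off by default: the profile can wiggle near the sparse end as single
edges enter and leave, and a premature stop there selects an empty graph.
Edge weights are standardized negative precision entries (regularized
partial correlations). The per-λ solver is scikit-learn's graphical lasso;
path construction, EBIC selection and the partial-correlation
standardization are this package's.

Centralities: strength = Σ|w|; betweenness and closeness on edge lengths
1/|w| (stronger tie = shorter path), with harmonic closeness so
disconnected pairs contribute zero. Louvain runs on |w| with seeded
best-of-20 restarts by modularity. Global metrics are the sum of absolute
upper-triangle weights and the proportion of realized edges.

Stability follows the case-dropping/bootstrap framework: CS(index) is the
largest drop proportion (grid 0.05…0.75, scanned upward, stopping at the
first failing level) at which subsample centralities correlate ≥ 0.7 with
the full-sample centralities in ≥ 95% of resamples; the grid is truncated
when the retained sample would fall below max(3p, 10). The edge bootstrap
resamples persons, reporting mean retention of full-sample edges, the
median correlation of bootstrap vs full-sample weights, and per-edge
percentile CIs. Structure-recovery frequency counts bootstraps whose
Louvain partition matches the reference in community count with adjusted
Rand ≥ 0.8. All resample seeds derive from (master seed, counter). Bootstrap
re-fits may use a looser solver tolerance (the orchestrated pipeline uses
1e-3 vs 1e-4 for full-sample fits) — a runtime/precision trade documented
here because near-threshold CS values can shift by one grid step under very
loose tolerances.

## Convergence and alignment

Person-level convergence correlates domain composites (unweighted means of
each domain's six facet z-columns) across instruments on the index
intersection, pairwise-complete per cell, with Pearson and Spearman
variants, matched-domain diagonal summaries, and a 30×30 facet-level scan
that reports the argmax |r| among cells with pairwise n ≥ 10.

Configuration alignment treats each facet as a point (the mean of its
anchor embeddings; a score-based facet-correlation configuration is the
fallback when only one lexicon exists) and asks whether the two instruments
share facet-space geometry:

- **RV** — tr(S_x S_y)/√(tr S_x² · tr S_y²) on column-centered
  configurations; rotation- and scale-invariant.
- **Procrustes similarity** — 1 − m² after optimal translation, isotropic
  scaling and rotation/reflection (narrower configurations are padded with
  zero columns).
- **Distance correlation** — from doubly-centered Euclidean distance
  matrices; sensitive to nonlinear dependence.
- **Mantel** — Pearson r of strict upper triangles of cosine-distance
  matrices; one-sided permutation p with the +1 correction under
  simultaneous row/column relabeling (entries are permuted, never
  resampled), default 5000 permutations.
- **CCA r1** — first canonical correlation after PCA reduction of each
  side; whenever the retained ranks make r1 = 1 a linear-algebra certainty
  (p_x + p_y ≥ n) the value is still returned but a machine-readable
  degeneracy flag is attached, because silently suppressing the number
  would hide behavior real analyses report descriptively.

## Pipeline and problem sizes

`run_full_analysis` chains QC → scoring → per-domain reliability → networks
for both instruments → stability → communities → convergence → alignment,
writes wide/long CSVs, a deterministic JSON report (sorted keys, no
timestamps; reruns are byte-identical) and a text summary, and marks the
report partial with the failing stage named if any stage errors. All seeds
are explicit in the config; a config hash is recorded in the provenance
block.

Default problem sizes are desk-scale by design: cohorts of 150–200 persons,
1000 omega bootstrap resamples, and 45/50/25 resamples for the CS, edge and
recovery bootstraps in the orchestrated pipeline (the underlying functions
default to the field-standard 1000 and accept any count). The analysis
scripts use 250 bootstrap replications for the stability battery. These
sizes keep a full run in minutes on one core while leaving every
statistical contract testable; the acceptance script reports the exact
sizes it used alongside each number.

## Known limitations

- ω_h depends on the rotation and the two-group √φ convention; values for
  k = 6 indicator sets should be read as descriptive hierarchy evidence,
  not estimates of a well-identified bifactor model.
- CS coefficients are grid-quantized (step 0.05) and use the cumulative
  scan convention; reported 0.75 means "stable at the grid maximum".
- The Mantel test permutes labels of the second matrix only, which is the
  standard convention; p-values are one-sided.
- Synthetic cohorts have no missing data except what QC removes; the
  pairwise-complete machinery is exercised by tests, not by the generator.
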