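# semlink

Anchor-based semantic scoring of open-response descriptor terms, with the
full psychometric evaluation battery needed to decide whether the scores
behave like trait measures.

## The problem

Expressive assessments ask people to produce short free-text descriptors
(e.g., terms attached to sketches) instead of answering Likert items. To
treat those responses as measurements, each term has to be projected onto a
predefined trait frame — here the Five-Factor hierarchy of 5 domains × 6
facets — and the resulting scores have to earn the usual psychometric
credentials. `semlink` provides both halves for researchers in
computational personality assessment and psychometric methods:

1. **Scoring.** Every facet f carries an anchor lexicon A_f of
   facet-language phrases. With a fixed text embedding e(·), a term t
   scores s_{t,f} = (1/|A_f|) Σ_{a∈A_f} cos(e_t, e_a); person i's raw
   composite is x_{if} = mean_{t∈T_i} s_{t,f} over their QC-retained terms,
   standardized across persons to z_{if}. QC deduplicates within person and
   removes stop-list noise.
2. **Evaluation.** McDonald's ω and ω_h (Schmid–Leiman) with percentile
   bootstrap CIs and indicator diagnostics; Spearman + EBIC-glasso
   regularized partial-correlation networks with case-dropping CS
   coefficients, edge-weight bootstraps, Louvain communities and global
   connectivity; two-way random-effects ICC(A,1)/(A,k) for rater
   agreement; person-level convergence correlations against a
   questionnaire instrument; and configuration-level alignment of the two
   instruments' facet spaces (CCA r1 with degeneracy flags, RV,
   Procrustes, distance correlation, Mantel permutation test).

Because real cohorts of this kind are proprietary, the package includes a
synthetic-cohort generator with known ground truth (latent five-domain
structure, facet-clustered vocabularies in a geometric embedding space,
within-person duplicates, configurable questionnaire convergence, ordinal
rater matrices). All tests and the acceptance script run on it; a real
sentence-transformer embedding can be plugged in behind the same contract.

## Worked example

The numbered scripts under `analysis/` run the full study on a simulated
176-person cohort:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_score_terms.py
python analysis/03_reliability.py
python analysis/04_network_stability.py
python analysis/05_convergence_alignment.py
```

`02_score_terms.py` prints

```
QC: 3520 terms, retention 88.2% (414 duplicates, 0 noise), 17.65 +/- 1.48 per person
scored 176 persons on 30 facets; mean inter-vector coherence 0.248
```

— the sanitizer removed within-person repeats (the generator plants ~12%),
and each person's retained terms have a mean pairwise cosine of 0.248,
the semantic-coherence index. `03_reliability.py` then reports per-domain
ω ≈ 0.999 with ω_h ≈ 0.93: on synthetic cohorts the six facet composites
of a domain are strongly collinear (every term scores on every facet and
anchor sets within a domain are geometrically close), so composite-level
reliability saturates — see `docs/methods.md` for why real expressive data
sits lower. `04_network_stability.py` estimates both instruments'
partial-correlation networks and prints the stability table: edge
stability is high (mean retention 0.95/0.80, median bootstrap weight
correlation 0.998/0.906 for the semantic and questionnaire networks), both
Louvain partitions recover the planted five-domain structure exactly
(adjusted Rand 1.0, Q = 0.74/0.79), while centrality-ordering CS
coefficients are modest (strength 0.15/0.20) because near-collinear facets
have near-tied strengths at n = 176 — edge patterns and communities are
stable long before centrality *orderings* are. `05_convergence_alignment.py`
prints matched-domain convergence mean |r| = 0.408 (range 0.276–0.502 at
the default convergence dial c = 0.6, overlap n = 176) and the alignment
indices: RV = 0.998, Procrustes = 0.992, dcor = 0.999, Mantel r = 0.997
(p = 2e-4, 5000 permutations), and CCA r1 = 1.000 carrying an explicit
rank-degeneracy flag — with 30 facet rows and high-dimensional
configurations a perfect first canonical correlation is a linear-algebra
certainty, so it is reported descriptively only.

The same pipeline is available as a library call (`semlink.pipeline.
run_full_analysis`) and as a CLI (`semlink simulate|score|reliability|
network|align|run`), and is byte-for-byte reproducible from its config and
seeds.

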