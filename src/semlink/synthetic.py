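"""Synthetic cohorts with known ground-truth trait structure.

The generator emulates the data-generating situation of an expressive
open-response assessment: persons carry latent scores on a small number of
broad trait domains (default five), each domain splits into facets (default
six), and a person emits short descriptor terms whose choice is biased toward
the facets they score high on. Terms live in a geometric embedding space in
which each facet's vocabulary and anchor phrases cluster around a facet
centroid; centroids of facets in the same domain share a common direction, so
the planted five-block community structure is recoverable downstream. A
parallel questionnaire-style score matrix (Big Five facet composites on a
T-score metric) is generated with a configurable convergence to the same
latent facets, and ordinal 1-5 rater matrices are simulated for agreement
analyses.

Everything is fully determined by the config seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .scoring import (
    PERSONAL,
    PROFESSIONAL,
    AnchorLexicon,
    EmbeddingProvider,
    TermRecord,
)

#: Stop-list-like noise tokens the emitter may inject (cf. junk strings such
#: as "nan" or stray advertising text that survive raw-text extraction).
NOISE_TOKENS = ("nan", "n/a", "lorem", "click here")


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    domain_cohesion in [0,1] sets how tightly a domain's facet centroids
    cluster around the shared domain direction; anchor_concentration scales
    the noise of anchors/vocabulary around facet centroids (smaller =
    tighter); facet_loading_a is the latent domain->facet loading;
    b5_convergence_c is the latent facet -> observed questionnaire loading.
    """

    n_persons: int = 200
    n_domains: int = 5
    facets_per_domain: int = 6
    vocab_per_facet: int = 8
    anchors_per_facet: int = 4
    embed_dim: int = 64
    domain_cohesion: float = 0.8
    anchor_concentration: float = 0.25
    facet_loading_a: float = 0.7
    terms_per_person: int = 20
    emission_temperature: float = 1.0
    # fresh draws avoid already-used vocabulary, so realized within-person
    # duplicates track the dial; 0.13 nominal puts the realized share near
    # 12.6% (the first emitted term can never duplicate) and retention near
    # 87%, the regime the generator is meant to emulate
    dup_rate: float = 0.13
    noise_rate: float = 0.0
    b5_convergence_c: float = 0.6
    # the comparison questionnaire is internally structured even where it
    # does not converge with the latent facets: its unique part loads on a
    # domain-level nuisance factor with this weight, giving the instrument
    # realistic within-domain facet correlations at any convergence level
    b5_structure_loading: float = 0.7
    n_raters: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dup_rate", "noise_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("domain_cohesion", "facet_loading_a", "b5_convergence_c"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.emission_temperature <= 0 or self.anchor_concentration < 0:
            raise ValueError("temperature must be positive, concentration non-negative")
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")

    @property
    def n_facets(self) -> int:
        return self.n_domains * self.facets_per_domain

    def domain_names(self) -> List[str]:
        return [f"D{k + 1}" for k in range(self.n_domains)]

    def facet_names(self) -> List[str]:
        return [
            f"D{k + 1}.F{m + 1}"
            for k in range(self.n_domains)
            for m in range(self.facets_per_domain)
        ]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _hash_unit_vector(text: str, dim: int, seed: int) -> np.ndarray:
    digest = hashlib.blake2b(f"{seed}|{text}".encode(), digest_size=8).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "little"))
    return _unit(rng.standard_normal(dim))


class GeometricEmbedding(EmbeddingProvider):
    """Deterministic geometric stand-in for a sentence embedding model.

    Known vocabulary/anchor strings map to precomputed unit vectors placed
    as noisy copies of facet centroids; any other string maps to a
    seeded-hash unit vector, so arbitrary text remains embeddable.
    """

    def __init__(self, dim: int, table: Dict[str, np.ndarray], seed: int):
        self.dim = dim
        self._table = table
        self._seed = seed

    def embed(self, text: str) -> np.ndarray:
        if text == "":
            raise ValueError("cannot embed the empty string")
        v = self._table.get(text)
        if v is None:
            v = _hash_unit_vector(text, self.dim, self._seed)
        return v.copy()

    def centroid(self, facet: str) -> np.ndarray:
        return self._table[f"__centroid__{facet}"].copy()


@dataclass
class SyntheticCohort:
    config: SimConfig
    term_records: List[TermRecord]
    anchor_lexicon: AnchorLexicon
    b5_lexicon: AnchorLexicon
    embedding_space: GeometricEmbedding
    b5_scores: np.ndarray  # person x facet, T-score metric
    latent_domains: np.ndarray  # person x domain
    latent_facets: np.ndarray  # person x facet
    ground_truth_partition: Dict[str, str]  # facet -> domain
    pids: List[str] = field(default_factory=list)
    vocab: Dict[str, List[str]] = field(default_factory=dict)  # facet -> terms


def make_embedding_space(
    cfg: SimConfig,
) -> Tuple[GeometricEmbedding, AnchorLexicon, AnchorLexicon]:
    """Build the embedding table, anchor lexicons and facet vocabularies.

    Facet centroids are unit-normalized mixtures
    ``w * domain_direction + (1 - w) * facet_direction`` with
    ``w = domain_cohesion``; anchors and vocabulary terms are unit-normalized
    ``centroid + anchor_concentration * noise``. Two parallel anchor
    lexicons are generated around the same centroids (distinct phrase
    strings, independent noise): the primary one scores the open-response
    terms, the second plays the role of the comparison instrument's facet
    descriptors for configuration-alignment analyses.
    """
    rng = np.random.default_rng(cfg.seed)
    dim = cfg.embed_dim
    table: Dict[str, np.ndarray] = {}

    domain_dirs = {d: _unit(rng.standard_normal(dim)) for d in cfg.domain_names()}
    facets = cfg.facet_names()
    anchors: Dict[str, List[str]] = {}
    b5_anchors: Dict[str, List[str]] = {}
    domain_map: Dict[str, str] = {}

    def noisy(centroid: np.ndarray) -> np.ndarray:
        eps = rng.standard_normal(dim) / np.sqrt(dim)
        return _unit(centroid + cfg.anchor_concentration * eps)

    for f in facets:
        d = f.split(".")[0]
        domain_map[f] = d
        facet_dir = _unit(rng.standard_normal(dim))
        centroid = _unit(
            cfg.domain_cohesion * domain_dirs[d] + (1 - cfg.domain_cohesion) * facet_dir
        )
        table[f"__centroid__{f}"] = centroid
        a_list = []
        for a in range(cfg.anchors_per_facet):
            name = f"anchor {f.lower()} {a + 1}"
            table[name] = noisy(centroid)
            a_list.append(name)
        anchors[f] = a_list
        for t in range(cfg.vocab_per_facet):
            name = f"term {f.lower()} {t + 1}"
            table[name] = noisy(centroid)
        b_list = []
        for a in range(cfg.anchors_per_facet):
            name = f"b5 descriptor {f.lower()} {a + 1}"
            table[name] = noisy(centroid)
            b_list.append(name)
        b5_anchors[f] = b_list

    lexicon = AnchorLexicon(facets=facets, anchors=anchors, domain_map=domain_map)
    b5_lexicon = AnchorLexicon(
        facets=list(facets), anchors=b5_anchors, domain_map=dict(domain_map)
    )
    return GeometricEmbedding(dim, table, cfg.seed), lexicon, b5_lexicon


def simulate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort under the configured conditions."""
    emb, lexicon, b5_lexicon = make_embedding_space(cfg)
    rng = np.random.default_rng(cfg.seed + 1)

    facets = cfg.facet_names()
    vocab = {
        f: [f"term {f.lower()} {t + 1}" for t in range(cfg.vocab_per_facet)]
        for f in facets
    }

    n, D, F = cfg.n_persons, cfg.n_domains, cfg.n_facets
    a = cfg.facet_loading_a
    theta = rng.standard_normal((n, D))
    eps = rng.standard_normal((n, F))
    dom_idx = np.repeat(np.arange(D), cfg.facets_per_domain)
    latent_facets = a * theta[:, dom_idx] + np.sqrt(1 - a**2) * eps

    pids = [f"P{i + 1:04d}" for i in range(n)]
    records: List[TermRecord] = []
    for i, pid in enumerate(pids):
        logits = latent_facets[i] / cfg.emission_temperature
        probs = np.exp(logits - logits.max())
        probs /= probs.sum()
        emitted: List[str] = []
        used: set = set()
        for slot in range(cfg.terms_per_person):
            u = rng.uniform()
            if u < cfg.noise_rate:
                term = NOISE_TOKENS[rng.integers(len(NOISE_TOKENS))]
            elif u < cfg.noise_rate + cfg.dup_rate and emitted:
                term = emitted[rng.integers(len(emitted))]
            else:
                # fresh draws avoid vocabulary already used by this person,
                # so duplicates arise only through the explicit dial
                term = None
                for _ in range(F):
                    f = facets[rng.choice(F, p=probs)]
                    fresh = [t for t in vocab[f] if t not in used]
                    if fresh:
                        term = fresh[rng.integers(len(fresh))]
                        break
                if term is None:
                    # renormalize over facets that still have unused vocabulary
                    avail = np.array(
                        [any(t not in used for t in vocab[f]) for f in facets]
                    )
                    if avail.any():
                        pr = probs * avail
                        f = facets[rng.choice(F, p=pr / pr.sum())]
                        fresh = [t for t in vocab[f] if t not in used]
                        term = fresh[rng.integers(len(fresh))]
                    else:  # entire vocabulary exhausted: a repeat is forced
                        f = facets[rng.choice(F, p=probs)]
                        term = vocab[f][rng.integers(cfg.vocab_per_facet)]
            emitted.append(term)
            used.add(term)
            cat = PROFESSIONAL if slot % 2 else PERSONAL
            records.append(TermRecord(pid=pid, raw_term=term, category=cat))

    c = cfg.b5_convergence_c
    ab = cfg.b5_structure_loading
    eta = rng.standard_normal((n, D))  # instrument-specific domain factors
    nu = rng.standard_normal((n, F))
    unique = ab * eta[:, dom_idx] + np.sqrt(1 - ab**2) * nu
    b5_latent = c * latent_facets + np.sqrt(1 - c**2) * unique
    b5_scores = 50.0 + 10.0 * b5_latent

    return SyntheticCohort(
        config=cfg,
        term_records=records,
        anchor_lexicon=lexicon,
        b5_lexicon=b5_lexicon,
        embedding_space=emb,
        b5_scores=b5_scores,
        latent_domains=theta,
        latent_facets=latent_facets,
        ground_truth_partition=dict(lexicon.domain_map),
        pids=pids,
        vocab=vocab,
    )


def sample_from_precision(Theta: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Draw n Gaussian rows whose population partial correlations are
    ``-Theta_ij / sqrt(Theta_ii Theta_jj)`` (covariance is the inverse of
    Theta, rescaled to unit variances)."""
    Theta = np.asarray(Theta, dtype=float)
    S = np.linalg.inv(Theta)
    d = np.sqrt(np.diag(S))
    C = S / np.outer(d, d)
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(np.zeros(len(C)), C, size=n)


def exact_corr_data(C: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Gaussian-shaped data whose *sample* correlation equals C exactly.

    Useful for noiseless strong-signal limits: random rows are whitened
    exactly (SVD) and the target correlation is imposed by its Cholesky
    factor, removing sampling error from the configuration itself.
    """
    C = np.asarray(C, dtype=float)
    p = len(C)
    if n <= p:
        raise ValueError("need n > p for exact whitening")
    Z = np.random.default_rng(seed).standard_normal((n, p))
    Z -= Z.mean(axis=0)
    U, _, Vt = np.linalg.svd(Z, full_matrices=False)
    W = U @ Vt * np.sqrt(n - 1)
    L = np.linalg.cholesky(C)
    return W @ L.T


def simulate_ratings(
    n_targets: int,
    n_raters: int,
    true_sd: float,
    rater_bias_sd: float,
    error_sd: float,
    seed: int,
    true_mean: float = 3.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Ordinal 1-5 ratings from a two-way random-effects model.

    rating = clamp(round(true_score + rater_bias + error), 1, 5). Returns
    (ratings matrix targets x raters, latent true scores) so recovery of the
    analytic ICC sigma_t^2 / (sigma_t^2 + sigma_b^2 + sigma_e^2) can be
    tested.
    """
    if n_targets < 2 or n_raters < 2:
        raise ValueError("need at least 2 targets and 2 raters")
    if true_sd <= 0 or rater_bias_sd < 0 or error_sd < 0:
        raise ValueError("sds must be positive (bias/error may be zero)")
    rng = np.random.default_rng(seed)
    true = true_mean + true_sd * rng.standard_normal(n_targets)
    bias = rater_bias_sd * rng.standard_normal(n_raters)
    err = error_sd * rng.standard_normal((n_targets, n_raters))
    raw = true[:, None] + bias[None, :] + err
    ratings = np.clip(np.rint(raw), 1, 5).astype(int)
    return ratings, true
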