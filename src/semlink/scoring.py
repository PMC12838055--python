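"""Anchor-based semantic scoring of open-response terms.

Open-response terms are scored against a facet *anchor lexicon*: each facet is
defined by a set of anchor phrases, and a term's similarity to a facet is the
mean cosine similarity between the term's embedding and the facet's anchor
embeddings,

    s_{t,f} = (1/|A_f|) * sum_{a in A_f} cos(e_t, e_a).

Person-by-facet raw composites are the mean of s_{t,f} over the person's
retained terms; standardized composites z-score each facet column across
persons. Quality control (deduplication within person, stop-list noise
removal) happens before scoring.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

logger = logging.getLogger(__name__)

#: Tokens treated as noise in addition to any user-supplied stop-list.
DEFAULT_STOPLIST: frozenset = frozenset({"nan", "n/a", "", "lorem", "click here"})

PERSONAL = "personal"
PROFESSIONAL = "professional"

QC_RETAINED = "retained"
QC_DUPLICATE = "duplicate"
QC_NOISE = "noise"
QC_NON_EMBEDDABLE = "non_embeddable"


def normalize_term(raw: str) -> str:
    """Lowercase, NFC-normalize, trim and collapse internal whitespace."""
    s = unicodedata.normalize("NFC", raw)
    s = " ".join(s.strip().lower().split())
    return s


@dataclass
class TermRecord:
    """One participant-produced term with its QC status."""

    pid: str
    raw_term: str
    category: str = PERSONAL
    norm_term: str = field(default="")
    qc_status: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.norm_term:
            self.norm_term = normalize_term(self.raw_term)


@dataclass
class AnchorLexicon:
    """Facet -> anchor-phrase lists plus the domain -> facet hierarchy.

    The canonical shape is 5 domains x 6 facets (the Five-Factor hierarchy),
    but any K x M layout is accepted.
    """

    facets: List[str]
    anchors: Dict[str, List[str]]
    domain_map: Dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.facets)) != len(self.facets):
            raise ValueError("facet names must be unique")
        for f in self.facets:
            if f not in self.anchors or not self.anchors[f]:
                raise ValueError(f"facet {f!r} has no anchors")
            if f not in self.domain_map:
                raise ValueError(f"facet {f!r} missing from domain_map")

    @property
    def domains(self) -> List[str]:
        seen: List[str] = []
        for f in self.facets:
            d = self.domain_map[f]
            if d not in seen:
                seen.append(d)
        return seen

    def facets_of(self, domain: str) -> List[str]:
        return [f for f in self.facets if self.domain_map[f] == domain]


class EmbeddingProvider:
    """Deterministic map from text to a fixed-dimensional vector.

    Concrete backends subclass or wrap this contract; the same text must
    always produce the same finite vector.
    """

    dim: int

    def embed(self, text: str) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def embed_many(self, texts: Sequence[str]) -> np.ndarray:
        return np.stack([self.embed(t) for t in texts])


class FunctionEmbedding(EmbeddingProvider):
    """Adapter wrapping a plain ``text -> vector`` callable."""

    def __init__(self, dim: int, fn: Callable[[str], np.ndarray]):
        self.dim = dim
        self._fn = fn

    def embed(self, text: str) -> np.ndarray:
        return np.asarray(self._fn(text), dtype=float)


@dataclass
class QCReport:
    total_terms: int
    retained: int
    duplicates_removed: int
    noise_removed: int
    non_embeddable: int
    retention_rate: float
    per_person_mean: float
    per_person_sd: float

    def as_dict(self) -> Dict[str, float]:
        return dict(self.__dict__)


@dataclass
class CompositeMatrix:
    """Person x facet raw (X) and standardized (Z) composite scores."""

    pids: List[str]
    facets: List[str]
    X: np.ndarray
    Z: np.ndarray
    col_means: np.ndarray
    col_sds: np.ndarray
    terms_used: Dict[str, int]
    excluded_pids: List[str] = field(default_factory=list)
    zero_variance_facets: List[str] = field(default_factory=list)


def sanitize_terms(
    records: Sequence[TermRecord],
    stoplist: Optional[Set[str]] = None,
) -> Tuple[List[TermRecord], QCReport]:
    """Flag duplicates and noise tokens; tally a QC report.

    Within each participant the first occurrence of a normalized term is
    retained and later occurrences are flagged as duplicates. Terms matching
    the stop-list are flagged as noise. Input order is preserved.
    """
    if not records:
        raise ValueError("no term records supplied")
    stop = set(DEFAULT_STOPLIST) if stoplist is None else set(stoplist)

    seen: Dict[str, Set[str]] = {}
    out: List[TermRecord] = []
    n_dup = n_noise = n_ret = 0
    for idx, rec in enumerate(records):
        if not rec.pid:
            raise ValueError(f"record {idx} has an empty participant id")
        rec = TermRecord(rec.pid, rec.raw_term, rec.category, rec.norm_term)
        if rec.norm_term in stop:
            rec.qc_status = QC_NOISE
            n_noise += 1
        elif rec.norm_term in seen.setdefault(rec.pid, set()):
            rec.qc_status = QC_DUPLICATE
            n_dup += 1
        else:
            rec.qc_status = QC_RETAINED
            seen[rec.pid].add(rec.norm_term)
            n_ret += 1
        out.append(rec)

    per_person = {}
    for rec in out:
        if rec.qc_status == QC_RETAINED:
            per_person[rec.pid] = per_person.get(rec.pid, 0) + 1
    counts = np.array(list(per_person.values()), dtype=float)
    report = QCReport(
        total_terms=len(out),
        retained=n_ret,
        duplicates_removed=n_dup,
        noise_removed=n_noise,
        non_embeddable=0,
        retention_rate=n_ret / len(out),
        per_person_mean=float(counts.mean()) if counts.size else 0.0,
        per_person_sd=float(counts.std(ddof=0)) if counts.size else 0.0,
    )
    return out, report


def _cosine_rows(M: np.ndarray, v: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=1) * np.linalg.norm(v)
    if np.any(norms == 0):
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return M @ v / norms


def term_facet_similarity(
    term: TermRecord,
    lexicon: AnchorLexicon,
    emb: EmbeddingProvider,
) -> Dict[str, float]:
    """Mean cosine similarity of one term to each facet's anchor set."""
    v = emb.embed(term.norm_term)
    out: Dict[str, float] = {}
    for f in lexicon.facets:
        A = emb.embed_many(lexicon.anchors[f])
        out[f] = float(np.mean(_cosine_rows(A, v)))
    return out


def _anchor_matrix(lexicon: AnchorLexicon, emb: EmbeddingProvider) -> List[np.ndarray]:
    return [emb.embed_many(lexicon.anchors[f]) for f in lexicon.facets]


def build_composites(
    records: Sequence[TermRecord],
    lexicon: AnchorLexicon,
    emb: EmbeddingProvider,
) -> CompositeMatrix:
    """Aggregate term-facet similarities into person x facet composites.

    X[i, f] is the mean similarity of person i's retained terms to facet f;
    Z standardizes each column with the sample (n-1) standard deviation.
    Persons with no retained terms are excluded (with a warning); facet
    columns with zero variance get an all-zero Z column and are flagged.
    """
    retained: Dict[str, List[TermRecord]] = {}
    order: List[str] = []
    for rec in records:
        if rec.qc_status != QC_RETAINED:
            continue
        if rec.pid not in retained:
            retained[rec.pid] = []
            order.append(rec.pid)
        retained[rec.pid].append(rec)

    all_pids = []
    seen = set()
    for rec in records:
        if rec.pid not in seen:
            seen.add(rec.pid)
            all_pids.append(rec.pid)
    excluded = [p for p in all_pids if p not in retained]
    for p in excluded:
        logger.warning("participant %s has no retained terms; excluded from scoring", p)
    if not order:
        raise ValueError("no participant has any retained term")

    anchor_mats = _anchor_matrix(lexicon, emb)
    n, p = len(order), len(lexicon.facets)
    X = np.empty((n, p))
    terms_used: Dict[str, int] = {}
    for i, pid in enumerate(order):
        vecs = emb.embed_many([r.norm_term for r in retained[pid]])
        vnorm = np.linalg.norm(vecs, axis=1, keepdims=True)
        if np.any(vnorm == 0):
            raise ValueError(f"zero-norm embedding for participant {pid}")
        vecs = vecs / vnorm
        for j, A in enumerate(anchor_mats):
            Anorm = A / np.linalg.norm(A, axis=1, keepdims=True)
            # mean over terms of mean over anchors of cosine
            X[i, j] = float(np.mean(vecs @ Anorm.T))
        terms_used[pid] = len(retained[pid])

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1) if n > 1 else np.zeros(p)
    Z = np.zeros_like(X)
    zero_var: List[str] = []
    for j in range(p):
        if sds[j] > 0:
            Z[:, j] = (X[:, j] - means[j]) / sds[j]
        else:
            zero_var.append(lexicon.facets[j])
            logger.warning("facet %s has zero variance; Z column zeroed", lexicon.facets[j])

    return CompositeMatrix(
        pids=order,
        facets=list(lexicon.facets),
        X=X,
        Z=Z,
        col_means=means,
        col_sds=sds,
        terms_used=terms_used,
        excluded_pids=excluded,
        zero_variance_facets=zero_var,
    )


def domain_composites(cm: CompositeMatrix, lexicon: AnchorLexicon) -> Tuple[np.ndarray, List[str]]:
    """Unweighted mean of each domain's facet Z columns; returns (matrix, domain names)."""
    for f in cm.facets:
        if f not in lexicon.domain_map:
            raise ValueError(f"facet {f!r} missing from domain_map")
    domains = lexicon.domains
    out = np.empty((cm.Z.shape[0], len(domains)))
    for k, d in enumerate(domains):
        idx = [cm.facets.index(f) for f in lexicon.facets_of(d) if f in cm.facets]
        out[:, k] = cm.Z[:, idx].mean(axis=1)
    return out, domains


def semantic_coherence(
    records: Sequence[TermRecord],
    emb: EmbeddingProvider,
) -> Dict[str, Optional[float]]:
    """Per-person mean pairwise cosine similarity among retained term vectors.

    Persons with fewer than two retained terms get ``None`` (undefined),
    not an error.
    """
    by_pid: Dict[str, List[str]] = {}
    for rec in records:
        if rec.qc_status == QC_RETAINED:
            by_pid.setdefault(rec.pid, []).append(rec.norm_term)

    out: Dict[str, Optional[float]] = {}
    for pid, terms in by_pid.items():
        if len(terms) < 2:
            out[pid] = None
            continue
        V = emb.embed_many(terms)
        V = V / np.linalg.norm(V, axis=1, keepdims=True)
        S = V @ V.T
        iu = np.triu_indices(len(terms), k=1)
        out[pid] = float(S[iu].mean())
    return out
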