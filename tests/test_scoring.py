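"""QC, term-facet similarity and composite construction against brute-force
reference implementations."""

import numpy as np
import pytest

from semlink.scoring import (
    AnchorLexicon,
    FunctionEmbedding,
    TermRecord,
    build_composites,
    domain_composites,
    sanitize_terms,
    semantic_coherence,
    term_facet_similarity,
)


def make_embedding(table, dim):
    return FunctionEmbedding(dim, lambda t: np.asarray(table[t], dtype=float))


def recs(pid, terms, status=None):
    out = [TermRecord(pid=pid, raw_term=t) for t in terms]
    if status:
        for r in out:
            r.qc_status = status
    return out


# ---------------------------------------------------------------------------
# sanitize_terms
# ---------------------------------------------------------------------------

class TestSanitize:
    def test_within_person_dedup(self):
        flagged, qc = sanitize_terms(recs("p1", ["calm", "calm", "bold"]))
        statuses = [r.qc_status for r in flagged]
        assert statuses == ["retained", "duplicate", "retained"]
        assert qc.duplicates_removed == 1
        assert qc.retention_rate == pytest.approx(2 / 3)

    def test_stoplist_noise(self):
        flagged, qc = sanitize_terms(recs("p1", ["nan", "focus"]))
        assert [r.qc_status for r in flagged] == ["noise", "retained"]
        assert qc.noise_removed == 1

    def test_clean_input_tallies(self):
        records = []
        for i in range(10):
            records += recs(f"p{i}", [f"term{j}" for j in range(10)])
        _, qc = sanitize_terms(records)
        assert qc.retention_rate == 1.0
        assert qc.per_person_mean == 10
        assert qc.per_person_sd == 0

    def test_normalization_drives_dedup(self):
        flagged, qc = sanitize_terms(recs("p1", ["Calm ", "  calm", "CALM"]))
        assert qc.duplicates_removed == 2

    def test_empty_pid_errors_with_index(self):
        records = recs("p1", ["a"]) + [TermRecord(pid="", raw_term="b")]
        with pytest.raises(ValueError, match="record 1"):
            sanitize_terms(records)

    def test_dedup_is_per_person(self):
        flagged, qc = sanitize_terms(recs("p1", ["calm"]) + recs("p2", ["calm"]))
        assert qc.duplicates_removed == 0


# ---------------------------------------------------------------------------
# term_facet_similarity
# ---------------------------------------------------------------------------

class TestSimilarity:
    def test_identical_anchor_gives_one(self):
        emb = make_embedding({"bold": [1.0, 0.0]}, 2)
        lex = AnchorLexicon(["f1"], {"f1": ["bold"]}, {"f1": "d1"})
        rec = TermRecord("p", "bold", qc_status="retained")
        assert term_facet_similarity(rec, lex, emb)["f1"] == pytest.approx(1.0)

    def test_opposed_anchors_cancel(self):
        emb = make_embedding(
            {"t": [0.3, 0.9], "a+": [1.0, 0.2], "a-": [-1.0, -0.2]}, 2
        )
        lex = AnchorLexicon(["f1"], {"f1": ["a+", "a-"]}, {"f1": "d1"})
        rec = TermRecord("p", "t", qc_status="retained")
        assert term_facet_similarity(rec, lex, emb)["f1"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_loop_and_average_oracle(self, rng):
        dim = 8
        anchors = [f"a{i}" for i in range(5)]
        table = {a: rng.standard_normal(dim) for a in anchors}
        table["term"] = rng.standard_normal(dim)
        emb = make_embedding(table, dim)
        lex = AnchorLexicon(["f"], {"f": anchors}, {"f": "d"})
        rec = TermRecord("p", "term", qc_status="retained")
        got = term_facet_similarity(rec, lex, emb)["f"]

        def cos(u, v):
            return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))

        expected = np.mean([cos(table["term"], table[a]) for a in anchors])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_errors(self):
        emb = make_embedding({"z": [0.0, 0.0], "a": [1.0, 0.0]}, 2)
        lex = AnchorLexicon(["f"], {"f": ["a"]}, {"f": "d"})
        with pytest.raises(ValueError):
            term_facet_similarity(TermRecord("p", "z", qc_status="retained"), lex, emb)


# ---------------------------------------------------------------------------
# build_composites
# ---------------------------------------------------------------------------

def _hand_world():
    """3 persons x 2 facets with hand-set facet-1 similarities 0.2/0.4/0.6
    and facet-2 exactly zero for everyone."""
    table = {
        "a1": [1.0, 0.0, 0.0],
        "a2": [0.0, 0.0, 1.0],
        "t1": [0.2, np.sqrt(1 - 0.04), 0.0],
        "t2": [0.4, np.sqrt(1 - 0.16), 0.0],
        "t3": [0.6, np.sqrt(1 - 0.36), 0.0],
    }
    emb = make_embedding(table, 3)
    lex = AnchorLexicon(["f1", "f2"], {"f1": ["a1"], "f2": ["a2"]}, {"f1": "d", "f2": "d"})
    records = []
    for pid, t in zip(["p1", "p2", "p3"], ["t1", "t2", "t3"]):
        records += recs(pid, [t], status="retained")
    return records, lex, emb


class TestComposites:
    def test_single_term_row_equals_similarity_map(self):
        records, lex, emb = _hand_world()
        cm = build_composites(records[:1], lex, emb)
        sims = term_facet_similarity(records[0], lex, emb)
        np.testing.assert_allclose(cm.X[0], [sims["f1"], sims["f2"]], atol=1e-12)

    def test_hand_computed_standardization(self):
        records, lex, emb = _hand_world()
        cm = build_composites(records, lex, emb)
        np.testing.assert_allclose(cm.X[:, 0], [0.2, 0.4, 0.6], atol=1e-12)
        # n-1 sd of (0.2, 0.4, 0.6) is exactly 0.2
        np.testing.assert_allclose(cm.Z[:, 0], [-1.0, 0.0, 1.0], atol=1e-10)
        assert cm.zero_variance_facets == ["f2"]
        np.testing.assert_allclose(cm.Z[:, 1], 0.0)

    def test_z_columns_standardized(self, small_cohort):
        flagged, _ = sanitize_terms(small_cohort.term_records)
        cm = build_composites(flagged, small_cohort.anchor_lexicon,
                              small_cohort.embedding_space)
        assert np.all(cm.X >= -1) and np.all(cm.X <= 1)
        for j, f in enumerate(cm.facets):
            if f in cm.zero_variance_facets:
                continue
            assert abs(cm.Z[:, j].mean()) < 1e-10
            assert cm.Z[:, j].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_unretained_person_excluded(self):
        records, lex, emb = _hand_world()
        records.append(TermRecord("p4", "t1", qc_status="duplicate"))
        cm = build_composites(records, lex, emb)
        assert cm.excluded_pids == ["p4"]
        assert "p4" not in cm.pids

    def test_order_invariance(self, small_cohort):
        """Scoring is invariant to term order within person and person order."""
        flagged, _ = sanitize_terms(small_cohort.term_records)
        cm1 = build_composites(flagged, small_cohort.anchor_lexicon,
                               small_cohort.embedding_space)
        # reverse each person's retained terms (keep person order stable)
        by_pid = {}
        for r in flagged:
            by_pid.setdefault(r.pid, []).append(r)
        shuffled = []
        for pid in by_pid:
            shuffled.extend(reversed(by_pid[pid]))
        cm2 = build_composites(shuffled, small_cohort.anchor_lexicon,
                               small_cohort.embedding_space)
        assert cm1.pids == cm2.pids
        np.testing.assert_allclose(cm1.X, cm2.X, atol=1e-12)

    def test_duplicate_injection_idempotent(self):
        """Adding duplicates of existing terms changes nothing after QC."""
        records, lex, emb = _hand_world()
        base, _ = sanitize_terms([TermRecord(r.pid, r.raw_term) for r in records])
        cm1 = build_composites(base, lex, emb)
        noisy = [TermRecord(r.pid, r.raw_term) for r in records]
        noisy += [TermRecord("p1", "t1"), TermRecord("p2", "t2")]
        flagged, _ = sanitize_terms(noisy)
        cm2 = build_composites(flagged, lex, emb)
        np.testing.assert_allclose(cm1.X, cm2.X, atol=1e-12)


def naive_records_to_z(records, lexicon, emb):
    """Nested-loop reference implementation of the records -> Z path."""
    per_person = {}
    for r in records:
        if r.qc_status != "retained":
            continue
        per_person.setdefault(r.pid, []).append(r.norm_term)
    pids = list(per_person)

    def cos(u, v):
        return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))

    X = np.zeros((len(pids), len(lexicon.facets)))
    for i, pid in enumerate(pids):
        for j, f in enumerate(lexicon.facets):
            vals = []
            for t in per_person[pid]:
                s = 0.0
                for a in lexicon.anchors[f]:
                    s += cos(emb.embed(t), emb.embed(a))
                vals.append(s / len(lexicon.anchors[f]))
            X[i, j] = sum(vals) / len(vals)
    Z = np.zeros_like(X)
    for j in range(X.shape[1]):
        mu = X[:, j].mean()
        sd = X[:, j].std(ddof=1)
        if sd > 0:
            Z[:, j] = (X[:, j] - mu) / sd
    return pids, X, Z


def test_full_path_matches_nested_loop_reference(small_cohort):
    flagged, _ = sanitize_terms(small_cohort.term_records)
    cm = build_composites(flagged, small_cohort.anchor_lexicon,
                          small_cohort.embedding_space)
    pids, X, Z = naive_records_to_z(flagged, small_cohort.anchor_lexicon,
                                    small_cohort.embedding_space)
    assert pids == cm.pids
    np.testing.assert_allclose(cm.X, X, atol=1e-10)
    np.testing.assert_allclose(cm.Z, Z, atol=1e-10)


# ---------------------------------------------------------------------------
# domain composites and coherence
# ---------------------------------------------------------------------------

class TestDomains:
    def test_identical_facets_pass_through(self, rng):
        from semlink.scoring import CompositeMatrix

        z = rng.standard_normal(5)
        cm = CompositeMatrix(
            pids=[f"p{i}" for i in range(5)], facets=["f1", "f2"],
            X=np.column_stack([z, z]), Z=np.column_stack([z, z]),
            col_means=np.zeros(2), col_sds=np.ones(2), terms_used={},
        )
        lex = AnchorLexicon(["f1", "f2"], {"f1": ["a"], "f2": ["a"]},
                            {"f1": "d", "f2": "d"})
        dom, names = domain_composites(cm, lex)
        assert names == ["d"]
        np.testing.assert_allclose(dom[:, 0], z, atol=1e-12)

    def test_random_domain_matches_row_means(self, rng):
        from semlink.scoring import CompositeMatrix

        Z = rng.standard_normal((7, 6))
        facets = [f"f{j}" for j in range(6)]
        cm = CompositeMatrix([f"p{i}" for i in range(7)], facets, Z.copy(), Z,
                             np.zeros(6), np.ones(6), {})
        lex = AnchorLexicon(facets, {f: ["a"] for f in facets},
                            {f: "d" for f in facets})
        dom, _ = domain_composites(cm, lex)
        np.testing.assert_allclose(dom[:, 0], Z.mean(axis=1), atol=1e-12)

    def test_missing_facet_errors(self, rng):
        from semlink.scoring import CompositeMatrix

        cm = CompositeMatrix(["p"], ["f1"], np.zeros((1, 1)), np.zeros((1, 1)),
                             np.zeros(1), np.ones(1), {})
        lex = AnchorLexicon(["f2"], {"f2": ["a"]}, {"f2": "d"})
        with pytest.raises(ValueError):
            domain_composites(cm, lex)


class TestCoherence:
    def test_identical_vectors_give_one(self):
        table = {"a": [0.6, 0.8], "b": [0.6, 0.8]}
        emb = make_embedding(table, 2)
        out = semantic_coherence(recs("p", ["a", "b"], status="retained"), emb)
        assert out["p"] == pytest.approx(1.0)

    def test_orthogonal_vectors_give_zero(self):
        emb = make_embedding({"a": [1.0, 0.0], "b": [0.0, 1.0]}, 2)
        out = semantic_coherence(recs("p", ["a", "b"], status="retained"), emb)
        assert out["p"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_pairwise_oracle(self, rng):
        terms = [f"t{i}" for i in range(5)]
        table = {t: rng.standard_normal(16) for t in terms}
        emb = make_embedding(table, 16)
        out = semantic_coherence(recs("p", terms, status="retained"), emb)

        def cos(u, v):
            return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))

        pairs = [cos(table[a], table[b]) for i, a in enumerate(terms)
                 for b in terms[i + 1:]]
        assert out["p"] == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_single_term_is_missing(self):
        emb = make_embedding({"a": [1.0, 0.0]}, 2)
        out = semantic_coherence(recs("p", ["a"], status="retained"), emb)
        assert out["p"] is None
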