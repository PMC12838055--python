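"""End-to-end orchestration: QC -> scoring -> reliability -> networks ->
convergence -> alignment.

The pipeline reads term records, one or two anchor lexicons and (optionally)
a questionnaire facet-score matrix, then runs the full evaluation battery
and writes CSV score matrices plus a single JSON run report. Every source of
randomness is seeded from the config, and the JSON serialization is stable,
so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from . import alignment as al
from . import io as sio
from . import network as nw
from . import reliability as rel
from . import scoring as sc
from .synthetic import SimConfig, _hash_unit_vector, make_embedding_space

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full analysis run. All seeds are explicit."""

    terms_path: str
    lexicon_path: str
    out_dir: str
    b5_scores_path: Optional[str] = None
    b5_lexicon_path: Optional[str] = None
    embedding: Dict = field(default_factory=lambda: {"backend": "hash", "dim": 64})
    stoplist: Optional[List[str]] = None
    seed: int = 0
    n_boot_omega: int = 1000
    n_boot_edges: int = 50
    n_boot_cs: int = 45
    n_boot_recovery: int = 25
    cs_indices: Tuple[str, ...] = ("strength", "betweenness", "closeness")
    ebic_gamma: float = 0.5
    n_lambda: int = 50
    n_lambda_boot: int = 10
    boot_tol: float = 1e-3  # looser glasso tolerance for bootstrap re-fits
    louvain_resolution: float = 1.0
    louvain_restarts: int = 20
    mantel_permutations: int = 5000
    reliability_groups: int = 2
    domain_matching: Optional[Dict[str, str]] = None

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        if "cs_indices" in obj:
            obj["cs_indices"] = tuple(obj["cs_indices"])
        return cls(**obj)

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["cs_indices"] = list(d["cs_indices"])
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class HashEmbedding(sc.EmbeddingProvider):
    """Seeded-hash unit-vector embedding; a structure-free fallback backend."""

    def __init__(self, dim: int = 64, seed: int = 0):
        self.dim = dim
        self._seed = seed

    def embed(self, text: str) -> np.ndarray:
        if text == "":
            raise ValueError("cannot embed the empty string")
        return _hash_unit_vector(text, self.dim, self._seed)


def build_embedding(spec: Dict) -> sc.EmbeddingProvider:
    """Instantiate an embedding backend from its config block.

    Backends: "geometric" (deterministic synthetic space reconstructed from
    generator parameters), "hash" (seeded-hash fallback), and
    "sentence-transformers" (optional plug-in; requires the package).
    """
    backend = spec.get("backend", "hash")
    if backend == "geometric":
        cfg = SimConfig(**spec.get("params", {}))
        emb, _, _ = make_embedding_space(cfg)
        return emb
    if backend == "hash":
        return HashEmbedding(dim=int(spec.get("dim", 64)), seed=int(spec.get("seed", 0)))
    if backend == "sentence-transformers":  # pragma: no cover - optional heavy dep
        from sentence_transformers import SentenceTransformer

        model = SentenceTransformer(spec.get("model", "all-MiniLM-L6-v2"))

        def fn(text: str) -> np.ndarray:
            return model.encode([text])[0]

        return sc.FunctionEmbedding(model.get_sentence_embedding_dimension(), fn)
    raise ValueError(f"unknown embedding backend {backend!r}")


def _standardize_columns(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1)
    out = (df - df.mean()) / sd.replace(0.0, np.nan)
    return out.fillna(0.0)


def _domain_means(facets: pd.DataFrame, domain_map: Dict[str, str]) -> pd.DataFrame:
    cols: Dict[str, pd.Series] = {}
    order: List[str] = []
    for f in facets.columns:
        d = domain_map.get(f)
        if d is None:
            continue
        if d not in order:
            order.append(d)
    for d in order:
        members = [f for f in facets.columns if domain_map.get(f) == d]
        cols[d] = facets[members].mean(axis=1)
    return pd.DataFrame(cols)[order]


def run_full_analysis(cfg: RunConfig) -> Dict:
    """Execute the full battery; on a stage failure the report is marked
    partial with the failing stage named and upstream results preserved."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: Dict = {
        "status": "complete",
        "failed_stage": None,
        "provenance": {
            "config": cfg.to_dict(),
            "config_hash": cfg.content_hash(),
            "package_version": __version__,
        },
    }

    state: Dict = {}

    def st_qc():
        records = sio.read_term_records(cfg.terms_path)
        lexicon = sio.read_lexicon(cfg.lexicon_path)
        emb = build_embedding(cfg.embedding)
        stoplist = set(cfg.stoplist) if cfg.stoplist is not None else None
        flagged, qc = sc.sanitize_terms(records, stoplist)
        state.update(records=flagged, lexicon=lexicon, emb=emb)
        report["qc"] = qc.as_dict()

    def st_scoring():
        cm = sc.build_composites(state["records"], state["lexicon"], state["emb"])
        dom, dom_names = sc.domain_composites(cm, state["lexicon"])
        coherence = sc.semantic_coherence(state["records"], state["emb"])
        state.update(cm=cm, dm_domains=pd.DataFrame(dom, index=cm.pids, columns=dom_names))
        Z = pd.DataFrame(cm.Z, index=cm.pids, columns=cm.facets)
        X = pd.DataFrame(cm.X, index=cm.pids, columns=cm.facets)
        state["Z"] = Z
        sio.write_scores_wide(X, out_dir / "dm_composites_raw_wide.csv")
        sio.write_scores_wide(Z, out_dir / "dm_composites_z_wide.csv")
        sio.write_scores_long(Z, out_dir / "dm_composites_z_long.csv")
        vals = [v for v in coherence.values() if v is not None]
        report["scoring"] = {
            "n_scored": len(cm.pids),
            "excluded_pids": cm.excluded_pids,
            "zero_variance_facets": cm.zero_variance_facets,
            "mean_semantic_coherence": float(np.mean(vals)) if vals else None,
        }

    def st_reliability():
        lexicon: sc.AnchorLexicon = state["lexicon"]
        Z: pd.DataFrame = state["Z"]
        out = {}
        for d in lexicon.domains:
            members = lexicon.facets_of(d)
            data = Z[members].to_numpy()
            k = len(members)
            n_groups = cfg.reliability_groups if k >= 3 * cfg.reliability_groups else None
            rep = rel.domain_reliability(
                data, members, d, n_groups=n_groups,
                n_boot=cfg.n_boot_omega, seed=cfg.seed,
            )
            out[d] = {
                "k": rep.k,
                "omega_total": rep.omega_total,
                "omega_h": rep.omega_h,
                "ci": [rep.ci_low, rep.ci_high],
                "n_boot": rep.n_boot,
                "item_total": rep.item_total,
                "loo_delta_omega": rep.loo_delta_omega,
            }
        report["reliability"] = out

    def _network_block(data: np.ndarray, nodes: Sequence[str], seed: int) -> Tuple[Dict, nw.NetworkModel]:
        net = nw.estimate_network(data, nodes=nodes, gamma=cfg.ebic_gamma, n_lambda=cfg.n_lambda)
        part = nw.louvain(net, cfg.louvain_resolution, seed=seed, restarts=cfg.louvain_restarts)
        glob = nw.global_metrics(net)
        cs = nw.case_drop_stability(
            data, indices=cfg.cs_indices, n_boot=cfg.n_boot_cs, seed=seed,
            gamma=cfg.ebic_gamma, n_lambda=cfg.n_lambda_boot, nodes=nodes,
            boot_tol=cfg.boot_tol,
        )
        eb = nw.edge_bootstrap(
            data, n_boot=cfg.n_boot_edges, seed=seed,
            gamma=cfg.ebic_gamma, n_lambda=cfg.n_lambda_boot, nodes=nodes,
            boot_tol=cfg.boot_tol,
        )
        recov = nw.structure_recovery_frequency(
            data, part, n_boot=cfg.n_boot_recovery, seed=seed,
            gamma=cfg.ebic_gamma, n_lambda=cfg.n_lambda_boot,
            resolution=cfg.louvain_resolution, nodes=nodes,
            boot_tol=cfg.boot_tol,
        )
        block = {
            "lambda_selected": net.lambda_selected,
            "gamma": net.gamma,
            "n_communities": part.n_communities,
            "communities": part.labels,
            "modularity_Q": part.Q,
            **glob,
            "cs": cs,
            "edge_mean_retention": eb["edge_mean_retention"],
            "edge_median_weight_corr": eb["edge_median_weight_corr"],
            "structure_recovery_frequency": recov,
            "centralities": nw.centralities(net),
        }
        return block, net

    def st_network_dm():
        Z: pd.DataFrame = state["Z"]
        block, net = _network_block(Z.to_numpy(), list(Z.columns), cfg.seed)
        state["net_dm"] = net
        report["network_dm"] = block

    def st_network_b5():
        if cfg.b5_scores_path is None:
            report["network_b5"] = None
            return
        b5 = sio.read_scores_wide(cfg.b5_scores_path).dropna()
        b5z = _standardize_columns(b5)
        state["b5"] = b5
        state["b5z"] = b5z
        block, net = _network_block(b5z.to_numpy(), list(b5z.columns), cfg.seed + 1)
        state["net_b5"] = net
        report["network_b5"] = block

    def st_convergence():
        if "b5z" not in state:
            report["convergence"] = None
            return
        lexicon: sc.AnchorLexicon = state["lexicon"]
        b5_lex = (
            sio.read_lexicon(cfg.b5_lexicon_path)
            if cfg.b5_lexicon_path
            else lexicon
        )
        b5_domains = _domain_means(state["b5z"], b5_lex.domain_map)
        conv = al.convergence_matrix(
            state["dm_domains"], b5_domains,
            matching=cfg.domain_matching,
            dm_facets=state["Z"], b5_facets=state["b5z"],
        )
        report["convergence"] = {
            "n_overlap": conv.n_overlap,
            "matched_mean_abs_r": conv.matched_mean_abs_r,
            "matched_range": list(conv.matched_range),
            "matched_mean_abs_rho": conv.matched_mean_abs_rho,
            "max_abs_facet_r": list(conv.max_abs_facet_r) if conv.max_abs_facet_r else None,
            "domain_corr_pearson": conv.domain_corr_pearson.round(6),
            "domain_corr_spearman": conv.domain_corr_spearman.round(6),
        }

    def st_alignment():
        lexicon: sc.AnchorLexicon = state["lexicon"]
        emb = state["emb"]
        if cfg.b5_lexicon_path:
            b5_lex = sio.read_lexicon(cfg.b5_lexicon_path)
            X, Y, names = al.facet_configurations(lexicon, b5_lex, emb)
        elif "b5z" in state:
            # score-based comparison configuration: facet correlation profiles
            X = np.stack(
                [emb.embed_many(lexicon.anchors[f]).mean(axis=0) for f in lexicon.facets]
            )
            Y = state["b5z"].corr().loc[lexicon.facets, lexicon.facets].to_numpy()
        else:
            report["alignment"] = None
            return
        rep = al.alignment_report(
            X, Y, n_perm=cfg.mantel_permutations, seed=cfg.seed,
        )
        report["alignment"] = rep.as_dict()

    stages = [
        ("qc", st_qc),
        ("scoring", st_scoring),
        ("reliability", st_reliability),
        ("network_dm", st_network_dm),
        ("network_b5", st_network_b5),
        ("convergence", st_convergence),
        ("alignment", st_alignment),
    ]
    for name, fn in stages:
        try:
            fn()
        except Exception as exc:
            logger.exception("stage %s failed", name)
            report["status"] = "partial"
            report["failed_stage"] = name
            report["error"] = f"{type(exc).__name__}: {exc}"
            break

    sio.write_json(report, out_dir / "run_report.json")
    _write_summary(report, out_dir / "summary.txt")
    return report


def _write_summary(report: Dict, path: Path) -> None:
    lines = [f"semlink run report (status: {report['status']})"]
    if report.get("qc"):
        q = report["qc"]
        lines.append(
            f"QC: {q['total_terms']} terms, retention {q['retention_rate']:.3f} "
            f"({q['duplicates_removed']} duplicates, {q['noise_removed']} noise)"
        )
    for d, r in (report.get("reliability") or {}).items():
        om_h = f"{r['omega_h']:.3f}" if r["omega_h"] is not None else "-"
        lines.append(
            f"reliability {d}: k={r['k']} omega={r['omega_total']:.3f} "
            f"CI=[{r['ci'][0]:.3f},{r['ci'][1]:.3f}] omega_h={om_h}"
        )
    for key in ("network_dm", "network_b5"):
        blk = report.get(key)
        if blk:
            lines.append(
                f"{key}: Q={blk['modularity_Q']:.3f} ({blk['n_communities']} communities), "
                f"strength={blk['global_strength']:.2f}, density={blk['density']:.3f}, "
                f"CS={ {k: round(v, 2) for k, v in blk['cs'].items()} }"
            )
    conv = report.get("convergence")
    if conv:
        lines.append(
            f"convergence: matched mean |r|={conv['matched_mean_abs_r']:.3f} "
            f"range={conv['matched_range']}"
        )
    alg = report.get("alignment")
    if alg:
        lines.append(
            f"alignment: RV={alg['rv']:.3f} procrustes={alg['procrustes_sim']:.3f} "
            f"dcor={alg['dcor']:.3f} mantel r={alg['mantel_r']:.3f} (p={alg['mantel_p']:.4g}) "
            f"cca r1={alg['cca_r1']:.3f} flags={alg['degeneracy_flags']}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
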