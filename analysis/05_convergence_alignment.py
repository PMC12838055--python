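"""Person-level convergence and configuration-level alignment.

Correlates the semantic domain composites with the questionnaire domain
composites across people (Pearson + Spearman, matched-domain summaries,
facet-level scan with pairwise n), then computes the configuration
alignment indices (CCA r1 with degeneracy flags, RV, Procrustes, distance
correlation, Mantel on cosine-distance matrices) between the two anchor
lexicons' facet configurations. Writes results/validity/.
"""

import json
from pathlib import Path

import pandas as pd

from semlink import io as sio
from semlink.alignment import alignment_report, convergence_matrix, facet_configurations
from semlink.pipeline import build_embedding
from semlink.scoring import domain_composites

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260105


def main() -> None:
    out = ROOT / "validity"
    out.mkdir(parents=True, exist_ok=True)
    gt = json.loads((ROOT / "cohort" / "ground_truth.json").read_text())
    emb = build_embedding({"backend": "geometric", "params": gt["sim_config"]})
    lexicon = sio.read_lexicon(ROOT / "cohort" / "lexicon.json")
    b5_lexicon = sio.read_lexicon(ROOT / "cohort" / "b5_lexicon.json")

    Z = sio.read_scores_wide(ROOT / "scores" / "dm_composites_z_wide.csv")
    b5 = sio.read_scores_wide(ROOT / "cohort" / "b5_scores_wide.csv").dropna()
    b5z = (b5 - b5.mean()) / b5.std()
    dm_dom = pd.DataFrame(
        {d: Z[lexicon.facets_of(d)].mean(axis=1) for d in lexicon.domains}
    )
    b5_dom = pd.DataFrame(
        {d: b5z[b5_lexicon.facets_of(d)].mean(axis=1) for d in b5_lexicon.domains}
    )

    conv = convergence_matrix(dm_dom, b5_dom, dm_facets=Z, b5_facets=b5z)
    conv.domain_corr_pearson.round(4).to_csv(out / "domain_corr_pearson.csv")
    conv.domain_corr_spearman.round(4).to_csv(out / "domain_corr_spearman.csv")
    print(f"overlap n = {conv.n_overlap}")
    print(f"matched-domain mean |r|  = {conv.matched_mean_abs_r:.3f} "
          f"(range {conv.matched_range[0]:.3f} to {conv.matched_range[1]:.3f})")
    print(f"matched-domain mean |rho| = {conv.matched_mean_abs_rho:.3f}")
    if conv.max_abs_facet_r:
        v, a, b, n = conv.max_abs_facet_r
        print(f"largest facet-level |r| = {v:.3f} ({a} x {b}, pairwise n={n})")

    X, Y, _ = facet_configurations(lexicon, b5_lexicon, emb)
    rep = alignment_report(X, Y, n_perm=5000, seed=SEED)
    sio.write_json(
        {"convergence": {
            "n_overlap": conv.n_overlap,
            "matched_mean_abs_r": conv.matched_mean_abs_r,
            "matched_range": list(conv.matched_range),
            "matched_mean_abs_rho": conv.matched_mean_abs_rho,
            "max_abs_facet_r": list(conv.max_abs_facet_r) if conv.max_abs_facet_r else None,
         },
         "alignment": rep.as_dict()},
        out / "validity.json",
    )
    print(f"alignment: CCA r1={rep.cca_r1:.3f} (flags: {rep.degeneracy_flags or 'none'}), "
          f"RV={rep.rv:.3f}, Procrustes={rep.procrustes_sim:.3f}, "
          f"dcor={rep.dcor:.3f}, Mantel r={rep.mantel_r:.3f} (p={rep.mantel_p:.2e})")
    print(f"wrote {out / 'validity.json'}")


if __name__ == "__main__":
    main()
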