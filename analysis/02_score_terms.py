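"""QC and anchor-based scoring of the simulated term records.

Reads results/cohort/, runs the sanitizer and the embedding-to-score
transformation, and writes the QC report plus raw and standardized
person-by-facet composites (wide and long CSV) under results/scores/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from semlink import io as sio
from semlink.pipeline import build_embedding
from semlink.scoring import build_composites, sanitize_terms, semantic_coherence

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort_dir = ROOT / "cohort"
    out = ROOT / "scores"
    out.mkdir(parents=True, exist_ok=True)

    gt = json.loads((cohort_dir / "ground_truth.json").read_text())
    emb = build_embedding({"backend": "geometric", "params": gt["sim_config"]})
    records = sio.read_term_records(cohort_dir / "terms.jsonl")
    lexicon = sio.read_lexicon(cohort_dir / "lexicon.json")

    flagged, qc = sanitize_terms(records)
    cm = build_composites(flagged, lexicon, emb)
    coh = semantic_coherence(flagged, emb)

    sio.write_json(qc.as_dict(), out / "qc_report.json")
    Z = pd.DataFrame(cm.Z, index=cm.pids, columns=cm.facets)
    X = pd.DataFrame(cm.X, index=cm.pids, columns=cm.facets)
    sio.write_scores_wide(X, out / "dm_composites_raw_wide.csv")
    sio.write_scores_wide(Z, out / "dm_composites_z_wide.csv")
    sio.write_scores_long(Z, out / "dm_composites_z_long.csv")

    vals = [v for v in coh.values() if v is not None]
    print(f"QC: {qc.total_terms} terms, retention {qc.retention_rate:.1%} "
          f"({qc.duplicates_removed} duplicates, {qc.noise_removed} noise), "
          f"{qc.per_person_mean:.2f} +/- {qc.per_person_sd:.2f} per person")
    print(f"scored {len(cm.pids)} persons on {len(cm.facets)} facets; "
          f"mean inter-vector coherence {np.mean(vals):.3f}")


if __name__ == "__main__":
    main()
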