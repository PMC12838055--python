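"""Per-domain reliability of the standardized composites.

For each trait domain: McDonald's omega with a 1000-resample percentile
bootstrap CI, omega hierarchical from a Schmid-Leiman decomposition of the
domain's facet correlation matrix, corrected indicator-total correlations,
and leave-one-out delta-omega. Writes a domain table under
results/reliability/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from semlink import io as sio
from semlink.reliability import domain_reliability

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260103


def main() -> None:
    Z = sio.read_scores_wide(ROOT / "scores" / "dm_composites_z_wide.csv")
    lexicon = sio.read_lexicon(ROOT / "cohort" / "lexicon.json")
    out = ROOT / "reliability"
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for d in lexicon.domains:
        members = [f for f in lexicon.facets_of(d) if f in Z.columns]
        rep = domain_reliability(Z[members].to_numpy(), members, d,
                                 n_boot=1000, seed=SEED)
        r_it = [v for v in rep.item_total.values() if v is not None]
        rows.append({
            "domain": d,
            "k": rep.k,
            "omega": round(rep.omega_total, 3),
            "omega_ci_low": round(rep.ci_low, 3),
            "omega_ci_high": round(rep.ci_high, 3),
            "omega_h": round(rep.omega_h, 3) if rep.omega_h is not None else "",
            "mean_r_it": round(float(np.mean(r_it)), 3),
            "min_r_it": round(float(np.min(r_it)), 3),
            "max_r_it": round(float(np.max(r_it)), 3),
            "max_abs_loo_delta_omega": round(
                max(abs(v) for v in rep.loo_delta_omega.values()), 4),
        })
    table = pd.DataFrame(rows)
    table.to_csv(out / "domain_reliability.csv", index=False)
    print(table.to_string(index=False))
    print(f"\nwrote {out / 'domain_reliability.csv'}")


if __name__ == "__main__":
    main()
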