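"""Generate the synthetic study cohort and write all downstream inputs.

Produces, under results/cohort/: term records (JSONL + long CSV), the two
anchor lexicons (scoring lexicon and comparison-instrument descriptors),
the wide questionnaire facet-score matrix, and the ground-truth facet ->
domain partition with the full generator configuration.
"""

import dataclasses
from pathlib import Path

from semlink import io as sio
from semlink.synthetic import SimConfig, simulate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20260101


def main() -> None:
    cfg = SimConfig(n_persons=176, seed=SEED)
    cohort = simulate_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    sio.write_term_records(cohort.term_records, OUT / "terms.jsonl")
    sio.write_term_records(cohort.term_records, OUT / "terms_long.csv")
    sio.write_lexicon(cohort.anchor_lexicon, OUT / "lexicon.json")
    sio.write_lexicon(cohort.b5_lexicon, OUT / "b5_lexicon.json")
    sio.write_scores_wide(cohort.b5_scores, OUT / "b5_scores_wide.csv",
                          pids=cohort.pids, columns=cfg.facet_names())
    sio.write_json(
        {"ground_truth_partition": cohort.ground_truth_partition,
         "sim_config": dataclasses.asdict(cfg)},
        OUT / "ground_truth.json",
    )
    print(f"simulated {cfg.n_persons} persons x {cfg.terms_per_person} terms "
          f"({len(cohort.term_records)} records), "
          f"{cfg.n_facets} facets in {cfg.n_domains} domains -> {OUT}")


if __name__ == "__main__":
    main()
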