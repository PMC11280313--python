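#!/usr/bin/env python
"""Match each cohort's measured metabolites against the three NP databases.

Writes per-metabolite match tables and per-source/union summaries under
results/matching/.  Run after 01_simulate_cohorts.py.
"""

from pathlib import Path

from oatnp import npdb, stats

DATA = Path("results/data")
OUT = Path("results/matching")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for cohort in ("oat1", "oat3"):
        panel = stats.MetabolomicsPanel.from_tsv(DATA / f"{cohort}_panel.tsv")
        dbs = {
            src: npdb.CompoundDatabase.from_tsv(
                DATA / f"{cohort}_db_{src.lower()}.tsv", source=src
            )
            for src in npdb.SOURCES
        }
        matches = npdb.match_panel(panel.annotations, dbs)
        diff = stats.differential_analysis(panel)
        summary = npdb.summarize_matches(matches, diff)
        npdb.matches_to_frame(matches).to_csv(OUT / f"{cohort}_matches.tsv", sep="\t")
        summary.to_json(OUT / f"{cohort}_match_summary.json")
        print(
            f"{cohort}: total matches per source {summary.total_per_source} "
            f"(union {summary.total_union}); significant "
            f"{summary.significant_per_source} (union {summary.significant_union})"
        )


if __name__ == "__main__":
    main()
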