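#!/usr/bin/env python
"""Per-metabolite differential statistics and volcano categories.

Welch test on log abundances, raw-scale fold changes, volcano lines at
0.9 / 1.1 with p < 0.05.  Writes results/differential/<cohort>_diff.tsv
and prints the category counts and the planted vitamin recoveries.
"""

from pathlib import Path

from oatnp import stats

DATA = Path("results/data")
OUT = Path("results/differential")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for cohort in ("oat1", "oat3"):
        panel = stats.MetabolomicsPanel.from_tsv(DATA / f"{cohort}_panel.tsv")
        diff = stats.differential_analysis(panel)
        diff.to_csv(OUT / f"{cohort}_diff.tsv", sep="\t")
        counts = diff["category"].value_counts()
        print(
            f"{cohort}: {counts.get('elevated', 0)} elevated, "
            f"{counts.get('decreased', 0)} decreased, "
            f"{counts.get('not_significant', 0)} unchanged"
        )
        if cohort == "oat3":
            for mid in ("biotin", "thiamine", "pyridoxal", "pyridoxamine"):
                row = diff.loc[mid]
                print(
                    f"  {mid}: FC {row['fold_change']:.2f}, p {row['p_value']:.2g}, "
                    f"{row['category']}"
                )


if __name__ == "__main__":
    main()
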