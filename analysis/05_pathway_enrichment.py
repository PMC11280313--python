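#!/usr/bin/env python
"""Superpathway and subpathway fold-enrichment rankings per cohort.

Scores every pathway with (k/m)/((n-k)/(N-m)); the subpathway ranking is
restricted to elevated compounds, mirroring how vitamin subpathways stand
out in the knockout serum.  Writes results/enrichment/ tables.
"""

from pathlib import Path

import pandas as pd

from oatnp import enrich, stats

DATA = Path("results/data")
DIFF = Path("results/differential")
OUT = Path("results/enrichment")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for cohort in ("oat1", "oat3"):
        panel = stats.MetabolomicsPanel.from_tsv(DATA / f"{cohort}_panel.tsv")
        diff = pd.read_csv(
            DIFF / f"{cohort}_diff.tsv", sep="\t", index_col="metabolite_id"
        )
        for level, direction in (("superpathway", "all"), ("subpathway", "elevated")):
            cells = enrich.pathway_enrichment(
                diff, panel.annotations, level=level, direction_filter=direction
            )
            table = enrich.enrichment_to_frame(cells)
            table.to_csv(OUT / f"{cohort}_{level}.tsv", sep="\t", index=False)
            shown = [
                f"{c.pathway_id} ({c.score:.2f}, k={c.k}/m={c.m})"
                for c in cells[:3]
                if c.k > 0
            ]
            print(f"{cohort} {level} ({direction}): top {shown}")


if __name__ == "__main__":
    main()
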