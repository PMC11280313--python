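#!/usr/bin/env python
"""Chemical-similarity enrichment of NP-matched compounds per cohort.

Fingerprints every matched NP structure, forms non-overlapping clusters
(chemical-class labels first, Tanimoto attachment for the rest), tests
each cluster's differential p-values against uniformity with the KS test
and writes the impact-plot table (median XLogP vs -log10 KS p) under
results/chemrich/.
"""

from pathlib import Path

import pandas as pd

from oatnp import chemcluster, chemspace, stats, synthdata

DATA = Path("results/data")
DIFF = Path("results/differential")
MATCH = Path("results/matching")
OUT = Path("results/chemrich")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pool = synthdata.load_compound_pool()
    for cohort in ("oat1", "oat3"):
        panel = stats.MetabolomicsPanel.from_tsv(DATA / f"{cohort}_panel.tsv")
        diff = pd.read_csv(DIFF / f"{cohort}_diff.tsv", sep="\t", index_col="metabolite_id")
        matches = pd.read_csv(
            MATCH / f"{cohort}_matches.tsv", sep="\t", index_col="metabolite_id"
        )
        ann = panel.annotations
        np_ids = [
            mid
            for mid in matches.index[matches["any_match"]]
            if isinstance(ann.loc[mid, "smiles"], str) and ann.loc[mid, "smiles"]
        ]
        fps = [
            fp
            for mid in np_ids
            if (fp := chemcluster.fingerprint(mid, ann.loc[mid, "smiles"])) is not None
        ]
        classes = {mid: pool.loc[mid, "chem_class"] for mid in np_ids if mid in pool.index}
        clusters, unclustered = chemcluster.cluster_compounds(fps, class_labels=classes)
        table_smiles = {m: ann.loc[m, "smiles"] for c in clusters for m in c.members}
        desc, _ = chemspace.compute_descriptors(table_smiles)
        summary, coverage = chemcluster.cluster_summary(
            clusters, diff, desc["MolLogP"]
        )
        summary.to_csv(OUT / f"{cohort}_clusters.tsv", sep="\t", index=False)
        sig = summary[summary["significant"]]
        print(
            f"{cohort}: {len(np_ids)} NP structures -> {len(clusters)} clusters "
            f"({len(sig)} significant), {len(unclustered)} unclustered; "
            f"{coverage} of {len(np_ids)} compounds in significant clusters"
        )
        for _, row in sig.head(5).iterrows():
            print(
                f"  {row['cluster']}: n={row['size']}, KS p={row['ks_p']:.2g}, "
                f"median XLogP {row['median_xlogp']:.2f}, key {row['key_compound']}"
            )


if __name__ == "__main__":
    main()
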