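#!/usr/bin/env python
"""Chemical space of OAT1- vs OAT3-dependent natural products.

Computes the pinned RDKit descriptor set for every NP structure altered
in either cohort, prunes correlated properties (|r| >= 0.9), ranks the
survivors by standardized class-mean difference between OAT1- and
OAT3-dependent compounds, and projects the top six properties with the
anchored (FreeViz-style) 2D embedding.  Writes results/chemspace/.
"""

from pathlib import Path

import pandas as pd
from sklearn.metrics import silhouette_score

from oatnp import chemspace, stats

DATA = Path("results/data")
DIFF = Path("results/differential")
OUT = Path("results/chemspace")


def significant_np_smiles(cohort: str) -> dict[str, str]:
    panel = stats.MetabolomicsPanel.from_tsv(DATA / f"{cohort}_panel.tsv")
    diff = pd.read_csv(DIFF / f"{cohort}_diff.tsv", sep="\t", index_col="metabolite_id")
    ann = panel.annotations
    sig = diff.index[diff["significant"]]
    return {
        mid: ann.loc[mid, "smiles"]
        for mid in sig
        if mid in ann.index and isinstance(ann.loc[mid, "smiles"], str) and ann.loc[mid, "smiles"]
    }


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    oat1 = significant_np_smiles("oat1")
    oat3 = significant_np_smiles("oat3")
    # a compound altered in both knockouts is assigned to the cohort where
    # it is observed first (oat1), keeping the two classes disjoint
    smiles = dict(oat3) | dict(oat1)
    labels = pd.Series(
        {cid: ("OAT1" if cid in oat1 else "OAT3") for cid in smiles}
    )
    table, failures = chemspace.compute_descriptors(smiles)
    print(f"{len(table)} structures, {table.shape[1]} descriptors, {len(failures)} parse failures")
    pruned, dropped = chemspace.prune_correlated(table, r_threshold=0.9)
    print(f"pruned {len(dropped)} correlated/constant properties -> {pruned.shape[1]} retained")
    if labels.reindex(pruned.index).nunique() < 2 or labels.value_counts().min() < 2:
        print("not enough compounds per class for a projection; stopping")
        return
    ranked = chemspace.rank_importance(pruned, labels)
    ranked.to_csv(OUT / "property_importance.tsv", sep="\t")
    top = list(ranked.index[:6])
    print(f"top discriminating properties: {top}")
    proj = chemspace.freeviz_project(pruned[top], labels.reindex(pruned.index), seed=0)
    emb = proj.embedding.copy()
    emb.insert(0, "class", labels.reindex(emb.index))
    emb.to_csv(OUT / "projection.tsv", sep="\t")
    pd.DataFrame(proj.anchors, index=top, columns=["x", "y"]).to_csv(
        OUT / "anchors.tsv", sep="\t"
    )
    sil = silhouette_score(proj.embedding.to_numpy(), labels.reindex(emb.index))
    print(f"projection objective {proj.objective:.4f}; class silhouette {sil:.2f}")


if __name__ == "__main__":
    main()
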