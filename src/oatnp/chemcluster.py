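"""ChemRICH-style chemical-similarity enrichment.

Compounds are partitioned into non-overlapping chemical clusters —
primarily by their chemical-class (ontology) label, with label-less
compounds attached by Tanimoto similarity over substructure fingerprints —
and each cluster's differential p-values are tested against Uniform(0,1)
with a one-sample two-sided Kolmogorov–Smirnov test.  The impact-plot
coordinates are median cluster XLogP (x) vs −log10 KS p (y), with the
"key compound" of a cluster being its member with the smallest
differential p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

FP_BITS = 2048


@dataclass(frozen=True)
class Fingerprint:
    compound_id: str
    bits: frozenset
    length: int = FP_BITS

    @property
    def bit_count(self) -> int:
        return len(self.bits)


def fingerprint(compound_id: str, smiles: str, length: int = FP_BITS) -> Fingerprint | None:
    """Substructure-hashed (path-based) binary fingerprint; None on parse failure."""
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None:
        return None
    fp = Chem.RDKFingerprint(mol, fpSize=length)
    return Fingerprint(compound_id, frozenset(fp.GetOnBits()), length)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A∩B| / |A∪B|; two empty bitsets give 0 by convention."""
    if a.length != b.length:
        raise ValueError(f"fingerprint length mismatch: {a.length} vs {b.length}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


@dataclass
class ChemCluster:
    cluster_id: str
    label: str
    members: list[str]
    ks_p: float | None = None
    median_xlogp: float | None = None
    key_compound: str | None = None
    significant: bool | None = None


def cluster_compounds(
    fingerprints: Sequence[Fingerprint],
    class_labels: Mapping[str, str] | None = None,
    similarity_cut: float = 0.5,
    min_size: int = 3,
) -> tuple[list[ChemCluster], list[str]]:
    """Partition compounds into disjoint chemical clusters.

    With class (ontology) labels: labeled compounds group by label;
    unlabeled ones attach to the cluster with the highest mean Tanimoto
    similarity if that mean reaches *similarity_cut*, else stay unclustered.
    Without labels: hierarchical clustering (average linkage on
    1 − Tanimoto) cut at *similarity_cut* distance.  Clusters smaller than
    *min_size* dissolve to unclustered.  Returns (clusters, unclustered ids).
    """
    fps = {f.compound_id: f for f in fingerprints}
    ids = list(fps)
    groups: dict[str, list[str]] = {}
    leftover: list[str] = []

    if class_labels:
        for cid in ids:
            lab = class_labels.get(cid)
            if lab:
                groups.setdefault(lab, []).append(cid)
            else:
                leftover.append(cid)
        for cid in leftover[:]:
            best_lab, best_sim = None, -1.0
            for lab, members in sorted(groups.items()):
                sims = [tanimoto(fps[cid], fps[m]) for m in members]
                s = float(np.mean(sims)) if sims else 0.0
                if s > best_sim:
                    best_lab, best_sim = lab, s
            if best_lab is not None and best_sim >= similarity_cut:
                groups[best_lab].append(cid)
                leftover.remove(cid)
    else:
        if len(ids) >= 2:
            from scipy.cluster.hierarchy import fcluster, linkage

            m = len(ids)
            dvec = np.array(
                [
                    1.0 - tanimoto(fps[ids[i]], fps[ids[j]])
                    for i in range(m)
                    for j in range(i + 1, m)
                ]
            )
            assign = fcluster(
                linkage(dvec, method="average"), t=similarity_cut, criterion="distance"
            )
            for cid, lab in zip(ids, assign):
                groups.setdefault(f"cluster_{lab}", []).append(cid)
        elif ids:
            leftover.extend(ids)

    clusters = []
    for lab in sorted(groups):
        members = groups[lab]
        if len(members) >= min_size:
            clusters.append(ChemCluster(cluster_id=lab, label=lab, members=members))
        else:
            leftover.extend(members)
    return clusters, sorted(leftover)


# ---------------------------------------------------------------------------
# Kolmogorov–Smirnov enrichment
# ---------------------------------------------------------------------------
def ks_uniform_statistic(sample: np.ndarray) -> float:
    """Two-sided one-sample KS D against Uniform(0,1), computed directly."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - x)
    d_minus = np.max(x - (i - 1) / n)
    return float(max(d_plus, d_minus))


def ks_uniform_pvalue(d: float, n: int, exact_max_n: int = 25) -> float:
    """Two-sided p for the KS D-statistic: exact distribution for small
    samples (n <= exact_max_n), Kolmogorov asymptotic otherwise."""
    if n <= exact_max_n:
        p = sps.kstwo.sf(d, n)
    else:
        p = sps.kstwobign.sf(d * np.sqrt(n))
    return float(min(1.0, max(0.0, p)))


def cluster_enrichment(member_pvalues: Sequence[float]) -> float:
    """KS enrichment p for one cluster: member differential p-values vs
    Uniform(0,1).  Small p means the cluster's members are collectively
    shifted toward significance (self-contained test: the rest of the
    compound set is not used)."""
    pv = np.asarray(list(member_pvalues), dtype=float)
    if pv.size == 0:
        raise ValueError("empty cluster")
    d = ks_uniform_statistic(pv)
    return ks_uniform_pvalue(d, pv.size)


def cluster_summary(
    clusters: Sequence[ChemCluster],
    diff: pd.DataFrame,
    xlogp: Mapping[str, float] | pd.Series,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """Per-cluster summary table and the coverage statistic.

    *diff* is indexed by compound id with ``p_value`` (and optionally
    ``fold_change``) columns; *xlogp* maps compound id to the lipophilicity
    descriptor.  Key compound = member with minimum differential p, ties by
    larger |log fold change| then name.  Coverage = number of compounds
    belonging to clusters with KS p < *alpha*.
    """
    import warnings

    if isinstance(xlogp, pd.Series):
        xlogp = xlogp.to_dict()
    rows, coverage = [], 0
    for cl in clusters:
        pv = diff.loc[cl.members, "p_value"]
        cl.ks_p = cluster_enrichment(pv.to_numpy())
        cl.significant = cl.ks_p < alpha
        with_x = [m for m in cl.members if m in xlogp and np.isfinite(xlogp[m])]
        if len(with_x) < len(cl.members):
            warnings.warn(
                f"cluster {cl.label}: {len(cl.members) - len(with_x)} members "
                "lack an XLogP descriptor; excluded from the median"
            )
        cl.median_xlogp = float(np.median([xlogp[m] for m in with_x])) if with_x else np.nan

        def key_rank(m):
            p = float(diff.loc[m, "p_value"])
            lfc = (
                abs(np.log(float(diff.loc[m, "fold_change"])))
                if "fold_change" in diff.columns and diff.loc[m, "fold_change"] > 0
                else 0.0
            )
            return (p, -lfc, m)

        cl.key_compound = min(cl.members, key=key_rank)
        if cl.significant:
            coverage += len(cl.members)
        rows.append(
            {
                "cluster": cl.label,
                "size": len(cl.members),
                "ks_p": cl.ks_p,
                "neg_log10_ks_p": -np.log10(cl.ks_p) if cl.ks_p > 0 else np.inf,
                "median_xlogp": cl.median_xlogp,
                "key_compound": cl.key_compound,
                "significant": cl.significant,
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values("ks_p").reset_index(drop=True)
    return table, coverage
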