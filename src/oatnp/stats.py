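"""Preprocessing and differential statistics for KO-vs-WT abundance panels.

The processing order is fixed: quantile normalization across samples, log
transform, pareto scaling per metabolite.  Significance is assessed on the
log scale with a Welch (unequal-variance) two-sample t-test; fold changes
are reported on the raw scale as mean(KO)/mean(WT), matching how
metabolomics vendors print them.  Volcano categories use a p-value cutoff
(default 0.05) and ratio-scale fold-change lines at 0.9 and 1.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

Category = Literal["elevated", "decreased", "not_significant"]


# ---------------------------------------------------------------------------
# Panel container
# ---------------------------------------------------------------------------
@dataclass
class MetabolomicsPanel:
    """Metabolite x sample abundance matrix with group labels and annotations.

    ``abundance``: DataFrame, rows = metabolite ids, columns = sample ids,
    nonnegative raw-scale values.  ``sample_groups``: Series mapping sample id
    to "KO"/"WT".  ``annotations``: DataFrame indexed by metabolite id with at
    least columns name / superpathway / subpathway (optionally smiles).
    """

    abundance: pd.DataFrame
    sample_groups: pd.Series
    annotations: pd.DataFrame

    def __post_init__(self):
        if (self.abundance.values < 0).any():
            raise ValueError("abundance matrix has negative entries")
        if not self.abundance.columns.equals(self.sample_groups.index):
            self.sample_groups = self.sample_groups.reindex(self.abundance.columns)
        if self.sample_groups.isna().any():
            raise ValueError("every sample needs a group label")
        bad = set(self.sample_groups) - {"KO", "WT"}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        if not self.abundance.index.is_unique:
            raise ValueError("metabolite ids must be unique")

    @property
    def ko_samples(self) -> list[str]:
        return list(self.sample_groups[self.sample_groups == "KO"].index)

    @property
    def wt_samples(self) -> list[str]:
        return list(self.sample_groups[self.sample_groups == "WT"].index)

    # TSV layout: annotation columns first, then one column per sample with
    # header "<sample_id>=<group>".
    def to_tsv(self, path: str | Path) -> None:
        df = self.annotations.join(self.abundance)
        df = df.rename(
            columns={s: f"{s}={g}" for s, g in self.sample_groups.items()}
        )
        df.to_csv(path, sep="\t", index_label="metabolite_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MetabolomicsPanel":
        df = pd.read_csv(path, sep="\t", index_col="metabolite_id")
        sample_cols = [c for c in df.columns if "=" in c]
        groups = pd.Series(
            {c.split("=")[0]: c.split("=")[1] for c in sample_cols}, name="group"
        )
        ab = df[sample_cols].copy()
        ab.columns = [c.split("=")[0] for c in sample_cols]
        ann = df[[c for c in df.columns if "=" not in c]].copy()
        if "smiles" in ann.columns:
            ann["smiles"] = ann["smiles"].fillna("")
        return cls(abundance=ab.astype(float), sample_groups=groups, annotations=ann)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------
def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns (samples) to a shared reference distribution.

    The reference is the vector of cross-sample rank means (mean of the
    sorted columns).  Ties within a column receive the mean of the reference
    values occupying their tied ranks, so after the transform every column's
    sorted multiset equals the reference (up to tie-averaging).
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    if matrix.isna().all(axis=0).any():
        raise ValueError("column with all-missing values")
    X = matrix.to_numpy(dtype=float)
    n, k = X.shape
    order = np.sort(X, axis=0)
    reference = order.mean(axis=1)  # length n, ascending
    out = np.empty_like(X)
    for j in range(k):
        col = X[:, j]
        idx = np.argsort(col, kind="mergesort")
        ranked = np.empty(n)
        ranked[idx] = reference
        # average reference values over tied groups
        vals = col[idx]
        start = 0
        for end in range(1, n + 1):
            if end == n or vals[end] != vals[start]:
                if end - start > 1:
                    ranked[idx[start:end]] = reference[start:end].mean()
                start = end
        out[:, j] = ranked
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log_transform(
    matrix: pd.DataFrame,
    base: float = 2.0,
    offset_policy: Literal["half_min", "none"] = "half_min",
) -> pd.DataFrame:
    """Entrywise logarithm of a nonnegative matrix.

    Zeros are imputed with half the smallest positive value of the matrix
    under the default ``half_min`` policy; with ``none`` a zero raises.
    Negative input always raises.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("log transform requires nonnegative input")
    if (X == 0).any():
        if offset_policy == "none":
            raise ValueError("zeros present and offset_policy='none'")
        pos = X[X > 0]
        if pos.size == 0:
            raise ValueError("all-zero matrix cannot be log transformed")
        X = np.where(X == 0, pos.min() / 2.0, X)
    out = np.log(X) / np.log(base)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def pareto_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pareto-scale each metabolite row: (x - mean) / sqrt(sd).

    Uses the sample (ddof=1) standard deviation; constant rows map to zero.
    A compromise between unit-variance scaling and none: large fold effects
    keep some weight but cannot dominate the multivariate analyses.
    """
    if matrix.shape[1] < 2:
        raise ValueError("pareto scaling needs >=2 samples")
    X = matrix.to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    denom = np.sqrt(sd)
    centered = X - mean
    out = np.divide(centered, denom, out=np.zeros_like(X), where=denom > 0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def preprocess(matrix: pd.DataFrame, log_base: float = 2.0) -> pd.DataFrame:
    """Fixed pipeline: quantile normalize -> log -> pareto scale."""
    return pareto_scale(log_transform(quantile_normalize(matrix), base=log_base))


# ---------------------------------------------------------------------------
# Differential statistics
# ---------------------------------------------------------------------------
def diff_test(ko: np.ndarray, wt: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t-test (two-sided) on log-scale values.

    Returns (t, p).  Degenerate zero-variance-both-groups cases: equal means
    give (0, 1); unequal means give (+/-inf, 0), i.e. certain separation.
    """
    ko = np.asarray(ko, dtype=float)
    wt = np.asarray(wt, dtype=float)
    if ko.size < 2 or wt.size < 2:
        raise ValueError("need >=2 values per group")
    if ko.std(ddof=1) == 0 and wt.std(ddof=1) == 0:
        if ko.mean() == wt.mean():
            return 0.0, 1.0
        return (np.inf if ko.mean() > wt.mean() else -np.inf), 0.0
    t, p = sps.ttest_ind(ko, wt, equal_var=False)
    return float(t), float(p)


def diff_test_matrix(ko: np.ndarray, wt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch test over rows: ko (m x n_ko), wt (m x n_wt)."""
    import warnings

    ko = np.asarray(ko, dtype=float)
    wt = np.asarray(wt, dtype=float)
    with warnings.catch_warnings():
        # zero-variance rows are resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(ko, wt, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # degenerate rows (zero variance in both groups) come back NaN
    degen = np.isnan(t)
    if degen.any():
        dm = ko[degen].mean(axis=1) - wt[degen].mean(axis=1)
        t[degen] = np.where(dm == 0, 0.0, np.where(dm > 0, np.inf, -np.inf))
        p[degen] = np.where(dm == 0, 1.0, 0.0)
    return t, p


def fold_change(ko: np.ndarray, wt: np.ndarray) -> float:
    """Raw-scale fold change: arithmetic mean(KO) / arithmetic mean(WT)."""
    ko = np.asarray(ko, dtype=float)
    wt = np.asarray(wt, dtype=float)
    wt_mean = wt.mean()
    if wt_mean <= 0:
        raise ValueError("WT group mean must be positive for a fold change")
    return float(ko.mean() / wt_mean)


def volcano_classify(
    fc: float, p: float, p_cut: float = 0.05, fc_up: float = 1.1, fc_down: float = 0.9
) -> Category:
    """Volcano category from (fold change, p).

    elevated iff p < p_cut and FC >= fc_up; decreased iff p < p_cut and
    FC <= fc_down; everything else (including significant p with FC between
    the lines) is not_significant.
    """
    if p < p_cut and fc >= fc_up:
        return "elevated"
    if p < p_cut and fc <= fc_down:
        return "decreased"
    return "not_significant"


def differential_analysis(
    panel: MetabolomicsPanel,
    p_cut: float = 0.05,
    fc_up: float = 1.1,
    fc_down: float = 0.9,
    log_base: float = 2.0,
    adjust: Literal["none", "bh"] = "none",
) -> pd.DataFrame:
    """Per-metabolite differential table for a KO-vs-WT panel.

    Significance is computed on log-transformed raw abundances (Welch test);
    fold change on the raw scale.  Multiplicity adjustment is off by default
    (plain p < 0.05 criterion); ``adjust='bh'`` adds Benjamini-Hochberg
    q-values and categorizes on those instead.
    """
    ko = panel.abundance[panel.ko_samples].to_numpy()
    wt = panel.abundance[panel.wt_samples].to_numpy()
    log_ko = log_transform(panel.abundance[panel.ko_samples], base=log_base).to_numpy()
    log_wt = log_transform(panel.abundance[panel.wt_samples], base=log_base).to_numpy()
    t, p = diff_test_matrix(log_ko, log_wt)
    fc = ko.mean(axis=1) / wt.mean(axis=1)
    df = pd.DataFrame(
        {"fold_change": fc, "t": t, "p_value": p}, index=panel.abundance.index
    )
    crit = df["p_value"].to_numpy()
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        crit = multipletests(p, method="fdr_bh")[1]
        df["q_value"] = crit
    df["category"] = [
        volcano_classify(f, q, p_cut=p_cut, fc_up=fc_up, fc_down=fc_down)
        for f, q in zip(fc, crit)
    ]
    df["significant"] = df["category"] != "not_significant"
    return df


# ---------------------------------------------------------------------------
# Heatmap column clustering
# ---------------------------------------------------------------------------
def hierarchical_cluster_columns(
    matrix: pd.DataFrame, method: str = "average", metric: str = "euclidean"
):
    """Agglomerative dendrogram over sample columns.

    Returns (linkage_matrix, leaf_order) where leaf_order lists column names
    in dendrogram order.  Scipy's linkage is deterministic: ties resolve by
    the original column index.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >=2 columns to cluster")
    X = matrix.to_numpy(dtype=float).T
    if np.isnan(X).any():
        raise ValueError("NaN entries in matrix")
    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    order = hierarchy.leaves_list(Z)
    return Z, [matrix.columns[i] for i in order]


def top_split(Z, labels: Sequence[str]) -> tuple[set, set]:
    """Partition leaves by the two branches of the final (top) merge."""
    n = len(labels)
    members: dict[int, set] = {i: {labels[i]} for i in range(n)}
    for i, (a, b, _, _) in enumerate(Z):
        members[n + i] = members[int(a)] | members[int(b)]
    a, b = int(Z[-1, 0]), int(Z[-1, 1])
    return members[a], members[b]
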