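"""Chemical-space characterization of transporter-dependent natural products.

Pipeline: compute ~200 RDKit molecular descriptors per structure from a
pinned manifest, drop highly correlated columns, rank the survivors by how
well they separate the two transporter classes (standardized class-mean
difference), and embed compounds in 2D with a FreeViz-style anchored
projection where each retained property is an anchor on the unit disc and
compounds are placed at the property-weighted sum of anchor positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import data_path


def load_descriptor_manifest() -> list[str]:
    """Names of the pinned descriptor set, in fixed column order."""
    out = []
    for ln in data_path("descriptor_manifest.txt").read_text().splitlines():
        ln = ln.strip()
        if ln and not ln.startswith("#"):
            out.append(ln)
    return out


def compute_descriptors(
    smiles: dict[str, str] | pd.Series,
) -> tuple[pd.DataFrame, list[str]]:
    """Descriptor table (compounds x descriptors) for a {id: SMILES} mapping.

    Columns follow the packaged manifest exactly; unparseable SMILES are
    recorded in the returned failure list and omitted from the table, and
    the run continues.  Deterministic: identical structures (any SMILES
    spelling) give identical rows.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import Descriptors

    RDLogger.DisableLog("rdApp.*")
    manifest = load_descriptor_manifest()
    if isinstance(smiles, pd.Series):
        smiles = smiles.to_dict()
    rows, failures = {}, []
    for cid, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi) if smi else None
        if mol is None:
            failures.append(cid)
            continue
        # renumber atoms canonically: a few descriptors are order-sensitive
        mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
        vals = Descriptors.CalcMolDescriptors(mol)
        rows[cid] = [vals.get(name, np.nan) for name in manifest]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=manifest)
    return table, failures


def prune_correlated(
    table: pd.DataFrame, r_threshold: float = 0.9
) -> tuple[pd.DataFrame, list[str]]:
    """Greedy correlated-column removal.

    Columns are visited in table order (the manifest order, which is the
    documented priority); a column is dropped when its |Pearson r| with any
    already-retained column is >= the threshold.  Constant (and all-NaN)
    columns are dropped first since their correlation is undefined.
    Returns (pruned table, dropped column names).
    """
    if len(table) < 2:
        raise ValueError("need >=2 compounds to estimate correlations")
    dropped = []
    X = table.to_numpy(dtype=float)
    sd = np.nanstd(X, axis=0)
    keep_mask = (sd > 0) & np.isfinite(sd)
    dropped.extend(table.columns[~keep_mask])
    cols = [c for c, k in zip(table.columns, keep_mask) if k]

    retained: list[str] = []
    sub = table[cols]
    corr = sub.corr().abs()
    for c in cols:
        if any(corr.loc[c, r] >= r_threshold for r in retained):
            dropped.append(c)
        else:
            retained.append(c)
    return table[retained], dropped


def rank_importance(table: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Rank properties by absolute standardized class-mean difference.

    d = |mean_A - mean_B| / pooled sd.  Deterministic tie-break by property
    name.  This is the documented surrogate for an unnamed dimensionality
    reduction: it favors exactly the properties a 2-class projection can use.
    """
    labels = labels.reindex(table.index)
    classes = sorted(labels.dropna().unique(), key=str)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    a = table[labels == classes[0]]
    b = table[labels == classes[1]]
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    d = (a.mean() - b.mean()).abs() / pooled.replace(0, np.nan)
    d = d.fillna(0.0)
    out = pd.DataFrame({"importance": d})
    out["_name"] = out.index
    out = out.sort_values(["importance", "_name"], ascending=[False, True])
    return out.drop(columns="_name")


@dataclass
class ProjectionModel:
    """FreeViz-style anchored 2D projection of standardized properties."""

    properties: list[str]
    anchors: np.ndarray          # p x 2, each row norm <= 1
    embedding: pd.DataFrame      # compounds x (x, y)
    objective: float
    objective_trace: list = field(default_factory=list)


def _freeviz_objective(E, same_i, same_j, diff_i, diff_j, eps=1e-3):
    """Force-field objective (to maximize): same-class pairs attract
    (negative squared distance), different-class pairs repel
    (negative inverse-distance potential)."""
    obj = 0.0
    if len(same_i):
        d2 = ((E[same_i] - E[same_j]) ** 2).sum(axis=1)
        obj -= d2.mean()
    if len(diff_i):
        d = np.sqrt(((E[diff_i] - E[diff_j]) ** 2).sum(axis=1))
        obj -= (1.0 / (d + eps)).mean()
    return obj


def freeviz_project(
    table: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> ProjectionModel:
    """Optimize anchor positions so classes separate in the 2D embedding.

    Columns are standardized (z-scored) internally; anchors start on a
    seeded random circle and move by gradient ascent with backtracking line
    search, projected into the unit disc after each step, so the objective
    is non-decreasing.  Stops when the improvement falls below *tol* or at
    *max_iter* iterations.  The objective depends only on pairwise embedded
    distances, hence is invariant to a common rotation of all anchors.
    """
    X = table.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite descriptor values")
    if X.shape[1] < 2:
        raise ValueError("need >=2 properties to project")
    labels = labels.reindex(table.index)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    lab = labels.to_numpy()
    n = len(Z)
    ii, jj = np.triu_indices(n, k=1)
    same = lab[ii] == lab[jj]
    same_i, same_j = ii[same], jj[same]
    diff_i, diff_j = ii[~same], jj[~same]

    rng = np.random.default_rng(seed)
    p = Z.shape[1]
    theta = rng.uniform(0, 2 * np.pi, size=p)
    A = 0.9 * np.column_stack([np.cos(theta), np.sin(theta)])

    def objective(Anch):
        return _freeviz_objective(Z @ Anch, same_i, same_j, diff_i, diff_j)

    def gradient(Anch):
        E = Z @ Anch
        G = np.zeros_like(Anch)
        if len(same_i):
            gvec = E[same_i] - E[same_j]                       # pairs x 2
            dZ = Z[same_i] - Z[same_j]                         # pairs x p
            # d/dA of -mean(d^2) = -2/|S| * sum dZ' gvec
            G -= (2.0 / len(same_i)) * dZ.T @ gvec
        if len(diff_i):
            gvec = E[diff_i] - E[diff_j]
            d = np.sqrt((gvec**2).sum(axis=1))
            dZ = Z[diff_i] - Z[diff_j]
            w = 1.0 / ((d + 1e-3) ** 2 * np.maximum(d, 1e-12))
            # d/dA of -mean(1/(d+eps)) = +1/|D| * sum w * dZ' gvec
            G += (1.0 / len(diff_i)) * dZ.T @ (gvec * w[:, None])
        return G

    def project_disc(Anch):
        norms = np.linalg.norm(Anch, axis=1, keepdims=True)
        scale = np.where(norms > 1.0, norms, 1.0)
        return Anch / scale

    obj = objective(A)
    trace = [obj]
    step = 0.1
    for _ in range(max_iter):
        G = gradient(A)
        improved = False
        s = step
        for _ in range(30):
            cand = project_disc(A + s * G)
            cobj = objective(cand)
            if cobj > obj:
                improved = True
                break
            s /= 2.0
        if not improved:
            break
        gain = cobj - obj
        A, obj = cand, cobj
        trace.append(obj)
        step = min(s * 2.0, 1.0)
        if gain < tol:
            break

    emb = pd.DataFrame(Z @ A, index=table.index, columns=["x", "y"])
    return ProjectionModel(
        properties=list(table.columns),
        anchors=A,
        embedding=emb,
        objective=float(obj),
        objective_trace=trace,
    )
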