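"""Pathway fold-enrichment scoring at superpathway and subpathway levels.

For a pathway holding m of the N annotated metabolites, k of which are
among the n significant ones, the enrichment score is

    score = (k/m) / ((n - k) / (N - m))

i.e. the in-pathway significant fraction over the out-of-pathway one.
Conventions: k = 0 gives 0; n = k (every significant metabolite inside the
pathway) gives +infinity, preserving ranking semantics; m = N (pathway is
the whole universe) is undefined and raises.  No p-value is attached to
the score; an optional hypergeometric tail probability is available as an
extension for users who want one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

Level = Literal["superpathway", "subpathway"]
Direction = Literal["elevated", "decreased", "all"]


def enrichment_score(k: int, m: int, n: int, N: int) -> float:
    """Evaluate the fold-enrichment formula with its boundary conventions."""
    if not (0 <= k <= min(m, n) and m <= N and n <= N and m >= 1):
        raise ValueError(f"invalid counts k={k}, m={m}, n={n}, N={N}")
    if m == N:
        raise ValueError("pathway equals the universe (m = N): score undefined")
    if k == 0:
        return 0.0
    if n == k:
        return math.inf
    return (k / m) / ((n - k) / (N - m))


def enrichment_score_log(k: int, m: int, n: int, N: int) -> float:
    """Log-space recomputation of the same score (independent arithmetic path)."""
    if k == 0:
        return 0.0
    if n == k:
        return math.inf
    return math.exp(
        math.log(k) - math.log(m) - (math.log(n - k) - math.log(N - m))
    )


@dataclass
class EnrichmentCell:
    pathway_id: str
    level: Level
    k: int
    m: int
    n: int
    N: int
    score: float
    direction_filter: Direction = "all"


def _hypergeom_p(k: int, m: int, n: int, N: int) -> float:
    from scipy.stats import hypergeom

    return float(hypergeom.sf(k - 1, N, m, n))


def pathway_enrichment(
    diff: pd.DataFrame,
    annotations: pd.DataFrame,
    level: Level = "superpathway",
    direction_filter: Direction = "all",
    with_hypergeom_p: bool = False,
) -> list[EnrichmentCell]:
    """Score every pathway at the requested annotation level.

    *diff* is indexed by metabolite id with ``category`` (and ``significant``)
    columns; *annotations* carries the pathway column named by *level*.
    ``direction_filter`` restricts which categories count as significant
    (Fig-5-style plots use elevated-only).  Metabolites without a pathway at
    the level are excluded from the universe N with a warning.  The returned
    cells are ranked by score descending, ties broken by k descending then
    pathway name.
    """
    import warnings

    if level not in annotations.columns:
        raise ValueError(f"annotations lack a {level!r} column")
    ann = annotations[level].reindex(diff.index)
    unannotated = ann.isna() | (ann == "")
    if unannotated.any():
        warnings.warn(
            f"{int(unannotated.sum())} metabolites lack a {level}; "
            "excluded from the universe"
        )
    ann = ann[~unannotated]
    d = diff.loc[ann.index]
    if direction_filter == "all":
        sig = d["category"] != "not_significant"
    else:
        sig = d["category"] == direction_filter

    N = len(ann)
    n = int(sig.sum())
    cells = []
    for pw, members in ann.groupby(ann):
        m = len(members)
        if m == N:
            raise ValueError(f"pathway {pw!r} equals the universe; cannot score")
        k = int(sig.loc[members.index].sum())
        cell = EnrichmentCell(
            pathway_id=str(pw),
            level=level,
            k=k,
            m=m,
            n=n,
            N=N,
            score=enrichment_score(k, m, n, N),
            direction_filter=direction_filter,
        )
        if with_hypergeom_p:
            cell.hypergeom_p = _hypergeom_p(k, m, n, N)  # extension attribute
        cells.append(cell)
    cells.sort(key=lambda c: (-c.score, -c.k, c.pathway_id))
    return cells


def enrichment_to_frame(cells: Sequence[EnrichmentCell]) -> pd.DataFrame:
    rows = [
        {
            "pathway": c.pathway_id,
            "level": c.level,
            "k": c.k,
            "m": c.m,
            "n": c.n,
            "N": c.N,
            "score": c.score,
            "direction_filter": c.direction_filter,
        }
        for c in cells
    ]
    return pd.DataFrame(rows)
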