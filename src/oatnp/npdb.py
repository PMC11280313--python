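"""Natural-product database records, name normalization and matching.

Measured metabolite names (Metabolon-style annotations) are matched
against three NP source databases -- NPASS (general NP activity/species),
TCMD (traditional Chinese medicine) and OSADHI (Indian herbal) -- by
normalized name, with an optional structure-key fallback when both sides
carry SMILES.  Matching is deliberately exact (no fuzzy matching by
default): precision over recall, since a false NP call propagates into
every downstream enrichment.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import data_path

SOURCES = ("NPASS", "TCMD", "OSADHI")

_PUNCT_RE = re.compile(r"[^\w]+", flags=re.UNICODE)
_WS_RE = re.compile(r"\s+")


def load_salt_suffixes() -> tuple[str, ...]:
    """Read the packaged, user-editable salt/counter-ion suffix list."""
    lines = data_path("salts.txt").read_text().splitlines()
    out = []
    for ln in lines:
        ln = ln.strip().lower()
        if ln and not ln.startswith("#"):
            out.append(ln)
    # longest first so "potassium salt" wins over a hypothetical "salt"
    return tuple(sorted(out, key=len, reverse=True))


_DEFAULT_SALTS = load_salt_suffixes()


def normalize_name(raw: str, salt_suffixes: Sequence[str] | None = None) -> str:
    """Canonicalize a compound name for matching.

    Lower-cases, applies Unicode NFKC normalization, collapses punctuation
    and whitespace to single spaces, and repeatedly strips trailing
    salt/counter-ion/hydrate suffixes ("hydrochloride", "potassium salt",
    ...).  Idempotent: ``normalize_name(normalize_name(x)) ==
    normalize_name(x)``.

    Raises ``ValueError`` on an empty (or all-punctuation) name.
    """
    if not raw or not raw.strip():
        raise ValueError("compound name must be nonempty")
    salts = _DEFAULT_SALTS if salt_suffixes is None else tuple(
        sorted((s.lower() for s in salt_suffixes), key=len, reverse=True)
    )
    s = unicodedata.normalize("NFKC", raw).lower()
    s = _PUNCT_RE.sub(" ", s)
    s = _WS_RE.sub(" ", s).strip()
    if not s:
        raise ValueError(f"name {raw!r} is empty after normalization")
    changed = True
    while changed:
        changed = False
        for suf in salts:
            if s == suf:
                continue  # never strip a name down to nothing
            if s.endswith(" " + suf):
                s = s[: -len(suf) - 1].rstrip()
                changed = True
    return s


def structure_key(smiles: str) -> str | None:
    """Stereo-insensitive structure identity key (InChIKey first block).

    Returns None when the SMILES does not parse or InChI generation fails.
    """
    from rdkit import Chem
    from rdkit.Chem import inchi
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None:
        return None
    try:
        key = inchi.MolToInchiKey(mol)
    except Exception:
        return None
    return key.split("-")[0] if key else None


@dataclass(frozen=True)
class CompoundRecord:
    """One database entry: primary name, synonyms, optional SMILES, source tag."""

    primary_name: str
    synonyms: tuple[str, ...] = ()
    smiles: str | None = None
    source: str = "NPASS"

    def __post_init__(self):
        if not self.primary_name:
            raise ValueError("primary_name must be nonempty")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")

    @property
    def all_names(self) -> tuple[str, ...]:
        return (self.primary_name, *self.synonyms)


class CompoundDatabase:
    """A single NP source database with normalized-name and structure indices."""

    def __init__(self, records: Iterable[CompoundRecord], source: str):
        if source not in SOURCES:
            raise ValueError(f"unknown source {source!r}")
        self.source = source
        self.records: list[CompoundRecord] = list(records)
        for r in self.records:
            if r.source != source:
                raise ValueError(
                    f"record {r.primary_name!r} tagged {r.source}, expected {source}"
                )
        self._by_name: dict[str, list[int]] = {}
        self._by_struct: dict[str, list[int]] = {}
        for i, rec in enumerate(self.records):
            for nm in rec.all_names:
                self._by_name.setdefault(normalize_name(nm), []).append(i)
            if rec.smiles:
                key = structure_key(rec.smiles)
                if key:
                    self._by_struct.setdefault(key, []).append(i)

    def __len__(self) -> int:
        return len(self.records)

    def lookup_name(self, name: str) -> list[int]:
        return list(self._by_name.get(normalize_name(name), []))

    def lookup_structure(self, smiles: str) -> list[int]:
        key = structure_key(smiles)
        return list(self._by_struct.get(key, [])) if key else []

    # ---- I/O -----------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path, source: str | None = None) -> "CompoundDatabase":
        """Read a database TSV with columns name / synonyms / smiles / source.

        Synonyms are '|'-separated.  If *source* is None every row must carry
        the same source tag.
        """
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        if source is None:
            tags = sorted(set(df["source"]))
            if len(tags) != 1:
                raise ValueError(f"mixed source tags in {path}: {tags}")
            source = tags[0]
        recs = [
            CompoundRecord(
                primary_name=row["name"],
                synonyms=tuple(s for s in row.get("synonyms", "").split("|") if s),
                smiles=row.get("smiles") or None,
                source=source,
            )
            for _, row in df.iterrows()
        ]
        return cls(recs, source)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "name": r.primary_name,
                "synonyms": "|".join(r.synonyms),
                "smiles": r.smiles or "",
                "source": r.source,
            }
            for r in self.records
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class MatchResult:
    """Per-metabolite match outcome against the three sources."""

    metabolite_id: str
    matched: dict[str, bool] = field(default_factory=dict)
    matched_record_ids: dict[str, list[int]] = field(default_factory=dict)
    matched_by: dict[str, str] = field(default_factory=dict)  # "name" | "structure"

    @property
    def any_match(self) -> bool:
        return any(self.matched.values())


def match_compound(
    metabolite_id: str,
    name: str,
    databases: Mapping[str, CompoundDatabase],
    smiles: str | None = None,
) -> MatchResult:
    """Match one measured metabolite against each source database.

    Name equality (after :func:`normalize_name` on both sides, including
    synonyms) is the primary route; when both the metabolite and database
    records carry SMILES, stereo-insensitive structure-key equality is a
    fallback.  A name match takes precedence for reporting.
    """
    res = MatchResult(metabolite_id=metabolite_id)
    for source, db in databases.items():
        ids = db.lookup_name(name)
        how = "name"
        if not ids and smiles:
            ids = db.lookup_structure(smiles)
            how = "structure"
        res.matched[source] = bool(ids)
        res.matched_record_ids[source] = ids
        if ids:
            res.matched_by[source] = how
    return res


def match_panel(
    annotations: pd.DataFrame,
    databases: Mapping[str, CompoundDatabase],
    smiles_col: str | None = "smiles",
) -> list[MatchResult]:
    """Match every metabolite of an annotation table (index = metabolite id)."""
    out = []
    has_smiles = smiles_col is not None and smiles_col in annotations.columns
    for mid, row in annotations.iterrows():
        smi = row[smiles_col] if has_smiles and row[smiles_col] else None
        out.append(match_compound(str(mid), row["name"], databases, smiles=smi))
    return out


@dataclass
class MatchSummary:
    total_per_source: dict[str, int]
    total_union: int
    significant_per_source: dict[str, int]
    significant_union: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def summarize_matches(
    matches: Sequence[MatchResult], diff: pd.DataFrame
) -> MatchSummary:
    """Count matches per source and their union, overall and significant-only.

    *diff* is the differential-results table indexed by metabolite id with a
    boolean ``significant`` column (or a ``category`` column where anything
    other than ``not_significant`` counts).  Ids must cover all matches.
    """
    if "significant" in diff.columns:
        sig = diff["significant"].astype(bool)
    elif "category" in diff.columns:
        sig = diff["category"] != "not_significant"
    else:
        raise ValueError("diff table needs a 'significant' or 'category' column")
    missing = [m.metabolite_id for m in matches if m.metabolite_id not in sig.index]
    if missing:
        raise ValueError(f"metabolites missing from diff table: {missing[:5]}...")

    total = {s: 0 for s in SOURCES}
    sig_cnt = {s: 0 for s in SOURCES}
    union, sig_union = 0, 0
    for m in matches:
        is_sig = bool(sig.loc[m.metabolite_id])
        if m.any_match:
            union += 1
            sig_union += is_sig
        for s in SOURCES:
            if m.matched.get(s, False):
                total[s] += 1
                sig_cnt[s] += is_sig
    return MatchSummary(
        total_per_source=total,
        total_union=union,
        significant_per_source=sig_cnt,
        significant_union=sig_union,
    )


def matches_to_frame(matches: Sequence[MatchResult]) -> pd.DataFrame:
    """Flatten match results to a table (one row per metabolite)."""
    rows = []
    for m in matches:
        row = {"metabolite_id": m.metabolite_id}
        for s in SOURCES:
            row[f"matched_{s.lower()}"] = m.matched.get(s, False)
        row["any_match"] = m.any_match
        rows.append(row)
    return pd.DataFrame(rows).set_index("metabolite_id")
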