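"""Synthetic metabolomics panels, NP databases and assay plates with
planted ground truth.

The generator emulates the study design it is meant to exercise: serum
metabolomics of transporter-knockout vs wildtype mice (groups of 4 vs 4 or
6 vs 6), Metabolon-style panels of ~1000 annotated metabolites with
super-/subpathway labels, log-normal abundance noise around per-metabolite
baselines spanning three orders of magnitude, planted fold changes on
named metabolites (e.g. a biotin-like analyte at 4.55), three NP source
databases with controlled overlap, and 96-well binding/uptake plates with
planted binder shifts and IC50s.  One global integer seed drives
independent per-purpose substreams so each stage can be tested alone.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import data_path
from .invitro import dilution_series, four_pl
from .npdb import SOURCES, CompoundDatabase, CompoundRecord
from .stats import MetabolomicsPanel

# substream tags
_STREAM_METABOLOME = 0
_STREAM_DATABASES = 1
_STREAM_PLATES = 2

# Planted effects mirroring the reported vitamin elevations in the
# knockout serum: biotin 4.55, thiamine 2.06, pyridoxal 1.86,
# pyridoxamine 2.32 (KO/WT raw-scale mean ratios).
DEFAULT_PLANTED_EFFECTS = (
    ("biotin", 4.55),
    ("thiamine", 2.06),
    ("pyridoxal", 1.86),
    ("pyridoxamine", 2.32),
)

_SUPERPATHWAYS = (
    ("Amino Acid", 0.30),
    ("Lipid", 0.33),
    ("Xenobiotics", 0.10),
    ("Carbohydrate", 0.08),
    ("Nucleotide", 0.07),
    ("Peptide", 0.05),
    ("Energy", 0.04),
    ("Cofactors and Vitamins", 0.03),
)

_CLASS_PATHWAYS = {
    "vitamin": ("Cofactors and Vitamins", "Vitamin Metabolism"),
    "indole": ("Amino Acid", "Tryptophan Metabolism"),
    "colic acid": ("Lipid", "Primary Bile Acid Metabolism"),
    "pregnenedione": ("Lipid", "Pregnenolone Steroids"),
    "carboxylic acid": ("Energy", "TCA Cycle"),
}
_VITAMIN_SUBPATHWAYS = {
    "biotin": "Biotin Metabolism",
    "thiamine": "Thiamine Metabolism",
    "pyridoxal": "Vitamin B6 Metabolism",
    "pyridoxamine": "Vitamin B6 Metabolism",
    "pyridoxine": "Vitamin B6 Metabolism",
    "niacin": "Nicotinate and Nicotinamide Metabolism",
    "pantothenic acid": "Pantothenate and CoA Metabolism",
    "ascorbic acid": "Ascorbate and Aldarate Metabolism",
    "folic acid": "Folate Metabolism",
    "riboflavin": "Riboflavin Metabolism",
}


def load_compound_pool() -> pd.DataFrame:
    """The packaged pool of named NP structures (name/synonyms/smiles/class)."""
    df = pd.read_csv(data_path("compounds.tsv"), sep="\t", dtype=str).fillna("")
    return df.set_index("name", drop=False)


# ---------------------------------------------------------------------------
# Configuration & ground truth
# ---------------------------------------------------------------------------
@dataclass
class DbOverlapSpec:
    """How compounds distribute over the three NP sources.

    ``membership_prob``: per-source probability that an NP compound belongs
    to that source.  ``overlap``: fraction in [0, 1] interpolating between
    fully shared membership (1.0: one Bernoulli draw decides all three
    sources at once, so the sets coincide) and exclusive membership (0.0:
    a compound joins at most one source, so pairwise intersections are
    empty).  ``significant_subset_counts`` optionally pins the exact
    source-subset assignment of the planted significant compounds (keys are
    frozensets of source names), used to reproduce printed match counts.
    """

    membership_prob: dict = field(
        default_factory=lambda: {s: 0.8 for s in SOURCES}
    )
    overlap: float = 0.6
    significant_subset_counts: dict | None = None

    def validate(self) -> None:
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError(f"overlap must be in [0,1], got {self.overlap}")
        for s in SOURCES:
            p = self.membership_prob.get(s)
            if p is None or not 0.0 <= p <= 1.0:
                raise ValueError(f"membership_prob[{s}] must be in [0,1], got {p}")


def plant_overlap_counts(sizes: Sequence[int], union: int) -> dict:
    """Deterministic source-subset counts realizing per-source sizes and union.

    Solves for nonnegative counts over the seven nonempty subsets of the
    three sources: maximize the triple overlap, place the remaining excess
    in pairwise overlaps (round-robin, capacity-checked), singles take the
    rest.  Raises when the constraints are unreachable.
    """
    s1, s2, s3 = sizes
    total = s1 + s2 + s3
    if union > total or union < max(sizes) or min(sizes) < 0:
        raise ValueError(f"unreachable overlap: sizes={sizes}, union={union}")
    excess = total - union  # = pairs + 2 * triple
    triple = min(min(sizes), excess // 2)
    pair_total = excess - 2 * triple
    pairs = {frozenset(p): 0 for p in itertools.combinations(SOURCES, 2)}
    caps = dict(zip(SOURCES, sizes))
    remaining = {s: caps[s] - triple for s in SOURCES}
    if any(v < 0 for v in remaining.values()):
        raise ValueError(f"unreachable overlap: sizes={sizes}, union={union}")
    pair_keys = sorted(pairs, key=lambda fs: sorted(fs))
    left = pair_total
    while left > 0:
        placed = False
        for key in pair_keys:
            if left == 0:
                break
            if all(remaining[s] - 1 >= 0 for s in key):
                pairs[key] += 1
                for s in key:
                    remaining[s] -= 1
                left -= 1
                placed = True
        if not placed:
            raise ValueError(f"unreachable overlap: sizes={sizes}, union={union}")
    counts = {frozenset(SOURCES): triple}
    counts.update(pairs)
    for s in SOURCES:
        counts[frozenset([s])] = remaining[s]
    assert sum(counts.values()) == union
    for s, size in zip(SOURCES, sizes):
        assert sum(c for fs, c in counts.items() if s in fs) == size
    return counts


@dataclass
class SynthConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the larger of the two knockout studies: 6 KO vs 6 WT
    mice, a 1000-metabolite panel, log-normal noise with sigma 0.3 on the
    natural-log scale, and the four reported vitamin fold changes planted
    on their named metabolites.
    """

    n_ko: int = 6
    n_wt: int = 6
    n_metabolites: int = 1000
    planted_effects: tuple = DEFAULT_PLANTED_EFFECTS
    noise_sigma: float = 0.3
    db_overlap_spec: DbOverlapSpec = field(default_factory=DbOverlapSpec)
    seed: int = 0
    missing_rate: float = 0.0
    median_scale: bool = False
    np_panel_compounds: tuple | None = None  # None -> whole pool
    pathway_scheme: Mapping[str, tuple] | None = None  # metabolite -> (super, sub)

    def validate(self) -> None:
        if self.n_ko < 2 or self.n_wt < 2:
            raise ValueError("need n_ko >= 2 and n_wt >= 2")
        if self.n_metabolites < 1:
            raise ValueError("n_metabolites must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0,1)")
        for mid, fc in self.planted_effects:
            if fc <= 0:
                raise ValueError(f"planted fold change for {mid} must be > 0")
        self.db_overlap_spec.validate()

    def substream(self, purpose: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), purpose])


@dataclass
class GroundTruth:
    """What was planted: consumed by tests, never by the pipeline."""

    true_fold_change: dict = field(default_factory=dict)
    true_differential: set = field(default_factory=set)
    db_membership: dict = field(default_factory=dict)  # name -> set of sources
    binder_set: set = field(default_factory=set)
    ic50: dict = field(default_factory=dict)  # compound -> molar

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_fold_change": self.true_fold_change,
            "true_differential": sorted(self.true_differential),
            "db_membership": {k: sorted(v) for k, v in self.db_membership.items()},
            "binder_set": sorted(self.binder_set),
            "ic50": self.ic50,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Metabolome
# ---------------------------------------------------------------------------
def _default_pathways(name: str, chem_class: str) -> tuple[str, str]:
    if chem_class == "vitamin":
        return ("Cofactors and Vitamins", _VITAMIN_SUBPATHWAYS.get(name, "Vitamin Metabolism"))
    if chem_class in _CLASS_PATHWAYS:
        return _CLASS_PATHWAYS[chem_class]
    return ("Xenobiotics", "Food Component/Plant")


def generate_metabolome(config: SynthConfig) -> tuple[MetabolomicsPanel, GroundTruth]:
    """Simulate the KO-vs-WT serum panel.

    abundance(sample, metabolite) = baseline_m x FC_m^[group==KO] x exp(eps),
    eps ~ Normal(0, noise_sigma^2).  Baselines are log-uniform over three
    orders of magnitude (1e2..1e5 arbitrary counts).  The packaged compound
    pool provides named, annotated NP metabolites (with SMILES); the rest
    of the panel is filler with pathway annotations drawn from a fixed
    superpathway frequency table.  Deterministic under a fixed seed.
    """
    config.validate()
    rng = config.substream(_STREAM_METABOLOME)
    pool = load_compound_pool()
    if config.np_panel_compounds is not None:
        np_names = list(config.np_panel_compounds)
    else:
        # small panels take a prefix of the pool
        np_names = list(pool.index)[: config.n_metabolites]
    unknown = [n for n in np_names if n not in pool.index]
    if unknown:
        raise ValueError(f"np_panel_compounds not in pool: {unknown[:5]}")
    if len(np_names) > config.n_metabolites:
        raise ValueError("n_metabolites smaller than the named NP compound list")

    n_filler = config.n_metabolites - len(np_names)
    ids = np_names + [f"metabolite_{i:04d}" for i in range(n_filler)]

    # annotations
    rows = []
    sp_names = [s for s, _ in _SUPERPATHWAYS]
    sp_probs = np.array([w for _, w in _SUPERPATHWAYS])
    sp_probs = sp_probs / sp_probs.sum()
    filler_sp = rng.choice(len(sp_names), size=n_filler, p=sp_probs)
    for mid in np_names:
        cls = pool.loc[mid, "chem_class"]
        sp, sub = _default_pathways(mid, cls)
        if config.pathway_scheme and mid in config.pathway_scheme:
            sp, sub = config.pathway_scheme[mid]
        rows.append(
            {
                "metabolite_id": mid,
                "name": mid,
                "superpathway": sp,
                "subpathway": sub,
                "smiles": pool.loc[mid, "smiles"],
            }
        )
    for i in range(n_filler):
        mid = f"metabolite_{i:04d}"
        sp = sp_names[filler_sp[i]]
        sub = f"{sp} subpathway {filler_sp[i] % 3 + 1}"
        if config.pathway_scheme and mid in config.pathway_scheme:
            sp, sub = config.pathway_scheme[mid]
        rows.append(
            {
                "metabolite_id": mid,
                "name": mid,
                "superpathway": sp,
                "subpathway": sub,
                "smiles": "",
            }
        )
    ann = pd.DataFrame(rows).set_index("metabolite_id")

    fc = pd.Series(1.0, index=ids)
    for mid, val in config.planted_effects:
        if mid not in fc.index:
            raise ValueError(f"planted effect on unknown metabolite {mid!r}")
        fc[mid] = float(val)

    baselines = 10.0 ** rng.uniform(2.0, 5.0, size=len(ids))
    samples = [f"KO{i+1}" for i in range(config.n_ko)] + [
        f"WT{i+1}" for i in range(config.n_wt)
    ]
    groups = pd.Series(
        ["KO"] * config.n_ko + ["WT"] * config.n_wt, index=samples, name="group"
    )
    is_ko = (groups == "KO").to_numpy()

    noise = (
        rng.normal(0.0, config.noise_sigma, size=(len(ids), len(samples)))
        if config.noise_sigma > 0
        else np.zeros((len(ids), len(samples)))
    )
    X = (
        baselines[:, None]
        * np.where(is_ko[None, :], fc.to_numpy()[:, None], 1.0)
        * np.exp(noise)
    )
    if config.missing_rate > 0:
        mask = rng.random(X.shape) < config.missing_rate
        X = np.where(mask, 0.0, X)  # below-detection truncation
    if config.median_scale:
        X = X / np.median(X, axis=0, keepdims=True)

    panel = MetabolomicsPanel(
        abundance=pd.DataFrame(
            X, index=pd.Index(ids, name="metabolite_id"), columns=samples
        ),
        sample_groups=groups,
        annotations=ann,
    )
    truth = GroundTruth(
        true_fold_change={m: float(v) for m, v in fc.items()},
        true_differential={m for m, v in fc.items() if v != 1.0},
    )
    return panel, truth


# ---------------------------------------------------------------------------
# NP databases
# ---------------------------------------------------------------------------
def generate_np_databases(
    config: SynthConfig, truth: GroundTruth
) -> dict[str, CompoundDatabase]:
    """Three synthetic source databases over the packaged compound pool.

    Source membership per compound follows ``config.db_overlap_spec``.  When
    ``significant_subset_counts`` is set, the planted-differential compounds
    are assigned to source subsets exactly per those counts (deterministic,
    pool order), pinning the significant-match bookkeeping; other compounds
    are sampled.  Membership is recorded into ``truth.db_membership``.
    """
    config.validate()
    spec = config.db_overlap_spec
    rng = config.substream(_STREAM_DATABASES)
    pool = load_compound_pool()
    names = (
        list(config.np_panel_compounds)
        if config.np_panel_compounds is not None
        else list(pool.index)
    )

    membership: dict[str, set] = {}
    pinned: set[str] = set()
    if spec.significant_subset_counts is not None:
        sig_names = [n for n in names if n in truth.true_differential]
        need = sum(spec.significant_subset_counts.values())
        if need > len(sig_names):
            raise ValueError(
                f"subset counts need {need} significant compounds, "
                f"only {len(sig_names)} planted"
            )
        it = iter(sig_names)
        for subset, count in sorted(
            spec.significant_subset_counts.items(), key=lambda kv: sorted(kv[0])
        ):
            for _ in range(count):
                nm = next(it)
                membership[nm] = set(subset)
                pinned.add(nm)
        for nm in it:  # leftover planted-significant compounds: no membership
            membership[nm] = set()
            pinned.add(nm)

    for nm in names:
        if nm in pinned:
            continue
        if rng.random() < spec.overlap:
            # shared draw: one coin decides all three sources
            p = float(np.mean([spec.membership_prob[s] for s in SOURCES]))
            membership[nm] = set(SOURCES) if rng.random() < p else set()
        else:
            # exclusive draw: at most one source
            probs = np.array([spec.membership_prob[s] for s in SOURCES])
            total = probs.sum()
            if total == 0:
                membership[nm] = set()
                continue
            stay = min(1.0, total / len(SOURCES))
            if rng.random() < stay:
                pick = rng.choice(len(SOURCES), p=probs / total)
                membership[nm] = {SOURCES[pick]}
            else:
                membership[nm] = set()

    truth.db_membership = membership
    dbs = {}
    for s in SOURCES:
        recs = []
        for nm in names:
            if s in membership[nm]:
                row = pool.loc[nm]
                syns = tuple(x for x in row["synonyms"].split("|") if x)
                if not syns:
                    raise AssertionError(f"pool compound {nm} lacks a synonym")
                recs.append(
                    CompoundRecord(
                        primary_name=nm, synonyms=syns, smiles=row["smiles"], source=s
                    )
                )
        dbs[s] = CompoundDatabase(recs, s)
    return dbs


def matched_counts_scenario(
    sizes: Sequence[int],
    union: int,
    seed: int = 0,
    extra_significant: int = 4,
    fc: float = 3.0,
    n_metabolites: int = 1000,
) -> SynthConfig:
    """Config planting exact per-source significant-match counts.

    Plants ``union + extra_significant`` differential compounds (noise-free,
    fold change *fc*) and pins the source-subset assignment of *union* of
    them to realize the requested per-source significant-match sizes; the
    extras match no database.  Noise-free generation makes the downstream
    Welch test deterministic (planted rows p=0, others p=1), so the
    summary counts reproduce exactly.
    """
    counts = plant_overlap_counts(sizes, union)
    pool = load_compound_pool()
    sig_names = list(pool.index)[: union + extra_significant]
    if len(sig_names) < union + extra_significant:
        raise ValueError("compound pool too small for requested counts")
    return SynthConfig(
        seed=seed,
        noise_sigma=0.0,
        n_metabolites=n_metabolites,
        planted_effects=tuple((n, fc) for n in sig_names),
        db_overlap_spec=DbOverlapSpec(significant_subset_counts=counts),
    )


# ---------------------------------------------------------------------------
# In vitro plates
# ---------------------------------------------------------------------------
def generate_binding_plate(
    config: SynthConfig,
    planted_shifts: Mapping[str, float],
    f0: float = 1000.0,
    noise_sd: float = 0.0,
    n_control_wells: int = 8,
    n_replicates: int = 2,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Bead-binding competition plate with planted fluorescence shifts.

    Control wells read F0 (+ noise); each test compound's wells read
    F0 x (1 + shift) + noise.  Ground-truth binders are the compounds with
    shift <= -0.05.
    """
    if f0 <= 0:
        raise ValueError("control fluorescence F0 must be positive")
    rng = config.substream(_STREAM_PLATES)
    rows = []
    well = 0
    for _ in range(n_control_wells):
        rows.append(
            {
                "well": f"W{well:03d}",
                "compound": "control",
                "fluorescence": f0 + rng.normal(0, noise_sd) if noise_sd > 0 else f0,
            }
        )
        well += 1
    for cmpd, shift in planted_shifts.items():
        for _ in range(n_replicates):
            val = f0 * (1.0 + shift)
            if noise_sd > 0:
                val += rng.normal(0, noise_sd)
            rows.append({"well": f"W{well:03d}", "compound": cmpd, "fluorescence": val})
            well += 1
    truth = GroundTruth(
        binder_set={c for c, s in planted_shifts.items() if s <= -0.05}
    )
    return pd.DataFrame(rows), truth


def generate_inhibition_series(
    config: SynthConfig,
    planted_ic50: Mapping[str, float],
    hill: float = 1.0,
    top_dose: float = 2e-3,
    n_points: int = 10,
    dilution_factor: float = 2.0,
    noise_pct_sd: float = 0.0,
    bottom: float = 0.0,
    top: float = 100.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Percent-inhibition dose-response series from a 4PL curve per compound.

    Default geometry matches the screen: 2 mM top dose serially diluted
    2-fold across 10 points.  Returns a long table (compound, concentration,
    inhibition_pct) plus ground truth IC50s.
    """
    rng = config.substream(_STREAM_PLATES)
    conc = dilution_series(top=top_dose, n_points=n_points, factor=dilution_factor)
    rows = []
    for cmpd, ic50 in planted_ic50.items():
        if ic50 <= 0:
            raise ValueError(f"planted IC50 for {cmpd} must be positive")
        resp = four_pl(conc, bottom, top, ic50, hill)
        if noise_pct_sd > 0:
            resp = resp + rng.normal(0, noise_pct_sd, size=resp.shape)
        for c, r in zip(conc, resp):
            rows.append({"compound": cmpd, "concentration": c, "inhibition_pct": r})
    truth = GroundTruth(ic50=dict(planted_ic50))
    return pd.DataFrame(rows), truth
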