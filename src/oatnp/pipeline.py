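"""Configuration-driven end-to-end pipeline.

Runs the full workflow on synthetic (or pre-generated, file-based) inputs:
synthesize cohort -> NP database matching -> differential statistics ->
PLS-DA -> pathway enrichment -> chemical space -> chemical-similarity
clusters -> in vitro assays (optional), writing every stage's table under
the output directory plus a machine-readable JSON run report that echoes
every threshold used.  Identical config + seed give identical reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, chemcluster, chemspace, enrich, invitro, npdb, plsda, stats
from .synthdata import (
    DbOverlapSpec,
    SynthConfig,
    generate_binding_plate,
    generate_inhibition_series,
    generate_metabolome,
    generate_np_databases,
)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Validated pipeline configuration with every stage's parameters."""

    outdir: str = "results/pipeline"
    seed: int = 0
    # data source: synthetic spec (default) or a panel TSV + database TSVs
    panel_path: str | None = None
    database_paths: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)  # kwargs for SynthConfig
    # stage parameters
    p_cut: float = 0.05
    fc_up: float = 1.1
    fc_down: float = 0.9
    log_base: float = 2.0
    adjust: str = "none"
    n_components: int = 2
    enrichment_level: str = "superpathway"
    enrichment_direction: str = "all"
    r_threshold: float = 0.9
    top_properties: int = 6
    similarity_cut: float = 0.5
    cluster_min_size: int = 3
    cluster_alpha: float = 0.05
    binder_threshold: float = -0.05
    # optional in vitro inputs
    binding_shifts: dict | None = None
    inhibition_ic50: dict | None = None


_FIELD_TYPES = {
    "outdir": str,
    "seed": int,
    "panel_path": (str, type(None)),
    "database_paths": dict,
    "synth": dict,
    "p_cut": float,
    "fc_up": float,
    "fc_down": float,
    "log_base": float,
    "adjust": str,
    "n_components": int,
    "enrichment_level": str,
    "enrichment_direction": str,
    "r_threshold": float,
    "top_properties": int,
    "similarity_cut": float,
    "cluster_min_size": int,
    "cluster_alpha": float,
    "binder_threshold": float,
    "binding_shifts": (dict, type(None)),
    "inhibition_ic50": (dict, type(None)),
}


def validate_config(source) -> tuple[RunConfig | None, list[str]]:
    """Normalize a config mapping (or YAML/JSON file path) into a RunConfig.

    Returns (config, errors); on any error the config is None and the error
    list enumerates every offending key with its problem.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            return None, [f"config file not found: {path}"]
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text) or {}
        else:
            raw = json.loads(text)
    else:
        raw = dict(source)

    errors = []
    unknown = sorted(set(raw) - set(_FIELD_TYPES))
    for k in unknown:
        errors.append(f"unknown config key: {k!r}")
    cleaned = {}
    for k, v in raw.items():
        if k in unknown:
            continue
        want = _FIELD_TYPES[k]
        if want is float and isinstance(v, int) and not isinstance(v, bool):
            v = float(v)
        if want is int and isinstance(v, bool):
            errors.append(f"{k}: expected int, got bool")
            continue
        if not isinstance(v, want):
            name = want.__name__ if isinstance(want, type) else "/".join(
                t.__name__ for t in want
            )
            errors.append(f"{k}: expected {name}, got {type(v).__name__} ({v!r})")
            continue
        cleaned[k] = v
    if cleaned.get("panel_path") and cleaned.get("synth"):
        errors.append("panel_path and synth are mutually exclusive panel sources")
    if errors:
        return None, errors
    return RunConfig(**cleaned), []


def _write_tsv(df: pd.DataFrame, path: Path, provenance: str, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# oatnp {__version__} | {provenance}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return (and write) the JSON run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "oatnp_version": __version__,
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("binding_shifts", "inhibition_ic50")
        },
        "stages": {},
    }

    # --- stage: data -------------------------------------------------------
    if config.panel_path:
        panel = stats.MetabolomicsPanel.from_tsv(config.panel_path)
        databases = {
            src: npdb.CompoundDatabase.from_tsv(p, source=src)
            for src, p in config.database_paths.items()
        }
    else:
        synth_kwargs = dict(config.synth)
        if "db_overlap_spec" in synth_kwargs and isinstance(
            synth_kwargs["db_overlap_spec"], dict
        ):
            synth_kwargs["db_overlap_spec"] = DbOverlapSpec(
                **synth_kwargs["db_overlap_spec"]
            )
        if "planted_effects" in synth_kwargs:
            synth_kwargs["planted_effects"] = tuple(
                (m, float(f)) for m, f in synth_kwargs["planted_effects"]
            )
        synth_cfg = SynthConfig(seed=config.seed, **synth_kwargs)
        panel, truth = generate_metabolome(synth_cfg)
        databases = generate_np_databases(synth_cfg, truth)
        panel.to_tsv(out / "panel.tsv")
        for src, db in databases.items():
            db.to_tsv(out / f"db_{src.lower()}.tsv")
        truth.to_json(out / "ground_truth.json")
    report["stages"]["data"] = {
        "n_metabolites": int(panel.abundance.shape[0]),
        "n_samples": int(panel.abundance.shape[1]),
        "db_sizes": {s: len(db) for s, db in databases.items()},
    }

    # --- stage: differential stats ----------------------------------------
    diff = stats.differential_analysis(
        panel,
        p_cut=config.p_cut,
        fc_up=config.fc_up,
        fc_down=config.fc_down,
        log_base=config.log_base,
        adjust=config.adjust,  # type: ignore[arg-type]
    )
    _write_tsv(diff, out / "differential.tsv", "differential abundance (Welch, raw-scale FC)")
    counts = diff["category"].value_counts().to_dict()
    report["stages"]["stats"] = {
        "volcano_counts": {
            k: int(counts.get(k, 0))
            for k in ("elevated", "decreased", "not_significant")
        }
    }

    # --- stage: matching ---------------------------------------------------
    matches = npdb.match_panel(panel.annotations, databases)
    summary = npdb.summarize_matches(matches, diff)
    _write_tsv(npdb.matches_to_frame(matches), out / "matches.tsv", "NP database matches")
    summary.to_json(out / "match_summary.json")
    report["stages"]["npdb"] = {
        "total_per_source": summary.total_per_source,
        "total_union": summary.total_union,
        "significant_per_source": summary.significant_per_source,
        "significant_union": summary.significant_union,
    }

    # --- stage: PLS-DA -----------------------------------------------------
    processed = stats.preprocess(panel.abundance, log_base=config.log_base)
    X = processed.to_numpy().T  # samples x features
    labels = list(panel.sample_groups)
    model = plsda.fit_plsda(X, labels, n_components=config.n_components)
    scores = pd.DataFrame(
        model.x_scores[:, :2],
        index=panel.abundance.columns,
        columns=["comp1", "comp2"],
    )
    scores.insert(0, "group", labels)
    _write_tsv(scores, out / "plsda_scores.tsv", "PLS-DA scores (components 1-2)")
    ve = plsda.variance_explained(model)
    (out / "plsda_variance.json").write_text(json.dumps(ve, indent=2))
    report["stages"]["plsda"] = ve

    # --- stage: heatmap column clustering ----------------------------------
    Z, leaf_order = stats.hierarchical_cluster_columns(processed)
    report["stages"]["heatmap"] = {"column_order": [str(c) for c in leaf_order]}

    # --- stage: enrichment --------------------------------------------------
    cells = enrich.pathway_enrichment(
        diff,
        panel.annotations,
        level=config.enrichment_level,  # type: ignore[arg-type]
        direction_filter=config.enrichment_direction,  # type: ignore[arg-type]
    )
    etable = enrich.enrichment_to_frame(cells)
    _write_tsv(etable, out / "enrichment.tsv", "pathway fold enrichment", index=False)
    report["stages"]["enrich"] = {
        "top": [
            {"pathway": c.pathway_id, "score": c.score, "k": c.k, "m": c.m}
            for c in cells[:5]
        ]
    }

    # --- stage: chemical space ---------------------------------------------
    ann = panel.annotations
    np_ids = [m.metabolite_id for m in matches if m.any_match]
    smiles = {
        mid: ann.loc[mid, "smiles"]
        for mid in np_ids
        if "smiles" in ann.columns and ann.loc[mid, "smiles"]
    }
    report["stages"]["chemspace"] = {}
    if len(smiles) >= 4:
        table, failures = chemspace.compute_descriptors(smiles)
        pruned, dropped = chemspace.prune_correlated(table, r_threshold=config.r_threshold)
        # two-class labels for the projection: elevated vs rest among NP matches
        lab = pd.Series(
            np.where(diff.loc[pruned.index, "category"] == "elevated", "elevated", "other"),
            index=pruned.index,
        )
        stage: dict = {
            "n_structures": len(table),
            "n_failures": len(failures),
            "n_descriptors_retained": int(pruned.shape[1]),
        }
        if lab.nunique() == 2 and lab.value_counts().min() >= 2:
            ranked = chemspace.rank_importance(pruned, lab)
            top = list(ranked.index[: config.top_properties])
            proj = chemspace.freeviz_project(pruned[top], lab, seed=config.seed)
            emb = proj.embedding.copy()
            emb.insert(0, "label", lab)
            _write_tsv(emb, out / "chemspace_projection.tsv", "anchored 2D projection")
            _write_tsv(
                ranked.head(25), out / "chemspace_importance.tsv", "property importance"
            )
            stage["top_properties"] = top
            stage["projection_objective"] = proj.objective
        report["stages"]["chemspace"] = stage

    # --- stage: chemical-similarity clusters --------------------------------
    report["stages"]["chemcluster"] = {}
    if len(smiles) >= config.cluster_min_size:
        fps = [
            fp
            for mid, smi in smiles.items()
            if (fp := chemcluster.fingerprint(mid, smi)) is not None
        ]
        pool_classes = {}
        from .synthdata import load_compound_pool

        pool = load_compound_pool()
        for mid in smiles:
            if mid in pool.index:
                pool_classes[mid] = pool.loc[mid, "chem_class"]
        clusters, unclustered = chemcluster.cluster_compounds(
            fps,
            class_labels=pool_classes or None,
            similarity_cut=config.similarity_cut,
            min_size=config.cluster_min_size,
        )
        if clusters:
            xlogp = {}
            tbl, _ = chemspace.compute_descriptors(
                {mid: smiles[mid] for c in clusters for mid in c.members}
            )
            xlogp = tbl["MolLogP"].to_dict()
            ctable, coverage = chemcluster.cluster_summary(
                clusters, diff, xlogp, alpha=config.cluster_alpha
            )
            _write_tsv(
                ctable, out / "chem_clusters.tsv", "chemical-similarity clusters",
                index=False,
            )
            report["stages"]["chemcluster"] = {
                "n_clusters": len(clusters),
                "n_significant": int(ctable["significant"].sum()),
                "coverage": int(coverage),
                "n_unclustered": len(unclustered),
            }

    # --- stage: in vitro (optional) ----------------------------------------
    if config.binding_shifts or config.inhibition_ic50:
        iv: dict = {}
        synth_cfg = SynthConfig(seed=config.seed)
        if config.binding_shifts:
            plate, _ = generate_binding_plate(synth_cfg, config.binding_shifts)
            calls = invitro.analyze_binding_plate(plate)
            _write_tsv(calls, out / "binding_calls.tsv", "bead-binding binder calls")
            iv["n_binders"] = int(calls["is_binder"].sum())
            iv["n_compounds"] = int(len(calls))
        if config.inhibition_ic50:
            series, _ = generate_inhibition_series(
                synth_cfg, {k: float(v) for k, v in config.inhibition_ic50.items()}
            )
            fits = []
            for cmpd, grp in series.groupby("compound"):
                g = grp.sort_values("concentration", ascending=False)
                fit = invitro.fit_inhibition_curve(
                    g["concentration"].to_numpy(),
                    g["inhibition_pct"].to_numpy(),
                    compound_id=str(cmpd),
                )
                fits.append(
                    {
                        "compound": cmpd,
                        "ic50": fit.ic50,
                        "hill": fit.hill,
                        "converged": fit.converged,
                    }
                )
            fdf = pd.DataFrame(fits).set_index("compound").sort_index()
            _write_tsv(fdf, out / "inhibition_fits.tsv", "4PL dose-response fits")
            iv["n_converged"] = int(fdf["converged"].sum())
        report["stages"]["invitro"] = iv

    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
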