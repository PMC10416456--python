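"""End-to-end orchestration: config, run_all, demo mode, recovery metrics."""

from __future__ import annotations

import json
import shutil
import warnings
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, chromatin, dynamics, quantify, regulators as reg_mod
from .io_formats import (
    FormatError,
    read_gene_annotation,
    read_gene_table,
    read_matrix,
    read_peaks,
    read_stage_counts,
    write_results,
)
from .synthetic import SimConfig, SimStudy, simulate_study

ALL_STAGES = ("quantify", "dynamics", "regulators", "chromatin")


@dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run.

    Numeric defaults are the study's canonical constants: input-count filter
    5, modified threshold 1.5, differential fold change 1.2 at alpha 0.05,
    m6A groups split at 1.5/4, accessibility groups 10/80/10, correlation
    extremes 5% with a +-0.1 not-correlated band.
    """

    peaks: str | None = None
    annotation: str | None = None
    ip_counts: str | None = None
    input_counts: str | None = None
    libsizes: str | None = None
    expression: str | None = None
    accessibility: str | None = None
    tf_binding: str | None = None
    sequences: str | None = None
    out_dir: str = "m6adyn_results"

    min_input: int = 5
    mod_threshold: float = 1.5
    fc_threshold: float = 1.2
    alpha: float = 0.05
    m6a_group_low: float = 1.5
    m6a_group_high: float = 4.0
    access_tail_frac: float = 0.10
    extreme_frac: float = 0.05
    not_cor_band: float = 0.1
    min_expr: float = 1.0
    k: int = 8
    seed: int = 0
    target_regulators: tuple[str, ...] = ("METTL14", "RBM15", "ALKBH5")

    def validate(self) -> "RunConfig":
        if self.fc_threshold <= 1.0:
            raise ValueError("fc_threshold must exceed 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("mod_threshold", "m6a_group_low", "m6a_group_high", "min_expr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.m6a_group_low >= self.m6a_group_high:
            raise ValueError("m6a_group_low must be below m6a_group_high")
        for name in ("access_tail_frac", "extreme_frac", "not_cor_band"):
            v = getattr(self, name)
            if not 0.0 < v < 0.5:
                raise ValueError(f"{name}={v} must lie in (0, 0.5)")
        if self.min_input < 0:
            raise ValueError("min_input must be non-negative")
        if self.k < 1:
            raise ValueError("k must be at least 1")
        return self


def validate_config(path: str | Path) -> RunConfig:
    """Load a YAML run config, applying defaults and rejecting bad fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    if "target_regulators" in raw:
        raw["target_regulators"] = tuple(raw["target_regulators"])
    return RunConfig(**raw).validate()


def _read_annotation(path: str):
    if str(path).endswith((".tsv", ".txt")):
        return read_gene_table(path)
    return read_gene_annotation(path)


def _read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_all(
    config: RunConfig, stages: tuple[str, ...] = ALL_STAGES
) -> dict[str, pd.DataFrame]:
    """Execute the pipeline stages and write one TSV per result table.

    Later stages depend on quantification, which always runs.  A missing
    accessibility matrix skips the chromatin stage with a warning.  On
    failure, partially written outputs are removed.
    """
    config.validate()
    for name in ("peaks", "annotation", "ip_counts", "input_counts", "libsizes", "expression"):
        if getattr(config, name) is None:
            raise ValueError(f"required input path {name!r} not set")
    out_dir = Path(config.out_dir)
    tables: dict[str, pd.DataFrame] = {}
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "versions": {
            "m6adyn": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
    }
    try:
        annotation = _read_annotation(config.annotation)
        peaks = read_peaks(config.peaks, annotation)
        counts = read_stage_counts(config.ip_counts, config.input_counts, config.libsizes)
        missing = counts.peak_ids.difference(peaks.peak_ids)
        if len(missing):
            raise FormatError(
                f"count matrix peaks absent from the peak catalog: {list(missing[:5])}"
            )
        expression = read_matrix(config.expression)

        # ---- quantify ----
        kept, removed = quantify.filter_peaks(counts, min_input=config.min_input)
        manifest["filter"] = {
            "peaks_in": int(len(counts.peak_ids)),
            "peaks_retained": int(len(kept.peak_ids)),
            "peaks_removed": int(len(removed)),
        }
        ip_cpm, input_cpm = quantify.normalize(kept)
        prof = quantify.aggregate_levels(ip_cpm, input_cpm, peaks)
        tables["peak_levels"] = prof.peak_level
        tables["gene_levels"] = prof.gene_level
        tables["region_levels"] = prof.region_level
        tables["sample_levels"] = prof.sample_level.to_frame()
        tables["gene_counts"] = quantify.count_m6a_genes(
            prof.gene_level, expression, config.mod_threshold, config.min_expr
        )
        tables["metagene"] = quantify.metagene_density(peaks, annotation)
        if config.sequences:
            drach = quantify.scan_drach(_read_fasta(config.sequences))
            tables["drach"] = drach
            tables["drach_summary"] = quantify.drach_summary(drach).to_frame()

        # ---- dynamics ----
        if any(s in stages for s in ("dynamics", "regulators", "chromatin")):
            dyn = dynamics.analyze_peaks(
                kept,
                prof.peak_level,
                fc_threshold=config.fc_threshold,
                alpha=config.alpha,
                mod_threshold=config.mod_threshold,
                k=min(config.k, len(prof.peak_level)),
                seed=config.seed,
            )
            pk = pd.DataFrame(
                {
                    "change_count": dyn.change_count,
                    "origin": dyn.origin,
                    "cluster": dyn.clusters,
                }
            )
            for name, df in dyn.differentials.items():
                pk[f"fc_{name}"] = df.fold_change
                pk[f"p_{name}"] = df.p
                pk[f"p_bh_{name}"] = df.p_bh
                pk[f"diff_{name}"] = df.is_differential
            for s in prof.peak_level.columns:
                pk[f"modified_{s}"] = dyn.modified[s]
            tables["peak_dynamics"] = pk
            tables["class_fractions"] = dyn.class_fractions.to_frame()
            tables["dynamic_genes"] = dynamics.dynamic_genes(
                prof.gene_level, config.fc_threshold
            ).to_frame()
            tables["dispersion"] = dynamics.dispersion_scores(expression).to_frame()

        # ---- regulators ----
        target_union: list[str] = []
        if any(s in stages for s in ("regulators", "chromatin")):
            regset = reg_mod.RegulatorSet.from_expression(expression)
            present = [r for r in config.target_regulators if r in regset.df.index]
            corrs = reg_mod.correlate_regulators(
                prof.gene_level, expression, regset, names=present
            )
            corr_cols = {}
            traj_rows = []
            for name in present:
                res = reg_mod.identify_targets(
                    name,
                    regset.role(name),
                    corrs[name]["m6a"],
                    corrs[name]["expression"],
                    extreme_frac=config.extreme_frac,
                    not_cor_band=config.not_cor_band,
                )
                t = pd.DataFrame(
                    {
                        "m6a_r": res.m6a_classes.r.loc[res.targets],
                        "expr_r": res.expr_classes.r.loc[res.targets],
                    }
                )
                t.index.name = "gene_id"
                t.attrs["p"] = res.p
                tables[f"targets_{name}"] = t
                manifest.setdefault("targets", {})[name] = {
                    "n": int(len(res.targets)),
                    "overlap_p": res.p,
                }
                target_union.extend(res.targets)
                corr_cols[f"{name}_m6a_r"] = corrs[name]["m6a"]
                corr_cols[f"{name}_m6a_label"] = res.m6a_classes.label.reindex(
                    corrs[name]["m6a"].index
                )
                corr_cols[f"{name}_expr_r"] = corrs[name]["expression"]
                corr_cols[f"{name}_expr_label"] = res.expr_classes.label.reindex(
                    corrs[name]["expression"].index
                )
                if name in prof.gene_level.index:
                    tr = reg_mod.regulator_m6a_vs_expression(
                        prof.gene_level.loc[name], expression.loc[name]
                    )
                    tr.insert(0, "regulator", name)
                    traj_rows.append(tr.reset_index())
            tables["regulator_correlations"] = pd.DataFrame(corr_cols)
            if traj_rows:
                tables["regulator_trajectories"] = pd.concat(
                    traj_rows, ignore_index=True
                )
            target_union = sorted(set(target_union))
            if target_union:
                mat, top = reg_mod.reader_association(
                    expression.loc[[g for g in target_union if g in expression.index]],
                    regset,
                )
                mat["top_reader"] = top
                tables["reader_association"] = mat

        # ---- chromatin ----
        if "chromatin" in stages:
            if config.accessibility is None:
                warnings.warn("no accessibility matrix; chromatin stage skipped")
            else:
                access = read_matrix(config.accessibility)
                comp = chromatin.compare_target_accessibility(
                    pd.Index(target_union), access, seed=config.seed
                )
                if comp is not None:
                    tables["target_accessibility"] = comp
                med, pv = chromatin.m6a_by_accessibility_group(
                    access,
                    prof.gene_level,
                    low_frac=config.access_tail_frac,
                    high_frac=config.access_tail_frac,
                )
                tables["accessibility_group_medians"] = med
                tables["accessibility_group_pvalues"] = pv
                gene_mod = dynamics.call_modified(prof.gene_level, config.mod_threshold)
                gene_mod = gene_mod.reindex(
                    gene_mod.index.union(access.index), fill_value=False
                ).loc[access.index.intersection(gene_mod.index.union(access.index))]
                try:
                    tables["modified_vs_unmodified"] = (
                        chromatin.accessibility_of_modified_vs_unmodified(
                            gene_mod, access
                        )
                    )
                except ValueError as e:
                    warnings.warn(f"modified-vs-unmodified comparison skipped: {e}")
                labels = chromatin.co_dynamics_categories(
                    prof.gene_level, access, config.fc_threshold
                )
                co = labels.per_transition.add_prefix("category_")
                co.insert(0, "category", labels.category)
                co["degenerate"] = labels.degenerate
                tables["co_dynamics"] = co
                tables["category_overlaps"] = chromatin.category_overlap(
                    labels.per_transition
                )
                try:
                    binned, _ = chromatin.pcc_bins(prof.gene_level, access)
                    tables["pcc_bins"] = binned
                except ValueError as e:
                    warnings.warn(f"pcc_bins skipped: {e}")
                if config.tf_binding is not None:
                    tables["tf_binding_groups"] = chromatin.tf_binding_by_m6a_group(
                        read_matrix(config.tf_binding),
                        prof.gene_level,
                        bounds=(config.m6a_group_low, config.m6a_group_high),
                    )

        written = write_results(tables, out_dir)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    except Exception:
        if out_dir.exists():
            shutil.rmtree(out_dir, ignore_errors=True)
        raise
    return tables


# ---------------------------------------------------------------------------
# demo mode and recovery metrics
# ---------------------------------------------------------------------------


def demo(
    out_dir: str | Path, seed: int = 42, sim_config: SimConfig | None = None
) -> tuple[SimStudy, dict[str, pd.DataFrame], dict]:
    """Simulate a study, run the full analysis on it, and score the recovery
    of every planted structure.  Requires no external data."""
    out = Path(out_dir)
    cfg = sim_config if sim_config is not None else SimConfig(seed=seed)
    study = simulate_study(cfg)
    study_dir = out / "study"
    paths = study.write(study_dir)
    run_cfg = RunConfig(
        peaks=str(paths["peaks"]),
        annotation=str(paths["annotation"]),
        ip_counts=str(paths["ip_counts"]),
        input_counts=str(paths["input_counts"]),
        libsizes=str(paths["libsizes"]),
        expression=str(paths["expression"]),
        accessibility=str(paths["accessibility"]),
        tf_binding=str(paths["tf_binding"]),
        sequences=str(paths["sequences"]),
        out_dir=str(out / "results"),
        seed=seed,
    )
    tables = run_all(run_cfg)
    recovery = evaluate_recovery(study, tables)
    with open(out / "results" / "recovery.json", "w") as fh:
        json.dump(recovery, fh, indent=2, sort_keys=True)
    return study, tables, recovery


def evaluate_recovery(study: SimStudy, tables: dict[str, pd.DataFrame]) -> dict:
    """Compare pipeline outputs against the planted truth."""
    truth = study.truth
    rec: dict = {}

    pk = tables["peak_dynamics"]
    common = pk.index.intersection(truth.peak_labels.index)
    t = truth.peak_labels.loc[common]
    rec["n_peaks_scored"] = int(len(common))
    rec["change_class_accuracy"] = float(
        (pk.loc[common, "change_count"] == t.change_count).mean()
    )
    rec["origin_accuracy"] = float((pk.loc[common, "origin"] == t.origin).mean())
    frac = pk.loc[common, "change_count"].value_counts(normalize=True)
    for i in range(4):
        rec[f"frac_change_{i}"] = float(frac.get(i, 0.0))
    orig = pk.loc[common, "origin"].value_counts(normalize=True)
    rec["frac_origin_d0"] = float(orig.get("D0", 0.0))

    lv = tables["peak_levels"]
    mu = truth.peak_mu.loc[lv.index]
    rel = ((lv - mu).abs() / mu).to_numpy()
    rec["median_level_rel_error"] = float(np.median(rel))
    in_range = (mu.to_numpy() >= 0.5) & (mu.to_numpy() <= 8.0)
    rec["frac_levels_within_5pct"] = float((rel[in_range] < 0.05).mean())

    for reg, genes in truth.target_map.items():
        key = f"targets_{reg}"
        if key not in tables:
            continue
        pred = set(tables[key].index)
        true = set(genes)
        tp = len(pred & true)
        prec = tp / len(pred) if pred else 0.0
        recall = tp / len(true) if true else 0.0
        f1 = 2 * prec * recall / (prec + recall) if prec + recall else 0.0
        rec[f"target_precision_{reg}"] = prec
        rec[f"target_recall_{reg}"] = recall
        rec[f"target_f1_{reg}"] = f1
        rec[f"n_targets_{reg}"] = len(pred)

    if "co_dynamics" in tables:
        co = tables["co_dynamics"]
        truth_cat = truth.gene_labels.category.dropna()
        common_g = co.index.intersection(truth_cat.index)
        rec["category_accuracy"] = float(
            (co.loc[common_g, "category"] == truth_cat.loc[common_g]).mean()
        )
        rec["n_genes_categorized"] = int(len(common_g))

    gc = tables["gene_counts"]
    rec["frac_genes_modified_d0"] = float(
        gc.loc["D0", "n_modified"] / gc.loc["D0", "n_expressed"]
    )
    return rec
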