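"""End-to-end orchestration: simulate/load -> filter -> normalize -> test -> select -> cluster.

A single :class:`RunConfig` (YAML-loadable, unknown keys rejected) drives the
whole chain; every stage writes its TSV artifacts and the final
:class:`RunReport` only contains numbers recomputable from those artifacts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core_io import (
    StudyDesign,
    read_design,
    read_intensity_table,
    write_design,
    write_intensity_table,
)
from .diffexpr import all_pairwise_contrasts
from .normalize import normalize_pipeline
from .setlogic import SelectionRule, any_vs_all_partition, quadrant_select, strict_group_select
from .simulate import SimConfig, simulate_dataset, truth_contrast_table
from .structure import hcluster_cut, heatmap_export, pca_samples, zscore_rows

__all__ = ["RunConfig", "ConfigError", "RunReport", "run_all", "proteome_coverage"]


class ConfigError(ValueError):
    """Run configuration failed schema validation."""


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    Either ``sim`` (synthetic-data parameters) or ``inputs`` (paths to batch
    intensity TSVs plus a design TSV) must be provided.
    """

    outdir: str = "run_out"
    seed: int = 0
    sim: dict | None = None
    inputs: dict | None = None
    apply_irs: bool = True
    apply_tmm: bool = True
    logfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    k_clusters: int = 9
    focal_condition: str = "Py-only"
    quadrant_donor: tuple = (("H2/Fu", "La/Fu"), ("H2/ClOHPA", "La/ClOHPA"))
    quadrant_acceptor: tuple = (("H2/ClOHPA", "H2/Fu"), ("La/ClOHPA", "La/Fu"))
    strict_groups: tuple = (("H2/ClOHPA", "La/ClOHPA"), ("Py-only", "Py/Fu", "La/Fu", "H2/Fu"))
    database_size: int | None = None
    write_figures: bool = False

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'sim' or 'inputs' must be given")
        if self.inputs is not None:
            missing = {"batches", "design"} - set(self.inputs)
            if missing:
                raise ConfigError(f"'inputs' lacks keys {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s) {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunReport:
    """Headline numbers of one run; every field is recomputable from the TSVs."""

    version: str
    seed: int
    counts: dict
    normalization: dict
    selection_sizes: dict
    cluster_sizes: dict
    pca_explained_percent: list
    qc: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def proteome_coverage(quantified: int, database_size: int):
    """Percentage of the theoretical proteome quantified.

    Returns ``(headline, exact)``: the exact value 100*quantified/database
    and its nearest-integer headline figure.
    """
    if database_size <= 0:
        raise ValueError("database size must be > 0")
    if not 0 <= quantified <= database_size:
        raise ValueError("quantified count must lie in [0, database size]")
    exact = 100.0 * quantified / database_size
    return int(round(exact)), exact


def _bridge_agreement(norm) -> float:
    """Max relative disagreement of per-protein bridge means across batches."""
    design = norm.design
    linear = 2.0 ** norm.data
    means = pd.DataFrame({
        b: linear[[f"{b}.{c}" for c in design.channels(b, bridges="only")]].mean(axis=1)
        for b in design.batches
    })
    rel = (means.max(axis=1) - means.min(axis=1)) / means.mean(axis=1)
    return float(rel.max())


def run_all(config: RunConfig):
    """Execute every stage, write artifacts under ``config.outdir``.

    Returns ``(report, artifacts)`` where ``artifacts`` holds the in-memory
    stage outputs (normalized matrix, contrast table, selections, clustering,
    truth when simulated) for downstream use.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"tmtbridge {__version__}"

    if config.sim is not None:
        sim_cfg = SimConfig(**{**config.sim, "seed": config.seed})
        matrices, design, truth = simulate_dataset(sim_cfg)
        for m in matrices:
            write_intensity_table(m, outdir / f"intensities_{m.batch_id}.tsv", stamp)
        write_design(design, outdir / "design.tsv", stamp)
        truth_contrast_table(truth, sim_cfg.conditions).to_csv(
            outdir / "truth_logfc.tsv", sep="\t", float_format="%.6g")
        truth.archetype.to_csv(outdir / "truth_archetypes.tsv", sep="\t")
        database_size = config.database_size or sim_cfg.n_proteins
    else:
        design = read_design(config.inputs["design"])
        matrices = [
            read_intensity_table(p, b)
            for b, p in sorted(config.inputs["batches"].items())
        ]
        truth = None
        detected_union = set().union(*(set(m.protein_ids) for m in matrices))
        database_size = config.database_size or len(detected_union)

    norm, filt_report = normalize_pipeline(
        matrices, design, apply_irs=config.apply_irs, apply_tmm=config.apply_tmm)
    norm.data.to_csv(outdir / "normalized_log2.tsv", sep="\t", float_format="%.10g")
    for rec in norm.applied_steps:
        fname = outdir / f"factors_{rec.step.lower()}.tsv"
        if isinstance(rec.factors, pd.Series):
            rec.factors.rename("factor").to_csv(fname, sep="\t", float_format="%.10g")
        else:
            rec.factors.to_csv(fname, sep="\t", float_format="%.10g")

    headline, exact = proteome_coverage(filt_report["quantified"], database_size)
    # post-IRS agreement is the meaningful QC number (TMM afterwards rescales
    # whole channels and so re-perturbs bridge means slightly by design)
    irs_recs = [r for r in norm.applied_steps if r.step == "IRS"]
    if irs_recs:
        bridge_dev = irs_recs[0].extra["bridge_max_rel_disagreement"]
    else:
        bridge_dev = _bridge_agreement(norm)

    contrasts = all_pairwise_contrasts(norm, design)
    contrasts.to_csv(outdir / "contrasts.tsv", sep="\t", index=False, float_format="%.6g")

    rule = SelectionRule(config.logfc_threshold, config.fdr_threshold, "up")
    both_rule = SelectionRule(config.logfc_threshold, config.fdr_threshold, "both")
    others = [c for c in design.conditions if c != config.focal_condition]
    fermentation = any_vs_all_partition(contrasts, config.focal_condition, others, rule)
    donor = quadrant_select(contrasts, *config.quadrant_donor, rule)
    acceptor = quadrant_select(contrasts, *config.quadrant_acceptor, rule)
    strict = strict_group_select(contrasts, *config.strict_groups, rule)

    selections = {
        "focal_vs_any_union": fermentation.union,
        "focal_vs_all_intersection": fermentation.intersection,
        "donor_both_up": donor.both_up,
        "donor_both_down": donor.both_down,
        "acceptor_both_up": acceptor.both_up,
        "acceptor_both_down": acceptor.both_down,
        "strict_group_up": strict,
    }
    sel_dir = outdir / "sets"
    sel_dir.mkdir(exist_ok=True)
    for name, sel in selections.items():
        pd.Series(sorted(sel.members), name="protein").to_csv(
            sel_dir / f"{name}.tsv", sep="\t", index=False)

    # regulated subset: passes the two-sided rule in >= 1 of the 15 contrasts
    passing = contrasts[(contrasts["logFC"].abs() > both_rule.logfc_threshold)
                        & (contrasts["fdr"] < both_rule.fdr_threshold)]
    regulated = sorted(set(passing["protein"]))
    pd.Series(regulated, name="protein").to_csv(
        sel_dir / "regulated_any_contrast.tsv", sep="\t", index=False)

    zmat, constant_rows = zscore_rows(norm.data, design, over="samples")
    cluster_sizes: dict = {}
    assignment = None
    k = min(config.k_clusters, len(regulated))
    if len(regulated) >= 2 and k >= 1:
        assignment = hcluster_cut(zmat.loc[regulated], k=k)
        assignment.labels.to_csv(outdir / "clusters.tsv", sep="\t")
        heatmap_export(
            zmat.loc[regulated], assignment, design,
            outdir / "heatmap_matrix.tsv",
            fig_path=(outdir / "heatmap.png") if config.write_figures else None,
        )
        cluster_sizes = {int(i): int(s) for i, s in assignment.sizes().items()}

    scores, frac = pca_samples(norm)
    scores.iloc[:, :2].assign().to_csv(outdir / "pca_scores.tsv", sep="\t",
                                       float_format="%.6g")

    report = RunReport(
        version=__version__,
        seed=config.seed,
        counts={
            "detected": filt_report["detected"],
            "quantified": filt_report["quantified"],
            "channels": filt_report["channels"],
            "database_size": database_size,
            "coverage_percent": headline,
            "coverage_percent_exact": exact,
            "regulated_any_contrast": len(regulated),
            "constant_rows": len(constant_rows),
        },
        normalization={
            "steps": [rec.step for rec in norm.applied_steps],
            "bridge_mean_max_rel_disagreement": bridge_dev,
            "bridge_qc_pass": bool(bridge_dev < 1e-9) if config.apply_irs else None,
        },
        selection_sizes={name: len(sel) for name, sel in selections.items()},
        cluster_sizes=cluster_sizes,
        pca_explained_percent=[round(100 * float(f), 4) for f in frac[:5]],
        qc={"irs_applied": config.apply_irs, "tmm_applied": config.apply_tmm},
    )
    if not config.apply_irs:
        report.qc["bridge_mean_max_rel_disagreement"] = bridge_dev
        report.qc["bridge_qc_warning"] = bool(bridge_dev > 1e-6)
    report.to_json(outdir / "report.json")

    artifacts = {
        "design": design,
        "norm": norm,
        "contrasts": contrasts,
        "selections": selections,
        "regulated": regulated,
        "assignment": assignment,
        "pca_scores": scores,
        "pca_fractions": frac,
        "truth": truth,
    }
    return report, artifacts
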