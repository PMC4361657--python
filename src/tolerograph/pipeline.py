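"""End-to-end pipeline driver and the immune-subset comparison utility.

The pipeline sequences the full analysis on one dataset: SAM two-group
differential expression (TOL vs non-TOL), SAM of each patient group vs
healthy controls, the three-group confound filter, the per-agent
immunosuppressant confounding check, gene-set enrichment (GSEA and
over-representation), and the cross-validated classifier. Every stage's
cardinalities, parameters and seed are written to a JSON manifest so a
run is fully reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from . import io as tio
from .classify import CvConfig, cross_validate, feature_stability
from .core import (CTRL, NONTOL, TOL, DataError, DirectionalGeneList,
                   ExpressionMatrix, Sample)
from .enrich import GeneSetCollection, gsea_test, ora_test
from .listops import agent_confound_check, derive_final_lists
from .sam import SamConfig, run_sam_groups

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    matrix_path: str
    annotation_path: str
    gene_sets_path: Optional[str] = None
    out_dir: str = "tolerograph_out"
    sam: SamConfig = field(default_factory=SamConfig)
    cv: CvConfig = field(default_factory=CvConfig)
    gsea_n_perm: int = 200
    gsea_perm_type: str = "phenotype"
    ora_fdr_alpha: float = 0.05
    seed: int = 0


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def compare_subsets(table, group_col: str = "group", alpha: float = 0.01
                    ) -> Dict[str, dict]:
    """Two-sided rank-sum comparison of immune-subset fractions between
    the two patient groups, at a pre-defined significance level.

    ``table`` is a DataFrame with one row per sample, a group column
    (TOL / NONTOL), and one numeric column per subset (percent of PBMC).
    Subsets with missing values are dropped with a warning; each group
    needs >= 2 values per subset.
    """
    results: Dict[str, dict] = {}
    for col in table.columns:
        if col == group_col:
            continue
        sub = table[[group_col, col]]
        if sub[col].isna().any():
            logger.warning("subset %s has missing values; rows dropped", col)
            sub = sub.dropna()
        a = sub.loc[sub[group_col] == TOL, col].to_numpy(dtype=float)
        b = sub.loc[sub[group_col] == NONTOL, col].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            logger.warning("subset %s skipped: too few samples", col)
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        results[col] = {"statistic": float(res.statistic),
                        "p": float(res.pvalue),
                        "significant": bool(res.pvalue < alpha)}
    return results


def _seeded(cfg, offset: int):
    """Copy a config dataclass with a derived stage seed."""
    import dataclasses
    return dataclasses.replace(cfg, seed=(cfg.seed + offset) % (2 ** 31))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis and write results + JSON manifest.

    Any stage failure raises StageError naming the stage; outputs
    produced before the failure remain on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed,
                      "parameters": {
                          "sam": asdict(cfg.sam), "cv": asdict(cfg.cv),
                          "gsea_n_perm": cfg.gsea_n_perm,
                          "gsea_perm_type": cfg.gsea_perm_type,
                          "ora_fdr_alpha": cfg.ora_fdr_alpha}}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                _write_manifest(manifest, out, partial=True)
                raise StageError(name, exc) from exc
        return deco

    x = stage("load")(lambda: tio.read_gct(cfg.matrix_path))
    samples = stage("load")(lambda: tio.read_annotation(cfg.annotation_path))

    sam_cfg = _seeded(cfg.sam, 0)
    two = stage("sam_two_group")(
        lambda: run_sam_groups(x, samples, TOL, NONTOL, sam_cfg))
    tol_c = stage("sam_tol_vs_ctrl")(
        lambda: run_sam_groups(x, samples, TOL, CTRL, _seeded(cfg.sam, 1)))
    ntol_c = stage("sam_ntol_vs_ctrl")(
        lambda: run_sam_groups(x, samples, NONTOL, CTRL, _seeded(cfg.sam, 2)))

    filt = stage("filter")(
        lambda: derive_final_lists(two.called, tol_c.called, ntol_c.called))
    manifest["cardinalities"] = filt.cardinalities()
    manifest["sam"] = {
        "two_group": {"s0": two.s0, "delta": two.delta, "est_fdr": two.est_fdr},
        "tol_vs_ctrl": {"s0": tol_c.s0, "delta": tol_c.delta,
                        "est_fdr": tol_c.est_fdr},
        "ntol_vs_ctrl": {"s0": ntol_c.s0, "delta": ntol_c.delta,
                         "est_fdr": ntol_c.est_fdr}}
    for name, lst in [("two_group", two.called), ("final_tol", filt.final_tol),
                      ("final_ntol", filt.final_ntol), ("shared", filt.shared),
                      ("unique_tol", filt.unique_tol),
                      ("unique_ntol", filt.unique_ntol)]:
        tio.write_lists(lst, out / f"{name}.tsv")

    agent_res = stage("agent_confound")(
        lambda: agent_confound_check(x, samples, two.called, _seeded(cfg.sam, 3)))
    manifest["agent_confound"] = {
        a: {k: v for k, v in r.items() if k != "overlap_ids"}
        for a, r in agent_res.items()}

    if cfg.gene_sets_path:
        sets = stage("enrich")(lambda: tio.read_gmt(cfg.gene_sets_path))
        patients = [s for s in samples if s.group in (TOL, NONTOL)]
        sub = x.subset_samples([s.sample_id for s in patients])
        labels = np.array([1 if s.group == TOL else 0 for s in patients])
        gsea = stage("enrich")(lambda: gsea_test(
            sub, labels, sets, n_perm=cfg.gsea_n_perm,
            perm_type=cfg.gsea_perm_type, seed=cfg.seed))
        gsea.table.to_csv(out / "gsea.tsv", sep="\t", index=False)
        manifest["gsea"] = {"n_sets": int(len(gsea.table)),
                            "n_perm": cfg.gsea_n_perm}
        universe = set(x.probe_ids)
        for name, lst in [("final_tol", filt.final_tol),
                          ("final_ntol", filt.final_ntol)]:
            if len(lst):
                ora = ora_test(lst, sets, universe, cfg.ora_fdr_alpha)
                ora.table.to_csv(out / f"ora_{name}.tsv", sep="\t", index=False)
                manifest[f"ora_{name}"] = {
                    "n_significant": int(len(ora.significant(cfg.ora_fdr_alpha)))}

    cv_cfg = _seeded(cfg.cv, 4)
    report = stage("classify")(lambda: cross_validate(x, samples, cv_cfg))
    manifest["classifier"] = {
        "weighted_accuracy": report.weighted_accuracy,
        "balanced_accuracy": report.balanced_accuracy,
        "per_class_accuracy": report.per_class_accuracy,
        "confusion": report.confusion,
        "auc": report.auc, "auc_ci": list(report.auc_ci),
        "n_stable_features": len(feature_stability(report))}
    with open(out / "roc.tsv", "w") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in report.roc:
            fh.write(f"{fpr}\t{tpr}\n")
    with open(out / "stability.tsv", "w") as fh:
        fh.write("probe_id\tn_selected\n")
        for p, c in sorted(report.stability.items(), key=lambda pc: (-pc[1], pc[0])):
            fh.write(f"{p}\t{c}\n")

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path, partial: bool = False) -> None:
    name = "manifest.partial.json" if partial else "manifest.json"
    with open(out / name, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
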