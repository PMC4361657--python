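"""Set algebra over directional gene lists: the three-group confound
filter, the immunosuppressant-agent confounding check, the matched-pair
secondary analysis, and list concordance.

The three-group filter addresses the study's structural confounder —
non-tolerant patients are on immunosuppression while tolerant patients
and healthy controls are not. Probes shifted unidirectionally in BOTH
patient groups relative to controls ("shared") are treated as
non-informative and removed; the final phenotype lists keep only probes
that separate a patient group from both the other patient group and the
controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .core import (DOWN, NONTOL, TOL, UP, DataError, DirectionalGeneList,
                   ExpressionMatrix, Sample)
from .sam import SamConfig, run_sam

logger = logging.getLogger(__name__)


@dataclass
class FilterResult:
    two_group: DirectionalGeneList
    tol_vs_ctrl: DirectionalGeneList
    ntol_vs_ctrl: DirectionalGeneList
    shared: DirectionalGeneList
    unique_tol: DirectionalGeneList
    unique_ntol: DirectionalGeneList
    final_tol: DirectionalGeneList
    final_ntol: DirectionalGeneList
    direction_conflicts: Set[str] = field(default_factory=set)

    def cardinalities(self) -> Dict[str, int]:
        return {
            "two_group": len(self.two_group),
            "tol_vs_ctrl": len(self.tol_vs_ctrl),
            "ntol_vs_ctrl": len(self.ntol_vs_ctrl),
            "shared": len(self.shared),
            "unique_tol": len(self.unique_tol),
            "unique_ntol": len(self.unique_ntol),
            "final_tol": len(self.final_tol),
            "final_ntol": len(self.final_ntol),
        }


def derive_unique_lists(tol_vs_ctrl: DirectionalGeneList,
                        ntol_vs_ctrl: DirectionalGeneList
                        ) -> Tuple[DirectionalGeneList, DirectionalGeneList,
                                   DirectionalGeneList]:
    """Split the two vs-control lists into shared and unique parts.

    Shared = probes present in both lists with the SAME direction
    (unidirectionally different from control in both patient groups).
    A probe present in both lists with opposite directions is retained
    in both unique lists.
    """
    shared = {p: d for p, d in tol_vs_ctrl.entries.items()
              if ntol_vs_ctrl.entries.get(p) == d}
    unique_tol = {p: d for p, d in tol_vs_ctrl.entries.items() if p not in shared}
    unique_ntol = {p: d for p, d in ntol_vs_ctrl.entries.items() if p not in shared}
    return (DirectionalGeneList(shared, "shared"),
            DirectionalGeneList(unique_tol, "unique_tol"),
            DirectionalGeneList(unique_ntol, "unique_ntol"))


def derive_final_lists(two_group: DirectionalGeneList,
                       tol_vs_ctrl: DirectionalGeneList,
                       ntol_vs_ctrl: DirectionalGeneList) -> FilterResult:
    """Full three-group filter.

    final_tol = two_group ∩ unique_tol and final_ntol = two_group ∩
    unique_ntol, matched by probe id; the reported direction is the one
    from the vs-control comparison. When it disagrees with the two-group
    direction the probe is kept and flagged in ``direction_conflicts``.
    """
    shared, unique_tol, unique_ntol = derive_unique_lists(tol_vs_ctrl, ntol_vs_ctrl)
    conflicts: Set[str] = set()

    def intersect(unique: DirectionalGeneList, label: str) -> DirectionalGeneList:
        out = {}
        for p, d in unique.entries.items():
            if p in two_group:
                out[p] = d
                if two_group.entries[p] != d:
                    conflicts.add(p)
        return DirectionalGeneList(out, label)

    return FilterResult(
        two_group=two_group, tol_vs_ctrl=tol_vs_ctrl, ntol_vs_ctrl=ntol_vs_ctrl,
        shared=shared, unique_tol=unique_tol, unique_ntol=unique_ntol,
        final_tol=intersect(unique_tol, "final_tol"),
        final_ntol=intersect(unique_ntol, "final_ntol"),
        direction_conflicts=conflicts)


def agent_confound_check(x: ExpressionMatrix, samples: Sequence[Sample],
                         phenotype_list: DirectionalGeneList,
                         cfg: SamConfig | None = None) -> Dict[str, dict]:
    """Per-agent SAM within the non-tolerant group, overlapped with the
    phenotype list.

    For each immunosuppressant agent, exposed vs unexposed non-tolerant
    samples are compared by SAM; the overlap of the resulting list with
    the phenotype list (by probe id) quantifies potential confounding by
    that agent. Agents with fewer than 2 samples on either side are
    skipped with a warning.
    """
    cfg = cfg or SamConfig()
    ntol = [s for s in samples if s.group == NONTOL]
    agents = sorted({a for s in ntol for a in s.agents})
    results: Dict[str, dict] = {}
    for agent in agents:
        exposed = [s.sample_id for s in ntol if agent in s.agents]
        unexposed = [s.sample_id for s in ntol if agent not in s.agents]
        if len(exposed) < 2 or len(unexposed) < 2:
            logger.warning("agent %s skipped: %d exposed vs %d unexposed",
                           agent, len(exposed), len(unexposed))
            results[agent] = {"skipped": True, "agent_list_size": 0,
                              "overlap": 0, "overlap_ids": []}
            continue
        sub = x.subset_samples(exposed + unexposed)
        labels = np.array([1] * len(exposed) + [0] * len(unexposed))
        res = run_sam(sub, labels, cfg, label=f"agent_{agent}")
        overlap = sorted(res.called.ids() & phenotype_list.ids())
        results[agent] = {"skipped": False, "agent_list_size": len(res.called),
                          "overlap": len(overlap), "overlap_ids": overlap}
    return results


def paired_analysis(x: ExpressionMatrix, samples: Sequence[Sample],
                    min_fold: float = 1.5, alpha: float = 0.05,
                    bh_correct: bool = False) -> DirectionalGeneList:
    """Matched-pair caller: per-pair log2 ratios (TOL minus NONTOL),
    Wilcoxon signed-rank test plus a geometric-mean fold filter.

    A probe is called when the signed-rank p-value is below ``alpha``
    (optionally Benjamini-Hochberg adjusted) and the geometric-mean
    ratio is at least ``min_fold``; the direction follows the sign of
    the median per-pair ratio.
    """
    pairs: Dict[str, dict] = {}
    for s in samples:
        if s.pair_id is not None:
            pairs.setdefault(s.pair_id, {})[s.group] = s.sample_id
    complete = {pid: m for pid, m in pairs.items() if TOL in m and NONTOL in m}
    if len(complete) != len(pairs):
        raise DataError("pairs with missing members present")
    if len(complete) < 5:
        raise DataError("paired analysis needs >= 5 complete pairs")

    tol_idx = x.sample_index([m[TOL] for m in complete.values()])
    ntol_idx = x.sample_index([m[NONTOL] for m in complete.values()])
    ratios = x.values[:, tol_idx] - x.values[:, ntol_idx]   # log2 per-pair ratios

    pvals = np.ones(x.n_probes)
    for i in range(x.n_probes):
        r = ratios[i]
        if np.allclose(r, 0):
            continue
        try:
            pvals[i] = stats.wilcoxon(r, zero_method="wilcox",
                                      method="auto").pvalue
        except ValueError:
            continue
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        pvals = multipletests(pvals, method="fdr_bh")[1]

    gm_ratio = np.exp2(np.abs(ratios.mean(axis=1)))
    med = np.median(ratios, axis=1)
    called = (pvals < alpha) & (gm_ratio >= min_fold)
    entries = {x.probe_ids[i]: (UP if med[i] >= 0 else DOWN)
               for i in np.flatnonzero(called)}
    return DirectionalGeneList(entries, "paired")


def concordance(a: DirectionalGeneList, b: DirectionalGeneList) -> float:
    """Fraction of entries of ``a`` present in ``b`` with the same direction."""
    if len(a) == 0:
        raise DataError("concordance undefined for an empty reference list")
    hits = sum(1 for p, d in a.entries.items() if b.entries.get(p) == d)
    return hits / len(a)
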