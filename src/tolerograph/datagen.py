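"""Synthetic expression data with planted ground truth.

Emulates the cross-sectional study design the pipeline analyzes: three
phenotype groups (15 tolerant patients, 17 non-tolerant patients, 10
healthy controls by default), thousands of probe sets on log2 scale,
heteroscedastic Gaussian noise, and planted structure:

* probes shifted only in the tolerant group (both directions),
* probes shifted only in the non-tolerant group,
* immunosuppression-confounded probes shifted unidirectionally in BOTH
  patient groups relative to controls (the structure the three-group
  filter must remove),
* optional agent-linked probes shifted in non-tolerant samples exposed
  to a given immunosuppressant,
* named lineage sets of probes for enrichment testing.

Every probe carries exactly one ground-truth category so recovery-based
tests can score sensitivity and false-call rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import (CTRL, NONTOL, TOL, DataError, ExpressionMatrix, Sample,
                   validate_annotation)

# Ground-truth categories
TOL_UP = "TOL_UP"
TOL_DOWN = "TOL_DOWN"
NTOL_UP = "NTOL_UP"
NTOL_DOWN = "NTOL_DOWN"
CONFOUNDED_UP = "CONFOUNDED_UP"
CONFOUNDED_DOWN = "CONFOUNDED_DOWN"
NULL = "NULL"


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study conditions the pipeline targets:
    15/17/10 samples, 2000 probe sets, planted log2 effect of 1.0
    (two-fold, comfortably above the 1.5-fold detectability floor) and
    per-probe noise sd drawn uniformly from (0.2, 0.6).
    """

    n_probes: int = 2000
    group_sizes: Dict[str, int] = field(
        default_factory=lambda: {TOL: 15, NONTOL: 17, CTRL: 10})
    n_tol_up: int = 50
    n_tol_down: int = 50
    n_ntol_up: int = 25
    n_ntol_down: int = 25
    n_confounded: int = 100
    effect_log2: float = 1.0
    sd_range: Tuple[float, float] = (0.2, 0.6)
    lineage_sets: Dict[str, int] = field(default_factory=dict)
    agent_names: List[str] = field(default_factory=list)
    n_agent_linked: int = 0
    agent_effect_log2: float = 1.0
    pairing: bool = False
    baseline_range: Tuple[float, float] = (4.0, 12.0)
    seed: int = 0

    def validate(self) -> None:
        counts = [self.n_tol_up, self.n_tol_down, self.n_ntol_up,
                  self.n_ntol_down, self.n_confounded,
                  self.n_agent_linked * len(self.agent_names)]
        if any(c < 0 for c in counts) or self.n_probes < 0:
            raise DataError("planted counts must be non-negative")
        if sum(counts) > self.n_probes:
            raise DataError("planted probes exceed n_probes")
        if sum(self.lineage_sets.values()) > self.n_probes:
            raise DataError("lineage set sizes exceed n_probes")
        if not (0 < self.sd_range[0] <= self.sd_range[1]):
            raise DataError("sd_range must satisfy 0 < lo <= hi")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise DataError(f"group {g} needs >= 2 samples, got {n}")
        if self.pairing and self.group_sizes[NONTOL] < self.group_sizes[TOL]:
            raise DataError("pairing requires at least as many NONTOL as TOL samples")


@dataclass
class SyntheticTruth:
    """Planted memberships and effect sizes.

    membership maps every probe to exactly one category; lineage_sets
    tag probes orthogonally (a lineage member may also be NULL or
    planted). true_signal carries the noiseless log2 matrix when the
    probe-level generator produced one.
    """

    membership: Dict[str, str]
    effect_log2: Dict[str, float]
    lineage_sets: Dict[str, List[str]] = field(default_factory=dict)
    agent_probes: Dict[str, List[str]] = field(default_factory=dict)
    true_signal: Optional[ExpressionMatrix] = None

    def probes_in(self, *categories: str) -> List[str]:
        want = set(categories)
        return [p for p, c in self.membership.items() if c in want]


@dataclass
class ProbeLevelSet:
    """Probe-level intensities grouped by probe set, natural scale.

    intensities maps probe_set_id -> (member probes x arrays) positive
    matrix; every probe set has >= 2 member probes.
    """

    sample_ids: List[str]
    intensities: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for pid, mat in self.intensities.items():
            mat = np.asarray(mat, dtype=float)
            if mat.ndim != 2 or mat.shape[0] < 2:
                raise DataError(f"probe set {pid} needs >= 2 member probes")
            if mat.shape[1] != len(self.sample_ids):
                raise DataError(f"probe set {pid} has wrong array count")
            if not np.all(mat > 0):
                raise DataError(f"probe set {pid} has non-positive intensities")
            self.intensities[pid] = mat


def _make_annotation(config: SimConfig, rng: np.random.Generator) -> List[Sample]:
    samples: List[Sample] = []
    n_tol = config.group_sizes[TOL]
    n_ntol = config.group_sizes[NONTOL]
    n_ctrl = config.group_sizes[CTRL]
    tol_ids = [f"TOL{i+1:02d}" for i in range(n_tol)]
    ntol_ids = [f"NT{i+1:02d}" for i in range(n_ntol)]
    ctrl_ids = [f"CTRL{i+1:02d}" for i in range(n_ctrl)]

    pair_of: Dict[str, str] = {}
    if config.pairing:
        # each TOL sample matched with one distinct NONTOL sample
        chosen = rng.permutation(n_ntol)[:n_tol]
        for k, j in enumerate(chosen):
            pair_of[tol_ids[k]] = f"P{k+1:02d}"
            pair_of[ntol_ids[j]] = f"P{k+1:02d}"

    agent_sets: Dict[str, frozenset] = {}
    for sid in ntol_ids:
        exposed = frozenset(a for a in config.agent_names if rng.random() < 0.5)
        agent_sets[sid] = exposed

    for sid in tol_ids:
        samples.append(Sample(sid, TOL, pair_id=pair_of.get(sid)))
    for sid in ntol_ids:
        samples.append(Sample(sid, NONTOL, pair_id=pair_of.get(sid),
                              agents=agent_sets[sid]))
    for sid in ctrl_ids:
        samples.append(Sample(sid, CTRL))
    return validate_annotation(samples)


def _plant_memberships(config: SimConfig, probe_ids: List[str],
                       rng: np.random.Generator) -> Tuple[Dict[str, str], Dict[str, List[str]]]:
    """Assign disjoint planted categories to a random subset of probes."""
    order = rng.permutation(len(probe_ids))
    membership = {p: NULL for p in probe_ids}
    agent_probes: Dict[str, List[str]] = {}
    cursor = 0

    def take(n: int) -> List[str]:
        nonlocal cursor
        picked = [probe_ids[i] for i in order[cursor:cursor + n]]
        cursor += n
        return picked

    half_conf = config.n_confounded // 2
    blocks = [
        (TOL_UP, config.n_tol_up), (TOL_DOWN, config.n_tol_down),
        (NTOL_UP, config.n_ntol_up), (NTOL_DOWN, config.n_ntol_down),
        (CONFOUNDED_UP, half_conf), (CONFOUNDED_DOWN, config.n_confounded - half_conf),
    ]
    for cat, n in blocks:
        for p in take(n):
            membership[p] = cat
    for agent in config.agent_names:
        picked = take(config.n_agent_linked)
        agent_probes[agent] = picked
        for p in picked:
            membership[p] = f"AGENT:{agent}"
    return membership, agent_probes


def generate_dataset(config: SimConfig
                     ) -> Tuple[ExpressionMatrix, List[Sample], SyntheticTruth]:
    """Generate a log2 expression matrix with planted differential structure.

    Deterministic for a fixed ``config.seed``. Planted probes receive a
    group-mean shift of exactly ``effect_log2`` in the stated direction;
    confounded probes are shifted identically (same sign) in both
    patient groups relative to controls; noise is independent Gaussian
    with a per-probe sd drawn uniformly from ``sd_range``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = _make_annotation(config, rng)
    sample_ids = [s.sample_id for s in samples]
    group_of = {s.sample_id: s.group for s in samples}

    probe_ids = [f"PS{i+1:05d}_at" for i in range(config.n_probes)]
    membership, agent_probes = _plant_memberships(config, probe_ids, rng)

    # lineage sets tag probes orthogonally to the planted categories
    lineage_sets: Dict[str, List[str]] = {}
    for name, size in config.lineage_sets.items():
        picked = rng.choice(len(probe_ids), size=size, replace=False)
        lineage_sets[name] = [probe_ids[i] for i in sorted(picked)]

    baseline = rng.uniform(*config.baseline_range, size=config.n_probes)
    sd = rng.uniform(config.sd_range[0], config.sd_range[1], size=config.n_probes)

    tol_mask = np.array([group_of[s] == TOL for s in sample_ids])
    ntol_mask = np.array([group_of[s] == NONTOL for s in sample_ids])
    exposed_masks = {
        agent: np.array([
            group_of[s] == NONTOL and agent in next(x.agents for x in samples
                                                    if x.sample_id == s)
            for s in sample_ids])
        for agent in config.agent_names
    }

    mean = np.tile(baseline[:, None], (1, len(sample_ids)))
    effect: Dict[str, float] = {}
    e = config.effect_log2
    for i, p in enumerate(probe_ids):
        cat = membership[p]
        if cat == TOL_UP:
            mean[i, tol_mask] += e
            effect[p] = e
        elif cat == TOL_DOWN:
            mean[i, tol_mask] -= e
            effect[p] = -e
        elif cat == NTOL_UP:
            mean[i, ntol_mask] += e
            effect[p] = e
        elif cat == NTOL_DOWN:
            mean[i, ntol_mask] -= e
            effect[p] = -e
        elif cat == CONFOUNDED_UP:
            mean[i, tol_mask | ntol_mask] += e
            effect[p] = e
        elif cat == CONFOUNDED_DOWN:
            mean[i, tol_mask | ntol_mask] -= e
            effect[p] = -e
        elif cat.startswith("AGENT:"):
            agent = cat.split(":", 1)[1]
            mean[i, exposed_masks[agent]] += config.agent_effect_log2
            effect[p] = config.agent_effect_log2

    noise = rng.standard_normal(mean.shape) * sd[:, None]
    x = ExpressionMatrix(probe_ids, sample_ids, mean + noise)
    truth = SyntheticTruth(membership, effect, lineage_sets, agent_probes)
    return x, samples, truth


def generate_probe_level(config: SimConfig, probes_per_set: int,
                         noise_sd: float = 0.1, affinity_sd: float = 1.0
                         ) -> Tuple[ProbeLevelSet, SyntheticTruth]:
    """Generate natural-scale probe-level intensities for preprocessing tests.

    Each probe set has ``probes_per_set`` member probes following the
    additive model log2(I) = signal + probe affinity + noise, with
    affinities fixed per probe across arrays. Set ``noise_sd=0`` and
    ``affinity_sd=0`` for an exactly additive fixture whose median-polish
    summary recovers the true signal.
    """
    if probes_per_set < 2:
        raise DataError("probes_per_set must be >= 2")
    x, samples, truth = generate_dataset(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7])
                                if config.seed is not None else None)
    intensities: Dict[str, np.ndarray] = {}
    for i, pid in enumerate(x.probe_ids):
        affin = rng.standard_normal(probes_per_set) * affinity_sd
        eps = rng.standard_normal((probes_per_set, x.n_samples)) * noise_sd
        log2_i = x.values[i][None, :] + affin[:, None] + eps
        intensities[pid] = np.exp2(log2_i)
    truth.true_signal = x
    return ProbeLevelSet([s.sample_id for s in samples], intensities), truth


def permute_group_labels(samples: List[Sample], scope: str = "patients_only",
                         seed: int = 0) -> List[Sample]:
    """Shuffle group labels (within patients, or across all samples).

    The label multiset within scope is preserved; pair ids and agent
    flags stay attached to their samples. Used to build null datasets
    for calibration tests.
    """
    if scope not in ("patients_only", "all"):
        raise DataError(f"unknown scope {scope!r}")
    in_scope = [i for i, s in enumerate(samples)
                if scope == "all" or s.group in (TOL, NONTOL)]
    if len(in_scope) < 2:
        raise DataError("need >= 2 samples in scope")
    rng = np.random.default_rng(seed)
    labels = [samples[i].group for i in in_scope]
    shuffled = [labels[j] for j in rng.permutation(len(labels))]
    out = list(samples)
    for i, lab in zip(in_scope, shuffled):
        s = out[i]
        # agents may be inconsistent with a reassigned label; keep them
        # attached (the spec of this operation preserves those fields)
        out[i] = Sample.__new__(Sample)
        object.__setattr__(out[i], "sample_id", s.sample_id)
        object.__setattr__(out[i], "group", lab)
        object.__setattr__(out[i], "pair_id", s.pair_id)
        object.__setattr__(out[i], "agents", s.agents)
    return out
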