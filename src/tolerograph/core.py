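"""Shared data containers for the tolerance-biomarker pipeline.

The pipeline moves three kinds of objects between stages: a log2
expression matrix (probe sets x samples), per-sample annotations
carrying the three-level phenotype (tolerant patients off all
immunosuppression, non-tolerant patients still on it, and healthy
controls), and directional gene lists produced by the differential
expression and filtering stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

# Phenotype groups
TOL = "TOL"
NONTOL = "NONTOL"
CTRL = "CTRL"
GROUPS = (TOL, NONTOL, CTRL)

UP = "up"
DOWN = "down"


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """Probe sets x samples matrix of log2 expression values.

    Parameters
    ----------
    probe_ids : sequence of str
        Unique row identifiers (probe sets).
    sample_ids : sequence of str
        Unique column identifiers.
    values : ndarray, shape (n_probes, n_samples)
        Finite log2-scale expression values.
    """

    probe_ids: list
    sample_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = list(self.probe_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise DataError("duplicate probe ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression matrix contains non-finite values")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_ids: Iterable[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise DataError(f"unknown sample id {exc.args[0]!r}") from exc

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        idx = self.sample_index(sample_ids)
        return ExpressionMatrix(self.probe_ids, sample_ids, self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))


@dataclass(frozen=True)
class Sample:
    """Annotation for one sample: phenotype group, optional matched-pair
    id linking one tolerant to one non-tolerant patient, and the set of
    immunosuppressant agents at sampling (empty for TOL and CTRL by
    definition of the tolerant phenotype)."""

    sample_id: str
    group: str
    pair_id: Optional[str] = None
    agents: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DataError(f"unknown group {self.group!r}")
        object.__setattr__(self, "agents", frozenset(self.agents))
        if self.group != NONTOL and self.agents:
            raise DataError(f"{self.group} sample {self.sample_id} must have empty agents")

    def with_group(self, group: str) -> "Sample":
        return replace(self, group=group)


def validate_annotation(samples: Iterable[Sample]) -> list:
    """Check uniqueness of sample ids and pairing consistency."""
    samples = list(samples)
    seen = set()
    for s in samples:
        if s.sample_id in seen:
            raise DataError(f"duplicate sample id {s.sample_id!r}")
        seen.add(s.sample_id)
    by_pair: dict = {}
    for s in samples:
        if s.pair_id is not None:
            by_pair.setdefault(s.pair_id, []).append(s)
    for pid, members in by_pair.items():
        if len(members) != 2 or {m.group for m in members} != {TOL, NONTOL}:
            raise DataError(f"pair {pid!r} must link exactly one TOL and one NONTOL sample")
    return samples


def group_ids(samples: Iterable[Sample], group: str) -> list:
    return [s.sample_id for s in samples if s.group == group]


@dataclass
class DirectionalGeneList:
    """A set of (probe id, direction) calls; each probe appears once."""

    entries: dict = field(default_factory=dict)  # probe_id -> "up"/"down"
    label: str = ""

    def __post_init__(self) -> None:
        for d in self.entries.values():
            if d not in (UP, DOWN):
                raise DataError(f"direction must be 'up' or 'down', got {d!r}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple], label: str = "") -> "DirectionalGeneList":
        entries: dict = {}
        for probe, direction in pairs:
            if probe in entries and entries[probe] != direction:
                raise DataError(f"probe {probe!r} listed with conflicting directions")
            entries[probe] = direction
        return cls(entries, label)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, probe) -> bool:
        return probe in self.entries

    def ids(self) -> set:
        return set(self.entries)

    def pairs(self) -> list:
        return sorted(self.entries.items())

    def direction(self, probe: str) -> str:
        return self.entries[probe]


def check_two_groups(samples: Iterable[Sample], group_a: str, group_b: str,
                     min_per_group: int = 2) -> tuple:
    """Return (ids_a, ids_b), rejecting groups below ``min_per_group``."""
    ids_a = group_ids(samples, group_a)
    ids_b = group_ids(samples, group_b)
    if len(ids_a) < min_per_group or len(ids_b) < min_per_group:
        raise DataError(
            f"need >= {min_per_group} samples per group; got "
            f"{group_a}={len(ids_a)}, {group_b}={len(ids_b)}"
        )
    return ids_a, ids_b
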