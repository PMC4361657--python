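"""Readers and writers for the standard expression-analysis text formats:
GCT 1.2 matrices, CLS phenotype files (three-class TOL/NONTOL/CTRL), GMT
gene-set collections, directional gene lists (2-column TSV), and the
annotation sidecar carrying pair ids and immunosuppressant agents.

All round-trips are lossless: full float precision (repr), preserved
row/column ordering, and distinct errors for malformed headers,
dimension mismatches, and duplicate identifiers.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import numpy as np

from .core import (GROUPS, DataError, DirectionalGeneList, ExpressionMatrix,
                   Sample, validate_annotation)
from .enrich import GeneSetCollection


class FormatError(DataError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------- GCT 1.2

def write_gct(x: ExpressionMatrix, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("#1.2\n")
        fh.write(f"{x.n_probes}\t{x.n_samples}\n")
        fh.write("NAME\tDescription\t" + "\t".join(x.sample_ids) + "\n")
        for i, pid in enumerate(x.probe_ids):
            row = "\t".join(repr(float(v)) for v in x.values[i])
            fh.write(f"{pid}\tna\t{row}\n")


def read_gct(path) -> ExpressionMatrix:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "#1.2":
        raise FormatError(f"{path}: missing GCT '#1.2' version header")
    try:
        n_rows, n_cols = (int(t) for t in lines[1].split("\t")[:2])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: malformed GCT dimensions line") from exc
    header = lines[2].split("\t")
    sample_ids = header[2:]
    if len(sample_ids) != n_cols:
        raise FormatError(f"{path}: header declares {len(sample_ids)} samples, "
                          f"dimensions line says {n_cols}")
    body = [ln for ln in lines[3:] if ln.strip()]
    if len(body) != n_rows:
        raise FormatError(f"{path}: {len(body)} data rows but {n_rows} declared")
    probe_ids, values = [], []
    for ln in body:
        parts = ln.split("\t")
        if len(parts) != n_cols + 2:
            raise FormatError(f"{path}: row {parts[0]!r} has wrong column count")
        probe_ids.append(parts[0])
        values.append([float(v) for v in parts[2:]])
    if len(set(probe_ids)) != len(probe_ids):
        raise FormatError(f"{path}: duplicate probe ids")
    return ExpressionMatrix(probe_ids, sample_ids, np.array(values))


def write_tsv_matrix(x: ExpressionMatrix, path) -> None:
    x.to_frame().to_csv(path, sep="\t", index_label="probe_id",
                        float_format=None)


# ---------------------------------------------------------------- CLS

def write_cls(samples: Sequence[Sample], path) -> None:
    groups = []
    for s in samples:
        if s.group not in groups:
            groups.append(s.group)
    with open(path, "w", newline="") as fh:
        fh.write(f"{len(samples)} {len(groups)} 1\n")
        fh.write("# " + " ".join(groups) + "\n")
        fh.write(" ".join(s.group for s in samples) + "\n")


def read_cls(path, sample_ids: Sequence[str]) -> List[Sample]:
    """Read a CLS file; sample ids come from the companion matrix."""
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: CLS needs 3 lines")
    try:
        n, n_classes, _one = (int(t) for t in lines[0].split()[:3])
    except ValueError as exc:
        raise FormatError(f"{path}: malformed CLS count header") from exc
    if not lines[1].startswith("#"):
        raise FormatError(f"{path}: CLS class-name line must start with '#'")
    class_names = lines[1][1:].split()
    labels = lines[2].split()
    if len(labels) != n:
        raise FormatError(f"{path}: {len(labels)} labels but {n} declared")
    if len(labels) != len(sample_ids):
        raise FormatError(f"{path}: label count does not match matrix samples")
    if len(class_names) != n_classes:
        raise FormatError(f"{path}: class-name count mismatch")
    # labels may be names or 0-based indices into the class-name line
    out = []
    for sid, lab in zip(sample_ids, labels):
        name = class_names[int(lab)] if lab.isdigit() else lab
        if name not in GROUPS:
            raise FormatError(f"{path}: unknown class {name!r}")
        out.append(Sample(sid, name))
    return out


# --------------------------------------------------- annotation sidecar

def write_annotation(samples: Sequence[Sample], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "group", "pair_id", "agents"])
        for s in samples:
            w.writerow([s.sample_id, s.group, s.pair_id or "",
                        ",".join(sorted(s.agents))])


def read_annotation(path) -> List[Sample]:
    samples = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            agents = frozenset(a for a in row.get("agents", "").split(",") if a)
            samples.append(Sample(
                row["sample_id"], row["group"],
                pair_id=row.get("pair_id") or None, agents=agents))
    return validate_annotation(samples)


# ---------------------------------------------------------------- GMT

def write_gmt(sets: GeneSetCollection, path,
              descriptions: Dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", newline="") as fh:
        for name in sorted(sets):
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(sets[name])]) + "\n")


def read_gmt(path) -> GeneSetCollection:
    sets: Dict[str, set] = {}
    with open(path) as fh:
        for ln in fh.read().splitlines():
            if not ln.strip():
                continue
            parts = ln.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: GMT line needs name, description, "
                                  f"and >= 1 member: {parts[0]!r}")
            if parts[0] in sets:
                raise FormatError(f"{path}: duplicate set name {parts[0]!r}")
            sets[parts[0]] = set(parts[2:])
    return GeneSetCollection(sets)


# --------------------------------------------------------------- lists

def write_lists(gene_list: DirectionalGeneList, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("probe_id\tdirection\n")
        for probe, direction in gene_list.pairs():
            fh.write(f"{probe}\t{direction}\n")


def read_lists(path, label: str = "") -> DirectionalGeneList:
    entries = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != ["probe_id", "direction"]:
            raise FormatError(f"{path}: expected columns probe_id, direction")
        for row in reader:
            if row["probe_id"] in entries:
                raise FormatError(f"{path}: duplicate probe {row['probe_id']!r}")
            entries[row["probe_id"]] = row["direction"]
    return DirectionalGeneList(entries, label or Path(path).stem)


def write_rnk(ranked: Sequence[tuple], path) -> None:
    """Ranked gene list export (gene<TAB>score)."""
    with open(path, "w", newline="") as fh:
        for gene, score in ranked:
            fh.write(f"{gene}\t{repr(float(score))}\n")
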