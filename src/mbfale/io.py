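"""Foci dataset containers and readers/writers.

The meta-analytic input is a collection of experiments, each contributing a
subject count and a list of activation peaks ("foci") in mm.  Two on-disk
dialects are supported:

* the Sleuth/GingerALE text format: blocks of ``//`` comment lines (one of
  which is ``// Subjects=N``) followed by whitespace-separated ``x y z`` rows,
  blocks separated by blank lines;
* a tabular form (CSV/TSV/DataFrame) with columns
  ``experiment, n_subjects, x, y, z`` — one row per focus.

A JSON serialization of the whole dataset is also provided.  Coordinates are
stored verbatim in the dataset's declared space; no Talairach/MNI conversion
is attempted.
"""

from __future__ import annotations

import io as _io
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, List

import numpy as np
import pandas as pd

__all__ = [
    "Experiment",
    "FociDataset",
    "SleuthParseError",
    "read_sleuth",
    "write_sleuth",
    "read_tabular",
    "write_tabular",
    "dataset_to_json",
    "dataset_from_json",
]

TABULAR_COLUMNS = ("experiment", "n_subjects", "x", "y", "z")


class SleuthParseError(ValueError):
    """Raised when a foci text file cannot be parsed."""


@dataclass
class Experiment:
    """One experiment: a label, a subject count and its peak coordinates."""

    id: str
    n_subjects: int
    foci: np.ndarray
    space_label: str = "MNI"

    def __post_init__(self) -> None:
        if int(self.n_subjects) < 1:
            raise ValueError(f"experiment {self.id!r}: n_subjects must be >= 1")
        self.n_subjects = int(self.n_subjects)
        foci = np.asarray(self.foci, dtype=float)
        if foci.ndim != 2 or foci.shape[1] != 3 or foci.shape[0] < 1:
            raise ValueError(f"experiment {self.id!r}: foci must be a (k, 3) array")
        if not np.isfinite(foci).all():
            raise ValueError(f"experiment {self.id!r}: non-finite focus coordinate")
        self.foci = foci

    @property
    def n_foci(self) -> int:
        return self.foci.shape[0]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Experiment)
            and self.id == other.id
            and self.n_subjects == other.n_subjects
            and self.space_label == other.space_label
            and self.foci.shape == other.foci.shape
            and np.array_equal(self.foci, other.foci)
        )


@dataclass
class FociDataset:
    """A named collection of experiments with unique ids."""

    experiments: List[Experiment]
    name: str = "dataset"
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.experiments) < 1:
            raise ValueError("dataset must contain at least one experiment")
        ids = [e.id for e in self.experiments]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate experiment ids: {dupes}")

    def __len__(self) -> int:
        return len(self.experiments)

    def __iter__(self) -> Iterable[Experiment]:
        return iter(self.experiments)

    @property
    def n_foci(self) -> int:
        return sum(e.n_foci for e in self.experiments)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FociDataset)
            and len(self) == len(other)
            and all(a == b for a, b in zip(self.experiments, other.experiments))
        )


_SUBJECTS_RE = re.compile(r"^//\s*subjects\s*=\s*(\S+)\s*$", re.IGNORECASE)
_KEYVAL_RE = re.compile(r"^//\s*(\w+)\s*=\s*(.*\S)\s*$")


def read_sleuth(source, name: str = "dataset") -> FociDataset:
    """Parse a Sleuth/GingerALE-style foci text file.

    ``source`` may be a path, a text stream, or the text itself.  A leading
    comment-only block without a ``Subjects=`` line is treated as a file
    header: a ``Reference=<space>`` entry sets the coordinate-space label and
    all header lines are kept as provenance.
    """
    text = _as_text(source)
    lines = text.splitlines()
    if not any(line.strip() for line in lines):
        raise SleuthParseError("empty foci file")

    blocks: list[list[tuple[int, str]]] = [[]]
    for lineno, raw in enumerate(lines, start=1):
        if raw.strip():
            blocks[-1].append((lineno, raw.strip()))
        elif blocks[-1]:
            blocks.append([])
    if not blocks[-1]:
        blocks.pop()

    space_label = "UNKNOWN"
    provenance_lines: list[str] = []
    experiments: list[Experiment] = []
    seen_ids: set[str] = set()

    for bi, block in enumerate(blocks):
        comments = [(n, l) for n, l in block if l.startswith("//")]
        rows = [(n, l) for n, l in block if not l.startswith("//")]

        n_subjects = None
        label = None
        for n, line in comments:
            m = _SUBJECTS_RE.match(line)
            if m:
                try:
                    n_subjects = int(m.group(1))
                except ValueError:
                    raise SleuthParseError(
                        f"line {n}: Subjects value {m.group(1)!r} is not an integer"
                    ) from None
                continue
            kv = _KEYVAL_RE.match(line)
            if kv and kv.group(1).lower() == "reference":
                space_label = kv.group(2)
                continue
            if label is None and not kv:
                label = line[2:].strip()

        if n_subjects is None:
            if not rows:
                # header / metadata block
                provenance_lines.extend(l for _, l in comments)
                continue
            raise SleuthParseError(
                f"block {bi + 1} (line {block[0][0]}): missing '// Subjects=' line"
            )

        foci = []
        for n, line in rows:
            parts = line.replace("\t", " ").split()
            if len(parts) != 3:
                raise SleuthParseError(
                    f"line {n}: expected 3 coordinates, got {len(parts)}"
                )
            try:
                # tolerate unicode minus from copy-pasted tables
                foci.append([float(p.replace("−", "-")) for p in parts])
            except ValueError:
                raise SleuthParseError(
                    f"line {n}: non-numeric coordinate row {line!r}"
                ) from None
        if not foci:
            raise SleuthParseError(
                f"block {bi + 1} (line {block[0][0]}): no coordinate rows"
            )

        exp_id = label if label else f"experiment_{bi + 1}"
        if exp_id in seen_ids:
            exp_id = f"{exp_id}_{bi + 1}"
        seen_ids.add(exp_id)
        experiments.append(
            Experiment(
                id=exp_id,
                n_subjects=n_subjects,
                foci=np.array(foci),
                space_label=space_label,
            )
        )

    if not experiments:
        raise SleuthParseError("no experiment blocks found")
    return FociDataset(
        experiments=experiments, name=name, provenance="\n".join(provenance_lines)
    )


def write_sleuth(dataset: FociDataset, precision: int = 3) -> str:
    """Serialize a dataset in the Sleuth text dialect.

    Coordinates are written with ``precision`` decimals (default 3, i.e.
    micron-level — far below voxel size), so a read-back round-trip reproduces
    ids, subject counts and coordinates to that precision.
    """
    out = [f"// Reference={dataset.experiments[0].space_label}"]
    for line in dataset.provenance.splitlines():
        out.append(line if line.startswith("//") else f"// {line}")
    out.append("")
    for exp in dataset:
        out.append(f"// {exp.id}")
        out.append(f"// Subjects={exp.n_subjects}")
        for x, y, z in exp.foci:
            out.append(f"{x:.{precision}f}\t{y:.{precision}f}\t{z:.{precision}f}")
        out.append("")
    return "\n".join(out)


def read_tabular(table, name: str = "dataset", space_label: str = "UNKNOWN") -> FociDataset:
    """Build a dataset from a DataFrame / CSV / TSV with one row per focus.

    Required columns: ``experiment, n_subjects, x, y, z``.  Rows are grouped
    by experiment id in order of first appearance; a subject count that varies
    within one id is an error.
    """
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.read_csv(table, sep=None, engine="python")
    missing = [c for c in TABULAR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    experiments = []
    for exp_id, grp in df.groupby("experiment", sort=False):
        n_vals = grp["n_subjects"].unique()
        if len(n_vals) != 1:
            raise ValueError(
                f"experiment {exp_id!r}: inconsistent n_subjects {sorted(n_vals)}"
            )
        experiments.append(
            Experiment(
                id=str(exp_id),
                n_subjects=int(n_vals[0]),
                foci=grp[["x", "y", "z"]].to_numpy(dtype=float),
                space_label=space_label,
            )
        )
    return FociDataset(experiments=experiments, name=name)


def write_tabular(dataset: FociDataset) -> pd.DataFrame:
    rows = []
    for exp in dataset:
        for x, y, z in exp.foci:
            rows.append((exp.id, exp.n_subjects, x, y, z))
    return pd.DataFrame(rows, columns=list(TABULAR_COLUMNS))


def dataset_to_json(dataset: FociDataset) -> str:
    """JSON schema: {name, provenance, experiments: [{id, n_subjects, space, foci: [[x,y,z]...]}]}."""
    obj = {
        "name": dataset.name,
        "provenance": dataset.provenance,
        "experiments": [
            {
                "id": e.id,
                "n_subjects": e.n_subjects,
                "space": e.space_label,
                "foci": e.foci.tolist(),
            }
            for e in dataset
        ],
    }
    return json.dumps(obj, indent=1)


def dataset_from_json(text: str) -> FociDataset:
    obj = json.loads(text)
    return FociDataset(
        experiments=[
            Experiment(
                id=e["id"],
                n_subjects=e["n_subjects"],
                foci=np.array(e["foci"], dtype=float),
                space_label=e.get("space", "UNKNOWN"),
            )
            for e in obj["experiments"]
        ],
        name=obj.get("name", "dataset"),
        provenance=obj.get("provenance", ""),
    )


def _as_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    s = str(source)
    if "\n" in s or s.strip().startswith("//") or not s.strip():
        return s
    with open(s, "r", encoding="utf-8") as fh:
        return fh.read()
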