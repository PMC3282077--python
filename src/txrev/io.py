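"""Readers, writers and core containers for the expression pipeline.

All downstream stages consume the types defined here: a dense probe-level
:class:`ExpressionMatrix`, a :class:`DesignTable` mapping samples to
treatment conditions, a :class:`ProbeAnnotation` (probe -> gene symbol),
a :class:`GeneSetCollection` parsed from GMT, and the packaged table of
cobalt/hypoxia shared genes with their cobalt (C-0) and zinc-rescue (ZC-C)
fold changes.

Fold changes throughout the package use the *signed linear* convention:
for a log2 difference ``d``, FC = 2**d when d >= 0 and FC = -2**(-d) when
d < 0, so a decrease carries a negative sign and |FC| >= 1 always.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DesignTable",
    "ProbeAnnotation",
    "GeneSetCollection",
    "SharedGeneRecord",
    "signed_fold_change",
    "log2_from_signed_fc",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_design_table",
    "read_probe_annotation",
    "read_gmt",
    "write_gmt",
    "load_shared_gene_table",
]

CONDITIONS_8 = ("0", "A", "Z", "C", "AZ", "AC", "ZC", "AZC")
"""Canonical labels of the 2x2x2 drug (A) x zinc (Z) x cobalt (C) design."""


def signed_fold_change(log2_diff):
    """Convert log2 differences to signed linear fold changes.

    Decreases carry a negative sign and the magnitude is always >= 1:
    ``d=1 -> +2``, ``d=-1 -> -2``, ``d=0 -> +1``.
    """
    d = np.asarray(log2_diff, dtype=float)
    fc = np.where(d >= 0, np.exp2(d), -np.exp2(-d))
    return fc if fc.ndim else float(fc)


def log2_from_signed_fc(fc):
    """Inverse of :func:`signed_fold_change`."""
    f = np.asarray(fc, dtype=float)
    if np.any(np.abs(f) < 1):
        raise ValueError("signed fold changes must satisfy |FC| >= 1")
    d = np.where(f >= 0, np.log2(np.abs(f)), -np.log2(np.abs(f)))
    return d if d.ndim else float(d)


@dataclass
class ExpressionMatrix:
    """Dense probes x samples intensity grid on a declared scale."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "log2"  # {"linear", "log2"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale flag {self.scale!r}")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"value grid {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {name} id {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at probe {self.probe_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


def _first_duplicate(ids: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class DesignTable:
    """sample_id -> (condition label, replicate index)."""

    assignments: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, int], str] = {}
        for sid, (cond, rep) in self.assignments.items():
            key = (cond, rep)
            if key in seen:
                raise ValueError(
                    f"replicate index {rep} duplicated within condition {cond!r} "
                    f"(samples {seen[key]!r}, {sid!r})"
                )
            seen[key] = sid

    @property
    def conditions(self) -> list[str]:
        out: list[str] = []
        for cond, _ in self.assignments.values():
            if cond not in out:
                out.append(cond)
        return out

    def samples_for(self, condition: str) -> list[str]:
        sids = [s for s, (c, r) in sorted(self.assignments.items(), key=lambda kv: kv[1][1])
                if c == condition]
        if not sids:
            raise KeyError(f"condition {condition!r} has no samples in the design")
        return sids

    def check_against(self, matrix: ExpressionMatrix) -> None:
        missing = [s for s in self.assignments if s not in matrix.sample_ids]
        if missing:
            raise ValueError(f"design samples absent from matrix: {missing}")


@dataclass
class ProbeAnnotation:
    """Probe id -> gene symbol; unannotated probes are simply absent."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        for probe, sym in self.mapping.items():
            if not sym or not str(sym).strip():
                raise ValueError(f"empty gene symbol for probe {probe!r}")

    def symbol(self, probe_id: str) -> str | None:
        return self.mapping.get(probe_id)

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class GeneSetCollection:
    """Named gene-symbol sets with an optional category tag per set."""

    sets: dict[str, frozenset[str]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass(frozen=True)
class SharedGeneRecord:
    """One gene of the packaged cobalt/hypoxia shared-gene table."""

    gene: str
    direction: str  # "up" or "down" under cobalt vs untreated
    fc_primary: float  # signed linear FC, cobalt vs untreated (C-0)
    fc_counter: float  # signed linear FC, zinc+cobalt vs cobalt (ZC-C)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path: str | Path, scale: str) -> ExpressionMatrix:
    """Read a TSV with a header row of sample ids and probe ids in column 1."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    probe_ids = [str(p) for p in df.index]
    sample_ids = [str(s) for s in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any():
                row = df.index[int(np.argmax(bad.isna().to_numpy()))]
                raise ValueError(
                    f"non-numeric cell at probe {row!r}, sample {col!r} in {path}"
                ) from None
        raise
    return ExpressionMatrix(probe_ids, sample_ids, values, scale=scale)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_design_table(path: str | Path) -> DesignTable:
    """Read a 3-column TSV: sample_id, condition, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["sample_id", "condition", "replicate"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"design table must have columns {expected}, got {list(df.columns)}")
    assignments = {
        str(r.sample_id): (str(r.condition), int(r.replicate)) for r in df.itertuples()
    }
    if len(assignments) != len(df):
        raise ValueError("duplicate sample_id in design table")
    return DesignTable(assignments)


def write_design_table(design: DesignTable, path: str | Path) -> None:
    rows = [(s, c, r) for s, (c, r) in design.assignments.items()]
    pd.DataFrame(rows, columns=["sample_id", "condition", "replicate"]).to_csv(
        path, sep="\t", index=False
    )


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a 2-column TSV: probe_id, gene_symbol. Empty symbol = unannotated."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mapping: dict[str, str] = {}
    for r in df.itertuples(index=False):
        probe, sym = str(r[0]), str(r[1]).strip()
        if probe in mapping:
            raise ValueError(f"probe {probe!r} annotated more than once")
        if sym:
            mapping[probe] = sym
    return ProbeAnnotation(mapping)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Duplicate members within a line are collapsed; duplicate set names are a
    hard error. Empty member fields (trailing tabs) are ignored.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = frozenset(m for m in fields[2:] if m.strip())
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection:
            desc = collection.categories.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


_SHARED_TABLE_RESOURCE = "cobalt_zinc_shared_genes.tsv"
_N_RECORDS = 66
_N_UP = 54
_N_DOWN = 12


def load_shared_gene_table() -> list[SharedGeneRecord]:
    """Load the packaged table of 66 genes modulated by both cobalt and hypoxia.

    Each record carries the gene's signed linear fold change under cobalt
    vs untreated (C-0) and under zinc+cobalt vs cobalt (ZC-C). The table is
    validated on load: 54 up / 12 down records, direction consistent with
    the sign of the primary fold change, and every |C-0| >= 1.5 (the table
    was built downstream of a 1.5-fold differential-expression filter).
    """
    text = (
        resources.files("txrev").joinpath("data", _SHARED_TABLE_RESOURCE).read_text("utf-8")
    )
    lines = text.strip().split("\n")
    if lines[0].split("\t") != ["gene", "direction", "fc_C0", "fc_ZCC"]:
        raise ValueError("shared-gene table header corrupted")
    records: list[SharedGeneRecord] = []
    for line in lines[1:]:
        gene, direction, fc0, fczc = line.split("\t")
        rec = SharedGeneRecord(gene, direction, float(fc0), float(fczc))
        if (rec.direction == "up") != (rec.fc_primary > 0):
            raise ValueError(f"direction/sign mismatch for {gene}")
        for fc in (rec.fc_primary, rec.fc_counter):
            if abs(fc) < 1:
                raise ValueError(f"fold change {fc} of {gene} violates |FC| >= 1")
        if abs(rec.fc_primary) < 1.5:
            raise ValueError(f"|C-0| of {gene} below the 1.5-fold filter")
        records.append(rec)
    n_up = sum(r.direction == "up" for r in records)
    if len(records) != _N_RECORDS or n_up != _N_UP:
        raise ValueError(
            f"shared-gene table corrupted: {len(records)} records, {n_up} up "
            f"(expected {_N_RECORDS}/{_N_UP})"
        )
    return records
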