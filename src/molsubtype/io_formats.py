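"""Readers, writers and validated containers for the pipeline's external artifacts.

All tabular artifacts are tab-separated by default (comma via ``delimiter``),
header-first, and every reader/writer pair is a lossless round trip on valid
objects. Gene identifiers are opaque, case-sensitive strings; no symbol/ID
mapping is attempted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "PathwayScoreMatrix",
    "GeneSetCollection",
    "DrugSignature",
    "DrugSignatureLibrary",
    "ValidationError",
    "ParseError",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_drug_library",
    "write_drug_library",
    "read_target_map",
    "write_target_map",
    "read_labels",
    "write_labels",
    "write_scores",
    "read_scores",
    "write_signatures",
    "read_signatures",
]


class ValidationError(ValueError):
    """An artifact violates a data-contract invariant."""


class ParseError(ValueError):
    """An artifact cannot be parsed; the message names the offending location."""


def _check_unique_ids(ids: Sequence[str], what: str) -> None:
    if any((not isinstance(i, str)) or i == "" for i in ids):
        raise ValidationError(f"{what} must be non-empty strings")
    seen: set[str] = set()
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log-scale normalized expression.

    Values are expected to be already normalized (e.g. log2(CPM+1)); this
    package performs no alignment, counting or library-size normalization.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique_ids(self.gene_ids, "gene ids")
        _check_unique_ids(self.sample_ids, "sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(map(str, frame.index)), list(map(str, frame.columns)),
                   frame.to_numpy(dtype=float))

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), self.sample_ids, self.values[rows])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(self.gene_ids, list(samples), self.values[:, cols])


@dataclass
class PathwayScoreMatrix:
    """Gene-set x sample matrix of single-sample enrichment scores.

    Raw enrichment scores lie in [-1, 1]; after :func:`molsubtype.gsva.normalize_scores`
    rows are z-scores and the bound no longer applies (``normalized`` records this).
    """

    set_names: list[str]
    sample_ids: list[str]
    scores: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.set_names = list(self.set_names)
        self.sample_ids = list(self.sample_ids)
        self.scores = np.asarray(self.scores, dtype=float)
        _check_unique_ids(self.set_names, "set names")
        _check_unique_ids(self.sample_ids, "sample ids")
        if self.scores.shape != (len(self.set_names), len(self.sample_ids)):
            raise ValidationError("score matrix shape does not match names")
        if not np.isfinite(self.scores).all():
            raise ValidationError("scores contain non-finite values")
        if not self.normalized and self.scores.size:
            if self.scores.min() < -1 - 1e-9 or self.scores.max() > 1 + 1e-9:
                raise ValidationError("raw enrichment scores must lie in [-1, 1]")

    @property
    def n_sets(self) -> int:
        return len(self.set_names)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.set_names, columns=self.sample_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> (description, member genes)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, frozenset[str]]] = {}
        for name, (desc, genes) in self.sets.items():
            genes = frozenset(genes)
            if not name:
                raise ValidationError("gene-set name must be non-empty")
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            clean[name] = (desc, genes)
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def items(self):
        return self.sets.items()

    def restricted(self, universe: set[str], min_size: int = 1,
                   max_size: int | None = None) -> "GeneSetCollection":
        """Intersect every set with ``universe`` and drop sets outside the size band."""
        out: dict[str, tuple[str, frozenset[str]]] = {}
        for name, (desc, genes) in self.sets.items():
            hit = genes & universe
            if len(hit) < min_size:
                continue
            if max_size is not None and len(hit) > max_size:
                continue
            out[name] = (desc, frozenset(hit))
        return GeneSetCollection(out)


@dataclass(frozen=True)
class DrugSignature:
    """One drug-induced expression signature in one cell line."""

    drug_id: str
    cell_line: str
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        if not self.up or not self.down:
            raise ValidationError(
                f"drug {self.drug_id!r} ({self.cell_line}): up and down sets must both be non-empty"
            )
        if self.up & self.down:
            raise ValidationError(
                f"drug {self.drug_id!r} ({self.cell_line}): up/down sets overlap: "
                f"{sorted(self.up & self.down)[:5]}"
            )


@dataclass
class DrugSignatureLibrary:
    """Collection of per-(drug, cell line) up/down signatures."""

    entries: list[DrugSignature] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(e.drug_id, e.cell_line) for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValidationError("duplicate (drug_id, cell_line) entries in library")

    def __len__(self) -> int:
        return len(self.entries)

    def drug_ids(self) -> list[str]:
        """Unique drug ids, first-appearance order."""
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.drug_id, None)
        return list(seen)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a genes-in-rows expression table (first column = gene ids)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        sample_ids = header[1:]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec or (len(rec) == 1 and rec[0] == ""):
                continue
            if len(rec) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} fields, got {len(rec)}")
            gene_ids.append(rec[0])
            vals = []
            for col, cell in enumerate(rec[1:], start=1):
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: malformed numeric cell {cell!r} "
                        f"(gene {rec[0]!r}, sample {header[col]!r})"
                    ) from None
                if not np.isfinite(vals[-1]):
                    raise ParseError(
                        f"{path}:{lineno}: non-finite cell {cell!r} "
                        f"(gene {rec[0]!r}, sample {header[col]!r})"
                    )
            rows.append(vals)
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=float))


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     delimiter: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=delimiter, index_label="gene_id",
                             lineterminator="\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name TAB description TAB gene...``.

    Duplicate genes within a line are collapsed; duplicate set names are an error.
    """
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = (desc, genes)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, (desc, genes) in collection.items():
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_drug_library(path: str | Path, delimiter: str = "\t") -> DrugSignatureLibrary:
    """Read a long-format drug signature table with columns
    (drug_id, cell_line, direction, gene); direction is ``up`` or ``down``."""
    frame = pd.read_csv(path, sep=delimiter, dtype=str)
    required = ["drug_id", "cell_line", "direction", "gene"]
    if list(frame.columns) != required:
        raise ParseError(f"{path}: expected columns {required}, got {list(frame.columns)}")
    entries = []
    for (drug, cell), grp in frame.groupby(["drug_id", "cell_line"], sort=True):
        bad = set(grp["direction"]) - {"up", "down"}
        if bad:
            raise ParseError(f"{path}: drug {drug!r}: unknown direction {sorted(bad)}")
        up = frozenset(grp.loc[grp["direction"] == "up", "gene"])
        down = frozenset(grp.loc[grp["direction"] == "down", "gene"])
        entries.append(DrugSignature(str(drug), str(cell), up, down))
    return DrugSignatureLibrary(entries)


def write_drug_library(library: DrugSignatureLibrary, path: str | Path,
                       delimiter: str = "\t") -> None:
    rows = []
    for e in library.entries:
        rows += [(e.drug_id, e.cell_line, "up", g) for g in sorted(e.up)]
        rows += [(e.drug_id, e.cell_line, "down", g) for g in sorted(e.down)]
    pd.DataFrame(rows, columns=["drug_id", "cell_line", "direction", "gene"]).to_csv(
        path, sep=delimiter, index=False, lineterminator="\n")


def read_target_map(path: str | Path, delimiter: str = "\t") -> dict[str, frozenset[str]]:
    """Read a (drug_id, target) long table into drug -> target-set mapping."""
    frame = pd.read_csv(path, sep=delimiter, dtype=str)
    if list(frame.columns) != ["drug_id", "target"]:
        raise ParseError(f"{path}: expected columns ['drug_id', 'target']")
    out: dict[str, set[str]] = {}
    for drug, grp in frame.groupby("drug_id", sort=True):
        targets = set(grp["target"].dropna())
        if not targets:
            raise ValidationError(f"{path}: drug {drug!r} mapped to no targets")
        out[str(drug)] = targets
    return {d: frozenset(t) for d, t in out.items()}


def write_target_map(target_map: Mapping[str, frozenset[str]], path: str | Path,
                     delimiter: str = "\t") -> None:
    rows = [(d, t) for d in sorted(target_map) for t in sorted(target_map[d])]
    pd.DataFrame(rows, columns=["drug_id", "target"]).to_csv(
        path, sep=delimiter, index=False, lineterminator="\n")


def write_labels(labels: Mapping[str, int], path: str | Path,
                 delimiter: str = "\t") -> None:
    pd.DataFrame({"sample_id": list(labels), "cluster": list(labels.values())}).to_csv(
        path, sep=delimiter, index=False, lineterminator="\n")


def read_labels(path: str | Path, delimiter: str = "\t") -> dict[str, int]:
    frame = pd.read_csv(path, sep=delimiter, dtype={"sample_id": str, "cluster": int})
    if list(frame.columns) != ["sample_id", "cluster"]:
        raise ParseError(f"{path}: expected columns ['sample_id', 'cluster']")
    return dict(zip(frame["sample_id"], frame["cluster"]))


def write_scores(scores: PathwayScoreMatrix, path: str | Path,
                 delimiter: str = "\t") -> None:
    scores.to_frame().to_csv(path, sep=delimiter, index_label="set_name",
                             lineterminator="\n")


def read_scores(path: str | Path, delimiter: str = "\t",
                normalized: bool = False) -> PathwayScoreMatrix:
    frame = pd.read_csv(path, sep=delimiter, index_col=0)
    return PathwayScoreMatrix(list(map(str, frame.index)),
                              list(map(str, frame.columns)),
                              frame.to_numpy(dtype=float), normalized=normalized)


def write_signatures(table: pd.DataFrame, path: str | Path,
                     delimiter: str = "\t") -> None:
    """Write a signature or enrichment table (delimiter-stable, header-first)."""
    table.to_csv(path, sep=delimiter, index=False, lineterminator="\n")


def read_signatures(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter)
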