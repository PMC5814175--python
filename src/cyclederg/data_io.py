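"""Readers and writers for expression matrices, gene sets, and clinical tables.

All on-disk formats are plain text: expression matrices are TSV with genes
as rows (first header cell ``gene_id``), gene sets use the standard GMT
dialect, and clinical tables are TSV with columns ``sample_id``,
``time_days``, ``event`` and an optional ``covariate``.

Missing expression values are the literal token ``NA`` only; they are
carried as NaN in memory, excluded from medians and tests downstream, and
never imputed.  Gene identifiers are matched case-sensitively with no alias
resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

__all__ = [
    "ExpressionDataset",
    "GeneSet",
    "SurvivalTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_survival_table",
    "write_survival_table",
    "write_run_summary",
]


class DataValidationError(ValueError):
    """Raised when an input file or in-memory object violates an invariant."""


def _check_unique(ids: Sequence[str], kind: str, path: object = None) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            where = f" in {path}" if path is not None else ""
            raise DataValidationError(f"duplicate {kind} ID {x!r}{where}")
        seen.add(x)
    if not seen:
        raise DataValidationError(f"no {kind} IDs found")


@dataclass
class ExpressionDataset:
    """Log2 expression values for genes × samples with cohort labels.

    ``values`` has one row per gene and one column per sample; entries are
    finite floats or NaN for flagged-missing.  ``cohort_of`` maps every
    sample to exactly one cohort label.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    cohort_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.isinf(self.values).any():
            raise DataValidationError("expression values must be finite or NA")
        if not self.cohort_of:
            self.cohort_of = {s: "default" for s in self.sample_ids}
        missing = [s for s in self.sample_ids if s not in self.cohort_of]
        if missing:
            raise DataValidationError(f"samples without cohort label: {missing[:5]}")
        extra = [s for s in self.cohort_of if s not in set(self.sample_ids)]
        if extra:
            raise DataValidationError(
                f"cohort map names samples absent from the matrix: {extra[:5]}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def cohorts(self) -> list[str]:
        """Cohort labels in first-appearance order over samples."""
        out: list[str] = []
        for s in self.sample_ids:
            c = self.cohort_of[s]
            if c not in out:
                out.append(c)
        return out

    def cohort_columns(self, cohort: str) -> np.ndarray:
        idx = [j for j, s in enumerate(self.sample_ids) if self.cohort_of[s] == cohort]
        if not idx:
            raise DataValidationError(f"unknown cohort {cohort!r}")
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSet:
    """A named flat set of gene identifiers (e.g. a GO term's members)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise DataValidationError("gene set name must be non-empty")
        self.members = frozenset(self.members)


@dataclass
class SurvivalRecord:
    sample_id: str
    time: float
    event: bool
    covariate: float | None = None


@dataclass
class SurvivalTable:
    """Time-to-event records; ``event`` is True when death was observed."""

    records: list[SurvivalRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise DataValidationError("survival table must have at least one record")
        _check_unique([r.sample_id for r in self.records], "sample")
        for r in self.records:
            if r.time < 0:
                raise DataValidationError(
                    f"negative time {r.time} for sample {r.sample_id!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records], dtype=float)

    @property
    def events(self) -> np.ndarray:
        return np.array([r.event for r in self.records], dtype=bool)

    @property
    def covariates(self) -> np.ndarray:
        return np.array(
            [np.nan if r.covariate is None else r.covariate for r in self.records],
            dtype=float,
        )

    def subset(self, sample_ids: Sequence[str]) -> "SurvivalTable":
        keep = set(sample_ids)
        return SurvivalTable([r for r in self.records if r.sample_id in keep])


# ---------------------------------------------------------------------------
# expression TSV

def read_expression_matrix(
    path: str | Path, cohort_map_path: str | Path | None = None
) -> ExpressionDataset:
    """Read a genes × samples TSV of log2 expression.

    First column holds gene IDs (header cell ``gene_id``); remaining header
    cells are sample IDs; data cells are numeric or the literal ``NA``.
    Without a cohort map every sample is assigned to cohort ``"default"``.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [ln for ln in fh.read().splitlines() if not ln.startswith("#")]
    if not lines:
        raise DataValidationError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[0] != "gene_id":
        raise DataValidationError(
            f"{path}: first header cell must be 'gene_id', got {header[0]!r} "
            "(column-oriented files are rejected, not guessed)"
        )
    sample_ids = header[1:]
    _check_unique(sample_ids, "sample", path)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for i, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise DataValidationError(
                f"{path}:{i}: expected {len(header)} fields, got {len(cells)}"
            )
        gene_ids.append(cells[0])
        row: list[float] = []
        for j, cell in enumerate(cells[1:], start=2):
            if cell == "NA":
                row.append(np.nan)
            else:
                try:
                    row.append(float(cell))
                except ValueError:
                    raise DataValidationError(
                        f"{path}:{i}: non-numeric cell {cell!r} in column {j}"
                    ) from None
        rows.append(row)
    _check_unique(gene_ids, "gene", path)
    cohort_of: dict[str, str] = {}
    if cohort_map_path is not None:
        cohort_of = _read_cohort_map(Path(cohort_map_path), set(sample_ids))
    return ExpressionDataset(gene_ids, sample_ids, np.array(rows, dtype=float), cohort_of)


def _read_cohort_map(path: Path, known_samples: set[str]) -> dict[str, str]:
    out: dict[str, str] = {}
    with path.open() as fh:
        for i, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if i == 1 and parts[:2] == ["sample_id", "cohort"]:
                continue
            if len(parts) < 2:
                raise DataValidationError(f"{path}:{i}: expected sample_id<TAB>cohort")
            sample, cohort = parts[0], parts[1]
            if sample not in known_samples:
                raise DataValidationError(
                    f"{path}:{i}: sample {sample!r} absent from expression matrix"
                )
            out[sample] = cohort
    return out


def _header_comment(seed: int | None) -> str:
    seed_part = "" if seed is None else f" seed={seed}"
    return f"# cyclederg v{__version__}{seed_part}"


def write_expression_matrix(
    dataset: ExpressionDataset, path: str | Path, seed: int | None = None
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header_comment(seed) + "\n")
        fh.write("gene_id\t" + "\t".join(dataset.sample_ids) + "\n")
        for g, row in zip(dataset.gene_ids, dataset.values):
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(g + "\t" + "\t".join(cells) + "\n")


def write_cohort_map(dataset: ExpressionDataset, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\tcohort\n")
        for s in dataset.sample_ids:
            fh.write(f"{s}\t{dataset.cohort_of[s]}\n")


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: one set per line, ``name TAB description TAB member...``."""
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open() as fh:
        for i, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln:
                continue
            fields = ln.split("\t")
            if len(fields) < 3:
                raise DataValidationError(
                    f"{path}:{i}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            sets.append(GeneSet(name, desc, frozenset(members)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for gs in sets:
            fh.write(gs.name + "\t" + gs.description + "\t")
            fh.write("\t".join(sorted(gs.members)) + "\n")


# ---------------------------------------------------------------------------
# clinical survival tables

def read_survival_table(path: str | Path) -> SurvivalTable:
    """Read a clinical TSV with columns sample_id, time_days, event[, covariate]."""
    path = Path(path)
    records: list[SurvivalRecord] = []
    with path.open() as fh:
        header: list[str] | None = None
        for i, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if header is None and parts[0] == "sample_id":
                header = parts
                continue
            if len(parts) < 3:
                raise DataValidationError(f"{path}:{i}: expected >= 3 fields")
            sample, time_s, event_s = parts[0], parts[1], parts[2]
            time = float(time_s)
            if time < 0:
                raise DataValidationError(f"{path}:{i}: negative time {time}")
            if event_s not in ("0", "1"):
                raise DataValidationError(
                    f"{path}:{i}: event must be 0 or 1, got {event_s!r}"
                )
            cov = float(parts[3]) if len(parts) > 3 and parts[3] != "NA" else None
            records.append(SurvivalRecord(sample, time, event_s == "1", cov))
    return SurvivalTable(records)


def write_survival_table(
    table: SurvivalTable, path: str | Path, seed: int | None = None
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header_comment(seed) + "\n")
        fh.write("sample_id\ttime_days\tevent\tcovariate\n")
        for r in table.records:
            cov = "NA" if r.covariate is None else repr(float(r.covariate))
            fh.write(f"{r.sample_id}\t{r.time!r}\t{int(r.event)}\t{cov}\n")


def write_run_summary(summary: Mapping, path: str | Path) -> None:
    """Write a JSON run summary next to result tables."""
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
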