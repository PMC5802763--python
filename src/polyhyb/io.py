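"""Table readers/writers and the roles/threshold configuration.

All tables are TSV with a header row. The only externally defined format
consumed is 12-column BLAST tabular output (``-outfmt 6``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._util import as_binary_array
from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

BLAST_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

__all__ = [
    "RolesConfig",
    "read_marker_table",
    "write_marker_table",
    "read_msap_table",
    "write_msap_table",
    "read_counts",
    "read_series",
    "read_blast_tabular",
    "write_tsv",
    "write_json",
]


@dataclass
class RolesConfig:
    """Line-role assignment plus analysis thresholds.

    Exactly one maternal, paternal and hybrid column name; zero or more
    allopolyploid column names. Threshold fields keep the analysis-wide
    defaults unless overridden in the config file.
    """

    maternal: str = "maternal"
    paternal: str = "paternal"
    hybrid: str = "hybrid"
    allopolyploids: list[str] = field(default_factory=list)
    deg_log2_fold: float = 1.0
    detection_fpkm: float = 0.0
    epsilon: float = 1e-3
    homolog_max_evalue: float = 9e-100
    homolog_min_align_length: int = 200
    homolog_min_identity: float = 90.0
    p_threshold: float | None = None
    seed: int = 0

    def __post_init__(self):
        names = [self.maternal, self.paternal, self.hybrid, *self.allopolyploids]
        if any(not isinstance(n, str) or not n for n in names):
            raise ConfigError("role names must be non-empty strings")
        if len(set(names)) != len(names):
            raise ConfigError("role column names must be distinct")
        for attr in ("deg_log2_fold", "homolog_min_align_length", "homolog_min_identity"):
            if getattr(self, attr) <= 0:
                raise ConfigError(f"{attr} must be positive")
        if self.epsilon <= 0 or self.homolog_max_evalue < 0 or self.detection_fpkm < 0:
            raise ConfigError("thresholds must be non-negative (epsilon positive)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RolesConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    @property
    def all_lines(self) -> list[str]:
        return [self.maternal, self.paternal, self.hybrid, *self.allopolyploids]


def _read_tsv(path: str | Path, index_col: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    table = pd.read_csv(path, sep="\t")
    if table.columns[0] != index_col:
        raise ValidationError(
            f"{path}: first column must be {index_col!r}, found {table.columns[0]!r}"
        )
    if table[index_col].duplicated().any():
        dup = table[index_col][table[index_col].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate {index_col} {dup!r}")
    table = table.set_index(index_col)
    logger.info("read %d rows from %s", len(table), path)
    return table


def _check_binary(table: pd.DataFrame, path) -> pd.DataFrame:
    for col in table.columns:
        values = table[col]
        bad = ~values.isin((0, 1))
        if bad.any():
            row = int(bad.to_numpy().nonzero()[0][0]) + 2  # header is line 1
            raise ValidationError(
                f"{path}: non-binary value {values[bad].iloc[0]!r} "
                f"in column {col!r} at line {row}"
            )
        table[col] = as_binary_array(values, col)
    return table


def read_marker_table(path: str | Path) -> pd.DataFrame:
    """Read a fragment x line presence/absence TSV (first column fragment_id)."""
    return _check_binary(_read_tsv(path, "fragment_id"), path)


def write_marker_table(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.rename_axis("fragment_id").to_csv(path, sep="\t")


def read_msap_table(path: str | Path) -> pd.DataFrame:
    """Read an MSAP dual-lane TSV: site_id, then ``<line>_H``/``<line>_M`` pairs."""
    table = _check_binary(_read_tsv(path, "site_id"), path)
    lines = {c[:-2] for c in table.columns if c.endswith(("_H", "_M"))}
    for line in sorted(lines):
        for suffix in ("_H", "_M"):
            if line + suffix not in table.columns:
                raise ValidationError(f"{path}: missing column {line + suffix!r}")
    stray = [c for c in table.columns if not c.endswith(("_H", "_M"))]
    if stray:
        raise ValidationError(f"{path}: column {stray[0]!r} is not a lane column")
    return table


def write_msap_table(table: pd.DataFrame, path: str | Path) -> None:
    table.rename_axis("site_id").to_csv(path, sep="\t")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample integer count TSV (first column gene_id)."""
    table = _read_tsv(path, "gene_id")
    for col in table.columns:
        if not pd.api.types.is_integer_dtype(table[col]):
            raise ValidationError(f"{path}: column {col!r} is not integer counts")
        if (table[col] < 0).any():
            raise ValidationError(f"{path}: negative count in column {col!r}")
    return table


def read_series(path: str | Path, index_col: str, value_col: str) -> pd.Series:
    """Read a two-column TSV (e.g. gene lengths, library sizes) into a Series."""
    table = _read_tsv(path, index_col)
    if value_col not in table.columns:
        raise ValidationError(f"{path}: missing column {value_col!r}")
    return table[value_col]


def read_blast_tabular(path: str | Path) -> pd.DataFrame:
    """Read 12-column BLAST tabular matches into the homolog-match schema.

    Malformed rows are skipped with a warning rather than aborting the run.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                logger.warning("%s:%d: expected 12 columns, got %d; skipped", path, lineno, len(parts))
                continue
            try:
                rows.append(
                    {
                        "query_id": parts[0],
                        "subject_id": parts[1],
                        "identity": float(parts[2]),
                        "alignment_length": int(parts[3]),
                        "evalue": float(parts[10]),
                        "bitscore": float(parts[11]),
                    }
                )
            except ValueError as exc:
                logger.warning("%s:%d: %s; skipped", path, lineno, exc)
    return pd.DataFrame(
        rows,
        columns=["query_id", "subject_id", "identity", "alignment_length", "evalue", "bitscore"],
    )


def write_tsv(table: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    table.to_csv(path, sep="\t", index_label=index_label)


def write_json(payload: dict, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")
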