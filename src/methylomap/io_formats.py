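"""Readers and writers for the external files the pipeline touches.

All tabular inputs are tab-delimited UTF-8 with a header row; lines starting
with ``#`` are comments.  Missing numeric cells are kept as explicit NaN
("absent") values — downstream substrate calling distinguishes a site whose
heavy channel was never observed from one observed at low intensity.
Residue positions are 1-based throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

METHYL_TYPES = ("MMA", "aDMA", "sDMA")
SPLICE_EVENT_TYPES = ("SE", "IR", "MXE", "A5SS", "A3SS")


class SchemaError(ValueError):
    """A table failed schema validation (missing column, bad value...)."""


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str  # one of: str, int, float, category:<v1|v2|...>
    required: bool = True


@dataclass(frozen=True)
class TableSchema:
    """Named, ordered column contract for one tab-delimited input."""

    name: str
    columns: tuple[ColumnSpec, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if len(names) != len(set(names)):
            raise SchemaError(f"schema {self.name!r}: duplicate column names")

    @property
    def required_names(self) -> list[str]:
        return [c.name for c in self.columns if c.required]


SITE_QUANT_SCHEMA = TableSchema(
    "site_quant",
    (
        ColumnSpec("protein", "str"),
        ColumnSpec("position", "int"),
        ColumnSpec("methyl_type", "category:" + "|".join(METHYL_TYPES)),
        ColumnSpec("intensity_L", "float"),
        ColumnSpec("intensity_H", "float"),
    ),
)

PROTEIN_QUANT_SCHEMA = TableSchema(
    "protein_quant",
    (
        ColumnSpec("protein", "str"),
        ColumnSpec("intensity_L", "float"),
        ColumnSpec("intensity_H", "float"),
    ),
)

PHOSPHO_SCHEMA = TableSchema(
    "phospho",
    (ColumnSpec("protein", "str"), ColumnSpec("position", "int")),
)

MUTATION_SCHEMA = TableSchema(
    "mutation",
    (
        ColumnSpec("protein", "str"),
        ColumnSpec("position", "int"),
        ColumnSpec("count", "int"),
    ),
)

SPLICE_COUNTS_SCHEMA = TableSchema(
    "splice_counts",
    (
        ColumnSpec("event_id", "str"),
        ColumnSpec("event_type", "category:" + "|".join(SPLICE_EVENT_TYPES)),
        ColumnSpec("condition", "str"),
        ColumnSpec("inc_count", "int"),
        ColumnSpec("skip_count", "int"),
        ColumnSpec("inc_len", "float"),
        ColumnSpec("skip_len", "float"),
    ),
)

EVENT_SEQ_SCHEMA = TableSchema(
    "event_seq",
    (ColumnSpec("event_id", "str"), ColumnSpec("upstream_sequence", "str")),
)


@dataclass
class ProteomeDB:
    """In-memory proteome: protein ID -> upper-case amino-acid sequence."""

    records: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, seq in self.records.items():
            if not seq:
                raise ValueError(f"protein {pid!r}: empty sequence")
            bad = set(seq) - AA_ALPHABET
            if bad:
                raise ValueError(
                    f"protein {pid!r}: illegal residues {sorted(bad)!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, pid: str) -> bool:
        return pid in self.records

    def __getitem__(self, pid: str) -> str:
        return self.records[pid]

    def items(self):
        return self.records.items()


def read_fasta(path: str | Path) -> ProteomeDB:
    """Read a protein FASTA into a :class:`ProteomeDB`.

    The header token before the first whitespace is the protein ID; any
    description is dropped.  Duplicate IDs and empty sequences are hard
    errors (silently keeping one copy would corrupt position-based joins).
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in records:
            raise ValueError(f"duplicate ID {pid!r} in {path}")
        seq = str(rec.seq).upper().strip()
        if not seq:
            raise ValueError(f"empty sequence for {pid!r} in {path}")
        records[pid] = seq
    return ProteomeDB(records)


def write_fasta(db: ProteomeDB, path: str | Path, width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in db.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def _coerce_column(series: pd.Series, spec: ColumnSpec, name: str) -> pd.Series:
    raw = series.astype("string").str.strip()
    blank = raw.isna() | (raw == "") | (raw.str.upper() == "NA")
    if spec.kind == "str":
        if blank.any() and spec.required:
            row = int(np.flatnonzero(blank.to_numpy())[0]) + 2
            raise SchemaError(
                f"table {name!r}, column {spec.name!r}: empty value at line {row}"
            )
        return raw.astype(object)
    if spec.kind.startswith("category:"):
        allowed = set(spec.kind.split(":", 1)[1].split("|"))
        bad = ~blank & ~raw.isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise SchemaError(
                f"table {name!r}, column {spec.name!r}: "
                f"illegal value {raw[bad].iloc[0]!r} at line {row} "
                f"(allowed: {sorted(allowed)})"
            )
        return raw.astype(object)
    # numeric kinds: blanks become NaN ("absent"), anything unparsable errors
    numeric = pd.to_numeric(raw.where(~blank, other=pd.NA), errors="coerce")
    unparsable = ~blank & numeric.isna()
    if unparsable.any():
        row = int(np.flatnonzero(unparsable.to_numpy())[0]) + 2
        raise SchemaError(
            f"table {name!r}, column {spec.name!r}: "
            f"unparsable numeric {raw[unparsable].iloc[0]!r} at line {row}"
        )
    if spec.kind == "int":
        vals = numeric.dropna()
        if ((vals % 1) != 0).any():
            raise SchemaError(
                f"table {name!r}, column {spec.name!r}: non-integer value"
            )
        return numeric.astype("Int64")
    return numeric.astype(float)


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read a tab-delimited table and validate it against *schema*.

    Returns a DataFrame with exactly the schema's columns (extra columns are
    carried through after them).  Missing numeric cells become NaN.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype="string", keep_default_na=False
    )
    missing = [c for c in schema.required_names if c not in df.columns]
    if missing:
        raise SchemaError(
            f"table {schema.name!r} at {path}: missing required column(s) "
            f"{missing}"
        )
    out = {}
    for spec in schema.columns:
        if spec.name in df.columns:
            out[spec.name] = _coerce_column(df[spec.name], spec, schema.name)
    result = pd.DataFrame(out)
    for col in df.columns:
        if col not in result.columns:
            result[col] = df[col].astype(object)
    return result


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: ``name TAB description TAB member...`` per line.

    Members are deduplicated; duplicate set names are a hard error; a set
    with no members is kept (empty) with a warning.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise SchemaError(
                    f"GMT {path}, line {lineno}: need name and description"
                )
            name = fields[0]
            if name in sets:
                raise SchemaError(f"GMT {path}: duplicate set name {name!r}")
            members = {m for m in fields[2:] if m}
            if not members:
                logger.warning("GMT %s: set %r is empty", path, name)
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, ""] + sorted(set(members))) + "\n")
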