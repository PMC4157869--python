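"""Shared I/O and primitive types: FASTA records, genomic intervals,
expression tables, flat key-value configs, and logging plumbing.

Coordinates are 1-based and inclusive at both ends throughout the package;
any half-open arithmetic is internal to a function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord


class PollenKitError(Exception):
    """Base class for all package errors."""


class ParseError(PollenKitError):
    """A file could not be parsed."""


class ValidationError(PollenKitError):
    """Input data violates a documented invariant."""


class ConfigurationError(PollenKitError):
    """Parameters or configuration are inconsistent with the data."""


def get_logger(name: str) -> logging.Logger:
    return logging.getLogger(f"pollenkit.{name}")


log = get_logger("io_core")

# IUPAC nucleotide codes; N matches any base, the others are ambiguity codes.
IUPAC_DNA = set("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Sequence records


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (promoter, plasmid, primer, genome region)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"sequence of record {self.id!r} is empty")
        bad = set(self.sequence.upper()) - IUPAC_DNA
        if bad:
            raise ValidationError(
                f"record {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file, uppercasing sequences.

    Record order is preserved; duplicate ids and empty files are errors.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path}:{lineno}: expected FASTA header '>' but got {line.strip()[:30]!r}"
                    )
                break
        else:
            raise ParseError(f"{path}: empty FASTA file")
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, str(rec.seq), desc))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, line_width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    records = list(records)
    if not records:
        raise ValidationError("refusing to write an empty FASTA file")
    if line_width < 1:
        raise ValidationError("line_width must be positive")
    bio = [
        _BioRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Genomic intervals


@dataclass(frozen=True)
class GenomicInterval:
    """1-based, both-ends-inclusive interval on a named reference."""

    reference_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"interval end ({self.end}) precedes start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")


def interval_length(iv: GenomicInterval) -> int:
    """Length in base pairs of a 1-based inclusive interval."""
    return iv.end - iv.start + 1


# ---------------------------------------------------------------------------
# Expression tables

PLATFORMS = ("mpss", "microarray", "rnaseq")
TISSUE_CLASSES = ("pollen", "anther", "vegetative", "other")


@dataclass
class ExpressionTable:
    """Gene x tissue abundance matrix with a tissue-class annotation.

    ``values`` is a DataFrame indexed by gene id with tissue-id columns.
    Units are TPM for MPSS-like data and normalized intensities/abundances
    for microarray and RNA-Seq-like data.
    """

    values: pd.DataFrame
    tissue_classes: Mapping[str, str]
    platform: str

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValidationError(
                f"platform must be one of {PLATFORMS}, got {self.platform!r}"
            )
        if self.values.isna().any().any():
            raise ValidationError("expression table contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression table contains negative values")
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene ids in expression table")
        missing = [t for t in self.values.columns if t not in self.tissue_classes]
        if missing:
            raise ValidationError(f"tissues without a class annotation: {missing}")
        bad = {
            t: c
            for t, c in self.tissue_classes.items()
            if c not in TISSUE_CLASSES
        }
        if bad:
            raise ValidationError(f"unknown tissue classes: {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.values.columns)

    def tissues_of_class(self, *classes: str) -> list[str]:
        return [t for t in self.values.columns if self.tissue_classes[t] in classes]

    def subset(self, gene_ids: Iterable[str]) -> "ExpressionTable":
        ids = [g for g in gene_ids if g in self.values.index]
        return ExpressionTable(self.values.loc[ids], dict(self.tissue_classes), self.platform)


def read_expression_table(
    path: str | Path, class_map: Mapping[str, str], platform: str
) -> ExpressionTable:
    """Read a TSV matrix (header = tissue ids, first column = gene ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: empty expression table")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value ({exc})") from exc
    df.index = df.index.astype(str)
    table = ExpressionTable(df, dict(class_map), platform)
    log.info(
        "read %s table %s: %d genes x %d tissues",
        platform, path, len(table.gene_ids), len(table.tissue_ids),
    )
    return table


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Flat key-value configuration


def read_config(path: str | Path) -> dict:
    """Read a flat key-value (YAML) config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a flat key-value mapping")
    for key, value in data.items():
        if isinstance(value, (dict, list)):
            raise ParseError(f"{path}: config key {key!r} is not a flat value")
    return data


def write_config(config: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, default_flow_style=False, sort_keys=True)
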