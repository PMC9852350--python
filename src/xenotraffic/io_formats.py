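"""Readers and writers for the external formats the pipeline touches.

The pipeline consumes assembled transcripts (FASTA), homology evidence
(12-column BLAST tabular hit tables), expression tables (TSV with one
column per sequencing library) and a YAML run configuration.  Everything
here is strict: malformed rows, duplicate identifiers and negative
expression values are hard errors rather than silent drops.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GROUPS = ("CD", "HC", "HA", "HI")
#: nucleotide alphabet accepted after parsing
_VALID_BASES = frozenset("ACGTN")

HIT_TABLE_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


class FormatError(ValueError):
    """Raised for any malformed input file."""


@dataclass(frozen=True)
class UnigeneRecord:
    """One assembled transcript (the unit gene proxy of the pipeline)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("unigene id must be non-empty")
        if not self.seq:
            raise ValueError(f"unigene {self.id!r}: empty sequence")
        bad = next((i for i, c in enumerate(self.seq) if c not in _VALID_BASES), None)
        if bad is not None:
            raise FormatError(
                f"unigene {self.id!r}: non-IUPAC character {self.seq[bad]!r} "
                f"at position {bad}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SampleDesign:
    """One sequencing library: group (CD/HC/HA/HI) and replicate number."""

    library_id: str
    group: str
    replicate: int

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


def default_design() -> list[SampleDesign]:
    """Three biological replicates for CD, HC and HA, one for HI."""
    design = []
    for group, nrep in (("CD", 3), ("HC", 3), ("HA", 3), ("HI", 1)):
        for rep in range(1, nrep + 1):
            design.append(SampleDesign(f"{group}_{rep}", group, rep))
    return design


def validate_design(design: Sequence[SampleDesign]) -> None:
    pairs = [(d.group, d.replicate) for d in design]
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate (group, replicate) pair in design")
    ids = [d.library_id for d in design]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate library_id in design")


@dataclass
class ExpressionMatrix:
    """Unigene x library expression values (raw counts or FPKM)."""

    unigene_ids: list[str]
    libraries: list[SampleDesign]
    values: np.ndarray
    value_kind: str  # "count" or "fpkm"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.unigene_ids), len(self.libraries)):
            raise ValueError(
                f"value matrix shape {self.values.shape} inconsistent with "
                f"{len(self.unigene_ids)} unigenes x {len(self.libraries)} libraries"
            )
        if len(set(self.unigene_ids)) != len(self.unigene_ids):
            raise ValueError("unigene_ids not unique")
        if self.value_kind not in ("count", "fpkm"):
            raise ValueError(f"value_kind must be 'count' or 'fpkm', got {self.value_kind!r}")
        if np.any(self.values < 0):
            raise ValueError("negative expression values are not allowed")
        validate_design(self.libraries)

    def group_columns(self, group: str) -> list[int]:
        cols = [j for j, d in enumerate(self.libraries) if d.group == group]
        return cols

    def group_values(self, group: str) -> np.ndarray:
        cols = self.group_columns(group)
        if not cols:
            raise ValueError(f"no libraries for group {group!r}")
        return self.values[:, cols]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.unigene_ids, name="unigene_id"),
            columns=[d.library_id for d in self.libraries],
        )


@dataclass(frozen=True)
class HomologyHit:
    """One local-alignment (or k-mer surrogate) match against a reference set."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    evalue: float
    bitscore: float
    refset: str

    def __post_init__(self):
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


@dataclass
class RunConfig:
    """All tunable thresholds of a pipeline run.

    The expression presence threshold (FPKM >= 0.3 in at least one
    replicate), the homology E-value cutoff (1e-10) and the enrichment
    FDR level (adjusted p < 0.05) are the study's stated constants; the
    ORF-length and k-mer parameters are package defaults.
    """

    fpkm_threshold: float = 0.3
    min_replicates_present: int = 1
    evalue_cutoff: float = 1e-10
    min_orf_nt: int = 300
    rng_seed: int = 0
    homology_backend: str = "kmer"  # "hit_table" or "kmer"
    kmer_k: int = 21
    kmer_containment_min: float = 0.10
    fdr_alpha: float = 0.05
    log_pseudocount: float = 0.01

    def __post_init__(self):
        if self.fpkm_threshold <= 0:
            raise ValueError("fpkm_threshold must be strictly positive")
        if self.min_replicates_present < 1:
            raise ValueError("min_replicates_present must be >= 1")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be strictly positive")
        if self.min_orf_nt < 3 or self.min_orf_nt % 3:
            raise ValueError("min_orf_nt must be a positive multiple of 3")
        if self.homology_backend not in ("hit_table", "kmer"):
            raise ValueError(f"unknown homology_backend {self.homology_backend!r}")
        if self.kmer_k < 11 or self.kmer_k % 2 == 0:
            raise ValueError("kmer_k must be odd and >= 11")
        if not (0 < self.kmer_containment_min < 1):
            raise ValueError("kmer_containment_min must be in (0, 1)")
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[UnigeneRecord]:
    """Read a FASTA file into :class:`UnigeneRecord` objects.

    The header token before the first whitespace becomes the id (the
    remainder is kept as description); sequences are uppercased and
    wrapped lines concatenated.  Duplicate ids, empty sequences and
    non-ACGTN characters are hard errors.
    """
    records: list[UnigeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate unigene id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append(UnigeneRecord(rec.id, str(rec.seq).upper(), desc))
    return records


def write_fasta(records: Iterable[UnigeneRecord], path: str | Path, width: int = 60) -> None:
    seqs = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# BLAST tabular hit tables (12-column outfmt-6 layout)

def read_hit_table(path: str | Path, refset: str) -> list[HomologyHit]:
    """Read a tab-separated 12-column BLAST tabular file.

    Column layout: qseqid sseqid pident length mismatch gapopen qstart
    qend sstart send evalue bitscore.  Rows with a different column
    count or unparseable numerics raise :class:`FormatError` with the
    offending line number.  Extra columns are rejected (fail-fast), not
    ignored.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                hits.append(
                    HomologyHit(
                        query_id=parts[0],
                        subject_id=parts[1],
                        pct_identity=float(parts[2]),
                        align_len=int(parts[3]),
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                        refset=refset,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable numeric field: {exc}") from exc
    return hits


def write_hit_table(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits in the 12-column layout (unused columns written as 0)."""
    with open(path, "w") as fh:
        for h in hits:
            row = (
                h.query_id, h.subject_id, f"{h.pct_identity:g}", str(h.align_len),
                "0", "0", "0", "0", "0", "0", f"{h.evalue:g}", f"{h.bitscore:g}",
            )
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Expression tables

def read_expression_table(
    path: str | Path,
    design: Sequence[SampleDesign],
    value_kind: str = "count",
) -> ExpressionMatrix:
    """Read a TSV whose header names the library ids of *design*.

    Columns are reordered to match the design; a design library missing
    from the header, any missing cell, or a negative value is an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [d.library_id for d in design if d.library_id not in df.columns]
    if missing:
        raise FormatError(f"{path}: libraries missing from header: {missing}")
    df = df[[d.library_id for d in design]]
    if df.isna().any().any():
        raise FormatError(f"{path}: missing cells are not allowed")
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative expression values")
    return ExpressionMatrix(
        unigene_ids=[str(i) for i in df.index],
        libraries=list(design),
        values=df.values.astype(float),
        value_kind=value_kind,
    )


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# Small generic TSV helpers (presence sets, truth tables, tallies)

def read_tally_table(path: str | Path) -> dict[str, float]:
    """Read a two-column (key, value) TSV of integer/real tallies."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"\t", line)
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            key, value = parts
            if key in out:
                raise FormatError(f"{path}:{lineno}: duplicate key {key!r}")
            out[key] = float(value)
    return out
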