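"""Readers and writers for every external format the pipeline touches.

Formats handled here:

* FASTA (DNA and protein), via Biopython;
* InterProScan-style 11+-column hit tables, comma- or tab-separated;
* the domain x sample count matrix as TSV with a ``#transform=`` header;
* sample metadata TSV (sample_id, ISO date, filter pore in um, station,
  depth class);
* newick serialisation of dendrograms, with bootstrap percentages as
  internal node labels.

Hit-table coordinates are 1-based inclusive amino-acid positions, the
InterProScan convention.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .containers import Dendrogram, DomainCountMatrix, TRANSFORMS

logger = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGT")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
#: characters tolerated in either alphabet (unknown residue / gap)
EXTRA_CHARS = set("NX-*")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class DomainHit:
    """One domain match on one protein (one row of an InterProScan table)."""

    protein_id: str
    domain_id: str
    start: int
    end: int
    md5: str = ""
    protein_length: int | None = None
    database: str = ""
    domain_name: str = ""
    evalue: float = 0.0
    matched: bool = True
    run_date: str = ""

    def __post_init__(self) -> None:
        if not self.domain_id:
            raise FormatError("domain_id must be non-empty")
        if not 1 <= self.start <= self.end:
            raise FormatError(
                f"invalid coordinates {self.start}..{self.end} (1-based inclusive)"
            )
        if self.protein_length is not None and self.end > self.protein_length:
            raise FormatError(
                f"hit end {self.end} beyond protein length {self.protein_length}"
            )
        if not (self.evalue >= 0 or math.isnan(self.evalue)):
            raise FormatError(f"negative e-value {self.evalue}")


@dataclass
class SampleMetadata:
    """One environmental sample: collection covariates used for grouping."""

    sample_id: str
    collection_date: _dt.date
    filter_pore: float  # um: 0.2, 0.8 or 5.0
    station: str
    depth_class: str  # "surface" | "SCM"
    season_class: str = field(init=False)

    def __post_init__(self) -> None:
        if self.depth_class not in ("surface", "SCM"):
            raise FormatError(f"unknown depth class {self.depth_class!r}")
        self.season_class = season_of(self.collection_date)


def season_of(date: _dt.date) -> str:
    """Dichotomise a date into the cold (Dec-Apr) vs warm (May-Nov) season."""
    return "DecApr" if date.month in (12, 1, 2, 3, 4) else "MayNov"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path,
    alphabet: str = "dna",
    strict: bool = False,
) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, uppercased_sequence), ...]``.

    Characters outside the alphabet (beyond the tolerated N/X/-/*) are masked
    to N (DNA) or X (protein), or rejected when ``strict`` is true.
    """
    if alphabet not in ("dna", "protein"):
        raise ValueError(f"alphabet must be 'dna' or 'protein', got {alphabet!r}")
    allowed = (DNA_ALPHABET if alphabet == "dna" else PROTEIN_ALPHABET) | EXTRA_CHARS
    mask_char = "N" if alphabet == "dna" else "X"

    records: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for record {rec.id!r}")
        bad = set(seq) - allowed
        if bad:
            if strict:
                raise FormatError(
                    f"record {rec.id!r} contains characters outside the "
                    f"{alphabet} alphabet: {sorted(bad)}"
                )
            seq = "".join(c if c in allowed else mask_char for c in seq)
        seen[rec.id] = seen.get(rec.id, 0) + 1
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    dups = sorted(i for i, c in seen.items() if c > 1)
    if dups:
        raise FormatError(f"duplicate FASTA ids: {dups}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Domain hit tables
# ---------------------------------------------------------------------------

_HIT_COLUMNS = 11


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def read_domain_hits(path: str | Path, dialect: str | None = None) -> list[DomainHit]:
    """Parse an InterProScan-style hit table (11 mandatory columns).

    Column order: protein accession, MD5, protein length, database, domain id,
    domain name, start, end, e-value, matched flag, run date. Extra trailing
    option columns are tolerated. Rows whose matched flag is not true are
    retained with ``matched=False``.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"empty hit table: {path}")
    if dialect is None:
        delim = _sniff_delimiter(lines[0])
    elif dialect in ("tsv", "csv"):
        delim = "\t" if dialect == "tsv" else ","
    else:
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")

    hits: list[DomainHit] = []
    for lineno, row in enumerate(csv.reader(io.StringIO("\n".join(lines)), delimiter=delim), 1):
        if len(row) < _HIT_COLUMNS:
            raise FormatError(
                f"line {lineno}: expected >= {_HIT_COLUMNS} columns, got {len(row)}"
            )
        try:
            length = int(row[2]) if row[2].strip() else None
            start = int(row[6])
            end = int(row[7])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-integer coordinate field: {exc}") from exc
        try:
            evalue = float(row[8])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric e-value {row[8]!r}") from exc
        try:
            hit = DomainHit(
                protein_id=row[0],
                md5=row[1],
                protein_length=length,
                database=row[3],
                domain_id=row[4],
                domain_name=row[5],
                start=start,
                end=end,
                evalue=evalue,
                matched=row[9].strip().upper() in ("T", "TRUE", "1"),
                run_date=row[10],
            )
        except FormatError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
        if not hit.matched:
            logger.warning("line %d: unmatched hit retained (matched=%r)", lineno, row[9])
        hits.append(hit)
    return hits


def write_domain_hits(hits: Sequence[DomainHit], path: str | Path, dialect: str = "tsv") -> None:
    delim = "\t" if dialect == "tsv" else ","
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        for h in hits:
            writer.writerow(
                [
                    h.protein_id,
                    h.md5,
                    "" if h.protein_length is None else h.protein_length,
                    h.database,
                    h.domain_id,
                    h.domain_name,
                    h.start,
                    h.end,
                    repr(h.evalue),
                    "T" if h.matched else "F",
                    h.run_date,
                ]
            )


# ---------------------------------------------------------------------------
# Count matrix TSV
# ---------------------------------------------------------------------------

def write_matrix(matrix: DomainCountMatrix, path: str | Path) -> None:
    """Write a count matrix as TSV with the transform tag in a header comment.

    Orientation is fixed: domains are rows, samples are columns.
    """
    if matrix.data.empty:
        raise FormatError("refusing to write an empty matrix")
    with open(path, "w") as fh:
        fh.write(f"#transform={matrix.transform}\n")
        matrix.data.to_csv(fh, sep="\t", index_label="domain_id")


def read_matrix(path: str | Path) -> DomainCountMatrix:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"empty matrix file: {path}")
    transform = "raw"
    body_start = 0
    if lines[0].startswith("#"):
        key, _, value = lines[0][1:].partition("=")
        if key.strip() != "transform" or value.strip() not in TRANSFORMS:
            raise FormatError(f"unrecognised matrix header {lines[0]!r}")
        transform = value.strip()
        body_start = 1
    body = [ln for ln in lines[body_start:] if ln.strip()]
    if len(body) < 2:
        raise FormatError("matrix file has no data rows")
    header = body[0].split("\t")
    if header[0] != "domain_id":
        raise FormatError(
            "matrix file must start with a 'domain_id' column "
            "(transposed input? domains must be rows)"
        )
    ncol = len(header)
    for lineno, ln in enumerate(body[1:], 2):
        if len(ln.split("\t")) != ncol:
            raise FormatError(f"line {lineno}: ragged row ({len(ln.split(chr(9)))} != {ncol} fields)")
    df = pd.read_csv(io.StringIO("\n".join(body)), sep="\t", index_col="domain_id")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if transform == "raw":
        df = df.astype(int)
    return DomainCountMatrix(df, transform=transform)


# ---------------------------------------------------------------------------
# Sample metadata TSV
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "date", "pore", "station", "depth_class"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                collection_date=_dt.date.fromisoformat(row["date"]),
                filter_pore=float(row["pore"]),
                station=row["station"],
                depth_class=row["depth_class"],
            )
        )
    return out


def write_metadata(samples: Sequence[SampleMetadata], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "date": s.collection_date.isoformat(),
            "pore": s.filter_pore,
            "station": s.station,
            "depth_class": s.depth_class,
            "season_class": s.season_class,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def metadata_frame(samples: Sequence[SampleMetadata]) -> pd.DataFrame:
    """Covariate table indexed by sample id (adds the derived season class)."""
    return pd.DataFrame(
        {
            "pore": [s.filter_pore for s in samples],
            "station": [s.station for s in samples],
            "depth_class": [s.depth_class for s in samples],
            "season_class": [s.season_class for s in samples],
            "date": [s.collection_date for s in samples],
        },
        index=pd.Index([s.sample_id for s in samples], name="sample_id"),
    )


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(dendrogram: Dendrogram) -> str:
    """Serialise a dendrogram as newick.

    Branch lengths are merge-height differences (leaves sit at height 0);
    bootstrap percentages, when present, appear as internal node labels.
    """
    n = dendrogram.n_leaves
    if len(set(dendrogram.leaf_ids)) != n:
        raise FormatError("leaf labels must be unique")
    if n == 1:
        return f"{dendrogram.leaf_ids[0]}:0.0;"

    heights = {i: 0.0 for i in range(n)}
    for i, (_a, _b, h) in enumerate(dendrogram.merges):
        heights[n + i] = h

    def render(node: int, parent_height: float) -> str:
        blen = parent_height - heights[node]
        if node < n:
            return f"{dendrogram.leaf_ids[node]}:{blen:g}"
        a, b, h = dendrogram.merges[node - n]
        inner = f"({render(a, h)},{render(b, h)})"
        label = ""
        if node in dendrogram.support:
            label = f"{dendrogram.support[node]:g}"
        return f"{inner}{label}:{blen:g}"

    root = n + len(dendrogram.merges) - 1
    a, b, h = dendrogram.merges[root - n]
    label = f"{dendrogram.support[root]:g}" if root in dendrogram.support else ""
    return f"({render(a, h)},{render(b, h)}){label};"
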