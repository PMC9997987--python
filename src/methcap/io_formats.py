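"""Readers/writers for the sequence, interval and methylation-call formats.

Coordinate conventions are explicit and fixed by the ecosystems that own the
formats:

* BED is 0-based, half-open ``[start, end)``.
* Bismark coverage files are 1-based with ``start == end`` (one base per
  record); the cytosine report and per-base depth TSV are likewise 1-based.

All cross-format interval logic converts at the boundary; see
:func:`methcap.capture_eval.intersect_with_regions`.

Lowercase FASTA characters are preserved on read and interpreted downstream
as soft-masking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from Bio import SeqIO

from .errors import FormatError

PathLike = Union[str, Path]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence; case is preserved (lowercase = soft mask)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record has an empty id")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TargetRegion:
    """A genomic interval in BED convention (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"region {self.name!r}: negative start {self.start}")
        if self.end <= self.start:
            raise FormatError(
                f"region {self.name!r}: end {self.end} must exceed start {self.start}"
            )
        if self.strand not in _STRANDS:
            raise FormatError(f"region {self.name!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_pos(self, chrom: str, pos: int) -> bool:
        """True iff a 1-based position lies inside this 0-based region."""
        return chrom == self.chrom and self.start < pos <= self.end


@dataclass(frozen=True)
class CpGRecord:
    """One CpG site's methylation call counts (Bismark coverage semantics)."""

    chrom: str
    pos: int  # 1-based
    percent: float
    count_m: int
    count_u: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"CpG record at {self.chrom}:{self.pos}: pos must be >= 1")
        if self.count_m < 0 or self.count_u < 0:
            raise FormatError(f"CpG record at {self.chrom}:{self.pos}: negative counts")

    @property
    def depth(self) -> int:
        return self.count_m + self.count_u


@dataclass(frozen=True)
class CytosineContextRecord:
    """One cytosine from a per-context report (CpG/CHG/CHH)."""

    chrom: str
    pos: int  # 1-based
    strand: str
    count_m: int
    count_u: int
    context: str
    trinucleotide: str

    def __post_init__(self) -> None:
        if self.context not in {"CpG", "CHG", "CHH"}:
            raise FormatError(
                f"cytosine record at {self.chrom}:{self.pos}: bad context {self.context!r}"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(
                f"cytosine record at {self.chrom}:{self.pos}: bad strand {self.strand!r}"
            )


def percent_methylation(count_m: int, count_u: int) -> float:
    """100 * methylated / (methylated + unmethylated); 0.0 at zero depth."""
    total = count_m + count_u
    if total == 0:
        return 0.0
    return 100.0 * count_m / total


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read FASTA, preserving case and record order.

    Raises :class:`FormatError` for an empty/headerless file or duplicate ids.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
        if not first.startswith(">"):
            raise FormatError(
                f"{path}: not FASTA (first non-blank line does not start with '>')"
            )
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise FormatError(f"{path}: empty FASTA")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: PathLike) -> list[TargetRegion]:
    """Read BED3/BED6 into 0-based half-open regions.

    Missing name -> ``region_<i>`` (1-based running count); missing strand -> ``.``.
    """
    path = Path(path)
    regions: list[TargetRegion] = []
    count = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            count += 1
            chrom = fields[0]
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric start/end") from exc
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else f"region_{count}"
            strand = fields[5] if len(fields) > 5 else "."
            strand = strand.replace("−", "-")
            if strand not in _STRANDS:
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            regions.append(TargetRegion(chrom, start, end, name, strand))
    return regions


def write_bed(regions: Iterable[TargetRegion], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# Bismark coverage


def read_bismark_cov(path: PathLike) -> list[CpGRecord]:
    """Read a 6-column Bismark coverage file.

    Counts are authoritative: if the stored percentage disagrees with the
    counts by more than 0.01 the percentage is recomputed and a warning is
    emitted. Zero-depth records are permitted but flagged with a warning.
    """
    path = Path(path)
    records: list[CpGRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start = int(fields[1])
                end = int(fields[2])
                percent = float(fields[3])
                count_m = int(fields[4])
                count_u = int(fields[5])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
            if start != end:
                raise FormatError(
                    f"{path}:{lineno}: coverage records are single-base (start != end)"
                )
            total = count_m + count_u
            if total == 0:
                warnings.warn(
                    f"{path}:{lineno}: zero-depth record at {chrom}:{start}", stacklevel=2
                )
                records.append(CpGRecord(chrom, start, 0.0, 0, 0))
                continue
            derived = percent_methylation(count_m, count_u)
            if not math.isclose(percent, derived, abs_tol=0.01):
                warnings.warn(
                    f"{path}:{lineno}: percent {percent} inconsistent with counts "
                    f"{count_m}m/{count_u}u; recomputed to {derived:.4f}",
                    stacklevel=2,
                )
                percent = derived
            records.append(CpGRecord(chrom, start, percent, count_m, count_u))
    return records


def write_bismark_cov(records: Iterable[CpGRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.pos}\t{r.percent:.6f}\t{r.count_m}\t{r.count_u}\n"
            )


# ---------------------------------------------------------------------------
# Cytosine context report


def _check_context(context: str, tri: str) -> bool:
    tri = tri.upper()
    if len(tri) != 3 or "N" in tri or tri[0] != "C":
        return True  # cannot check; accept
    if tri[1] == "G":
        return context == "CpG"
    if tri[2] == "G":
        return context == "CHG"
    return context == "CHH"


def read_cytosine_report(path: PathLike) -> list[CytosineContextRecord]:
    """Read a 7-column per-cytosine context report (Bismark dialect)."""
    path = Path(path)
    records: list[CytosineContextRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns, got {len(fields)}")
            chrom, pos_s, strand, m_s, u_s, context, tri = fields
            try:
                pos = int(pos_s)
                count_m = int(m_s)
                count_u = int(u_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
            if not _check_context(context, tri):
                raise FormatError(
                    f"{path}:{lineno}: context {context!r} inconsistent with "
                    f"trinucleotide {tri!r}"
                )
            records.append(
                CytosineContextRecord(chrom, pos, strand, count_m, count_u, context, tri)
            )
    return records


def write_cytosine_report(records: Iterable[CytosineContextRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.count_m}\t{r.count_u}\t"
                f"{r.context}\t{r.trinucleotide}\n"
            )


# ---------------------------------------------------------------------------
# Per-base depth TSV


def read_depth_tsv(path: PathLike) -> dict[tuple[str, int], int]:
    """Read a 3-column depth track (chrom, pos 1-based, depth) into a dict."""
    path = Path(path)
    track: dict[tuple[str, int], int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            try:
                pos = int(fields[1])
                depth = int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
            if depth < 0:
                raise FormatError(f"{path}:{lineno}: negative depth")
            track[(fields[0], pos)] = depth
    return track


def write_depth_tsv(track: Mapping[tuple[str, int], int], path: PathLike) -> None:
    with open(path, "w") as fh:
        for (chrom, pos), depth in sorted(track.items()):
            fh.write(f"{chrom}\t{pos}\t{depth}\n")


def genome_as_dict(genome: Sequence[SequenceRecord]) -> dict[str, SequenceRecord]:
    out: dict[str, SequenceRecord] = {}
    for rec in genome:
        if rec.id in out:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        out[rec.id] = rec
    return out
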