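"""Domain types, tab-separated file I/O, and call-level filters.

Coordinates are 0-based half-open (BED convention) everywhere. Files are
plain TSV with a fixed column order; lines starting with ``#`` are comments
and an optional header line is auto-detected.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

__all__ = [
    "GenomicInterval",
    "CNVCall",
    "Sample",
    "SampleSheet",
    "TranscriptionUnit",
    "SegmentalDuplication",
    "Genome",
    "TableFormatError",
    "read_cnv_calls",
    "read_intervals",
    "read_genes",
    "read_sds",
    "read_sample_sheet",
    "read_chrom_sizes",
    "filter_calls",
    "write_table",
    "write_cnv_calls",
    "write_intervals",
    "write_genes",
    "write_sample_sheet",
    "write_chrom_sizes",
    "DUPLICATION",
    "DELETION",
]

DUPLICATION = "duplication"
DELETION = "deletion"


class TableFormatError(ValueError):
    """A malformed row in a TSV input, reported with its line number."""

    def __init__(self, path: str | os.PathLike, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        """Closed containment on half-open intervals: equal bounds count."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class CNVCall:
    """One duplication/deletion interval in one individual."""

    interval: GenomicInterval
    sample_id: str
    call_type: str
    cn: float

    def __post_init__(self) -> None:
        if self.call_type not in (DUPLICATION, DELETION):
            raise ValueError(f"unknown call_type {self.call_type!r}")
        if self.cn < 0:
            raise ValueError(f"cn must be >= 0, got {self.cn}")


@dataclass(frozen=True)
class Sample:
    sample_id: str
    population: str
    sex: str

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male or female, got {self.sex!r}")


class SampleSheet:
    """Ordered sample collection mapping sample -> population and sex."""

    def __init__(self, samples: Iterable[Sample]):
        self.samples: tuple[Sample, ...] = tuple(samples)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        self._by_id = {s.sample_id: s for s in self.samples}

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleSheet) and self.samples == other.samples

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def populations(self) -> list[str]:
        """Population labels in first-seen order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.population, None)
        return list(seen)

    def samples_in(self, population: str) -> list[Sample]:
        return [s for s in self.samples if s.population == population]

    def sex_of(self, sample_id: str) -> str:
        return self._by_id[sample_id].sex

    def population_of(self, sample_id: str) -> str:
        return self._by_id[sample_id].population


@dataclass(frozen=True)
class TranscriptionUnit:
    """A gene as a transcription-unit interval (TSS to TES)."""

    interval: GenomicInterval
    gene_id: str


@dataclass(frozen=True)
class SegmentalDuplication:
    interval: GenomicInterval


@dataclass
class Genome:
    """Chromosome lengths, the X chromosome name, and assembly gaps."""

    chrom_lengths: dict[str, int]
    sex_chrom: str | None = None
    gaps: tuple[GenomicInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.gaps = tuple(self.gaps)
        for g in self.gaps:
            self._check(g)

    def _check(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.chrom_lengths:
            raise ValueError(f"chromosome {iv.chrom!r} not in genome")
        if iv.end > self.chrom_lengths[iv.chrom]:
            raise ValueError(
                f"interval {iv} exceeds chromosome length "
                f"{self.chrom_lengths[iv.chrom]}"
            )

    def gaps_on(self, chrom: str) -> list[GenomicInterval]:
        return [g for g in self.gaps if g.chrom == chrom]

    def is_x(self, chrom: str) -> bool:
        return self.sex_chrom is not None and chrom == self.sex_chrom


# ---------------------------------------------------------------------------
# readers


def _data_lines(path: str | os.PathLike):
    """Yield (lineno, fields) skipping comments/blank lines; header skipped
    if its coordinate columns do not parse as integers."""
    with open(path) as fh:
        first = True
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if first:
                first = False
                if _looks_like_header(fields):
                    continue
            yield lineno, fields


def _looks_like_header(fields: Sequence[str]) -> bool:
    if len(fields) < 2:
        return False
    try:
        int(fields[1])
    except ValueError:
        return True
    return False


def read_cnv_calls(path: str | os.PathLike, sample_id: str) -> list[CNVCall]:
    """Read CNV calls (chrom, start, end, call_type, cn) for one sample.

    Malformed rows raise :class:`TableFormatError` naming the line number;
    input row order is preserved.
    """
    calls: list[CNVCall] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 5:
            raise TableFormatError(path, lineno, "expected 5 columns")
        chrom, s, e, call_type, cn = fields[:5]
        try:
            start, end = int(s), int(e)
        except ValueError as exc:
            raise TableFormatError(path, lineno, f"bad coordinate: {exc}")
        try:
            cn_val = float(cn)
        except ValueError:
            raise TableFormatError(path, lineno, f"cn not a number: {cn!r}")
        if cn_val < 0:
            raise TableFormatError(path, lineno, f"cn must be >= 0: {cn_val}")
        try:
            iv = GenomicInterval(chrom, start, end)
            calls.append(CNVCall(iv, sample_id, call_type, cn_val))
        except ValueError as exc:
            raise TableFormatError(path, lineno, str(exc))
    return calls


def read_intervals(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read a BED3 file of intervals (gaps, generic regions)."""
    out = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise TableFormatError(path, lineno, "expected 3 columns")
        try:
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
        except ValueError as exc:
            raise TableFormatError(path, lineno, str(exc))
    return out


def read_genes(path: str | os.PathLike) -> list[TranscriptionUnit]:
    """Read transcription units (chrom, start, end, gene_id); ids unique."""
    genes = []
    seen: set[str] = set()
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise TableFormatError(path, lineno, "expected 4 columns")
        gene_id = fields[3]
        if gene_id in seen:
            raise TableFormatError(path, lineno, f"duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        try:
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
        except ValueError as exc:
            raise TableFormatError(path, lineno, str(exc))
        genes.append(TranscriptionUnit(iv, gene_id))
    return genes


def read_sds(
    path: str | os.PathLike, min_len: int = 10_000
) -> list[SegmentalDuplication]:
    """Read segmental duplications, keeping only those longer than min_len."""
    return [
        SegmentalDuplication(iv)
        for iv in read_intervals(path)
        if iv.length > min_len
    ]


def read_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    samples = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise TableFormatError(path, lineno, "expected 3 columns")
        try:
            samples.append(Sample(fields[0], fields[1], fields[2]))
        except ValueError as exc:
            raise TableFormatError(path, lineno, str(exc))
    return SampleSheet(samples)


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise TableFormatError(path, lineno, "expected 2 columns")
        try:
            sizes[fields[0]] = int(fields[1])
        except ValueError as exc:
            raise TableFormatError(path, lineno, str(exc))
    return sizes


# ---------------------------------------------------------------------------
# filters


def filter_calls(
    calls: Iterable[CNVCall], genome: Genome, min_len: int = 1000
) -> list[CNVCall]:
    """Retain calls with length >= min_len and zero overlap with any gap.

    Calls shorter than the threshold are dropped; the boundary length
    (exactly min_len) is kept. Any gap overlap of >= 1 bp removes the call.
    Input order is preserved; retained calls are unmodified. A call on a
    chromosome absent from the genome is an error.
    """
    gaps_by_chrom: dict[str, list[GenomicInterval]] = {}
    for g in genome.gaps:
        gaps_by_chrom.setdefault(g.chrom, []).append(g)

    kept = []
    for call in calls:
        chrom = call.interval.chrom
        if chrom not in genome.chrom_lengths:
            raise ValueError(f"call on unknown chromosome {chrom!r}")
        if call.interval.length < min_len:
            continue
        if any(call.interval.overlaps(g) for g in gaps_by_chrom.get(chrom, ())):
            continue
        kept.append(call)
    return kept


# ---------------------------------------------------------------------------
# writers


def write_table(
    records: Sequence[Mapping[str, object]],
    path: str | os.PathLike,
    columns: Sequence[str] | None = None,
) -> None:
    """Write mappings as TSV with a deterministic column order.

    Column order is the order given, or the key order of the first record.
    An empty collection requires explicit columns and yields a header-only
    file.
    """
    if columns is None:
        if not records:
            raise ValueError("columns required for an empty record set")
        columns = list(records[0].keys())
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for rec in records:
            fh.write("\t".join(str(rec[c]) for c in columns) + "\n")


def _sorted_by_locus(items, key):
    return sorted(items, key=key)


def write_cnv_calls(calls: Iterable[CNVCall], path: str | os.PathLike) -> None:
    """Write calls sorted by (chrom, start); round-trips via read_cnv_calls."""
    rows = _sorted_by_locus(
        calls, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end)
    )
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcall_type\tcn\n")
        for c in rows:
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}"
                f"\t{c.call_type}\t{c.cn!r}\n"
            )


def write_intervals(
    intervals: Iterable[GenomicInterval], path: str | os.PathLike
) -> None:
    rows = _sorted_by_locus(intervals, key=lambda i: (i.chrom, i.start, i.end))
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\n")
        for iv in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_genes(
    genes: Iterable[TranscriptionUnit], path: str | os.PathLike
) -> None:
    rows = _sorted_by_locus(
        genes, key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id)
    )
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tgene_id\n")
        for g in rows:
            fh.write(
                f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}"
                f"\t{g.gene_id}\n"
            )


def write_sample_sheet(sheet: SampleSheet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\tsex\n")
        for s in sheet:
            fh.write(f"{s.sample_id}\t{s.population}\t{s.sex}\n")


def write_chrom_sizes(sizes: Mapping[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")
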