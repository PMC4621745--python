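"""Readers and writers for the cohort file formats, plus the internal data model.

All coordinate and strand conventions are fixed in this module:

* BEDPE and BED are 0-based half-open on disk, as usual for those formats.
* SEG and the mutation table are 1-based inclusive on disk.
* Every internal coordinate is 0-based half-open.

The breakpoint position of a BEDPE end interval is its start coordinate
(the intervals are typically 1 bp; a single representative point is needed
for ordering the two ends of an event).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "GenomeDef",
    "RearrangementEvent",
    "Segment",
    "SegmentProfile",
    "MutationObservation",
    "SampleSheet",
    "Region",
    "read_genome",
    "read_rearrangements",
    "write_rearrangements",
    "read_segments",
    "write_segments",
    "read_mutations",
    "read_sample_sheet",
    "read_regions",
    "read_expression",
    "read_gmt",
    "write_results",
]

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y", "chrM", "MT", "M"})

_STRANDS = {"+": "+", "-": "-", "−": "-"}  # accept the unicode minus


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed input violates a contract of the data model."""


@dataclass(frozen=True)
class GenomeDef:
    """Ordered chromosome names and lengths.

    The genome definition fixes which chromosome names are legal and provides
    the denominator for fraction-of-genome-altered.  Sex chromosomes (and the
    mitochondrion) are accepted in the data but excluded from the FGA
    denominator by default.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in genome definition")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {name} has non-positive length {length}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length(self, name: str) -> int:
        try:
            return self.lengths[name]
        except KeyError:
            raise ValidationError(f"chromosome {name!r} not in genome definition") from None

    def total_length(self, include_sex: bool = False) -> int:
        return sum(
            length
            for name, length in self.chromosomes
            if include_sex or name not in SEX_CHROMOSOMES
        )


@dataclass(frozen=True)
class RearrangementEvent:
    """One somatic structural rearrangement: a pair of breakpoint ends.

    Ends are stored sorted (``pos_a <= pos_b`` when both lie on one
    chromosome) and each end carries the strand of the paired-end signature,
    from which the subtype (deletion / tandem duplication / inversion /
    interchromosomal) is derived downstream.
    """

    sample_id: str
    chrom_a: str
    pos_a: int
    strand_a: str
    chrom_b: str
    pos_b: int
    strand_b: str
    subtype: str | None = None

    def __post_init__(self) -> None:
        if self.strand_a not in ("+", "-") or self.strand_b not in ("+", "-"):
            raise ValidationError(
                f"strands must be '+' or '-', got {self.strand_a!r}/{self.strand_b!r}"
            )
        if self.chrom_a == self.chrom_b and self.pos_a > self.pos_b:
            raise ValidationError("event ends on one chromosome must be position-sorted")

    @property
    def intrachromosomal(self) -> bool:
        return self.chrom_a == self.chrom_b


def _sorted_ends(
    chrom_a: str, pos_a: int, strand_a: str, chrom_b: str, pos_b: int, strand_b: str
) -> tuple[str, int, str, str, int, str]:
    if chrom_a == chrom_b and pos_a > pos_b:
        return chrom_b, pos_b, strand_b, chrom_a, pos_a, strand_a
    return chrom_a, pos_a, strand_a, chrom_b, pos_b, strand_b


def make_event(
    sample_id: str,
    chrom_a: str,
    pos_a: int,
    strand_a: str,
    chrom_b: str,
    pos_b: int,
    strand_b: str,
    subtype: str | None = None,
) -> RearrangementEvent:
    """Construct an event with ends put in sorted order."""
    ends = _sorted_ends(chrom_a, pos_a, strand_a, chrom_b, pos_b, strand_b)
    return RearrangementEvent(sample_id, *ends, subtype=subtype)


@dataclass(frozen=True)
class Segment:
    """A copy-number segment (0-based half-open) with a log2 tumor/normal ratio."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end} has start >= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentProfile:
    """All copy-number segments of one sample, overlap-checked per chromosome."""

    sample_id: str
    segments: list[Segment] = field(default_factory=list)

    def validate(self) -> "SegmentProfile":
        by_chrom: dict[str, list[Segment]] = {}
        for seg in self.segments:
            if seg.sample_id != self.sample_id:
                raise ValidationError(
                    f"segment sample {seg.sample_id} != profile sample {self.sample_id}"
                )
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs.sort(key=lambda s: s.start)
            for prev, cur in zip(segs, segs[1:]):
                if cur.start < prev.end:
                    raise ValidationError(
                        f"overlapping segments for sample {self.sample_id} on {chrom}: "
                        f"{prev.start}-{prev.end} and {cur.start}-{cur.end}"
                    )
        return self


@dataclass(frozen=True)
class MutationObservation:
    """A somatic point mutation with allele read counts and sample context.

    ``pos`` is 0-based internally (the on-disk table is 1-based).  ``purity``
    is the tumor-cell fraction of the specimen and ``local_cn`` the total
    copy number at the locus in tumor cells (2 when unknown); both feed the
    cancer-cell-fraction estimate.
    """

    sample_id: str
    chrom: str
    pos: int
    gene: str
    ref_count: int
    alt_count: int
    purity: float
    local_cn: int = 2

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValidationError(
                f"negative read counts for {self.sample_id}/{self.gene}"
            )
        if not 0.0 < self.purity <= 1.0:
            raise ValidationError(f"purity must be in (0, 1], got {self.purity}")
        if self.local_cn < 1:
            raise ValidationError(f"local_cn must be >= 1, got {self.local_cn}")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def vaf(self) -> float:
        if self.depth == 0:
            raise ValidationError("zero-depth observation has no VAF")
        return self.alt_count / self.depth


@dataclass
class SampleSheet:
    """Per-sample metadata: identifier, purity, and categorical labels."""

    samples: pd.DataFrame  # index: sample_id; columns: purity + label columns

    def __post_init__(self) -> None:
        if self.samples.index.has_duplicates:
            dup = self.samples.index[self.samples.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids in sheet: {dup}")
        if "purity" not in self.samples.columns:
            raise ValidationError("sample sheet must have a 'purity' column")
        bad = self.samples.index[
            (self.samples["purity"] <= 0) | (self.samples["purity"] > 1)
        ].tolist()
        if bad:
            raise ValidationError(f"purity outside (0, 1] for samples: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def purity(self, sample_id: str) -> float:
        try:
            return float(self.samples.at[sample_id, "purity"])
        except KeyError:
            raise ValidationError(f"sample {sample_id!r} not in sample sheet") from None

    def labels(self, name: str) -> pd.Series:
        if name not in self.samples.columns:
            raise ValidationError(f"label column {name!r} not in sample sheet")
        return self.samples[name]


@dataclass(frozen=True)
class Region:
    """A named genomic region (0-based half-open), e.g. a recurrent deletion peak."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"region {self.name} has start >= end")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and start < self.end and self.start < end


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _data_lines(path: Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) skipping blank and '#' comment lines."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_genome(path: str | Path) -> GenomeDef:
    """Read a two-column TSV genome definition (chromosome name, length)."""
    chroms: list[tuple[str, int]] = []
    for lineno, fields in _data_lines(Path(path)):
        if fields and fields[0].lower() in ("chrom", "chromosome", "name"):
            continue  # optional header
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        try:
            chroms.append((fields[0], int(fields[1])))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
    return GenomeDef(tuple(chroms))


def _parse_strand(raw: str, path: Path, lineno: int) -> str:
    try:
        return _STRANDS[raw]
    except KeyError:
        raise ParseError(f"{path}:{lineno}: bad strand {raw!r}") from None


def read_rearrangements(
    path: str | Path,
    genome: GenomeDef,
    sample_id: str | None = None,
) -> list[RearrangementEvent]:
    """Read 10-column BEDPE breakpoint pairs.

    The sample identifier is taken from the BEDPE ``name`` column unless
    ``sample_id`` overrides it for the whole file.  The breakpoint position
    of each end interval is its start coordinate; ends on one chromosome are
    stored sorted by position.
    """
    path = Path(path)
    events: list[RearrangementEvent] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 10:
            raise ParseError(
                f"{path}:{lineno}: BEDPE needs >= 10 columns, got {len(fields)}"
            )
        chrom1, start1, _end1, chrom2, start2, _end2, name = fields[:7]
        strand1 = _parse_strand(fields[8], path, lineno)
        strand2 = _parse_strand(fields[9], path, lineno)
        for chrom in (chrom1, chrom2):
            if chrom not in genome:
                raise ValidationError(
                    f"{path}:{lineno}: chromosome {chrom!r} not in genome definition"
                )
        try:
            pos1, pos2 = int(start1), int(start2)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad coordinate") from exc
        events.append(
            make_event(sample_id or name, chrom1, pos1, strand1, chrom2, pos2, strand2)
        )
    return events


def write_rearrangements(events: Sequence[RearrangementEvent], path: str | Path) -> None:
    """Write events as 10-column BEDPE (each end as a 1 bp interval)."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        ev.chrom_a, ev.pos_a, ev.pos_a + 1,
                        ev.chrom_b, ev.pos_b, ev.pos_b + 1,
                        ev.sample_id, ".", ev.strand_a, ev.strand_b,
                    )
                )
                + "\n"
            )


def read_segments(path: str | Path, genome: GenomeDef) -> list[SegmentProfile]:
    """Read a SEG file into per-sample segment profiles.

    On-disk SEG coordinates are 1-based inclusive; they are converted to
    0-based half-open.  Segments of one sample on one chromosome must not
    overlap.
    """
    path = Path(path)
    profiles: dict[str, SegmentProfile] = {}
    for lineno, fields in _data_lines(path):
        if fields[0].lower() in ("sample", "sample_id", "id"):
            continue  # header
        if len(fields) < 5:
            raise ParseError(f"{path}:{lineno}: SEG needs >= 5 columns")
        sample, chrom = fields[0], fields[1]
        if chrom not in genome:
            raise ValidationError(
                f"{path}:{lineno}: chromosome {chrom!r} not in genome definition"
            )
        try:
            start1, end1 = int(fields[2]), int(fields[3])
            log2 = float(fields[-1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad numeric field") from exc
        seg = Segment(sample, chrom, start1 - 1, end1, log2)
        profiles.setdefault(sample, SegmentProfile(sample)).segments.append(seg)
    return [profiles[s].validate() for s in sorted(profiles)]


def write_segments(profiles: Sequence[SegmentProfile], path: str | Path) -> None:
    """Write profiles as a 6-column SEG file (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tnum_mark\tseg_mean\n")
        for profile in profiles:
            for seg in sorted(profile.segments, key=lambda s: (s.chrom, s.start)):
                fh.write(
                    f"{seg.sample_id}\t{seg.chrom}\t{seg.start + 1}\t{seg.end}\t.\t"
                    f"{seg.log2_ratio:.6g}\n"
                )


def read_mutations(path: str | Path, samples: SampleSheet) -> list[MutationObservation]:
    """Read a MAF-like mutation TSV and join purity from the sample sheet.

    Expected columns: sample_id, chrom, pos (1-based), gene, ref_count,
    alt_count, optional local_cn (defaults to 2).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    required = ["sample_id", "chrom", "pos", "gene", "ref_count", "alt_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    observations = []
    for row in df.itertuples(index=False):
        purity = samples.purity(str(row.sample_id))
        local_cn = int(getattr(row, "local_cn", 2)) if hasattr(row, "local_cn") else 2
        observations.append(
            MutationObservation(
                sample_id=str(row.sample_id),
                chrom=str(row.chrom),
                pos=int(row.pos) - 1,
                gene=str(row.gene),
                ref_count=int(row.ref_count),
                alt_count=int(row.alt_count),
                purity=purity,
                local_cn=local_cn,
            )
        )
    return observations


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read the sample sheet TSV (sample_id, purity, free label columns)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: sample sheet needs a 'sample_id' column")
    return SampleSheet(df.set_index("sample_id"))


def read_regions(path: str | Path, genome: GenomeDef) -> list[Region]:
    """Read a BED file of named recurrent regions (0-based half-open)."""
    path = Path(path)
    regions: list[Region] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: BED needs >= 4 columns (incl. name)")
        chrom = fields[0]
        if chrom not in genome:
            raise ValidationError(
                f"{path}:{lineno}: chromosome {chrom!r} not in genome definition"
            )
        regions.append(Region(fields[3], chrom, int(fields[1]), int(fields[2])))
    names = [r.name for r in regions]
    if len(set(names)) != len(names):
        raise ValidationError(f"{path}: duplicate region names")
    return regions


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.isna().any().any():
        raise ValidationError(f"{path}: expression matrix contains missing values")
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name, description, then gene ids."""
    sets: dict[str, set[str]] = {}
    for lineno, fields in _data_lines(Path(path)):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT needs >= 3 columns")
        sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    metadata: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Write named result tables as TSV and return a manifest.

    Each table gets an optional ``# key: value`` metadata block before the
    header.  Files are byte-identical across reruns on identical inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name in sorted(tables):
        table = tables[name]
        fname = f"{name}.tsv"
        fpath = out_dir / fname
        try:
            with open(fpath, "w") as fh:
                for key in sorted(metadata or {}):
                    fh.write(f"# {key}: {metadata[key]}\n")
                table.to_csv(fh, sep="\t", index=False, lineterminator="\n",
                             float_format="%.10g")
        except OSError as exc:
            raise OSError(f"failed writing result table to {fpath}: {exc}") from exc
        digest = hashlib.sha256(fpath.read_bytes()).hexdigest()
        entries.append({"file": fname, "rows": len(table), "sha256": digest})
    return pd.DataFrame(entries, columns=["file", "rows", "sha256"])
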