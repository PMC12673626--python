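"""Genome annotation model and coordinate bookkeeping.

Conventions
-----------
* Bands and gene spans are stored 0-based half-open (UCSC dialect).
* Variant positions are 1-based (GWAS-catalog dialect).
* A 1-based position ``p`` lies inside a band ``[start, end)`` iff
  ``start < p <= end`` — equivalently ``start <= p-1 < end`` in 0-based
  coordinates.
* Chromosome labels are normalized by stripping a leading ``"chr"``.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

from .errors import InputError

log = logging.getLogger(__name__)

_BAND_NAME_RE = re.compile(r"^[pq][0-9]+(\.[0-9]+)?$")

#: Ordering key used wherever chromosomes are sorted.
def chrom_sort_key(chrom: str) -> tuple[int, str]:
    if chrom.isdigit():
        return (int(chrom), "")
    return ({"X": 23, "Y": 24, "M": 25, "MT": 25}.get(chrom, 26), chrom)


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix; leave the label otherwise untouched."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CytoBandRecord:
    """One sub-band row of a UCSC ``cytoBand`` file (0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: str
    stain: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError(
                f"cytoband {self.chrom}{self.name}: start {self.start} >= end {self.end}"
            )
        if not _BAND_NAME_RE.match(self.name):
            raise InputError(f"cytoband name {self.name!r} does not match arm pattern")

    @property
    def major_name(self) -> str:
        """Band name truncated at the first ``"."`` (``q24.21`` -> ``q24``)."""
        return self.name.split(".", 1)[0]

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MajorBand:
    """A collapsed cytogenetic band (e.g. ``8q24``) — the scan unit."""

    band_id: str
    chrom: str
    start: int
    end: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """The genome frame: non-overlapping major bands plus total length."""

    bands: list[MajorBand]

    def __post_init__(self) -> None:
        ids = [b.band_id for b in self.bands]
        if len(set(ids)) != len(ids):
            dup = [i for i, c in Counter(ids).items() if c > 1]
            raise InputError(f"duplicate band ids: {dup}")
        for chrom, group in self.by_chrom().items():
            ordered = sorted(group, key=lambda b: b.start)
            for a, b in zip(ordered, ordered[1:]):
                if b.start < a.end:
                    raise InputError(
                        f"overlapping bands on chromosome {chrom}: "
                        f"{a.band_id} and {b.band_id}"
                    )

    @property
    def total_length_bp(self) -> int:
        return sum(b.length_bp for b in self.bands)

    def band_ids(self) -> list[str]:
        return [b.band_id for b in self.bands]

    def get(self, band_id: str) -> MajorBand:
        for b in self.bands:
            if b.band_id == band_id:
                return b
        raise KeyError(band_id)

    def by_chrom(self) -> dict[str, list[MajorBand]]:
        out: dict[str, list[MajorBand]] = defaultdict(list)
        for b in self.bands:
            out[b.chrom].append(b)
        return dict(out)

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)


@dataclass(frozen=True)
class VariantSite:
    """One polymorphism position (1-based)."""

    chrom: str
    pos: int
    variant_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"variant position must be >= 1, got {self.pos}")


@dataclass
class GeneRecord:
    """A gene with optional band assignment and mutation-burden fields."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    band_id: str | None = None
    cds_length_bp: int | None = None
    mutation_count: int | None = None
    adjusted_count: float | None = None

    @property
    def midpoint(self) -> int:
        """0-based midpoint used for the single-band assignment rule."""
        return (self.start + self.end) // 2


# ---------------------------------------------------------------------------
# Parsing / collapsing
# ---------------------------------------------------------------------------


def parse_cytoband(stream: TextIO | Iterable[str]) -> list[CytoBandRecord]:
    """Parse a UCSC cytoBand TSV into normalized :class:`CytoBandRecord` rows.

    Lines starting with ``#`` and blank lines are skipped.  Malformed lines
    raise :class:`InputError` naming the offending line number.
    """
    records: list[CytoBandRecord] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise InputError(
                f"cytoband line {lineno}: expected >=4 tab-separated fields, "
                f"got {len(fields)}"
            )
        chrom = normalize_chrom(fields[0].strip())
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise InputError(f"cytoband line {lineno}: non-integer coordinate") from exc
        name = fields[3].strip()
        stain = fields[4].strip() if len(fields) > 4 else ""
        try:
            records.append(CytoBandRecord(chrom, start, end, name, stain))
        except InputError as exc:
            raise InputError(f"cytoband line {lineno}: {exc}") from exc
    if not records:
        raise InputError("empty cytoband input")
    return records


def collapse_to_major_bands(records: Sequence[CytoBandRecord]) -> GenomeAnnotation:
    """Merge sub-bands into major bands (``8q24.1``+``8q24.2`` -> ``8q24``).

    Constituent sub-bands of one major band must tile a contiguous interval;
    a gap means the annotation is corrupt and raises :class:`InputError`.
    """
    groups: dict[tuple[str, str], list[CytoBandRecord]] = defaultdict(list)
    for rec in records:
        groups[(rec.chrom, rec.major_name)].append(rec)

    bands: list[MajorBand] = []
    for (chrom, major), members in groups.items():
        members = sorted(members, key=lambda r: r.start)
        for a, b in zip(members, members[1:]):
            if a.end != b.start:
                raise InputError(
                    f"major band {chrom}{major}: constituents not contiguous "
                    f"({a.name} ends at {a.end}, {b.name} starts at {b.start})"
                )
        bands.append(MajorBand(f"{chrom}{major}", chrom, members[0].start, members[-1].end))

    bands.sort(key=lambda b: (chrom_sort_key(b.chrom), b.start))
    return GenomeAnnotation(bands)


# ---------------------------------------------------------------------------
# Variant bookkeeping
# ---------------------------------------------------------------------------


def dedup_variants(variants: Sequence[VariantSite]) -> list[VariantSite]:
    """Drop duplicate variants, keeping the first occurrence per id.

    Records with a missing id are deduplicated by ``(chrom, pos)`` instead.
    """
    seen: set[tuple] = set()
    out: list[VariantSite] = []
    for v in variants:
        key = ("id", v.variant_id) if v.variant_id else ("pos", v.chrom, v.pos)
        if key in seen:
            continue
        seen.add(key)
        out.append(v)
    return out


class _BandIndex:
    """Sorted per-chromosome interval arrays for O(log n) point lookup."""

    def __init__(self, annotation: GenomeAnnotation) -> None:
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        for chrom, group in annotation.by_chrom().items():
            group = sorted(group, key=lambda b: b.start)
            self._by_chrom[chrom] = (
                np.array([b.start for b in group]),
                np.array([b.end for b in group]),
                [b.band_id for b in group],
            )

    def lookup(self, chrom: str, point_0based: int) -> str | None:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, ids = entry
        i = int(np.searchsorted(starts, point_0based, side="right")) - 1
        if i >= 0 and point_0based < ends[i]:
            return ids[i]
        return None


def assign_variants(
    variants: Sequence[VariantSite], annotation: GenomeAnnotation
) -> tuple[dict[str, int], list[VariantSite]]:
    """Count variants per major band; return (counts, unassigned).

    Conservation holds by construction: sum of counts plus the number of
    unassigned variants equals the input size.
    """
    if not len(annotation):
        raise InputError("empty annotation")
    index = _BandIndex(annotation)
    counts: dict[str, int] = {b.band_id: 0 for b in annotation}
    unassigned: list[VariantSite] = []
    for v in variants:
        band_id = index.lookup(v.chrom, v.pos - 1)
        if band_id is None:
            unassigned.append(v)
        else:
            counts[band_id] += 1
    if unassigned:
        log.info("%d of %d variants fell outside the annotation", len(unassigned), len(variants))
    return counts, unassigned


def assign_genes(
    genes: Sequence[GeneRecord], annotation: GenomeAnnotation
) -> list[GeneRecord]:
    """Assign each gene to exactly one band by its midpoint (partition rule)."""
    index = _BandIndex(annotation)
    return [replace(g, band_id=index.lookup(g.chrom, g.midpoint)) for g in genes]


# ---------------------------------------------------------------------------
# Genomic-context classification
# ---------------------------------------------------------------------------

Span = tuple[str, int, int]  # (chrom, start, end), 0-based half-open


def _merge_spans(spans: Iterable[Span]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    per_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for chrom, start, end in spans:
        if start >= end:
            raise InputError(f"degenerate span on {chrom}: [{start}, {end})")
        per_chrom[normalize_chrom(chrom)].append((start, end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = (np.array([s for s, _ in out]), np.array([e for _, e in out]))
    return merged


def _point_in(merged: Mapping[str, tuple[np.ndarray, np.ndarray]], chrom: str, p0: int) -> bool:
    entry = merged.get(chrom)
    if entry is None:
        return False
    starts, ends = entry
    i = int(np.searchsorted(starts, p0, side="right")) - 1
    return i >= 0 and p0 < ends[i]


def classify_variant_context(
    variants: Sequence[VariantSite],
    gene_spans: Sequence[Span],
    exon_spans: Sequence[Span],
) -> tuple[list[str], Counter]:
    """Label each variant ``genic_exonic`` / ``genic_intronic`` / ``intergenic``.

    A variant is genic iff it lies inside any gene span; a genic variant is
    intronic iff it lies outside all exon spans.  Exon spans must nest inside
    gene spans.  Labels are mutually exclusive and counts sum to the input.
    """
    genes = _merge_spans(gene_spans)
    exons = _merge_spans(exon_spans)
    for chrom, (starts, ends) in exons.items():
        for s, e in zip(starts, ends):
            if not (_point_in(genes, chrom, int(s)) and _point_in(genes, chrom, int(e) - 1)):
                raise InputError(f"exon [{s},{e}) on {chrom} not nested in any gene span")

    labels: list[str] = []
    for v in variants:
        p0 = v.pos - 1
        if _point_in(genes, v.chrom, p0):
            labels.append("genic_exonic" if _point_in(exons, v.chrom, p0) else "genic_intronic")
        else:
            labels.append("intergenic")
    return labels, Counter(labels)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_variants_tsv(stream: TextIO | Iterable[str]) -> list[VariantSite]:
    """Read variants from 3-column TSV: chrom, 1-based position, id.

    A header line is tolerated (detected by a non-numeric position field).
    """
    out: list[VariantSite] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise InputError(f"variant line {lineno}: expected >=2 fields")
        try:
            pos = int(fields[1])
        except ValueError:
            if lineno == 1:
                continue  # header
            raise InputError(f"variant line {lineno}: non-integer position {fields[1]!r}")
        vid = fields[2].strip() if len(fields) > 2 else ""
        out.append(VariantSite(normalize_chrom(fields[0].strip()), pos, vid))
    return out


def read_variants_bed(stream: TextIO | Iterable[str]) -> list[VariantSite]:
    """Read variants from BED3+name (0-based start converted to 1-based pos)."""
    out: list[VariantSite] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise InputError(f"BED line {lineno}: expected >=3 fields")
        start = int(fields[1])
        vid = fields[3].strip() if len(fields) > 3 else ""
        out.append(VariantSite(normalize_chrom(fields[0].strip()), start + 1, vid))
    return out


def read_genes_tsv(stream: TextIO | Iterable[str]) -> list[GeneRecord]:
    """Read genes from 6-column TSV: gene_id, chrom, start, end, strand, cds_length."""
    out: list[GeneRecord] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise InputError(f"gene line {lineno}: expected 6 fields, got {len(fields)}")
        try:
            start, end, cds = int(fields[2]), int(fields[3]), int(fields[5])
        except ValueError:
            if lineno == 1:
                continue  # header
            raise InputError(f"gene line {lineno}: non-integer coordinate")
        if start >= end:
            raise InputError(f"gene line {lineno}: start >= end")
        out.append(
            GeneRecord(
                gene_id=fields[0].strip(),
                chrom=normalize_chrom(fields[1].strip()),
                start=start,
                end=end,
                strand=fields[4].strip() or "+",
                cds_length_bp=cds,
            )
        )
    return out


def read_gene_list(stream: TextIO | Iterable[str]) -> list[str]:
    """Read a plain gene-id list (one id per line; first column of a TSV)."""
    out: list[str] = []
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        out.append(line.split("\t")[0])
    return out


def write_bands_bed(annotation: GenomeAnnotation, stream: TextIO) -> None:
    """Write major bands as BED4 (chrom, start, end, band_id)."""
    for b in annotation:
        stream.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.band_id}\n")


def read_bands_bed(stream: TextIO | Iterable[str]) -> GenomeAnnotation:
    """Read a BED4 written by :func:`write_bands_bed` back into an annotation."""
    bands: list[MajorBand] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise InputError(f"BED line {lineno}: expected 4 fields")
        bands.append(
            MajorBand(fields[3].strip(), normalize_chrom(fields[0].strip()),
                      int(fields[1]), int(fields[2]))
        )
    return GenomeAnnotation(bands)


def write_counts_tsv(counts: Mapping[str, int], stream: TextIO) -> None:
    stream.write("band_id\tcount\n")
    for band_id in sorted(counts):
        stream.write(f"{band_id}\t{counts[band_id]}\n")
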