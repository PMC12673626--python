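"""Synthetic genomes, variants, genes, mutations and gene sets.

Every generator is a pure function of ``(config, seed)``: repeated calls
with the same arguments produce identical objects and byte-identical
on-disk fixtures.  All fixtures are written in the same plain-text formats
the package's readers consume, and generators that return parsed objects
round-trip through those readers so no generator-only code path exists.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .enrichment import GeneSet, write_gmt
from .errors import InputError
from .genome import (
    GeneRecord,
    GenomeAnnotation,
    VariantSite,
    assign_genes,
    collapse_to_major_bands,
    parse_cytoband,
)

_STAINS = ("gneg", "gpos25", "gpos50", "gpos75", "gpos100", "acen")


@dataclass
class SimulationConfig:
    """Knobs for all generators.  Multipliers must be >= 1, fractions in [0, 1]."""

    seed: int = 0
    # genome
    n_chromosomes: int = 23
    bands_per_chromosome: int = 14
    band_length_median_bp: float = 8e6
    band_length_sigma: float = 0.5
    # variants
    n_variants: int = 1346
    enriched_bands: tuple[tuple[str, float], ...] = ()
    n_duplicate_variants: int = 0
    # genes / mutations
    n_genes: int = 4000
    gene_span_bp: int = 20_000
    cds_length_median_bp: float = 1500.0
    cds_length_sigma: float = 0.6
    mutation_rate_per_bp: float = 2e-3
    burden_multiplier_bands: tuple[tuple[str, float], ...] = ()
    n_samples: int = 50
    # gene sets
    n_gene_sets: int = 20
    set_size_mean: int = 40
    band_concentration: float = 0.5
    planted_set_bands: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.bands_per_chromosome < 1:
            raise InputError("need at least one chromosome and one band")
        for band_id, mult in (*self.enriched_bands, *self.burden_multiplier_bands):
            if mult < 1:
                raise InputError(f"multiplier for {band_id} must be >= 1, got {mult}")
        if not 0.0 <= self.band_concentration <= 1.0:
            raise InputError("band_concentration must lie in [0, 1]")
        if self.n_variants < 0 or self.n_duplicate_variants < 0:
            raise InputError("variant counts must be non-negative")


def _chrom_label(i: int) -> str:
    return {23: "X", 24: "Y"}.get(i, str(i))


def make_genome(
    config: SimulationConfig, cytoband_path: str | Path | None = None
) -> GenomeAnnotation:
    """Generate a genome and return it parsed through the real cytoband reader.

    Band lengths are log-normal; every third major band is split into
    sub-bands (``q12.1``/``q12.2``) so major-band collapsing is exercised.
    The fixture text is always produced; if ``cytoband_path`` is given it is
    written there byte-for-byte deterministically.
    """
    rng = np.random.default_rng([config.seed, 0])
    n_b = config.bands_per_chromosome
    n_p = n_b // 2
    lines: list[str] = []
    for ci in range(1, config.n_chromosomes + 1):
        chrom = _chrom_label(ci)
        names = [f"p{10 + j}" for j in range(n_p)] + [f"q{10 + j}" for j in range(n_b - n_p)]
        lengths = rng.lognormal(np.log(config.band_length_median_bp),
                                config.band_length_sigma, size=n_b)
        lengths = np.maximum(lengths.astype(np.int64), 100_000)
        pos = 0
        for j, (name, length) in enumerate(zip(names, lengths)):
            n_sub = (j % 3) + 1
            if n_sub == 1:
                sub = [(name, int(length))]
            else:
                cut = int(length) // n_sub
                sub = [(f"{name}.{s + 1}", cut) for s in range(n_sub - 1)]
                sub.append((f"{name}.{n_sub}", int(length) - cut * (n_sub - 1)))
            for sub_name, sub_len in sub:
                stain = _STAINS[(ci + j) % len(_STAINS)]
                lines.append(f"chr{chrom}\t{pos}\t{pos + sub_len}\t{sub_name}\t{stain}\n")
                pos += sub_len
    text = "".join(lines)
    if cytoband_path is not None:
        Path(cytoband_path).write_text(text)
    return collapse_to_major_bands(parse_cytoband(io.StringIO(text)))


def simulate_variants(
    annotation: GenomeAnnotation,
    n_variants: int,
    enriched_bands: Sequence[tuple[str, float]] = (),
    seed: int = 0,
    n_duplicates: int = 0,
) -> list[VariantSite]:
    """Draw variant positions from a piecewise-uniform density.

    Band weights are proportional to length times the band's rate
    multiplier (1 outside ``enriched_bands``); positions are uniform within
    the band.  ``n_duplicates`` extra records copying existing ids are
    appended and the list is shuffled (for dedup tests).
    """
    rng = np.random.default_rng([seed, 1])
    known = set(annotation.band_ids())
    mult = dict(enriched_bands)
    unknown = set(mult) - known
    if unknown:
        raise InputError(f"unknown enriched band ids: {sorted(unknown)}")

    bands = list(annotation)
    weights = np.array([b.length_bp * mult.get(b.band_id, 1.0) for b in bands])
    counts = rng.multinomial(n_variants, weights / weights.sum())

    variants: list[VariantSite] = []
    i = 0
    for band, c in zip(bands, counts):
        if c == 0:
            continue
        # 1-based positions in (start, end]
        for pos in rng.integers(band.start + 1, band.end + 1, size=c):
            i += 1
            variants.append(VariantSite(band.chrom, int(pos), f"rs{i}"))
    if n_duplicates:
        if not variants:
            raise InputError("cannot duplicate from an empty variant list")
        picks = rng.choice(len(variants), size=n_duplicates,
                           replace=n_duplicates > len(variants))
        variants.extend(variants[int(p)] for p in picks)
        order = rng.permutation(len(variants))
        variants = [variants[int(j)] for j in order]
    return variants


def write_variants_tsv(variants: Sequence[VariantSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tvariant_id\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.variant_id}\n")


def write_genes_tsv(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\tcds_length\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t{g.cds_length_bp}\n"
            )


def simulate_genes_and_mutations(
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    genes_path: str | Path | None = None,
    maf_path: str | Path | None = None,
) -> tuple[list[GeneRecord], dict[str, int]]:
    """Place genes uniformly (per band, proportional to length), draw CDS
    lengths log-normally and mutation counts Poisson(rate * CDS * multiplier).

    Returns the gene records (band-assigned) and the generator's own
    per-gene mutation bookkeeping (only genes with m > 0).  The optional
    MAF-lite fixture includes non-coding (``3'UTR``) decoy rows that the
    reader must filter out; coding totals still match the bookkeeping.
    """
    rng = np.random.default_rng([config.seed, 2])
    mult = dict(config.burden_multiplier_bands)
    unknown = set(mult) - set(annotation.band_ids())
    if unknown:
        raise InputError(f"unknown burden multiplier bands: {sorted(unknown)}")

    bands = list(annotation)
    weights = np.array([b.length_bp for b in bands], dtype=float)
    per_band = rng.multinomial(config.n_genes, weights / weights.sum())

    genes: list[GeneRecord] = []
    counts: dict[str, int] = {}
    gi = 0
    for band, n_g in zip(bands, per_band):
        span = min(config.gene_span_bp, band.length_bp - 1)
        for _ in range(n_g):
            gi += 1
            start = int(rng.integers(band.start, band.end - span))
            cds = max(
                100,
                int(round(rng.lognormal(np.log(config.cds_length_median_bp),
                                        config.cds_length_sigma))),
            )
            m = int(rng.poisson(config.mutation_rate_per_bp * cds
                                * mult.get(band.band_id, 1.0)))
            genes.append(
                GeneRecord(f"G{gi:05d}", band.chrom, start, start + span,
                           strand="+", cds_length_bp=cds)
            )
            if m > 0:
                counts[f"G{gi:05d}"] = m
    genes = assign_genes(genes, annotation)

    if genes_path is not None:
        write_genes_tsv(genes, genes_path)
    if maf_path is not None:
        gene_by_id = {g.gene_id: g for g in genes}
        with open(maf_path, "w") as fh:
            fh.write(
                "Hugo_Symbol\tChromosome\tStart_Position\t"
                "Variant_Classification\tTumor_Sample_Barcode\n"
            )
            row = 0
            for gene_id in sorted(counts):
                g = gene_by_id[gene_id]
                m = counts[gene_id]
                n_decoy = int(rng.poisson(0.2 * m))
                classes = ["Missense_Mutation" if r % 3 else "Silent" for r in range(m)]
                classes += ["3'UTR"] * n_decoy
                for cls in classes:
                    row += 1
                    pos = g.start + 1 + (row * 37) % (g.end - g.start)
                    sample = f"S{row % max(config.n_samples, 1):03d}"
                    fh.write(f"{gene_id}\t{g.chrom}\t{pos}\t{cls}\t{sample}\n")
    return genes, counts


def simulate_gene_sets(
    genes: Sequence[GeneRecord],
    config: SimulationConfig,
    gmt_path: str | Path | None = None,
) -> list[GeneSet]:
    """Generate gene sets; planted sets concentrate a fraction of members in
    one target band, the remainder (and all null sets) are uniform draws."""
    rng = np.random.default_rng([config.seed, 3])
    all_ids = [g.gene_id for g in genes]
    if config.set_size_mean > len(all_ids):
        raise InputError("set size exceeds the gene universe")
    by_band: dict[str, list[str]] = {}
    for g in genes:
        if g.band_id is not None:
            by_band.setdefault(g.band_id, []).append(g.gene_id)

    sets: list[GeneSet] = []
    for si in range(config.n_gene_sets):
        size = max(5, int(rng.poisson(config.set_size_mean)))
        size = min(size, len(all_ids))
        if si < len(config.planted_set_bands):
            band_id = config.planted_set_bands[si]
            if band_id not in by_band:
                raise InputError(f"planted band {band_id!r} has no genes")
            pool = by_band[band_id]
            n_in = min(int(round(config.band_concentration * size)), len(pool))
            inside = [str(g) for g in rng.choice(pool, size=n_in, replace=False)]
            outside_pool = [g for g in all_ids if g not in set(inside)]
            outside = [str(g) for g in rng.choice(outside_pool, size=size - n_in, replace=False)]
            members = tuple(inside + outside)
            desc = f"planted:{band_id}"
        else:
            members = tuple(str(g) for g in rng.choice(all_ids, size=size, replace=False))
            desc = "null"
        sets.append(GeneSet(f"SET{si:03d}", desc, members))
    if gmt_path is not None:
        with open(gmt_path, "w") as fh:
            write_gmt(sets, fh)
    return sets
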