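"""End-to-end orchestration of the four analysis stages.

Stage 1 scans variant density per band; stages 2 (term ORA + reciprocal
set-to-band enrichment), 4 (DEG-to-band enrichment) and 5 (mutation burden)
default to the band list stage 1 declares significant, but accept an
explicit list.  Every run writes TSV reports plus a JSON manifest recording
input checksums, the configuration and each BH family size, so every
adjusted p-value is traceable to its multiplicity family.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .burden import (
    DEFAULT_CODING_CLASSES,
    annotate_burden,
    band_burden_tests,
    read_gene_counts_tsv,
    read_maf_counts,
    write_burden_tsv,
)
from .enrichment import (
    GeneSet,
    enrich_sets_in_bands,
    read_gmt,
    term_overrepresentation,
    write_enrichment_tsv,
)
from .errors import InputError
from .genome import (
    assign_genes,
    assign_variants,
    collapse_to_major_bands,
    dedup_variants,
    parse_cytoband,
    read_gene_list,
    read_genes_tsv,
    read_variants_bed,
    read_variants_tsv,
    write_bands_bed,
)
from .scan import scan_bands, write_scan_tsv

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and options for a full pipeline run."""

    cytoband: str
    variants: str | None = None
    genes: str | None = None
    gene_sets: str | None = None
    deg_list: str | None = None
    mutations: str | None = None           # MAF-lite TSV
    mutation_counts: str | None = None     # pre-aggregated per-gene counts
    out_dir: str = "cytoscan_out"
    alpha: float = 0.05
    bands: tuple[str, ...] = ()            # explicit band list; overrides stage 1
    welch: bool = True
    drop_genes_without_mutations: bool = False
    report_zero_overlap: bool = True
    coding_classes: tuple[str, ...] = tuple(sorted(DEFAULT_CODING_CLASSES))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InputError(f"alpha must lie in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        for key in ("bands", "coding_classes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise InputError(f"missing required input: {what}")
    p = Path(path)
    if not p.exists():
        raise InputError(f"{what} not found: {path}")
    return p


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Manifest:
    """Accumulates provenance for one run; written as JSON (deterministic)."""

    def __init__(self, config: RunConfig) -> None:
        self.data: dict = {
            "software": {"name": "cytoscan", "version": __version__},
            "config": asdict(config),
            "inputs": {},
            "bh_families": {},
            "stages": {},
        }

    def add_input(self, name: str, path: Path) -> None:
        self.data["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def add_family(self, name: str, size: int) -> None:
        self.data["bh_families"][name] = size

    def write(self, out_dir: Path) -> None:
        self.data["total_tests"] = sum(self.data["bh_families"].values())
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _load_annotation(config: RunConfig, manifest: Manifest):
    path = _require(config.cytoband, "cytoband file")
    manifest.add_input("cytoband", path)
    with open(path) as fh:
        return collapse_to_major_bands(parse_cytoband(fh))


def _load_genes(config: RunConfig, annotation, manifest: Manifest):
    path = _require(config.genes, "gene table")
    manifest.add_input("genes", path)
    with open(path) as fh:
        genes = read_genes_tsv(fh)
    return assign_genes(genes, annotation)


def _band_list(config: RunConfig, significant_bands: Sequence[str]) -> list[str]:
    bands = list(config.bands) if config.bands else list(significant_bands)
    deduped = list(dict.fromkeys(bands))
    if len(deduped) != len(bands):
        log.warning("duplicate band ids in list; deduplicated")
    if not deduped:
        raise InputError("empty band list")
    return deduped


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def run_step1(config: RunConfig, out_dir: str | Path | None = None):
    """Variant dedup + band assignment + density scan; writes scan.tsv."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config)
    annotation = _load_annotation(config, manifest)

    vpath = _require(config.variants, "variant table")
    manifest.add_input("variants", vpath)
    with open(vpath) as fh:
        reader = read_variants_bed if vpath.suffix == ".bed" else read_variants_tsv
        variants = reader(fh)
    variants = dedup_variants(variants)
    if not variants:
        raise InputError("no variants after deduplication")

    counts, unassigned = assign_variants(variants, annotation)
    results = scan_bands(counts, annotation, N=len(variants), alpha=config.alpha)
    manifest.add_family("band_scan", len(results))
    manifest.data["stages"]["step1"] = {
        "n_variants_unique": len(variants),
        "n_unassigned": len(unassigned),
        "n_bands_tested": len(results),
        "n_significant": sum(r.significant for r in results),
    }
    with open(out / "scan.tsv", "w") as fh:
        write_scan_tsv(results, fh, sort_by_band=True)
    with open(out / "bands.bed", "w") as fh:
        write_bands_bed(annotation, fh)
    manifest.write(out)
    return results


def run_step2(
    config: RunConfig,
    significant_bands: Sequence[str],
    out_dir: str | Path | None = None,
):
    """Term ORA on band genes + reciprocal set-to-band enrichment."""
    if config.gene_sets is None:
        log.info("no gene sets supplied; stage 2 skipped")
        return None
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config)
    annotation = _load_annotation(config, manifest)
    genes = _load_genes(config, annotation, manifest)
    bands = _band_list(config, significant_bands)

    gpath = _require(config.gene_sets, "gene sets (GMT)")
    manifest.add_input("gene_sets", gpath)
    with open(gpath) as fh:
        sets = read_gmt(fh)

    universe = [g.gene_id for g in genes]
    band_set = set(bands)
    query = [g.gene_id for g in genes if g.band_id in band_set]
    ora = term_overrepresentation(query, sets, universe,
                                  report_zero_overlap=config.report_zero_overlap)
    reciprocal = enrich_sets_in_bands(sets, genes, bands, universe=universe,
                                      report_zero_overlap=config.report_zero_overlap)
    manifest.add_family("term_ora", len(ora))
    manifest.add_family("reciprocal_band_enrichment", len(reciprocal))
    manifest.data["stages"]["step2"] = {
        "bands": bands,
        "n_query_genes": len(query),
        "alpha": config.alpha,
    }
    with open(out / "ora.tsv", "w") as fh:
        write_enrichment_tsv(ora, fh)
    with open(out / "reciprocal.tsv", "w") as fh:
        write_enrichment_tsv(reciprocal, fh)
    manifest.write(out)
    return ora, reciprocal


def run_step4(
    config: RunConfig,
    significant_bands: Sequence[str],
    out_dir: str | Path | None = None,
):
    """DEG-to-band hypergeometric enrichment; writes deg_bands.tsv."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config)
    annotation = _load_annotation(config, manifest)
    genes = _load_genes(config, annotation, manifest)
    bands = _band_list(config, significant_bands)

    dpath = _require(config.deg_list, "DEG list")
    manifest.add_input("deg_list", dpath)
    with open(dpath) as fh:
        degs = read_gene_list(fh)
    known = {g.gene_id for g in genes}
    kept = [d for d in degs if d in known]
    if len(kept) < len(degs):
        log.info("%d DEG ids absent from gene table dropped", len(degs) - len(kept))
    if not kept:
        raise InputError("no DEG ids found in the gene table")

    deg_set = GeneSet("DEG", "differentially expressed genes", tuple(kept))
    results = enrich_sets_in_bands([deg_set], genes, bands,
                                   report_zero_overlap=True)
    manifest.add_family("deg_band_enrichment", len(results))
    manifest.data["stages"]["step4"] = {
        "bands": bands,
        "n_degs_input": len(degs),
        "n_degs_in_table": len(kept),
    }
    with open(out / "deg_bands.tsv", "w") as fh:
        fh.write(f"# bh_family_size={len(results)}\n")
        fh.write("band_id\tn_genes\tn_degs\tp_raw\tp_adj\n")
        for r in results:
            fh.write(f"{r.target_id}\t{r.n_target}\t{r.k_overlap}\t"
                     f"{r.p_raw:.4g}\t{r.p_adj:.4g}\n")
    manifest.write(out)
    return results


def run_step5(
    config: RunConfig,
    significant_bands: Sequence[str],
    out_dir: str | Path | None = None,
):
    """Length-adjusted mutation burden per band; writes burden.tsv."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config)
    annotation = _load_annotation(config, manifest)
    genes = _load_genes(config, annotation, manifest)
    bands = _band_list(config, significant_bands)

    if config.mutations is not None:
        mpath = _require(config.mutations, "mutation MAF")
        manifest.add_input("mutations", mpath)
        with open(mpath) as fh:
            table = read_maf_counts(fh, coding_classes=set(config.coding_classes))
    elif config.mutation_counts is not None:
        mpath = _require(config.mutation_counts, "mutation counts")
        manifest.add_input("mutation_counts", mpath)
        with open(mpath) as fh:
            table = read_gene_counts_tsv(fh)
    else:
        raise InputError("missing required input: mutation data (MAF or counts)")

    burden = annotate_burden(genes, table,
                             drop_missing=config.drop_genes_without_mutations)
    results = band_burden_tests(burden.genes, bands,
                                high_mutation=burden.high_mutation,
                                welch=config.welch, alpha=config.alpha)
    manifest.add_family("burden_hypergeometric", len(results))
    manifest.add_family("burden_ttest", sum(r.p_ttest_raw is not None for r in results))
    manifest.data["stages"]["step5"] = {
        "bands": bands,
        "q1_cds_length": burden.q1,
        "median_adjusted": burden.median_adjusted,
        "n_genes": len(burden.genes),
        "n_high_mutation": sum(burden.high_mutation.values()),
        "ttest": "welch" if config.welch else "student",
    }
    with open(out / "burden.tsv", "w") as fh:
        write_burden_tsv(results, fh)
    manifest.write(out)
    return results


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run stage 1 then feed its significant bands into stages 2, 4 and 5.

    Stages lacking their inputs are skipped with a log notice.
    """
    out = Path(out_dir or config.out_dir)
    scan_results = run_step1(config, out)
    significant = [r.band_id for r in scan_results if r.significant]
    report: dict = {"step1": scan_results, "significant_bands": significant}
    band_source = list(config.bands) if config.bands else significant
    if not band_source:
        log.warning("no significant bands and no explicit list; stages 2/4/5 skipped")
        return report

    if config.gene_sets and config.genes:
        report["step2"] = run_step2(config, band_source, out)
    else:
        log.info("stage 2 skipped (gene sets or gene table missing)")
    if config.deg_list and config.genes:
        report["step4"] = run_step4(config, band_source, out)
    else:
        log.info("stage 4 skipped (DEG list or gene table missing)")
    if (config.mutations or config.mutation_counts) and config.genes:
        report["step5"] = run_step5(config, band_source, out)
    else:
        log.info("stage 5 skipped (mutation data or gene table missing)")
    return report
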