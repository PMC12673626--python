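"""Length-adjusted somatic mutation burden per gene and per-band tests.

Per-gene coding mutation totals are normalized for gene size by

    adjusted = m / (L + Q1 * log2(L))

where ``L`` is the CDS length and ``Q1`` the first quartile of CDS lengths
across the analyzed genes.  Genes with adjusted counts strictly above the
median are classified as high-mutation; bands are then tested for
over-representation of high-mutation genes (hypergeometric) and for a shift
in mean adjusted burden (two-sample t-test vs. all other genes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from statistics import median
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import hypergeometric_upper
from .errors import InputError
from .genome import GeneRecord
from .scan import benjamini_hochberg

log = logging.getLogger(__name__)

#: Variant_Classification values counted as coding by default.
DEFAULT_CODING_CLASSES: frozenset[str] = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Silent",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Nonstop_Mutation",
    }
)


@dataclass
class MutationTable:
    """Per-gene total coding mutation counts plus the sample count."""

    counts: dict[str, int]
    n_samples: int = 0

    def __post_init__(self) -> None:
        bad = {g: c for g, c in self.counts.items() if c < 0}
        if bad:
            raise InputError(f"negative mutation counts: {bad}")

    def get(self, gene_id: str, default: int = 0) -> int:
        return self.counts.get(gene_id, default)


@dataclass
class BurdenResult:
    band_id: str
    n_genes: int
    n_high_mut: int
    mean_adjusted: float
    p_hyper_raw: float
    p_hyper_adj: float
    p_ttest_raw: float | None
    p_ttest_adj: float | None


def read_maf_counts(
    stream: TextIO,
    coding_classes: Iterable[str] = DEFAULT_CODING_CLASSES,
) -> MutationTable:
    """Tally per-gene coding mutations from a MAF-lite TSV.

    Requires ``Hugo_Symbol`` and ``Variant_Classification`` columns; only
    rows whose classification is in ``coding_classes`` are counted.
    """
    df = pd.read_csv(stream, sep="\t", comment="#", dtype=str)
    for col in ("Hugo_Symbol", "Variant_Classification"):
        if col not in df.columns:
            raise InputError(f"MAF input is missing required column {col!r}")
    coding = df[df["Variant_Classification"].isin(set(coding_classes))]
    counts = coding.groupby("Hugo_Symbol").size().to_dict()
    n_samples = (
        df["Tumor_Sample_Barcode"].nunique() if "Tumor_Sample_Barcode" in df.columns else 0
    )
    return MutationTable({g: int(c) for g, c in counts.items()}, n_samples)


def read_gene_counts_tsv(stream: TextIO | Iterable[str]) -> MutationTable:
    """Read pre-aggregated per-gene counts (gene_id <tab> count)."""
    counts: dict[str, int] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise InputError(f"counts line {lineno}: expected 2 fields")
        try:
            c = int(fields[1])
        except ValueError:
            if lineno == 1:
                continue  # header
            raise InputError(f"counts line {lineno}: non-integer count {fields[1]!r}")
        counts[fields[0].strip()] = counts.get(fields[0].strip(), 0) + c
    return MutationTable(counts)


def first_quartile(lengths: Sequence[float]) -> float:
    """25th percentile with linear interpolation between order statistics."""
    if len(lengths) == 0:
        raise InputError("cannot take the first quartile of an empty list")
    arr = np.asarray(lengths, dtype=float)
    if np.any(arr <= 0):
        raise InputError("lengths must be positive")
    return float(np.quantile(arr, 0.25))


def adjusted_mutation_count(m: float, cds_length: float, q1: float) -> float:
    """Length-adjusted mutation count ``m / (L + Q1 * log2(L))``."""
    if cds_length < 2:
        raise InputError(f"cds_length must be >= 2 (log2 term), got {cds_length}")
    if q1 <= 0:
        raise InputError(f"Q1 must be positive, got {q1}")
    if m < 0:
        raise InputError(f"mutation count must be >= 0, got {m}")
    return m / (cds_length + q1 * math.log2(cds_length))


def classify_high_mutation(adjusted: Mapping[str, float]) -> dict[str, bool]:
    """Flag genes with adjusted counts strictly above the median."""
    if not adjusted:
        raise InputError("no adjusted counts to classify")
    med = median(adjusted.values())
    return {g: v > med for g, v in adjusted.items()}


@dataclass
class BurdenAnnotation:
    """Genes with burden fields filled, plus the thresholds used."""

    genes: list[GeneRecord]
    q1: float
    median_adjusted: float
    high_mutation: dict[str, bool]


def annotate_burden(
    genes: Sequence[GeneRecord],
    mutations: MutationTable,
    drop_missing: bool = False,
) -> BurdenAnnotation:
    """Fill ``mutation_count`` / ``adjusted_count`` on every gene.

    Genes absent from the mutation table are kept with m = 0 by default
    (``drop_missing=True`` removes them from the analysis instead).
    """
    kept = [g for g in genes if not drop_missing or g.gene_id in mutations.counts]
    if not kept:
        raise InputError("no genes left after dropping those without mutation data")
    for g in kept:
        if g.cds_length_bp is None or g.cds_length_bp < 2:
            raise InputError(f"gene {g.gene_id}: cds_length must be >= 2")
    q1 = first_quartile([g.cds_length_bp for g in kept])
    out: list[GeneRecord] = []
    for g in kept:
        m = mutations.get(g.gene_id)
        out.append(
            replace(g, mutation_count=m,
                    adjusted_count=adjusted_mutation_count(m, g.cds_length_bp, q1))
        )
    adjusted = {g.gene_id: g.adjusted_count for g in out}
    flags = classify_high_mutation(adjusted)
    return BurdenAnnotation(out, q1, float(median(adjusted.values())), flags)


def band_burden_tests(
    genes: Sequence[GeneRecord],
    bands_of_interest: Sequence[str],
    high_mutation: Mapping[str, bool] | None = None,
    welch: bool = True,
    alpha: float = 0.05,
) -> list[BurdenResult]:
    """Per-band burden tests against the rest of the genome.

    For each band: a hypergeometric upper-tail test of high-mutation genes
    (universe = all genes supplied) and a two-sample t-test of the band's
    adjusted counts against all other genes (Welch by default).  BH is
    applied separately within each test family; bands with fewer than two
    genes skip the t-test (reported as ``None``).
    """
    for g in genes:
        if g.band_id is None or g.adjusted_count is None:
            raise InputError(
                f"gene {g.gene_id}: band assignment and adjusted count required"
            )
    if high_mutation is None:
        high_mutation = classify_high_mutation({g.gene_id: g.adjusted_count for g in genes})

    N = len(genes)
    bands_arr = np.array([g.band_id for g in genes])
    high_arr = np.array([bool(high_mutation.get(g.gene_id, False)) for g in genes])
    K_high = int(high_arr.sum())
    all_values = np.array([g.adjusted_count for g in genes], dtype=float)

    results: list[BurdenResult] = []
    hyper_ps: list[float] = []
    ttest_ps: list[float] = []
    ttest_idx: list[int] = []
    for band_id in dict.fromkeys(bands_of_interest):
        mask = bands_arr == band_id
        n_genes = int(mask.sum())
        n_high = int(high_arr[mask].sum())
        mean_adj = float(all_values[mask].mean()) if n_genes else float("nan")
        p_hyper = hypergeometric_upper(n_high, K_high, n_genes, N)
        hyper_ps.append(p_hyper)

        p_t: float | None = None
        if n_genes >= 2 and (N - n_genes) >= 2:
            t = stats.ttest_ind(all_values[mask], all_values[~mask], equal_var=not welch)
            p_t = float(t.pvalue)
            if math.isnan(p_t):  # zero variance in both groups
                p_t = 1.0
            ttest_ps.append(p_t)
            ttest_idx.append(len(results))
        else:
            log.info("band %s: t-test skipped (%d genes)", band_id, n_genes)
        results.append(
            BurdenResult(band_id, n_genes, n_high, mean_adj, p_hyper, 1.0, p_t, None)
        )

    if results:
        for r, a in zip(results, benjamini_hochberg(hyper_ps)):
            r.p_hyper_adj = float(a)
    if ttest_ps:
        for idx, a in zip(ttest_idx, benjamini_hochberg(ttest_ps)):
            results[idx].p_ttest_adj = float(a)
    return results


def write_burden_tsv(results: Sequence[BurdenResult], stream: TextIO) -> None:
    n_t = sum(r.p_ttest_raw is not None for r in results)
    stream.write(f"# bh_family_size_hyper={len(results)}\n")
    stream.write(f"# bh_family_size_ttest={n_t}\n")
    stream.write(
        "band_id\tn_genes\tn_high_mut\tmean_adjusted\t"
        "p_hyper_raw\tp_hyper_adj\tp_ttest_raw\tp_ttest_adj\n"
    )
    for r in results:
        t_raw = "NA" if r.p_ttest_raw is None else f"{r.p_ttest_raw:.4g}"
        t_adj = "NA" if r.p_ttest_adj is None else f"{r.p_ttest_adj:.4g}"
        stream.write(
            f"{r.band_id}\t{r.n_genes}\t{r.n_high_mut}\t{r.mean_adjusted:.6g}\t"
            f"{r.p_hyper_raw:.4g}\t{r.p_hyper_adj:.4g}\t{t_raw}\t{t_adj}\n"
        )
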