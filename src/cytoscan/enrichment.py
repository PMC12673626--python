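"""Hypergeometric over-representation analysis in both directions.

Two symmetric questions share one test core:

* Are a gene set's members concentrated in a cytogenetic band
  (:func:`enrich_sets_in_bands`, the "reciprocal" direction)?
* Is a query gene list over-represented in annotation terms
  (:func:`term_overrepresentation`, classic ORA)?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

from scipy import stats

from .errors import InputError
from .genome import GeneRecord
from .scan import benjamini_hochberg

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set; members are deduplicated preserving order."""

    set_id: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        unique = tuple(dict.fromkeys(self.members))
        if len(unique) != len(self.members):
            object.__setattr__(self, "members", unique)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class EnrichmentResult:
    query_id: str
    target_id: str
    n_target: int
    k_overlap: int
    K_query: int
    N_universe: int
    p_raw: float
    p_adj: float


def hypergeometric_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``X`` counts query members among ``n`` draws without replacement from a
    universe of ``N`` containing ``K`` query members.  Symmetric in
    ``K <-> n``.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise InputError(
            f"inconsistent hypergeometric counts: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _resolve_universe(
    universe: Iterable[str] | None, genes: Sequence[GeneRecord]
) -> list[str]:
    if universe is None:
        universe = (g.gene_id for g in genes)
    out = list(dict.fromkeys(universe))
    if not out:
        raise InputError("empty gene universe")
    return out


def enrich_sets_in_bands(
    sets: Sequence[GeneSet],
    genes: Sequence[GeneRecord],
    bands_of_interest: Sequence[str],
    universe: Iterable[str] | None = None,
    min_set_size: int = 2,
    report_zero_overlap: bool = True,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every (gene set, band) pair for over-representation.

    The universe defaults to all genes in the supplied gene table.  Set
    members outside the universe are dropped (logged); sets smaller than
    ``min_set_size`` after intersection are skipped.  BH is applied across
    all pairs in the run; output order is (set_id, band_id).
    """
    universe_list = _resolve_universe(universe, genes)
    universe_set = set(universe_list)
    N = len(universe_list)

    known_bands = {g.band_id for g in genes if g.band_id is not None}
    band_members: dict[str, set[str]] = {}
    for band_id in dict.fromkeys(bands_of_interest):
        if band_id not in known_bands:
            raise InputError(f"band of interest {band_id!r} has no genes in the table")
        band_members[band_id] = {
            g.gene_id for g in genes if g.band_id == band_id and g.gene_id in universe_set
        }

    results: list[EnrichmentResult] = []
    pending: list[float] = []
    for gs in sorted(sets, key=lambda s: s.set_id):
        members = set(gs.members) & universe_set
        dropped = len(set(gs.members)) - len(members)
        if dropped:
            log.info("set %s: %d members outside universe dropped", gs.set_id, dropped)
        if len(members) < min_set_size:
            log.info("set %s: skipped (%d members after intersection)", gs.set_id, len(members))
            continue
        for band_id in band_members:
            in_band = band_members[band_id]
            k = len(members & in_band)
            if k == 0 and not report_zero_overlap:
                continue
            p = hypergeometric_upper(k, len(members), len(in_band), N)
            results.append(
                EnrichmentResult(gs.set_id, band_id, len(in_band), k, len(members), N, p, 1.0)
            )
            pending.append(p)
    if results:
        adj = benjamini_hochberg(pending)
        for r, a in zip(results, adj):
            r.p_adj = float(a)
    results.sort(key=lambda r: (r.query_id, r.target_id))
    return results


def term_overrepresentation(
    query_genes: Sequence[str],
    annotation_sets: Sequence[GeneSet],
    universe: Iterable[str],
    min_set_size: int = 2,
    report_zero_overlap: bool = True,
) -> list[EnrichmentResult]:
    """Classic ORA: one hypergeometric test of the query per term, BH across
    terms.  Zero-overlap terms are reported with p = 1 unless disabled."""
    universe_list = list(dict.fromkeys(universe))
    if not universe_list:
        raise InputError("empty gene universe")
    universe_set = set(universe_list)
    N = len(universe_list)

    query = set(query_genes) & universe_set
    if not query:
        raise InputError("query gene list is empty after universe intersection")
    dropped = len(set(query_genes)) - len(query)
    if dropped:
        log.info("%d query genes outside universe dropped", dropped)

    results: list[EnrichmentResult] = []
    pending: list[float] = []
    for gs in sorted(annotation_sets, key=lambda s: s.set_id):
        members = set(gs.members) & universe_set
        if len(members) < min_set_size:
            log.info("term %s: skipped (%d members after intersection)", gs.set_id, len(members))
            continue
        k = len(query & members)
        if k == 0 and not report_zero_overlap:
            continue
        p = hypergeometric_upper(k, len(query), len(members), N)
        results.append(
            EnrichmentResult("query", gs.set_id, len(members), k, len(query), N, p, 1.0)
        )
        pending.append(p)
    if results:
        adj = benjamini_hochberg(pending)
        for r, a in zip(results, adj):
            r.p_adj = float(a)
    results.sort(key=lambda r: (r.p_raw, r.target_id))
    return results


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------


def read_gmt(stream: TextIO | Iterable[str]) -> list[GeneSet]:
    """Read gene sets from GMT (set_id <tab> description <tab> members...)."""
    sets: list[GeneSet] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise InputError(f"GMT line {lineno}: expected >=3 fields")
        members = tuple(f.strip() for f in fields[2:] if f.strip())
        sets.append(GeneSet(fields[0].strip(), fields[1].strip(), members))
    if not sets:
        raise InputError("empty GMT input")
    return sets


def write_gmt(sets: Sequence[GeneSet], stream: TextIO) -> None:
    for gs in sets:
        stream.write("\t".join([gs.set_id, gs.description, *gs.members]) + "\n")


def write_enrichment_tsv(results: Sequence[EnrichmentResult], stream: TextIO) -> None:
    stream.write(f"# bh_family_size={len(results)}\n")
    stream.write(
        "query_id\ttarget_id\tn_target\tk_overlap\tK_query\tN_universe\tp_raw\tp_adj\n"
    )
    for r in results:
        stream.write(
            f"{r.query_id}\t{r.target_id}\t{r.n_target}\t{r.k_overlap}\t"
            f"{r.K_query}\t{r.N_universe}\t{r.p_raw:.4g}\t{r.p_adj:.4g}\n"
        )
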