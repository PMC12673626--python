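# cytoscan

Detect nonrandom clustering of disease-associated polymorphisms across
cytogenetic bands, test gene sets for reciprocal band enrichment, and run a
length-adjusted somatic mutation-burden analysis — with a synthetic-data
module so every stage is testable offline.

## What it does

1. **Band scan** (`cytoscan scan`): deduplicate variant sites, assign them
   to collapsed major cytogenetic bands (e.g. `8q24`), and test every
   occupied band for elevated density with an exact Poisson rate-ratio
   F test — `F = (k/L_band) / ((N−k+1)/(L_total−L_band))` with
   df = `(2(N−k+1), 2k)` — followed by Benjamini–Hochberg FDR control.
   The p-value is exact: it equals the conditional binomial upper tail
   `P(X ≥ k)` for `X ~ Binomial(N, L_band/L_total)`.
2. **Enrichment** (`cytoscan enrich`): hypergeometric over-representation
   in both directions — terms enriched among the genes of selected bands
   (classic ORA), and gene sets enriched within bands (reciprocal).
3. **DEG analysis** (`cytoscan deg`): hypergeometric enrichment of a
   differentially-expressed-gene list within the selected bands.
4. **Mutation burden** (`cytoscan burden`): per-gene coding mutation
   counts from a MAF-lite TSV, normalized as
   `m / (L_CDS + Q1·log2(L_CDS))` (Q1 = first quartile of CDS lengths);
   genes strictly above the median are "high-mutation", and each band is
   tested by a hypergeometric test of high-mutation genes plus a Welch
   t-test of mean adjusted burden against the background.
5. **Simulation** (`cytoscan simulate`): deterministic synthetic genomes,
   variants (with planted rate multipliers and duplicate injection),
   genes, mutations and gene sets, written in the same plain-text formats
   the readers consume.

## CLI

```sh
# generate a synthetic fixture set
cytoscan simulate --out fixtures --seed 1 --enriched-band 8q24:4

# stage 1: band scan
cytoscan scan --cytoband fixtures/cytoband.tsv \
              --variants fixtures/variants.tsv --out out/

# stages 2/4/5 take a band list (comma-separated, or a file)
cytoscan enrich --cytoband fixtures/cytoband.tsv --genes fixtures/genes.tsv \
                --gene-sets fixtures/gene_sets.gmt --bands 8q24,20q13 --out out/
cytoscan deg    --cytoband fixtures/cytoband.tsv --genes fixtures/genes.tsv \
                --deg-list fixtures/deg_list.txt --bands 8q24,20q13 --out out/
cytoscan burden --cytoband fixtures/cytoband.tsv --genes fixtures/genes.tsv \
                --maf fixtures/mutations.maf.tsv --bands 8q24,20q13 --out out/

# or everything end-to-end from a YAML config (stages 2/4/5 use the
# bands stage 1 flags significant, unless `bands:` is given explicitly)
cytoscan all --config run.yaml --out out/
```

Every run writes TSV reports plus a `manifest.json` with input checksums,
the configuration echo and each BH multiplicity family size. Exit code is
0 on success and 2 on input errors.

### Input formats

| input | format |
|---|---|
| cytogenetic bands | UCSC cytoBand TSV (chrom, start, end, name, stain); `chr` prefixes stripped |
| variants | TSV (chrom, 1-based pos, id) or BED3+name (0-based, converted) |
| genes | TSV (gene_id, chrom, start, end, strand, cds_length) |
| gene sets | GMT |
| mutations | MAF-lite TSV (`Hugo_Symbol`, `Variant_Classification`, …) or per-gene counts TSV |

Coordinates: bands and gene spans are 0-based half-open; variant positions
are 1-based; a position `p` is in band `[start, end)` iff `start < p ≤ end`.
Genes are assigned to the single band containing their midpoint.

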