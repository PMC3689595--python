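# genoverlap

Comparative analysis of positionally overlapping genes: detection and
classification of overlapping gene pairs from genome annotations,
cross-species retention/rearrangement accounting through one-to-one
orthologs, and the associated statistics — Yates-corrected chi-square,
Spearman rank correlation, Mantel row-permutation tests, a binary logit of
overlap status on dS/dN, correlated binary-trait evolution on phylogenies
(dependent vs independent Markov models with a likelihood-ratio test), an
SSR (microsatellite) scanner with mismatch scoring, and average-linkage
city-block clustering.

## Layout

| module | purpose |
|---|---|
| `genoverlap.annotation_io` | readers/writers (GFF3, BED6, TSV gene tables, ortholog maps, newick, FASTA, expression, dS/dN) and the shared data model |
| `genoverlap.overlap_core` | overlap detection; nested (E/H) vs partial (P/O) classification; orientation; clusters (≥3 genes, excluded from pair analyses); intron embedding |
| `genoverlap.ortholog_compare` | young/old pair age classes, cross-species localization profiles and retained/rearranged accounting, intron contingency tables, binary overlap/orthology matrices, expression correlation by orientation |
| `genoverlap.ssr_scan` | perfect/imperfect SSR scanner (motifs 1–6 bp, mismatch penalty 5, ≤3 consecutive mismatches, min score 15) and alignment-normalized SSR content |
| `genoverlap.stats_kit` | Yates chi-square, Spearman (exact permutation p for n ≤ 10), Mantel and multi-predictor Mantel, logistic IRLS with Wald tests, likelihood-ratio test, hierarchical clustering |
| `genoverlap.trait_phylo` | 4-state CTMC likelihoods by pruning, independent (4-rate) vs dependent (8-rate) model fits, LRT (df = 4), trait simulation |
| `genoverlap.synthetic_data` | seeded generators with truth tables: toy genomes with controlled overlap architecture, multi-species ortholog families with covariate-linked rearrangement, implanted SSRs, orientation-correlated expression, logistic dS/dN data, random phylogenies |
| `genoverlap.cli` | `genoverlap` command-line pipeline |

## CLI

One subcommand per analysis; every run writes TSV outputs plus
`params.json` (parameters, seeds, version, config hash) and a
`MANIFEST.tsv` of output checksums. Reruns with identical inputs and seeds
are byte-identical.

```sh
genoverlap simulate --n-genes 400 --seed 1 --out run/sim
genoverlap detect  --genes run/sim/genes.gff3 --format gff3 --species A --out run/detect
genoverlap compare --genes-a a.gff3 --genes-b b.gff3 --orthologs orth.tsv \
                   --species-a A --species-b B --out run/compare
genoverlap ssr     --fasta genes.fasta --min-ssr-score 15 --out run/ssr
genoverlap phylo   --tree species.nwk --traits traits.tsv --seed 1 --out run/phylo
genoverlap mantel  --dep overlap_matrix.tsv --indep orthology_matrix.tsv \
                   --n-perm 999 --seed 1 --out run/mantel
genoverlap logit   --dnds dnds.tsv --out run/logit
genoverlap expression --pairs run/detect/pairs.tsv --expression expr.tsv --out run/expr
```

## File formats

- gene tables: GFF3 (`gene` + `exon` features, `ID`/`Parent`), BED6
  (0-based half-open, converted on read), or TSV with columns
  `gene_id seq_id start end strand exon_starts exon_ends`
  (1-based inclusive, comma-separated exon lists)
- ortholog maps: two-column TSV of one-to-one gene id pairs
- trees: newick with branch lengths (polytomies resolved to binary with
  zero-length edges)
- traits: TSV with columns `species trait1 trait2` (binary)
- expression: TSV, first column gene id, remaining columns conditions
- dS/dN tables: TSV with columns
  `pair_id species gene1_dS gene1_dN gene2_dS gene2_dN overlap_status`
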