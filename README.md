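# refclust

Curation toolkit for DNA-barcode reference databases.

DNA metabarcoding classifies environmental reads against a reference
dataset of barcode sequences (for plants, typically the nuclear
ribosomal ITS region). Public-database records are messy: headers carry
warning words like `PREDICTED:` or `UNVERIFIED:`, fragments are too
short to be informative, and some records are deposited under the wrong
taxon. Redundancy is usually reduced by clustering at high identity and
keeping the longest sequence of each cluster — but that convention
silently propagates misidentifications: the longest member may be the
one wrong record in an otherwise clean cluster, and a weak marker can
lump several congeneric species together.

`refclust` turns a raw FASTA plus a six-rank taxonomy map
(`Phylum;Class;Order;Family;Genus;Species`, `NA` = not assigned) into a
curated, redundancy-reduced, QIIME-formatted reference:

1. **Filter** — drop records whose description contains a suspect
   keyword (`predicted`, `putative`, `uncharacterized`, `unverified`,
   `scaffold`, `protein`, `hypothetical`; case-insensitive substring)
   or whose sequence is shorter than 150 nt. Helpers concatenate
   ITS1 + 5.8S + ITS2 region files into full-ITS records.
2. **Cluster** — greedy incremental clustering at 99% identity
   (CD-HIT convention, reimplemented so no external binary is needed):
   records are visited longest-first and join the earliest cluster
   whose representative aligns at ≥ the threshold. Identity is
   computed from an optimal global alignment and defined relative to
   the *shorter* sequence. Pre-computed CD-HIT `.clstr` files are also
   accepted directly.
3. **Curate** (the bc4q rule) — for each cluster, tally the members'
   species; the cluster resolves at species level only if one species
   accounts for **strictly more than 90%** of the taxonomically
   informative members. Otherwise the check escalates to genus, then
   family, blanking the finer ranks to `NA` in the output taxonomy. A
   cluster failing even at family level is discarded, with every
   member's full lineage written to a log for manual review. The
   representative must belong to the dominant taxon — a minority
   representative is replaced by the longest conforming member.
   Clusters with more than two distinct species are highlighted, which
   feeds the second pass: review the warnings, list misidentified
   accessions, and re-run with `--exclude-file` to re-cluster and
   re-curate the cleaned input.

A deterministic synthetic-fixture generator (`refclust simulate`)
produces taxonomy-structured datasets with controlled intra-species /
inter-species / inter-genus divergence, planted mislabels and planted
suspect keywords, so the whole pipeline is testable offline.

## Worked example

```sh
refclust simulate --seed 7 --mislabel-rate 0.02 --keyword-rate 0.05 \
    --config small.yaml --out-fasta demo.fasta --out-tax demo.tax.tsv
# 40 records, 8 species (0 mislabeled, 2 keyword-flagged)

refclust pipeline --fasta demo.fasta --taxonomy demo.tax.tsv --out-dir out
# INFO loaded 40 records, 40 taxonomy entries
# INFO clustered 38 records into 8 clusters at 0.99 identity
# done: 8 clusters, outputs in out
```

`out/run_summary.tsv` shows the record flow — every stage's output
count is the next stage's input, and removals are itemized:

```
stage            n_in  n_removed  n_out
filter_headers   40    2          38
filter_length    38    0          38
cluster          38    0          38
curate           8     0          8
```

The two keyword-flagged records were removed; the 38 clean records
collapsed into 8 clusters, one per planted species, and every cluster
resolved at species level. `out/curated.report.tsv` holds one verdict
per cluster (resolved rank, dominant taxon, representative, flags), and
`out/curated.tax.tsv` is the QIIME-style two-column taxonomy for the
eight representatives, e.g.

```
Sp01_01_01_r01	Synthophyta;Synthopsida;Synthales;Fam01;Gen01_01;Sp01_01_01
```

A cluster that had resolved only at genus level would show
`...;Gen01_01;NA` here, and a discarded cluster would appear in
`out/curated.discards.log` with all member lineages.

Subcommands `filter`, `cluster`, `curate` and `simulate` expose the
stages individually; every threshold is a flag, and the library API
(`refclust.filter_headers`, `refclust.greedy_cluster`,
`refclust.run_curation`, ...) mirrors the CLI.

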