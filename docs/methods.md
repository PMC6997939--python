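# Methods

## The curation model

The toolkit assumes the standard dereplication setting for barcode
reference databases: a set of orientation-normalized marker sequences
(e.g. ITS1, ITS2 or full ITS), each tied to a six-rank lineage
(phylum, class, order, family, genus, species; `NA` = not assigned),
where true conspecific sequences are nearly identical (≳99%) and
congeneric species diverge enough to separate at that threshold, but
where a minority of records carry wrong taxonomy or unreliable
annotations.

Curation then rests on one statistic per cluster: the fraction of
taxonomically informative members sharing the most frequent taxon at a
rank. A cluster is labeled with a taxon only when that fraction
**strictly exceeds** the dominance threshold (default 0.90 — "more than
90%", so 9/10 and 18/20 fail while 10/11 and 19/21 pass). The check
walks a rank ladder fine → coarse (species → genus → family by
default); the first resolving rank wins, finer ranks are blanked to
`NA` in the emitted lineage, and a cluster resolving nowhere is
discarded into a review log that lists every member's full lineage.

Interpretation choices where the procedure is genuinely open, made once
and fixed:

* **NA handling.** Members with `NA` at the evaluated rank are excluded
  from numerator *and* denominator: missing annotation is not evidence
  of heterogeneity. A rank where every member is `NA` fails and
  escalates. (The alternative — counting `NA` members in the
  denominator — would let unannotated records veto a perfectly
  homogeneous cluster.)
* **Presence counts.** Dominance is computed over unique members, not
  read abundances; the input is a sequence database.
* **Representative choice.** "Most frequent" is read at the taxon
  level: the representative must belong to the dominant taxon at the
  resolved rank. If the incoming (longest) representative does not, it
  is replaced by the longest member that does, ties broken by accession
  (`rep_replaced` flag). In a dereplicated database each sequence
  occurs once, so per-sequence duplicate counts would be degenerate.
* **Higher ranks from one source.** A genus- or family-resolved
  cluster's coarser ranks come from the representative's lineage alone;
  per-rank majority voting could assemble a chimeric lineage that no
  member carries. Disagreement above the resolved rank raises
  `higher_rank_conflict` instead.
* **Ties in the tally.** Equal counts at a rank are broken
  alphabetically — relevant only below the 50% dominance a tie implies,
  i.e. never at the default threshold.

Warning flags: `multi_species` (more than one distinct non-NA species
among members) and `gt2_species` (more than two, the trigger for manual
review and the exclusion-list second pass). The second pass is the
composition `apply_exclusion_list → greedy_cluster → run_curation`; the
manual review between passes is human work by design.

## Clustering and alignment conventions

Greedy incremental clustering follows the convention CD-HIT
established: process sequences longest-first (ties by accession
ascending), join the earliest-created cluster whose *representative*
reaches the identity threshold (first-fit; members are never compared
to each other), else found a new cluster. Consequences, asserted as
test invariants: each representative is the longest member of its
cluster; any two representatives are mutually below threshold;
lowering the threshold never increases the cluster count.

Pairwise identity is computed from a Needleman–Wunsch global alignment
with linear gap scoring (match +1, mismatch −1, gap −2) as

    identity = identical aligned columns / length of the shorter sequence.

The shorter-sequence denominator is CD-HIT's global-identity
convention and differs from BLAST-style local identity: a perfect
substring match scores 1.0. Where several alignments share the optimal
score, the maximum identical-column count among them is used, which
makes the value well defined; the DP carries that maximum alongside the
score, and the test suite checks it against an exhaustive
alignment-enumeration oracle on short sequences. IUPAC ambiguity codes
count as matches only when the characters are literally identical
(N vs A is a mismatch), for determinism. The kernel is JIT-compiled
with numba when available, with an identical pure-Python fallback; no
word-filter or banded heuristics are used, so results are exact under
the stated rule. Equivalence with the CD-HIT binary's own tie-breaking
is not claimed — only with this rule.

Reverse-strand matching (`both_strands`) is off by default because
region-extracted barcode sets are orientation-normalized.

## Synthetic fixtures

The generator emulates exactly the structure the 99%/90% thresholds
assume: one random ancestor per family; genus ancestors mutated from it
at the inter-genus rate (default 0.12 substitutions/site); species
consensus sequences mutated from the genus ancestor at the
inter-species rate (0.05); records mutated from the species consensus
at the intra-species rate (0.002). Defaults: 5 families × 4 genera ×
3 species × 6 records = 360 records of 300 nt — the standard study
condition used by the acceptance checks, sized so conspecific pairs sit
at ≈99.6% identity (above the clustering threshold) and congeneric
species at ≈90% (well below it). Perturbations are planted on top:
`mislabel_rate` swaps the *emitted* species label while the ground
truth retains reality; `keyword_rate` injects one of the seven suspect
header words. Substitutions only by default so identity arithmetic
stays analyzable; `indel_rate` adds single-base indels to exercise the
aligner. Everything derives from one integer seed via a single
`numpy` generator: same config, same fixture, byte for byte.

What the fixtures do **not** model — and hence what passing tests do
not show about real data: realistic ITS length variation and secondary
structure, rate heterogeneity along the sequence, chimeras,
cross-kingdom contamination, and the long-tailed taxon abundance of
GenBank. The generator validates the method's decision logic, not its
end-to-end accuracy on public data.

## Formats and numerical details

* FASTA: accession = first whitespace-delimited token; description =
  rest of the header (written without a trailing space when empty, so
  round trips are byte-identical); sequences uppercased, U→T, wrapped
  at 80 columns.
* `.clstr`: CD-HIT 4.x dialect, identities printed to two decimals;
  accessions are read up to the literal `...`, so accessions containing
  `...` are unsupported. Parsed clusters retain member lengths,
  identities and strands so a file can be re-emitted byte-identically.
* Taxonomy TSV: classic QIIME two-column form, plain rank names; a
  writer flag adds Greengenes-style `p__` prefixes for QIIME 2 import.
  Short lineages are right-padded with `NA` (warned), over-long ones
  are errors; parsers are strict by default with a lenient mode that
  downgrades recoverable problems to warnings.
* Pipeline artifacts contain no timestamps; re-running with identical
  config and inputs is byte-identical (the config snapshot records the
  run's own paths and is the one file tied to its output directory).

## Problem sizes and limitations

The package favours exactness over throughput: clustering is O(n·k)
full alignments against k representatives (seconds for hundreds of
300-nt records, the fixture scale used throughout the tests and the
acceptance script). For hundreds of thousands of records, run CD-HIT
itself and feed its `.clstr` output to `refclust curate --clstr`; the
curation stage is linear in the number of members and fast at any
scale. Contamination screening by sequence similarity (e.g. against a
fungal database) and region extraction from raw records are outside
the toolkit's scope: it consumes already-extracted, already-screened
region files.
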