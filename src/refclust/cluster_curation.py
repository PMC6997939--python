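"""Taxonomy-aware cluster evaluation (the bc4q procedure).

Picking the longest sequence as a cluster's representative — the usual
dereplication convention — silently propagates misidentified records:
the longest member may carry the wrong name while the bulk of the
cluster is correct, and a marker with weak resolution can lump several
congeneric species into one cluster.  This module evaluates each
cluster's taxonomic composition instead:

1. tally the members' species; if one species accounts for strictly
   more than the dominance threshold (default 90%) of the informative
   members, the cluster resolves at species level;
2. otherwise escalate to genus, then family, with the same strict rule;
3. a cluster that resolves at a coarser rank is kept with every finer
   rank blanked to NA in the output taxonomy;
4. a cluster that fails even at family level is discarded, and every
   member's full lineage is written to the log for manual review;
5. the representative must belong to the dominant taxon at the
   resolving rank — if the incoming (longest) representative does not,
   it is replaced by the longest member that does (``rep_replaced``).

Clusters containing more than one species are genus-informative
warnings (``multi_species``); clusters with more than two distinct
species are highlighted for manual review (``gt2_species``), the
trigger for the exclusion-list second pass.

Members with NA at the evaluated rank are excluded from both numerator
and denominator: absent annotation is not evidence of heterogeneity.  A
rank where every member is NA fails and escalates.  Dominance is
computed over unique members (presence, not abundance), since the input
is a dereplicated sequence database, not a read set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from refclust.formats_io import (
    NA,
    RANKS,
    Cluster,
    Lineage,
    SequenceRecord,
    TaxonomyMap,
)

__all__ = [
    "DISCARDED",
    "CurationConfig",
    "ClusterDecision",
    "CurationReport",
    "tally_composition",
    "evaluate_cluster",
    "select_representative",
    "build_output_taxonomy",
    "run_curation",
]

#: Sentinel resolved_rank for clusters failing at every rank of the ladder.
DISCARDED = "discarded"


@dataclass(frozen=True)
class CurationConfig:
    """Dominance rule and rank ladder for cluster evaluation.

    ``dominance_threshold`` is strict: a fraction exactly equal to it
    (e.g. 9/10 at the default 0.90) fails and escalates.  The ladder
    runs fine to coarse and must be a contiguous run of the lineage
    ranks ending no coarser than phylum.
    """

    dominance_threshold: float = 0.90
    rank_ladder: tuple[str, ...] = ("species", "genus", "family")
    flag_species_gt: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.dominance_threshold < 1.0:
            raise ValueError("dominance_threshold must be in (0, 1)")
        if not self.rank_ladder:
            raise ValueError("rank_ladder must be non-empty")
        indices = [RANKS.index(r) for r in self.rank_ladder]  # raises on unknown rank
        expected = list(range(indices[0], indices[0] - len(indices), -1))
        if indices != expected:
            raise ValueError(
                "rank_ladder must run fine to coarse through adjacent ranks, "
                f"e.g. ('species', 'genus', 'family'); got {self.rank_ladder!r}"
            )


@dataclass(frozen=True)
class ClusterDecision:
    """The curation verdict for one cluster."""

    cluster_id: int
    n_members: int
    resolved_rank: str  # 'species' | 'genus' | 'family' | ... | DISCARDED
    dominant_taxon: str | None
    representative: str | None
    flags: frozenset[str]
    tallies: dict[str, dict[str, int]]  # rank -> taxon -> member count (ranks tried)

    @property
    def kept(self) -> bool:
        return self.resolved_rank != DISCARDED


@dataclass
class CurationReport:
    """Aggregate curation outcome: decisions, tallies, and review detail."""

    decisions: list[ClusterDecision] = field(default_factory=list)
    #: clusters resolved per rank, e.g. {'species': 57, 'genus': 2}
    resolved_counts: dict[str, int] = field(default_factory=dict)
    discarded_count: int = 0
    flag_counts: dict[str, int] = field(default_factory=dict)
    #: (cluster_id, [(accession, lineage), ...]) for discarded clusters
    discarded_detail: list[tuple[int, list[tuple[str, Lineage]]]] = field(default_factory=list)
    #: same detail for clusters flagged with > flag_species_gt species
    flagged_detail: list[tuple[int, list[tuple[str, Lineage]]]] = field(default_factory=list)

    def recount(self) -> "CurationReport":
        """Recompute all tallies from ``decisions`` (consistency check)."""
        fresh = CurationReport(
            decisions=self.decisions,
            discarded_detail=self.discarded_detail,
            flagged_detail=self.flagged_detail,
        )
        for d in self.decisions:
            if d.kept:
                fresh.resolved_counts[d.resolved_rank] = (
                    fresh.resolved_counts.get(d.resolved_rank, 0) + 1
                )
            else:
                fresh.discarded_count += 1
            for f in d.flags:
                fresh.flag_counts[f] = fresh.flag_counts.get(f, 0) + 1
        return fresh


def tally_composition(
    cluster: Cluster, taxmap: TaxonomyMap, rank: str
) -> tuple[dict[str, int], int, int]:
    """Count members per taxon name at `rank`, excluding NA annotations.

    Returns ``(taxon -> count, n_informative, n_na)``.  Every member is
    counted once (presence).  A member missing from the taxonomy map is
    an error: taxonomy must be attached before curation.
    """
    counts: Counter[str] = Counter()
    n_na = 0
    for accession in cluster.members:
        name = taxmap[accession].at(rank)  # raises MissingTaxonomyError on a miss
        if name == NA:
            n_na += 1
        else:
            counts[name] += 1
    return dict(counts), sum(counts.values()), n_na


def evaluate_cluster(
    cluster: Cluster,
    taxmap: TaxonomyMap,
    config: CurationConfig = CurationConfig(),
    records: Mapping[str, SequenceRecord] | None = None,
) -> ClusterDecision:
    """Walk the rank ladder fine -> coarse and decide the cluster's fate.

    A rank resolves iff its most frequent taxon exceeds the dominance
    threshold strictly among informative members (and at least one
    member is informative).  The first resolving rank wins; if none
    does, the cluster is discarded.  When ``records`` is provided the
    representative choice is length-aware (see
    :func:`select_representative`); otherwise a minority representative
    is provisionally replaced by the accession-first dominant member.
    """
    flags: set[str] = set()
    species_tally, _, _ = tally_composition(cluster, taxmap, "species")
    if len(species_tally) > 1:
        flags.add("multi_species")
    if len(species_tally) > config.flag_species_gt:
        flags.add("gt2_species")

    tallies: dict[str, dict[str, int]] = {}
    resolved_rank = DISCARDED
    dominant: str | None = None
    for rank in config.rank_ladder:
        counts, n_informative, _ = tally_composition(cluster, taxmap, rank)
        tallies[rank] = counts
        if n_informative == 0:
            continue
        # deterministic argmax: count desc, then name asc
        taxon, top = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if top / n_informative > config.dominance_threshold:
            resolved_rank, dominant = rank, taxon
            break

    decision = ClusterDecision(
        cluster_id=cluster.cluster_id,
        n_members=cluster.size,
        resolved_rank=resolved_rank,
        dominant_taxon=dominant,
        representative=None,
        flags=frozenset(flags),
        tallies=tallies,
    )
    if resolved_rank == DISCARDED:
        return decision

    if taxmap[cluster.representative].at(resolved_rank) == dominant:
        rep = cluster.representative
    else:
        flags.add("rep_replaced")
        decision = replace(decision, flags=frozenset(flags))
        rep = select_representative(cluster, taxmap, decision, records)
    return replace(decision, representative=rep, flags=frozenset(flags))


def select_representative(
    cluster: Cluster,
    taxmap: TaxonomyMap,
    decision: ClusterDecision,
    records: Mapping[str, SequenceRecord] | None = None,
) -> str:
    """Representative for a kept cluster: the dominant taxon's longest member.

    The incoming representative is kept when it already belongs to the
    dominant taxon at the resolved rank; otherwise the longest member of
    the dominant taxon is chosen (ties by accession ascending).  Without
    ``records`` lengths are unknown and the accession-first dominant
    member is returned.
    """
    if not decision.kept:
        raise ValueError(f"cluster {cluster.cluster_id}: cannot select a representative when discarded")
    rank, dominant = decision.resolved_rank, decision.dominant_taxon
    if taxmap[cluster.representative].at(rank) == dominant:
        return cluster.representative
    candidates = [acc for acc in cluster.members if taxmap[acc].at(rank) == dominant]
    if not candidates:
        raise RuntimeError(
            f"cluster {cluster.cluster_id}: no member carries dominant taxon {dominant!r}"
        )
    if records is None:
        return min(candidates)
    return min(candidates, key=lambda acc: (-records[acc].length, acc))


def build_output_taxonomy(
    cluster: Cluster, decision: ClusterDecision, taxmap: TaxonomyMap
) -> tuple[Lineage, frozenset[str]]:
    """Output lineage for a kept cluster, plus any added flags.

    The lineage is the representative's with every rank strictly finer
    than the resolved rank set to NA.  Ranks at and above the resolved
    rank come from the representative alone (no per-rank majority vote,
    which could stitch together a chimeric lineage); if any member's
    non-NA annotation above the resolved rank disagrees, the
    ``higher_rank_conflict`` flag is raised instead.
    """
    if not decision.kept:
        raise ValueError(f"cluster {cluster.cluster_id}: discarded clusters have no output lineage")
    rep_lineage = taxmap[decision.representative]
    cut = RANKS.index(decision.resolved_rank)
    ranks = tuple(
        name if idx <= cut else NA for idx, name in enumerate(rep_lineage.ranks)
    )
    flags: set[str] = set()
    for accession in cluster.members:
        lineage = taxmap[accession]
        for idx in range(cut):  # ranks strictly coarser than the resolved rank
            if lineage.ranks[idx] != NA and lineage.ranks[idx] != rep_lineage.ranks[idx]:
                flags.add("higher_rank_conflict")
    return Lineage(ranks), frozenset(flags)


def run_curation(
    clusters: Sequence[Cluster],
    taxmap: TaxonomyMap,
    records: Sequence[SequenceRecord],
    config: CurationConfig = CurationConfig(),
) -> tuple[list[SequenceRecord], TaxonomyMap, CurationReport]:
    """Evaluate every cluster and assemble the curated dataset.

    Returns one output record and one taxonomy entry per kept cluster,
    keyed by the (possibly replaced) representative accession, plus the
    report with per-cluster decisions and review detail.  Deterministic:
    identical inputs and config give byte-identical outputs.
    """
    by_acc = {r.accession: r for r in records}
    report = CurationReport()
    curated_records: list[SequenceRecord] = []
    curated_tax = TaxonomyMap()

    for cluster in clusters:
        decision = evaluate_cluster(cluster, taxmap, config, records=by_acc)
        if decision.kept:
            lineage, extra_flags = build_output_taxonomy(cluster, decision, taxmap)
            if extra_flags:
                decision = replace(decision, flags=decision.flags | extra_flags)
            rep = decision.representative
            assert rep is not None
            curated_records.append(by_acc[rep])
            curated_tax[rep] = lineage
        else:
            report.discarded_detail.append(
                (cluster.cluster_id, [(acc, taxmap[acc]) for acc in cluster.members])
            )
        if "gt2_species" in decision.flags:
            report.flagged_detail.append(
                (cluster.cluster_id, [(acc, taxmap[acc]) for acc in cluster.members])
            )
        report.decisions.append(decision)

    counted = report.recount()
    report.resolved_counts = counted.resolved_counts
    report.discarded_count = counted.discarded_count
    report.flag_counts = counted.flag_counts
    return curated_records, curated_tax, report
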