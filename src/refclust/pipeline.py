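"""End-to-end curation pipeline: filter -> cluster -> curate -> report.

One entry point runs the whole flow on a FASTA + taxonomy pair:

1. header-keyword filtering;
2. minimum-length filtering;
3. optional exclusion-list removal (the second-pass protocol: curate,
   review the warned clusters manually, list the misidentified
   accessions, re-cluster and re-curate the cleaned input);
4. greedy clustering — or, when a pre-computed ``.clstr`` file is
   supplied, parsing it instead;
5. taxonomy-aware cluster curation.

Every stage's record counts (in / removed / out) go into a
machine-readable run summary, and a config snapshot is written next to
the outputs, so a run can be reproduced exactly.  Data artifacts carry
no timestamps: re-running with identical inputs and config is
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from refclust.cluster_curation import CurationConfig, run_curation
from refclust.formats_io import (
    parse_clstr,
    read_fasta,
    read_taxonomy_map,
    write_clstr,
    write_decision_table,
    write_discard_log,
    write_fasta,
    write_taxonomy_map,
)
from refclust.greedy_clustering import ClusteringConfig, greedy_cluster
from refclust.sequence_filters import FilterConfig, apply_exclusion_list, filter_headers, filter_length

__all__ = ["PipelineConfig", "PipelineResult", "StageCount", "run_pipeline"]

logger = logging.getLogger("refclust")


@dataclass(frozen=True)
class PipelineConfig:
    """Paths plus the three stage configs for one pipeline run."""

    input_fasta: Path
    taxonomy: Path
    out_dir: Path
    clstr: Path | None = None  # skip clustering, parse this instead
    exclusion_list: Path | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    curation: CurationConfig = field(default_factory=CurationConfig)

    def snapshot(self) -> dict:
        data = asdict(self)
        for key in ("input_fasta", "taxonomy", "out_dir", "clstr", "exclusion_list"):
            if data[key] is not None:
                data[key] = str(data[key])
        return data


@dataclass
class StageCount:
    stage: str
    n_in: int
    n_removed: int
    n_out: int


@dataclass
class PipelineResult:
    stages: list[StageCount]
    n_clusters: int
    report: object  # CurationReport
    out_dir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full curation flow and write all artifacts to ``out_dir``.

    Artifacts: ``filtered.fasta``, ``removed.fasta``, ``clusters.clstr``
    (when clustering is run), ``curated.fasta``, ``curated.tax.tsv``,
    ``curated.report.tsv``, ``curated.discards.log``,
    ``run_summary.tsv`` and ``config_snapshot.yaml``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: list[StageCount] = []

    records = read_fasta(config.input_fasta)
    taxmap = read_taxonomy_map(config.taxonomy)
    logger.info("loaded %d records, %d taxonomy entries", len(records), len(taxmap))

    removed_all = []
    kept, removed = filter_headers(records, config.filters)
    stages.append(StageCount("filter_headers", len(records), len(removed), len(kept)))
    removed_all.extend(removed)

    kept2, removed = filter_length(kept, config.filters)
    stages.append(StageCount("filter_length", len(kept), len(removed), len(kept2)))
    removed_all.extend(removed)
    kept = kept2

    if config.exclusion_list is not None:
        ids = [
            line.strip()
            for line in Path(config.exclusion_list).read_text().splitlines()
            if line.strip()
        ]
        kept2, removed, missing = apply_exclusion_list(kept, ids)
        if missing:
            logger.warning("exclusion list: %d id(s) not found: %s", len(missing), missing)
        stages.append(StageCount("apply_exclusion_list", len(kept), len(removed), len(kept2)))
        removed_all.extend(removed)
        kept = kept2

    write_fasta(kept, out_dir / "filtered.fasta")
    write_fasta(removed_all, out_dir / "removed.fasta")

    if config.clstr is not None:
        clusters = parse_clstr(config.clstr)
        logger.info("parsed %d clusters from %s", len(clusters), config.clstr)
    else:
        clusters = greedy_cluster(kept, config.clustering)
        write_clstr(clusters, out_dir / "clusters.clstr")
        logger.info(
            "clustered %d records into %d clusters at %.2f identity",
            len(kept),
            len(clusters),
            config.clustering.identity_threshold,
        )
    stages.append(StageCount("cluster", len(kept), 0, len(kept)))

    curated_records, curated_tax, report = run_curation(clusters, taxmap, kept, config.curation)
    stages.append(
        StageCount("curate", len(clusters), report.discarded_count, len(curated_records))
    )
    write_fasta(curated_records, out_dir / "curated.fasta")
    write_taxonomy_map(curated_tax, out_dir / "curated.tax.tsv")
    write_decision_table(report, out_dir / "curated.report.tsv")
    write_discard_log(report, out_dir / "curated.discards.log")

    with open(out_dir / "run_summary.tsv", "w") as handle:
        handle.write("stage\tn_in\tn_removed\tn_out\n")
        for s in stages:
            handle.write(f"{s.stage}\t{s.n_in}\t{s.n_removed}\t{s.n_out}\n")

    from refclust import __version__

    with open(out_dir / "config_snapshot.yaml", "w") as handle:
        yaml.safe_dump({"refclust_version": __version__, **config.snapshot()}, handle, sort_keys=True)

    return PipelineResult(stages=stages, n_clusters=len(clusters), report=report, out_dir=out_dir)
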