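"""Record-level cleaning rules applied before clustering.

Four operations, each a pure partition of its input (no record is ever
mutated, |kept| + |removed| == |input|, order preserved):

* header-keyword screening — records whose description contains any of
  the flagged words (``predicted``, ``putative``, ``uncharacterized``,
  ``unverified``, ``scaffold``, ``protein``, ``hypothetical``) are
  removed.  Matching is case-insensitive substring matching on the
  description only; "protein" therefore also hits "proteinase", an
  accepted over-removal for a conservative cleaning step.
* minimum-length trimming — records strictly shorter than ``min_length``
  (default 150 nt) are removed.
* full-ITS concatenation — accessions present in all three of the ITS1,
  5.8S and ITS2 region sets are concatenated in that order.
* exclusion-list removal — drops listed accessions for the second
  curation pass, reporting listed ids that were not found.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from refclust.formats_io import SequenceRecord

__all__ = [
    "DEFAULT_KEYWORDS",
    "FilterConfig",
    "Partition",
    "ExclusionResult",
    "filter_headers",
    "filter_length",
    "concatenate_its",
    "apply_exclusion_list",
]

#: Header words flagging unreliable annotations (matched case-insensitively).
DEFAULT_KEYWORDS = (
    "predicted",
    "putative",
    "uncharacterized",
    "unverified",
    "scaffold",
    "protein",
    "hypothetical",
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the record-level cleaning rules."""

    keywords: tuple[str, ...] = DEFAULT_KEYWORDS
    min_length: int = 150

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("keyword list must be non-empty")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        object.__setattr__(self, "keywords", tuple(k.lower() for k in self.keywords))


class Partition(NamedTuple):
    kept: list[SequenceRecord]
    removed: list[SequenceRecord]


class ExclusionResult(NamedTuple):
    kept: list[SequenceRecord]
    removed: list[SequenceRecord]
    missing: list[str]  # listed ids not present in the input


def filter_headers(
    records: Iterable[SequenceRecord], config: FilterConfig = FilterConfig()
) -> Partition:
    """Remove records whose description contains any flagged keyword."""
    kept: list[SequenceRecord] = []
    removed: list[SequenceRecord] = []
    for rec in records:
        desc = rec.description.lower()
        (removed if any(k in desc for k in config.keywords) else kept).append(rec)
    return Partition(kept, removed)


def filter_length(
    records: Iterable[SequenceRecord], config: FilterConfig = FilterConfig()
) -> Partition:
    """Remove records strictly shorter than ``config.min_length``."""
    kept: list[SequenceRecord] = []
    removed: list[SequenceRecord] = []
    for rec in records:
        (removed if rec.length < config.min_length else kept).append(rec)
    return Partition(kept, removed)


def concatenate_its(
    its1: Sequence[SequenceRecord],
    s58: Sequence[SequenceRecord],
    its2: Sequence[SequenceRecord],
) -> list[SequenceRecord]:
    """Concatenate ITS1 + 5.8S + ITS2 for accessions present in all three sets.

    Accessions missing from any set are silently excluded.  The output
    inherits the ITS1 record's description and is sorted by accession.
    Accession matching is strict string equality — versioned accessions
    (ACC.1 vs ACC.2) are distinct; normalize upstream if needed.
    """
    by_acc = [_index_unique(part, name) for part, name in ((its1, "ITS1"), (s58, "5.8S"), (its2, "ITS2"))]
    shared = set(by_acc[0]) & set(by_acc[1]) & set(by_acc[2])
    out = []
    for acc in sorted(shared):
        seq = by_acc[0][acc].sequence + by_acc[1][acc].sequence + by_acc[2][acc].sequence
        out.append(SequenceRecord(acc, by_acc[0][acc].description, seq))
    return out


def apply_exclusion_list(
    records: Iterable[SequenceRecord], accession_ids: Iterable[str]
) -> ExclusionResult:
    """Remove listed accessions; report listed ids absent from the input."""
    ids = set(accession_ids)
    kept: list[SequenceRecord] = []
    removed: list[SequenceRecord] = []
    for rec in records:
        (removed if rec.accession in ids else kept).append(rec)
    found = {rec.accession for rec in removed}
    return ExclusionResult(kept, removed, sorted(ids - found))


def _index_unique(part: Sequence[SequenceRecord], name: str) -> dict[str, SequenceRecord]:
    index: dict[str, SequenceRecord] = {}
    for rec in part:
        if rec.accession in index:
            raise ValueError(f"{name} set: duplicate accession {rec.accession!r}")
        index[rec.accession] = rec
    return index
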