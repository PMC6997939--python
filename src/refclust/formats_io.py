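"""Readers and writers for every external format the toolkit touches.

Formats handled:

* multi-line FASTA (read/write, 80-column default wrap);
* CD-HIT ``.clstr`` companion files (read/write);
* two-column tab-separated taxonomy maps in classic QIIME style,
  ``accession<TAB>Phylum;Class;Order;Family;Genus;Species`` with the
  literal token ``NA`` marking an unassigned rank;
* the plain-text discard/warning log and the per-cluster decision table
  produced by curation.

All parsers are strict by default; ``strict=False`` downgrades
recoverable format problems to :class:`UserWarning` and skips or repairs
the offending entry.  Round trips (write -> read -> write) are
byte-identical for all three data formats.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "RANKS",
    "NA",
    "FormatError",
    "SequenceRecord",
    "Lineage",
    "TaxonomyMap",
    "MissingTaxonomyError",
    "Cluster",
    "read_fasta",
    "write_fasta",
    "parse_clstr",
    "write_clstr",
    "read_taxonomy_map",
    "write_taxonomy_map",
    "write_discard_log",
    "write_decision_table",
]

#: Taxonomic ranks carried by every lineage, coarse to fine.
RANKS = ("phylum", "class", "order", "family", "genus", "species")

#: Literal token marking an unassigned rank.
NA = "NA"

_IUPAC_NT = frozenset("ACGTURYSWKMBDHVN")


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class MissingTaxonomyError(KeyError):
    """An accession was looked up in a taxonomy map that does not contain it."""


@dataclass(frozen=True)
class SequenceRecord:
    """One accession's DNA sequence plus its free-text description.

    The sequence is uppercase-normalized with U converted to T on
    construction and must stay within the IUPAC nucleotide alphabet.
    """

    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession or any(c.isspace() for c in self.accession):
            raise ValueError(f"invalid accession {self.accession!r}: empty or contains whitespace")
        seq = self.sequence.upper().replace("U", "T")
        if not seq:
            raise ValueError(f"record {self.accession}: empty sequence")
        bad = set(seq) - _IUPAC_NT
        if bad:
            raise ValueError(
                f"record {self.accession}: non-IUPAC characters {sorted(bad)!r} in sequence"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Lineage:
    """Ordered six-rank taxonomy (phylum..species); ``NA`` marks unassigned.

    No cross-rank consistency is enforced: a named species under an NA
    genus is legal, because public-database annotations really do look
    like that.
    """

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != len(RANKS):
            raise ValueError(f"lineage needs exactly {len(RANKS)} ranks, got {len(self.ranks)}")
        if any(not r for r in self.ranks):
            raise ValueError("lineage ranks must be non-empty strings (use 'NA' for unassigned)")

    @classmethod
    def from_names(cls, *names: str) -> "Lineage":
        return cls(tuple(names))

    def at(self, rank: str) -> str:
        """Name at `rank` ('phylum'..'species')."""
        return self.ranks[RANKS.index(rank)]

    def replace(self, **kw: str) -> "Lineage":
        ranks = list(self.ranks)
        for rank, name in kw.items():
            ranks[RANKS.index(rank)] = name
        return Lineage(tuple(ranks))

    def __str__(self) -> str:
        return ";".join(self.ranks)


class TaxonomyMap:
    """Mapping accession -> :class:`Lineage` with a loud miss.

    Looking up an accession that is absent raises
    :class:`MissingTaxonomyError` rather than returning an all-NA
    lineage: taxonomy must be attached explicitly before curation.
    """

    def __init__(self, entries: Mapping[str, Lineage] | None = None) -> None:
        self.entries: dict[str, Lineage] = dict(entries or {})

    def __getitem__(self, accession: str) -> Lineage:
        try:
            return self.entries[accession]
        except KeyError:
            raise MissingTaxonomyError(
                f"accession {accession!r} has no taxonomy entry"
            ) from None

    def __setitem__(self, accession: str, lineage: Lineage) -> None:
        self.entries[accession] = lineage

    def __contains__(self, accession: str) -> bool:
        return accession in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxonomyMap) and self.entries == other.entries

    def items(self) -> Iterable[tuple[str, Lineage]]:
        return self.entries.items()


@dataclass(frozen=True)
class Cluster:
    """One cluster from a clustering round.

    ``members`` always contains the representative.  ``member_lengths``,
    ``member_identities`` and ``member_strands`` are optional parallel
    tuples (identity is the fraction to the representative, ``None`` for
    the representative itself); they are carried so a parsed ``.clstr``
    file can be re-emitted byte-identically.
    """

    cluster_id: int
    representative: str
    members: tuple[str, ...]
    member_lengths: tuple[int, ...] | None = None
    member_identities: tuple[float | None, ...] | None = None
    member_strands: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.cluster_id < 0:
            raise ValueError("cluster_id must be >= 0")
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id}: no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"cluster {self.cluster_id}: duplicate members")
        if self.representative not in self.members:
            raise ValueError(
                f"cluster {self.cluster_id}: representative {self.representative!r} not a member"
            )
        for name, extra in (
            ("member_lengths", self.member_lengths),
            ("member_identities", self.member_identities),
            ("member_strands", self.member_strands),
        ):
            if extra is not None and len(extra) != len(self.members):
                raise ValueError(f"cluster {self.cluster_id}: {name} length mismatch")

    @property
    def size(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, strict: bool = True) -> list[SequenceRecord]:
    """Read a FASTA file into an ordered list of records.

    The accession is the first whitespace-delimited token of the header;
    the remainder of the header line is the description.  Multi-line
    sequences are joined, lowercase and U are normalized.  An empty file
    yields an empty list.  Duplicate accessions and headers without a
    sequence body are errors (warnings + skip when ``strict=False``).
    """
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    duplicates: list[str] = []
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            parts = title.split(None, 1)
            if not parts:
                _complain(f"{path}: FASTA header with no accession", strict)
                continue
            accession = parts[0]
            description = parts[1] if len(parts) > 1 else ""
            if not seq:
                _complain(f"{path}: header {accession!r} has no sequence body", strict)
                continue
            if accession in seen:
                duplicates.append(accession)
                continue
            seen[accession] = len(records)
            try:
                records.append(SequenceRecord(accession, description, "".join(seq.split())))
            except ValueError as exc:
                _complain(f"{path}: {exc}", strict)
    if duplicates:
        _complain(f"{path}: duplicate accessions {sorted(set(duplicates))!r}", strict)
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, line_width: int = 80
) -> None:
    """Write records as multi-line FASTA; empty description means no trailing space."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with open(path, "w") as handle:
        for rec in records:
            header = f">{rec.accession} {rec.description}" if rec.description else f">{rec.accession}"
            handle.write(header + "\n")
            for start in range(0, rec.length, line_width):
                handle.write(rec.sequence[start : start + line_width] + "\n")


# ---------------------------------------------------------------------------
# CD-HIT .clstr

_CLSTR_HEADER = re.compile(r"^>Cluster\s+(\d+)\s*$")
_CLSTR_MEMBER = re.compile(
    r"^(\d+)\t(\d+)nt, >(.*?)\.\.\. (\*|at ([+-])/([0-9.]+)%)\s*$"
)


def parse_clstr(path: str | Path, strict: bool = True) -> list[Cluster]:
    """Parse a CD-HIT 4.x-style ``.clstr`` file.

    Representative = the member line ending in ``*``; exactly one per
    cluster.  Accessions are taken up to the literal ``...`` terminator,
    so accessions containing ``...`` are unsupported.
    """
    clusters: list[Cluster] = []
    current: list[tuple[str, int, float | None, str]] | None = None
    current_id: int | None = None

    def _flush() -> None:
        nonlocal current, current_id
        if current_id is None:
            return
        if not current:
            raise FormatError(f"{path}: cluster {current_id} has no members")
        reps = [m for m in current if m[2] is None]
        if len(reps) != 1:
            raise FormatError(
                f"{path}: cluster {current_id} has {len(reps)} representative lines ('*'), expected 1"
            )
        clusters.append(
            Cluster(
                cluster_id=current_id,
                representative=reps[0][0],
                members=tuple(m[0] for m in current),
                member_lengths=tuple(m[1] for m in current),
                member_identities=tuple(m[2] for m in current),
                member_strands=tuple(m[3] for m in current),
            )
        )
        current, current_id = None, None

    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip():
                continue
            m = _CLSTR_HEADER.match(line)
            if m:
                _flush()
                current_id = int(m.group(1))
                current = []
                continue
            m = _CLSTR_MEMBER.match(line)
            if m is None:
                _complain(f"{path}:{lineno}: unparseable .clstr line {line!r}", strict)
                continue
            if current is None:
                raise FormatError(f"{path}:{lineno}: member line before any cluster header")
            if m.group(4) == "*":
                current.append((m.group(3), int(m.group(2)), None, "+"))
            else:
                current.append((m.group(3), int(m.group(2)), float(m.group(6)) / 100.0, m.group(5)))
    _flush()
    return clusters


def write_clstr(clusters: Iterable[Cluster], path: str | Path) -> None:
    """Emit clusters in the CD-HIT ``.clstr`` dialect (identities to 2 dp)."""
    with open(path, "w") as handle:
        for cluster in clusters:
            if cluster.member_lengths is None:
                raise ValueError(
                    f"cluster {cluster.cluster_id}: member lengths required to write .clstr"
                )
            idents = cluster.member_identities or (None,) * cluster.size
            strands = cluster.member_strands or ("+",) * cluster.size
            handle.write(f">Cluster {cluster.cluster_id}\n")
            for idx, (acc, length, ident, strand) in enumerate(
                zip(cluster.members, cluster.member_lengths, idents, strands)
            ):
                if acc == cluster.representative:
                    tail = "*"
                else:
                    if ident is None:
                        raise ValueError(
                            f"cluster {cluster.cluster_id}: member {acc} lacks an identity value"
                        )
                    tail = f"at {strand}/{ident * 100.0:.2f}%"
                handle.write(f"{idx}\t{length}nt, >{acc}... {tail}\n")


# ---------------------------------------------------------------------------
# Taxonomy map (classic QIIME 2-column TSV)

_GG_PREFIXES = ("p__", "c__", "o__", "f__", "g__", "s__")


def read_taxonomy_map(path: str | Path, strict: bool = True) -> TaxonomyMap:
    """Read ``accession<TAB>semicolon-lineage`` taxonomy.

    Lines with fewer than six ranks are right-padded with NA (counted in
    a single warning); more than six ranks is an error.  Empty rank
    fields become NA.
    """
    entries: dict[str, Lineage] = {}
    padded = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                _complain(f"{path}:{lineno}: expected 2 tab-separated columns", strict)
                continue
            accession, lineage_text = parts
            names = [f.strip() or NA for f in lineage_text.split(";")]
            if len(names) > len(RANKS):
                _complain(
                    f"{path}:{lineno}: {len(names)} lineage fields for {accession} (max {len(RANKS)})",
                    strict,
                )
                names = names[: len(RANKS)]
            if len(names) < len(RANKS):
                padded += 1
                names += [NA] * (len(RANKS) - len(names))
            if accession in entries:
                _complain(f"{path}:{lineno}: duplicate accession {accession!r}", strict)
                continue
            entries[accession] = Lineage(tuple(names))
    if padded:
        warnings.warn(
            f"{path}: {padded} taxonomy line(s) had fewer than {len(RANKS)} ranks; padded with NA",
            stacklevel=2,
        )
    return TaxonomyMap(entries)


def write_taxonomy_map(
    taxmap: TaxonomyMap, path: str | Path, greengenes_prefixes: bool = False
) -> None:
    """Write a 2-column TSV taxonomy; optional ``p__``-style rank prefixes."""
    with open(path, "w") as handle:
        for accession, lineage in taxmap.items():
            if greengenes_prefixes:
                text = ";".join(p + n for p, n in zip(_GG_PREFIXES, lineage.ranks))
            else:
                text = str(lineage)
            handle.write(f"{accession}\t{text}\n")


# ---------------------------------------------------------------------------
# Curation report output


def write_discard_log(report, path: str | Path) -> None:  # report: CurationReport
    """Plain-text log of discarded clusters and >2-species warnings.

    One block per discarded cluster with every member's accession and
    full six-rank lineage, then the same per-member detail for clusters
    flagged as containing more than two species.
    """
    with open(path, "w") as handle:
        handle.write("Curation discard log\n")
        handle.write("====================\n")
        handle.write(f"{len(report.discarded_detail)} clusters discarded\n")
        for cluster_id, members in report.discarded_detail:
            handle.write(f"\nCluster {cluster_id} ({len(members)} members)\n")
            for accession, lineage in members:
                handle.write(f"  {accession}\t{lineage}\n")
        handle.write("\nWarnings: clusters with more than 2 distinct species\n")
        handle.write("====================================================\n")
        handle.write(f"{len(report.flagged_detail)} clusters flagged\n")
        for cluster_id, members in report.flagged_detail:
            handle.write(f"\nCluster {cluster_id} ({len(members)} members)\n")
            for accession, lineage in members:
                handle.write(f"  {accession}\t{lineage}\n")


def write_decision_table(report, path: str | Path) -> None:  # report: CurationReport
    """Per-cluster decision table as TSV (one row per evaluated cluster)."""
    with open(path, "w") as handle:
        handle.write(
            "cluster_id\tn_members\tresolved_rank\tdominant_taxon\trepresentative\tflags\n"
        )
        for d in report.decisions:
            handle.write(
                f"{d.cluster_id}\t{d.n_members}\t{d.resolved_rank}\t"
                f"{d.dominant_taxon or '-'}\t{d.representative or '-'}\t"
                f"{','.join(sorted(d.flags)) or '-'}\n"
            )


def _complain(message: str, strict: bool) -> None:
    if strict:
        raise FormatError(message)
    warnings.warn(message, stacklevel=3)
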