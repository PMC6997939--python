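"""Greedy incremental clustering at a configurable identity threshold.

A convention-level reimplementation of the clustering scheme CD-HIT
popularized for building non-redundant sequence databases, so the full
curation pipeline runs without external binaries:

* records are processed longest-first (ties broken by accession);
* each record joins the earliest-created cluster whose *representative*
  aligns to it at >= the identity threshold, otherwise it founds a new
  cluster with itself as representative;
* the representative is therefore always the longest member of its
  cluster, and any two representatives are mutually below threshold.

Identity is computed from an optimal global (Needleman-Wunsch)
alignment under linear gap scoring and is defined relative to the
SHORTER sequence — CD-HIT's global-identity convention, which differs
from BLAST-style local identity: a perfect substring match scores 1.0.
Among co-optimal alignments the one with the most identical columns is
used, which makes the reported fraction deterministic.  IUPAC ambiguity
codes only count as matches when the characters are identical.

No short-word prefilter or banded shortcuts are attempted: the O(n*k)
representative comparisons are exact and fast enough at desk scale
(the inner alignment is JIT-compiled via numba when available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from refclust.formats_io import Cluster, SequenceRecord

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(func):
            return func

        return wrap(args[0]) if args and callable(args[0]) else wrap


__all__ = ["ClusteringConfig", "pairwise_identity", "greedy_cluster"]

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


@dataclass(frozen=True)
class ClusteringConfig:
    """Identity threshold and alignment scoring for greedy clustering."""

    identity_threshold: float = 0.99
    both_strands: bool = False
    match_score: int = 1
    mismatch_score: int = -1
    gap_score: int = -2

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValueError("identity_threshold must be in (0, 1]")


@njit(cache=True)
def _nw_max_identities(a: np.ndarray, b: np.ndarray, match: int, mismatch: int, gap: int) -> int:
    """Max number of identical aligned columns over all optimal-score
    global alignments of `a` and `b` under linear gap scoring."""
    n, m = a.size, b.size
    score = np.empty((n + 1, m + 1), dtype=np.int64)
    ident = np.empty((n + 1, m + 1), dtype=np.int64)
    score[0, 0] = 0
    ident[0, 0] = 0
    for j in range(1, m + 1):
        score[0, j] = j * gap
        ident[0, j] = 0
    for i in range(1, n + 1):
        score[i, 0] = i * gap
        ident[i, 0] = 0
        for j in range(1, m + 1):
            eq = a[i - 1] == b[j - 1]
            diag = score[i - 1, j - 1] + (match if eq else mismatch)
            up = score[i - 1, j] + gap
            left = score[i, j - 1] + gap
            best = diag
            if up > best:
                best = up
            if left > best:
                best = left
            bi = -1
            if diag == best:
                bi = ident[i - 1, j - 1] + (1 if eq else 0)
            if up == best and ident[i - 1, j] > bi:
                bi = ident[i - 1, j]
            if left == best and ident[i, j - 1] > bi:
                bi = ident[i, j - 1]
            score[i, j] = best
            ident[i, j] = bi
    return ident[n, m]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    return seq.translate(_COMPLEMENT)[::-1]


def _identity_one_strand(a: str, b: str, config: ClusteringConfig) -> float:
    matches = _nw_max_identities(
        _encode(a), _encode(b), config.match_score, config.mismatch_score, config.gap_score
    )
    return matches / min(len(a), len(b))


def pairwise_identity(
    a: SequenceRecord | str, b: SequenceRecord | str, config: ClusteringConfig = ClusteringConfig()
) -> float:
    """Global-alignment identity of two sequences, in [0, 1].

    Identity = identical aligned columns / length of the shorter
    sequence, maximized over co-optimal alignments.  With
    ``both_strands`` the reverse complement of ``b`` is also evaluated
    and the larger identity returned.
    """
    seq_a = a.sequence if isinstance(a, SequenceRecord) else a
    seq_b = b.sequence if isinstance(b, SequenceRecord) else b
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    ident = _identity_one_strand(seq_a, seq_b, config)
    if config.both_strands:
        ident = max(ident, _identity_one_strand(seq_a, reverse_complement(seq_b), config))
    return ident


def greedy_cluster(
    records: Sequence[SequenceRecord], config: ClusteringConfig = ClusteringConfig()
) -> list[Cluster]:
    """Cluster records greedily; returns clusters in creation order.

    Records are visited length-descending (ties by accession ascending);
    each joins the earliest cluster whose representative reaches the
    identity threshold, else founds a new one.  The returned clusters
    carry member lengths, identities to the representative, and strands,
    ready for ``.clstr`` output.
    """
    accs = [r.accession for r in records]
    if len(set(accs)) != len(accs):
        raise ValueError("duplicate accessions in clustering input")
    order = sorted(records, key=lambda r: (-r.length, r.accession))

    reps: list[SequenceRecord] = []
    # per cluster: list of (accession, length, identity|None, strand)
    built: list[list[tuple[str, int, float | None, str]]] = []
    for rec in order:
        for ci, rep in enumerate(reps):
            ident = _identity_one_strand(rep.sequence, rec.sequence, config)
            strand = "+"
            if config.both_strands:
                rc_ident = _identity_one_strand(
                    rep.sequence, reverse_complement(rec.sequence), config
                )
                if rc_ident > ident:
                    ident, strand = rc_ident, "-"
            if ident >= config.identity_threshold:
                built[ci].append((rec.accession, rec.length, ident, strand))
                break
        else:
            reps.append(rec)
            built.append([(rec.accession, rec.length, None, "+")])

    return [
        Cluster(
            cluster_id=ci,
            representative=members[0][0],
            members=tuple(m[0] for m in members),
            member_lengths=tuple(m[1] for m in members),
            member_identities=tuple(m[2] for m in members),
            member_strands=tuple(m[3] for m in members),
        )
        for ci, members in enumerate(built)
    ]
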