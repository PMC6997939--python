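"""Deterministic generator of taxonomy-structured sequence fixtures.

Emulates the population structure the 99%-identity / 90%-dominance rules
assume: a hierarchy of families, genera and species; low intra-species
divergence (default 0.2% substitutions per site, so conspecific records
cluster together at 99% identity); higher inter-species divergence
(default 5% from the genus ancestor, so species separate); still higher
inter-genus divergence (default 12% from the family ancestor).  On top
of the clean hierarchy it can plant two kinds of real-world mess:

* mislabeled records — the emitted taxonomy assigns a wrong species
  while the ground-truth map retains reality;
* flagged headers — descriptions seeded with one of the suspect
  annotation keywords (``predicted``, ``unverified``, ...).

Sequences evolve by substitutions only by default, which keeps identity
arithmetic analyzable; ``indel_rate`` adds single-base indels to
exercise the aligner.  Everything is a pure function of the config
(including its seed): same config, same fixture, byte for byte.
Naming is systematic and collision-free (``Fam03``, ``Gen03_02``,
``Sp03_02_01``, accession ``Sp03_02_01_r04``) so logs are human-diffable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from refclust.formats_io import Lineage, SequenceRecord, TaxonomyMap
from refclust.sequence_filters import DEFAULT_KEYWORDS

__all__ = ["FixtureConfig", "Fixture", "generate_taxonomy", "generate_sequences"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Fixed synthetic higher taxonomy shared by every generated lineage.
_PHYLUM, _CLASS, _ORDER = "Synthophyta", "Synthopsida", "Synthales"


@dataclass(frozen=True)
class FixtureConfig:
    """Shape, divergence and perturbation settings for one fixture."""

    n_families: int = 5
    genera_per_family: int = 4
    species_per_genus: int = 3
    seqs_per_species: int = 6
    seq_length: int = 300
    intra_species_divergence: float = 0.002
    inter_species_divergence: float = 0.05
    inter_genus_divergence: float = 0.12
    mislabel_rate: float = 0.0
    keyword_rate: float = 0.0
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_families", "genera_per_family", "species_per_genus", "seqs_per_species"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if not (
            self.intra_species_divergence
            < self.inter_species_divergence
            < self.inter_genus_divergence
        ):
            raise ValueError("divergences must be ordered intra_species < inter_species < inter_genus")
        for name in ("mislabel_rate", "keyword_rate", "indel_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def n_species(self) -> int:
        return self.n_families * self.genera_per_family * self.species_per_genus

    @property
    def n_records(self) -> int:
        return self.n_species * self.seqs_per_species


@dataclass(frozen=True)
class Fixture:
    """A generated dataset plus its ground truth."""

    records: tuple[SequenceRecord, ...]
    taxonomy: TaxonomyMap  # as emitted (contains the planted mislabels)
    truth: TaxonomyMap  # reality (what each record actually is)
    mislabeled: frozenset[str]  # accessions whose emitted label is wrong
    keyword_flagged: frozenset[str]  # accessions with a suspect header word


def _species_names(config: FixtureConfig) -> Iterator[tuple[str, str, str]]:
    for f in range(1, config.n_families + 1):
        family = f"Fam{f:02d}"
        for g in range(1, config.genera_per_family + 1):
            genus = f"Gen{f:02d}_{g:02d}"
            for s in range(1, config.species_per_genus + 1):
                yield family, genus, f"Sp{f:02d}_{g:02d}_{s:02d}"


def generate_taxonomy(config: FixtureConfig) -> tuple[dict[str, Lineage], list[str]]:
    """Systematic species lineages: ``species name -> six-rank Lineage``.

    Deterministic for a given config; the species list preserves
    generation order (families, then genera, then species).
    """
    lineages: dict[str, Lineage] = {}
    species_list: list[str] = []
    for family, genus, species in _species_names(config):
        lineages[species] = Lineage((_PHYLUM, _CLASS, _ORDER, family, genus, species))
        species_list.append(species)
    return lineages, species_list


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each site with probability `rate` to a different base."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < rate)
    if hit.size:
        # shift by 1-3 positions in base order: always a different base
        idx = np.searchsorted(_BASES, out[hit])
        out[hit] = _BASES[(idx + rng.integers(1, 4, hit.size)) % 4]
    return out


def _indel(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Apply single-base insertions/deletions at the given per-site rate."""
    if rate == 0.0:
        return seq
    keep = rng.random(seq.size) >= rate / 2.0  # deletions
    seq = seq[keep]
    ins_mask = rng.random(seq.size) < rate / 2.0
    if not ins_mask.any():
        return seq
    pieces: list[np.ndarray] = []
    last = 0
    for pos in np.flatnonzero(ins_mask):
        pieces.append(seq[last : pos + 1])
        pieces.append(_BASES[rng.integers(0, 4, 1)])
        last = pos + 1
    pieces.append(seq[last:])
    return np.concatenate(pieces)


def generate_sequences(config: FixtureConfig) -> Fixture:
    """Generate records plus emitted and ground-truth taxonomy maps.

    One random ancestor per family; genus ancestors mutated from it at
    the inter-genus rate; per-species consensus mutated from the genus
    ancestor at the inter-species rate; each record mutated from its
    species consensus at the intra-species rate.  Mislabeled records get
    a different species' lineage in the emitted taxonomy only; keyword
    records get one of the suspect words injected into the description.
    """
    rng = np.random.default_rng(config.seed)
    lineages, species_list = generate_taxonomy(config)

    records: list[SequenceRecord] = []
    emitted = TaxonomyMap()
    truth = TaxonomyMap()
    mislabeled: set[str] = set()
    keyword_flagged: set[str] = set()

    for f in range(config.n_families):
        family_anc = rng.choice(_BASES, size=config.seq_length)
        for g in range(config.genera_per_family):
            genus_anc = _mutate(rng, family_anc, config.inter_genus_divergence)
            for s in range(config.species_per_genus):
                species = species_list[
                    (f * config.genera_per_family + g) * config.species_per_genus + s
                ]
                consensus = _mutate(rng, genus_anc, config.inter_species_divergence)
                for r in range(1, config.seqs_per_species + 1):
                    seq = _mutate(rng, consensus, config.intra_species_divergence)
                    seq = _indel(rng, seq, config.indel_rate)
                    accession = f"{species}_r{r:02d}"
                    description = f"{species} internal transcribed spacer, partial sequence"
                    if rng.random() < config.keyword_rate:
                        word = DEFAULT_KEYWORDS[rng.integers(0, len(DEFAULT_KEYWORDS))]
                        description = f"{word.upper()}: {description}"
                        keyword_flagged.add(accession)
                    label = species
                    if rng.random() < config.mislabel_rate and config.n_species > 1:
                        others = [sp for sp in species_list if sp != species]
                        label = others[rng.integers(0, len(others))]
                        mislabeled.add(accession)
                    records.append(
                        SequenceRecord(accession, description, seq.tobytes().decode("ascii"))
                    )
                    emitted[accession] = lineages[label]
                    truth[accession] = lineages[species]

    return Fixture(
        records=tuple(records),
        taxonomy=emitted,
        truth=truth,
        mislabeled=frozenset(mislabeled),
        keyword_flagged=frozenset(keyword_flagged),
    )
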