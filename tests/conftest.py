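import pytest

from refclust.formats_io import Cluster, Lineage, SequenceRecord, TaxonomyMap


def lineage(family="Betulaceae", genus="Corylus", species="Corylus avellana",
            phylum="Streptophyta", cls="Magnoliopsida", order="Fagales"):
    return Lineage((phylum, cls, order, family, genus, species))


def make_cluster(members, cluster_id=0, representative=None):
    return Cluster(
        cluster_id=cluster_id,
        representative=representative or members[0],
        members=tuple(members),
    )


def species_cluster(n_major, n_minor, major="Quercus robur", minor="Quercus petraea",
                    minor_genus=None, minor_family=None, cluster_id=0):
    """Cluster of n_major members of one species + n_minor of another.

    The minority species defaults to a congener; pass minor_genus /
    minor_family to push the disagreement to coarser ranks.
    """
    taxmap = TaxonomyMap()
    members = []
    for i in range(n_major):
        acc = f"MAJ{i:03d}"
        members.append(acc)
        taxmap[acc] = lineage(family="Fagaceae", genus="Quercus", species=major)
    for i in range(n_minor):
        acc = f"MIN{i:03d}"
        members.append(acc)
        taxmap[acc] = lineage(
            family=minor_family or "Fagaceae",
            genus=minor_genus or "Quercus",
            species=minor,
        )
    return make_cluster(members, cluster_id=cluster_id), taxmap


@pytest.fixture
def records_abc():
    return [
        SequenceRecord("A1", "Corylus avellana internal transcribed spacer", "ACGT" * 50),
        SequenceRecord("B1", "Betula pendula ITS region", "AGGT" * 50),
        SequenceRecord("C1", "", "ACGTAC"),
    ]
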