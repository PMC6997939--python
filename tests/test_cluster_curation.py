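"""Taxonomy-aware cluster evaluation: dominance rule, escalation, NA discipline."""

import pytest

from refclust.cluster_curation import (
    DISCARDED,
    CurationConfig,
    build_output_taxonomy,
    evaluate_cluster,
    run_curation,
    select_representative,
    tally_composition,
)
from refclust.formats_io import NA, MissingTaxonomyError, SequenceRecord, TaxonomyMap

from conftest import lineage, make_cluster, species_cluster


class TestTallyComposition:
    def test_uniform_cluster(self):
        cluster, taxmap = species_cluster(10, 0)
        counts, n_inf, n_na = tally_composition(cluster, taxmap, "species")
        assert counts == {"Quercus robur": 10} and (n_inf, n_na) == (10, 0)

    def test_na_members_excluded_from_both_sides(self):
        cluster, taxmap = species_cluster(9, 1)
        taxmap["MIN000"] = taxmap["MIN000"].replace(species=NA)
        counts, n_inf, n_na = tally_composition(cluster, taxmap, "species")
        assert counts == {"Quercus robur": 9} and (n_inf, n_na) == (9, 1)

    def test_three_way_split(self):
        cluster = make_cluster(["X", "Y", "Z"])
        taxmap = TaxonomyMap(
            {a: lineage(species=f"Sp {a}") for a in "XYZ"}
        )
        counts, n_inf, n_na = tally_composition(cluster, taxmap, "species")
        assert set(counts.values()) == {1} and n_inf == 3

    def test_missing_taxonomy_is_loud(self):
        cluster = make_cluster(["X", "Y"])
        with pytest.raises(MissingTaxonomyError, match="Y"):
            tally_composition(cluster, TaxonomyMap({"X": lineage()}), "species")


class TestEvaluateCluster:
    def test_pure_cluster_resolves_at_species(self):
        cluster, taxmap = species_cluster(10, 0)
        d = evaluate_cluster(cluster, taxmap)
        assert d.resolved_rank == "species" and d.dominant_taxon == "Quercus robur"
        assert d.flags == frozenset()

    def test_nine_plus_one_escalates_to_genus(self):
        # 9/10 == 0.9 is NOT more than 90%: the species check fails,
        # the genus tally is 10/10 and resolves
        cluster, taxmap = species_cluster(9, 1)
        d = evaluate_cluster(cluster, taxmap)
        assert d.resolved_rank == "genus" and d.dominant_taxon == "Quercus"
        assert "multi_species" in d.flags

    def test_nineteen_plus_two_resolves_at_species(self):
        cluster, taxmap = species_cluster(19, 2)
        d = evaluate_cluster(cluster, taxmap)
        assert d.resolved_rank == "species" and d.dominant_taxon == "Quercus robur"
        assert "multi_species" in d.flags and "gt2_species" not in d.flags

    def test_three_families_discarded(self):
        cluster = make_cluster(["X", "Y", "Z"])
        taxmap = TaxonomyMap(
            {
                "X": lineage(family="Fagaceae", genus="Quercus", species="Q. robur"),
                "Y": lineage(family="Betulaceae", genus="Betula", species="B. pendula"),
                "Z": lineage(family="Salicaceae", genus="Salix", species="S. alba"),
            }
        )
        d = evaluate_cluster(cluster, taxmap)
        assert d.resolved_rank == DISCARDED
        assert d.dominant_taxon is None and d.representative is None
        assert "gt2_species" in d.flags

    def test_all_na_rank_escalates(self):
        cluster, taxmap = species_cluster(3, 0)
        for acc in cluster.members:
            taxmap[acc] = taxmap[acc].replace(species=NA)
        d = evaluate_cluster(cluster, taxmap)
        assert d.resolved_rank == "genus"

    def test_minority_representative_flagged_replaced(self):
        cluster, taxmap = species_cluster(1, 10, minor_genus="Betula", minor_family="Betulaceae")
        cluster = make_cluster(list(cluster.members), representative="MAJ000")
        d = evaluate_cluster(cluster, taxmap)
        assert d.resolved_rank == "species" and d.dominant_taxon == "Quercus petraea"
        assert "rep_replaced" in d.flags and d.representative.startswith("MIN")

    def test_dominant_tie_broken_by_name(self):
        cluster, taxmap = species_cluster(5, 5)
        d = evaluate_cluster(cluster, taxmap)
        # 5/10 fails species; genus is uniform so it resolves there
        assert d.resolved_rank == "genus"
        # force a genuine tie at the evaluated rank: 1-vs-1 species
        cluster2, taxmap2 = species_cluster(1, 1)
        d2 = evaluate_cluster(cluster2, taxmap2, CurationConfig(dominance_threshold=0.4))
        assert d2.resolved_rank == "species"
        assert d2.dominant_taxon == "Quercus petraea"  # alphabetical among equal counts


class TestSelectRepresentative:
    def test_conforming_representative_kept(self):
        cluster, taxmap = species_cluster(10, 1)
        d = evaluate_cluster(cluster, taxmap)
        assert d.resolved_rank == "species"
        assert select_representative(cluster, taxmap, d) == cluster.representative
        assert "rep_replaced" not in d.flags

    def test_replacement_picks_longest_dominant_member(self):
        cluster, taxmap = species_cluster(1, 10, minor_genus="Betula", minor_family="Betulaceae")
        cluster = make_cluster(list(cluster.members), representative="MAJ000")
        records = {
            acc: SequenceRecord(acc, "", "A" * (200 + i))
            for i, acc in enumerate(cluster.members)
        }
        d = evaluate_cluster(cluster, taxmap, records=records)
        longest_min = max(
            (a for a in cluster.members if a.startswith("MIN")), key=lambda a: records[a].length
        )
        assert d.representative == longest_min and "rep_replaced" in d.flags

    def test_equal_lengths_tie_on_accession(self):
        cluster, taxmap = species_cluster(1, 10, minor_genus="Betula", minor_family="Betulaceae")
        cluster = make_cluster(list(cluster.members), representative="MAJ000")
        records = {acc: SequenceRecord(acc, "", "A" * 200) for acc in cluster.members}
        d = evaluate_cluster(cluster, taxmap, records=records)
        assert d.representative == "MIN000"


class TestBuildOutputTaxonomy:
    def test_species_resolution_keeps_lineage(self):
        cluster, taxmap = species_cluster(10, 0)
        d = evaluate_cluster(cluster, taxmap)
        lin, flags = build_output_taxonomy(cluster, d, taxmap)
        assert lin == taxmap[d.representative] and flags == frozenset()

    def test_genus_resolution_blanks_species(self):
        cluster, taxmap = species_cluster(9, 1)
        d = evaluate_cluster(cluster, taxmap)
        lin, _ = build_output_taxonomy(cluster, d, taxmap)
        assert lin.at("species") == NA and lin.at("genus") == "Quercus"
        assert lin.at("family") == "Fagaceae"

    def test_family_resolution_blanks_genus_and_species(self):
        cluster, taxmap = species_cluster(9, 1, minor_genus="Fagus")
        d = evaluate_cluster(cluster, taxmap)
        assert d.resolved_rank == "family"
        lin, _ = build_output_taxonomy(cluster, d, taxmap)
        assert lin.at("species") == NA and lin.at("genus") == NA
        assert lin.at("family") == "Fagaceae"

    def test_higher_rank_conflict_flagged_not_resolved(self):
        cluster, taxmap = species_cluster(19, 2)
        taxmap["MIN000"] = taxmap["MIN000"].replace(phylum="Chlorophyta")
        d = evaluate_cluster(cluster, taxmap)
        lin, flags = build_output_taxonomy(cluster, d, taxmap)
        assert "higher_rank_conflict" in flags
        assert lin.at("phylum") == "Streptophyta"  # representative's, not a vote


class TestRunCuration:
    def _records(self, cluster):
        return [SequenceRecord(a, "", "ACGT" * 50) for a in cluster.members]

    def test_clean_clusters_pass_through(self):
        clusters, taxmaps, records = [], TaxonomyMap(), []
        for i in range(5):
            c, t = species_cluster(4, 0, major=f"Quercus sp{i}", cluster_id=i)
            c = make_cluster([f"C{i}_{m}" for m in c.members], cluster_id=i)
            for m, old in zip(c.members, t.entries.values()):
                taxmaps[m] = old
            clusters.append(c)
            records += self._records(c)
        out_records, out_tax, report = run_curation(clusters, taxmaps, records)
        assert len(out_records) == 5 and report.discarded_count == 0
        assert report.resolved_counts == {"species": 5}
        assert report.flag_counts == {}

    def test_discarded_cluster_only_in_report(self):
        good, taxmap = species_cluster(5, 0, cluster_id=0)
        bad = make_cluster(["X", "Y", "Z"], cluster_id=1)
        taxmap["X"] = lineage(family="Fagaceae", genus="Quercus", species="Quercus robur")
        taxmap["Y"] = lineage(family="Betulaceae", genus="Betula", species="Betula pendula")
        taxmap["Z"] = lineage(family="Salicaceae", genus="Salix", species="Salix alba")
        records = self._records(good) + self._records(bad)
        out_records, out_tax, report = run_curation([good, bad], taxmap, records)
        assert len(out_records) == 1
        assert report.discarded_count == 1
        assert report.discarded_detail[0][0] == 1
        assert {acc for acc, _ in report.discarded_detail[0][1]} == {"X", "Y", "Z"}

    def test_mixed_fixture_counts(self):
        clusters, taxmap, records = [], TaxonomyMap(), []
        for i in range(9):
            c, t = species_cluster(4, 0, major=f"Quercus sp{i}", cluster_id=i)
            c = make_cluster([f"C{i}_{m}" for m in c.members], cluster_id=i)
            for m, old in zip(c.members, t.entries.values()):
                taxmap[m] = old
            clusters.append(c)
            records += self._records(c)
        mixed, t = species_cluster(9, 1, cluster_id=9)
        for m in mixed.members:
            taxmap[m] = t[m]
        clusters.append(mixed)
        records += self._records(mixed)
        _, out_tax, report = run_curation(clusters, taxmap, records)
        assert report.resolved_counts == {"species": 9, "genus": 1}
        assert report.flag_counts.get("multi_species") == 1
        # the genus-resolved entry carries species=NA in the output taxonomy
        genus_decision = next(d for d in report.decisions if d.resolved_rank == "genus")
        assert out_tax[genus_decision.representative].at("species") == NA

    def test_determinism(self):
        cluster, taxmap = species_cluster(9, 1)
        records = self._records(cluster)
        a = run_curation([cluster], taxmap, records)
        b = run_curation([cluster], taxmap, records)
        assert a[0] == b[0] and a[1] == b[1] and a[2].decisions == b[2].decisions


class TestConfigValidation:
    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            CurationConfig(dominance_threshold=1.0)

    def test_ladder_must_be_contiguous_fine_to_coarse(self):
        with pytest.raises(ValueError):
            CurationConfig(rank_ladder=("species", "family"))
        CurationConfig(rank_ladder=("species", "genus", "family", "order"))

    def test_custom_ladder_stops_early(self):
        cluster, taxmap = species_cluster(9, 1, minor_genus="Fagus")
        d = evaluate_cluster(cluster, taxmap, CurationConfig(rank_ladder=("species", "genus")))
        assert d.resolved_rank == DISCARDED
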