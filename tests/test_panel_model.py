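import copy
import random

import pytest
from hypothesis import given, settings, strategies as st

from panelscreen import (
    DiseaseTerm, DuplicateError, GenomicRegion, LookupFailure, PanelCollection,
    RegionOrigin, SchemaError, Source, ValidationError, add_custom_mutation,
    add_disease, add_genes, add_regions_bed, export_panel, export_regions_bed,
    import_panel, merged_regions, new_panel, remove_disease, remove_gene,
)
from panelscreen.errors import ParseError

from conftest import DEMO, OTHER, random_panel


class TestNewPanel:
    def test_empty_construction(self):
        panel = new_panel("BRCA-test")
        assert (len(panel.diseases), len(panel.regions), len(panel.mutations)) == (0, 0, 0)
        assert panel.thresholds.sift_max is None
        assert panel.thresholds.polyphen_min is None
        assert panel.created  # today's date

    def test_empty_name_rejected(self):
        with pytest.raises(ValidationError):
            new_panel("")

    def test_duplicate_name_rejected_in_collection(self):
        coll = PanelCollection()
        coll.add(new_panel("X"))
        with pytest.raises(DuplicateError):
            coll.add(new_panel("X"))


class TestAddRemoveDisease:
    def test_counts_propagate(self, catalogue):
        panel = add_disease(new_panel("p"), DEMO, catalogue)
        assert len(panel.diseases) == 1
        assert len(panel.regions) == 2      # GA, GB
        assert len(panel.mutations) == 3

    def test_idempotent(self, catalogue):
        panel = add_disease(new_panel("p"), DEMO, catalogue)
        snapshot = copy.deepcopy(panel)
        add_disease(panel, DEMO, catalogue)
        assert panel == snapshot

    def test_shared_gene_deduplicated(self, catalogue, demo_panel):
        # GB belongs to both disease terms: present once, and equal to the
        # brute-force union of the catalogue gene sets
        labels = [r.label for r in demo_panel.regions]
        assert labels.count("GB") == 1
        union = {
            g.label
            for term in (DEMO, OTHER)
            for g in catalogue[term].genes
        }
        assert set(labels) == union

    def test_remove_sole_term_restores_prior_state(self, catalogue):
        panel = new_panel("p")
        add_custom_mutation(panel, "9", 42, "A", "C", "My disease")
        before = copy.deepcopy(panel)
        add_disease(panel, DEMO, catalogue)
        remove_disease(panel, DEMO)
        assert panel.diseases == before.diseases + []  # custom term kept
        assert panel.regions == before.regions
        assert panel.mutations == before.mutations

    def test_remove_keeps_shared_gene(self, catalogue, demo_panel):
        remove_disease(demo_panel, DEMO)
        # recompute expectation from scratch for the remaining term
        expected = {g.label for g in catalogue[OTHER].genes}
        assert {r.label for r in demo_panel.regions} == expected
        assert "GB" in expected
        expected_keys = {m.key for m in catalogue[OTHER].mutations}
        assert {m.key for m in demo_panel.mutations} == expected_keys

    def test_remove_absent_term_errors(self, catalogue):
        with pytest.raises(LookupFailure):
            remove_disease(new_panel("p"), DEMO)

    def test_unknown_term_errors(self, catalogue):
        with pytest.raises(LookupFailure):
            add_disease(new_panel("p"), DiseaseTerm("Nope", Source.CLINVAR), catalogue)


class TestGenes:
    INDEX = {
        "TP53": GenomicRegion("17", 7_571_000, 7_591_000, "TP53"),
        "GA": GenomicRegion("1", 100, 1000, "GA"),
    }

    def test_add_resolvable(self):
        panel = add_genes(new_panel("p"), ["TP53"], self.INDEX)
        assert len(panel.regions) == 1
        assert panel.regions[0].origin is RegionOrigin.USER_GENE

    def test_atomic_on_unknown_names(self):
        panel = new_panel("p")
        with pytest.raises(LookupFailure, match="NOSUCH"):
            add_genes(panel, ["TP53", "NOSUCH"], self.INDEX)
        assert panel.regions == []

    def test_no_duplicate_by_label(self, catalogue, demo_panel):
        n = len(demo_panel.regions)
        add_genes(demo_panel, ["GA"], self.INDEX)
        assert len(demo_panel.regions) == n

    def test_remove_gene_flags_uncovered_mutation(self, catalogue):
        panel = add_disease(new_panel("p"), DEMO, catalogue)
        remove_gene(panel, "GA")
        flagged = {m.key for m in panel.out_of_region_mutations}
        assert {str(k) for k in flagged} == {"1:200:A>T", "1:300:C>G"}
        # mutations retained, not deleted
        assert len(panel.mutations) == 3

    def test_remove_one_of_two_covering_regions_keeps_coverage(self, catalogue):
        panel = add_disease(new_panel("p"), DEMO, catalogue)
        add_regions_bed(panel, "1\t99\t1000\tGA2\n")  # duplicate cover of GA span
        remove_gene(panel, "GA")
        assert panel.out_of_region_mutations == []

    def test_remove_unknown_label_errors(self):
        with pytest.raises(LookupFailure):
            remove_gene(new_panel("p"), "GX")


class TestBed:
    def test_coordinate_conversion(self):
        panel = add_regions_bed(new_panel("p"), "1\t99\t101\tGX\n")
        region = panel.regions[0]
        assert (region.chrom, region.start, region.end, region.label) == ("1", 100, 101, "GX")
        assert region.origin is RegionOrigin.USER_BED

    def test_chr_prefix_stripped_and_default_label(self):
        panel = add_regions_bed(new_panel("p"), "chr2\t0\t10\n")
        region = panel.regions[0]
        assert (region.chrom, region.start, region.end) == ("2", 1, 10)
        assert region.label == "2:1-10"

    def test_empty_interval_rejected(self):
        with pytest.raises(ParseError) as exc:
            add_regions_bed(new_panel("p"), "1\t5\t5\n")
        assert exc.value.line == 1

    def test_non_integer_coords_rejected_with_line(self):
        with pytest.raises(ParseError) as exc:
            add_regions_bed(new_panel("p"), "1\t10\t20\tA\n1\tx\t30\n")
        assert exc.value.line == 2

    def test_export_inverse_of_import_example(self):
        panel = new_panel("p")
        panel.regions.append(GenomicRegion("1", 100, 101, "GX"))
        assert export_regions_bed(panel) == "1\t99\t101\tGX\n"
        assert export_regions_bed(new_panel("q")) == ""

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.data())
    def test_bed_round_trip_random_regions(self, data):
        n = data.draw(st.integers(0, 30))
        regions = []
        for k in range(n):
            start = data.draw(st.integers(1, 10_000))
            regions.append(GenomicRegion(
                chrom=data.draw(st.sampled_from(["1", "2", "X", "MT"])),
                start=start,
                end=start + data.draw(st.integers(0, 5_000)),
                label=f"R{k}",
            ))
        source = new_panel("src")
        source.regions = regions
        reimported = add_regions_bed(new_panel("dst"), export_regions_bed(source))
        assert (
            {(r.chrom, r.start, r.end, r.label) for r in reimported.regions}
            == {(r.chrom, r.start, r.end, r.label) for r in regions}
        )


class TestCustomMutations:
    def test_attach_to_existing_term_case_insensitive(self, demo_panel):
        n_dis, n_mut = len(demo_panel.diseases), len(demo_panel.mutations)
        add_custom_mutation(demo_panel, "1", 150, "A", "T", "demo SYNDROME")
        assert len(demo_panel.diseases) == n_dis
        assert len(demo_panel.mutations) == n_mut + 1
        added = demo_panel.mutations[-1]
        assert added.source is Source.CUSTOM
        assert added.phenotype == "Demo syndrome"
        assert added.gene == "GA"  # enclosing region label

    def test_unseen_name_creates_custom_term(self, demo_panel):
        n_dis = len(demo_panel.diseases)
        add_custom_mutation(demo_panel, "1", 150, "A", "T", "New disease")
        assert len(demo_panel.diseases) == n_dis + 1
        assert demo_panel.diseases[-1].source is Source.CUSTOM

    def test_duplicate_key_rejected_even_respelled(self, demo_panel):
        add_custom_mutation(demo_panel, "1", 150, "A", "T", "D")
        with pytest.raises(DuplicateError):
            add_custom_mutation(demo_panel, "1", 149, "GA", "GT", "D")

    @pytest.mark.parametrize("ref, alt", [("A", "A"), ("AN", "AT"), ("", "A")])
    def test_invalid_alleles_rejected(self, demo_panel, ref, alt):
        with pytest.raises(ValidationError):
            add_custom_mutation(demo_panel, "1", 150, ref, alt, "D")

    def test_custom_survives_disease_removal(self, catalogue):
        panel = add_disease(new_panel("p"), DEMO, catalogue)
        add_custom_mutation(panel, "1", 150, "A", "T", "Demo syndrome")
        remove_disease(panel, DEMO)
        assert [str(m.key) for m in panel.mutations] == ["1:150:A>T"]


class TestPanelJson:
    def test_round_trip_two_disease_panel(self, demo_panel):
        assert import_panel(export_panel(demo_panel)) == demo_panel

    def test_missing_regions_is_schema_error_with_path(self, demo_panel):
        import json
        doc = json.loads(export_panel(demo_panel))
        del doc["regions"]
        with pytest.raises(SchemaError, match=r"\$\.regions"):
            import_panel(json.dumps(doc))

    def test_reordered_mutations_compare_equal(self, demo_panel):
        import json
        doc = json.loads(export_panel(demo_panel))
        doc["mutations"] = list(reversed(doc["mutations"]))
        doc["regions"] = list(reversed(doc["regions"]))
        assert import_panel(json.dumps(doc)) == demo_panel

    def test_random_panels_round_trip(self):
        rng = random.Random(2024)
        for _ in range(100):
            panel = random_panel(rng)
            assert import_panel(export_panel(panel)) == panel


class TestMergedRegions:
    def test_overlap_merged(self):
        merged = merged_regions([
            GenomicRegion("1", 100, 200, "a"), GenomicRegion("1", 150, 300, "b"),
        ])
        assert [(r.chrom, r.start, r.end) for r in merged] == [("1", 100, 300)]

    def test_adjacent_merged_distinct_chroms_kept(self):
        merged = merged_regions([
            GenomicRegion("2", 100, 200, "c"),
            GenomicRegion("1", 100, 200, "a"),
            GenomicRegion("1", 201, 250, "b"),
        ])
        assert [(r.chrom, r.start, r.end) for r in merged] == [
            ("1", 100, 250), ("2", 100, 200),
        ]

    def test_covered_bases_equal_brute_force_union(self):
        rng = random.Random(11)
        for _ in range(20):
            regions = []
            for _ in range(rng.randint(1, 500)):
                start = rng.randint(1, 9_000)
                regions.append(GenomicRegion(
                    rng.choice(["1", "2"]), start,
                    min(start + rng.randint(0, 400), 10_000), "r",
                ))
            merged = merged_regions(regions)
            brute = {
                (r.chrom, p) for r in regions for p in range(r.start, r.end + 1)
            }
            assert sum(r.length for r in merged) == len(brute)
            # merged set is disjoint and sorted per chromosome
            for a, b in zip(merged, merged[1:]):
                if a.chrom == b.chrom:
                    assert b.start > a.end + 1
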