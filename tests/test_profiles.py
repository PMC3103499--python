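import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crmkit.profiles import (
    BindingSite,
    GeneProfile,
    MalformedRecordError,
    battery_presence_vector,
    build_promoter_profile,
    find_min_instance,
    gene_min_instance,
    genes_from_sites,
    gff_to_tss_relative,
    has_oriented_site,
    oriented_key,
    read_site_table,
    split_oriented_key,
    write_site_table,
)

from conftest import (
    brute_gene_min_span,
    brute_min_span,
    make_gene,
    make_profile,
    random_gene,
    random_profile,
    site,
)


class TestBindingSite:
    def test_validation(self):
        with pytest.raises(MalformedRecordError):
            BindingSite(start=5, end=1, factor_id="A", orientation="+")
        with pytest.raises(MalformedRecordError):
            BindingSite(start=0, end=5, factor_id="", orientation="+")
        with pytest.raises(MalformedRecordError):
            BindingSite(start=0, end=5, factor_id="A", orientation="*")

    def test_key_and_width(self):
        s = site("ETSF", -386, -374)
        assert s.key == "+ETSF"
        assert s.width == 13

    def test_oriented_key_roundtrip(self):
        assert oriented_key("ETSF", "+") == "+ETSF"
        assert split_oriented_key("-PAX6") == ("PAX6", "-")
        with pytest.raises(ValueError):
            split_oriented_key("ETSF")
        with pytest.raises(ValueError):
            split_oriented_key("+")


class TestBuildPromoterProfile:
    def test_empty(self):
        profile = build_promoter_profile("G1", "G1.P1", [])
        assert profile.sites == ()
        assert profile.index == {}

    def test_worked_example_two_forward_sites(self):
        # two forward ETSF sites upstream index under one oriented key
        profile = build_promoter_profile("G1", "G1.P1", [
            site("ETSF", -386, -374), site("ETSF", -373, -361),
        ])
        assert profile.index == {"+ETSF": [-386, -373]}

    def test_order_invariance_and_dedup(self, rng):
        sites = [
            site(str(rng.choice(["A", "B"])), int(rng.integers(-500, 80)))
            for _ in range(20)
        ]
        a = build_promoter_profile("G1", "P1", sites)
        shuffled = list(sites)
        rng.shuffle(shuffled)
        b = build_promoter_profile("G1", "P1", shuffled + sites[:3])  # extra dups
        assert a.sites == b.sites
        assert a.index == b.index

    def test_index_rebuild_identity(self, rng):
        profile = random_profile(rng, n_sites=15)
        assert profile.index == profile.rebuild_index()
        starts = [s.start for s in profile.sites]
        assert starts == sorted(starts)


class TestHasOrientedSite:
    @pytest.fixture
    def profile(self):
        return make_profile("G1", "P1", [site("ETSF", -386, -374)])

    def test_present(self, profile):
        assert has_oriented_site(profile, "+ETSF")

    def test_orientation_mismatch(self, profile):
        assert not has_oriented_site(profile, "-ETSF")

    def test_empty_profile(self):
        empty = make_profile("G1", "P1", [])
        assert not has_oriented_site(empty, "+ETSF")

    def test_malformed_key(self, profile):
        with pytest.raises(ValueError):
            has_oriented_site(profile, "ETSF")


class TestFindMinInstance:
    def test_singleton_tie_breaks_upstream(self):
        profile = make_profile("G1", "P1", [site("A", -400), site("A", -50)])
        inst = find_min_instance(profile, [("A", "+")])
        assert inst.span == 12
        assert profile.sites[inst.site_refs[0]].start == -400

    def test_two_element_span(self):
        profile = make_profile("G1", "P1", [
            site("A", -300, -290), site("B", -200, -190, "-"),
        ])
        inst = find_min_instance(profile, [("A", "+"), ("B", "-")])
        assert inst.span == 111
        assert inst.span == brute_min_span(profile, [("A", "+"), ("B", "-")])

    def test_order_violation_absent(self):
        profile = make_profile("G1", "P1", [
            site("A", -300, -290), site("B", -200, -190, "-"),
        ])
        assert find_min_instance(profile, [("B", "-"), ("A", "+")]) is None
        assert brute_min_span(profile, [("B", "-"), ("A", "+")]) is None

    def test_overlap_excluded(self):
        profile = make_profile("G1", "P1", [
            site("A", -100, -90), site("B", -95, -85),
        ])
        assert find_min_instance(profile, [("A", "+"), ("B", "+")]) is None

    def test_adjacent_sites_strictly_nonoverlapping(self):
        # next.start must exceed prev.end: touching coordinates are overlap
        profile = make_profile("G1", "P1", [
            site("A", -100, -90), site("B", -90, -80), site("B", -89, -79),
        ])
        inst = find_min_instance(profile, [("A", "+"), ("B", "+")])
        assert profile.sites[inst.site_refs[1]].start == -89

    def test_repeated_factor_uses_distinct_sites(self):
        profile = make_profile("G1", "P1", [site("A", -100, -90)])
        assert find_min_instance(profile, [("A", "+"), ("A", "+")]) is None

    def test_matches_bruteforce_on_random_profiles(self, rng):
        elements_pool = [("A", "+"), ("A", "-"), ("B", "+"), ("B", "-"), ("C", "+")]
        for _ in range(150):
            profile = random_profile(rng, n_sites=int(rng.integers(0, 26)))
            size = int(rng.integers(1, 5))
            elements = [
                elements_pool[i] for i in rng.integers(0, len(elements_pool), size)
            ]
            inst = find_min_instance(profile, elements)
            expected = brute_min_span(profile, elements)
            if expected is None:
                assert inst is None
            else:
                assert inst is not None and inst.span == expected

    def test_instance_invariants(self, rng):
        profile = random_profile(rng, n_sites=20)
        inst = find_min_instance(profile, [("A", "+"), ("B", "-")])
        if inst is not None:
            refs = inst.site_refs
            assert list(refs) == sorted(refs)
            picked = [profile.sites[i] for i in refs]
            assert all(b.start > a.end for a, b in zip(picked, picked[1:]))
            assert [s.key for s in picked] == ["+A", "-B"]
            assert inst.span == picked[-1].end - picked[0].start + 1

    def test_empty_elements_rejected(self):
        profile = make_profile("G1", "P1", [site("A", -100)])
        with pytest.raises(ValueError):
            find_min_instance(profile, [])


class TestGeneMinInstance:
    def test_any_promoter_presence(self):
        gene = make_gene(
            "G1",
            [site("X", -100)],
            [site("A", -300, -290), site("B", -200, -190, "-")],
            [],
        )
        present, span = gene_min_instance(gene, [("A", "+"), ("B", "-")])
        assert present and span == 111

    def test_absent_everywhere(self):
        gene = make_gene("G1", [site("X", -100)], [])
        assert gene_min_instance(gene, [("A", "+")]) == (False, None)

    def test_minimum_across_promoters(self):
        gene = make_gene(
            "G1",
            [site("A", -300, -290), site("B", -172, -161, "-")],  # span 140
            [site("A", -200, -190), site("B", -117, -106, "-")],  # span 95
        )
        present, span = gene_min_instance(gene, [("A", "+"), ("B", "-")])
        assert (present, span) == (True, 95)
        assert span == brute_gene_min_span(gene, [("A", "+"), ("B", "-")])

    def test_matches_bruteforce_on_random_genes(self, rng):
        for i in range(60):
            gene = random_gene(rng, f"G{i}")
            elements = [("A", "+"), ("B", "-")][: int(rng.integers(1, 3))]
            present, span = gene_min_instance(gene, elements)
            expected = brute_gene_min_span(gene, elements)
            assert span == expected
            assert present == (expected is not None)

    def test_prefix_suffix_monotonicity(self, rng):
        # if a module is present, every contiguous sub-module is present
        for i in range(40):
            gene = random_gene(rng, f"G{i}", n_sites=8)
            elements = [("A", "+"), ("B", "-"), ("C", "+")]
            if gene_min_instance(gene, elements)[0]:
                for lo in range(3):
                    for hi in range(lo + 1, 4):
                        assert gene_min_instance(gene, elements[lo:hi])[0]


class TestBatteryPresenceVector:
    def test_matches_per_gene_calls(self, rng):
        genes = [random_gene(rng, f"G{i}") for i in range(8)]
        elements = [("A", "+"), ("B", "-")]
        table = battery_presence_vector(genes, elements)
        assert [row[0] for row in table] == [g.gene_id for g in genes]
        for g, row in zip(genes, table):
            assert row[1:] == gene_min_instance(g, elements)

    def test_empty(self):
        assert battery_presence_vector([], [("A", "+")]) == []

    def test_duplicate_gene_ids_rejected(self):
        g = make_gene("G1", [site("A", -100)])
        with pytest.raises(ValueError):
            battery_presence_vector([g, g], [("A", "+")])


class TestSiteTableIO:
    def test_roundtrip(self, rng, tmp_path):
        genes = [random_gene(rng, f"G{i}", n_sites=5) for i in range(4)]
        rows = [
            (g.gene_id, p.promoter_id, s)
            for g in genes for p in g.promoters for s in p.sites
        ]
        path = tmp_path / "sites.tsv"
        write_site_table(path, rows)
        back = read_site_table(path)
        assert back == rows
        # re-grouping reproduces identical profiles (empty promoters declared)
        layout = {
            g.gene_id: [p.promoter_id for p in g.promoters] for g in genes
        }
        rebuilt = genes_from_sites(back, promoters_per_gene=layout)
        assert [g.gene_id for g in rebuilt] == sorted(g.gene_id for g in genes)
        by_id = {g.gene_id: g for g in genes}
        for g in rebuilt:
            orig = by_id[g.gene_id]
            assert [(p.promoter_id, p.sites, p.index) for p in g.promoters] == \
                   [(p.promoter_id, p.sites, p.index) for p in sorted(
                       orig.promoters, key=lambda p: p.promoter_id)]

    def test_malformed_record_names_promoter(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene_id\tpromoter_id\tfactor_id\tstart\tend\tstrand\n"
                        "G1\tG1.P7\tA\t-10\t-20\t+\n")
        with pytest.raises(MalformedRecordError, match="G1.P7"):
            read_site_table(path)


class TestGffConversion:
    def test_plus_strand(self):
        # TSS at genomic 1000, feature [995, 1005) -> -5..+4 inclusive
        assert gff_to_tss_relative(995, 1005, 1000, "+") == (-5, 4)

    def test_minus_strand_flips_axis(self):
        # upstream of a minus-strand TSS lies at larger genomic coordinates
        assert gff_to_tss_relative(1001, 1011, 1000, "-") == (-10, -1)

    def test_bad_strand(self):
        with pytest.raises(ValueError):
            gff_to_tss_relative(0, 10, 5, ".")


class TestGeneProfileValidation:
    def test_gene_id_mismatch(self):
        prom = make_profile("G2", "P1", [])
        with pytest.raises(MalformedRecordError):
            GeneProfile(gene_id="G1", promoters=(prom,))

    def test_duplicate_promoter_ids(self):
        p = make_profile("G1", "P1", [])
        with pytest.raises(MalformedRecordError):
            GeneProfile(gene_id="G1", promoters=(p, p))

    def test_no_promoters(self):
        with pytest.raises(MalformedRecordError):
            GeneProfile(gene_id="G1", promoters=())


@settings(max_examples=60, deadline=None)
@given(
    data=st.lists(
        st.tuples(
            st.sampled_from(["A", "B", "C"]),
            st.integers(-500, 80),
            st.integers(1, 20),
            st.sampled_from(["+", "-"]),
        ),
        max_size=15,
    )
)
def test_profile_roundtrip_property(data, tmp_path_factory):
    """Profile -> site table -> profile is the identity."""
    sites = [
        BindingSite(start=s, end=s + w - 1, factor_id=f, orientation=o)
        for f, s, w, o in data
    ]
    profile = build_promoter_profile("G1", "G1.P1", sites)
    path = tmp_path_factory.mktemp("rt") / "sites.tsv"
    write_site_table(path, [("G1", "G1.P1", s) for s in profile.sites])
    back = read_site_table(path)
    rebuilt = build_promoter_profile("G1", "G1.P1", [s for _, _, s in back])
    assert rebuilt.sites == profile.sites
    assert rebuilt.index == profile.index
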