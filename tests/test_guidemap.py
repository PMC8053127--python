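import numpy as np
import pytest

import ribometh as rm
from ribometh.guidemap import (
    AssignConfig,
    BoxAnnotation,
    assign_all,
    conservation_intersect,
    detect_noncanonical,
    extend_gu,
    find_boxes,
    is_wc,
    search_extra,
    search_primary,
)
from ribometh.refdata import NmSite, ReferenceRNA, SnoRNA
from ribometh.simdata import SiteSpec, revcomp


# ---------------------------------------------------------------------------
# independent brute-force oracle for the primary duplex search


def brute_force_primary(nm, target, snorna, boxes, seed_min=7, flank_window=100):
    """Exhaustive enumeration of all maximal ungapped antiparallel WC duplexes
    satisfying the D+5 rule with the 2-/3-bp substrate flank constraint.
    Returns {(substrate_interval, sno_interval, box_used, box_interval)}."""
    w_lo = max(1, nm.position - flank_window)
    w_hi = min(target.length, nm.position + flank_window)
    t, s = target.sequence, snorna.sequence
    candidates = ([("D", boxes.boxD)] if boxes.boxD else []) \
        + [("Dprime", iv) for iv in boxes.boxDprime_candidates]
    hits = set()
    for box_used, iv in candidates:
        bs = iv[0]
        for p_lo in range(w_lo, w_hi + 1):
            for p_hi in range(p_lo + seed_min - 1, w_hi + 1):
                diag = nm.position + bs - 5  # Nm paired with guide position 5
                s_hi, s_lo = diag - p_lo, diag - p_hi
                if s_lo < 1 or s_hi > bs - 1:
                    continue
                if not (p_lo <= nm.position <= p_hi):
                    continue
                if nm.position - p_lo < 2 or p_hi - nm.position < 3:
                    continue
                if not all(is_wc(t[p - 1], s[diag - p - 1])
                           for p in range(p_lo, p_hi + 1)):
                    continue
                # maximality on both ends (within window/guide bounds)
                if (p_lo - 1 >= w_lo and diag - (p_lo - 1) <= bs - 1
                        and is_wc(t[p_lo - 2], s[diag - p_lo])):
                    continue
                if (p_hi + 1 <= w_hi and diag - (p_hi + 1) >= 1
                        and is_wc(t[p_hi], s[diag - p_hi - 2])):
                    continue
                hits.add(((p_lo, p_hi), (s_lo, s_hi), box_used, iv))
    return hits


def record_keys(records):
    return {(r.substrate_interval, r.sno_interval, r.box_used, r.box_interval)
            for r in records}


# ---------------------------------------------------------------------------


class TestFindBoxes:
    def test_toy_sequence_missing_boxc(self):
        # GUGAUGGA holds only a 6/7 match to RUGAUGA: box C must be None
        seq = "GUGAUGGA" + "ACCAUGGAAUUC" * 3 + "CUGA" + "GG"
        sno = SnoRNA("toy", seq)
        ann = find_boxes(sno)
        assert ann.boxC is None
        assert ann.boxD is not None
        assert sno.sequence[ann.boxD[0] - 1:ann.boxD[1]] == "CUGA"

    def test_boxd_must_sit_near_three_prime_end(self):
        seq = "GGGGG" + "AUGAUGA" + "CUGA" + "CCCCAAAACCCCAAAACCCC"
        assert find_boxes(SnoRNA("s", seq)).boxD is None

    def test_every_internal_nnga_is_a_dprime_candidate(self):
        seq = "GGGGG" + "AUGAUGA" + "CCCCCCCC" + "AAGA" + "CCCC" + "UUGA" + "CCCC" + "CUGA" + "GGG"
        ann = find_boxes(SnoRNA("s", seq))
        motifs = {SnoRNA("s", seq).subseq(iv) for iv in ann.boxDprime_candidates}
        assert {"AAGA", "UUGA"} <= motifs
        for iv in ann.boxDprime_candidates:
            assert seq[iv[0] + 1:iv[1]] == "GA"

    def test_catalog_coordinates_override_search(self):
        seq = "GGGGG" + "AUGAUGA" + "A" * 20 + "CUGA" + "GGG"
        sno = SnoRNA("s", seq, boxC=(6, 12), boxD=(33, 36), boxDprime=(15, 18))
        ann = find_boxes(sno)
        assert ann.provenance == "catalog"
        assert ann.boxDprime_candidates == [(15, 18)]

    def test_synthetic_snorna_boxes_match_generator_truth(self, small_scene):
        for sno in small_scene.snornas[:10]:
            stripped = SnoRNA(sno.name, sno.sequence)
            ann = find_boxes(stripped)
            assert ann.boxD == sno.boxD
            assert sno.boxDprime in ann.boxDprime_candidates

    def test_hacas_are_rejected(self):
        with pytest.raises(ValueError):
            find_boxes(SnoRNA("h", "ACGU" * 20, klass="HACA"))


class TestSearchPrimary:
    def constructed_case(self):
        """Hand-built D+5 duplex: substrate window 5'-UAGCCUCGAU-3' with the
        Nm at window position 5, guide 5'-AUCGAGGCUA-3' upstream of CUGA."""
        target = ReferenceRNA("t", "UAGCCUCGAU" + "A" * 30)
        sno = SnoRNA("g", "AUCGAGGCUA" + "CUGA")
        boxes = BoxAnnotation("g", boxD=(11, 14))
        nm = NmSite("t", 5, "C")
        return nm, target, sno, boxes

    def test_constructed_ten_bp_duplex_found_at_offset_five(self):
        nm, target, sno, boxes = self.constructed_case()
        records = search_primary(nm, target, sno, boxes)
        assert len(records) == 1
        rec = records[0]
        assert rec.nm_offset == 5
        assert rec.substrate_interval == (1, 10)
        assert rec.sno_interval == (1, 10)
        assert rec.length == 10
        rec.revalidate(target, sno)

    def test_constructed_case_matches_brute_force(self):
        nm, target, sno, boxes = self.constructed_case()
        assert record_keys(search_primary(nm, target, sno, boxes)) == \
            brute_force_primary(nm, target, sno, boxes)

    def test_random_sequences_without_complement_give_empty(self):
        rng = np.random.default_rng(0)
        target = ReferenceRNA("t", "".join(rng.choice(list("AC"), 100)))
        sno = SnoRNA("g", "".join(rng.choice(list("AC"), 60)) + "CUGA")
        nm = NmSite("t", 50, target.base(50))
        assert search_primary(nm, target, sno, find_boxes(sno)) == []

    def test_flank_rule_enforced(self):
        # complement only 3' of the Nm: 1 pair 5' of the site -> rejected
        target = ReferenceRNA("t", "GGGGCUCGAU" + "A" * 30)
        sno = SnoRNA("g", "AUCGAGGCUA" + "CUGA")
        boxes = BoxAnnotation("g", boxD=(11, 14))
        nm = NmSite("t", 5, "C")
        recs = search_primary(nm, target, sno, boxes)
        assert all(nm.position - r.substrate_interval[0] >= 2 for r in recs)

    def test_oracle_equivalence_on_random_instances(self):
        """50 random small instances: enumeration equals the brute force."""
        rng = np.random.default_rng(17)
        n_with_hits = 0
        for _ in range(50):
            target = ReferenceRNA("t", "".join(rng.choice(list("ACGU"), 160)))
            sno_seq = "".join(rng.choice(list("ACGU"), 50))
            # plant a guide for about half the instances
            if rng.random() < 0.6:
                nm_pos = int(rng.integers(20, 140))
                glen = int(rng.integers(8, 13))
                guide = revcomp(target.sequence[nm_pos - 5:nm_pos + glen - 5])
                sno_seq = sno_seq[:20] + guide + "CUGA" + sno_seq[20:30]
            else:
                nm_pos = int(rng.integers(20, 140))
            sno = SnoRNA("g", sno_seq)
            boxes = find_boxes(sno)
            nm = NmSite("t", nm_pos, target.base(nm_pos))
            got = record_keys(search_primary(nm, target, sno, boxes))
            expected = brute_force_primary(nm, target, sno, boxes)
            assert got == expected
            n_with_hits += bool(got)
        assert n_with_hits >= 10  # the comparison must exercise real hits

    def test_reversed_sequences_give_mirrored_intervals(self):
        """Coordinate involution: reversing both sequences (and complementing
        nothing) maps a duplex at [a,b] x [c,d] to [L-b+1, L-a+1] x [M-d+1, M-c+1]."""
        nm, target, sno, boxes = self.constructed_case()
        fwd = search_primary(nm, target, sno, boxes)[0]
        L, M = target.length, sno.length
        r_target = ReferenceRNA("t", target.sequence[::-1])
        r_sno = SnoRNA("g", sno.sequence[::-1])
        # the reversed duplex is no longer box-anchored; check raw pairing
        a, b = fwd.substrate_interval
        c, d = fwd.sno_interval
        for p, s, _ in fwd.pairs:
            rp, rs = L - p + 1, M - s + 1
            assert is_wc(r_target.base(rp), r_sno.sequence[rs - 1])


class TestExtendGu:
    def build(self, window, guide_core, flank5="", flank3=""):
        target = ReferenceRNA("t", window + "A" * 20)
        sno = SnoRNA("g", flank3 + guide_core + flank5 + "CUGA")
        return target, sno

    def test_gu_pair_extends_by_one(self):
        # substrate ...G adjacent to duplex, snoRNA U opposite: one GU pair
        target = ReferenceRNA("t", "UAGCCUCGAG" + "C" * 20)
        sno = SnoRNA("g", "UUCGAGGCUA" + "CUGA")
        boxes = BoxAnnotation("g", boxD=(11, 14))
        rec = search_primary(NmSite("t", 5, "C"), target, sno, boxes)[0]
        assert rec.length == 9
        ext = extend_gu(rec, target, sno)
        assert ext.length == 10
        assert ext.pairs[-1][2] == "GU"
        ext.revalidate(target, sno)

    def test_non_pair_is_a_no_op(self):
        target = ReferenceRNA("t", "UAGCCUCGAA" + "C" * 20)
        sno = SnoRNA("g", "AUCGAGGCUA" + "CUGA")
        boxes = BoxAnnotation("g", boxD=(11, 14))
        rec = search_primary(NmSite("t", 5, "C"), target, sno, boxes)[0]
        ext = extend_gu(rec, target, sno)
        assert ext.length == rec.length

    def test_two_gu_then_mismatch_extends_exactly_two(self):
        # 3' of the 9-bp core: substrate GG vs snoRNA UU (2 GU), then A/C stop
        target = ReferenceRNA("t", "UAGCCUCGAGG" + "A" * 20)
        sno = SnoRNA("g", "GCUUUCGAGGCUA" + "CUGA")
        boxes = BoxAnnotation("g", boxD=(14, 17))
        rec = search_primary(NmSite("t", 5, "C"), target, sno, boxes)[0]
        assert rec.length == 9
        ext = extend_gu(rec, target, sno)
        assert ext.length == 11
        assert [t for _, _, t in ext.pairs[-2:]] == ["GU", "GU"]

    def test_extension_never_shortens_nor_breaks_pairing(self, small_scene):
        sites = small_scene.truth_sites()
        report = assign_all(sites, small_scene.references, small_scene.snornas,
                            AssignConfig(search_extras=False))
        sno_by_name = {s.name: s for s in small_scene.snornas}
        checked = 0
        for a in report.sites:
            for rec in a.primaries:
                rec.revalidate(small_scene.reference(a.site.rna_id),
                               sno_by_name[rec.snorna])
                assert rec.length >= 7
                checked += 1
        assert checked >= 30


class TestSearchExtra:
    def test_planted_adjacent_extra_pair_found(self):
        config = rm.SimulationConfig(seed=21, rna_length=1200, n_sites=1)
        scene = rm.make_scene(config, site_specs=[SiteSpec(position=600, extra_pair=True)])
        (site,) = scene.truth_sites()
        target = scene.reference("rna0")
        sno = scene.snornas[0]
        boxes = find_boxes(sno)
        primary = extend_gu(
            search_primary(site, target, sno, boxes)[0], target, sno)
        extras = search_extra(primary, target, sno, boxes)
        assert extras, "planted extra pair not found"
        assert any(e.side == "3prime" and e.dist_substrate == 0 for e in extras)

    def test_candidate_inside_box_c_discarded(self):
        # snoRNA whose box C region is complementary to the substrate flank
        window = "A" * 40 + "UAGCCUCGAU" + "UCAUCAU" + "A" * 40
        target = ReferenceRNA("t", window)
        sno = SnoRNA("g", "AUGAUGA" + "GG" + "AUCGAGGCUA" + "CUGA")
        boxes = BoxAnnotation("g", boxC=(1, 7), boxD=(20, 23))
        nm = NmSite("t", 45, target.base(45))
        primary = search_primary(nm, target, sno, boxes)[0]
        extras = search_extra(primary, target, sno, boxes)
        from ribometh.guidemap import _overlap
        for e in extras:
            assert _overlap(e.sno_interval, boxes.boxC) <= 2

    def test_no_secondary_complementarity_gives_empty(self):
        target = ReferenceRNA("t", "UAGCCUCGAU" + "A" * 100)
        sno = SnoRNA("g", "AUCGAGGCUA" + "CUGA")
        boxes = BoxAnnotation("g", boxD=(11, 14))
        primary = search_primary(NmSite("t", 5, "C"), target, sno, boxes)[0]
        assert search_extra(primary, target, sno, boxes) == []


class TestNoncanonical:
    def tandem_scene(self, offset):
        config = rm.SimulationConfig(seed=3, rna_length=1200, n_sites=2)
        specs = [SiteSpec(position=500, box="Dprime"),
                 SiteSpec(position=500 + offset - 5, offset=offset)]
        return rm.make_scene(config, site_specs=specs)

    @pytest.mark.parametrize("offset", [6, 7])
    def test_tandem_dprime_pattern_recovered(self, offset):
        scene = self.tandem_scene(offset)
        report = assign_all(scene.truth_sites(), scene.references, scene.snornas)
        a = report[("rna0", 500 + offset - 5)]
        assert not a.unassigned
        rec = a.primaries[0]
        assert rec.nm_offset == offset
        assert rec.noncanonical
        assert rec.snorna == "sno0"

    def test_isolated_unassigned_site_unchanged(self):
        config = rm.SimulationConfig(seed=5, rna_length=1200, n_sites=1)
        scene = rm.make_scene(config, site_specs=[SiteSpec(position=400, guided=False)])
        report = assign_all(scene.truth_sites(), scene.references, scene.snornas)
        assert report[("rna0", 400)].unassigned


class TestAssignAll:
    def test_zero_site_scene_returns_nothing(self):
        config = rm.SimulationConfig(seed=1, rna_length=800, n_sites=0)
        scene = rm.make_scene(config)
        report = assign_all([], scene.references, scene.snornas)
        assert report.sites == []

    def test_all_planted_guides_recovered(self, small_scene):
        report = assign_all(small_scene.truth_sites(), small_scene.references,
                            small_scene.snornas)
        for t in small_scene.truth:
            a = report[(t.rna_id, t.position)]
            assert any(r.snorna == t.guide_snorna and r.nm_offset == 5
                       for r in a.primaries)
        assert report.stats()["n_assigned"] == 30

    def test_scrambled_guides_lose_exactly_their_sites(self):
        config = rm.SimulationConfig(seed=7, rna_length=2000, n_sites=30)
        scrambled = [f"sno{k}" for k in range(5)]
        scene = rm.make_scene(config, scramble_guides=scrambled)
        report = assign_all(scene.truth_sites(), scene.references, scene.snornas)
        recovered = sum(
            any(r.snorna == t.guide_snorna and r.nm_offset == 5
                for r in report[(t.rna_id, t.position)].primaries)
            for t in scene.truth)
        assert recovered == 25

    def test_recovery_degrades_monotonically_with_mutation_rate(self):
        rates = [0.0, 0.1, 0.3]
        recoveries = []
        for rate in rates:
            config = rm.SimulationConfig(seed=19, rna_length=2000, n_sites=30,
                                         mutation_rate=rate)
            scene = rm.make_scene(config)
            report = assign_all(scene.truth_sites(), scene.references,
                                scene.snornas, AssignConfig(search_extras=False))
            recoveries.append(sum(
                any(r.snorna == t.guide_snorna for r in
                    report[(t.rna_id, t.position)].primaries)
                for t in scene.truth))
        assert recoveries[0] == 30
        assert recoveries[0] >= recoveries[1] >= recoveries[2]
        assert recoveries[2] < 30

    def test_stats_recomputable_from_records(self, small_scene):
        report = assign_all(small_scene.truth_sites(), small_scene.references,
                            small_scene.snornas)
        stats = report.stats()
        assert stats["n_sites"] == 30
        assert stats["n_assigned"] + stats["n_unassigned"] == 30
        assert sum(stats["primary_length_hist"].values()) == stats["n_assigned"]


class TestConservationIntersect:
    def sites(self, labels):
        return [NmSite("18S", p, "A") for p in labels]

    def test_identity_map_all_shared(self):
        lists = {"a": self.sites([1, 2]), "b": self.sites([1, 2])}
        labels, venn = conservation_intersect(lists)
        assert venn == {frozenset({"a", "b"}): 2}
        assert all(lab == frozenset({"a", "b"}) for _, lab in labels["a"])

    def test_disjoint_lists_do_not_overlap(self):
        lists = {"a": self.sites([1]), "b": self.sites([9])}
        _, venn = conservation_intersect(lists)
        assert venn == {frozenset({"a"}): 1, frozenset({"b"}): 1}

    def test_three_way_intersection_counts(self):
        lists = {
            "ath": self.sites([1, 2, 3, 4]),
            "sce": self.sites([2, 3, 5]),
            "hsa": self.sites([3, 4, 5]),
        }
        _, venn = conservation_intersect(lists)
        assert venn[frozenset({"ath", "sce", "hsa"})] == 1  # position 3
        assert venn[frozenset({"ath"})] == 1  # position 1

    def test_alignment_map_translates_coordinates(self):
        lists = {"a": self.sites([10]), "b": [NmSite("SSU", 99, "A")]}
        maps = {"b": {("SSU", 99): ("18S", 10)}}
        _, venn = conservation_intersect(lists, maps)
        assert venn == {frozenset({"a", "b"}): 1}

    def test_unmapped_position_counts_species_specific(self):
        lists = {"a": self.sites([10]), "b": self.sites([10])}
        maps = {"b": {}}  # nothing maps
        _, venn = conservation_intersect(lists, maps)
        assert venn[frozenset({"a"})] == 1
        assert venn[frozenset({"b"})] == 1
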