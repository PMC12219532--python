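"""Contact-site detection, contact fractions and closest-partner classes."""

import numpy as np
import pytest

from orgspat.contacts import (
    ContactProfile,
    DistanceSpec,
    classify_by_partner,
    contact_profiles,
    enrichment_by_contact_class,
    euclidean_distance,
    find_contacts,
    find_contacts_bruteforce,
)
from orgspat.preprocess import LabeledObjects
from orgspat.synthetic import generate_blob_field


def objs_from(labels, classes):
    return LabeledObjects(np.asarray(labels, dtype=np.int32), classes)


def norm(sites):
    return {
        (s.id_a, s.id_b, s.pixels_a, s.pixels_b, round(s.min_dist_px, 9))
        for s in sites
    }


class TestEuclidean:
    def test_345_triangle(self):
        assert euclidean_distance((0, 0), (3, 4)) == 5.0

    def test_identity_and_diagonal(self):
        assert euclidean_distance((2, 2), (2, 2)) == 0.0
        assert euclidean_distance((0, 0), (1, 1)) == pytest.approx(np.sqrt(2))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            euclidean_distance((0, 0), (1, 1, 1))


class TestFindContacts:
    def test_two_bars_across_one_background_column(self):
        # A at col 0, B at col 2: cross-pair distances are 2 (same row) or
        # sqrt(5); with m=2 all four pixels contact, forming one site
        labels = np.zeros((4, 5), int)
        labels[1:3, 0] = 1
        labels[1:3, 2] = 2
        o = objs_from(labels, {1: "mitochondria", 2: "er"})
        sites = find_contacts(o, DistanceSpec(m=2))
        assert len(sites) == 1
        s = sites[0]
        assert s.size == 4
        assert s.pixels_a == frozenset({(1, 0), (2, 0)})
        assert s.pixels_b == frozenset({(1, 2), (2, 2)})
        assert s.min_dist_px == 2.0

    def test_min_distance_three_is_out_of_reach(self):
        labels = np.zeros((4, 6), int)
        labels[1:3, 0] = 1
        labels[1:3, 3] = 2
        o = objs_from(labels, {1: "mitochondria", 2: "er"})
        assert find_contacts(o, DistanceSpec(m=2)) == []

    def test_single_pixel_pair_site_removed(self):
        # two single-pixel objects touching once: noise, filtered out
        labels = np.zeros((3, 3), int)
        labels[1, 0] = 1
        labels[1, 2] = 2
        o = objs_from(labels, {1: "er", 2: "ld"})
        assert find_contacts(o, DistanceSpec(m=2)) == []

    def test_symmetry_of_sides(self, rng):
        o = generate_blob_field((96, 96), n_objects=12, seed=7)
        for s in find_contacts(o, DistanceSpec(m=2)):
            assert s.id_a < s.id_b
            assert s.pixels_a and s.pixels_b
            # pixels really lie on their object's perimeter
            for (y, x) in s.pixels_a:
                assert o.labels[y, x] == s.id_a
            for (y, x) in s.pixels_b:
                assert o.labels[y, x] == s.id_b

    def test_monotone_in_search_radius(self):
        o = generate_blob_field((96, 96), n_objects=14, seed=3)
        pix1 = {
            (s.id_a, s.id_b): s.pixels_a | s.pixels_b
            for s in find_contacts(o, DistanceSpec(m=1))
        }
        sites2 = find_contacts(o, DistanceSpec(m=2))
        pix2: dict = {}
        for s in sites2:
            pix2.setdefault((s.id_a, s.id_b), set()).update(s.pixels_a | s.pixels_b)
        for pair, pix in pix1.items():
            assert pix <= pix2.get(pair, set())

    def test_matches_bruteforce_on_random_fields(self):
        for seed in range(25):
            o = generate_blob_field((128, 128), n_objects=10, seed=seed)
            for m in (1, 2):
                spec = DistanceSpec(m=m)
                assert norm(find_contacts(o, spec)) == norm(
                    find_contacts_bruteforce(o, spec)
                )

    def test_scale_consistency(self):
        o = generate_blob_field((64, 64), n_objects=8, seed=2)
        s5 = find_contacts(o, DistanceSpec(m=2, pixel_size_nm=5.0))
        s10 = find_contacts(o, DistanceSpec(m=2, pixel_size_nm=10.0))
        assert norm(s5) == norm(s10)  # pixel-level result unchanged
        assert DistanceSpec(m=2, pixel_size_nm=10.0).window_nm == 2 * DistanceSpec(
            m=2, pixel_size_nm=5.0
        ).window_nm


class TestProfiles:
    def test_half_perimeter_in_contact(self):
        # 2x2 object (perimeter 4) with two pixels at distance 2 from an ER bar
        labels = np.zeros((4, 5), int)
        labels[1:3, 0:2] = 1
        labels[1:3, 3] = 2
        o = objs_from(labels, {1: "mitochondria", 2: "er"})
        sites = find_contacts(o, DistanceSpec(m=2))
        prof = contact_profiles(o, sites)[1]
        assert prof.perimeter_px == 4
        assert prof.partner_fractions["er"] == 0.5
        assert prof.label == "Mito-ER"

    def test_object_without_sites_is_isolated(self):
        labels = np.zeros((6, 6), int)
        labels[1:3, 1:3] = 1
        o = objs_from(labels, {1: "mitochondria"})
        prof = contact_profiles(o, [])[1]
        assert prof.partner_counts == {} and prof.label == "isolated"
        assert prof.total_fraction == 0.0

    def test_planted_scene_contacts_found(self, scene):
        from orgspat.preprocess import label_objects

        # combine ground-truth class labelings into one raster
        stack = scene.mask_stack
        combined = np.zeros(stack.shape, np.int32)
        classes = {}
        offset = 0
        gt_ids = {}
        for cls in stack.organelle_classes:
            lab = scene.labeled(cls)
            combined[lab.labels > 0] = lab.labels[lab.labels > 0] + offset
            for i in lab.ids:
                classes[i + offset] = cls
            gt_ids[cls] = offset
            offset += lab.n_objects
        o = LabeledObjects(combined, classes, stack.pixel_size_nm)
        sites = find_contacts(o, DistanceSpec(m=2))
        pairs = {(s.id_a, s.id_b) for s in sites}
        for (cls_a, ia), (cls_b, ib), gap in scene.planted_contacts:
            ga, gb = ia + gt_ids[cls_a], ib + gt_ids[cls_b]
            assert (min(ga, gb), max(ga, gb)) in pairs
            site = [s for s in sites if {s.id_a, s.id_b} == {ga, gb}][0]
            assert site.min_dist_px == gap + 1


class TestPartnerClassification:
    def _profile(self, dists, counts, cls="mitochondria"):
        return ContactProfile(
            object_id=1,
            cls=cls,
            perimeter_px=100,
            partner_counts=counts,
            partner_fractions={k: v / 100 for k, v in counts.items()},
            partner_min_dist_px=dists,
        )

    def test_closest_partner_wins(self):
        p = self._profile({"er": 1.0, "ld": 2.0}, {"er": 5, "ld": 50})
        assert classify_by_partner(p) == "Mito-ER"

    def test_no_partners_isolated(self):
        p = self._profile({}, {})
        assert classify_by_partner(p) == "isolated"

    def test_tie_broken_by_count_then_class_order(self):
        p = self._profile({"er": 1.0, "ld": 1.0}, {"er": 3, "ld": 9})
        assert classify_by_partner(p) == "Mito-LD"
        p2 = self._profile({"er": 1.0, "ld": 1.0}, {"er": 4, "ld": 4})
        assert classify_by_partner(p2) == "Mito-ER"


class TestEnrichmentByContactClass:
    def test_two_groups(self):
        profiles = {
            1: ContactProfile(1, "mitochondria", 10, {"er": 2}, {"er": 0.2}, {"er": 1.0}, 0.2, "Mito-ER"),
            2: ContactProfile(2, "mitochondria", 10, label="isolated"),
        }
        tab = enrichment_by_contact_class(profiles, {1: 120.0, 2: 110.0})
        tab = tab.set_index("contact_class")
        assert tab.loc["Mito-ER", "mean_ratio"] == 120.0
        assert tab.loc["isolated", "mean_ratio"] == 110.0
        assert (tab["n"] == 1).all()

    def test_single_group_grand_mean(self):
        profiles = {
            i: ContactProfile(i, "er", 10, label="isolated") for i in (1, 2, 3)
        }
        tab = enrichment_by_contact_class(profiles, {1: 100.0, 2: 110.0, 3: 120.0})
        assert len(tab) == 1
        assert tab.iloc[0]["mean_ratio"] == 110.0
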