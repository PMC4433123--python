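import numpy as np
import pytest
from scipy.cluster.hierarchy import average as scipy_average_linkage
from scipy.spatial.distance import squareform

from glioseg import isolation
from glioseg.isolation import (ClassDensity, TissueProbabilityMaps,
                               assign_brats_labels, attribute_classes,
                               compute_lesion_mask, correct_tissue_maps,
                               estimate_class_densities, js_divergence,
                               jsd_matrix, merge_similar_classes,
                               remove_low_rate_classes,
                               remove_perimeter_classes)
from glioseg.volume_io import LabelVolume, MultiChannelStudy


def _study_with(flair, t1c, mask):
    base = np.zeros(mask.shape)
    return MultiChannelStudy(
        channels={"T1": base.copy(), "T1c": t1c, "T2": base.copy(), "Flair": flair},
        brain_mask=mask)


class TestLesionMask:
    def test_constant_channels_give_empty_mask(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        study = _study_with(np.full(mask.shape, 5.0), np.full(mask.shape, 7.0), mask)
        assert compute_lesion_mask(study).sum() == 0

    def test_threshold_is_median_plus_std(self):
        """Interior voxels carrying 1..10 in Flair: selected = those above
        median + std, per direct computation."""
        mask = np.ones((14, 7, 7), dtype=bool)
        flair = np.zeros(mask.shape)
        # keep the test voxels well inside so the perimeter-shell removal
        # does not interfere; background in-mask voxels hold the value 1
        flair[mask] = 1.0
        vals = np.arange(1.0, 11.0)
        flair[2:12, 3, 3] = vals
        study = _study_with(flair, np.zeros(mask.shape), mask)
        lesion = compute_lesion_mask(study)
        all_vals = flair[mask]
        thr = np.median(all_vals) + all_vals.std()
        expected = (flair > thr) & mask
        expected &= ~isolation.brain_perimeter_shell(mask)
        assert np.array_equal(lesion, expected)
        assert lesion.sum() == (vals > thr).sum()

    def test_interior_hole_filled(self):
        mask = np.ones((12, 12, 12), dtype=bool)
        flair = np.zeros(mask.shape)
        flair[4:9, 4:9, 4:9] = 100.0   # bright blob ...
        flair[6, 6, 6] = 0.0           # ... with a dark hole
        study = _study_with(flair, np.zeros(mask.shape), mask)
        lesion = compute_lesion_mask(study)
        assert lesion[6, 6, 6]

    def test_empty_brain_mask_rejected(self):
        with pytest.raises(ValueError):
            MultiChannelStudy(channels={}, brain_mask=np.zeros((3, 3, 3)))


class TestCorrectTissueMaps:
    def _maps(self, shape=(5, 5, 5)):
        w = np.full(shape, 0.5)
        g = np.full(shape, 0.3)
        c = np.full(shape, 0.2)
        return TissueProbabilityMaps(maps={"WM": w, "GM": g, "CSF": c})

    def test_empty_lesion_is_identity(self):
        maps = self._maps()
        out = correct_tissue_maps(maps, np.zeros((5, 5, 5), dtype=bool))
        for t in ("WM", "GM", "CSF"):
            np.testing.assert_array_equal(out.maps[t], maps.maps[t])
        assert out.corrected

    def test_full_lesion_sets_epsilon_everywhere(self):
        out = correct_tissue_maps(self._maps(), np.ones((5, 5, 5), dtype=bool),
                                  epsilon=1e-6)
        for t in ("WM", "GM", "CSF"):
            assert (out.maps[t] == 1e-6).all()

    def test_single_voxel_locality(self):
        lesion = np.zeros((5, 5, 5), dtype=bool)
        lesion[2, 2, 2] = True
        maps = self._maps()
        out = correct_tissue_maps(maps, lesion)
        changed = out.maps["WM"] != maps.maps["WM"]
        assert changed.sum() == 1 and changed[2, 2, 2]

    def test_epsilon_bounds(self):
        with pytest.raises(ValueError):
            correct_tissue_maps(self._maps(), np.zeros((5, 5, 5), dtype=bool),
                                epsilon=1.0)


def _attribution_setup(p_wm):
    """Four one-voxel-per-class columns engineered so p(c|WM,S) = p_wm."""
    n = len(p_wm)
    shape = (n, 1, 1)
    labels = np.arange(1, n + 1).reshape(shape)
    mask = np.ones(shape, dtype=bool)
    wm = np.array(p_wm).reshape(shape)
    gm = np.full(shape, 1.0 / n)
    csf = np.full(shape, 1.0 / n)
    maps = TissueProbabilityMaps(maps={"WM": wm, "GM": gm, "CSF": csf})
    return LabelVolume(labels=labels), maps, mask


class TestAttribution:
    def test_hand_cumulative_sum_literal_rule(self):
        """P_WM = (.6,.3,.08,.02) => S = (.6,.9,.98,1.0); literal Z_WM is the
        classes at ranks 2-4."""
        vol, maps, mask = _attribution_setup([0.6, 0.3, 0.08, 0.02])
        table = attribute_classes(vol, maps, mask, tau=0.8, rule="literal")
        np.testing.assert_allclose(table.cumsums["WM"], [0.6, 0.9, 0.98, 1.0])
        assert table.z_sets["WM"] == {2, 3, 4}

    def test_exclusive_rule_spares_the_crossing_class(self):
        vol, maps, mask = _attribution_setup([0.6, 0.3, 0.08, 0.02])
        table = attribute_classes(vol, maps, mask, tau=0.8, rule="exclusive")
        assert table.z_sets["WM"] == {3, 4}

    def test_single_class_degenerate_warns(self):
        shape = (4, 1, 1)
        vol = LabelVolume(labels=np.ones(shape, dtype=int))
        maps = TissueProbabilityMaps(maps={t: np.full(shape, 1 / 3)
                                           for t in ("WM", "GM", "CSF")})
        with pytest.warns(UserWarning, match="literal"):
            table = attribute_classes(vol, maps, np.ones(shape, dtype=bool),
                                      rule="literal")
        assert table.z_sets["WM"] == {1}

    def test_zero_mass_tissue_is_vacuous(self):
        vol, maps, mask = _attribution_setup([0.5, 0.3, 0.15, 0.05])
        maps.maps["CSF"][:] = 0.0
        with pytest.warns(UserWarning, match="CSF"):
            table = attribute_classes(vol, maps, mask)
        assert table.z_sets["CSF"] == {1, 2, 3, 4}

    def test_columns_sum_to_one(self):
        vol, maps, mask = _attribution_setup([0.4, 0.3, 0.2, 0.1])
        table = attribute_classes(vol, maps, mask)
        np.testing.assert_allclose(table.p_ct.sum(axis=0), 1.0, atol=1e-9)

    @pytest.mark.parametrize("rule", ["literal", "exclusive"])
    def test_z_shrinks_as_tau_increases(self, rule, rng):
        shape = (60, 1, 1)
        labels = rng.integers(1, 7, size=shape)
        mask = np.ones(shape, dtype=bool)
        raw = rng.random((3,) + shape[0:1]).reshape(3, -1)
        raw /= raw.sum(axis=0)
        maps = TissueProbabilityMaps(maps={
            t: raw[i].reshape(shape) for i, t in enumerate(("WM", "GM", "CSF"))})
        vol = LabelVolume(labels=labels)
        previous = None
        for tau in (0.5, 0.7, 0.9):
            z = attribute_classes(vol, maps, mask, tau=tau, rule=rule).z
            if previous is not None:
                assert z <= previous
            previous = z

    def test_lesion_aligned_class_is_isolated(self, rng):
        """Classes aligned with WM/GM/CSF maps stay out; the lesion class is Z."""
        shape = (8, 8, 8)
        mask = np.ones(shape, dtype=bool)
        labels = np.ones(shape, dtype=int)
        labels[:, :, 4:] = 2
        labels[:4, :, :4] = 3
        lesion = np.zeros(shape, dtype=bool)
        lesion[5:8, 5:8, :3] = True
        labels[lesion] = 4
        maps = {}
        for t, cls in (("WM", 1), ("GM", 2), ("CSF", 3)):
            m = np.where(labels == cls, 0.9, 0.05)
            maps[t] = m
        tpm = TissueProbabilityMaps(maps=maps)
        corrected = correct_tissue_maps(tpm, lesion, epsilon=1e-6)
        table = attribute_classes(LabelVolume(labels=labels), corrected, mask)
        assert table.z == {4}


class TestOutlierRemoval:
    def _brain(self, shape=(16, 16, 16)):
        mask = np.zeros(shape, dtype=bool)
        mask[1:-1, 1:-1, 1:-1] = True
        return mask

    def test_interior_component_untouched(self):
        mask = self._brain()
        labels = np.zeros(mask.shape, dtype=int)
        labels[7:9, 7:9, 7:9] = 1
        out = remove_perimeter_classes(LabelVolume(labels=labels), mask)
        assert (out.labels == labels).all()

    def test_component_on_shell_erased(self):
        mask = self._brain()
        labels = np.zeros(mask.shape, dtype=int)
        labels[1:3, 4:8, 4:8] = 1   # hugging the boundary shell
        out = remove_perimeter_classes(LabelVolume(labels=labels), mask)
        assert (out.labels == 0).all()

    def test_exactly_half_inside_is_kept(self):
        mask = np.zeros((20, 9, 9), dtype=bool)
        mask[1:-1, 1:-1, 1:-1] = True
        shell = isolation.brain_perimeter_shell(mask, 2)
        perimeter = __import__("scipy.ndimage", fromlist=["ndimage"]).binary_dilation(
            shell, iterations=isolation.PERIMETER_DILATION)
        # build a bar crossing the perimeter with exactly 50% inside
        labels = np.zeros(mask.shape, dtype=int)
        bar = np.zeros(mask.shape, dtype=bool)
        inside = np.argwhere(perimeter & mask)
        outside = np.argwhere(~perimeter & mask)
        k = 10
        bar[tuple(inside[:k].T)] = True
        bar[tuple(outside[:k].T)] = True
        labels[bar] = 1
        # the bar may be split into several components; check the rule by
        # counting survivors: every component with <= 50% inside stays
        out = remove_perimeter_classes(LabelVolume(labels=labels), mask)
        from scipy import ndimage
        comp, n = ndimage.label(labels == 1, structure=np.ones((3, 3, 3)))
        for i in range(1, n + 1):
            sel = comp == i
            frac_in = (sel & perimeter).sum() / sel.sum()
            survived = bool(out.labels[sel].any())
            assert survived == (frac_in <= 0.5)

    def test_low_rate_boundary_is_strict(self):
        labels = np.zeros((10, 10, 1), dtype=int)
        labels[:, :9, 0] = 1          # 90 voxels
        labels[0, 9, 0] = 2           # exactly 1% of 100... build 99/1
        labels[1:10, 9, 0] = 1        # class1 = 99, class2 = 1 -> 1%
        out = remove_low_rate_classes(LabelVolume(labels=labels), min_fraction=0.01)
        assert set(out.present_labels()) == {1, 2}

    def test_low_rate_hand_fractions(self):
        labels = np.zeros((1000, 1, 1), dtype=int)
        labels[:985] = 1
        labels[985:995] = 2
        labels[995:] = 3   # 0.5%
        out = remove_low_rate_classes(LabelVolume(labels=labels), min_fraction=0.01)
        assert set(out.present_labels()) == {1, 2}

    def test_single_class_kept_and_total_nonincreasing(self):
        labels = np.ones((4, 4, 4), dtype=int)
        out = remove_low_rate_classes(LabelVolume(labels=labels))
        assert (out.labels == 1).all()

    def test_all_removed_raises(self):
        labels = np.zeros((4, 4, 4), dtype=int)
        with pytest.raises(ValueError):
            remove_low_rate_classes(LabelVolume(labels=labels))


class TestDensitiesAndJsd:
    def test_degenerate_class_concentrates_with_unit_mass(self):
        x = np.array([[1.0], [1.0], [1.0], [5.0], [6.0]])
        assign = np.array([1, 1, 1, 2, 2])
        dens = estimate_class_densities(x, assign, [1, 2])
        grid, d1 = dens.grid[0], dens.densities[1][0]
        assert np.trapezoid(d1, grid) == pytest.approx(1.0, abs=1e-3)
        assert grid[np.argmax(d1)] == pytest.approx(1.0, abs=0.2)

    def test_identical_member_sets_give_identical_densities(self, rng):
        x = rng.normal(size=(100, 2))
        assign = np.array([1] * 50 + [2] * 50)
        x[50:] = x[:50]
        dens = estimate_class_densities(x, assign, [1, 2])
        np.testing.assert_allclose(dens.densities[1], dens.densities[2])
        assert js_divergence(dens.densities[1], dens.densities[2]) == 0.0

    def test_kde_close_to_analytic_normal(self, rng):
        x = rng.standard_normal((5000, 1))
        dens = estimate_class_densities(x, np.ones(5000, dtype=int), [1])
        grid = dens.grid[0]
        analytic = np.exp(-grid**2 / 2) / np.sqrt(2 * np.pi)
        assert np.abs(dens.densities[1][0] - analytic).max() < 0.05

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            estimate_class_densities(np.zeros((3, 1)), np.array([1, 1, 2]), [1, 2])

    def test_jsd_bounds_symmetry_and_extremes(self, rng):
        g = np.linspace(0, 1, 128)
        p = np.exp(-((g - 0.3) ** 2) / 0.01)
        q = np.exp(-((g - 0.7) ** 2) / 0.01)
        assert js_divergence(p, p) == 0.0
        assert js_divergence(p, q) == pytest.approx(js_divergence(q, p))
        disjoint_p = np.zeros(128); disjoint_p[:40] = 1.0
        disjoint_q = np.zeros(128); disjoint_q[60:] = 1.0
        assert js_divergence(disjoint_p, disjoint_q) == pytest.approx(1.0)
        for _ in range(20):
            a, b = rng.random(128) + 1e-9, rng.random(128) + 1e-9
            v = js_divergence(a, b)
            assert 0.0 <= v <= 1.0 + 1e-12


def _density_from_samples(samples_by_class, rng):
    x = np.concatenate(list(samples_by_class.values()))[:, None]
    assign = np.concatenate([np.full(len(v), c)
                             for c, v in samples_by_class.items()])
    return estimate_class_densities(x, assign, sorted(samples_by_class))


class TestMerge:
    def test_identical_densities_merge_to_one(self, rng):
        v = rng.normal(size=200)
        dens = _density_from_samples({1: v, 2: v.copy()}, rng)
        mapping = merge_similar_classes(dens, max_classes=4, merge_threshold=0.1)
        assert mapping == {1: 1, 2: 1}

    def test_six_distant_classes_forced_to_four(self, rng):
        samples = {c: rng.normal(10.0 * c, 0.1, size=100) for c in range(1, 7)}
        dens = _density_from_samples(samples, rng)
        mapping = merge_similar_classes(dens, max_classes=4, merge_threshold=0.1)
        assert len(set(mapping.values())) == 4
        assert set(mapping.values()) == {1, 2, 3, 4}

    def test_distant_classes_above_threshold_untouched(self, rng):
        samples = {c: rng.normal(10.0 * c, 0.1, size=100) for c in (1, 2, 3)}
        dens = _density_from_samples(samples, rng)
        mapping = merge_similar_classes(dens, max_classes=4, merge_threshold=0.1)
        assert mapping == {1: 1, 2: 2, 3: 3}

    def test_merge_order_matches_scipy_average_linkage(self, rng):
        """UPGMA agglomeration against scipy's average linkage on the same
        JSD matrix: forcing down to 2 groups must give the same partition."""
        # overlapping densities so all pairwise JSDs are distinct (far-apart
        # classes all saturate at JSD = 1, which only tests tie-breaking)
        samples = {c: rng.normal(rng.uniform(0, 6), 1.5, size=80)
                   for c in range(1, 7)}
        dens = _density_from_samples(samples, rng)
        dist = jsd_matrix(dens)
        link = scipy_average_linkage(squareform(dist, checks=False))
        from scipy.cluster.hierarchy import fcluster
        scipy_groups = fcluster(link, t=2, criterion="maxclust")
        mapping = merge_similar_classes(dens, max_classes=2, merge_threshold=0.0)
        ours = np.array([mapping[c] for c in sorted(samples)])
        # compare partitions up to relabelling
        pairs_ours = {(i, j) for i in range(6) for j in range(i + 1, 6)
                      if ours[i] == ours[j]}
        pairs_scipy = {(i, j) for i in range(6) for j in range(i + 1, 6)
                       if scipy_groups[i] == scipy_groups[j]}
        assert pairs_ours == pairs_scipy

    def test_merge_map_is_surjective_onto_range(self, rng):
        samples = {c: rng.normal(3.0 * c, 1.0, size=60) for c in (2, 5, 9)}
        dens = _density_from_samples(samples, rng)
        mapping = merge_similar_classes(dens, max_classes=2, merge_threshold=0.0)
        k = len(set(mapping.values()))
        assert set(mapping.values()) == set(range(1, k + 1))


class TestBratsAssignment:
    def _study(self, t1, t1c, t2, flair, labels):
        return MultiChannelStudy(
            channels={"T1": t1, "T1c": t1c, "T2": t2, "Flair": flair},
            brain_mask=labels >= 0), LabelVolume(labels=labels)

    def test_contrast_constructed_classes_map_to_their_codes(self):
        shape = (8, 1, 1)
        labels = np.array([1, 1, 2, 2, 3, 3, 4, 4]).reshape(shape)
        t1 = np.full(shape, 50.0)
        t1c = t1.copy()
        flair = np.full(shape, 50.0)
        t1c[labels == 1] += 60.0       # class 1: enhancing (highest T1d)
        flair[labels == 2] = 95.0      # class 2: edema (highest Flair)
        t1c[labels == 3] -= 20.0       # class 3: darkest T1c -> necrosis
        study, vol = self._study(t1, t1c, t1.copy(), flair, labels)
        out = assign_brats_labels(vol, study)
        mapping = out.legend_mapping
        assert mapping == {1: 4, 2: 2, 3: 1, 4: 3}

    def test_single_bright_class_is_enhancing(self):
        shape = (4, 1, 1)
        labels = np.ones(shape, dtype=int)
        t1 = np.full(shape, 10.0)
        t1c = np.full(shape, 90.0)
        study, vol = self._study(t1, t1c, t1.copy(), t1.copy(), labels)
        out = assign_brats_labels(vol, study)
        assert set(out.labels.ravel()) == {4}

    def test_t1d_tie_breaks_to_lower_class_id(self):
        shape = (4, 1, 1)
        labels = np.array([1, 1, 2, 2]).reshape(shape)
        t1 = np.full(shape, 10.0)
        t1c = np.full(shape, 30.0)     # equal T1d for both classes
        study, vol = self._study(t1, t1c, t1.copy(), t1.copy(), labels)
        out = assign_brats_labels(vol, study)
        assert out.legend_mapping[1] == 4
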