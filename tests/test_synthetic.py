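import numpy as np
import pytest
from scipy import ndimage, stats

from dticnn import features as ft
from dticnn import scalars as sc
from dticnn import synthetic as syn
from dticnn.errors import DomainError


class TestAtlas:
    def test_label_set_matches_request(self, small_atlas):
        assert sorted(np.unique(small_atlas.labels)) == list(range(11))

    def test_deterministic(self, small_atlas):
        again = syn.generate_atlas((24, 28, 24), n_gray=6, n_white=4, seed=7)
        np.testing.assert_array_equal(again.labels, small_atlas.labels)

    def test_every_roi_nonempty_brute_force(self, small_atlas):
        counts = {rid: 0 for rid in range(1, 11)}
        arr = small_atlas.labels
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                for k in range(arr.shape[2]):
                    if arr[i, j, k] > 0:
                        counts[int(arr[i, j, k])] += 1
        assert all(c >= 1 for c in counts.values())

    def test_rois_connected(self, small_atlas):
        for rid in small_atlas.roi_ids:
            _, n_comp = ndimage.label(small_atlas.labels == rid)
            assert n_comp == 1

    def test_tissue_split(self, small_atlas):
        tissues = [small_atlas.roi_table[r]["tissue"] for r in small_atlas.roi_ids]
        assert tissues.count("gray") == 6 and tissues.count("white") == 4

    def test_too_small_shape_rejected(self):
        with pytest.raises(DomainError):
            syn.generate_atlas((8, 8, 8), n_gray=500, n_white=100, seed=0)


class TestTensorField:
    def test_noiseless_hits_fa_target(self, tiny_atlas):
        fld = syn.generate_tensor_field(
            (12, 12, 12), tiny_atlas, {"gray": 0.2, "white": 0.6}, noise_sd=0.0, seed=1
        )
        fa = sc.scalar_maps_from_field(fld)["FA"].values
        gm = tiny_atlas.tissue_masks()["gray"]
        assert np.abs(fa[gm] - 0.2).max() < 1e-10

    def test_all_eigenvalues_nonnegative_brute_force(self, tiny_atlas):
        fld = syn.generate_tensor_field(
            (12, 12, 12), tiny_atlas, {"gray": 0.3, "white": 0.7}, noise_sd=0.1, seed=2
        )
        for idx in np.ndindex(*fld.shape):
            lams = np.linalg.eigvalsh(fld.tensors[idx])
            assert lams.min() >= -1e-12

    def test_deterministic(self, tiny_atlas):
        kw = dict(labels=tiny_atlas, base_fa_by_tissue={"gray": 0.3, "white": 0.7},
                  noise_sd=0.05, seed=9)
        a = syn.generate_tensor_field((12, 12, 12), **kw)
        b = syn.generate_tensor_field((12, 12, 12), **kw)
        np.testing.assert_array_equal(a.tensors, b.tensors)

    def test_negative_noise_rejected(self, tiny_atlas):
        with pytest.raises(DomainError):
            syn.generate_tensor_field(
                (12, 12, 12), tiny_atlas, {"gray": 0.3}, noise_sd=-1.0, seed=0
            )

    def test_symmetry(self, tiny_atlas):
        fld = syn.generate_tensor_field(
            (12, 12, 12), tiny_atlas, {"gray": 0.3, "white": 0.7}, noise_sd=0.05, seed=2
        )
        fld.validate_symmetry()


class TestEffects:
    def test_unknown_kind_rejected(self):
        with pytest.raises(DomainError):
            syn.GroupEffect("volume_shift", magnitude=1.0)

    def test_missing_roi_rejected(self, tiny_atlas):
        spec = syn.CohortSpec(n_subjects=4, volume_shape=(12, 12, 12), seed=0)
        eff = syn.GroupEffect("mean_shift", target_roi_ids={99}, magnitude=1.0)
        with pytest.raises(DomainError, match="99"):
            syn.inject_group_effect(syn.make_records(spec), eff, tiny_atlas, spec)

    def test_zero_effect_null_pvalues(self):
        # t-test on ROI-mean FA across groups consistent with the null
        pvals = []
        for seed in range(8):
            spec = syn.CohortSpec(
                n_subjects=30, volume_shape=(12, 12, 12), effects=[],
                n_gray_rois=3, n_white_rois=1, seed=seed,
            )
            vols, groups, atlas = syn.render_cohort_volumes(spec)
            m = atlas.labels == 1
            roimeans = vols[:, m].mean(axis=1)
            g = np.asarray(groups)
            _, p = stats.ttest_ind(roimeans[g == "A"], roimeans[g == "B"])
            pvals.append(p)
        assert min(pvals) > 0.001  # no systematic effect
        assert max(pvals) > 0.2  # p not uniformly tiny

    def test_mean_shift_d_recovered(self):
        eff = syn.GroupEffect("mean_shift", target_roi_ids={1, 2}, magnitude=1.0)
        spec = syn.CohortSpec(
            n_subjects=200, volume_shape=(16, 16, 16), effects=[eff],
            n_gray_rois=4, n_white_rois=2, seed=3,
        )
        vols, groups, atlas = syn.render_cohort_volumes(spec)
        m = np.isin(atlas.labels, [1, 2])
        roimeans = vols[:, m].mean(axis=1)
        g = np.asarray(groups)
        a, b = roimeans[g == "A"], roimeans[g == "B"]
        pooled = np.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
            / (len(a) + len(b) - 2)
        )
        d = (a.mean() - b.mean()) / pooled
        assert 0.8 <= d <= 1.2

    def test_texture_effect_entropy_direction(self):
        # group A keeps the rough maps -> higher quantized-map entropy
        eff = syn.GroupEffect("texture_complexity", magnitude=1.5, direction=+1)
        spec = syn.CohortSpec(
            n_subjects=20, volume_shape=(12, 12, 12), effects=[eff],
            noise_sd=0.05, n_gray_rois=3, n_white_rois=1, seed=4,
        )
        vols, groups, _ = syn.render_cohort_volumes(spec)
        ents = np.array([ft.entropy(ft.quantize_map(v)) for v in vols])
        g = np.asarray(groups)
        assert ents[g == "A"].mean() > ents[g == "B"].mean()


class TestGenerateCohort:
    def test_even_split(self, tmp_path):
        spec = syn.CohortSpec(n_subjects=20, volume_shape=(12, 12, 12), seed=5,
                              n_gray_rois=3, n_white_rois=1)
        records, _, manifest = syn.generate_cohort(spec, tmp_path / "c")
        groups = [r.group for r in records]
        assert groups.count("A") == 10 and groups.count("B") == 10
        lines = manifest.read_text().strip().split("\n")
        assert lines[0] == "subject_id\tgroup\tpath"
        assert len(lines) == 21

    def test_odd_split_floor_rule(self):
        spec = syn.CohortSpec(n_subjects=21, volume_shape=(12, 12, 12), seed=5)
        groups = [r.group for r in syn.make_records(spec)]
        assert groups.count("A") == 10 and groups.count("B") == 11

    def test_regeneration_identical(self, tmp_path):
        spec = syn.CohortSpec(n_subjects=4, volume_shape=(12, 12, 12), seed=6,
                              n_gray_rois=3, n_white_rois=1)
        _, _, m1 = syn.generate_cohort(spec, tmp_path / "a")
        _, _, m2 = syn.generate_cohort(spec, tmp_path / "b")
        import nibabel as nib

        for line1, line2 in zip(m1.read_text().splitlines()[1:], m2.read_text().splitlines()[1:]):
            p1, p2 = line1.split("\t")[2], line2.split("\t")[2]
            np.testing.assert_array_equal(
                np.asarray(nib.load(p1).dataobj), np.asarray(nib.load(p2).dataobj)
            )

    def test_spec_validation(self):
        with pytest.raises(DomainError):
            syn.CohortSpec(n_subjects=1, volume_shape=(12, 12, 12))
        with pytest.raises(DomainError):
            syn.CohortSpec(n_subjects=10, volume_shape=(4, 12, 12))
        with pytest.raises(DomainError):
            syn.CohortSpec(n_subjects=10, volume_shape=(12, 12, 12), group_fraction=1.5)
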