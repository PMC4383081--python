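"""Reconstruction core: reference filtering, Fourier-insertion
backprojection, pseudo-helical symmetrization, masking, and FSC."""

import numpy as np
import pytest

from mtseam.fourier import lowpass, radial_freq
from mtseam.geometry import euler_matrix
from mtseam.imaging import project_volume
from mtseam.lattice import LatticeSpec, build_lattice
from mtseam.micrograph import SegmentStack
from mtseam.pipeline import masked_band_correlation
from mtseam.reconstruct import (
    AlignmentRecord,
    FSCCurve,
    backproject,
    flip_polarity,
    fsc,
    helical_transform,
    make_reference,
    make_tight_mask,
    resolution_at,
    symmetrize_pseudo_helical,
    wedge_masks,
)
from mtseam.render import Volume, render_density, render_projection
from mtseam.simulate import contained_phantom


@pytest.fixture(scope="module")
def phantom(spec14):
    vol, lat = contained_phantom(spec14, n_repeats=3)
    return vol, lat


class TestMakeReference:
    def test_power_beyond_cutoff_removed(self, ref_volume_14):
        ref = make_reference(ref_volume_14, 20.0)
        q = radial_freq(ref.shape, ref.voxel_size)
        F = np.abs(np.fft.fftn(ref.data)) ** 2
        beyond = F[q > 1.0 / 20.0].sum()
        assert beyond / F.sum() < 0.01

    def test_infinite_cutoff_is_identity(self, ref_volume_14):
        ref = make_reference(ref_volume_14, np.inf)
        np.testing.assert_allclose(ref.data, ref_volume_14.data, atol=1e-12)

    def test_cutoff_below_nyquist_rejected(self, ref_volume_14):
        with pytest.raises(ValueError):
            make_reference(ref_volume_14, 2.0 * ref_volume_14.voxel_size - 1.0)

    def test_noise_autocorrelation_width_matches_cutoff(self):
        """Low-passed white noise decorrelates over ~the cutoff length."""
        rng = np.random.default_rng(0)
        vol = Volume(rng.normal(size=(64, 64, 64)), 5.0, np.zeros(3))
        ref = make_reference(vol, 20.0)
        a = ref.data - ref.data.mean()
        ac = np.real(np.fft.ifftn(np.abs(np.fft.fftn(a)) ** 2))
        ac /= ac[0, 0, 0]
        # 20 Å cutoff = 4 voxels: correlation decays strongly by 1 cutoff
        assert ac[4, 0, 0] < 0.3
        assert ac[1, 0, 0] > 0.5


class TestWedgeMasks:
    @pytest.mark.parametrize("n_pf", [12, 13, 14, 15])
    def test_partition_of_unity(self, n_pf):
        masks = wedge_masks((40, 40, 4), n_pf)
        np.testing.assert_allclose(masks.sum(axis=0), 1.0, atol=1e-12)

    def test_each_mask_peaks_at_its_protofilament_azimuth(self):
        masks = wedge_masks((64, 64, 2), 14)
        c = (64 - 1) / 2.0
        for k in [0, 3, 7]:
            phi = np.deg2rad(k * 360.0 / 14)
            i = int(round(c + 20 * np.cos(phi)))
            j = int(round(c + 20 * np.sin(phi)))
            assert masks[k][i, j] > 0.9


class TestHelicalOps:
    def test_transform_and_inverse_cancel(self, ref_volume_14):
        v1 = helical_transform(ref_volume_14, 25.7, 8.57, wrap=True)
        v2 = helical_transform(v1, -25.7, -8.57, wrap=True)
        interior = ref_volume_14.data[8:-8, 8:-8, 8:-8]
        back = v2.data[8:-8, 8:-8, 8:-8]
        err = np.abs(back - interior).max() / np.abs(interior).max()
        assert err < 0.2  # two trilinear resamplings of a sharp map

    def test_polarity_flip_is_involution(self, ref_volume_14):
        flipped = flip_polarity(flip_polarity(ref_volume_14))
        np.testing.assert_array_equal(flipped.data, ref_volume_14.data)


class TestSymmetrize:
    def test_fixed_point_on_helically_symmetric_volume(self, spec14):
        """A seamless 1-start helical density is unchanged by
        symmetrization up to interpolation error."""
        N, vox = 64, 5.0
        twist, rise = spec14.twist_per_pf, spec14.rise_per_pf
        c = (N - 1) / 2.0
        x = (np.arange(N) - c) * vox
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        box_len = N * vox
        repeat = spec14.monomer_rise  # 40 Å: the monomer lattice is the
        # largest axial tiling consistent with the 3-start closure, so
        # this point set is exactly invariant under the (twist, rise)
        # operator with wrapped z
        data = np.zeros((N, N, N))
        for k in range(spec14.n_pf):
            phi = np.deg2rad(k * twist)
            z0 = (k * rise) % repeat
            n_tiles = int(box_len / repeat)
            for m in range(-1, n_tiles + 1):
                zb = z0 + m * repeat - box_len / 2
                r2 = (
                    (X - 110 * np.cos(phi)) ** 2
                    + (Y - 110 * np.sin(phi)) ** 2
                    + (Z - zb) ** 2
                )
                data += np.exp(-r2 / (2 * 12.0**2))
        vol = Volume(data, vox, -vox * (np.array([N, N, N]) - 1) / 2.0)
        sym = symmetrize_pseudo_helical(vol, spec14.n_pf, rise, wrap=True)
        core = np.s_[10:-10, 10:-10, :]
        num = np.abs(sym.data[core] - vol.data[core]).max()
        assert num / np.abs(vol.data[core]).max() < 0.1

    def test_idempotence(self, ref_volume_14, spec14):
        s1 = symmetrize_pseudo_helical(ref_volume_14, 14, spec14.rise_per_pf)
        s2 = symmetrize_pseudo_helical(s1, 14, spec14.rise_per_pf)
        a = s1.data[10:-10, 10:-10, :]
        b = s2.data[10:-10, 10:-10, :]
        corr = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert corr > 0.995

    def test_noise_averaging_gain_on_good_protofilament(self, spec14):
        """Averaging n_pf transformed copies of independent noise reduces
        its standard deviation by ~sqrt(n_pf)."""
        rng = np.random.default_rng(1)
        vol = Volume(rng.normal(size=(64, 64, 64)), 5.0, -5.0 * (np.array([64] * 3) - 1) / 2)
        n_pf = spec14.n_pf
        avg = vol.data.copy()
        for k in range(1, n_pf):
            avg += helical_transform(vol, -k * spec14.twist_per_pf, -k * spec14.rise_per_pf, wrap=True).data
        avg /= n_pf
        core = np.s_[20:-20, 20:-20, 20:-20]
        gain = vol.data[core].std() / avg[core].std()
        # trilinear interpolation correlates neighbours, so the gain is
        # larger than sqrt(n_pf); it must be well above no-gain
        assert gain > 0.6 * np.sqrt(n_pf)

    def test_inconsistent_twist_rejected(self, ref_volume_14):
        with pytest.raises(ValueError):
            symmetrize_pseudo_helical(ref_volume_14, 14, 8.57, twist=30.0)


class TestTightMask:
    def test_values_bounded_and_default_smoothing(self, ref_volume_14):
        mask = make_tight_mask(ref_volume_14, threshold=0.2, smooth=10.0)
        assert mask.data.min() >= 0.0
        assert mask.data.max() <= 1.0

    def test_zero_threshold_gives_unit_mask(self, ref_volume_14):
        mask = make_tight_mask(ref_volume_14, threshold=0.0)
        np.testing.assert_allclose(mask.data, 1.0, atol=1e-9)

    def test_spherical_blob_half_level_near_blob_radius(self):
        N, vox = 64, 2.0
        c = (N - 1) / 2.0
        x = np.arange(N) - c
        r = np.sqrt(sum(g**2 for g in np.meshgrid(x, x, x, indexing="ij"))) * vox
        blob = (r < 20.0).astype(float)
        vol = Volume(blob, vox, np.zeros(3))
        mask = make_tight_mask(vol, threshold=0.5, smooth=6.0, lowpass_res=np.inf)
        mid = N // 2
        profile = mask.data[mid:, mid, mid]
        r_half = np.interp(0.5, profile[::-1], (np.arange(len(profile)) * vox)[::-1])
        assert r_half == pytest.approx(20.0, abs=3.0)

    def test_empty_mask_rejected(self, ref_volume_14):
        with pytest.raises(ValueError, match="empty mask"):
            make_tight_mask(ref_volume_14, threshold=1.5)


class TestFSC:
    def test_map_against_itself_is_unity(self, ref_volume_14):
        curve = fsc(ref_volume_14, ref_volume_14)
        valid = ~np.isnan(curve.correlation)
        np.testing.assert_allclose(curve.correlation[valid], 1.0, atol=1e-9)

    def test_independent_noise_decorrelates(self):
        rng = np.random.default_rng(7)
        a = Volume(rng.normal(size=(48, 48, 48)), 4.0, np.zeros(3))
        b = Volume(rng.normal(size=(48, 48, 48)), 4.0, np.zeros(3))
        curve = fsc(a, b)
        n_vox_shell = 4 * np.pi * (np.arange(1, len(curve.correlation) + 1) ** 2)
        bound = 3.0 / np.sqrt(n_vox_shell)
        frac_ok = np.mean(np.abs(curve.correlation) < bound)
        assert frac_ok > 0.9

    def test_symmetric_and_scale_invariant(self, ref_volume_14):
        rng = np.random.default_rng(2)
        noisy = Volume(ref_volume_14.data + rng.normal(size=ref_volume_14.shape),
                       ref_volume_14.voxel_size, ref_volume_14.origin)
        c_ab = fsc(ref_volume_14, noisy).correlation
        c_ba = fsc(noisy, ref_volume_14).correlation
        np.testing.assert_allclose(c_ab, c_ba, atol=1e-10)
        scaled = Volume(3.7 * noisy.data, noisy.voxel_size, noisy.origin)
        c_scaled = fsc(ref_volume_14, scaled).correlation
        np.testing.assert_allclose(c_scaled, c_ab, atol=1e-10)

    def test_threshold_crossing_interpolation_oracle(self):
        """Hand-computed: FSC falling 0.5 -> 0.1 between 1/10 and 1/5 Å⁻¹
        crosses 0.143 at 0.18925 Å⁻¹, i.e. 5.28 Å."""
        curve = FSCCurve(shell_freq=np.array([0.05, 0.1, 0.2, 0.25]),
                         correlation=np.array([0.9, 0.5, 0.1, 0.05]))
        res, crossed = resolution_at(curve, threshold=0.143)
        assert crossed
        assert res == pytest.approx(1.0 / 0.18925, abs=1e-3)

    def test_no_crossing_returns_nyquist_with_flag(self):
        curve = FSCCurve(shell_freq=np.array([0.05, 0.1, 0.2]),
                         correlation=np.array([0.99, 0.98, 0.97]))
        res, crossed = resolution_at(curve)
        assert not crossed
        assert res == pytest.approx(1.0 / 0.2)


class TestBackprojection:
    def make_projection_set(self, lat, n_views, tilts=(80.0, 90.0, 100.0), box=80, vox=5.0):
        boxes, records = [], []
        for i in range(n_views):
            rot = i * 360.0 / n_views
            tilt = tilts[i % len(tilts)]
            boxes.append(render_projection(lat, euler_matrix(rot, tilt, 0.0), (box, box), vox))
            records.append(AlignmentRecord(rot=rot, tilt=tilt, repeat_index=i))
        return SegmentStack(np.array(boxes), vox, np.zeros((n_views, 2)), 80.0), records

    def test_projection_matches_ray_sum_oracle(self, phantom):
        """The fast projector agrees with brute-force ray summation."""
        vol, _ = phantom
        img = project_volume(vol, euler_matrix(0.0, 90.0, 0.0))
        # tilt 90, rot 0: ray sum along body -x maps z->img0, y->img1
        oracle = vol.data[::-1, :, :].sum(axis=0).T * vol.voxel_size
        a = img - img.mean()
        b = oracle - oracle.mean()
        corr = (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())
        assert corr > 0.99

    def test_noiseless_reconstruction_matches_phantom(self, phantom):
        vol, lat = phantom
        stack, records = self.make_projection_set(lat, 96)
        full = backproject(stack, records, half_split=False)
        mask = make_tight_mask(vol, threshold=0.1)
        corr = masked_band_correlation(full, vol, mask, cutoff=20.0)
        assert corr >= 0.99

    def test_half_split_by_repeat_parity(self, phantom):
        _, lat = phantom
        stack, records = self.make_projection_set(lat, 24)
        half_a, half_b = backproject(stack, records, half_split=True)
        assert half_a.shape == half_b.shape
        assert not np.array_equal(half_a.data, half_b.data)

    def test_single_view_is_constant_along_projection_axis(self, phantom):
        """Central-slice theorem: one projection constrains nothing along
        its viewing direction, so the volume is smeared along it."""
        _, lat = phantom
        stack, records = self.make_projection_set(lat, 1, tilts=(90.0,))
        vol = backproject(stack, records, half_split=False)
        # viewing direction at rot 0, tilt 90 is the body x axis... the
        # reconstruction along that axis varies much less than across it
        var_along = vol.data.var(axis=0).mean()
        var_total = vol.data.var()
        assert var_along < 0.5 * var_total

    def test_shuffled_records_destroy_lattice_detail(self, phantom):
        """Random orientations still recover the cylindrically averaged
        envelope of a filament, so the negative control is judged on the
        azimuth-dependent (lattice) component of the map."""
        vol, lat = phantom
        stack, records = self.make_projection_set(lat, 48)
        rng = np.random.default_rng(0)
        bad = [AlignmentRecord(rot=float(rng.uniform(0, 360)),
                               tilt=float(rng.uniform(75, 105)), repeat_index=i)
               for i in range(48)]
        good = backproject(stack, records, half_split=False)
        wrong = backproject(stack, bad, half_split=False)

        def deviatoric(v):
            """Band-limited map minus its azimuthal (cylindrical) mean."""
            data = lowpass(v.data, v.voxel_size, 20.0)
            n = data.shape[0]
            c = (n - 1) / 2.0
            x = np.arange(n) - c
            r = np.sqrt(x[:, None] ** 2 + x[None, :] ** 2)
            rbin = np.round(r).astype(int)
            out = data.copy()
            for z in range(data.shape[2]):
                means = np.bincount(rbin.ravel(), data[:, :, z].ravel()) / np.bincount(rbin.ravel())
                out[:, :, z] -= means[rbin]
            return out

        dv = deviatoric(vol)
        dg = deviatoric(good)
        dw = deviatoric(wrong)

        def corr(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())

        assert corr(dg, dv) > 0.7
        assert corr(dw, dv) < 0.3

    def test_empty_half_rejected(self, phantom):
        _, lat = phantom
        stack, records = self.make_projection_set(lat, 4)
        for r in records:
            r.repeat_index = 0  # all even
        with pytest.raises(ValueError, match="half-set"):
            backproject(stack, records, half_split=True)
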