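"""Sample entropy and ALFF mapping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import benpipe as bp
import benpipe.entropy as ent
from benpipe.errors import DataError, DomainError, ParameterError
from benpipe.preprocess import BoldSeries

from _oracles import sampen_bruteforce, sampen_counts_bruteforce


def _series(data, tr=2.0):
    return BoldSeries(
        data=data, voxel_size_mm=[3, 3, 3], tr_s=tr, affine=np.eye(4)
    )


class TestSampleEntropy:
    def test_all_match_series_gives_zero(self):
        # every template pair matches at both lengths -> A/B = 1 -> 0
        rng = np.random.default_rng(0)
        x = 1.0 + 1e-6 * rng.standard_normal(20)
        assert ent.sample_entropy(x, ent.SampEnParams(m=3, r_frac=1e6)) == 0.0

    def test_paper_literal_all_match_normalizers(self):
        # the published normalizers give -ln[(N-m+1)/(N-m-1)] on all-match
        # input: negative entropy, the anomaly that motivates the default
        rng = np.random.default_rng(1)
        n, m = 20, 3
        x = 1.0 + 1e-6 * rng.standard_normal(n)
        got = ent.sample_entropy(
            x, ent.SampEnParams(m=m, r_frac=1e6, normalization="paper_literal")
        )
        assert got == pytest.approx(-math.log((n - m + 1) / (n - m - 1)), abs=1e-12)
        assert got == pytest.approx(-math.log(18 / 16), abs=1e-12)
        assert got < 0

    def test_constant_series_flagged_undefined(self):
        assert math.isnan(ent.sample_entropy(np.ones(30)))

    def test_too_short_series_rejected(self):
        with pytest.raises(ParameterError):
            ent.sample_entropy(np.arange(4.0), ent.SampEnParams(m=3))

    def test_matches_bruteforce_on_seeded_gaussian(self, rng):
        # short series can legitimately have zero (m+1)-matches, in which
        # case both implementations must flag the result as undefined
        for _ in range(10):
            x = rng.standard_normal(20)
            got = ent.sample_entropy(x, ent.SampEnParams(m=3, r_frac=0.6))
            expected = sampen_bruteforce(x, 3, 0.6)
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_counts_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 41))
        m = int(rng.choice([1, 2, 3]))
        r_frac = float(rng.choice([0.2, 0.6, 1.0]))
        x = rng.standard_normal(n)
        b, a, r = ent.sample_entropy_counts(x, ent.SampEnParams(m=m, r_frac=r_frac))
        assert (b, a) == sampen_counts_bruteforce(x, m, r)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            ent.SampEnParams(m=0)
        with pytest.raises(ParameterError):
            ent.SampEnParams(r_frac=0)
        with pytest.raises(ParameterError):
            ent.SampEnParams(normalization="bogus")
        with pytest.raises(ParameterError):
            ent.SampEnParams(distance="euclidean")

    def test_white_noise_entropy_exceeds_ar1(self):
        # monotone discrimination at the study's series length
        params = ent.SampEnParams()
        white, ar = [], []
        for seed in range(50):
            white.append(ent.sample_entropy(bp.synth_voxel_signal(1.0, 0.9, 230, seed), params))
            ar.append(ent.sample_entropy(bp.synth_voxel_signal(0.0, 0.9, 230, seed), params))
        assert np.nanmean(white) > np.nanmean(ar)

    def test_batch_kernels_agree_with_scalar_path(self, rng):
        # the m=3 fast path and the generic batch kernel must produce the
        # same counts as the single-series implementation
        mat = rng.standard_normal((40, 60))
        r = 0.6 * mat.std(axis=1)
        for m, kernel in ((3, "fast"), (2, "generic")):
            b = np.zeros(40, np.int64)
            a = np.zeros(40, np.int64)
            if m == 3:
                ent._sampen_batch_m3(mat, r, b, a)
            else:
                ent._sampen_batch(mat, m, r, b, a)
            for v in range(40):
                bb, aa, _ = ent.sample_entropy_counts(
                    mat[v], ent.SampEnParams(m=m, r_frac=0.6)
                )
                assert (b[v], a[v]) == (bb, aa)


class TestBenMap:
    def test_equals_per_voxel_sample_entropy(self, rng):
        data = rng.standard_normal((4, 4, 3, 40))
        mask = np.zeros((4, 4, 3), dtype=bool)
        mask[1:3, 1:3, 1] = True
        bmap = ent.ben_map(_series(data), mask)
        for idx in zip(*np.nonzero(mask)):
            expected = ent.sample_entropy(data[idx])
            assert bmap.values[idx] == pytest.approx(expected, abs=1e-12)
        assert (bmap.values[~mask] == 0).all()

    def test_constant_volumes_all_undefined(self):
        data = np.ones((4, 4, 3, 30))
        mask = np.ones((4, 4, 3), dtype=bool)
        bmap = ent.ben_map(_series(data), mask)
        assert bmap.qc["n_undefined"] == mask.sum()
        assert not bmap.defined.any()
        assert np.isnan(bmap.values[mask]).all()

    def test_mask_shape_mismatch_rejected(self, rng):
        data = rng.standard_normal((4, 4, 3, 30))
        with pytest.raises(DataError):
            ent.ben_map(_series(data), np.ones((5, 4, 3), dtype=bool))

    def test_planted_group_difference_recovered(self, small_cohort, small_cohort_ben):
        # patients carry a higher white-noise weight in the planted region:
        # the across-subject BEN contrast must be positive at alpha = 0.01
        from scipy import stats as sps

        roi = small_cohort.roi_masks["sma_analog"]
        vals = {"patient": [], "control": []}
        for rec in small_cohort.subjects:
            bmap = small_cohort_ben["maps"][rec.subject_id]
            vals[rec.group].append(np.nanmean(bmap.values[roi]))
        t, p = sps.ttest_ind(vals["patient"], vals["control"], alternative="greater")
        assert p < 0.01

    @pytest.mark.parametrize("r_frac", [0.3, 0.45, 0.6, 0.75])
    def test_planted_contrast_sign_stable_across_r(
        self, r_frac, small_cohort, small_cohort_ben
    ):
        # tolerance-parameter sweep: the direction of the planted group
        # difference must not depend on the match tolerance r
        roi_up = small_cohort.roi_masks["sma_analog"]
        roi_down = small_cohort.roi_masks["phipp_analog"]
        params = ent.SampEnParams(r_frac=r_frac)
        up = {"patient": [], "control": []}
        down = {"patient": [], "control": []}
        for rec in small_cohort.subjects:
            bmap = ent.ben_map(
                small_cohort_ben["preprocessed"][rec.subject_id],
                small_cohort.brain_mask,
                params,
            )
            up[rec.group].append(np.nanmean(bmap.values[roi_up]))
            down[rec.group].append(np.nanmean(bmap.values[roi_down]))
        assert np.mean(up["patient"]) > np.mean(up["control"])
        assert np.mean(down["patient"]) < np.mean(down["control"])

    def test_gm_wm_compartment_contrast(self, small_cohort, small_cohort_ben):
        # the GM shell is generated more irregular than the WM core, so
        # mean BEN must be higher in GM (direction fixed by ground truth)
        gm = small_cohort.tissue_probs["gm"] > 0
        wm = small_cohort.tissue_probs["wm"] > 0
        diffs = []
        for rec in small_cohort.subjects:
            bm = small_cohort_ben["maps"][rec.subject_id].values
            diffs.append(np.nanmean(bm[gm]) - np.nanmean(bm[wm]))
        assert np.mean(diffs) > 0


class TestStandardization:
    def _map(self, rng, shape=(8, 8, 6)):
        mask = np.zeros(shape, dtype=bool)
        mask[1:-1, 1:-1, 1:-1] = True
        values = np.where(mask, rng.standard_normal(shape) + 1.0, 0.0)
        return ent.BenMap(values, mask, ent.SampEnParams())

    def test_zscore_contract(self, rng):
        out = ent.smooth_and_standardize_ben(self._map(rng), 6.0, 3.0, "zscore")
        inside = out.values[out.defined]
        assert abs(inside.mean()) < 1e-8
        assert abs(inside.std() - 1) < 1e-8
        assert out.standardized

    def test_artanh_rejects_out_of_domain(self, rng):
        m = self._map(rng)
        m.values[2, 2, 2] = 1.2
        with pytest.raises(DomainError):
            ent.smooth_and_standardize_ben(m, 0.0, 3.0, "artanh")

    def test_artanh_applies_inside_domain(self, rng):
        m = self._map(rng)
        m.values[m.mask] = np.tanh(m.values[m.mask])  # force into (-1, 1)
        out = ent.smooth_and_standardize_ben(m, 0.0, 3.0, "artanh")
        assert np.allclose(
            out.values[out.defined], np.arctanh(m.values[m.defined]), atol=1e-12
        )

    def test_zero_fwhm_zscore_is_affine(self, rng):
        m = self._map(rng)
        out = ent.smooth_and_standardize_ben(m, 0.0, 3.0, "zscore")
        r = np.corrcoef(out.values[m.mask], m.values[m.mask])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_double_standardization_rejected(self, rng):
        out = ent.smooth_and_standardize_ben(self._map(rng), 0.0, 3.0)
        with pytest.raises(ParameterError):
            ent.smooth_and_standardize_ben(out, 0.0, 3.0)

    def test_undefined_voxels_stay_flagged(self, rng):
        m = self._map(rng)
        m.values[3, 3, 3] = np.nan
        m = ent.BenMap(m.values, m.mask, m.params)
        out = ent.smooth_and_standardize_ben(m, 6.0, 3.0)
        assert not out.defined[3, 3, 3]
        assert np.isfinite(out.values[out.defined]).all()


class TestAlff:
    def test_zero_series_gives_zero(self):
        data = np.zeros((3, 3, 2, 64))
        mask = np.ones((3, 3, 2), dtype=bool)
        amap = ent.alff_map(_series(data), mask)
        assert (amap.values == 0).all()

    def test_unit_sine_on_bin_closed_form(self):
        # |DFT| of sin(2 pi k t / N) at bin k is N/2 under the unnormalized
        # forward transform, so ALFF = N/2 when only that bin is in band
        n, tr = 200, 2.0
        k = 10  # 0.025 Hz
        t = np.arange(n)
        x = np.sin(2 * np.pi * k * t / n)
        data = np.tile(x, (2, 2, 1, 1))
        mask = np.ones((2, 2, 1), dtype=bool)
        amap = ent.alff_map(_series(data, tr), mask, band=(0.01, 0.08))
        assert amap.values[mask] == pytest.approx(n / 2, rel=1e-10)

    def test_white_noise_parseval_bound(self, rng):
        data = rng.standard_normal((4, 4, 2, 100))
        mask = np.ones((4, 4, 2), dtype=bool)
        amap = ent.alff_map(_series(data), mask)
        total = np.sqrt((np.abs(np.fft.rfft(data, axis=3)) ** 2).sum(axis=3))
        assert (amap.values[mask] <= total[mask] + 1e-9).all()
        assert (amap.values[mask] >= 0).all()

    def test_empty_band_rejected(self, rng):
        data = rng.standard_normal((2, 2, 2, 24))
        mask = np.ones((2, 2, 2), dtype=bool)
        with pytest.raises(ParameterError):
            # 24 volumes at TR=2 -> frequency resolution 0.021 Hz; nothing
            # falls inside (0.001, 0.01)
            ent.alff_map(_series(data), mask, band=(0.001, 0.01))

    def test_band_above_nyquist_rejected(self, rng):
        data = rng.standard_normal((2, 2, 2, 50))
        mask = np.ones((2, 2, 2), dtype=bool)
        with pytest.raises(ParameterError):
            ent.alff_map(_series(data), mask, band=(0.01, 0.3))
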