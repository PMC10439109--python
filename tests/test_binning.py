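from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from blink import (
    Spectrum,
    SpectrumSet,
    bin_index,
    blur,
    discretize,
    make_kernel,
    preprocess_set,
)


def exact_bin(mz_str: str, bw_str: str) -> int:
    """Rational-arithmetic floor binning for decimal-literal inputs."""
    return int(Fraction(mz_str) / Fraction(bw_str))


class TestBinIndex:
    @pytest.mark.parametrize(
        "mz,bw,expected",
        [
            (100.0005, 0.001, 100000),  # floor(100000.5)
            (0.0005, 0.001, 0),
            (100.0005, 0.01, exact_bin("100.0005", "0.01")),
        ],
    )
    def test_examples(self, mz, bw, expected):
        assert bin_index(mz, bw) == expected

    @given(
        k=st.integers(min_value=1, max_value=2_000_000),
        bw=st.sampled_from(["0.001", "0.01", "0.0001", "0.005"]),
        half=st.booleans(),
    )
    def test_matches_rational_floor_on_grid(self, k, bw, half):
        # Values intended as exact multiples of the bin width must land in
        # the upper bin; mid-bin values must land in bin k as well.
        frac = Fraction(bw)
        mz_exact = Fraction(k) * frac + (frac / 2 if half else 0)
        mz = float(mz_exact)
        if mz <= 0 or float(k) * float(bw) > 2500:
            return
        assert bin_index(mz, float(bw)) == k

    def test_vectorized_matches_scalar(self):
        mz = np.array([50.0, 100.0005, 1999.9999])
        assert list(bin_index(mz, 0.001)) == [bin_index(v, 0.001) for v in mz]

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            bin_index(-1.0, 0.001)
        with pytest.raises(ValueError):
            bin_index(100.0, 0.0)


class TestKernel:
    @pytest.mark.parametrize(
        "tol,bw,half_width",
        [(0.01, 0.001, 9), (0.002, 0.001, 1), (0.01, 0.0001, 99)],
    )
    def test_half_width(self, tol, bw, half_width):
        k = make_kernel(tol, bw)
        assert k.half_width == half_width
        assert abs(k.effective_tolerance - (tol - bw)) < 1e-12

    def test_bin_width_equal_to_tolerance_gives_identity_kernel(self):
        assert make_kernel(0.01, 0.01).half_width == 0

    def test_bin_width_above_tolerance_rejected(self):
        with pytest.raises(ValueError, match="cannot exceed tolerance"):
            make_kernel(0.01, 0.02)

    def test_linkage_bounds_brute_force(self):
        # Pairs closer than tolerance - bin_width always share a blurred
        # bin; pairs further than tolerance never do.
        tol, bw = 0.01, 0.0001
        k = make_kernel(tol, bw)
        rng = np.random.default_rng(5)
        a = rng.uniform(50, 2000, 20_000)
        d = rng.uniform(0, 3 * tol, 20_000) * rng.choice([-1, 1], 20_000)
        b = np.abs(a + d)
        linked = np.abs(bin_index(a, bw) - bin_index(b, bw)) <= k.half_width
        gap = np.abs(a - b)
        assert linked[gap <= tol - bw].all()
        assert not linked[gap > tol].any()


def one_frag_set(mzs, precursor=2100.0):
    spectra = [
        Spectrum(f"s{i}", precursor, [m], [1.0]) for i, m in enumerate(mzs)
    ]
    return SpectrumSet(spectra)


class TestDiscretize:
    def test_shared_bin_across_spectra(self):
        m = discretize(one_frag_set([100.0005, 100.0009]), 0.001)
        assert m.nnz == 2
        assert m.bins[0] == m.bins[1]
        assert set(m.cols) == {0, 1}

    def test_same_bin_accumulates_at_scoring_not_storage(self):
        s = Spectrum("s", 300.0, [100.0001, 100.0004], [0.3, 0.4])
        m = discretize(SpectrumSet([s]), 0.001)
        assert m.nnz == 2  # entries kept separate; CSR construction sums
        assert np.allclose(sorted(m.intensity), [0.3, 0.4])
        assert m.column_fragment_counts().tolist() == [2]

    def test_precursor_shift_uses_neutral_loss_coordinate(self):
        s = Spectrum("s", 300.0, [100.0], [1.0])
        m = discretize(SpectrumSet([s]), 0.001, shift_mode="precursor")
        assert m.bins[0] == bin_index(200.0, 0.001)

    def test_fixed_shift(self):
        s = Spectrum("s", 300.0, [100.0], [1.0])
        m = discretize(SpectrumSet([s]), 0.001, shift_mode="fixed", shift_delta=14.016)
        assert m.bins[0] == bin_index(114.016, 0.001)

    def test_negative_shifted_fragments_dropped(self):
        s = Spectrum("s", 300.0, [100.0, 200.0], [1.0, 1.0])
        m = discretize(SpectrumSet([s]), 0.001, shift_mode="fixed", shift_delta=-150.0)
        assert m.nnz == 1

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            discretize(SpectrumSet([]), 0.001)


def dense_blur_oracle(values_by_bin: dict[int, float], half_width: int) -> dict[int, float]:
    """Dense convolution with a ones-vector of length 2*half_width + 1."""
    out: dict[int, float] = {}
    for b, v in values_by_bin.items():
        for d in range(-half_width, half_width + 1):
            out[b + d] = out.get(b + d, 0.0) + v
    return out


class TestBlur:
    def test_half_width_zero_is_identity(self):
        m = discretize(one_frag_set([100.0]), 0.01)
        out = blur(m, make_kernel(0.01, 0.01))
        assert out.blurred
        assert np.array_equal(out.bins, m.bins)
        assert np.allclose(out.intensity, m.intensity)

    def test_single_fragment_expands_to_19_bins(self):
        m = discretize(one_frag_set([100.0005]), 0.001)
        out = blur(m, make_kernel(0.01, 0.001))
        assert out.nnz == 19
        assert np.allclose(out.intensity, 1.0)
        assert sorted(out.bins) == list(range(100000 - 9, 100000 + 10))

    def test_overlapping_fragments_match_dense_convolution(self):
        s = Spectrum("s", 300.0, [100.000, 100.005], [0.6, 0.8])
        m = discretize(SpectrumSet([s]), 0.001)
        out = blur(m, make_kernel(0.01, 0.001))
        sparse = {}
        for b, v in zip(out.bins, out.intensity):
            sparse[b] = sparse.get(b, 0.0) + v
        dense = dense_blur_oracle(dict(zip(m.bins.tolist(), m.intensity.tolist())), 9)
        assert sparse.keys() == dense.keys()
        for b in dense:
            assert abs(sparse[b] - dense[b]) < 1e-12

    @given(tol=st.sampled_from([0.002, 0.01, 0.02]), seed=st.integers(0, 50))
    def test_conservation_and_permutation_invariance(self, tol, seed):
        from blink import random_library

        lib = random_library(6, (3, 8), (50.0, 500.0), seed=seed)
        lib, _ = preprocess_set(lib)
        m = discretize(lib, 0.001)
        k = make_kernel(tol, 0.001)
        out = blur(m, k)
        assert abs(out.total_intensity() - k.width * m.total_intensity()) < 1e-9
        # column permutation of spectra commutes with blur
        perm = list(reversed(range(len(lib))))
        m2 = discretize(lib.subset(perm), 0.001)
        out2 = blur(m2, k)
        assert abs(out2.total_intensity() - out.total_intensity()) < 1e-9

    def test_double_blur_rejected(self):
        m = discretize(one_frag_set([100.0]), 0.001)
        out = blur(m, make_kernel(0.01, 0.001))
        with pytest.raises(ValueError, match="already blurred"):
            blur(out, make_kernel(0.01, 0.001))

    def test_bin_width_mismatch_rejected(self):
        m = discretize(one_frag_set([100.0]), 0.001)
        with pytest.raises(ValueError, match="bin_width"):
            blur(m, make_kernel(0.01, 0.002))
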