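import numpy as np
import pytest
from scipy import stats

from lphist.pattern_histogram import PatternHistogram, normalize
from lphist.distances import (
    DistanceMatrix,
    bd_distance,
    distance_matrix,
    hi_distance,
    js_divergence,
    kendall_tau_distance,
    kendall_tau_stats,
    matrix_correlation,
    md_distance,
    read_phylip,
    write_matrix_tsv,
    write_phylip,
)

from oracles import random_histogram


def hist_from(freqs: dict[int, float]) -> PatternHistogram:
    """Build a normalized histogram with the given exact frequencies."""
    scale = 1000
    counts = {s: round(f * scale) for s, f in freqs.items() if f > 0}
    return normalize(PatternHistogram(counts=counts))


P_HALF = hist_from({1: 0.5, 2: 0.5})
Q_HALF = hist_from({1: 0.5, 3: 0.5})
P_ONE = hist_from({1: 1.0})
Q_SPLIT = hist_from({1: 0.5, 2: 0.5})
DISJOINT_A = hist_from({1: 0.5, 2: 0.5})
DISJOINT_B = hist_from({3: 0.5, 4: 0.5})


class TestElementaryDistances:
    @pytest.mark.parametrize(
        "func", [hi_distance, md_distance, bd_distance, js_divergence]
    )
    def test_zero_on_identical(self, func, rng):
        h = random_histogram(rng)
        assert func(h, h) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "func, expected",
        [(hi_distance, 1.0), (md_distance, 2.0), (js_divergence, 1.0)],
    )
    def test_disjoint_supports(self, func, expected):
        assert func(DISJOINT_A, DISJOINT_B) == pytest.approx(expected)

    def test_bd_disjoint_is_infinite(self):
        assert bd_distance(DISJOINT_A, DISJOINT_B) == float("inf")

    def test_hi_half_overlap(self):
        assert hi_distance(P_HALF, Q_HALF) == pytest.approx(0.5)

    def test_md_half_overlap(self):
        assert md_distance(P_HALF, Q_HALF) == pytest.approx(1.0)

    def test_bd_point_vs_split(self):
        assert bd_distance(P_ONE, Q_SPLIT) == pytest.approx(-np.log(np.sqrt(0.5)))

    def test_js_point_vs_split(self):
        assert js_divergence(P_ONE, Q_SPLIT) == pytest.approx(0.311278, abs=1e-6)

    def test_unnormalized_input_rejected(self):
        raw = PatternHistogram(counts={1: 1})
        with pytest.raises(ValueError, match="normalized"):
            hi_distance(raw, raw)

    def test_symmetry(self, rng):
        for func in (hi_distance, md_distance, bd_distance, js_divergence,
                     kendall_tau_distance):
            a, b = random_histogram(rng), random_histogram(rng)
            assert func(a, b) == pytest.approx(func(b, a))

    def test_hi_equals_half_md(self, rng):
        for _ in range(50):
            a, b = random_histogram(rng), random_histogram(rng)
            assert abs(hi_distance(a, b) - md_distance(a, b) / 2) < 1e-12

    def test_md_triangle_inequality(self, rng):
        for _ in range(50):
            a, b, c = (random_histogram(rng) for _ in range(3))
            assert md_distance(a, c) <= md_distance(a, b) + md_distance(b, c) + 1e-12

    def test_js_bounded_and_one_iff_disjoint(self, rng):
        for _ in range(50):
            a, b = random_histogram(rng), random_histogram(rng)
            d = js_divergence(a, b)
            assert 0.0 <= d <= 1.0 + 1e-12
            disjoint = not (set(a.frequencies) & set(b.frequencies))
            assert (d > 1.0 - 1e-9) == disjoint


class TestKendallTau:
    def test_identical_distinct_ranks(self):
        h = hist_from({1: 0.1, 2: 0.2, 3: 0.3, 4: 0.4})
        assert kendall_tau_distance(h, h) == pytest.approx(0.0)

    def test_reversed_ranks(self):
        # support confined to the same serials, opposite order, no ties
        p = np.array([0.1, 0.2, 0.3, 0.4])
        q = np.array([0.4, 0.3, 0.2, 0.1])
        X, Y, r, s = kendall_tau_stats(p, q)
        assert (X, Y, r, s) == (0, 6, 0, 0)
        tau = (X - Y) / np.sqrt((X + Y + r) * (X + Y + s))
        assert (1 - tau) / 2 == pytest.approx(1.0)

    def test_hand_enumerated_example(self):
        # all 6 pairs of the 4-element vectors: 5 concordant, 1 discordant
        p = np.array([0.1, 0.2, 0.3, 0.4])
        q = np.array([0.1, 0.3, 0.2, 0.4])
        assert kendall_tau_stats(p, q) == (5, 1, 0, 0)
        tau = (5 - 1) / np.sqrt(6 * 6)
        assert (1 - tau) / 2 == pytest.approx(1 / 6, abs=1e-12)

    def test_histogram_tau_matches_scipy_on_full_serial_range(self):
        # over serials 1..511 the zero-zero pairs are doubly tied and drop
        # out, but zero-vs-support pairs still count, exactly as tau-b does
        h1 = hist_from({1: 0.1, 2: 0.2, 3: 0.3, 4: 0.4})
        h2 = hist_from({1: 0.1, 2: 0.3, 3: 0.2, 4: 0.4})
        p = np.zeros(511)
        q = np.zeros(511)
        p[:4] = [0.1, 0.2, 0.3, 0.4]
        q[:4] = [0.1, 0.3, 0.2, 0.4]
        ref = stats.kendalltau(p, q, variant="b").statistic
        assert kendall_tau_distance(h1, h2) == pytest.approx(
            (1 - ref) / 2, abs=1e-12
        )

    def test_all_pairs_tied_rejected(self):
        # uniform support over every serial makes both vectors constant,
        # so every pair is doubly tied
        h = normalize(PatternHistogram(counts={s: 1 for s in range(1, 512)}))
        with pytest.raises(ValueError, match="tied"):
            kendall_tau_distance(h, h)

    def test_matches_scipy_tau_b(self, rng):
        for _ in range(20):
            # coarse frequencies to force plenty of ties
            a = rng.integers(0, 4, size=30).astype(float)
            b = rng.integers(0, 4, size=30).astype(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            X, Y, r, s = kendall_tau_stats(a, b)
            tau = (X - Y) / np.sqrt((X + Y + r) * (X + Y + s))
            ref = stats.kendalltau(a, b, variant="b").statistic
            assert tau == pytest.approx(ref, abs=1e-12)


class TestDistanceMatrix:
    def test_identical_histograms_zero_matrix(self, rng):
        h = random_histogram(rng)
        m = distance_matrix({"a": h, "b": h}, "HI")
        assert np.allclose(m.values, 0.0)

    def test_symmetric_zero_diagonal(self, rng):
        hists = {f"t{k}": random_histogram(rng) for k in range(4)}
        for measure in ("HI", "MD", "JS", "TAU"):
            m = distance_matrix(hists, measure)
            assert np.allclose(m.values, m.values.T)
            assert np.allclose(np.diag(m.values), 0.0)

    def test_hi_matrix_is_half_md_matrix(self, rng):
        hists = {f"t{k}": random_histogram(rng) for k in range(3)}
        hi = distance_matrix(hists, "HI")
        md = distance_matrix(hists, "MD")
        assert np.allclose(hi.values, md.values / 2, atol=1e-12)

    def test_bd_infinite_entry_names_pair(self):
        with pytest.raises(ValueError, match="'a'.*'b'"):
            distance_matrix({"a": DISJOINT_A, "b": DISJOINT_B}, "BD")

    def test_unknown_measure(self, rng):
        h = random_histogram(rng)
        with pytest.raises(ValueError, match="unknown measure"):
            distance_matrix({"a": h, "b": h}, "EMD")

    def test_needs_two_histograms(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            distance_matrix({"a": random_histogram(rng)}, "HI")


class TestMatrixCorrelation:
    def _matrix(self, values, measure="HI"):
        return DistanceMatrix(labels=("a", "b", "c"), values=values, measure=measure)

    def test_self_correlation_is_one(self, rng):
        hists = {f"t{k}": random_histogram(rng) for k in range(4)}
        m = distance_matrix(hists, "HI")
        assert matrix_correlation(m, m) == pytest.approx(1.0)

    def test_scale_invariance(self):
        v = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        assert matrix_correlation(
            self._matrix(v), self._matrix(2 * v, "MD")
        ) == pytest.approx(1.0)

    def test_affine_reversal(self):
        v = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        w = np.max(v) - v
        np.fill_diagonal(w, 0.0)
        assert matrix_correlation(
            self._matrix(v), self._matrix(w, "MD")
        ) == pytest.approx(-1.0)

    def test_label_mismatch(self):
        v = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        m1 = self._matrix(v)
        m2 = DistanceMatrix(labels=("a", "b", "d"), values=v, measure="HI")
        with pytest.raises(ValueError, match="labels"):
            matrix_correlation(m1, m2)

    def test_constant_matrix_rejected(self):
        v = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="constant"):
            matrix_correlation(self._matrix(v), self._matrix(v))


def test_phylip_round_trip(tmp_path, rng):
    hists = {f"taxon_{k}": random_histogram(rng) for k in range(4)}
    m = distance_matrix(hists, "HI")
    path = tmp_path / "m.phylip"
    write_phylip(m, path)
    back = read_phylip(path, measure="HI")
    assert back.labels == m.labels
    assert np.allclose(back.values, m.values, atol=1e-9)
    write_matrix_tsv(m, tmp_path / "m.tsv")
    header = (tmp_path / "m.tsv").read_text().splitlines()[0]
    assert header.split("\t")[1:] == list(m.labels)
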