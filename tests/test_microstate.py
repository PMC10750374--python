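import numpy as np
import pytest

from mstate_ri.errors import (
    DimensionError,
    EmptyResultError,
    InvalidParameterError,
    UndefinedStatisticError,
)
from mstate_ri.io_preprocess import Recording
from mstate_ri.microstate import (
    LabelSequence,
    TemplateSet,
    aahc_cluster,
    align_to_reference,
    backfit,
    choose_k,
    find_gfp_peaks,
    gfp,
    GfpSeries,
    microstate_metrics,
    modified_kmeans,
    spatial_correlation,
    transition_probabilities,
)
from mstate_ri.montage import standard_montage

from conftest import unit_maps


def _frame_rec(frame, fs=500.0):
    frame = np.asarray(frame, float)[:, None]
    mon = standard_montage(len(frame))
    return Recording(np.tile(frame, (1, 4)), fs, mon)


# ---------------------------------------------------------------------------
# GFP

def test_gfp_zero_frame():
    assert gfp(_frame_rec([0, 0, 0, 0])).values[0] == 0.0


def test_gfp_alternating_frame():
    np.testing.assert_allclose(gfp(_frame_rec([1, -1, 1, -1])).values[0], 1.0,
                               atol=1e-12)


def test_gfp_single_active_channel():
    # (2,0,0,0): mean 0.5, deviations (1.5,-.5,-.5,-.5) -> sqrt(3/4)
    np.testing.assert_allclose(gfp(_frame_rec([2, 0, 0, 0])).values[0],
                               np.sqrt(0.75), atol=1e-12)


def test_gfp_reference_independent():
    rec = _frame_rec([3, 1, 4, 1])
    shifted = Recording(rec.data + 10.0, rec.fs_hz, rec.montage)
    np.testing.assert_allclose(gfp(rec).values, gfp(shifted).values,
                               atol=1e-12)


# ---------------------------------------------------------------------------
# peaks

def test_peaks_monotone_series_empty():
    g = GfpSeries(np.arange(10.0), 500.0)
    assert find_gfp_peaks(g, min_separation_ms=0).size == 0


def test_peaks_simple_series():
    g = GfpSeries(np.array([0.0, 1.0, 0.0, 2.0, 0.0]), 500.0)
    assert list(find_gfp_peaks(g, min_separation_ms=0)) == [1, 3]


def test_peaks_min_separation_keeps_larger():
    g = GfpSeries(np.array([0, 1.0, 0.5, 2.0, 0, 0, 0, 0, 0, 0]), 1000.0)
    peaks = find_gfp_peaks(g, min_separation_ms=5.0)
    assert list(peaks) == [3]


def test_peaks_rectified_envelope_count(clean_render):
    srec, cfg = clean_render
    peaks = find_gfp_peaks(gfp(srec.recording))
    # 5 Hz rectified envelope -> 10 maxima/s over 10 s
    assert abs(len(peaks) - 100) <= 2


# ---------------------------------------------------------------------------
# spatial correlation

def test_spatial_correlation_self():
    u = np.array([1.0, 2.0, -3.0, 0.5])
    assert spatial_correlation(u, u) == pytest.approx(1.0)


def test_spatial_correlation_polarity():
    u = np.array([1.0, 2.0, -3.0, 0.5])
    assert spatial_correlation(u, -u) == pytest.approx(1.0)
    assert spatial_correlation(u, -u, ignore_polarity=False) == pytest.approx(-1.0)


def test_spatial_correlation_orthogonal():
    a = np.array([1.0, -1.0, 0.0, 0.0])
    b = np.array([0.0, 0.0, 1.0, -1.0])
    assert spatial_correlation(a, b) == pytest.approx(0.0, abs=1e-12)


def test_spatial_correlation_zero_variance_errors():
    with pytest.raises(UndefinedStatisticError):
        spatial_correlation(np.ones(4), np.array([1.0, 2.0, 3.0, 4.0]))


def test_spatial_correlation_shape_mismatch():
    with pytest.raises(DimensionError):
        spatial_correlation(np.ones(4), np.ones(5))


# ---------------------------------------------------------------------------
# AAHC / k-means

@pytest.fixture(scope="module")
def copies_of_orthogonal_templates():
    rng = np.random.default_rng(0)
    base = np.linalg.qr(rng.standard_normal((8, 8)))[0][:4]
    base = unit_maps(base)
    maps = np.repeat(base, 10, axis=0)
    return base, maps


def test_aahc_exact_recovery(copies_of_orthogonal_templates):
    base, maps = copies_of_orthogonal_templates
    ts = aahc_cluster(maps, 4)
    corr = np.abs(unit_maps(ts.maps) @ base.T)
    # each true template recovered by exactly one cluster with |r| = 1
    assert np.allclose(np.sort(corr.max(axis=0)), 1.0, atol=1e-9)
    assert ts.explained_variance == pytest.approx(1.0, abs=1e-9)


def test_aahc_polarity_invariance(copies_of_orthogonal_templates):
    base, maps = copies_of_orthogonal_templates
    rng = np.random.default_rng(3)
    signs = rng.choice([-1.0, 1.0], size=len(maps))
    ts1 = aahc_cluster(maps, 4)
    ts2 = aahc_cluster(maps * signs[:, None], 4)
    corr = np.abs(unit_maps(ts1.maps) @ unit_maps(ts2.maps).T)
    assert np.allclose(np.sort(corr.max(axis=0)), 1.0, atol=1e-9)


def test_aahc_k_too_large(copies_of_orthogonal_templates):
    _, maps = copies_of_orthogonal_templates
    with pytest.raises(InvalidParameterError):
        aahc_cluster(maps, len(maps) + 1)


def test_kmeans_exact_recovery(copies_of_orthogonal_templates):
    base, maps = copies_of_orthogonal_templates
    ts = modified_kmeans(maps, 4, seed=0)
    corr = np.abs(unit_maps(ts.maps) @ base.T)
    assert np.allclose(np.sort(corr.max(axis=0)), 1.0, atol=1e-9)


def test_kmeans_seed_reproducible(copies_of_orthogonal_templates):
    _, maps = copies_of_orthogonal_templates
    a = modified_kmeans(maps, 4, seed=5)
    b = modified_kmeans(maps, 4, seed=5)
    np.testing.assert_array_equal(a.maps, b.maps)


def test_aahc_and_kmeans_agree_on_synthetic(noisy_render):
    srec, _ = noisy_render
    from mstate_ri.microstate import gfp_peak_maps

    maps, gfps = gfp_peak_maps(srec.recording, max_maps=800)
    a = aahc_cluster(maps, 4, gfps)
    k = modified_kmeans(maps, 4, gfps=gfps, seed=0)
    corr = np.abs(unit_maps(a.maps) @ unit_maps(k.maps).T)
    assert (corr.max(axis=0) >= 0.90).all()


def test_choose_k_narrow_range_errors():
    rng = np.random.default_rng(0)
    with pytest.raises(InvalidParameterError):
        choose_k(rng.standard_normal((50, 20)), (4, 4))


def test_choose_k_white_noise_low_confidence():
    rng = np.random.default_rng(0)
    sel = choose_k(rng.standard_normal((300, 30)), (2, 8))
    assert sel.low_confidence


# ---------------------------------------------------------------------------
# back-fitting

def test_backfit_noise_free_perfect(clean_render, templates4):
    srec, _ = clean_render
    fitted = backfit(srec.recording, templates4)
    peaks = find_gfp_peaks(gfp(srec.recording))
    assert np.array_equal(fitted.labels[peaks], srec.truth_labels.labels[peaks])


def test_backfit_sign_flip_invariant(clean_render, templates4):
    srec, _ = clean_render
    rec = srec.recording
    flipped = Recording(-rec.data, rec.fs_hz, rec.montage)
    a = backfit(rec, templates4)
    b = backfit(flipped, templates4)
    np.testing.assert_array_equal(a.labels, b.labels)


def test_backfit_scale_invariant(noisy_render, templates4):
    srec, _ = noisy_render
    rec = srec.recording
    scaled = Recording(rec.data * 7.3, rec.fs_hz, rec.montage)
    a = backfit(rec, templates4)
    b = backfit(scaled, templates4)
    np.testing.assert_array_equal(a.labels, b.labels)


def test_backfit_channel_mismatch(templates4):
    mon = standard_montage(19)
    rec = Recording(np.random.default_rng(0).standard_normal((19, 100)),
                    512.0, mon)
    with pytest.raises(DimensionError):
        backfit(rec, templates4)


def test_backfit_nearest_neighbor_tie_goes_earlier():
    # two peaks at samples 1 and 5 with distinct best templates; sample 3
    # is equidistant and must take peak 1's label
    maps = np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
    ts = TemplateSet(unit_maps(maps), ("A", "B"))
    frames = np.zeros((3, 7))
    frames[:, 1] = maps[0] * 2
    frames[:, 5] = maps[1] * 2
    rec = Recording(frames, 500.0, standard_montage(3))
    fitted = backfit(rec, ts, min_separation_ms=0.0)
    assert fitted.labels[1] == 0 and fitted.labels[5] == 1
    assert fitted.labels[3] == 0  # tie -> earlier peak
    assert fitted.labels[0] == 0 and fitted.labels[6] == 1


# ---------------------------------------------------------------------------
# metrics and transitions: hand oracles

def test_metrics_hand_example():
    seq = LabelSequence(np.array([0, 0, 0, 1, 1]), 500.0, 2)
    m = microstate_metrics(seq)
    assert m.duration_ms[0] == pytest.approx(6.0)
    assert m.duration_ms[1] == pytest.approx(4.0)
    assert m.coverage[0] == pytest.approx(0.6)
    assert m.coverage[1] == pytest.approx(0.4)
    assert m.occurrence_per_s[0] == pytest.approx(100.0)
    assert m.occurrence_per_s[1] == pytest.approx(100.0)


def test_metrics_single_state():
    fs, n = 500.0, 1000
    seq = LabelSequence(np.zeros(n, dtype=int), fs, 1)
    m = microstate_metrics(seq)
    t = n / fs
    assert m.coverage[0] == pytest.approx(1.0)
    assert m.duration_ms[0] == pytest.approx(t * 1000)
    assert m.occurrence_per_s[0] == pytest.approx(1 / t)


def test_transitions_hand_example():
    # runs A,B,A,C -> P(A->B)=P(A->C)=0.5, P(B->A)=1, C row zero
    seq = LabelSequence(np.array([0, 0, 1, 0, 0, 2]), 500.0, 3)
    p = transition_probabilities(seq)
    assert p[0, 1] == pytest.approx(0.5)
    assert p[0, 2] == pytest.approx(0.5)
    assert p[1, 0] == pytest.approx(1.0)
    assert p[2].sum() == 0.0
    assert np.all(np.diag(p) == 0)


def test_transitions_alternating():
    seq = LabelSequence(np.array([0, 1] * 10), 500.0, 2)
    p = transition_probabilities(seq)
    assert p[0, 1] == pytest.approx(1.0)
    assert p[1, 0] == pytest.approx(1.0)


def test_transitions_single_run_warns(caplog):
    seq = LabelSequence(np.zeros(10, dtype=int), 500.0, 2)
    with caplog.at_level("WARNING"):
        p = transition_probabilities(seq)
    assert p.sum() == 0.0


# ---------------------------------------------------------------------------
# brute-force oracle equivalence (the metrics/transition dual route)

def oracle_metrics(labels, fs, k):
    """Definitional re-computation from explicit runs."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[i - 1]:
            runs.append((labels[start], i - start))
            start = i
    total = len(labels)
    out = {}
    for s in range(k):
        lens = [ln for st, ln in runs if st == s]
        dur = np.mean(lens) * 1000 / fs if lens else np.nan
        occ = len(lens) / (total / fs)
        cov = sum(lens) / total
        out[s] = (dur, occ, cov)
    trans = np.zeros((k, k))
    for (a, _), (b, _) in zip(runs[:-1], runs[1:]):
        trans[a, b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = trans.sum(axis=1, keepdims=True)
        probs = np.where(rs > 0, trans / rs, 0.0)
    return out, probs


def test_oracle_equivalence_random_sequences():
    rng = np.random.default_rng(12)
    for _ in range(1000):
        k = int(rng.integers(2, 5))
        n = int(rng.integers(2, 60))
        labels = rng.integers(0, k, size=n)
        seq = LabelSequence(labels, 250.0, k)
        m = microstate_metrics(seq)
        p = transition_probabilities(seq)
        om, op = oracle_metrics(labels, 250.0, k)
        for s in range(k):
            dur, occ, cov = om[s]
            if np.isnan(dur):
                assert np.isnan(m.duration_ms[s])
            else:
                assert m.duration_ms[s] == pytest.approx(dur)
            assert m.occurrence_per_s[s] == pytest.approx(occ)
            assert m.coverage[s] == pytest.approx(cov)
        np.testing.assert_allclose(p, op, atol=1e-12)
        rows = p.sum(axis=1)
        assert np.all((np.abs(rows - 1) < 1e-9) | (rows == 0))
        assert m.coverage.sum() == pytest.approx(1.0, abs=1e-9)


def test_coverage_occurrence_duration_identity():
    rng = np.random.default_rng(5)
    labels = rng.integers(0, 4, size=5000)
    seq = LabelSequence(labels, 500.0, 4)
    m = microstate_metrics(seq)
    recon = m.occurrence_per_s * m.duration_ms / 1000.0
    np.testing.assert_allclose(recon, m.coverage, rtol=0.02)


# ---------------------------------------------------------------------------
# global invariances

def test_global_polarity_invariance(noisy_render, templates4):
    srec, _ = noisy_render
    rec = srec.recording
    neg = Recording(-rec.data, rec.fs_hz, rec.montage)
    np.testing.assert_allclose(gfp(rec).values, gfp(neg).values, atol=1e-12)
    a = backfit(rec, templates4)
    b = backfit(neg, templates4)
    np.testing.assert_array_equal(a.labels, b.labels)
    pa = transition_probabilities(a)
    pb = transition_probabilities(b)
    np.testing.assert_array_equal(pa, pb)


def test_align_to_reference_permutes_labels(templates4):
    perm = np.array([2, 0, 3, 1])
    shuffled = TemplateSet(templates4.maps[perm] * -1.0,
                           ("A", "B", "C", "D"))
    aligned = align_to_reference(shuffled, templates4)
    corr = np.abs(unit_maps(aligned.maps) @ unit_maps(templates4.maps).T)
    np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-9)
    assert aligned.class_labels == templates4.class_labels


def test_empty_labels_error():
    with pytest.raises(EmptyResultError):
        microstate_metrics(LabelSequence(np.array([], dtype=int), 500.0, 2))
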