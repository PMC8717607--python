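import numpy as np
import pytest

from mudia.acquisition import SpectrumScan, build_window_scheme
from mudia.xic import (BinnedRun, extract_ms2_chromatogram, fit_rt_model,
                       normalize_intensities_local, pick_reference_run,
                       transfer_ids)


class FakeIon:
    """Stub peptide ion with prescribed fragment m/z values."""

    def __init__(self, fragment_mz, precursor_mz=436.0):
        self._mz = np.asarray(fragment_mz, float)
        self.precursor_mz = precursor_mz
        self.ion_id = "FAKE/2"

    def fragment_mz_array(self, min_mz=0.0, max_mz=np.inf):
        return self._mz[(self._mz >= min_mz) & (self._mz <= max_mz)]


def _binned(scan_defs, scheme=None):
    """Build a BinnedRun from (rt, {mz: intensity}) tuples in one bin."""
    scheme = scheme or build_window_scheme(436, 436, 8, 12)
    scans = []
    for rt, peaks in scan_defs:
        mz = np.array(sorted(peaks))
        scans.append(SpectrumScan(2, rt, mz,
                                  np.array([peaks[m] for m in sorted(peaks)]),
                                  window=(436.0, 4.0), cycle_index=0,
                                  bin_index=0))
    return BinnedRun(scans, scheme, run_id="r1")


F1, F2, F3, F4 = 400.0, 500.0, 600.0, 700.0


class TestExtract:
    def test_worked_example_coelution_and_five_scan_sum(self):
        # f1/f2 co-elute around RT 106; f3 peaks elsewhere (RT 160) and is
        # dropped by the 70%/+/-20 s rule.
        rts = [100, 103, 106, 109, 112]
        f1 = [10, 50, 100, 40, 20]
        f2 = [5, 25, 50, 20, 10]
        scans = [(rt, {F1: a, F2: b}) for rt, a, b in zip(rts, f1, f2)]
        scans.append((160.0, {F3: 200.0}))
        run = _binned(scans)
        ion = FakeIon([F1, F2, F3])
        chrom = extract_ms2_chromatogram(ion, run, rt_center=106.0,
                                         min_fragments=2)
        assert chrom.apex_rt == 106.0
        assert chrom.n_fragments_retained == 2
        assert chrom.summed_intensity == pytest.approx(330.0)
        # with the >=4-fragment quantification floor the peptide is dropped
        assert extract_ms2_chromatogram(ion, run, rt_center=106.0) is None

    def test_four_constant_fragments_quantifiable(self):
        scans = [(100 + 3 * i, {F1: 10.0, F2: 10.0, F3: 10.0, F4: 10.0})
                 for i in range(5)]
        chrom = extract_ms2_chromatogram(FakeIon([F1, F2, F3, F4]),
                                         _binned(scans), rt_center=106.0)
        assert chrom.n_fragments_retained == 4
        assert chrom.summed_intensity == pytest.approx(4 * 10 * 5)

    def test_apex_at_boundary_truncates_summation(self):
        # decreasing signal puts the apex on the first scan: 3-scan sum
        scans = [(100 + 3 * i, {F1: v, F2: v, F3: v, F4: v})
                 for i, v in enumerate([100.0, 50.0, 25.0, 12.0, 6.0])]
        chrom = extract_ms2_chromatogram(FakeIon([F1, F2, F3, F4]),
                                         _binned(scans), rt_center=100.0)
        assert chrom.apex_index == 0
        assert chrom.summed_intensity == pytest.approx(4 * (100 + 50 + 25))

    def test_no_scans_in_bin_returns_none(self):
        run = _binned([(100.0, {F1: 1.0})])
        ion = FakeIon([F1], precursor_mz=900.0)  # outside the single window
        assert extract_ms2_chromatogram(ion, run, rt_center=100.0) is None

    def test_fragments_below_300_excluded(self):
        scans = [(100 + 3 * i, {250.0: 10.0, F1: 10.0, F2: 10.0, F3: 10.0})
                 for i in range(5)]
        chrom = extract_ms2_chromatogram(FakeIon([250.0, F1, F2, F3]),
                                         _binned(scans), rt_center=106.0,
                                         min_fragments=3)
        assert 250.0 not in chrom.fragment_mz
        assert chrom.n_fragments_retained == 3

    def test_matches_brute_force_oracle_on_randomized_fixtures(self):
        rng = np.random.default_rng(42)
        frag_mz = np.array([350.0, 450.0, 560.0, 640.0, 720.0, 810.0])
        for trial in range(100):
            n_scans = int(rng.integers(5, 15))
            rts = np.sort(rng.uniform(50, 200, size=n_scans))
            traces = rng.uniform(0, 100, size=(6, n_scans))
            traces[rng.uniform(size=traces.shape) < 0.3] = 0.0
            scans = [(rts[s], {m: traces[f, s] for f, m in enumerate(frag_mz)
                               if traces[f, s] > 0}) for s in range(n_scans)]
            rt_center = float(rng.uniform(60, 190))
            min_frag = int(rng.integers(1, 5))
            chrom = extract_ms2_chromatogram(
                FakeIon(frag_mz), _binned(scans), rt_center=rt_center,
                min_fragments=min_frag)
            oracle = _oracle(frag_mz, rts, traces, rt_center, min_frag)
            if oracle is None:
                assert chrom is None
            else:
                apex, kept, total = oracle
                assert chrom is not None
                assert chrom.apex_index == apex
                assert chrom.n_fragments_retained == len(kept)
                assert chrom.summed_intensity == pytest.approx(total, rel=1e-12)


def _oracle(frag_mz, rts, traces, rt_center, min_fragments,
            halfwidth=20.0, frac=0.7):
    """Brute-force restatement of the co-elution and five-scan-sum rules."""
    candidates = [s for s in range(len(rts)) if abs(rts[s] - rt_center) <= halfwidth]
    if not candidates:
        return None
    sums = {s: sum(traces[f][s] for f in range(len(frag_mz))) for s in candidates}
    apex = min(candidates,
               key=lambda s: (-sums[s], abs(rts[s] - rt_center), s))
    if sums[apex] <= 0:
        return None
    kept = []
    for f in range(len(frag_mz)):
        gmax = max(traces[f])
        if gmax <= 0:
            continue
        ok = any(traces[f][s] > frac * gmax
                 for s in range(len(rts))
                 if abs(rts[s] - rts[apex]) <= halfwidth)
        if ok:
            kept.append(f)
    if len(kept) < min_fragments:
        return None
    window = range(max(apex - 2, 0), min(apex + 2, len(rts) - 1) + 1)
    total = sum(traces[f][s] for f in kept for s in window)
    return apex, kept, total


class TestRTModel:
    def test_identity_anchors_give_identity_map(self):
        anchors = [(10.0 * i, 10.0 * i) for i in range(20)]
        model = fit_rt_model(anchors)
        assert model.residual_scale == pytest.approx(0.0, abs=1e-9)
        assert model.predict(95.0) == pytest.approx(95.0)

    def test_constant_shift_recovered(self):
        anchors = [(10.0 * i, 10.0 * i + 5.0) for i in range(20)]
        model = fit_rt_model(anchors)
        assert model.predict(95.0) == pytest.approx(100.0)
        assert model.residual_scale == pytest.approx(0.0, abs=1e-9)

    def test_monotone_mapping(self):
        rng = np.random.default_rng(0)
        anchors = [(t, t + rng.normal(0, 5)) for t in np.linspace(0, 300, 60)]
        model = fit_rt_model(anchors)
        xs = np.linspace(0, 300, 301)
        assert (np.diff(model.predict(xs)) >= 0).all()

    def test_gaussian_jitter_residual_scale(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            anchors = [(t, t + rng.normal(0, 2.0))
                       for t in np.linspace(10, 290, 40)]
            model = fit_rt_model(anchors)
            assert model.residual_scale <= 3.0

    def test_too_few_anchors_falls_back_to_identity(self, caplog):
        with caplog.at_level("WARNING"):
            model = fit_rt_model([(1.0, 5.0)] * 3)
        assert model.identity
        assert model.predict(42.0) == 42.0


class TestTransfer:
    def test_identity_transfer_equals_direct_extraction(self):
        scans = [(100 + 3 * i, {F1: 10.0, F2: 20.0, F3: 30.0, F4: 40.0})
                 for i in range(7)]
        run = _binned(scans)
        ion = FakeIon([F1, F2, F3, F4])
        model = fit_rt_model([(10.0 * i, 10.0 * i) for i in range(20)])
        direct = extract_ms2_chromatogram(ion, run, rt_center=109.0)
        moved = transfer_ids(ion, run, model, reference_rt=109.0)
        assert moved.source == "transferred"
        assert moved.summed_intensity == direct.summed_intensity
        assert moved.apex_rt == direct.apex_rt

    def test_prediction_outside_gradient_returns_none(self):
        run = _binned([(100.0, {F1: 1.0, F2: 1.0, F3: 1.0, F4: 1.0})])
        ion = FakeIon([F1, F2, F3, F4])
        model = fit_rt_model([(10.0 * i, 10.0 * i) for i in range(20)])
        assert transfer_ids(ion, run, model, reference_rt=500.0) is None


class TestNormalize:
    def test_global_factor_removed_exactly(self):
        ref = {f"p{i}": (10.0 * i, 100.0 + i) for i in range(30)}
        run = {k: (rt, 2.0 * v) for k, (rt, v) in ref.items()}
        out = normalize_intensities_local({"ref": ref, "r": run}, "ref")
        for k in ref:
            assert out["r"][k] == pytest.approx(ref[k][1], rel=1e-12)

    def test_reference_unchanged(self):
        ref = {f"p{i}": (10.0 * i, 50.0) for i in range(10)}
        out = normalize_intensities_local({"ref": ref}, "ref")
        assert out["ref"] == {k: v[1] for k, v in ref.items()}

    def test_two_regime_scale_corrected(self):
        rng = np.random.default_rng(1)
        ref = {f"p{i}": (float(rng.uniform(0, 300)), float(rng.uniform(50, 150)))
               for i in range(200)}
        run = {k: (rt, v * (2.0 if rt < 150 else 1.0))
               for k, (rt, v) in ref.items()}
        out = normalize_intensities_local({"ref": ref, "r": run}, "ref",
                                          rt_window=60.0)
        ratios = np.array([out["r"][k] / ref[k][1] for k in ref
                           if not 130 < ref[k][0] < 170])
        assert np.median(np.abs(np.log2(ratios))) < 0.1

    def test_reference_pick_most_identified_with_tie_break(self):
        assert pick_reference_run({"b": 5, "a": 5, "c": 3}) == "a"
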