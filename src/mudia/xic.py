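"""MS2 extracted-ion chromatograms, RT transfer, and local normalization.

A peptide ion is quantified from the fragment-ion traces (m/z >= 300) of
the MS2 scans sharing its effective precursor bin. The apex scan is the
one maximizing the summed fragment intensity near the expected RT;
fragments that never reach >70% of their own run-wide maximum within
+/-20 s of the apex are discarded as non-co-eluting, and the reported
intensity sums the surviving fragments over the apex scan plus the two
scans on either side. Identifications are transferred across runs with a
monotone piecewise-linear RT model fit on shared endogenous peptides, and
systematic intensity differences between runs are removed by a sliding
median log-ratio in retention time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .acquisition import SpectrumScan, WindowScheme
from .chem import PeptideIon

logger = logging.getLogger(__name__)

__all__ = [
    "MS2Chromatogram",
    "RTModel",
    "BinnedRun",
    "extract_ms2_chromatogram",
    "fit_rt_model",
    "transfer_ids",
    "normalize_intensities_local",
    "pick_reference_run",
]


@dataclass
class MS2Chromatogram:
    ion_id: str
    run_id: object
    fragment_mz: np.ndarray        # retained fragments
    scan_rts: np.ndarray           # RTs of the bin's scans (time order)
    traces: np.ndarray             # retained fragments x scans
    apex_index: int                # index into scan_rts
    apex_rt: float
    summed_intensity: float
    n_fragments_retained: int
    source: str = "identified"     # or "transferred"


@dataclass
class RTModel:
    """Monotone piecewise-linear map from reference RT to run RT."""

    knots_x: np.ndarray
    knots_y: np.ndarray
    residual_scale: float
    n_anchors: int
    identity: bool = False

    def predict(self, rt_reference):
        if self.identity:
            return rt_reference
        return np.interp(rt_reference, self.knots_x, self.knots_y)


class BinnedRun:
    """Demultiplexed scans of one run indexed by effective precursor bin.

    Per bin the scans are time-ordered and their peaks concatenated into a
    single m/z-sorted array, so a fragment trace is one ``searchsorted``
    range query followed by a scatter-add over scan indices.
    """

    def __init__(self, scans: Sequence[SpectrumScan], scheme: WindowScheme,
                 run_id: object = None):
        self.scheme = scheme
        self.run_id = run_id
        by_bin: dict[int, list[SpectrumScan]] = {}
        for s in scans:
            if s.ms_level == 2 and s.bin_index is not None:
                by_bin.setdefault(s.bin_index, []).append(s)
        self._bins: dict[int, dict] = {}
        for b, bscans in by_bin.items():
            bscans.sort(key=lambda s: s.rt)
            mz = np.concatenate([s.mz for s in bscans]) if bscans else np.empty(0)
            inten = np.concatenate([s.intensity for s in bscans])
            scan_idx = np.concatenate([
                np.full(s.n_peaks, i) for i, s in enumerate(bscans)
            ]).astype(int) if len(mz) else np.empty(0, dtype=int)
            order = np.argsort(mz, kind="stable")
            self._bins[b] = {
                "rts": np.array([s.rt for s in bscans]),
                "mz": mz[order],
                "intensity": inten[order],
                "scan_idx": scan_idx[order],
            }

    def bin_for_ion(self, ion: PeptideIon) -> int | None:
        return self.scheme.bin_index_for_mz(ion.precursor_mz)

    def scan_rts(self, bin_index: int) -> np.ndarray:
        entry = self._bins.get(bin_index)
        return entry["rts"] if entry else np.empty(0)

    def traces(self, bin_index: int, fragment_mz: np.ndarray,
               tolerance_ppm: float) -> tuple[np.ndarray, np.ndarray]:
        """(fragments x scans) intensity matrix plus the scans' RTs."""
        entry = self._bins.get(bin_index)
        if entry is None or len(entry["rts"]) == 0:
            return np.zeros((len(fragment_mz), 0)), np.empty(0)
        mz, inten, scan_idx = entry["mz"], entry["intensity"], entry["scan_idx"]
        n_scans = len(entry["rts"])
        tol = tolerance_ppm * 1e-6
        out = np.zeros((len(fragment_mz), n_scans))
        lo = np.searchsorted(mz, fragment_mz * (1 - tol), side="left")
        hi = np.searchsorted(mz, fragment_mz * (1 + tol), side="right")
        for f in range(len(fragment_mz)):
            if hi[f] > lo[f]:
                np.add.at(out[f], scan_idx[lo[f]:hi[f]], inten[lo[f]:hi[f]])
        return out, entry["rts"]


def extract_ms2_chromatogram(
    peptide_ion: PeptideIon,
    binned_run: BinnedRun,
    rt_center: float,
    rt_halfwidth: float = 20.0,
    tolerance_ppm: float = 15.0,
    min_fragment_mz: float = 300.0,
    min_fragments: int = 4,
    coelution_fraction: float = 0.7,
    coelution_halfwidth: float = 20.0,
    source: str = "identified",
) -> MS2Chromatogram | None:
    """Extract and score one peptide ion's MS2 chromatogram in one run.

    Returns ``None`` when no scans share the ion's bin near ``rt_center``
    or when fewer than ``min_fragments`` fragments survive the co-elution
    filter. The summed intensity covers the apex scan and the two bin
    scans immediately before and after it (truncated at the trace
    boundaries, so fewer than five scans near the gradient edges).
    """
    bin_index = binned_run.bin_for_ion(peptide_ion)
    if bin_index is None:
        return None
    frag_mz = peptide_ion.fragment_mz_array(min_mz=min_fragment_mz)
    if frag_mz.size == 0:
        return None
    traces, rts = binned_run.traces(bin_index, frag_mz, tolerance_ppm)
    if rts.size == 0:
        return None
    if rt_center is None:
        candidate = np.ones(rts.shape, dtype=bool)
    else:
        candidate = np.abs(rts - rt_center) <= rt_halfwidth
    if not candidate.any():
        return None
    totals = traces.sum(axis=0)
    cand_idx = np.flatnonzero(candidate)
    # apex = candidate scan with the largest summed fragment intensity;
    # exact ties (e.g. flat-top signal) resolve to the scan nearest the
    # expected RT, then to the earlier scan
    center = rt_center if rt_center is not None else float(np.median(rts[cand_idx]))
    apex = int(min(cand_idx,
                   key=lambda s: (-totals[s], abs(rts[s] - center), s)))
    if totals[apex] <= 0:
        return None
    apex_rt = float(rts[apex])

    near_apex = np.abs(rts - apex_rt) <= coelution_halfwidth
    gmax = traces.max(axis=1)
    keep = np.zeros(len(frag_mz), dtype=bool)
    for f in range(len(frag_mz)):
        if gmax[f] <= 0:
            continue
        keep[f] = bool(
            (traces[f, near_apex] > coelution_fraction * gmax[f]).any())
    if keep.sum() < min_fragments:
        return None
    lo = max(apex - 2, 0)
    hi = min(apex + 2, len(rts) - 1)
    summed = float(traces[keep, lo:hi + 1].sum())
    return MS2Chromatogram(
        ion_id=peptide_ion.ion_id,
        run_id=binned_run.run_id,
        fragment_mz=frag_mz[keep],
        scan_rts=rts,
        traces=traces[keep],
        apex_index=apex,
        apex_rt=apex_rt,
        summed_intensity=summed,
        n_fragments_retained=int(keep.sum()),
        source=source,
    )


def fit_rt_model(
    anchors: Sequence[tuple[float, float]],
    min_anchors: int = 10,
    n_segments: int | None = None,
) -> RTModel:
    """Fit a robust monotone RT map from (reference RT, run RT) anchors.

    Anchors are sorted by reference RT, grouped into segments, and each
    segment contributes a (median reference RT, median run RT) knot;
    prediction interpolates linearly between knots with monotonicity
    enforced. With fewer than ``min_anchors`` anchors, falls back to the
    identity map with a warning.
    """
    pairs = np.array(sorted(anchors), dtype=float)
    if len(pairs) < min_anchors:
        logger.warning("only %d RT anchors (<%d); using identity mapping",
                       len(pairs), min_anchors)
        return RTModel(np.empty(0), np.empty(0), 0.0, len(pairs), identity=True)
    if n_segments is None:
        n_segments = int(np.clip(len(pairs) // 10, 2, 20))
    splits = np.array_split(pairs, n_segments)
    knots_x = np.array([np.median(s[:, 0]) for s in splits if len(s)])
    knots_y = np.array([np.median(s[:, 1]) for s in splits if len(s)])
    # extend to the anchor range with the edge segments' slopes so the map
    # extrapolates linearly instead of clamping at the outer knots
    if len(knots_x) >= 2:
        lo_slope = ((knots_y[1] - knots_y[0]) / (knots_x[1] - knots_x[0])
                    if knots_x[1] > knots_x[0] else 1.0)
        hi_slope = ((knots_y[-1] - knots_y[-2]) / (knots_x[-1] - knots_x[-2])
                    if knots_x[-1] > knots_x[-2] else 1.0)
        x_lo, x_hi = pairs[0, 0], pairs[-1, 0]
        knots_x = np.concatenate(
            [[x_lo - 1.0], knots_x, [x_hi + 1.0]])
        knots_y = np.concatenate(
            [[knots_y[0] - lo_slope * (knots_x[1] - knots_x[0])], knots_y,
             [knots_y[-1] + hi_slope * (knots_x[-1] - knots_x[-2])]])
    knots_y = np.maximum.accumulate(knots_y)  # enforce monotone non-decreasing
    model = RTModel(knots_x, knots_y, 0.0, len(pairs))
    residuals = np.abs(model.predict(pairs[:, 0]) - pairs[:, 1])
    model.residual_scale = float(np.median(residuals))
    return model


def transfer_ids(
    peptide_ion: PeptideIon,
    binned_run: BinnedRun,
    rt_model: RTModel,
    reference_rt: float,
    rt_halfwidth: float = 20.0,
    **extract_kwargs,
) -> MS2Chromatogram | None:
    """Extract a chromatogram in a run where the ion was not identified.

    The elution time is predicted through ``rt_model`` from the reference
    run's RT; extraction then proceeds as for identified peptides within
    +/-``rt_halfwidth`` seconds. Predictions outside the run's gradient
    return ``None``.
    """
    rt_pred = float(rt_model.predict(reference_rt))
    bin_index = binned_run.bin_for_ion(peptide_ion)
    if bin_index is None:
        return None
    rts = binned_run.scan_rts(bin_index)
    if rts.size == 0:
        return None
    if rt_pred < rts[0] - rt_halfwidth or rt_pred > rts[-1] + rt_halfwidth:
        return None
    return extract_ms2_chromatogram(
        peptide_ion, binned_run, rt_center=rt_pred,
        rt_halfwidth=rt_halfwidth, source="transferred", **extract_kwargs)


def pick_reference_run(peptides_per_run: Mapping[object, int]):
    """Run with the most identified peptides; ties break by run id."""
    return sorted(peptides_per_run.items(), key=lambda kv: (-kv[1], str(kv[0])))[0][0]


def normalize_intensities_local(
    per_run: Mapping[object, Mapping[str, tuple[float, float]]],
    reference_run: object,
    rt_window: float = 120.0,
    min_shared: int = 3,
) -> dict[object, dict[str, float]]:
    """Local retention-time intensity normalization against a reference run.

    ``per_run`` maps run id -> {ion_id: (apex RT, intensity)}. For each run,
    the median log2 intensity ratio (run / reference) over shared peptides
    is computed in sliding RT windows (centres every ``rt_window/2``) and
    subtracted from every peptide's log2 intensity, interpolating between
    window centres; windows with fewer than ``min_shared`` shared peptides
    inherit the nearest estimated factor. Returns normalized linear
    intensities per run.
    """
    ref = per_run[reference_run]
    out: dict[object, dict[str, float]] = {}
    for run_id, obs in per_run.items():
        if run_id == reference_run:
            out[run_id] = {i: v[1] for i, v in obs.items()}
            continue
        shared = [
            (rt, np.log2(inten) - np.log2(ref[ion][1]))
            for ion, (rt, inten) in obs.items()
            if ion in ref and inten > 0 and ref[ion][1] > 0
        ]
        if not shared:
            logger.warning("run %s shares no quantified peptides with the "
                           "reference; left unnormalized", run_id)
            out[run_id] = {i: v[1] for i, v in obs.items()}
            continue
        shared_rt = np.array([s[0] for s in shared])
        shared_ratio = np.array([s[1] for s in shared])
        lo, hi = shared_rt.min(), shared_rt.max()
        centers = np.arange(lo, hi + rt_window / 2, rt_window / 2)
        factors = np.full(len(centers), np.nan)
        for i, c in enumerate(centers):
            mask = np.abs(shared_rt - c) <= rt_window / 2
            if mask.sum() >= min_shared:
                factors[i] = np.median(shared_ratio[mask])
        valid = ~np.isnan(factors)
        if not valid.any():
            factors[:] = np.median(shared_ratio)
            valid[:] = True
        centers, factors = centers[valid], factors[valid]
        normalized = {}
        for ion, (rt, inten) in obs.items():
            if inten <= 0:
                normalized[ion] = 0.0
                continue
            corr = float(np.interp(rt, centers, factors))
            normalized[ion] = float(2 ** (np.log2(inten) - corr))
        out[run_id] = normalized
    return out
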