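"""DIA window scheme and demultiplexing of overlapping isolation windows.

The acquisition uses isolation windows wider than their spacing (12 m/z wide,
stepped by 8 m/z), so adjacent windows overlap. A fragment peak observed in
two adjacent windows of the same cycle must come from a precursor in their
overlap; a peak observed in only one window comes from that window's unique
region. Exploiting this reduces the effective precursor specificity from the
isolation width to ``isolation_width - step`` (4 m/z for the default scheme).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterError",
    "WindowScheme",
    "SpectrumScan",
    "build_window_scheme",
    "demultiplex_cycle",
    "demultiplex_run",
]


class ParameterError(ValueError):
    """Raised for invalid acquisition/demultiplexing parameters."""


@dataclass(frozen=True)
class WindowScheme:
    """An overlapped DIA isolation-window scheme."""

    centers: tuple[float, ...]
    isolation_width: float
    step: float

    @property
    def n_windows(self) -> int:
        return len(self.centers)

    @property
    def effective_bin_width(self) -> float:
        return self.isolation_width - self.step

    @property
    def precursor_range(self) -> tuple[float, float]:
        half = self.isolation_width / 2
        return (self.centers[0] - half, self.centers[-1] + half)

    def window_bounds(self, i: int) -> tuple[float, float]:
        half = self.isolation_width / 2
        return (self.centers[i] - half, self.centers[i] + half)

    def windows_containing(self, mz: float) -> list[int]:
        """Indices of all isolation windows whose range contains ``mz``."""
        half = self.isolation_width / 2
        return [
            i
            for i, c in enumerate(self.centers)
            if c - half <= mz <= c + half
        ]

    def bin_edges(self) -> np.ndarray:
        """Edges of the effective precursor bins tiling the precursor range.

        Interior bins are ``effective_bin_width`` wide; the two edge bins
        extend to the scheme boundary and are therefore wider (documented
        exception to the tiling invariant).
        """
        half = self.isolation_width / 2
        edges = [self.centers[0] - half]
        for i in range(self.n_windows - 1):
            edges.append(self.centers[i + 1] - half)  # start of overlap(i,i+1)
            edges.append(self.centers[i] + half)      # end of overlap(i,i+1)
        edges.append(self.centers[-1] + half)
        return np.array(edges)

    @property
    def n_bins(self) -> int:
        return 2 * self.n_windows - 1

    def bin_bounds(self, b: int) -> tuple[float, float]:
        edges = self.bin_edges()
        return float(edges[b]), float(edges[b + 1])

    def bin_index_for_mz(self, mz: float) -> int | None:
        """Effective bin containing precursor ``mz`` (None if outside)."""
        edges = self.bin_edges()
        if mz < edges[0] or mz > edges[-1]:
            return None
        b = int(np.searchsorted(edges, mz, side="right")) - 1
        return min(max(b, 0), self.n_bins - 1)

    def unique_bin(self, window: int) -> int:
        return 2 * window

    def overlap_bin(self, window: int) -> int:
        """Bin shared by windows ``window`` and ``window + 1``."""
        return 2 * window + 1


@dataclass
class SpectrumScan:
    """One centroided scan. ``window`` is ``(center, width)`` for MS2 scans;
    after demultiplexing it describes the effective precursor bin and
    ``bin_index`` is set."""

    ms_level: int
    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    window: tuple[float, float] | None = None
    cycle_index: int = 0
    bin_index: int | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ParameterError("mz and intensity arrays differ in length")
        if np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return len(self.mz)


def build_window_scheme(
    first_center: float,
    last_center: float,
    step: float,
    isolation_width: float,
) -> WindowScheme:
    """Arithmetic-progression window scheme (default 436..900 by 8, 12 wide)."""
    if step <= 0:
        raise ParameterError("step must be positive")
    if first_center > last_center:
        raise ParameterError("first_center must be <= last_center")
    if isolation_width <= step:
        raise ParameterError(
            "isolation_width must exceed step (windows must overlap)")
    if isolation_width >= 2 * step:
        raise ParameterError(
            "isolation_width must be < 2*step (windows two apart must be "
            "disjoint for pairwise demultiplexing)")
    span = last_center - first_center
    n_steps = round(span / step)
    if abs(n_steps * step - span) > 1e-9 * max(1.0, span):
        raise ParameterError("(last_center - first_center) must be a multiple of step")
    centers = tuple(first_center + i * step for i in range(n_steps + 1))
    return WindowScheme(centers=centers, isolation_width=isolation_width, step=step)


def _greedy_match(
    mz_a: np.ndarray, mz_b: np.ndarray, tolerance_ppm: float
) -> list[tuple[int, int]]:
    """Pair peaks of two windows within tolerance, greedily by m/z distance.

    The tolerance is computed relative to the lower-window (``a``) peak m/z.
    Each peak is matched at most once.
    """
    candidates: list[tuple[float, int, int]] = []
    tol = tolerance_ppm * 1e-6
    lo = np.searchsorted(mz_b, mz_a * (1 - tol), side="left")
    hi = np.searchsorted(mz_b, mz_a * (1 + tol), side="right")
    for a in range(len(mz_a)):
        for b in range(lo[a], hi[a]):
            candidates.append((abs(mz_b[b] - mz_a[a]), a, b))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, a, b in candidates:
        if a in used_a or b in used_b:
            continue
        used_a.add(a)
        used_b.add(b)
        pairs.append((a, b))
    return pairs


def demultiplex_cycle(
    cycle: Sequence[SpectrumScan],
    scheme: WindowScheme,
    tolerance_ppm: float = 15.0,
) -> list[SpectrumScan]:
    """Resolve one cycle of overlapped MS2 scans into effective-bin scans.

    A peak in window ``i`` matched (within ``tolerance_ppm``) to a peak in
    window ``i+1`` of the same cycle is assigned to the two windows'
    precursor intersection with intensity equal to the mean of the matched
    intensities; an unmatched peak is assigned to its window's unique region.
    Edge windows' unique regions extend to the scheme boundary. RT and
    cycle index are preserved (each output scan inherits them from its
    lower-index source window).
    """
    if tolerance_ppm <= 0:
        raise ParameterError("tolerance_ppm must be positive")
    if not cycle:
        return []
    by_window: dict[int, SpectrumScan] = {}
    center_to_idx = {c: i for i, c in enumerate(scheme.centers)}
    for scan in cycle:
        if scan.ms_level != 2 or scan.window is None:
            raise ParameterError("demultiplex_cycle expects MS2 scans with windows")
        idx = center_to_idx.get(scan.window[0])
        if idx is None:
            raise ParameterError(
                f"scan window center {scan.window[0]} not in scheme")
        by_window[idx] = scan
    if len(by_window) != scheme.n_windows:
        logger.warning(
            "cycle %s missing %d of %d windows; skipped",
            cycle[0].cycle_index, scheme.n_windows - len(by_window),
            scheme.n_windows)
        return []

    available = {
        i: np.ones(by_window[i].n_peaks, dtype=bool)
        for i in range(scheme.n_windows)
    }
    out_peaks: dict[int, list[tuple[float, float]]] = {}
    out_src: dict[int, int] = {}

    def _emit(bin_idx: int, src_window: int, mz: float, inten: float) -> None:
        out_peaks.setdefault(bin_idx, []).append((mz, inten))
        out_src.setdefault(bin_idx, src_window)

    for i in range(scheme.n_windows - 1):
        a, b = by_window[i], by_window[i + 1]
        mask_a, mask_b = available[i], available[i + 1]
        ia = np.flatnonzero(mask_a)
        ib = np.flatnonzero(mask_b)
        pairs = _greedy_match(a.mz[ia], b.mz[ib], tolerance_ppm)
        for pa, pb in pairs:
            ja, jb = ia[pa], ib[pb]
            _emit(scheme.overlap_bin(i), i, float(a.mz[ja]),
                  0.5 * (float(a.intensity[ja]) + float(b.intensity[jb])))
            mask_a[ja] = False
            mask_b[jb] = False

    for i in range(scheme.n_windows):
        scan = by_window[i]
        for j in np.flatnonzero(available[i]):
            _emit(scheme.unique_bin(i), i, float(scan.mz[j]),
                  float(scan.intensity[j]))

    out: list[SpectrumScan] = []
    for bin_idx in sorted(out_peaks):
        peaks = sorted(out_peaks[bin_idx])
        lo, hi = scheme.bin_bounds(bin_idx)
        src = by_window[out_src[bin_idx]]
        out.append(
            SpectrumScan(
                ms_level=2,
                rt=src.rt,
                mz=np.array([p[0] for p in peaks]),
                intensity=np.array([p[1] for p in peaks]),
                window=((lo + hi) / 2, hi - lo),
                cycle_index=src.cycle_index,
                bin_index=bin_idx,
            )
        )
    return out


def demultiplex_run(
    scans: Sequence[SpectrumScan],
    scheme: WindowScheme,
    tolerance_ppm: float = 15.0,
) -> list[SpectrumScan]:
    """Demultiplex every complete MS2 cycle of a run (MS1 scans are passed over)."""
    cycles: dict[int, list[SpectrumScan]] = {}
    for scan in scans:
        if scan.ms_level == 2:
            cycles.setdefault(scan.cycle_index, []).append(scan)
    out: list[SpectrumScan] = []
    for c in sorted(cycles):
        out.extend(demultiplex_cycle(cycles[c], scheme, tolerance_ppm))
    return out
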