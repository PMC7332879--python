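"""Per-run feature extraction: crop, mass detection, chromatogram building,
baseline-cutoff deconvolution, RT (mobile-phase) filtering, isotope grouping.

The stages mirror an MZmine-style batch queue and share its tolerance
semantics: an "X m/z or Y ppm" tolerance means a window of
``max(X, Y * mz / 1e6)`` Th at query mass ``mz``.  Boundary conventions:
"minimum" thresholds are inclusive (>=), the deconvolution "baseline"
cut-off is exclusive (>).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .io import CentroidRun, CentroidScan

log = logging.getLogger(__name__)

__all__ = [
    "Tolerance",
    "Trace",
    "Feature",
    "FeatureParams",
    "crop",
    "detect_masses",
    "build_chromatograms",
    "deconvolve",
    "duration_filter",
    "group_isotopes",
    "extract_features",
    "representatives",
]

#: 13C-12C spacing used by the isotope grouper.
ISOTOPE_SPACING = 1.003355


@dataclass(frozen=True)
class Tolerance:
    """An "abs Th or ppm" m/z tolerance; the wider window wins."""

    mz_abs: float = 0.01
    ppm: float = 5.0

    def window(self, mz: float | np.ndarray) -> float | np.ndarray:
        return np.maximum(self.mz_abs, self.ppm * np.asarray(mz) / 1e6)


@dataclass
class Trace:
    """An extracted-ion chromatogram: at most one point per scan."""

    scan_index: np.ndarray
    rt: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray

    @property
    def representative_mz(self) -> float:
        return float(np.average(self.mz, weights=self.intensity))

    @property
    def span(self) -> float:
        return float(self.rt[-1] - self.rt[0])


@dataclass
class Feature:
    """One deconvolved chromatographic peak."""

    mz: float
    rt: float
    height: float
    area: float
    charge: int | None = None
    group: int | None = None
    representative: bool = True


def crop(
    run: CentroidRun,
    scan_range: tuple[int, int] = (1, 1130),
    rt_range: tuple[float, float] = (0.01, 12.51),
    mz_range: tuple[float, float] = (100.0, 1200.0),
) -> CentroidRun:
    """Keep scans inside the index and RT windows and centroids inside the
    m/z window (all bounds inclusive); order is preserved.  An empty result
    is allowed."""
    for rng, name in ((scan_range, "scan"), (rt_range, "rt"), (mz_range, "mz")):
        if rng[0] > rng[1]:
            raise ValueError(f"inverted {name} range: {rng}")
    out = []
    for scan in run.scans:
        if not (scan_range[0] <= scan.index <= scan_range[1]):
            continue
        if not (rt_range[0] <= scan.rt <= rt_range[1]):
            continue
        keep = (scan.mz >= mz_range[0]) & (scan.mz <= mz_range[1])
        out.append(CentroidScan(scan.index, scan.rt, scan.mz[keep], scan.intensity[keep]))
    return CentroidRun(metadata=run.metadata, scans=out)


def detect_masses(run_or_scan, noise_level: float = 600.0):
    """Centroid mass detector: drop centroids below ``noise_level`` counts
    (boundary kept: >= survives)."""
    if noise_level < 0:
        raise ValueError("noise level must be >= 0")
    if isinstance(run_or_scan, CentroidScan):
        scan = run_or_scan
        keep = scan.intensity >= noise_level
        return CentroidScan(scan.index, scan.rt, scan.mz[keep], scan.intensity[keep])
    return CentroidRun(
        metadata=run_or_scan.metadata,
        scans=[detect_masses(s, noise_level) for s in run_or_scan.scans],
    )


def build_chromatograms(
    run: CentroidRun,
    min_span: float = 0.01,
    min_height: float = 5.0e3,
    mz_tol: Tolerance = Tolerance(0.01, 5.0),
) -> list[Trace]:
    """Greedy scan-by-scan chromatogram builder.

    Each centroid joins the open trace whose intensity-weighted
    representative m/z is within tolerance (closest wins; ties go to the
    more intense centroid); unmatched centroids open new traces.  Traces
    opened during a scan are not candidates for that same scan, so a trace
    holds at most one point per scan.  Traces with span >= ``min_span`` and
    max intensity >= ``min_height`` are returned.
    """
    # open traces as growing column lists; weighted-mean reps kept in
    # preallocated buffers so the per-scan cost stays numpy-bound
    t_scan: list[list[int]] = []
    t_rt: list[list[float]] = []
    t_mz: list[list[float]] = []
    t_int: list[list[float]] = []
    cap = 256
    rep_num = np.zeros(cap)   # sum(mz * intensity)
    rep_den = np.zeros(cap)   # sum(intensity)
    n_open = 0

    for scan in run.scans:
        if scan.mz.size == 0:
            continue
        assigned_traces: set[int] = set()
        proposals: list[tuple[float, float, int, int]] = []
        if n_open:
            reps = rep_num[:n_open] / rep_den[:n_open]
            order = np.argsort(reps)
            sorted_reps = reps[order]
            pos_arr = np.searchsorted(sorted_reps, scan.mz)
            for ci, (mz, inten) in enumerate(zip(scan.mz, scan.intensity)):
                pos = pos_arr[ci]
                best_j, best_d = -1, np.inf
                for p in (pos - 1, pos):
                    if 0 <= p < n_open:
                        d = abs(sorted_reps[p] - mz)
                        if d < best_d:
                            best_d, best_j = d, int(order[p])
                if best_j >= 0 and best_d <= mz_tol.window(mz):
                    proposals.append((best_d, -inten, ci, best_j))
        proposals.sort()
        assigned_centroids: set[int] = set()
        for d, neg_int, ci, tj in proposals:
            if ci in assigned_centroids or tj in assigned_traces:
                continue
            assigned_centroids.add(ci)
            assigned_traces.add(tj)
            mz, inten = float(scan.mz[ci]), float(scan.intensity[ci])
            t_scan[tj].append(scan.index)
            t_rt[tj].append(scan.rt)
            t_mz[tj].append(mz)
            t_int[tj].append(inten)
            rep_num[tj] += mz * inten
            rep_den[tj] += inten
        for ci, (mz, inten) in enumerate(zip(scan.mz, scan.intensity)):
            if ci in assigned_centroids:
                continue
            if n_open == cap:
                cap *= 2
                grown_num, grown_den = np.zeros(cap), np.zeros(cap)
                grown_num[:n_open], grown_den[:n_open] = rep_num, rep_den
                rep_num, rep_den = grown_num, grown_den
            t_scan.append([scan.index])
            t_rt.append([scan.rt])
            t_mz.append([float(mz)])
            t_int.append([float(inten)])
            rep_num[n_open] = float(mz) * float(inten)
            rep_den[n_open] = float(inten)
            n_open += 1

    traces = []
    for sc, rt, mz, inten in zip(t_scan, t_rt, t_mz, t_int):
        trace = Trace(np.array(sc), np.array(rt), np.array(mz), np.array(inten))
        if trace.span >= min_span and trace.intensity.max() >= min_height:
            traces.append(trace)
    traces.sort(key=lambda t: (t.representative_mz, t.rt[0]))
    return traces


def deconvolve(
    trace: Trace,
    baseline: float = 9.0e3,
    min_peak_height: float = 1.0e4,
    duration_range: tuple[float, float] = (0.0, 2.0),
) -> list[Feature]:
    """Baseline cut-off deconvolution.

    Maximal contiguous sub-regions with intensity strictly above
    ``baseline`` become candidate peaks, kept when the apex is >=
    ``min_peak_height`` and the RT duration falls inside
    ``duration_range`` (inclusive).  Feature m/z is the intensity-weighted
    mean over the region; area is the trapezoidal integral in counts*min.
    """
    above = trace.intensity > baseline
    features = []
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        seg = slice(i, j)
        inten = trace.intensity[seg]
        rt = trace.rt[seg]
        apex = float(inten.max())
        duration = float(rt[-1] - rt[0])
        if apex >= min_peak_height and duration_range[0] <= duration <= duration_range[1]:
            apex_rt = float(rt[int(np.argmax(inten))])
            mz = float(np.average(trace.mz[seg], weights=inten))
            area = float(np.trapezoid(inten, rt)) if len(rt) > 1 else 0.0
            features.append(Feature(mz=mz, rt=apex_rt, height=apex, area=area))
        i = j
    return features


def duration_filter(
    features: list[Feature], rt_window: tuple[float, float] = (0.01, 12.01)
) -> list[Feature]:
    """Keep features whose apex RT lies inside the keep-window (inclusive).

    Guards against mobile-phase artifacts at the extremes of the gradient;
    the window is configurable because keep- vs drop-window conventions
    differ between processing pipelines.
    """
    lo, hi = rt_window
    return [f for f in features if lo <= f.rt <= hi]


def group_isotopes(
    features: list[Feature],
    mz_tol: Tolerance = Tolerance(0.01, 5.0),
    rt_tol: float = 0.05,
    max_charge: int = 1,
    monotonic: bool = True,
) -> list[Feature]:
    """Collapse 13C isotopologue ladders into groups.

    Features within ``rt_tol`` of a chain whose m/z continues the
    ~1.00336/z spacing (z <= ``max_charge``) are chained greedily from the
    lowest m/z; with ``monotonic`` each successor's height must not exceed
    its predecessor's.  Every input feature appears exactly once in the
    output; one representative (most intense) per group is flagged and
    carries the charge.
    """
    feats = [replace(f) for f in features]
    order = sorted(range(len(feats)), key=lambda i: (feats[i].mz, feats[i].rt))
    assigned = [False] * len(feats)
    group_id = 0
    for start in order:
        if assigned[start]:
            continue
        chain = [start]
        assigned[start] = True
        charge: int | None = None
        while True:
            last = feats[chain[-1]]
            best = None
            for z in ([charge] if charge else range(1, max_charge + 1)):
                target = last.mz + ISOTOPE_SPACING / z
                for i in order:
                    if assigned[i]:
                        continue
                    f = feats[i]
                    if abs(f.mz - target) > mz_tol.window(target):
                        continue
                    if abs(f.rt - feats[start].rt) > rt_tol:
                        continue
                    if monotonic and f.height > last.height:
                        continue
                    d = abs(f.mz - target)
                    if best is None or d < best[0]:
                        best = (d, i, z)
            if best is None:
                break
            _, i, z = best
            charge = z
            chain.append(i)
            assigned[i] = True
        rep = max(chain, key=lambda i: feats[i].height)
        for i in chain:
            feats[i].group = group_id
            feats[i].representative = i == rep
        feats[rep].charge = charge if len(chain) > 1 else feats[rep].charge
        group_id += 1
    return feats


def representatives(features: list[Feature]) -> list[Feature]:
    """The per-group representative features (downstream analysis input)."""
    return [f for f in features if f.representative]


@dataclass(frozen=True)
class FeatureParams:
    """All knobs of the six per-run stages, in processing order."""

    scan_range: tuple[int, int] = (1, 1130)
    rt_range: tuple[float, float] = (0.01, 12.51)
    mz_range: tuple[float, float] = (100.0, 1200.0)
    noise_level: float = 600.0
    chrom_min_span: float = 0.01
    chrom_min_height: float = 5.0e3
    chrom_mz_tol: Tolerance = Tolerance(0.01, 5.0)
    baseline: float = 9.0e3
    min_peak_height: float = 1.0e4
    duration_range: tuple[float, float] = (0.0, 2.0)
    rt_keep_window: tuple[float, float] = (0.01, 12.01)
    iso_mz_tol: Tolerance = Tolerance(0.01, 5.0)
    iso_rt_tol: float = 0.05
    iso_max_charge: int = 1
    iso_monotonic: bool = True


def extract_features(run: CentroidRun, params: FeatureParams = FeatureParams()) -> list[Feature]:
    """The full per-run chain: crop -> detect -> build -> deconvolve ->
    duration filter -> isotope grouping.  Returns all features with group
    annotations; use :func:`representatives` for downstream analysis."""
    run = crop(run, params.scan_range, params.rt_range, params.mz_range)
    run = detect_masses(run, params.noise_level)
    traces = build_chromatograms(run, params.chrom_min_span,
                                 params.chrom_min_height, params.chrom_mz_tol)
    features: list[Feature] = []
    for trace in traces:
        features.extend(deconvolve(trace, params.baseline,
                                   params.min_peak_height, params.duration_range))
    features = duration_filter(features, params.rt_keep_window)
    features = group_isotopes(features, params.iso_mz_tol, params.iso_rt_tol,
                              params.iso_max_charge, params.iso_monotonic)
    log.debug("run %s: %d features (%d representative)", run.run_id,
              len(features), sum(f.representative for f in features))
    return features
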