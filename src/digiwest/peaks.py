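"""Peak detection and quantification for 96-strip bead-western traces.

A DigiWest readout is one fluorescence value per molecular-weight strip
(96 strips per lane).  Protein bands appear as peaks in the strip-index
domain; the quantity of interest is the integral of a peak above its local
background.  This module turns raw traces into a samples x signals matrix:

* :func:`calibrate_mw` maps strip index to kDa (log-linear through ladder
  anchors),
* :func:`detect_peaks` finds local maxima above prominence/SNR thresholds
  and merges maxima closer than ``min_separation`` strips,
* :func:`quantify_peak` integrates a band after subtracting a linear
  background bridged between the peak bounds,
* :func:`match_signals` annotates peaks with their deviation from the
  antibody's expected molecular weight (>20 % deviation disqualifies),
* :func:`build_signal_matrix` aligns detected bands across samples into
  signal rows (one antibody may contribute several rows, one per band).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig
from scipy.interpolate import interp1d
from scipy.stats import median_abs_deviation

from .errors import ConfigurationError

__all__ = [
    "Trace",
    "TraceSet",
    "Peak",
    "MatchedSignal",
    "QuantConfig",
    "SignalMatrix",
    "calibrate_mw",
    "detect_peaks",
    "quantify_peak",
    "match_signals",
    "build_signal_matrix",
]


@dataclass
class Trace:
    """One antibody x one sample readout: intensities on a calibrated MW axis."""

    sample_id: str
    antibody_id: str
    intensities: np.ndarray
    mw_axis: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mw_axis = np.asarray(self.mw_axis, dtype=float)
        if self.intensities.shape != self.mw_axis.shape or self.intensities.ndim != 1:
            raise ValueError("intensities and mw_axis must be 1-D of equal length")
        if np.any(self.intensities < 0) or not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"negative or non-finite intensity in trace "
                             f"({self.sample_id}, {self.antibody_id})")
        d = np.diff(self.mw_axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("mw_axis must be strictly monotone")

    def __len__(self) -> int:
        return self.intensities.size


@dataclass
class TraceSet:
    """A bag of traces sharing one preservation condition."""

    traces: list[Trace]
    preservation: str | None = None

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.traces:
            seen.setdefault(t.sample_id)
        return list(seen)

    @property
    def antibody_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.traces:
            seen.setdefault(t.antibody_id)
        return list(seen)

    def __iter__(self):
        return iter(self.traces)

    def __len__(self) -> int:
        return len(self.traces)


@dataclass(frozen=True)
class Peak:
    """A detected band: strip bounds, apex position, background-subtracted area."""

    left_strip: int
    apex_strip: int
    right_strip: int
    apex_mw: float
    area: float
    background_area: float
    snr: float

    def __post_init__(self) -> None:
        if not self.left_strip <= self.apex_strip <= self.right_strip:
            raise ValueError("peak bounds must satisfy left <= apex <= right")
        if self.area < 0:
            raise ValueError("peak area must be non-negative")


@dataclass(frozen=True)
class MatchedSignal:
    """A peak annotated against the antibody's expected molecular weight."""

    antibody_id: str
    peak: Peak
    expected_mw: float
    relative_shift: float
    shift_flag: bool
    detected: bool
    is_primary: bool


@dataclass(frozen=True)
class QuantConfig:
    """Tunables of the quantification stage.

    ``shift_tolerance`` is inclusive: a band exactly 20 % off its expected
    molecular weight is still accepted.  ``detection_floor`` is the minimum
    background-subtracted area (RFU*strips) for a band to count as detected.
    ``group_window`` is the maximum apex-strip gap for two bands of the same
    antibody in different samples to be treated as the same signal.
    """

    min_snr: float = 3.0
    min_prominence: float = 5.0
    min_separation: int = 3
    shift_tolerance: float = 0.20
    detection_floor: float = 50.0
    group_window: int = 5

    def __post_init__(self) -> None:
        if self.shift_tolerance < 0 or self.detection_floor < 0:
            raise ConfigurationError("thresholds must be non-negative")
        if self.min_separation < 1 or self.group_window < 1:
            raise ConfigurationError("strip windows must be >= 1")


@dataclass
class SignalMatrix:
    """Samples x analyte-signals matrix of quantified (optionally log2) values.

    ``values`` has one row per signal, one column per sample; NaN marks an
    undetected entry.  ``signal_info`` (indexed by signal id) keeps per-signal
    metadata: antibody, rank, apex MW, relative shift and shift flag.
    """

    values: pd.DataFrame
    signal_info: pd.DataFrame
    log2: bool = False
    detection_floor: float = float("nan")

    @property
    def signal_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def antibody_detection(self) -> pd.DataFrame:
        """Antibody x sample boolean table: any signal of the antibody detected."""
        det = self.values.notna()
        det = det.groupby(self.signal_info.loc[det.index, "antibody_id"].values).any()
        det.index.name = "antibody_id"
        return det

    def subset_signals(self, signal_ids: Sequence[str]) -> "SignalMatrix":
        ids = list(signal_ids)
        return SignalMatrix(self.values.loc[ids].copy(),
                            self.signal_info.loc[ids].copy(),
                            log2=self.log2, detection_floor=self.detection_floor)


def calibrate_mw(trace_length: int, anchors: Iterable[tuple[int, float]]) -> np.ndarray:
    """Map strip indices 0..trace_length-1 to kDa.

    log10(MW) is piecewise linear in strip index through the ladder anchors
    and extrapolated linearly beyond the outermost anchors.
    """
    pts = sorted(anchors)
    if trace_length < 2:
        raise ConfigurationError("trace_length must be >= 2")
    if len(pts) < 2:
        raise ConfigurationError("need at least two calibration anchors")
    strips = np.array([s for s, _ in pts], dtype=float)
    kda = np.array([k for _, k in pts], dtype=float)
    if len(np.unique(strips)) != len(strips):
        raise ConfigurationError("anchor strips must be distinct")
    if np.any(kda <= 0):
        raise ConfigurationError("anchor molecular weights must be positive")
    d = np.diff(np.log10(kda))
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ConfigurationError("anchors must be strictly monotone in kDa")
    f = interp1d(strips, np.log10(kda), fill_value="extrapolate", assume_sorted=True)
    axis = np.power(10.0, f(np.arange(trace_length, dtype=float)))
    return axis


def _integrate(y: np.ndarray, left: int, right: int) -> tuple[float, float]:
    """Net area above the linear background bridged between the bounds.

    Background-subtracted values are clipped at zero so the area can never
    go negative on concave flanks.
    """
    if right == left:
        return 0.0, float(y[left])
    xs = np.arange(left, right + 1, dtype=float)
    bg = y[left] + (y[right] - y[left]) * (xs - left) / (right - left)
    net = np.maximum(y[left : right + 1] - bg, 0.0)
    return float(net.sum()), float(bg.sum())


def detect_peaks(trace: Trace, min_snr: float = 3.0, min_prominence: float = 5.0,
                 min_separation: int = 3) -> list[Peak]:
    """Strict local maxima above prominence and SNR thresholds.

    Maxima closer than ``min_separation`` strips are merged into the higher
    one; bounds extend from the apex to the nearest flanking minima.  Noise
    is estimated as MAD of the first-differenced trace divided by sqrt(2);
    SNR is apex height above the local background over that noise.
    """
    y = trace.intensities
    n = y.size
    if n < 3:
        return []
    interior = np.arange(1, n - 1)
    cand = interior[(y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])]
    if cand.size == 0:
        return []
    prom = _sig.peak_prominences(y, cand)[0]
    cand = list(cand[prom >= min_prominence])
    i = 0
    while i < len(cand) - 1:
        if cand[i + 1] - cand[i] < min_separation:
            # keep the higher apex; ties keep the left one
            drop = i if y[cand[i + 1]] > y[cand[i]] else i + 1
            del cand[drop]
            i = max(i - 1, 0)
        else:
            i += 1
    noise = float(median_abs_deviation(np.diff(y))) / np.sqrt(2.0)
    peaks: list[Peak] = []
    for apex in cand:
        left = apex
        while left > 0 and y[left - 1] < y[left]:
            left -= 1
        right = apex
        while right < n - 1 and y[right + 1] < y[right]:
            right += 1
        area, bg_area = _integrate(y, left, right)
        if right > left:
            bg_apex = y[left] + (y[right] - y[left]) * (apex - left) / (right - left)
        else:
            bg_apex = y[left]
        height = float(y[apex] - bg_apex)
        snr = float("inf") if noise == 0 else height / noise
        if snr < min_snr:
            continue
        peaks.append(Peak(int(left), int(apex), int(right),
                          float(trace.mw_axis[apex]), area, bg_area, snr))
    return peaks


def quantify_peak(trace: Trace, peak: Peak) -> float:
    """Background-subtracted area (RFU*strips) of ``peak`` within ``trace``."""
    n = len(trace)
    if not (0 <= peak.left_strip <= peak.apex_strip <= peak.right_strip < n):
        raise ValueError("peak bounds outside trace or inverted")
    area, _ = _integrate(trace.intensities, peak.left_strip, peak.right_strip)
    return area


def match_signals(peaks: Sequence[Peak], expected_mw: float,
                  shift_tolerance: float = 0.20, detection_floor: float = 0.0,
                  antibody_id: str = "") -> list[MatchedSignal]:
    """Annotate peaks with their relative deviation from ``expected_mw``.

    The peak with the smallest relative shift is marked primary (ties go to
    the larger area, then the smaller strip index).  ``shift_flag`` is set
    strictly above the tolerance, i.e. exactly 20 % deviation passes.
    """
    if expected_mw <= 0:
        raise ValueError("expected_mw must be positive")
    if not peaks:
        return []
    shifts = [abs(p.apex_mw - expected_mw) / expected_mw for p in peaks]
    order = sorted(range(len(peaks)),
                   key=lambda i: (shifts[i], -peaks[i].area, peaks[i].apex_strip))
    primary = order[0]
    return [
        MatchedSignal(
            antibody_id=antibody_id,
            peak=p,
            expected_mw=float(expected_mw),
            relative_shift=float(s),
            shift_flag=bool(s > shift_tolerance),
            detected=bool(p.area > detection_floor),
            is_primary=(i == primary),
        )
        for i, (p, s) in enumerate(zip(peaks, shifts))
    ]


def build_signal_matrix(traces: TraceSet | Iterable[Trace], antibodies: pd.DataFrame,
                        config: QuantConfig = QuantConfig()) -> SignalMatrix:
    """Quantify every trace and align bands across samples into signal rows.

    ``antibodies`` must carry ``antibody_id`` and ``expected_mw`` columns (or
    be indexed by antibody id).  Bands of one antibody are grouped across
    samples by apex strip (single-linkage with gap > ``group_window`` starting
    a new group); groups are ranked by their median relative shift, giving
    signal ids ``<antibody>#<rank>``.  Entries below the detection floor are
    missing (NaN).
    """
    trace_list = list(traces)
    ann = antibodies
    if "antibody_id" in ann.columns:
        ann = ann.set_index("antibody_id")
    known = set(ann.index)
    offenders = sorted({t.antibody_id for t in trace_list} - known)
    if offenders:
        raise KeyError(f"traces reference unknown antibodies: {offenders}")

    sample_order: dict[str, None] = {}
    per_ab: dict[str, list[tuple[str, MatchedSignal]]] = defaultdict(list)
    for t in trace_list:
        sample_order.setdefault(t.sample_id)
        pks = detect_peaks(t, config.min_snr, config.min_prominence, config.min_separation)
        for m in match_signals(pks, float(ann.loc[t.antibody_id, "expected_mw"]),
                               config.shift_tolerance, config.detection_floor,
                               t.antibody_id):
            if m.detected:
                per_ab[t.antibody_id].append((t.sample_id, m))

    samples = list(sample_order)
    rows: dict[str, dict[str, float]] = {}
    info_records: list[dict] = []
    for ab in ann.index:
        entries = per_ab.get(ab, [])
        if not entries:
            continue
        entries.sort(key=lambda e: e[1].peak.apex_strip)
        groups: list[list[tuple[str, MatchedSignal]]] = [[entries[0]]]
        for e in entries[1:]:
            if e[1].peak.apex_strip - groups[-1][-1][1].peak.apex_strip > config.group_window:
                groups.append([e])
            else:
                groups[-1].append(e)
        groups.sort(key=lambda g: float(np.median([m.relative_shift for _, m in g])))
        for rank, grp in enumerate(groups, start=1):
            sig_id = f"{ab}#{rank}"
            best: dict[str, MatchedSignal] = {}
            for sample, m in grp:
                if sample not in best or m.peak.area > best[sample].peak.area:
                    best[sample] = m
            rows[sig_id] = {s: m.peak.area for s, m in best.items()}
            med_shift = float(np.median([m.relative_shift for m in best.values()]))
            info_records.append({
                "signal_id": sig_id,
                "antibody_id": ab,
                "rank": rank,
                "apex_mw": float(np.median([m.peak.apex_mw for m in best.values()])),
                "relative_shift": med_shift,
                "shift_flag": bool(med_shift > config.shift_tolerance),
                "n_detected": len(best),
            })

    values = pd.DataFrame(rows).T.reindex(columns=samples) if rows else \
        pd.DataFrame(index=pd.Index([], name="signal_id"), columns=samples, dtype=float)
    values.index.name = "signal_id"
    info = pd.DataFrame(info_records).set_index("signal_id") if info_records else \
        pd.DataFrame(columns=["antibody_id", "rank", "apex_mw", "relative_shift",
                              "shift_flag", "n_detected"],
                     index=pd.Index([], name="signal_id"))
    values = values.loc[info.index]
    return SignalMatrix(values, info, log2=False, detection_floor=config.detection_floor)
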