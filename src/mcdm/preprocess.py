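"""Denoising, channel averaging and cardiac-cycle segmentation.

The denoising chain applies, in order, a 0.5-150 Hz band-pass, a 50 Hz
power-line notch and a 5-sample median filter.  The recursive filters
run forward-backward (zero phase) so fiducial timing is preserved.  The
36 channels are then averaged pointwise and smoothed into one
representative waveform, which is cut into single cardiac cycles whose
samples carry one of seven segment labels (pre-P, P, post-P, QRS, ST, T,
post-T) — the palette categories of the chaotic-dynamics map.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage, signal as sps

from .synthetic import FiducialSet, MCGRecord, TimeSeries

__all__ = [
    "SEGMENTS",
    "FilterSpec",
    "SegmentOffsets",
    "CardiacCycle",
    "apply_filters",
    "average_channels",
    "moving_average",
    "detect_r_peaks",
    "segment_cycles",
]

#: Canonical temporal order of the seven cardiac-cycle segments.
SEGMENTS = ("pre-P", "P", "post-P", "QRS", "ST", "T", "post-T")

_MIN_FILTER_LENGTH = 64  # conservative floor for stable forward-backward filtering


@dataclass(frozen=True)
class FilterSpec:
    """Denoising-chain parameters.

    band_low/band_high bound the band-pass (Hz), ``notch`` is the
    power-line frequency removed by an IIR notch of quality ``notch_q``,
    and ``median_window`` (odd, >= 3 samples) sets the despiking median
    filter.
    """

    band_low: float = 0.5
    band_high: float = 150.0
    notch: float = 50.0
    median_window: int = 5
    order: int = 4
    notch_q: float = 30.0

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("require 0 < band_low < band_high")
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise ValueError("median_window must be odd and >= 3")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.notch_q <= 0:
            raise ValueError("notch_q must be positive")

    def validate_for(self, sampling_rate: float) -> None:
        nyquist = sampling_rate / 2.0
        if self.band_high >= nyquist:
            raise ValueError(
                f"band_high={self.band_high} Hz requires sampling_rate > "
                f"{2 * self.band_high} Hz (got {sampling_rate})"
            )
        if not 0 < self.notch < nyquist:
            raise ValueError("notch frequency must lie below the Nyquist frequency")


@dataclass(frozen=True)
class SegmentOffsets:
    """Segment boundaries relative to the R peak, in seconds.

    Used when no fiducial annotations are available.  Defaults mirror
    the synthetic generator's template at a 1 s cycle.
    """

    cycle_start: float = -0.40
    p_on: float = -0.275
    p_off: float = -0.125
    qrs_on: float = -0.065
    qrs_off: float = 0.065
    t_on: float = 0.15
    t_off: float = 0.45
    cycle_end: float = 0.60

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.cycle_start, self.p_on, self.p_off, self.qrs_on,
            self.qrs_off, self.t_on, self.t_off, self.cycle_end,
        )

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if not all(b < a for b, a in zip(vals, vals[1:])):
            raise ValueError("segment offsets must be strictly increasing")


@dataclass(frozen=True)
class CardiacCycle:
    """One beat of a representative waveform with per-sample segment labels."""

    values: np.ndarray
    sampling_rate: float
    segment_labels: np.ndarray
    subject_id: str = ""
    cycle_index: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.segment_labels)
        if values.ndim != 1 or labels.shape != values.shape:
            raise ValueError("segment_labels must match values in length")
        runs = [labels[0]] if labels.size else []
        for lab in labels[1:]:
            if lab != runs[-1]:
                runs.append(lab)
        if tuple(runs) != SEGMENTS:
            raise ValueError(
                "segment labels must form the seven canonical contiguous runs "
                f"{SEGMENTS}, got runs {tuple(runs)}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "segment_labels", labels)

    def __len__(self) -> int:
        return self.values.size


def apply_filters(series: TimeSeries, spec: FilterSpec | None = None) -> TimeSeries:
    """Apply the denoising chain: median despike, band-pass, notch.

    The median filter runs first — a transient single-sample spike can
    only be rejected before the recursive filters smear it across their
    impulse response.  The band-pass and notch stages use
    forward-backward (zero-phase) filtering so fiducial timing is
    preserved; the median filter uses reflection padding.  Output length
    equals input length.
    """
    spec = spec or FilterSpec()
    spec.validate_for(series.sampling_rate)
    x = series.values
    if x.size < _MIN_FILTER_LENGTH:
        raise ValueError(
            f"series too short for stable filtering (need >= {_MIN_FILTER_LENGTH} samples)"
        )
    y = ndimage.median_filter(x, size=spec.median_window, mode="reflect")
    sos = sps.butter(
        spec.order, [spec.band_low, spec.band_high], btype="bandpass",
        fs=series.sampling_rate, output="sos",
    )
    y = sps.sosfiltfilt(sos, y)
    b, a = sps.iirnotch(spec.notch, spec.notch_q, fs=series.sampling_rate)
    y = sps.filtfilt(b, a, y)
    return TimeSeries(values=y, sampling_rate=series.sampling_rate,
                      name=f"{series.name}|filtered" if series.name else "filtered")


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Length-preserving moving average with reflection padding."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window == 1:
        return np.asarray(x, dtype=float).copy()
    half = window // 2
    padded = np.pad(np.asarray(x, dtype=float), half, mode="reflect")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def average_channels(record: MCGRecord, smooth_window: int = 5) -> TimeSeries:
    """Pointwise channel mean followed by a moving-average smoother."""
    if record.n_channels < 1:
        raise ValueError("record must contain at least one channel")
    mean = record.channels.mean(axis=0)
    smoothed = moving_average(mean, smooth_window)
    return TimeSeries(values=smoothed, sampling_rate=record.sampling_rate,
                      name=f"{record.subject_id}|averaged")


def detect_r_peaks(
    series: TimeSeries,
    refractory: float = 0.25,
    energy_window: float = 0.031,
    threshold_fraction: float = 0.25,
) -> np.ndarray:
    """Detect R peaks via a smoothed derivative-energy threshold.

    The squared first difference is smoothed over ``energy_window``
    seconds; peaks above ``threshold_fraction`` of the maximum energy,
    separated by at least ``refractory`` seconds, seed the detections,
    which are refined to the local signal maximum within +-50 ms.
    """
    x = series.values
    fs = series.sampling_rate
    d = np.gradient(x)
    win = max(3, int(round(energy_window * fs)) | 1)
    energy = moving_average(d * d, win)
    peak_height = threshold_fraction * energy.max()
    if energy.max() <= 0 or not np.isfinite(peak_height) or peak_height <= 0:
        raise ValueError("no cycles detected: signal has no derivative energy")
    locs, _ = sps.find_peaks(energy, height=peak_height,
                             distance=max(1, int(round(refractory * fs))))
    if locs.size == 0:
        raise ValueError("no cycles detected")
    half = int(round(0.05 * fs))
    refined = []
    for loc in locs:
        lo, hi = max(0, loc - half), min(x.size, loc + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    return np.unique(refined)


def _labels_from_bounds(bounds: Sequence[int]) -> np.ndarray:
    labels = np.empty(bounds[-1] - bounds[0], dtype="<U6")
    for seg, lo, hi in zip(SEGMENTS, bounds, bounds[1:]):
        labels[lo - bounds[0]:hi - bounds[0]] = seg
    return labels


def segment_cycles(
    series: TimeSeries,
    fiducials: FiducialSet | None = None,
    offsets: SegmentOffsets | None = None,
    subject_id: str = "",
) -> list[CardiacCycle]:
    """Cut a representative waveform into labelled cardiac cycles.

    With ``fiducials`` (synthetic mode) cycles and segment runs are cut
    exactly from the annotations.  Otherwise R peaks are detected with
    :func:`detect_r_peaks` and boundaries placed at fixed physiologic
    offsets from each R peak (``offsets``, configurable); only cycles
    fully contained in the record are returned.
    """
    x = series.values
    cycles: list[CardiacCycle] = []
    if fiducials is not None:
        if np.any(fiducials.cycle_end > x.size):
            raise ValueError("fiducials exceed series length")
        for k in range(fiducials.n_cycles):
            bounds = [
                int(fiducials.cycle_start[k]), int(fiducials.p_on[k]),
                int(fiducials.p_off[k]), int(fiducials.qrs_on[k]),
                int(fiducials.qrs_off[k]), int(fiducials.t_on[k]),
                int(fiducials.t_off[k]), int(fiducials.cycle_end[k]),
            ]
            cycles.append(CardiacCycle(
                values=x[bounds[0]:bounds[-1]],
                sampling_rate=series.sampling_rate,
                segment_labels=_labels_from_bounds(bounds),
                subject_id=subject_id,
                cycle_index=k,
            ))
    else:
        offsets = offsets or SegmentOffsets()
        peaks = detect_r_peaks(series)
        fs = series.sampling_rate
        rel = [int(round(o * fs)) for o in offsets.as_tuple()]
        index = 0
        for r in peaks:
            bounds = [r + o for o in rel]
            if bounds[0] < 0 or bounds[-1] > x.size:
                continue
            cycles.append(CardiacCycle(
                values=x[bounds[0]:bounds[-1]],
                sampling_rate=fs,
                segment_labels=_labels_from_bounds(bounds),
                subject_id=subject_id,
                cycle_index=index,
            ))
            index += 1
        if not cycles:
            raise ValueError("no cycles detected: no full cycle fits the record")
    return cycles
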