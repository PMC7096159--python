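"""Force-extension trace analysis for AFM single-molecule force spectroscopy.

The chain mirrors standard SMFS practice: raw deflection/piezo channels are
converted to force and tip-sample separation (with cantilever-bending
correction), force and distance zero points are determined per trace, the
force channel is denoised, each trace is transformed into contour-length
space by pointwise WLC inversion, unfolding events are detected as force
peaks with contour-length increments, traces are certified by the two-step
unfolding fingerprint of the ddFLN4 domain, and the terminal bond rupture
(force + loading rate) is extracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .units import KBT_300K_PN_NM
from .wlc import wlc_contour_length

__all__ = [
    "ForceExtensionTrace",
    "UnfoldingEvent",
    "RuptureEvent",
    "BaselineError",
    "convert_raw",
    "determine_zero_points",
    "denoise",
    "contour_length_transform",
    "detect_unfolding_events",
    "classify_fingerprint",
    "extract_rupture",
    "filter_traces",
]

logger = logging.getLogger(__name__)


class BaselineError(ValueError):
    """Raised when a trace has no detectable detached baseline."""


@dataclass
class ForceExtensionTrace:
    """One approach-retraction cycle: time (s), extension (nm, tip-sample
    separation after bending correction), force (pN), plus metadata."""

    time: np.ndarray
    extension: np.ndarray
    force: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = self.time.size
        if self.extension.size != n or self.force.size != n:
            raise ValueError("time, extension and force must have equal length")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def trace_id(self) -> str:
        return str(self.metadata.get("trace_id", ""))

    def replace(self, **channels) -> "ForceExtensionTrace":
        kw = {
            "time": self.time,
            "extension": self.extension,
            "force": self.force,
            "metadata": dict(self.metadata),
        }
        kw.update(channels)
        return ForceExtensionTrace(**kw)


@dataclass
class UnfoldingEvent:
    """A force peak with the contour lengths of its flanking stretches."""

    index: int
    peak_force: float
    contour_length_before: float
    contour_length_after: float

    @property
    def delta_Lc(self) -> float:
        return self.contour_length_after - self.contour_length_before


@dataclass
class RuptureEvent:
    """Terminal complex rupture of one trace."""

    rupture_force: float
    loading_rate: float
    fingerprint_valid: bool
    spot_label: str = ""
    trace_id: str = ""


# ---------------------------------------------------------------------------
# Channel conversion and zeroing
# ---------------------------------------------------------------------------


def convert_raw(
    deflection_V: np.ndarray,
    piezo_V: np.ndarray,
    invols: float,
    piezo_sensitivity: float,
    k_c: float,
    sampling_rate: float = 12_000.0,
) -> ForceExtensionTrace:
    """Convert raw deflection/piezo voltages to a force-extension trace.

    force [pN] = k_c [N/m] * invols [nm/V] * deflection [V] * 1000;
    extension [nm] = piezo_sensitivity * piezo - invols * deflection,
    the second term being the cantilever-bending correction.
    """
    if min(invols, piezo_sensitivity, k_c, sampling_rate) <= 0:
        raise ValueError("calibration constants must be strictly positive")
    d = np.asarray(deflection_V, dtype=float)
    z = np.asarray(piezo_V, dtype=float)
    if d.shape != z.shape:
        raise ValueError(f"channel length mismatch: {d.shape} vs {z.shape}")
    force = k_c * invols * d * 1000.0  # N/m * nm = nN -> pN
    extension = piezo_sensitivity * z - invols * d
    time = np.arange(d.size) / sampling_rate
    meta = {
        "invols_nm_per_V": invols,
        "piezo_sensitivity_nm_per_V": piezo_sensitivity,
        "cantilever_stiffness_N_per_m": k_c,
    }
    return ForceExtensionTrace(time=time, extension=extension, force=force, metadata=meta)


def determine_zero_points(
    trace: ForceExtensionTrace,
    baseline_fraction: float = 0.1,
    max_baseline_force: float = 25.0,
) -> tuple[float, float, ForceExtensionTrace]:
    """Per-trace force and distance zero points.

    The force offset is the median of the terminal (detached) baseline
    window; the distance offset is where the smoothed contact-region force
    crosses zero after force zeroing (the first sample for traces recorded
    from the contact point). Raises :class:`BaselineError` when the
    terminal window is not a plausible baseline (e.g. an all-contact trace).
    """
    n = trace.n_samples
    w = max(int(n * baseline_fraction), 5)
    if w >= n:
        raise BaselineError("trace too short for baseline estimation")
    tail = trace.force[-w:]
    force_offset = float(np.median(tail))
    spread = float(np.median(np.abs(tail - force_offset))) * 1.4826
    if abs(force_offset) > max_baseline_force and abs(force_offset) > 5 * max(spread, 1e-12):
        raise BaselineError(
            f"no detached baseline: terminal window sits at {force_offset:.1f} pN"
        )
    corrected_force = trace.force - force_offset
    # contact slope: where the smoothed leading force crosses zero
    lead = corrected_force[: max(w, 5)]
    smooth = np.convolve(lead, np.ones(5) / 5.0, mode="same")
    below = np.flatnonzero(smooth < 0)
    if below.size and below[0] == 0:
        crossings = np.flatnonzero(np.diff(np.signbit(smooth)))
        idx = int(crossings[0]) + 1 if crossings.size else 0
    else:
        idx = 0
    distance_offset = float(trace.extension[idx])
    corrected = trace.replace(
        extension=trace.extension - distance_offset, force=corrected_force
    )
    corrected.metadata["force_offset_pN"] = force_offset
    corrected.metadata["distance_offset_nm"] = distance_offset
    return force_offset, distance_offset, corrected


def denoise(trace: ForceExtensionTrace, window: int = 5) -> ForceExtensionTrace:
    """Boxcar (moving-average) smoothing of the force channel.

    `window` must be odd; window=1 is the identity. Edges are padded with
    edge values so the trace length is preserved.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window > trace.n_samples:
        raise ValueError("smoothing window longer than trace")
    if window == 1:
        return trace.replace()
    half = window // 2
    padded = np.pad(trace.force, half, mode="edge")
    smooth = np.convolve(padded, np.ones(window) / window, mode="valid")
    out = trace.replace(force=smooth)
    out.metadata["denoise_window"] = window
    return out


# ---------------------------------------------------------------------------
# Contour-length space
# ---------------------------------------------------------------------------


def contour_length_transform(
    trace: ForceExtensionTrace,
    Lp: float = 0.38,
    kBT: float = KBT_300K_PN_NM,
    min_force: float = 10.0,
) -> np.ndarray:
    """Transform a trace into contour-length space by pointwise WLC inversion.

    For each sample the contour length Lc solving F = WLC(extension; Lc, Lp)
    with Lc > extension. Unfolding steps appear as jumps between flat levels
    of this series. Samples with force below `min_force` (where the
    inversion is ill-conditioned) or nonpositive extension are NaN-masked.
    """
    if min_force <= 0:
        raise ValueError("min_force must be strictly positive")
    Lc = np.full(trace.n_samples, np.nan)
    ok = (trace.force >= min_force) & (trace.extension > 0)
    if np.any(ok):
        Lc[ok] = wlc_contour_length(trace.extension[ok], trace.force[ok], Lp, kBT)
    Lc[~np.isfinite(Lc)] = np.nan
    return Lc


def _segment_Lc_mode(
    Lc_seg: np.ndarray,
    force_seg: np.ndarray | None = None,
    bin_width: float = 0.5,
    min_samples: int = 5,
) -> float:
    """Mode of a contour-length stretch via histogram peak, refined by the
    median of samples within the modal bin +/- one bin.

    When the segment's forces are supplied, only the upper-force half of
    the stretch enters the histogram: the WLC inversion is best
    conditioned there, and the low-force part of a stretch carries the
    largest noise-induced Lc bias.
    """
    finite = np.isfinite(Lc_seg)
    v = Lc_seg[finite]
    if v.size < min_samples:
        return float("nan")
    if force_seg is not None:
        f = np.asarray(force_seg)[finite]
        sel = f >= 0.5 * (f.min() + f.max())
        if sel.sum() >= min_samples:
            v = v[sel]
    lo, hi = v.min(), v.max()
    if hi - lo < bin_width:
        return float(np.median(v))
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(v, bins=edges)
    k = int(np.argmax(counts))
    sel = (v >= edges[max(k - 1, 0)]) & (v <= edges[min(k + 2, len(edges) - 1)])
    return float(np.median(v[sel]))


def _events_from_peaks(
    f: np.ndarray, Lc_series: np.ndarray, peaks: list[int], n: int,
    drop_fraction: float = 0.25,
) -> list[UnfoldingEvent]:
    events = []
    bounds = [0] + peaks + [n]
    for k, p in enumerate(peaks):
        before = _segment_Lc_mode(Lc_series[bounds[k] : p + 1], f[bounds[k] : p + 1])
        is_last = k == len(peaks) - 1
        if is_last:
            after = float("nan")
        else:
            # the new contour-length state begins once the force has
            # actually dropped; earlier samples may still sit on the old
            # state when noise shifts the detected peak off the true one
            end = bounds[k + 2]
            dropped = np.flatnonzero(f[p + 1 : end] < (1.0 - drop_fraction) * f[p])
            start = p + 1 + int(dropped[0]) if dropped.size else p + 1
            after = _segment_Lc_mode(Lc_series[start:end], f[start:end])
        events.append(
            UnfoldingEvent(index=p, peak_force=float(f[p]),
                           contour_length_before=before, contour_length_after=after)
        )
    return events


def detect_unfolding_events(
    trace: ForceExtensionTrace,
    Lc_series: np.ndarray,
    min_peak_force: float = 30.0,
    min_delta_Lc: float = 8.0,
    drop_fraction: float = 0.25,
) -> list[UnfoldingEvent]:
    """Detect force peaks followed by a relative force drop, with the contour
    lengths of the flanking stretches.

    A peak qualifies if its force exceeds `min_peak_force` and the force
    falls by at least `drop_fraction` of the peak value before the next
    qualifying peak (or the end of the trace). The contour length before/
    after each event is the mode of the Lc histogram on the flanking
    stretch; for the final (detachment) event the after-value is NaN.
    Non-terminal events whose contour-length increment is defined and
    smaller than `min_delta_Lc` (noise blips that do not lengthen the
    tether) are discarded, their flanking stretches merged, and the modes
    recomputed until the event list is stable.
    """
    f = trace.force
    peaks, _ = find_peaks(f, height=min_peak_force, prominence=drop_fraction * min_peak_force)
    kept: list[int] = []
    for p in peaks:
        nxt = f[p + 1 :]
        if nxt.size == 0:
            continue
        if f[p] - nxt.min() >= drop_fraction * f[p]:
            kept.append(int(p))
    # collapse runs of peaks without an intervening sufficient drop
    final_peaks: list[int] = []
    for p in kept:
        if final_peaks:
            seg = f[final_peaks[-1] : p + 1]
            if seg.min() > (1 - drop_fraction) * f[final_peaks[-1]]:
                if f[p] > f[final_peaks[-1]]:
                    final_peaks[-1] = p
                continue
        final_peaks.append(p)

    events = _events_from_peaks(f, Lc_series, final_peaks, trace.n_samples, drop_fraction)
    for _ in range(10):
        small = [
            e.index
            for e in events[:-1]
            if np.isfinite(e.delta_Lc) and e.delta_Lc < min_delta_Lc
        ]
        if not small:
            break
        final_peaks = [p for p in final_peaks if p not in small]
        events = _events_from_peaks(f, Lc_series, final_peaks, trace.n_samples, drop_fraction)
    return events


def classify_fingerprint(
    events: Sequence[UnfoldingEvent],
    expected_delta_Lcs: Sequence[float] = (15.0, 16.0),
    tolerance: float = 2.0,
) -> bool:
    """True iff the events contain, in order, one contour-length increment
    matching each expected step within +/- tolerance, all before the final
    rupture.

    This is the certification that the characteristic two-step unfolding of
    the ddFLN4 fingerprint domain occurred directly before the complex
    ruptured, i.e. that a specific single tether was loaded.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be strictly positive")
    increments = [e.delta_Lc for e in events[:-1] if np.isfinite(e.delta_Lc)]
    if len(events) < len(expected_delta_Lcs) + 1:
        return False
    pos = 0
    for expected in expected_delta_Lcs:
        found = False
        while pos < len(increments):
            if abs(increments[pos] - expected) <= tolerance:
                found = True
                pos += 1
                break
            pos += 1
        if not found:
            return False
    return True


def extract_rupture(
    trace: ForceExtensionTrace,
    events: Sequence[UnfoldingEvent],
    fit_fraction: float = 0.25,
    fingerprint_valid: bool = False,
    baseline_force: float = 15.0,
) -> RuptureEvent:
    """Terminal rupture force and loading rate of a trace.

    The rupture force is the force at the last detected peak before final
    detachment (the force must return to baseline afterwards). The loading
    rate is the least-squares slope of force vs time over the last
    `fit_fraction` of the final rising flank — the loading immediately
    before rupture.
    """
    if not events:
        raise ValueError("no events: trace has no detectable rupture")
    last = events[-1]
    tail = trace.force[last.index + 1 :]
    if tail.size == 0 or tail.min() > baseline_force:
        raise ValueError("no terminal detachment: force does not return to baseline")
    # final rising flank: from the preceding valley to the rupture peak;
    # fit on its top force fraction (the loading immediately before rupture).
    # The window is the contiguous run scanned back from the peak — a
    # per-sample force cut would preferentially admit upward noise at the
    # window edge and bias the slope downward.
    start = events[-2].index + 1 if len(events) > 1 else 0
    seg = trace.force[start : last.index + 1]
    valley = start + int(np.argmin(seg))
    threshold = (1.0 - fit_fraction) * trace.force[last.index]
    i0 = last.index
    while i0 > valley and trace.force[i0 - 1] >= threshold:
        i0 -= 1
    if last.index - i0 < 2:
        i0 = max(last.index - 2, 0)
    idx = np.arange(i0, last.index + 1)
    slope = float(np.polyfit(trace.time[idx], trace.force[idx], 1)[0])
    return RuptureEvent(
        rupture_force=float(trace.force[last.index]),
        loading_rate=slope,
        fingerprint_valid=fingerprint_valid,
        spot_label=str(trace.metadata.get("spot_label", "")),
        trace_id=trace.trace_id,
    )


def filter_traces(
    traces: Sequence[ForceExtensionTrace],
    force_threshold: float = 50.0,
) -> list[ForceExtensionTrace]:
    """Keep traces whose maximum force exceeds `force_threshold` (pN).

    The 50 pN default separates genuine tip-surface interactions from
    empty approach-retraction cycles. Kept/discarded counts are logged.
    """
    if force_threshold < 0:
        raise ValueError("force threshold must be nonnegative")
    kept = [t for t in traces if t.force.max() > force_threshold]
    logger.info(
        "filter_traces: kept %d of %d traces above %.1f pN (discarded %d)",
        len(kept), len(traces), force_threshold, len(traces) - len(kept),
    )
    return kept
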