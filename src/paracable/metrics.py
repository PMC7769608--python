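"""Action-potential metrics extracted from simulation traces.

Amplitude is the peak-to-afterpotential voltage span (V_max minus the most
negative voltage after the peak), width is the full duration at half that
amplitude, and conduction velocity is the node-4 to node-16 distance divided
by the peak-time difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cable import SimulationTrace
from .geometry import AxonGeometry

DEFAULT_DETECTION_THRESHOLD_MV = -20.0


class WidthError(ValueError):
    """Raised when the half-amplitude level is never re-crossed."""


class OrderingError(ValueError):
    """Raised when spike peak times are not causally ordered."""


@dataclass(frozen=True)
class SpikeEvent:
    node: int  # 1-based
    peak_time_ms: float
    peak_voltage_mV: float
    trough_voltage_mV: float

    @property
    def amplitude_mV(self) -> float:
        return self.peak_voltage_mV - self.trough_voltage_mV


@dataclass(frozen=True)
class ConductionResult:
    velocity_m_s: float | None
    amplitude_mV: float | None
    width_ms: float | None
    failed: bool
    nodes: tuple[int, int] = (4, 16)


def _parabolic_refine(t: np.ndarray, v: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample peak location by parabola through (i-1, i, i+1)."""
    if i == 0 or i == len(v) - 1:
        return float(t[i]), float(v[i])
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not a local max in the parabolic sense
        return float(t[i]), float(v[i])
    delta = 0.5 * (y0 - y2) / denom
    dt = t[i + 1] - t[i]
    return float(t[i] + delta * dt), float(y1 - 0.25 * (y0 - y2) * delta)


def detect_spike(
    trace: SimulationTrace,
    node: int,
    threshold_mV: float = DEFAULT_DETECTION_THRESHOLD_MV,
    t_min_ms: float = 0.0,
) -> SpikeEvent | None:
    """Find the evoked spike at a node, or None if no threshold crossing.

    A spike exists iff the voltage crosses ``threshold_mV`` upward at or
    after ``t_min_ms``; the peak is the global maximum after the crossing
    (parabolically refined) and the trough the minimum after the peak.
    """
    t = trace.time_ms
    v = trace.node(node)
    sel = t >= t_min_ms
    t, v = t[sel], v[sel]
    above = np.nonzero(v >= threshold_mV)[0]
    if len(above) == 0:
        return None
    start = above[0]
    i_peak = start + int(np.argmax(v[start:]))
    peak_t, peak_v = _parabolic_refine(t, v, i_peak)
    trough = float(np.min(v[i_peak:]))
    return SpikeEvent(node, peak_t, peak_v, trough)


def ap_width(spike: SpikeEvent, trace: SimulationTrace, t_min_ms: float = 0.0) -> float:
    """Full width (ms) at half amplitude, linearly interpolated at crossings."""
    t = trace.time_ms
    v = trace.node(spike.node)
    sel = t >= t_min_ms
    t, v = t[sel], v[sel]
    level = spike.trough_voltage_mV + spike.amplitude_mV / 2.0

    i_peak = int(np.argmin(np.abs(t - spike.peak_time_ms)))
    above = v >= level

    # walk outward from the peak to the last contiguous above-level samples
    if not above[i_peak]:
        raise WidthError("peak sample below half-amplitude level")
    i_lo = i_peak
    while i_lo > 0 and above[i_lo - 1]:
        i_lo -= 1
    i_hi = i_peak
    while i_hi < len(v) - 1 and above[i_hi + 1]:
        i_hi += 1
    if i_hi == len(v) - 1:
        raise WidthError("half-amplitude level never re-crossed before trace end")

    def interp_cross(i_in: int, i_out: int) -> float:
        v_in, v_out = v[i_in], v[i_out]
        frac = (level - v_in) / (v_out - v_in)
        return float(t[i_in] + frac * (t[i_out] - t[i_in]))

    t_rise = interp_cross(i_lo, i_lo - 1) if i_lo > 0 else float(t[0])
    t_fall = interp_cross(i_hi, i_hi + 1)
    return t_fall - t_rise


def conduction_velocity(
    trace: SimulationTrace,
    geometry: AxonGeometry,
    nodes: tuple[int, int] = (4, 16),
    threshold_mV: float = DEFAULT_DETECTION_THRESHOLD_MV,
) -> ConductionResult:
    """Conduction velocity between two nodes from spike peak times, m/s.

    Distance is the node-midpoint separation from the geometry.  Failure is
    flagged when the distal node shows no threshold crossing within the
    trace window; amplitude and width are reported at the distal node.
    """
    near, far = nodes
    spike_near = detect_spike(trace, near, threshold_mV)
    spike_far = detect_spike(trace, far, threshold_mV)
    if spike_far is None or spike_near is None:
        return ConductionResult(None, None, None, failed=True, nodes=nodes)

    positions = geometry.node_positions()
    dist_um = abs(positions[far - 1] - positions[near - 1])
    dt_ms = spike_far.peak_time_ms - spike_near.peak_time_ms
    if dt_ms <= 0:
        raise OrderingError(
            f"non-positive peak-time difference {dt_ms} ms between nodes {nodes}"
        )
    velocity = dist_um / dt_ms * 1e-3  # um/ms -> m/s
    return ConductionResult(
        velocity_m_s=velocity,
        amplitude_mV=spike_far.amplitude_mV,
        width_ms=ap_width(spike_far, trace),
        failed=False,
        nodes=nodes,
    )
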