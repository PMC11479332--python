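"""Centre-of-mass and respiration signals from four-channel load-cell traces.

A bed instrumented with one vertical load cell under each leg measures the
combined weight of the frame and its occupant. Denoting the corner forces
LH, RH (head end, left/right) and LF, RF (foot end), the planar centre of
mass follows from moment balance about the two bed axes:

    CoM_x = (w/2) * (LH + LF - RH - RF) / (LH + RH + LF + RF)
    CoM_y = (l/2) * (LH + RH - LF - RF) / (LH + RH + LF + RF)

with l, w the load-cell spacings along the bed length and width. Breathing
moves the occupant's centre of mass by a fraction of a millimetre each
cycle; a zero-phase low-pass isolates that component (CoM_resp), whose
trajectory traces an ellipse whose principal-axis angle

    ang = arctan[(CoM_resp_y(tmax) - CoM_resp_y(tmin)) /
                 (CoM_resp_x(tmax) - CoM_resp_x(tmin))]

depends on body orientation. Maxima tmax and minima tmin of the respiration
signal mark the ends of exhalation and inhalation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

CHANNELS = ("LH", "RH", "LF", "RF")


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but analytically degenerate."""


@dataclass(frozen=True)
class BedModel:
    """Load-cell geometry and frame properties of the instrumented bed."""

    length_l: float = 2.0
    width_w: float = 0.9
    frame_mass: float = 60.0
    gravity: float = 9.81

    def __post_init__(self) -> None:
        if self.length_l <= 0 or self.width_w <= 0:
            raise ValueError("bed dimensions must be positive")
        if self.frame_mass < 0:
            raise ValueError("frame_mass must be >= 0")


@dataclass
class ForceTrace:
    """Uniformly sampled vertical forces at the four bed corners (newtons)."""

    time: np.ndarray
    LH: np.ndarray
    RH: np.ndarray
    LF: np.ndarray
    RF: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in CHANNELS:
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length != time length")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("time must be strictly increasing and uniform")

    @property
    def rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def channel_sum(self) -> np.ndarray:
        return self.LH + self.RH + self.LF + self.RF

    def channels(self) -> np.ndarray:
        """(n, 4) array in LH, RH, LF, RF order."""
        return np.column_stack([self.LH, self.RH, self.LF, self.RF])

    def slice(self, start: int, stop: int) -> "ForceTrace":
        return ForceTrace(
            self.time[start:stop],
            self.LH[start:stop],
            self.RH[start:stop],
            self.LF[start:stop],
            self.RF[start:stop],
        )


@dataclass
class CoMTrace:
    """Planar centre of mass relative to the bed centre (metres)."""

    time: np.ndarray
    com_x: np.ndarray
    com_y: np.ndarray

    @property
    def rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])


@dataclass
class RespTrace:
    """Respiration-band CoM components with breath extrema indices."""

    time: np.ndarray
    resp_x: np.ndarray
    resp_y: np.ndarray
    tmax_indices: np.ndarray | None = None
    tmin_indices: np.ndarray | None = None


@dataclass(frozen=True)
class FilterSpec:
    """Chebyshev type II low-pass specification for respiration isolation.

    ``cutoff=None`` selects personalization: the cutoff is set to 1.5x the
    dominant 0.1-0.5 Hz peak of the CoM power spectrum of the recording
    being filtered.
    """

    order: int = 4
    stopband_attenuation: float = 40.0
    cutoff: float | None = None
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError("order must be >= 2")
        if self.cutoff is not None and not 0 < self.cutoff < 25.0:
            raise ValueError("cutoff must lie in (0, 25) Hz")


def compute_com(trace: ForceTrace, bed: BedModel) -> CoMTrace:
    """Centre of mass from corner forces by moment balance.

    Raises :class:`DegenerateInputError` if the channel sum is not strictly
    positive at every sample (the moment balance divides by it).
    """
    total = trace.channel_sum()
    bad = np.flatnonzero(total <= 0)
    if bad.size:
        raise DegenerateInputError(
            f"non-positive total force at sample {bad[0]} "
            f"(t={trace.time[bad[0]]:.3f} s)"
        )
    com_x = 0.5 * bed.width_w * (trace.LH + trace.LF - trace.RH - trace.RF) / total
    com_y = 0.5 * bed.length_l * (trace.LH + trace.RH - trace.LF - trace.RF) / total
    return CoMTrace(trace.time, com_x, com_y)


def estimate_resp_frequency(
    com: CoMTrace, band: tuple[float, float] = (0.1, 0.5)
) -> float:
    """Dominant respiration frequency from the CoM power spectrum.

    The periodogram of the demeaned x and y components is summed and the
    peak inside ``band`` returned; if the band holds no power the band
    centre is returned.
    """
    fs = com.rate
    n = len(com.com_x)
    psd = np.zeros(n // 2 + 1)
    for comp in (com.com_x, com.com_y):
        f, p = sps.periodogram(comp - comp.mean(), fs=fs)
        psd += p
    mask = (f >= band[0]) & (f <= band[1])
    if not mask.any() or psd[mask].max() <= 0:
        return 0.5 * (band[0] + band[1])
    return float(f[mask][np.argmax(psd[mask])])


def _lowpass_sos(cutoff: float, fs: float, spec: FilterSpec):
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {fs / 2} Hz")
    return sps.cheby2(
        spec.order, spec.stopband_attenuation, cutoff, btype="low", fs=fs, output="sos"
    )


def isolate_respiration(com: CoMTrace, spec: FilterSpec = FilterSpec()) -> RespTrace:
    """Zero-phase Chebyshev-II low-pass of both CoM components.

    With ``spec.cutoff is None`` the cutoff is personalized to 1.5x the
    recording's dominant respiration frequency (clipped to [0.15, 1.5] Hz).
    Forward-backward filtering gives zero net phase, so breath extrema in
    the output are time-aligned with the underlying breaths.
    """
    fs = com.rate
    cutoff = spec.cutoff
    if cutoff is None:
        cutoff = float(np.clip(1.5 * estimate_resp_frequency(com), 0.15, 1.5))
    sos = _lowpass_sos(cutoff, fs, spec)
    resp_x = sps.sosfiltfilt(sos, com.com_x)
    resp_y = sps.sosfiltfilt(sos, com.com_y)
    return RespTrace(com.time, resp_x, resp_y)


def detect_breath_extrema(resp_signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima via derivative sign changes.

    The forward difference's sign is tracked with exact zeros carrying the
    previous sign; a +→− change marks a maximum, −→+ a minimum. Alternation
    is enforced by keeping only the more prominent member of any same-type
    adjacent pair, so maxima and minima strictly alternate in the output.
    A monotone signal yields empty arrays.
    """
    x = np.asarray(resp_signal, dtype=float)
    if len(x) < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    d = np.diff(x)
    sign = np.sign(d)
    # carry previous sign across exact zeros
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    events: list[tuple[int, int]] = []  # (index, +1 max / -1 min)
    for i in range(1, len(sign)):
        if sign[i - 1] > 0 and sign[i] < 0:
            events.append((i, +1))
        elif sign[i - 1] < 0 and sign[i] > 0:
            events.append((i, -1))
    # enforce alternation: among same-type runs keep the extreme sample
    pruned: list[tuple[int, int]] = []
    for idx, kind in events:
        if pruned and pruned[-1][1] == kind:
            prev_idx, _ = pruned[-1]
            if kind == +1:
                keep = idx if x[idx] > x[prev_idx] else prev_idx
            else:
                keep = idx if x[idx] < x[prev_idx] else prev_idx
            pruned[-1] = (keep, kind)
        else:
            pruned.append((idx, kind))
    tmax = np.array([i for i, k in pruned if k == +1], dtype=int)
    tmin = np.array([i for i, k in pruned if k == -1], dtype=int)
    return tmax, tmin


def com_resp_angle(resp: RespTrace, tmax: int, tmin: int) -> float:
    """Principal-axis angle (degrees) of one breath's CoM excursion.

    Computed from the respiration-band CoM displacement between a maximum
    and the subsequent minimum; range (−90°, 90°], with a vertical
    excursion (zero x-difference) mapped to the 90° limit.
    """
    dy = resp.resp_y[tmax] - resp.resp_y[tmin]
    dx = resp.resp_x[tmax] - resp.resp_x[tmin]
    if dx == 0:
        return 90.0
    return float(np.degrees(np.arctan(dy / dx)))


def breath_angle_series(resp: RespTrace, extrema_axis: str = "auto") -> np.ndarray:
    """Per-breath principal-axis angles for every (tmax, next tmin) pair.

    Extrema are detected on the respiration component with the larger
    variance when ``extrema_axis='auto'`` (or on ``'x'``/``'y'``
    explicitly); each maximum is paired with the first following minimum.
    """
    if extrema_axis == "auto":
        extrema_axis = "x" if np.var(resp.resp_x) >= np.var(resp.resp_y) else "y"
    series = resp.resp_x if extrema_axis == "x" else resp.resp_y
    tmax, tmin = detect_breath_extrema(series)
    angles = []
    for m in tmax:
        following = tmin[tmin > m]
        if following.size:
            angles.append(com_resp_angle(resp, m, int(following[0])))
    return np.asarray(angles, dtype=float)


def pulse_band_filter(
    trace: ForceTrace, band: tuple[float, float] = (0.8, 2.5), order: int = 4
) -> np.ndarray:
    """Zero-phase band-pass of all four channels for the cardiac band.

    Returns an (n, 4) array. The ballistocardiographic recoil of each heart
    beat sits above the respiration band; the default 0.8-2.5 Hz window
    covers resting heart rates of 48-150 bpm.
    """
    low, high = band
    fs = trace.rate
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band {band} must satisfy 0 < low < high < Nyquist")
    sos = sps.butter(order, band, btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, trace.channels(), axis=0)
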