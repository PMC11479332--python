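"""Windowed feature extraction from load-cell recordings.

Each held pose is cut into 45-second windows stepped by 15 seconds (2250
samples per window at 50 Hz, roughly ten windows per three-minute pose) and
every window is summarized by twelve features:

=================  ==========================================================
meanCoM_x/_y       mean centre-of-mass coordinates over the window (m)
ratio_meanCoM      meanCoM_y / meanCoM_x
stdCoM_x/_y        standard deviation of the CoM coordinates (m)
ratio_stdCoM       stdCoM_y / stdCoM_x
CoM_resp_ANG       mean per-breath respiration-ellipse angle (degrees)
stdCoM_resp_ANG    standard deviation of the per-breath angles (degrees)
rmsCoM_resp_x/_y   rms of the respiration-band CoM oscillation, normalized
                   to the 97th percentile of the recording's oscillation
ratio_rmsCoM_resp  rmsCoM_resp_y / rmsCoM_resp_x
rmsPulse           rms of the cardiac-band force channels (N)
=================  ==========================================================

Windows without a detectable breath (or with a zero denominator in a ratio)
carry NaN in the affected fields; those are filled by linear interpolation
across the pose's window sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import circmean
from sklearn.ensemble import GradientBoostingClassifier

from .signal import (
    BedModel,
    FilterSpec,
    ForceTrace,
    breath_angle_series,
    compute_com,
    estimate_resp_frequency,
    isolate_respiration,
    pulse_band_filter,
)
from .simulate import SimulatedRecording

FEATURE_NAMES = (
    "meanCoM_x",
    "meanCoM_y",
    "ratio_meanCoM",
    "stdCoM_x",
    "stdCoM_y",
    "ratio_stdCoM",
    "CoM_resp_ANG",
    "stdCoM_resp_ANG",
    "rmsCoM_resp_x",
    "rmsCoM_resp_y",
    "ratio_rmsCoM_resp",
    "rmsPulse",
)

RESP_FEATURES = (
    "CoM_resp_ANG",
    "stdCoM_resp_ANG",
    "rmsCoM_resp_x",
    "rmsCoM_resp_y",
    "ratio_rmsCoM_resp",
)

DEFAULT_PULSE_BAND = (0.8, 2.5)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in seconds."""

    length: float = 45.0
    step: float = 15.0

    def __post_init__(self) -> None:
        if not self.length > self.step > 0:
            raise ValueError("require length > step > 0")

    def n_samples(self, rate: float) -> int:
        return int(round(self.length * rate))

    def step_samples(self, rate: float) -> int:
        return int(round(self.step * rate))


def segment_windows(
    recording: SimulatedRecording, spec: WindowSpec = WindowSpec()
) -> list[tuple[int, int, int]]:
    """Fully contained windows per pose: (segment_index, start, stop) sample spans.

    A pose of N samples yields floor((N - L) / S) + 1 windows with window
    length L and step S; poses shorter than one window contribute none (a
    warning is emitted).
    """
    rate = recording.force_trace.rate
    L = spec.n_samples(rate)
    S = spec.step_samples(rate)
    out: list[tuple[int, int, int]] = []
    for seg_idx, (start, stop, _target) in enumerate(recording.segments):
        n = stop - start
        if n < L:
            warnings.warn(
                f"pose segment {seg_idx} shorter than one window; skipped",
                stacklevel=2,
            )
            continue
        count = (n - L) // S + 1
        for k in range(count):
            s = start + k * S
            out.append((seg_idx, s, s + L))
    return out


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den != 0 else np.nan


def extract_features(
    window: ForceTrace,
    bed: BedModel,
    filter_spec: FilterSpec = FilterSpec(),
    pulse_band: tuple[float, float] = DEFAULT_PULSE_BAND,
    resp_scale: float | None = None,
) -> dict[str, float]:
    """The twelve features of one window.

    ``resp_scale`` is the 97th percentile of the resultant respiration
    oscillation magnitude over the whole participant-phase recording; both
    rms components are normalized by this common scale so their ratio
    still reflects the ellipse orientation. When omitted, the window's own
    scale is used (adequate for isolated windows, but recording-level
    scales keep windows comparable).
    """
    com = compute_com(window, bed)
    mean_x, mean_y = float(com.com_x.mean()), float(com.com_y.mean())
    std_x, std_y = float(com.com_x.std()), float(com.com_y.std())

    resp = isolate_respiration(com, filter_spec)
    osc_x = resp.resp_x - resp.resp_x.mean()
    osc_y = resp.resp_y - resp.resp_y.mean()
    if resp_scale is None:
        resp_scale = float(np.percentile(np.hypot(osc_x, osc_y), 97))
    rms_x = _safe_ratio(float(np.sqrt(np.mean(osc_x**2))), resp_scale)
    rms_y = _safe_ratio(float(np.sqrt(np.mean(osc_y**2))), resp_scale)

    angles = breath_angle_series(resp)
    if angles.size:
        ang_mean = float(angles.mean())
        ang_std = float(angles.std())
    else:
        ang_mean = ang_std = np.nan

    pulse = pulse_band_filter(window, pulse_band)
    rms_pulse = float(np.sqrt(np.mean(pulse**2)))

    return {
        "meanCoM_x": mean_x,
        "meanCoM_y": mean_y,
        "ratio_meanCoM": _safe_ratio(mean_y, mean_x),
        "stdCoM_x": std_x,
        "stdCoM_y": std_y,
        "ratio_stdCoM": _safe_ratio(std_y, std_x),
        "CoM_resp_ANG": ang_mean,
        "stdCoM_resp_ANG": ang_std,
        "rmsCoM_resp_x": rms_x,
        "rmsCoM_resp_y": rms_y,
        "ratio_rmsCoM_resp": _safe_ratio(rms_y, rms_x),
        "rmsPulse": rms_pulse,
    }


def _recording_resp_scale(
    recording: SimulatedRecording,
    bed: BedModel,
    filter_spec: FilterSpec,
) -> float:
    """97th percentile of the pose-demeaned respiration oscillation magnitude."""
    mags = []
    for start, stop, _ in recording.segments:
        com = compute_com(recording.force_trace.slice(start, stop), bed)
        resp = isolate_respiration(com, filter_spec)
        mags.append(
            np.hypot(
                resp.resp_x - resp.resp_x.mean(),
                resp.resp_y - resp.resp_y.mean(),
            )
        )
    return float(np.percentile(np.concatenate(mags), 97))


def features_from_recording(
    recording: SimulatedRecording,
    bed: BedModel,
    window_spec: WindowSpec = WindowSpec(),
    filter_spec: FilterSpec | None = None,
    pulse_band: tuple[float, float] = DEFAULT_PULSE_BAND,
    impute: bool = True,
) -> pd.DataFrame:
    """Feature table for one recording: one row per window.

    With ``filter_spec=None`` the respiration low-pass is personalized once
    per recording (cutoff = 1.5x the dominant breathing frequency of the
    whole recording) and reused for every window, so all of a participant's
    windows see the same filter. Ground-truth TPA per window is the
    circular mean of the per-sample truth, mapped back to (-180, 180].
    """
    if filter_spec is None:
        # estimate the breathing rate per pose and pool with the median:
        # a whole-recording spectrum is dominated by pose-to-pose CoM steps
        freqs = []
        for start, stop, _ in recording.segments:
            com_seg = compute_com(recording.force_trace.slice(start, stop), bed)
            freqs.append(estimate_resp_frequency(com_seg))
        cutoff = float(np.clip(1.5 * np.median(freqs), 0.15, 1.5))
        filter_spec = FilterSpec(cutoff=cutoff)
    scale = _recording_resp_scale(recording, bed, filter_spec)

    rows = []
    windows = segment_windows(recording, window_spec)
    for w_idx, (seg_idx, start, stop) in enumerate(windows):
        feats = extract_features(
            recording.force_trace.slice(start, stop),
            bed,
            filter_spec,
            pulse_band,
            resp_scale=scale,
        )
        truth = float(
            np.degrees(
                circmean(np.radians(recording.truth_tpa[start:stop]))
            )
        )
        if truth > 180.0:
            truth -= 360.0
        feats.update(
            truth_tpa=truth,
            participant_id=recording.participant_id,
            phase=recording.protocol_phase,
            pose_index=seg_idx,
            window_index=w_idx,
        )
        rows.append(feats)
    df = pd.DataFrame(
        rows,
        columns=list(FEATURE_NAMES)
        + ["truth_tpa", "participant_id", "phase", "pose_index", "window_index"],
    )
    if impute and len(df):
        df = (
            df.groupby("pose_index", group_keys=False)[df.columns]
            .apply(impute_missing)
            .reset_index(drop=True)
        )
    return df


def impute_missing(pose_features: pd.DataFrame) -> pd.DataFrame:
    """Fill NaN feature fields within one pose's window sequence.

    Linear interpolation across the windows of the pose, nearest value at
    the edges. A pose in which some field is missing everywhere is dropped
    with a warning (there is nothing to interpolate from).
    """
    df = pose_features.copy()
    cols = [c for c in FEATURE_NAMES if c in df.columns]
    if df[cols].isna().all(axis=0).any():
        bad = [c for c in cols if df[c].isna().all()]
        warnings.warn(
            f"pose dropped: field(s) {bad} missing in every window", stacklevel=2
        )
        return df.iloc[0:0]
    df[cols] = (
        df[cols].interpolate(method="linear", limit_direction="both", axis=0)
    )
    return df


def rank_feature_importance(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    seed: int = 0,
    n_estimators: int = 100,
) -> pd.Series:
    """Impurity-based feature importances from a gradient-boosted-tree fit.

    Returns importances over the twelve features, normalized to sum to 1
    and sorted descending. Requires at least two classes.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("feature importance needs >= 2 classes")
    X = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        med = np.nanmedian(X, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    X = np.where(np.isnan(X), med, X)
    model = GradientBoostingClassifier(
        n_estimators=n_estimators, random_state=seed
    ).fit(X, y)
    imp = np.clip(model.feature_importances_, 0.0, None)  # fp dust can go <0
    imp = imp / imp.sum()
    return pd.Series(imp, index=list(FEATURE_NAMES)).sort_values(ascending=False)
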