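"""Synthetic four-channel load-cell recordings for virtual bed occupants.

Real recordings of this kind come from a hospital bed standing on four
single-axis load cells while a participant holds a series of known
transverse pelvic angles (TPA). No such data ships with this package, so
this module synthesizes it from a minimal physical model:

* The static corner forces are the unique solution that (a) sums to the
  total weight, (b) reproduces a configured centre of mass through the
  moment-balance relations used by :func:`bedpose.signal.compute_com`, and
  (c) has zero diagonal force difference (the remaining degree of freedom,
  which the moment balance does not constrain).
* Respiration moves the centre of mass sinusoidally with a small amplitude
  along a direction that depends on the held TPA (``resp_angle_map``), so
  the respiration-ellipse angle carries the posture information the
  downstream features rely on.
* The cardiac cycle adds a small ballistocardiographic force sinusoid, and
  each channel carries additive white sensor noise.
* Within a held pose the realized TPA wanders slowly but is kept within
  +/-5 degrees of the target, emulating an experimenter nudging the
  participant back on target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .signal import BedModel, ForceTrace

DEFAULT_RATE = 50.0
POSE_TOLERANCE_DEG = 5.0

#: primary pose angles of the scripted protocol (degrees)
PRIMARY_ANGLES = (0, 15, -15, 30, -30, 45, -45, 60, -60, 90, -90)


class InvalidConfigurationError(ValueError):
    """Simulation parameters produce a physically impossible recording."""


def default_resp_angle_map(tpa_deg: np.ndarray | float) -> np.ndarray | float:
    """Respiration-ellipse principal-axis angle (degrees) for a given TPA.

    Monotone in TPA on (-180, 180], zero when supine and saturating toward
    +/-75 degrees when fully rolled, so the three coarse classes and the
    finer side bins occupy distinct angle ranges while staying inside the
    (-90, 90] range an arctangent can recover.
    """
    return 75.0 * np.sin(np.radians(np.asarray(tpa_deg, dtype=float) / 2.0))


@dataclass(frozen=True)
class VirtualParticipant:
    """Anthropometrics and signal parameters of one simulated occupant.

    Defaults describe a typical adult of the emulated cohort (mean body
    mass 77.9 kg, height 1.744 m) breathing at 15 breaths/min with a
    2.5 mm centre-of-mass excursion per breath.
    """

    mass: float = 77.9
    height: float = 1.744
    com_longitudinal_frac: float = 0.45
    #: habitual lateral lying position relative to the bed midline (m);
    #: differs between people, which makes the static CoM an unreliable
    #: posture cue across participants (as for real occupants)
    lateral_offset: float = 0.0
    lateral_shift_coeff: float = 0.025
    resp_rate: float = 0.25
    resp_amplitude: float = 0.0025
    resp_angle_map: Callable[[np.ndarray], np.ndarray] = default_resp_angle_map
    cardiac_rate: float = 1.1
    cardiac_amplitude: float = 0.5
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 40 <= self.mass <= 130:
            raise ValueError("mass must lie in [40, 130] kg")
        if not 0.1 <= self.resp_rate <= 0.5:
            raise ValueError("resp_rate must lie in [0.1, 0.5] Hz")
        if self.resp_amplitude <= 0:
            raise ValueError("resp_amplitude must be positive")
        if self.cardiac_rate <= self.resp_rate:
            raise ValueError("cardiac_rate must exceed resp_rate")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PoseProtocol:
    """Ordered pose segments: (target TPA degrees, duration s, jitter sd degrees)."""

    segments: tuple[tuple[float, float, float], ...]
    #: parallel flags marking scripted primary poses (vs intermediate holds)
    primary: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if not self.primary:
            object.__setattr__(self, "primary", (True,) * len(self.segments))
        for tpa, dur, jit in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")
            if abs(tpa) > 180:
                raise ValueError("target TPA must lie in [-180, 180]")
            if jit < 0:
                raise ValueError("jitter sd must be >= 0")

    @property
    def n_primary(self) -> int:
        return int(sum(self.primary))

    def primary_angles(self) -> tuple[float, ...]:
        return tuple(s[0] for s, p in zip(self.segments, self.primary) if p)


@dataclass
class SimulatedRecording:
    """One participant-phase recording with per-sample ground truth."""

    force_trace: ForceTrace
    truth_tpa: np.ndarray
    participant_id: str
    protocol_phase: str
    #: per pose: (start_sample, stop_sample, target_tpa)
    segments: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.truth_tpa) != self.force_trace.n_samples:
            raise ValueError("truth_tpa length must match the force trace")


@dataclass
class CohortMember:
    participant_id: str
    participant: VirtualParticipant
    phase_one: SimulatedRecording
    phase_two: SimulatedRecording


def _tpa_jitter(n: int, jitter_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Slow bounded wander of the realized TPA around its target.

    Low-pass-filtered white noise rescaled to ``jitter_sd`` and clipped just
    inside the +/-5 degree correction tolerance.
    """
    if jitter_sd == 0 or n == 0:
        return np.zeros(n)
    raw = rng.standard_normal(n)
    # single-pole smoothing: ~30 s correlation time at 50 Hz
    alpha = 0.999
    out = np.empty(n)
    acc = 0.0
    for i in range(n):
        acc = alpha * acc + (1 - alpha) * raw[i]
        out[i] = acc
    sd = out.std()
    if sd > 0:
        out *= jitter_sd / sd
    return np.clip(out, -(POSE_TOLERANCE_DEG - 0.1), POSE_TOLERANCE_DEG - 0.1)


def _corner_forces(
    total: np.ndarray, com_x: np.ndarray, com_y: np.ndarray, bed: BedModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Invert the moment balance: unique corner forces with zero diagonal term."""
    dx = total * 2.0 * com_x / bed.width_w
    dy = total * 2.0 * com_y / bed.length_l
    lh = (total + dx + dy) / 4.0
    rh = (total - dx + dy) / 4.0
    lf = (total + dx - dy) / 4.0
    rf = (total - dx - dy) / 4.0
    return lh, rh, lf, rf


def _synthesize(
    participant: VirtualParticipant,
    bed: BedModel,
    tpa_deg: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    t0: float = 0.0,
) -> ForceTrace:
    """Force channels for a per-sample TPA series."""
    n = len(tpa_deg)
    t = t0 + np.arange(n) / rate
    weight = (participant.mass + bed.frame_mass) * bed.gravity

    tpa_rad = np.radians(tpa_deg)
    base_x = participant.lateral_offset + participant.lateral_shift_coeff * tpa_rad
    base_y = (participant.com_longitudinal_frac - 0.5) * bed.length_l

    breath_phase = rng.uniform(0, 2 * np.pi)
    breath = participant.resp_amplitude * np.sin(
        2 * np.pi * participant.resp_rate * t + breath_phase
    )
    ang = np.radians(np.asarray(participant.resp_angle_map(tpa_deg), dtype=float))
    com_x = base_x + breath * np.cos(ang)
    com_y = base_y + breath * np.sin(ang)

    if np.any(np.abs(com_x) > bed.width_w / 2) or np.any(
        np.abs(com_y) > bed.length_l / 2
    ):
        raise InvalidConfigurationError(
            "configured motion drives the CoM outside the load-cell footprint"
        )

    total = np.full(n, weight)
    lh, rh, lf, rf = _corner_forces(total, com_x, com_y, bed)

    cardiac_phase = rng.uniform(0, 2 * np.pi)
    cardiac = (
        participant.cardiac_amplitude
        * np.sin(2 * np.pi * participant.cardiac_rate * t + cardiac_phase)
        / 4.0
    )
    channels = [c + cardiac for c in (lh, rh, lf, rf)]
    if participant.noise_sd > 0:
        channels = [
            c + rng.normal(0, participant.noise_sd, n) for c in channels
        ]
    return ForceTrace(t, *channels)


def simulate_pose(
    participant: VirtualParticipant,
    bed: BedModel,
    tpa: float,
    duration: float,
    rate: float = DEFAULT_RATE,
    jitter_sd: float = 0.0,
    participant_id: str = "p0",
) -> SimulatedRecording:
    """Simulate one held pose at a fixed target TPA.

    ``duration`` must cover at least one breath so the respiration
    signature is present in the record.
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    if duration < 1.0 / participant.resp_rate:
        raise ValueError("duration must cover at least one breath period")
    rng = np.random.default_rng(participant.seed)
    n = int(round(duration * rate))
    tpa_series = tpa + _tpa_jitter(n, jitter_sd, rng)
    trace = _synthesize(participant, bed, tpa_series, rate, rng)
    return SimulatedRecording(
        trace, tpa_series, participant_id, "one", [(0, n, tpa)]
    )


def simulate_protocol(
    participant: VirtualParticipant,
    bed: BedModel,
    protocol: PoseProtocol,
    phase: str,
    rate: float = DEFAULT_RATE,
    participant_id: str = "p0",
    seed: int | None = None,
) -> SimulatedRecording:
    """Simulate a full pose protocol as one continuous recording.

    Transition intervals between poses are not synthesized: segment
    boundaries delimit clean per-pose trials, mirroring data that has
    already had positional-change intervals removed.
    """
    rng = np.random.default_rng(participant.seed if seed is None else seed)
    traces: list[ForceTrace] = []
    truths: list[np.ndarray] = []
    bounds: list[tuple[int, int, float]] = []
    cursor = 0
    for tpa, duration, jitter_sd in protocol.segments:
        n = int(round(duration * rate))
        tpa_series = tpa + _tpa_jitter(n, jitter_sd, rng)
        traces.append(
            _synthesize(participant, bed, tpa_series, rate, rng, t0=cursor / rate)
        )
        truths.append(tpa_series)
        bounds.append((cursor, cursor + n, tpa))
        cursor += n
    full = ForceTrace(
        np.concatenate([tr.time for tr in traces]),
        np.concatenate([tr.LH for tr in traces]),
        np.concatenate([tr.RH for tr in traces]),
        np.concatenate([tr.LF for tr in traces]),
        np.concatenate([tr.RF for tr in traces]),
    )
    return SimulatedRecording(
        full, np.concatenate(truths), participant_id, phase, bounds
    )


def phase_one_protocol(
    seed: int = 0,
    primary_duration: float = 180.0,
    intermediate_duration: float = 60.0,
    jitter_sd: float = 2.0,
) -> PoseProtocol:
    """The scripted protocol: 11 primary poses with intermediate holds.

    Primary poses cover 0, +/-15, +/-30, +/-45, +/-60 and +/-90 degrees,
    each held for three minutes by default. One-minute intermediate holds
    separate consecutive primaries — supine in general, with a 90-degree
    side hold staged immediately before each fully rolled primary.
    """
    del seed  # the scripted order is fixed; kept for interface symmetry
    segments: list[tuple[float, float, float]] = []
    primary_flags: list[bool] = []
    for i, angle in enumerate(PRIMARY_ANGLES):
        if i > 0:
            inter = 0.0
            if angle == 90:
                inter = 90.0
            elif angle == -90:
                inter = -90.0
            segments.append((inter, intermediate_duration, jitter_sd))
            primary_flags.append(False)
        segments.append((float(angle), primary_duration, jitter_sd))
        primary_flags.append(True)
    return PoseProtocol(tuple(segments), tuple(primary_flags))


def phase_two_protocol(
    seed: int = 0,
    n_poses: int = 10,
    duration: float = 180.0,
    jitter_sd: float = 2.0,
) -> PoseProtocol:
    """Free-choice protocol: ``n_poses`` random targets in (-180, 180] degrees."""
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    rng = np.random.default_rng(seed)
    # uniform on (-180, 180]
    angles = 180.0 - rng.uniform(0.0, 360.0, size=n_poses)
    segments = tuple((float(a), duration, jitter_sd) for a in angles)
    return PoseProtocol(segments)


def sample_participant(rng: np.random.Generator, seed: int) -> VirtualParticipant:
    """Draw one participant from the emulated cohort distribution.

    Body mass and height are normal around the cohort means (77.9 +/- 19.2 kg,
    1.744 +/- 0.106 m), truncated to plausible adult ranges; breathing and
    cardiac parameters vary within resting physiological ranges.
    """
    mass = float(np.clip(rng.normal(77.9, 19.2), 45.0, 125.0))
    height = float(np.clip(rng.normal(1.744, 0.106), 1.50, 2.05))
    return VirtualParticipant(
        mass=mass,
        height=height,
        com_longitudinal_frac=float(rng.uniform(0.42, 0.50)),
        lateral_offset=float(rng.uniform(-0.05, 0.05)),
        lateral_shift_coeff=float(rng.uniform(0.015, 0.035)),
        resp_rate=float(rng.uniform(0.2, 0.33)),
        resp_amplitude=float(rng.uniform(0.0018, 0.0035)),
        cardiac_rate=float(rng.uniform(0.9, 1.4)),
        cardiac_amplitude=float(rng.uniform(0.3, 0.8)),
        noise_sd=0.5,
        seed=seed,
    )


def generate_cohort(
    n: int,
    bed: BedModel | None = None,
    master_seed: int = 0,
    rate: float = DEFAULT_RATE,
    primary_duration: float = 180.0,
    intermediate_duration: float = 60.0,
    n_random_poses: int = 10,
    random_pose_duration: float = 180.0,
    noise_sd: float | None = None,
    jitter_sd: float = 2.0,
) -> list[CohortMember]:
    """Simulate scripted and free-choice recordings for ``n`` participants.

    Per-participant seeds are spawned deterministically from
    ``master_seed``; the same master seed reproduces the cohort exactly.
    ``noise_sd`` overrides the sensor-noise level for every participant
    (useful for noise-free oracle checks).
    """
    if n < 2:
        raise ValueError("a cohort needs n >= 2 (leave-one-out requires it)")
    bed = bed or BedModel()
    children = np.random.SeedSequence(master_seed).spawn(n)
    members: list[CohortMember] = []
    for i, child in enumerate(children):
        sub = child.generate_state(3) % (2**31)
        rng = np.random.default_rng(int(sub[0]))
        participant = sample_participant(rng, seed=int(sub[1]))
        if noise_sd is not None:
            participant = replace(participant, noise_sd=noise_sd)
        pid = f"p{i:02d}"
        proto1 = phase_one_protocol(
            seed=int(sub[1]),
            primary_duration=primary_duration,
            intermediate_duration=intermediate_duration,
            jitter_sd=jitter_sd,
        )
        proto2 = phase_two_protocol(
            seed=int(sub[2]),
            n_poses=n_random_poses,
            duration=random_pose_duration,
            jitter_sd=jitter_sd,
        )
        rec1 = simulate_protocol(
            participant, bed, proto1, "one", rate, pid, seed=int(sub[1])
        )
        rec2 = simulate_protocol(
            participant, bed, proto2, "two", rate, pid, seed=int(sub[2]) + 1
        )
        members.append(CohortMember(pid, participant, rec1, rec2))
    return members
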