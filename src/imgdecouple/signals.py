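"""Raw sensor ingestion and six-degree-of-freedom head-CG kinematics.

An instrumented mouthguard (iMG) samples three linear-accelerometer channels
(in g) and three gyroscope channels (in rad/s) at 3200 Hz around an 8-g
trigger.  This module turns such a record into head-center-of-gravity (CG)
kinematics in the SAE J211 convention:

1. re-orient sensor axes into the J211 head frame,
2. low-pass filter (phaseless Butterworth, 175 Hz linear / 250 Hz gyro),
3. differentiate angular velocity with a five-point stencil,
4. apply the rigid-body transport relation
   ``a_CG = a_P + w x (w x r) + alpha x r``
   where ``r`` points from the CG to the sensor point P,
5. form per-sample resultants.

Accelerations live in g inside files and records; the rigid-body transform
works internally in m/s^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .errors import (
    AlignmentError,
    InvalidFilterSpecError,
    SignalLengthError,
)

#: standard gravity, m/s^2 per g
G = 9.80665

COUPLED = "coupled"
DECOUPLED = "decoupled"
UNKNOWN = "unknown"


@dataclass
class ChannelSignal:
    """One uniformly sampled sensor or kinematic channel.

    Parameters
    ----------
    samples
        Sample values; units are carried by context (g, rad/s, m/s^2,
        rad/s^2).
    sample_rate
        Sampling rate in Hz.
    trigger_index
        Sample index of t = 0 (the trigger instant).
    """

    samples: np.ndarray
    sample_rate: float
    trigger_index: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not (0 <= self.trigger_index < len(self.samples)):
            raise ValueError("trigger_index outside the signal")
        if len(self.samples) < 5:
            raise SignalLengthError("a channel needs at least 5 samples")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def time_s(self) -> np.ndarray:
        """Sample times in seconds, t = 0 at the trigger."""
        n = np.arange(len(self.samples), dtype=float)
        return (n - self.trigger_index) / self.sample_rate

    @property
    def time_ms(self) -> np.ndarray:
        return self.time_s * 1e3

    def with_samples(self, samples: np.ndarray) -> "ChannelSignal":
        """New channel sharing this one's time base."""
        return ChannelSignal(np.asarray(samples, dtype=float),
                             self.sample_rate, self.trigger_index)


@dataclass
class FilterSpec:
    """Phaseless low-pass specification.

    ``order_per_pass`` Butterworth sections are applied forward and backward
    (``filtfilt``), so the effective magnitude response has twice that order
    and zero phase lag.  The default (order 2 per pass) realises the
    conventional "fourth-order phaseless" filter of impact biomechanics.
    """

    cutoff_hz: float
    order_per_pass: int = 2
    zero_phase: bool = True

    def validate(self, sample_rate: float) -> None:
        if not 0 < self.cutoff_hz < sample_rate / 2:
            raise InvalidFilterSpecError(
                f"cutoff {self.cutoff_hz} Hz outside (0, Nyquist={sample_rate / 2} Hz)"
            )
        if self.order_per_pass < 1:
            raise InvalidFilterSpecError("order_per_pass must be >= 1")


@dataclass
class ProximityTrace:
    """Infrared proximity readings around one impact (arbitrary units)."""

    pre: float
    post: float
    mid: Optional[float] = None
    series: Optional[list] = None  # list of (time_s, reading) before impact


@dataclass
class RawImgRecord:
    """One triggered iMG event: six raw channels plus metadata.

    ``orientation`` rotates sensor-frame vectors into the SAE J211 head
    frame; ``lever_arm_r`` points from the head CG to the sensor point P,
    in meters, expressed in the head frame.
    """

    lin: tuple  # 3 ChannelSignal, g, sensor frame
    gyro: tuple  # 3 ChannelSignal, rad/s, sensor frame
    event_id: str
    device_id: str = "sim-device"
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    lever_arm_r: np.ndarray = field(default_factory=lambda: np.zeros(3))
    proximity: Optional[ProximityTrace] = None
    quality: Optional[int] = None
    label: str = UNKNOWN

    def __post_init__(self):
        self.orientation = np.asarray(self.orientation, dtype=float)
        self.lever_arm_r = np.asarray(self.lever_arm_r, dtype=float)
        if self.orientation.shape != (3, 3):
            raise ValueError("orientation must be 3x3")
        if not np.allclose(self.orientation @ self.orientation.T, np.eye(3),
                           atol=1e-9):
            raise ValueError("orientation must be orthonormal (R R^T = I)")
        chans = list(self.lin) + list(self.gyro)
        if len(self.lin) != 3 or len(self.gyro) != 3:
            raise ValueError("need exactly 3 linear and 3 gyro channels")
        n = len(chans[0])
        fs = chans[0].sample_rate
        ti = chans[0].trigger_index
        for c in chans[1:]:
            if len(c) != n or c.sample_rate != fs or c.trigger_index != ti:
                raise AlignmentError("all six channels must share length, "
                                     "rate and trigger")

    @property
    def sample_rate(self) -> float:
        return self.lin[0].sample_rate

    @property
    def trigger_index(self) -> int:
        return self.lin[0].trigger_index

    @property
    def n_samples(self) -> int:
        return len(self.lin[0])


@dataclass
class CgKinematics:
    """Processed event at the head CG, SAE J211 frame.

    Linear acceleration is reported in g; angular velocity in rad/s;
    angular acceleration in rad/s^2.
    """

    lin_acc_cg: tuple  # 3 ChannelSignal, g
    ang_vel: tuple  # 3 ChannelSignal, rad/s
    ang_acc: tuple  # 3 ChannelSignal, rad/s^2
    resultant_lin: ChannelSignal
    resultant_ang_vel: ChannelSignal
    resultant_ang_acc: ChannelSignal


def butterworth_phaseless(sig: ChannelSignal, spec: FilterSpec) -> ChannelSignal:
    """Zero-phase Butterworth low-pass via forward-backward filtering.

    Preserves length and trigger alignment; passband gain is ~1 and the
    output has no phase lag (both passes cancel each other's delay).
    """
    spec.validate(sig.sample_rate)
    b, a = _butter(spec, sig.sample_rate)
    padlen = 3 * max(len(b), len(a))
    if len(sig) <= padlen:
        raise SignalLengthError(
            f"signal of {len(sig)} samples too short for filtfilt "
            f"(needs > {padlen})")
    if spec.zero_phase:
        out = sps.filtfilt(b, a, sig.samples)
    else:
        out = sps.lfilter(b, a, sig.samples)
    return sig.with_samples(out)


def _butter(spec: FilterSpec, fs: float):
    return sps.butter(spec.order_per_pass, spec.cutoff_hz, btype="low", fs=fs)


def five_point_derivative(sig: ChannelSignal) -> ChannelSignal:
    """Differentiate with the central five-point stencil.

    Interior samples use ``(f[-2h] - 8 f[-h] + 8 f[+h] - f[+2h]) / (12 h)``,
    exact for polynomials up to degree 4.  The two samples at each edge use
    second-order one-sided differences.
    """
    if len(sig) < 5:
        raise SignalLengthError("five-point stencil needs >= 5 samples")
    f = sig.samples
    h = 1.0 / sig.sample_rate
    d = np.empty_like(f)
    d[2:-2] = (f[:-4] - 8 * f[1:-3] + 8 * f[3:-1] - f[4:]) / (12 * h)
    # 2nd-order one-sided differences at the edges
    d[0] = (-3 * f[0] + 4 * f[1] - f[2]) / (2 * h)
    d[1] = (-3 * f[1] + 4 * f[2] - f[3]) / (2 * h)
    d[-2] = (3 * f[-2] - 4 * f[-3] + f[-4]) / (2 * h)
    d[-1] = (3 * f[-1] - 4 * f[-2] + f[-3]) / (2 * h)
    return sig.with_samples(d)


def transform_to_cg(lin_acc_p: np.ndarray, ang_vel: np.ndarray,
                    ang_acc: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Rigid-body transport of linear acceleration to the head CG.

    ``a_CG(t) = a_P(t) + w(t) x (w(t) x r) + alpha(t) x r`` applied per
    sample.  All inputs in SI units (m/s^2, rad/s, rad/s^2, m); arrays are
    (n, 3) except ``r`` which is a single 3-vector from CG to P.
    """
    lin_acc_p = np.atleast_2d(np.asarray(lin_acc_p, dtype=float))
    ang_vel = np.atleast_2d(np.asarray(ang_vel, dtype=float))
    ang_acc = np.atleast_2d(np.asarray(ang_acc, dtype=float))
    r = np.asarray(r, dtype=float)
    if not (lin_acc_p.shape == ang_vel.shape == ang_acc.shape):
        raise AlignmentError("kinematic sequences must have equal shapes")
    centripetal = np.cross(ang_vel, np.cross(ang_vel, r[None, :]))
    tangential = np.cross(ang_acc, r[None, :])
    return lin_acc_p + centripetal + tangential


def sensor_from_cg(lin_acc_cg: np.ndarray, ang_vel: np.ndarray,
                   ang_acc: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Inverse of :func:`transform_to_cg`: sensor-point acceleration from
    CG-frame ground truth.  Used by the simulator so the forward/inverse
    pair is self-consistent by construction."""
    lin_acc_cg = np.atleast_2d(np.asarray(lin_acc_cg, dtype=float))
    ang_vel = np.atleast_2d(np.asarray(ang_vel, dtype=float))
    ang_acc = np.atleast_2d(np.asarray(ang_acc, dtype=float))
    r = np.asarray(r, dtype=float)
    centripetal = np.cross(ang_vel, np.cross(ang_vel, r[None, :]))
    tangential = np.cross(ang_acc, r[None, :])
    return lin_acc_cg - centripetal - tangential


def resultant(x: ChannelSignal, y: ChannelSignal, z: ChannelSignal) -> ChannelSignal:
    """Per-sample Euclidean norm of three aligned channels."""
    if not (len(x) == len(y) == len(z)):
        raise AlignmentError("resultant needs equal-length channels")
    out = np.sqrt(x.samples ** 2 + y.samples ** 2 + z.samples ** 2)
    return x.with_samples(out)


DEFAULT_LIN_CUTOFF_HZ = 175.0
DEFAULT_GYRO_CUTOFF_HZ = 250.0


def process_event(record: RawImgRecord,
                  lin_cutoff_hz: float = DEFAULT_LIN_CUTOFF_HZ,
                  gyro_cutoff_hz: float = DEFAULT_GYRO_CUTOFF_HZ,
                  order_per_pass: int = 2) -> CgKinematics:
    """Full processing chain: reorient, filter, differentiate, CG transform.

    The gyroscope channels are filtered at ``gyro_cutoff_hz`` before
    differentiation; linear channels are filtered at ``lin_cutoff_hz``.
    Deterministic for a fixed record.
    """
    fs = record.sample_rate
    ti = record.trigger_index

    lin_raw = np.column_stack([c.samples for c in record.lin])  # g
    gyro_raw = np.column_stack([c.samples for c in record.gyro])  # rad/s

    # reorient sensor frame -> J211 head frame
    R = record.orientation
    lin_head = lin_raw @ R.T
    gyro_head = gyro_raw @ R.T

    lin_spec = FilterSpec(lin_cutoff_hz, order_per_pass)
    gyro_spec = FilterSpec(gyro_cutoff_hz, order_per_pass)

    def _filt(mat, spec):
        return np.column_stack([
            butterworth_phaseless(ChannelSignal(mat[:, i], fs, ti), spec).samples
            for i in range(3)])

    lin_f = _filt(lin_head, lin_spec)  # g
    gyro_f = _filt(gyro_head, gyro_spec)  # rad/s

    ang_acc = np.column_stack([
        five_point_derivative(ChannelSignal(gyro_f[:, i], fs, ti)).samples
        for i in range(3)])  # rad/s^2

    a_cg_si = transform_to_cg(lin_f * G, gyro_f, ang_acc, record.lever_arm_r)
    a_cg_g = a_cg_si / G

    def _chans(mat):
        return tuple(ChannelSignal(mat[:, i], fs, ti) for i in range(3))

    lin_ch = _chans(a_cg_g)
    gyro_ch = _chans(gyro_f)
    aacc_ch = _chans(ang_acc)
    return CgKinematics(
        lin_acc_cg=lin_ch,
        ang_vel=gyro_ch,
        ang_acc=aacc_ch,
        resultant_lin=resultant(*lin_ch),
        resultant_ang_vel=resultant(*gyro_ch),
        resultant_ang_acc=resultant(*aacc_ch),
    )
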