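"""Wavelet-multiresolution salvaging of decoupled iMG signals.

Decoupling superimposes 100-500 Hz artifact oscillations on the raw sensor
channels.  Salvaging decomposes each filtered channel into a shift-invariant
(maximal-overlap) wavelet multiresolution analysis — five detail bands and
one approximation with the db10 wavelet — and rebuilds the signal from the
levels whose energy timing looks like a genuine impact:

* Details 1 and 2 (above ~400 Hz) are always rejected; the approximation
  (below ~50 Hz) is always kept.
* Details 3-5 are judged by relative section energy ``E_r``: the level's
  time signal is cut into 10-ms sections aligned to the trigger and each
  section's energy is divided by the level's total energy.  A level whose
  later sections out-weigh the primary section by more than 10 percentage
  points is artifact-dominated and rejected.
* Linear accelerometer channels use the 0-10 ms section as primary and
  compare 10-20 and 20-30 ms against it.  Gyroscope channels peak later:
  their primary section is 10-20 ms (compared against 20-30 and 30-40 ms),
  detail 3 is always rejected, and detail 4 is rejected outright when it
  carries more than 10% of the channel's total component energy.
* The pre-trigger (-10 to 0 ms) portion of every detail re-enters the
  reconstruction so the pre-trigger region sums back to the raw baseline
  regardless of which levels were rejected.

Nominal dyadic sub-bands at 3200 Hz: D1 800-1600, D2 400-800, D3 200-400,
D4 100-200, D5 50-100, approximation 0-50 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pywt

from .errors import SignalLengthError
from .signals import (
    COUPLED,
    DECOUPLED,
    DEFAULT_GYRO_CUTOFF_HZ,
    DEFAULT_LIN_CUTOFF_HZ,
    ChannelSignal,
    FilterSpec,
    RawImgRecord,
    butterworth_phaseless,
    process_event,
)

LEVEL_NAMES = ("D1", "D2", "D3", "D4", "D5", "A")

#: nominal dyadic pass-bands (Hz) of the five details and the approximation
#: at fs = 3200 Hz
NOMINAL_BANDS: Dict[str, Tuple[float, float]] = {
    "D1": (800.0, 1600.0),
    "D2": (400.0, 800.0),
    "D3": (200.0, 400.0),
    "D4": (100.0, 200.0),
    "D5": (50.0, 100.0),
    "A": (0.0, 50.0),
}

ALWAYS_REJECT = ("D1", "D2")


@dataclass
class SalvageConfig:
    """Tunable salvaging parameters (defaults reproduce the standard rule)."""

    wavelet: str = "db10"
    levels: int = 5
    section_ms: float = 10.0
    #: additive increment, in section-energy fraction, by which a later
    #: section must exceed the primary section to reject a level
    late_energy_increment: float = 0.10
    #: whole-level energy share triggering outright rejection (gyro D4)
    outright_energy_frac: float = 0.10
    #: extend the outright-rejection clause to linear channels too
    outright_on_linear: bool = False
    lin_cutoff_hz: float = DEFAULT_LIN_CUTOFF_HZ
    gyro_cutoff_hz: float = DEFAULT_GYRO_CUTOFF_HZ


@dataclass
class Decomposition:
    """Additive MRA of one channel: components sum back to the input."""

    input: ChannelSignal
    components: Dict[str, np.ndarray]  # keys D1..D5, A; same length as input
    wavelet: str
    levels: int
    padding: Tuple[int, int]  # (left, right) samples padded then trimmed

    def component_energy(self, name: str) -> float:
        return float(np.sum(self.components[name] ** 2))

    def total_energy(self) -> float:
        return float(sum(self.component_energy(n) for n in self.components))


@dataclass
class SectionEnergyProfile:
    """Relative energy of one level across 10-ms sections."""

    level: str
    section_start_ms: np.ndarray  # left edge of each section
    relative_energies: np.ndarray  # fractions summing to 1
    defined: bool  # False when the level carries no energy

    def energy_at(self, start_ms: float) -> float:
        idx = np.flatnonzero(np.isclose(self.section_start_ms, start_ms))
        if len(idx) == 0:
            return 0.0
        return float(self.relative_energies[idx[0]])


@dataclass
class SalvageResult:
    """Per-event salvaging outcome."""

    event_id: str
    kept_levels: Dict[str, List[str]]  # channel name -> kept level names
    rejected_levels: Dict[str, Dict[str, str]]  # channel -> level -> reason
    salvaged_record: RawImgRecord
    reclassified_as: Optional[str] = None
    salvage_success: Optional[bool] = None


def modwt_mra(sig: ChannelSignal, wavelet: str = "db10",
              levels: int = 5) -> Decomposition:
    """Shift-invariant multiresolution analysis of one channel.

    The signal is reflection-padded on both ends (at least one filter
    support at the deepest level, rounded so the padded length is a
    multiple of 2**levels), decomposed with the stationary-wavelet MRA,
    and the padding is trimmed from every component.  The components sum
    to the input exactly (to floating-point precision).
    """
    x = sig.samples
    n = len(x)
    support = (pywt.Wavelet(wavelet).dec_len - 1) * (2 ** levels - 1)
    pad_left = min(support, n - 1)  # np.pad reflect cannot exceed n-1
    block = 2 ** levels
    total = n + 2 * pad_left
    pad_right = pad_left + (-total) % block
    if n < 2 * pywt.Wavelet(wavelet).dec_len:
        raise SignalLengthError(
            f"signal of {n} samples too short for {wavelet} level-{levels} MRA")
    padded = np.pad(x, (pad_left, pad_right), mode="reflect")
    comps = pywt.mra(padded, wavelet, level=levels, transform="swt")
    # pywt.mra returns [A_L, D_L, D_{L-1}, ..., D_1]
    names = ["A"] + [f"D{j}" for j in range(levels, 0, -1)]
    sl = slice(pad_left, pad_left + n)
    components = {name: comp[sl].copy() for name, comp in zip(names, comps)}
    return Decomposition(input=sig, components=components, wavelet=wavelet,
                         levels=levels, padding=(pad_left, pad_right))


def section_relative_energy(level_samples: np.ndarray, sig: ChannelSignal,
                            section_ms: float = 10.0) -> SectionEnergyProfile:
    """Relative energy per 10-ms section, grid aligned to the trigger.

    Each section's sum of squares is divided by the level's total sum of
    squares, so the fractions sum to one.  A level with zero total energy
    returns an undefined profile (treated downstream as keepable silence).
    """
    x = np.asarray(level_samples, dtype=float)
    t_ms = sig.time_ms
    sec_idx = np.floor(t_ms / section_ms).astype(int)
    starts = np.arange(sec_idx.min(), sec_idx.max() + 1) * section_ms
    total = float(np.sum(x ** 2))
    energies = np.array([np.sum(x[sec_idx == s] ** 2)
                         for s in range(sec_idx.min(), sec_idx.max() + 1)])
    if total == 0.0:
        return SectionEnergyProfile("", starts, np.zeros_like(energies),
                                    defined=False)
    return SectionEnergyProfile("", starts, energies / total, defined=True)


def _late_energy_reject(profile: SectionEnergyProfile, primary_ms: float,
                        later_ms: Tuple[float, ...], increment: float) -> bool:
    if not profile.defined:
        return False
    primary = profile.energy_at(primary_ms)
    return any(profile.energy_at(t) > primary + increment for t in later_ms)


def select_levels_linear(decomp: Decomposition,
                         cfg: SalvageConfig = SalvageConfig()):
    """Keep/reject decision for a linear-accelerometer channel.

    D1/D2 always rejected, A always kept; D3-D5 rejected when the 10-20 or
    20-30 ms section exceeds the 0-10 ms primary section by more than the
    configured increment.
    """
    kept, rejected = ["A"], {"D1": "always_reject", "D2": "always_reject"}
    total = decomp.total_energy()
    for name in ("D3", "D4", "D5"):
        if cfg.outright_on_linear and total > 0 and \
                name in ("D3", "D4") and \
                decomp.component_energy(name) / total > cfg.outright_energy_frac:
            rejected[name] = "outright_energy"
            continue
        prof = section_relative_energy(decomp.components[name], decomp.input,
                                       cfg.section_ms)
        if _late_energy_reject(prof, 0.0, (10.0, 20.0),
                               cfg.late_energy_increment):
            rejected[name] = "late_energy"
        else:
            kept.append(name)
    return kept, rejected


def select_levels_angular(decomp: Decomposition,
                          cfg: SalvageConfig = SalvageConfig()):
    """Keep/reject decision for a gyroscope channel.

    D3 is always rejected (angular signals carry lower frequencies); D4 is
    rejected outright when it holds more than 10% of the channel's total
    component energy; surviving D4 and D5 use the 10-20 ms primary section
    against 20-30 and 30-40 ms.
    """
    kept, rejected = ["A"], {"D1": "always_reject", "D2": "always_reject",
                             "D3": "angular_always_reject"}
    total = decomp.total_energy()
    for name in ("D4", "D5"):
        if name == "D4" and total > 0 and \
                decomp.component_energy(name) / total > cfg.outright_energy_frac:
            rejected[name] = "outright_energy"
            continue
        prof = section_relative_energy(decomp.components[name], decomp.input,
                                       cfg.section_ms)
        if _late_energy_reject(prof, 10.0, (20.0, 30.0),
                               cfg.late_energy_increment):
            rejected[name] = "late_energy"
        else:
            kept.append(name)
    return kept, rejected


def reconstruct(decomp: Decomposition, kept: List[str]) -> ChannelSignal:
    """Rebuild a channel from the kept levels.

    For t >= 0 the output is the approximation plus the kept details; for
    t < 0 every detail is restored so the pre-trigger region reproduces
    the input exactly, keeping the baseline physical.
    """
    sig = decomp.input
    out = np.zeros(len(sig))
    kept_set = set(kept) | {"A"}
    for name, comp in decomp.components.items():
        if name in kept_set:
            out += comp
        else:
            out[: sig.trigger_index] += comp[: sig.trigger_index]
    return sig.with_samples(out)


_CHANNEL_NAMES = ("lin_x", "lin_y", "lin_z", "gyro_x", "gyro_y", "gyro_z")


def salvage_event(record: RawImgRecord, model=None,
                  cfg: SalvageConfig = SalvageConfig()) -> SalvageResult:
    """Salvage all six raw channels of one event atomically.

    Each channel is phaseless-Butterworth filtered (175 Hz linear, 250 Hz
    gyro), MRA-decomposed, level-selected with the linear or angular rule,
    and reconstructed.  When a fitted detector ``model`` is supplied, the
    salvaged record is pushed through the standard processing chain and
    re-classified; ``salvage_success`` records whether the verdict flipped
    to coupled.

    Salvaging is meant for decoupled-classified events; running it on a
    coupled event is supported (for misclassification studies) and is
    nearly benign.
    """
    kept_all: Dict[str, List[str]] = {}
    rejected_all: Dict[str, Dict[str, str]] = {}
    new_lin, new_gyro = [], []
    for i, name in enumerate(_CHANNEL_NAMES):
        is_lin = name.startswith("lin")
        chan = record.lin[i] if is_lin else record.gyro[i - 3]
        cutoff = cfg.lin_cutoff_hz if is_lin else cfg.gyro_cutoff_hz
        filt = butterworth_phaseless(chan, FilterSpec(cutoff))
        decomp = modwt_mra(filt, cfg.wavelet, cfg.levels)
        if is_lin:
            kept, rejected = select_levels_linear(decomp, cfg)
        else:
            kept, rejected = select_levels_angular(decomp, cfg)
        kept_all[name] = kept
        rejected_all[name] = rejected
        rebuilt = reconstruct(decomp, kept)
        (new_lin if is_lin else new_gyro).append(rebuilt)

    salvaged = replace(record, lin=tuple(new_lin), gyro=tuple(new_gyro))
    result = SalvageResult(event_id=record.event_id, kept_levels=kept_all,
                           rejected_levels=rejected_all,
                           salvaged_record=salvaged)
    if model is not None:
        from .detector import predict
        from .features import extract_features

        kin = process_event(salvaged, cfg.lin_cutoff_hz, cfg.gyro_cutoff_hz)
        fv = extract_features(kin, event_id=record.event_id)
        result.reclassified_as = predict(model, fv)
        result.salvage_success = result.reclassified_as == COUPLED
    return result
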