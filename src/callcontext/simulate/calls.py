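"""Parametric source-filter call synthesis.

A call is an additive harmonic source with a linear f0 contour and
per-period multiplicative jitter, filtered through four two-pole
resonators (formants), shaped by an attack/decay envelope, with white
noise mixed in at a stated SNR.  Each acoustic feature family the
downstream analysis measures (duration, intensity, f0, formants) maps to
exactly one generator knob, so feature-recovery tests can manipulate one
dimension at a time.

Context effects and caller profiles are both expressed as field-wise
offsets (additive or multiplicative) on the base configuration, applied
in the order caller → context.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from ..features import Waveform

__all__ = [
    "SynthCallConfig",
    "ContextEffect",
    "CallerProfile",
    "CONTEXTS",
    "default_context_effects",
    "synth_call",
    "generate_call_dataset",
]

CONTEXTS: tuple[str, ...] = ("high_social", "low_social", "non_social")


@dataclass(frozen=True)
class SynthCallConfig:
    """Generator parameters for a single call.

    Defaults describe a schematic primate vocalization: ~200 Hz source,
    four formants in increasing order, 16-bit-style recording at
    44.1 kHz.
    """

    sample_rate_hz: int = 44100
    duration_s: float = 0.6
    f0_base_hz: float = 200.0
    f0_slope_hz_per_s: float = -40.0
    jitter_cv: float = 0.02
    harmonic_rolloff_db_per_octave: float = 6.0
    formant_centers_hz: tuple[float, float, float, float] = (730.0, 1300.0, 2500.0, 3500.0)
    formant_bandwidths_hz: tuple[float, float, float, float] = (90.0, 110.0, 160.0, 200.0)
    snr_db: float = 25.0
    envelope_attack_frac: float = 0.15

    def validate(self) -> None:
        nyq = self.sample_rate_hz / 2
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.duration_s * self.sample_rate_hz < 256:
            raise ValueError("call must be at least 256 samples long")
        if not (0 <= self.jitter_cv < 1):
            raise ValueError("jitter_cv must lie in [0, 1)")
        if not (0 < self.envelope_attack_frac < 1):
            raise ValueError("envelope_attack_frac must lie in (0, 1)")
        if self.f0_base_hz <= 0:
            raise ValueError("f0_base_hz must be positive")
        fc = self.formant_centers_hz
        if len(fc) != 4 or any(b <= a for a, b in zip(fc, fc[1:])):
            raise ValueError("formant centers must be 4 strictly increasing values")
        if fc[-1] >= nyq:
            raise ValueError(f"formant center {fc[-1]:.0f} Hz at or above Nyquist {nyq:.0f} Hz")
        if any(b <= 0 for b in self.formant_bandwidths_hz):
            raise ValueError("formant bandwidths must be positive")


#: shift spec: field name -> ("add" | "mul", value); tuple fields accept a
#: scalar applied element-wise.
ShiftMap = Mapping[str, tuple[str, float]]


def _apply_shifts(config: SynthCallConfig, shifts: ShiftMap) -> SynthCallConfig:
    updates = {}
    valid = {f.name for f in fields(SynthCallConfig)}
    for name, (mode, value) in shifts.items():
        if name not in valid:
            raise KeyError(f"unknown SynthCallConfig field: {name}")
        current = getattr(config, name)
        if isinstance(current, tuple):
            if mode == "add":
                updates[name] = tuple(c + value for c in current)
            elif mode == "mul":
                updates[name] = tuple(c * value for c in current)
            else:
                raise ValueError(f"shift mode must be 'add' or 'mul', got {mode!r}")
        else:
            if mode == "add":
                updates[name] = current + value
            elif mode == "mul":
                updates[name] = current * value
            else:
                raise ValueError(f"shift mode must be 'add' or 'mul', got {mode!r}")
    return replace(config, **updates)


@dataclass(frozen=True)
class ContextEffect:
    """Systematic acoustic shift associated with an emission context."""

    context: str
    shifts: ShiftMap = field(default_factory=dict)

    def apply(self, config: SynthCallConfig) -> SynthCallConfig:
        return _apply_shifts(config, self.shifts)


def default_context_effects(scale: float = 1.0) -> dict[str, ContextEffect]:
    """Context shifts used as the study conditions for simulations.

    Non-social calls are the baseline; the two social contexts raise f0,
    lengthen the call and shift the filter, with the high-intensity
    social context moving furthest — mirroring an arousal gradient.
    ``scale`` multiplies every departure from baseline (0 → perfect null).
    """

    def eff(context: str, f0_mul: float, dur_mul: float, formant_mul: float, slope_add: float) -> ContextEffect:
        return ContextEffect(
            context,
            {
                "f0_base_hz": ("mul", 1 + (f0_mul - 1) * scale),
                "duration_s": ("mul", 1 + (dur_mul - 1) * scale),
                "formant_centers_hz": ("mul", 1 + (formant_mul - 1) * scale),
                "f0_slope_hz_per_s": ("add", slope_add * scale),
            },
        )

    return {
        "high_social": eff("high_social", 1.18, 1.15, 1.06, -25.0),
        "low_social": eff("low_social", 1.08, 1.06, 1.03, -10.0),
        "non_social": eff("non_social", 1.0, 1.0, 1.0, 0.0),
    }


@dataclass(frozen=True)
class CallerProfile:
    """Per-caller random offsets, a function of (caller_id, seed) only."""

    caller_id: str
    offsets: ShiftMap
    seed: int

    @classmethod
    def draw(
        cls,
        caller_id: str,
        seed: int,
        f0_sd: float = 0.06,
        formant_sd: float = 0.03,
        duration_sd: float = 0.05,
    ) -> "CallerProfile":
        """Draw multiplicative log-normal offsets for f0, formants, duration.

        The RNG stream is keyed by (seed, crc32(caller_id)) so the same
        pair always reproduces the same profile regardless of draw order.
        """
        rng = np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(caller_id.encode())])
        offsets: dict[str, tuple[str, float]] = {
            "f0_base_hz": ("mul", float(np.exp(rng.normal(0, f0_sd)))),
            "formant_centers_hz": ("mul", float(np.exp(rng.normal(0, formant_sd)))),
            "duration_s": ("mul", float(np.exp(rng.normal(0, duration_sd)))),
        }
        return cls(caller_id, offsets, seed)

    def apply(self, config: SynthCallConfig) -> SynthCallConfig:
        return _apply_shifts(config, self.offsets)


def _resonator_coeffs(center_hz: float, bandwidth_hz: float, sr: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-pole resonator with unit gain at the center frequency."""
    r = np.exp(-np.pi * bandwidth_hz / sr)
    theta = 2 * np.pi * center_hz / sr
    a = np.array([1.0, -2 * r * np.cos(theta), r * r])
    # normalize |H| at the center frequency
    w = np.exp(-1j * theta)
    gain = np.abs(1.0 / (a[0] + a[1] * w + a[2] * w * w))
    return np.array([1.0 / gain]), a


def synth_call(
    config: SynthCallConfig,
    context_effect: ContextEffect | None = None,
    caller: CallerProfile | None = None,
    seed: int = 0,
) -> Waveform:
    """Render one call; deterministic given (config, effect, caller, seed)."""
    if caller is not None:
        config = caller.apply(config)
    if context_effect is not None:
        config = context_effect.apply(config)
    config.validate()

    sr = config.sample_rate_hz
    n = int(round(config.duration_s * sr))
    rng = np.random.default_rng(seed & 0x7FFFFFFF)

    # instantaneous f0: linear contour with per-period multiplicative jitter
    t = np.arange(n) / sr
    f0_contour = np.clip(config.f0_base_hz + config.f0_slope_hz_per_s * t, 20.0, sr / 2 - 1)
    if config.jitter_cv > 0:
        # period boundaries walked sequentially; each period gets one factor
        factors = np.ones(n)
        pos = 0.0
        while pos < config.duration_s:
            i = int(pos * sr)
            f_here = max(20.0, config.f0_base_hz + config.f0_slope_hz_per_s * pos)
            jit = float(np.clip(rng.normal(1.0, config.jitter_cv), 0.5, 1.5))
            period = 1.0 / (f_here * jit)
            j = min(n, int((pos + period) * sr) + 1)
            factors[i:j] = jit
            pos += period
        f0_inst = f0_contour * factors
    else:
        f0_inst = f0_contour
    phase = 2 * np.pi * np.cumsum(f0_inst) / sr

    f0_max = float(f0_inst.max())
    n_harm = max(1, min(60, int((sr / 2 - 1) / f0_max)))
    k = np.arange(1, n_harm + 1)
    amps = 10 ** (-config.harmonic_rolloff_db_per_octave * np.log2(k) / 20)
    # drop harmonics that would alias past Nyquist anywhere in the call
    source = (np.sin(np.outer(phase, k)) * amps).sum(axis=1)

    x = source
    for fc, bw in zip(config.formant_centers_hz, config.formant_bandwidths_hz):
        b, a = _resonator_coeffs(fc, bw, sr)
        x = sps.lfilter(b, a, x)

    # attack/decay envelope: half-cosine rise, sustain, half-cosine release
    attack = max(2, int(config.envelope_attack_frac * n))
    release = max(2, int(0.1 * n))
    env = np.ones(n)
    env[:attack] = 0.5 * (1 - np.cos(np.pi * np.arange(attack) / attack))
    env[n - release :] = 0.5 * (1 + np.cos(np.pi * np.arange(release) / release))
    x = x * env

    if np.isfinite(config.snr_db):
        sig_rms = np.sqrt(np.mean(x**2))
        noise_rms = sig_rms / (10 ** (config.snr_db / 20))
        x = x + rng.normal(0, noise_rms, n)

    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.9 * x / peak
    return Waveform(x, sr)


#: within-caller call-to-call scatter (log-normal sd for "mul", plain sd
#: for "add"): successive calls by one animal are similar, not identical
CALL_SCATTER: dict[str, tuple[str, float]] = {
    "f0_base_hz": ("mul", 0.04),
    "duration_s": ("mul", 0.06),
    "formant_centers_hz": ("mul", 0.015),
    "f0_slope_hz_per_s": ("add", 8.0),
}


def _draw_call_scatter(rng: np.random.Generator, scatter: Mapping[str, tuple[str, float]]) -> dict[str, tuple[str, float]]:
    out: dict[str, tuple[str, float]] = {}
    for name, (mode, sd) in scatter.items():
        if mode == "mul":
            out[name] = ("mul", float(np.exp(rng.normal(0.0, sd))))
        else:
            out[name] = ("add", float(rng.normal(0.0, sd)))
    return out


def generate_call_dataset(
    base_config: SynthCallConfig | None = None,
    context_effects: Mapping[str, ContextEffect] | None = None,
    n_callers: int = 5,
    calls_per_caller_per_context: int = 3,
    counts: Mapping[str, int] | None = None,
    call_scatter: Mapping[str, tuple[str, float]] | None = None,
    seed: int = 0,
) -> tuple[list[Waveform], pd.DataFrame]:
    """Generate a labeled call pool and its manifest.

    By default every caller contributes ``calls_per_caller_per_context``
    calls to every context (equal contribution guards against
    pseudo-replication).  ``counts`` overrides with per-context totals
    (e.g. ``{"high_social": 41, "low_social": 26, "non_social": 21}``),
    distributed across callers as evenly as the total allows.  Each call
    additionally receives within-caller scatter (:data:`CALL_SCATTER`
    by default; pass ``{}`` for identical repeats).  The manifest
    records the true generating parameters per call.
    """
    if n_callers < 2:
        raise ValueError("need at least 2 callers")
    base_config = base_config or SynthCallConfig()
    context_effects = dict(context_effects) if context_effects else default_context_effects()
    scatter = CALL_SCATTER if call_scatter is None else call_scatter
    callers = [CallerProfile.draw(f"M{i + 1}", seed) for i in range(n_callers)]

    plan: list[tuple[str, CallerProfile]] = []
    for context in context_effects:
        if counts is not None:
            total = int(counts[context])
            per = [total // n_callers + (1 if i < total % n_callers else 0) for i in range(n_callers)]
        else:
            per = [calls_per_caller_per_context] * n_callers
        for caller, m in zip(callers, per):
            plan.extend((context, caller) for _ in range(m))

    waveforms: list[Waveform] = []
    rows = []
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    for idx, (context, caller) in enumerate(plan):
        call_seed = int(rng.integers(0, 2**31 - 1))
        per_call = _draw_call_scatter(rng, scatter)
        config_i = _apply_shifts(base_config, per_call)
        w = synth_call(config_i, context_effects[context], caller, seed=call_seed)
        cid = f"call{idx:04d}"
        w.call_id, w.caller_id, w.context = cid, caller.caller_id, context
        effective = context_effects[context].apply(caller.apply(config_i))
        rows.append(
            {
                "call_id": cid,
                "caller_id": caller.caller_id,
                "context": context,
                "seed": call_seed,
                "duration_s": effective.duration_s,
                "f0_base_hz": effective.f0_base_hz,
                "f0_slope_hz_per_s": effective.f0_slope_hz_per_s,
                "f1_hz": effective.formant_centers_hz[0],
                "peak_amp": float(np.max(np.abs(w.samples))),
            }
        )
        waveforms.append(w)
    return waveforms, pd.DataFrame(rows)
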