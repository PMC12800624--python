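"""Acoustic feature extraction for single calls.

Computes a ~31-feature panel per call covering the four families a
context-coding analysis of vocalizations cares about: temporal (duration),
intensity (frame RMS in dB re full scale), source (fundamental frequency
contour via normalized autocorrelation) and filter (formants F1-F4 via
linear-prediction root finding).  Spectral shape statistics are computed
on the Welch average periodogram so results are reproducible bit-for-bit
for fixed settings.

The extraction is deterministic: no random numbers are drawn anywhere in
this module.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile
from scipy.linalg import solve_toeplitz

log = logging.getLogger(__name__)

__all__ = [
    "Waveform",
    "FrameSettings",
    "FEATURE_NAMES",
    "load_wav",
    "save_wav",
    "track_f0",
    "estimate_formants",
    "extract_features",
    "extract_table",
]


@dataclass
class Waveform:
    """Mono audio samples in [-1, 1] plus call-level metadata."""

    samples: np.ndarray
    sample_rate_hz: int
    call_id: str = ""
    caller_id: str = ""
    context: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("waveform must be a nonempty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz


@dataclass(frozen=True)
class FrameSettings:
    """Framing and analysis settings shared by all per-frame operations.

    ``lpc_order`` defaults to the classic sample_rate/1000 + 2 rule when
    left at None.
    """

    frame_length: int = 1024
    hop_fraction: float = 0.5
    f0_min_hz: float = 40.0
    f0_max_hz: float = 1200.0
    voicing_threshold: float = 0.45
    lpc_order: int | None = None
    max_formant_bandwidth_hz: float = 1000.0
    formant_downsample_hz: int = 10000  # LPC runs at this rate when input is faster

    def hop(self) -> int:
        return max(1, int(round(self.frame_length * self.hop_fraction)))

    def order(self, sample_rate_hz: int) -> int:
        if self.lpc_order is not None:
            return self.lpc_order
        return int(sample_rate_hz / 1000) + 2

    def settings_hash(self) -> str:
        key = repr(
            (
                self.frame_length,
                self.hop_fraction,
                self.f0_min_hz,
                self.f0_max_hz,
                self.voicing_threshold,
                self.lpc_order,
                self.max_formant_bandwidth_hz,
                self.formant_downsample_hz,
            )
        )
        return hashlib.sha1(key.encode()).hexdigest()[:12]


FEATURE_NAMES: tuple[str, ...] = (
    "dur_s",
    "rms_db_mean",
    "rms_db_median",
    "rms_db_sd",
    "rms_db_max",
    "spec_centroid_hz",
    "spec_sd_hz",
    "spec_skew",
    "spec_kurt",
    "spec_q25_hz",
    "spec_q50_hz",
    "spec_q75_hz",
    "spec_iqr_hz",
    "spec_entropy",
    "spec_flatness",
    "domfreq_mean_hz",
    "domfreq_median_hz",
    "domfreq_sd_hz",
    "f0_mean_hz",
    "f0_median_hz",
    "f0_sd_hz",
    "f0_min_hz",
    "f0_max_hz",
    "f0_range_hz",
    "f0_slope_hz_per_s",
    "voiced_frac",
    "f1_median_hz",
    "f2_median_hz",
    "f3_median_hz",
    "f4_median_hz",
    "formant_dispersion_hz",
)


# ---------------------------------------------------------------------------
# I/O


def load_wav(path: str | Path, call_id: str = "", caller_id: str = "", context: str = "") -> Waveform:
    """Read a WAV file, scale to [-1, 1] and down-mix stereo by channel mean."""
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # pragma: no cover - message path
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise IOError(f"empty WAV file: {path}")
    dtype = data.dtype
    if data.ndim == 2:
        warnings.warn(f"{path}: stereo input down-mixed to mono by channel mean")
        data = data.mean(axis=1)
    data = np.asarray(data, dtype=np.float64)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        data = data / max(abs(info.min), info.max)
    return Waveform(data, int(rate), call_id=call_id or path.stem, caller_id=caller_id, context=context)


def save_wav(path: str | Path, w: Waveform) -> None:
    """Write a waveform as mono 16-bit PCM."""
    clipped = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(Path(path), w.sample_rate_hz, (clipped * 32767.0).astype(np.int16))


# ---------------------------------------------------------------------------
# framing helpers


def _frames(x: np.ndarray, settings: FrameSettings) -> np.ndarray:
    """(n_frames, frame_length) view with zero padding of short signals."""
    n = settings.frame_length
    hop = settings.hop()
    if x.size < n:
        log.info("signal shorter than one frame: zero-padding %d -> %d", x.size, n)
        x = np.pad(x, (0, n - x.size))
    n_frames = 1 + (x.size - n) // hop
    idx = np.arange(n)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def _frame_times(n_frames: int, settings: FrameSettings, sr: int) -> np.ndarray:
    return (np.arange(n_frames) * settings.hop() + settings.frame_length / 2) / sr


def _downsampled(w: Waveform, target_hz: int) -> Waveform:
    if w.sample_rate_hz <= target_hz:
        return w
    g = np.gcd(int(w.sample_rate_hz), int(target_hz))
    x = sps.resample_poly(w.samples, target_hz // g, w.sample_rate_hz // g)
    return Waveform(x, target_hz, call_id=w.call_id, caller_id=w.caller_id, context=w.context)


# ---------------------------------------------------------------------------
# source features: f0 tracking


def track_f0(w: Waveform, settings: FrameSettings = FrameSettings()) -> pd.DataFrame:
    """Frame-wise f0 via the lag maximizing normalized autocorrelation.

    A frame is voiced iff the autocorrelation peak inside the search band
    reaches ``voicing_threshold``.  Returns a frame-indexed DataFrame with
    ``time_s``, ``f0_hz`` (NaN when unvoiced) and ``voiced``.
    """
    sr = w.sample_rate_hz
    if settings.f0_max_hz >= sr / 2:
        raise ValueError("f0 search interval must lie below Nyquist")
    frames = _frames(w.samples, settings) * np.hanning(settings.frame_length)
    n = settings.frame_length
    # batch autocorrelation via rFFT (Wiener-Khinchin)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(frames, nfft, axis=1)
    ac = np.fft.irfft(np.abs(spec) ** 2, nfft, axis=1)[:, :n]
    norm = ac[:, :1].copy()
    norm[norm <= 0] = np.finfo(float).tiny
    ac = ac / norm

    lag_min = max(2, int(np.floor(sr / settings.f0_max_hz)))
    lag_max = min(n - 2, int(np.ceil(sr / settings.f0_min_hz)))
    if lag_max <= lag_min:
        raise ValueError("f0 search band empty for this frame length")
    band = ac[:, lag_min : lag_max + 1]
    best = np.argmax(band, axis=1)
    peak = band[np.arange(band.shape[0]), best]
    lags = (lag_min + best).astype(float)
    # parabolic interpolation around the peak for sub-sample lag precision
    li = lag_min + best
    valid = (li > 1) & (li < n - 1)
    a = ac[np.arange(len(li)), np.clip(li - 1, 0, n - 1)]
    b = ac[np.arange(len(li)), li]
    c = ac[np.arange(len(li)), np.clip(li + 1, 0, n - 1)]
    denom = a - 2 * b + c
    shift = np.where((np.abs(denom) > 1e-12) & valid, 0.5 * (a - c) / np.where(denom == 0, 1, denom), 0.0)
    lags = lags + np.clip(shift, -1, 1)

    voiced = peak >= settings.voicing_threshold
    f0 = np.where(voiced, sr / lags, np.nan)
    return pd.DataFrame(
        {
            "time_s": _frame_times(frames.shape[0], settings, sr),
            "f0_hz": f0,
            "voiced": voiced,
        }
    )


# ---------------------------------------------------------------------------
# filter features: LPC formants


def _lpc(frame: np.ndarray, order: int) -> np.ndarray | None:
    """Autocorrelation-method LPC coefficients [1, a1..ap]; None if singular."""
    r = np.correlate(frame, frame, "full")[frame.size - 1 : frame.size + order]
    if r[0] <= 0:
        return None
    r = r / r[0]
    try:
        a = solve_toeplitz((r[:-1], r[:-1]), -r[1:])
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(a)):
        return None
    return np.concatenate(([1.0], a))


def estimate_formants(
    w: Waveform, settings: FrameSettings = FrameSettings()
) -> tuple[pd.DataFrame, float]:
    """Per-frame F1..F4 from LPC roots on voiced frames.

    Roots of the prediction polynomial with bandwidth below
    ``max_formant_bandwidth_hz`` are converted to frequencies; the lowest
    four ascending are F1..F4.  Frames with fewer than four admissible
    roots are skipped.  Returns (frame table, admissible-frame fraction);
    a low fraction flags unreliable (e.g. unfiltered-tone) input.

    The signal is resampled to ``formant_downsample_hz`` first (when
    recorded faster) so the prediction order only has to cover the
    formant band, which stabilizes the root estimates considerably.
    """
    w = _downsampled(w, settings.formant_downsample_hz)
    sr = w.sample_rate_hz
    voicing = track_f0(w, settings)
    # pre-emphasis flattens the source spectrum before LPC
    emph = np.append(w.samples[0], w.samples[1:] - 0.97 * w.samples[:-1])
    frames = _frames(emph, settings) * np.hanning(settings.frame_length)
    order = settings.order(sr)
    # frame spectra gate out noise-floor poles: a genuine resonance carries
    # energy within 60 dB of the frame's spectral peak
    spec_db = 20 * np.log10(np.abs(np.fft.rfft(frames, axis=1)) + 1e-300)
    bin_hz = sr / settings.frame_length
    rows = []
    voiced_idx = np.flatnonzero(voicing["voiced"].to_numpy()[: frames.shape[0]])
    for i in voiced_idx:
        a = _lpc(frames[i], order)
        if a is None:
            continue
        roots = np.roots(a)
        roots = roots[np.imag(roots) > 0]
        freqs = np.angle(roots) * sr / (2 * np.pi)
        bws = -np.log(np.clip(np.abs(roots), 1e-12, None)) * sr / np.pi
        bins = np.clip(np.round(freqs / bin_hz).astype(int), 0, spec_db.shape[1] - 1)
        prominent = spec_db[i, bins] > spec_db[i].max() - 60.0
        keep = (bws < settings.max_formant_bandwidth_hz) & (freqs > 90) & (freqs < sr / 2 - 50) & prominent
        cand = np.sort(freqs[keep])
        if cand.size < 4:
            continue
        rows.append((voicing["time_s"].iloc[i], *cand[:4]))
    table = pd.DataFrame(rows, columns=["time_s", "f1_hz", "f2_hz", "f3_hz", "f4_hz"])
    n_voiced = max(1, voiced_idx.size)
    return table, len(table) / n_voiced


# ---------------------------------------------------------------------------
# full feature vector


def _spectral_stats(x: np.ndarray, sr: int, settings: FrameSettings) -> dict[str, float]:
    nper = min(settings.frame_length, x.size)
    freqs, psd = sps.welch(x, fs=sr, window="hann", nperseg=nper, noverlap=nper // 2)
    p = psd / psd.sum() if psd.sum() > 0 else np.full_like(psd, 1 / psd.size)
    centroid = float(np.sum(freqs * p))
    sd = float(np.sqrt(np.sum((freqs - centroid) ** 2 * p)))
    if sd > 0:
        z = (freqs - centroid) / sd
        skew = float(np.sum(z**3 * p))
        kurt = float(np.sum(z**4 * p))
    else:
        skew, kurt = 0.0, 0.0
    cdf = np.cumsum(p)
    q25, q50, q75 = (float(freqs[np.searchsorted(cdf, q)]) for q in (0.25, 0.5, 0.75))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log(nz)) / np.log(p.size))
    flatness = float(np.exp(np.mean(np.log(np.clip(psd, 1e-300, None)))) / np.mean(psd)) if np.mean(psd) > 0 else 0.0
    return {
        "spec_centroid_hz": centroid,
        "spec_sd_hz": sd,
        "spec_skew": skew,
        "spec_kurt": kurt,
        "spec_q25_hz": q25,
        "spec_q50_hz": q50,
        "spec_q75_hz": q75,
        "spec_iqr_hz": q75 - q25,
        "spec_entropy": entropy,
        "spec_flatness": flatness,
    }


def extract_features(w: Waveform, settings: FrameSettings = FrameSettings()) -> dict[str, float | str]:
    """Compute the full feature vector for one call.

    f0 statistics are computed over voiced frames only and set to NaN for
    an all-unvoiced call; formant medians come from admissible LPC frames.
    """
    sr = w.sample_rate_hz
    x = w.samples
    out: dict[str, float | str] = {
        "call_id": w.call_id,
        "caller_id": w.caller_id,
        "context": w.context,
        "dur_s": w.duration_s,
    }

    frames = _frames(x, settings)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    rms_db = 20 * np.log10(np.clip(rms, 1e-10, None))
    out.update(
        rms_db_mean=float(rms_db.mean()),
        rms_db_median=float(np.median(rms_db)),
        rms_db_sd=float(rms_db.std(ddof=1)) if rms_db.size > 1 else 0.0,
        rms_db_max=float(rms_db.max()),
    )

    out.update(_spectral_stats(x, sr, settings))

    # dominant frequency: per-frame argmax of the windowed periodogram
    win = np.hanning(settings.frame_length)
    mags = np.abs(np.fft.rfft(frames * win, axis=1))
    freqs = np.fft.rfftfreq(settings.frame_length, 1 / sr)
    dom = freqs[np.argmax(mags, axis=1)]
    out.update(
        domfreq_mean_hz=float(dom.mean()),
        domfreq_median_hz=float(np.median(dom)),
        domfreq_sd_hz=float(dom.std(ddof=1)) if dom.size > 1 else 0.0,
    )

    track = track_f0(w, settings)
    voiced = track[track["voiced"]]
    out["voiced_frac"] = float(track["voiced"].mean()) if len(track) else 0.0
    if len(voiced) >= 2:
        f0 = voiced["f0_hz"].to_numpy()
        slope = float(np.polyfit(voiced["time_s"].to_numpy(), f0, 1)[0])
        out.update(
            f0_mean_hz=float(f0.mean()),
            f0_median_hz=float(np.median(f0)),
            f0_sd_hz=float(f0.std(ddof=1)),
            f0_min_hz=float(f0.min()),
            f0_max_hz=float(f0.max()),
            f0_range_hz=float(f0.max() - f0.min()),
            f0_slope_hz_per_s=slope,
        )
    else:
        for k in ("f0_mean_hz", "f0_median_hz", "f0_sd_hz", "f0_min_hz", "f0_max_hz", "f0_range_hz", "f0_slope_hz_per_s"):
            out[k] = np.nan

    formants, admissible = estimate_formants(w, settings)
    if len(formants):
        meds = formants[["f1_hz", "f2_hz", "f3_hz", "f4_hz"]].median()
        out.update(
            f1_median_hz=float(meds["f1_hz"]),
            f2_median_hz=float(meds["f2_hz"]),
            f3_median_hz=float(meds["f3_hz"]),
            f4_median_hz=float(meds["f4_hz"]),
            formant_dispersion_hz=float((meds["f4_hz"] - meds["f1_hz"]) / 3),
        )
    else:
        for k in ("f1_median_hz", "f2_median_hz", "f3_median_hz", "f4_median_hz", "formant_dispersion_hz"):
            out[k] = np.nan
    out["formant_frame_frac"] = admissible
    return out


def extract_table(
    waveforms: Iterable[Waveform] | None = None,
    settings: FrameSettings = FrameSettings(),
    manifest: pd.DataFrame | str | Path | None = None,
    audio_dir: str | Path | None = None,
    skip_bad: bool = False,
) -> pd.DataFrame:
    """Extract features for a collection of calls into a FeatureTable.

    Either pass in-memory ``waveforms`` or a ``manifest`` (DataFrame or CSV
    path) with columns ``call_id, caller_id, context, file``.  Failures are
    collected; unless ``skip_bad`` the whole job raises listing them.
    The returned DataFrame carries ``settings_hash`` in ``df.attrs``.
    """
    rows, failures = [], []
    if waveforms is None:
        if manifest is None:
            raise ValueError("pass either waveforms or a manifest")
        if not isinstance(manifest, pd.DataFrame):
            manifest = pd.read_csv(manifest)
        base = Path(audio_dir) if audio_dir else Path(".")
        for r in manifest.itertuples(index=False):
            try:
                w = load_wav(base / r.file, call_id=str(r.call_id), caller_id=str(r.caller_id), context=str(r.context))
                rows.append(extract_features(w, settings))
            except Exception as exc:
                failures.append((str(r.call_id), str(exc)))
    else:
        for w in waveforms:
            try:
                rows.append(extract_features(w, settings))
            except Exception as exc:
                failures.append((w.call_id, str(exc)))

    if failures and not skip_bad:
        detail = "; ".join(f"{cid}: {msg}" for cid, msg in failures)
        raise RuntimeError(f"feature extraction failed for {len(failures)} call(s): {detail}")
    for cid, msg in failures:
        warnings.warn(f"skipped call {cid}: {msg}")

    table = pd.DataFrame(rows)
    if table.empty:
        raise RuntimeError("no calls could be processed")
    dup = table["call_id"][table["call_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate call_id values: {sorted(set(dup))}")
    table.attrs["settings_hash"] = settings.settings_hash()
    return table


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """CSV dump with a ``#settings:`` header comment line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#settings:{table.attrs.get('settings_hash', 'unknown')}\n")
        table.to_csv(fh, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        table = pd.read_csv(fh) if first.startswith("#") else pd.read_csv(path)
    if first.startswith("#settings:"):
        table.attrs["settings_hash"] = first.split(":", 1)[1].strip()
    return table
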