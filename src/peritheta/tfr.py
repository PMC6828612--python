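"""Time-frequency analysis: moving-window Hann FFT power and FM-theta.

The representation follows the common short-time-Fourier recipe for
response-locked EEG: 0.5 s Hann-tapered windows moved from -1.5 to
+1.5 s around the response in 50 ms steps, frequencies 2-36 Hz in 2 Hz
steps (a 0.5 s window at 500 Hz gives exactly 2 Hz bin spacing, no zero
padding).  Power is expressed as 10*log10(uV^2); differences of
log-power are therefore decibels.  Baseline correction subtracts, per
trial and frequency, the mean log-power of windows whose centres fall
in a pre-prime interval (-0.75 to -0.25 s relative to the prime), so
the corrected values are dB change from the pre-trial state.

Frontal-midline theta (FM-theta) is the mean over the 4, 6 and 8 Hz
bins and electrodes Fz and Cz; its scalar per-trial summary is the
time average over -0.4..+0.4 s around the response (17 grid points).

Power normalisation: for a sinusoid of amplitude A centred on a bin,
the reported power equals A^2/2 (its mean square), independent of
phase — the periodic Hann window makes the on-bin response exact.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.fft import rfft
from scipy.signal.windows import hann

WINDOW_S = 0.5
STEP_S = 0.05
GRID_TIMES = np.round(np.arange(-1.5, 1.5 + 1e-9, STEP_S), 10)   # 61 points
FREQS = np.arange(2.0, 36.0 + 1e-9, 2.0)                          # 18 bins
BASELINE_WINDOW_S = (-0.75, -0.25)
DB_FLOOR = -300.0
_POWER_EPS = 1e-30


def _window_power(epochs: np.ndarray, center_idx: np.ndarray,
                  sfreq: float) -> np.ndarray:
    """Hann-windowed FFT power at the analysis bins.

    epochs : (n, ch, S); center_idx : any shape of sample indices.
    Returns power of shape (n, ch, *center_idx.shape, n_freqs).
    """
    N = int(round(WINDOW_S * sfreq))
    w = hann(N, sym=False).astype(epochs.dtype)
    Wsum = w.sum()
    seg = center_idx[..., None] - N // 2 + np.arange(N)
    if seg.min() < 0 or seg.max() >= epochs.shape[-1]:
        raise ValueError("analysis window exceeds epoch extent")
    n_bins = len(FREQS)
    out = np.empty(epochs.shape[:2] + center_idx.shape + (n_bins,),
                   dtype=np.float64)
    # chunk over trials to bound the gathered-segment scratch memory
    per_trial = epochs.shape[1] * seg.size * epochs.dtype.itemsize
    chunk = max(1, int(2e8 // max(per_trial, 1)))
    for a in range(0, epochs.shape[0], chunk):
        b = min(a + chunk, epochs.shape[0])
        x = epochs[a:b][:, :, seg] * w          # (b-a, ch, ..., N)
        X = rfft(x, axis=-1)[..., 1:n_bins + 1]
        out[a:b] = (2.0 * np.abs(X) / Wsum) ** 2 / 2.0
    return out


def stft_power(epochs: np.ndarray, tmin: float, sfreq: float,
               times: np.ndarray = GRID_TIMES) -> np.ndarray:
    """Moving-window power on the time x frequency grid.

    Parameters
    ----------
    epochs : (n_trials, n_channels, n_samples)
        Response-locked epochs, microvolts; sample at ``-tmin*sfreq``
        is the response.
    tmin : float
        Time of the first sample relative to the response (seconds).

    Returns
    -------
    power : (n_trials, n_channels, 18, 61), linear uV^2 units.
    """
    epochs = np.asarray(epochs)
    centers = np.round((times - tmin) * sfreq).astype(int)
    P = _window_power(epochs, centers, sfreq)       # (n, ch, 61, 18)
    return np.moveaxis(P, -1, 2)                    # (n, ch, 18, 61)


def to_db(power: np.ndarray) -> np.ndarray:
    """10*log10 with a -300 dB floor guarding silent (zero-power) input."""
    return np.maximum(10.0 * np.log10(np.maximum(power, 0.0) + _POWER_EPS),
                      DB_FLOOR)


def baseline_correct(log_power: np.ndarray, epochs: np.ndarray,
                     prime_offsets_s: np.ndarray, tmin: float, sfreq: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Subtract each trial's pre-prime baseline log-power per frequency.

    The baseline is the mean 10*log10 power of windows whose centres
    fall at ``prime_offset + [-0.75 .. -0.25]`` s (11 centres, 50 ms
    step) — computed from the same response-locked epoch through the
    stored prime offset.  Trials whose baseline windows do not fit in
    the epoch are flagged invalid (returned mask False) and left
    uncorrected; callers must exclude them from summaries.

    Returns ``(db, valid)`` with ``db`` shaped like ``log_power``.
    """
    epochs = np.asarray(epochs)
    prime_offsets_s = np.asarray(prime_offsets_s, dtype=float)
    n, n_ch, n_freq, _ = log_power.shape
    S = epochs.shape[-1]
    tmax = tmin + (S - 1) / sfreq
    rel = np.round(np.arange(BASELINE_WINDOW_S[0], BASELINE_WINDOW_S[1] + 1e-9,
                             STEP_S), 10)
    centers_s = prime_offsets_s[:, None] + rel[None, :]       # (n, 11)
    half = WINDOW_S / 2
    valid = ((centers_s.min(axis=1) >= tmin + half - 1e-9)
             & (centers_s.max(axis=1) <= tmax - half + 1e-9)
             & np.isfinite(prime_offsets_s))
    db = log_power.copy()
    if not valid.any():
        warnings.warn("no trial has a usable pre-prime baseline",
                      RuntimeWarning, stacklevel=2)
        return db, valid
    idx = np.flatnonzero(valid)
    centers_idx = np.round((centers_s[idx] - tmin) * sfreq).astype(int)
    # per-trial centres differ, so gather trial-by-trial
    N = int(round(WINDOW_S * sfreq))
    w = hann(N, sym=False)
    Wsum = w.sum()
    segs = []
    for k, i in enumerate(idx):
        si = centers_idx[k][:, None] - N // 2 + np.arange(N)
        segs.append(epochs[i][:, si])           # (ch, 11, N)
    x = np.stack(segs) * w                      # (m, ch, 11, N)
    X = rfft(x, axis=-1)[..., 1:n_freq + 1]
    Pb = (2.0 * np.abs(X) / Wsum) ** 2 / 2.0    # (m, ch, 11, n_freq)
    base_log = np.maximum(
        10.0 * np.log10(np.maximum(Pb, 0.0) + _POWER_EPS), DB_FLOOR)
    base_mean = base_log.mean(axis=2)           # (m, ch, n_freq)
    db[idx] = log_power[idx] - base_mean[..., None]
    return db, valid


def fmtheta_timecourse(db: np.ndarray, ch_names, channels=("Fz", "Cz"),
                       band=(4.0, 8.0)) -> np.ndarray:
    """Mean dB over the theta bins and fronto-central channels.

    Returns (n_trials, n_times).  With the 2 Hz grid, a 4-8 Hz band is
    the arithmetic mean of the 4, 6 and 8 Hz bins.
    """
    ch_names = list(ch_names)
    try:
        ci = [ch_names.index(c) for c in channels]
    except ValueError as e:
        raise ValueError(f"channel missing for FM-theta: {e}") from e
    fi = np.flatnonzero((FREQS >= band[0] - 1e-9) & (FREQS <= band[1] + 1e-9))
    return db[:, ci][:, :, fi].mean(axis=(1, 2))


def time_average(timecourse: np.ndarray, times: np.ndarray = GRID_TIMES,
                 half_window_s: float = 0.4) -> np.ndarray:
    """Per-trial mean over -0.4..+0.4 s relative to the response."""
    m = np.abs(times) <= half_window_s + 1e-9
    return timecourse[:, m].mean(axis=1)


def save_tfr(path, tfr_db: np.ndarray, meta: pd.DataFrame,
             times: np.ndarray = GRID_TIMES,
             freqs: np.ndarray = FREQS, ch_names=("Fz", "Cz")) -> None:
    """Write a trials x channels x freqs x times array plus metadata to
    an HDF5 container (layout: /tfr, /time, /freq, meta as JSON attr)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("tfr", data=np.asarray(tfr_db, dtype=np.float32),
                         compression="gzip", compression_opts=1)
        f.create_dataset("time", data=np.asarray(times))
        f.create_dataset("freq", data=np.asarray(freqs))
        f.attrs["ch_names"] = ",".join(ch_names)
        f.attrs["meta_json"] = meta.to_json(orient="table")


def load_tfr(path):
    """Read a container written by :func:`save_tfr`; returns
    (tfr, times, freqs, ch_names, meta)."""
    import io

    import h5py

    with h5py.File(path, "r") as f:
        meta = pd.read_json(io.StringIO(f.attrs["meta_json"]),
                            orient="table")
        return (f["tfr"][...], f["time"][...], f["freq"][...],
                tuple(f.attrs["ch_names"].split(",")), meta)


def theta_summaries(timecourse: np.ndarray, meta: pd.DataFrame,
                    valid: np.ndarray | None = None,
                    mode: str = "vs_baseline") -> pd.DataFrame:
    """Per-trial time-averaged FM-theta, ready for group statistics.

    ``meta`` must align row-wise with ``timecourse`` and carry at least
    ``subject``, ``group`` and ``label``.  Mode ``vs_baseline`` keeps
    the baseline-corrected dB; ``vs_errorfree`` additionally subtracts
    the subject's mean error-free summary (subjects without error-free
    trials are dropped with a warning).
    """
    from .behavior import ERROR_FREE

    if mode not in ("vs_baseline", "vs_errorfree"):
        raise ValueError("mode must be vs_baseline or vs_errorfree")
    vals = time_average(timecourse)
    out = meta.copy().reset_index(drop=True)
    out["theta_db"] = vals
    if valid is not None:
        out = out[np.asarray(valid, dtype=bool)]
    out["baseline_mode"] = mode
    if mode == "vs_errorfree":
        ef = out[out["label"] == ERROR_FREE].groupby("subject")["theta_db"] \
            .mean()
        missing = set(out["subject"]) - set(ef.index)
        if missing:
            warnings.warn(f"no error-free trials for subjects {sorted(missing)};"
                          " dropped from vs_errorfree summaries",
                          RuntimeWarning, stacklevel=2)
            out = out[~out["subject"].isin(missing)]
        out["theta_db"] = out["theta_db"] - out["subject"].map(ef)
    return out.reset_index(drop=True)
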