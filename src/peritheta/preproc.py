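"""EEG preprocessing: filtering, ocular cleaning, epoching, rejection.

The chain is fixed: notch (48.5-51.5 Hz) -> bandpass (0.3-40 Hz) ->
blink detection on VEOG -> joint-decorrelation removal of the blink
component -> response-locked epoching (-2..+2 s) -> +/-80 uV artifact
rejection on the scalp channels.  All filters are 4th-order Butterworth
applied forward-backward (zero phase; the effective attenuation is the
squared one-pass magnitude response).

Joint decorrelation finds, by generalized eigendecomposition of a
blink-biased covariance against the whole-recording covariance, the
spatial components that maximally express blinks, and projects them out
of the sensor data.  Only the scalp channels enter the decomposition;
the EOG channels are kept raw for detection and excluded from the
rejection threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy import linalg, signal

SCALP_CHANNELS = ("F3", "Fz", "F4", "C3", "Cz", "C4", "O1", "O2")
EPOCH_TMIN, EPOCH_TMAX = -2.0, 2.0
REJECT_UV = 80.0


def _sos(kind: str, sfreq: float):
    if kind == "notch":
        return signal.butter(4, [48.5, 51.5], btype="bandstop", fs=sfreq,
                             output="sos")
    if kind == "bandpass":
        return signal.butter(4, [0.3, 40.0], btype="bandpass", fs=sfreq,
                             output="sos")
    raise ValueError(kind)


def notch_filter(data: np.ndarray, sfreq: float) -> np.ndarray:
    """Zero-phase 48.5-51.5 Hz band-stop (4th-order Butterworth per pass)."""
    if sfreq < 2 * 51.5:
        raise ValueError(f"sample rate {sfreq} too low for the 50 Hz notch")
    return signal.sosfiltfilt(_sos("notch", sfreq), data, axis=-1)


def bandpass_filter(data: np.ndarray, sfreq: float) -> np.ndarray:
    """Zero-phase 0.3-40 Hz band-pass (4th-order Butterworth per pass)."""
    if sfreq < 2 * 40.0:
        raise ValueError(f"sample rate {sfreq} too low for the 40 Hz edge")
    return signal.sosfiltfilt(_sos("bandpass", sfreq), data, axis=-1)


def filter_response(kind: str, freqs_hz, sfreq: float) -> np.ndarray:
    """Two-pass (zero-phase) magnitude response |H(f)|^2 of a stage."""
    w, h = signal.sosfreqz(_sos(kind, sfreq), worN=2 * np.pi *
                           np.asarray(freqs_hz, dtype=float) / sfreq)
    return np.abs(h) ** 2


@dataclass
class BlinkEvents:
    peaks: np.ndarray          # sample indices, strictly increasing
    threshold_uv: float
    k: float

    def __len__(self):
        return self.peaks.size


def detect_blinks(veog: np.ndarray, sfreq: float, k: float = 5.0,
                  min_separation_s: float = 0.3) -> BlinkEvents:
    """Blink peaks on the vertical EOG channel.

    Peaks are local maxima of |VEOG - median| exceeding ``k`` times the
    MAD-based robust SD (1.4826*MAD), at least ``min_separation_s``
    apart — a threshold rule standing in for per-recording visual
    verification.
    """
    veog = np.asarray(veog, dtype=float).ravel()
    med = np.median(veog)
    dev = np.abs(veog - med)
    mad = np.median(dev)
    if mad == 0:
        warnings.warn("flat VEOG channel: no blinks detectable",
                      RuntimeWarning, stacklevel=2)
        return BlinkEvents(np.empty(0, dtype=int), np.inf, k)
    thr = k * 1.4826 * mad
    peaks, _ = signal.find_peaks(dev, height=thr,
                                 distance=int(min_separation_s * sfreq))
    return BlinkEvents(peaks.astype(int), float(thr), k)


@dataclass
class JDResult:
    cleaned: np.ndarray
    eigenvalue_ratios: np.ndarray   # descending; blink/total power ratio
    n_removed: int


def joint_decorrelation_clean(data: np.ndarray, blinks: BlinkEvents,
                              sfreq: float, window_s: float = 0.3,
                              n_remove: int | None = 1,
                              ratio_threshold: float | None = None
                              ) -> JDResult:
    """Remove the dominant blink component(s) from multichannel data.

    The bias covariance is accumulated over +/-``window_s`` around each
    blink peak; generalized eigendecomposition against the full-data
    covariance ranks components by their blink-to-total power ratio.
    By default the single top component is projected out; alternatively
    all components whose ratio exceeds ``ratio_threshold`` are removed.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_s = data.shape
    if n_ch < 2:
        raise ValueError("need at least 2 channels")
    if len(blinks) == 0:
        raise ValueError("need at least one blink event for biasing")
    half = int(window_s * sfreq)
    segs = []
    for p in blinks.peaks:
        a, b = max(0, p - half), min(n_s, p + half)
        segs.append(data[:, a:b])
    xb = np.concatenate(segs, axis=1)
    C0 = data @ data.T / n_s
    Cb = xb @ xb.T / xb.shape[1]
    ridge = 1e-9 * np.trace(C0) / n_ch
    C0r = C0 + ridge * np.eye(n_ch)
    evals, evecs = linalg.eigh(Cb, C0r)      # ascending, B-orthonormal
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if ratio_threshold is not None:
        k = int((evals > ratio_threshold).sum())
    else:
        k = int(n_remove)
    if k >= n_ch:
        warnings.warn("removing all components leaves zero output",
                      RuntimeWarning, stacklevel=2)
    W = evecs[:, :k]                          # unmixing (components = W'x)
    A = C0r @ W                               # mixing (sensor patterns)
    cleaned = data - A @ (W.T @ data)
    return JDResult(cleaned=cleaned, eigenvalue_ratios=evals,
                    n_removed=k)


@dataclass
class EpochSet:
    """Response-locked epochs with per-trial metadata and rejection mask."""

    data: np.ndarray           # (n_trials, n_channels, n_samples)
    ch_names: tuple
    sfreq: float
    tmin: float
    meta: pd.DataFrame         # incl. prime_offset_s (negative seconds)
    rejected: np.ndarray = field(default=None)   # True = excluded

    def __post_init__(self):
        if self.rejected is None:
            self.rejected = np.zeros(len(self.data), dtype=bool)
        self.ch_names = tuple(self.ch_names)

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[-1]) / self.sfreq

    @property
    def n_kept(self) -> int:
        return int((~self.rejected).sum())

    def kept(self) -> "EpochSet":
        m = ~self.rejected
        return EpochSet(self.data[m], self.ch_names, self.sfreq, self.tmin,
                        self.meta[m].reset_index(drop=True))

    # -- hierarchical container (HDF5) ------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data.astype(np.float32),
                             compression="gzip", compression_opts=1)
            f.create_dataset("time", data=self.times)
            f.create_dataset("rejected", data=self.rejected)
            f.attrs["sfreq"] = self.sfreq
            f.attrs["tmin"] = self.tmin
            f.attrs["ch_names"] = ",".join(self.ch_names)
            f.attrs["meta_json"] = self.meta.to_json(orient="table")

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        import io
        with h5py.File(path, "r") as f:
            meta = pd.read_json(io.StringIO(f.attrs["meta_json"]),
                                orient="table")
            return cls(data=f["data"][...], sfreq=float(f.attrs["sfreq"]),
                       tmin=float(f.attrs["tmin"]),
                       ch_names=tuple(f.attrs["ch_names"].split(",")),
                       meta=meta, rejected=f["rejected"][...])


def epoch_responses(data: np.ndarray, ch_names, sfreq: float,
                    events: pd.DataFrame, tmin: float = EPOCH_TMIN,
                    tmax: float = EPOCH_TMAX) -> EpochSet:
    """Cut response-locked epochs; trials too close to the recording
    edges are dropped (and listed in the returned metadata log)."""
    n_s = data.shape[-1]
    n_before = int(round(-tmin * sfreq))
    n_after = int(round(tmax * sfreq))
    resp = events["response_onset_s"].to_numpy(dtype=float)
    centers = np.where(np.isfinite(resp),
                       np.round(resp * sfreq), -1).astype(int)
    fits = (centers - n_before >= 0) & (centers + n_after < n_s)
    usable = np.isfinite(resp)
    dropped = events.loc[usable & ~fits, "trial"].tolist()
    if dropped:
        warnings.warn(f"dropped {len(dropped)} trial(s) at recording edges: "
                      f"{dropped}", RuntimeWarning, stacklevel=2)
    keep = usable & fits
    if not keep.any():
        raise ValueError("no epochable responses")
    cuts = np.stack([data[:, c - n_before:c + n_after + 1]
                     for c in centers[keep]])
    meta = events[keep].copy().reset_index(drop=True)
    meta["prime_offset_s"] = (meta["prime_onset_s"]
                              - meta["response_onset_s"])
    return EpochSet(data=cuts, ch_names=tuple(ch_names),
                    sfreq=sfreq, tmin=tmin, meta=meta)


def reject_artifacts(epochs: EpochSet, threshold_uv: float = REJECT_UV
                     ) -> EpochSet:
    """Mark epochs with any scalp sample beyond +/-threshold as rejected.

    EOG channels are exempt: residual ocular activity there is expected
    and carries no cost for the scalp analysis.
    """
    scalp = [i for i, c in enumerate(epochs.ch_names) if c in SCALP_CHANNELS]
    peak = np.abs(epochs.data[:, scalp]).max(axis=(1, 2))
    out = EpochSet(epochs.data, epochs.ch_names, epochs.sfreq, epochs.tmin,
                   epochs.meta, rejected=epochs.rejected | (peak > threshold_uv))
    return out


def preprocess_recording(data: np.ndarray, ch_names, sfreq: float,
                         events: pd.DataFrame, n_remove: int = 1,
                         blink_k: float = 5.0) -> tuple[EpochSet, dict]:
    """Full chain on one recording; returns clean epochs and a log."""
    if sfreq != 500.0:
        raise ValueError(f"expected 500 Hz recordings, got {sfreq}")
    ch_names = list(ch_names)
    x = notch_filter(np.asarray(data, dtype=float), sfreq)
    x = bandpass_filter(x, sfreq)
    veog = x[ch_names.index("VEOG")]
    blinks = detect_blinks(veog, sfreq, k=blink_k)
    scalp_idx = [ch_names.index(c) for c in SCALP_CHANNELS]
    log = {"n_blinks": len(blinks), "n_removed_components": 0}
    if len(blinks):
        # decompose over all channels including EOG: the blink component
        # then loads dominantly on VEOG, which keeps the spatial filter
        # nearly orthogonal to fronto-central oscillatory activity
        jd = joint_decorrelation_clean(x, blinks, sfreq, n_remove=n_remove)
        x[scalp_idx] = jd.cleaned[scalp_idx]
        log["n_removed_components"] = jd.n_removed
        log["eigenvalue_ratios"] = jd.eigenvalue_ratios.tolist()
    epochs = epoch_responses(x, ch_names, sfreq, events)
    epochs = reject_artifacts(epochs)
    log["n_epochs"] = len(epochs.data)
    log["n_rejected"] = int(epochs.rejected.sum())
    return epochs, log
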