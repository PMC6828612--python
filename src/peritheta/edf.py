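"""Minimal 16-bit EDF (European Data Format) writing, plus reading
through MNE.

Only the features the simulated recordings need are implemented on the
writing side: one fixed sample rate for all signals, 1-second data
records, a physical unit of microvolts and a symmetric physical range.
Recordings are zero-padded to a whole number of records (EDF stores an
integer record count); readers therefore see up to one extra second of
zeros at the end.  Reading goes through :func:`mne.io.read_raw_edf`, an
independent implementation, which keeps the round-trip test honest.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

HEADER_BYTES = 256


def _field(text: str, width: int) -> bytes:
    b = str(text)[:width].encode("ascii")
    return b + b" " * (width - len(b))


def write_edf(path, data: np.ndarray, sfreq: float, ch_names,
              phys_range_uv: float = 500.0, patient: str = "X",
              recording: str = "synthetic") -> None:
    """Write ``data`` (n_channels x n_samples, microvolts) as 16-bit EDF.

    Samples are quantized to the declared physical range
    ``[-phys_range_uv, +phys_range_uv]`` over the full 16-bit digital
    span, so the quantization step is ``2*phys_range_uv / 65535`` uV.
    Values outside the range are clipped.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    if len(ch_names) != n_ch:
        raise ValueError("channel name count mismatch")
    if sfreq != int(sfreq):
        raise ValueError("integer sample rates only")
    spr = int(sfreq)                       # samples per 1 s record
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data

    pmin, pmax = -phys_range_uv, phys_range_uv
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(np.round((padded - pmin) * scale) + dmin, dmin, dmax
                      ).astype("<i2")

    header_bytes = HEADER_BYTES * (1 + n_ch)
    hdr = b"".join([
        _field("0", 8),
        _field(patient, 80),
        _field(recording, 80),
        _field("01.01.20", 8),
        _field("00.00.00", 8),
        _field(str(header_bytes), 8),
        _field("", 44),
        _field(str(n_rec), 8),
        _field("1", 8),
        _field(str(n_ch), 4),
    ])
    per_signal = b"".join([
        b"".join(_field(name, 16) for name in ch_names),
        b"".join(_field("AgAgCl electrode", 80) for _ in ch_names),
        b"".join(_field("uV", 8) for _ in ch_names),
        b"".join(_field(f"{pmin:g}", 8) for _ in ch_names),
        b"".join(_field(f"{pmax:g}", 8) for _ in ch_names),
        b"".join(_field(str(dmin), 8) for _ in ch_names),
        b"".join(_field(str(dmax), 8) for _ in ch_names),
        b"".join(_field("", 80) for _ in ch_names),
        b"".join(_field(str(spr), 8) for _ in ch_names),
        b"".join(_field("", 32) for _ in ch_names),
    ])
    with open(path, "wb") as f:
        f.write(hdr + per_signal)
        # data records: per record, each signal's samples contiguously
        recs = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
        f.write(np.ascontiguousarray(recs).tobytes())


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; returns (data in uV, sfreq, channel names)."""
    import mne

    raw = mne.io.read_raw_edf(Path(path), preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), raw.ch_names
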