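"""Synthetic two-group cohort: behaviour tables and continuous EEG.

The generator produces data with the statistical structure the
peri-error analysis assumes, with every effect injected as an explicit
parameter so downstream stages can be tested by parameter recovery:

* trial-level correctness at a group-specific error rate, with at least
  five isolated errors per subject (layouts are redrawn otherwise,
  mirroring the analysis inclusion rule);
* standardized reaction times built additively — subject intercept,
  peri-error offsets around isolated errors (pre-error speeding, error
  speeding, group-specific post-error recovery), a compatibility
  (priming) effect, and a unit-variance residual — then mapped to
  milliseconds through the group mean/SD;
* continuous 10-channel EEG at 500 Hz: 1/f background, 50 Hz line
  component, frontally-weighted eyeblinks mirrored into VEOG,
  response-locked 6 Hz theta bursts with a Hann envelope spanning
  +/-0.4 s, and occasional high-amplitude artifact segments that the
  +/-80 uV rejection must catch.

Theta-burst amplitudes are not free-handed: they are calibrated by
Monte-Carlo bisection so that the *pipeline's own* dB measure (Hann
STFT, pre-prime baseline, 4-8 Hz x {Fz, Cz} x +/-0.4 s average)
recovers the requested dB value in expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior

SFREQ = 500.0
CHANNELS = ("F3", "Fz", "F4", "C3", "Cz", "C4", "O1", "O2", "VEOG", "HEOG")
SCALP = CHANNELS[:8]
SOA_S = 0.150            # prime -> target stimulus-onset asynchrony
ITI_RANGE_S = (1.5, 2.0)  # response -> next prime, jittered uniform
MISS_ADVANCE_S = 1.0      # virtual response deadline for omissions

#: scalp projection of the theta source (only Fz/Cz enter the FM-theta
#: measure; neighbours get a plausible spread)
THETA_WEIGHTS = {"Fz": 1.0, "Cz": 1.0, "F3": 0.5, "F4": 0.5,
                 "C3": 0.5, "C4": 0.5, "O1": 0.1, "O2": 0.1}
BLINK_WEIGHTS = {"F3": 0.45, "Fz": 0.5, "F4": 0.45, "C3": 0.18, "Cz": 0.2,
                 "C4": 0.18, "O1": 0.05, "O2": 0.05, "VEOG": 1.0, "HEOG": 0.0}


@dataclass
class GroupParams:
    """Generative parameters for one diagnostic group."""

    mean_rt_ms: float = 427.0
    sd_rt_ms: float = 31.0
    error_rate: float = 0.068
    z_error: float = -1.39
    z_pre: tuple = (-0.16, -0.26, -0.36)    # ER-3, ER-2, ER-1
    z_post: tuple = (0.0, 0.0, 0.0)         # ER+1, ER+2, ER+3
    compat_effect_ms: float = 20.0
    compat_post_extra_ms: float = 27.0      # added to the effect in ER+1
    subject_sd: float = 0.05 ** 0.5         # random-intercept SD, z units
    miss_rate: float = 0.0
    theta_burst_db: float = 3.0             # error-locked FM-theta
    theta_correct_db: float = 0.8
    blink_rate_hz: float = 0.2
    noise_exponent: float = 1.0             # 1/f slope
    noise_scale_uv: float = 10.0            # scalp background RMS
    line_amp_uv: float = 2.0
    blink_amp_uv: float = 200.0
    artifacts_per_recording: float = 4.0

    def __post_init__(self):
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.sd_rt_ms <= 0:
            raise ValueError("sd_rt_ms must be positive")
        if self.theta_burst_db < 0 or self.theta_correct_db < 0:
            raise ValueError("theta burst dB must be >= 0")
        if len(self.z_pre) != 3 or len(self.z_post) != 3:
            raise ValueError("z_pre/z_post must have 3 entries (ER+/-1..3)")


def default_group_params() -> dict:
    """Defaults for typically-developing controls and the ADHD group."""
    return {
        "TD": GroupParams(),
        "ADHD": GroupParams(mean_rt_ms=459.0, sd_rt_ms=41.0, error_rate=0.097,
                            z_post=(-0.44, -0.02, 0.0), theta_burst_db=1.5),
    }


@dataclass
class CohortParams:
    n_td: int = 14
    n_adhd: int = 26
    trials_per_block: int = 96
    n_blocks: int = 3
    seed: int = 0
    group_params: dict = field(default_factory=default_group_params)

    def __post_init__(self):
        if self.n_td < 1 or self.n_adhd < 1:
            raise ValueError("need at least one subject per group")
        if self.trials_per_block < 8 or self.n_blocks < 1:
            raise ValueError("implausible block structure")
        for g in ("TD", "ADHD"):
            if g not in self.group_params:
                raise ValueError(f"missing group parameters for {g}")

    @property
    def n_trials(self) -> int:
        return self.trials_per_block * self.n_blocks

    def to_dict(self) -> dict:
        d = asdict(self)
        for g, gp in d["group_params"].items():
            gp["z_pre"] = list(gp["z_pre"])
            gp["z_post"] = list(gp["z_post"])
        return d


@dataclass
class RecordingBundle:
    """One subject's continuous EEG plus its behaviour table."""

    data: np.ndarray          # (10, n_samples) float32, microvolts
    sfreq: float
    ch_names: tuple
    events: pd.DataFrame      # trial-level behaviour table
    subject: str
    group: str
    subtype: str
    blink_times_s: np.ndarray
    artifact_times_s: np.ndarray


# --------------------------------------------------------------------------
# behaviour
# --------------------------------------------------------------------------

def _offset_map(gp: GroupParams) -> dict:
    m = {behavior.ERROR_ISOLATED: gp.z_error}
    for lab, val in zip((behavior.ER_M3, behavior.ER_M2, behavior.ER_M1),
                        gp.z_pre):
        m[lab] = val
    for lab, val in zip((behavior.ER_P1, behavior.ER_P2, behavior.ER_P3),
                        gp.z_post):
        m[lab] = val
    return m


def _sample_subject(rng: np.random.Generator, gp: GroupParams,
                    trials_per_block: int, n_blocks: int,
                    min_isolated: int = 5, max_retries: int = 200):
    """Correctness layout, compatibility, standardized z and RT for one
    subject.  The correctness layout is redrawn until at least
    ``min_isolated`` isolated errors exist (commission errors only)."""
    n = trials_per_block * n_blocks
    blocks = np.repeat(np.arange(1, n_blocks + 1), trials_per_block)

    if gp.error_rate == 0 and gp.miss_rate == 0:
        correct = np.ones(n, dtype=bool)
        miss = np.zeros(n, dtype=bool)
        labels = np.array([behavior.ERROR_FREE] * n, dtype=object)
    else:
        for attempt in range(max_retries):
            u = rng.random(n)
            miss = u < gp.miss_rate
            err = (~miss) & (u < gp.miss_rate + gp.error_rate)
            correct = ~(miss | err)
            labels = np.empty(n, dtype=object)
            for b in range(n_blocks):
                s = slice(b * trials_per_block, (b + 1) * trials_per_block)
                labels[s] = behavior.classify_block(correct[s],
                                                    commission=err[s])
            if (labels == behavior.ERROR_ISOLATED).sum() >= min_isolated:
                break
        else:
            raise RuntimeError(
                f"could not draw >= {min_isolated} isolated errors in "
                f"{max_retries} attempts (error_rate={gp.error_rate})")

    # balanced compatibility within block, random order
    compat = np.empty(n, dtype=object)
    for b in range(n_blocks):
        s = slice(b * trials_per_block, (b + 1) * trials_per_block)
        half = trials_per_block // 2
        arr = np.array(["compatible"] * half
                       + ["incompatible"] * (trials_per_block - half))
        rng.shuffle(arr)
        compat[s] = arr

    # standardized RT: intercept + peri-error offset + compatibility + noise
    offsets = _offset_map(gp)
    peri = np.array([offsets.get(l, 0.0) for l in labels])
    compat_ms = np.where(compat == "compatible", 0.5, -0.5) * (
        gp.compat_effect_ms
        + np.where(labels == behavior.ER_P1, gp.compat_post_extra_ms, 0.0))
    compat_z = compat_ms / gp.sd_rt_ms
    half_effect = 0.5 * gp.compat_effect_ms / gp.sd_rt_ms
    if half_effect >= 1.0:
        raise ValueError("compatibility effect too large for unit variance")
    resid_sd = np.sqrt(1.0 - half_effect ** 2)  # error-free variance == 1
    b_i = rng.normal(0.0, gp.subject_sd)
    z = b_i + peri + compat_z + resid_sd * rng.standard_normal(n)
    rt_ms = np.clip(gp.mean_rt_ms + z * gp.sd_rt_ms, 100.0, None)
    rt_ms[miss] = np.nan

    return pd.DataFrame({
        "block": blocks,
        "trial": np.tile(np.arange(1, trials_per_block + 1), n_blocks),
        "correct": correct.astype(int),
        "compatibility": compat,
        "rt_ms": rt_ms,
        "z_true": z,
        "label_true": labels,
    })


def _add_timeline(df: pd.DataFrame, rng: np.random.Generator,
                  start_pad_s: float = 3.0) -> pd.DataFrame:
    """Prime/target/response onsets with jittered inter-trial intervals."""
    n = len(df)
    iti = rng.uniform(*ITI_RANGE_S, size=n)
    prime = np.empty(n)
    target = np.empty(n)
    resp = np.empty(n)
    t = start_pad_s
    for i in range(n):
        prime[i] = t
        target[i] = t + SOA_S
        if np.isnan(df["rt_ms"].iloc[i]):
            resp[i] = np.nan
            t = target[i] + MISS_ADVANCE_S + iti[i]
        else:
            resp[i] = target[i] + df["rt_ms"].iloc[i] / 1000.0
            t = resp[i] + iti[i]
    out = df.copy()
    out["prime_onset_s"] = prime
    out["target_onset_s"] = target
    out["response_onset_s"] = resp
    return out


def sample_behavior(params: CohortParams) -> pd.DataFrame:
    """Behaviour tables for the whole cohort (one row per trial).

    Deterministic in ``params.seed``; subjects are drawn from
    independent child streams so cohort size changes do not reshuffle
    earlier subjects.
    """
    ss = np.random.SeedSequence(params.seed)
    n_total = params.n_td + params.n_adhd
    children = ss.spawn(n_total)
    rows = []
    k = 0
    for group, n_g in (("TD", params.n_td), ("ADHD", params.n_adhd)):
        gp = params.group_params[group]
        for j in range(n_g):
            rng = np.random.default_rng(children[k])
            k += 1
            df = _sample_subject(rng, gp, params.trials_per_block,
                                 params.n_blocks)
            df = _add_timeline(df, rng)
            df.insert(0, "subject", f"{group.lower()}{j + 1:03d}")
            df.insert(1, "group", group)
            df.insert(2, "subtype", "" if group == "TD"
                      else ("I" if rng.random() < 0.5 else "H/C"))
            rows.append(df)
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# EEG rendering
# --------------------------------------------------------------------------

def one_over_f_noise(rng: np.random.Generator, n_samples: int, n_channels: int,
                     exponent: float = 1.0, scale_uv: float = 10.0,
                     sfreq: float = SFREQ) -> np.ndarray:
    """Gaussian 1/f^exponent noise by spectral synthesis, unit-RMS scaled.

    The amplitude spectrum is flattened below 0.5 Hz so the variance
    stays finite; the output is rescaled to ``scale_uv`` RMS exactly.
    """
    nf = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    amp = np.where(freqs < 0.5, 0.5, freqs) ** (-exponent / 2.0)
    amp[0] = 0.0
    spec = (rng.standard_normal((n_channels, nf))
            + 1j * rng.standard_normal((n_channels, nf))) * amp
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    rms = x.std(axis=1, keepdims=True)
    return x / rms * scale_uv


def _blink_template(sfreq: float = SFREQ) -> np.ndarray:
    """Biphasic ~400 ms eyeblink: dominant positive lobe, small rebound."""
    n1, n2 = int(0.24 * sfreq), int(0.16 * sfreq)
    lobe1 = np.hanning(n1)
    lobe2 = -0.3 * np.hanning(n2)
    return np.concatenate([lobe1, lobe2])


def _burst_waveform(env_halfwidth_s: float = 0.4, freq: float = 6.0,
                    phase: float = 0.0, sfreq: float = SFREQ) -> np.ndarray:
    """Unit-amplitude 6 Hz burst under a Hann envelope of +/-0.4 s."""
    n = int(round(2 * env_halfwidth_s * sfreq)) + 1
    t = (np.arange(n) - n // 2) / sfreq
    env = 0.5 * (1 + np.cos(np.pi * t / env_halfwidth_s))
    return env * np.cos(2 * np.pi * freq * t + phase)


def _add_at(signal: np.ndarray, center_idx: int, wave: np.ndarray,
            weight: float = 1.0) -> None:
    """Add ``wave`` (centered) into ``signal`` in place, clipped to range."""
    half = len(wave) // 2
    a = center_idx - half
    b = a + len(wave)
    wa, wb = max(0, -a), len(wave) - max(0, b - signal.size)
    a, b = max(a, 0), min(b, signal.size)
    if b > a:
        signal[a:b] += weight * wave[wa:wb]


# cache of calibrated burst amplitudes, keyed by the parameters that
# affect the measure (noise shape/level and target dB)
_AMP_CACHE: dict = {}


def calibrate_burst_amplitude(target_db: float, noise_exponent: float,
                              noise_scale_uv: float, n_mc: int = 384,
                              cal_seed: int = 987654321) -> float:
    """Burst amplitude (uV) whose expected pipeline dB measure equals
    ``target_db``.

    Monte-Carlo: noise-only 4 s epochs with the generator's own PSD are
    run through the package's STFT / pre-prime baseline / FM-theta
    measure with a candidate burst added, and the amplitude is bisected
    until the mean measure hits the target.  Uses a fixed internal seed,
    so calibration is deterministic and cacheable.
    """
    key = (round(target_db, 6), round(noise_exponent, 6),
           round(noise_scale_uv, 6), n_mc, cal_seed)
    if key in _AMP_CACHE:
        return _AMP_CACHE[key]
    if target_db == 0:
        _AMP_CACHE[key] = 0.0
        return 0.0

    from . import tfr

    rng = np.random.default_rng(cal_seed)
    n_samp = int(4 * SFREQ) + 1           # epoch -2..+2 s
    n_ch = 2                              # Fz, Cz (independent noise)
    # slice epochs out of one long stream so the noise floor at the
    # analysis bins matches a recording-length synthesis (a short
    # per-epoch synthesis lacks the slow components that soak up part
    # of the normalized variance in real recordings)
    stream = one_over_f_noise(rng, n_mc * n_samp, n_ch, noise_exponent,
                              noise_scale_uv)
    noise = np.stack([stream[:, k * n_samp:(k + 1) * n_samp]
                      for k in range(n_mc)])   # (n_mc, 2, n_samp)
    phases = rng.uniform(0, 2 * np.pi, size=n_mc)
    bursts = np.stack([_burst_waveform(phase=ph) for ph in phases])
    wave = np.zeros((n_mc, n_samp))
    c = n_samp // 2
    h = bursts.shape[1] // 2
    wave[:, c - h:c - h + bursts.shape[1]] = bursts
    # typical prime offset; baseline windows then sit well clear of the burst
    prime_off = np.full(n_mc, -0.6)

    def raw_measure(a: float) -> float:
        x = noise + a * wave[:, None, :]
        P = tfr.stft_power(x, tmin=-2.0, sfreq=SFREQ)
        logP = tfr.to_db(P)
        db, valid = tfr.baseline_correct(logP, x, prime_off, tmin=-2.0,
                                         sfreq=SFREQ)
        tc = tfr.fmtheta_timecourse(db, ("Fz", "Cz"))
        summ = tfr.time_average(tc, tfr.GRID_TIMES, half_window_s=0.4)
        return float(summ[valid].mean())

    # control variate: the null measure is 0 in expectation (baseline
    # and activation windows are exchangeable without a burst), so
    # subtracting the same noise realisation's null measure removes the
    # dominant Monte-Carlo fluctuation from the bisection target
    null = raw_measure(0.0)

    def measure(a: float) -> float:
        return raw_measure(a) - null

    lo, hi = 0.0, noise_scale_uv
    while measure(hi) < target_db:
        hi *= 2
        if hi > 1e4:
            raise RuntimeError("burst calibration failed to bracket target")
    for _ in range(24):
        mid = 0.5 * (lo + hi)
        if measure(mid) < target_db:
            lo = mid
        else:
            hi = mid
    amp = 0.5 * (lo + hi)
    _AMP_CACHE[key] = amp
    return amp


def render_eeg(events: pd.DataFrame, gp: GroupParams, seed,
               end_pad_s: float = 3.0) -> RecordingBundle:
    """Continuous 10-channel EEG for one subject's behaviour table."""
    rng = np.random.default_rng(seed)
    last = np.nanmax(events[["target_onset_s", "response_onset_s"]]
                     .to_numpy())
    dur_s = float(np.ceil(last + end_pad_s))
    n = int(dur_s * SFREQ)

    data = one_over_f_noise(rng, n, 8, gp.noise_exponent, gp.noise_scale_uv)
    t = np.arange(n) / SFREQ
    data += gp.line_amp_uv * np.sin(2 * np.pi * 50.0 * t
                                    + rng.uniform(0, 2 * np.pi))[None, :]
    eog = one_over_f_noise(rng, n, 2, gp.noise_exponent, 5.0)
    data = np.vstack([data, eog])

    # eyeblinks: Poisson process, frontally weighted, mirrored into VEOG
    n_blinks = rng.poisson(gp.blink_rate_hz * dur_s)
    blink_times = np.sort(rng.uniform(1.0, dur_s - 1.0, size=n_blinks))
    tpl = _blink_template()
    for bt in blink_times:
        idx = int(round(bt * SFREQ))
        amp = gp.blink_amp_uv * rng.uniform(0.8, 1.2)
        for ci, ch in enumerate(CHANNELS):
            _add_at(data[ci], idx, tpl, amp * BLINK_WEIGHTS[ch])

    # response-locked theta bursts
    a_err = calibrate_burst_amplitude(gp.theta_burst_db, gp.noise_exponent,
                                      gp.noise_scale_uv)
    a_cor = calibrate_burst_amplitude(gp.theta_correct_db, gp.noise_exponent,
                                      gp.noise_scale_uv)
    for _, row in events.iterrows():
        if np.isnan(row["response_onset_s"]):
            continue
        amp = a_cor if row["correct"] else a_err
        if amp == 0:
            continue
        wave = _burst_waveform(phase=rng.uniform(0, 2 * np.pi))
        idx = int(round(row["response_onset_s"] * SFREQ))
        for ci, ch in enumerate(CHANNELS):
            w = THETA_WEIGHTS.get(ch, 0.0)
            if w:
                _add_at(data[ci], idx, wave, amp * w)

    # occasional high-amplitude artifact segments (exercise rejection)
    n_art = rng.poisson(gp.artifacts_per_recording)
    art_times = np.sort(rng.uniform(1.0, dur_s - 1.0, size=n_art))
    art_len = int(0.2 * SFREQ)
    tt = np.arange(art_len) / SFREQ
    art_wave = 150.0 * np.hanning(art_len) * np.sin(2 * np.pi * 5.0 * tt)
    for at in art_times:
        ch = rng.integers(0, 8)
        _add_at(data[ch], int(round(at * SFREQ)), art_wave)

    return RecordingBundle(
        data=data.astype(np.float32), sfreq=SFREQ, ch_names=CHANNELS,
        events=events.reset_index(drop=True),
        subject=str(events["subject"].iloc[0]),
        group=str(events["group"].iloc[0]),
        subtype=str(events["subtype"].iloc[0]),
        blink_times_s=blink_times, artifact_times_s=art_times)


def render_cohort(params: CohortParams, behavior_table: pd.DataFrame | None = None):
    """Yield a RecordingBundle per subject (EEG seeds derived from the
    cohort seed, offset so they never collide with behaviour streams)."""
    if behavior_table is None:
        behavior_table = sample_behavior(params)
    ss = np.random.SeedSequence((params.seed, 1))
    subjects = behavior_table["subject"].unique()
    children = ss.spawn(len(subjects))
    for subj, child in zip(subjects, children):
        ev = behavior_table[behavior_table["subject"] == subj]
        gp = params.group_params[str(ev["group"].iloc[0])]
        yield render_eeg(ev, gp, child)


# --------------------------------------------------------------------------
# dataset I/O
# --------------------------------------------------------------------------

def behavior_to_events(df: pd.DataFrame) -> pd.DataFrame:
    """Trial table -> long BIDS-like events table (3 rows per trial)."""
    rows = []
    for kind, col in (("prime", "prime_onset_s"), ("target", "target_onset_s"),
                      ("response", "response_onset_s")):
        sub = df.copy()
        sub["event_type"] = kind
        sub["onset_s"] = sub[col]
        rows.append(sub)
    ev = pd.concat(rows)
    ev = ev[ev["onset_s"].notna()]
    ev["duration_s"] = 0.0
    cols = ["onset_s", "duration_s", "event_type", "block", "trial",
            "compatibility", "correct", "rt_ms", "subject", "group", "subtype"]
    return ev[cols].sort_values(["onset_s"], kind="stable").reset_index(drop=True)


def events_to_behavior(ev: pd.DataFrame) -> pd.DataFrame:
    """Long events table -> one-row-per-trial behaviour table."""
    base = ev[ev["event_type"] == "prime"].copy()
    base = base.rename(columns={"onset_s": "prime_onset_s"})
    for kind, col in (("target", "target_onset_s"),
                      ("response", "response_onset_s")):
        sub = ev.loc[ev["event_type"] == kind,
                     ["subject", "block", "trial", "onset_s"]]
        sub = sub.rename(columns={"onset_s": col})
        base = base.merge(sub, on=["subject", "block", "trial"], how="left")
    cols = ["subject", "group", "subtype", "block", "trial", "compatibility",
            "correct", "rt_ms", "prime_onset_s", "target_onset_s",
            "response_onset_s"]
    return (base[cols].sort_values(["subject", "block", "trial"],
                                   kind="stable").reset_index(drop=True))


def write_dataset(bundles, directory, params: CohortParams) -> list[Path]:
    """Write one EDF + one events TSV per subject plus a cohort manifest."""
    from . import edf

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    n_subjects = 0
    for b in bundles:
        n_subjects += 1
        stem = directory / f"sub-{b.subject}"
        edf_path = stem.with_suffix(".edf")
        edf.write_edf(edf_path, b.data, b.sfreq, b.ch_names,
                      phys_range_uv=500.0)
        ev = behavior_to_events(b.events)
        tsv_path = directory / f"sub-{b.subject}_events.tsv"
        ev.to_csv(tsv_path, sep="\t", index=False)
        written += [edf_path, tsv_path]
    if n_subjects == 0:
        raise ValueError("empty cohort: nothing to write")
    manifest = directory / "cohort.json"
    manifest.write_text(json.dumps(params.to_dict(), indent=2))
    written.append(manifest)
    return written
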