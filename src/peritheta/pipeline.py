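"""End-to-end orchestration: simulate -> preprocess -> analyze -> report.

The behavioural battery mirrors the standard peri-error analysis plan:
an intercept-only mixed model for error-trial standardized RT, pre- and
post-error models with a trial-position covariate (positions coded
-3..-1 and 1..3, centred within each period so the intercept is the
period mean), group effects and group x position interactions tested by
likelihood-ratio tests, post-hoc refits on group subsets, a logistic
mixed model for trial-wise accuracy, a 2x2 split-plot ANOVA cross-check
on subject means, pooled t-tests on error-free RT, and the
compatibility (priming) effect per peri-error stratum.

EEG analysis reduces each trial to a time-averaged FM-theta value
(baseline-corrected dB) and compares groups on participant-wise means,
as is standard when few error trials per subject are available.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import behavior, cohort, models, preproc, tfr

log = logging.getLogger("peritheta")


# --------------------------------------------------------------------------
# behavioural analysis
# --------------------------------------------------------------------------

def _row(analysis, term, estimate, stat_name, stat, df, p):
    return {"analysis": analysis, "term": term, "estimate": estimate,
            "stat": stat_name, "value": stat, "df": df, "p": p}


def _lmm(sub: pd.DataFrame, fixed, add_intercept=True):
    return models.RandomInterceptLM.from_dataframe(
        sub, "z_rt", fixed=fixed, groups="subject",
        add_intercept=add_intercept).fit()


def _period_models(sub: pd.DataFrame, name: str, center: float, rows: list):
    """Pre- or post-error period: mean, slope, group, interaction tests."""
    sub = sub.copy()
    sub["pos_c"] = sub["position"] - center
    sub["adhd"] = (sub["group"] == "ADHD").astype(float)
    sub["adhd_pos"] = sub["adhd"] * sub["pos_c"]
    m_base = _lmm(sub, ["pos_c"])
    m_nointc = _lmm(sub, ["pos_c"], add_intercept=False)
    m_noslope = _lmm(sub, [])
    m_group = _lmm(sub, ["pos_c", "adhd"])
    m_full = _lmm(sub, ["pos_c", "adhd", "adhd_pos"])
    t = models.lrt(m_base, m_nointc)
    rows.append(_row(name, "intercept", m_base.params["Intercept"],
                     "chi2", t.chi2, t.df, t.pvalue))
    t = models.lrt(m_base, m_noslope)
    rows.append(_row(name, "position", m_base.params["pos_c"],
                     "chi2", t.chi2, t.df, t.pvalue))
    t = models.lrt(m_group, m_base)
    rows.append(_row(name, "group", m_group.params["adhd"],
                     "chi2", t.chi2, t.df, t.pvalue))
    t = models.lrt(m_full, m_group)
    rows.append(_row(name, "group_x_position", m_full.params["adhd_pos"],
                     "chi2", t.chi2, t.df, t.pvalue))
    return m_base


def _contrast_model(sub: pd.DataFrame, indicator: pd.Series, name: str,
                    term: str, rows: list):
    sub = sub.copy()
    sub["ind"] = indicator.astype(float)
    m1 = _lmm(sub, ["ind"])
    m0 = _lmm(sub, [])
    t = models.lrt(m1, m0)
    rows.append(_row(name, term, m1.params["ind"], "chi2", t.chi2, t.df,
                     t.pvalue))
    return m1


def behavioral_analysis(trials: pd.DataFrame) -> dict:
    """Run the full behavioural battery on a cohort trial table.

    Returns the analysis table, the inclusion report and a tidy results
    frame (one row per test).
    """
    table = behavior.peri_error_table(trials)
    table, incl = behavior.subject_inclusion_filter(table)
    if table.empty:
        raise ValueError("no subjects survive the >=5 isolated-error rule")
    retained = set(table["subject"])
    rows: list[dict] = []

    # error-trial standardized RT
    err = table[table["label"] == behavior.ERROR_ISOLATED].copy()
    err["adhd"] = (err["group"] == "ADHD").astype(float)
    m1 = _lmm(err, [])
    m0 = _lmm(err, [], add_intercept=False)
    t = models.lrt(m1, m0)
    rows.append(_row("error", "intercept", m1.params["Intercept"], "chi2",
                     t.chi2, t.df, t.pvalue))
    mg = _lmm(err, ["adhd"])
    t = models.lrt(mg, m1)
    rows.append(_row("error", "group", mg.params["adhd"], "chi2", t.chi2,
                     t.df, t.pvalue))

    # pre- and post-error periods (positions -3..-1 and 1..3)
    pre = table[table["position"].isin([-3, -2, -1])]
    post = table[table["position"].isin([1, 2, 3])]
    m_pre = _period_models(pre, "pre_error", -2.0, rows)
    m_post = _period_models(post, "post_error", 2.0, rows)

    # post-hoc, group-wise contrasts
    adhd_p1 = table[(table["group"] == "ADHD")
                    & (table["label"] == behavior.ER_P1)]
    m = _lmm(adhd_p1, [])
    m0 = _lmm(adhd_p1, [], add_intercept=False)
    t = models.lrt(m, m0)
    rows.append(_row("adhd_er_p1", "intercept", m.params["Intercept"],
                     "chi2", t.chi2, t.df, t.pvalue))

    adhd_p12 = table[(table["group"] == "ADHD")
                     & table["label"].isin([behavior.ER_P1, behavior.ER_P2])]
    _contrast_model(adhd_p12, adhd_p12["label"] == behavior.ER_P2,
                    "adhd_er_p1_vs_p2", "er_p2", rows)
    td_pp = table[(table["group"] == "TD")
                  & table["label"].isin([behavior.ER_M1, behavior.ER_P1])]
    _contrast_model(td_pp, td_pp["label"] == behavior.ER_P1,
                    "td_er_m1_vs_p1", "er_p1", rows)

    # trial-wise accuracy (logistic mixed model), retained subjects
    acc = trials[trials["subject"].isin(retained)
                 & trials["rt_ms"].notna()].copy()
    acc["adhd"] = (acc["group"] == "ADHD").astype(float)
    lg1 = models.RandomInterceptLogit.from_dataframe(
        acc, "correct", fixed=["adhd"], groups="subject").fit()
    lg0 = models.RandomInterceptLogit.from_dataframe(
        acc, "correct", fixed=[], groups="subject").fit()
    t = models.lrt(lg1, lg0)
    rows.append(_row("accuracy", "group", lg1.params["adhd"], "chi2",
                     t.chi2, t.df, t.pvalue))

    # error-free RT between groups (subject means, pooled t)
    ef = table[table["label"] == behavior.ERROR_FREE]
    ef_subj = ef.groupby(["subject", "group"], sort=False)["rt_ms"] \
        .mean().reset_index()
    td_rt = ef_subj.loc[ef_subj["group"] == "TD", "rt_ms"]
    ad_rt = ef_subj.loc[ef_subj["group"] == "ADHD", "rt_ms"]
    tt, df_t, p = models.two_sample_t(td_rt, ad_rt)
    rows.append(_row("ef_rt_group", "TD-ADHD", td_rt.mean() - ad_rt.mean(),
                     "t", tt, df_t, p))

    # compatibility (priming) effect per stratum
    compat = {s: behavior.compatibility_effect(table, s)
              for s in (behavior.ER_M1, behavior.ER_P1, behavior.ERROR_FREE)}
    rows.append(_row("compatibility", "er_p1_minus_er_m1",
                     compat[behavior.ER_P1] - compat[behavior.ER_M1],
                     "ms", np.nan, np.nan, np.nan))

    # 2x2 mixed-ANOVA cross-check on subject means (ER-1 vs ER+1)
    anova = {}
    for dv in ("rt_ms", "z_rt"):
        sm = table[table["label"].isin([behavior.ER_M1, behavior.ER_P1])] \
            .groupby(["subject", "group", "label"], sort=False)[dv] \
            .mean().reset_index().rename(columns={dv: "value",
                                                  "label": "position"})
        anova[dv] = models.mixed_anova_2x2(sm)

    results = pd.DataFrame(rows)
    return {
        "table": table, "inclusion": incl, "results": results,
        "compatibility": compat, "anova": anova,
        "models": {"pre": m_pre, "post": m_post},
        "ef_rt_means": {"TD": float(td_rt.mean()), "ADHD": float(ad_rt.mean())},
    }


# --------------------------------------------------------------------------
# EEG analysis
# --------------------------------------------------------------------------

def subject_theta_table(bundle: cohort.RecordingBundle, n_remove: int = 1,
                        channels=("Fz", "Cz")) -> pd.DataFrame:
    """Preprocess one recording and reduce it to per-trial FM-theta.

    Returns one row per kept epoch with the baseline-corrected,
    time-averaged theta value and the trial's peri-error label.  Only
    the channels entering the FM-theta average are transformed (the
    full-grid TFR of every scalp channel is available through
    :func:`peritheta.tfr.stft_power` when a topography is wanted).
    """
    ev = bundle.events.sort_values(["block", "trial"], kind="stable")
    labels = behavior.classify_trials(ev)
    lab_df = ev[["subject", "group", "subtype", "block", "trial"]].copy()
    lab_df["label"] = labels.to_numpy()

    epochs, plog = preproc.preprocess_recording(
        bundle.data, bundle.ch_names, bundle.sfreq, bundle.events,
        n_remove=n_remove)
    kept = epochs.kept()
    ch_idx = [list(kept.ch_names).index(c) for c in channels]
    x = np.ascontiguousarray(kept.data[:, ch_idx], dtype=np.float32)
    P = tfr.stft_power(x, tmin=kept.tmin, sfreq=kept.sfreq)
    db, valid = tfr.baseline_correct(
        tfr.to_db(P), x, kept.meta["prime_offset_s"].to_numpy(),
        tmin=kept.tmin, sfreq=kept.sfreq)
    tc = tfr.fmtheta_timecourse(db, channels, channels=channels)
    meta = kept.meta.merge(lab_df, on=["subject", "group", "subtype",
                                       "block", "trial"], how="left")
    summ = tfr.theta_summaries(tc, meta, valid=valid, mode="vs_baseline")
    summ.attrs["preproc_log"] = plog
    return summ


def eeg_analysis(theta: pd.DataFrame) -> dict:
    """Group statistics on per-trial FM-theta summaries.

    ``theta`` concatenates :func:`subject_theta_table` outputs over
    subjects.  Statistics run on participant-wise means, matching the
    low trial counts the peri-error design produces.
    """
    rows = []
    subj = theta.groupby(["subject", "group", "label"], sort=False)[
        "theta_db"].mean().reset_index()

    def _group_vals(label):
        sel = subj[subj["label"] == label]
        return (sel.loc[sel["group"] == "TD", "theta_db"],
                sel.loc[sel["group"] == "ADHD", "theta_db"])

    for label, name in ((behavior.ERROR_ISOLATED, "error"),
                        (behavior.ERROR_FREE, "error_free")):
        td, ad = _group_vals(label)
        allv = pd.concat([td, ad])
        t1 = sps.ttest_1samp(allv, 0.0)
        rows.append(_row(f"theta_{name}", "vs_zero", allv.mean(), "t",
                         float(t1.statistic), len(allv) - 1,
                         float(t1.pvalue)))
        tt, df_t, p = models.two_sample_t(ad, td)
        rows.append(_row(f"theta_{name}", "ADHD-TD", ad.mean() - td.mean(),
                         "t", tt, df_t, p))

    # error relative to error-free, per subject
    wide = subj.pivot_table(index=["subject", "group"], columns="label",
                            values="theta_db").reset_index()
    if behavior.ERROR_ISOLATED in wide and behavior.ERROR_FREE in wide:
        wide["contrast"] = (wide[behavior.ERROR_ISOLATED]
                            - wide[behavior.ERROR_FREE])
        td = wide.loc[wide["group"] == "TD", "contrast"].dropna()
        ad = wide.loc[wide["group"] == "ADHD", "contrast"].dropna()
        tt, df_t, p = models.two_sample_t(ad, td)
        rows.append(_row("theta_error_vs_errorfree", "ADHD-TD",
                         ad.mean() - td.mean(), "t", tt, df_t, p))

    # peri-error region mixed models on participant-wise averages
    peri = subj[subj["label"].isin(behavior.PERI_LABELS)].copy()
    peri["position"] = peri["label"].map(behavior.LABEL_POSITION)
    ef_mean = subj[subj["label"] == behavior.ERROR_FREE] \
        .set_index("subject")["theta_db"]
    peri = peri[peri["subject"].isin(ef_mean.index)]
    peri["z_rt"] = peri["theta_db"] - peri["subject"].map(ef_mean)
    for name, positions, center in (("theta_pre", [-3, -2, -1], -2.0),
                                    ("theta_post", [1, 2, 3], 2.0)):
        sub = peri[peri["position"].isin(positions)]
        if sub["subject"].nunique() >= 2:
            _period_models(sub, name, center, rows)

    means = subj.groupby(["group", "label"], sort=False)["theta_db"] \
        .mean().unstack()
    return {"results": pd.DataFrame(rows), "subject_means": subj,
            "group_means": means}


def preprocess_dataset(data_dir, out_dir, n_remove: int = 1) -> list[Path]:
    """Preprocess a written dataset (EDF + events TSVs) from disk.

    For every ``sub-*.edf`` in ``data_dir``, runs the full chain and
    writes the cleaned epochs as an HDF5 container plus a per-trial
    FM-theta TSV; returns the written paths.
    """
    from . import edf

    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for edf_path in sorted(data_dir.glob("sub-*.edf")):
        stem = edf_path.stem
        ev = pd.read_csv(data_dir / f"{stem}_events.tsv", sep="\t")
        trials = cohort.events_to_behavior(ev)
        data, sfreq, ch_names = edf.read_edf(edf_path)
        epochs, plog = preproc.preprocess_recording(
            data, ch_names, sfreq, trials, n_remove=n_remove)
        h5 = out_dir / f"{stem}_epochs.h5"
        epochs.to_hdf5(h5)
        written.append(h5)
        log.info("  %s: %d epochs, %d rejected, %d blinks", stem,
                 plog["n_epochs"], plog["n_rejected"], plog["n_blinks"])
    if not written:
        raise FileNotFoundError(f"no sub-*.edf recordings in {data_dir}")
    return written


def report_from_outdir(outdir) -> dict:
    """Regenerate results tables and figures from a run's stored
    behaviour (and, when present, theta) TSVs."""
    outdir = Path(outdir)
    trials = pd.read_csv(outdir / "behavior.tsv", sep="\t")
    beh = behavioral_analysis(trials)
    beh["results"].to_csv(outdir / "behavior_results.tsv", sep="\t",
                          index=False)
    eeg = None
    theta_path = outdir / "theta_trials.tsv"
    if theta_path.exists():
        theta = pd.read_csv(theta_path, sep="\t")
        eeg = eeg_analysis(theta)
        eeg["results"].to_csv(outdir / "eeg_results.tsv", sep="\t",
                              index=False)
    _figures(beh, eeg, outdir)
    return {"behavior": beh, "eeg": eeg}


# --------------------------------------------------------------------------
# power report
# --------------------------------------------------------------------------

def power_report(n1: int = 26, n2: int = 14, alpha: float = 0.05,
                 d_grid=(0.2, 0.42, 0.6, 0.8, 0.95, 1.0, 1.2)) -> pd.DataFrame:
    """Two-sample t-test power across effect sizes, plus the minimum
    detectable effect at 80% power."""
    rows = [{"d": d, "power": models.ttest_power(d, n1, n2, alpha).power}
            for d in d_grid]
    dmin = models.min_detectable_d(0.80, n1, n2, alpha)
    rows.append({"d": round(dmin, 2), "power": 0.80, "note": "min d @ 80%"})
    out = pd.DataFrame(rows)
    out.attrs.update({"n1": n1, "n2": n2, "alpha": alpha})
    return out


# --------------------------------------------------------------------------
# configuration and end-to-end run
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    n_td: int = 14
    n_adhd: int = 26
    trials_per_block: int = 96
    n_blocks: int = 3
    seed: int = 0
    outdir: str = "peritheta_out"
    skip_eeg: bool = False
    n_remove_components: int = 1
    blink_k: float = 5.0
    verbose: bool = False

    def cohort_params(self) -> cohort.CohortParams:
        return cohort.CohortParams(n_td=self.n_td, n_adhd=self.n_adhd,
                                   trials_per_block=self.trials_per_block,
                                   n_blocks=self.n_blocks, seed=self.seed)

    def to_yaml(self, path) -> None:
        import yaml
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> preprocess -> analyze -> report.

    Writes per-subject EDF + events TSVs, the behavioural and EEG
    results tables, a JSON summary and summary figures into
    ``config.outdir``; returns the in-memory result objects.
    """
    level = logging.DEBUG if config.verbose else logging.INFO
    logging.basicConfig(level=level, format="%(levelname)s %(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.cohort_params()
    config.to_yaml(outdir / "config.yaml")

    t0 = time.time()
    log.info("stage simulate: %d TD + %d ADHD subjects, %d trials each",
             params.n_td, params.n_adhd, params.n_trials)
    trials = cohort.sample_behavior(params)
    trials.to_csv(outdir / "behavior.tsv", sep="\t", index=False)

    theta = None
    if not config.skip_eeg:
        log.info("stage simulate-eeg + preprocess")
        pieces, plogs = [], []
        data_dir = outdir / "raw"
        bundles = cohort.render_cohort(params, trials)
        all_bundles = []
        for b in bundles:
            all_bundles.append(b)
            pieces.append(subject_theta_table(
                b, n_remove=config.n_remove_components))
            plogs.append({"subject": b.subject,
                          **{k: v for k, v in
                             pieces[-1].attrs["preproc_log"].items()
                             if not isinstance(v, list)}})
            log.debug("  subject %s: %d theta trials", b.subject,
                      len(pieces[-1]))
        cohort.write_dataset(all_bundles, data_dir, params)
        theta = pd.concat(pieces, ignore_index=True)
        theta.to_csv(outdir / "theta_trials.tsv", sep="\t", index=False)
        pd.DataFrame(plogs).to_csv(outdir / "preproc_report.tsv", sep="\t",
                                   index=False)

    log.info("stage analyze-behavior")
    beh = behavioral_analysis(trials)
    beh["results"].to_csv(outdir / "behavior_results.tsv", sep="\t",
                          index=False)
    beh["table"].to_csv(outdir / "analysis_table.tsv", sep="\t", index=False)

    eeg = None
    if theta is not None and not theta.empty:
        log.info("stage analyze-eeg")
        eeg = eeg_analysis(theta)
        eeg["results"].to_csv(outdir / "eeg_results.tsv", sep="\t",
                              index=False)

    power = power_report()
    power.to_csv(outdir / "power.tsv", sep="\t", index=False)

    summary = {
        "seed": params.seed,
        "n_subjects_retained": beh["inclusion"].summary["n_retained"],
        "isolated_errors": beh["inclusion"].summary,
        "ef_rt_means_ms": beh["ef_rt_means"],
        "runtime_s": round(time.time() - t0, 2),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    _figures(beh, eeg, outdir)
    log.info("done in %.1f s -> %s", summary["runtime_s"], outdir)
    return {"behavior": beh, "eeg": eeg, "power": power, "summary": summary}


def _figures(beh: dict, eeg: dict | None, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = beh["table"]
    fig, ax = plt.subplots(figsize=(6, 4))
    for grp, color in (("TD", "tab:blue"), ("ADHD", "tab:red")):
        sel = table[(table["group"] == grp) & table["position"].notna()]
        prof = sel.groupby("position")["z_rt"].agg(["mean", "sem"])
        ax.errorbar(prof.index, prof["mean"], yerr=prof["sem"], color=color,
                    marker="o", label=grp)
    ax.axhline(0.0, ls="--", c="gray", lw=0.8)
    ax.set_xlabel("trial position relative to error")
    ax.set_ylabel("standardized RT (SD units)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "peri_error_rt.png", dpi=120)
    plt.close(fig)

    if eeg is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        gm = eeg["group_means"]
        gm.T.plot(kind="bar", ax=ax)
        ax.set_ylabel("FM-theta (dB vs pre-prime baseline)")
        fig.tight_layout()
        fig.savefig(outdir / "fmtheta_by_condition.png", dpi=120)
        plt.close(fig)
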