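"""Trial classification and reaction-time standardization.

Trials are classified by their position relative to *isolated* commission
errors — errors preceded and followed by at least three correct trials
within the same block.  The three correct trials on either side are the
peri-error trials (ER-3 .. ER-1 before, ER+1 .. ER+3 after); correct
trials more than three positions away from every error are *error-free*;
everything else (non-isolated errors, their surroundings, misses) is
excluded from analysis.

Reaction times are standardized per subject against that subject's
error-free trials: ``z = (rt - mean_EF) / sd_EF``, so error-free trials
have mean 0 and SD 1 exactly and peri-error effects are expressed in
within-subject SD units.

Classification windows never cross block boundaries: blocks were
separated in time, so the first trials of a block have no usable error
context and edge context is treated as error-free.  A trial claimed as a
peri-error neighbour by two different isolated errors (possible when two
isolated errors sit exactly four trials apart) is excluded, since its RT
would mix pre- and post-error effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

# peri-error class labels
ERROR_ISOLATED = "error_isolated"
ER_M3, ER_M2, ER_M1 = "er_m3", "er_m2", "er_m1"
ER_P1, ER_P2, ER_P3 = "er_p1", "er_p2", "er_p3"
ERROR_FREE = "error_free"
EXCLUDED = "excluded"

PERI_LABELS = (ER_M3, ER_M2, ER_M1, ER_P1, ER_P2, ER_P3)
ALL_LABELS = (ERROR_ISOLATED,) + PERI_LABELS + (ERROR_FREE, EXCLUDED)

#: signed position of each peri-error label relative to the error
LABEL_POSITION = {ER_M3: -3, ER_M2: -2, ER_M1: -1, ERROR_ISOLATED: 0,
                  ER_P1: 1, ER_P2: 2, ER_P3: 3}
_OFFSET_LABEL = {v: k for k, v in LABEL_POSITION.items()}


def classify_block(correct: np.ndarray, commission: np.ndarray | None = None
                   ) -> list[str]:
    """Classify one block's ordered trial sequence.

    Parameters
    ----------
    correct : boolean array
        Per-trial correctness, in presentation order.
    commission : boolean array, optional
        True where an incorrect trial was a commission error (a wrong
        keypress) rather than a miss.  Defaults to all-commission.
        Misses break correct runs and disqualify neighbouring errors
        from isolation but are never themselves isolated errors.
    """
    correct = np.asarray(correct, dtype=bool)
    n = correct.size
    if commission is None:
        commission = np.ones(n, dtype=bool)
    else:
        commission = np.asarray(commission, dtype=bool)

    err_idx = np.flatnonzero(~correct)
    labels: list[str | None] = [None] * n

    # error-free: correct trials more than 3 positions from every error
    if err_idx.size:
        for i in np.flatnonzero(correct):
            if np.abs(err_idx - i).min() > 3:
                labels[i] = ERROR_FREE
    else:
        return [ERROR_FREE] * n

    isolated = [
        i for i in err_idx
        if commission[i] and i >= 3 and i <= n - 4
        and correct[i - 3:i].all() and correct[i + 1:i + 4].all()
    ]
    for i in isolated:
        labels[i] = ERROR_ISOLATED
        for off in (-3, -2, -1, 1, 2, 3):
            j = i + off
            lab = _OFFSET_LABEL[off]
            if labels[j] is None:
                labels[j] = lab
            else:  # claimed by another isolated error: contaminated
                labels[j] = EXCLUDED
    return [EXCLUDED if l is None else l for l in labels]


def classify_trials(trials: pd.DataFrame) -> pd.Series:
    """Peri-error class per trial for one subject's full session.

    ``trials`` must contain columns ``block``, ``trial`` (1-based index
    within block), ``correct`` and, if misses are present, ``rt_ms``
    (NaN marks an omission).  Rows must be ordered by (block, trial).
    """
    bt = trials[["block", "trial"]].to_numpy()
    if not (np.lexsort((bt[:, 1], bt[:, 0])) == np.arange(len(bt))).all():
        raise ValueError("trials must be ordered by (block, trial)")
    has_rt = trials["rt_ms"].notna().to_numpy() if "rt_ms" in trials \
        else np.ones(len(trials), dtype=bool)
    correct = trials["correct"].to_numpy(dtype=bool)
    commission = ~correct & has_rt
    out = np.empty(len(trials), dtype=object)
    for b in np.unique(bt[:, 0]):
        m = bt[:, 0] == b
        out[m] = classify_block(correct[m], commission[m])
    return pd.Series(out, index=trials.index, name="label")


def standardize_rt(trials: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Per-subject standardized RT using error-free trials as reference.

    Returns ``z = (rt - mean_EF) / sd_EF`` for every trial with an RT
    (including errors); sample SD with ddof=1.
    """
    ef = trials["rt_ms"][(labels == ERROR_FREE) & trials["rt_ms"].notna()]
    if ef.size < 2:
        raise ValueError("need >= 2 error-free trials with RT to standardize")
    mu, sd = ef.mean(), ef.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate subject: zero error-free RT variance")
    return (trials["rt_ms"] - mu) / sd


@dataclass
class InclusionReport:
    """Per-subject isolated-error counts and the resulting sample."""

    counts: pd.Series          # isolated errors per subject (all subjects)
    retained: list
    dropped: list
    min_isolated: int = 5

    @property
    def summary(self) -> dict:
        c = self.counts.loc[self.retained]
        return {
            "n_retained": len(self.retained),
            "n_dropped": len(self.dropped),
            "mean_isolated": float(c.mean()) if len(c) else float("nan"),
            "sd_isolated": float(c.std(ddof=1)) if len(c) > 1 else float("nan"),
            "range_isolated": (int(c.min()), int(c.max())) if len(c) else None,
        }


def subject_inclusion_filter(table: pd.DataFrame, min_isolated: int = 5
                             ) -> tuple[pd.DataFrame, InclusionReport]:
    """Drop subjects with fewer than ``min_isolated`` isolated errors."""
    counts = (table["label"] == ERROR_ISOLATED).groupby(
        table["subject"]).sum().astype(int)
    retained = counts.index[counts >= min_isolated].tolist()
    dropped = counts.index[counts < min_isolated].tolist()
    report = InclusionReport(counts=counts, retained=retained,
                             dropped=dropped, min_isolated=min_isolated)
    return table[table["subject"].isin(retained)].copy(), report


def compatibility_effect(table: pd.DataFrame, stratum: str) -> float:
    """Mean RT(compatible) - mean RT(incompatible), correct trials only,
    within one peri-error stratum (ER-1, ER+1 or error-free).

    Returns NaN with a warning if either condition is empty.
    """
    sel = table[(table["label"] == stratum) & (table["correct"] == 1)
                & table["rt_ms"].notna()]
    comp = sel.loc[sel["compatibility"] == "compatible", "rt_ms"]
    incomp = sel.loc[sel["compatibility"] == "incompatible", "rt_ms"]
    if comp.empty or incomp.empty:
        warnings.warn(f"compatibility effect undefined in stratum {stratum!r}:"
                      " a condition is empty", RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(comp.mean() - incomp.mean())


def peri_error_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Classify, standardize and assemble the cohort analysis table.

    ``trials`` holds every subject's trials (columns ``subject``,
    ``group``, ``subtype``, ``block``, ``trial``, ``correct``,
    ``compatibility``, ``rt_ms``), ordered by (block, trial) within
    subject.  Returns one row per retained (non-excluded) trial with
    ``label``, signed ``position`` (-3..3 for peri-error trials, NaN for
    error-free) and standardized ``z_rt``.
    """
    pieces = []
    for subj, sub in trials.groupby("subject", sort=False):
        sub = sub.sort_values(["block", "trial"], kind="stable")
        labels = classify_trials(sub)
        z = standardize_rt(sub, labels)
        out = sub.copy()
        out["label"] = labels
        out["z_rt"] = z
        pieces.append(out[out["label"] != EXCLUDED])
    table = pd.concat(pieces, ignore_index=True)
    table["position"] = table["label"].map(LABEL_POSITION).astype(float)
    return table
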