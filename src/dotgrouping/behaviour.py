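"""Behavioural and oculomotor summaries.

Accuracy and reaction time by number of groupings (with across-subject
paired comparisons), the strict >80%-valid eye-tracking session filter,
and the correlation between per-epoch gaze dispersion and a binary
grouping indicator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AccuracyResult",
    "ValidityResult",
    "GazeCorrelation",
    "accuracy_rt_by_groups",
    "session_validity",
    "gaze_grouping_correlation",
]


@dataclass
class AccuracyResult:
    """Per-grouping-count accuracy/RT plus paired across-subject tests."""

    summary: pd.DataFrame  # index n_groups; accuracy, mean_rt_ms, n_trials
    pairwise_accuracy_p: dict
    pairwise_rt_p: dict


def _paired_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided paired t-test p; identical series give p = 1 by convention."""
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if diff.size < 2 or np.allclose(diff, diff[0]):
        return 1.0 if np.allclose(diff, 0.0) else float("nan")
    return float(stats.ttest_rel(a, b).pvalue)


def accuracy_rt_by_groups(
    responses: pd.DataFrame, group_levels=(1, 2, 3)
) -> AccuracyResult:
    """Accuracy and mean correct-response RT per true grouping count.

    ``responses`` needs columns n_groups (true count), response (reported
    count, NaN if missing) and rt (ms); an optional ``subject`` column
    enables the across-subject paired two-sided t-tests between counts.
    Cells with no trials are flagged as missing (NaN), never as zero.
    """
    df = responses.copy()
    df["correct"] = df["response"] == df["n_groups"]
    rows = []
    for g in group_levels:
        cell = df[df["n_groups"] == g]
        answered = cell[cell["response"].notna()]
        correct = answered[answered["correct"]]
        rows.append(
            {
                "n_groups": g,
                "n_trials": len(answered),
                "accuracy": len(correct) / len(answered) if len(answered) else np.nan,
                "mean_rt_ms": correct["rt"].mean() if len(correct) else np.nan,
            }
        )
    summary = pd.DataFrame(rows).set_index("n_groups")

    pairwise_acc: dict = {}
    pairwise_rt: dict = {}
    if "subject" in df.columns and df["subject"].nunique() >= 2:
        per_subj = (
            df[df["response"].notna()]
            .groupby(["subject", "n_groups"])
            .agg(accuracy=("correct", "mean"))
            .reset_index()
        )
        per_subj_rt = (
            df[df["correct"] & df["response"].notna()]
            .groupby(["subject", "n_groups"])
            .agg(rt=("rt", "mean"))
            .reset_index()
        )
        for a, b in itertools.combinations(group_levels, 2):
            wide = per_subj.pivot(index="subject", columns="n_groups", values="accuracy")
            if a in wide.columns and b in wide.columns:
                paired = wide[[a, b]].dropna()
                pairwise_acc[(a, b)] = _paired_p(paired[a].to_numpy(), paired[b].to_numpy())
            wide_rt = per_subj_rt.pivot(index="subject", columns="n_groups", values="rt")
            if a in wide_rt.columns and b in wide_rt.columns:
                paired = wide_rt[[a, b]].dropna()
                pairwise_rt[(a, b)] = _paired_p(paired[a].to_numpy(), paired[b].to_numpy())
    return AccuracyResult(summary=summary, pairwise_accuracy_p=pairwise_acc, pairwise_rt_p=pairwise_rt)


@dataclass
class ValidityResult:
    fraction_valid: float
    keep: bool
    n_samples: int


def session_validity(valid_flags, threshold: float = 0.80) -> ValidityResult:
    """Eye-tracking session filter: keep iff fraction valid is STRICTLY
    above the threshold (a session at exactly 80% is dropped)."""
    flags = np.asarray(valid_flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("empty gaze record")
    frac = float(flags.mean())
    return ValidityResult(fraction_valid=frac, keep=frac > threshold, n_samples=flags.size)


@dataclass
class GazeCorrelation:
    """Pearson correlation of per-epoch gaze dispersion with grouping."""

    r: float
    n_epochs: int
    defined: bool
    dispersions: np.ndarray
    grouping: np.ndarray
    reason: str = ""


def _epoch_dispersion(x: np.ndarray, y: np.ndarray, window: int | None) -> float:
    """Combined 2-D positional scatter: sqrt of the mean of the two axis
    variances; optionally the mean of sliding-window dispersions."""

    def _disp(xs, ys):
        return float(np.sqrt((np.var(xs) + np.var(ys)) / 2.0))

    if window is None or x.size <= window:
        return _disp(x, y)
    vals = [
        _disp(x[i : i + window], y[i : i + window])
        for i in range(0, x.size - window + 1, window)
    ]
    return float(np.mean(vals))


def gaze_grouping_correlation(
    gaze: pd.DataFrame,
    events: pd.DataFrame,
    window_samples: int | None = None,
    min_epoch_samples: int = 2,
) -> GazeCorrelation:
    """Correlate per-stimulus-epoch gaze dispersion with grouping presence.

    For each event, valid samples within [onset, onset+duration) yield one
    dispersion value paired with the binary indicator n_groups > 0;
    the result is the Pearson correlation across epochs.  Undefined when
    fewer than 3 usable epochs remain or either series has zero variance
    — flagged, never silently zero.  Invalid samples are dropped without
    interpolation.
    """
    t = gaze["t"].to_numpy()
    if not np.all(np.diff(t) > 0):
        raise ValueError("gaze timestamps must be strictly increasing")
    valid = gaze["valid"].to_numpy(dtype=bool)
    x = gaze["x"].to_numpy()
    y = gaze["y"].to_numpy()

    dispersions = []
    labels = []
    for _, ev in events.iterrows():
        sel = (t >= ev["onset"]) & (t < ev["onset"] + ev["duration"]) & valid
        if sel.sum() < min_epoch_samples:
            continue
        dispersions.append(_epoch_dispersion(x[sel], y[sel], window_samples))
        labels.append(1.0 if ev["n_groups"] > 0 else 0.0)
    disp = np.asarray(dispersions)
    lab = np.asarray(labels)

    if disp.size < 3:
        return GazeCorrelation(np.nan, disp.size, False, disp, lab, "fewer than 3 epochs")
    # ptp, not std: the float mean of identical values is not exact
    if np.ptp(disp) == 0.0 or np.ptp(lab) == 0.0:
        return GazeCorrelation(np.nan, disp.size, False, disp, lab, "zero variance")
    r = float(np.corrcoef(disp, lab)[0, 1])
    return GazeCorrelation(r, disp.size, True, disp, lab)
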