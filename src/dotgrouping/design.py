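"""GLM design matrices for the grouping experiment.

Two variants mirror the study's two models:

* ``six_condition`` — one 5-s boxcar regressor per analysis category
  (moving colour with / without grouping, moving greyscale with / without
  grouping, static colour, static greyscale), each with its temporal
  derivative;
* ``four_condition_parametric`` — one boxcar per trial type (moving
  colour, moving greyscale, static colour, static greyscale) plus, for the
  two moving types, a linear parametric modulator carrying the number of
  groupings (0-3), mean-centred across that condition's events before
  convolution, with derivatives for conditions and modulators alike.

Nuisance columns (keypress regressor and six motion parameters) are
appended unconvolved; an intercept closes the matrix.  Slow drift is
handled by projecting out a discrete-cosine basis of periods >= 120 s
(equivalently: including the DCT set as confounds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hrf import HRFSpec, hrf_derivative_kernel, hrf_kernel

__all__ = [
    "DesignError",
    "DesignMatrix",
    "SIX_CONDITIONS",
    "FOUR_CONDITIONS",
    "build_design",
    "dct_basis",
    "highpass",
    "standard_contrasts",
]

SIX_CONDITIONS = (
    "moving_colour_grouped",
    "moving_colour_ungrouped",
    "moving_greyscale_grouped",
    "moving_greyscale_ungrouped",
    "static_colour",
    "static_greyscale",
)
FOUR_CONDITIONS = (
    "moving_colour",
    "moving_greyscale",
    "static_colour",
    "static_greyscale",
)
MODULATED_CONDITIONS = ("moving_colour", "moving_greyscale")


class DesignError(ValueError):
    """Raised for unusable designs (rank deficiency, size mismatch)."""


@dataclass
class DesignMatrix:
    """A named, role-annotated design matrix (time x regressors)."""

    matrix: np.ndarray
    names: list[str]
    roles: list[str]
    tr: float
    highpass_cutoff_s: float | None = None
    extra: dict = field(default_factory=dict)

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        """Expand a {column name: weight} mapping to a full-length vector."""
        c = np.zeros(self.n_regressors)
        for name, w in weights.items():
            c[self.names.index(name)] = w
        return c

    def check_rank(self) -> None:
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < self.n_regressors:
            # name the columns whose R diagonal collapses in a QR factorisation
            _, r = np.linalg.qr(self.matrix)
            diag = np.abs(np.diag(r))
            bad = [self.names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
            raise DesignError(f"design is rank deficient; collinear columns: {bad}")


def _category6(row: pd.Series) -> str:
    trial_type = row["trial_type"]
    if trial_type.startswith("static"):
        return trial_type
    return f"{trial_type}_{'grouped' if row['n_groups'] > 0 else 'ungrouped'}"


def _convolved_columns(
    onsets: np.ndarray,
    durations: np.ndarray,
    heights: np.ndarray,
    n_volumes: int,
    tr: float,
    spec: HRFSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Boxcar series at microtime resolution convolved with HRF and its
    derivative, sampled at volume onsets.  Returns (column, derivative)."""
    dt = tr / spec.oversample
    n_micro = n_volumes * spec.oversample
    series = np.zeros(n_micro)
    for onset, duration, height in zip(onsets, durations, heights):
        lo = int(np.round(onset / dt))
        hi = int(np.round((onset + duration) / dt))
        series[max(lo, 0) : min(hi, n_micro)] += height
    kern = hrf_kernel(spec, dt)
    dkern = hrf_derivative_kernel(spec, dt)
    conv = np.convolve(series, kern)[:n_micro]
    dconv = np.convolve(series, dkern)[:n_micro] * dt
    sample = np.arange(n_volumes) * spec.oversample
    return conv[sample], dconv[sample]


def build_design(
    events: pd.DataFrame,
    n_volumes: int,
    tr: float,
    variant: str = "four_condition_parametric",
    nuisance: pd.DataFrame | None = None,
    hrf_spec: HRFSpec | None = None,
    add_derivatives: bool = True,
    add_intercept: bool = True,
) -> DesignMatrix:
    """Assemble the design matrix for one session.

    ``events`` needs columns onset (s), duration (s), trial_type and
    n_groups.  Modulator values are the per-trial grouping counts centred
    across that condition's events, so the condition column keeps the mean
    response and the modulator carries the per-grouping increment.
    """
    if variant not in ("six_condition", "four_condition_parametric"):
        raise DesignError(f"unknown design variant {variant!r}")
    if hrf_spec is None:
        hrf_spec = HRFSpec()
    events = events.reset_index(drop=True)
    if (events["onset"] < 0).any() or (
        events["onset"] + events["duration"] > n_volumes * tr
    ).any():
        raise DesignError("events fall outside the scan")

    cols: list[np.ndarray] = []
    names: list[str] = []
    roles: list[str] = []

    def _add(column: np.ndarray, name: str, role: str) -> None:
        cols.append(column)
        names.append(name)
        roles.append(role)

    if variant == "six_condition":
        categories = {cat: events.apply(_category6, axis=1) == cat for cat in SIX_CONDITIONS}
        for cat, sel in categories.items():
            if not sel.any():
                continue
            sub = events[sel]
            col, dcol = _convolved_columns(
                sub["onset"].to_numpy(),
                sub["duration"].to_numpy(),
                np.ones(len(sub)),
                n_volumes,
                tr,
                hrf_spec,
            )
            _add(col, cat, "condition")
            if add_derivatives:
                _add(dcol, f"{cat}_derivative", "derivative")
    else:
        for cat in FOUR_CONDITIONS:
            sel = events["trial_type"] == cat
            if not sel.any():
                continue
            sub = events[sel]
            onsets = sub["onset"].to_numpy()
            durations = sub["duration"].to_numpy()
            col, dcol = _convolved_columns(
                onsets, durations, np.ones(len(sub)), n_volumes, tr, hrf_spec
            )
            _add(col, cat, "condition")
            if add_derivatives:
                _add(dcol, f"{cat}_derivative", "derivative")
        for cat in MODULATED_CONDITIONS:
            sel = events["trial_type"] == cat
            if not sel.any():
                continue
            sub = events[sel]
            values = sub["n_groups"].to_numpy(dtype=float)
            centred = values - values.mean()
            if np.allclose(centred, 0.0):
                continue  # no grouping variation: the modulator carries nothing
            col, dcol = _convolved_columns(
                sub["onset"].to_numpy(),
                sub["duration"].to_numpy(),
                centred,
                n_volumes,
                tr,
                hrf_spec,
            )
            _add(col, f"{cat}_x_n_groups", "modulator")
            if add_derivatives:
                _add(dcol, f"{cat}_x_n_groups_derivative", "modulator_derivative")

    if nuisance is not None:
        nuis = pd.DataFrame(nuisance)
        if len(nuis) != n_volumes:
            raise DesignError(
                f"nuisance has {len(nuis)} rows, expected {n_volumes} volumes"
            )
        for name in nuis.columns:
            _add(nuis[name].to_numpy(dtype=float), str(name), "nuisance")

    if add_intercept:
        _add(np.ones(n_volumes), "intercept", "intercept")

    dm = DesignMatrix(
        matrix=np.column_stack(cols), names=names, roles=roles, tr=tr
    )
    dm.check_rank()
    return dm


def dct_basis(n_timepoints: int, tr: float, cutoff_s: float = 120.0) -> np.ndarray:
    """Orthonormal DCT drift basis: all cosines with period >= ``cutoff_s``.

    The k-th function is sqrt(2/N)*cos(pi*(2t+1)*k/(2N)) with period
    2*N*TR/k; the highest retained order is floor(2*N*TR/cutoff).  The
    basis excludes the constant and is orthogonal to it.
    """
    k_max = int(np.floor(2.0 * n_timepoints * tr / cutoff_s))
    t = np.arange(n_timepoints)
    basis = np.column_stack(
        [
            np.sqrt(2.0 / n_timepoints)
            * np.cos(np.pi * (2 * t + 1) * k / (2.0 * n_timepoints))
            for k in range(1, k_max + 1)
        ]
    ) if k_max >= 1 else np.empty((n_timepoints, 0))
    return basis


def highpass(
    dm: DesignMatrix, data: np.ndarray, cutoff_s: float = 120.0
) -> tuple[DesignMatrix, np.ndarray]:
    """Project the slow DCT subspace out of both data and design.

    Idempotent (a residual-forming projection).  Scans shorter than the
    cutoff leave nothing to remove and pass through with a warning.  The
    intercept column is untouched because the basis is zero-mean.
    """
    n = dm.n_timepoints
    if data.shape[0] != n:
        raise DesignError("data and design have different numbers of timepoints")
    basis = dct_basis(n, dm.tr, cutoff_s)
    if basis.shape[1] == 0:
        warnings.warn("scan shorter than high-pass cutoff; filter is a no-op")
        return replace(dm, highpass_cutoff_s=cutoff_s), data
    # R y = y - C (C' y) with orthonormal C
    filt_data = data - basis @ (basis.T @ data)
    filt_matrix = dm.matrix - basis @ (basis.T @ dm.matrix)
    # the projection removes basis.shape[1] dimensions from the data; the
    # GLM dof must account for them (kept in extra for fit_glm)
    extra = dict(dm.extra)
    if dm.highpass_cutoff_s != cutoff_s:  # re-application removes nothing new
        extra["n_filtered_components"] = (
            extra.get("n_filtered_components", 0) + basis.shape[1]
        )
    out = replace(dm, matrix=filt_matrix, highpass_cutoff_s=cutoff_s, extra=extra)
    return out, filt_data


def standard_contrasts(dm: DesignMatrix) -> dict[str, np.ndarray]:
    """The experiment's named contrasts, as weight vectors over ``dm``.

    Activations (grouping > no grouping), their reversals (deactivations),
    the V4/V5 localizers and — for the parametric variant — the linear
    number-of-groupings slopes for colour and motion.
    """
    have = set(dm.names)
    out: dict[str, np.ndarray] = {}

    def _maybe(name: str, weights: dict[str, float]) -> None:
        if set(weights) <= have:
            out[name] = dm.contrast_vector(weights)

    _maybe(
        "colour_grouping_gt_none",
        {"moving_colour_grouped": 1.0, "moving_colour_ungrouped": -1.0},
    )
    _maybe(
        "motion_grouping_gt_none",
        {"moving_greyscale_grouped": 1.0, "moving_greyscale_ungrouped": -1.0},
    )
    _maybe(
        "none_gt_colour_grouping",
        {"moving_colour_grouped": -1.0, "moving_colour_ungrouped": 1.0},
    )
    _maybe(
        "none_gt_motion_grouping",
        {"moving_greyscale_grouped": -1.0, "moving_greyscale_ungrouped": 1.0},
    )
    _maybe(
        "colour_gt_greyscale_static",
        {"static_colour": 1.0, "static_greyscale": -1.0},
    )
    _maybe(
        "moving_greyscale_gt_static",
        {
            "moving_greyscale_grouped": 0.5,
            "moving_greyscale_ungrouped": 0.5,
            "static_greyscale": -1.0,
        },
    )
    _maybe(
        "moving_greyscale_gt_static",
        {"moving_greyscale": 1.0, "static_greyscale": -1.0},
    )
    _maybe("colour_slope", {"moving_colour_x_n_groups": 1.0})
    _maybe("motion_slope", {"moving_greyscale_x_n_groups": 1.0})
    return out
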