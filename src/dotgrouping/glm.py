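"""Ordinary least-squares GLM fitting and t-contrasts, two-level.

First level: per-voxel OLS of the (high-pass-filtered) BOLD series on the
design, t = c'b / sqrt(s2 * c'(X'X)^+ c).  Sessions of one subject are
concatenated with session-specific intercepts and per-session drift
removal.  Second level: the summary-statistics random-effects approach —
a voxelwise one-sample t-test on per-subject contrast images with
n_subjects - 1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import DesignError, DesignMatrix, build_design, highpass, standard_contrasts

__all__ = [
    "GLMResult",
    "StatMap",
    "fit_glm",
    "contrast_t",
    "second_level",
    "fit_subject",
]


@dataclass
class GLMResult:
    """Per-voxel OLS estimates for one (possibly concatenated) session."""

    betas: np.ndarray  # (p, v)
    residual_variance: np.ndarray  # (v,)
    dof: int
    design: DesignMatrix
    xtx_pinv: np.ndarray  # (p, p)


@dataclass
class StatMap:
    """Voxelwise effect, standard error and t statistic on a fixed grid.

    ``defined`` flags voxels where the statistic exists (positive SE);
    undefined voxels keep their effect values but are excluded from
    thresholding rather than silently zeroed.
    """

    effect: np.ndarray
    se: np.ndarray
    t: np.ndarray
    dof: int
    shape: tuple[int, ...] | None = None
    defined: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.defined is None:
            self.defined = np.isfinite(self.t) & (self.se > 0)

    def p_values(self, tail: str = "pos") -> np.ndarray:
        """One-sided (or two-sided) p-values; undefined voxels get p = 1."""
        p = np.ones_like(self.t, dtype=float)
        d = self.defined
        if tail == "pos":
            p[d] = stats.t.sf(self.t[d], self.dof)
        elif tail == "neg":
            p[d] = stats.t.cdf(self.t[d], self.dof)
        elif tail == "two":
            p[d] = 2.0 * stats.t.sf(np.abs(self.t[d]), self.dof)
        else:
            raise ValueError(f"unknown tail {tail!r}")
        return p

    def volume(self, which: str = "t") -> np.ndarray:
        if self.shape is None:
            raise ValueError("StatMap has no volume geometry")
        return getattr(self, which).reshape(self.shape)


def fit_glm(dm: DesignMatrix, data: np.ndarray) -> GLMResult:
    """OLS fit of every voxel's time series on the design matrix."""
    x = dm.matrix
    n, p = x.shape
    if data.shape[0] != n:
        raise DesignError("data and design have different numbers of timepoints")
    rank = np.linalg.matrix_rank(x)
    if n <= rank:
        raise DesignError(f"{n} timepoints cannot estimate rank-{rank} design")
    dm.check_rank()
    pinv = np.linalg.pinv(x)
    betas = pinv @ data
    resid = data - x @ betas
    # dimensions projected out by the high-pass filter also cost dof
    dof = n - rank - dm.extra.get("n_filtered_components", 0)
    if dof <= 0:
        raise DesignError("no residual degrees of freedom left")
    resvar = np.einsum("tv,tv->v", resid, resid) / dof
    return GLMResult(
        betas=betas,
        residual_variance=resvar,
        dof=dof,
        design=dm,
        xtx_pinv=pinv @ pinv.T,
    )


def contrast_t(result: GLMResult, weights: np.ndarray, shape=None) -> StatMap:
    """t-map for a contrast vector over the fitted design.

    Voxels with zero residual variance (and nonzero contrast) are flagged
    undefined instead of dividing by zero.
    """
    c = np.asarray(weights, dtype=float)
    if c.shape != (result.design.n_regressors,):
        raise DesignError(
            f"contrast length {c.size} != regressor count {result.design.n_regressors}"
        )
    effect = c @ result.betas
    var_factor = float(c @ result.xtx_pinv @ c)
    se = np.sqrt(np.clip(result.residual_variance * var_factor, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    if not c.any():
        t = np.zeros_like(effect)
    return StatMap(effect=effect, se=se, t=t, dof=result.dof, shape=shape)


def second_level(con_images: np.ndarray, shape=None) -> StatMap:
    """One-sample t across subjects at every voxel (random effects).

    ``con_images`` is (n_subjects, n_voxels).  Voxels with zero
    between-subject variance are flagged undefined; their effect is still
    the common value.
    """
    arr = np.asarray(con_images, dtype=float)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("second level needs at least 2 subjects")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / se, np.nan)
    defined = se > 0
    return StatMap(effect=mean, se=se, t=t, dof=n - 1, shape=shape, defined=defined)


def fit_subject(
    sessions,
    variant: str = "four_condition_parametric",
    highpass_cutoff_s: float = 120.0,
    hrf_spec=None,
):
    """Concatenated-sessions first-level fit for one subject.

    Each session's design and data are high-pass filtered separately, the
    rows stacked, shared regressors pooled by column name, and one
    intercept kept per session.  Returns (GLMResult, contrast dict) where
    contrasts are the named experiment contrasts expanded over the pooled
    columns.

    ``sessions`` is an iterable of objects with ``data`` (time x voxels),
    ``events`` and ``nuisance`` attributes.
    """
    sessions = list(sessions)
    if not sessions:
        raise ValueError("no sessions given")
    pieces = []
    for sess in sessions:
        dm = build_design(
            sess.events,
            n_volumes=sess.data.shape[0],
            tr=sess.tr,
            variant=variant,
            nuisance=sess.nuisance,
            hrf_spec=hrf_spec,
        )
        dm_f, data_f = highpass(dm, sess.data, highpass_cutoff_s)
        pieces.append((dm_f, data_f))

    # pooled column order: union of shared names, then per-session nuisance
    # and intercept columns
    shared_names: list[str] = []
    shared_roles: dict[str, str] = {}
    for dm_f, _ in pieces:
        for name, role in zip(dm_f.names, dm_f.roles):
            if role in ("nuisance", "intercept"):
                continue
            if name not in shared_roles:
                shared_names.append(name)
                shared_roles[name] = role

    blocks = []
    sess_cols: list[tuple[str, str, int, np.ndarray]] = []  # per-session columns
    for s_idx, (dm_f, _) in enumerate(pieces):
        for name, role in zip(dm_f.names, dm_f.roles):
            if role in ("nuisance", "intercept"):
                sess_cols.append((f"session{s_idx}_{name}", role, s_idx, dm_f.column(name)))

    n_total = sum(d.shape[0] for _, d in pieces)
    names = list(shared_names) + [c[0] for c in sess_cols]
    roles = [shared_roles[n] for n in shared_names] + [c[1] for c in sess_cols]
    matrix = np.zeros((n_total, len(names)))
    row = 0
    for s_idx, (dm_f, _) in enumerate(pieces):
        n_rows = dm_f.n_timepoints
        for j, name in enumerate(shared_names):
            if name in dm_f.names:
                matrix[row : row + n_rows, j] = dm_f.column(name)
        row += n_rows
    row_offsets = np.cumsum([0] + [d.shape[0] for _, d in pieces])
    for k, (name, role, s_idx, col) in enumerate(sess_cols):
        j = len(shared_names) + k
        matrix[row_offsets[s_idx] : row_offsets[s_idx + 1], j] = col

    pooled = DesignMatrix(
        matrix=matrix,
        names=names,
        roles=roles,
        tr=pieces[0][0].tr,
        highpass_cutoff_s=highpass_cutoff_s,
        extra={
            "n_filtered_components": sum(
                dm_f.extra.get("n_filtered_components", 0) for dm_f, _ in pieces
            )
        },
    )
    data = np.vstack([d for _, d in pieces])
    result = fit_glm(pooled, data)
    return result, standard_contrasts(pooled)
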