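"""Cluster-extent inference by sign-flip permutation, and conjunctions.

Group maps are thresholded voxelwise (default p < 0.001 uncorrected,
one-sided), suprathreshold voxels are grouped into clusters by
18-connectivity, and each cluster's familywise-corrected p-value is the
permutation probability that the maximum cluster size under random sign
flips of the subject maps reaches its size.  Sign flipping is exact under
symmetric errors and needs no smoothness estimate.  A Bonferroni factor
accounts for testing a declared family of contrasts.

Conjunctions follow the masking approach: the primary contrast's
suprathreshold voxels are restricted to voxels also suprathreshold in the
masking contrast at a liberal uncorrected threshold (default p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .glm import StatMap, second_level

__all__ = [
    "ClusterResult",
    "ConjunctionResult",
    "connectivity_structure",
    "cluster_inference",
    "max_cluster_size",
    "conjunction_by_masking",
]

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


def connectivity_structure(connectivity: int = 18) -> np.ndarray:
    """3-D binary structuring element for 6/18/26-neighbour clustering."""
    try:
        return ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    except KeyError:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")


@dataclass
class ClusterResult:
    """Labelled clusters of a thresholded group map with corrected p-values."""

    label_volume: np.ndarray
    table: pd.DataFrame  # label, size, peak_x/y/z, peak_t, p_corrected, significant
    threshold_t: float
    null_max_sizes: np.ndarray

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def any_significant(self) -> bool:
        return self.n_significant > 0


def _sign_flip_t(data: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """One-sample t-maps under sign flips, vectorised over permutations.

    Flipping signs leaves sum(x^2) unchanged, so only the mean needs the
    (n_perm, n_subjects) @ (n_subjects, n_voxels) product.
    """
    n = data.shape[0]
    sumsq = np.einsum("sv,sv->v", data, data)
    means = (signs @ data) / n
    var = np.clip((sumsq[None, :] - n * means**2) / (n - 1), 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, means / np.sqrt(var / n), 0.0)
    return t


def max_cluster_size(
    volume_above: np.ndarray, structure: np.ndarray
) -> int:
    """Largest connected suprathreshold cluster (0 if none)."""
    labels, n_lab = ndimage.label(volume_above, structure=structure)
    if n_lab == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def cluster_inference(
    subject_maps: np.ndarray,
    shape: tuple[int, int, int],
    voxel_p: float = 0.001,
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    connectivity: int = 18,
    n_contrast_corrections: int = 1,
    seed: int | np.random.Generator | None = 0,
) -> ClusterResult:
    """Sign-flip cluster-extent inference on per-subject contrast maps.

    ``subject_maps`` is (n_subjects, n_voxels) with voxels in C order over
    ``shape``.  The observed and permuted maps are thresholded at the
    one-sided t quantile of ``voxel_p``; corrected p-values use the
    add-one permutation estimator and are then Bonferroni-multiplied by
    ``n_contrast_corrections``.
    """
    if n_perm < 100:
        raise ValueError("n_perm below 100 gives an unstable null; refuse")
    data = np.asarray(subject_maps, dtype=float)
    n_sub = data.shape[0]
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    structure = connectivity_structure(connectivity)
    t_crit = stats.t.isf(voxel_p, n_sub - 1)

    group = second_level(data, shape=shape)
    t_obs = np.where(group.defined, group.t, -np.inf).reshape(shape)
    above = t_obs >= t_crit
    labels, n_lab = ndimage.label(above, structure=structure)

    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    t_perm = _sign_flip_t(data, signs)
    null_sizes = np.fromiter(
        (
            max_cluster_size(t_perm[i].reshape(shape) >= t_crit, structure)
            for i in range(n_perm)
        ),
        dtype=np.int64,
        count=n_perm,
    )

    rows = []
    for lab in range(1, n_lab + 1):
        mask = labels == lab
        size = int(mask.sum())
        peak_flat = np.argmax(np.where(mask, t_obs, -np.inf))
        peak = np.unravel_index(peak_flat, shape)
        p_corr = (1 + int((null_sizes >= size).sum())) / (n_perm + 1)
        p_corr = min(1.0, p_corr * n_contrast_corrections)
        rows.append(
            {
                "label": lab,
                "size": size,
                "peak_x": int(peak[0]),
                "peak_y": int(peak[1]),
                "peak_z": int(peak[2]),
                "peak_t": float(t_obs[peak]),
                "p_corrected": p_corr,
                "significant": p_corr <= cluster_alpha,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "label",
            "size",
            "peak_x",
            "peak_y",
            "peak_z",
            "peak_t",
            "p_corrected",
            "significant",
        ],
    )
    return ClusterResult(
        label_volume=labels,
        table=table,
        threshold_t=float(t_crit),
        null_max_sizes=null_sizes,
    )


@dataclass
class ConjunctionResult:
    """Primary-contrast voxels surviving inside the mask contrast."""

    masked_t: np.ndarray
    overlap_mask: np.ndarray
    overlap_indices: np.ndarray  # (k, ndim) voxel coordinates

    @property
    def n_overlap(self) -> int:
        return int(self.overlap_mask.sum())


def conjunction_by_masking(
    contrast_a: StatMap,
    contrast_b: StatMap,
    mask_p: float = 0.05,
    primary_p: float = 0.001,
    tail: str = "pos",
) -> ConjunctionResult:
    """Conjunction of two contrasts by masking.

    Keeps voxels of ``contrast_a`` with p < ``primary_p`` that also reach
    p < ``mask_p`` (uncorrected) in ``contrast_b``.  Both maps must share
    geometry.
    """
    if contrast_a.t.shape != contrast_b.t.shape or contrast_a.shape != contrast_b.shape:
        raise ValueError("conjunction requires maps with identical geometry")
    p_a = contrast_a.p_values(tail)
    p_b = contrast_b.p_values(tail)
    overlap = (p_a < primary_p) & (p_b < mask_p)
    masked_t = np.where(overlap, contrast_a.t, np.nan)
    shape = contrast_a.shape if contrast_a.shape is not None else contrast_a.t.shape
    coords = np.column_stack(np.unravel_index(np.flatnonzero(overlap), shape))
    return ConjunctionResult(
        masked_t=masked_t, overlap_mask=overlap, overlap_indices=coords
    )
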