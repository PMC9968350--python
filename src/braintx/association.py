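"""Transcription-neuroimaging spatial association.

Each tissue sample's imaging value is the mean of the meta-analytic z map
over in-mask voxels within a 3-mm-radius sphere centred at the sample's
MNI coordinate.  Gene-wise Pearson correlations across samples between
expression and these z values, with Benjamini-Hochberg FDR control,
identify genes whose cortical expression tracks the disease-related
functional alterations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .volume import VolumeMap

__all__ = [
    "extract_sphere_values",
    "genewise_correlation",
    "bh_fdr",
    "associate",
]


def extract_sphere_values(
    vmap: VolumeMap,
    coords_mm: np.ndarray,
    radius_mm: float = 3.0,
    empty_policy: str = "drop",
):
    """Mean map value over in-mask voxels within ``radius_mm`` of each point.

    The radius comparison is inclusive (a voxel centre exactly at the
    radius counts).  Points whose sphere contains no in-mask voxel are
    handled by ``empty_policy``: ``"drop"`` marks them invalid (NaN),
    ``"nearest"`` substitutes the nearest in-mask voxel's value.

    Returns ``(values, valid)`` arrays aligned with ``coords_mm``.
    """
    coords_mm = np.atleast_2d(np.asarray(coords_mm, dtype=float))
    if not np.all(np.isfinite(coords_mm)):
        raise ValueError("coordinates must be finite")
    if empty_policy not in ("drop", "nearest"):
        raise ValueError(f"unknown empty_policy {empty_policy!r}")

    vox_idx = np.argwhere(vmap.mask)
    vox_mm = vmap.voxel_to_mm(vox_idx)
    vox_val = vmap.data[vox_idx[:, 0], vox_idx[:, 1], vox_idx[:, 2]]
    tree = cKDTree(vox_mm)
    # small epsilon keeps centres exactly at the radius inside despite FP error
    hits = tree.query_ball_point(coords_mm, r=radius_mm * (1 + 1e-12))

    values = np.full(len(coords_mm), np.nan)
    valid = np.zeros(len(coords_mm), dtype=bool)
    for i, h in enumerate(hits):
        if h:
            values[i] = vox_val[h].mean()
            valid[i] = True
        elif empty_policy == "nearest":
            _, j = tree.query(coords_mm[i])
            values[i] = vox_val[j]
            valid[i] = True
    return values, valid


def pearson_with_p(matrix: np.ndarray, y: np.ndarray):
    """Vectorised Pearson r of each column of ``matrix`` with ``y``.

    Two-sided p from the t transform with n-2 degrees of freedom.
    Constant columns (or constant y) yield NaN.
    """
    x = np.asarray(matrix, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    bad = ~np.isfinite(r)
    r[bad] = np.nan
    p[bad] = np.nan
    return r, p


def bh_fdr(pvals, alpha: float = 0.05):
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(qvals, rejected)``; rejection uses q <= alpha (the standard
    step-up rule).  NaN p-values propagate as NaN q and are never rejected.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.zeros(0, dtype=bool)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        _, q_ok, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        q[ok] = q_ok
    rejected = np.zeros(p.shape, dtype=bool)
    rejected[ok] = q[ok] <= alpha
    return q, rejected


def genewise_correlation(
    matrix: pd.DataFrame,
    zvec: np.ndarray | pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Pearson correlation with the imaging values plus BH-FDR.

    ``matrix`` is samples x genes; ``zvec`` is row-aligned.  Constant
    genes carry undefined r and are excluded from multiple testing.
    """
    z = np.asarray(zvec, dtype=float)
    if len(z) != matrix.shape[0]:
        raise ValueError("expression matrix and z vector are misaligned")
    if matrix.shape[0] < 4:
        raise ValueError("need at least 4 samples for gene-wise correlation")
    r, p = pearson_with_p(matrix.to_numpy(), z)
    q, rejected = bh_fdr(p, alpha=alpha)
    return pd.DataFrame(
        {"gene_id": matrix.columns, "r": r, "p": p, "q": q, "significant": rejected}
    ).set_index("gene_id")


def associate(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    z_map: VolumeMap,
    radius_mm: float = 3.0,
    alpha: float = 0.05,
    empty_policy: str = "drop",
):
    """Sphere-extract imaging values at sample coordinates and correlate.

    Returns ``(table, zvec, kept_matrix)`` where ``zvec`` is the per-sample
    sphere mean (samples with empty spheres dropped under the default
    policy) and ``kept_matrix`` the matching expression rows.
    """
    coords = samples.loc[matrix.index, ["x", "y", "z"]].to_numpy()
    zvals, valid = extract_sphere_values(z_map, coords, radius_mm=radius_mm,
                                         empty_policy=empty_policy)
    if not valid.all():
        warnings.warn(f"dropping {int((~valid).sum())} samples with empty spheres",
                      stacklevel=2)
    kept = matrix.loc[valid]
    zvec = pd.Series(zvals[valid], index=kept.index, name="z_value")
    table = genewise_correlation(kept, zvec, alpha=alpha)
    return table, zvec, kept
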