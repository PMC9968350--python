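"""Microarray expression preprocessing.

The processing chain mirrors the standard multi-donor brain-atlas
workflow: (1) intensity-based probe filtering against background flags,
(2) representative-probe selection by correlation with an RNA-seq
reference, (3) restriction to left-hemisphere cortical samples inside the
analysis mask, (4) two-stage scaled robust sigmoid (SRS) normalisation —
within-sample across genes, then within-gene across samples, donor by
donor — and (5) differential-stability (DS) filtering, keeping genes
whose regional expression profiles are most consistent across donors.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import ProbeTable
from .volume import VolumeMap

__all__ = [
    "ExpressionBundle",
    "filter_probes_intensity",
    "select_probes_rnaseq",
    "filter_samples",
    "srs_normalize",
    "differential_stability",
    "filter_genes_ds",
    "preprocess",
]

logger = logging.getLogger(__name__)

#: IQR of a standard normal; divides the IQR to approximate sigma.
IQR_TO_SIGMA = 1.35


@dataclass
class ExpressionBundle:
    """Gene-level expression (samples x genes) with sample annotations."""

    expression: pd.DataFrame
    samples: pd.DataFrame
    ds: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.expression.index.isin(self.samples.index).all():
            raise ValueError("every expression row needs a sample annotation")

    def copy_with(self, expression=None, samples=None, ds=None) -> "ExpressionBundle":
        return ExpressionBundle(
            expression=self.expression if expression is None else expression,
            samples=self.samples if samples is None else samples,
            ds=self.ds if ds is None else ds,
        )


def filter_probes_intensity(pt: ProbeTable, min_frac: float = 0.5) -> ProbeTable:
    """Keep probes above background in at least ``min_frac`` of all samples.

    The fraction pools samples across all donors.
    """
    if pt.above_background is None:
        raise ValueError("above_background flags are required")
    frac = pt.above_background.mean(axis=1)
    keep = frac >= min_frac
    logger.info("intensity filter: %d/%d probes kept", int(keep.sum()), len(keep))
    return ProbeTable(
        probes=pt.probes.loc[keep],
        expression=pt.expression.loc[keep],
        above_background=pt.above_background.loc[keep],
        samples=pt.samples,
    )


def _rank_or_pearson(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    return float(stats.pearsonr(x, y).statistic)


def select_probes_rnaseq(
    pt: ProbeTable,
    rnaseq: pd.DataFrame,
    min_r: float = 0.2,
    method: str = "spearman",
) -> ExpressionBundle:
    """Pick one representative probe per gene by correlation with RNA-seq.

    Genes absent from the reference are dropped.  Per probe, the rank
    correlation with its gene's reference row over the matched samples is
    computed; probes with r < ``min_r`` are ruled out and the highest-r
    survivor represents the gene.  Genes with no surviving probe are
    dropped.
    """
    matched = pt.expression.columns.intersection(rnaseq.columns)
    if len(matched) < 3:
        raise ValueError("need at least 3 matched samples between platforms")

    best: dict[str, tuple[float, str]] = {}
    for pid, gene in pt.probes["gene_id"].items():
        if gene not in rnaseq.index:
            continue
        x = pt.expression.loc[pid, matched].to_numpy(dtype=float)
        y = rnaseq.loc[gene, matched].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"probe {pid}: constant values, dropped", stacklevel=2)
            continue
        r = _rank_or_pearson(x, y, method)
        if not np.isfinite(r) or r < min_r:
            continue
        if gene not in best or r > best[gene][0]:
            best[gene] = (r, pid)

    genes = sorted(best)
    probe_ids = [best[g][1] for g in genes]
    matrix = pt.expression.loc[probe_ids].T
    matrix.columns = genes
    logger.info("RNA-seq probe selection: %d genes represented", len(genes))
    return ExpressionBundle(expression=matrix, samples=pt.samples)


def filter_samples(bundle: ExpressionBundle, mask: VolumeMap) -> ExpressionBundle:
    """Keep left-hemisphere cortical samples whose coordinate falls in the mask."""
    ann = bundle.samples.loc[bundle.expression.index]
    keep = (ann["hemisphere"] == "left") & (ann["structure"] == "cortex")
    coords = ann[["x", "y", "z"]].to_numpy(dtype=float)
    keep &= mask.contains_mm(coords)
    if not keep.any():
        warnings.warn("sample filter removed every sample", stacklevel=2)
    logger.info("sample filter: %d/%d samples kept", int(keep.sum()), len(keep))
    return bundle.copy_with(expression=bundle.expression.loc[keep])


def _srs_vector(x: np.ndarray) -> np.ndarray:
    """Scaled robust sigmoid of one vector, rescaled to [0, 1]."""
    med = np.median(x)
    q1, q3 = np.percentile(x, [25, 75])  # linear-interpolation quartiles
    iqr = q3 - q1
    if iqr == 0:
        logger.debug("zero IQR in SRS vector; returning 0.5")
        return np.full_like(np.asarray(x, dtype=float), 0.5)
    arg = np.clip((x - med) / (iqr / IQR_TO_SIGMA), -700, 700)  # avoid exp overflow
    s = 1.0 / (1.0 + np.exp(-arg))
    lo, hi = s.min(), s.max()
    if hi == lo:
        return np.full_like(s, 0.5)
    return (s - lo) / (hi - lo)


def srs_normalize(
    matrix: pd.DataFrame,
    donors: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-stage scaled robust sigmoid normalisation.

    Each vector x maps through 1/(1 + exp(-(x - median)/(IQR/1.35))) and is
    then min-max rescaled to [0, 1].  Applied across genes within each
    sample, then across samples within each gene.  When ``donors`` is
    given, each donor's sample block is normalised separately, which
    removes additive/multiplicative donor effects.
    """
    if matrix.shape[1] < 3 or matrix.shape[0] < 3:
        raise ValueError("SRS needs at least 3 values per normalised vector")

    def _one_block(block: pd.DataFrame) -> pd.DataFrame:
        within_sample = np.apply_along_axis(_srs_vector, 1, block.to_numpy(dtype=float))
        within_gene = np.apply_along_axis(_srs_vector, 0, within_sample)
        return pd.DataFrame(within_gene, index=block.index, columns=block.columns)

    if donors is None:
        return _one_block(matrix)
    donors = donors.loc[matrix.index]
    parts = [_one_block(matrix.loc[donors == d]) for d in donors.unique()]
    return pd.concat(parts).loc[matrix.index]


def differential_stability(
    bundle: ExpressionBundle,
    method: str = "spearman",
    min_shared_regions: int = 3,
) -> pd.Series:
    """Mean cross-donor correlation of each gene's regional expression profile.

    Expression is averaged per region within each donor; DS is the mean,
    over donor pairs sharing at least ``min_shared_regions`` regions, of
    the correlation between the two donors' regional profiles.
    """
    ann = bundle.samples.loc[bundle.expression.index]
    donors = ann["donor"].unique()
    if len(donors) < 2:
        raise ValueError("differential stability needs at least 2 donors")

    regional = {
        d: bundle.expression.loc[ann["donor"] == d].groupby(
            ann.loc[ann["donor"] == d, "region"]).mean()
        for d in donors
    }
    genes = bundle.expression.columns
    sums = np.zeros(len(genes))
    n_pairs = 0
    for d1, d2 in combinations(donors, 2):
        shared = regional[d1].index.intersection(regional[d2].index)
        if len(shared) < min_shared_regions:
            continue
        a = regional[d1].loc[shared].to_numpy(dtype=float)
        b = regional[d2].loc[shared].to_numpy(dtype=float)
        if method == "spearman":
            a = np.apply_along_axis(stats.rankdata, 0, a)
            b = np.apply_along_axis(stats.rankdata, 0, b)
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        denom = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (ac * bc).sum(axis=0) / denom
        sums += np.nan_to_num(r)
        n_pairs += 1
    if n_pairs == 0:
        raise ValueError(
            f"no donor pair shares >= {min_shared_regions} regions; DS undefined")
    return pd.Series(sums / n_pairs, index=genes, name="DS")


def filter_genes_ds(bundle: ExpressionBundle, top_frac: float = 0.5) -> ExpressionBundle:
    """Keep the ceil(top_frac * G) genes with highest DS (ties by gene id)."""
    if bundle.ds is None:
        raise ValueError("DS scores must be computed before filtering")
    n_keep = math.ceil(top_frac * len(bundle.ds))
    order = bundle.ds.to_frame().assign(gene_id=bundle.ds.index).sort_values(
        ["DS", "gene_id"], ascending=[False, True])
    kept = order.index[:n_keep]
    kept = bundle.expression.columns[bundle.expression.columns.isin(kept)]
    logger.info("DS filter: %d/%d genes kept", len(kept), bundle.expression.shape[1])
    return bundle.copy_with(expression=bundle.expression[kept],
                            ds=bundle.ds.loc[kept])


def preprocess(
    pt: ProbeTable,
    rnaseq: pd.DataFrame,
    mask: VolumeMap,
    min_frac: float = 0.5,
    min_r: float = 0.2,
    top_frac_ds: float = 0.5,
    per_donor: bool = True,
    ds_method: str = "spearman",
) -> ExpressionBundle:
    """Run the full preprocessing chain in its fixed order.

    intensity filter -> RNA-seq probe selection -> sample filter ->
    SRS normalisation -> DS computation -> DS filter.
    """
    pt = filter_probes_intensity(pt, min_frac=min_frac)
    bundle = select_probes_rnaseq(pt, rnaseq, min_r=min_r)
    bundle = filter_samples(bundle, mask)
    donors = bundle.samples.loc[bundle.expression.index, "donor"] if per_donor else None
    normalized = srs_normalize(bundle.expression, donors=donors)
    bundle = bundle.copy_with(expression=normalized)
    bundle = bundle.copy_with(ds=differential_stability(bundle, method=ds_method))
    return filter_genes_ds(bundle, top_frac=top_frac_ds)
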