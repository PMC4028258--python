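"""Probe filtering and expression normalization.

The detection threshold is anchored on biology: Y-chromosome transcripts are
absent in females, so the median Y-probe signal across female samples
estimates pure background, and probes whose cohort-wide median falls below
it are treated as unexpressed.  Normalization is offset background
subtraction followed by quantile normalization across samples (the scan
consumes any normalized log2 matrix, so this is an interface contract, not a
claim of equivalence with any particular array-preprocessing algorithm).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .datatypes import ExpressionMatrix, ValidationError


def _is_female(sex: pd.Series) -> pd.Series:
    s = sex.astype(str).str.strip().str.upper()
    return s.isin(["F", "FEMALE", "2"])


def detection_threshold(E: ExpressionMatrix, sex: pd.Series) -> float:
    """Median expression of Y-chromosome probes in female samples.

    Parameters
    ----------
    E : ExpressionMatrix whose probe annotation carries ``chrom``.
    sex : per-sample labels aligned with ``E.sample_ids`` ("F"/"M",
        "female"/"male" or 1/2 codes).

    Raises
    ------
    ValidationError if there are no female samples or no Y probes.
    """
    sex = sex.reindex(E.sample_ids)
    females = E.sample_ids[_is_female(sex)]
    y_probes = E.probes.index[E.probes["chrom"].astype(str) == "Y"]
    if len(females) == 0 or len(y_probes) == 0:
        raise ValidationError(
            "detection threshold needs >=1 female sample and >=1 Y-chromosome probe "
            f"(found {len(females)} females, {len(y_probes)} Y probes)"
        )
    block = E.values.loc[females, y_probes].to_numpy(dtype=float)
    return float(np.median(block))


def filter_probes(E: ExpressionMatrix, threshold: float):
    """Apply the three probe-exclusion rules.

    A probe is excluded when it contains a common SNP, maps ambiguously, or
    its median expression across all samples is below ``threshold``.  Rules
    are evaluated independently (order-free); exclusion is their union.

    Returns
    -------
    (retained_ids, counts) where ``counts`` has per-rule exclusion counts
    (a probe failing several rules is counted under each) plus the total.
    """
    anno = E.probes
    medians = E.values.median(axis=0)
    by_snp = anno["contains_snp"].astype(bool)
    by_ambiguous = anno["ambiguous_mapping"].astype(bool)
    by_background = medians < threshold
    excluded = by_snp | by_ambiguous | by_background
    counts = {
        "contains_snp": int(by_snp.sum()),
        "ambiguous_mapping": int(by_ambiguous.sum()),
        "below_threshold": int(by_background.sum()),
        "excluded_total": int(excluded.sum()),
        "retained": int((~excluded).sum()),
    }
    return list(anno.index[~excluded]), counts


def _quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize rows (samples) to the mean quantile vector.

    Ties within a sample receive the mean of the reference quantiles they
    span, so tied inputs stay tied and the per-sample rank order is kept.
    """
    n, m = values.shape
    reference = np.sort(values, axis=1).mean(axis=0)
    out = np.empty_like(values)
    for i in range(n):
        order = np.argsort(values[i], kind="stable")
        assigned = np.empty(m)
        assigned[order] = reference
        # average the assigned reference values over ties
        row = pd.Series(assigned).groupby(pd.Series(values[i])).transform("mean")
        out[i] = row.to_numpy()
    return out


def normalize(
    E: ExpressionMatrix,
    background_offset: float = 0.0,
    floor: float = 1.0,
    input_scale: str = "auto",
) -> ExpressionMatrix:
    """Background-correct and quantile-normalize.

    Steps: subtract ``background_offset`` (e.g. a negative-control summary)
    with a floor at ``floor``; log2-transform if the input is linear-scale
    (``input_scale``: "auto" decides by magnitude, max > 30 means linear);
    quantile-normalize across samples so every sample shares the mean
    quantile distribution.

    With a single sample the matrix is returned unchanged with a warning.
    """
    vals = E.values.to_numpy(dtype=float).copy()
    if not np.isfinite(vals).all():
        raise ValidationError("expression contains non-finite values")
    if background_offset:
        vals = np.maximum(vals - background_offset, floor)
    linear = {"auto": bool(np.nanmax(vals) > 30), "linear": True, "log2": False}[input_scale]
    if linear:
        vals = np.log2(np.maximum(vals, floor))
    if vals.shape[0] < 2:
        warnings.warn("quantile normalization needs >=2 samples; returning input unchanged")
        out = vals
    else:
        out = _quantile_normalize(vals)
    values = pd.DataFrame(out, index=E.sample_ids.copy(), columns=E.probe_ids.copy())
    return ExpressionMatrix(values=values, probes=E.probes)


def expression_outlier_samples(
    E: ExpressionMatrix,
    cut_scale: float = 1.3,
    min_cluster_frac: float = 0.25,
):
    """Flag transcriptionally stratified samples.

    Average-linkage hierarchical clustering on correlation distance
    (1 - Pearson r between samples over probes); the dendrogram is cut at
    ``cut_scale`` times the median pairwise distance and samples in clusters
    smaller than ``min_cluster_frac * n`` are flagged.  Deterministic.
    """
    n = len(E.sample_ids)
    if n < 3:
        raise ValidationError("expression outlier detection needs >=3 samples")
    corr = np.corrcoef(E.values.to_numpy(dtype=float))
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    condensed = squareform(dist, checks=False)
    Z = average(condensed)
    cut = cut_scale * float(np.median(condensed))
    assignment = fcluster(Z, t=cut, criterion="distance")
    sizes = pd.Series(assignment).value_counts()
    small = sizes.index[sizes < min_cluster_frac * n]
    flagged = [sid for sid, a in zip(E.sample_ids, assignment) if a in set(small)]
    return flagged
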