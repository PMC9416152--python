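"""Filtering, outlier detection, normalization and imputation.

Covers both omics blocks:

* 16S: rare-OTU removal (observed in fewer than ``min_otu_samples``
  samples), a permutation outlier test on pairwise Jaccard distances,
  and upper-quartile (75th percentile of nonzero counts) library-size
  normalization.
* GC-MS: log2 transform, per-sample median centering, global
  half-minimum imputation of missing values, and the
  observed-in-enough-treatments filter used before univariate testing.

"Observed" means non-missing for metabolites and nonzero for OTU counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    ConfigError,
    InsufficientDataError,
    MetabotuError,
    MetaboliteMatrix,
    OtuCountTable,
    SampleMetadata,
    ScaleError,
    check_aligned,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ProcessingParams",
    "filter_rare_otus",
    "jaccard_distance",
    "detect_sample_outliers",
    "upper_quartile_normalize",
    "log2_transform",
    "median_center",
    "impute_half_minimum",
    "filter_metabolites_for_univariate",
]


@dataclass(frozen=True)
class ProcessingParams:
    """Thresholds for the filtering and outlier-detection steps.

    ``quantile_method`` fixes the percentile convention (numpy's
    linear interpolation between order statistics) because "75th
    quartile" is ambiguous across software.
    """

    min_otu_samples: int = 2
    outlier_permutations: int = 999
    outlier_alpha: float = 0.05
    metabolite_min_samples: int = 2
    metabolite_min_treatments: int = 2
    quantile_method: str = "linear"
    upper_quartile_rescale: bool = True

    def __post_init__(self) -> None:
        if self.min_otu_samples < 1 or self.metabolite_min_samples < 1:
            raise ConfigError("sample thresholds must be >= 1")
        if self.metabolite_min_treatments < 1:
            raise ConfigError("metabolite_min_treatments must be >= 1")
        if self.outlier_permutations < 1:
            raise ConfigError("outlier_permutations must be >= 1")
        if not (0 < self.outlier_alpha < 1):
            raise ConfigError("outlier_alpha must be in (0, 1)")


def filter_rare_otus(table: OtuCountTable, min_otu_samples: int = 2) -> OtuCountTable:
    """Drop OTUs with nonzero counts in fewer than ``min_otu_samples`` samples."""
    if min_otu_samples < 1:
        raise ConfigError("min_otu_samples must be >= 1")
    observed = (table.counts > 0).sum(axis=0)
    keep = observed.index[observed >= min_otu_samples]
    return table.subset_otus(keep)


def jaccard_distance(a, b) -> float:
    """Jaccard distance 1 - |A & B| / |A | B| between two presence vectors.

    If both vectors are all-absent the distance is undefined; 0 is
    returned by convention with a warning.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ConfigError("presence vectors must have equal length")
    union = int(np.sum(a | b))
    if union == 0:
        warnings.warn("Jaccard distance of two empty presence sets; returning 0")
        return 0.0
    inter = int(np.sum(a & b))
    return 1.0 - inter / union


def _mean_jaccard_to_others(P: np.ndarray) -> np.ndarray:
    """Per-sample mean Jaccard distance to all other samples (P binary n x p)."""
    P = P.astype(np.float64)
    inter = P @ P.T
    sizes = P.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        D = 1.0 - inter / union
    D[union == 0] = 0.0  # empty-vs-empty convention
    np.fill_diagonal(D, 0.0)
    n = P.shape[0]
    return D.sum(axis=1) / (n - 1)


def detect_sample_outliers(
    table: OtuCountTable, params: ProcessingParams = ProcessingParams(), seed: int = 0
) -> pd.DataFrame:
    """Randomization outlier test on pairwise Jaccard distances.

    The statistic for sample i is its mean Jaccard distance (on OTU
    presence profiles) to all other samples. The null is built from
    ``outlier_permutations`` datasets in which every OTU column's
    presence entries are independently permuted across samples, which
    preserves each OTU's prevalence while breaking sample identity. The
    one-sided p-value for sample i compares its observed statistic to
    its statistic in each permuted dataset; Bonferroni correction is
    applied across samples.

    Returns a DataFrame indexed by sample_id with columns
    ``statistic``, ``p_value``, ``p_bonferroni``, ``flagged``. The test
    is deterministic for a fixed seed and invariant to sample order.
    """
    n = len(table.sample_ids)
    if n < 3:
        raise InsufficientDataError("outlier detection needs at least 3 samples")
    # canonical sample order so the permutation stream does not depend on
    # the input row order
    order = np.argsort(np.asarray(table.sample_ids, dtype=object), kind="stable")
    ids = [table.sample_ids[i] for i in order]
    P = table.presence().to_numpy()[order].astype(np.uint8)

    observed = _mean_jaccard_to_others(P)
    B = params.outlier_permutations
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n, dtype=np.int64)
    for _ in range(B):
        perm = np.argsort(rng.random(P.shape), axis=0)
        Pp = np.take_along_axis(P, perm, axis=0)
        s_perm = _mean_jaccard_to_others(Pp)
        exceed += s_perm >= observed
    p = (1.0 + exceed) / (1.0 + B)
    p_bonf = np.minimum(p * n, 1.0)
    out = pd.DataFrame(
        {
            "statistic": observed,
            "p_value": p,
            "p_bonferroni": p_bonf,
            "flagged": p_bonf <= params.outlier_alpha,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return out.loc[table.sample_ids]


def upper_quartile_normalize(
    table: OtuCountTable, params: ProcessingParams = ProcessingParams()
) -> pd.DataFrame:
    """Upper-quartile library-size normalization (Bullard-style).

    Each sample's counts are divided by the 75th percentile of that
    sample's *nonzero* counts and, by default, re-multiplied by the
    across-sample mean of those percentiles so magnitudes stay
    count-like. Zeros map to zeros.
    """
    counts = table.counts.to_numpy(dtype=np.float64)
    q75 = np.empty(counts.shape[0])
    for i, sid in enumerate(table.sample_ids):
        nonzero = counts[i][counts[i] > 0]
        if nonzero.size == 0:
            raise MetabotuError(f"sample {sid!r} has all-zero counts; normalization undefined")
        q75[i] = np.percentile(nonzero, 75, method=params.quantile_method)
    scale = q75.mean() if params.upper_quartile_rescale else 1.0
    normalized = counts / q75[:, None] * scale
    return pd.DataFrame(normalized, index=table.counts.index, columns=table.counts.columns)


def log2_transform(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """log2 of every observed abundance; missing entries stay missing."""
    if matrix.scale != "raw":
        raise ScaleError(f"log2_transform expects raw scale, got {matrix.scale!r}")
    values = matrix.values.to_numpy(dtype=np.float64)
    if np.any(values[~np.isnan(values)] <= 0):
        raise MetabotuError("log2 transform requires all observed abundances > 0")
    with np.errstate(invalid="ignore"):
        out = np.log2(values)
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return MetaboliteMatrix(frame, scale="log2", imputation_value=matrix.imputation_value)


def median_center(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Subtract each sample's median observed value (log2 scale in, centered out)."""
    if matrix.scale != "log2":
        raise ScaleError(f"median_center expects log2 scale, got {matrix.scale!r}")
    values = matrix.values.to_numpy(dtype=np.float64)
    n_obs = (~np.isnan(values)).sum(axis=1)
    if (n_obs == 0).any():
        bad = [sid for sid, k in zip(matrix.sample_ids, n_obs) if k == 0]
        raise MetabotuError(f"samples with no observed values cannot be centered: {bad}")
    medians = np.nanmedian(values, axis=1)
    frame = pd.DataFrame(
        values - medians[:, None], index=matrix.values.index, columns=matrix.values.columns
    )
    return MetaboliteMatrix(frame, scale="log2-centered", imputation_value=matrix.imputation_value)


def impute_half_minimum(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Replace every missing entry by half the global minimum observed value.

    Applied on the log2 scale, before median centering, as required for
    classifiers that need complete observations. The imputation constant
    is recorded on the returned matrix.
    """
    if matrix.scale != "log2":
        raise ScaleError(f"impute_half_minimum expects log2 scale, got {matrix.scale!r}")
    values = matrix.values.to_numpy(dtype=np.float64)
    observed = values[~np.isnan(values)]
    if observed.size == 0:
        raise MetabotuError("no observed values; cannot impute")
    fill = float(observed.min() / 2.0)
    out = np.where(np.isnan(values), fill, values)
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return MetaboliteMatrix(frame, scale="log2", imputation_value=fill)


def filter_metabolites_for_univariate(
    matrix: MetaboliteMatrix,
    meta: SampleMetadata,
    params: ProcessingParams = ProcessingParams(),
) -> MetaboliteMatrix:
    """Keep metabolites observed in >= ``metabolite_min_samples`` samples
    within each of >= ``metabolite_min_treatments`` treatments."""
    check_aligned(meta, matrix)
    observed = matrix.observed_mask()
    counts_by_treatment = observed.groupby(meta.treatments.to_numpy()).sum()
    enough = (counts_by_treatment >= params.metabolite_min_samples).sum(axis=0)
    keep = enough.index[enough >= params.metabolite_min_treatments]
    frame = matrix.values.loc[:, list(keep)]
    return MetaboliteMatrix(frame, scale=matrix.scale, imputation_value=matrix.imputation_value)
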