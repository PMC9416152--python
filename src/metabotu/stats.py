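"""Per-feature significance testing.

Metabolites: a linear mixed model per metabolite (moisture treatment as
fixed effect, soil core as random intercept, REML) with all pairwise
treatment contrasts and a single-step max-|z| multiplicity adjustment
over the contrast family.

OTUs: two-sample location tests on upper-quartile-normalized abundances
per treatment pair, Benjamini-Hochberg corrected across the full
OTU x pair family at p-adj < 0.05.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import (
    ConfigError,
    InsufficientDataError,
    MetabotuError,
    SampleMetadata,
    check_aligned,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastResult",
    "MixedModelFit",
    "benjamini_hochberg",
    "fit_metabolite_mixed_model",
    "test_otu_abundance_shifts",
]


@dataclass(frozen=True)
class ContrastResult:
    pair: tuple
    estimate: float
    std_error: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class MixedModelFit:
    metabolite_id: str
    treatment_means: dict
    core_variance: float
    residual_variance: float
    contrasts: list


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values.

    adj_(i) = min over j >= i of p_(j) * m / j, capped at 1, returned in
    the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ConfigError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ConfigError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _max_abs_prob(A: np.ndarray, z: float) -> float:
    """P(max_i |A_i . w| <= z) for w ~ N(0, I_r), exploiting small rank.

    r = 1 is closed-form; r = 2 integrates the closed-form conditional
    interval probability over a fine grid (deterministic); larger ranks
    fall back to scipy's multivariate-normal rectangle probability.
    """
    k, r = A.shape
    if z <= 0:
        return 0.0
    if r == 1:
        a = np.abs(A[:, 0])
        bound = np.min(np.where(a > 0, z / np.maximum(a, 1e-300), np.inf))
        return float(np.clip(2.0 * sps.norm.cdf(bound) - 1.0, 0.0, 1.0))
    if r == 2:
        u1 = np.linspace(-8.5, 8.5, 2001)
        lo = np.full_like(u1, -np.inf)
        hi = np.full_like(u1, np.inf)
        ok = np.ones_like(u1, dtype=bool)
        for a1, a2 in A:
            if abs(a2) < 1e-12:
                if abs(a1) >= 1e-12:
                    ok &= np.abs(a1 * u1) <= z
                continue
            b1 = (-z - a1 * u1) / a2
            b2 = (z - a1 * u1) / a2
            lo = np.maximum(lo, np.minimum(b1, b2))
            hi = np.minimum(hi, np.maximum(b1, b2))
        inner = np.clip(sps.norm.cdf(hi) - sps.norm.cdf(lo), 0.0, 1.0)
        inner[~ok] = 0.0
        integrand = sps.norm.pdf(u1) * inner
        return float(np.clip(np.trapezoid(integrand, u1), 0.0, 1.0))
    dist = sps.multivariate_normal(
        mean=np.zeros(k), cov=A @ A.T, allow_singular=True, seed=0
    )
    return float(np.clip(dist.cdf(np.full(k, z), lower_limit=np.full(k, -z)), 0.0, 1.0))


def _single_step_adjust(z_values: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Single-step max-|z| adjustment: p_i = 1 - P(all |Z_j| <= |z_i|).

    The joint probability is a multivariate-normal rectangle probability
    with the contrast correlation matrix; this is the same idea as the
    max-t single-step adjustment over a small contrast family.
    """
    k = len(z_values)
    if k == 1:
        return 2.0 * sps.norm.sf(np.abs(z_values))
    lam, V = np.linalg.eigh((corr + corr.T) / 2.0)
    pos = lam > 1e-10 * lam.max()
    A = V[:, pos] * np.sqrt(lam[pos])
    return np.array([1.0 - _max_abs_prob(A, abs(z)) for z in z_values])


def fit_metabolite_mixed_model(
    values: pd.Series,
    meta: SampleMetadata,
    metabolite_id: str = "",
    adjustment: str = "single-step",
) -> MixedModelFit:
    """REML mixed model for one metabolite: treatment mean + core intercept.

    ``values`` is a per-sample series on the log2(-centered) scale aligned
    to ``meta``; missing entries are dropped. Returns treatment-mean
    estimates, variance components, and all pairwise treatment contrasts
    with single-step (max-|z|; ``adjustment="bonferroni"`` as fallback)
    adjusted p-values based on the large-sample normal reference.
    """
    import statsmodels.api as sm

    check_aligned(meta, values.to_frame())
    data = pd.DataFrame(
        {
            "y": values.to_numpy(dtype=float),
            "treatment": meta.treatments.to_numpy(),
            "core": meta.frame["core"].to_numpy(),
        }
    ).dropna(subset=["y"])
    if data.empty:
        raise MetabotuError(f"metabolite {metabolite_id!r}: all values missing")
    group_sizes = data.groupby("treatment").size()
    usable = group_sizes[group_sizes >= 2]
    if len(usable) < 2:
        raise InsufficientDataError(
            f"metabolite {metabolite_id!r}: need >= 2 treatments with >= 2 samples"
        )
    data = data[data["treatment"].isin(usable.index)]
    levels = sorted(usable.index)

    exog = pd.get_dummies(data["treatment"], dtype=float)[levels]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(data["y"].to_numpy(), exog.to_numpy(), groups=data["core"].to_numpy())
        result = None
        for method in (None, "powell"):
            try:
                candidate = model.fit(reml=True) if method is None else model.fit(
                    reml=True, method=method
                )
            except Exception:
                continue
            cov_try = np.asarray(candidate.cov_params())[: len(levels), : len(levels)]
            if np.all(np.isfinite(cov_try)) and np.all(np.diag(cov_try) > 0):
                result = candidate
                break

    if result is not None:
        means = dict(zip(levels, result.fe_params))
        cov = np.asarray(result.cov_params())[: len(levels), : len(levels)]
        core_var = float(np.asarray(result.cov_re)[0, 0]) if result.cov_re.size else 0.0
        resid_var = float(result.scale)
    else:
        # REML failed to produce a usable covariance (boundary fit on a
        # sparse/unbalanced metabolite); fall back to the fixed-effects
        # model, i.e. zero core variance
        ols = sm.OLS(data["y"].to_numpy(), exog.to_numpy()).fit()
        means = dict(zip(levels, ols.params))
        cov = np.asarray(ols.cov_params())
        core_var = 0.0
        resid_var = float(ols.mse_resid)
        logger.info("metabolite %r: mixed model degenerate; fixed-effects fallback", metabolite_id)

    pairs = list(itertools.combinations(levels, 2))
    C = np.zeros((len(pairs), len(levels)))
    for r, (a, b) in enumerate(pairs):
        C[r, levels.index(a)] = 1.0
        C[r, levels.index(b)] = -1.0
    est = C @ np.asarray(list(means.values()))
    vcov = C @ cov @ C.T
    se = np.sqrt(np.diag(vcov))
    z = est / se
    p_raw = 2.0 * sps.norm.sf(np.abs(z))
    if adjustment == "single-step":
        d = np.sqrt(np.diag(vcov))
        corr = vcov / np.outer(d, d)
        p_adj = _single_step_adjust(z, corr)
    elif adjustment == "bonferroni":
        p_adj = np.minimum(p_raw * len(pairs), 1.0)
    else:
        raise ConfigError(f"unknown adjustment {adjustment!r}")
    p_adj = np.maximum(p_adj, p_raw)  # adjustment can never help

    contrasts = [
        ContrastResult(pair, float(e), float(s), float(pr), float(pa))
        for pair, e, s, pr, pa in zip(pairs, est, se, p_raw, p_adj)
    ]
    return MixedModelFit(
        metabolite_id=metabolite_id,
        treatment_means={k: float(v) for k, v in means.items()},
        core_variance=max(core_var, 0.0),
        residual_variance=resid_var,
        contrasts=contrasts,
    )


def test_otu_abundance_shifts(
    normalized: pd.DataFrame,
    meta: SampleMetadata,
    method: str = "welch",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen OTUs for relative-abundance shifts between treatment pairs.

    ``normalized`` comes from :func:`upper_quartile_normalize`. The default
    test is Welch's t on log2(abundance + pseudocount) where the
    pseudocount is half the smallest nonzero normalized value;
    ``method="wilcoxon"`` switches to a rank-sum test on the raw
    normalized values. BH correction is applied across the whole
    OTU x pair family; ``significant`` flags adjusted p < ``alpha``.
    """
    if method not in ("welch", "wilcoxon"):
        raise ConfigError(f"unknown method {method!r}")
    check_aligned(meta, normalized)
    values = normalized.to_numpy(dtype=float)
    treatments = meta.treatments.to_numpy()
    present = [t for t in pd.unique(treatments)]
    pairs = list(itertools.combinations(sorted(present), 2))

    nonzero = values[values > 0]
    pseudo = float(nonzero.min() / 2.0) if nonzero.size else 1.0
    logv = np.log2(values + pseudo)

    rows = []
    for a, b in pairs:
        ia = treatments == a
        ib = treatments == b
        if ia.sum() < 2 or ib.sum() < 2:
            logger.warning("pair (%s, %s) skipped: a group has < 2 samples", a, b)
            continue
        for j, otu in enumerate(normalized.columns):
            if method == "welch":
                xa, xb = logv[ia, j], logv[ib, j]
                if np.ptp(np.concatenate([xa, xb])) == 0:
                    stat, p = 0.0, 1.0
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        stat, p = sps.ttest_ind(xa, xb, equal_var=False)
                    if np.isnan(p):  # zero variance in both groups, distinct means
                        stat, p = np.inf, 0.0
            else:
                xa, xb = values[ia, j], values[ib, j]
                if np.ptp(np.concatenate([xa, xb])) == 0:
                    stat, p = 0.0, 1.0
                else:
                    stat, p = sps.mannwhitneyu(xa, xb, alternative="two-sided")
            rows.append((otu, a, b, float(stat), float(p)))

    out = pd.DataFrame(rows, columns=["otu_id", "treatment_a", "treatment_b", "statistic", "p_raw"])
    if len(out):
        out["p_adjusted"] = benjamini_hochberg(out["p_raw"].to_numpy())
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["p_adjusted"] = []
        out["significant"] = []
    return out
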