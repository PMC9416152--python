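"""Per-treatment OTU presence/absence modelling and biomarker ranking.

For each moisture treatment, every eligible OTU (at least ``min_present``
present and ``min_absent`` absent samples within the treatment) gets its
own random forest with the processed metabolite profiles as predictors.
Models are gated on out-of-bag balanced accuracy; the mean-decrease-Gini
importance scores of the retained models are pooled, and every
(metabolite, OTU) score in the top ``importance_top_fraction`` of the
pool is reported as a strong-predictor pair. Metabolites are additionally
ranked by their mean importance across retained models.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field, replace

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
    TREATMENTS,
    check_aligned,
)
from .forest import ForestParams, fit_random_forest, mean_decrease_gini, oob_predict

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ModelSummary",
    "BiomarkerRanking",
    "binarize_otu",
    "select_eligible_otus",
    "balanced_accuracy",
    "fit_models_for_treatment",
    "rank_biomarkers",
    "derive_otu_seed",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds of the classification / ranking stage."""

    min_present: int = 3
    min_absent: int = 3
    balanced_accuracy_threshold: float = 0.80
    importance_top_fraction: float = 0.20
    forest: ForestParams = field(default_factory=ForestParams)
    pooling_scope: str = "per-treatment"
    tie_rule: str = "present"

    def __post_init__(self) -> None:
        if self.min_present < 1 or self.min_absent < 1:
            raise ConfigError("min_present and min_absent must be >= 1")
        if not (0 <= self.balanced_accuracy_threshold <= 1):
            raise ConfigError("balanced_accuracy_threshold must be in [0, 1]")
        if not (0 < self.importance_top_fraction <= 1):
            raise ConfigError("importance_top_fraction must be in (0, 1]")
        if self.pooling_scope not in ("per-treatment", "global"):
            raise ConfigError("pooling_scope must be 'per-treatment' or 'global'")


@dataclass
class ModelSummary:
    """One fitted per-OTU forest within one treatment."""

    otu_id: str
    treatment: str
    n_present: int
    n_absent: int
    oob_predictions: np.ndarray
    true_positive_rate: float
    true_negative_rate: float
    balanced_accuracy: float
    importance: dict  # metabolite -> mean decrease in Gini
    seed: int


@dataclass
class BiomarkerRanking:
    """Pooled importance ranking for one treatment (or the global pool)."""

    treatment: str
    retained_models: list
    pooled_importance_cutoff: float
    strong_pairs: list  # (metabolite, otu_id, importance), importance desc
    metabolite_rank: pd.Series  # mean importance across retained models, desc


def binarize_otu(counts) -> np.ndarray:
    """Present (True) iff count > 0."""
    arr = np.asarray(counts)
    if (arr < 0).any():
        raise ConfigError("counts must be non-negative")
    return arr > 0


def select_eligible_otus(
    table: OtuCountTable,
    meta: SampleMetadata,
    treatment: str,
    config: PipelineConfig = PipelineConfig(),
) -> list:
    """OTUs with >= min_present present and >= min_absent absent samples
    within the treatment's samples."""
    samples = meta.samples_for(treatment)
    if len(samples) < config.min_present + config.min_absent:
        raise InsufficientDataError(
            f"treatment {treatment!r} has {len(samples)} samples; needs at least "
            f"{config.min_present + config.min_absent}"
        )
    sub = table.counts.loc[samples]
    present = (sub > 0).sum(axis=0)
    absent = len(samples) - present
    keep = (present >= config.min_present) & (absent >= config.min_absent)
    return list(sub.columns[keep])


def balanced_accuracy(truth, predicted) -> float:
    """(TPR + TNR) / 2; equals plain accuracy when classes are balanced.

    Samples with no prediction (coded -1, possible only at very small
    tree counts) are excluded.
    """
    t = np.asarray(truth).astype(int)
    p = np.asarray(predicted).astype(int)
    if t.shape != p.shape:
        raise ConfigError("truth and prediction must have equal length")
    has_pred = p >= 0
    t, p = t[has_pred], p[has_pred]
    n_pos = int((t == 1).sum())
    n_neg = int((t == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetabotuError("balanced accuracy undefined: truth is single-class")
    tpr = int(((t == 1) & (p == 1)).sum()) / n_pos
    tnr = int(((t == 0) & (p == 0)).sum()) / n_neg
    return (tpr + tnr) / 2.0


def derive_otu_seed(master_seed: int, otu_id: str) -> int:
    """Stable per-OTU forest seed, independent of which other OTUs run."""
    return zlib.crc32(f"{master_seed}:{otu_id}".encode()) & 0x7FFFFFFF


def fit_models_for_treatment(
    otus: OtuCountTable,
    metab: MetaboliteMatrix,
    meta: SampleMetadata,
    treatment: str,
    config: PipelineConfig = PipelineConfig(),
    master_seed: int = 0,
) -> list:
    """Fit one presence/absence forest per eligible OTU in one treatment.

    ``metab`` must be fully imputed and median-centered; predictors are
    its per-sample metabolite profiles restricted to the treatment's
    samples. Each OTU's forest is seeded from (master_seed, otu_id) so
    adding or removing OTUs does not perturb other models.
    """
    if metab.scale != "log2-centered":
        raise ScaleError("metabolite matrix must be log2-centered for classification")
    if metab.values.isna().any().any():
        raise MetabotuError("metabolite matrix still has missing values; impute first")
    check_aligned(meta, otus, metab)

    samples = meta.samples_for(treatment)
    eligible = select_eligible_otus(otus, meta, treatment, config)
    X = metab.values.loc[samples].to_numpy(dtype=np.float64)
    met_ids = metab.metabolite_ids

    summaries = []
    for otu_id in eligible:
        y = binarize_otu(otus.counts.loc[samples, otu_id].to_numpy()).astype(np.int8)
        seed = derive_otu_seed(master_seed, otu_id)
        params = replace(config.forest, seed=seed)
        model = fit_random_forest(X, y, params, predictor_ids=met_ids)
        pred = oob_predict(model, tie_rule=config.tie_rule)
        ba = balanced_accuracy(y, pred)
        has_pred = pred >= 0
        tpr = float(((y == 1) & (pred == 1))[has_pred].sum() / max((y == 1).sum(), 1))
        tnr = float(((y == 0) & (pred == 0))[has_pred].sum() / max((y == 0).sum(), 1))
        summaries.append(
            ModelSummary(
                otu_id=otu_id,
                treatment=treatment,
                n_present=int(y.sum()),
                n_absent=int(len(y) - y.sum()),
                oob_predictions=pred,
                true_positive_rate=tpr,
                true_negative_rate=tnr,
                balanced_accuracy=float(ba),
                importance=mean_decrease_gini(model),
                seed=seed,
            )
        )
    return summaries


def rank_biomarkers(
    summaries: list, config: PipelineConfig = PipelineConfig(), treatment: str | None = None
) -> BiomarkerRanking:
    """Gate models on balanced accuracy and pool importance scores.

    Models with OOB balanced accuracy >= the threshold are retained; the
    cutoff is the (1 - importance_top_fraction) empirical quantile of all
    (metabolite, model) importance scores across retained models, and
    strong pairs are the scores at or above it. With zero retained models
    an empty ranking is returned with a warning -- exactly the outcome a
    treatment with no predictable OTUs produces.
    """
    if treatment is None:
        treatments = {s.treatment for s in summaries}
        treatment = treatments.pop() if len(treatments) == 1 else "global"
    retained = [s for s in summaries if s.balanced_accuracy >= config.balanced_accuracy_threshold]
    if not retained:
        warnings.warn(f"no models passed the balanced-accuracy gate for {treatment!r}")
        return BiomarkerRanking(
            treatment=treatment,
            retained_models=[],
            pooled_importance_cutoff=float("nan"),
            strong_pairs=[],
            metabolite_rank=pd.Series(dtype=float),
        )

    pooled = np.concatenate([np.fromiter(s.importance.values(), dtype=float) for s in retained])
    cutoff = float(np.quantile(pooled, 1.0 - config.importance_top_fraction))
    pairs = [
        (met, s.otu_id, float(imp))
        for s in retained
        for met, imp in s.importance.items()
        if imp >= cutoff
    ]
    pairs.sort(key=lambda x: (-x[2], x[0], x[1]))
    rank = (
        pd.DataFrame([s.importance for s in retained])
        .mean(axis=0)
        .sort_values(ascending=False, kind="stable")
    )
    return BiomarkerRanking(
        treatment=treatment,
        retained_models=[s.otu_id for s in retained],
        pooled_importance_cutoff=cutoff,
        strong_pairs=pairs,
        metabolite_rank=rank,
    )


@dataclass
class PipelineResult:
    """Everything a full run produces, plus the manifest describing it."""

    metadata: SampleMetadata
    otus: OtuCountTable  # after outlier and rare-OTU filtering
    metabolites_rf: MetaboliteMatrix  # imputed, median-centered
    outliers: pd.DataFrame | None
    metabolite_tests: pd.DataFrame | None
    otu_shift_tests: pd.DataFrame | None
    summaries: list
    rankings: dict  # treatment -> BiomarkerRanking
    truth: object | None
    manifest: dict


def _jsonable(obj):
    import dataclasses

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def summaries_frame(summaries: list) -> pd.DataFrame:
    """Tabular view of ModelSummary records (one row per OTU x treatment)."""
    return pd.DataFrame(
        [
            {
                "otu_id": s.otu_id,
                "treatment": s.treatment,
                "n_present": s.n_present,
                "n_absent": s.n_absent,
                "true_positive_rate": s.true_positive_rate,
                "true_negative_rate": s.true_negative_rate,
                "balanced_accuracy": s.balanced_accuracy,
                "seed": s.seed,
            }
            for s in summaries
        ]
    )


def run_full_pipeline(
    sim_config=None,
    *,
    inputs: tuple | None = None,
    pipeline_config: PipelineConfig = PipelineConfig(),
    processing=None,
    master_seed: int = 0,
    outdir=None,
    detect_outliers: bool = True,
    run_univariate: bool = True,
    include_timestamp: bool = False,
) -> PipelineResult:
    """Execute preprocess -> univariate -> classify -> rank end to end.

    Either ``sim_config`` (a :class:`~metabotu.simulate.SimulationConfig`;
    its seed is overridden by ``master_seed``) or ``inputs`` -- a
    ``(metadata, otu_table, raw_metabolite_matrix)`` triple -- must be
    given. If ``outdir`` is set, all artifacts (summaries, importance
    matrix, strong pairs, rankings, test tables, manifest) are written
    there as TSV/JSON. The manifest records configs, the master seed and
    row/column counts at every stage; timestamps are off by default so
    identical runs produce byte-identical manifests.
    """
    from . import __version__
    from .preprocess import (
        ProcessingParams,
        detect_sample_outliers,
        filter_metabolites_for_univariate,
        filter_rare_otus,
        impute_half_minimum,
        log2_transform,
        median_center,
        upper_quartile_normalize,
    )
    from .stats import fit_metabolite_mixed_model, test_otu_abundance_shifts

    if processing is None:
        processing = ProcessingParams()
    if (sim_config is None) == (inputs is None):
        raise ConfigError("provide exactly one of sim_config or inputs")

    manifest: dict = {
        "version": __version__,
        "master_seed": int(master_seed),
        "configs": {
            "pipeline": _jsonable(pipeline_config),
            "processing": _jsonable(processing),
        },
        "stages": {},
        "notes": [
            "technical replicates are treated as independent samples within "
            "treatment; core nesting is not modelled in the forests"
        ],
    }
    if include_timestamp:
        import datetime

        manifest["timestamp"] = datetime.datetime.now().isoformat()

    truth = None
    if sim_config is not None:
        from dataclasses import replace as _replace

        from .simulate import generate_dataset

        sim_config = _replace(sim_config, seed=int(master_seed))
        manifest["configs"]["simulation"] = _jsonable(sim_config)
        data = generate_dataset(sim_config)
        meta, metab_raw, otus, truth = data.metadata, data.metabolites, data.otus, data.truth
    else:
        meta, otus, metab_raw = inputs
    check_aligned(meta, otus, metab_raw)
    manifest["stages"]["input"] = {
        "n_samples": len(meta),
        "samples_per_treatment": {t: len(meta.samples_for(t)) for t in TREATMENTS},
        "n_otus": len(otus.otu_ids),
        "n_metabolites": len(metab_raw.metabolite_ids),
    }

    outliers = None
    if detect_outliers:
        outliers = detect_sample_outliers(otus, processing, seed=master_seed)
        flagged = list(outliers.index[outliers["flagged"]])
        if flagged:
            logger.info("removing flagged outlier samples: %s", flagged)
            keep = [s for s in meta.sample_ids if s not in flagged]
            meta = SampleMetadata(meta.frame.loc[keep])
            otus = otus.subset_samples(keep)
            metab_raw = MetaboliteMatrix(metab_raw.values.loc[keep], scale=metab_raw.scale)
        manifest["stages"]["outlier_removal"] = {
            "flagged_samples": flagged,
            "n_samples_after": len(meta),
        }

    n_before = len(otus.otu_ids)
    otus = filter_rare_otus(otus, processing.min_otu_samples)
    manifest["stages"]["rare_otu_filter"] = {
        "n_otus_before": n_before,
        "n_otus_removed": n_before - len(otus.otu_ids),
        "n_otus_after": len(otus.otu_ids),
    }

    # random-forest branch: log2 -> half-minimum imputation -> median centering
    metab_log2 = log2_transform(metab_raw)
    metab_imputed = impute_half_minimum(metab_log2)
    metab_rf = median_center(metab_imputed)
    manifest["stages"]["metabolite_rf_processing"] = {
        "imputation_value": metab_imputed.imputation_value,
        "n_missing_imputed": int(metab_raw.values.isna().sum().sum()),
    }

    metab_tests = None
    otu_tests = None
    if run_univariate:
        # univariate branch: observation filter -> log2 -> median centering,
        # missing values retained
        metab_uni = filter_metabolites_for_univariate(metab_raw, meta, processing)
        metab_uni = median_center(log2_transform(metab_uni))
        rows = []
        for met in metab_uni.metabolite_ids:
            try:
                fit = fit_metabolite_mixed_model(metab_uni.values[met], meta, metabolite_id=met)
            except (InsufficientDataError, MetabotuError):
                continue
            for c in fit.contrasts:
                rows.append(
                    {
                        "metabolite_id": met,
                        "treatment_a": c.pair[0],
                        "treatment_b": c.pair[1],
                        "estimate": c.estimate,
                        "std_error": c.std_error,
                        "p_raw": c.p_raw,
                        "p_adjusted": c.p_adjusted,
                        "core_variance": fit.core_variance,
                        "residual_variance": fit.residual_variance,
                    }
                )
        metab_tests = pd.DataFrame(rows)
        normalized = upper_quartile_normalize(otus, processing)
        otu_tests = test_otu_abundance_shifts(normalized, meta)
        manifest["stages"]["univariate"] = {
            "n_metabolites_tested": len(metab_uni.metabolite_ids),
            "n_metabolites_removed": len(metab_raw.metabolite_ids)
            - len(metab_uni.metabolite_ids),
            "n_otu_tests": int(len(otu_tests)),
            "n_otu_tests_significant": int(otu_tests["significant"].sum())
            if len(otu_tests)
            else 0,
        }

    summaries: list = []
    rankings: dict = {}
    eligible_counts: dict = {}
    for treatment in TREATMENTS:
        n_t = len(meta.samples_for(treatment))
        if n_t < pipeline_config.min_present + pipeline_config.min_absent:
            if n_t:
                logger.warning("treatment %s has too few samples (%d); skipped", treatment, n_t)
            continue
        eligible_counts[treatment] = len(
            select_eligible_otus(otus, meta, treatment, pipeline_config)
        )
        treatment_summaries = fit_models_for_treatment(
            otus, metab_rf, meta, treatment, pipeline_config, master_seed
        )
        summaries.extend(treatment_summaries)
        if pipeline_config.pooling_scope == "per-treatment":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rankings[treatment] = rank_biomarkers(
                    treatment_summaries, pipeline_config, treatment
                )
    if pipeline_config.pooling_scope == "global":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rankings["global"] = rank_biomarkers(summaries, pipeline_config, "global")

    manifest["stages"]["classification"] = {
        "eligible_otus_per_treatment": eligible_counts,
        "n_models": len(summaries),
        "n_retained_per_treatment": {
            t: len(r.retained_models) for t, r in rankings.items()
        },
        "n_strong_pairs_per_treatment": {t: len(r.strong_pairs) for t, r in rankings.items()},
    }

    result = PipelineResult(
        metadata=meta,
        otus=otus,
        metabolites_rf=metab_rf,
        outliers=outliers,
        metabolite_tests=metab_tests,
        otu_shift_tests=otu_tests,
        summaries=summaries,
        rankings=rankings,
        truth=truth,
        manifest=manifest,
    )
    if outdir is not None:
        _write_artifacts(result, outdir)
    return result


def _write_artifacts(result: PipelineResult, outdir) -> None:
    from pathlib import Path

    from . import io as mio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_metadata(result.metadata, outdir / "metadata.tsv")
    mio.write_otu_table(result.otus, outdir / "otu_counts.tsv")
    mio.write_metabolite_matrix(result.metabolites_rf, outdir / "metabolites_processed.tsv")

    summaries_frame(result.summaries).to_csv(
        outdir / "model_summaries.tsv", sep="\t", index=False, float_format="%.10g"
    )
    if result.summaries:
        imp = pd.DataFrame(
            [s.importance for s in result.summaries],
            index=pd.Index(
                [f"{s.treatment}:{s.otu_id}" for s in result.summaries], name="model"
            ),
        )
        imp.to_csv(outdir / "importance_matrix.tsv", sep="\t", float_format="%.10g")

    pair_rows = [
        {"treatment": t, "metabolite_id": m, "otu_id": o, "importance": v}
        for t, r in result.rankings.items()
        for m, o, v in r.strong_pairs
    ]
    pd.DataFrame(pair_rows, columns=["treatment", "metabolite_id", "otu_id", "importance"]).to_csv(
        outdir / "strong_pairs.tsv", sep="\t", index=False, float_format="%.10g"
    )
    rank_rows = [
        {"treatment": t, "metabolite_id": m, "mean_importance": v}
        for t, r in result.rankings.items()
        for m, v in r.metabolite_rank.items()
    ]
    pd.DataFrame(rank_rows, columns=["treatment", "metabolite_id", "mean_importance"]).to_csv(
        outdir / "metabolite_ranking.tsv", sep="\t", index=False, float_format="%.10g"
    )
    if result.metabolite_tests is not None:
        result.metabolite_tests.to_csv(
            outdir / "metabolite_tests.tsv", sep="\t", index=False, float_format="%.10g"
        )
    if result.otu_shift_tests is not None:
        result.otu_shift_tests.to_csv(
            outdir / "otu_shift_tests.tsv", sep="\t", index=False, float_format="%.10g"
        )
    if result.outliers is not None:
        result.outliers.to_csv(outdir / "outliers.tsv", sep="\t", float_format="%.10g")
    if result.truth is not None:
        mio.write_truth(result.truth, outdir / "truth.json")
    mio.write_manifest(result.manifest, outdir / "manifest.json")
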