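"""Coupled synthetic soil metabolome / OTU-table generator.

Emulates the statistical structure the downstream analysis assumes: samples
nested in soil cores under three moisture treatments, a log-normal GC-MS
metabolite block with treatment and core effects plus missingness, and a
sparse OTU count block in which a subset of "target" OTUs have their
presence driven by "driver" metabolites through a logistic link. The
planted links are returned as ground truth so recovery can be scored.

The defaults reproduce the study conditions the analysis was designed for:
41 samples split 10 (D-W) / 18 (W-D) / 13 (Sat), 125 metabolites, and an
OTU table at reduced scale (hundreds rather than ~12,600 OTUs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    ConfigError,
    MetaboliteMatrix,
    OtuCountTable,
    SampleMetadata,
    TREATMENTS,
    check_aligned,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SimulatedDataset",
    "generate_metadata",
    "generate_metabolite_matrix",
    "generate_otu_table",
    "generate_dataset",
]


def _default_samples() -> dict:
    return {"D-W": 10, "W-D": 18, "Sat": 13}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator.

    ``effect_size`` is the log-odds slope linking a standardized driver
    metabolite's log2 abundance to a target OTU's presence probability.
    ``count_dispersion`` is the negative-binomial size parameter for
    present-entry counts (smaller = more overdispersed).
    """

    samples_per_treatment: dict = field(default_factory=_default_samples)
    cores_per_treatment: int = 4
    n_otus: int = 250
    n_metabolites: int = 125
    n_driver_metabolites: int = 5
    n_target_otus: int = 10
    n_drivers_per_target: int = 1
    effect_size: float = 3.0
    missing_rate: float = 0.10
    otu_zero_inflation: float = 0.15
    count_dispersion: float = 0.5
    treatment_shift_sd: float = 1.0
    core_sd: float = 0.5
    residual_sd: float = 1.0
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 2.0
    mean_count_log: float = 3.0  # log of per-OTU mean count for present entries
    background_prevalence_range: tuple = (0.2, 0.8)
    target_intercept_range: tuple = (-0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.samples_per_treatment:
            raise ConfigError("samples_per_treatment must be nonempty")
        for t, n in self.samples_per_treatment.items():
            if t not in TREATMENTS:
                raise ConfigError(f"unknown treatment {t!r}; expected subset of {TREATMENTS}")
            if n < 1:
                raise ConfigError(f"treatment {t} has zero samples")
        if self.cores_per_treatment < 1:
            raise ConfigError("cores_per_treatment must be >= 1")
        for name in ("n_otus", "n_metabolites"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must be in [0, 1)")
        if not (0 <= self.otu_zero_inflation < 1):
            raise ConfigError("otu_zero_inflation must be in [0, 1)")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.count_dispersion <= 0:
            raise ConfigError("count_dispersion must be > 0")
        if self.treatment_shift_sd < 0 or self.core_sd < 0:
            raise ConfigError("treatment_shift_sd and core_sd must be >= 0")
        if self.residual_sd <= 0:
            raise ConfigError("residual_sd must be > 0")
        if self.n_driver_metabolites > self.n_metabolites:
            raise ConfigError("n_driver_metabolites exceeds n_metabolites")
        if self.n_target_otus > self.n_otus:
            raise ConfigError("n_target_otus exceeds n_otus")
        if self.n_target_otus and self.n_driver_metabolites == 0 and self.effect_size > 0:
            raise ConfigError("target OTUs require at least one driver metabolite")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset.

    driver_map maps each target OTU to its (driver metabolite, signed
    slope) pairs; treatment_effects and core_effects record the drawn
    metabolite-block effects; intercepts the per-target logistic
    intercepts.
    """

    driver_map: dict = field(default_factory=dict)
    treatment_effects: dict = field(default_factory=dict)
    core_effects: dict = field(default_factory=dict)
    intercepts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "driver_map": {
                otu: [[m, float(s)] for m, s in pairs] for otu, pairs in self.driver_map.items()
            },
            "treatment_effects": {
                m: {t: float(v) for t, v in shifts.items()}
                for m, shifts in self.treatment_effects.items()
            },
            "core_effects": {c: float(v) for c, v in self.core_effects.items()},
            "intercepts": {o: float(v) for o, v in self.intercepts.items()},
        }


@dataclass
class SimulatedDataset:
    metadata: SampleMetadata
    metabolites: MetaboliteMatrix
    otus: OtuCountTable
    truth: SyntheticTruth


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # independent streams per stage so regenerating one block does not
    # perturb the others
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def generate_metadata(config: SimulationConfig) -> SampleMetadata:
    """Lay out samples across treatments, cores and technical replicates.

    Samples are spread round-robin across ``cores_per_treatment`` cores
    within each treatment; the replicate index counts samples within a
    core. The layout is a deterministic function of the configuration.
    """
    records = []
    for treatment in TREATMENTS:
        if treatment not in config.samples_per_treatment:
            continue
        n = config.samples_per_treatment[treatment]
        tslug = treatment.replace("-", "")
        for i in range(n):
            core_idx = i % config.cores_per_treatment
            replicate = i // config.cores_per_treatment + 1
            records.append(
                {
                    "sample_id": f"{tslug}_s{i + 1:02d}",
                    "treatment": treatment,
                    "core": f"{tslug}_core{core_idx + 1}",
                    "replicate": replicate,
                }
            )
    frame = pd.DataFrame.from_records(records).set_index("sample_id")
    return SampleMetadata(frame)


def generate_metabolite_matrix(
    meta: SampleMetadata, config: SimulationConfig
) -> tuple[MetaboliteMatrix, SyntheticTruth]:
    """Draw the GC-MS block on the raw (abundance) scale.

    log2 value = metabolite baseline + treatment shift (one draw per
    metabolite x treatment, sd = treatment_shift_sd) + core intercept
    (sd = core_sd, shared across metabolites) + residual
    (sd = residual_sd); entries then go missing independently at
    ``missing_rate``. Technical replicates share their core's intercept
    but have independent residuals.
    """
    if len(meta) == 0:
        raise ConfigError("metadata is empty")
    rng = _rng(config, stage=1)
    n = len(meta)
    p = config.n_metabolites
    met_ids = [f"met{j + 1:03d}" for j in range(p)]
    treatments_present = list(dict.fromkeys(meta.frame["treatment"]))

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=p)
    shift = {
        t: rng.normal(0.0, config.treatment_shift_sd, size=p) if config.treatment_shift_sd > 0
        else np.zeros(p)
        for t in treatments_present
    }
    cores = list(dict.fromkeys(meta.frame["core"]))
    core_eff = {
        c: (rng.normal(0.0, config.core_sd) if config.core_sd > 0 else 0.0) for c in cores
    }

    log2 = np.empty((n, p))
    for i, sid in enumerate(meta.sample_ids):
        row = meta.frame.loc[sid]
        log2[i] = (
            baseline
            + shift[row["treatment"]]
            + core_eff[row["core"]]
            + rng.normal(0.0, config.residual_sd, size=p)
        )
    values = np.exp2(log2)
    if config.missing_rate > 0:
        mask = rng.random(size=(n, p)) < config.missing_rate
        values = np.where(mask, np.nan, values)

    truth = SyntheticTruth(
        treatment_effects={
            m: {t: float(shift[t][j]) for t in treatments_present}
            for j, m in enumerate(met_ids)
        },
        core_effects=core_eff,
    )
    frame = pd.DataFrame(values, index=meta.sample_ids, columns=met_ids)
    return MetaboliteMatrix(frame, scale="raw"), truth


def generate_otu_table(
    meta: SampleMetadata,
    metab: MetaboliteMatrix,
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> tuple[OtuCountTable, SyntheticTruth]:
    """Draw the OTU count block, planting metabolite -> presence links.

    Each target OTU's per-sample presence probability is
    logistic(intercept + sum of slope * z), where z is the globally
    standardized observed log2 abundance of a driver metabolite (missing
    observations contribute z = 0, i.e. the mean). Slope magnitudes equal
    ``effect_size`` with randomized signs. Background OTUs are present
    independently at a prevalence drawn uniformly per OTU, thinned by the
    zero-inflation fraction. Present entries receive 1 + negative-binomial
    counts, so presence always corresponds to a nonzero count.
    """
    check_aligned(meta, metab)
    rng = _rng(config, stage=2)
    n = len(meta)
    otu_ids = [f"otu{j + 1:04d}" for j in range(config.n_otus)]

    # standardized observed log2 abundances; missing -> 0 (column mean)
    with np.errstate(invalid="ignore"):
        log2obs = np.log2(metab.values.to_numpy()) if metab.scale == "raw" else metab.values.to_numpy()
    mu = np.nanmean(log2obs, axis=0)
    sd = np.nanstd(log2obs, axis=0)
    sd[sd == 0] = 1.0
    z = (log2obs - mu) / sd
    z = np.nan_to_num(z, nan=0.0)

    target_idx = rng.choice(config.n_otus, size=config.n_target_otus, replace=False)
    driver_pool = rng.choice(config.n_metabolites, size=config.n_driver_metabolites, replace=False)

    presence = np.zeros((n, config.n_otus), dtype=bool)
    driver_map: dict = {}
    intercepts: dict = {}
    met_ids = metab.metabolite_ids

    is_target = np.zeros(config.n_otus, dtype=bool)
    is_target[target_idx] = True
    for j in target_idx:
        otu = otu_ids[j]
        k = min(config.n_drivers_per_target, len(driver_pool)) if len(driver_pool) else 0
        chosen = rng.choice(driver_pool, size=k, replace=False) if k else np.array([], dtype=int)
        slopes = config.effect_size * rng.choice([-1.0, 1.0], size=k)
        intercept = float(rng.uniform(*config.target_intercept_range))
        logit = intercept + z[:, chosen] @ slopes if k else np.full(n, intercept)
        prob = 1.0 / (1.0 + np.exp(-logit))
        presence[:, j] = rng.random(n) < prob
        driver_map[otu] = [(met_ids[int(m)], float(s)) for m, s in zip(chosen, slopes)]
        intercepts[otu] = intercept

    lo, hi = config.background_prevalence_range
    prevalence = rng.uniform(lo, hi, size=config.n_otus)
    background = ~is_target
    presence[:, background] = rng.random((n, int(background.sum()))) < prevalence[background]
    if config.otu_zero_inflation > 0:
        # extra sparsity applied to background OTUs only, so the planted
        # links stay exactly as drawn
        thin = rng.random((n, int(background.sum()))) < config.otu_zero_inflation
        sub = presence[:, background]
        sub[thin] = False
        presence[:, background] = sub

    mean_count = np.exp(rng.normal(config.mean_count_log, 1.0, size=config.n_otus))
    k_disp = config.count_dispersion
    p_nb = k_disp / (k_disp + np.maximum(mean_count - 1.0, 1e-9))
    counts = np.zeros((n, config.n_otus), dtype=np.int64)
    draws = 1 + rng.negative_binomial(k_disp, np.broadcast_to(p_nb, (n, config.n_otus)))
    counts[presence] = draws[presence]

    taxonomy = pd.Series(
        [
            f"p__Phylum{1 + j % 12};c__Class{1 + j % 30};g__Genus{1 + j % 60}"
            for j in range(config.n_otus)
        ],
        index=otu_ids,
        dtype=object,
    )
    table = OtuCountTable(
        pd.DataFrame(counts, index=meta.sample_ids, columns=otu_ids), taxonomy
    )
    truth.driver_map = driver_map
    truth.intercepts = intercepts
    return table, truth


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the coupled metadata / metabolite / OTU dataset in one call."""
    meta = generate_metadata(config)
    metab, truth = generate_metabolite_matrix(meta, config)
    otus, truth = generate_otu_table(meta, metab, truth, config)
    return SimulatedDataset(meta, metab, otus, truth)
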