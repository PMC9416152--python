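"""Run both preprocessing branches on a simulated dataset.

The 16S branch removes rare OTUs (observed in < 2 samples), screens for
outlying samples with a Jaccard-distance randomization test, and applies
upper-quartile library-size normalization. The GC-MS branch is
log2 -> half-minimum imputation -> per-sample median centering for the
classifier, and the observation filter + log2 + centering (missing
retained) for univariate testing. The printed imputation constant is
half the smallest observed log2 abundance in the whole matrix.
"""

import numpy as np

from metabotu import (
    ProcessingParams,
    SimulationConfig,
    detect_sample_outliers,
    filter_metabolites_for_univariate,
    filter_rare_otus,
    generate_dataset,
    impute_half_minimum,
    log2_transform,
    median_center,
    upper_quartile_normalize,
)

data = generate_dataset(SimulationConfig(n_otus=120, seed=3))
params = ProcessingParams()

filtered = filter_rare_otus(data.otus, params.min_otu_samples)
print(f"rare-OTU filter: {len(data.otus.otu_ids)} -> {len(filtered.otu_ids)} OTUs")

outliers = detect_sample_outliers(filtered, params, seed=3)
print(f"outlier test:    {int(outliers['flagged'].sum())} flagged "
      f"(smallest adjusted p = {outliers['p_bonferroni'].min():.3f})")

normalized = upper_quartile_normalize(filtered, params)
print(f"upper-quartile normalization: per-sample 75th percentiles equalized, "
      f"grand scale {normalized.to_numpy().max():.0f} max")

log2 = log2_transform(data.metabolites)
imputed = impute_half_minimum(log2)
centered = median_center(imputed)
print(f"imputation constant: {imputed.imputation_value:.7f} "
      f"(= half of min observed log2 abundance)")
print(f"after centering, max |per-sample median| = "
      f"{np.abs(np.median(centered.values.to_numpy(), axis=1)).max():.1e}")

univariate = filter_metabolites_for_univariate(data.metabolites, data.metadata, params)
print(f"univariate observation filter keeps "
      f"{len(univariate.metabolite_ids)}/{len(data.metabolites.metabolite_ids)} metabolites")
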