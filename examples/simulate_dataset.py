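"""Generate a coupled synthetic soil dataset and inspect its ground truth.

Builds the default study layout -- 41 samples split 10 (Dry-Wet) /
18 (Wet-Dry) / 13 (Saturation), 125 GC-MS metabolites with 10%
missingness, and a sparse OTU table in which a few "target" OTUs have
their presence driven by "driver" metabolites -- then prints the shapes
and the planted links. The printed slopes are log-odds per standard
deviation of the driver's log2 abundance.
"""

from metabotu import SimulationConfig, generate_dataset

config = SimulationConfig(n_otus=100, seed=7)
data = generate_dataset(config)

print(f"samples:     {len(data.metadata)}")
print(data.metadata.treatments.value_counts().to_string())
print(f"metabolites: {data.metabolites.values.shape[1]} "
      f"({data.metabolites.values.isna().to_numpy().mean():.0%} missing)")
print(f"OTUs:        {data.otus.counts.shape[1]} "
      f"({(data.otus.counts.to_numpy() == 0).mean():.0%} zeros)")
print("\nplanted driver -> OTU links (slope = log-odds per SD):")
for otu, pairs in data.truth.driver_map.items():
    for met, slope in pairs:
        print(f"  {met} -> {otu}  slope {slope:+.1f}")
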