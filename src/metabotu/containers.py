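"""In-memory containers for the two omics blocks and the sample metadata.

The pipeline couples a 16S OTU count table (samples x OTUs, non-negative
integers) with a GC-MS metabolite abundance matrix (samples x metabolites,
positive reals with missing entries) through shared sample identifiers.
Both blocks are stored as pandas DataFrames with samples in rows; the
metabolite matrix additionally carries a transform-state marker so that
scale-dependent operations (log2, centering, imputation) can enforce their
preconditions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: Moisture treatment labels: Dry-Wet (dried then rewetted), Wet-Dry
#: (saturated then dried) and continuous saturation.
TREATMENTS = ("D-W", "W-D", "Sat")

#: Legal transform states for a metabolite matrix, in order.
SCALES = ("raw", "log2", "log2-centered")


class MetabotuError(Exception):
    """Base class for all package errors."""


class ConfigError(MetabotuError):
    """An invalid configuration or parameter value."""


class AlignmentError(MetabotuError):
    """Sample identifiers disagree between coupled tables."""


class ScaleError(MetabotuError):
    """An operation was applied to a matrix in the wrong transform state."""


class InsufficientDataError(MetabotuError):
    """Too few samples, classes or treatments for the requested analysis."""


class ParseError(MetabotuError):
    """A file could not be parsed into a valid table."""


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample design information: treatment, soil core, technical replicate.

    Samples are nested in soil cores (a physical soil column), and cores in
    treatments; several technical replicates may be measured per core.
    """

    frame: pd.DataFrame  # index: sample_id; columns: treatment, core, replicate

    def __post_init__(self) -> None:
        required = {"treatment", "core", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ConfigError(f"metadata missing columns: {sorted(missing)}")
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ConfigError(f"duplicate sample IDs: {dupes}")
        unknown = set(self.frame["treatment"]) - set(TREATMENTS)
        if unknown:
            raise ConfigError(
                f"unknown treatment labels {sorted(unknown)}; expected {TREATMENTS}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def treatments(self) -> pd.Series:
        return self.frame["treatment"]

    def samples_for(self, treatment: str) -> list[str]:
        if treatment not in TREATMENTS:
            raise ConfigError(f"unknown treatment {treatment!r}")
        return list(self.frame.index[self.frame["treatment"] == treatment])

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class OtuCountTable:
    """Samples x OTUs non-negative integer counts plus taxonomy lineages."""

    counts: pd.DataFrame  # index: sample_id, columns: otu_id, dtype int
    taxonomy: pd.Series = None  # otu_id -> lineage string

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ConfigError("duplicate sample or OTU IDs in count table")
        values = self.counts.to_numpy()
        if values.size and (not np.issubdtype(values.dtype, np.integer)):
            raise ConfigError("OTU counts must be integers")
        if values.size and (values < 0).any():
            raise ConfigError("OTU counts must be non-negative")
        if self.taxonomy is None:
            object.__setattr__(
                self, "taxonomy", pd.Series("", index=self.counts.columns, dtype=object)
            )
        else:
            missing = set(self.counts.columns) - set(self.taxonomy.index)
            if missing:
                raise ConfigError(f"taxonomy missing for OTUs: {sorted(missing)[:5]}")
            object.__setattr__(self, "taxonomy", self.taxonomy.loc[self.counts.columns])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def presence(self) -> pd.DataFrame:
        """Binary presence/absence view: present iff count > 0."""
        return self.counts > 0

    def subset_otus(self, otu_ids) -> "OtuCountTable":
        return OtuCountTable(self.counts.loc[:, list(otu_ids)], self.taxonomy.loc[list(otu_ids)])

    def subset_samples(self, sample_ids) -> "OtuCountTable":
        return OtuCountTable(self.counts.loc[list(sample_ids)], self.taxonomy)


@dataclass(frozen=True)
class MetaboliteMatrix:
    """Samples x metabolites real abundances with explicit missingness.

    ``scale`` tracks the transform state (raw -> log2 -> log2-centered);
    ``imputation_value`` is recorded once half-minimum imputation has run.
    Missing entries are NaN.
    """

    values: pd.DataFrame  # index: sample_id, columns: metabolite_id, float
    scale: str = "raw"
    imputation_value: float | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ScaleError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ConfigError("duplicate sample or metabolite IDs")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    def observed_mask(self) -> pd.DataFrame:
        return self.values.notna()

    def with_values(self, values: pd.DataFrame, **kwargs) -> "MetaboliteMatrix":
        out = replace(self, values=values)
        return replace(out, **kwargs) if kwargs else out


def check_aligned(meta: SampleMetadata, *tables) -> None:
    """Raise AlignmentError unless every table shares metadata's sample IDs in order."""
    ref = list(meta.frame.index)
    for t in tables:
        ids = t.sample_ids if hasattr(t, "sample_ids") else list(t.index)
        if ids != ref:
            extra = sorted(set(ids) - set(ref))
            absent = sorted(set(ref) - set(ids))
            raise AlignmentError(
                f"sample IDs misaligned: unexpected={extra[:5]} missing={absent[:5]}"
                f" (or identical sets in a different order)"
            )
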