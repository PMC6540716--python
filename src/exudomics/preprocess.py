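"""Feature-table I/O, blank and singleton filtering, and binarization.

All community statistics in this package run on a presence/absence matrix:
compound number, not intensity, is the analysis currency.  The two filters
applied before binarization remove procedural artefacts (features occurring
in at least half of the water controls) and features observed only once
across all exudate samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "PresenceAbsenceMatrix",
    "SchemaError",
    "DataError",
    "read_feature_table",
    "filter_blank_features",
    "filter_singletons",
    "to_presence_absence",
]

REQUIRED_METADATA = ("species", "plot", "sample_type")


class SchemaError(ValueError):
    """Input files do not conform to the expected schema."""


class DataError(ValueError):
    """Input values are invalid (e.g. negative intensities)."""


@dataclass(frozen=True)
class FeatureTable:
    """Samples x features intensity matrix joined to sample metadata.

    ``intensities`` rows are samples (exudates and blanks), columns are
    aligned LC-MS features; ``metadata`` must cover every sample and carry
    at least species, plot and sample_type ('exudate' or 'blank').
    ``provenance`` records every filter applied, with its parameters.
    """

    intensities: pd.DataFrame
    metadata: pd.DataFrame
    provenance: tuple[dict, ...] = ()

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_METADATA if c not in self.metadata]
        if missing:
            raise SchemaError(f"metadata lacks required columns: {missing}")
        unmatched = self.intensities.index.difference(self.metadata.index)
        if len(unmatched):
            raise SchemaError(
                "samples missing from metadata: "
                + ", ".join(map(str, unmatched[:10]))
            )
        if not self.intensities.columns.is_unique:
            raise SchemaError("feature ids are not unique")
        vals = self.intensities.to_numpy()
        if vals.size and np.nanmin(vals) < 0:
            raise DataError("negative intensities found")

    @property
    def is_blank(self) -> pd.Series:
        return (
            self.metadata.loc[self.intensities.index, "sample_type"]
            == "blank"
        )

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def drop_blanks(self) -> "FeatureTable":
        keep = self.intensities.index[~self.is_blank.to_numpy()]
        return replace(
            self,
            intensities=self.intensities.loc[keep],
            metadata=self.metadata.loc[keep],
            provenance=self.provenance + ({"step": "drop_blanks"},),
        )


@dataclass(frozen=True)
class PresenceAbsenceMatrix:
    """Binary samples x features matrix (exudate samples only)."""

    values: pd.DataFrame
    metadata: pd.DataFrame
    provenance: tuple[dict, ...] = ()

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise DataError("presence/absence entries must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_feature_table(
    matrix_path: str | Path, metadata_path: str | Path
) -> FeatureTable:
    """Read an intensity TSV (samples x features) and its sample metadata.

    Sample ids must match between the two files; mismatches are reported by
    name.
    """
    intensities = pd.read_csv(matrix_path, sep="\t", index_col=0)
    metadata = pd.read_csv(
        metadata_path, sep="\t", index_col=0, keep_default_na=False
    )
    intensities = intensities.astype(float)
    intensities.index.name = None
    intensities.columns.name = None
    metadata.index.name = None
    missing = intensities.index.difference(metadata.index)
    if len(missing):
        raise SchemaError(
            "metadata is missing sample ids: " + ", ".join(map(str, missing))
        )
    return FeatureTable(
        intensities=intensities, metadata=metadata.loc[intensities.index]
    )


def filter_blank_features(
    table: FeatureTable,
    blank_fraction: float = 0.5,
    presence_threshold: float = 0.0,
    per_region: bool = False,
) -> FeatureTable:
    """Drop features present in at least ``blank_fraction`` of water controls.

    The boundary is inclusive: a feature occurring in exactly half of the
    blanks is removed.  Blank samples themselves are retained until
    explicitly dropped.  ``per_region=True`` evaluates the criterion within
    each region separately and removes a feature failing it anywhere;
    pooled blanks are the default.
    """
    if not 0.0 < blank_fraction <= 1.0:
        raise DataError("blank_fraction must be in (0, 1]")
    blanks = table.is_blank.to_numpy()
    if not blanks.any():
        raise DataError("no blank samples present; blank filter inapplicable")
    present = table.intensities.to_numpy() > presence_threshold

    def frac(mask: np.ndarray) -> np.ndarray:
        return present[mask].sum(axis=0) / mask.sum()

    if per_region:
        regions = table.metadata.loc[
            table.intensities.index, "region"
        ].to_numpy()
        drop = np.zeros(table.n_features, dtype=bool)
        for reg in np.unique(regions[blanks]):
            m = blanks & (regions == reg)
            drop |= frac(m) >= blank_fraction
    else:
        drop = frac(blanks) >= blank_fraction
    kept = table.intensities.columns[~drop]
    prov = {
        "step": "filter_blank_features",
        "blank_fraction": blank_fraction,
        "presence_threshold": presence_threshold,
        "per_region": per_region,
        "n_removed": int(drop.sum()),
    }
    return replace(
        table,
        intensities=table.intensities[kept],
        provenance=table.provenance + (prov,),
    )


def filter_singletons(
    table: FeatureTable,
    presence_threshold: float = 0.0,
    count_blanks: bool = False,
) -> FeatureTable:
    """Drop features observed at most once.

    Occurrence is counted over exudate samples by default (blanks are a
    different population); ``count_blanks=True`` pools all samples.
    Idempotent: a second application removes nothing.
    """
    present = table.intensities.to_numpy() > presence_threshold
    if not count_blanks:
        present = present[~table.is_blank.to_numpy()]
    counts = present.sum(axis=0)
    kept = table.intensities.columns[counts > 1]
    prov = {
        "step": "filter_singletons",
        "presence_threshold": presence_threshold,
        "count_blanks": count_blanks,
        "n_removed": int((counts <= 1).sum()),
    }
    return replace(
        table,
        intensities=table.intensities[kept],
        provenance=table.provenance + (prov,),
    )


def to_presence_absence(
    table: FeatureTable, presence_threshold: float = 0.0
) -> PresenceAbsenceMatrix:
    """Binarize: entry 1 iff intensity strictly exceeds the threshold.

    Blank samples are excluded from the output matrix.
    """
    exu = ~table.is_blank.to_numpy()
    sub = table.intensities.loc[table.intensities.index[exu]]
    binary = (sub > presence_threshold).astype(np.int8)
    prov = table.provenance + (
        {"step": "to_presence_absence",
         "presence_threshold": presence_threshold},
    )
    return PresenceAbsenceMatrix(
        values=binary,
        metadata=table.metadata.loc[binary.index],
        provenance=prov,
    )
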