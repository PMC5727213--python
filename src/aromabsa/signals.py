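"""Feature x sample signal matrices from bulk hybridisations.

The genotyping platform is a subtracted-diversity genomic microarray (287
anonymous cloned fragments in the original panel).  Each extreme bulk is
hybridised with two biological replicates and six technical replicates,
giving 12 data points per feature per bulk.  The quantitative signal is the
feature's signal-to-noise ratio (SNR).  This module loads long-format SNR
tables, optionally applies per-sample median scaling, and reduces the
matrix to per-bulk group statistics (mean, SD, variance, n per feature)
that drive the downstream discriminant and univariate filters.

Long-format TSV columns: ``feature, bulk, bio_rep, tech_rep, snr``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataFormatError, DegenerateInputError

SIGNAL_COLUMNS = ("feature", "bulk", "bio_rep", "tech_rep", "snr")
BULK_LABELS = ("H", "L")
#: Complete replicate design: 2 biological x 6 technical replicates.
POINTS_PER_BULK = 12

SAMPLE_COLUMNS = ["bulk", "bio_rep", "tech_rep"]


@dataclass
class SignalMatrix:
    """Validated long-format SNR matrix with replicate metadata.

    ``complete`` records whether every feature carries the full 12-point
    design in both bulks.
    """

    data: pd.DataFrame
    complete: bool = True

    @property
    def features(self) -> list[str]:
        return sorted(self.data["feature"].unique())

    @property
    def n_samples(self) -> int:
        return len(self.data[SAMPLE_COLUMNS].drop_duplicates())

    def to_wide(self) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
        """Samples x features matrix plus bulk labels and biological reps.

        Sample order is fixed (bulk, bio_rep, tech_rep) so downstream
        results do not depend on input row order.
        """
        wide = self.data.pivot_table(
            index=SAMPLE_COLUMNS, columns="feature", values="snr",
        ).sort_index()
        labels = wide.index.get_level_values("bulk").to_series(index=wide.index)
        bio = wide.index.get_level_values("bio_rep").to_series(index=wide.index)
        return wide, labels, bio

    def to_tsv(self, path) -> None:
        out = self.data.sort_values(
            ["feature", *SAMPLE_COLUMNS]).reset_index(drop=True)
        out.to_csv(path, sep="\t", index=False)


def validate_signal_frame(data: pd.DataFrame) -> SignalMatrix:
    """Validate a long-format frame and wrap it as a :class:`SignalMatrix`.

    Duplicate (feature, sample) cells and non-numeric or negative SNR raise
    :class:`DataFormatError`; an incomplete replicate design only triggers a
    warning and marks the matrix ``complete=False``.
    """
    missing = set(SIGNAL_COLUMNS) - set(data.columns)
    if missing:
        raise DataFormatError(f"signal table missing columns: {sorted(missing)}")
    snr = pd.to_numeric(data["snr"], errors="coerce")
    if snr.isna().any():
        bad = data.loc[snr.isna()].iloc[0]
        raise DataFormatError(
            f"non-numeric SNR for feature {bad['feature']!r}"
        )
    data = data.assign(snr=snr.astype(float))
    if (data["snr"] < 0).any():
        raise DataFormatError("negative SNR")
    unknown = set(data["bulk"]) - set(BULK_LABELS)
    if unknown:
        raise DataFormatError(f"unknown bulk labels: {sorted(unknown)}")
    dup = data.duplicated(["feature", *SAMPLE_COLUMNS])
    if dup.any():
        row = data[dup].iloc[0]
        raise DataFormatError(
            f"duplicate cell for feature {row['feature']!r}, sample "
            f"({row['bulk']}, bio {row['bio_rep']}, tech {row['tech_rep']})"
        )
    counts = data.groupby(["feature", "bulk"]).size()
    complete = bool((counts == POINTS_PER_BULK).all()) and set(
        counts.index.get_level_values("bulk")) == set(BULK_LABELS)
    if not complete:
        warnings.warn(
            "incomplete replicate design: expected "
            f"{POINTS_PER_BULK} data points per feature per bulk",
            stacklevel=2,
        )
    return SignalMatrix(data=data.reset_index(drop=True), complete=complete)


def load_signal_matrix(path) -> SignalMatrix:
    """Read a long-format SNR TSV and validate it."""
    data = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return validate_signal_frame(data)


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def normalize(matrix: SignalMatrix, method: str = "none") -> SignalMatrix:
    """Normalise SNR values across samples.

    ``none`` is the identity (the default: printed summary statistics are
    already normalised upstream).  ``median`` divides each sample's values
    by that sample's median and multiplies by the global median, so every
    sample ends up with the same median.  A zero sample median raises
    :class:`DegenerateInputError`.
    """
    if method == "none":
        return SignalMatrix(data=matrix.data.copy(), complete=matrix.complete)
    if method != "median":
        raise ValueError(f"unknown normalisation method {method!r}")
    data = matrix.data.copy()
    global_median = float(data["snr"].median())
    sample_medians = data.groupby(SAMPLE_COLUMNS)["snr"].transform("median")
    if (sample_medians == 0).any():
        raise DegenerateInputError("sample with zero median SNR")
    data["snr"] = data["snr"] / sample_medians * global_median
    return SignalMatrix(data=data, complete=matrix.complete)


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def group_statistics(matrix: SignalMatrix) -> pd.DataFrame:
    """Per-feature mean/SD/variance/n for each bulk (replicates pooled).

    Both biological replicates are pooled into a single group per bulk, so a
    complete design yields n = 12 per bulk.  Variances use the sample (n-1)
    denominator.  Any (feature, bulk) group with fewer than 2 data points
    raises :class:`DegenerateInputError`.
    """
    counts = matrix.data.groupby(["feature", "bulk"]).size()
    if (counts < 2).any():
        feat, bulk = counts[counts < 2].index[0]
        raise DegenerateInputError(
            f"bulk {bulk} of feature {feat!r} has fewer than 2 data points"
        )
    agg = matrix.data.groupby(["feature", "bulk"])["snr"].agg(
        ["mean", "std", "var", "count"])
    out = agg.unstack("bulk")
    frame = pd.DataFrame({
        "feature": out.index,
        "mean_h": out[("mean", "H")], "sd_h": out[("std", "H")],
        "var_h": out[("var", "H")], "n_h": out[("count", "H")].astype(int),
        "mean_l": out[("mean", "L")], "sd_l": out[("std", "L")],
        "var_l": out[("var", "L")], "n_l": out[("count", "L")].astype(int),
    }).reset_index(drop=True)
    return frame.sort_values("feature").reset_index(drop=True)
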