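"""GC-MS aroma quantitation: peak-area normalisation and compound filtering.

Aroma compounds are quantified from headspace GC-MS peak tables by area
normalisation: the relative composition of compound *i* in one chromatogram
is ``C_i = A_i / A_t * 100`` where ``A_i`` is the compound's peak area and
``A_t`` the total peak area of the chromatogram.  Each fruit sample is run in
technical replicates (three in the original screen); a peak is only trusted
when its spectral library match quality exceeds a threshold and the compound
shows up in a minimum number of replicates.  Per-individual phenotypes are
the replicate means (with sample SDs), and compounds are carried into marker
discovery only when the population expresses them above a floor and the two
parents differ significantly.

Peak tables are long-format TSV with columns
``sample_id, replicate, compound, area, quality``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DataFormatError,
    DegenerateInputError,
    UndefinedStatisticError,
)

PEAK_COLUMNS = ("sample_id", "replicate", "compound", "area", "quality")

#: Spectral library match quality must be strictly greater than this.
DEFAULT_MIN_QUALITY = 80
#: A compound must appear in at least this many technical replicates.
DEFAULT_MIN_REPLICATES = 2
#: Compounds with an F1 population mean below this (%) are dropped.
DEFAULT_MEAN_FLOOR_PCT = 0.1


# ---------------------------------------------------------------------------
# Peak table I/O and validation
# ---------------------------------------------------------------------------

def validate_peak_table(peaks: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format peak table invariants and return it.

    Raises :class:`DataFormatError` on missing columns, negative areas,
    replicate indices below 1, qualities outside 0..100, or a compound
    listed twice within one chromatogram.
    """
    missing = set(PEAK_COLUMNS) - set(peaks.columns)
    if missing:
        raise DataFormatError(f"peak table missing columns: {sorted(missing)}")
    if (peaks["area"] < 0).any():
        raise DataFormatError("negative peak area")
    if (peaks["replicate"] < 1).any():
        raise DataFormatError("replicate index below 1")
    if ((peaks["quality"] < 0) | (peaks["quality"] > 100)).any():
        raise DataFormatError("match quality outside 0..100")
    dup = peaks.duplicated(["sample_id", "replicate", "compound"])
    if dup.any():
        row = peaks[dup].iloc[0]
        raise DataFormatError(
            f"duplicate compound {row['compound']!r} in chromatogram "
            f"({row['sample_id']!r}, replicate {row['replicate']})"
        )
    return peaks


def read_peak_table(path) -> pd.DataFrame:
    """Read and validate a peak table TSV (header row required)."""
    peaks = pd.read_csv(path, sep="\t")
    return validate_peak_table(peaks)


# ---------------------------------------------------------------------------
# Area normalisation
# ---------------------------------------------------------------------------

def relative_composition(
    peaks: pd.DataFrame,
    compounds: Sequence[str] | None = None,
) -> pd.Series:
    """Relative composition (%) of one chromatogram by area normalisation.

    ``peaks`` holds the rows of a single (sample, replicate).  Compounds in
    ``compounds`` but absent from the table get 0 %.  The result always sums
    to 100 % (to numerical precision).

    Raises :class:`DegenerateInputError` when the total peak area is zero.
    """
    total = float(peaks["area"].sum())
    if not total > 0:
        raise DegenerateInputError("all-zero total peak area")
    comp = peaks.set_index("compound")["area"] / total * 100.0
    if compounds is not None:
        comp = comp.reindex(compounds, fill_value=0.0)
    comp.name = "pct"
    return comp


def compositions(peaks: pd.DataFrame,
                 compounds: Sequence[str] | None = None) -> pd.DataFrame:
    """Apply :func:`relative_composition` per chromatogram.

    Returns a long DataFrame (sample_id, replicate, compound, pct).
    """
    universe = (
        list(compounds) if compounds is not None
        else sorted(peaks["compound"].unique())
    )
    out = []
    for (sample, rep), group in peaks.groupby(["sample_id", "replicate"],
                                              sort=True):
        comp = relative_composition(group, universe)
        out.append(pd.DataFrame({
            "sample_id": sample, "replicate": rep,
            "compound": comp.index, "pct": comp.to_numpy(),
        }))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Replicate / quality filtering
# ---------------------------------------------------------------------------

def quality_replicate_filter(
    peaks: pd.DataFrame,
    min_quality: int = DEFAULT_MIN_QUALITY,
    min_replicates: int = DEFAULT_MIN_REPLICATES,
) -> pd.DataFrame:
    """Keep peaks confirmed across technical replicates at high match quality.

    A compound is retained for a sample only if it appears in at least
    ``min_replicates`` replicates with quality strictly greater than
    ``min_quality``; sub-threshold rows of retained compounds are also
    dropped.  Raises :class:`ConfigurationError` if ``min_replicates``
    exceeds the number of replicates run for some sample.
    """
    if peaks.empty:
        return peaks.copy()
    reps_per_sample = peaks.groupby("sample_id")["replicate"].nunique()
    if (reps_per_sample < min_replicates).any():
        short = reps_per_sample[reps_per_sample < min_replicates].index[0]
        raise ConfigurationError(
            f"min_replicates={min_replicates} exceeds the "
            f"{reps_per_sample[short]} replicate(s) run for sample {short!r}"
        )
    good = peaks[peaks["quality"] > min_quality]
    support = good.groupby(["sample_id", "compound"])["replicate"].nunique()
    keep = support[support >= min_replicates].index
    mask = pd.MultiIndex.from_frame(good[["sample_id", "compound"]]).isin(keep)
    return good[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Phenotype table
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Individuals x compounds relative compositions (%).

    ``means`` holds per-cell replicate means, ``sds`` the sample SDs (n-1
    denominator; 0 where only one replicate was available) and ``counts``
    the replicate count per cell.  ``single_replicate`` flags cells whose SD
    is undefined because only one replicate contributed.
    """

    means: pd.DataFrame
    sds: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if ((self.means < 0) | (self.means > 100)).any().any():
            raise DataFormatError("phenotype values outside [0, 100] %")
        if (self.sds < 0).any().any():
            raise DataFormatError("negative SD")
        if (self.counts < 1).any().any():
            raise DataFormatError("replicate count below 1")

    @property
    def individuals(self) -> list[str]:
        return list(self.means.index)

    @property
    def compounds(self) -> list[str]:
        return list(self.means.columns)

    @property
    def single_replicate(self) -> pd.DataFrame:
        return self.counts == 1

    def values_for(self, compound: str) -> pd.Series:
        if compound not in self.means.columns:
            raise KeyError(f"compound {compound!r} not in phenotype table")
        return self.means[compound]

    def to_tsv(self, path) -> None:
        """Write the wide mean matrix (first column = individual id)."""
        out = self.means.round(10)
        out.index.name = "individual"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeTable":
        """Read a wide mean matrix; SDs unknown -> 0, counts -> 1."""
        means = pd.read_csv(path, sep="\t", index_col=0,
                            float_precision="round_trip")
        zero = pd.DataFrame(0.0, index=means.index, columns=means.columns)
        one = pd.DataFrame(1, index=means.index, columns=means.columns)
        return cls(means=means, sds=zero, counts=one)


def aggregate_replicates(comp_long: pd.DataFrame) -> PhenotypeTable:
    """Aggregate per-replicate composition vectors into a phenotype table.

    ``comp_long`` is the long output of :func:`compositions` (any number of
    individuals).  Per (individual, compound): mean, sample SD (n-1; 0 when
    a single replicate) and replicate count.  A compound missing from one
    replicate of an individual counts as 0 % in that replicate.
    """
    wide = comp_long.pivot_table(
        index=["sample_id", "replicate"], columns="compound", values="pct",
        fill_value=0.0,
    )
    grouped = wide.groupby(level="sample_id")
    means = grouped.mean()
    sds = grouped.std(ddof=1).fillna(0.0)
    counts = grouped.count()
    means.index.name = sds.index.name = counts.index.name = "individual"
    return PhenotypeTable(means=means, sds=sds, counts=counts)


def profile_peaks(
    peaks: pd.DataFrame,
    min_quality: int = DEFAULT_MIN_QUALITY,
    min_replicates: int = DEFAULT_MIN_REPLICATES,
) -> PhenotypeTable:
    """Full quantitation pipeline: filter peaks, normalise, aggregate."""
    kept = quality_replicate_filter(peaks, min_quality, min_replicates)
    if kept.empty:
        raise DegenerateInputError("no peaks survive the quality filter")
    return aggregate_replicates(compositions(kept))


# ---------------------------------------------------------------------------
# Descriptive statistics and compound selection
# ---------------------------------------------------------------------------

@dataclass
class CompoundSummary:
    """Descriptive and parental-contrast statistics for one compound."""

    compound: str
    f1_mean: float
    f1_min: float
    f1_max: float
    parent1_mean: float
    parent1_sd: float
    parent2_mean: float
    parent2_sd: float
    t: float | None
    df: float | None
    p: float | None
    significance: str  # "ns" | "*" | "**" | "undefined"
    transgressive: bool


def significance_class(p: float | None) -> str:
    """Star classification of a p-value (thresholds 0.05 and 0.01)."""
    if p is None or math.isnan(p):
        return "undefined"
    if p > 0.05:
        return "ns"
    if p > 0.01:
        return "*"
    return "**"


def summarize_compound(
    pheno: PhenotypeTable,
    parents: PhenotypeTable,
    compound: str,
    variant: str = "welch",
) -> CompoundSummary:
    """Descriptive F1 statistics plus the parental two-sample contrast.

    ``parents`` is a two-individual phenotype table whose per-cell SDs and
    replicate counts feed the t-test (delegated to
    :func:`aromabsa.filters.two_sample_t`).  The transgressive flag is true
    when the F1 range exceeds the interval spanned by the parental means;
    progeny in which the compound is undetectable (exactly 0 %) count as
    "low/undetectable" rather than low-side transgressive, since absence of
    a volatile is not a phenotype beyond the parental range in kind.
    """
    from .filters import two_sample_t  # local import: avoid module cycle

    if compound not in pheno.compounds:
        raise KeyError(f"compound {compound!r} not in phenotype table")
    if len(parents.individuals) != 2:
        raise DataFormatError("parents table must hold exactly 2 individuals")
    values = pheno.values_for(compound)
    if compound in parents.compounds:
        pmeans = parents.means[compound]
        psds = parents.sds[compound]
        pns = parents.counts[compound]
    else:  # compound never detected in either parent
        pmeans = pd.Series(0.0, index=parents.individuals)
        psds = pd.Series(0.0, index=parents.individuals)
        pns = pd.Series(1, index=parents.individuals)
    p1, p2 = parents.individuals
    t = df = p = None
    if pns[p1] >= 2 and pns[p2] >= 2:
        try:
            res = two_sample_t(pmeans[p1], psds[p1], int(pns[p1]),
                               pmeans[p2], psds[p2], int(pns[p2]),
                               variant=variant)
            t, df, p = res.t, res.df, res.p
        except UndefinedStatisticError:
            pass  # identical constant parents: contrast undefined
    lo, hi = min(pmeans[p1], pmeans[p2]), max(pmeans[p1], pmeans[p2])
    f1_min = float(values.min())
    transgressive = bool(values.max() > hi or 0.0 < f1_min < lo)
    return CompoundSummary(
        compound=compound,
        f1_mean=float(values.mean()),
        f1_min=float(values.min()),
        f1_max=float(values.max()),
        parent1_mean=float(pmeans[p1]), parent1_sd=float(psds[p1]),
        parent2_mean=float(pmeans[p2]), parent2_sd=float(psds[p2]),
        t=t, df=df, p=p,
        significance=significance_class(p),
        transgressive=transgressive,
    )


def select_target_compounds(
    summaries: Iterable[CompoundSummary],
    mean_floor_pct: float = DEFAULT_MEAN_FLOOR_PCT,
    alpha: float = 0.05,
) -> list[str]:
    """Compounds worth marker discovery, sorted by F1 mean descending.

    Excludes compounds whose population mean falls below ``mean_floor_pct``
    and compounds whose parental contrast is undefined (undetected in both
    parents) or not significant at ``alpha``.
    """
    kept = [
        s for s in summaries
        if s.f1_mean >= mean_floor_pct
        and s.p is not None
        and s.p < alpha
    ]
    kept.sort(key=lambda s: (-s.f1_mean, s.compound))
    return [s.compound for s in kept]


# ---------------------------------------------------------------------------
# Frequency distributions
# ---------------------------------------------------------------------------

def frequency_histogram(
    values: Sequence[float],
    bin_width: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Half-open histogram of relative compositions starting at 0 %.

    Bins are ``[k*w, (k+1)*w)`` so every value lands in exactly one bin and
    the counts always sum to ``len(values)``.  Returns (edges, counts) with
    ``len(edges) == len(counts) + 1``.
    """
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be positive")
    arr = np.asarray(values, dtype=float)
    if arr.size and ((arr < 0) | (arr > 100)).any():
        raise DataFormatError("values outside [0, 100] %")
    idx = np.floor(arr / bin_width).astype(int) if arr.size else np.array([], int)
    nbins = int(idx.max()) + 1 if arr.size else 1
    counts = np.bincount(idx, minlength=nbins)
    edges = np.arange(nbins + 1) * bin_width
    return edges, counts
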