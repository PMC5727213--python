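"""Construction of extreme-phenotype DNA bulks for bulked segregant analysis.

For each target compound, F1 individuals at the phenotypic extremes are
pooled into a high ('H') bulk and a low/undetectable ('L') bulk; individuals
in the middle of the distribution are left out.  The default rule cuts at
symmetric quantiles (q and 1-q of the compound's distribution); ties at a
cut value are all included, and zero-valued (undetectable) individuals are
always eligible for the L bulk.  Absolute thresholds are available for
hand-curated designs.  In the original screen bulk sizes ranged from 3 to
27 plants per compound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import BulkSizeError, ConfigurationError
from .gcms import PhenotypeTable

DEFAULT_QUANTILE = 0.2
MIN_BULK_SIZE = 3
#: Published range of bulk sizes; enforced only by strict bulk reports.
STUDY_BULK_RANGE = (3, 27)


@dataclass(frozen=True)
class BulkDesign:
    """Per-compound membership of the high and low bulks."""

    compound: str
    high: tuple[str, ...]
    low: tuple[str, ...]
    rule: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.high) & set(self.low):
            raise ConfigurationError(
                f"bulks overlap for {self.compound!r}: "
                f"{sorted(set(self.high) & set(self.low))}"
            )

    @property
    def sizes(self) -> tuple[int, int]:
        return len(self.high), len(self.low)

    def to_dict(self) -> dict:
        return {
            "compound": self.compound,
            "high": list(self.high),
            "low": list(self.low),
            "rule": dict(self.rule),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, obj: Mapping) -> "BulkDesign":
        return cls(
            compound=obj["compound"],
            high=tuple(obj["high"]),
            low=tuple(obj["low"]),
            rule=dict(obj.get("rule", {})),
        )

    @classmethod
    def from_json(cls, path) -> "BulkDesign":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def assign_extremes(
    pheno: PhenotypeTable,
    compound: str,
    q: float | None = DEFAULT_QUANTILE,
    thresholds: tuple[float, float] | None = None,
    min_bulk_size: int = MIN_BULK_SIZE,
) -> BulkDesign:
    """Assign individuals with extreme phenotypes to the H and L bulks.

    With the quantile rule (default, ``q``), the low cut is the q-quantile
    and the high cut the (1-q)-quantile of the compound's values:
    L = values <= low cut (exact zeros always qualify), H = values >= high
    cut.  With ``thresholds=(lo, hi)`` the cuts are absolute.  Membership is
    independent of input order; ties at a cut are all included.

    Raises :class:`BulkSizeError` when a bulk ends up smaller than
    ``min_bulk_size`` or the cuts cannot separate the distribution (for
    example all values identical).
    """
    values = pheno.values_for(compound)
    if thresholds is not None:
        lo_cut, hi_cut = thresholds
        rule: dict[str, object] = {"method": "absolute",
                                   "lo": lo_cut, "hi": hi_cut}
    else:
        if not 0 < q < 0.5:
            raise ConfigurationError("quantile q must be in (0, 0.5)")
        lo_cut = float(np.quantile(values, q))
        hi_cut = float(np.quantile(values, 1 - q))
        rule = {"method": "quantile", "q": q}
    if not lo_cut < hi_cut:
        raise BulkSizeError(
            f"no phenotypic extremes for {compound!r}: low cut {lo_cut:g} "
            f"does not fall below high cut {hi_cut:g}"
        )
    low = values.index[(values <= lo_cut) | (values == 0.0)]
    high = values.index[values >= hi_cut]
    design = BulkDesign(
        compound=compound,
        high=tuple(sorted(high)),
        low=tuple(sorted(low)),
        rule=rule,
    )
    for label, size in zip("HL", design.sizes):
        if size < min_bulk_size:
            raise BulkSizeError(
                f"{label} bulk for {compound!r} has {size} member(s); "
                f"minimum is {min_bulk_size}"
            )
    return design


def bulk_report(
    designs: Iterable[BulkDesign],
    strict: bool = False,
) -> pd.DataFrame:
    """Summary table of bulk designs: sizes, membership, rule.

    In strict mode an extra ``violation`` column flags any bulk whose size
    falls outside the published 3-27 range.
    """
    rows = []
    for d in designs:
        row = {
            "compound": d.compound,
            "n_high": len(d.high),
            "n_low": len(d.low),
            "high": ";".join(d.high),
            "low": ";".join(d.low),
            "rule": json.dumps(dict(d.rule), sort_keys=True),
        }
        if strict:
            lo, hi = STUDY_BULK_RANGE
            row["violation"] = not (
                lo <= len(d.high) <= hi and lo <= len(d.low) <= hi
            )
        rows.append(row)
    columns = ["compound", "n_high", "n_low", "high", "low", "rule"]
    if strict:
        columns.append("violation")
    return pd.DataFrame(rows, columns=columns)
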