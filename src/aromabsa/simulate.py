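"""Synthetic phenotype and array-signal generation with known ground truth.

The generator emulates the study conditions of the bulked-segregant aroma
screen: 50 F1 individuals phenotyped for eight aroma compounds whose
distributions are right-skewed and zero-inflated with transgressive
segregation, and a 287-feature array hybridised per compound with 2 bulks x
2 biological x 6 technical replicates.  Compound values follow a
zero-inflated polygenic model — ``Bernoulli(1 - pi) * (sum of locus effects
+ Gamma noise)``, truncated to [0, 100] — with disomic inheritance from the
two parental genotypes.  Array SNR is multiplicative log-normal noise
around a per-feature baseline; planted marker features receive a bulk
effect calibrated so the bulk-mean gap equals ``delta`` within-bulk SDs,
in either direction (high-bulk-up or low-bulk-up, both of which occurred
in the real screen).

Every random draw comes from a stream derived from the master seed plus a
fixed label, so adding a new consumer never perturbs existing draws and a
fixed config reproduces byte-identical fixtures.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bulks import BulkDesign, assign_extremes
from .errors import ConfigurationError
from .gcms import PhenotypeTable
from .signals import SignalMatrix, validate_signal_frame


def stream(seed: int, label: str) -> np.random.Generator:
    """Independent reproducible RNG stream for one consumer label."""
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


@dataclass(frozen=True)
class PlantedMarker:
    """A feature carrying a real bulk effect for one compound."""

    feature: str
    delta: float = 4.0  # bulk-mean gap in within-bulk SDs
    direction: str = "H"  # which bulk gets the stronger signal

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ConfigurationError("delta must be nonnegative")
        if self.direction not in ("H", "L"):
            raise ConfigurationError("direction must be 'H' or 'L'")


@dataclass(frozen=True)
class CompoundSpec:
    """Zero-inflated polygenic model for one compound.

    ``parent1``/``parent2`` give the parental dosage (0/1/2 copies of the
    high allele) at each locus; each F1 inherits one allele per parent per
    locus.  ``locus_effect_pct`` is the composition gain (%) per high
    allele copy.
    """

    name: str
    zero_inflation: float = 0.3
    gamma_shape: float = 1.5
    gamma_scale: float = 1.5
    locus_effect_pct: float = 6.0
    parent1: tuple[int, ...] = (1, 0)
    parent2: tuple[int, ...] = (0, 1)
    planted: tuple[PlantedMarker, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.zero_inflation <= 1:
            raise ConfigurationError("zero_inflation must lie in [0, 1]")
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ConfigurationError("gamma parameters must be positive")
        if len(self.parent1) != len(self.parent2):
            raise ConfigurationError("parents need dosages at every locus")
        if any(d not in (0, 1, 2) for d in self.parent1 + self.parent2):
            raise ConfigurationError("dosages must be 0, 1 or 2")

    @property
    def n_loci(self) -> int:
        return len(self.parent1)


def _default_compounds() -> tuple[CompoundSpec, ...]:
    """Eight compounds emulating the key aroma compounds of the screen.

    Zero-inflation, noise and locus effects are set so the population
    distributions come out right-skewed or zero-inflated with transgressive
    segregation; planted-marker counts per compound span 1-4, matching the
    published model sizes, with both effect directions represented.
    """
    def planted(ids: Sequence[int], directions: str) -> tuple[PlantedMarker, ...]:
        return tuple(
            PlantedMarker(feature=f"ft{i:03d}", delta=4.0, direction=d)
            for i, d in zip(ids, directions)
        )

    return (
        CompoundSpec("methyl_butanoate", 0.30, 1.2, 2.0, 8.0,
                     (1, 1), (0, 0), planted([1, 2], "LH")),
        CompoundSpec("ethyl_butanoate", 0.25, 1.5, 1.5, 5.0,
                     (1, 0), (0, 1), planted([3, 4, 5], "LHH")),
        CompoundSpec("methyl_hexanoate", 0.20, 1.5, 2.0, 12.0,
                     (2, 0), (0, 0), planted([6, 7], "HL")),
        CompoundSpec("ethyl_hexanoate", 0.30, 1.5, 1.5, 7.0,
                     (2, 0), (1, 0), planted([8, 9], "HH")),
        CompoundSpec("mesifuranne", 0.50, 1.2, 1.5, 9.0,
                     (0,), (1,), planted([10, 11, 12], "HHL")),
        CompoundSpec("linalool", 0.40, 1.5, 1.0, 6.0,
                     (1,), (1,), planted([13], "H")),
        CompoundSpec("e_nerolidol", 0.20, 1.5, 2.0, 10.0,
                     (1, 0), (2, 2), planted([14, 15, 16], "HLH")),
        CompoundSpec("gamma_dodecalactone", 0.50, 1.2, 1.0, 4.0,
                     (0,), (1,), planted([17, 18, 19, 20], "HHHL")),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults for the synthetic screen."""

    seed: int = 0
    n_individuals: int = 50
    compounds: tuple[CompoundSpec, ...] = field(
        default_factory=_default_compounds)
    n_features: int = 287
    baseline_log_mu: float = 5.0  # e^5 ~ 150 SNR, the printed magnitude
    baseline_log_sigma: float = 0.8
    tech_noise_sd: float = 0.25  # log-scale multiplicative technical noise
    bio_batch_sd: float = 0.0  # log-scale biological-replicate batch effect
    n_bio: int = 2
    n_tech: int = 6
    tech_rep_cv: float = 0.05  # GC-MS technical replicate CV
    n_pheno_reps: int = 3

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ConfigurationError("need at least one array feature")
        if min(self.tech_noise_sd, self.bio_batch_sd, self.tech_rep_cv) < 0:
            raise ConfigurationError("noise SDs must be nonnegative")
        if self.n_individuals < 2:
            raise ConfigurationError("need at least two individuals")
        planted = [m.feature for c in self.compounds for m in c.planted]
        universe = set(self.feature_ids)
        missing = set(planted) - universe
        if missing:
            raise ConfigurationError(
                f"planted features outside the universe: {sorted(missing)}")

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return tuple(f"ft{i:03d}" for i in range(1, self.n_features + 1))

    @property
    def individual_ids(self) -> tuple[str, ...]:
        return tuple(f"P{i:02d}" for i in range(1, self.n_individuals + 1))


@dataclass
class SimTruth:
    """Ground truth behind one simulated dataset."""

    planted: dict[str, tuple[PlantedMarker, ...]]
    genotypes: dict[str, pd.DataFrame]  # compound -> individuals x loci
    genetic_values: dict[str, pd.Series]  # noise-free compound values
    parents: PhenotypeTable | None = None

    def planted_features(self, compound: str | None = None) -> set[str]:
        if compound is not None:
            return {m.feature for m in self.planted.get(compound, ())}
        return {m.feature for ms in self.planted.values() for m in ms}


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _parent_value(spec: CompoundSpec, dosages: Sequence[int]) -> float:
    genetic = sum(d * spec.locus_effect_pct for d in dosages)
    if genetic == 0:
        return 0.0
    return min(100.0, genetic + spec.gamma_shape * spec.gamma_scale)


def simulate_phenotypes(config: SimConfig) -> tuple[PhenotypeTable, SimTruth]:
    """Simulate the F1 phenotype table (and parental profiles).

    Per individual and compound: dosage at each locus is the sum of one
    allele drawn from each parent (Bernoulli(dosage/2)); the compound value
    is ``Bernoulli(1 - pi) * (dosage . effect + Gamma(shape, scale))``
    truncated to [0, 100].  Technical replicates add a small multiplicative
    CV and are aggregated to mean/SD/count.  Parents' values derive from
    their own genotypes.
    """
    individuals = list(config.individual_ids)
    means, sds, counts = {}, {}, {}
    planted, genotypes, genetic_values = {}, {}, {}
    parent_rows = {}
    for spec in config.compounds:
        rng = stream(config.seed, f"phenotype:{spec.name}")
        p1 = np.asarray(spec.parent1, dtype=float) / 2.0
        p2 = np.asarray(spec.parent2, dtype=float) / 2.0
        n, L = config.n_individuals, spec.n_loci
        dosage = (
            (rng.random((n, L)) < p1).astype(int)
            + (rng.random((n, L)) < p2).astype(int)
        )
        genetic = dosage @ np.full(L, spec.locus_effect_pct)
        expressed = rng.random(n) >= spec.zero_inflation
        noise = rng.gamma(spec.gamma_shape, spec.gamma_scale, size=n)
        value = np.where(expressed, np.clip(genetic + noise, 0.0, 100.0), 0.0)
        reps = value[:, None] * (
            1.0 + rng.normal(0.0, config.tech_rep_cv,
                             size=(n, config.n_pheno_reps))
        )
        reps = np.clip(reps, 0.0, 100.0)
        means[spec.name] = reps.mean(axis=1)
        sds[spec.name] = reps.std(axis=1, ddof=1)
        counts[spec.name] = np.full(n, config.n_pheno_reps)
        planted[spec.name] = spec.planted
        genotypes[spec.name] = pd.DataFrame(
            dosage, index=individuals,
            columns=[f"locus{j + 1}" for j in range(L)])
        genetic_values[spec.name] = pd.Series(genetic, index=individuals)
        parent_rows[spec.name] = (
            _parent_value(spec, spec.parent1),
            _parent_value(spec, spec.parent2),
        )
    idx = pd.Index(individuals, name="individual")
    pheno = PhenotypeTable(
        means=pd.DataFrame(means, index=idx),
        sds=pd.DataFrame(sds, index=idx),
        counts=pd.DataFrame(counts, index=idx),
    )
    pidx = pd.Index(["parent1", "parent2"], name="individual")
    pmeans = pd.DataFrame(
        {c: list(v) for c, v in parent_rows.items()}, index=pidx)
    parents = PhenotypeTable(
        means=pmeans,
        sds=pmeans * 0.2,  # harvest-to-harvest spread ~20 % of the mean
        counts=pmeans * 0 + config.n_pheno_reps,
    )
    truth = SimTruth(planted=planted, genotypes=genotypes,
                     genetic_values=genetic_values, parents=parents)
    return pheno, truth


# ---------------------------------------------------------------------------
# Array signals
# ---------------------------------------------------------------------------

def _effect_factor(delta: float, cv: float) -> float:
    """Multiplicative bulk boost giving a mean gap of ``delta`` pooled SDs.

    Both bulks share the coefficient of variation ``cv`` of the
    multiplicative noise, so boosting one bulk by ``kappa`` scales its SD
    too; the boost solving ``(kappa - 1) = delta * cv * sqrt((1 + kappa^2)/2)``
    makes the mean gap exactly ``delta`` pooled within-bulk SDs.  Because
    two positive log-normal bulks can never sit more than ``sqrt(2)/cv``
    pooled SDs apart, the calibration is only feasible for
    ``delta * cv < sqrt(2)``.  In the zero-noise limit any boost separates
    the bulks exactly; ``1 + delta`` is used as the nominal factor.
    """
    if cv == 0:
        return 1.0 + delta
    c2 = (delta * cv) ** 2 / 2.0
    if c2 >= 1.0:
        raise ConfigurationError(
            f"planted effect delta={delta:g} is not representable at noise "
            f"CV {cv:.3f} (need delta*cv < sqrt(2)); lower the noise or delta"
        )
    # root of (1-c^2) kappa^2 - 2 kappa + (1-c^2) = 0 with kappa > 1
    kappa = (1.0 + math.sqrt(1.0 - (1.0 - c2) ** 2)) / (1.0 - c2)
    return kappa


def _bulk_allele_freq(truth: SimTruth, compound: str,
                      members: Sequence[str], locus: int) -> float:
    geno = truth.genotypes[compound]
    col = geno.columns[min(locus, len(geno.columns) - 1)]
    return float(geno.loc[list(members), col].mean()) / 2.0


def simulate_array(
    config: SimConfig,
    design: BulkDesign,
    truth: SimTruth | None = None,
    effect_mode: str = "direct",
) -> tuple[SignalMatrix, SimTruth]:
    """Simulate one compound's bulk-hybridisation signal matrix.

    Baseline SNR per feature is log-normal across features; each data point
    multiplies in a biological-replicate batch factor and technical noise
    (both log-normal).  Planted features multiply the favoured bulk by a
    factor calibrated so the bulk-mean gap equals ``delta`` within-bulk SDs
    of the unboosted bulk.

    ``effect_mode="genotype"`` instead scales each bulk by its realised
    high-allele frequency at the compound's loci (requires ``truth``), so a
    misclassified bulk member dilutes the observed effect the way a wrongly
    pooled plant would on a real array.
    """
    if effect_mode not in ("direct", "genotype"):
        raise ConfigurationError(f"unknown effect mode {effect_mode!r}")
    if effect_mode == "genotype" and truth is None:
        raise ConfigurationError("genotype effect mode needs ground truth")
    compound = design.compound
    spec = {c.name: c for c in config.compounds}.get(compound)
    planted = spec.planted if spec is not None else ()
    rng = stream(config.seed, f"array:{compound}")
    features = list(config.feature_ids)
    n_f = len(features)
    baseline = np.exp(rng.normal(config.baseline_log_mu,
                                 config.baseline_log_sigma, size=n_f))
    sigma_tot = math.hypot(config.tech_noise_sd, config.bio_batch_sd)
    cv = math.sqrt(math.expm1(sigma_tot ** 2)) if sigma_tot > 0 else 0.0
    boost = {}
    for i, marker in enumerate(planted):
        kappa = _effect_factor(marker.delta, cv)
        if effect_mode == "genotype":
            f_h = _bulk_allele_freq(truth, compound, design.high, i)
            f_l = _bulk_allele_freq(truth, compound, design.low, i)
            contrast = f_h - f_l if marker.direction == "H" else f_l - f_h
            kappa = 1.0 + (kappa - 1.0) * max(contrast, 0.0)
        boost[marker.feature] = (marker.direction, kappa)
    rows = []
    for bulk in ("H", "L"):
        for bio in range(1, config.n_bio + 1):
            batch = math.exp(rng.normal(0.0, config.bio_batch_sd)) \
                if config.bio_batch_sd > 0 else 1.0
            noise = np.exp(rng.normal(
                0.0, config.tech_noise_sd, size=(config.n_tech, n_f))) \
                if config.tech_noise_sd > 0 else np.ones((config.n_tech, n_f))
            snr = baseline[None, :] * batch * noise
            for j, feat in enumerate(features):
                if feat in boost:
                    direction, kappa = boost[feat]
                    if direction == bulk:
                        snr[:, j] = snr[:, j] * kappa
            for tech in range(1, config.n_tech + 1):
                for j, feat in enumerate(features):
                    rows.append((feat, bulk, bio, tech, snr[tech - 1, j]))
    data = pd.DataFrame(rows, columns=["feature", "bulk", "bio_rep",
                                       "tech_rep", "snr"])
    matrix = validate_signal_frame(data)
    if truth is None:
        truth = SimTruth(planted={compound: planted}, genotypes={},
                         genetic_values={})
    return matrix, truth


# ---------------------------------------------------------------------------
# End-to-end fixtures
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    """Self-consistent file set for one simulated screen."""

    pheno: PhenotypeTable
    parents: PhenotypeTable
    designs: dict[str, BulkDesign]
    matrices: dict[str, SignalMatrix]
    truth: SimTruth
    paths: dict[str, Path]


def end_to_end_fixture(
    config: SimConfig,
    out_dir: str | Path | None = None,
    q: float = 0.2,
) -> FixtureBundle:
    """Simulate phenotypes, build bulks, simulate arrays; optionally write.

    With ``out_dir`` the bundle is written as TSV/JSON (phenotypes, one
    bulk-design JSON and signal TSV per compound, and a ground-truth JSON);
    output is byte-stable for a fixed config.  Compounds whose distribution
    yields an undersized bulk under the quantile rule are skipped (recorded
    in the truth file) rather than fatal.
    """
    pheno, truth = simulate_phenotypes(config)
    designs: dict[str, BulkDesign] = {}
    matrices: dict[str, SignalMatrix] = {}
    skipped: list[str] = []
    for spec in config.compounds:
        try:
            design = assign_extremes(pheno, spec.name, q=q)
        except Exception:
            skipped.append(spec.name)
            continue
        designs[spec.name] = design
        matrices[spec.name], _ = simulate_array(config, design, truth)
    paths: dict[str, Path] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths["phenotypes"] = out / "phenotypes.tsv"
        pheno.to_tsv(paths["phenotypes"])
        paths["parents"] = out / "parents.tsv"
        truth.parents.to_tsv(paths["parents"])
        for name, design in designs.items():
            paths[f"bulks:{name}"] = out / f"bulks_{name}.json"
            design.to_json(paths[f"bulks:{name}"])
            paths[f"signals:{name}"] = out / f"signals_{name}.tsv"
            matrices[name].to_tsv(paths[f"signals:{name}"])
        truth_obj = {
            "seed": config.seed,
            "skipped": skipped,
            "planted": {
                c: [{"feature": m.feature, "delta": m.delta,
                     "direction": m.direction} for m in ms]
                for c, ms in truth.planted.items()
            },
            "bulks": {c: d.to_dict() for c, d in designs.items()},
        }
        paths["truth"] = out / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(truth_obj, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return FixtureBundle(pheno=pheno, parents=truth.parents, designs=designs,
                         matrices=matrices, truth=truth, paths=paths)
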