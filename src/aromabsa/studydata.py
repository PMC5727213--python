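"""Published summary tables from the strawberry aroma marker study.

The screen behind this package crossed the strawberry cultivar Juliette with
breeding line 07-102-41, phenotyped 50 F1 progeny by GC-MS, and hybridised
high/low DNA bulks for eight key aroma compounds onto the 287-feature
*Fragaria* Discovery Panel (raw hybridisations deposited as GEO series
GSE70145; marker amplicons as GenBank KT162989-KT163008).  The raw data are
not redistributed here; what this module carries are the *printed* summary
tables of that screen — descriptive phenotype statistics, the stepwise-DFA
marker sets with their classification rates, the top-10 Fisher's-ratio
rankings, and the per-bulk group statistics — which are sufficient inputs for
every summary-statistic computation in the package (t tests, Fisher's ratios,
three-criterion intersections, concordance checks).

All signal values are normalised signal-to-noise ratios (SNR); phenotype
values are relative compositions in percent.
"""

from __future__ import annotations

import pandas as pd

#: The eight key aroma compounds carried into marker discovery.
KEY_COMPOUNDS = (
    "methyl butanoate",
    "ethyl butanoate",
    "methyl hexanoate",
    "ethyl hexanoate",
    "mesifuranne",
    "linalool",
    "(E)-nerolidol",
    "gamma-dodecalactone",
)

# ---------------------------------------------------------------------------
# Descriptive phenotype statistics for the eight key compounds.
# Columns: F1 mean/min/max (%); parental means and SDs (07-102-41 and
# Juliette); printed significance class of the parental contrast
# (ns / * / ** / None when undetected in both parents).
# ---------------------------------------------------------------------------
PHENOTYPE_SUMMARY_ROWS = [
    # compound, f1_mean, f1_min, f1_max, p1_mean, p1_sd, p2_mean, p2_sd, sig
    ("methyl butanoate", 9.4, 0.0, 34.3, 15.4, 6.1, 0.0, 0.0, "*"),
    ("ethyl butanoate", 4.8, 0.0, 23.2, 7.2, 1.9, 3.2, 1.4, "*"),
    ("methyl hexanoate", 14.1, 0.0, 48.1, 25.0, 1.6, 0.0, 0.0, "**"),
    ("ethyl hexanoate", 6.9, 0.0, 35.6, 16.2, 1.3, 10.1, 1.2, "**"),
    ("mesifuranne", 3.2, 0.0, 32.4, 0.0, 0.0, 5.7, 3.1, "*"),
    ("linalool", 3.3, 0.0, 18.3, 9.1, 0.8, 6.2, 1.1, "*"),
    ("(E)-nerolidol", 7.7, 0.0, 36.9, 17.4, 4.1, 60.6, 6.4, "**"),
    ("gamma-dodecalactone", 1.4, 0.0, 7.9, 0.0, 0.0, 4.8, 1.8, "**"),
]


def phenotype_summary() -> pd.DataFrame:
    """Descriptive statistics of the eight key compounds as a DataFrame."""
    return pd.DataFrame(
        PHENOTYPE_SUMMARY_ROWS,
        columns=[
            "compound", "f1_mean", "f1_min", "f1_max",
            "p1_mean", "p1_sd", "p2_mean", "p2_sd", "parental_sig",
        ],
    )


# ---------------------------------------------------------------------------
# Stepwise-DFA marker sets per compound, with the published classification
# rates (percent correct, original cases / cross-validated).
# ---------------------------------------------------------------------------
DFA_SELECTED = {
    "methyl butanoate": ("FaP1E7MB", "FaP1D7"),
    "ethyl butanoate": ("FaP1D11", "FaP3B9", "FaP3A2"),
    "methyl hexanoate": ("FaP2A11", "FaP1E7MH"),
    "ethyl hexanoate": ("FaP1B3", "FaP1G2"),
    "mesifuranne": ("FaP2G4", "FaP2E6", "FaP3H11"),
    "linalool": ("FaP3E12",),
    "(E)-nerolidol": ("FaP2D11", "FaP1G8", "FaP3F10"),
    "gamma-dodecalactone": ("FaP2E1", "FaP1A7", "FaP3F8", "FaP3E8"),
}

CLASSIFICATION_RATES = {
    # compound: (original %, cross-validated %)
    "methyl butanoate": (95.8, 95.8),
    "ethyl butanoate": (100.0, 95.8),
    "methyl hexanoate": (87.5, 87.5),
    "ethyl hexanoate": (95.8, 95.8),
    "mesifuranne": (100.0, 100.0),
    "linalool": (83.3, 79.2),
    "(E)-nerolidol": (95.8, 95.8),
    "gamma-dodecalactone": (100.0, 87.5),
}

# ---------------------------------------------------------------------------
# Top-10 features per compound ranked by decreasing Fisher's ratio.
# ---------------------------------------------------------------------------
FISHER_TOP10 = {
    "methyl butanoate": (
        "FaP1C8", "FaP1A4", "FaP1A10", "FaP1E11", "FaP1D7",
        "FaP1F1", "FaP1E1", "FaP2D7", "FaP2F4", "FaP2B5",
    ),
    "ethyl butanoate": (
        "FaP3C12", "FaP4D1", "FaP1F12", "FaP3E8", "FaP2C2",
        "FaP1D11", "FaP4C4", "FaP3C7", "FaP1C6", "FaP2F8",
    ),
    "methyl hexanoate": (
        "FaP3H11", "FaP4B10", "FaP4C4", "FaP3C12", "FaP3E11",
        "FaP4D6", "FaP3F4", "FaP2H3", "FaP4A3", "FaP3D10",
    ),
    "ethyl hexanoate": (
        "FaP2B5", "FaP2B8", "FaP1B3", "FaP4B3", "FaP2E3",
        "FaP2B1", "FaP1D7", "FaP3G10", "FaP2C6", "FaP3F4",
    ),
    "mesifuranne": (
        "FaP1H10", "FaP2G5", "FaP2E2", "FaP3F8", "FaP1H5",
        "FaP4C11", "FaP2F3", "FaP1H8", "FaP1E11", "FaP1D5",
    ),
    "linalool": (
        "FaP2F6", "FaP1D1", "FaP1C11", "FaP4A8", "FaP3E11",
        "FaP1B3", "FaP3E12", "FaP2F12", "FaP1C1", "FaP2B3",
    ),
    "(E)-nerolidol": (
        "FaP2D4", "FaP2E3", "FaP2B1", "FaP2A12", "FaP1B3",
        "FaP2D11", "FaP1B5", "FaP2D9", "FaP1D1", "FaP3F2",
    ),
    "gamma-dodecalactone": (
        "FaP1A7", "FaP1G9", "FaP1H3", "FaP1G8", "FaP1D1",
        "FaP4C11", "FaP4C8", "FaP1G6", "FaP4B6", "FaP4D4",
    ),
}

# ---------------------------------------------------------------------------
# Group statistics (normalised SNR, n = 12 data points per bulk) for the 20
# DFA-selected markers, with the published t value, degrees of freedom and
# significance class.  Integer df 22 marks the equal-variance (pooled) form;
# fractional df marks the Welch form.
# ---------------------------------------------------------------------------
GROUP_STATS_ROWS = [
    # compound, feature, mean_h, sd_h, mean_l, sd_l, t, df, sig
    ("methyl butanoate", "FaP1D7", 248.23, 84.05, 578.61, 291.75, -3.77, 12.8, "**"),
    ("methyl butanoate", "FaP1E7MB", 242.69, 91.59, 192.24, 97.77, 1.31, 22.0, "ns"),
    ("ethyl butanoate", "FaP1D11", 279.03, 85.56, 1333.86, 541.59, -6.66, 11.6, "**"),
    ("ethyl butanoate", "FaP3A2", 81.80, 16.68, 180.47, 72.65, -4.59, 12.2, "**"),
    ("ethyl butanoate", "FaP3B9", 17.72, 4.95, 35.11, 16.73, -3.45, 12.9, "**"),
    ("methyl hexanoate", "FaP1E7MH", 13.48, 6.31, 136.56, 95.59, -4.45, 11.1, "**"),
    ("methyl hexanoate", "FaP2A11", 96.35, 48.97, 151.74, 111.30, -1.58, 15.1, "ns"),
    ("ethyl hexanoate", "FaP1B3", 44.43, 14.18, 142.83, 35.33, -8.95, 14.5, "**"),
    ("ethyl hexanoate", "FaP1G2", 340.87, 113.77, 640.48, 293.72, -3.30, 14.2, "**"),
    ("mesifuranne", "FaP2E6", 90.28, 26.69, 18.70, 8.90, 8.81, 13.4, "**"),
    ("mesifuranne", "FaP2G4", 78.51, 53.40, 64.81, 18.80, 0.84, 22.0, "ns"),
    ("mesifuranne", "FaP3H11", 34.96, 12.62, 37.67, 15.79, -0.47, 22.0, "ns"),
    ("linalool", "FaP3E12", 884.13, 521.74, 226.77, 218.23, 4.03, 14.7, "**"),
    ("(E)-nerolidol", "FaP1G8", 684.26, 421.21, 807.65, 535.49, -0.63, 22.0, "ns"),
    ("(E)-nerolidol", "FaP2D11", 493.63, 156.16, 303.39, 130.25, 3.24, 22.0, "**"),
    ("(E)-nerolidol", "FaP3F10", 448.95, 276.61, 274.31, 155.03, 1.91, 17.3, "ns"),
    ("gamma-dodecalactone", "FaP1A7", 282.66, 119.63, 106.71, 57.26, 4.60, 22.0, "**"),
    ("gamma-dodecalactone", "FaP2E1", 1451.21, 887.38, 795.11, 989.51, 1.71, 22.0, "ns"),
    ("gamma-dodecalactone", "FaP3E8", 317.99, 214.62, 314.93, 224.38, 0.03, 22.0, "ns"),
    ("gamma-dodecalactone", "FaP3F8", 175.01, 132.88, 223.85, 468.06, -0.35, 22.0, "ns"),
]

#: Data points per bulk behind every group-statistics row (2 biological x 6
#: technical replicates).
N_PER_BULK = 12


def group_stats() -> pd.DataFrame:
    """Published per-bulk group statistics for the DFA-selected markers.

    Adds ``n_h``/``n_l`` (12 each) and a ``variant`` column: ``pooled`` for
    rows printed with the equal-variance df (n1 + n2 - 2 = 22), ``welch``
    for rows printed with a fractional Satterthwaite df.
    """
    df = pd.DataFrame(
        GROUP_STATS_ROWS,
        columns=["compound", "feature", "mean_h", "sd_h", "mean_l", "sd_l",
                 "t", "df", "sig"],
    )
    df["n_h"] = N_PER_BULK
    df["n_l"] = N_PER_BULK
    df["variant"] = ["pooled" if d == 22.0 else "welch" for d in df["df"]]
    return df


# ---------------------------------------------------------------------------
# FaP1D7 hybridisation snapshots quoted in the SNP analysis: parental SNRs
# and per-bulk SNRs.  These come from a different normalisation snapshot than
# the group-statistics means and are deliberately kept separate.
# ---------------------------------------------------------------------------
FAP1D7_SNR = {
    "juliette": 513.10,
    "07-102-41": 386.38,
    "L_bulk": 467.90,
    "H_bulk": 268.67,
}

# ---------------------------------------------------------------------------
# FaP1D7 C/T SNP validation panel: allele at the SNP site and measured
# methyl butanoate relative composition (%) per genotype.  P1/P63 are
# low-bulk F1 progeny, P38/P99 high-bulk progeny.  The six commercial
# cultivars all carry C; their individual compositions were printed only as
# the range 3.9-5.6 %, so the per-cultivar values below are representative
# values within that printed range (synthetic placement, inert to any
# high/low threshold between 5.6 and 24.1 %).
# ---------------------------------------------------------------------------
VALIDATION_ALLELES = {
    "P1": "C", "P63": "T", "P38": "T", "P99": "T",
    "Albion": "C", "Melba": "C", "Palomar": "C",
    "San Andreas": "C", "Camino Real": "C", "Portola": "C",
}

VALIDATION_LEVELS = {
    "P1": 0.0, "P63": 0.0, "P38": 24.1, "P99": 25.3,
    "Albion": 3.9, "Melba": 4.2, "Palomar": 4.6,
    "San Andreas": 5.0, "Camino Real": 5.3, "Portola": 5.6,
}

# ---------------------------------------------------------------------------
# Genomic placements of the six sequenced markers on the Fragaria vesca
# draft genome (v1.1).  Coordinates are 1-based inclusive; linkage group is
# None for placements reported on chloroplast scaffolds only.
# ---------------------------------------------------------------------------
MARKER_PLACEMENTS = [
    # feature, length_bp, linkage_group, start, end, e_value, compound
    ("FaP1A7", 442, "LG6", 21708323, 21708764, 0.0, "gamma-dodecalactone"),
    ("FaP1D7", 627, "LG2", 17544790, 17544932, 1e-38, "methyl butanoate"),
    ("FaP1B3", 343, None, 52, 396, 5e-45, "ethyl hexanoate"),
    ("FaP1D11", 850, None, 190, 1040, 1e-133, "ethyl butanoate"),
    ("FaP2D11", 670, None, 1, 513, 0.0, "(E)-nerolidol"),
    ("FaP3E12", 539, None, 141, 680, 0.0, "linalool"),
]
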