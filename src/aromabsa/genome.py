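"""Genomic anchoring of sequenced markers and parental SNP detection.

Sequenced marker fragments are placed on the reference genome from tabular
similarity-search hits (best hit per query, E-value strictly below 1e-5).
Candidate genes are looked up within a genetic-distance window around each
anchor: assuming a chromosome spans 100 cM, the physical span of ``c`` cM on
a linkage group of length ``L`` bp is ``(L / 100) * c``.  Parental amplicon
alignments are scanned column by column for substitutions and indels, and a
diagnostic SNP is validated by checking genotype-phenotype concordance: a
genotype is expected to produce high compound levels iff it carries the
high-associated allele.

All genomic coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataFormatError, DegenerateInputError

E_VALUE_CUTOFF = 1e-5
ALIGNMENT_ALPHABET = set("ACGTN-")
#: Default high/low phenotype threshold (% relative composition) for
#: concordance checks; any value between the observed low and high clusters
#: is equivalent.
DEFAULT_HIGH_THRESHOLD = 10.0


@dataclass(frozen=True)
class GenomicAnchor:
    """Placement of a marker fragment on a linkage group."""

    feature: str
    linkage_group: str
    start: int
    end: int
    e_value: float
    scaffold: str | None = None
    scaffold_start: int | None = None
    scaffold_end: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise DataFormatError(
                f"bad anchor interval {self.start}..{self.end}")
        if self.e_value < 0:
            raise DataFormatError("negative E-value")

    @property
    def significant(self) -> bool:
        return self.e_value < E_VALUE_CUTOFF


@dataclass(frozen=True)
class GeneRecord:
    """Annotated gene on a linkage group (1-based inclusive coordinates)."""

    gene_id: str
    linkage_group: str
    start: int
    end: int
    description: str = ""


@dataclass(frozen=True)
class SnpCall:
    """One variant column between two aligned sequences."""

    position: int  # 1-based alignment column
    alleles: tuple[str, str]
    kind: str  # "substitution" | "indel"


# ---------------------------------------------------------------------------
# Genetic-to-physical windows and gene lookup
# ---------------------------------------------------------------------------

def physical_window(lg_length_bp: float, cm: float) -> float:
    """Physical span (bp) of ``cm`` centiMorgan on a linkage group.

    Assumes the linkage group spans 100 cM, so the window is
    ``(lg_length_bp / 100) * cm`` — linear in both arguments.
    """
    if lg_length_bp <= 0:
        raise ValueError("linkage-group length must be positive")
    if cm < 0:
        raise ValueError("cM distance must be nonnegative")
    return lg_length_bp / 100.0 * cm


def genes_within_window(
    anchor: GenomicAnchor,
    genes: Iterable[GeneRecord],
    window_bp: float,
) -> list[tuple[GeneRecord, float]]:
    """Genes whose nearest edge lies within ``window_bp`` of the anchor.

    Returns (gene, signed offset) pairs sorted by |offset| then gene id.
    The offset is the edge-to-edge distance, positive downstream (towards
    increasing coordinates), negative upstream, and 0 for overlap.  Genes on
    other linkage groups are silently skipped.
    """
    if window_bp < 0:
        raise ValueError("window must be nonnegative")
    hits = []
    for gene in genes:
        if gene.linkage_group != anchor.linkage_group:
            continue
        if gene.start > anchor.end:
            offset = float(gene.start - anchor.end)
        elif gene.end < anchor.start:
            offset = float(gene.end - anchor.start)
        else:
            offset = 0.0
        if abs(offset) <= window_bp:
            hits.append((gene, offset))
    hits.sort(key=lambda go: (abs(go[1]), go[0].gene_id))
    return hits


# ---------------------------------------------------------------------------
# Similarity-search hit tables (12-column tabular dialect)
# ---------------------------------------------------------------------------

HIT_COLUMNS = (
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


def load_hit_table(
    path,
    e_cutoff: float = E_VALUE_CUTOFF,
) -> tuple[list[GenomicAnchor], list[str]]:
    """Best significant placement per query from a 12-column hit table.

    The best hit per query is the one with the lowest E-value (ties broken
    by higher bit score, then subject id); it becomes an anchor only when
    its E-value is strictly below ``e_cutoff``.  Returns
    ``(anchors, unplaced_query_ids)``.  Subject coordinates on the minus
    strand (sstart > send) are normalised to start <= end.
    """
    try:
        hits = pd.read_csv(path, sep="\t", header=None,
                           names=HIT_COLUMNS, comment="#")
    except pd.errors.EmptyDataError:
        return [], []
    if hits.empty:
        return [], []
    for col in ("evalue", "bitscore"):
        vals = pd.to_numeric(hits[col], errors="coerce")
        if vals.isna().any():
            raise DataFormatError(f"non-numeric {col} in hit table")
        hits[col] = vals
    anchors: list[GenomicAnchor] = []
    unplaced: list[str] = []
    for query, rows in hits.groupby("query", sort=True):
        rows = rows.sort_values(["evalue", "bitscore", "subject"],
                                ascending=[True, False, True])
        best = rows.iloc[0]
        if not best["evalue"] < e_cutoff:
            unplaced.append(str(query))
            continue
        s1, s2 = int(best["sstart"]), int(best["send"])
        anchors.append(GenomicAnchor(
            feature=str(query),
            linkage_group=str(best["subject"]),
            start=min(s1, s2),
            end=max(s1, s2),
            e_value=float(best["evalue"]),
        ))
    return anchors, unplaced


# ---------------------------------------------------------------------------
# SNP detection between aligned parental amplicons
# ---------------------------------------------------------------------------

def call_snps(seq_a: str, seq_b: str) -> list[SnpCall]:
    """Column-wise variant calls between two equal-length aligned sequences.

    A call is made for every column where the two characters differ and
    neither is N; a column involving a gap is an indel, otherwise a
    substitution.  Swapping the inputs swaps the allele order but keeps
    positions and count.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise DataFormatError(
            f"aligned lengths differ: {len(a)} vs {len(b)}")
    bad = (set(a) | set(b)) - ALIGNMENT_ALPHABET
    if bad:
        raise DataFormatError(f"characters outside A/C/G/T/N/-: {sorted(bad)}")
    calls = []
    for pos, (ca, cb) in enumerate(zip(a, b), start=1):
        if ca == cb or "N" in (ca, cb):
            continue
        kind = "indel" if "-" in (ca, cb) else "substitution"
        calls.append(SnpCall(position=pos, alleles=(ca, cb), kind=kind))
    return calls


def align_pair(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global end-gap-free alignment of two raw sequences (fixture helper).

    Thin wrapper over Biopython's pairwise aligner so test fixtures can be
    built from unaligned sequences; production SNP calls consume alignments
    produced elsewhere.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    aligner.target_end_gap_score = 0
    aligner.query_end_gap_score = 0
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    return str(aln[0]), str(aln[1])


# ---------------------------------------------------------------------------
# Genotype-phenotype concordance
# ---------------------------------------------------------------------------

def genotype_concordance(
    genotypes: Mapping[str, str],
    levels: Mapping[str, float],
    high_threshold_pct: float = DEFAULT_HIGH_THRESHOLD,
    high_allele: str = "T",
    allele_classes: Mapping[str, str] | None = None,
) -> tuple[float, list[str]]:
    """Fraction of genotypes whose phenotype matches their marker allele.

    A genotype is expected to show a high compound level iff its allele is
    ``high_allele`` (or maps to "high" via ``allele_classes``; the default
    map admits only the C/T diagnostic alleles).  Concordant means
    (level >= threshold) equals that expectation.  Returns the concordant
    fraction over the shared ids and the sorted discordant ids.
    """
    shared = sorted(set(genotypes) & set(levels))
    if not shared:
        raise DegenerateInputError("no shared ids between calls and levels")
    if allele_classes is None:
        low_allele = "C" if high_allele != "C" else "T"
        allele_classes = {high_allele: "high", low_allele: "low"}
    discordant = []
    for gid in shared:
        allele = genotypes[gid]
        if allele not in allele_classes:
            raise DataFormatError(
                f"allele {allele!r} for {gid!r} outside the configured map")
        expected_high = allele_classes[allele] == "high"
        observed_high = levels[gid] >= high_threshold_pct
        if expected_high != observed_high:
            discordant.append(gid)
    fraction = (len(shared) - len(discordant)) / len(shared)
    return fraction, discordant
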