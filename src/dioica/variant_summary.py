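"""SNP spectrum and sequence summary statistics.

Covers the descriptive layer of a transcriptome SNP survey: typing each
biallelic substitution as a transition (purine<->purine, pyrimidine<->
pyrimidine) or transversion, tallying the six unordered substitution pairs,
per-kilobase SNP density, codon-position assignment within an annotated CDS,
synonymous/nonsynonymous classification under the standard genetic code,
assembly N50, and basic FASTQ quality metrics (Q20/Q30/GC/mean error rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

from dioica.errors import InputError

BASES = ("A", "C", "G", "T")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: canonical labels for the six unordered substitution pairs
PAIR_LABELS = ("C/T", "A/G", "A/T", "A/C", "T/G", "C/G")
_PAIR_BY_SET = {frozenset(lbl.split("/")): lbl for lbl in PAIR_LABELS}

TRANSITION = "transition"
TRANSVERSION = "transversion"

#: codon -> amino acid (stop encoded as '*') under the standard genetic code
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TABLE.update({c: "*" for c in standard_dna_table.stop_codons})


def classify_substitution(ref: str, alt: str) -> tuple[str, str]:
    """Return (pair label, transition|transversion) for a substitution.

    The pair is unordered: (C, T) and (T, C) both map to ``"C/T"``.
    """
    if ref not in BASES or alt not in BASES:
        raise InputError(f"bases must be one of {BASES}, got {ref!r}/{alt!r}")
    if ref == alt:
        raise InputError(f"ref and alt are identical ({ref})")
    pair = frozenset((ref, alt))
    kind = TRANSITION if pair <= PURINES or pair <= PYRIMIDINES else TRANSVERSION
    return _PAIR_BY_SET[pair], kind


@dataclass
class SpectrumTally:
    """Counts of the six substitution pairs with transition/transversion totals."""

    pair_counts: dict[str, int] = field(
        default_factory=lambda: {lbl: 0 for lbl in PAIR_LABELS}
    )

    @property
    def transitions(self) -> int:
        return sum(
            n for lbl, n in self.pair_counts.items()
            if classify_substitution(*lbl.split("/"))[1] == TRANSITION
        )

    @property
    def transversions(self) -> int:
        return sum(
            n for lbl, n in self.pair_counts.items()
            if classify_substitution(*lbl.split("/"))[1] == TRANSVERSION
        )

    @property
    def total(self) -> int:
        return sum(self.pair_counts.values())

    def to_frame(self, total_length_bp: int | None = None) -> pd.DataFrame:
        """Spectrum as a report table (Type, Count[, Occurrence per kb])."""
        rows = [(lbl, self.pair_counts[lbl]) for lbl in PAIR_LABELS]
        rows += [
            ("Transition", self.transitions),
            ("Transversion", self.transversions),
            ("Total", self.total),
        ]
        df = pd.DataFrame(rows, columns=["Type", "Count"])
        if total_length_bp is not None:
            df["Occurrence per kb"] = [
                round_half_up(snp_density(n, total_length_bp), 2) for _, n in rows
            ]
        return df


def tally_spectrum(substitutions) -> SpectrumTally:
    """Tally an iterable of (ref, alt) pairs into a :class:`SpectrumTally`."""
    tally = SpectrumTally()
    for ref, alt in substitutions:
        label, _ = classify_substitution(ref, alt)
        tally.pair_counts[label] += 1
    return tally


def spectrum_from_counts(counts: dict[str, int]) -> SpectrumTally:
    """Build a tally from pre-counted pairs, e.g. a published summary table.

    Keys may be written in either base order (``"T/C"`` == ``"C/T"``).
    """
    tally = SpectrumTally()
    for key, n in counts.items():
        ref, alt = key.split("/")
        label, _ = classify_substitution(ref, alt)
        tally.pair_counts[label] += int(n)
    return tally


def snp_density(total_snps: int, total_length_bp: int) -> float:
    """SNPs per kilobase, full precision (round only for reporting)."""
    if total_length_bp <= 0:
        raise InputError("total length must be positive")
    if total_snps < 0:
        raise InputError("SNP count must be non-negative")
    return total_snps / (total_length_bp / 1000.0)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), for report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def codon_position(position: int, cds_start: int, cds_end: int) -> int | None:
    """Codon position (1, 2 or 3) of a site, or None outside the CDS.

    Coordinates are 1-based inclusive on the transcript; the CDS is assumed
    in frame 0 starting at *cds_start*.
    """
    if cds_start > cds_end or cds_start < 1:
        raise InputError(f"invalid CDS bounds [{cds_start}, {cds_end}]")
    if position < cds_start or position > cds_end:
        return None
    return 1 + (position - cds_start) % 3


SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"


def classify_synonymy(
    sequence: str,
    cds_start: int,
    cds_end: int,
    position: int,
    ref: str,
    alt: str,
    gene: str = "?",
) -> str:
    """Classify a CDS substitution as synonymous or nonsynonymous.

    Translates the reference codon and the alt-substituted codon under the
    standard genetic code; equal products (stop counting as its own product)
    mean synonymous.  The transcript base at *position* must equal *ref*.
    """
    classify_substitution(ref, alt)  # validates bases
    if codon_position(position, cds_start, cds_end) is None:
        raise InputError(f"{gene}:{position} lies outside the CDS")
    if (cds_end - cds_start + 1) % 3 != 0:
        raise InputError(f"CDS of {gene} is not a whole number of codons")
    seq = sequence.upper()
    if seq[position - 1] != ref:
        raise InputError(
            f"reference mismatch at {gene}:{position}: "
            f"sequence has {seq[position - 1]!r}, expected {ref!r}"
        )
    offset = (position - cds_start) % 3
    codon_start = position - offset
    codon = seq[codon_start - 1 : codon_start + 2]
    mutated = codon[:offset] + alt + codon[offset + 1 :]
    try:
        aa_ref, aa_alt = CODON_TABLE[codon], CODON_TABLE[mutated]
    except KeyError as exc:
        raise InputError(f"ambiguous codon near {gene}:{position}") from exc
    return SYNONYMOUS if aa_ref == aa_alt else NONSYNONYMOUS


def n50(lengths) -> int:
    """N50: largest L such that sequences of length >= L hold half the bases.

    Computed by sorting lengths in descending order and returning the length
    at which the cumulative sum first reaches half the total.
    """
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        raise InputError("n50 of an empty length list is undefined")
    if (arr <= 0).any():
        raise InputError("lengths must be positive")
    desc = np.sort(arr)[::-1]
    csum = np.cumsum(desc)
    idx = int(np.searchsorted(csum, csum[-1] / 2.0))
    return int(desc[idx])


@dataclass
class ReadQc:
    """Per-file FASTQ quality summary (percent scale, like run QC tables)."""

    n_reads: int
    n_bases: int
    q20_pct: float
    q30_pct: float
    gc_pct: float
    error_rate_pct: float


def read_qc(fastq_path: str | Path) -> ReadQc:
    """Q20/Q30/GC/error summary of a Phred+33 FASTQ file.

    Q20/Q30 are the percentage of bases with quality >= 20 / >= 30; GC is the
    percentage of G+C among unambiguous (ACGT) bases, ambiguous bases being
    excluded from the denominator; the error rate is the mean per-base error
    probability ``10**(-Q/10)``, in percent.
    """
    n_reads = n_bases = q20 = q30 = gc = acgt = 0
    err_sum = 0.0
    try:
        records = list(SeqIO.parse(str(fastq_path), "fastq"))
    except ValueError as exc:
        raise InputError(f"malformed FASTQ {fastq_path}: {exc}") from exc
    for i, rec in enumerate(records):
        quals = np.asarray(rec.letter_annotations["phred_quality"], dtype=float)
        seq = str(rec.seq).upper()
        if len(seq) != quals.size:
            raise InputError(f"record {i} of {fastq_path}: length/quality mismatch")
        n_reads += 1
        n_bases += quals.size
        q20 += int((quals >= 20).sum())
        q30 += int((quals >= 30).sum())
        err_sum += float(np.power(10.0, -quals / 10.0).sum())
        gc += seq.count("G") + seq.count("C")
        acgt += sum(seq.count(b) for b in BASES)
    if n_bases == 0:
        raise InputError(f"FASTQ {fastq_path} contains no bases")
    return ReadQc(
        n_reads=n_reads,
        n_bases=n_bases,
        q20_pct=100.0 * q20 / n_bases,
        q30_pct=100.0 * q30 / n_bases,
        gc_pct=100.0 * gc / acgt if acgt else float("nan"),
        error_rate_pct=100.0 * err_sum / n_bases,
    )


@dataclass
class VariantSummary:
    """Aggregate SNP report: spectrum, density, codon and synonymy tallies."""

    spectrum: SpectrumTally
    total_length_bp: int
    codon_counts: dict[str, int]  # keys: first/second/third/noncoding
    synonymy_counts: dict[str, int]  # keys: synonymous/nonsynonymous
    per_individual: dict[str, int]

    @property
    def density_per_kb(self) -> float:
        return snp_density(self.spectrum.total, self.total_length_bp)

    def to_frame(self) -> pd.DataFrame:
        return self.spectrum.to_frame(self.total_length_bp)


_CODON_KEYS = {1: "first", 2: "second", 3: "third", None: "noncoding"}


def summarize_variants(
    snps: pd.DataFrame,
    total_length_bp: int,
    sequences: dict[str, str] | None = None,
    cds: pd.DataFrame | None = None,
    calls: pd.DataFrame | None = None,
) -> VariantSummary:
    """Build a :class:`VariantSummary` from a SNP table.

    Parameters
    ----------
    snps :
        DataFrame with columns ``gene``, ``pos``, ``ref``, ``alt``.
    total_length_bp :
        Denominator for the per-kb densities (total assembled length).
    sequences, cds :
        Optional transcript sequences and a CDS table (``gene``,
        ``cds_start``, ``cds_end``; 1-based inclusive) enabling the codon
        position and synonymy tallies.  Genes without a CDS annotation count
        as noncoding.
    calls :
        Optional genotype calls (see :mod:`dioica.sex_association`) used for
        per-individual SNP counts: for each individual, the number of sites
        where it carries the alternate allele.
    """
    spectrum = tally_spectrum(zip(snps["ref"], snps["alt"]))
    codon_counts = {k: 0 for k in ("first", "second", "third", "noncoding")}
    synonymy_counts = {SYNONYMOUS: 0, NONSYNONYMOUS: 0}
    cds_by_gene: dict[str, tuple[int, int]] = {}
    if cds is not None:
        cds_by_gene = {
            str(r["gene"]): (int(r["cds_start"]), int(r["cds_end"]))
            for _, r in cds.iterrows()
        }
    for _, row in snps.iterrows():
        bounds = cds_by_gene.get(str(row["gene"]))
        if bounds is None:
            codon_counts["noncoding"] += 1
            continue
        cp = codon_position(int(row["pos"]), *bounds)
        codon_counts[_CODON_KEYS[cp]] += 1
        if cp is not None and sequences is not None:
            seq = sequences.get(str(row["gene"]))
            if seq is not None:
                kind = classify_synonymy(
                    seq, *bounds, int(row["pos"]), row["ref"], row["alt"],
                    gene=str(row["gene"]),
                )
                synonymy_counts[kind] += 1
    per_individual: dict[str, int] = {}
    if calls is not None and not calls.empty:
        alt_by_site = {
            (g, p): a for g, p, a in zip(snps["gene"], snps["pos"], snps["alt"])
        }
        for _, c in calls.iterrows():
            alt = alt_by_site.get((c["gene"], c["pos"]))
            if alt is not None and c["allele"] == alt:
                per_individual[c["individual"]] = (
                    per_individual.get(c["individual"], 0) + 1
                )
    return VariantSummary(
        spectrum=spectrum,
        total_length_bp=total_length_bp,
        codon_counts=codon_counts,
        synonymy_counts=synonymy_counts,
        per_individual=per_individual,
    )
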