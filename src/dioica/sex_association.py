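"""Sex-segregating SNP filter over multi-sample genotype calls.

In a dioecious species, a SNP tightly linked to the sex-determining region
shows a distinctive pattern across sampled individuals: one allele fixed in
every female, a different allele fixed in every male.  Given per-individual
genotype calls on assembled transcripts, the filter applies three criteria:

1. depth — every individual covers the position with at least ``min_depth``
   reads (default 5);
2. polymorphism — the site carries two alleles across the individuals;
3. sex sharing — the allele set within females is a single base X, within
   males a single base Y, and X != Y (which entails criterion 2).

Positions are 1-based along the transcript, counted 5' to 3'.  Heterozygous
or missing genotypes make an individual uncallable at that position, and a
position where any individual is uncallable is ineligible (the criteria
quantify over *each* individual).

Calls are exchanged as a pandas DataFrame with columns ``gene``, ``pos``,
``individual``, ``sex``, ``allele`` (single base, or NA for no-call) and
``depth``; loaders are provided for multi-sample VCF and for flat genotype
tables with one column per individual.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from dioica.design import SampleDesign
from dioica.errors import ConfigurationError, InputError

CALL_COLUMNS = ["gene", "pos", "individual", "sex", "allele", "depth"]
BASES = ("A", "C", "G", "T")

#: how to treat heterozygous genotypes; both make the position ineligible
#: (a het individual has no single shared allele), so the site sets coincide —
#: the flag exists to make the choice explicit in reports and configs.
HET_POLICIES = ("nocall", "fail-site")


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame(columns=CALL_COLUMNS)


def load_genotypes(
    vcf_path: str | Path,
    design: SampleDesign,
    het_policy: str = "nocall",
) -> pd.DataFrame:
    """Load biallelic SNP genotype calls from a multi-sample VCF.

    Homozygous genotypes are expanded to the carried base; heterozygous and
    missing genotypes become no-calls (``allele`` NA).  Per-sample read depth
    is taken from ``FORMAT/DP`` (0 when absent).  Records that are not
    biallelic SNPs are skipped.  Every VCF sample must appear in *design*.
    """
    if het_policy not in HET_POLICIES:
        raise ConfigurationError(f"het_policy must be one of {HET_POLICIES}")
    rows: list[tuple] = []
    try:
        vcf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read VCF {vcf_path}: {exc}") from exc
    with vcf:
        vcf_samples = list(vcf.header.samples)
        unknown = [s for s in vcf_samples if s not in design.sex]
        if unknown:
            raise InputError(
                f"VCF samples missing from the sample sheet: {unknown}"
            )
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                continue
            for sample in vcf_samples:
                call = rec.samples[sample]
                gt = call.get("GT")
                depth = call.get("DP")
                depth = 0 if depth is None else int(depth)
                allele: str | float
                if gt is None or any(a is None for a in gt):
                    allele = np.nan
                elif len(set(gt)) > 1:  # heterozygous
                    allele = np.nan
                else:
                    allele = ref if gt[0] == 0 else alt
                rows.append(
                    (rec.chrom, rec.pos, sample, design.sex[sample], allele, depth)
                )
    if not rows:
        return _empty_calls()
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def load_genotype_table(
    table: str | Path | pd.DataFrame,
    design: SampleDesign,
    assumed_depth: int = 5,
) -> pd.DataFrame:
    """Load calls from a flat genotype table (one column per individual).

    Expected columns: ``Gene_ID``, ``Position``, one single-base column per
    individual named by its sample id, and optionally extra annotation
    columns (ignored).  Such tables usually print already depth-filtered
    calls, so every call is assigned *assumed_depth*.
    """
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table, sep="\t", dtype=str)
    else:
        df = table.copy()
    if "Gene_ID" not in df.columns or "Position" not in df.columns:
        raise InputError("genotype table needs Gene_ID and Position columns")
    missing = [s for s in design.samples if s not in df.columns]
    if missing:
        raise InputError(f"genotype table lacks columns for individuals: {missing}")
    # gene ids may be blank on continuation rows (one gene, several positions)
    df["Gene_ID"] = df["Gene_ID"].replace("", np.nan).ffill()
    rows = []
    for _, row in df.iterrows():
        gene = row["Gene_ID"]
        pos = int(row["Position"])
        for sample in design.samples:
            base = str(row[sample]).strip().upper()
            if base not in BASES:
                raise InputError(
                    f"bad allele {base!r} for {sample} at {gene}:{pos}"
                )
            rows.append((gene, pos, sample, design.sex[sample], base, assumed_depth))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def apply_depth_filter(
    calls: pd.DataFrame, design: SampleDesign, min_depth: int = 5
) -> pd.DataFrame:
    """Keep positions where every individual has a call with depth >= min_depth.

    The comparison is inclusive (depth exactly ``min_depth`` passes).  A
    position missing a call for any individual is dropped.
    """
    if min_depth < 1:
        raise ConfigurationError("min_depth must be >= 1")
    if calls.empty:
        return _empty_calls()
    required = set(design.samples)

    def _ok(group: pd.DataFrame) -> bool:
        seen = set(group["individual"])
        if seen != required:
            return False
        return bool((group["depth"] >= min_depth).all())

    keep = calls.groupby(["gene", "pos"], sort=False).filter(_ok)
    return keep.reset_index(drop=True)


def find_sex_segregating_sites(
    calls: pd.DataFrame, design: SampleDesign
) -> pd.DataFrame:
    """Sites where females are fixed for one base and males for another.

    Expects depth-filtered calls.  A site is emitted iff every individual has
    a non-missing allele, the female alleles are a single base X, the male
    alleles a single base Y, and X != Y.  The result has one row per site,
    sorted by gene then position, with columns ``gene``, ``pos``,
    ``female_allele``, ``male_allele`` and one audit column per individual.
    """
    out_cols = ["gene", "pos", "female_allele", "male_allele", *design.samples]
    if calls.empty:
        return pd.DataFrame(columns=out_cols)
    rows = []
    for (gene, pos), group in calls.groupby(["gene", "pos"], sort=False):
        alleles = dict(zip(group["individual"], group["allele"]))
        if set(alleles) != set(design.samples):
            continue
        if any(pd.isna(a) for a in alleles.values()):
            continue
        female = {alleles[s] for s in design.females}
        male = {alleles[s] for s in design.males}
        if len(female) == 1 and len(male) == 1 and female != male:
            rows.append(
                (gene, pos, female.pop(), male.pop(), *[alleles[s] for s in design.samples])
            )
    out = pd.DataFrame(rows, columns=out_cols)
    return out.sort_values(["gene", "pos"], kind="stable").reset_index(drop=True)


def summarize_by_gene(sites: pd.DataFrame) -> pd.DataFrame:
    """Group sex-segregating sites into a per-gene report.

    Returns one row per gene with its number of segregating positions and a
    comma-joined position list; ``len(report)`` is the putative
    sex-associated gene count.
    """
    if sites.empty:
        return pd.DataFrame(columns=["gene", "n_sites", "positions"])
    grouped = (
        sites.groupby("gene", sort=True)["pos"]
        .agg(n_sites="count", positions=lambda p: ",".join(str(v) for v in p))
        .reset_index()
    )
    return grouped


def run_filter(
    calls: pd.DataFrame, design: SampleDesign, min_depth: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Depth filter then segregation filter; returns (sites, per-gene report)."""
    deep = apply_depth_filter(calls, design, min_depth=min_depth)
    sites = find_sex_segregating_sites(deep, design)
    return sites, summarize_by_gene(sites)


def segregation_null_rate(n_males: int, n_females: int) -> float:
    """Chance a random polymorphic biallelic site segregates perfectly by sex.

    Model: each of the ``n = n_males + n_females`` individuals independently
    carries one of two alleles, all ``2**n`` assignments equally likely, and
    the site is conditioned on being polymorphic (both alleles present).
    Exactly two of the remaining assignments split along sex (either allele
    can be the female one), hence ``2 / (2**n - 2)``.
    """
    if n_males < 1 or n_females < 1:
        raise ConfigurationError("need at least one individual per sex")
    n = n_males + n_females
    return 2.0 / (2.0**n - 2.0)
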