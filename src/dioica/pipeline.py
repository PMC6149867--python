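"""End-to-end orchestration: counts + FASTA + VCF (+ annotation) -> reports.

``run_all`` chains the four analysis stages — differential expression,
sex-segregating SNP filtering, SNP spectrum summary, category enrichment —
over real or simulated inputs and writes TSV tables plus a machine-readable
JSON run report.  Percentages in the report are recomputed from counts at
render time, never stored.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

import dioica
from dioica import enrichment, expression, sex_association, variant_summary
from dioica.design import SampleDesign
from dioica.errors import DioicaError, InputError


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run."""

    counts: Path
    samples: Path
    fasta: Path
    out_dir: Path
    vcf: Path | None = None
    genotype_table: Path | None = None
    annotation: Path | None = None
    cds: Path | None = None
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    fpkm_floor: float = 0.03
    fpkm_floor_mode: str = "mean"
    min_depth: int = 5
    het_policy: str = "nocall"
    enrichment_mode: str = "wallenius"
    pwf_bins: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("counts", "samples", "fasta", "out_dir", "vcf",
                     "genotype_table", "annotation", "cds"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))

    def content_hash(self) -> str:
        payload = {k: str(v) for k, v in self.__dict__.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect every configuration problem; an empty list means valid."""
    problems: list[str] = []
    for name in ("counts", "samples", "fasta"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            problems.append(f"input '{name}' missing: {path}")
    for name in ("vcf", "genotype_table", "annotation", "cds"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            problems.append(f"input '{name}' does not exist: {path}")
    if not 0.0 <= config.alpha <= 1.0:
        problems.append(f"alpha outside [0, 1]: {config.alpha}")
    if config.lfc_threshold < 0:
        problems.append(f"lfc_threshold must be >= 0: {config.lfc_threshold}")
    if config.fpkm_floor < 0:
        problems.append(f"fpkm_floor must be >= 0: {config.fpkm_floor}")
    if config.fpkm_floor_mode not in ("mean", "all"):
        problems.append(f"unknown fpkm_floor_mode: {config.fpkm_floor_mode}")
    if config.min_depth < 1:
        problems.append(f"min_depth must be >= 1: {config.min_depth}")
    if config.het_policy not in sex_association.HET_POLICIES:
        problems.append(f"unknown het_policy: {config.het_policy}")
    if config.enrichment_mode not in ("wallenius", "hypergeometric"):
        problems.append(f"unknown enrichment_mode: {config.enrichment_mode}")
    if config.pwf_bins < 1:
        problems.append(f"pwf_bins must be >= 1: {config.pwf_bins}")
    if config.samples is not None and Path(config.samples).exists():
        try:
            SampleDesign.from_table(config.samples)
        except DioicaError as exc:
            problems.append(f"sample sheet invalid: {exc}")
    return problems


@dataclass
class RunReport:
    """Aggregated result of one pipeline run."""

    deg_counts: dict[str, int]
    sex_associated_genes: pd.DataFrame
    sex_associated_sites: pd.DataFrame
    snp_summary: pd.DataFrame
    enrichment_table: pd.DataFrame | None
    provenance: dict[str, object]
    samples_cluster_by_sex: bool | None = None
    extra: dict[str, object] = field(default_factory=dict)

    def deg_percentages(self) -> dict[str, float]:
        total = self.deg_counts.get("total", 0)
        if total == 0:
            return {k: 0.0 for k in self.deg_counts if k != "total"}
        return {
            k: round(100.0 * v / total, 1)
            for k, v in self.deg_counts.items()
            if k != "total"
        }

    def to_dict(self) -> dict:
        return {
            "deg_counts": self.deg_counts,
            "deg_percentages": self.deg_percentages(),
            "n_sex_associated_genes": int(len(self.sex_associated_genes)),
            "n_sex_associated_sites": int(len(self.sex_associated_sites)),
            "sex_associated_genes": self.sex_associated_genes.to_dict("records"),
            "sex_associated_sites": self.sex_associated_sites.to_dict("records"),
            "snp_summary": self.snp_summary.to_dict("records"),
            "enrichment": (
                None
                if self.enrichment_table is None
                else self.enrichment_table.to_dict("records")
            ),
            "samples_cluster_by_sex": self.samples_cluster_by_sex,
            "provenance": self.provenance,
            **self.extra,
        }


def _load_fasta(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def run_all(config: PipelineConfig) -> RunReport:
    """Run every stage in order and write all outputs under ``out_dir``."""
    problems = validate_config(config)
    if problems:
        raise InputError("invalid pipeline configuration: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    design = SampleDesign.from_table(config.samples)
    counts = pd.read_csv(config.counts, sep="\t", index_col=0)
    missing = [s for s in design.samples if s not in counts.columns]
    if missing:
        raise InputError(f"count matrix lacks columns for samples: {missing}")
    counts = counts[list(design.samples)]
    sequences = _load_fasta(config.fasta)
    lengths = pd.Series({g: len(s) for g, s in sequences.items()}, name="length")

    # --- expression -------------------------------------------------------
    res = expression.run_differential_expression(
        counts,
        design,
        lengths,
        alpha=config.alpha,
        lfc_threshold=config.lfc_threshold,
        fpkm_floor=config.fpkm_floor,
        floor_mode=config.fpkm_floor_mode,
    )
    res.rename_axis("gene").to_csv(out / "deg_results.tsv", sep="\t")
    fpkm = expression.compute_fpkm(counts, lengths)
    fpkm.rename_axis("gene").to_csv(out / "fpkm.tsv", sep="\t")
    deg_mask = res["bias_class"] != expression.UNBIASED
    cluster_ok: bool | None = None
    if deg_mask.sum() >= 2:
        clustering = expression.cluster_samples(fpkm.loc[deg_mask], design)
        (out / "sample_dendrogram.nwk").write_text(clustering.newick + "\n")
        cluster_ok = clustering.splits_by_sex(design)
    deg_counts = {
        "total": int(deg_mask.sum()),
        "male_biased": int((res["bias_class"] == expression.MALE_BIASED).sum()),
        "female_biased": int((res["bias_class"] == expression.FEMALE_BIASED).sum()),
        "male_specific": int((res["specificity"] == expression.MALE_SPECIFIC).sum()),
        "female_specific": int(
            (res["specificity"] == expression.FEMALE_SPECIFIC).sum()
        ),
    }

    # --- sex-segregating SNP filter --------------------------------------
    if config.vcf is not None:
        calls = sex_association.load_genotypes(
            config.vcf, design, het_policy=config.het_policy
        )
    elif config.genotype_table is not None:
        calls = sex_association.load_genotype_table(
            config.genotype_table, design, assumed_depth=config.min_depth
        )
    else:
        calls = pd.DataFrame(columns=sex_association.CALL_COLUMNS)
    sites, gene_report = sex_association.run_filter(
        calls, design, min_depth=config.min_depth
    )
    sites.to_csv(out / "sex_associated_sites.tsv", sep="\t", index=False)
    gene_report.to_csv(out / "sex_associated_genes.tsv", sep="\t", index=False)

    # --- SNP spectrum summary --------------------------------------------
    if config.vcf is not None and not calls.empty:
        snps = (
            calls.groupby(["gene", "pos"], sort=True)
            .first()
            .reset_index()[["gene", "pos"]]
        )
        vcf_alleles = _vcf_ref_alt(config.vcf)
        snps["ref"] = [vcf_alleles[(g, p)][0] for g, p in zip(snps["gene"], snps["pos"])]
        snps["alt"] = [vcf_alleles[(g, p)][1] for g, p in zip(snps["gene"], snps["pos"])]
    else:
        snps = pd.DataFrame(columns=["gene", "pos", "ref", "alt"])
    cds = None
    if config.cds is not None:
        cds = pd.read_csv(config.cds, sep="\t")
    summary = variant_summary.summarize_variants(
        snps,
        total_length_bp=int(lengths.sum()),
        sequences=sequences,
        cds=cds,
        calls=calls if not calls.empty else None,
    )
    summary_frame = summary.to_frame()
    summary_frame.to_csv(out / "snp_summary.tsv", sep="\t", index=False)

    # --- enrichment -------------------------------------------------------
    enr: pd.DataFrame | None = None
    if config.annotation is not None:
        cat_map = enrichment.load_category_map(config.annotation)
        annotated = sorted({g for genes in cat_map.values() for g in genes})
        universe = [g for g in counts.index if g in set(annotated)]
        de_flags = deg_mask.loc[universe]
        if len(universe) and de_flags.any() and not de_flags.all():
            weights = (
                enrichment.build_pwf(de_flags, lengths, n_bins=config.pwf_bins)
                if config.enrichment_mode == "wallenius"
                else None
            )
            enr = enrichment.enrich_all(
                cat_map, de_flags, weights, mode=config.enrichment_mode
            )
        else:
            enr = pd.DataFrame(
                columns=["category", "size", "overlap", "expected",
                         "rich_factor", "p", "q"]
            )
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    report = RunReport(
        deg_counts=deg_counts,
        sex_associated_genes=gene_report,
        sex_associated_sites=sites,
        snp_summary=summary_frame,
        enrichment_table=enr,
        samples_cluster_by_sex=cluster_ok,
        provenance={
            "tool": "dioica",
            "version": dioica.__version__,
            "config_hash": config.content_hash(),
            "seed": config.seed,
        },
        extra={
            "snp_codon_counts": summary.codon_counts,
            "snp_synonymy_counts": summary.synonymy_counts,
            "snp_density_per_kb": variant_summary.round_half_up(
                summary.density_per_kb, 2
            )
            if len(snps)
            else 0.0,
        },
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _vcf_ref_alt(vcf_path: Path) -> dict[tuple[str, int], tuple[str, str]]:
    import pysam

    out: dict[tuple[str, int], tuple[str, str]] = {}
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            if rec.alts and len(rec.alts) == 1:
                out[(rec.chrom, rec.pos)] = (rec.ref, rec.alts[0])
    return out
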