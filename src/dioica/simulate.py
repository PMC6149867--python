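"""Seeded synthetic inputs for the whole pipeline, with a truth manifest.

The generator emulates a replicated male/female leaf RNA-seq experiment in a
dioecious species: three biological replicates per sex by default, negative-
binomial read counts (``Var = mu + dispersion * mu**2``), a planted set of
strongly sex-biased genes (|log2 fold change| of 5 split symmetrically
around the baseline mean), sex-specific genes planted as structural zeros in
one sex, and biallelic SNP sites of which a chosen subset segregates
perfectly by sex at read depth of at least 5 in every individual.  Decoy
sites are planted alongside: polymorphic sites whose genotype pattern does
not split by sex, and perfectly segregating patterns whose depth falls below
threshold in at least one individual, so recovery tests exercise every
filter criterion.

All randomness flows from a single seed that fans out into independent
per-stage substreams, so each stage is reproducible on its own and the whole
dataset is byte-identical across runs.  A :class:`TruthManifest` records the
planted classes so downstream modules can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dioica.design import SampleDesign
from dioica.errors import ConfigurationError

UNBIASED = "unbiased"
MALE_BIASED = "male-biased"
FEMALE_BIASED = "female-biased"
MALE_SPECIFIC = "male-specific"
FEMALE_SPECIFIC = "female-specific"

#: substream indices hashed together with the seed, one per stage
_STREAMS = {"unigenes": 0, "counts": 1, "variants": 2, "reads": 3}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment.

    The defaults mirror the study design this toolkit targets: 3 male and 3
    female replicates; 116 differential genes out of 2,000 — 73 male-side
    (33 biased + 40 male-specific) and 43 female-side (12 biased + 31
    female-specific); planted |log2FC| of 5; 60 SNP sites of which 9
    segregate perfectly by sex.  ``dispersion`` is the NB shape ``alpha`` in
    ``Var = mu + alpha * mu**2`` (0.05 is a moderate biological dispersion
    for replicated plant tissue; the studies this emulates do not report
    one, so it is an assumption, not an estimate).
    """

    seed: int = 0
    n_genes: int = 2000
    n_males: int = 3
    n_females: int = 3
    gene_length_range: tuple[int, int] = (200, 2000)
    baseline_mean: float = 100.0
    dispersion: float = 0.05
    n_male_biased: int = 33
    n_female_biased: int = 12
    planted_log2fc: float = 5.0
    n_male_specific: int = 40
    n_female_specific: int = 31
    n_snp_sites: int = 60
    n_sex_segregating: int = 9
    depth_mean: float = 20.0
    min_planted_depth: int = 5
    # read simulation (QC stage)
    n_reads_per_sample: int = 200
    read_length: int = 100
    gc_content: float = 0.5
    quality_range: tuple[int, int] = (30, 40)

    def validate(self) -> None:
        lo, hi = self.gene_length_range
        if not (1 <= lo <= hi):
            raise ConfigurationError(f"invalid gene length range ({lo}, {hi})")
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        if self.n_males < 1 or self.n_females < 1:
            raise ConfigurationError("need at least one individual per sex")
        planted = (
            self.n_male_biased
            + self.n_female_biased
            + self.n_male_specific
            + self.n_female_specific
        )
        if min(
            self.n_male_biased,
            self.n_female_biased,
            self.n_male_specific,
            self.n_female_specific,
        ) < 0:
            raise ConfigurationError("planted gene counts must be >= 0")
        if planted > self.n_genes:
            raise ConfigurationError(
                f"{planted} planted genes exceed n_genes={self.n_genes}"
            )
        if self.n_sex_segregating > self.n_snp_sites:
            raise ConfigurationError(
                "n_sex_segregating cannot exceed n_snp_sites"
            )
        if min(self.n_snp_sites, self.n_sex_segregating) < 0:
            raise ConfigurationError("SNP site counts must be >= 0")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ConfigurationError("baseline_mean and dispersion must be > 0")
        if self.min_planted_depth < 1:
            raise ConfigurationError("min_planted_depth must be >= 1")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ConfigurationError("gc_content must lie in [0, 1]")
        qlo, qhi = self.quality_range
        if not (0 <= qlo <= qhi <= 41):
            raise ConfigurationError("quality_range must satisfy 0 <= lo <= hi <= 41")

    def rng(self, stage: str) -> np.random.Generator:
        """Independent generator for one stage, derived from the global seed."""
        return np.random.default_rng([self.seed, _STREAMS[stage]])

    def design(self) -> SampleDesign:
        males = [f"M{i + 1}" for i in range(self.n_males)]
        females = [f"F{i + 1}" for i in range(self.n_females)]
        return SampleDesign.from_lists(males, females)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("gene_length_range", "quality_range"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class TruthManifest:
    """Ground truth of the planted structure, for recovery scoring."""

    #: gene id -> true expression class
    gene_class: pd.Series
    #: planted sex-segregating sites (gene, pos, female_allele, male_allele)
    seg_sites: pd.DataFrame
    #: polymorphic decoy sites that never segregate by sex (gene, pos, kind)
    decoy_sites: pd.DataFrame
    #: segregating patterns whose depth is sub-threshold in >= 1 individual
    low_depth_sites: pd.DataFrame

    def genes_of_class(self, cls: str) -> list[str]:
        return self.gene_class.index[self.gene_class == cls].tolist()

    @property
    def deg_genes(self) -> list[str]:
        return self.gene_class.index[self.gene_class != UNBIASED].tolist()


def simulate_unigenes(config: SimulationConfig) -> dict[str, str]:
    """Random transcript sequences with lengths uniform in the configured range.

    Returns an ordered mapping ``gene id -> sequence`` over {A, C, G, T}.
    """
    config.validate()
    rng = config.rng("unigenes")
    lo, hi = config.gene_length_range
    bases = np.array(list("ACGT"))
    out: dict[str, str] = {}
    for i in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        out[f"unigene_{i + 1:05d}"] = "".join(
            bases[rng.integers(0, 4, size=length)]
        )
    return out


def gene_lengths(unigenes: dict[str, str]) -> pd.Series:
    return pd.Series({g: len(s) for g, s in unigenes.items()}, name="length")


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB sample with Var = mu + dispersion * mu**2 (mean 0 yields 0)."""
    size = 1.0 / dispersion
    p = size / (size + np.maximum(mean, 1e-300))
    draw = rng.negative_binomial(size, p)
    return np.where(mean > 0, draw, 0)


def simulate_counts(
    config: SimulationConfig, unigenes: dict[str, str]
) -> tuple[pd.DataFrame, TruthManifest]:
    """Replicated NB count matrix with planted sex-biased structure.

    Biased genes split the planted fold change symmetrically: the favoured
    sex has mean ``baseline * 2**(lfc/2)`` and the other
    ``baseline * 2**(-lfc/2)``, so the expected log2 ratio is exactly the
    planted value.  Sex-specific genes are structural zeros in the silent
    sex (counts identically 0, not sampled) with baseline mean in the other.
    """
    config.validate()
    if not unigenes:
        raise ConfigurationError("simulate_counts needs a non-empty unigene set")
    rng = config.rng("counts")
    genes = list(unigenes)
    design = config.design()

    order = rng.permutation(len(genes))
    classes = pd.Series(UNBIASED, index=genes, name="true_class")
    cursor = 0
    for cls, n in (
        (MALE_BIASED, config.n_male_biased),
        (FEMALE_BIASED, config.n_female_biased),
        (MALE_SPECIFIC, config.n_male_specific),
        (FEMALE_SPECIFIC, config.n_female_specific),
    ):
        for j in order[cursor : cursor + n]:
            classes.iloc[j] = cls
        cursor += n

    base = config.baseline_mean
    up = base * 2.0 ** (config.planted_log2fc / 2.0)
    down = base * 2.0 ** (-config.planted_log2fc / 2.0)
    mean_m = np.full(len(genes), base)
    mean_f = np.full(len(genes), base)
    cls_arr = classes.to_numpy()
    mean_m[cls_arr == MALE_BIASED] = up
    mean_f[cls_arr == MALE_BIASED] = down
    mean_m[cls_arr == FEMALE_BIASED] = down
    mean_f[cls_arr == FEMALE_BIASED] = up
    mean_f[cls_arr == MALE_SPECIFIC] = 0.0
    mean_m[cls_arr == FEMALE_SPECIFIC] = 0.0

    cols = {}
    for s in design.samples:
        mu = mean_m if design.sex[s] == "M" else mean_f
        cols[s] = _nb_draw(rng, mu, config.dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    manifest = TruthManifest(
        gene_class=classes,
        seg_sites=pd.DataFrame(
            columns=["gene", "pos", "female_allele", "male_allele"]
        ),
        decoy_sites=pd.DataFrame(columns=["gene", "pos", "kind"]),
        low_depth_sites=pd.DataFrame(columns=["gene", "pos"]),
    )
    return counts, manifest


def _other_base(rng, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def simulate_variants(
    config: SimulationConfig,
    unigenes: dict[str, str],
    manifest: TruthManifest | None = None,
) -> tuple[pd.DataFrame, TruthManifest]:
    """Biallelic SNP records with per-individual genotype and depth.

    Emits ``n_snp_sites`` sites total: ``n_sex_segregating`` perfectly
    sex-segregating at depth >= ``min_planted_depth`` everywhere, and decoys
    split between polymorphic non-segregating patterns (adequate depth) and
    segregating patterns failing the depth criterion in >= 1 individual.
    The REF allele is the transcript base at the site, so records are
    consistent with the emitted FASTA.  Sites are sorted by gene then
    position.  Returns (records, manifest): one record row per site with
    columns ``gene, pos, ref, alt`` plus ``GT:<sample>`` and ``DP:<sample>``
    columns.
    """
    config.validate()
    if not unigenes:
        raise ConfigurationError("simulate_variants needs a non-empty unigene set")
    rng = config.rng("variants")
    design = config.design()
    genes = list(unigenes)
    n_sites = config.n_snp_sites
    n_seg = config.n_sex_segregating
    n_rest = n_sites - n_seg
    n_low = n_rest // 3
    n_mixed = n_rest - n_low

    # unique (gene, pos) coordinates
    coords: set[tuple[str, int]] = set()
    attempts = 0
    while len(coords) < n_sites:
        g = genes[int(rng.integers(0, len(genes)))]
        p = int(rng.integers(1, len(unigenes[g]) + 1))
        coords.add((g, p))
        attempts += 1
        if attempts > 100 * max(n_sites, 1) + 100:
            raise ConfigurationError(
                "cannot place the requested number of unique SNP sites"
            )
    coord_list = sorted(coords)
    rng.shuffle(coord_list)

    kinds = [("seg", None)] * n_seg + [("mixed", None)] * n_mixed + [
        ("low_depth", None)
    ] * n_low

    records = []
    seg_rows, decoy_rows, low_rows = [], [], []
    n_ind = len(design.samples)
    for (gene, pos), (kind, _) in zip(coord_list, kinds):
        ref = unigenes[gene][pos - 1]
        alt = _other_base(rng, ref)
        depth = np.maximum(
            rng.poisson(config.depth_mean, size=n_ind), config.min_planted_depth
        )
        if kind in ("seg", "low_depth"):
            female_allele, male_allele = (
                (ref, alt) if rng.integers(0, 2) == 0 else (alt, ref)
            )
            alleles = {
                s: (female_allele if design.sex[s] == "F" else male_allele)
                for s in design.samples
            }
            if kind == "low_depth":
                # sink the depth of at least one individual below threshold
                n_bad = 1 + int(rng.integers(0, n_ind))
                bad = rng.choice(n_ind, size=n_bad, replace=False)
                depth = depth.copy()
                depth[bad] = rng.integers(0, config.min_planted_depth, size=n_bad)
                low_rows.append((gene, pos))
            else:
                seg_rows.append((gene, pos, female_allele, male_allele))
        else:
            # polymorphic pattern that does not split along sex
            tries = 0
            while True:
                tries += 1
                if tries > 1000:
                    raise ConfigurationError(
                        "cannot draw a non-segregating polymorphic pattern "
                        "for this design (too few individuals)"
                    )
                mask = rng.integers(0, 2, size=n_ind)
                if mask.min() == mask.max():
                    continue  # monomorphic
                sexes = np.array([design.sex[s] for s in design.samples])
                by_sex_f = set(mask[sexes == "F"])
                by_sex_m = set(mask[sexes == "M"])
                if len(by_sex_f) == 1 and len(by_sex_m) == 1 and by_sex_f != by_sex_m:
                    continue  # would segregate perfectly; redraw
                break
            alleles = {
                s: (ref if mask[i] == 0 else alt)
                for i, s in enumerate(design.samples)
            }
            decoy_rows.append((gene, pos, "non-segregating"))
        row: dict[str, object] = {"gene": gene, "pos": pos, "ref": ref, "alt": alt}
        for i, s in enumerate(design.samples):
            row[f"GT:{s}"] = alleles[s]
            row[f"DP:{s}"] = int(depth[i])
        records.append(row)

    rec_df = pd.DataFrame(records)
    if len(rec_df):
        rec_df = rec_df.sort_values(["gene", "pos"], kind="stable").reset_index(
            drop=True
        )
    if manifest is None:
        manifest = TruthManifest(
            gene_class=pd.Series(dtype=object),
            seg_sites=pd.DataFrame(),
            decoy_sites=pd.DataFrame(),
            low_depth_sites=pd.DataFrame(),
        )
    manifest.seg_sites = (
        pd.DataFrame(
            seg_rows, columns=["gene", "pos", "female_allele", "male_allele"]
        )
        .sort_values(["gene", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    manifest.decoy_sites = (
        pd.DataFrame(decoy_rows, columns=["gene", "pos", "kind"])
        .sort_values(["gene", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    manifest.low_depth_sites = (
        pd.DataFrame(low_rows, columns=["gene", "pos"])
        .sort_values(["gene", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    return rec_df, manifest


def simulate_reads(config: SimulationConfig) -> dict[str, list[tuple[str, str, str]]]:
    """Small per-sample FASTQ read sets with controlled GC and quality.

    Bases are drawn iid with P(G) = P(C) = gc/2; per-base Phred qualities
    are uniform integers over ``quality_range`` (inclusive).  Returns
    ``sample -> [(read id, sequence, quality string), ...]``.
    """
    config.validate()
    rng = config.rng("reads")
    design = config.design()
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(["A", "G", "C", "T"])  # order matches probs
    qlo, qhi = config.quality_range
    out: dict[str, list[tuple[str, str, str]]] = {}
    for s in design.samples:
        reads = []
        for r in range(config.n_reads_per_sample):
            seq = "".join(
                bases[rng.choice(4, size=config.read_length, p=probs)]
            )
            quals = rng.integers(qlo, qhi + 1, size=config.read_length)
            qual = "".join(chr(33 + q) for q in quals)
            reads.append((f"{s}_read{r + 1}", seq, qual))
        out[s] = reads
    return out


# ---------------------------------------------------------------------------
# writers


def write_fasta(unigenes: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, seq in unigenes.items():
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def write_vcf(
    records: pd.DataFrame,
    unigenes: dict[str, str],
    design: SampleDesign,
    path: str | Path,
) -> None:
    """Write variant records as a sorted VCF v4.2 with GT:DP genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source="dioica synthetic variant generator"\n')
        for gene, seq in unigenes.items():
            fh.write(f"##contig=<ID={gene},length={len(seq)}>\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(design.samples)
            + "\n"
        )
        for _, row in records.iterrows():
            fields = [
                str(row["gene"]),
                str(int(row["pos"])),
                ".",
                row["ref"],
                row["alt"],
                ".",
                "PASS",
                ".",
                "GT:DP",
            ]
            for s in design.samples:
                allele = row[f"GT:{s}"]
                gt = "0/0" if allele == row["ref"] else "1/1"
                fields.append(f"{gt}:{int(row[f'DP:{s}'])}")
            fh.write("\t".join(fields) + "\n")


def genotype_table(records: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Flat genotype table (Gene_ID, Position, one column per individual)."""
    cols = {"Gene_ID": records["gene"], "Position": records["pos"]}
    for s in design.samples:
        cols[s] = records[f"GT:{s}"]
    return pd.DataFrame(cols)


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


@dataclass
class SyntheticDataset:
    """All pipeline inputs for one simulated experiment, plus ground truth."""

    config: SimulationConfig
    design: SampleDesign
    unigenes: dict[str, str]
    counts: pd.DataFrame
    variants: pd.DataFrame
    reads: dict[str, list[tuple[str, str, str]]]
    manifest: TruthManifest
    paths: dict[str, Path] = field(default_factory=dict)


def simulate_dataset(
    config: SimulationConfig, outdir: str | Path | None = None
) -> SyntheticDataset:
    """Generate every pipeline input; optionally write them under *outdir*.

    Writes, when *outdir* is given: ``unigenes.fasta``, ``counts.tsv``,
    ``samples.tsv``, ``variants.vcf``, ``genotypes.tsv`` (flat table),
    ``reads_<sample>.fastq``, ``truth_genes.tsv``, ``truth_sites.tsv`` and
    ``config.yaml``.
    """
    config.validate()
    design = config.design()
    unigenes = simulate_unigenes(config)
    counts, manifest = simulate_counts(config, unigenes)
    variants, manifest = simulate_variants(config, unigenes, manifest)
    reads = simulate_reads(config)
    ds = SyntheticDataset(config, design, unigenes, counts, variants, reads, manifest)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "unigenes.fasta",
            "counts": outdir / "counts.tsv",
            "samples": outdir / "samples.tsv",
            "vcf": outdir / "variants.vcf",
            "genotypes": outdir / "genotypes.tsv",
            "truth_genes": outdir / "truth_genes.tsv",
            "truth_sites": outdir / "truth_sites.tsv",
            "config": outdir / "config.yaml",
        }
        write_fasta(unigenes, paths["fasta"])
        write_counts(counts, paths["counts"])
        design.to_table(paths["samples"])
        write_vcf(variants, unigenes, design, paths["vcf"])
        genotype_table(variants, design).to_csv(
            paths["genotypes"], sep="\t", index=False
        )
        for s in design.samples:
            p = outdir / f"reads_{s}.fastq"
            write_fastq(reads[s], p)
            paths[f"fastq_{s}"] = p
        manifest.gene_class.rename_axis("gene").to_frame().to_csv(
            paths["truth_genes"], sep="\t"
        )
        truth_sites = manifest.seg_sites.assign(kind="sex-segregating")
        truth_sites = pd.concat(
            [
                truth_sites,
                manifest.decoy_sites,
                manifest.low_depth_sites.assign(kind="low-depth"),
            ],
            ignore_index=True,
        )
        truth_sites.to_csv(paths["truth_sites"], sep="\t", index=False)
        config.to_yaml(paths["config"])
        ds.paths = paths
    return ds
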