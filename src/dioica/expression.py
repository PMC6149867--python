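"""Sex-biased differential expression from a replicated count matrix.

The workflow mirrors the classic two-group RNA-seq comparison used in
male/female transcriptome studies of dioecious species:

1. median-of-ratios size factors normalise library depth;
2. a per-gene negative-binomial Wald test compares male and female means,
   with a method-of-moments dispersion pooled across the two groups and
   floored by the across-gene median so that triplicate designs stay
   calibrated (see :func:`test_differential`);
3. Benjamini-Hochberg step-up adjustment controls the false discovery rate;
4. genes are classed male-/female-biased at ``p_adj < alpha`` and
   ``|log2FC| >= lfc_threshold`` (log2FC is male over female, so male-biased
   means up-regulated in males);
5. among the biased genes, sex-specific genes are those with zero raw counts
   in every replicate of one sex and mean FPKM above a floor in the other;
6. a hierarchical clustering of samples on the biased genes checks that
   expression separates the sexes.

The NB model is parametrised by mean ``mu`` and dispersion ``alpha`` with
``Var = mu + alpha * mu**2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from dioica.design import SampleDesign
from dioica.errors import InputError

#: dispersion estimates are floored at this value (quasi-Poisson limit)
DISPERSION_FLOOR = 1e-8
#: pseudo-count used when a group mean is zero, so fold changes stay finite
PSEUDOCOUNT = 0.5

MALE_BIASED = "male-biased"
FEMALE_BIASED = "female-biased"
UNBIASED = "unbiased"
MALE_SPECIFIC = "male-specific"
FEMALE_SPECIFIC = "female-specific"
NOT_SPECIFIC = "none"


def _as_count_frame(counts: pd.DataFrame) -> pd.DataFrame:
    if counts.index.has_duplicates:
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate gene ids in count matrix: {dupes[:5]}")
    if (counts.values < 0).any():
        raise InputError("count matrix contains negative values")
    return counts


def compute_size_factors(
    counts: pd.DataFrame, allow_pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios size factors, one positive scalar per sample.

    Each gene's geometric mean across samples defines a pseudo-reference;
    a sample's factor is the median over genes of its count divided by that
    reference.  By default only genes with strictly positive counts in every
    sample enter the reference (the standard estimator); if none exist,
    ``allow_pseudo_reference=True`` switches to a zero-tolerant variant where
    each gene's geometric mean is taken over its positive counts only.
    """
    counts = _as_count_frame(counts)
    x = counts.to_numpy(dtype=float)
    all_positive = (x > 0).all(axis=1)
    if all_positive.any():
        ref = x[all_positive]
        log_geo = np.log(ref).mean(axis=1)
        ratios = np.log(ref) - log_geo[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    elif allow_pseudo_reference:
        logx = np.where(x > 0, np.log(np.maximum(x, 1e-300)), np.nan)
        log_geo = np.nanmean(logx, axis=1)
        usable = np.isfinite(log_geo)
        if not usable.any():
            raise InputError("count matrix is all zero; cannot normalise")
        ratios = logx[usable] - log_geo[usable, None]
        factors = np.exp(np.nanmedian(ratios, axis=0))
    else:
        raise InputError(
            "no gene has positive counts in every sample; rerun with "
            "allow_pseudo_reference=True to use a zero-tolerant reference"
        )
    if not np.all(np.isfinite(factors)) or (factors <= 0).any():
        raise InputError("size factor estimation produced non-positive factors")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``FPKM[g, s] = count[g, s] / (length_g / 1e3) / (library_size_s / 1e6)``.
    When *library_sizes* is omitted the column sums of *counts* are used.
    """
    counts = _as_count_frame(counts)
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise InputError(f"genes without a length: {missing[:5]}")
    bad = lengths[lengths < 1]
    if len(bad):
        raise InputError(f"non-positive length for gene {bad.index[0]!r}")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise InputError("library sizes must be positive")
    kb = lengths.to_numpy(dtype=float) / 1e3
    mil = library_sizes.to_numpy(dtype=float) / 1e6
    fpkm = counts.to_numpy(dtype=float) / kb[:, None] / mil[None, :]
    return pd.DataFrame(fpkm, index=counts.index, columns=counts.columns)


def test_differential(
    counts: pd.DataFrame,
    design: SampleDesign,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of male vs female mean expression.

    Returns a frame indexed by gene with columns ``baseMeanM``, ``baseMeanF``
    (group means of normalised counts), ``log2fc`` (male over female) and
    ``p``.  Genes with all-zero counts get ``log2fc = 0`` and ``p = 1``.

    Dispersion: each sex contributes a method-of-moments estimate
    ``(s^2 - m) / m^2`` on its normalised counts; the two are pooled by
    degrees of freedom, floored at ``DISPERSION_FLOOR``, and — because a
    3-replicate moment estimate is extremely noisy — floored again at the
    median of these estimates across all genes expressed in both sexes.
    Taking the larger of the per-gene and shared values shares information
    across genes without ever shrinking a gene's variance below its own
    evidence, so the Wald statistic for ``log(meanM) - log(meanF)`` (delta
    method on the NB variance of a group mean) can be referred to a normal
    distribution and stays calibrated at triplicate sample sizes.
    """
    counts = _as_count_frame(counts)
    design.require_replicates(2)
    if size_factors is None:
        size_factors = compute_size_factors(counts)
    norm = counts / size_factors

    cm = norm[design.males].to_numpy(dtype=float)
    cf = norm[design.females].to_numpy(dtype=float)
    n1, n2 = cm.shape[1], cf.shape[1]

    m1 = cm.mean(axis=1)
    m2 = cf.mean(axis=1)
    v1 = cm.var(axis=1, ddof=1)
    v2 = cf.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = np.where(m1 > 0, (v1 - m1) / np.square(np.maximum(m1, 1e-12)), 0.0)
        a2 = np.where(m2 > 0, (v2 - m2) / np.square(np.maximum(m2, 1e-12)), 0.0)
    w1 = np.where(m1 > 0, n1 - 1.0, 0.0)
    w2 = np.where(m2 > 0, n2 - 1.0, 0.0)
    disp = np.where(
        w1 + w2 > 0, (w1 * a1 + w2 * a2) / np.maximum(w1 + w2, 1.0), 0.0
    )
    disp = np.maximum(disp, DISPERSION_FLOOR)
    both_expressed = (m1 > 0) & (m2 > 0)
    shared = (
        float(np.median(disp[both_expressed]))
        if both_expressed.any()
        else DISPERSION_FLOOR
    )
    disp = np.maximum(disp, shared)

    # delta method: Var(log mean_k) ~= (mu_k + disp * mu_k^2) / (n_k * mu_k^2)
    m1f = np.maximum(m1, PSEUDOCOUNT)
    m2f = np.maximum(m2, PSEUDOCOUNT)
    var_log = (m1f + disp * m1f**2) / (n1 * m1f**2) + (
        m2f + disp * m2f**2
    ) / (n2 * m2f**2)
    z = (np.log(m1f) - np.log(m2f)) / np.sqrt(var_log)
    p = 2.0 * stats.norm.sf(np.abs(z))

    zero_either = (m1 == 0) | (m2 == 0)
    log2fc = np.where(
        zero_either,
        np.log2((m1 + PSEUDOCOUNT) / (m2 + PSEUDOCOUNT)),
        np.log2(np.where(zero_either, 1.0, m1) / np.where(zero_either, 1.0, m2)),
    )
    all_zero = (m1 == 0) & (m2 == 0)
    log2fc = np.where(all_zero, 0.0, log2fc)
    p = np.where(all_zero, 1.0, p)

    return pd.DataFrame(
        {"baseMeanM": m1, "baseMeanF": m2, "log2fc": log2fc, "p": p},
        index=counts.index,
    )


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorted p-values are scaled by ``m / rank``, a running minimum from the
    largest rank down enforces monotonicity, and values are capped at 1.
    Ties keep their original (stable) order, which cannot change the result.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InputError("adjust_bh expects a 1-d array of p-values")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def classify_deg(
    result: pd.DataFrame, alpha: float = 0.05, lfc_threshold: float = 1.0
) -> pd.Series:
    """Assign male-biased / female-biased / unbiased labels.

    A gene is male-biased iff ``p_adj < alpha`` (strict) and
    ``log2fc >= lfc_threshold`` (inclusive); female-biased symmetric with
    ``log2fc <= -lfc_threshold``; anything else is unbiased.
    """
    if "p_adj" not in result:
        raise InputError("result frame lacks a p_adj column; run adjust_bh first")
    sig = result["p_adj"] < alpha
    cls = pd.Series(UNBIASED, index=result.index, name="bias_class")
    cls[sig & (result["log2fc"] >= lfc_threshold)] = MALE_BIASED
    cls[sig & (result["log2fc"] <= -lfc_threshold)] = FEMALE_BIASED
    return cls


def classify_sex_specific(
    counts: pd.DataFrame,
    fpkm: pd.DataFrame,
    design: SampleDesign,
    deg_mask: pd.Series,
    fpkm_floor: float = 0.03,
    floor_mode: str = "mean",
) -> pd.Series:
    """Flag sex-specific genes among the differentially expressed ones.

    A male-specific gene has raw count 0 in every female replicate and
    expression above *fpkm_floor* in males (strictly greater); symmetric for
    female-specific.  ``floor_mode`` decides whether the floor applies to the
    mean FPKM of the expressing sex (``"mean"``) or to every replicate of it
    (``"all"``).  Genes outside *deg_mask* are never flagged: specificity is
    defined within the biased set.
    """
    if floor_mode not in ("mean", "all"):
        raise InputError(f"floor_mode must be 'mean' or 'all', got {floor_mode!r}")
    cls = pd.Series(NOT_SPECIFIC, index=counts.index, name="specificity")
    zero_f = (counts[design.females] == 0).all(axis=1)
    zero_m = (counts[design.males] == 0).all(axis=1)
    if floor_mode == "mean":
        expr_m = fpkm[design.males].mean(axis=1) > fpkm_floor
        expr_f = fpkm[design.females].mean(axis=1) > fpkm_floor
    else:
        expr_m = (fpkm[design.males] > fpkm_floor).all(axis=1)
        expr_f = (fpkm[design.females] > fpkm_floor).all(axis=1)
    deg = deg_mask.reindex(counts.index).fillna(False).astype(bool)
    cls[deg & zero_f & expr_m] = MALE_SPECIFIC
    cls[deg & zero_m & expr_f] = FEMALE_SPECIFIC
    return cls


@dataclass
class SampleClustering:
    """Hierarchical clustering of samples on biased-gene expression."""

    samples: tuple[str, ...]
    linkage: np.ndarray
    #: sample id -> cluster label (0 or 1) from cutting the tree into 2
    partition: dict[str, int]
    newick: str

    def splits_by_sex(self, design: SampleDesign) -> bool:
        """True iff the 2-group cut coincides with the sex labels."""
        a = {s for s, g in self.partition.items() if g == 0}
        return a == set(design.males) or a == set(design.females)


def cluster_samples(fpkm_degs: pd.DataFrame, design: SampleDesign) -> SampleClustering:
    """Average-linkage clustering of samples on log2(FPKM+1) of biased genes.

    Distance is ``1 - Pearson correlation`` between sample expression
    profiles.  Requires at least two genes; samples must follow the design.
    """
    if fpkm_degs.shape[0] < 2:
        raise InputError("sample clustering needs at least 2 differential genes")
    # canonical sample order so the result is invariant to column order
    mat = np.log2(fpkm_degs[list(design.samples)].to_numpy(dtype=float) + 1.0)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat.T)
    corr = np.nan_to_num(corr, nan=0.0)  # constant profiles: treat as uncorrelated
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.average(squareform(dist, checks=False))
    cut = hierarchy.fcluster(link, t=2, criterion="maxclust")
    # relabel so cluster ids are stable: first sample gets 0
    first = cut[0]
    partition = {s: int(c != first) for s, c in zip(design.samples, cut)}
    newick = _linkage_to_newick(link, list(design.samples))
    return SampleClustering(tuple(design.samples), link, partition, newick)


def _linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(link, labels)
    return str(tree).strip()


def run_differential_expression(
    counts: pd.DataFrame,
    design: SampleDesign,
    gene_lengths: pd.Series,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    fpkm_floor: float = 0.03,
    floor_mode: str = "mean",
) -> pd.DataFrame:
    """Full DE workflow: normalise, test, adjust, classify.

    Returns one row per gene with columns ``baseMeanM``, ``baseMeanF``,
    ``log2fc``, ``p``, ``p_adj``, ``bias_class`` and ``specificity``.
    """
    res = test_differential(counts, design)
    res["p_adj"] = adjust_bh(res["p"].to_numpy())
    res["bias_class"] = classify_deg(res, alpha=alpha, lfc_threshold=lfc_threshold)
    fpkm = compute_fpkm(counts, gene_lengths)
    deg_mask = res["bias_class"] != UNBIASED
    res["specificity"] = classify_sex_specific(
        counts, fpkm, design, deg_mask, fpkm_floor=fpkm_floor, floor_mode=floor_mode
    )
    return res
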