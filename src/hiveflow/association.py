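"""Genotype-behavior association statistics.

Polygenic scores (effect-size-weighted allele-dosage sums), hypergeometric
gene-list overlap with fold enrichment, and the standard group comparisons
used in reporting (one-way ANOVA with Tukey HSD post-hoc, Wilcoxon rank-sum,
Spearman rank correlation).  The effect allele is the alternative allele:
dosages count alternative-allele copies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["polygenic_score", "overlap_test", "OverlapResult", "group_stats",
           "GroupStatsResult", "rank_sum_test", "rank_correlation", "read_vcf_dosages"]


def polygenic_score(dosages: pd.DataFrame, effects) -> pd.Series:
    """Per-bee polygenic score: sum over SNPs of dosage times effect size.

    Parameters
    ----------
    dosages : DataFrame
        Bees x SNPs matrix of alternative-allele dosages in {0, 1, 2}; an
        optional ``bee_id`` column indexes the result.
    effects : mapping snp_id -> beta, or DataFrame with columns snp_id, beta

    Raises
    ------
    KeyError
        If any effect SNP is missing from the dosage matrix (all missing ids
        are listed).
    """
    if isinstance(effects, pd.DataFrame):
        effects = dict(zip(effects["snp_id"], effects["beta"]))
    df = dosages
    index = None
    if "bee_id" in df.columns:
        index = df["bee_id"]
        df = df.drop(columns=["bee_id"])
    missing = [s for s in effects if s not in df.columns]
    if missing:
        raise KeyError(f"SNPs absent from dosage matrix: {missing}")
    snps = list(effects)
    beta = np.array([effects[s] for s in snps], dtype=float)
    scores = df[snps].to_numpy(dtype=float) @ beta
    return pd.Series(scores, index=index, name="polygenic_score")


@dataclass(frozen=True)
class OverlapResult:
    overlap: int
    fold_enrichment: float
    p_value: float
    p_adjusted: float
    background_size: int
    size_a: int
    size_b: int


def overlap_test(list_a, list_b, background_size: int, n_tests: int = 1) -> OverlapResult:
    """Hypergeometric overlap test between two gene lists.

    The p-value is the upper tail P(X >= k) including the observed overlap,
    for a population of ``background_size`` genes with |A| successes and |B|
    draws; fold enrichment is k / (|A| |B| / N).  Bonferroni adjustment
    multiplies by ``n_tests``, capped at 1.
    """
    a, b = set(list_a), set(list_b)
    N = int(background_size)
    if len(a) > N or len(b) > N:
        raise ValueError("list larger than background")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    k = len(a & b)
    expected = len(a) * len(b) / N if N > 0 else np.nan
    fold = k / expected if expected > 0 else 0.0
    p = float(stats.hypergeom.sf(k - 1, N, len(a), len(b)))
    p = min(p, 1.0)
    return OverlapResult(
        overlap=k, fold_enrichment=float(fold), p_value=p,
        p_adjusted=min(1.0, p * n_tests), background_size=N,
        size_a=len(a), size_b=len(b),
    )


@dataclass
class GroupStatsResult:
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame
    rank_sum: tuple[float, float] | None   # (U statistic, p) when exactly 2 groups


def group_stats(values, groups) -> GroupStatsResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons (plus rank-sum for 2 groups).

    ``values`` and ``groups`` are equal-length sequences (one observation per
    bee).  Requires at least two groups, each with at least two observations
    and non-zero overall variance.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must align")
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("ANOVA needs at least two groups")
    samples = [values[groups == g] for g in uniq]
    for g, s in zip(uniq, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    if np.ptp(values) == 0:
        raise ValueError("all observations identical: F statistic undefined")
    f, p = stats.f_oneway(*samples)
    if not np.isfinite(f):
        raise ValueError("F statistic undefined (zero within-group variance)")

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tk = pairwise_tukeyhsd(values, groups)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    rank_sum = rank_sum_test(samples[0], samples[1]) if len(uniq) == 2 else None
    return GroupStatsResult(anova_f=float(f), anova_p=float(p), tukey=tukey,
                            rank_sum=rank_sum)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test; ties use midranks."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation for paired numeric vectors; ties use midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def read_vcf_dosages(path: str) -> pd.DataFrame:
    """Alternative-allele dosage matrix (samples x SNPs) from the GT fields of a VCF."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(path)
    samples = list(vcf.samples)
    snp_ids, columns = [], []
    for variant in vcf:
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        snp_ids.append(vid)
        gts = variant.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        dos = np.where(gts == 3, 2, np.where(gts == 1, 1, np.where(gts == 0, 0, -1)))
        columns.append(dos)
    df = pd.DataFrame(np.column_stack(columns) if columns else np.empty((len(samples), 0)),
                      columns=snp_ids)
    df.insert(0, "bee_id", samples)
    return df
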