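"""Differential genomic-feature battery between molecular grades.

Somatic mutations are VAF- and class-filtered, reduced to the most-mutated
genes, and tested per gene with two-sided Fisher's exact tests; copy-number
segments are ploidy-normalized, clipped to [-2, 2], intersected with cytoband
annotations, called amp/del at the clipped extremes and Fisher-tested with
amplifications and deletions as separate feature families; protein levels are
compared with two-sided Mann-Whitney U tests. Every family is BH-corrected.
The fold change for binary features is log2 of the ratio of altered-sample
percentages (high over low grade).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EXCLUDED_VARIANT_CLASSES",
    "EXCLUDED_GENES",
    "filter_mutations",
    "differential_mutation_test",
    "normalize_and_call_cna",
    "differential_cytoband_test",
    "differential_protein_test",
]

#: Variant classifications dropped before testing. "Silent" is the standard
#: MAF spelling of a synonymous change; both dialects are accepted.
EXCLUDED_VARIANT_CLASSES = frozenset(
    {"Intron", "3'Flank", "5'Flank", "Synonymous_Mutation", "Silent"}
)

#: Genes excluded for their high background mutation frequency driven by
#: sheer coding length.
EXCLUDED_GENES = frozenset({"TTN", "MUC16", "RYR2"})

VAF_FLOOR = 0.05


def filter_mutations(
    muts: pd.DataFrame,
    top_k: int = 15,
    excluded_genes: frozenset[str] = EXCLUDED_GENES,
    excluded_classes: frozenset[str] = EXCLUDED_VARIANT_CLASSES,
    vaf_floor: float = VAF_FLOOR,
) -> pd.DataFrame:
    """Apply the mutation-testing filters.

    Keeps variants with VAF > ``vaf_floor`` whose classification and gene are
    not excluded, then restricts to the ``top_k`` genes mutated in the most
    samples (ties broken alphabetically for determinism). Empty output is
    allowed.
    """
    df = muts.loc[
        (muts["vaf"] > vaf_floor)
        & ~muts["variant_classification"].isin(excluded_classes)
        & ~muts["gene"].isin(excluded_genes)
    ]
    if df.empty:
        return df.copy()
    per_gene = df.groupby("gene")["sample_id"].nunique()
    ranked = per_gene.sort_values(ascending=False).index
    ranked = sorted(ranked, key=lambda g: (-per_gene[g], g))
    keep = set(ranked[:top_k])
    return df[df["gene"].isin(keep)].copy()


def _binary_fisher_family(
    altered: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """Fisher + BH over a samples x features boolean alteration matrix."""
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    low_name, high_name = groups[0], groups[-1]
    # "m" prefix sorts mG1 < mG3 < mG4 so high is last; generic high/low too
    if set(groups) == {"high", "low"}:
        low_name, high_name = "low", "high"
    hi_ids = labels.index[labels == high_name]
    lo_ids = labels.index[labels == low_name]
    rows = []
    for feature in altered.columns:
        a = altered.loc[hi_ids, feature]
        b = altered.loc[lo_ids, feature]
        table = [[int(a.sum()), int(len(a) - a.sum())],
                 [int(b.sum()), int(len(b) - b.sum())]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        pct_hi = a.mean() * 100.0
        pct_lo = b.mean() * 100.0
        if pct_hi > 0 and pct_lo > 0:
            logfc = float(np.log2(pct_hi / pct_lo))
        elif pct_hi == 0 and pct_lo == 0:
            logfc = float("nan")
        else:
            logfc = float("inf") if pct_lo == 0 else float("-inf")
        rows.append((feature, table[0][0], len(a), table[1][0], len(b), p, logfc))
    res = pd.DataFrame(
        rows,
        columns=["feature", "n_altered_high", "n_high", "n_altered_low", "n_low", "p", "logfc"],
    ).set_index("feature")
    res["q"] = multipletests(res["p"].to_numpy(), method="fdr_bh")[1] if len(res) else []
    return res[["n_altered_high", "n_high", "n_altered_low", "n_low", "p", "q", "logfc"]]


def differential_mutation_test(muts: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-gene two-sided Fisher test of mutated/not x high/low grade.

    ``muts`` should already be filtered (:func:`filter_mutations`);
    ``labels`` maps sample_id -> mGrade. Samples absent from ``muts`` count
    as unmutated. logfc = log2(% mutated high / % mutated low), with +-inf
    sentinels when one group has no mutated sample (the test is still run).
    """
    if labels.nunique() != 2:
        raise ValueError("both mGrade groups must be represented")
    genes = sorted(muts["gene"].unique())
    altered = pd.DataFrame(False, index=labels.index, columns=genes)
    hits = muts[muts["sample_id"].isin(labels.index)]
    for gene, sub in hits.groupby("gene"):
        altered.loc[altered.index.intersection(sub["sample_id"].unique()), gene] = True
    return _binary_fisher_family(altered, labels)


def normalize_and_call_cna(segs: pd.DataFrame, cytobands: pd.DataFrame) -> pd.DataFrame:
    """Ploidy-normalize segments and call cytobands del/amp/neutral.

    normalized = clip(total_cn - ploidy, -2, 2). A cytoband is deleted for a
    sample when any overlapping segment (>= 1 bp, half-open coordinates)
    reaches -2, amplified when any reaches +2, neutral otherwise. A band hit
    by both extremes takes the state covering more of its bases (tie: amp) —
    calls therefore depend only on overlap topology, not on how segments are
    fragmented.

    Returns a samples x cytobands DataFrame with values in
    {"del", "amp", "neutral"}.
    """
    segs = segs.copy()
    if (segs["end"] <= segs["start"]).any():
        raise ValueError("segment with end <= start (coordinate convention mismatch?)")
    segs["norm_cn"] = np.clip(segs["total_cn"] - segs["ploidy"], -2, 2)
    samples = sorted(segs["sample_id"].unique())
    bands = list(cytobands["name"])
    calls = pd.DataFrame("neutral", index=pd.Index(samples, name="sample_id"), columns=bands)

    amp_cov = pd.DataFrame(0.0, index=calls.index, columns=bands)
    del_cov = pd.DataFrame(0.0, index=calls.index, columns=bands)
    for chrom, band_chr in cytobands.groupby("chrom"):
        seg_chr = segs[segs["chrom"] == chrom]
        if seg_chr.empty:
            continue
        for _, band in band_chr.iterrows():
            ov = seg_chr[(seg_chr["start"] < band["end"]) & (seg_chr["end"] > band["start"])]
            if ov.empty:
                continue
            width = np.minimum(ov["end"], band["end"]) - np.maximum(ov["start"], band["start"])
            extreme = ov.assign(width=width)
            amp = extreme[extreme["norm_cn"] >= 2].groupby("sample_id")["width"].sum()
            dele = extreme[extreme["norm_cn"] <= -2].groupby("sample_id")["width"].sum()
            amp_cov.loc[amp.index, band["name"]] += amp
            del_cov.loc[dele.index, band["name"]] += dele
    calls = calls.mask((amp_cov > 0) & (amp_cov >= del_cov), "amp")
    calls = calls.mask((del_cov > 0) & (del_cov > amp_cov), "del")
    return calls


def differential_cytoband_test(
    calls: pd.DataFrame, labels: pd.Series, min_altered: int = 3
) -> dict[str, pd.DataFrame]:
    """Fisher tests of cytoband amplification and deletion vs mGrade.

    Amplifications and deletions are separate feature families: each is
    BH-corrected on its own. Cytobands altered in fewer than ``min_altered``
    samples (within the family) are dropped before testing. Returns
    ``{"amp": table, "del": table}``.
    """
    if labels.nunique() != 2:
        raise ValueError("both mGrade groups must be represented")
    calls = calls.reindex(labels.index).fillna("neutral")
    out = {}
    for kind in ("amp", "del"):
        altered = calls == kind
        enough = altered.sum(axis=0) >= min_altered
        family = altered.loc[:, enough]
        out[kind] = (
            _binary_fisher_family(family, labels)
            if family.shape[1]
            else pd.DataFrame(
                columns=["n_altered_high", "n_high", "n_altered_low", "n_low", "p", "q", "logfc"]
            )
        )
    return out


def differential_protein_test(proteins: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per protein, BH-corrected.

    ``proteins`` is samples x proteins on a log-like scale; logfc is the
    difference of group means (high minus low). Proteins constant across
    both groups get p = 1 by convention.
    """
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    low_name, high_name = groups[0], groups[-1]
    if set(groups) == {"high", "low"}:
        low_name, high_name = "low", "high"
    hi = proteins.loc[labels.index[labels == high_name]]
    lo = proteins.loc[labels.index[labels == low_name]]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("need >= 2 samples per group")
    rows = []
    for protein in proteins.columns:
        a = hi[protein].dropna().to_numpy()
        b = lo[protein].dropna().to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            u, p = len(a) * len(b) / 2.0, 1.0
        else:
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append((protein, float(u), float(a.mean() - b.mean()), float(p)))
    res = pd.DataFrame(rows, columns=["feature", "U", "logfc", "p"]).set_index("feature")
    res["q"] = multipletests(res["p"].to_numpy(), method="fdr_bh")[1] if len(res) else []
    return res[["U", "logfc", "p", "q"]]
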