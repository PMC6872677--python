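"""Rarefaction and alpha diversity.

Richness, Shannon entropy (natural log by default) and Faith's phylogenetic
diversity (root-inclusive), with one-way ANOVA group comparisons and a
Spearman alpha-vs-environment correlation screen under Holm correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.oneway import anova_oneway

from .io import ENV_VARIABLES, OtuTable

logger = logging.getLogger(__name__)

__all__ = [
    "rarefy",
    "richness",
    "shannon",
    "faith_pd",
    "alpha_table",
    "alpha_group_test",
    "alpha_env_correlations",
]


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped (logged). A sample
    whose total equals ``depth`` is passed through unchanged. Single random
    draw (not an average over draws); deterministic under ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals.index[totals >= depth]
    dropped = totals.index.difference(keep)
    if len(dropped):
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                       len(dropped), depth, ", ".join(map(str, dropped)))
    if len(keep) == 0:
        raise ValueError(f"all samples have fewer than {depth} reads")
    out = {}
    for sid in keep:
        row = table.data.loc[sid].to_numpy()
        if row.sum() == depth:
            out[sid] = row
        else:
            out[sid] = rng.multivariate_hypergeometric(row, depth)
    df = pd.DataFrame.from_dict(out, orient="index", columns=table.otu_ids)
    return OtuTable(df.loc[list(keep)])


def _as_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("expected a 1-D vector of counts")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    if c.sum() == 0:
        raise ValueError("all-zero sample")
    return c


def richness(counts) -> int:
    """Number of OTUs with count > 0."""
    return int(np.count_nonzero(_as_counts(counts)))


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy H' = -sum p_i log p_i (natural log unless ``base``)."""
    c = _as_counts(counts)
    p = c[c > 0] / c.sum()
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base else h


def faith_pd(counts, otu_ids, tree: TreeNode, include_root: bool = True) -> float:
    """Faith's PD: branch length of the minimal subtree spanning observed tips.

    Root-inclusive by default (the path to the tree root counts even when a
    single taxon is present). With ``include_root=False`` the subtree is
    re-rooted at the most recent common ancestor of the observed tips.
    """
    c = _as_counts(counts)
    if len(c) != len(otu_ids):
        raise ValueError("counts and otu_ids length mismatch")
    present = [o for o, x in zip(otu_ids, c) if x > 0]
    tips = {t.name for t in tree.tips()}
    absent = [o for o in present if o not in tips]
    if absent:
        raise ValueError(f"OTU(s) not in tree: {absent[:5]}")
    pd_root = float(_skbio_faith_pd(c, taxa=list(otu_ids), tree=tree))
    if include_root:
        return pd_root
    if len(present) == 1:
        return 0.0
    mrca = tree.lca(present)
    return pd_root - _root_path_length(tree, mrca)


def _root_path_length(tree: TreeNode, node: TreeNode) -> float:
    total = 0.0
    while node is not tree:
        total += node.length or 0.0
        node = node.parent
    return total


def alpha_table(table: OtuTable, tree: TreeNode,
                shannon_base: float | None = None) -> pd.DataFrame:
    """Per-sample richness, Shannon and Faith's PD."""
    rows = {}
    for sid in table.sample_ids:
        c = table.data.loc[sid].to_numpy()
        rows[sid] = dict(
            richness=richness(c),
            shannon=shannon(c, base=shannon_base),
            faith_pd=faith_pd(c, table.otu_ids, tree),
        )
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def alpha_group_test(alpha: pd.DataFrame, groups: pd.Series,
                     welch: bool = False) -> pd.DataFrame:
    """One-way ANOVA of each alpha metric across groups.

    Classic equal-variance ANOVA by default; ``welch=True`` uses the
    unequal-variance (Welch) variant. Returns F, degrees of freedom and p
    per metric.
    """
    groups = groups.loc[alpha.index]
    sizes = groups.value_counts()
    if (sizes < 2).any() or len(sizes) < 2:
        raise ValueError("each of >= 2 groups needs >= 2 samples")
    rows = {}
    for metric in alpha.columns:
        arrays = [alpha.loc[groups == g, metric].to_numpy() for g in sizes.index]
        if welch:
            res = anova_oneway(arrays, use_var="unequal", welch_correction=True)
            f, p, df1, df2 = res.statistic, res.pvalue, res.df_num, res.df_denom
        else:
            f, p = stats.f_oneway(*arrays)
            df1 = len(arrays) - 1
            df2 = sum(len(a) for a in arrays) - len(arrays)
        rows[metric] = dict(F=float(f), df1=float(df1), df2=float(df2),
                            p=float(p))
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "metric"
    return out


def alpha_env_correlations(alpha: pd.DataFrame, meta: pd.DataFrame,
                           variables=None, min_n: int = 4) -> pd.DataFrame:
    """Spearman rho between each alpha metric and each environmental variable.

    Missing values are dropped pairwise per variable (the effective n is
    reported). p-values are Holm-adjusted within each metric's family of
    environmental variables; variables with fewer than ``min_n`` complete
    pairs yield NA and are excluded from the family.
    """
    if variables is None:
        variables = [v for v in ENV_VARIABLES if v in meta.columns]
    rows = []
    for metric in alpha.columns:
        fam = []
        for var in variables:
            pair = pd.concat([alpha[metric], meta.loc[alpha.index, var]],
                             axis=1).dropna()
            n = len(pair)
            if n >= min_n and pair.iloc[:, 1].nunique() == 1:
                logger.warning("alpha~%s vs %s: variable is constant, skipped",
                               metric, var)
                rows.append(dict(metric=metric, variable=var, rho=np.nan,
                                 p=np.nan, p_holm=np.nan, n=n))
                continue
            if n < min_n:
                logger.warning("alpha~%s vs %s: only %d complete pairs, skipped",
                               metric, var, n)
                rows.append(dict(metric=metric, variable=var, rho=np.nan,
                                 p=np.nan, p_holm=np.nan, n=n))
                continue
            rho, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            fam.append(len(rows))
            rows.append(dict(metric=metric, variable=var, rho=float(rho),
                             p=float(p), p_holm=np.nan, n=n))
        if fam:
            raw = np.array([rows[i]["p"] for i in fam])
            adj = multipletests(raw, method="holm")[1]
            for i, pa in zip(fam, adj):
                rows[i]["p_holm"] = float(pa)
    return pd.DataFrame(rows)
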