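"""Two-step phylogenetic null model for community assembly processes.

For every pair of communities the analysis computes:

1. **betaMNTD / betaNTI** — the abundance-weighted mean nearest-taxon
   phylogenetic distance between the two communities, standardised against a
   null distribution obtained by shuffling OTU labels across the tips of the
   phylogeny (equivalently, jointly permuting rows and columns of the
   patristic matrix). betaNTI = (obs - mean_null) / sd_null.
2. **RC_bray** — the position of the observed Bray-Curtis dissimilarity in a
   null distribution of dissimilarities between randomly assembled
   communities that preserve each sample's observed richness and read total:
   taxa are drawn with probability proportional to regional occupancy, then
   reads are filled with probability proportional to regional relative
   abundance. RC_bray = 2 * (ecdf - 0.5), in [-1, 1].

Pairs with betaNTI > +2 are classified heterogeneous selection and < -2
homogeneous selection; the remainder are split by RC_bray > +0.95 (dispersal
limitation), < -0.95 (homogenizing dispersal), or ecological drift.

The user-facing entry point is :class:`CommunityAssemblyModel`, whose
``fit()`` returns an :class:`AssemblyResults` carrying the pairwise tables,
classification and per-group process fractions.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

from .io import OtuTable, write_table

logger = logging.getLogger(__name__)

__all__ = [
    "PROCESSES",
    "patristic_matrix",
    "bmntd",
    "bnti_matrix",
    "rc_bray_matrix",
    "classify_process",
    "summarize_processes",
    "CommunityAssemblyModel",
    "AssemblyResults",
    "run_assembly",
]

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


def patristic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Sum of branch lengths along the path between every pair of tips."""
    return tree.tip_tip_distances()


def bmntd(x, y, pd_matrix, weighted: bool = True) -> float:
    """Between-community mean nearest-taxon distance for one sample pair.

    betaMNTD = 0.5 * [ sum_i f_i(x) min_{j in y} d(i,j)
                     + sum_j f_j(y) min_{i in x} d(j,i) ]
    with f the relative abundances (``weighted=True``) or 1/richness.
    Shared taxa have nearest-neighbour distance 0 (the match may be the
    taxon itself).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    D = pd_matrix.data if isinstance(pd_matrix, DistanceMatrix) else np.asarray(pd_matrix, float)
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("empty sample in betaMNTD")
    ix, iy = np.nonzero(x)[0], np.nonzero(y)[0]
    if not weighted:
        fx = np.ones(len(ix)) / len(ix)
        fy = np.ones(len(iy)) / len(iy)
    else:
        fx = x[ix] / x.sum()
        fy = y[iy] / y.sum()
    dxy = D[np.ix_(ix, iy)]
    return 0.5 * (float(fx @ dxy.min(axis=1)) + float(fy @ dxy.min(axis=0)))


def _freq_matrix(counts: np.ndarray, weighted: bool) -> np.ndarray:
    """Taxa-by-samples relative abundance (or incidence/richness) matrix."""
    C = counts.T.astype(float)
    if not weighted:
        C = (C > 0).astype(float)
    return C / C.sum(axis=0, keepdims=True)


def _bmntd_all_pairs(F: np.ndarray, D: np.ndarray,
                     taxa_of: list[np.ndarray]) -> np.ndarray:
    """betaMNTD for all sample pairs given frequency matrix and patristic D."""
    n_taxa, n_samples = F.shape
    dmin = np.empty((n_taxa, n_samples))
    for s in range(n_samples):
        dmin[:, s] = D[:, taxa_of[s]].min(axis=1)
    M = F.T @ dmin
    return 0.5 * (M + M.T)


def bnti_matrix(table: OtuTable, tree: TreeNode, n_null: int = 999,
                weighted: bool = True, seed: int | None = None):
    """Pairwise betaNTI against the tip-shuffling null.

    One tip-label permutation is drawn per null iteration and shared by all
    sample pairs. Returns ``(bnti, bmntd_obs)`` DataFrames; a pair whose
    null standard deviation is zero gets NA (warned).
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    pdm = patristic_matrix(tree)
    order = list(pdm.ids)
    missing = set(table.otu_ids) - set(order)
    if missing:
        raise ValueError(f"{len(missing)} OTU(s) not in tree")
    data = table.data.reindex(columns=[o for o in order if o in set(table.otu_ids)])
    D = pdm.filter(list(data.columns)).data
    counts = data.to_numpy()
    F = _freq_matrix(counts, weighted)
    taxa_of = [np.nonzero(counts[s])[0] for s in range(counts.shape[0])]

    obs = _bmntd_all_pairs(F, D, taxa_of)
    rng = np.random.default_rng(seed)
    n_taxa = D.shape[0]
    total = np.zeros_like(obs)
    total_sq = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n_taxa)
        null = _bmntd_all_pairs(F, D[np.ix_(perm, perm)], taxa_of)
        total += null
        total_sq += null**2
    mean = total / n_null
    var = (total_sq - n_null * mean**2) / (n_null - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        bnti = (obs - mean) / sd
    bnti[sd == 0] = np.nan
    np.fill_diagonal(bnti, 0.0)
    if np.isnan(bnti[np.triu_indices_from(bnti, 1)]).any():
        logger.warning("betaNTI undefined (zero null variance) for some pairs")
    ids = table.sample_ids
    return (pd.DataFrame(bnti, index=ids, columns=ids),
            pd.DataFrame(obs, index=ids, columns=ids))


def _weighted_subset(rng: np.random.Generator, log_w: np.ndarray, k: int) -> np.ndarray:
    """k indices sampled without replacement with prob ∝ exp(log_w).

    Exponential-keys (Efraimidis-Spirakis) scheme: the k largest values of
    log_w + Gumbel noise form an exact weighted sample.
    """
    keys = log_w + rng.gumbel(size=log_w.shape)
    return np.argpartition(keys, -k)[-k:]


def rc_bray_matrix(table: OtuTable, n_null: int = 999, seed: int | None = None,
                   mode: str = "abundance") -> pd.DataFrame:
    """Pairwise Bray-Curtis Raup-Crick against a null-assembly model.

    Each null iteration rebuilds every sample independently: its observed
    richness is drawn as taxa sampled with probability proportional to
    regional occupancy frequency, then the sample is filled to its observed
    read total with probability proportional to regional relative abundance
    (``mode='abundance'``; ``mode='richness_only'`` stops at presence).
    RC = 2 * ([#null < obs] + 0.5 [#null = obs]) / n_null - 1.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    if mode not in ("abundance", "richness_only"):
        raise ValueError("mode must be 'abundance' or 'richness_only'")
    counts = table.counts
    n_samples, n_taxa = counts.shape
    if n_samples < 2:
        raise ValueError("RC_bray needs at least two samples")
    occupancy = (counts > 0).sum(axis=0).astype(float)
    pool = counts.sum(axis=0).astype(float)
    pool_rel = pool / pool.sum()
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)

    if mode == "richness_only":
        obs_bc = pdist((counts > 0).astype(float), metric="braycurtis")
    else:
        obs_bc = pdist(counts.astype(float), metric="braycurtis")

    rng = np.random.default_rng(seed)
    log_occ = np.log(occupancy)  # occupancy >= 1 for every retained OTU
    n_less = np.zeros_like(obs_bc)
    n_eq = np.zeros_like(obs_bc)
    null = np.zeros((n_samples, n_taxa))
    for _ in range(n_null):
        null[:] = 0.0
        for s in range(n_samples):
            chosen = _weighted_subset(rng, log_occ, int(richness[s]))
            null[s, chosen] = 1.0
            fill = int(totals[s] - richness[s])
            if mode == "abundance" and fill > 0:
                p = pool_rel[chosen]
                null[s, chosen] += rng.multinomial(fill, p / p.sum())
        null_bc = pdist(null, metric="braycurtis")
        n_less += null_bc < obs_bc - 1e-10
        n_eq += np.abs(null_bc - obs_bc) <= 1e-10
    rc_raw = (n_less + 0.5 * n_eq) / n_null
    rc = squareform(2.0 * (rc_raw - 0.5), checks=False)
    ids = table.sample_ids
    return pd.DataFrame(rc, index=ids, columns=ids)


def classify_process(bnti: float, rc: float,
                     bnti_threshold: float = BNTI_THRESHOLD,
                     rc_threshold: float = RC_THRESHOLD):
    """Assign one pairwise comparison to an ecological process.

    Selection first (betaNTI beyond +-threshold, sign giving heterogeneous
    vs homogeneous), then dispersal by RC_bray beyond +-rc_threshold, with
    ecological drift as the residual category. NA inputs give NA.
    """
    if bnti is None or (isinstance(bnti, float) and np.isnan(bnti)):
        return np.nan
    if bnti > bnti_threshold:
        return "heterogeneous_selection"
    if bnti < -bnti_threshold:
        return "homogeneous_selection"
    if rc is None or (isinstance(rc, float) and np.isnan(rc)):
        return np.nan
    if rc > rc_threshold:
        return "dispersal_limitation"
    if rc < -rc_threshold:
        return "homogenizing_dispersal"
    return "drift"


def summarize_processes(pairs: pd.DataFrame, grouping: pd.Series | None = None,
                        scope: str = "within_group") -> pd.DataFrame:
    """Fraction of pairwise comparisons assigned to each process, per group.

    ``scope='within_group'`` restricts each group's denominator to pairs
    where both samples belong to the group; ``'all_pairs'`` pools everything
    into one row. NA-classified pairs are excluded from the denominator and
    reported in ``n_na``.
    """
    if scope not in ("within_group", "all_pairs"):
        raise ValueError("scope must be 'within_group' or 'all_pairs'")

    def _row(sub: pd.DataFrame) -> dict:
        valid = sub["process"].dropna()
        row = {p: np.nan for p in PROCESSES}
        if len(valid):
            frac = valid.value_counts(normalize=True)
            row = {p: float(frac.get(p, 0.0)) for p in PROCESSES}
        row["n_pairs"] = int(len(valid))
        row["n_na"] = int(len(sub) - len(valid))
        return row

    if scope == "all_pairs" or grouping is None:
        out = pd.DataFrame.from_dict({"all": _row(pairs)}, orient="index")
    else:
        g = pd.Series(grouping)
        rows = {}
        for label in pd.unique(g):
            members = set(g.index[g == label])
            sub = pairs[pairs["sample_1"].isin(members)
                        & pairs["sample_2"].isin(members)]
            rows[label] = _row(sub)
            if rows[label]["n_pairs"] == 0:
                logger.warning("group %s has no valid within-group pairs", label)
        out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "group"
    return out


class CommunityAssemblyModel:
    """Phylogenetic null model of pairwise community assembly.

    Parameters
    ----------
    table : OtuTable
        Rarefied, untransformed integer counts (the RC null resamples reads).
    tree : TreeNode
        Rooted phylogeny whose tips cover every OTU in the table.
    metadata : DataFrame, optional
        Per-sample metadata; used for group summaries.
    weighted : bool
        Abundance-weight betaMNTD (default) or use incidence.
    bnti_threshold, rc_threshold : float
        Classification cutoffs (|betaNTI| = 2 and |RC| = 0.95 by convention).
    rc_mode : str
        RC null variant: ``'abundance'`` (richness + read total preserved)
        or ``'richness_only'``.
    """

    def __init__(self, table: OtuTable, tree: TreeNode,
                 metadata: pd.DataFrame | None = None, weighted: bool = True,
                 bnti_threshold: float = BNTI_THRESHOLD,
                 rc_threshold: float = RC_THRESHOLD,
                 rc_mode: str = "abundance"):
        tips = {t.name for t in tree.tips()}
        missing = set(table.otu_ids) - tips
        if missing:
            raise ValueError(
                f"{len(missing)} OTU(s) in the table are not tips of the tree; "
                "run align_inputs first")
        self.table = table
        self.tree = tree
        self.metadata = metadata
        self.weighted = weighted
        self.bnti_threshold = float(bnti_threshold)
        self.rc_threshold = float(rc_threshold)
        self.rc_mode = rc_mode

    def fit(self, n_null: int = 999, seed: int | None = None) -> "AssemblyResults":
        """Run both null models and classify every sample pair."""
        ss = np.random.SeedSequence(seed if seed is not None else 0)
        s_bnti, s_rc = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2)]
        bnti, bmntd_obs = bnti_matrix(self.table, self.tree, n_null=n_null,
                                      weighted=self.weighted, seed=s_bnti)
        rc = rc_bray_matrix(self.table, n_null=n_null, seed=s_rc,
                            mode=self.rc_mode)
        ids = self.table.sample_ids
        recs = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                b = bnti.iat[i, j]
                r = rc.iat[i, j]
                recs.append(dict(
                    sample_1=ids[i], sample_2=ids[j],
                    bmntd=bmntd_obs.iat[i, j], bnti=b, rc_bray=r,
                    process=classify_process(b, r, self.bnti_threshold,
                                             self.rc_threshold)))
        pairs = pd.DataFrame(recs)
        return AssemblyResults(model=self, bnti=bnti, rc_bray=rc,
                               bmntd_obs=bmntd_obs, pairs=pairs,
                               n_null=n_null, seed=seed)


class AssemblyResults:
    """Fitted pairwise assembly inference.

    Attributes
    ----------
    bnti, rc_bray, bmntd_obs : DataFrame
        Square sample-by-sample matrices.
    pairs : DataFrame
        One row per unordered sample pair with betaMNTD, betaNTI, RC_bray
        and the assigned process.
    """

    def __init__(self, model, bnti, rc_bray, bmntd_obs, pairs, n_null, seed):
        self.model = model
        self.bnti = bnti
        self.rc_bray = rc_bray
        self.bmntd_obs = bmntd_obs
        self.pairs = pairs
        self.n_null = n_null
        self.seed = seed

    def process_fractions(self, grouping: pd.Series | None = None,
                          scope: str = "within_group") -> pd.DataFrame:
        """Per-group (or pooled) fractions of pairs assigned to each process."""
        if grouping is None and scope == "within_group":
            scope = "all_pairs"
        return summarize_processes(self.pairs, grouping, scope=scope)

    def summary(self) -> str:
        """Human-readable account of the fit."""
        frac = self.process_fractions(scope="all_pairs").iloc[0]
        b = self.pairs["bnti"].dropna()
        lines = [
            "Community assembly null-model results",
            "=" * 45,
            f"samples:            {self.model.table.n_samples}",
            f"OTUs:               {self.model.table.n_otus}",
            f"pairs:              {len(self.pairs)}",
            f"null iterations:    {self.n_null}",
            f"betaMNTD weighting: {'abundance' if self.model.weighted else 'incidence'}",
            f"thresholds:         |betaNTI| > {self.model.bnti_threshold:g}, "
            f"|RC_bray| > {self.model.rc_threshold:g}",
            f"betaNTI:            mean {b.mean():.3f}, sd {b.std():.3f}",
            "-" * 45,
            "process fractions (all pairs):",
        ]
        for p in PROCESSES:
            lines.append(f"  {p:<24s} {frac[p]:6.1%}")
        lines.append(f"  valid pairs: {int(frac['n_pairs'])}, NA: {int(frac['n_na'])}")
        return "\n".join(lines)

    def to_files(self, out_dir, grouping: pd.Series | None = None,
                 scope: str = "within_group", header_lines=()) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(self.bnti, out / "bnti.tsv", header_lines)
        write_table(self.rc_bray, out / "rcbray.tsv", header_lines)
        write_table(self.pairs, out / "processes.tsv", header_lines, index=False)
        write_table(self.process_fractions(grouping, scope=scope),
                    out / "process_summary.tsv", header_lines)
        run = dict(n_null=self.n_null, seed=self.seed,
                   weighted=self.model.weighted,
                   bnti_threshold=self.model.bnti_threshold,
                   rc_threshold=self.model.rc_threshold,
                   rc_mode=self.model.rc_mode, scope=scope,
                   n_samples=self.model.table.n_samples,
                   n_otus=self.model.table.n_otus)
        with open(out / "assembly_run.json", "w", encoding="utf-8") as fh:
            json.dump(run, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_assembly(table: OtuTable, tree: TreeNode, meta: pd.DataFrame,
                 n_null: int = 999, seed: int | None = None,
                 weighted: bool = True, bnti_threshold: float = BNTI_THRESHOLD,
                 rc_threshold: float = RC_THRESHOLD, scope: str = "within_group",
                 group_col: str = "subgroup", out_dir=None) -> AssemblyResults:
    """Convenience wrapper: fit the model and optionally write result tables."""
    model = CommunityAssemblyModel(table, tree, metadata=meta, weighted=weighted,
                                   bnti_threshold=bnti_threshold,
                                   rc_threshold=rc_threshold)
    results = model.fit(n_null=n_null, seed=seed)
    grouping = meta[group_col] if (meta is not None and group_col in meta) else None
    if out_dir is not None:
        results.to_files(out_dir, grouping=grouping, scope=scope)
    return results
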