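"""One-command orchestration: rarefy -> alpha -> beta/ordination -> assembly.

`run_all` executes the full analysis on real or synthetic inputs with named,
per-stage seeded random streams, writes every result table with a header
recording version, config hash and seeds, and returns a machine-readable
run report. Identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, assembly, community, diversity, io, simulate

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "validate_config", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Normalized configuration of a full pipeline run."""

    otu_table: str | None = None
    tree: str | None = None
    metadata: str | None = None
    generate: dict | None = None          # ScenarioConfig kwargs
    out_dir: str = "results"
    depth: int = 13595
    seed: int = 0
    n_perm: int = 9999
    n_null: int = 999
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    group_col: str = "subgroup"
    geo_mode: str = "cartesian"
    mantel_method: str = "spearman"
    scope: str = "within_group"
    weighted: bool = True
    samples_in_rows: bool = False
    nmds_restarts: int = 20
    shannon_base: float | None = None

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        if self.n_null < 99:
            raise ValueError("n_null must be >= 99")
        if self.generate is None and not (self.otu_table and self.tree
                                          and self.metadata):
            raise ValueError("provide either input paths (otu_table, tree, "
                             "metadata) or a generate scenario")


def validate_config(raw: dict) -> RunConfig:
    """Fill defaults and reject unknown keys (with a spelling suggestion)."""
    accepted = {f.name for f in dataclasses.fields(RunConfig)}
    for key in raw:
        if key not in accepted:
            hint = difflib.get_close_matches(key, accepted, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {key!r}{suggestion} "
                             f"(accepted: {', '.join(sorted(accepted))})")
    return RunConfig(**raw)


def _config_hash(config: RunConfig) -> str:
    payload = dataclasses.asdict(config)
    payload.pop("out_dir", None)  # analysis settings only, not where they land
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("scenario", "rarefy", "nmds", "anosim", "mantel",
             "partial_mantel", "decay", "assembly")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31))
            for n, c in zip(names, children)}


def _usable_grouping(groups: pd.Series) -> bool:
    sizes = groups.value_counts()
    return len(sizes) >= 2 and (sizes >= 2).all()


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run report (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    header = [f"intertidal {__version__}",
              f"config {_config_hash(config)}",
              "seeds " + " ".join(f"{k}={v}" for k, v in sorted(seeds.items()))]
    report: dict = {"version": __version__, "config_hash": _config_hash(config),
                    "seeds": seeds, "stages": {}, "effective_n": {}}

    def _stage(name):
        def deco(fn):
            try:
                value = fn()
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            report["stages"][name] = "ok"
            return value
        return deco

    @_stage("load")
    def inputs():
        if config.generate is not None:
            scen = dict(config.generate)
            scen.setdefault("seed", seeds["scenario"])
            bundle = simulate.generate_bundle(simulate.ScenarioConfig(**scen),
                                              out_dir=out / "inputs")
            return bundle.table, bundle.tree, bundle.metadata
        table = io.read_otu_table(config.otu_table,
                                  samples_in_rows=config.samples_in_rows)
        tree = io.read_tree(config.tree)
        meta = io.read_metadata(config.metadata)
        return table, tree, meta

    table, tree, meta = inputs

    @_stage("align")
    def aligned():
        return io.align_inputs(table, tree, meta)

    table, tree, meta = aligned

    @_stage("rarefy")
    def rarefied():
        t = diversity.rarefy(table, config.depth, seed=seeds["rarefy"])
        return io.align_inputs(t, tree, meta)

    table, tree, meta = rarefied
    report["effective_n"]["samples"] = table.n_samples
    report["effective_n"]["otus"] = table.n_otus
    groups = meta[config.group_col] if config.group_col in meta else None
    grouping_ok = groups is not None and _usable_grouping(groups)
    if not grouping_ok:
        logger.warning("grouping %r unusable (needs >= 2 groups of >= 2); "
                       "group-based tests skipped", config.group_col)

    @_stage("alpha")
    def alpha_tables():
        alpha = diversity.alpha_table(table, tree, shannon_base=config.shannon_base)
        io.write_table(alpha, out / "alpha.tsv", header)
        if grouping_ok:
            tests = diversity.alpha_group_test(alpha, groups)
            io.write_table(tests, out / "alpha_tests.tsv", header)
        corr = diversity.alpha_env_correlations(alpha, meta)
        io.write_table(corr, out / "alpha_env_corr.tsv", header, index=False)
        return alpha

    alpha = alpha_tables

    @_stage("beta")
    def beta_results():
        res: dict = {}
        logged = community.transform_community(table)
        bc = community.bray_curtis(logged)
        io.write_distance_matrix(bc, out / "bray_curtis.tsv", header)
        ord_ = community.nmds(bc, k=2, n_restarts=config.nmds_restarts,
                              seed=seeds["nmds"])
        io.write_table(ord_.coordinates, out / "nmds.tsv",
                       header + [f"stress {ord_.stress:.6f}"])
        res["nmds_stress"] = ord_.stress
        if grouping_ok:
            a = community.anosim(bc, groups, n_perm=config.n_perm,
                                 seed=seeds["anosim"])
            io.write_table(pd.DataFrame([dataclasses.asdict(a)]),
                           out / "anosim.tsv", header, index=False)
            res["anosim_R"] = a.statistic
            res["anosim_p"] = a.p_value
            community.plot_nmds(ord_, groups, out / "nmds.png")
        env = community.transform_env(meta)
        env_complete = env.dropna(axis=1)
        geo = community.geo_distance_matrix(meta, mode=config.geo_mode)
        rows = []
        if env_complete.shape[1] >= 2:
            z = (env_complete - env_complete.mean()) / env_complete.std(ddof=1)
            z = z.dropna(axis=1)
            from scipy.spatial.distance import pdist, squareform
            envd = community.DistanceMatrix(
                squareform(pdist(z.to_numpy())), ids=[str(i) for i in z.index])
            report["effective_n"]["env_variables"] = z.shape[1]
            m_env = community.mantel(bc, envd, n_perm=config.n_perm,
                                     method=config.mantel_method,
                                     seed=seeds["mantel"])
            rows.append(dict(test="mantel_env", **dataclasses.asdict(m_env)))
            pm_env = community.partial_mantel(bc, envd, geo,
                                              n_perm=config.n_perm,
                                              method=config.mantel_method,
                                              seed=seeds["partial_mantel"])
            rows.append(dict(test="partial_mantel_env_given_geo",
                             **dataclasses.asdict(pm_env)))
            pm_geo = community.partial_mantel(bc, geo, envd,
                                              n_perm=config.n_perm,
                                              method=config.mantel_method,
                                              seed=seeds["partial_mantel"])
            rows.append(dict(test="partial_mantel_geo_given_env",
                             **dataclasses.asdict(pm_geo)))
            pca = community.pca_env(env_complete)
            io.write_table(pca.scores, out / "env_pca.tsv",
                           header + ["variance_fractions " + " ".join(
                               f"{f:.4f}" for f in pca.proportion_explained)])
        m_geo = community.mantel(bc, geo, n_perm=config.n_perm,
                                 method=config.mantel_method,
                                 seed=seeds["mantel"])
        rows.append(dict(test="mantel_geo", **dataclasses.asdict(m_geo)))
        dd = community.distance_decay(bc, geo, n_perm=config.n_perm,
                                      seed=seeds["decay"])
        rows.append(dict(test="distance_decay", **dataclasses.asdict(dd)))
        io.write_table(pd.DataFrame(rows), out / "mantel.tsv", header, index=False)
        io.write_table(pd.DataFrame(rows[-1:]), out / "distance_decay.tsv",
                       header, index=False)
        res["distance_decay_r"] = dd.statistic
        res["distance_decay_p"] = dd.p_value
        if grouping_ok and meta["habitat"].nunique() == 2:
            tt = community.env_group_test(env, meta["habitat"])
            io.write_table(tt, out / "env_group_tests.tsv", header)
        return res

    report["beta"] = beta_results

    @_stage("assembly")
    def assembly_results():
        model = assembly.CommunityAssemblyModel(
            table, tree, metadata=meta, weighted=config.weighted,
            bnti_threshold=config.bnti_threshold,
            rc_threshold=config.rc_threshold)
        results = model.fit(n_null=config.n_null, seed=seeds["assembly"])
        results.to_files(out, grouping=groups if grouping_ok else None,
                         scope=config.scope, header_lines=header)
        frac = results.process_fractions(
            groups if grouping_ok else None,
            scope=config.scope if grouping_ok else "all_pairs")
        return {"process_fractions": json.loads(frac.to_json(orient="index")),
                "n_pairs": int(len(results.pairs))}

    report["assembly"] = assembly_results
    report["alpha_mean"] = {k: float(alpha[k].mean()) for k in alpha.columns}
    with open(out / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
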