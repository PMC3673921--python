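"""Config-driven orchestration of the full multi-scale analysis.

:func:`run_pipeline` reproduces the whole workflow on one community table:
per-site additive diversity partition, per-estuary accumulation curves,
within-estuary Jaccard / |Δβ-conn| / spatial / environmental distance
matrices, a Mantel battery, Spearman correlations among diversity levels,
Kruskal-Wallis comparisons across estuaries, and a correlation-matrix PCA of
the estuary environment.  Every output is a tidy CSV in the output
directory, plus a plain-text run log recording versions, seed and options.

Any stage failure aborts the run with a stage-named error and removes the
partial outputs already written.  All randomness derives from the single
top-level seed, fanned out deterministically per stage, so identical
config + seed reruns are byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import (
    IncidenceMatrix,
    read_community,
    read_estuary_environment,
    read_site_environment,
)
from .distance import (
    environmental_distance,
    pairwise_jaccard,
    site_label,
    spatial_distance,
    value_difference_matrix,
    within_estuary_jaccard,
    write_distance_matrix,
)
from .inference import (
    collinearity_screen,
    holm_adjust,
    kruskal_wallis,
    mantel_test,
    pca_correlation,
    spearman_rho,
)
from .partition import estuary_diversity_table, site_diversity_table
from .rarefaction import accumulation_curve

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

MIN_MANTEL_UNITS = 4  # permutation null is degenerate below this


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Inputs and options for one pipeline run."""

    community: Path
    outdir: Path
    site_env: Path | None = None
    estuary_env: Path | None = None
    site_coords: Path | None = None
    estuary_coords: Path | None = None
    rarefy_to: int | None = None
    standardize: bool = True
    spatial_mode: str = "euclidean"
    mantel_method: str = "pearson"
    mantel_tail: str = "greater"
    n_permutations: int = 9999
    accumulation_permutations: int = 200
    holm: bool = False
    seed: int | None = None

    def __post_init__(self):
        self.community = Path(self.community)
        self.outdir = Path(self.outdir)
        for name in ("site_env", "estuary_env", "site_coords", "estuary_coords"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))
        for name in ("community", "site_env", "estuary_env", "site_coords", "estuary_coords"):
            v = getattr(self, name)
            if v is not None and not v.exists():
                raise FileNotFoundError(f"{name} path does not exist: {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _keyed_table(path: Path, keys: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [k for k in keys if k not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing key columns {missing}")
    return df.set_index(keys)


class _OutputTracker:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.written: list[Path] = []

    def path(self, name: str) -> Path:
        p = self.outdir / name
        self.written.append(p)
        return p

    def cleanup(self) -> None:
        for p in self.written:
            p.unlink(missing_ok=True)


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns a name -> path map of the written outputs."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    out = _OutputTracker(cfg.outdir)
    outputs: dict[str, Path] = {}
    stage = "load"
    root_seed = np.random.SeedSequence(cfg.seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ("accumulation", "mantel"), root_seed.spawn(2)
        )
    }
    try:
        m = read_community(cfg.community)
        site_env = (
            read_site_environment(cfg.site_env) if cfg.site_env else None
        )
        estuary_env = (
            read_estuary_environment(cfg.estuary_env) if cfg.estuary_env else None
        )
        site_coords = (
            _keyed_table(cfg.site_coords, ["estuary", "site"])
            if cfg.site_coords
            else None
        )
        estuary_coords = (
            _keyed_table(cfg.estuary_coords, ["estuary"])
            if cfg.estuary_coords
            else None
        )

        stage = "site_diversity"
        site_div = site_diversity_table(m, rarefy_to=cfg.rarefy_to)
        p = out.path("site_diversity.csv")
        site_div.to_csv(p, index=False)
        outputs["site_diversity"] = p

        stage = "estuary_diversity"
        est_div = estuary_diversity_table(m)
        p = out.path("estuary_diversity.csv")
        est_div.to_csv(p, index=False)
        outputs["estuary_diversity"] = p

        stage = "accumulation"
        curves = []
        for e in m.estuaries():
            curve = accumulation_curve(
                m.estuary_incidence(e),
                n_perm=cfg.accumulation_permutations,
                seed=stage_seeds["accumulation"],
            )
            curves.append(curve.to_frame(unit=e))
        p = out.path("accumulation_curves.csv")
        pd.concat(curves, ignore_index=True).to_csv(p, index=False)
        outputs["accumulation_curves"] = p

        stage = "distance_matrices"
        jac_site = within_estuary_jaccard(m)
        matrices: dict[str, dict[str, object]] = {"jaccard": jac_site}
        dconn: dict[str, object] = {}
        for e in m.estuaries():
            sub = site_div[site_div["estuary"] == e]
            if len(sub) >= 2:
                series = pd.Series(
                    sub["beta_conn"].to_numpy(),
                    index=[site_label(e, s) for s in sub["site"]],
                )
                dconn[e] = value_difference_matrix(series)
        matrices["beta_conn_diff"] = dconn
        dspace: dict[str, object] = {}
        if site_coords is not None:
            for e in m.estuaries():
                keys = [k for k in m.sites(e)]
                rows = site_coords.loc[keys]
                rows.index = [site_label(*k) for k in keys]
                if len(rows) >= 2:
                    dspace[e] = spatial_distance(rows, mode=cfg.spatial_mode)
        matrices["spatial"] = dspace
        denv: dict[str, object] = {}
        if site_env is not None:
            for e in m.estuaries():
                keys = [k for k in m.sites(e) if k in site_env.table.index]
                if len(keys) >= 2:
                    rows = site_env.variables().loc[keys]
                    rows.index = [site_label(*k) for k in keys]
                    denv[e] = environmental_distance(
                        rows, standardize=cfg.standardize
                    )
        matrices["environmental"] = denv
        for kind, per_est in matrices.items():
            for e, dm in per_est.items():
                p = out.path(f"dist_{kind}_{e}.csv")
                write_distance_matrix(dm, p)
                outputs[f"dist_{kind}_{e}"] = p
        between: dict[str, object] = {}
        if len(m.estuaries()) >= 2:
            between["jaccard"] = pairwise_jaccard(m, level="estuary")
            if estuary_coords is not None:
                common = [e for e in m.estuaries() if e in estuary_coords.index]
                if len(common) >= 2:
                    between["spatial"] = spatial_distance(
                        estuary_coords.loc[common], mode=cfg.spatial_mode
                    )
                else:
                    warnings.warn(
                        "estuary coordinates share <2 estuaries with the "
                        "community; skipping between-estuary spatial distance",
                        stacklevel=2,
                    )
            if estuary_env is not None:
                common = [e for e in m.estuaries() if e in estuary_env.table.index]
                if len(common) >= 2:
                    between["environmental"] = environmental_distance(
                        estuary_env.variables().loc[common],
                        standardize=cfg.standardize,
                    )
                else:
                    warnings.warn(
                        "estuary environment shares <2 estuaries with the "
                        "community; skipping between-estuary environmental "
                        "distance",
                        stacklevel=2,
                    )
            for kind, dm in between.items():
                p = out.path(f"dist_{kind}_estuaries.csv")
                write_distance_matrix(dm, p)
                outputs[f"dist_{kind}_estuaries"] = p

        stage = "mantel"
        mantel_rows = []
        pairs = [
            ("jaccard", "spatial"),
            ("jaccard", "environmental"),
            ("beta_conn_diff", "spatial"),
            ("beta_conn_diff", "environmental"),
        ]
        for a, b in pairs:
            for e in m.estuaries():
                dx = matrices[a].get(e)
                dy = matrices[b].get(e)
                if dx is None or dy is None:
                    continue
                if len(dx.ids) < MIN_MANTEL_UNITS:
                    warnings.warn(
                        f"estuary {e}: <{MIN_MANTEL_UNITS} sites, "
                        f"skipping Mantel {a} vs {b}",
                        stacklevel=2,
                    )
                    continue
                res = mantel_test(
                    dx,
                    dy,
                    n_perm=cfg.n_permutations,
                    method=cfg.mantel_method,
                    tail=cfg.mantel_tail,
                    seed=stage_seeds["mantel"],
                )
                mantel_rows.append(
                    {
                        "scope": "within",
                        "unit": e,
                        "test": f"{a}-vs-{b}",
                        "n_units": res.n,
                        "r": res.r,
                        "r2": res.r2,
                        "p": res.p,
                        "n_perm": res.n_perm,
                    }
                )
        for b in ("spatial", "environmental"):
            if "jaccard" in between and b in between:
                ids = [i for i in between["jaccard"].ids if i in set(between[b].ids)]
                if len(ids) >= MIN_MANTEL_UNITS:
                    res = mantel_test(
                        between["jaccard"].filter(ids),
                        between[b].filter(ids),
                        n_perm=cfg.n_permutations,
                        method=cfg.mantel_method,
                        tail=cfg.mantel_tail,
                        seed=stage_seeds["mantel"],
                    )
                    mantel_rows.append(
                        {
                            "scope": "between",
                            "unit": "all",
                            "test": f"jaccard-vs-{b}",
                            "n_units": res.n,
                            "r": res.r,
                            "r2": res.r2,
                            "p": res.p,
                            "n_perm": res.n_perm,
                        }
                    )
        mantel_df = pd.DataFrame(mantel_rows)
        if cfg.holm and len(mantel_df):
            mantel_df["p_holm"] = holm_adjust(mantel_df["p"].to_numpy())
        p = out.path("mantel_results.csv")
        mantel_df.to_csv(p, index=False)
        outputs["mantel"] = p

        stage = "spearman"
        levels = ["alpha_mean", "gamma_site", "beta_site", "beta_conn"]
        sp_rows = []
        scopes = [("overall", site_div)] + [
            (e, site_div[site_div["estuary"] == e]) for e in m.estuaries()
        ]
        for scope, sub in scopes:
            for i, a in enumerate(levels):
                for b in levels[i + 1 :]:
                    if len(sub) < 3:
                        continue
                    try:
                        rho, pval = spearman_rho(sub[a], sub[b])
                    except ValueError:
                        continue  # constant vector within this scope
                    sp_rows.append(
                        {"scope": scope, "var1": a, "var2": b, "rho": rho,
                         "p": pval, "n": len(sub)}
                    )
        p = out.path("spearman_diversity.csv")
        pd.DataFrame(sp_rows).to_csv(p, index=False)
        outputs["spearman"] = p

        stage = "kruskal_wallis"
        kw_rows = []
        for measure in ("beta_site", "beta_conn"):
            groups = [
                site_div.loc[site_div["estuary"] == e, measure].to_numpy()
                for e in m.estuaries()
            ]
            groups = [g for g in groups if g.size > 0]
            if len(groups) >= 2:
                try:
                    h, pval = kruskal_wallis(groups)
                except ValueError:
                    continue
                kw_rows.append({"measure": measure, "H": h, "p": pval})
        jac_groups, jac_names = [], []
        for e, dm in jac_site.items():
            jac_groups.append(dm.condensed_form())
            jac_names.append(e)
        if len(jac_groups) >= 2:
            try:
                h, pval = kruskal_wallis(jac_groups)
                kw_rows.append({"measure": "jaccard_between_sites", "H": h, "p": pval})
            except ValueError:
                pass
        p = out.path("kruskal_wallis.csv")
        pd.DataFrame(kw_rows).to_csv(p, index=False)
        outputs["kruskal_wallis"] = p

        stage = "pca"
        if estuary_env is not None:
            vars_ = estuary_env.variables().dropna(axis=1)
            screen = collinearity_screen(vars_)
            p = out.path("collinearity_screen.csv")
            screen.to_csv(p, index=False)
            outputs["collinearity_screen"] = p
            pca = pca_correlation(vars_)
            p = out.path("pca_variance.csv")
            pd.DataFrame(
                {
                    "axis": [f"PC{i+1}" for i in range(pca.n_axes)],
                    "eigenvalue": pca.eigenvalues,
                    "variance_fraction": pca.variance_fractions,
                }
            ).to_csv(p, index=False)
            outputs["pca_variance"] = p
            p = out.path("pca_loadings.csv")
            pca.loadings.to_csv(p)
            outputs["pca_loadings"] = p
            p = out.path("pca_scores.csv")
            pca.scores.to_csv(p)
            outputs["pca_scores"] = p

        stage = "run_log"
        p = out.path("run_log.txt")
        with open(p, "w") as fh:
            fh.write(_run_log(cfg, m))
        outputs["run_log"] = p
    except Exception as exc:
        out.cleanup()
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outputs


def _run_log(cfg: PipelineConfig, m: IncidenceMatrix) -> str:
    import scipy
    import skbio

    rep = m.validation_report()
    lines = [
        f"betadiv {__version__}",
        f"numpy {np.__version__}, scipy {scipy.__version__}, "
        f"pandas {pd.__version__}, scikit-bio {skbio.__version__}",
        f"seed: {cfg.seed}",
        f"community: {cfg.community}",
        f"replicates: {rep.n_replicates}, taxa: {rep.n_taxa}, "
        f"sites: {rep.n_sites}, estuaries: {rep.n_estuaries}",
        f"taxa never observed: {len(rep.absent_taxa)}",
        f"empty replicates: {len(rep.empty_replicates)}",
        f"options: rarefy_to={cfg.rarefy_to} standardize={cfg.standardize} "
        f"spatial_mode={cfg.spatial_mode} mantel={cfg.mantel_method}/"
        f"{cfg.mantel_tail}/{cfg.n_permutations} holm={cfg.holm}",
    ]
    return "\n".join(lines) + "\n"
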