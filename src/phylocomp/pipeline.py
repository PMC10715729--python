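"""End-to-end orchestration of the comparative workflow.

`run_all` sequences the analyses in study order — brumation estimation,
environmental PGLS, tissue allometry and PGLS, pre/post percent change,
partial correlations, compositional MANOVA, phylogenetic PCA, confirmatory
path analysis and directional tests — writing one CSV per stage plus a
combined text report.  All statistics are computed by the module
operations; nothing is fit inline here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate, compositions, pagel, paths, pcor, pgls, ppca, seasonal, simulate
from .phylo import Phylogeny, read_newick

log = logging.getLogger("phylocomp")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    out_dir: str
    tree_file: str | None = None
    traits_file: str | None = None
    thresholds_file: str | None = None
    temperatures_file: str | None = None
    climate_file: str | None = None
    breeding_file: str | None = None
    prepost_file: str | None = None
    latitude_file: str | None = None
    synthetic_seed: int | None = None  # when set, inputs come from the preset
    years: tuple[int, ...] = (2012, 2013, 2014, 2015, 2016)
    buffer: int = 0
    n_boot: int = 100
    n_perm: int = 999
    seed: int = 1
    tissues: tuple[str, ...] = ("brain", "fat", "testes", "hindlimb", "gut")

    def to_json(self) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        return json.dumps(d, indent=2)


def _load_inputs(cfg: PipelineConfig) -> dict:
    if cfg.synthetic_seed is not None:
        log.info("generating synthetic study bundle (seed=%s)", cfg.synthetic_seed)
        return simulate.paper_scale(cfg.synthetic_seed)
    data: dict = {}
    with open(cfg.tree_file) as fh:
        data["tree"] = read_newick(fh.read())
    data["traits"] = pd.read_csv(cfg.traits_file)
    data["thresholds"] = pd.read_csv(cfg.thresholds_file)
    temps = pd.read_csv(cfg.temperatures_file)
    data["temperatures"] = {
        sp: climate.TemperatureSeries.from_frame(g)
        for sp, g in temps.groupby("species")
    } if "species" in temps.columns else {
        site: climate.TemperatureSeries.from_frame(g)
        for site, g in temps.groupby("site")
    }
    data["climate"] = pd.read_csv(cfg.climate_file) if cfg.climate_file else None
    data["breeding"] = pd.read_csv(cfg.breeding_file) if cfg.breeding_file else None
    data["prepost"] = pd.read_csv(cfg.prepost_file) if cfg.prepost_file else None
    data["latitude"] = pd.read_csv(cfg.latitude_file) if cfg.latitude_file else None
    return data


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the result objects keyed by stage name."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(cfg.to_json())
    report: list[str] = []
    results: dict = {}

    def stage(name):
        log.info("stage: %s", name)
        report.append(f"\n== {name} ==")

    data = _load_inputs(cfg)
    tree: Phylogeny = data["tree"]
    traits: pd.DataFrame = data["traits"].copy()

    # ---- brumation estimation -------------------------------------------
    stage("brumation")
    thr_df = data["thresholds"]
    rows = []
    for _, r in thr_df.iterrows():
        sp = r["species"]
        if sp not in data["temperatures"]:
            continue
        thr = climate.ActivityThresholds(
            sp, float(r["entry_c"]),
            float(r.get("emergence_c", r["entry_c"])),
        )
        series = data["temperatures"][sp]
        years = [y for y in cfg.years]
        if cfg.buffer:
            per_year = {
                y: climate.buffered_days(series, thr, y, buffer=cfg.buffer)
                for y in years
            }
            est = climate.BrumationEstimate(sp, per_year)
        else:
            est = climate.estimate_brumation(series, thr, years)
        row = {"species": sp, "mean_days": est.mean_days, "status": est.status}
        row.update({f"days_{y}": d for y, d in est.per_year_days.items()})
        rows.append(row)
    brum = pd.DataFrame(rows)
    brum.to_csv(out / "brumation.csv", index=False)
    results["brumation"] = brum
    report.append(
        f"{len(brum)} species; {sum(brum['status'] == 'brumating')} brumating, "
        f"{sum(brum['status'] == 'non-brumating')} non-brumating"
    )

    # repeatability of per-year estimates across species
    year_cols = [c for c in brum.columns if c.startswith("days_")]
    long = brum.melt(id_vars="species", value_vars=year_cols, value_name="days")
    rep = seasonal.repeatability(
        long["days"], long["species"], n_boot=min(cfg.n_boot, 200), seed=cfg.seed
    )
    report.append(f"repeatability R = {rep.R:.3f} [{rep.ci[0]:.3f}, {rep.ci[1]:.3f}]")
    results["repeatability"] = rep

    # merge brumation into traits
    traits = traits.merge(brum[["species", "mean_days"]], on="species", how="inner")
    traits = traits.rename(columns={"mean_days": "brumation_days"})
    traits["log_svl"] = np.log(traits["svl"])
    for t in cfg.tissues:
        traits[f"log_{t}"] = np.log(traits[t])
    log.info("n = %d species after merging brumation", len(traits))

    # ---- climate summaries & environmental PGLS -------------------------
    if data.get("climate") is not None:
        stage("environment")
        summ = []
        for sp, g in data["climate"].groupby("species"):
            summ.append(
                {
                    "species": sp,
                    "mean_temp": g["temp_c"].mean(),
                    "cv_temp": climate.climate_cv(g["temp_c"]),
                    "total_precip": g["precip_mm"].sum(),
                    "dry_months": climate.dry_season_p2t(g["precip_mm"], g["temp_c"]),
                }
            )
        env = pd.DataFrame(summ)
        env.to_csv(out / "climate_summaries.csv", index=False)
        results["environment"] = env
        etab = traits.merge(env, on="species")
        if data.get("latitude") is not None:
            etab = etab.merge(data["latitude"], on="species")
            fit = pgls.fit_pgls(
                etab, "brumation_days ~ latitude", tree,
                n_boot=cfg.n_boot, seed=cfg.seed,
            )
            results["env_pgls"] = fit
            report.append(
                f"brumation ~ latitude: r = {fit.r['latitude']:.2f}, "
                f"t_{fit.fit.df} = {fit.fit.t_statistics[1]:.2f}, "
                f"lambda = {fit.lambda_hat:.2f}"
            )

    # ---- allometry and tissue PGLS --------------------------------------
    stage("allometry")
    allo_rows = []
    for t in cfg.tissues:
        res = pgls.fit_allometry(
            traits[t].to_numpy(), traits["svl"].to_numpy(), tree,
            species=list(traits["species"]), n_boot=cfg.n_boot, seed=cfg.seed,
        )
        allo_rows.append(
            {
                "tissue": t,
                "slope": res.slope,
                "ci_low": res.ci[0],
                "ci_high": res.ci[1],
                "classification": res.classification,
                "lambda": res.lambda_hat,
            }
        )
        report.append(
            f"{t}: beta = {res.slope:.2f} [{res.ci[0]:.2f}, {res.ci[1]:.2f}] "
            f"({res.classification})"
        )
    allo = pd.DataFrame(allo_rows)
    allo.to_csv(out / "allometry.csv", index=False)
    results["allometry"] = allo

    stage("tissue PGLS vs brumation")
    tis_rows = []
    for t in cfg.tissues:
        fit = pgls.fit_pgls(
            traits, f"log_{t} ~ log_svl + brumation_days", tree,
            n_boot=0,
        )
        tstat = fit.fit.t_statistics[2]
        tis_rows.append(
            {
                "tissue": t,
                "r_partial": fit.r["brumation_days"],
                "t": tstat,
                "df": fit.fit.df,
                "lambda": fit.lambda_hat,
            }
        )
    tis = pd.DataFrame(tis_rows)
    tis.to_csv(out / "tissue_pgls.csv", index=False)
    results["tissue_pgls"] = tis
    for _, r in tis.iterrows():
        report.append(
            f"log_{r['tissue']} ~ svl + brumation: r_p = {r['r_partial']:.2f}, "
            f"t_{int(r['df'])} = {r['t']:.2f}"
        )

    # ---- pre/post percent change ----------------------------------------
    if data.get("prepost") is not None:
        stage("percent change")
        pc_rows = []
        for t in cfg.tissues:
            pre_c, post_c = f"{t}_pre", f"{t}_post"
            if pre_c not in data["prepost"].columns:
                continue
            pc = seasonal.percent_change(
                data["prepost"][pre_c], data["prepost"][post_c]
            )
            pc_rows.append(
                {
                    "tissue": t,
                    "mean_pct": pc.mean,
                    "ci_low": pc.ci[0],
                    "ci_high": pc.ci[1],
                    "n": pc.n,
                }
            )
            report.append(
                f"{t}: {pc.mean:+.1f}% [{pc.ci[0]:.1f}, {pc.ci[1]:.1f}] (n={pc.n})"
            )
        pd.DataFrame(pc_rows).to_csv(out / "percent_change.csv", index=False)
        results["percent_change"] = pd.DataFrame(pc_rows)

    # ---- partial correlations -------------------------------------------
    stage("partial correlations")
    pc_table = pcor.all_pairwise_partials(
        traits, [f"log_{t}" for t in cfg.tissues], tree, control="log_svl"
    )
    pc_table.to_csv(out / "partial_correlations.csv", index=False)
    results["partial_correlations"] = pc_table

    # ---- composition -----------------------------------------------------
    stage("composition")
    comp = compositions.body_composition(
        traits, part_cols=("brain", "fat", "testes", "hindlimb")
    )
    parts = ["brain", "fat", "testes", "hindlimb", "rest"]
    clr_tab = pd.DataFrame(
        compositions.clr(comp[parts].to_numpy()), columns=[f"clr_{p}" for p in parts]
    )
    clr_tab.insert(0, "species", comp["species"])
    clr_tab.to_csv(out / "clr_composition.csv", index=False)
    Y = compositions.ilr(comp[parts].to_numpy())
    mv = compositions.fit_mv_pgls(
        Y, traits["brumation_days"].to_numpy(), tree,
        species=list(traits["species"]), n_perm=cfg.n_perm, seed=cfg.seed,
    )
    results["composition"] = mv
    report.append(
        f"Pillai = {mv.pillai:.2f}, xi2 = {mv.xi2:.2f}, p = {mv.p_perm:.3f}; "
        "back-transformed coefficients: "
        + ", ".join(f"{p} {c:.2f}" for p, c in zip(parts, mv.coef_simplex))
    )

    # ---- pPCA ------------------------------------------------------------
    stage("phylogenetic PCA")
    logm = traits.set_index("species")[[f"log_{t}" for t in cfg.tissues[:4]]]
    pp = ppca.fit_ppca(logm, tree, species=list(logm.index))
    pp.loadings.to_csv(out / "ppca_loadings.csv")
    pp.scores.to_csv(out / "ppca_scores.csv")
    results["ppca"] = pp
    report.append(
        "percent variance: "
        + ", ".join(f"{v:.1f}" for v in pp.percent_variance)
    )

    # ---- path analysis ---------------------------------------------------
    if data.get("breeding") is not None and data.get("latitude") is not None:
        stage("path analysis (climate set)")
        ptab = (
            traits[["species", "brumation_days"]]
            .merge(data["breeding"], on="species")
            .merge(data["latitude"], on="species")
        )
        ptab = ptab.rename(
            columns={"brumation_days": "brumation", "season_days": "breeding_season"}
        )
        fits = []
        for model in paths.bundled_model_set("climate8"):
            try:
                fits.append(paths.fit_path_model(model, ptab, tree))
            except ValueError as exc:
                log.warning("model %s skipped: %s", model.name, exc)
        ranked = paths.rank_models(fits)
        ranked.to_csv(out / "path_ranking.csv", index=False)
        avg = paths.average_models(fits)
        avg.to_csv(out / "path_averaged.csv", index=False)
        results["path_ranking"] = ranked
        results["path_averaged"] = avg
        report.append(ranked.head(3).to_string(index=False))

    # ---- directional tests ----------------------------------------------
    if data.get("breeding") is not None:
        stage("directional tests")
        dtab = traits.merge(data["breeding"], on="species")
        sub = tree.prune_to(list(dtab["species"]))
        order = {sp: i for i, sp in enumerate(sub.taxa)}
        dtab = dtab.sort_values("species", key=lambda s: s.map(order))
        x = pagel.binarize_residual(
            dtab["testes"].to_numpy(), dtab["svl"].to_numpy(), sub,
            species=list(dtab["species"]),
        )
        y = pagel.binarize_mean_split(dtab["season_days"].to_numpy())
        fits = pagel.fit_directional(
            x, y, sub, species=list(dtab["species"]), seed=cfg.seed, n_starts=3
        )
        dd = pd.DataFrame(
            [
                {
                    "model": f.model,
                    "logL": f.log_likelihood,
                    "k": f.k,
                    "AIC": f.aic,
                    "delta_AIC": f.delta_aic,
                    "w_AIC": f.w_aic,
                }
                for f in fits
            ]
        )
        dd.to_csv(out / "directional_tests.csv", index=False)
        results["directional"] = dd
        report.append(dd.to_string(index=False))

    (out / "report.txt").write_text("\n".join(report) + "\n")
    log.info("report written to %s", out / "report.txt")
    return results
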