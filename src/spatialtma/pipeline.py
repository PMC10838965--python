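"""End-to-end orchestration: simulate/read -> phenotype -> neighborhoods -> stats.

Each stage writes its outputs (CSV) into the run directory before the next
stage begins, so a failed run leaves all completed artifacts behind. The
numeric CSVs are the contract surface; figures are best-effort PNGs.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import neighborhoods as nb
from . import phenotyping as ph
from . import simulate as sim
from . import stats as st
from .io import RunConfig, read_cell_table, read_clinical_table, write_csv

log = logging.getLogger(__name__)


@dataclass
class ReportBundle:
    manifest: dict
    outputs: dict[str, Path]
    model: nb.NeighborhoodModel | None
    coverage: nb.CoverageTable | None
    survival_results: pd.DataFrame | None


def _build_simulation_config(block: dict, seed: int) -> sim.SimulationConfig:
    block = dict(block)
    hotspots = [sim.HotspotSpec(**h) if isinstance(h, dict) else h
                for h in block.pop("hotspots", [sim.HotspotSpec()])]
    cov = block.pop("covariates", None)
    surv = block.pop("survival", None)
    for key in ("nest_radius_range", "patient_hotspot_scale"):
        if key in block:
            block[key] = tuple(block[key])
    cfg = sim.SimulationConfig(
        hotspots=hotspots,
        covariates=(sim.CovariateSpec(**cov) if isinstance(cov, dict)
                    else cov or sim.CovariateSpec()),
        survival=(sim.SurvivalSpec(**surv) if isinstance(surv, dict)
                  else surv or sim.SurvivalSpec()),
        **block)
    cfg.seed = seed
    return cfg


@contextmanager
def _stage(name):
    """Attach the failing stage's name to any error it raises."""
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis described by ``config``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("spatialtma")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    outputs: dict[str, Path] = {"log": log_path}
    try:
        return _run(config, out, outputs)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path, outputs: dict) -> ReportBundle:
    panel = ph.PANELS[config.panel]

    with _stage("input"):
        cores = None
        clinical = None
        if config.simulate is not None:
            simcfg = _build_simulation_config(config.simulate, config.seed)
            cohort = sim.simulate_cohort(simcfg)
            cells, cores, clinical = (cohort.cells, cohort.cores,
                                      cohort.patients)
            outputs["cells"] = write_csv(cells, out / "cells.csv")
            outputs["cores"] = write_csv(cores, out / "cores.csv")
            outputs["clinical"] = write_csv(clinical, out / "clinical.csv")
            outputs["truth_cells"] = write_csv(cohort.truth_cells,
                                               out / "truth_cells.csv")
            outputs["truth_patients"] = write_csv(cohort.truth_patients,
                                                  out / "truth_patients.csv")
        else:
            cells = read_cell_table(config.cells_path)
            if config.clinical_path:
                clinical = read_clinical_table(config.clinical_path)

    with _stage("phenotype"):
        if "phenotype" in cells.columns:
            log.info("phenotype column present; gating skipped, "
                     "labels taken as-is")
        elif any(c.startswith("pos_") for c in cells.columns):
            gated = ph.assign_phenotypes(cells, panel)
            cells = pd.concat([cells, gated], axis=1)
        else:
            labels, model, _ = ph.phenotype_by_clustering(
                cells, panel, thresholds=config.thresholds, seed=config.seed)
            cells = cells.assign(phenotype=labels)
            outputs["elbow"] = write_csv(
                pd.DataFrame(sorted(model.elbow_curve.items()),
                             columns=["n_clusters", "inertia"]),
                out / "elbow.csv")
        outputs["phenotyped_cells"] = write_csv(cells,
                                                out / "phenotyped_cells.csv")

    with _stage("profiles"):
        pset = nb.neighbor_profiles(cells, k=config.k)
        outputs["profiles"] = write_csv(pset.profiles, out / "profiles.csv")
        coloc = nb.colocalization_matrix(pset)
        outputs["colocalization"] = write_csv(
            coloc, out / "colocalization.csv", index=True)

    if config.k_grid and config.n_grid:
        with _stage("kn_sweep"):
            diag, rec = nb.select_k_n(cells, k_grid=tuple(config.k_grid),
                                      n_grid=tuple(config.n_grid),
                                      seed=config.seed,
                                      threshold=config.similarity_threshold,
                                      mini_batch=config.mini_batch)
            outputs["kn_diagnostics"] = write_csv(diag,
                                                  out / "kn_diagnostics.csv")
            log.info("k/n sweep recommendation (advisory): %s", rec)

    with _stage("cluster"):
        model = nb.cluster_neighborhoods(pset, n=config.n, seed=config.seed,
                                         mini_batch=config.mini_batch)
        comp = nb.neighborhood_composition(model, pset)
        sim_df, flagged = nb.neighborhood_similarity(
            model, config.similarity_threshold)
        if flagged:
            log.warning("highly similar neighborhood pairs: %s", flagged)
        model.names = nb.annotate_neighborhoods(
            comp, overrides=config.neighborhood_names)
        labels_df = model.labels.reset_index()
        labels_df["name"] = labels_df["neighborhood"].map(model.name_of)
        outputs["labels"] = write_csv(labels_df, out / "labels.csv")
        outputs["composition"] = write_csv(
            comp.mean_counts.rename(index=model.name_of),
            out / "composition_means.csv", index=True)
        if comp.zscores is not None:
            outputs["enrichment"] = write_csv(
                comp.zscores.rename(index=model.name_of),
                out / "composition_zscores.csv", index=True)
        outputs["similarity"] = write_csv(sim_df, out / "similarity.csv",
                                          index=True)

    with _stage("coverage"):
        cov = nb.coverage(model, pset, patients=clinical)
        named_cov = cov.patient.rename(columns=model.name_of)
        outputs["coverage_core"] = write_csv(
            cov.core.rename(columns=model.name_of), out / "coverage_core.csv",
            index=True)
        outputs["coverage_patient"] = write_csv(
            named_cov, out / "coverage_patient.csv", index=True)
        name_to_id = {v: k for k, v in model.names.items()}
        ratio_cols = {}
        for spec in config.ratios:
            num, den = spec["numerator"], spec["denominator"]
            num_id = name_to_id.get(num, num if isinstance(num, int) else None)
            den_id = name_to_id.get(den, den if isinstance(den, int) else None)
            if num_id is None or den_id is None:
                log.warning("ratio %s/%s skipped: unknown neighborhood name",
                            num, den)
                continue
            ratio_cols[f"ratio {num}:{den}"] = nb.coverage_ratio(
                cov, num_id, den_id)
        if ratio_cols:
            outputs["ratios"] = write_csv(pd.DataFrame(ratio_cols),
                                          out / "coverage_ratios.csv",
                                          index=True)

    with _stage("statistics"):
        surv_df = None
        if cores is not None:
            dens = st.densities(cells, cores)
            outputs["densities"] = write_csv(dens, out / "densities.csv")
            wide = dens.pivot_table(index="patient_id",
                                    columns=["compartment", "phenotype"],
                                    values="density")
            wide.columns = [f"{'E' if c == 'epithelium' else 'S'}_{p}"
                            for c, p in wide.columns]
            outputs["density_correlation"] = write_csv(
                st.pearson_matrix(wide), out / "density_correlation.csv",
                index=True)
        outputs["coverage_correlation"] = write_csv(
            st.pearson_matrix(named_cov), out / "coverage_correlation.csv",
            index=True)

        if clinical is not None and "os_months" in clinical.columns:
            surv_df = _survival_stage(config, clinical, named_cov, ratio_cols,
                                      out, outputs)
        elif clinical is not None:
            log.warning("clinical table lacks survival columns; "
                        "Cox/KM skipped")

    manifest = {
        "config": config.to_jsonable(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_cells": int(len(cells)),
        "n_profiled": int(len(pset.profiles)),
        "excluded_cores": pset.excluded_cores,
        "neighborhood_names": {int(k): v for k, v in model.names.items()},
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    outputs["manifest"] = out / "manifest.json"

    if config.figures:
        _figures(cells, model, comp, cov, out, outputs)
    return ReportBundle(manifest=manifest, outputs=outputs, model=model,
                        coverage=cov, survival_results=surv_df)


def _survival_stage(config, clinical, named_cov, ratio_cols, out, outputs):
    variables = named_cov.copy()
    for name, s in ratio_cols.items():
        variables[name] = s
    results = []
    for endpoint in config.endpoints:
        tcol, ecol = f"{endpoint}_months", f"{endpoint}_event"
        if tcol not in clinical.columns:
            continue
        clin = clinical.set_index("patient_id")
        joined = variables.join(clin[[tcol, ecol]], how="inner")
        fam = []
        for var in variables.columns:
            grp = st.dichotomize(joined[var], mode=config.split_mode)
            if grp.degenerate:
                log.warning("degenerate split for %r; skipped", var)
                continue
            r = st.cox_univariate(grp.labels, joined[tcol], joined[ecol],
                                  endpoint=endpoint,
                                  horizon=config.horizon_months, variable=var)
            if r is not None:
                fam.append(r)
        if fam:
            adj = st.fdr_adjust([r.p for r in fam])
            for r, a in zip(fam, adj):
                r.p_adj = float(a)
            results.extend(fam)
            # multivariate pass over clinical covariates + significant variables
            mv_vars = joined[[v for v in variables.columns]].copy()
            for covname in ("age", "stage", "debulking"):
                if covname in clin.columns:
                    mv_vars[covname] = clin[covname]
            mv, _ = st.cox_multivariate(mv_vars, joined[tcol], joined[ecol],
                                        endpoint=endpoint,
                                        horizon=config.horizon_months)
            results.extend(mv)
    surv_df = pd.DataFrame([r.as_dict() for r in results])
    outputs["survival_results"] = write_csv(surv_df,
                                            out / "survival_results.csv")

    # one-way ANOVA of each neighborhood's coverage across clinical factors
    clin = clinical.set_index("patient_id")
    tests = []
    for factor in ("grade", "stage", "chemo_sensitivity"):
        if factor in clin.columns:
            for var in named_cov.columns:
                joined = named_cov[var].to_frame().join(clin[factor], how="inner")
                tests.append((f"{var}~{factor}", joined[var], joined[factor]))
    if tests:
        outputs["anova"] = write_csv(st.anova_fdr(tests), out / "anova.csv")

    if config.figures and len(surv_df):
        _survival_figures(config, clinical, named_cov, surv_df, out, outputs)
    return surv_df


def _survival_figures(config, clinical, named_cov, surv_df, out, outputs):
    """Best-effort forest plot and a KM plot for the first coverage variable."""
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        uni = surv_df[surv_df["model"] == "univariate"]
        if len(uni):
            fig, ax = plt.subplots(figsize=(6, 0.4 * len(uni) + 1.5))
            y = np.arange(len(uni))[::-1]
            ax.errorbar(uni["hr"], y,
                        xerr=[uni["hr"] - uni["ci_low"],
                              uni["ci_high"] - uni["hr"]],
                        fmt="s", color="k", capsize=3)
            ax.axvline(1.0, color="grey", ls="--", lw=1)
            ax.set_yticks(y, uni["variable"] + " (" + uni["endpoint"] + ")",
                          fontsize=7)
            ax.set_xscale("log")
            ax.set_xlabel("hazard ratio (95% CI)")
            fig.tight_layout()
            fig.savefig(out / "forest.png", dpi=120)
            plt.close(fig)
            outputs["forest_plot"] = out / "forest.png"

        var = named_cov.columns[0]
        clin = clinical.set_index("patient_id")
        joined = named_cov[var].to_frame().join(
            clin[["os_months", "os_event"]], how="inner")
        grp = st.dichotomize(joined[var], mode=config.split_mode)
        if not grp.degenerate:
            curves = st.km_curve(joined["os_months"], joined["os_event"],
                                 grp.labels, horizon=config.horizon_months)
            fig, ax = plt.subplots(figsize=(5, 4))
            for g, c in curves.items():
                ax.step(c["time"], c["survival"], where="post", label=g)
            ax.set_xlabel("months")
            ax.set_ylabel("OS (KM)")
            ax.set_ylim(0, 1.02)
            ax.legend(title=var, fontsize=8)
            fig.tight_layout()
            fig.savefig(out / "km_os.png", dpi=120)
            plt.close(fig)
            outputs["km_plot"] = out / "km_os.png"
    except Exception as exc:                     # pragma: no cover
        log.warning("survival figure generation failed: %s", exc)


def _figures(cells, model, comp, cov, out, outputs):
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if comp.zscores is not None:
            fig, ax = plt.subplots(figsize=(8, 4))
            z = comp.zscores
            im = ax.imshow(z.to_numpy(), cmap="RdBu_r", aspect="auto")
            ax.set_xticks(range(len(z.columns)), z.columns, rotation=90,
                          fontsize=7)
            ax.set_yticks(range(len(z.index)),
                          [model.name_of(int(i)) for i in z.index], fontsize=8)
            fig.colorbar(im, ax=ax, label="enrichment (z)")
            fig.tight_layout()
            fig.savefig(out / "composition_heatmap.png", dpi=120)
            plt.close(fig)
            outputs["composition_heatmap"] = out / "composition_heatmap.png"
        core_ids = cells["core_id"].drop_duplicates().head(3)
        nb.plot_cores(cells, model, core_ids, out / "cores.png")
        outputs["core_plots"] = out / "cores.png"
    except Exception as exc:                     # pragma: no cover
        log.warning("figure generation failed: %s", exc)
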