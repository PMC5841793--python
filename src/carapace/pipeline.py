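"""Study pipeline orchestration.

``run_pipeline`` executes the stages of the carapace study in order --
simulate (or load), maturity filter, superposition per view, repeatability,
dimorphism, geographic variation, fossils -- writing one CSV table per
result and a machine-readable JSON summary plus a run log. Every stochastic
stage has its own seed derived from the config's base seed, all recorded in
the log, so two runs with the same config produce identical outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dimorphism import sdi_bootstrap_ci, sex_shape_analysis, size_dimorphism_test
from .fossilcompare import (allometric_correct, fit_allometry,
                            fossil_disparity_report, fossil_sdi_test,
                            site_comparisons, slope_homogeneity_test,
                            split_bimodal)
from .geospatial import forward_select_se, haversine_matrix, morans_i, \
    spatial_eigenvectors
from .io import write_metadata, write_tps
from .maturity import maturity_filter, proxy_analysis
from .schemes import get_scheme
from .shapestats import repeatability
from .superposition import procrustes_align, symmetric_component, tangent_pca
from .synthgen import (SimulationParams, build_shape_model, simulate_dataset,
                       simulate_fossil_sites, simulate_maturity_sample,
                       simulate_replicates)

log = logging.getLogger("carapace.pipeline")

VIEWS = ("dorsal", "lateral", "posterior")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    output_dir: str = "results/pipeline"
    seed: int = 0
    n_perm: int = 499
    n_boot: int = 1000
    sdi_n_boot: int = 2000
    mgr_threshold: int = 8
    gap_threshold_mm: float = 60.0
    alpha: float = 0.05
    views: tuple[str, ...] = VIEWS
    stages: tuple[str, ...] = ("simulate", "maturity", "align", "repeatability",
                               "dimorphism", "geography", "fossils")
    n_modern: int = 200
    write_tps_files: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        for name in ("views", "stages"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


def _seed_for(base: int, stage: str) -> int:
    return int(np.random.SeedSequence([base, abs(hash(stage)) % (2**20)])
               .generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run enabled stages in order; returns the machine-readable summary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"version": __version__, "config": asdict(config)}
    log.info("carapace %s starting; seed %d", __version__, config.seed)

    try:
        stages = set(config.stages)
        if "simulate" not in stages:
            raise ValueError("this pipeline currently drives the synthetic "
                             "study; enable the 'simulate' stage")

        params = SimulationParams(seed=config.seed, n_modern=config.n_modern)
        model = build_shape_model(params)
        geo_configs, geo_meta = simulate_dataset(params, model)
        sex_configs, sex_meta = simulate_dataset(params, model, record_sex=True,
                                                 seed_offset=1)
        fossil_configs, fossil_meta = simulate_fossil_sites(params, model)
        maturity_meta = simulate_maturity_sample(params)
        if config.write_tps_files:
            for view in config.views:
                write_tps(geo_configs[view], out / f"modern_{view}.tps")
                write_tps(fossil_configs[view], out / f"fossil_{view}.tps")
            write_metadata(pd.concat([geo_meta, fossil_meta]), out / "metadata.csv")
        log.info("simulated %d modern, %d sexed, %d fossil specimens",
                 len(geo_meta), len(sex_meta), len(fossil_meta))

        if "maturity" in stages:
            report = proxy_analysis(maturity_meta, config.mgr_threshold)
            report.to_frame().to_csv(out / "maturity_proxies.csv", index=False)
            mask = maturity_filter(pd.concat([geo_meta, fossil_meta],
                                             ignore_index=True),
                                   config.mgr_threshold)
            summary["maturity"] = {
                "lm_r2_below": report.lm_below.r_squared_adj,
                "lm_r2_above": report.lm_above.r_squared_adj,
                "n_pass_filter": int(mask.sum()),
            }
            log.info("maturity: r2 below=%.3f above=%.3f",
                     report.lm_below.r_squared_adj, report.lm_above.r_squared_adj)

        aligned, pcs = {}, {}
        if "align" in stages:
            for view in config.views:
                scheme = get_scheme(view)
                sample = procrustes_align(geo_configs[view], scheme, slide=True)
                if scheme.symmetric:
                    sample = symmetric_component(sample, scheme)
                aligned[view] = sample
                pcs[view] = tangent_pca(sample, scheme.repeatable_pc_count)
                sample.to_frame().to_csv(out / f"aligned_{view}.csv", index=False)
            summary["align"] = {
                view: {"n": aligned[view].n_specimens,
                       "pc1_var": float(pcs[view].variance_explained[0])}
                for view in aligned
            }

        if "repeatability" in stages and aligned:
            seed = _seed_for(config.seed, "repeatability")
            rep_rows = {}
            for view in config.views:
                chosen = geo_configs[view][:3]
                reps = simulate_replicates(chosen, 3,
                                           params.digitization_noise_sd, seed)
                scheme = get_scheme(view)
                rsample = procrustes_align(reps, scheme, slide=True)
                res = repeatability(rsample.flat(),
                                    [c.specimen_id for c in reps])
                rep_rows[view] = {"me_percent": res.me_percent, "icc": res.icc}
            pd.DataFrame(rep_rows).T.to_csv(out / "repeatability.csv")
            summary["repeatability"] = rep_rows

        if "dimorphism" in stages:
            seed = _seed_for(config.seed, "dimorphism")
            males = sex_meta.loc[sex_meta.sex == "M", "carapace_length"].to_numpy()
            females = sex_meta.loc[sex_meta.sex == "F", "carapace_length"].to_numpy()
            t, p = size_dimorphism_test(sex_meta)
            sdi = sdi_bootstrap_ci(males, females, n_boot=config.sdi_n_boot,
                                   seed=seed)
            summary["dimorphism"] = {
                "t": t, "p": p, "sdi": sdi.sdi,
                "ci": [sdi.ci_low, sdi.ci_high],
            }
            rows = {}
            for view in config.views:
                scheme = get_scheme(view)
                sample = procrustes_align(sex_configs[view], scheme, slide=True)
                if scheme.symmetric:
                    sample = symmetric_component(sample, scheme)
                anova, assign = sex_shape_analysis(
                    sample, sex_meta, scheme.repeatable_pc_count,
                    n_perm=config.n_perm, seed=seed)
                anova.to_frame().to_csv(out / f"sex_anova_{view}.csv", index=False)
                rows[view] = {
                    "sex_r2": float(anova.r_squared[anova.terms.index("sex")]),
                    "sex_p": float(anova.p[anova.terms.index("sex")]),
                    "cva_accuracy": assign.accuracy,
                }
            summary["dimorphism"]["views"] = rows
            pd.DataFrame(rows).T.to_csv(out / "sex_shape.csv")
            log.info("dimorphism: SDI=%.3f CI=[%.3f, %.3f]",
                     sdi.sdi, sdi.ci_low, sdi.ci_high)

        if "geography" in stages and aligned:
            seed = _seed_for(config.seed, "geography")
            coords = geo_meta[["latitude", "longitude"]].to_numpy()
            d = haversine_matrix(coords)
            sevm = spatial_eigenvectors(d, coords)
            sevm.to_frame(geo_meta.specimen_id).to_csv(
                out / "spatial_eigenvectors.csv", index=False)
            geo_rows = {}
            for view in config.views:
                scores = pcs[view].repeatable_scores()
                sel = forward_select_se(sevm.se_scores, scores,
                                        alpha=config.alpha, max_keep=2,
                                        n_perm=config.n_perm, seed=seed,
                                        labels=sevm.labels)
                sel.to_csv(out / f"se_selection_{view}.csv", index=False)
                mi = morans_i(
                    np.column_stack([np.log(aligned[view].centroid_sizes),
                                     scores[:, 0]]),
                    coords, n_perm=min(config.n_perm, 199), seed=seed)
                geo_rows[view] = {
                    "selected_ses": ",".join(sel.se) if len(sel) else "",
                    "se_r2": float(sel.cumulative_r2.iloc[-1]) if len(sel) else 0.0,
                    "morans_i_logcs": float(mi.I.iloc[0]),
                }
            summary["geography"] = geo_rows
            pd.DataFrame(geo_rows).T.to_csv(out / "geography.csv")

        if "fossils" in stages and aligned:
            seed = _seed_for(config.seed, "fossils")
            males = sex_meta.loc[sex_meta.sex == "M", "carapace_length"].to_numpy()
            females = sex_meta.loc[sex_meta.sex == "F", "carapace_length"].to_numpy()
            modern_sdi = sdi_bootstrap_ci(males, females,
                                          n_boot=config.sdi_n_boot, seed=seed)
            splits = {}
            for site, sub in fossil_meta.groupby("site"):
                split = split_bimodal(sub.carapace_length.to_numpy(),
                                      sub.specimen_id.to_numpy(), site,
                                      config.gap_threshold_mm)
                entry = {"bimodal": split.bimodal, "gap_mm": split.gap_mm}
                if split.bimodal:
                    large = sub.set_index("specimen_id").loc[split.large_ids,
                                                             "carapace_length"]
                    small = sub.set_index("specimen_id").loc[split.small_ids,
                                                             "carapace_length"]
                    sdi, reject = fossil_sdi_test(large.to_numpy(),
                                                  small.to_numpy(), modern_sdi)
                    entry.update({"sdi": sdi, "dimorphism_rejected": reject})
                splits[site] = entry
            summary["fossil_morphs"] = splits

            fossil_rows = {}
            for view in config.views:
                scheme = get_scheme(view)
                all_cfg = geo_configs[view] + fossil_configs[view]
                pooled = procrustes_align(all_cfg, scheme, slide=True)
                if scheme.symmetric:
                    pooled = symmetric_component(pooled, scheme)
                n_mod = len(geo_configs[view])
                flat = pooled.flat()
                log_cs = np.log(pooled.centroid_sizes)
                era = np.array(["modern"] * n_mod
                               + ["fossil"] * len(fossil_configs[view]))
                slopes = slope_homogeneity_test(flat, log_cs, era,
                                                n_perm=config.n_perm, seed=seed)
                inter_p = float(slopes.p[-1])
                model_fit = fit_allometry(flat[:n_mod], log_cs[:n_mod])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    corrected = allometric_correct(flat, log_cs, model_fit)
                labels = np.array(
                    ["Modern"] * n_mod
                    + [fossil_meta.site.iloc[k]
                       for k in range(len(fossil_configs[view]))])
                # split bimodal sites into morph labels for comparison
                for site, entry in splits.items():
                    if entry["bimodal"]:
                        split = split_bimodal(
                            fossil_meta.loc[fossil_meta.site == site,
                                            "carapace_length"].to_numpy(),
                            fossil_meta.loc[fossil_meta.site == site,
                                            "specimen_id"].to_numpy(),
                            site, config.gap_threshold_mm)
                        id_to_morph = {i: f"{site}_large" for i in split.large_ids}
                        id_to_morph.update(
                            {i: f"{site}_small" for i in split.small_ids})
                        for k, sid in enumerate(fossil_meta.specimen_id):
                            if sid in id_to_morph:
                                labels[n_mod + k] = id_to_morph[sid]
                comp = site_comparisons(corrected, labels,
                                        n_perm=config.n_perm, seed=seed)
                comp.to_csv(out / f"site_comparisons_{view}.csv")

                # PC space from corrected moderns only; corrected fossils are
                # projected onto it (never a joint re-PCA)
                from .superposition import AlignedSample
                modern_sample = AlignedSample(
                    coords=corrected[:n_mod].reshape(n_mod, -1, 2),
                    centroid_sizes=pooled.centroid_sizes[:n_mod],
                    mean_shape=pooled.mean_shape, view=pooled.view,
                    specimen_ids=pooled.specimen_ids[:n_mod])
                space = tangent_pca(modern_sample, scheme.repeatable_pc_count)
                modern_scores = space.repeatable_scores()
                by_site = {}
                for site in sorted(set(labels[n_mod:])):
                    sel = labels[n_mod:] == site
                    proj = space.project(corrected[n_mod:][sel])
                    by_site[site] = proj[:, : space.repeatable_count]
                curve = fossil_disparity_report(modern_scores, by_site,
                                                n_boot=config.n_boot, seed=seed)
                curve.to_frame().to_csv(out / f"disparity_curve_{view}.csv",
                                        index=False)
                fossil_rows[view] = {
                    "slope_interaction_p": inter_p,
                    "modern_disparity": float(np.trace(np.cov(modern_scores.T))),
                    "all_fossils_exceed": bool(
                        curve.exceeds.get("all_fossils", False)),
                }
            summary["fossils"] = fossil_rows

        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str, sort_keys=True)
        log.info("pipeline complete")
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()
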