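"""End-to-end orchestration: simulate → clocks → acceleration → EWAS → report.

``run_pipeline`` mirrors the full study sequence on one dataset:

1. simulate a two-tissue cattle cohort with a human blood panel plus an
   isogenic blood/oocyte pairing;
2. train and cross-validate the cattle blood, cattle oocyte and dual-tissue
   clocks (leave-one-sample-out) and the dual-species chronological and
   relative-age clocks (10-fold CV);
3. apply the blood clock to oocytes (tissue-transfer check);
4. correlate donor-paired age acceleration across tissues;
5. run the per-tissue EWAS, Stouffer meta-analysis, top-CpG selection,
   divergence classification, island and promoter statistics.

All summary numbers land in one versioned JSON report; artifacts are written
in the package's delimited-text formats.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clock as clockmod
from . import ewas as ewasmod
from . import io as iomod
from .datamodel import ValidationError
from .simulate import SimulationConfig, simulate_dataset, simulate_isogenic_pairs
from .transforms import AgeTransform

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_isogenic_donors: int = 40
    penalty_mix: float = 0.5
    kfold: int = 10
    cv_scheme: str = "loo"  # for the single-species clocks: "loo" or "kfold"
    p_threshold: float = ewasmod.P_THRESHOLD
    max_per_direction: int = ewasmod.MAX_PER_DIRECTION
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.cv_scheme not in ("loo", "kfold"):
            raise ValidationError("cv_scheme must be 'loo' or 'kfold'")


def _cv(config: PipelineConfig, betas, samples, transform=None, group_by_donor=False):
    if config.cv_scheme == "loo" and not group_by_donor:
        return clockmod.loo_estimates(
            betas, samples, transform, config.penalty_mix, config.seed
        )
    k = min(config.kfold, len(samples))
    return clockmod.kfold_estimates(
        betas, samples, transform, config.penalty_mix, k, group_by_donor, config.seed
    )


def _eval_row(evaluation: pd.DataFrame, group: str) -> dict:
    row = evaluation.loc[evaluation["group"] == group]
    if row.empty:
        return {}
    row = row.iloc[0]
    return {
        "n": int(row["n"]),
        "r": None if pd.isna(row["pearson_r"]) else float(row["pearson_r"]),
        "mae_years": float(row["median_abs_error_years"]),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the report dict (also written to disk
    when ``config.out_dir`` is set)."""
    t0 = time.time()
    sim = config.simulation
    if sim.seed is None:
        sim = dataclasses.replace(sim, seed=config.seed)
    if sim.n_cattle_blood == 0 or sim.n_cattle_oocyte == 0:
        raise ValidationError("pipeline requires both cattle tissues in the design")

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "config": {
            "penalty_mix": config.penalty_mix,
            "kfold": config.kfold,
            "cv_scheme": config.cv_scheme,
            "p_threshold": config.p_threshold,
            "max_per_direction": config.max_per_direction,
            "n_probes": sim.n_probes,
            "n_cattle_blood": sim.n_cattle_blood,
            "n_cattle_oocyte": sim.n_cattle_oocyte,
            "n_human_blood": sim.n_human_blood,
            "n_isogenic_donors": config.n_isogenic_donors,
        },
    }

    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        ds = simulate_dataset(sim)
        betas, samples, annotation, truth = ds
        cattle = samples.subset(species="cattle")
        cattle_blood = cattle.subset(tissue="blood")
        cattle_oocyte = cattle.subset(tissue="oocyte")
        logger.info("simulated %d probes × %d samples", *betas.shape)
        if out:
            iomod.write_beta_matrix(betas, out / "betas.tsv")
            iomod.write_sample_sheet(samples, out / "samples.tsv")
            iomod.write_annotation(annotation, out / "annotation.tsv")
            truth.to_csv(out / "truth.tsv", sep="\t")

        # --- single- and dual-tissue cattle clocks (chronological age) ---
        stage = "clocks"
        identity = AgeTransform("identity")
        clocks: dict[str, dict] = {}
        estimates: dict[str, pd.DataFrame] = {}
        for name, subset in (
            ("cattle_blood", cattle_blood),
            ("cattle_oocyte", cattle_oocyte),
            ("cattle_dual_tissue", cattle),
        ):
            est = _cv(config, betas, subset, identity)
            estimates[name] = est
            ev = clockmod.evaluate(est)
            clocks[name] = {"cv": config.cv_scheme, "overall": _eval_row(ev, "overall")}
            for grp in ev["group"]:
                if grp != "overall":
                    clocks[name][grp] = _eval_row(ev, grp)
            full = clockmod.train_clock(
                betas, subset, identity, config.penalty_mix, config.seed
            )
            clocks[name]["n_nonzero_coefficients"] = len(full.coefficients)
            if out:
                iomod.write_clock(full, out / f"clock_{name}.tsv")
                est.to_csv(out / f"cv_estimates_{name}.tsv", sep="\t")

        # --- dual-species clocks: chronological years and relative age ---
        stage = "dual_species_clocks"
        if sim.n_human_blood > 0:
            for name, transform in (
                ("dual_species_years", identity),
                ("dual_species_relative", AgeTransform("relative")),
            ):
                k = min(config.kfold, len(samples))
                est = clockmod.kfold_estimates(
                    betas, samples, transform, config.penalty_mix, k, False, config.seed
                )
                estimates[name] = est
                ev = clockmod.evaluate(est, groups=("species",))
                clocks[name] = {"cv": f"{k}-fold", "overall": _eval_row(ev, "overall")}
                for grp in ev["group"]:
                    if grp != "overall":
                        clocks[name][grp] = _eval_row(ev, grp)
                if name == "dual_species_relative":
                    # error on the relative-age scale, per species
                    for sp in sorted(set(est["species"])):
                        sub = est[est["species"] == sp]
                        lifespan = samples.lifespan_of(sp)
                        rel_err = (
                            sub["dnam_age_years"] - sub["age_years"]
                        ).abs() / lifespan
                        clocks[name][f"species={sp}"]["mae_relative"] = float(
                            rel_err.median()
                        )
                if out:
                    est.to_csv(out / f"cv_estimates_{name}.tsv", sep="\t")
        report["clocks"] = clocks

        # --- tissue transfer: blood-trained clock applied to oocytes ---
        stage = "tissue_transfer"
        blood_clock = clockmod.train_clock(
            betas, cattle_blood, identity, config.penalty_mix, config.seed
        )
        pred = clockmod.predict_age(
            blood_clock, betas.subset_samples(cattle_oocyte.sample_ids), samples
        )
        ages = cattle_oocyte.df.set_index("sample_id")["age_years"]
        aligned = ages.reindex(pred.index).to_numpy(float)
        r_transfer = (
            float(np.corrcoef(aligned, pred.to_numpy())[0, 1])
            if np.ptp(pred.to_numpy()) > 0
            else float("nan")
        )
        report["tissue_transfer"] = {
            "blood_clock_on_oocytes_r": None if np.isnan(r_transfer) else r_transfer,
            "n": int(len(pred)),
        }

        # --- isogenic acceleration comparison ---
        stage = "acceleration"
        iso_sim = dataclasses.replace(sim, seed=sim.seed + 1)
        iso = simulate_isogenic_pairs(iso_sim, n_donors=config.n_isogenic_donors)
        iso_blood = iso.samples.subset(tissue="blood")
        iso_oocyte = iso.samples.subset(tissue="oocyte")
        k = min(config.kfold, config.n_isogenic_donors)
        est_b = clockmod.kfold_estimates(
            iso.betas, iso_blood, identity, config.penalty_mix, k, True, config.seed
        )
        est_o = clockmod.kfold_estimates(
            iso.betas, iso_oocyte, identity, config.penalty_mix, k, True, config.seed
        )
        accel = clockmod.acceleration_correlation(est_b, est_o, iso.samples)
        report["acceleration"] = accel

        # --- EWAS, meta-analysis, selection, divergence, enrichment ---
        stage = "ewas"
        cattle_betas = betas.subset_samples(cattle.sample_ids)
        ew_blood = ewasmod.correlation_screen(cattle_betas, cattle, tissue="blood")
        ew_oocyte = ewasmod.correlation_screen(cattle_betas, cattle, tissue="oocyte")
        meta = ewasmod.meta_analysis(ew_blood, ew_oocyte)
        if out:
            iomod.write_ewas(ew_blood, out / "ewas_blood.tsv")
            iomod.write_ewas(ew_oocyte, out / "ewas_oocyte.tsv")
            iomod.write_ewas(meta, out / "ewas_meta.tsv")

        sel_blood = ewasmod.select_top_cpgs(
            ew_blood, config.p_threshold, config.max_per_direction
        )
        sel_oocyte = ewasmod.select_top_cpgs(
            ew_oocyte, config.p_threshold, config.max_per_direction
        )
        sel_meta = ewasmod.select_top_cpgs(
            meta, config.p_threshold, config.max_per_direction,
            p_col="p_meta", z_col="z_meta",
        )
        divergence = ewasmod.classify_divergent(ew_blood, ew_oocyte, config.p_threshold)
        z_corr = ewasmod.cross_tissue_z_correlation(ew_blood, ew_oocyte)

        background = list(ew_blood.index[ew_blood["z"].notna()])
        promoters = annotation.probes_with("region_class", "promoter")
        enrich = ewasmod.feature_enrichment(
            sel_blood["hyper"], background, promoters & set(background)
        )
        island_blood = ewasmod.island_z_comparison(ew_blood, annotation)
        island_oocyte = ewasmod.island_z_comparison(ew_oocyte, annotation)
        island_meth = ewasmod.mean_methylation_by_island(cattle_betas, cattle, annotation)

        report["ewas"] = {
            "p_threshold": config.p_threshold,
            "counts": {
                "blood_hyper": len(sel_blood["hyper"]),
                "blood_hypo": len(sel_blood["hypo"]),
                "oocyte_hyper": len(sel_oocyte["hyper"]),
                "oocyte_hypo": len(sel_oocyte["hypo"]),
                "meta_hyper": len(sel_meta["hyper"]),
                "meta_hypo": len(sel_meta["hypo"]),
            },
            "divergence_classes": divergence.value_counts().to_dict(),
            "cross_tissue_z_r": z_corr,
            "promoter_enrichment_blood_hyper": {
                "odds_ratio": enrich.odds_ratio,
                "p": enrich.p_value,
                "table": [enrich.a, enrich.b, enrich.c, enrich.d],
            },
            "island_z_blood": island_blood,
            "island_z_oocyte": island_oocyte,
            "mean_methylation_by_island": island_meth.to_dict(orient="records"),
        }

        report["elapsed_seconds"] = round(time.time() - t0, 2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if out:
        with (out / "report.json").open("w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        manifest = sorted(p.name for p in out.iterdir())
        (out / "MANIFEST").write_text("\n".join(manifest) + "\n")
    return report
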