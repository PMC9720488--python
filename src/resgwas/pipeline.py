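"""End-to-end driver: simulate -> indicators -> QC -> kinship -> variance
components -> GWAS for the eight study traits (IgM, IgG, and LNvar / Skew /
Rauto for the two laying periods).

Each stage writes its artifacts under the output directory and appends
timings and filter counts to a structured run log, so a run reproduces the
kind of bookkeeping narrative (SNPs dropped per QC step, hens filtered per
period, inflation factor per trait) a batch analysis reports.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gwas as gwas_mod
from . import indicators as ind
from . import io as io_mod
from . import kinship, qc, varcomp
from .simulate import SimulationConfig, simulate_batch

__all__ = ["PipelineConfig", "run_pipeline", "NAB_TRAITS", "INDICATOR_TRAITS"]

NAB_TRAITS = ["IgM", "IgG"]
INDICATOR_TRAITS = ["ln_var", "skew", "r_auto"]


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_eggs: int = ind.MIN_EGGS
    fdr_suggestive: float = gwas_mod.FDR_SUGGESTIVE
    fdr_significant: float = gwas_mod.FDR_SIGNIFICANT
    qc_max_missing: float = qc.MAX_MISSING
    qc_min_class_count: int = qc.MIN_CLASS_COUNT
    grm_blend: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        self.simulation.validate()
        for t in (self.fdr_suggestive, self.fdr_significant, self.qc_max_missing):
            if not 0.0 < t < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")


def _trait_table(batch, weekly, res_table) -> pd.DataFrame:
    """Hen-level table with all eight responses and their fixed factors."""
    ped = batch.pedigree.hens[["animal", "hatch_week", "row"]].copy()
    nab_wide = batch.nab.pivot(index="hen", columns="isotype", values="titer")
    meta = batch.nab.drop_duplicates("hen").set_index("hen")[["plate", "age_class"]]
    df = ped.merge(nab_wide, left_on="animal", right_index=True, how="left")
    df = df.merge(meta, left_on="animal", right_index=True, how="left")
    for period in res_table["period"].unique():
        sub = res_table[res_table["period"] == period].set_index("hen")
        suffix = period.replace("-", "_")
        for t in INDICATOR_TRAITS:
            df[f"{t}_{suffix}"] = sub[t].reindex(df["animal"]).to_numpy()
    return df


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage at the configured scale; returns the run summary
    (also written as ``summary.json``)."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stages": {}}

    def stage(name):
        t0 = time.perf_counter()
        def done(**info):
            log["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **info}
        return done

    # --- simulate -----------------------------------------------------
    end = stage("simulate")
    batch = simulate_batch(config.simulation, seed=config.seed)
    io_mod.write_pedigree(batch.pedigree, out / "pedigree.csv")
    io_mod.write_genotypes(
        batch.panel.subset_individuals(batch.genotyped_hens),
        out / "genotypes.tsv", out / "snp_map.tsv",
    )
    io_mod.write_egg_logs(batch.egg_logs, out / "egg_logs.csv")
    io_mod.write_nab(batch.nab, out / "nab.csv")
    io_mod.dump_config(config.simulation, out / "simulation_config.yaml")
    end(n_hens=len(batch.pedigree.hens), n_genotyped=len(batch.genotyped_hens),
        n_snps=batch.panel.n_snps)

    # --- indicators ---------------------------------------------------
    end = stage("indicators")
    origin = 7 * (config.simulation.first_collection_week - 1)
    weekly = ind.weekly_production(batch.egg_logs, coverage_start=origin)
    curve = ind.batch_mean(weekly)
    dev = ind.deviations(weekly, curve)
    res_table, counts = ind.resilience_indicators(dev, weekly, min_eggs=config.min_eggs)
    res_table.to_csv(out / "indicators.csv", index=False)
    curve.rename("mean_eggs").to_csv(out / "batch_curve.csv")
    end(filters=[vars(c) for c in counts])

    # --- QC -----------------------------------------------------------
    end = stage("qc")
    gpanel = batch.panel.subset_individuals(batch.genotyped_hens)
    gpanel_qc, report = qc.qc_pipeline(
        gpanel, config.qc_max_missing, config.qc_min_class_count
    )
    io_mod.write_json(report.to_dict(), out / "qc_report.json")
    io_mod.write_genotypes(gpanel_qc, out / "genotypes_qc.tsv", out / "snp_map_qc.tsv")
    end(**report.to_dict())

    # --- kinship ------------------------------------------------------
    end = stage("kinship")
    A = kinship.additive_relationship_matrix(batch.pedigree)
    G = kinship.stabilize(kinship.vanraden_grm(gpanel_qc), config.grm_blend)
    io_mod.write_matrix(G, out / "grm.tsv")
    end(mean_G_diag=float(np.mean(np.diag(G.matrix))))

    # --- variance components and GWAS per trait -----------------------
    traits = _trait_table(batch, weekly, res_table)
    hens_all = traits["animal"].tolist()
    A_sub = A.submatrix(hens_all)
    a_eig = varcomp.eigendecompose(A_sub)
    g_hens = [h for h in hens_all if h in set(batch.genotyped_hens)]
    g_eig = varcomp.eigendecompose(G.submatrix(g_hens))

    specs: dict[str, varcomp.ModelSpec] = {}
    for t in NAB_TRAITS:
        specs[t] = varcomp.ModelSpec(t, ["plate", "age_class"])
    for t in INDICATOR_TRAITS:
        for period in ("25_83", "83_end"):
            specs[f"{t}_{period}"] = varcomp.ModelSpec(
                f"{t}_{period}", ["hatch_week", "row"]
            )

    summary: dict = {"seed": config.seed, "traits": {}, "qc": report.to_dict()}
    for name, spec in specs.items():
        end = stage(f"varcomp:{name}")
        sub = traits.dropna(subset=[name])
        eig = a_eig if set(sub["animal"]) == set(a_eig.ids) else None
        est = varcomp.fit_animal_model(sub, spec, K=A, k_eig=eig)
        lrt_stat, lrt_p = varcomp.lrt_additive_variance(est)
        io_mod.write_json(
            {**est.to_dict(), "lrt_stat": lrt_stat, "lrt_p": lrt_p},
            out / f"varcomp_{name}.json",
        )
        end(h2=round(est.h2, 4), n=est.n_records)

        end = stage(f"gwas:{name}")
        gsub = traits[traits["animal"].isin(g_hens)].dropna(subset=[name])
        ratio = est.sigma_a2 / est.sigma_e2
        eig_for_scan = g_eig if gsub["animal"].tolist() == g_eig.ids else None
        table, gsummary = gwas_mod.run_gwas(
            gsub, spec, gpanel_qc, G, ratio, g_eig=eig_for_scan,
            fdr_suggestive=config.fdr_suggestive,
            fdr_significant=config.fdr_significant,
        )
        table.to_csv(out / f"gwas_{name}.tsv", sep="\t", index=False)
        summary["traits"][name] = {
            "h2": est.h2, "se_h2": est.se_h2, "lrt_p": lrt_p,
            **gsummary.to_dict(),
        }
        end(lambda_gc=round(gsummary.lambda_gc, 4), n_tested=gsummary.n_snps_tested)

    summary["log"] = log
    io_mod.write_json(summary, out / "summary.json")
    return summary
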