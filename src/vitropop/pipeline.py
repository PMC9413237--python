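"""End-to-end orchestration: simulate -> QC -> fit -> POD/TDVF -> GWAS.

A single :class:`PipelineConfig` (loadable from YAML) carries the
simulation conditions, MCMC settings, QC thresholds, TDVF benchmarks and
GWAS thresholds, plus one global seed from which every stochastic stage
derives its own stream.  ``run_pipeline`` writes per-stage tabular outputs
and a JSON report; a :class:`RunManifest` records the config hash, seeds
and stage status so identical inputs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gwas as gw
from . import plate_qc as qc
from . import pod as podm
from .hill import FitConfig, fit_population
from .synthetic import (GenotypeSimSpec, PlateLayoutSpec, PopulationSpec,
                        simulate_genotypes, simulate_plates,
                        simulate_population, write_genotype_tsv, write_plates,
                        write_sample_metadata)

logger = logging.getLogger("vitropop")

__all__ = ["PipelineConfig", "RunManifest", "cmd_simulate", "cmd_run"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Defaults mirror the screen design: five 10x dilutions to 100 uM on
    3 replicate plates, 4 chains x 4000 iterations with R-hat <= 1.2,
    MAF >= 0.05, suggestive/significant thresholds 1e-5 / 5e-8, TDVF
    benchmarks 10^(1/2) and 10."""

    out_dir: str = "vitropop_out"
    n_individuals: int = 20
    substances: tuple[str, ...] = ("chem01",)
    population: dict = field(default_factory=dict)     # PopulationSpec overrides
    layout: dict = field(default_factory=dict)         # PlateLayoutSpec overrides
    genotypes: dict = field(default_factory=dict)      # GenotypeSimSpec overrides
    fit: dict = field(default_factory=dict)            # FitConfig overrides
    vehicle_cv_max: float = 20.0
    positive_control_max: float = 0.05
    inactivity_factor: float = 3.0
    tdvf_benchmarks: tuple[float, float] = (podm.DEFAULT_TD_BENCHMARK,
                                            podm.DEFAULT_TOTAL_BENCHMARK)
    maf_threshold: float = 0.05
    n_pcs: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("substances", "tdvf_benchmarks"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stage_seed(self, stage: str, index: int = 0) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}:{index}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class RunManifest:
    config_hash: str
    global_seed: int
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, status: str, seconds: float,
               seed: int | None = None, **info) -> None:
        self.stages[stage] = dict(status=status, wall_seconds=round(seconds, 3),
                                  seed=seed, **info)
        logger.info("stage %-10s %-8s %.2fs seed=%s", stage, status,
                    seconds, seed)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _outdir(config: PipelineConfig, force: bool) -> Path:
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out} is non-empty; pass force=True/--force")
    out.mkdir(parents=True, exist_ok=True)
    return out


def cmd_simulate(config: PipelineConfig, force: bool = False) -> dict:
    """Generate the synthetic screen: plates per substance, genotypes,
    sample metadata and a truth table for recovery checks."""
    if config.n_individuals < 2:
        raise ValueError(
            "n_individuals must be >= 2: the TDVF and the hierarchical fit "
            "are undefined for a single donor")
    out = _outdir(config, force)
    manifest = RunManifest(config.config_hash(), config.seed)
    t0 = time.perf_counter()

    pop_spec = PopulationSpec(n_individuals=config.n_individuals,
                              seed=config.stage_seed("population"),
                              **config.population)
    params = simulate_population(pop_spec)
    gspec = GenotypeSimSpec(seed=config.stage_seed("genotypes"),
                            **config.genotypes)
    gm, params = simulate_genotypes(gspec, params)
    params["population_label"] = gm.samples["ancestry_group"].values

    layout = PlateLayoutSpec(**config.layout)
    plate_files = {}
    for i, chem in enumerate(config.substances):
        plates = simulate_plates(params, layout,
                                 error_scale=pop_spec.error_scale,
                                 error_df=pop_spec.error_df,
                                 seed=config.stage_seed("plates", i),
                                 chemical_id=chem)
        path = out / f"plates_{chem}.csv"
        write_plates(plates, path)
        plate_files[chem] = str(path)

    params.to_csv(out / "truth_params.csv")
    write_genotype_tsv(gm, out / "genotypes.tsv")
    write_sample_metadata(gm, out / "samples.tsv")
    manifest.record("simulate", "ok", time.perf_counter() - t0,
                    seed=config.seed, plates=plate_files)
    manifest.write(out / f"manifest_{manifest.config_hash}.json")
    return dict(plates=plate_files, genotypes=str(out / "genotypes.tsv"),
                samples=str(out / "samples.tsv"),
                truth=str(out / "truth_params.csv"), manifest=manifest)


def _fit_config(config: PipelineConfig) -> FitConfig:
    return FitConfig(seed=config.stage_seed("fit"), **config.fit)


def cmd_run(config: PipelineConfig, plates_by_substance: dict[str, pd.DataFrame],
            genotypes=None, force: bool = False) -> dict:
    """QC, hierarchical fit, POD/TDVF and (optionally) GWAS for every
    substance; returns all stage outputs plus a summary report."""
    out = _outdir(config, force)
    manifest = RunManifest(config.config_hash(), config.seed)
    report: dict = {"substances": {}, "benchmarks": {
        "tdvf_default_td": config.tdvf_benchmarks[0],
        "tdvf_default_total": config.tdvf_benchmarks[1]}}
    pods: dict[str, float] = {}
    tdvfs: dict[str, podm.TDVFDistribution] = {}
    pod_tables: dict[str, pd.DataFrame] = {}
    gwas_tables: dict[str, pd.DataFrame] = {}

    for chem, plates in plates_by_substance.items():
        t0 = time.perf_counter()
        try:
            normalized = qc.normalize_plates(plates)
            qc_report = qc.qc_plates(normalized, config.vehicle_cv_max,
                                     config.positive_control_max)
            excluded = qc_report[~qc_report["qc_pass"]]
            for _, row in excluded.iterrows():
                logger.warning("plate %s excluded: %s", row["plate_id"],
                               row["failure_reasons"])
            kept = qc.filter_qc(normalized, qc_report)
            if kept.empty:
                raise StageError(f"qc[{chem}]: every plate failed QC")
            dose = qc.to_dose_response(kept)
            qc_report.to_csv(out / f"qc_{chem}.tsv", sep="\t", index=False)
            dose.to_csv(out / f"dose_response_{chem}.csv", index=False)
            manifest.record(f"qc[{chem}]", "ok", time.perf_counter() - t0,
                            n_excluded=int(len(excluded)))
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"qc[{chem}]: {exc}") from exc

        t0 = time.perf_counter()
        try:
            post = fit_population(dose, _fit_config(config), substance=chem)
            post.rhat_table.to_csv(out / f"convergence_{chem}.tsv",
                                   sep="\t", index=False)
            manifest.record(f"fit[{chem}]", "ok", time.perf_counter() - t0,
                            seed=config.stage_seed("fit"),
                            iterations=post.iterations,
                            converged=post.converged,
                            max_rhat=post.max_rhat())
        except Exception as exc:
            raise StageError(f"fit[{chem}]: {exc}") from exc

        t0 = time.perf_counter()
        max_conc = float(plates.loc[plates["well_role"] == "treatment",
                                    "concentration_uM"].max())
        pod_tbl = podm.pod_table(post)
        pod_tbl.to_csv(out / f"pod_{chem}.tsv", sep="\t", index=False)
        pod_tables[chem] = pod_tbl
        call = podm.classify_activity(post, max_conc,
                                      rule_factor=config.inactivity_factor)
        entry = dict(active=call.active,
                     population_median_ec10=call.population_median_ec10,
                     max_concentration=max_conc,
                     fit_converged=post.converged,
                     max_rhat=post.max_rhat())
        if call.active:
            td = podm.tdvf05(post)
            tdvfs[chem] = td
            pods[chem] = call.population_median_ec10
            entry["tdvf05"] = dict(
                median=td.median, ci05=td.ci05, ci95=td.ci95,
                exceeds_default_td=bool(td.median > config.tdvf_benchmarks[0]),
                exceeds_default_total=bool(td.median > config.tdvf_benchmarks[1]))
        report["substances"][chem] = entry
        manifest.record(f"pod[{chem}]", "ok", time.perf_counter() - t0)

        if genotypes is not None and call.active:
            t0 = time.perf_counter()
            try:
                filtered = gw.filter_maf(genotypes, config.maf_threshold)
                pcs = gw.genotype_pcs(filtered, config.n_pcs)
                pheno = gw.phenotype_from_pods(pod_tbl)
                tbl = gw.snp_association(pheno, filtered, pcs)
                tbl.to_csv(out / f"gwas_{chem}.tsv", sep="\t", index=False)
                gwas_tables[chem] = tbl
                infl = gw.genomic_lambda(tbl["p"].dropna())
                entry["gwas"] = dict(
                    lam=infl.lam, lambda_acceptable=infl.acceptable,
                    n_suggestive=int((tbl["hit_class"] == "suggestive").sum()
                                     + (tbl["hit_class"] == "significant").sum()),
                    n_significant=int((tbl["hit_class"] == "significant").sum()))
                manifest.record(f"gwas[{chem}]", "ok",
                                time.perf_counter() - t0)
            except Exception as exc:
                raise StageError(f"gwas[{chem}]: {exc}") from exc

    if len(pods) >= 2:
        summary = podm.summarize_variability(pods, tdvfs)
        summary["table"].to_csv(out / "tdvf_summary.tsv", sep="\t", index=False)
        report["ec10_tdvf_correlation"] = summary["ec10_tdvf_correlation"]
        report["median_tdvf"] = summary["median_tdvf"]
    if len(gwas_tables) >= 2:
        overlap = gw.overlap_loci(gwas_tables)
        overlap.to_csv(out / "overlap_loci.tsv", sep="\t", index=False)
        report["n_overlap_loci"] = int(len(overlap))

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    manifest.write(out / f"manifest_{manifest.config_hash}.json")
    return dict(report=report, manifest=manifest, pods=pod_tables,
                tdvfs=tdvfs, gwas=gwas_tables)
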