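"""End-to-end orchestration: simulate/load → filter → F_ST → hybrid index →
SMI → sympatry comparison → model averaging, with a JSON report and manifest.

Each stage writes its documented table under the output directory so any
stage can be rerun or inspected on its own; a failure aborts with the
stage named while earlier outputs are retained. Given the same config
(including seeds) the report is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from chickadmix import __version__
from chickadmix.body_condition import compare_groups, compute_smi, fit_sma
from chickadmix.differentiation import fst_scan, select_diagnostic_loci
from chickadmix.genotype_io import (
    GenotypeMatrix,
    filter_report,
    filter_sites,
    read_metadata,
    read_vcf,
)
from chickadmix.hybrid_index import (
    estimate_h_mcmc,
    estimates_to_frame,
    hybrid_summary,
)
from chickadmix.model_averaging import enumerate_models, fit_model, model_average, z_scale
from chickadmix.synthetic_data import SimulationDesign, parental_panels, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; every stochastic stage has an explicit seed."""

    outdir: str = "chickadmix_run"
    # input: either a simulation design, or paths to a VCF + metadata CSV
    simulate: bool = True
    design: SimulationDesign | None = None
    vcf_path: str | None = None
    metadata_path: str | None = None
    # parental reference panels (band lists); None = from simulation truth
    panel_a: list[str] | None = None
    panel_b: list[str] | None = None
    # site filters
    min_qual: float = 30.0
    min_maf: float = 0.0001
    max_missing: float = 0.5
    depth_bounds: tuple | None = None
    # differentiation
    fst_threshold: float = 0.65
    pseudocount: float = 0.5
    # hybrid-index MCMC
    mcmc_iterations: int = 6000
    mcmc_burn_in: int = 3000
    mcmc_proposal_sd: float = 0.05
    mcmc_seed: int = 1
    hybrid_cutoff: float = 0.20
    # SMI
    l0_overrides: dict = field(default_factory=dict)
    # model averaging
    model_terms: list[str] = field(
        default_factory=lambda: [
            "sex",
            "age",
            "sympatry",
            "elevation",
            "latitude",
            "elevation:latitude",
        ]
    )
    include_hybrid_index: bool = False
    random_intercept: str | None = "year"
    delta_cutoff: float = 4.0


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "design" in raw and raw["design"] is not None:
        raw["design"] = SimulationDesign(**raw["design"])
    if raw.get("depth_bounds") is not None:
        raw["depth_bounds"] = tuple(raw["depth_bounds"])
    return PipelineConfig(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrix, metadata, design = _load_inputs(config)
    panel_a, panel_b = _resolve_panels(config, metadata)

    matrix_f = _filter(config, matrix, outdir)
    locus_table = _differentiate(config, matrix_f, panel_a, panel_b, outdir)
    estimates = _hybrid_indices(config, matrix_f, locus_table, outdir)
    smi_table, comparisons = _condition(config, metadata, outdir)
    hyb = hybrid_summary(estimates, metadata)
    averaged = _model_average(config, smi_table, estimates, outdir)

    report = {
        "n_individuals": int(matrix.n_individuals),
        "n_loci_input": int(matrix.n_loci),
        "n_loci_after_filter": int(matrix_f.n_loci),
        "n_diagnostic_loci": int(locus_table["diagnostic"].sum()),
        "hybrid_summary": hyb,
        "condition_comparisons": comparisons,
        "model_averaging": averaged,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    manifest = {
        "package_version": __version__,
        "config": _config_dict(config, design),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return report


def _config_dict(config: PipelineConfig, design: SimulationDesign | None) -> dict:
    d = dataclasses.asdict(config)
    if design is not None:
        d["design"] = dataclasses.asdict(design)
    return d


@_stage("load_inputs")
def _load_inputs(config: PipelineConfig):
    if config.simulate:
        design = config.design or SimulationDesign()
        _, matrix, metadata = simulate_dataset(design)
        return matrix, metadata, design
    if not config.vcf_path or not config.metadata_path:
        raise ValueError("need vcf_path and metadata_path when simulate is false")
    return read_vcf(config.vcf_path), read_metadata(config.metadata_path), None


@_stage("resolve_panels")
def _resolve_panels(config: PipelineConfig, metadata: pd.DataFrame):
    if config.panel_a is not None and config.panel_b is not None:
        return list(config.panel_a), list(config.panel_b)
    if "ancestry_class" not in metadata.columns:
        raise ValueError("panel_a/panel_b must be given for non-simulated input")
    return parental_panels(metadata)


@_stage("filter_sites")
def _filter(config: PipelineConfig, matrix: GenotypeMatrix, outdir: Path):
    report = filter_report(
        matrix, config.min_qual, config.min_maf, config.max_missing, config.depth_bounds
    )
    report.to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    out = filter_sites(
        matrix, config.min_qual, config.min_maf, config.max_missing, config.depth_bounds
    )
    logger.info("retained %d/%d loci after site filters", out.n_loci, matrix.n_loci)
    return out


@_stage("fst_scan")
def _differentiate(config, matrix, panel_a, panel_b, outdir: Path):
    table = fst_scan(matrix, panel_a, panel_b, pseudocount=config.pseudocount)
    table = select_diagnostic_loci(table, threshold=config.fst_threshold)
    table.to_csv(outdir / "fst_table.tsv", sep="\t", index=False)
    return table


@_stage("hybrid_index")
def _hybrid_indices(config, matrix: GenotypeMatrix, locus_table: pd.DataFrame, outdir: Path):
    diag = locus_table["diagnostic"].to_numpy()
    p_a = locus_table.loc[diag, "p_a"].to_numpy()
    p_b = locus_table.loc[diag, "p_b"].to_numpy()
    calls = matrix.calls[:, diag]
    ests = []
    rng = np.random.default_rng(config.mcmc_seed)
    for i, band in enumerate(matrix.individuals):
        ests.append(
            estimate_h_mcmc(
                calls[i],
                p_a,
                p_b,
                n_iter=config.mcmc_iterations,
                burn_in=config.mcmc_burn_in,
                proposal_sd=config.mcmc_proposal_sd,
                seed=int(rng.integers(2**31 - 1)),
                band=band,
                cutoff=config.hybrid_cutoff,
            )
        )
    frame = estimates_to_frame(ests)
    frame.to_csv(outdir / "hybrid_indices.tsv", sep="\t", index=False)
    return frame


@_stage("body_condition")
def _condition(config: PipelineConfig, metadata: pd.DataFrame, outdir: Path):
    rows = []
    comparisons = {}
    for sp, grp in metadata.groupby("species"):
        params = fit_sma(
            grp["mass"], grp["tarsus"], species=sp, l0=config.l0_overrides.get(sp)
        )
        smi = compute_smi(grp["mass"].to_numpy(), grp["tarsus"].to_numpy(), params)
        sub = grp[["band", "species", "sympatry"]].copy()
        sub["smi"] = smi
        rows.append(sub)
        symp = sub.loc[sub["sympatry"] == "sympatric", "smi"]
        allo = sub.loc[sub["sympatry"] == "allopatric", "smi"]
        if len(symp) >= 2 and len(allo) >= 2:
            cmp_ = compare_groups(symp, allo, params, params)
            comparisons[sp] = {
                "b_sma": params.b_sma,
                "l0": params.l0,
                "mean_sympatric": round(cmp_.mean_sympatric, 2),
                "mean_allopatric": round(cmp_.mean_allopatric, 2),
                "se_sympatric": round(cmp_.se_sympatric, 2),
                "se_allopatric": round(cmp_.se_allopatric, 2),
                "percent_lower": round(cmp_.percent_lower, 1),
                "t": cmp_.t_stat,
                "df": cmp_.df,
                "p": cmp_.p_value,
                "n_sympatric": cmp_.n_sympatric,
                "n_allopatric": cmp_.n_allopatric,
            }
    smi_table = pd.concat(rows, ignore_index=True).merge(
        metadata.drop(columns=["species", "sympatry"]), on="band"
    )
    smi_table.to_csv(outdir / "smi.tsv", sep="\t", index=False)
    with open(outdir / "condition_comparison.json", "w") as fh:
        json.dump(comparisons, fh, indent=2, sort_keys=True)
    return smi_table, comparisons


@_stage("model_averaging")
def _model_average(config: PipelineConfig, smi_table: pd.DataFrame, estimates, outdir: Path):
    data = smi_table.copy()
    if config.include_hybrid_index:
        data = data.merge(estimates[["band", "h_rescaled"]], on="band", how="inner")
        data = data.rename(columns={"h_rescaled": "hybrid_index"})
    results = {}
    for sp, grp in data.groupby("species"):
        grp = grp.copy()
        terms = list(config.model_terms)
        if config.include_hybrid_index and "hybrid_index" not in terms:
            terms.append("hybrid_index")
        # Z-scale the numeric predictors; drop terms constant in this subset
        usable = []
        for t in terms:
            cols = t.split(":")
            ok = True
            for c in cols:
                if c not in grp.columns:
                    ok = False
                    continue
                if grp[c].nunique() < 2:
                    warnings.warn(f"term {c!r} constant for species {sp}; dropped")
                    ok = False
                elif pd.api.types.is_numeric_dtype(grp[c]):
                    grp[c] = z_scale(grp[c])
            if ok:
                usable.append(t)
        fits = []
        for subset in enumerate_models(usable):
            fits.append(
                fit_model(grp, "smi", subset, random_intercept=config.random_intercept)
            )
        table = model_average(fits, delta_cutoff=config.delta_cutoff)
        table.model_set.to_csv(outdir / f"model_set_{sp}.tsv", sep="\t", index=False)
        table.coefficients.to_csv(
            outdir / f"averaged_coefficients_{sp}.tsv", sep="\t", index=False
        )
        results[sp] = {
            "n_models": len(fits),
            "n_top": int((table.model_set["weight"] > 0).sum()),
            "coefficients": table.coefficients.to_dict(orient="records"),
        }
    return results
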