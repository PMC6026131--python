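"""End-to-end orchestration: simulate → validate → decompose → tile →
count → fit → test → summarize.

The pipeline mirrors the analysis order of the underlying study: build
(or load) a cohort of traced networks, assemble per-animal × per-region
count tables for each requested flavor, fit the full Poisson mixed
model, run drop-one likelihood-ratio tests for deprivation, the
deprivation × region interaction, age and sex, post-hoc region
contrasts, the Poisson dispersion check, the per-animal LMA-vs-PA
regressions (pooled / plucked / sham, Bonferroni k = 3) and the
detectable-effect-size summary.

A single top-level seed deterministically spawns per-stage substreams so
the run is reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import PialnetError
from .inference import (FULL_TERMS, ModelSpec, PowerSpec, detectable_effect_size,
                        dispersion_check, fit_poisson_glmm,
                        likelihood_ratio_test, lma_pa_regression, tukey_posthoc)
from .netcore import validate_network
from .synthgen import GeneratorParams, export_cohort, generate_cohort
from .territories import build_count_table

#: regions entering the LMA-vs-PA per-animal totals (the best-reconstructed
#: somatosensory territories)
LMA_PA_REGIONS = ("barrels", "forelimb", "hindlimb")

_TESTABLE = ("S", "S:R", "Y", "G")


@dataclass
class PipelineConfig:
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    flavors: tuple = ("pa", "lma", "offshoot_vertices")
    near_cutoff_mm: float = 0.3
    n_quad: int = 15
    posthoc_draws: int = 100_000
    posthoc_seed: int = 2024
    seed: Optional[int] = None    # overrides generator.seed when set

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        gen = GeneratorParams(**doc.pop("generator", {}))
        known = {f.name for f in dataclasses.fields(cls)} - {"generator"}
        bad = set(doc) - known
        if bad:
            raise PialnetError(f"unknown config keys: {sorted(bad)}")
        if "flavors" in doc:
            doc["flavors"] = tuple(doc["flavors"])
        return cls(generator=gen, **doc)


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> dict:
    """Run the full analysis on a freshly simulated cohort.

    Returns the report bundle (cohort, tables, fits, tests, summaries);
    when ``out_dir`` is given, also writes count tables (CSV), fit and
    test results (JSON/CSV) and the run log there.
    """
    gen = cfg.generator
    if cfg.seed is not None:
        gen = dataclasses.replace(gen, seed=cfg.seed)
    log = {"seed": gen.seed, "stages": []}

    cohort = generate_cohort(gen)
    log["stages"].append({"stage": "simulate", "n_animals": len(cohort)})
    for s in cohort:
        bad = [f for f in validate_network(s.network, s.regions)
               if f.severity == "error"]
        if bad:
            raise PialnetError(f"stage=validate animal={s.animal_id}: {bad[0]}")
    log["stages"].append({"stage": "validate"})

    bundle: dict = {"config": cfg, "cohort": cohort, "flavors": {}, "log": log}
    for flavor in cfg.flavors:
        try:
            table = build_count_table(cohort, flavor, cfg.near_cutoff_mm)
        except PialnetError as exc:
            raise PialnetError(f"stage=count flavor={flavor}: {exc}") from exc
        spec = ModelSpec(FULL_TERMS, n_quad=cfg.n_quad)
        full = fit_poisson_glmm(table, spec)
        lrts = {}
        for factor in _TESTABLE:
            red = fit_poisson_glmm(table, spec.reduced(factor))
            lrts[factor] = likelihood_ratio_test(full, red, factor)
        posthoc = tukey_posthoc(full, "R", cfg.posthoc_draws, cfg.posthoc_seed)
        disp = dispersion_check(full)
        bundle["flavors"][flavor] = {
            "table": table, "fit": full, "lrt": lrts,
            "posthoc": posthoc, "dispersion": disp,
        }
        log["stages"].append({"stage": "fit", "flavor": flavor,
                              "loglik": full.loglik, "sigma_u": full.sigma_u})

    # per-animal LMA-vs-PA totals over the somatosensory regions
    bundle["lma_pa"] = {}
    if {"pa", "lma"} <= set(cfg.flavors):
        pa_df = bundle["flavors"]["pa"]["table"].df
        lma_df = bundle["flavors"]["lma"]["table"].df
        sel = list(LMA_PA_REGIONS)
        pa_tot = (pa_df[pa_df.region.isin(sel)]
                  .groupby("animal_id")["count"].sum())
        lma_tot = (lma_df[lma_df.region.isin(sel)]
                   .groupby("animal_id")["count"].sum())
        groups = pa_df.drop_duplicates("animal_id").set_index("animal_id")["group"]
        merged = pd.DataFrame({"pa": pa_tot, "lma": lma_tot,
                               "group": groups}).dropna()
        subsets = {"pooled": merged,
                   "plucked": merged[merged.group == "plucked"],
                   "sham": merged[merged.group == "sham"]}
        for name, sub in subsets.items():
            if len(sub) >= 3 and sub["pa"].nunique() > 1:
                bundle["lma_pa"][name] = lma_pa_regression(
                    list(zip(sub["pa"], sub["lma"])), k_comparisons=3)

    n_plucked = sum(1 for s in cohort if s.group == "plucked")
    n_sham = len(cohort) - n_plucked
    bundle["power"] = {
        "spec": PowerSpec(n1=n_sham, n2=n_plucked),
        "detectable_d": detectable_effect_size(PowerSpec(n1=n_sham, n2=n_plucked)),
    }
    log["stages"].append({"stage": "power", "d": bundle["power"]["detectable_d"]})

    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_bundle(bundle: dict, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    export_cohort(bundle["cohort"], os.path.join(out_dir, "cohort"))
    test_rows = []
    for flavor, res in bundle["flavors"].items():
        res["table"].to_csv(os.path.join(out_dir, f"counts_{flavor}.csv"))
        fit = res["fit"]
        with open(os.path.join(out_dir, f"fit_{flavor}.json"), "w") as fh:
            json.dump({
                "flavor": flavor,
                "estimates": fit.estimates.to_dict(),
                "se": fit.se.to_dict(),
                "sigma_u": fit.sigma_u,
                "loglik": fit.loglik,
                "converged": fit.converged,
                "n_obs": fit.n_obs,
                "n_fixed_params": fit.n_fixed_params,
            }, fh, indent=1, sort_keys=True)
        for factor, lrt in res["lrt"].items():
            test_rows.append([flavor, factor, lrt.statistic, lrt.df, lrt.p_value])
        res["posthoc"].to_frame().to_csv(
            os.path.join(out_dir, f"posthoc_{flavor}.csv"), index=False)
    pd.DataFrame(test_rows, columns=["flavor", "factor", "statistic", "df", "p"]
                 ).to_csv(os.path.join(out_dir, "lrt_tests.csv"), index=False)
    with open(os.path.join(out_dir, "lma_pa_regression.json"), "w") as fh:
        json.dump(_jsonable(bundle["lma_pa"]), fh, indent=1, sort_keys=True)
    with open(os.path.join(out_dir, "run_log.json"), "w") as fh:
        json.dump(_jsonable({"log": bundle["log"],
                             "power": bundle["power"]}), fh,
                  indent=1, sort_keys=True)
    with open(os.path.join(out_dir, "summary.txt"), "w") as fh:
        fh.write(report_summary(bundle))


def report_summary(bundle: dict) -> str:
    """Human-readable tables: per-region density means by group, LRT
    table, dispersion ratios, regressions and the power line."""
    if not bundle.get("flavors"):
        raise PialnetError("empty bundle: nothing to summarize")
    lines = []
    dens_rows = []
    for flavor, res in bundle["flavors"].items():
        df = res["table"].df.copy()
        df["density"] = df["count"] / df["area_mm2"]
        for (region, group), sub in df.groupby(["region", "group"]):
            dens_rows.append([flavor, region, group,
                              sub["count"].sum() / sub["area_mm2"].sum(),
                              sub["density"].mean(), len(sub)])
    dens = pd.DataFrame(dens_rows, columns=[
        "flavor", "region", "group", "pooled_density_per_mm2",
        "mean_animal_density", "n_animals"])
    lines.append("Per-region densities (count per mm²) by group and flavor")
    lines.append(dens.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    lines.append("")
    lines.append("Drop-one likelihood-ratio tests")
    for flavor, res in bundle["flavors"].items():
        for factor, lrt in res["lrt"].items():
            lines.append(f"  {flavor:18s} drop {factor:4s} "
                         f"chi2({lrt.df}) = {lrt.statistic:6.2f}  p = {lrt.p_value:.3f}")
        d = res["dispersion"]
        lines.append(f"  {flavor:18s} dispersion ratio = {d.ratio:.2f} "
                     f"(df {d.df}; p_over = {d.p_over:.3f}, p_under = {d.p_under:.3f})")
    if bundle.get("lma_pa"):
        lines.append("")
        lines.append("LMA vs PA per-animal totals (least squares, Bonferroni k=3)")
        for name, reg in bundle["lma_pa"].items():
            lines.append(f"  {name:8s} y = {reg.intercept:.3f} + {reg.slope:.3f}x, "
                         f"R² = {reg.r_squared:.3f}, t({reg.df}) = {reg.t:.2f}, "
                         f"p = {reg.p_adjusted:.3f}")
    pw = bundle["power"]
    lines.append("")
    lines.append(f"Detectable effect size (one-tailed t, α={pw['spec'].alpha}, "
                 f"power={pw['spec'].power}, n={pw['spec'].n1}/{pw['spec'].n2}): "
                 f"d = {pw['detectable_d']:.2f}")
    return "\n".join(lines) + "\n"
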