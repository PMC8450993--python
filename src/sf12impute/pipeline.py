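"""Orchestration: generate -> simulate -> impute -> evaluate as one run.

A run is fully described by a :class:`RunConfig` (cohorts, missingness
model source, per-item target rates, methods, replication count, seed,
output directory).  ``run_all`` executes every stage, writes cohort CSVs,
masked datasets, fills tables, result tables and a JSON manifest with
enough seed bookkeeping to re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, presets
from .amputation import complete_cases, simulate_replicates
from .cohort import CohortConfig, attach_auxiliary_measures, cohort_config, generate_cohort
from .concordance import evaluate_method, summarize
from .diagnostics import LogisticMissingnessModel, fit_all_items
from .imputers import METHOD_NAMES, impute
from .instrument import ITEM_CODES, ResponseMatrix

__all__ = ["RunConfig", "RunResult", "ConfigError", "validate_config", "run_all",
           "preset_models", "preset_rates"]


class ConfigError(ValueError):
    """Run configuration violates the schema; message lists every problem."""


@dataclass
class RunConfig:
    cohorts: list[CohortConfig]
    model_source: str = "preset"          # "preset" | "fit"
    rates: dict[str, float] | None = None  # None -> per-profile preset
    methods: list[str] = field(default_factory=lambda: list(METHOD_NAMES))
    replications: int = 10
    seed: int = 0
    outdir: str = "sf12impute_run"
    attach_aux: bool = True
    write_datasets: bool = True
    write_fills: bool = True
    mi_m: int = 5


@dataclass
class RunResult:
    summary: pd.DataFrame
    long: pd.DataFrame
    manifest: dict


_TOP_KEYS = {
    "cohorts", "model_source", "rates", "methods", "replications", "seed",
    "outdir", "attach_aux", "write_datasets", "write_fills", "mi_m",
}
_COHORT_KEYS = {
    "profile", "n", "seed", "age_mean", "age_sd", "age_min", "age_max",
    "p_female", "p_ssc", "p_ueq", "factor_corr", "loadings", "thresholds",
    "pair_loading", "age_health_slope",
}


def preset_rates(profile: str) -> dict[str, float]:
    if profile not in presets.MISSING_RATES:
        raise ValueError(f"no missing-rate preset for profile {profile!r}")
    return dict(presets.MISSING_RATES[profile])


def preset_models() -> dict[str, LogisticMissingnessModel]:
    return {
        item: LogisticMissingnessModel.from_coefficients(item, coefs)
        for item, coefs in presets.MISSINGNESS_COEFFICIENTS.items()
    }


def validate_config(doc: dict | None) -> RunConfig:
    """Turn a raw key-value document into a fully defaulted RunConfig.

    Unknown keys are rejected; every schema violation found is reported.
    """
    doc = dict(doc or {})
    errors: list[str] = []
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown keys: {sorted(unknown)}")

    cohort_docs = doc.get("cohorts") or [{"profile": "clinical", "n": 1000}]
    cohorts: list[CohortConfig] = []
    if not isinstance(cohort_docs, list):
        errors.append("cohorts must be a list")
        cohort_docs = []
    for idx, cdoc in enumerate(cohort_docs):
        if not isinstance(cdoc, dict):
            errors.append(f"cohorts[{idx}] must be a mapping")
            continue
        bad = set(cdoc) - _COHORT_KEYS
        if bad:
            errors.append(f"cohorts[{idx}]: unknown keys {sorted(bad)}")
            continue
        params = dict(cdoc)
        profile = params.pop("profile", "clinical")
        n = params.pop("n", 1000)
        seed = params.pop("seed", idx)
        try:
            cohorts.append(cohort_config(profile, n=int(n), seed=int(seed), **params))
        except (ValueError, TypeError) as exc:
            errors.append(f"cohorts[{idx}]: {exc}")

    model_source = doc.get("model_source", "preset")
    if model_source not in ("preset", "fit"):
        errors.append("model_source must be 'preset' or 'fit'")

    rates = doc.get("rates")
    if rates is not None:
        if not isinstance(rates, dict):
            errors.append("rates must be a mapping item -> rate")
        else:
            bad_items = set(rates) - set(ITEM_CODES)
            if bad_items:
                errors.append(f"rates: unknown items {sorted(bad_items)}")
            for item, h in rates.items():
                if not isinstance(h, (int, float)) or not 0.0 <= h <= 1.0:
                    errors.append(f"rates[{item}] must be in [0, 1]")

    methods = doc.get("methods", list(METHOD_NAMES))
    if not isinstance(methods, list) or not methods:
        errors.append("methods must be a non-empty list")
    else:
        bad_methods = [m for m in methods if m not in METHOD_NAMES]
        if bad_methods:
            errors.append(f"unknown methods {bad_methods}")

    replications = doc.get("replications", 10)
    if not isinstance(replications, int) or replications < 1:
        errors.append("replications must be an integer >= 1")

    seed = doc.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed must be an integer")

    mi_m = doc.get("mi_m", 5)
    if not isinstance(mi_m, int) or mi_m < 2:
        errors.append("mi_m must be an integer >= 2")

    if errors:
        raise ConfigError("; ".join(errors))

    return RunConfig(
        cohorts=cohorts,
        model_source=model_source,
        rates=None if rates is None else {k: float(v) for k, v in rates.items()},
        methods=list(methods),
        replications=replications,
        seed=seed,
        outdir=str(doc.get("outdir", "sf12impute_run")),
        attach_aux=bool(doc.get("attach_aux", True)),
        write_datasets=bool(doc.get("write_datasets", True)),
        write_fills=bool(doc.get("write_fills", True)),
        mi_m=mi_m,
    )


def _derived_seed(root: int, *key: int) -> int:
    """A stable sub-seed below 2**31 for a stage identified by ``key``."""
    ss = np.random.SeedSequence(root, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def _cohort_rates(config: RunConfig, cohort: CohortConfig) -> dict[str, float]:
    if config.rates is not None:
        full = preset_rates(cohort.profile if cohort.profile in presets.MISSING_RATES
                            else "clinical")
        full.update(config.rates)
        return full
    return preset_rates(cohort.profile)


def run_all(config: RunConfig) -> RunResult:
    """Execute every stage for every cohort; see module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    method_index = {m: i for i, m in enumerate(METHOD_NAMES)}
    item_index = {c: i for i, c in enumerate(ITEM_CODES)}

    long_rows: list[dict] = []
    dataset_records: list[dict] = []
    stage_seeds: dict[str, int] = {}

    for c_idx, ccfg in enumerate(config.cohorts):
        profile = ccfg.profile
        tag = f"{profile}{c_idx}"
        base = generate_cohort(ccfg)
        if config.attach_aux:
            aux_seed = _derived_seed(config.seed, c_idx, 1001)
            stage_seeds[f"aux/{tag}"] = aux_seed
            base = attach_auxiliary_measures(base, seed=aux_seed)
        base = complete_cases(base)
        base.to_csv(outdir / f"cohort_{tag}.csv")

        if config.model_source == "preset":
            models = preset_models()
        else:
            models = fit_all_items(base)
        rates = _cohort_rates(config, ccfg)

        sim_seed = _derived_seed(config.seed, c_idx, 2002)
        stage_seeds[f"simulate/{tag}"] = sim_seed
        masked_sets = simulate_replicates(
            base, models, rates, n_replicates=config.replications, seed=sim_seed
        )

        masked_dir = outdir / f"masked_{tag}"
        if config.write_datasets:
            masked_dir.mkdir(exist_ok=True)

        fills_frames: list[pd.DataFrame] = []
        for masked in masked_sets:
            dataset_records.append({
                "cohort": tag, "item": masked.item, "replicate": masked.replicate,
                "seed_path": masked.seed_path, "h": rates[masked.item],
                "n_masked": masked.n_masked,
            })
            if config.write_datasets:
                out = masked.data.copy()
                out.insert(0, "id", np.arange(1, len(out) + 1))
                out.to_csv(
                    masked_dir / f"{masked.item}_r{masked.replicate}.csv",
                    index=False, na_rep="",
                )
            for method in config.methods:
                row = {
                    "cohort": tag, "item": masked.item, "method": method,
                    "replicate": masked.replicate, "n_pairs": masked.n_masked,
                }
                if masked.n_masked < 3:
                    row["icc"] = float("nan")
                    long_rows.append(row)
                    continue
                rs = _derived_seed(
                    config.seed, c_idx, item_index[masked.item],
                    masked.replicate, method_index[method],
                )
                opts = {"m": config.mi_m} if method in ("MI_DA", "MI_FCS") else {}
                imp = impute(masked, method, random_state=rs, **opts)
                row["icc"] = evaluate_method(imp)
                long_rows.append(row)
                if config.write_fills:
                    f = imp.fills.copy()
                    f.insert(0, "method", method)
                    f.insert(0, "replicate", masked.replicate)
                    fills_frames.append(f)
        if config.write_fills and fills_frames:
            pd.concat(fills_frames, ignore_index=True).to_csv(
                outdir / f"fills_{tag}.csv", index=False
            )

    long = pd.DataFrame(long_rows)
    summaries = []
    for tag, grp in long.groupby("cohort", sort=False):
        s = summarize(grp.dropna(subset=["icc"]))
        s.insert(0, "cohort", tag)
        summaries.append(s)
    summary = pd.concat(summaries, ignore_index=True)

    long.to_csv(outdir / "results_long.csv", index=False)
    summary.to_csv(outdir / "results_summary.csv", index=False)

    manifest = {
        "version": __version__,
        "config": _config_snapshot(config),
        "stage_seeds": stage_seeds,
        "datasets": dataset_records,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return RunResult(summary=summary, long=long, manifest=manifest)


def _config_snapshot(config: RunConfig) -> dict:
    snap = dataclasses.asdict(config)
    for cdoc in snap["cohorts"]:
        cdoc.pop("instrument", None)
        cdoc["thresholds"] = {
            k: np.asarray(v).tolist() for k, v in cdoc["thresholds"].items()
        }
    return snap
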