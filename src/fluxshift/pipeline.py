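"""Config-driven end-to-end runner.

One YAML config describes a full run: model -> WT/MUT condition pair ->
uniform flux sampling of both states -> exchange scoring and ranking ->
FVA comparator -> optional evaluation against an observed metabolite list.
Outputs are flat TSV files plus a YAML manifest (config echo, model digest,
seeds, versions, per-stage wall times) sufficient to reproduce the run.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conditions import ConditionSpec, build_condition_pair
from .evaluation import rank_cutoff_scan, read_observed_tsv, scan_to_frame
from .fva import fva_direction_call, run_fva
from .io import read_model
from .sampling import (
    convergence_diagnostics,
    sample_chains,
    validate_samples,
    write_samples_tsv,
    FluxSamples,
)
from .scoring import score_exchanges

log = logging.getLogger("fluxshift")

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    model: str
    targets: list
    seed: int
    outdir: str = "fluxshift_out"
    model_format: str = "auto"
    name: str = "condition"
    target_kind: str = "genes"
    mode: str = "knockout"
    knockdown_fraction: float | None = None
    medium_uptake_X: float | None = 1.0
    biomass_reaction: str | None = None
    biomass_fraction: float = 0.0
    forcing_fraction: float = 0.05
    n_samples: int = 100_000
    thinning: int = 100
    n_chains: int = 2
    n_pairs: int | None = None
    observed_tsv: str | None = None
    cutoffs: list | None = None
    write_samples: bool = False

    def condition_spec(self) -> ConditionSpec:
        return ConditionSpec(
            name=self.name,
            perturbation_targets=list(self.targets),
            target_kind=self.target_kind,
            mode=self.mode,
            knockdown_fraction=self.knockdown_fraction,
            medium_uptake_X=self.medium_uptake_X,
            biomass_reaction=self.biomass_reaction,
            biomass_fraction=self.biomass_fraction,
            forcing_fraction=self.forcing_fraction,
        )


_CONFIG_TYPES = {
    "model": str,
    "targets": list,
    "seed": int,
    "outdir": str,
    "model_format": str,
    "name": str,
    "target_kind": str,
    "mode": str,
    "knockdown_fraction": (int, float, type(None)),
    "medium_uptake_X": (int, float, type(None)),
    "biomass_reaction": (str, type(None)),
    "biomass_fraction": (int, float),
    "forcing_fraction": (int, float),
    "n_samples": int,
    "thinning": int,
    "n_chains": int,
    "n_pairs": (int, type(None)),
    "observed_tsv": (str, type(None)),
    "cutoffs": (list, type(None)),
    "write_samples": bool,
}


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run config (fail-closed on unknown keys)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    unknown = set(raw) - set(_CONFIG_TYPES)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("model", "targets", "seed"):
        if key not in raw:
            raise ConfigError(f"config key {key!r} is mandatory")
    for key, value in raw.items():
        if not isinstance(value, _CONFIG_TYPES[key]) or isinstance(value, bool) and _CONFIG_TYPES[key] is int:
            raise ConfigError(
                f"config key {key!r}: expected {_CONFIG_TYPES[key]}, got {type(value).__name__}"
            )
    cfg = RunConfig(**raw)
    if cfg.medium_uptake_X is not None and cfg.medium_uptake_X < 0:
        raise ConfigError("medium_uptake_X must be nonnegative")
    if cfg.mode == "knockdown" and cfg.knockdown_fraction is None:
        raise ConfigError("knockdown mode requires knockdown_fraction")
    if not Path(cfg.model).exists():
        raise ConfigError(f"model file not found: {cfg.model}")
    if cfg.observed_tsv is not None and not Path(cfg.observed_tsv).exists():
        raise ConfigError(f"observed TSV not found: {cfg.observed_tsv}")
    cfg.condition_spec()  # surfaces ConditionSpec-level violations early
    return cfg


def _stage(manifest, name, t0, **counts):
    dt = time.perf_counter() - t0
    manifest["stages"].append({"stage": name, "seconds": round(dt, 3), **counts})
    log.info("stage %-12s %7.2fs %s", name, dt,
             " ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write all artifacts to config.outdir.

    Returns the manifest dict.  On any stage failure a FAILED marker file is
    written next to the partial artifacts and the error re-raised.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "version": __version__,
        "stages": [],
    }
    try:
        _run_stages(config, outdir, manifest)
    except Exception as err:
        (outdir / "FAILED").write_text(f"{type(err).__name__}: {err}\n")
        raise
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def _run_stages(config: RunConfig, outdir: Path, manifest: dict) -> None:
    t0 = time.perf_counter()
    model = read_model(config.model, config.model_format)
    manifest["model_digest"] = model.digest()
    _stage(manifest, "load_model", t0,
           metabolites=model.n_metabolites, reactions=model.n_reactions)

    t0 = time.perf_counter()
    pair = build_condition_pair(model, config.condition_spec())
    manifest["affected_reactions"] = pair.affected_reactions
    manifest["unforceable_reactions"] = pair.unforceable_reactions
    _stage(manifest, "conditions", t0, affected=len(pair.affected_reactions))

    t0 = time.perf_counter()
    exchange_ids = sorted(pair.wt.exchange_ids)
    wt_fva = run_fva(pair.wt, exchange_ids)
    mut_fva = run_fva(pair.mut, exchange_ids)
    calls = fva_direction_call(wt_fva, mut_fva)
    fva_df = pd.DataFrame(
        {
            "reaction_id": exchange_ids,
            "wt_min": wt_fva.min_flux,
            "wt_max": wt_fva.max_flux,
            "mut_min": mut_fva.min_flux,
            "mut_max": mut_fva.max_flux,
            "direction": [c.direction for c in calls],
            "magnitude": [c.magnitude for c in calls],
        }
    )
    fva_df.to_csv(outdir / "fva_comparison.tsv", sep="\t", index=False)
    _stage(manifest, "fva", t0, exchanges=len(exchange_ids))

    samples = {}
    for tag, m in (("wt", pair.wt), ("mut", pair.mut)):
        t0 = time.perf_counter()
        chains = sample_chains(
            m,
            n_samples=-(-config.n_samples // config.n_chains),
            thinning=config.thinning,
            seed=config.seed,
            n_chains=config.n_chains,
        )
        merged = FluxSamples(
            np.vstack([c.matrix for c in chains])[: config.n_samples],
            list(m.reaction_ids),
            {"seed": config.seed, "n_chains": config.n_chains,
             "thinning": config.thinning, "model_digest": m.digest(),
             "state": tag},
        )
        if not validate_samples(m, merged):
            raise RuntimeError(f"{tag} samples violate feasibility invariants")
        samples[tag] = merged
        if config.write_samples:
            write_samples_tsv(merged, outdir / f"samples_{tag}.tsv")
        if len(chains) >= 2:
            report = convergence_diagnostics(chains)
            pd.DataFrame(
                {"reaction_id": report.reaction_ids, "psrf": report.psrf}
            ).to_csv(outdir / f"convergence_{tag}.tsv", sep="\t", index=False)
            manifest[f"max_psrf_{tag}"] = report.max_psrf()
        _stage(manifest, f"sample_{tag}", t0, samples=merged.n_samples)

    t0 = time.perf_counter()
    profile = score_exchanges(
        samples["wt"],
        samples["mut"],
        pair.wt,
        wt_fva=wt_fva,
        mut_fva=mut_fva,
        n_pairs=config.n_pairs,
        seed=config.seed,
        condition=config.name,
    )
    profile_df = profile.to_frame()
    profile_df.to_csv(outdir / "profile.tsv", sep="\t", index=False)
    _stage(manifest, "score", t0, scored=profile.n_scored,
           rows=len(profile_df))

    if config.observed_tsv:
        t0 = time.perf_counter()
        observed = read_observed_tsv(config.observed_tsv)
        cutoffs = config.cutoffs or sorted(
            {min(profile.n_scored, c) for c in (5, 10, 25, 50, profile.n_scored)}
        )
        results = rank_cutoff_scan(profile, observed, cutoffs)
        scan_to_frame(results).to_csv(outdir / "evaluation.tsv", sep="\t", index=False)
        _stage(manifest, "evaluate", t0, cutoffs=len(results))
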