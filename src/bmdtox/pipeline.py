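"""End-to-end analysis pipeline: incidence table → BMD → RfD → MCLG.

Drives the full chain from a single YAML config: frequentist suite fit and
model selection, Bayesian model averaging, HED conversion and deterministic
uncertainty-factor RfD, probabilistic RfD via lognormal adjustment-factor
propagation, and the drinking-water guideline.  The returned manifest
records every input, seed and config version next to each stage's outputs,
so a run can be reproduced from the manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from ._version import __version__
from .bayes import default_priors, fit_bayesian_suite, load_priors, model_average_bmd
from .datasets import BenchmarkResponse, builtin_fixture, load_quantal
from .prfd import default_af_config, default_chain, load_af_config, propagate
from .quantal import compute_bmd, compute_bmdl, fit_suite, goodness_of_fit, select_model
from .rfd import GuidelineInputs, PointOfDeparture, UncertaintyFactorSet, derive_rfd, hed, mclg

__all__ = ["run_pipeline", "load_config", "default_genx_config", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and a remedy hint."""


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def default_genx_config() -> dict:
    """The packaged configuration reproducing the GenX chronic-bioassay chain."""
    ref = resources.files("bmdtox.data").joinpath("genx_paper.yaml")
    with resources.as_file(ref) as path:
        return load_config(path)


def _load_dataset(cfg: dict):
    if "fixture" in cfg:
        return builtin_fixture(cfg["fixture"])
    if "path" in cfg:
        return load_quantal(cfg["path"])
    raise PipelineError("dataset stage: config needs 'fixture' or 'path'")


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the full chain described by ``config``; returns the manifest.

    The manifest is JSON-serializable and contains, per stage, the inputs
    used (including every default made explicit), the outputs, and rounding
    annotations (raw vs one-significant-figure reported values).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    bmr_cfg = config.get("bmr", {"kind": "extra_risk", "level": 0.10})
    bmr = BenchmarkResponse(bmr_cfg["kind"], bmr_cfg.get("level"))
    confidence = float(config.get("confidence", 0.95))
    manifest: dict = {
        "tool": {"name": "bmdtox", "version": __version__},
        "seed": seed,
        "bmr": {"kind": bmr.kind, "level": bmr.level},
        "confidence_level": confidence,
        "stages": {},
    }

    # --- stage: data -----------------------------------------------------
    try:
        data = _load_dataset(config["dataset"])
    except Exception as exc:
        raise PipelineError(f"dataset stage failed: {exc}") from exc
    manifest["stages"]["data"] = {
        "endpoint": data.endpoint_name,
        "groups": [list(g) for g in data.groups],
    }

    # --- stage: frequentist BMD -----------------------------------------
    try:
        fits = fit_suite(data, restricted=config.get("frequentist", {}).get("restricted", True),
                         seed=seed)
        selected = select_model(fits, bmr, confidence_level=confidence)
    except Exception as exc:
        raise PipelineError(
            f"frequentist stage failed: {exc}; consider relaxing model constraints"
        ) from exc
    per_model = []
    for f in fits:
        gof_p, resid = goodness_of_fit(f)
        per_model.append(
            {
                "model": f.spec.label,
                "converged": f.converged,
                "log_likelihood": f.log_likelihood,
                "n_params_estimated": f.n_params_estimated,
                "aic": f.aic,
                "gof_p": gof_p,
                "scaled_residuals": [float(r) for r in resid],
                "theta": [float(t) for t in f.theta_hat],
            }
        )
    manifest["stages"]["frequentist"] = {
        "models": per_model,
        "selected": {
            "model": selected.model_name,
            "bmd": selected.bmd,
            "bmdl": selected.bmdl,
            "bmd_bmdl_ratio": selected.ratio,
            "high_uncertainty": selected.high_uncertainty,
            "bmdl_at_search_floor": selected.bmdl_at_search_floor,
        },
    }

    # --- stage: Bayesian model average ----------------------------------
    bayes_cfg = config.get("bayesian", {})
    try:
        priors_path = bayes_cfg.get("priors")
        priors = load_priors(priors_path) if priors_path else default_priors()
        bfits = fit_bayesian_suite(data, priors=priors, seed=seed)
        ma = model_average_bmd(
            bfits, bmr, n_draws=int(bayes_cfg.get("draws", 100_000)), seed=seed
        )
    except Exception as exc:
        raise PipelineError(f"bayesian stage failed: {exc}") from exc
    manifest["stages"]["bayesian"] = {
        "priors": priors_path or "packaged priors_default.yaml v1",
        "n_draws": ma.n_draws,
        "seed": ma.seed,
        "weights": ma.weights,
        "bmd_ma": ma.bmd_ma,
        "bmdl_ma": ma.bmdl_ma,
        "censored_fraction": ma.censored_fraction,
    }

    # --- stage: deterministic RfD ---------------------------------------
    hed_cfg = config.get("hed", {})
    if "animal_bw" not in hed_cfg:
        raise PipelineError(
            "hed stage: animal body weight is a required input (no hidden default); "
            "set hed.animal_bw in the config"
        )
    animal_bw = float(hed_cfg["animal_bw"])
    human_bw = float(hed_cfg.get("human_bw", 70.0))
    pod = PointOfDeparture(
        value=selected.bmdl, basis="BMDL", bmr=bmr, endpoint=data.endpoint_name,
        species=hed_cfg.get("species", ""),
    )
    hed_value = hed(pod, animal_bw, human_bw)
    uf_cfg = config.get("uncertainty_factors", {})
    ufs = UncertaintyFactorSet(
        uf_a=int(uf_cfg.get("uf_a", 1)), uf_h=int(uf_cfg.get("uf_h", 1)),
        uf_s=int(uf_cfg.get("uf_s", 1)), uf_d=int(uf_cfg.get("uf_d", 1)),
    )
    det = derive_rfd(hed_value, ufs, pod=pod, animal_bw=animal_bw, human_bw=human_bw)
    manifest["stages"]["deterministic_rfd"] = {
        "pod": {"value": pod.value, "basis": pod.basis, "endpoint": pod.endpoint},
        "animal_bw_kg": animal_bw,
        "human_bw_kg": human_bw,
        "hed": hed_value,
        "uncertainty_factors": {
            "uf_a": ufs.uf_a, "uf_h": ufs.uf_h, "uf_s": ufs.uf_s, "uf_d": ufs.uf_d,
            "composite_half_log": ufs.composite,
        },
        "rfd_raw": det.rfd_raw,
        "rfd_reported_1sf": det.rfd_reported,
    }

    # --- stage: probabilistic RfD ---------------------------------------
    p_cfg = config.get("probabilistic", {})
    try:
        af_path = p_cfg.get("af_config")
        af_cfg = load_af_config(af_path) if af_path else default_af_config()
        chain = default_chain(
            bmd=ma.bmd_ma,
            bmdl=ma.bmdl_ma,
            animal_bw=animal_bw,
            human_bw=human_bw,
            target_incidence=float(p_cfg.get("target_incidence", 0.01)),
            uf_d=float(p_cfg.get("uf_d", 1.0)),
            config=af_cfg,
            n_samples=int(p_cfg.get("draws", 100_000)),
            seed=seed,
        )
        pres = propagate(chain)
    except Exception as exc:
        raise PipelineError(f"probabilistic stage failed: {exc}") from exc
    manifest["stages"]["probabilistic_rfd"] = {
        "af_config": af_path or "packaged aprob_defaults.yaml v1",
        "ad": {"p50": chain.ad.p50, "p95_over_p50": chain.ad.p95_over_p50},
        "af_bw": {"p50": chain.af_bw.p50, "p95_over_p50": chain.af_bw.p95_over_p50},
        "af_tktd": {"p50": chain.af_tktd.p50, "p95_over_p50": chain.af_tktd.p95_over_p50},
        "af_h": {"p50": chain.af_h.p50, "p95_over_p50": chain.af_h.p95_over_p50},
        "target_incidence": pres.target_incidence,
        "uf_d": pres.uf_d,
        "hd50_percentiles": pres.hd50_percentiles,
        "hd_i_percentiles": pres.hd_i_percentiles,
        "hd_i_p5_closed_form": pres.hd_i_p5_closed,
        "hd_i_p5_monte_carlo": pres.hd_i_p5_mc,
        "n_samples": pres.n_samples,
        "seed": pres.seed,
        "variance_budget": pres.variance_budget,
        "prfd_raw": pres.prfd_raw,
        "prfd_reported_1sf": pres.prfd_reported,
    }

    # --- stage: guideline (MCLG) ----------------------------------------
    g_cfg = config.get("guideline", {})
    gi = GuidelineInputs(
        body_weight=float(g_cfg.get("body_weight", 70.0)),
        drinking_water_intake=float(g_cfg.get("drinking_water_intake", 2.0)),
        rsc=float(g_cfg.get("rsc", 0.2)),
    )
    rfd_basis = g_cfg.get("rfd_basis", "probabilistic")
    rfd_for_mclg = pres.prfd_reported if rfd_basis == "probabilistic" else det.rfd_reported
    manifest["stages"]["guideline"] = {
        "rfd_basis": rfd_basis,
        "rfd_used": rfd_for_mclg,
        "body_weight_kg": gi.body_weight,
        "drinking_water_intake_l_per_day": gi.drinking_water_intake,
        "relative_source_contribution": gi.rsc,
        "mclg_ug_per_l": mclg(rfd_for_mclg, gi),
    }
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def manifest_to_json(manifest: dict) -> str:
    """Canonical (sorted, indented) JSON so identical runs are byte-identical."""
    return json.dumps(manifest, indent=2, sort_keys=True, allow_nan=True, default=_jsonable)
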