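"""End-to-end workflows: sensitivity simulation and synthetic GLM -> RSA.

Each workflow is driven by a single nested config (YAML/JSON-style dict)
with one namespace per stage and a single top-level seed; per-stage
substream seeds are derived deterministically from it, so changing one
stage's parameters never perturbs another stage's random draws. Every run
writes the fully resolved config beside its outputs, making output
directories self-describing.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .glm import RunGLM, censor_broken_fixation, flag_motion_outliers
from .irf import InvalidParameterError, gamma_hrf
from .rsa import PatternEstimates, average_rdms, split_half_rdm
from .sensitivity import compare_alternating_design
from .synth import NoiseSpec, PatternSpec, generate_session

log = logging.getLogger("mbsim")


class ConfigError(ValueError):
    """The pipeline config contains an unknown or invalid key."""


class EmptySessionError(RuntimeError):
    """Censoring removed every usable run."""


_DEFAULTS: dict[str, dict] = {
    "sensitivity": {
        "switch_every": 2.0,
        "total_duration": 480.0,
        "tr": 2.0,
        "peak_ratio": 1.8,
        "smooth_width": 1.0,
        "noise_sd": 1.0,
        "ratios": [round(float(r), 1) for r in np.arange(1.8, 0.95, -0.1)],
        "f_max": 0.25,
    },
    "irf": {
        "dt": 0.1,
        "duration": 60.0,
        "mion_mean_lag": 6.0,
        "mion_sd": 4.1,
    },
    "synth": {
        "n_runs": 10,
        "n_conditions": 48,
        "n_voxels": 60,
        "noise_sd": 1.0,
        "noise_corr_length": 2.0,
        "pattern_amplitude": 1.0,
        "within_category_corr": 0.3,
        "n_categories": 4,
        "censor_rate": 0.163,
        "motion_rate": 0.03,
        "drift_amplitude": 0.0,
        "motion_artifact": 0.0,
        "tr": 2.0,
    },
    "glm": {
        "hrf_mean_lag": 3.0,
        "hrf_sd": 1.5,
        "drift_order": 1,
    },
    "rsa": {
        "n_folds": 50,
        "shrinkage": 0.1,
        "noise_cov": "estimate",
    },
}
_TOP_KEYS = {"workflow", "seed", "out_dir"} | set(_DEFAULTS)


def resolve_config(config: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    resolved = {
        "workflow": config.get("workflow"),
        "seed": config.get("seed"),
        "out_dir": config.get("out_dir", "."),
    }
    for section, defaults in _DEFAULTS.items():
        user = config.get(section, {})
        bad = set(user) - set(defaults)
        if bad:
            raise ConfigError(f"unknown keys in '{section}': {sorted(bad)}")
        resolved[section] = {**defaults, **user}
    return resolved


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _substream_seeds(seed: int, n: int) -> list[int]:
    """Derive n per-stage seeds (< 2**31) from the top-level seed."""
    return [int(s >> 1) for s in np.random.SeedSequence(seed).generate_state(n)]


def _write_resolved(resolved: dict, out_dir: Path) -> None:
    with open(out_dir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump({**resolved, "package_version": __version__}, fh, sort_keys=True)


def run_sensitivity(config: dict, out_dir=None) -> dict:
    """BOLD vs MION sensitivity workflow: IRFs, design, SEs, ratio sweep.

    Writes ``sensitivity_report.json`` (and the resolved config) to
    ``out_dir`` when given; returns the report dict either way.
    """
    resolved = resolve_config(config)
    if resolved["workflow"] not in (None, "sensitivity"):
        raise ConfigError(f"workflow is {resolved['workflow']!r}, not 'sensitivity'")
    sens = resolved["sensitivity"]
    irf_cfg = resolved["irf"]
    log.info("sensitivity: design switch=%ss, ratios %s", sens["switch_every"],
             sens["ratios"])
    report = compare_alternating_design(
        switch_every=sens["switch_every"],
        total_duration=sens["total_duration"],
        tr=sens["tr"],
        peak_ratio=sens["peak_ratio"],
        smooth_width=sens["smooth_width"],
        noise_sd=sens["noise_sd"],
        ratios=sens["ratios"],
        f_max=sens["f_max"],
        dt=irf_cfg["dt"],
        duration=irf_cfg["duration"],
        mion_mean_lag=irf_cfg["mion_mean_lag"],
        mion_sd=irf_cfg["mion_sd"],
    ).to_dict()
    report["ratios_swept"] = list(sens["ratios"])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "sensitivity_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        _write_resolved(resolved, out_dir)
    return report


def run_glm_rsa(config: dict, out_dir=None):
    """Synthetic session -> censoring -> per-run GLMs -> split-half RDM.

    Returns ``(rdm, qc)``; when ``out_dir`` is given also writes
    ``rdm.csv``, a JSON sidecar, ``qc.json`` and the resolved config.
    """
    resolved = resolve_config(config)
    if resolved["workflow"] not in (None, "glm_rsa"):
        raise ConfigError(f"workflow is {resolved['workflow']!r}, not 'glm_rsa'")
    if resolved["seed"] is None:
        raise ConfigError("glm_rsa workflow requires a top-level seed")
    synth_seed, rsa_seed = _substream_seeds(resolved["seed"], 2)
    s = resolved["synth"]
    g = resolved["glm"]
    r = resolved["rsa"]
    hrf = gamma_hrf(mean_lag=g["hrf_mean_lag"], sd=g["hrf_sd"], dt=0.1)
    dataset = generate_session(
        n_runs=s["n_runs"],
        n_conditions=s["n_conditions"],
        n_voxels=s["n_voxels"],
        pattern_spec=PatternSpec(
            n_categories=s["n_categories"],
            amplitude=s["pattern_amplitude"],
            within_category_corr=s["within_category_corr"],
        ),
        noise_spec=NoiseSpec(sd=s["noise_sd"], corr_length=s["noise_corr_length"]),
        censor_rate=s["censor_rate"],
        motion_rate=s["motion_rate"],
        drift_amplitude=s["drift_amplitude"],
        motion_artifact=s["motion_artifact"],
        hrf=hrf,
        tr=s["tr"],
        seed=synth_seed,
    )
    log.info("glm_rsa: generated %d runs, %d conditions, %d voxels",
             s["n_runs"], s["n_conditions"], s["n_voxels"])
    results = []
    qc_runs = []
    for i, run in enumerate(dataset.runs):
        censor = censor_broken_fixation(run.eye_trace, run.schedule.tr)
        motion = flag_motion_outliers(run.motion_series)
        if not censor.keep.any():
            continue
        model = RunGLM.from_schedule(
            run.data,
            run.schedule,
            hrf=hrf,
            eye_trace=run.eye_trace,
            motion_variance=run.motion_series,
            drift_order=g["drift_order"],
        )
        res = model.fit()
        results.append(res)
        n_vol = run.schedule.n_volumes
        qc_runs.append(
            {
                "run": i,
                "n_volumes": n_vol,
                "censored_fraction": len(censor.excluded("fixation")) / n_vol,
                "motion_outlier_fraction": len(motion.excluded("motion")) / n_vol,
                "dof": res.df_resid,
                "dropped_conditions": len(res.model.design.all_zero),
            }
        )
        log.info("run %d: dof=%d censored=%.1f%%", i, res.df_resid,
                 100 * qc_runs[-1]["censored_fraction"])
    if len(results) < 2:
        raise EmptySessionError("fewer than 2 usable runs after censoring")
    patterns = PatternEstimates.from_glm_results(results)
    residuals = [res.resid.to_numpy() for res in results]
    rdm = split_half_rdm(
        patterns,
        residuals,
        n_folds=r["n_folds"],
        seed=rsa_seed,
        shrinkage=r["shrinkage"],
        noise_cov=r["noise_cov"],
    )
    rdm = average_rdms([rdm], grouping="session")
    qc = {
        "runs": qc_runs,
        "n_usable_runs": len(results),
        "mean_censored_fraction": float(
            np.mean([q["censored_fraction"] for q in qc_runs])
        ),
        "mean_motion_outlier_fraction": float(
            np.mean([q["motion_outlier_fraction"] for q in qc_runs])
        ),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rdm.to_csv(out_dir / "rdm.csv")
        with open(out_dir / "rdm.json", "w") as fh:
            json.dump(
                {"n_folds": rdm.n_folds, "provenance": rdm.provenance},
                fh, indent=2, sort_keys=True, default=str,
            )
            fh.write("\n")
        with open(out_dir / "qc.json", "w") as fh:
            json.dump(qc, fh, indent=2, sort_keys=True)
            fh.write("\n")
        _write_resolved(resolved, out_dir)
    return rdm, qc
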