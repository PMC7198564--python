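"""Synthetic ROI sessions with planted ground truth.

Generates every input the GLM/RSA pipeline consumes — multi-run voxel time
series with planted condition patterns, 20 Hz eye-position traces, and
per-volume head-motion variance series — with the statistical structure the
analysis assumes (linear HRF convolution, additive spatially correlated
Gaussian noise, optional polynomial drift). The planted truth (patterns,
their squared-Euclidean RDM, censor and motion flags, the noise covariance)
is returned alongside the data so every analysis stage can be tested for
exact or statistical recovery without any real recordings.

The generator and the censoring rules are mutually consistent by
construction: broken-fixation volumes get strictly more than half their
gaze samples outside the fixation window, motion-spike volumes exceed the
mean + 2 SD variance threshold, and both contracts are validated post hoc.

Defaults mirror the emulated study's conditions: 48 stimulus conditions
(4 categories x 12 exemplars) of 0.5 s + 2.5 s ISI with 30 null trials per
117-volume run at TR 2 s, 10 runs per session, ~16% broken-fixation volumes
and ~3% motion outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import EventSchedule, convolve_schedule, rapid_er_schedule
from .glm import EyeTrace, censor_broken_fixation, flag_motion_outliers
from .irf import ImpulseResponse, InvalidParameterError, gamma_hrf


@dataclass(frozen=True)
class PatternSpec:
    """Planted condition-pattern structure: categories sharing a component.

    Each condition pattern is amplitude * (sqrt(rho) * category_component +
    sqrt(1-rho) * exemplar_component) with standard-normal components, so
    ``within_category_corr`` (rho) is the expected correlation between
    patterns of the same category.
    """

    n_categories: int = 4
    amplitude: float = 1.0
    within_category_corr: float = 0.3


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise: N(0, sd^2 * C), C_ij = exp(-|i-j|/corr_length).

    ``corr_length`` is in voxel-index units (0 = white across voxels);
    temporal structure is white, matching the GLM's i.i.d. noise assumption.
    """

    sd: float = 1.0
    corr_length: float = 2.0


@dataclass(frozen=True)
class SyntheticRun:
    data: np.ndarray = field(repr=False)          # volumes x voxels
    schedule: EventSchedule = field(repr=False)
    eye_trace: EyeTrace = field(repr=False)
    motion_series: np.ndarray = field(repr=False)  # per-volume variance
    broken_volumes: frozenset = frozenset()
    motion_volumes: frozenset = frozenset()


@dataclass(frozen=True)
class SyntheticROIDataset:
    """Multi-run session plus the planted truth for recovery testing."""

    runs: tuple[SyntheticRun, ...]
    patterns: np.ndarray = field(repr=False)      # conditions x voxels
    planted_rdm: np.ndarray = field(repr=False)   # squared Euclidean distances
    noise_cov: np.ndarray = field(repr=False)
    seed: int = 0

    @property
    def n_conditions(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]


def _spatial_cov(n_voxels: int, spec: NoiseSpec) -> np.ndarray:
    idx = np.arange(n_voxels)
    if spec.corr_length <= 0:
        corr = np.eye(n_voxels)
    else:
        corr = np.exp(-np.abs(idx[:, None] - idx[None, :]) / spec.corr_length)
    return spec.sd**2 * corr


def _draw_patterns(
    n_conditions: int, n_voxels: int, spec: PatternSpec, rng: np.random.Generator
) -> np.ndarray:
    if n_conditions % spec.n_categories != 0:
        raise InvalidParameterError(
            f"{n_conditions} conditions do not split into {spec.n_categories} categories"
        )
    rho = spec.within_category_corr
    if not 0.0 <= rho < 1.0:
        raise InvalidParameterError("within_category_corr must be in [0, 1)")
    per_cat = n_conditions // spec.n_categories
    cat = rng.standard_normal((spec.n_categories, n_voxels))
    exemplar = rng.standard_normal((n_conditions, n_voxels))
    patterns = spec.amplitude * (
        np.sqrt(rho) * np.repeat(cat, per_cat, axis=0)
        + np.sqrt(1.0 - rho) * exemplar
    )
    return patterns


def generate_eye_trace(
    schedule: EventSchedule,
    broken_volumes,
    sample_rate: float = 20.0,
    window_half_width: float = 5.0,
    seed: int | None = None,
) -> EyeTrace:
    """Gaze trace whose censoring reproduces the planted broken volumes exactly.

    Kept volumes receive all samples inside the fixation box (fixational
    scatter, SD 1.5 deg, clipped); each broken volume receives a random
    number (strictly more than half) of samples displaced outside the box.
    """
    if seed is None:
        raise InvalidParameterError("a seed is required")
    broken = set(int(v) for v in broken_volumes)
    n_vol = schedule.n_volumes
    if broken - set(range(n_vol)):
        raise InvalidParameterError("broken_volumes outside the run")
    spv = sample_rate * schedule.tr
    if abs(spv - round(spv)) > 1e-9:
        raise InvalidParameterError("sample_rate * tr must be an integer")
    spv = int(round(spv))
    rng = np.random.default_rng(seed)
    w = window_half_width
    inside_sd = min(1.5, w / 3.0)
    x = np.clip(rng.normal(0.0, inside_sd, n_vol * spv), -0.9 * w, 0.9 * w)
    y = np.clip(rng.normal(0.0, inside_sd, n_vol * spv), -0.9 * w, 0.9 * w)
    for v in broken:
        n_out = int(rng.integers(spv // 2 + 1, spv + 1))
        out_idx = v * spv + rng.choice(spv, size=n_out, replace=False)
        sign = rng.choice([-1.0, 1.0], size=n_out)
        x[out_idx] = sign * rng.uniform(1.1 * w, 2.0 * w, n_out)
    trace = EyeTrace(sample_rate, x, y, w)
    planted = np.ones(n_vol, dtype=bool)
    planted[sorted(broken)] = False
    if not np.array_equal(censor_broken_fixation(trace, schedule.tr).keep, planted):
        raise AssertionError("generator/censor contract violated")  # pragma: no cover
    return trace


def generate_motion_series(
    n_volumes: int,
    outlier_volumes,
    base_level: float = 1.0,
    spike_scale: float = 8.0,
    seed: int | None = None,
) -> np.ndarray:
    """Per-volume motion variance whose outlier rule recovers the planted spikes.

    Baseline volumes fluctuate mildly around ``base_level``; planted
    outliers sit at ``spike_scale`` times the base. The mean + 2 SD rule is
    validated post hoc and a too-small ``spike_scale`` raises instead of
    silently mislabelling volumes.
    """
    if seed is None:
        raise InvalidParameterError("a seed is required")
    if base_level <= 0 or spike_scale <= 1:
        raise InvalidParameterError("base_level must be > 0 and spike_scale > 1")
    outliers = sorted(int(v) for v in outlier_volumes)
    if outliers and (outliers[0] < 0 or outliers[-1] >= n_volumes):
        raise InvalidParameterError("outlier_volumes outside the run")
    rng = np.random.default_rng(seed)
    if outliers:
        series = np.abs(rng.normal(base_level, 0.05 * base_level, n_volumes))
        series[outliers] = base_level * spike_scale * rng.uniform(
            0.95, 1.05, len(outliers)
        )
    else:
        # without spikes the 2-SD rule would flag the baseline's own jitter
        series = np.full(n_volumes, base_level)
    planted = np.ones(n_volumes, dtype=bool)
    planted[outliers] = False
    if not np.array_equal(flag_motion_outliers(series).keep, planted):
        raise InvalidParameterError(
            "planted spikes do not exceed the mean + 2 SD threshold; "
            "increase spike_scale or lower the outlier rate"
        )
    return series


def generate_session(
    n_runs: int = 10,
    n_conditions: int = 48,
    n_voxels: int = 60,
    pattern_spec: PatternSpec | None = None,
    noise_spec: NoiseSpec | None = None,
    censor_rate: float = 0.163,
    motion_rate: float = 0.03,
    hrf: ImpulseResponse | None = None,
    drift_amplitude: float = 0.0,
    motion_artifact: float = 0.0,
    seed: int | None = None,
    stim_duration: float = 0.5,
    isi: float = 2.5,
    n_null: int = 30,
    tr: float = 2.0,
) -> SyntheticROIDataset:
    """Generate a full multi-run session with planted truth.

    Per run: a fresh seeded rapid event-related schedule; signal = sum over
    conditions of (HRF-convolved single-presentation regressor x planted
    pattern); plus spatially correlated Gaussian noise, optional linear
    drift of peak-to-peak ``drift_amplitude``, and an additive offset of
    ``motion_artifact`` at motion-spike volumes. Broken-fixation volumes are
    drawn Bernoulli(``censor_rate``) per volume, motion spikes
    Bernoulli(``motion_rate``); matching eye traces and motion series are
    generated so the censoring operations recover the flags exactly.
    """
    if seed is None:
        raise InvalidParameterError("a seed is required")
    if not (0.0 <= censor_rate < 1.0 and 0.0 <= motion_rate < 1.0):
        raise InvalidParameterError("rates must be in [0, 1)")
    if n_voxels < 2:
        raise InvalidParameterError("need at least 2 voxels for covariance specs")
    pattern_spec = pattern_spec or PatternSpec()
    noise_spec = noise_spec or NoiseSpec()
    hrf = hrf if hrf is not None else gamma_hrf(dt=0.1)

    root = np.random.SeedSequence(seed)
    pattern_ss, *run_ss = root.spawn(1 + n_runs)
    rng = np.random.default_rng(pattern_ss)
    patterns = _draw_patterns(n_conditions, n_voxels, pattern_spec, rng)
    diffs = patterns[:, None, :] - patterns[None, :, :]
    planted_rdm = np.sum(diffs**2, axis=2)
    cov = _spatial_cov(n_voxels, noise_spec)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n_voxels))

    runs = []
    for r, ss in enumerate(run_ss):
        child = np.random.default_rng(ss)
        sched_seed, eye_seed, motion_seed = ss.generate_state(3) >> 1  # < 2**31
        schedule = rapid_er_schedule(
            n_stimuli=n_conditions,
            stim_duration=stim_duration,
            isi=isi,
            n_null=n_null,
            tr=tr,
            seed=int(sched_seed),
        )
        n_vol = schedule.n_volumes
        X = np.column_stack(
            [convolve_schedule(schedule, hrf, condition=c).values
             for c in range(n_conditions)]
        )
        signal = X @ patterns
        if noise_spec.sd > 0:
            noise = child.standard_normal((n_vol, n_voxels)) @ chol.T
        else:
            noise = 0.0
        drift = 0.0
        if drift_amplitude:
            drift = drift_amplitude * np.linspace(-0.5, 0.5, n_vol)[:, None]
        broken = frozenset(np.flatnonzero(child.random(n_vol) < censor_rate).tolist())
        spikes = frozenset(np.flatnonzero(child.random(n_vol) < motion_rate).tolist())
        data = signal + noise + drift
        if motion_artifact and spikes:
            data[sorted(spikes)] += motion_artifact
        eye = generate_eye_trace(schedule, broken, seed=int(eye_seed))
        motion = generate_motion_series(n_vol, spikes, seed=int(motion_seed))
        runs.append(
            SyntheticRun(
                data=data,
                schedule=schedule,
                eye_trace=eye,
                motion_series=motion,
                broken_volumes=broken,
                motion_volumes=spikes,
            )
        )
    return SyntheticROIDataset(
        runs=tuple(runs),
        patterns=patterns,
        planted_rdm=planted_rdm,
        noise_cov=cov,
        seed=seed,
    )
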