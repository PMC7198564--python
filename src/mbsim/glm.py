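"""Per-run GLM estimation with trial censoring, in a Model/Results shape.

The workflow mirrors a standard event-related fMRI first-level analysis for
a single ROI: volumes are censored when gaze left the +/-5 deg fixation
window for more than half the volume, head-motion outlier volumes get
one-hot nuisance regressors, every stimulus condition gets an HRF-convolved
regressor, and ordinary least squares per voxel yields parameter estimates,
standard errors, t and z statistics. ``RunGLM`` is the model object;
``RunGLM.fit()`` returns a ``GLMResults`` carrying estimates, residuals and
degrees of freedom, plus a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .design import NULL, EventSchedule, convolve_schedule
from .irf import ImpulseResponse, InvalidParameterError, gamma_hrf
from .sensitivity import SingularDesignError

REASON_FIXATION = "fixation"
REASON_MOTION = "motion"


# ---------------------------------------------------------------------------
# censoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EyeTrace:
    """Gaze position samples in degrees of visual angle, fixation at (0, 0)."""

    sample_rate: float
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    window_half_width: float = 5.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or self.window_half_width <= 0:
            raise InvalidParameterError(
                "sample_rate and window_half_width must be positive"
            )
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise InvalidParameterError("x and y must be equal-length 1-D arrays")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def outside_window(self) -> np.ndarray:
        """Boolean per sample: gaze strictly outside the fixation box."""
        w = self.window_half_width
        return (np.abs(self.x) > w) | (np.abs(self.y) > w)


@dataclass(frozen=True)
class CensorMask:
    """Per-volume keep/exclude flags with an exclusion reason."""

    keep: np.ndarray = field(repr=False)
    reason: tuple[str, ...] = field(repr=False)

    def __post_init__(self) -> None:
        keep = np.asarray(self.keep, dtype=bool)
        if len(self.reason) != keep.size:
            raise InvalidParameterError("reason length must match keep length")
        allowed = {"", REASON_FIXATION, REASON_MOTION,
                   f"{REASON_FIXATION}+{REASON_MOTION}"}
        if not set(self.reason) <= allowed:
            raise InvalidParameterError(f"unknown reasons: {set(self.reason) - allowed}")
        object.__setattr__(self, "keep", keep)

    @property
    def n_volumes(self) -> int:
        return self.keep.size

    def excluded(self, reason: str | None = None) -> np.ndarray:
        """Indices of excluded volumes, optionally only for one reason."""
        if reason is None:
            return np.flatnonzero(~self.keep)
        return np.flatnonzero([reason in r for r in self.reason])

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.reason:
            if r:
                for part in r.split("+"):
                    out[part] = out.get(part, 0) + 1
        return out

    def combine(self, other: "CensorMask") -> "CensorMask":
        """Union of exclusions; commutative (reasons stored in fixed order)."""
        if other.n_volumes != self.n_volumes:
            raise InvalidParameterError("masks cover different volume counts")
        keep = self.keep & other.keep
        reasons = []
        for a, b in zip(self.reason, other.reason):
            parts = set(a.split("+")) | set(b.split("+"))
            parts.discard("")
            reasons.append(
                "+".join(p for p in (REASON_FIXATION, REASON_MOTION) if p in parts)
            )
        return CensorMask(keep, tuple(reasons))

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("volume,keep,reason\n")
            for i, (k, r) in enumerate(zip(self.keep, self.reason)):
                fh.write(f"{i},{int(k)},{r}\n")


def censor_broken_fixation(trace: EyeTrace, tr: float) -> CensorMask:
    """Exclude volumes where gaze was outside the window more than half the time.

    At 20 Hz and TR 2 s each volume has 40 samples; a volume is excluded iff
    STRICTLY more than half of them (>20, i.e. >1 s) fall outside the
    +/-window_half_width box. Exactly half keeps the volume.
    """
    spv = trace.sample_rate * tr
    if abs(spv - round(spv)) > 1e-9:
        raise InvalidParameterError("sample_rate * tr must be an integer")
    spv = int(round(spv))
    if trace.x.size < spv:
        raise InvalidParameterError("trace shorter than one volume")
    if trace.x.size % spv != 0:
        raise InvalidParameterError(
            f"trace length {trace.x.size} is not a whole number of volumes"
        )
    out = trace.outside_window().reshape(-1, spv).sum(axis=1)
    keep = ~(out > spv // 2) if spv % 2 == 0 else ~(out > spv / 2)
    reason = tuple("" if k else REASON_FIXATION for k in keep)
    return CensorMask(keep, reason)


def flag_motion_outliers(motion_variance) -> CensorMask:
    """Flag volumes with motion variance > mean + 2*SD of the series.

    Moments are computed over the full series (sample SD); the threshold is
    strict, so a constant series (SD = 0) flags nothing and a value exactly
    at the threshold is kept.
    """
    v = np.asarray(motion_variance, dtype=float)
    if v.size < 3:
        raise InvalidParameterError("need at least 3 volumes")
    if not np.all(np.isfinite(v)):
        raise InvalidParameterError("motion variance must be finite")
    threshold = v.mean() + 2.0 * v.std(ddof=1)
    keep = ~(v > threshold)
    reason = tuple("" if k else REASON_MOTION for k in keep)
    return CensorMask(keep, reason)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignMatrix:
    """Labelled design matrix with interest/nuisance bookkeeping."""

    frame: pd.DataFrame
    interest: tuple[str, ...]
    nuisance: tuple[str, ...]
    all_zero: tuple[str, ...]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="volume")


def _event_volumes(onset: float, duration: float, tr: float) -> range:
    first = int(np.floor(onset / tr + 1e-9))
    last = int(np.ceil((onset + duration) / tr - 1e-9)) - 1
    return range(first, max(last, first) + 1)


def build_design_matrix(
    schedule: EventSchedule,
    hrf: ImpulseResponse | None = None,
    censor: CensorMask | None = None,
    motion: CensorMask | None = None,
    drift_order: int = 1,
) -> DesignMatrix:
    """One HRF-convolved column per condition, plus nuisance columns.

    Stimulus events any of whose volumes are fixation-censored are removed
    from their condition's boxcar before convolution ("not modelled"); a
    condition losing all its events yields an all-zero column, flagged and
    excluded from invertibility requirements. Each motion-flagged volume
    gets a one-hot nuisance column; polynomial drift terms (constant through
    order ``drift_order``) are always appended.
    """
    hrf = hrf if hrf is not None else gamma_hrf(dt=0.1)
    n_vol = schedule.n_volumes
    censored_vols: set[int] = set()
    if censor is not None:
        if censor.n_volumes != n_vol:
            raise InvalidParameterError("censor mask does not match volume count")
        censored_vols = set(censor.excluded(REASON_FIXATION).tolist())

    cols: dict[str, np.ndarray] = {}
    interest, all_zero = [], []
    for cond in schedule.conditions:
        kept_events = [
            ev
            for ev in schedule.events_for(cond)
            if not any(v in censored_vols for v in _event_volumes(ev.onset, ev.duration, schedule.tr))
        ]
        label = f"cond_{cond}"
        if kept_events:
            sub = EventSchedule(tuple(kept_events), schedule.tr, schedule.total_duration)
            cols[label] = convolve_schedule(sub, hrf, condition=cond).values
        else:
            cols[label] = np.zeros(n_vol)
            all_zero.append(label)
        interest.append(label)

    nuisance = []
    if motion is not None:
        if motion.n_volumes != n_vol:
            raise InvalidParameterError("motion mask does not match volume count")
        for v in motion.excluded(REASON_MOTION):
            label = f"motion_{v}"
            col = np.zeros(n_vol)
            col[v] = 1.0
            cols[label] = col
            nuisance.append(label)
    if drift_order >= 0:
        # Legendre polynomials over [-1, 1]: orthogonal-ish drift basis
        u = np.linspace(-1.0, 1.0, n_vol)
        for d in range(drift_order + 1):
            label = f"drift_{d}"
            cols[label] = np.polynomial.legendre.Legendre.basis(d)(u)
            nuisance.append(label)

    frame = pd.DataFrame(cols, index=pd.RangeIndex(n_vol, name="volume"))
    return DesignMatrix(frame, tuple(interest), tuple(nuisance), tuple(all_zero))


# ---------------------------------------------------------------------------
# statistics helpers
# ---------------------------------------------------------------------------

def t_to_z(t, dof):
    """Convert t statistics to tail-matched standard-normal deviates.

    Two-sided, sign-preserving: the returned z has the same upper-tail
    probability under N(0, 1) as |t| has under the t distribution with
    ``dof`` degrees of freedom. Computed in log-tail space so |t| up to ~40
    maps to finite z instead of overflowing to infinity.
    """
    t = np.asarray(t, dtype=float)
    dof = np.asarray(dof)
    if np.any(dof < 1):
        raise InvalidParameterError("dof must be >= 1")
    log_tail = stats.t.logsf(np.abs(t), dof)
    z = -special.ndtri_exp(log_tail)
    result = np.sign(t) * z
    return float(result) if result.ndim == 0 else result


def percent_signal_change(
    beta: float, regressor_height: float, baseline_mean: float
) -> float:
    """Convert a beta to percent signal change (Featquery-style scaling).

    ``regressor_height`` is the peak of an isolated single-event regressor
    (see :func:`isolated_event_height`); ``baseline_mean`` is the mean
    baseline signal the percentage is taken against.
    """
    if baseline_mean <= 0:
        raise InvalidParameterError("baseline_mean must be positive")
    return 100.0 * beta * regressor_height / baseline_mean


def isolated_event_height(
    hrf: ImpulseResponse, stim_duration: float = 0.5
) -> float:
    """Peak of the regressor evoked by one isolated event of given duration."""
    n_stim = max(int(round(stim_duration / hrf.dt)), 1)
    box = np.zeros(n_stim + hrf.samples.size)
    box[:n_stim] = 1.0
    return float(np.convolve(box, hrf.samples).max())


def spherical_roi_mask(
    center: tuple[int, int, int], radius: float, voxel_size: float
) -> set[tuple[int, int, int]]:
    """Voxel indices whose centres lie within ``radius`` mm (inclusive) of center.

    A 2 mm radius on a 1.5 mm grid gives the centre plus its 6 face
    neighbours (diagonals at 1.5*sqrt(2) ~ 2.12 mm are excluded).
    """
    if radius < 0:
        raise InvalidParameterError("radius must be >= 0")
    if voxel_size <= 0:
        raise InvalidParameterError("voxel_size must be positive")
    r_idx = int(np.floor(radius / voxel_size + 1e-9))
    cx, cy, cz = center
    out = set()
    for i in range(-r_idx, r_idx + 1):
        for j in range(-r_idx, r_idx + 1):
            for k in range(-r_idx, r_idx + 1):
                if (i * i + j * j + k * k) * voxel_size**2 <= radius**2 + 1e-9:
                    out.add((cx + i, cy + j, cz + k))
    return out


# ---------------------------------------------------------------------------
# the model / results pair
# ---------------------------------------------------------------------------

class RunGLM:
    """Ordinary-least-squares GLM for one run's ROI data.

    Parameters
    ----------
    data : DataFrame or ndarray, volumes x voxels
        The ROI time series.
    design : DesignMatrix or DataFrame
        The labelled design matrix (see :func:`build_design_matrix`).
    """

    def __init__(self, data, design: DesignMatrix | pd.DataFrame):
        if isinstance(design, pd.DataFrame):
            design = DesignMatrix(design, tuple(design.columns), (), ())
        self.design = design
        data = pd.DataFrame(data)
        if not np.all(np.isfinite(data.to_numpy())):
            raise InvalidParameterError("data must be finite")
        if data.shape[0] != design.frame.shape[0]:
            raise InvalidParameterError(
                f"data has {data.shape[0]} volumes, design {design.frame.shape[0]}"
            )
        self.data = data

    @classmethod
    def from_schedule(
        cls,
        data,
        schedule: EventSchedule,
        hrf: ImpulseResponse | None = None,
        eye_trace: EyeTrace | None = None,
        motion_variance=None,
        drift_order: int = 1,
    ) -> "RunGLM":
        """Build censoring masks and the design matrix, then the model."""
        censor = (
            censor_broken_fixation(eye_trace, schedule.tr)
            if eye_trace is not None
            else None
        )
        motion = (
            flag_motion_outliers(motion_variance)
            if motion_variance is not None
            else None
        )
        design = build_design_matrix(schedule, hrf, censor, motion, drift_order)
        model = cls(data, design)
        model.censor = censor
        model.motion = motion
        return model

    def fit(self) -> "GLMResults":
        frame = self.design.frame.drop(columns=list(self.design.all_zero))
        X = frame.to_numpy()
        Y = self.data.to_numpy()
        T, p = X.shape
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            raise SingularDesignError(
                f"design matrix rank {rank} < {p} after dropping all-zero columns"
            )
        if T <= p:
            raise InvalidParameterError(
                f"need more volumes ({T}) than regressors ({p})"
            )
        beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        dof = T - rank
        sigma2 = (resid**2).sum(axis=0) / dof
        xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))
        se = np.sqrt(np.outer(xtx_inv_diag, sigma2))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / se, 0.0)
        zvals = t_to_z(tvals, dof)
        cols = self.data.columns
        return GLMResults(
            model=self,
            params=pd.DataFrame(beta, index=frame.columns, columns=cols),
            bse=pd.DataFrame(se, index=frame.columns, columns=cols),
            tvalues=pd.DataFrame(tvals, index=frame.columns, columns=cols),
            zvalues=pd.DataFrame(zvals, index=frame.columns, columns=cols),
            resid=pd.DataFrame(resid, index=self.data.index, columns=cols),
            df_resid=int(dof),
            n_volumes=int(T),
        )


@dataclass(frozen=True)
class GLMResults:
    """Estimates, uncertainties and diagnostics from one run's regression."""

    model: RunGLM
    params: pd.DataFrame      # regressors x voxels
    bse: pd.DataFrame
    tvalues: pd.DataFrame
    zvalues: pd.DataFrame
    resid: pd.DataFrame       # volumes x voxels
    df_resid: int
    n_volumes: int

    @property
    def interest_params(self) -> pd.DataFrame:
        """Betas for the condition regressors only (nuisance dropped)."""
        rows = [c for c in self.model.design.interest if c in self.params.index]
        return self.params.loc[rows]

    def condition_availability(self) -> dict[str, bool]:
        """Condition label -> was its regressor estimable (not all-zero)."""
        return {
            c: c not in self.model.design.all_zero
            for c in self.model.design.interest
        }

    def percent_signal_change(
        self, hrf: ImpulseResponse, stim_duration: float = 0.5
    ) -> pd.DataFrame:
        """Interest betas converted to % signal change per voxel.

        Baseline is each voxel's fitted constant-drift level (``drift_0``
        column); requires the design to contain a constant term.
        """
        if "drift_0" not in self.params.index:
            raise InvalidParameterError("design has no constant (drift_0) term")
        height = isolated_event_height(hrf, stim_duration)
        baseline = self.params.loc["drift_0"]
        if (baseline <= 0).any():
            raise InvalidParameterError("non-positive baseline signal")
        return 100.0 * self.interest_params * height / baseline

    def summary(self) -> str:
        design = self.model.design
        lines = [
            "Run GLM (ordinary least squares)",
            "=" * 40,
            f"volumes:            {self.n_volumes}",
            f"voxels:             {self.params.shape[1]}",
            f"regressors:         {self.params.shape[0]}"
            f" ({len(design.interest)} interest, {len(design.nuisance)} nuisance)",
            f"dropped (all-zero): {len(design.all_zero)}",
            f"residual dof:       {self.df_resid}",
            "",
            "mean |t| per condition regressor (across voxels):",
        ]
        for label in design.interest:
            if label in self.tvalues.index:
                lines.append(
                    f"  {label:<10s} {np.abs(self.tvalues.loc[label]).mean():8.3f}"
                )
        return "\n".join(lines)
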