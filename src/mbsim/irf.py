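"""Hemodynamic impulse-response function (IRF) models.

Builds the linear-system kernels used throughout the package: the Boynton
gamma model for BOLD, a gamma-density model for the MION (iron-oxide
contrast agent) response, the spliced smooth-onset MION variant, optional
extra onset smoothing, and the fast macaque HRF (gamma with 3 s mean lag,
1.5 s SD) used by the GLM.

Sign convention: magnitudes only. The physical MION signal change is
negative (blood-volume weighting); it is represented here as a positive
response so that amplitude and spectral comparisons read directly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class InvalidParameterError(ValueError):
    """A constructor parameter is outside its allowed range."""


class TruncationError(ValueError):
    """The requested duration is too short to contain the response."""


class GridMismatchError(ValueError):
    """Two IRFs or signals do not share the same sampling grid."""


@dataclass(frozen=True)
class ImpulseResponse:
    """A sampled impulse-response function on a regular time grid.

    Parameters
    ----------
    name : str
        Human-readable label (e.g. ``"bold"``, ``"mion(1.8)"``).
    dt : float
        Grid spacing in seconds. Samples start at t = 0.
    samples : ndarray
        Amplitudes, one per grid point (arbitrary units).
    """

    name: str
    dt: float
    samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidParameterError(f"dt must be positive, got {self.dt}")
        samples = np.array(self.samples, dtype=float)  # defensive copy
        if samples.ndim != 1 or samples.size < 2:
            raise InvalidParameterError("need at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise InvalidParameterError("samples must be finite")
        samples.flags.writeable = False
        object.__setattr__(self, "samples", samples)

    # -- derived metadata -------------------------------------------------
    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) * self.dt

    @property
    def peak_index(self) -> int:
        # ties broken by earliest index (np.argmax convention)
        return int(np.argmax(self.samples))

    @property
    def peak_amplitude(self) -> float:
        return float(self.samples[self.peak_index])

    @property
    def peak_time(self) -> float:
        return self.peak_index * self.dt

    def fwhm(self) -> float:
        """Full width at half maximum, in seconds (grid resolution)."""
        half = self.peak_amplitude / 2.0
        above = np.flatnonzero(self.samples >= half)
        return float((above[-1] - above[0]) * self.dt)

    def scaled(self, factor: float, name: str | None = None) -> "ImpulseResponse":
        return ImpulseResponse(name or self.name, self.dt, self.samples * factor)

    # -- serialization -----------------------------------------------------
    def to_csv(self, path) -> None:
        """Write as two-column CSV (time_s, amplitude) with a comment header."""
        with open(path, "w") as fh:
            fh.write(f"# name={self.name}, dt={self.dt!r}\n")
            fh.write("time_s,amplitude\n")
            for t, a in zip(self.times, self.samples):
                fh.write(f"{float(t)!r},{float(a)!r}\n")

    @classmethod
    def from_csv(cls, path) -> "ImpulseResponse":
        with open(path) as fh:
            header = fh.readline().strip()
            body = fh.read()
        meta = {}
        for part in header.lstrip("# ").split(", "):
            key, _, value = part.partition("=")
            meta[key] = value
        arr = np.loadtxt(io.StringIO(body), delimiter=",", skiprows=1)
        return cls(meta.get("name", "irf"), float(meta["dt"]), arr[:, 1])


def bold_boynton(
    dt: float = 0.1,
    duration: float = 60.0,
    n: int = 3,
    tau: float = 1.2,
    delay: float = 0.0,
) -> ImpulseResponse:
    """Boynton gamma model of the BOLD impulse response, peak-normalized to 1.

    h(t) = ((t - delay)/tau)**(n-1) * exp(-(t - delay)/tau) for t >= delay,
    zero before; the analytic mode is at delay + (n-1)*tau (2.4 s at the
    defaults n=3, tau=1.2 s).
    """
    if dt <= 0 or tau <= 0:
        raise InvalidParameterError("dt and tau must be positive")
    if n < 1:
        raise InvalidParameterError("shape n must be >= 1")
    if delay < 0:
        raise InvalidParameterError("delay must be >= 0")
    peak_t = delay + (n - 1) * tau
    if duration < peak_t:
        raise TruncationError(
            f"duration {duration} s shorter than the peak time {peak_t} s"
        )
    t = np.arange(0.0, duration + dt / 2, dt)
    ts = np.maximum(t - delay, 0.0)
    with np.errstate(invalid="ignore"):
        h = (ts / tau) ** (n - 1) * np.exp(-ts / tau)
    h[t < delay] = 0.0
    return ImpulseResponse("bold", dt, h / h.max())


def mion_model(
    dt: float = 0.1,
    duration: float = 60.0,
    peak_ratio: float = 1.8,
    mean_lag: float = 6.0,
    sd: float = 4.1,
) -> ImpulseResponse:
    """Gamma-density MION impulse response, peak-normalized to ``peak_ratio``.

    The MION (blood-volume) response is larger and temporally wider than
    BOLD; the default mean lag 6.0 s / SD 4.1 s puts its peak later than the
    Boynton BOLD default and makes it substantially wider, and is calibrated
    so that the smooth-onset spectral-dominance sweep reproduces the known
    dominance boundary at peak ratio 1.5 (see docs/methods.md). ``peak_ratio``
    is the peak amplitude relative to the BOLD peak of 1 (default 1.8).
    """
    if dt <= 0 or mean_lag <= 0 or sd <= 0:
        raise InvalidParameterError("dt, mean_lag and sd must be positive")
    if peak_ratio <= 0:
        raise InvalidParameterError("peak_ratio must be positive")
    k = (mean_lag / sd) ** 2
    theta = sd**2 / mean_lag
    if stats.gamma.cdf(duration, a=k, scale=theta) < 0.99:
        raise TruncationError(
            f"duration {duration} s contains <99% of the MION response mass"
        )
    t = np.arange(0.0, duration + dt / 2, dt)
    h = stats.gamma.pdf(t, a=k, scale=theta)
    return ImpulseResponse(f"mion({peak_ratio:g})", dt, h / h.max() * peak_ratio)


def splice_smooth_onset(
    mion: ImpulseResponse, onset_source: ImpulseResponse
) -> ImpulseResponse:
    """Replace the rising limb of ``mion`` with ``onset_source``'s onset.

    For t >= mion.peak_time the output equals ``mion``. Before the peak, the
    onset source's rising limb is time-rescaled so its peak lands at the MION
    peak time and amplitude-rescaled to the MION peak, guaranteeing
    continuity at the splice point. This is the conservative smooth-onset
    MION variant: the sharp early rise of the plain gamma model is replaced
    with the slower BOLD-shaped onset.
    """
    if abs(mion.dt - onset_source.dt) > 1e-12:
        raise GridMismatchError(
            f"dt mismatch: {mion.dt} vs {onset_source.dt}"
        )
    if onset_source.peak_amplitude <= 0:
        raise InvalidParameterError("onset_source must have a positive peak")
    p = mion.peak_index
    out = np.array(mion.samples)
    if p > 0:
        # map [0, mion peak) onto [0, onset peak) and interpolate
        t_scaled = mion.times[:p] * (onset_source.peak_time / mion.peak_time)
        rising = np.interp(t_scaled, onset_source.times, onset_source.samples)
        out[:p] = rising / onset_source.peak_amplitude * mion.peak_amplitude
    return ImpulseResponse(f"{mion.name}+{onset_source.name}-onset", mion.dt, out)


def smooth_onset_variant(irf: ImpulseResponse, width: float) -> ImpulseResponse:
    """Convolve with a causal unit-area Hann kernel, then restore the peak.

    ``width`` is the total kernel support in seconds; 0 returns an identical
    copy. The kernel starts at lag 0 so the response onset stays at t = 0
    with samples[0] unchanged; smoothing therefore also slightly delays the
    response, which is the intended "even smoother onset" behaviour. The
    output is renormalized so its peak amplitude equals the input's.
    """
    if width < 0:
        raise InvalidParameterError("width must be >= 0")
    if width == 0:
        return ImpulseResponse(irf.name, irf.dt, np.array(irf.samples))
    n_kernel = max(int(round(width / irf.dt)) + 1, 2)
    kernel = np.hanning(n_kernel + 2)[1:-1]  # strictly positive interior
    kernel = kernel / kernel.sum()
    out = np.convolve(irf.samples, kernel)[: irf.samples.size]
    out *= irf.peak_amplitude / out.max()
    return ImpulseResponse(f"{irf.name}~{width:g}s", irf.dt, out)


def gamma_hrf(
    mean_lag: float = 3.0,
    sd: float = 1.5,
    dt: float = 0.1,
    duration: float = 30.0,
) -> ImpulseResponse:
    """Gamma HRF with the given first moment and SD, unit peak.

    The defaults (3 s mean lag, 1.5 s SD) are the fast macaque BOLD HRF used
    for GLM regressor construction; the underlying gamma has shape
    k = (mean/sd)^2 and scale sd^2/mean (k = 4, scale = 0.75 s at defaults).
    """
    if mean_lag <= 0 or sd <= 0 or dt <= 0:
        raise InvalidParameterError("mean_lag, sd and dt must be positive")
    if duration < mean_lag + 4 * sd:
        raise TruncationError(
            f"duration {duration} s < mean_lag + 4*sd = {mean_lag + 4 * sd} s"
        )
    k = (mean_lag / sd) ** 2
    theta = sd**2 / mean_lag
    t = np.arange(0.0, duration + dt / 2, dt)
    h = stats.gamma.pdf(t, a=k, scale=theta)
    return ImpulseResponse("gamma-hrf", dt, h / h.max())
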