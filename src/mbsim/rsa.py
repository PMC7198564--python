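"""Cross-validated Mahalanobis (crossnobis) distances and RDM assembly.

The crossnobis estimator of the squared Mahalanobis distance between the
activity patterns of conditions k and j is

    d(k, j) = (b_kA - b_jA) Sigma_A^{-1} (b_kB - b_jB)^T

where A/B are independent training/test halves of the runs and Sigma_A is
the voxel noise covariance estimated from the training half's GLM
residuals, Sigma = (1/T) R^T R. Because the two halves carry independent
noise, the estimator is unbiased (zero in expectation for identical
patterns) and individual entries may be negative. ``CrossnobisRSA`` is the
model object; ``fit()`` runs the repeated split-half fold loop (default 50
folds, one run dropped at random when the run count is odd) and returns the
fold-averaged :class:`RDM`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .irf import InvalidParameterError


class SingularCovarianceError(ValueError):
    """The noise covariance is singular; raise shrinkage above 0."""


@dataclass(frozen=True)
class NoiseCov:
    """Voxel x voxel noise covariance with optional diagonal shrinkage."""

    matrix: np.ndarray = field(repr=False)
    source: str = ""
    shrinkage: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InvalidParameterError("covariance must be square")
        object.__setattr__(self, "matrix", m)

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]

    def solve(self, vectors: np.ndarray) -> np.ndarray:
        """Sigma^{-1} @ vectors, raising a helpful error when singular."""
        try:
            result = np.linalg.solve(self.matrix, vectors)
        except np.linalg.LinAlgError as exc:
            raise SingularCovarianceError(
                "noise covariance is singular; use shrinkage > 0 "
                f"(current shrinkage={self.shrinkage})"
            ) from exc
        if not np.all(np.isfinite(result)):
            raise SingularCovarianceError(
                "noise covariance is numerically singular; use shrinkage > 0"
            )
        return result


def noise_covariance(
    residuals, shrinkage: float = 0.1, source: str = ""
) -> NoiseCov:
    """Sigma = (1/T) R'R, blended toward its own diagonal.

    ``shrinkage`` in [0, 1] weights a diagonal target: the returned matrix
    is (1-s)*Sigma + s*diag(Sigma), which is strictly positive definite for
    s > 0 whenever the diagonal is positive. s = 0 is the plain residual
    covariance; s = 1 is exactly the diagonal target.
    """
    R = np.asarray(residuals, dtype=float)
    if R.ndim != 2:
        raise InvalidParameterError("residuals must be a volumes x voxels table")
    if not np.all(np.isfinite(R)):
        raise InvalidParameterError("residuals must be finite")
    T, P = R.shape
    if T < 2 or P < 1:
        raise InvalidParameterError("need T >= 2 volumes and P >= 1 voxels")
    if not 0.0 <= shrinkage <= 1.0:
        raise InvalidParameterError("shrinkage must be in [0, 1]")
    sigma = R.T @ R / T
    target = np.diag(np.diag(sigma))
    return NoiseCov((1.0 - shrinkage) * sigma + shrinkage * target, source, shrinkage)


def crossnobis(delta_A, delta_B, cov_A: NoiseCov) -> float:
    """Bilinear form delta_A Sigma_A^{-1} delta_B' (may be negative)."""
    a = np.asarray(delta_A, dtype=float)
    b = np.asarray(delta_B, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size != cov_A.n_voxels:
        raise InvalidParameterError("delta vectors must match the covariance size")
    return float(a @ cov_A.solve(b))


@dataclass(frozen=True)
class PatternEstimates:
    """Per-run condition x voxel beta patterns with availability flags.

    ``betas`` has shape (n_runs, n_conditions, n_voxels); ``available`` is
    (n_runs, n_conditions) and is False where a run's regressor for the
    condition was dropped (all events censored).
    """

    betas: np.ndarray = field(repr=False)
    available: np.ndarray = field(repr=False)
    run_ids: tuple = ()
    condition_labels: tuple = ()
    voxel_ids: tuple = ()

    def __post_init__(self) -> None:
        betas = np.asarray(self.betas, dtype=float)
        avail = np.asarray(self.available, dtype=bool)
        if betas.ndim != 3:
            raise InvalidParameterError("betas must be runs x conditions x voxels")
        if avail.shape != betas.shape[:2]:
            raise InvalidParameterError("availability must be runs x conditions")
        object.__setattr__(self, "betas", betas)
        object.__setattr__(self, "available", avail)
        if not self.run_ids:
            object.__setattr__(self, "run_ids", tuple(range(betas.shape[0])))
        if not self.condition_labels:
            object.__setattr__(
                self, "condition_labels", tuple(range(betas.shape[1]))
            )
        if not self.voxel_ids:
            object.__setattr__(self, "voxel_ids", tuple(range(betas.shape[2])))

    @property
    def n_runs(self) -> int:
        return self.betas.shape[0]

    @classmethod
    def from_glm_results(cls, results: Sequence) -> "PatternEstimates":
        """Stack interest betas from per-run :class:`~mbsim.glm.GLMResults`."""
        labels = list(results[0].model.design.interest)
        voxels = tuple(results[0].params.columns)
        betas, avail = [], []
        for res in results:
            mat = np.zeros((len(labels), len(voxels)))
            ok = np.zeros(len(labels), dtype=bool)
            for i, lab in enumerate(labels):
                if lab in res.params.index:
                    mat[i] = res.params.loc[lab].to_numpy()
                    ok[i] = lab not in res.model.design.all_zero
            betas.append(mat)
            avail.append(ok)
        return cls(
            np.stack(betas),
            np.stack(avail),
            condition_labels=tuple(labels),
            voxel_ids=voxels,
        )


@dataclass(frozen=True)
class RDM:
    """Symmetric condition x condition matrix of crossnobis distances."""

    matrix: pd.DataFrame
    n_folds: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy()
        if m.shape[0] != m.shape[1]:
            raise InvalidParameterError("RDM must be square")

    @property
    def condition_labels(self) -> tuple:
        return tuple(self.matrix.index)

    def values(self) -> np.ndarray:
        return self.matrix.to_numpy()

    def off_diagonal(self) -> np.ndarray:
        m = self.matrix.to_numpy()
        return m[~np.eye(m.shape[0], dtype=bool)]

    def summary(self) -> str:
        off = self.off_diagonal()
        finite = off[np.isfinite(off)]
        lines = [
            "Crossnobis RDM",
            "=" * 40,
            f"conditions:     {self.matrix.shape[0]}",
            f"folds averaged: {self.n_folds}",
            f"missing pairs:  {int(np.sum(~np.isfinite(off))) // 2}",
            f"mean distance:  {finite.mean():.6g}" if finite.size else "mean distance:  n/a",
            f"min / max:      {finite.min():.6g} / {finite.max():.6g}"
            if finite.size
            else "",
        ]
        for key, value in self.provenance.items():
            lines.append(f"{key}: {value}")
        return "\n".join(line for line in lines if line)

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path, index_label="condition")

    @classmethod
    def from_csv(cls, path, **provenance) -> "RDM":
        frame = pd.read_csv(path, index_col="condition")
        frame.columns = frame.index
        return cls(frame, provenance.pop("n_folds", 0), provenance)


def _fold_distance_matrix(
    mean_A: np.ndarray, mean_B: np.ndarray, cov: NoiseCov
) -> np.ndarray:
    """All-pairs crossnobis for one fold via the cross-Gram matrix.

    With M = B_A Sigma^{-1} B_B', the pair distance is
    d(k, j) = M_kk + M_jj - M_kj - M_jk, symmetric with zero diagonal.
    """
    M = mean_A @ cov.solve(mean_B.T)
    diag = np.diag(M)
    return diag[:, None] + diag[None, :] - M - M.T


class CrossnobisRSA:
    """Split-half crossnobis RSA model for one session.

    Parameters
    ----------
    patterns : PatternEstimates
        Per-run beta patterns.
    residuals : sequence of ndarray, optional
        Per-run GLM residual tables (volumes x voxels), used to estimate the
        training-half noise covariance. May be omitted when fitting with
        ``noise_cov="identity"``.
    """

    def __init__(self, patterns: PatternEstimates, residuals=None):
        self.patterns = patterns
        if residuals is not None:
            residuals = [np.asarray(r, dtype=float) for r in residuals]
            if len(residuals) != patterns.n_runs:
                raise InvalidParameterError("one residual table per run required")
        self.residuals = residuals

    def fit(
        self,
        n_folds: int = 50,
        seed: int | None = None,
        shrinkage: float = 0.1,
        noise_cov: str = "estimate",
    ) -> RDM:
        """Average crossnobis distances over seeded random split-half folds.

        Each fold randomly drops one run when the count is odd, splits the
        rest into halves A and B, averages each half's available betas per
        condition, estimates Sigma_A from the A-half residuals (or uses the
        identity when ``noise_cov="identity"``), and computes all pairwise
        distances. Pairs with a condition unavailable in either half are
        skipped for that fold; pairs available in no fold come out NaN.
        """
        if seed is None:
            raise InvalidParameterError("a seed is required for fold assignment")
        if n_folds < 1:
            raise InvalidParameterError("n_folds must be >= 1")
        if noise_cov not in ("estimate", "identity"):
            raise InvalidParameterError("noise_cov must be 'estimate' or 'identity'")
        if noise_cov == "estimate" and self.residuals is None:
            raise InvalidParameterError("residuals are required to estimate Sigma")
        pats = self.patterns
        n_runs = pats.n_runs
        if n_runs < 2:
            raise InvalidParameterError("need at least 2 runs for split-half folds")
        C = pats.betas.shape[1]
        P = pats.betas.shape[2]
        rng = np.random.default_rng(seed)
        acc = np.zeros((C, C))
        count = np.zeros((C, C))
        for _ in range(n_folds):
            order = rng.permutation(n_runs)
            usable = order[: n_runs - (n_runs % 2)]  # drop one random run if odd
            half = usable.size // 2
            runs_A, runs_B = usable[:half], usable[half:]
            mean_A, ok_A = _half_mean(pats, runs_A)
            mean_B, ok_B = _half_mean(pats, runs_B)
            if noise_cov == "identity":
                cov = NoiseCov(np.eye(P), source="identity")
            else:
                stacked = np.vstack([self.residuals[r] for r in runs_A])
                cov = noise_covariance(
                    stacked, shrinkage, source=f"runs {sorted(runs_A.tolist())}"
                )
            dists = _fold_distance_matrix(mean_A, mean_B, cov)
            ok_pair = np.outer(ok_A & ok_B, ok_A & ok_B)
            acc[ok_pair] += dists[ok_pair]
            count[ok_pair] += 1
        with np.errstate(invalid="ignore"):
            mean = np.where(count > 0, acc / np.maximum(count, 1), np.nan)
        np.fill_diagonal(mean, 0.0)
        labels = pats.condition_labels
        frame = pd.DataFrame(mean, index=labels, columns=labels)
        return RDM(
            frame,
            n_folds=n_folds,
            provenance={
                "seed": seed,
                "shrinkage": shrinkage if noise_cov == "estimate" else None,
                "noise_cov": noise_cov,
                "n_runs": n_runs,
            },
        )


def _half_mean(pats: PatternEstimates, runs: np.ndarray):
    """Mean pattern per condition over a half's available runs."""
    avail = pats.available[runs]            # runs x C
    betas = pats.betas[runs]                # runs x C x P
    n_avail = avail.sum(axis=0)             # C
    ok = n_avail > 0
    weights = avail[:, :, None].astype(float)
    with np.errstate(invalid="ignore"):
        mean = (betas * weights).sum(axis=0) / np.maximum(n_avail, 1)[:, None]
    mean[~ok] = 0.0
    return mean, ok


def split_half_rdm(
    patterns: PatternEstimates,
    residuals=None,
    n_folds: int = 50,
    seed: int | None = None,
    shrinkage: float = 0.1,
    noise_cov: str = "estimate",
) -> RDM:
    """Functional wrapper around :class:`CrossnobisRSA` (model + fit)."""
    return CrossnobisRSA(patterns, residuals).fit(
        n_folds=n_folds, seed=seed, shrinkage=shrinkage, noise_cov=noise_cov
    )


def average_rdms(rdms: Sequence[RDM], grouping: str = "") -> RDM:
    """Entrywise mean of RDMs, ignoring missing (NaN) entries."""
    if not rdms:
        raise InvalidParameterError("no RDMs to average")
    labels = rdms[0].condition_labels
    for r in rdms[1:]:
        if r.condition_labels != labels:
            raise InvalidParameterError("condition labels differ across RDMs")
    stack = np.stack([r.values() for r in rdms])
    finite = np.isfinite(stack)
    counts = finite.sum(axis=0)
    sums = np.where(finite, stack, 0.0).sum(axis=0)
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    frame = pd.DataFrame(mean, index=labels, columns=labels)
    provenance = {
        "grouping": grouping,
        "sources": [r.provenance for r in rdms],
    }
    return RDM(frame, n_folds=rdms[0].n_folds, provenance=provenance)
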