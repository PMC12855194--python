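"""Particle-size distribution statistics for bistable yeast populations.

Coulter-counter style particle-diameter tables are decomposed into the two
morphotype subpopulations — small ancestral-like clusters (3–13 μm) and large
multicellular clusters (>13 μm) — with a two-component univariate Gaussian
mixture fitted by EM.  Bimodality of a sample is decided by ΔBIC between the
one- and two-component fits.  Similarity between diameter distributions is the
overlap index η: the integral of the pointwise minimum of the two
Gaussian-kernel density estimates (η = 1 identical, η = 0 disjoint).  Overlap
matrices are clustered hierarchically (Euclidean distances, Ward-D2 linkage),
and particles are classified into small/large size classes by a hard diameter
threshold (default 13 μm, closed on the small side).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.special import logsumexp
from scipy.stats import gaussian_kde, norm

from .exceptions import (
    DegenerateDataError,
    NotConvergedError,
    ParticleCSVError,
    ValidationError,
)

__all__ = [
    "ParticleSample",
    "MixtureFit",
    "OverlapMatrix",
    "MergeTree",
    "SizeClassCounts",
    "read_particle_csv",
    "write_particle_csv",
    "fit_two_component_mixture",
    "bimodality_decision",
    "posterior_small",
    "overlap_index",
    "overlap_matrix",
    "cluster_overlap",
    "classify_particles",
]

#: Lower bound on mixture-component standard deviations (μm); prevents the EM
#: likelihood singularity when a component collapses onto a single point.
SD_FLOOR = 1e-6


@dataclass
class ParticleSample:
    """One strain/time/condition's particle-diameter measurements (μm)."""

    sample_id: str
    time_h: float
    diameters: np.ndarray
    condition: str | None = None
    detection_threshold: float | None = None

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.diameters.ndim != 1:
            raise ValidationError("diameters must be a 1-d array")
        if self.diameters.size and not np.all(self.diameters > 0):
            raise ValidationError(f"all diameters must be > 0 in sample {self.sample_id!r}")
        if self.detection_threshold is not None:
            if self.detection_threshold < 0:
                raise ValidationError("detection_threshold must be >= 0")
            if self.diameters.size and np.any(self.diameters < self.detection_threshold):
                raise ValidationError(
                    f"sample {self.sample_id!r} has diameters below the declared "
                    f"detection threshold {self.detection_threshold}"
                )

    def __len__(self) -> int:
        return int(self.diameters.size)

    @property
    def label(self) -> str:
        return f"{self.sample_id}@{self.time_h:g}h"


def read_particle_csv(path) -> list[ParticleSample]:
    """Read a particle table (columns sample_id, time_h, diameter_um).

    Returns one :class:`ParticleSample` per (sample_id, time_h) group, with
    row order preserved within groups.  An optional ``condition`` column is
    carried through.  Malformed rows raise :class:`ParticleCSVError` naming
    the offending row (1-based, counting the header as row 1).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"sample_id", "time_h", "diameter_um"}
    missing = required - set(df.columns)
    if missing:
        raise ParticleCSVError(f"{path}: missing column(s) {sorted(missing)}")
    for col in ("time_h", "diameter_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals.to_numpy(dtype=float))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParticleCSVError(
                f"{path}: non-numeric {col} {df[col].iloc[row]!r} at row {row + 2}"
            )
        df[col] = vals
    nonpos = df["diameter_um"].to_numpy(dtype=float) <= 0
    if nonpos.any():
        row = int(np.flatnonzero(nonpos)[0])
        raise ParticleCSVError(
            f"{path}: non-positive diameter {df['diameter_um'].iloc[row]} at row {row + 2}"
        )
    samples = []
    for (sid, t), grp in df.groupby(["sample_id", "time_h"], sort=False):
        condition = None
        if "condition" in grp.columns and grp["condition"].notna().any():
            condition = str(grp["condition"].iloc[0])
        thr = None
        if "detection_threshold" in grp.columns and grp["detection_threshold"].notna().any():
            thr = float(grp["detection_threshold"].iloc[0])
        samples.append(
            ParticleSample(
                sample_id=str(sid),
                time_h=float(t),
                diameters=grp["diameter_um"].to_numpy(dtype=float),
                condition=condition,
                detection_threshold=thr,
            )
        )
    return samples


def write_particle_csv(samples, path) -> None:
    """Write samples as CSV with columns sample_id, time_h, diameter_um (+condition)."""
    frames = []
    for s in samples:
        frame = pd.DataFrame(
            {
                "sample_id": s.sample_id,
                "time_h": s.time_h,
                "diameter_um": s.diameters,
            }
        )
        if s.condition is not None:
            frame["condition"] = s.condition
        if s.detection_threshold is not None:
            frame["detection_threshold"] = s.detection_threshold
        frames.append(frame)
    # %.17g guarantees float64 values survive the write -> read round trip bitwise
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


@dataclass
class MixtureFit:
    """Two-component Gaussian decomposition of a diameter distribution.

    Components are sorted so that ``mean_small <= mean_large``.  The
    one-component (single Gaussian) fit is reported alongside so that ΔBIC
    model selection can decide bimodality.
    """

    weight_small: float
    weight_large: float
    mean_small: float
    mean_large: float
    sd_small: float
    sd_large: float
    log_likelihood_2comp: float
    log_likelihood_1comp: float
    bic_2comp: float
    bic_1comp: float
    n_iterations: int
    converged: bool
    sd_floor_hit: bool = False
    log_likelihood_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "weight_small": self.weight_small,
            "weight_large": self.weight_large,
            "mean_small": self.mean_small,
            "mean_large": self.mean_large,
            "sd_small": self.sd_small,
            "sd_large": self.sd_large,
            "log_likelihood_2comp": self.log_likelihood_2comp,
            "log_likelihood_1comp": self.log_likelihood_1comp,
            "bic_2comp": self.bic_2comp,
            "bic_1comp": self.bic_1comp,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "sd_floor_hit": self.sd_floor_hit,
        }


def _diameters(sample) -> np.ndarray:
    if isinstance(sample, ParticleSample):
        return sample.diameters
    return np.asarray(sample, dtype=float)


def _mixture_log_likelihood(x, w, mu, sd) -> tuple[float, np.ndarray]:
    logp = np.log(w)[None, :] + norm.logpdf(x[:, None], mu[None, :], sd[None, :])
    per_point = logsumexp(logp, axis=1)
    return float(per_point.sum()), np.exp(logp - per_point[:, None])


def fit_two_component_mixture(
    sample,
    tol: float = 1e-6,
    max_iter: int = 2000,
    seed: int | None = None,
) -> MixtureFit:
    """EM fit of a two-component univariate Gaussian mixture.

    Initialisation is deterministic — means at the 25th/75th sample quantiles,
    both SDs at the sample SD, equal weights — so ``seed`` is accepted for
    interface uniformity but unused.  The log-likelihood is non-decreasing
    across iterations; convergence is declared when successive log-likelihoods
    differ by less than ``tol``.  A variance collapse is prevented by flooring
    SDs at ``SD_FLOOR`` and flagged via ``sd_floor_hit``.

    Raises :class:`DegenerateDataError` for fewer than 10 points or zero
    variance.
    """
    x = _diameters(sample)
    n = x.size
    if n < 10:
        raise DegenerateDataError(f"mixture fit needs >= 10 diameters, got {n}")
    if np.var(x) == 0:
        raise DegenerateDataError("mixture fit needs nonzero variance")

    mu = np.percentile(x, [25.0, 75.0]).astype(float)
    sd = np.full(2, max(float(np.std(x)), SD_FLOOR))
    w = np.array([0.5, 0.5])

    trace: list[float] = []
    converged = False
    sd_floor_hit = False
    n_iterations = 0
    ll_prev = -np.inf
    for it in range(1, max_iter + 1):
        ll, resp = _mixture_log_likelihood(x, w, mu, sd)
        trace.append(ll)
        n_iterations = it
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
        # M-step
        nj = np.maximum(resp.sum(axis=0), 1e-300)
        w = nj / n
        w = w / w.sum()
        mu = (resp * x[:, None]).sum(axis=0) / nj
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nj
        sd_new = np.sqrt(var)
        if np.any(sd_new < SD_FLOOR):
            sd_floor_hit = True
        sd = np.maximum(sd_new, SD_FLOOR)

    ll2, _ = _mixture_log_likelihood(x, w, mu, sd)
    if not converged and (not trace or ll2 != trace[-1]):
        trace.append(ll2)  # likelihood at the returned (post-M-step) parameters

    order = np.lexsort((sd, mu))  # sort by mean, ties by SD
    w, mu, sd = w[order], mu[order], sd[order]

    mu1 = float(np.mean(x))
    sd1 = max(float(np.std(x)), SD_FLOOR)
    ll1 = float(norm.logpdf(x, mu1, sd1).sum())
    log_n = math.log(n)
    return MixtureFit(
        weight_small=float(w[0]),
        weight_large=float(w[1]),
        mean_small=float(mu[0]),
        mean_large=float(mu[1]),
        sd_small=float(sd[0]),
        sd_large=float(sd[1]),
        log_likelihood_2comp=ll2,
        log_likelihood_1comp=ll1,
        bic_2comp=5.0 * log_n - 2.0 * ll2,
        bic_1comp=2.0 * log_n - 2.0 * ll1,
        n_iterations=n_iterations,
        converged=converged,
        sd_floor_hit=sd_floor_hit,
        log_likelihood_trace=np.asarray(trace),
    )


def bimodality_decision(fit: MixtureFit, delta_bic_threshold: float = 10.0) -> str:
    """Decide "bimodal" vs "unimodal" by BIC model selection.

    Bimodal iff ``bic_1comp - bic_2comp > delta_bic_threshold`` (strict); a
    ΔBIC exactly at the threshold is therefore unimodal.  Refuses
    non-converged fits.
    """
    if not fit.converged:
        raise NotConvergedError(
            "mixture fit did not converge; rerun with larger max_iter before "
            "deciding bimodality"
        )
    return "bimodal" if (fit.bic_1comp - fit.bic_2comp) > delta_bic_threshold else "unimodal"


def posterior_small(fit: MixtureFit, diameters) -> np.ndarray:
    """Posterior probability that each particle belongs to the small component."""
    x = _diameters(diameters)
    w = np.array([fit.weight_small, fit.weight_large])
    mu = np.array([fit.mean_small, fit.mean_large])
    sd = np.array([fit.sd_small, fit.sd_large])
    _, resp = _mixture_log_likelihood(x, w, mu, sd)
    return resp[:, 0]


def _nrd0_bandwidth(x: np.ndarray) -> float:
    """Silverman rule-of-thumb bandwidth 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    n = x.size
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75.0, 25.0])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise DegenerateDataError("cannot form a KDE bandwidth: sample has no spread")
    return 0.9 * spread * n ** (-0.2)


def overlap_index(a, b, n_grid: int = 1024) -> float:
    """Overlap index η between two diameter distributions.

    Gaussian-kernel density estimates of both samples (Silverman rule-of-thumb
    bandwidth per sample) are evaluated on a common equispaced grid spanning
    the union range padded by 3 bandwidths; η is the trapezoidal integral of
    the pointwise minimum of the two densities, clamped to [0, 1].
    """
    x = _diameters(a)
    y = _diameters(b)
    for arr, which in ((x, "first"), (y, "second")):
        if np.unique(arr).size < 2:
            raise DegenerateDataError(
                f"overlap index needs >= 2 distinct values in the {which} sample"
            )
    hx = _nrd0_bandwidth(x)
    hy = _nrd0_bandwidth(y)
    lo = min(x.min() - 3 * hx, y.min() - 3 * hy)
    hi = max(x.max() + 3 * hx, y.max() + 3 * hy)
    grid = np.linspace(lo, hi, n_grid)
    fx = gaussian_kde(x, bw_method=hx / np.std(x, ddof=1))(grid)
    fy = gaussian_kde(y, bw_method=hy / np.std(y, ddof=1))(grid)
    eta = float(np.trapezoid(np.minimum(fx, fy), grid))
    return min(max(eta, 0.0), 1.0)


@dataclass
class OverlapMatrix:
    """Symmetric matrix of pairwise overlap indices with unit diagonal."""

    labels: list[str]
    eta: np.ndarray

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float)
        n = len(self.labels)
        if self.eta.shape != (n, n):
            raise ValidationError("eta must be square and match labels")
        if not np.allclose(self.eta, self.eta.T, atol=1e-9):
            raise ValidationError("eta must be symmetric")
        if not np.allclose(np.diag(self.eta), 1.0, atol=1e-6):
            raise ValidationError("eta diagonal must be 1")
        if np.any(self.eta < -1e-12) or np.any(self.eta > 1 + 1e-12):
            raise ValidationError("eta entries must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.eta, index=self.labels, columns=self.labels)


def overlap_matrix(samples, n_grid: int = 1024) -> OverlapMatrix:
    """All pairwise overlap indices; computed once per unordered pair."""
    samples = list(samples)
    if len(samples) < 2:
        raise ValidationError("overlap matrix needs >= 2 samples")
    ids = [s.sample_id for s in samples]
    labels = ids if len(set(ids)) == len(ids) else [s.label for s in samples]
    n = len(samples)
    eta = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                eta[i, j] = eta[j, i] = overlap_index(samples[i], samples[j], n_grid=n_grid)
            except DegenerateDataError as exc:
                raise DegenerateDataError(
                    f"overlap failed for pair ({labels[i]}, {labels[j]}): {exc}"
                ) from exc
    return OverlapMatrix(labels=labels, eta=eta)


@dataclass
class MergeTree:
    """Agglomerative merge list (Ward-D2 linkage on Euclidean row distances)."""

    labels: list[str]
    linkage_matrix: np.ndarray  # scipy (n-1, 4) format

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_table(self) -> pd.DataFrame:
        """Flat parent/child/height table; leaves are named by label."""
        n = len(self.labels)

        def name(idx: float) -> str:
            i = int(idx)
            return self.labels[i] if i < n else f"node{i}"

        rows = []
        for m, (a, b, h, size) in enumerate(self.linkage_matrix):
            rows.append(
                {
                    "parent": f"node{n + m}",
                    "child_a": name(a),
                    "child_b": name(b),
                    "height": float(h),
                    "n_leaves": int(size),
                }
            )
        return pd.DataFrame(rows)


def cluster_overlap(matrix: OverlapMatrix) -> MergeTree:
    """Hierarchically cluster overlap-matrix rows (Euclidean, Ward-D2).

    Rows of η are the feature vectors; merge heights are non-decreasing by
    construction of the Ward criterion.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValidationError(f"clustering needs >= 3 items, got {n}")
    Z = linkage(matrix.eta, method="ward")
    return MergeTree(labels=list(matrix.labels), linkage_matrix=Z)


@dataclass(frozen=True)
class SizeClassCounts:
    """Small/large classification of one sample at a hard size threshold."""

    threshold: float
    count_small: int
    count_large: int

    @property
    def fraction_small(self) -> float:
        total = self.count_small + self.count_large
        return self.count_small / total if total else float("nan")

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "count_small": self.count_small,
            "count_large": self.count_large,
            "fraction_small": self.fraction_small,
        }


def classify_particles(sample, threshold: float = 13.0) -> SizeClassCounts:
    """Classify particles as small (diameter <= threshold) or large.

    The small class is closed at the threshold — the empirical small class is
    3 to 13 μm inclusive — so a diameter exactly at the threshold is small.
    """
    x = _diameters(sample)
    if x.size == 0:
        raise DegenerateDataError("cannot classify an empty sample")
    small = int(np.count_nonzero(x <= threshold))
    return SizeClassCounts(
        threshold=float(threshold), count_small=small, count_large=int(x.size - small)
    )
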