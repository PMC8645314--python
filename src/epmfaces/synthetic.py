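"""Synthetic face-appearance trajectories and noisy similarity ratings.

A person's outward facial appearance is modelled as a point drifting through an
abstract d-dimensional feature space across the lifespan.  Two processes move
that point:

* **slow age-dependent drift** — a Gaussian random walk whose per-year step
  scale ``sigma(age) = sigma0 / (1 + age / tau)`` decreases with age, so early
  years change the face more than late ones;
* **rare sudden jumps** — discrete appearance changes (a radical haircut, a
  beard) injected as a fixed-magnitude displacement along a random direction at
  a configured age.  Jumps are deterministic events so the ground-truth
  segmentation of a trajectory into "episodes of life" is exactly known.

Dissimilarity between any two exemplars is Euclidean distance in feature
space; noisy 7-point Likert similarity ratings are an affine map of those
distances plus Gaussian rater noise.
"""

from __future__ import annotations


import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FaceExemplar",
    "LifespanTrajectory",
    "RatingMatrix",
    "generate_trajectory",
    "dissimilarity_matrix",
    "simulate_ratings",
    "trajectory_to_frame",
    "trajectory_from_frame",
    "write_dissimilarity_csv",
    "read_dissimilarity_csv",
]


@dataclass(frozen=True)
class FaceExemplar:
    """One dated appearance of one identity as a feature vector."""

    exemplar_id: str
    identity_id: str
    capture_age: float
    feature_vector: np.ndarray

    def __post_init__(self):
        vec = np.asarray(self.feature_vector, dtype=float)
        if not np.all(np.isfinite(vec)):
            raise ValueError("feature_vector must be finite")
        if not math.isfinite(self.capture_age) or self.capture_age < 0:
            raise ValueError("capture_age must be finite and nonnegative")
        object.__setattr__(self, "feature_vector", vec)


@dataclass
class LifespanTrajectory:
    """Ordered exemplars of one identity plus the ground-truth jump events.

    ``segment_labels()`` returns, for each exemplar, the index of the
    between-jump segment it falls in — the ground truth that jump-recovery
    tests score against.
    """

    identity_id: str
    exemplars: list[FaceExemplar]
    jump_events: list[tuple[float, float]] = field(default_factory=list)
    drift_params: tuple[float, float] = (1.0, math.inf)

    def __post_init__(self):
        ages = [e.capture_age for e in self.exemplars]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("exemplar ages must be strictly increasing")
        if self.exemplars and self.jump_events:
            lo, hi = ages[0], ages[-1]
            for age, _mag in self.jump_events:
                if not (lo <= age <= hi):
                    raise ValueError(f"jump age {age} outside span [{lo}, {hi}]")

    @property
    def ages(self) -> np.ndarray:
        return np.array([e.capture_age for e in self.exemplars])

    @property
    def features(self) -> np.ndarray:
        """(n, d) matrix of feature vectors, rows in age order."""
        return np.vstack([e.feature_vector for e in self.exemplars])

    def segment_labels(self) -> np.ndarray:
        """Ground-truth segment index per exemplar (0 before the first jump)."""
        jump_ages = sorted(a for a, _ in self.jump_events)
        return np.searchsorted(jump_ages, self.ages, side="left")


@dataclass
class RatingMatrix:
    """Symmetric n×n matrix of 7-point Likert similarity ratings."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("rating matrix must be square")
        if not np.array_equal(v, v.T):
            raise ValueError("rating matrix must be symmetric")
        off = v[~np.eye(len(v), dtype=bool)]
        if off.size and (off.min() < 1 or off.max() > 7 or not np.array_equal(off, off.astype(int))):
            raise ValueError("ratings must be integers in [1, 7]")
        self.values = v


def _drift_step_sd(a0: float, a1: float, sigma0: float, tau: float) -> float:
    """Per-dimension SD of the drift displacement accumulated from age a0 to a1.

    The walk has instantaneous per-year variance sigma(a)^2 with
    sigma(a) = sigma0/(1 + a/tau); the displacement variance is the integral
    of sigma(a)^2 over [a0, a1], which has the closed form
    sigma0^2 * tau * (1/(1+a0/tau) - 1/(1+a1/tau)) and degenerates to
    sigma0^2 * (a1 - a0) as tau -> inf.
    """
    if math.isinf(tau):
        var = sigma0 ** 2 * (a1 - a0)
    else:
        var = sigma0 ** 2 * tau * (1.0 / (1.0 + a0 / tau) - 1.0 / (1.0 + a1 / tau))
    return math.sqrt(max(var, 0.0))


def generate_trajectory(
    identity_id: str,
    n_exemplars: int = 20,
    age_start: float = 0.0,
    age_end: float = 60.0,
    spacing_jitter: float = 0.0,
    d: int = 16,
    drift_params: tuple[float, float] = (1.0, math.inf),
    jump_spec: list[tuple[float, float]] | None = None,
    seed: int | np.random.Generator = 0,
    base_norm: float = 0.0,
) -> LifespanTrajectory:
    """Simulate one identity's lifelong stream of face exemplars.

    Parameters
    ----------
    n_exemplars
        Number of dated appearances (the studies use 20 over ~60 years,
        i.e. roughly 3-year spacing).
    spacing_jitter
        Uniform ±jitter (years) on the interior capture ages.
    drift_params
        ``(sigma0, tau)``: initial per-year drift scale and the age-decay
        constant of ``sigma(age) = sigma0/(1 + age/tau)``.
    jump_spec
        List of ``(age, magnitude)`` sudden-change events; each adds a
        displacement of the given magnitude along a random unit direction to
        every exemplar at or after that age.
    base_norm
        Norm of the identity's base appearance vector (the walk's starting
        point, drawn as a random direction).  Zero starts the walk at the
        origin; a positive value gives the identity a stable appearance
        axis, which matters for direction-based (cosine) similarity.
    """
    sigma0, tau = drift_params
    if n_exemplars < 1:
        raise ValueError("n_exemplars must be >= 1")
    if age_end <= age_start:
        raise ValueError("age_end must exceed age_start")
    if not (math.isfinite(sigma0) and sigma0 >= 0):
        raise ValueError("sigma0 must be finite and >= 0")
    if not (tau > 0):
        raise ValueError("tau must be positive (may be inf)")
    if spacing_jitter < 0 or not math.isfinite(spacing_jitter):
        raise ValueError("spacing_jitter must be finite and >= 0")
    jump_spec = list(jump_spec or [])
    for age, mag in jump_spec:
        if not (age_start <= age <= age_end):
            raise ValueError(f"jump age {age} outside [{age_start}, {age_end}]")
        if not (math.isfinite(mag) and mag >= 0):
            raise ValueError("jump magnitude must be finite and >= 0")

    rng = np.random.default_rng(seed)

    if n_exemplars == 1:
        ages = np.array([age_start])
    else:
        ages = np.linspace(age_start, age_end, n_exemplars)
        if spacing_jitter > 0:
            ages[1:-1] += rng.uniform(-spacing_jitter, spacing_jitter, n_exemplars - 2)
            ages = np.sort(ages)
            # jitter must not collapse two capture dates
            ages = np.maximum.accumulate(ages + np.arange(n_exemplars) * 1e-9)

    if base_norm < 0 or not math.isfinite(base_norm):
        raise ValueError("base_norm must be finite and >= 0")
    if base_norm > 0:
        direction = rng.normal(size=d)
        x = base_norm * direction / np.linalg.norm(direction)
    else:
        x = np.zeros(d)
    path = [x.copy()]
    for a0, a1 in zip(ages, ages[1:]):
        sd = _drift_step_sd(a0, a1, sigma0, tau)
        x = x + rng.normal(0.0, 1.0, d) * sd
        path.append(x.copy())
    feats = np.vstack(path)

    for age, mag in jump_spec:
        direction = rng.normal(size=d)
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else np.eye(d)[0]
        feats[ages >= age] += mag * direction

    exemplars = [
        FaceExemplar(f"{identity_id}_{i:03d}", identity_id, float(a), feats[i])
        for i, a in enumerate(ages)
    ]
    return LifespanTrajectory(identity_id, exemplars, jump_spec, (sigma0, tau))


def dissimilarity_matrix(trajectory: LifespanTrajectory | np.ndarray) -> np.ndarray:
    """Square symmetric matrix of Euclidean distances between exemplars."""
    feats = trajectory.features if isinstance(trajectory, LifespanTrajectory) else np.asarray(trajectory, float)
    if feats.ndim != 2 or len(feats) < 2:
        raise ValueError("need at least 2 exemplars with consistent dimension")
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(feats, metric="euclidean"))


def simulate_ratings(D: np.ndarray, noise_sd: float = 0.0, seed: int | np.random.Generator = 0) -> RatingMatrix:
    """Map a dissimilarity matrix to noisy 7-point Likert similarity ratings.

    rating = clamp(round(7 - 6*D/max(D) + eps), 1, 7), eps ~ N(0, noise_sd),
    drawn once per unordered pair so the output stays symmetric.  A zero-range
    matrix (all faces identical) rates every pair maximally similar (7).
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("D must be a square symmetric matrix")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n = len(D)
    rng = np.random.default_rng(seed)
    dmax = D.max()
    out = np.full((n, n), 7, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            base = 7.0 if dmax == 0 else 7.0 - 6.0 * D[i, j] / dmax
            eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            r = int(np.clip(np.round(base + eps), 1, 7))
            out[i, j] = out[j, i] = r
    return RatingMatrix(out)


# ---------------------------------------------------------------------------
# CSV interchange

def trajectory_to_frame(traj: LifespanTrajectory) -> pd.DataFrame:
    d = traj.features.shape[1]
    df = pd.DataFrame(traj.features, columns=[f"f{i}" for i in range(d)])
    df.insert(0, "capture_age", traj.ages)
    df.insert(0, "identity_id", traj.identity_id)
    df.insert(0, "exemplar_id", [e.exemplar_id for e in traj.exemplars])
    return df


def trajectory_from_frame(df: pd.DataFrame) -> LifespanTrajectory:
    fcols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    fcols.sort(key=lambda c: int(c[1:]))
    identities = df["identity_id"].unique()
    if len(identities) != 1:
        raise ValueError("frame must contain exactly one identity")
    df = df.sort_values("capture_age")
    exemplars = [
        FaceExemplar(str(r.exemplar_id), str(r.identity_id), float(r.capture_age),
                     np.array([getattr(r, c) for c in fcols]))
        for r in df.itertuples(index=False)
    ]
    return LifespanTrajectory(str(identities[0]), exemplars)


def write_dissimilarity_csv(path, D: np.ndarray, ids: list[str]) -> None:
    pd.DataFrame(D, columns=ids).to_csv(path, index=False)


def read_dissimilarity_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    return df.to_numpy(dtype=float), list(df.columns)
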