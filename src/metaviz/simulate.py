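"""Signal-plus-noise benchmark generators with ground truth retained.

Observations follow ``Y_i = Y*_i + Z_i`` where the noiseless signals ``Y*``
are drawn from a low-dimensional structure isometrically embedded in R^p under
a Haar-random rotation, and ``Z_i ~ N(0, I_p)`` i.i.d.  Three structure
families are provided:

``mixture``
    r+1 mutually orthogonal cluster centers of norm theta (intrinsic
    dimension r after centering); cluster assignments are uniform.
``smiley``
    a fixed 2-D "smiley face" geometry (outline circle, two eye discs, a
    mouth arc) scaled to diameter theta.
``mammoth``
    a synthetic 3-D mammoth-shaped point cloud (procedurally assembled from
    parametric body parts) scaled to diameter theta.

theta is the signal-to-noise parameter: the norm/diameter of the latent
structure against unit-variance per-coordinate noise.

A single integer seed is split into independent child streams for the
rotation, the latent sampling and the noise, so e.g. changing ``n`` never
changes the rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SyntheticDataset",
    "random_rotation",
    "gaussian_mixture_signals",
    "smiley_face_signals",
    "mammoth_signals",
    "simulate_dataset",
    "add_noise",
    "theta_grid",
    "THETA_RANGES",
]

#: default equispaced theta ranges, chosen so per-coordinate SNR spans weak to
#: strong for every structure (the mixture range brackets theta = 5)
THETA_RANGES = {
    "mixture": (2.0, 8.0),
    "smiley": (10.0, 40.0),
    "mammoth": (10.0, 40.0),
}

#: sampling weights for the smiley components (outline, mouth, left eye,
#: right eye); fixed so the small eye discs remain visible at n ~ 500
SMILEY_WEIGHTS = {"outline": 0.55, "mouth": 0.25, "eye_left": 0.10, "eye_right": 0.10}

#: number of points in the deterministic latent mammoth cloud
MAMMOTH_CLOUD_SIZE = 4096


@dataclass
class SyntheticDataset:
    """Paired noiseless signals and noisy observations with ground truth."""

    structure: str
    signals: np.ndarray  # Y*, (n, p)
    observations: np.ndarray  # Y = Y* + Z, (n, p)
    labels: np.ndarray  # cluster id / component name per sample
    latent: np.ndarray  # pre-rotation low-dimensional points, (n, r or r+1)
    rotation: np.ndarray  # (p, r) orthonormal columns used for the embedding
    theta: float
    r: int  # intrinsic dimension of the centered signals
    seed: int

    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]

    @property
    def p(self) -> int:
        return self.signals.shape[1]


def _streams(seed: int, n_children: int = 3):
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(n_children)]


def random_rotation(p: int, r: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Haar-distributed p x r matrix with orthonormal columns.

    QR of a Gaussian matrix with the sign convention that makes R's diagonal
    positive, which yields the invariant (Haar) distribution on the Stiefel
    manifold.
    """
    if r > p:
        raise ValueError(f"r={r} must not exceed p={p}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = rng.standard_normal((p, r))
    Q, R = np.linalg.qr(A)
    return Q * np.sign(np.diag(R))


def add_noise(signals: np.ndarray, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Observations Y = Y* + Z with Z i.i.d. standard normal."""
    signals = np.asarray(signals, dtype=float)
    if not np.all(np.isfinite(signals)):
        raise ValueError("signals must be finite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return signals + rng.standard_normal(signals.shape)


def gaussian_mixture_signals(
    n: int, p: int, theta: float, r: int = 5, seed: int = 0
) -> SyntheticDataset:
    """Finite orthogonal point mixture: Y*_i drawn uniformly from r+1 mutually
    orthogonal vectors of norm theta."""
    if r + 1 > p:
        raise ValueError(f"need r+1={r + 1} <= p={p}")
    if n < r + 1:
        raise ValueError(f"need n >= r+1={r + 1}, got n={n}")
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    rot_rng, latent_rng, noise_rng = _streams(seed)
    Q = random_rotation(p, r + 1, rot_rng)  # centers live in an (r+1)-dim subspace
    labels = latent_rng.integers(0, r + 1, size=n)
    latent = theta * np.eye(r + 1)[labels]  # orthogonal centers pre-rotation
    signals = latent @ Q.T
    return SyntheticDataset(
        structure="mixture",
        signals=signals,
        observations=add_noise(signals, noise_rng),
        labels=labels,
        latent=latent,
        rotation=Q,
        theta=float(theta),
        r=r,
        seed=seed,
    )


def _smiley_cloud(n: int, rng: np.random.Generator):
    """Sample n labelled points from the unit-diameter smiley geometry."""
    names = list(SMILEY_WEIGHTS)
    weights = np.array([SMILEY_WEIGHTS[c] for c in names])
    comp = rng.choice(len(names), size=n, p=weights / weights.sum())
    pts = np.empty((n, 2))
    for j, name in enumerate(names):
        idx = np.flatnonzero(comp == j)
        m = idx.size
        if m == 0:
            continue
        if name == "outline":  # circle of radius 0.5, uniform by arc length
            ang = rng.uniform(0, 2 * np.pi, m)
            pts[idx] = 0.5 * np.column_stack([np.cos(ang), np.sin(ang)])
        elif name == "mouth":  # arc of radius 0.3 spanning 200..340 deg
            ang = np.deg2rad(rng.uniform(200.0, 340.0, m))
            pts[idx] = np.column_stack(
                [0.3 * np.cos(ang), 0.05 + 0.3 * np.sin(ang)]
            )
        else:  # eye discs of radius 0.05, uniform by area
            cx = -0.18 if name == "eye_left" else 0.18
            rad = 0.05 * np.sqrt(rng.uniform(0, 1, m))
            ang = rng.uniform(0, 2 * np.pi, m)
            pts[idx] = np.column_stack(
                [cx + rad * np.cos(ang), 0.15 + rad * np.sin(ang)]
            )
    return pts, np.array([names[c] for c in comp], dtype=object)


def smiley_face_signals(n: int, p: int, theta: float, seed: int = 0) -> SyntheticDataset:
    """2-D smiley-face structure of diameter theta, Haar-rotated into R^p."""
    if p < 2:
        raise ValueError(f"need p >= 2, got p={p}")
    rot_rng, latent_rng, noise_rng = _streams(seed)
    Q = random_rotation(p, 2, rot_rng)
    pts, labels = _smiley_cloud(n, latent_rng)
    latent = theta * pts  # geometry has unit diameter (outline circle)
    signals = latent @ Q.T
    return SyntheticDataset(
        structure="smiley",
        signals=signals,
        observations=add_noise(signals, noise_rng),
        labels=labels,
        latent=latent,
        rotation=Q,
        theta=float(theta),
        r=2,
        seed=seed,
    )


def _mammoth_parts(m: int, rng: np.random.Generator):
    """Procedural synthetic mammoth-shaped 3-D cloud (unit diameter).

    A stand-in geometry assembled from parametric parts — ellipsoidal body,
    spherical head, four leg cylinders, a curved trunk and two tusk arcs —
    not the public photogrammetry reconstruction.
    """
    parts = {
        "body": 0.40,
        "head": 0.12,
        "legs": 0.24,
        "trunk": 0.12,
        "tusks": 0.12,
    }
    names = list(parts)
    weights = np.array([parts[c] for c in names])
    comp = rng.choice(len(names), size=m, p=weights / weights.sum())
    pts = np.empty((m, 3))
    for j, name in enumerate(names):
        idx = np.flatnonzero(comp == j)
        k = idx.size
        if k == 0:
            continue
        if name == "body":  # ellipsoid surface
            u = rng.standard_normal((k, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            pts[idx] = u * np.array([0.50, 0.22, 0.28]) + np.array([0.0, 0.0, 0.55])
        elif name == "head":  # sphere
            u = rng.standard_normal((k, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            pts[idx] = 0.16 * u + np.array([0.58, 0.0, 0.70])
        elif name == "legs":  # four vertical cylinders
            leg = rng.integers(0, 4, k)
            cx = np.where(leg % 2 == 0, 0.30, -0.30)
            cy = np.where(leg // 2 == 0, 0.14, -0.14)
            ang = rng.uniform(0, 2 * np.pi, k)
            z = rng.uniform(0.0, 0.40, k)
            pts[idx] = np.column_stack(
                [cx + 0.06 * np.cos(ang), cy + 0.06 * np.sin(ang), z]
            )
        elif name == "trunk":  # downward-curving tube from the head
            t = rng.uniform(0, 1, k)
            cx = 0.70 + 0.22 * t
            cz = 0.62 - 0.55 * t**1.5
            ang = rng.uniform(0, 2 * np.pi, k)
            pts[idx] = np.column_stack(
                [
                    cx + 0.03 * np.cos(ang),
                    0.03 * np.sin(ang),
                    cz,
                ]
            )
        else:  # two tusk arcs curving forward
            side = np.where(rng.uniform(size=k) < 0.5, 1.0, -1.0)
            t = rng.uniform(0, 1, k)
            pts[idx] = np.column_stack(
                [
                    0.62 + 0.25 * np.sin(1.2 * t),
                    side * (0.10 - 0.04 * t),
                    0.55 - 0.28 * (1 - np.cos(1.2 * t)),
                ]
            )
    return pts, np.array([names[c] for c in comp], dtype=object)


def _unit_diameter(pts: np.ndarray) -> np.ndarray:
    centered = pts - pts.mean(axis=0)
    diff = centered[:, None, :] - centered[None, :, :]
    diam = np.sqrt((diff**2).sum(-1).max())
    return centered / diam


# latent mammoth cloud is a fixed function of this generation seed
_MAMMOTH_FIXTURE_SEED = 20230211


def mammoth_cloud() -> tuple[np.ndarray, np.ndarray]:
    """The deterministic unit-diameter synthetic mammoth cloud and its part
    labels."""
    rng = np.random.default_rng(_MAMMOTH_FIXTURE_SEED)
    pts, labels = _mammoth_parts(MAMMOTH_CLOUD_SIZE, rng)
    return _unit_diameter(pts), labels


def mammoth_signals(
    n: int, p: int, theta: float, seed: int = 0, jitter: float = 0.0
) -> SyntheticDataset:
    """3-D mammoth-shaped manifold of diameter theta, Haar-rotated into R^p.

    Samples uniformly with replacement from the fixed synthetic cloud; an
    optional isotropic jitter (fraction of the diameter) can be added to the
    latent points.
    """
    if p < 3:
        raise ValueError(f"need p >= 3, got p={p}")
    rot_rng, latent_rng, noise_rng = _streams(seed)
    Q = random_rotation(p, 3, rot_rng)
    cloud, cloud_labels = mammoth_cloud()
    pick = latent_rng.integers(0, cloud.shape[0], size=n)
    latent = theta * cloud[pick]
    if jitter > 0:
        latent = latent + theta * jitter * latent_rng.standard_normal(latent.shape)
    signals = latent @ Q.T
    return SyntheticDataset(
        structure="mammoth",
        signals=signals,
        observations=add_noise(signals, noise_rng),
        labels=cloud_labels[pick],
        latent=latent,
        rotation=Q,
        theta=float(theta),
        r=3,
        seed=seed,
    )


def simulate_dataset(
    structure: str, n: int, p: int, theta: float, seed: int = 0, **kwargs
) -> SyntheticDataset:
    """Dispatch on structure name ('mixture', 'smiley', 'mammoth')."""
    if structure == "mixture":
        return gaussian_mixture_signals(n, p, theta, seed=seed, **kwargs)
    if structure == "smiley":
        return smiley_face_signals(n, p, theta, seed=seed, **kwargs)
    if structure == "mammoth":
        return mammoth_signals(n, p, theta, seed=seed, **kwargs)
    raise ValueError(f"unknown structure {structure!r}; expected one of "
                     f"{sorted(THETA_RANGES)}")


def theta_grid(structure: str, count: int = 20, theta_range=None) -> np.ndarray:
    """Equispaced SNR grid for a structure family (default 20 values over the
    documented per-structure range; count=1 gives the midpoint)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    if theta_range is None:
        if structure not in THETA_RANGES:
            raise ValueError(f"unknown structure {structure!r}")
        theta_range = THETA_RANGES[structure]
    lo, hi = map(float, theta_range)
    if count == 1:
        return np.array([(lo + hi) / 2.0])
    return np.linspace(lo, hi, count)
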