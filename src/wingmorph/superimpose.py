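"""Generalized Procrustes analysis (GPA) for 2D landmark configurations.

Shape is what remains of a landmark configuration after removing position,
scale and orientation.  GPA does this jointly for a set of wings: every
configuration is centred, scaled to unit centroid size and rotated to a
consensus, which is itself re-estimated until it stops moving.  The aligned
coordinates are then projected orthogonally onto the tangent plane of shape
space at the consensus, where ordinary multivariate statistics apply.

For 19 landmarks the 38 raw coordinates lose 2 dimensions to translation,
1 to scale and 1 to rotation, so tangent coordinates of generic data span
exactly 34 dimensions — the dimensionality used downstream ("wing shape").

Reflections are never fitted: a left wing is mirrored explicitly (x -> -x)
before alignment when ``mirror_left`` is on, keeping the raw digitization
faithful to the image while analysing both sides in one shape space.

Internally 2D configurations are handled as complex vectors (one complex
number per landmark), for which the optimal rotation has a closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

import numpy as np

from .landmark_io import LandmarkConfiguration, SampleSet, _require_valid

logger = logging.getLogger(__name__)

ArrayLike = Union[np.ndarray, LandmarkConfiguration]

#: convergence tolerance on consensus displacement and iteration cap
GPA_TOL = 1e-10
GPA_MAX_ITER = 100


def _as_points(a: ArrayLike) -> np.ndarray:
    if isinstance(a, LandmarkConfiguration):
        return a.points
    return np.asarray(a, dtype=float)


def centroid_size(c: ArrayLike) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid.

    Invariant to translation and rotation; scales linearly under uniform
    scaling.  Degenerate configurations (all landmarks coincident) raise.
    """
    pts = _as_points(c)
    centred = pts - pts.mean(axis=0)
    cs = float(np.sqrt(np.sum(centred**2)))
    if cs <= 0.0 or not np.isfinite(cs):
        raise ValueError("degenerate configuration: zero centroid size")
    return cs


def optimal_rotation(a: ArrayLike, b: ArrayLike) -> np.ndarray:
    """Proper rotation R (2x2, det=+1) minimizing ||a - b R||_F.

    Both shapes must be centred.  Solved by the Kabsch construction with the
    determinant correction, so a reflection is never returned even when it
    would fit better.
    """
    A = _as_points(a)
    B = _as_points(b)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    H = B.T @ A  # cross-covariance; maximize tr(R^T H)
    if not np.isfinite(H).all() or np.linalg.matrix_rank(H) == 0:
        raise ValueError("degenerate cross-covariance between shapes")
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, d]) @ Vt
    return R


def procrustes_distance(a: ArrayLike, b: ArrayLike) -> float:
    """Full Procrustes distance: residual after translation, scale and rotation.

    Zero iff the shapes are similarity-equivalent (reflections excluded).
    """
    A = _as_points(a).astype(float)
    B = _as_points(b).astype(float)
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    A = A / centroid_size(A)
    B = B / centroid_size(B)
    R = optimal_rotation(A, B)
    return float(np.linalg.norm(A - B @ R))


@dataclass
class AlignedSet:
    """GPA output: tangent-space coordinates plus alignment bookkeeping."""

    tangent_coordinates: np.ndarray  # (n_wings, 38)
    consensus: np.ndarray  # (19, 2), centred, unit centroid size
    centroid_sizes: np.ndarray  # (n_wings,), original pixel units
    ln_centroid_sizes: np.ndarray  # (n_wings,)
    wing_index: list[tuple[str, str]]  # row -> (sample_id, wing_id)
    iterations_used: int
    converged: bool

    @property
    def n_wings(self) -> int:
        return self.tangent_coordinates.shape[0]

    def sample_means(self) -> "tuple[np.ndarray, list[str]]":
        """Average tangent coordinates within samples (colony means).

        Returns the (n_samples, 38) matrix and the sample ids in first-seen
        order — the unit of all colony-level analyses.
        """
        order: list[str] = []
        rows: dict[str, list[int]] = {}
        for i, (sid, _) in enumerate(self.wing_index):
            if sid not in rows:
                rows[sid] = []
                order.append(sid)
            rows[sid].append(i)
        means = np.vstack(
            [self.tangent_coordinates[rows[sid]].mean(axis=0) for sid in order]
        )
        return means, order

    def sample_mean_ln_cs(self) -> "tuple[np.ndarray, list[str]]":
        order: list[str] = []
        rows: dict[str, list[int]] = {}
        for i, (sid, _) in enumerate(self.wing_index):
            rows.setdefault(sid, []).append(i)
            if sid not in order:
                order.append(sid)
        vals = np.array([self.ln_centroid_sizes[rows[sid]].mean() for sid in order])
        return vals, order


def _complex(x: np.ndarray) -> np.ndarray:
    return x[..., 0] + 1j * x[..., 1]


def _canonical_rotation(w_pts: np.ndarray) -> np.ndarray:
    """Proper rotation taking a centred shape to its principal-axis frame."""
    M = w_pts.T @ w_pts
    _, evecs = np.linalg.eigh(M)
    R = evecs[:, ::-1].copy()  # major axis first
    if np.linalg.det(R) < 0:
        R[:, 1] *= -1.0
    cand = w_pts @ R
    skew = np.sum(cand[:, 0] ** 3)
    if skew == 0.0:
        skew = np.sum(cand[:, 1] ** 3)
    if skew < 0:
        R = -R  # rotate by a further half turn (still det +1)
    return R


def _rotate_to(z: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Rotate each row of z (n, k complex) to best fit consensus w (k,)."""
    s = np.sum(np.conj(z) * w[None, :], axis=1)
    theta = np.angle(s)
    return z * np.exp(1j * theta)[:, None]


def gpa(
    samples: Union[SampleSet, np.ndarray],
    mirror_left: bool = True,
    tol: float = GPA_TOL,
    max_iter: int = GPA_MAX_ITER,
    validate: bool = True,
) -> AlignedSet:
    """Generalized Procrustes superimposition of a set of wings.

    Accepts a :class:`SampleSet` or a raw ``(n, k, 2)`` array (then all
    wings are treated as right wings of one anonymous sample).  Left wings
    are mirrored (x -> -x) before alignment when ``mirror_left`` is on.

    The algorithm is deterministic: the first wing initializes the
    consensus, each iteration rotates all unit-size centred configurations
    to the consensus and re-estimates it, until the consensus moves by less
    than ``tol`` (or ``max_iter`` is hit, flagged via ``converged=False``).
    Finally every aligned configuration is projected orthogonally onto the
    tangent plane at the consensus.
    """
    if isinstance(samples, SampleSet):
        wings = []
        sides = []
        index = []
        for s, cfg in samples.iter_wings():
            if validate:
                _require_valid(cfg)
            wings.append(cfg.points)
            sides.append(cfg.side)
            index.append((s.sample_id, cfg.wing_id))
        X = np.asarray(wings, dtype=float)
    else:
        X = np.asarray(samples, dtype=float)
        if X.ndim != 3 or X.shape[-1] != 2:
            raise ValueError(f"expected (n, k, 2) array, got {X.shape}")
        sides = ["right"] * X.shape[0]
        index = [("sample", f"wing{i}") for i in range(X.shape[0])]

    n = X.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least 2 wings")

    X = X.copy()
    if mirror_left:
        left = np.array([s == "left" for s in sides])
        X[left, :, 0] *= -1.0

    z = _complex(X)
    z = z - z.mean(axis=1, keepdims=True)
    cs = np.sqrt(np.sum(np.abs(z) ** 2, axis=1))
    if np.any(cs <= 0):
        bad = int(np.argmin(cs))
        raise ValueError(f"degenerate wing at row {bad}: zero centroid size")
    z = z / cs[:, None]

    w = z[0].copy()
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        z_rot = _rotate_to(z, w)
        w_new = z_rot.mean(axis=0)
        w_new = w_new - w_new.mean()
        w_new = w_new / np.sqrt(np.sum(np.abs(w_new) ** 2))
        # remove rotational drift of the consensus itself
        s = np.sum(np.conj(w_new) * w)
        w_new = w_new * np.exp(1j * np.angle(s))
        delta = np.sqrt(np.sum(np.abs(w_new - w) ** 2))
        w = w_new
        z = z_rot
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("GPA did not converge in %d iterations", max_iter)

    z = _rotate_to(z, w)

    # Canonical orientation: the consensus orientation would otherwise be an
    # arbitrary gauge inherited from the first wing.  Rotate everything so
    # the consensus lies along its principal axes, with the sign fixed by
    # the x-skewness of its landmarks (generic shapes only; exact ties
    # would leave the gauge to floating-point luck, which wing data never
    # exhibits).
    w_pts = np.stack([w.real, w.imag], axis=-1)
    Rc = _canonical_rotation(w_pts)
    w_pts = w_pts @ Rc
    pts = np.stack([z.real, z.imag], axis=-1) @ Rc
    w = _complex(w_pts)

    aligned = pts.reshape(n, -1)
    c = w_pts.reshape(-1)
    # orthogonal projection onto the tangent plane {t : t . c = 1} at c
    tangent = aligned - np.outer(aligned @ c, c) + c

    return AlignedSet(
        tangent_coordinates=tangent,
        consensus=np.stack([w.real, w.imag], axis=-1),
        centroid_sizes=cs,
        ln_centroid_sizes=np.log(cs),
        wing_index=index,
        iterations_used=iterations,
        converged=converged,
    )


def align_to_reference(
    points: np.ndarray, consensus: np.ndarray
) -> np.ndarray:
    """Superimpose one configuration on a fixed consensus; tangent coords.

    Centres, scales to unit centroid size, rotates to the consensus and
    projects onto the tangent plane at it.  Used when classifying new wings
    against a stored reference alignment.
    """
    pts = np.asarray(points, dtype=float)
    pts = pts - pts.mean(axis=0)
    pts = pts / centroid_size(pts)
    R = optimal_rotation(consensus, pts)
    aligned = (pts @ R).reshape(-1)
    c = np.asarray(consensus, dtype=float).reshape(-1)
    c = c / np.linalg.norm(c)
    return aligned - (aligned @ c) * c + c
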