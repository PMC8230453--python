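"""Shape-space statistics: PCA, group models, CVA, Mahalanobis, LDA, LOO.

The tangent coordinates produced by GPA live in a 34-dimensional subspace
of the 38 raw variables.  PCA re-expresses them on an orthonormal basis
("wing shape" = the 34 PC scores).  Group structure is modelled by group
mean vectors plus a single pooled within-group covariance (df = N - g),
which underlies canonical variate analysis, squared Mahalanobis distances
between groups, and the linear discriminant classifier.  Classification
accuracy is estimated by leave-one-out cross-validation over colony-level
units.

Singular pooled covariances (tiny groups, reduced dimension) are handled by
an eigenvalue-thresholded pseudo-inverse (relative tolerance 1e-8) and
flagged rather than refused.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .superimpose import AlignedSet

logger = logging.getLogger(__name__)

#: relative eigenvalue tolerance for pseudo-inversion of singular covariances
PINV_RTOL = 1e-8


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class ShapeSpace:
    """Principal component basis of tangent coordinates."""

    mean_vector: np.ndarray  # (d,)
    basis: np.ndarray  # (d, k), orthonormal columns
    eigenvalues: np.ndarray  # (k,), descending
    scores: np.ndarray  # (n, k)

    @property
    def k(self) -> int:
        return self.basis.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new observations (rows of d variables) onto the basis."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean_vector) @ self.basis


def pca(aligned: Union[AlignedSet, np.ndarray], k: int = 34) -> ShapeSpace:
    """Eigendecomposition of the covariance of tangent coordinates.

    ``aligned`` may be an :class:`AlignedSet` or any (n, d) matrix (e.g.
    colony means).  Retains the top ``k`` components; if ``k`` exceeds the
    numerical rank available from the data it is truncated with a warning.
    Eigenvalues are clipped at zero and returned in descending order.
    """
    X = aligned.tangent_coordinates if isinstance(aligned, AlignedSet) else np.asarray(aligned, dtype=float)
    n, d = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 observations")
    mean = X.mean(axis=0)
    C = np.cov(X - mean, rowvar=False, ddof=1)
    evals, evecs = scipy.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    max_rank = min(n - 1, d)
    if k > max_rank:
        warnings.warn(
            f"requested k={k} exceeds available rank {max_rank}; truncating",
            stacklevel=2,
        )
        k = max_rank
    k = min(k, d)
    basis = evecs[:, :k]
    return ShapeSpace(
        mean_vector=mean,
        basis=basis,
        eigenvalues=evals[:k],
        scores=(X - mean) @ basis,
    )


def significant_dimensions(space: ShapeSpace, rel_tol: float = 1e-9) -> int:
    """Number of eigenvalues above ``rel_tol`` times the largest."""
    ev = space.eigenvalues
    if ev.size == 0 or ev[0] <= 0:
        return 0
    return int(np.sum(ev > rel_tol * ev[0]))


# ---------------------------------------------------------------------------
# Group model
# ---------------------------------------------------------------------------

@dataclass
class GroupModel:
    """Group means plus pooled within-group covariance in score space."""

    labels: list  # group labels, fixed order
    means: np.ndarray  # (g, k)
    pooled_covariance: np.ndarray  # (k, k)
    df: int  # N - g
    counts: np.ndarray  # (g,)
    priors: np.ndarray  # (g,), equal by default
    singular: bool = False
    _pinv: np.ndarray = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return self.means.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    @property
    def pooled_inverse(self) -> np.ndarray:
        if self._pinv is None:
            object.__setattr__(self, "_pinv", _safe_inverse(self.pooled_covariance))
        return self._pinv

    def index_of(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown group {label!r}") from None


def _safe_inverse(S: np.ndarray) -> np.ndarray:
    """Inverse, falling back to an eigenvalue-thresholded pseudo-inverse."""
    ev = scipy.linalg.eigvalsh(S)
    if ev.min() > PINV_RTOL * max(ev.max(), 0) and ev.min() > 0:
        return scipy.linalg.inv(S)
    logger.info("singular pooled covariance; using pseudo-inverse (rtol=%g)", PINV_RTOL)
    return scipy.linalg.pinvh(S, rtol=PINV_RTOL)


def fit_groups(
    scores: np.ndarray,
    labels: Sequence,
    priors: Optional[np.ndarray] = None,
) -> GroupModel:
    """Fit per-group means and the pooled within-group covariance.

    Pooled covariance = sum of within-group squared deviations / (N - g);
    a numerically singular result is flagged (``singular=True``) and later
    inverted by pseudo-inverse.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = list(labels)
    if X.shape[0] != len(labels):
        raise ValueError("scores and labels length mismatch")
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    n, k = X.shape
    g = len(uniq)
    if n - g < 1:
        raise ValueError("N - g must be >= 1")
    lab = np.asarray(labels, dtype=object)
    means = np.empty((g, k))
    counts = np.empty(g, dtype=int)
    W = np.zeros((k, k))
    for i, u in enumerate(uniq):
        rows = X[lab == u]
        if rows.shape[0] == 0:
            raise ValueError(f"group {u!r} has no observations")
        counts[i] = rows.shape[0]
        means[i] = rows.mean(axis=0)
        R = rows - means[i]
        W += R.T @ R
    pooled = W / (n - g)
    ev = scipy.linalg.eigvalsh(pooled)
    singular = bool(ev.min() <= PINV_RTOL * max(ev.max(), 0.0))
    if priors is None:
        priors = np.full(g, 1.0 / g)
    return GroupModel(
        labels=uniq,
        means=means,
        pooled_covariance=pooled,
        df=n - g,
        counts=counts,
        priors=np.asarray(priors, dtype=float),
        singular=singular,
    )


def mahalanobis_sq(
    model: GroupModel, g1, g2, unbiased: bool = False
) -> float:
    """Squared Mahalanobis distance between two group means.

    D^2 = (mu1 - mu2)^T S^-1 (mu1 - mu2) with S the pooled within-group
    covariance.  The plain estimator is positively biased in small samples;
    ``unbiased=True`` applies the classical correction
    (df - k - 1)/df * D^2 - k (1/n1 + 1/n2), clipped at zero.
    """
    i, j = model.index_of(g1), model.index_of(g2)
    if i == j:
        return 0.0
    d = model.means[i] - model.means[j]
    d2 = float(d @ model.pooled_inverse @ d)
    if unbiased:
        k = model.k
        n1, n2 = model.counts[i], model.counts[j]
        d2 = max(0.0, (model.df - k - 1) / model.df * d2 - k * (1 / n1 + 1 / n2))
    return d2


def mahalanobis_sq_point(model: GroupModel, x: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distance of one observation to every group mean."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.k,):
        raise ValueError(f"expected score vector of length {model.k}, got {x.shape}")
    diff = model.means - x
    return np.einsum("gi,ij,gj->g", diff, model.pooled_inverse, diff)


# ---------------------------------------------------------------------------
# CVA
# ---------------------------------------------------------------------------

@dataclass
class CVAResult:
    """Canonical variate analysis output."""

    labels: list
    canonical_axes: np.ndarray  # (k, n_axes)
    canonical_eigenvalues: np.ndarray  # (n_axes,), descending
    scores: np.ndarray  # (n, n_axes) observation scores on canonical axes
    squared_mahalanobis: pd.DataFrame  # (g, g), symmetric, zero diagonal
    pairwise_p: pd.DataFrame  # (g, g) Hotelling T^2 -> F p-values


def hotelling_pairwise_p(model: GroupModel, g1, g2) -> float:
    """Two-group mean comparison via Hotelling's T^2 with the F transform.

    Uses the pooled covariance over all groups (df = N - g).  Returns the
    p-value of F = T^2 (df - k + 1) / (df k) on (k, df - k + 1) df.
    """
    i, j = model.index_of(g1), model.index_of(g2)
    n1, n2 = model.counts[i], model.counts[j]
    d2 = mahalanobis_sq(model, g1, g2)
    t2 = (n1 * n2) / (n1 + n2) * d2
    k, nu = model.k, model.df
    if nu - k + 1 <= 0:
        return float("nan")
    f = t2 * (nu - k + 1) / (nu * k)
    return float(scipy.stats.f.sf(f, k, nu - k + 1))


def cva(model: GroupModel, scores: np.ndarray, labels: Sequence) -> CVAResult:
    """Canonical variate analysis on a fitted group model.

    Solves the between-group vs pooled within-group generalized
    eigenproblem (via whitening with an eigenvalue-thresholded inverse
    square root, so singular within-matrices are tolerated), returning at
    most min(g - 1, k) canonical axes sorted by eigenvalue, observation
    scores, the full pairwise squared-Mahalanobis matrix and pairwise
    Hotelling significance.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    lab = np.asarray(list(labels), dtype=object)
    g = model.n_groups
    k = model.k

    grand = np.average(model.means, axis=0, weights=model.counts)
    B = np.zeros((k, k))
    for i in range(g):
        d = model.means[i] - grand
        B += model.counts[i] * np.outer(d, d)
    B /= max(g - 1, 1)

    W = model.pooled_covariance
    ew, Vw = scipy.linalg.eigh(W)
    keep = ew > PINV_RTOL * max(ew.max(), 0.0)
    if not keep.all():
        logger.info(
            "singular within-group matrix in CVA: %d of %d dimensions kept "
            "(rtol=%g)", int(keep.sum()), k, PINV_RTOL,
        )
    T = Vw[:, keep] / np.sqrt(ew[keep])  # whitening map, (k, r)
    M = T.T @ B @ T
    em, Um = scipy.linalg.eigh(M)
    order = np.argsort(em)[::-1]
    n_axes = min(g - 1, int(keep.sum()))
    em = np.clip(em[order][:n_axes], 0.0, None)
    axes = (T @ Um[:, order])[:, :n_axes]  # columns: a^T W a = 1

    d2 = np.zeros((g, g))
    pv = np.full((g, g), np.nan)
    for i in range(g):
        for j in range(i + 1, g):
            d2[i, j] = d2[j, i] = mahalanobis_sq(model, model.labels[i], model.labels[j])
            pv[i, j] = pv[j, i] = hotelling_pairwise_p(model, model.labels[i], model.labels[j])

    return CVAResult(
        labels=list(model.labels),
        canonical_axes=axes,
        canonical_eigenvalues=em,
        scores=(X - grand) @ axes,
        squared_mahalanobis=pd.DataFrame(d2, index=model.labels, columns=model.labels),
        pairwise_p=pd.DataFrame(pv, index=model.labels, columns=model.labels),
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def lda_classify(model: GroupModel, x: np.ndarray) -> tuple[object, dict]:
    """Assign x to the group with the smallest squared Mahalanobis distance.

    Equal priors.  Returns the label and a posterior-like score per group
    (softmax of -D^2/2, normalized).  Exact ties are broken by group order
    with a logged warning.
    """
    d2 = mahalanobis_sq_point(model, x)
    best = int(np.argmin(d2))
    ties = np.flatnonzero(np.abs(d2 - d2[best]) < 1e-12)
    if ties.size > 1:
        logger.warning(
            "classification tie between groups %s; choosing %r",
            [model.labels[t] for t in ties], model.labels[best],
        )
        best = int(ties[0])
    logp = -0.5 * (d2 - d2.min())
    post = np.exp(logp)
    post /= post.sum()
    return model.labels[best], dict(zip(model.labels, post))


def loo_cross_validation(
    scores: np.ndarray,
    labels: Sequence,
    unit_ids: Optional[Sequence[str]] = None,
) -> tuple[float, pd.DataFrame]:
    """Leave-one-out cross-validated classification rate over units.

    Each row is one colony-level unit.  For every unit the group model
    (means + pooled covariance) is refitted without it and the unit is
    classified; the rate is 100 * correct / classified.  A unit whose
    removal would empty its group is skipped with a warning.  Returns the
    rate and a per-unit table (unit_id, true, predicted, correct).
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    lab = list(labels)
    n = X.shape[0]
    if unit_ids is None:
        unit_ids = [f"unit{i}" for i in range(n)]
    counts: dict = {}
    for l in lab:
        counts[l] = counts.get(l, 0) + 1

    records = []
    correct = 0
    total = 0
    idx = np.arange(n)
    for i in range(n):
        if counts[lab[i]] <= 1:
            logger.warning(
                "unit %s skipped in LOO: its group %r would be empty",
                unit_ids[i], lab[i],
            )
            records.append(
                {"unit_id": unit_ids[i], "true": lab[i], "predicted": None,
                 "correct": None}
            )
            continue
        keep = idx != i
        model = fit_groups(X[keep], [lab[j] for j in range(n) if j != i])
        pred, _ = lda_classify(model, X[i])
        ok = pred == lab[i]
        correct += int(ok)
        total += 1
        records.append(
            {"unit_id": unit_ids[i], "true": lab[i], "predicted": pred,
             "correct": bool(ok)}
        )
    if total == 0:
        raise ValueError("no unit could be cross-validated")
    rate = 100.0 * correct / total
    return rate, pd.DataFrame(records)


def loo_cross_validation_refit_pca(
    tangent_means: np.ndarray,
    labels: Sequence,
    unit_ids: Optional[Sequence[str]] = None,
    k: int = 34,
) -> tuple[float, pd.DataFrame]:
    """LOO variant refitting the PCA basis inside every fold.

    More expensive and usually indistinguishable from the fixed-basis
    protocol of :func:`loo_cross_validation` (the basis change is rank-
    preserving and Mahalanobis classification is affine-invariant up to
    the truncation), but exposed because published workflows differ on it.
    Operates on colony-mean tangent coordinates rather than scores.
    """
    X = np.atleast_2d(np.asarray(tangent_means, dtype=float))
    lab = list(labels)
    n = X.shape[0]
    if unit_ids is None:
        unit_ids = [f"unit{i}" for i in range(n)]
    counts: dict = {}
    for l in lab:
        counts[l] = counts.get(l, 0) + 1
    records = []
    correct = 0
    total = 0
    for i in range(n):
        if counts[lab[i]] <= 1:
            logger.warning("unit %s skipped in LOO: group would be empty", unit_ids[i])
            records.append({"unit_id": unit_ids[i], "true": lab[i],
                            "predicted": None, "correct": None})
            continue
        keep = np.arange(n) != i
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            space = pca(X[keep], k=min(k, n - 2))
        model = fit_groups(space.scores, [lab[j] for j in range(n) if j != i])
        pred, _ = lda_classify(model, space.transform(X[i])[0])
        ok = pred == lab[i]
        correct += int(ok)
        total += 1
        records.append({"unit_id": unit_ids[i], "true": lab[i],
                        "predicted": pred, "correct": bool(ok)})
    if total == 0:
        raise ValueError("no unit could be cross-validated")
    return 100.0 * correct / total, pd.DataFrame(records)
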