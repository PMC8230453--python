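"""Synthetic wing-landmark studies with known ground truth.

The study's raw wing data are not deposited, so every pipeline stage is
exercised on simulated studies whose statistical structure matches what
the analysis assumes:

* a 19-landmark template forewing (unit centroid size, cubital index
  calibrated to the intra-Carpathian value 2.75);
* group mean shapes displaced in the 34-dimensional tangent space at the
  template, constructed so that the *true* squared Mahalanobis separations
  under the configured within-group covariance hit requested targets
  exactly (classical-MDS construction, checked to 1e-10);
* a two-level hierarchy, colony effect + wing noise, both isotropic
  multivariate normal in tangent space;
* a size model (ln centroid size per group with a latitude slope) and a
  geography model (per-area latitude/longitude/altitude ranges,
  temperature = intercept + lapse x altitude + noise, calibrated so the
  temperature-altitude correlation is about -0.93);
* similarity nuisance transforms (rotation, scale, translation, left-wing
  mirroring) applied last, so superimposition is genuinely tested.

All randomness flows through one ``numpy.random.Generator``; a fixed seed
reproduces a study bitwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .landmark_io import LandmarkConfiguration, Sample, SampleSet, N_LANDMARKS
from .superimpose import centroid_size
from .traits import CubitalIndexConvention, IDENTIFLY_19

TANGENT_DIM = 2 * N_LANDMARKS - 4  # 38 - translation(2) - scale(1) - rotation(1)

#: seed of the packaged deterministic reference fixture
DEFAULT_FIXTURE_SEED = 1982

# Hand-laid template landmark positions (mm) loosely following a worker
# forewing venation layout: proximal landmarks left, wing tip right, the
# cubital cell in the posterior half.  Anatomical fidelity is not claimed;
# what matters is a generic, non-degenerate configuration whose vein
# convention supports the cubital index.
_TEMPLATE_MM = np.array([
    [0.30, 1.60], [1.30, 2.10], [2.60, 2.50], [4.00, 2.70], [5.40, 2.80],
    [6.60, 2.60], [2.20, 1.80], [3.40, 2.10], [4.60, 2.25], [5.80, 2.20],
    [2.90, 1.30], [4.10, 1.50], [5.20, 1.60], [6.30, 1.70], [7.60, 1.90],
    [3.60, 0.70], [4.80, 0.90], [5.50, 0.55], [6.90, 0.80],
])


def default_template(
    cubital_index: float = 2.75,
    conv: CubitalIndexConvention = IDENTIFLY_19,
) -> np.ndarray:
    """The centred, unit-centroid-size template wing.

    The endpoint of the second cubital vein is placed along its nominal
    direction so the template's cubital index equals ``cubital_index``
    exactly.
    """
    pts = _TEMPLATE_MM.copy()
    a0, a1 = conv.vein_a
    b0, b1 = conv.vein_b
    len_a = np.linalg.norm(pts[a1] - pts[a0])
    direction = pts[b1] - pts[b0]
    direction = direction / np.linalg.norm(direction)
    pts[b1] = pts[b0] + direction * (len_a / cubital_index)
    pts = pts - pts.mean(axis=0)
    return pts / centroid_size(pts)


def tangent_basis(shape: np.ndarray) -> np.ndarray:
    """Orthonormal basis (38 x 34) of the tangent space at a shape.

    The tangent space is the orthogonal complement of the four similarity
    directions at the (centred, unit-size) shape: x-translation,
    y-translation, scaling (the shape itself) and infinitesimal rotation
    (the shape rotated 90 degrees).
    """
    s = np.asarray(shape, dtype=float)
    k = s.shape[0]
    flat = s.reshape(-1)
    tx = np.tile([1.0, 0.0], k) / math.sqrt(k)
    ty = np.tile([0.0, 1.0], k) / math.sqrt(k)
    scale = flat / np.linalg.norm(flat)
    rot = np.stack([-s[:, 1], s[:, 0]], axis=1).reshape(-1)
    rot = rot / np.linalg.norm(rot)
    sim = np.stack([tx, ty, scale, rot])
    basis = scipy.linalg.null_space(sim)
    assert basis.shape == (2 * k, 2 * k - 4)
    return basis


# ---------------------------------------------------------------------------
# Offset construction
# ---------------------------------------------------------------------------

def make_group_offsets(
    target_d2: np.ndarray,
    within_sd: float = 1.0,
    dim: int = TANGENT_DIM,
    fixed_directions: Optional[np.ndarray] = None,
    fixed_components: Optional[np.ndarray] = None,
    tol: float = 1e-9,
) -> np.ndarray:
    """Group mean offsets realizing target squared Mahalanobis separations.

    Under an isotropic within-group covariance ``within_sd**2 * I``, the
    squared Mahalanobis distance between groups g and h is
    ``|o_g - o_h|^2 / within_sd^2``, so offsets are a classical
    multidimensional scaling embedding of the target matrix, scaled by
    ``within_sd``.  An infeasible target set (the matrix is not Euclidean-
    embeddable, e.g. triangle violations) raises ``ValueError``.

    ``fixed_directions`` (an orthonormal ``(dim, m)`` block) together with
    ``fixed_components`` ``(g, m)`` pin each group's offset inside that
    subspace — used to overlay trait differences such as the cubital index
    at prescribed absolute positions.  The remaining separation is embedded
    in the orthogonal complement, so the targets stay exact.  Shape of the
    result: ``(g, dim)``; the construction is deterministic.
    """
    D = np.asarray(target_d2, dtype=float)
    g = D.shape[0]
    if D.shape != (g, g) or not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("target_d2 must be a symmetric hollow matrix")
    if np.any(D < 0):
        raise ValueError("squared distances must be nonnegative")
    if within_sd == 0.0:
        if np.any(D != 0):
            raise ValueError(
                "nonzero separation targets are unreachable with zero "
                "within-group variation"
            )
        return np.zeros((g, dim))

    if fixed_directions is not None:
        U = np.atleast_2d(np.asarray(fixed_directions, dtype=float))
        if U.shape[0] != dim:
            U = U.T
        if not np.allclose(U.T @ U, np.eye(U.shape[1]), atol=1e-10):
            raise ValueError("fixed_directions must be orthonormal columns")
        C = np.atleast_2d(np.asarray(fixed_components, dtype=float))
        if C.shape != (g, U.shape[1]):
            raise ValueError(f"fixed_components must be ({g}, {U.shape[1]})")
        D_fixed = _pairwise_sq(C) / within_sd**2
        D_red = D - D_fixed
        off = D_red[~np.eye(g, dtype=bool)]
        if off.size and off.min() < -tol * max(D.max(), 1.0):
            raise ValueError(
                "fixed components exceed the target separations; infeasible"
            )
        D_red = np.clip(D_red, 0.0, None)
        np.fill_diagonal(D_red, 0.0)
        comp = scipy.linalg.null_space(U.T)  # (dim, dim - m)
        red = _mds_embed(D_red, tol)
        if red.shape[1] > comp.shape[1]:
            raise ValueError("embedding dimension exceeds available space")
        offsets = C @ U.T + within_sd * red @ comp[:, : red.shape[1]].T
    else:
        emb = _mds_embed(D, tol)
        if emb.shape[1] > dim:
            raise ValueError(
                f"targets need {emb.shape[1]} dimensions, only {dim} available"
            )
        offsets = np.zeros((g, dim))
        offsets[:, : emb.shape[1]] = within_sd * emb

    realized = _pairwise_sq(offsets) / within_sd**2
    scale = max(D.max(), 1.0)
    if not np.allclose(realized, D, atol=1e-8 * scale):
        raise AssertionError("offset construction failed to reproduce targets")
    return offsets


def _mds_embed(D: np.ndarray, tol: float) -> np.ndarray:
    """Classical MDS: coordinates whose squared distances reproduce D."""
    g = D.shape[0]
    J = np.eye(g) - np.ones((g, g)) / g
    G = -0.5 * J @ D @ J
    w, V = scipy.linalg.eigh(G)
    scale = max(abs(w).max(), 1.0)
    if w.min() < -1e-8 * scale:
        raise ValueError(
            "target squared-distance matrix is not Euclidean-embeddable "
            f"(most negative Gram eigenvalue {w.min():.3g})"
        )
    keep = w > 1e-12 * scale
    return V[:, keep] * np.sqrt(w[keep])


def _pairwise_sq(X: np.ndarray) -> np.ndarray:
    d = X[:, None, :] - X[None, :, :]
    return np.sum(d**2, axis=-1)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class Geography:
    """Sampling box and altitude model of one collection area."""

    lat_range: tuple[float, float]
    lon_range: tuple[float, float]
    alt_mean: float
    alt_sd: float
    alt_min: float = 0.0


DEFAULT_GEOGRAPHY = {
    "intra": Geography((45.8, 48.0), (21.5, 25.0), 550.0, 150.0, 150.0),
    "extra": Geography((43.7, 46.3), (23.0, 28.3), 250.0, 130.0, 10.0),
    "carnica": Geography((45.8, 46.4), (14.0, 15.5), 400.0, 100.0, 100.0),
    "macedonica": Geography((40.8, 41.8), (21.5, 23.0), 300.0, 100.0, 50.0),
}


@dataclass
class GroupSpec:
    """One simulated group of colonies."""

    label: str
    n_colonies: int
    area: str = "intra"  # "intra" | "extra" | "reference"
    period: str = "post2000"
    source: str = "colony"  # "colony" | "flowers"
    reference_taxon: Optional[str] = None
    geography: Optional[str] = None  # key into the geography table
    ln_cs_mean: float = 6.48
    cubital_index: Optional[float] = None  # None -> template value
    wings_mean: float = 30.0
    flowers_fraction: float = 0.0  # per-colony probability of a flower sample

    def __post_init__(self) -> None:
        if self.n_colonies < 1:
            raise ValueError(f"group {self.label}: n_colonies must be >= 1")
        if self.area == "reference" and not self.reference_taxon:
            raise ValueError(f"group {self.label}: reference area needs a taxon")


@dataclass
class SyntheticConfig:
    """Full description of a simulated study (the generator's stated world).

    Shape noise is expressed per tangent-space coordinate: the colony
    effect (between-colony sd 0.004) and wing noise (within-colony sd
    0.006) are on the scale of Procrustes-aligned unit-size coordinates,
    giving within-group variation of the magnitude typical for honey bee
    wing studies.  ``target_d2`` places group means at exact true squared
    Mahalanobis separations under the colony-mean covariance.
    """

    groups: list[GroupSpec]
    target_d2: Optional[np.ndarray] = None
    explicit_offsets: Optional[np.ndarray] = None
    colony_effect_sd: float = 0.004
    wing_noise_sd: float = 0.006
    wings_distribution: str = "poisson"  # "poisson" | "fixed"
    min_wings: int = 5
    size_colony_sd: float = 0.02
    size_wing_sd: float = 0.015
    lat_slope: float = 0.008  # ln CS per degree latitude, about 46 N
    reference_latitude: float = 46.0
    temp_intercept: float = 11.3  # deg C at sea level
    temp_lapse: float = -0.0065  # deg C per metre altitude
    temp_sd: float = 0.45
    resolution_dpi: float = 2400.0
    translation_range: float = 3000.0  # pixels
    base_cubital_index: float = 2.75
    convention: CubitalIndexConvention = IDENTIFLY_19
    geography: dict = field(default_factory=lambda: dict(DEFAULT_GEOGRAPHY))

    def __post_init__(self) -> None:
        for name in ("colony_effect_sd", "wing_noise_sd", "size_colony_sd",
                     "size_wing_sd", "temp_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels")
        if self.target_d2 is not None:
            self.target_d2 = np.asarray(self.target_d2, dtype=float)
            if self.target_d2.shape != (len(self.groups),) * 2:
                raise ValueError("target_d2 must be (g, g)")
        if self.wings_distribution not in ("poisson", "fixed"):
            raise ValueError("wings_distribution must be 'poisson' or 'fixed'")


@dataclass
class SimulationTruth:
    """Ground-truth parameters of a simulated study."""

    labels: list[str]
    offsets: np.ndarray  # (g, 34) true tangent-space group means
    colony_mean_sd: float  # sd of colony means per tangent coordinate
    true_d2: pd.DataFrame  # (g, g) true squared Mahalanobis separations
    template: np.ndarray  # (19, 2)
    basis: np.ndarray  # (38, 34)


def _mean_inverse_wings(cfg: SyntheticConfig, mu: float) -> float:
    """E[1/n] for the wings-per-colony distribution (Poisson truncated below)."""
    if cfg.wings_distribution == "fixed":
        return 1.0 / round(mu)
    lo = cfg.min_wings
    hi = int(mu + 10 * math.sqrt(mu) + 20)
    ns = np.arange(lo, hi)
    pmf = scipy.stats.poisson.pmf(ns, mu)
    pmf = pmf / pmf.sum()
    return float(np.sum(pmf / ns))


def colony_mean_sd(cfg: SyntheticConfig) -> float:
    """Per-coordinate sd of colony mean tangent coordinates.

    Colony means carry the colony effect plus averaged wing noise; the
    wing-noise contribution uses E[1/n] under the configured wings-per-
    colony distribution, weighted over groups by colony count.
    """
    weights = np.array([g.n_colonies for g in cfg.groups], dtype=float)
    einv = np.array([_mean_inverse_wings(cfg, g.wings_mean) for g in cfg.groups])
    mean_einv = float(np.average(einv, weights=weights))
    return math.sqrt(cfg.colony_effect_sd**2 + cfg.wing_noise_sd**2 * mean_einv)


def _vein_gradients(
    template: np.ndarray, basis: np.ndarray, conv: CubitalIndexConvention
) -> tuple[np.ndarray, np.ndarray]:
    """Tangent-space gradients of the two cubital vein lengths."""
    grads = []
    for i0, i1 in (conv.vein_a, conv.vein_b):
        u = template[i1] - template[i0]
        u = u / np.linalg.norm(u)
        d = np.zeros(template.size)
        d[2 * i1 : 2 * i1 + 2] = u
        d[2 * i0 : 2 * i0 + 2] = -u
        grads.append(basis.T @ d)
    return grads[0], grads[1]


def _ci_inflation(
    template: np.ndarray,
    basis: np.ndarray,
    conv: CubitalIndexConvention,
    sigma_total: float,
    len_b: float,
) -> float:
    """Second-order inflation of E[cubital index] under landmark noise.

    The index is a ratio of two vein lengths; isotropic tangent-space noise
    of per-coordinate sd ``sigma_total`` makes the expected ratio exceed
    the ratio of expected lengths (the denominator vein is short), by a
    delta-method factor computed from the noise covariance of the two vein
    difference vectors.  Used to pre-compensate group index targets so the
    realized per-wing mean hits the target.
    """
    P = basis @ basis.T  # coordinate covariance / sigma^2
    a0, a1 = conv.vein_a
    b0, b1 = conv.vein_b

    def diff_cov(i0, i1, j0, j1):
        # Cov(x_{i1}-x_{i0}, x_{j1}-x_{j0}), 2x2 block
        out = np.empty((2, 2))
        for r in range(2):
            for c in range(2):
                out[r, c] = (
                    P[2 * i1 + r, 2 * j1 + c] - P[2 * i1 + r, 2 * j0 + c]
                    - P[2 * i0 + r, 2 * j1 + c] + P[2 * i0 + r, 2 * j0 + c]
                )
        return sigma_total**2 * out

    da = template[a1] - template[a0]
    La = np.linalg.norm(da)
    ua = da / La
    # denominator vein at its group-target length, along the template direction
    db = template[b1] - template[b0]
    ub = db / np.linalg.norm(db)
    Lb = len_b
    Sa = diff_cov(a0, a1, a0, a1)
    Sb = diff_cov(b0, b1, b0, b1)
    Sab = diff_cov(a0, a1, b0, b1)
    perp_a = np.array([-ua[1], ua[0]])
    perp_b = np.array([-ub[1], ub[0]])
    var_perp_a = perp_a @ Sa @ perp_a
    var_perp_b = perp_b @ Sb @ perp_b
    var_par_b = ub @ Sb @ ub
    cov_par_ab = ua @ Sab @ ub
    return (
        1.0
        + var_perp_a / (2 * La**2)
        - var_perp_b / (2 * Lb**2)
        + var_par_b / Lb**2
        - cov_par_ab / (La * Lb)
    )


def group_offsets_for(cfg: SyntheticConfig) -> tuple[np.ndarray, float]:
    """Resolve the per-group tangent offsets and the colony-mean sd.

    Explicit offsets win; otherwise target separations are realized by
    :func:`make_group_offsets`.  Cubital-index targets (if any) are pinned
    exactly to first order: each group's offset carries a component inside
    the span of the two vein-length gradients that shifts the second vein
    length by exactly the amount the index target requires while leaving
    the first vein length unchanged, and the D^2 embedding is confined to
    the orthogonal complement so it cannot disturb either vein length.
    """
    sd = colony_mean_sd(cfg)
    g = len(cfg.groups)
    if cfg.explicit_offsets is not None:
        off = np.asarray(cfg.explicit_offsets, dtype=float)
        if off.shape != (g, TANGENT_DIM):
            raise ValueError(f"explicit_offsets must be ({g}, {TANGENT_DIM})")
        return off, sd
    if cfg.target_d2 is None:
        return np.zeros((g, TANGENT_DIM)), sd

    template = default_template(cfg.base_cubital_index, cfg.convention)
    basis = tangent_basis(template)
    ci_targets = [gr.cubital_index for gr in cfg.groups]
    if any(c is not None for c in ci_targets):
        a0, a1 = cfg.convention.vein_a
        b0, b1 = cfg.convention.vein_b
        len_a = np.linalg.norm(template[a1] - template[a0])
        len_b = np.linalg.norm(template[b1] - template[b0])
        g_a, g_b = _vein_gradients(template, basis, cfg.convention)
        Q, _ = np.linalg.qr(np.column_stack([g_a, g_b]))  # (34, 2) orthonormal
        M = np.vstack([g_a @ Q, g_b @ Q])  # constraint matrix in Q coords
        sigma_total = math.hypot(cfg.colony_effect_sd, cfg.wing_noise_sd)
        comps = np.empty((g, 2))
        for i, c in enumerate(ci_targets):
            if c is None:
                comps[i] = 0.0
                continue
            # pre-compensate for the noise inflation of the expected ratio
            f = _ci_inflation(template, basis, cfg.convention, sigma_total,
                              len_b=len_a / c)
            s = len_a * f / c - len_b
            comps[i] = np.linalg.solve(M, np.array([0.0, s]))
        offsets = make_group_offsets(
            cfg.target_d2, within_sd=sd,
            fixed_directions=Q, fixed_components=comps,
        )
    else:
        offsets = make_group_offsets(cfg.target_d2, within_sd=sd)
    return offsets, sd


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_study(
    cfg: SyntheticConfig,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    return_truth: bool = False,
):
    """Draw one synthetic study as a :class:`SampleSet`.

    Hierarchy: colony tangent mean = group offset + colony effect; wing =
    colony mean + wing noise, mapped back to 19-landmark coordinates and
    then rotated, scaled (the size model) and translated at random; half
    the wings are stored as left wings (mirrored).  Metadata (area, period,
    geography, temperature) is drawn from the geography model.  With a
    fixed seed the output is bitwise reproducible.

    Returns the sample set, or ``(sample_set, SimulationTruth)`` when
    ``return_truth`` is set.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    template = default_template(cfg.base_cubital_index, cfg.convention)
    basis = tangent_basis(template)
    offsets, sd = group_offsets_for(cfg)

    samples = []
    for gi, grp in enumerate(cfg.groups):
        geo = cfg.geography[grp.geography or grp.reference_taxon or grp.area]
        for ci in range(grp.n_colonies):
            sample_id = f"{grp.label}-c{ci:03d}"
            lat = rng.uniform(*geo.lat_range)
            lon = rng.uniform(*geo.lon_range)
            alt = max(geo.alt_min, rng.normal(geo.alt_mean, geo.alt_sd))
            temp = cfg.temp_intercept + cfg.temp_lapse * alt + rng.normal(0.0, cfg.temp_sd)

            is_flowers = grp.source == "flowers" or (
                grp.flowers_fraction > 0 and rng.random() < grp.flowers_fraction
            )
            if grp.period == "pre2000":
                year = int(rng.integers(1982, 1998))
            else:
                year = 2019 if is_flowers else 2016
            wings_mean = 39.1 if (is_flowers and grp.flowers_fraction > 0) else grp.wings_mean
            if cfg.wings_distribution == "fixed":
                n_wings = int(round(wings_mean))
            else:
                n_wings = max(cfg.min_wings, int(rng.poisson(wings_mean)))

            colony_mean = offsets[gi] + rng.normal(0.0, cfg.colony_effect_sd, TANGENT_DIM)
            colony_ln_cs = (
                grp.ln_cs_mean
                + cfg.lat_slope * (lat - cfg.reference_latitude)
                + rng.normal(0.0, cfg.size_colony_sd)
            )

            configs = []
            for wi in range(n_wings):
                v = colony_mean + rng.normal(0.0, cfg.wing_noise_sd, TANGENT_DIM)
                shape = template + (basis @ v).reshape(N_LANDMARKS, 2)
                shape = shape / centroid_size(shape)
                ln_cs = colony_ln_cs + rng.normal(0.0, cfg.size_wing_sd)
                theta = rng.uniform(-math.pi, math.pi)
                R = np.array([[math.cos(theta), -math.sin(theta)],
                              [math.sin(theta), math.cos(theta)]])
                pts = math.exp(ln_cs) * shape @ R.T
                side = "left" if rng.random() < 0.5 else "right"
                if side == "left":
                    pts = pts * np.array([-1.0, 1.0])
                pts = pts + rng.uniform(0.0, cfg.translation_range, 2)
                configs.append(
                    LandmarkConfiguration(
                        pts, wing_id=f"{sample_id}-w{wi:03d}", side=side,
                        resolution_dpi=cfg.resolution_dpi,
                    )
                )
            samples.append(
                Sample(
                    sample_id=sample_id,
                    configurations=configs,
                    source="flowers" if is_flowers else "colony",
                    year=year,
                    area=grp.area,
                    reference_taxon=grp.reference_taxon,
                    latitude=float(lat),
                    longitude=float(lon),
                    altitude=float(alt),
                    mean_annual_temperature=float(temp),
                )
            )

    sample_set = SampleSet(samples, provenance="simulate_study")
    if not return_truth:
        return sample_set
    labels = [g.label for g in cfg.groups]
    d2 = pd.DataFrame(
        _pairwise_sq(offsets) / sd**2, index=labels, columns=labels
    )
    truth = SimulationTruth(
        labels=labels, offsets=offsets, colony_mean_sd=sd, true_d2=d2,
        template=template, basis=basis,
    )
    return sample_set, truth


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

#: True squared Mahalanobis separations of the reference fixture, on the
#: scale documented for Carpathian honey bee area/period groups and the
#: two reference taxa of neighbouring subspecies.
FIXTURE_D2 = np.array([
    #  i<00    e<00    i>00    e>00    carn    maced
    [  0.00,   9.28,   6.92,  15.68,  81.03, 151.34],
    [  9.28,   0.00,  11.59,   7.79,  96.22, 135.31],
    [  6.92,  11.59,   0.00,   8.00,  85.33, 140.40],
    [ 15.68,   7.79,   8.00,   0.00, 104.45, 136.41],
    [ 81.03,  96.22,  85.33, 104.45,   0.00,  92.67],
    [151.34, 135.31, 140.40, 136.41,  92.67,   0.00],
])

FIXTURE_GROUPS = [
    GroupSpec("intra_pre", 52, area="intra", period="pre2000",
              ln_cs_mean=6.48, cubital_index=2.75, wings_mean=34.2),
    GroupSpec("extra_pre", 50, area="extra", period="pre2000",
              ln_cs_mean=6.44, cubital_index=2.67, wings_mean=34.2),
    GroupSpec("intra_post", 36, area="intra", period="post2000",
              ln_cs_mean=6.48, cubital_index=2.75, wings_mean=28.1,
              flowers_fraction=0.33),
    GroupSpec("extra_post", 59, area="extra", period="post2000",
              ln_cs_mean=6.44, cubital_index=2.67, wings_mean=28.1,
              flowers_fraction=0.33),
    GroupSpec("carnica", 15, area="reference", reference_taxon="A. m. carnica",
              geography="carnica", ln_cs_mean=6.49, cubital_index=2.46,
              wings_mean=20.0),
    GroupSpec("macedonica", 2, area="reference", reference_taxon="A. m. macedonica",
              geography="macedonica", ln_cs_mean=6.42, cubital_index=2.40,
              wings_mean=20.0),
]


def reference_fixture_config() -> SyntheticConfig:
    """Configuration of the packaged study-scale fixture.

    Two areas x two periods with colony counts 52/50/36/59 (197 Romanian
    samples) plus two reference taxa (15 and 2 colonies), true separations
    on the documented between-group scale, wings-per-sample means 34.2 / 28.1 /
    39.1 by collection mode.
    """
    return SyntheticConfig(groups=list(FIXTURE_GROUPS), target_d2=FIXTURE_D2.copy())


def reference_fixture(
    seed: int = DEFAULT_FIXTURE_SEED, return_truth: bool = False
):
    """The deterministic packaged fixture (study-scale synthetic data)."""
    cfg = reference_fixture_config()
    return simulate_study(cfg, seed=seed, return_truth=return_truth)


def two_group_config(
    d2: float,
    n_colonies: int,
    wings_per_colony: int = 10,
    colony_effect_sd: float = 0.004,
    wing_noise_sd: float = 0.006,
) -> SyntheticConfig:
    """Minimal two-group design at a known true separation.

    Wings per colony are fixed, so the colony-mean covariance (and hence
    the true D^2) is exact.  Used for parameter-recovery experiments.
    """
    groups = [
        GroupSpec("intra_pre", n_colonies, area="intra", period="pre2000",
                  wings_mean=wings_per_colony),
        GroupSpec("extra_pre", n_colonies, area="extra", period="pre2000",
                  ln_cs_mean=6.44, wings_mean=wings_per_colony),
    ]
    return SyntheticConfig(
        groups=groups,
        target_d2=np.array([[0.0, d2], [d2, 0.0]]),
        colony_effect_sd=colony_effect_sd,
        wing_noise_sd=wing_noise_sd,
        wings_distribution="fixed",
    )
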