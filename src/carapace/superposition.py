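"""Generalized Procrustes superposition with sliding semilandmarks.

Shapes are 2-D point configurations. Superposition removes translation
(centering), scale (unit centroid size), and rotation (orthogonal Procrustes
with reflections disallowed, since specimens are digitized in a consistent
anatomical orientation). Semilandmarks optionally slide along the chord
through their two scheme neighbors, with minimization of Procrustes distance
to the current mean as the criterion. Shape variation is analyzed as
Procrustes residuals in the linear tangent space at the mean.

Also here: missing-landmark estimation by reflection across the best-fit
midline axis, the symmetric component of object-symmetric views, and
tangent-space PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import LandmarkConfiguration
from .schemes import LandmarkScheme


class DegenerateConfigurationError(ValueError):
    pass


class UnrecoverablePointError(ValueError):
    pass


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared distances of points from their centroid."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or len(coords) < 3:
        raise DegenerateConfigurationError("centroid size needs >= 3 points")
    if np.isnan(coords).any():
        raise DegenerateConfigurationError("estimate missing points before computing CS")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def _center_and_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    cs = centroid_size(coords)
    return (coords - coords.mean(axis=0)) / cs, cs


def rotation_to(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||a @ R - b||, both centered."""
    u, _, vt = np.linalg.svd(a.T @ b)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations.

    Both are centered, scaled to unit centroid size, and optimally rotated
    (no reflection) before the root-sum-of-squares difference is taken.
    """
    a0, _ = _center_and_scale(np.asarray(a, float))
    b0, _ = _center_and_scale(np.asarray(b, float))
    a0 = a0 @ rotation_to(a0, b0)
    return float(np.sqrt(np.sum((a0 - b0) ** 2)))


def full_procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance: scale of ``a`` is also optimized.

    Equals ``sin(rho)`` where ``rho`` is the Procrustes arc distance; used as
    a closed-form two-configuration oracle for the generalized fit.
    """
    a0, _ = _center_and_scale(np.asarray(a, float))
    b0, _ = _center_and_scale(np.asarray(b, float))
    r = rotation_to(a0, b0)
    beta = np.trace(b0.T @ (a0 @ r))  # optimal scale for unit-CS configs
    return float(np.sqrt(max(0.0, 1.0 - beta**2)))


@dataclass
class AlignedSample:
    """A Procrustes-superimposed set of configurations sharing a mean shape."""

    coords: np.ndarray        # (n_specimens, n_points, 2), unit centroid size
    centroid_sizes: np.ndarray  # pre-scaling CS, one per specimen
    mean_shape: np.ndarray    # (n_points, 2), unit centroid size
    view: str
    specimen_ids: list[str]

    @property
    def n_specimens(self) -> int:
        return len(self.coords)

    @property
    def n_points(self) -> int:
        return self.coords.shape[1]

    def flat(self) -> np.ndarray:
        """Flattened (n_specimens, 2 * n_points) coordinate matrix."""
        return self.coords.reshape(self.n_specimens, -1)

    def to_frame(self):
        """One row per specimen: flattened coordinates plus centroid size."""
        import pandas as pd

        cols = [f"{ax}{k + 1}" for k in range(self.n_points) for ax in ("x", "y")]
        df = pd.DataFrame(self.flat(), columns=cols)
        df.insert(0, "specimen_id", self.specimen_ids)
        df["centroid_size"] = self.centroid_sizes
        return df


def _mean_of(coords: np.ndarray) -> np.ndarray:
    m = coords.mean(axis=0)
    return m / np.sqrt(np.sum((m - m.mean(axis=0)) ** 2))


def _objective(coords: np.ndarray, mean: np.ndarray) -> float:
    return float(np.sum((coords - mean[None]) ** 2))


def _fit_to_mean(coords: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Re-center, re-scale, and rotate every configuration onto ``mean``."""
    out = np.empty_like(coords)
    for i, c in enumerate(coords):
        c0 = c - c.mean(axis=0)
        c0 = c0 / np.sqrt(np.sum(c0**2))
        out[i] = c0 @ rotation_to(c0, mean)
    return out


def _slide_pass(coords: np.ndarray, mean: np.ndarray,
                scheme: LandmarkScheme) -> np.ndarray:
    """Slide each semilandmark along its neighbor chord toward the mean."""
    out = coords.copy()
    semis = sorted(scheme.semilandmark_indices)
    for s in semis:
        a, b = scheme.sliding_neighbors[s]
        chord = coords[:, b] - coords[:, a]           # (n, 2)
        norm = np.linalg.norm(chord, axis=1, keepdims=True)
        t = chord / np.where(norm > 0, norm, 1.0)
        dev = mean[None, s] - coords[:, s]
        out[:, s] = coords[:, s] + t * np.sum(dev * t, axis=1, keepdims=True)
    return out


def procrustes_align(
    configs: list[LandmarkConfiguration] | np.ndarray,
    scheme: LandmarkScheme | None = None,
    slide: bool = False,
    tol: float = 1e-10,
    max_iter: int = 300,
    slide_tol: float = 1e-8,
    max_slide_passes: int = 10,
) -> AlignedSample:
    """Generalized Procrustes superposition, optionally with sliding.

    Iterates center / unit-CS scale / rotate-to-mean / mean update until the
    mean changes by less than ``tol`` (or ``max_iter``). With ``slide=True``,
    semilandmark sliding passes are interleaved after GPA convergence; each
    pass slides along scheme chords, re-superimposes, and repeats until the
    summed squared distance to the mean drops by less than ``slide_tol``
    (or ``max_slide_passes``). A pass that fails to decrease the objective is
    reverted, which keeps the descent monotone.
    """
    if isinstance(configs, np.ndarray):
        raw = [np.asarray(c, float) for c in configs]
        ids = [f"spec_{i + 1}" for i in range(len(raw))]
        view = scheme.view if scheme is not None else "unknown"
    else:
        raw = [np.asarray(c.coords, float) for c in configs]
        ids = [c.specimen_id for c in configs]
        view = configs[0].view if configs else "unknown"
    if len(raw) < 2:
        raise ValueError("superposition needs at least 2 configurations")
    if any(np.isnan(c).any() for c in raw):
        raise ValueError("estimate missing points before superposition")
    if slide and (scheme is None or not scheme.semilandmark_indices):
        slide = False

    centered = np.stack([_center_and_scale(c)[0] for c in raw])
    sizes = np.array([centroid_size(c) for c in raw])

    mean = centered[0].copy()  # initialization; order invariance is tested
    coords = centered
    delta = np.inf
    for _ in range(max_iter):
        coords = _fit_to_mean(coords, mean)
        new_mean = _mean_of(coords)
        # remove rotational drift of the mean so convergence is well-defined
        new_mean = new_mean @ rotation_to(new_mean, mean)
        delta = float(np.sqrt(np.sum((new_mean - mean) ** 2)))
        mean = new_mean
        if delta < tol:
            break
    else:
        warnings.warn(f"GPA did not converge: final mean delta {delta:.3e}")

    if slide:
        obj = _objective(coords, mean)
        for _ in range(max_slide_passes):
            slid = _slide_pass(coords, mean, scheme)
            slid = _fit_to_mean(slid, mean)
            new_mean = _mean_of(slid)
            slid = _fit_to_mean(slid, new_mean)
            new_obj = _objective(slid, new_mean)
            if new_obj > obj - slide_tol:
                if new_obj <= obj:
                    coords, mean, obj = slid, new_mean, new_obj
                break
            coords, mean, obj = slid, new_mean, new_obj
        # final GPA polish at the slid positions
        for _ in range(max_iter):
            coords = _fit_to_mean(coords, mean)
            new_mean = _mean_of(coords)
            if np.sqrt(np.sum((new_mean - mean) ** 2)) < tol:
                mean = new_mean
                break
            mean = new_mean

    return AlignedSample(coords=coords, centroid_sizes=sizes, mean_shape=mean,
                         view=view, specimen_ids=ids)


def _tls_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through points: (point on line, unit direction)."""
    center = points.mean(axis=0)
    u, s, vt = np.linalg.svd(points - center)
    return center, vt[0]


def _reflect_across_line(points: np.ndarray, origin: np.ndarray,
                         direction: np.ndarray) -> np.ndarray:
    d = direction / np.linalg.norm(direction)
    rel = points - origin
    along = rel @ d
    perp = rel - np.outer(along, d)
    return origin + np.outer(along, d) - perp


def estimate_missing_by_reflection(
    config: LandmarkConfiguration, scheme: LandmarkScheme
) -> LandmarkConfiguration:
    """Fill missing bilateral points by reflecting their pair across the midline.

    The midline axis is the total-least-squares line through the present
    midline points. Present points are left untouched.
    """
    if not scheme.symmetric:
        raise ValueError(f"view {scheme.view!r} has no symmetry to exploit")
    if config.is_complete():
        return config
    mask = config.missing_mask
    midline = sorted(scheme.midline_indices)
    present_mid = [i for i in midline if not mask[i]]
    if len(present_mid) < 2:
        raise UnrecoverablePointError("need >= 2 present midline points for the axis")
    unrecoverable = []
    for i in np.flatnonzero(mask):
        j = scheme.pair_map.get(i)
        if j is None or mask[j]:
            unrecoverable.append(int(i))
    if unrecoverable:
        raise UnrecoverablePointError(
            f"missing points with no recoverable pair: {unrecoverable}")

    origin, direction = _tls_line(config.coords[present_mid])
    coords = config.coords.copy()
    new_mask = mask.copy()
    for i in np.flatnonzero(mask):
        j = scheme.pair_map[i]
        coords[i] = _reflect_across_line(coords[None, j], origin, direction)[0]
        new_mask[i] = False
    return LandmarkConfiguration(
        specimen_id=config.specimen_id, view=config.view, coords=coords,
        scale=config.scale, missing_mask=new_mask, image=config.image,
    )


def symmetric_component(aligned: AlignedSample,
                        scheme: LandmarkScheme) -> AlignedSample:
    """Symmetric component of an object-symmetric view, reduced to one half.

    Each specimen is paired with its mirrored (y-negated), pair-relabeled
    copy; originals and copies are superimposed jointly and averaged per
    specimen. The output keeps the midline plus one side's points (scheme
    order) and is re-superimposed so AlignedSample invariants hold.
    """
    if not scheme.symmetric:
        raise ValueError(f"view {scheme.view!r} is not a symmetric view")
    perm = scheme.mirror_permutation()
    orig = aligned.coords
    mirrored = orig.copy()
    mirrored[:, :, 1] *= -1.0
    mirrored = mirrored[:, perm, :]
    both = np.concatenate([orig, mirrored], axis=0)
    joint = procrustes_align(both, scheme=scheme, slide=False)
    n = aligned.n_specimens
    sym = 0.5 * (joint.coords[:n] + joint.coords[n:])
    half = scheme.half_indices()
    half_coords = sym[:, half, :]
    out = procrustes_align(half_coords, scheme=scheme.half_scheme(), slide=False)
    return AlignedSample(
        coords=out.coords, centroid_sizes=aligned.centroid_sizes.copy(),
        mean_shape=out.mean_shape, view=f"{aligned.view}_half",
        specimen_ids=list(aligned.specimen_ids),
    )


@dataclass
class PCSpace:
    """Tangent-space principal components of an aligned sample."""

    mean: np.ndarray               # flattened mean shape
    axes: np.ndarray               # (n_axes, n_coords) orthonormal loadings
    scores: np.ndarray             # (n_specimens, n_axes)
    variance_explained: np.ndarray
    repeatable_count: int

    def project(self, flat_shapes: np.ndarray) -> np.ndarray:
        """Scores of new flattened shapes on the existing axes."""
        return (np.atleast_2d(flat_shapes) - self.mean) @ self.axes.T

    def repeatable_scores(self, scores: np.ndarray | None = None) -> np.ndarray:
        s = self.scores if scores is None else scores
        return s[:, : self.repeatable_count]


def tangent_pca(aligned: AlignedSample,
                repeatable_count: int | None = None) -> PCSpace:
    """PCA of flattened aligned coordinates about their mean."""
    if aligned.n_specimens < 3:
        raise ValueError("PCA needs at least 3 specimens")
    x = aligned.flat()
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # fix axis signs for reproducibility: largest-magnitude loading positive
    for k in range(len(vt)):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    if repeatable_count is None:
        repeatable_count = min(len(s), 5)
    return PCSpace(mean=mean, axes=vt, scores=u * s,
                   variance_explained=frac,
                   repeatable_count=min(repeatable_count, len(s)))
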