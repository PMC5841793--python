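"""Spatial structure of size and shape: SEVM and Moran's I.

Spatial eigenvector mapping (SEVM) turns a great-circle distance matrix
between specimen localities into orthogonal spatial basis functions
(principal coordinates of the Gower-centered distance matrix). Eigenvectors
with positive eigenvalues, ordered by descending eigenvalue, serve as
covariates that absorb spatially autocorrelated variation; a greedy forward
selection picks the few that explain the most shape variation. Moran's I
with row-standardized k-nearest-neighbor weights screens individual
variables for spatial autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088


def haversine_matrix(coords: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix (km) from (lat, lon) decimal degrees."""
    c = np.asarray(coords, dtype=float)
    lat, lon = c[:, 0], c[:, 1]
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range (lat +-90, lon +-180)")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (np.sin(dphi / 2) ** 2
         + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2)
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class SpatialEigenvectors:
    localities: np.ndarray       # (n, 2) lat/lon
    distance_km: np.ndarray
    se_scores: np.ndarray        # (n, n_se), unit-norm columns
    eigenvalues: np.ndarray
    labels: list[str]

    def to_frame(self, specimen_ids=None) -> pd.DataFrame:
        df = pd.DataFrame(self.se_scores, columns=self.labels)
        if specimen_ids is not None:
            df.insert(0, "specimen_id", list(specimen_ids))
        return df


def spatial_eigenvectors(distance_km: np.ndarray,
                         localities: np.ndarray | None = None,
                         truncation: float | None = None) -> SpatialEigenvectors:
    """Principal-coordinate spatial eigenvectors of a distance matrix.

    Gower double-centering of -D^2/2 followed by eigendecomposition;
    eigenvectors with positive eigenvalues are kept, unit-normalized, and
    labelled SE1, SE2, ... by descending eigenvalue. ``truncation`` (km)
    optionally caps distances at a threshold (times 4, the usual PCNM
    device) before centering, for dbMEM-style analysis; default is the plain
    untruncated decomposition. Signs are fixed by positive correlation with
    longitude (tie-break: latitude) when localities are supplied.
    """
    d = np.asarray(distance_km, dtype=float)
    n = len(d)
    if n < 3:
        raise ValueError("need >= 3 localities")
    if truncation is not None:
        d = d.copy()
        d[d > truncation] = 4.0 * truncation
    if np.allclose(d, 0.0):
        raise ValueError("all localities identical; no spatial structure")
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-8 * vals.max(), 0.0)
    vals, vecs = vals[pos], vecs[:, pos]
    for k in range(vecs.shape[1]):
        ref = None
        if localities is not None:
            lon = np.asarray(localities, float)[:, 1]
            lat = np.asarray(localities, float)[:, 0]
            r = np.corrcoef(vecs[:, k], lon)[0, 1]
            if abs(r) < 1e-10 or np.isnan(r):
                r = np.corrcoef(vecs[:, k], lat)[0, 1]
            ref = r
        else:
            ref = vecs[np.argmax(np.abs(vecs[:, k])), k]
        if ref is not None and ref < 0:
            vecs[:, k] *= -1
    return SpatialEigenvectors(
        localities=np.asarray(localities, float) if localities is not None else np.empty((n, 2)),
        distance_km=np.asarray(distance_km, float),
        se_scores=vecs, eigenvalues=vals,
        labels=[f"SE{k + 1}" for k in range(vecs.shape[1])],
    )


def _knn_weights(distance: np.ndarray, k: int) -> np.ndarray:
    n = len(distance)
    w = np.zeros((n, n))
    for i in range(n):
        order = np.argsort(distance[i], kind="stable")
        neighbors = [j for j in order if j != i][:k]
        w[i, neighbors] = 1.0
    rows = w.sum(axis=1, keepdims=True)
    return w / np.where(rows > 0, rows, 1.0)


def morans_i(values: np.ndarray, coords: np.ndarray, k_neighbors: int = 5,
             n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Moran's I per value column with one-tailed (positive) permutation p.

    Weights are row-standardized k-nearest-neighbor adjacency on great-
    circle distances. Constant columns return NaN.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    d = haversine_matrix(coords)
    w = _knn_weights(d, k_neighbors)
    rng = np.random.default_rng(seed)
    n = len(v)
    rows = []
    for col in range(v.shape[1]):
        z = v[:, col] - v[:, col].mean()
        denom = float(z @ z)
        if denom == 0.0:
            rows.append({"I": np.nan, "p": np.nan, "expected": -1.0 / (n - 1)})
            continue
        i_obs = float(z @ (w @ z)) / denom  # S0 = n for row-standardized W
        count = 1
        for _ in range(n_perm):
            zp = z[rng.permutation(n)]
            i_star = float(zp @ (w @ zp)) / denom
            if i_star >= i_obs - 1e-15:
                count += 1
        rows.append({"I": i_obs, "p": count / (n_perm + 1),
                     "expected": -1.0 / (n - 1)})
    return pd.DataFrame(rows)


def _multivariate_r2(y: np.ndarray, x: np.ndarray | None) -> float:
    """Redundancy R^2 of multivariate y on design x (intercept implicit)."""
    yc = y - y.mean(axis=0)
    total = float(np.sum(yc**2))
    if total == 0.0:
        return 0.0
    if x is None or x.shape[1] == 0:
        return 0.0
    xc = x - x.mean(axis=0)
    q, r = np.linalg.qr(xc)
    keep = np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(r).max())
    q = q[:, keep]
    fit = q @ (q.T @ yc)
    return float(np.sum(fit**2)) / total


def forward_select_se(
    se_scores: np.ndarray,
    shape_pc_scores: np.ndarray,
    alpha: float = 0.05,
    max_keep: int = 2,
    n_perm: int = 999,
    seed: int = 0,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Greedy forward selection of spatial eigenvectors explaining shape.

    At each step the candidate SE adding the most redundancy R^2 is admitted
    if its permutation p (residuals of the current model permuted) is below
    ``alpha``; stops at ``max_keep`` or when no candidate is admissible.
    Returns one row per selected SE: label, added R^2, cumulative R^2, p.
    """
    se = np.asarray(se_scores, dtype=float)
    y = np.asarray(shape_pc_scores, dtype=float)
    if len(se) != len(y):
        raise ValueError("SE scores and shape scores are not row-aligned")
    if labels is None:
        labels = [f"SE{k + 1}" for k in range(se.shape[1])]
    rng = np.random.default_rng(seed)
    n = len(y)
    selected: list[int] = []
    rows = []
    while len(selected) < max_keep:
        x_cur = se[:, selected] if selected else None
        r2_cur = _multivariate_r2(y, x_cur)
        best_j, best_gain = -1, -np.inf
        for j in range(se.shape[1]):
            if j in selected:
                continue
            gain = _multivariate_r2(y, se[:, selected + [j]]) - r2_cur
            if gain > best_gain:
                best_j, best_gain = j, gain
        if best_j < 0:
            break
        # permutation test: permute reduced-model residuals, re-evaluate gain
        yc = y - y.mean(axis=0)
        if x_cur is not None:
            xc = x_cur - x_cur.mean(axis=0)
            q, _ = np.linalg.qr(xc)
            fitted = q @ (q.T @ yc)
        else:
            fitted = np.zeros_like(yc)
        resid = yc - fitted
        count = 1
        for _ in range(n_perm):
            y_star = fitted + resid[rng.permutation(n)]
            gain_star = (_multivariate_r2(y_star, se[:, selected + [best_j]])
                         - _multivariate_r2(y_star, x_cur))
            if gain_star >= best_gain - 1e-15:
                count += 1
        p = count / (n_perm + 1)
        if p >= alpha:
            break
        selected.append(best_j)
        rows.append({"se": labels[best_j], "added_r2": best_gain,
                     "cumulative_r2": r2_cur + best_gain, "p": p})
    return pd.DataFrame(rows, columns=["se", "added_r2", "cumulative_r2", "p"])
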