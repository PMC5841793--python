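"""Fossil-record inference chain.

Order of operations mirrors how the fossil carapaces are interrogated:
(1) screen each site's carapace-length distribution for a non-overlapping
bimodal split (largest-gap rule, 60 mm default); (2) test whether such
bimodality could be sexual size dimorphism by computing the site's SDI with
the large morph as the modern larger sex and rejecting when it falls outside
the modern bootstrap CI; (3) compare modern and fossil allometric slopes
(homogeneity-of-slopes Procrustes ANOVA); (4) when slopes differ, regress
everything against the modern allometric model and use residual shapes as
allometrically corrected samples; (5) pairwise site-vs-site and site-vs-
modern shape tests with FDR control; (6) ask whether fossils add disparity
beyond a bootstrap rarefaction bound on the modern sample.

Fossil specimens are always projected onto the modern PC basis, never pooled
into a re-fit PCA, so modern-only statistics are unchanged by adding fossils.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dimorphism import SDIResult, sdi_compressed
from .shapestats import (AnovaResult, DisparityCurve, disparity_rarefaction,
                         pairwise_group_tests, procrustes_anova)

GAP_THRESHOLD_MM_DEFAULT = 60.0


@dataclass
class MorphSplit:
    """Partition of one site's specimens into size morphs."""

    site: str
    bimodal: bool
    gap_mm: float
    large_ids: list[str]
    small_ids: list[str]

    @property
    def groups(self) -> dict[str, list[str]]:
        if self.bimodal:
            return {"large": self.large_ids, "small": self.small_ids}
        return {"all": self.large_ids + self.small_ids}


def split_bimodal(lengths: np.ndarray, specimen_ids=None, site: str = "",
                  gap_threshold_mm: float = GAP_THRESHOLD_MM_DEFAULT) -> MorphSplit:
    """Split a site's lengths at the largest inter-specimen gap if wide enough.

    Lengths are sorted; if the largest gap between consecutive values is at
    least the threshold, the site is declared bimodal and split there, large
    and small morphs both non-empty by construction. With ``gap_threshold_mm``
    = 0 any site with >= 2 distinct lengths splits at its largest gap.
    """
    x = np.asarray(lengths, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 specimens to assess bimodality")
    if specimen_ids is None:
        specimen_ids = [str(i) for i in range(len(x))]
    ids = np.asarray(specimen_ids, dtype=object)
    order = np.argsort(x, kind="stable")
    xs, ids_sorted = x[order], ids[order]
    gaps = np.diff(xs)
    k = int(np.argmax(gaps))
    gap = float(gaps[k])
    if gap >= gap_threshold_mm and gap > 0:
        return MorphSplit(site=site, bimodal=True, gap_mm=gap,
                          small_ids=list(ids_sorted[: k + 1]),
                          large_ids=list(ids_sorted[k + 1:]))
    return MorphSplit(site=site, bimodal=False, gap_mm=gap,
                      large_ids=list(ids_sorted), small_ids=[])


def fossil_sdi_test(large_lengths: np.ndarray, small_lengths: np.ndarray,
                    modern_sdi: SDIResult) -> tuple[float, bool]:
    """Model a bimodal site as two sexes and test against the modern SDI CI.

    The large morph plays the larger modern sex (males, given the modern
    male-biased dimorphism); the compressed SDI is computed and the
    two-sexes hypothesis rejected iff it falls outside the closed interval
    [ci_low, ci_high] of the modern bootstrap CI.
    """
    sdi = sdi_compressed(np.asarray(large_lengths, float),
                         np.asarray(small_lengths, float))
    reject = not (modern_sdi.ci_low <= sdi <= modern_sdi.ci_high)
    return float(sdi), bool(reject)


@dataclass
class AllometricModel:
    """Multivariate regression of shape on log centroid size, fit on moderns."""

    intercept_shape: np.ndarray   # flattened shape at log CS = 0
    slope_vector: np.ndarray      # flattened shape change per unit log CS
    mean_log_cs: float
    grand_mean: np.ndarray        # flattened mean shape of the fit sample
    log_cs_range: tuple[float, float]
    r_squared: float
    n: int

    def predict(self, log_cs: np.ndarray) -> np.ndarray:
        log_cs = np.atleast_1d(np.asarray(log_cs, dtype=float))
        return self.intercept_shape[None, :] + np.outer(log_cs, self.slope_vector)


def fit_allometry(flat_shapes: np.ndarray, log_cs: np.ndarray) -> AllometricModel:
    """Least-squares allometric model; R^2 is the fraction of shape SS explained."""
    y = np.asarray(flat_shapes, dtype=float)
    s = np.asarray(log_cs, dtype=float)
    if np.allclose(s.var(), 0.0):
        raise ValueError("no size variance; allometry unidentifiable")
    sc = s - s.mean()
    yc = y - y.mean(axis=0)
    slope = (sc @ yc) / float(sc @ sc)
    intercept = y.mean(axis=0) - s.mean() * slope
    fitted_c = np.outer(sc, slope)
    total = float(np.sum(yc**2))
    r2 = float(np.sum(fitted_c**2)) / total if total > 0 else 0.0
    return AllometricModel(
        intercept_shape=intercept, slope_vector=slope,
        mean_log_cs=float(s.mean()), grand_mean=y.mean(axis=0),
        log_cs_range=(float(s.min()), float(s.max())), r_squared=r2, n=len(y),
    )


def slope_homogeneity_test(flat_shapes: np.ndarray, log_cs: np.ndarray,
                           era_group: np.ndarray, n_perm: int = 999,
                           seed: int = 0) -> AnovaResult:
    """Homogeneity-of-slopes test: the log CS x group interaction p-value.

    Procrustes ANOVA with terms (log CS, group, log CS x group) on the
    pooled modern + fossil sample.
    """
    groups = pd.Series(np.asarray(era_group).astype(str))
    sizes = groups.value_counts()
    if sizes.min() < 3:
        warnings.warn(
            f"smallest group has {sizes.min()} specimens; slope test underpowered")
    data = pd.DataFrame({"log_cs": np.asarray(log_cs, float),
                         "group": groups.to_numpy()})
    return procrustes_anova(np.asarray(flat_shapes, float), data,
                            ["log_cs", "group", "log_cs:group"],
                            n_perm=n_perm, seed=seed)


def allometric_correct(flat_shapes: np.ndarray, log_cs: np.ndarray,
                       model: AllometricModel) -> np.ndarray:
    """Residual shapes about the modern growth model, re-centered at its mean.

    corrected = observed - prediction(log CS) + modern grand mean; applied
    identically to modern and fossil specimens. Sizes outside the modern fit
    range trigger an extrapolation warning.
    """
    y = np.asarray(flat_shapes, dtype=float)
    s = np.atleast_1d(np.asarray(log_cs, dtype=float))
    lo, hi = model.log_cs_range
    outside = (s < lo) | (s > hi)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} specimens outside the modern size range "
            f"[{lo:.3f}, {hi:.3f}]; allometric correction extrapolates "
            f"(rows {np.flatnonzero(outside).tolist()})")
    return y - model.predict(s) + model.grand_mean[None, :]


def site_comparisons(corrected_shapes: np.ndarray, site_labels: np.ndarray,
                     n_perm: int = 999, seed: int = 0,
                     min_site_size: int = 2) -> pd.DataFrame:
    """Pairwise Procrustes-ANOVA p-matrix across sites (FDR-adjusted).

    ``site_labels`` should include a ``Modern`` pseudo-site for the pooled
    modern sample; sites below ``min_site_size`` are excluded with a warning.
    """
    return pairwise_group_tests(
        corrected_shapes, site_labels, covariates=None, covariate_terms=None,
        n_perm=n_perm, seed=seed, min_group_size=min_site_size,
    )


def fossil_disparity_report(
    modern_scores: np.ndarray,
    fossil_scores_by_site: dict[str, np.ndarray],
    n_boot: int = 1000,
    sizes: np.ndarray | None = None,
    seed: int = 0,
    method: str = "variance",
) -> DisparityCurve:
    """Rarefied disparity curve plus per-site and all-fossil augmented values.

    Fossil scores must already live in the modern repeatable-PC space
    (projected onto the modern axes). An ``all_fossils`` pooled entry is
    added alongside the per-site sets; the ``exceeds`` flags mark additions
    beyond the one-tailed 95% bound at the pooled sample size.
    """
    sets = {k: np.asarray(v, float) for k, v in fossil_scores_by_site.items()
            if len(np.atleast_1d(v)) > 0}
    skipped = set(fossil_scores_by_site) - set(sets)
    if skipped:
        warnings.warn(f"empty fossil sets skipped: {sorted(skipped)}")
    if sets:
        sets["all_fossils"] = np.concatenate(
            [np.atleast_2d(v) for v in sets.values()], axis=0)
    return disparity_rarefaction(modern_scores, sets, n_boot=n_boot,
                                 sizes=sizes, seed=seed, method=method)
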