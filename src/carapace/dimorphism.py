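"""Sexual size and shape dimorphism.

Size dimorphism uses untransformed carapace lengths and the "compressed"
sexual dimorphism index (SDI): the signed larger/smaller mean ratio minus
one, negative when males are the larger sex. The compressed form is
antisymmetric around zero, which makes it convenient for modelling and for
bootstrap confidence intervals. Shape dimorphism is tested by Procrustes
ANOVA with log centroid size and subspecies entered before sex, and its
practical diagnosability by a jackknifed CVA assignment of specimens to sex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .shapestats import (AnovaResult, AssignmentResult, cva_jackknife,
                         procrustes_anova)
from .superposition import AlignedSample, tangent_pca


def sdi_compressed(male_lengths: np.ndarray, female_lengths: np.ndarray) -> float:
    """Compressed sexual dimorphism index from untransformed lengths.

    With sample means F and M: ``F/M - 1`` when females are at least as
    large, else ``-(M/F - 1)``. Negative values denote male-larger
    dimorphism; the index is antisymmetric under swapping the sexes and
    invariant to rescaling all lengths.
    """
    m = np.asarray(male_lengths, dtype=float)
    f = np.asarray(female_lengths, dtype=float)
    if len(m) == 0 or len(f) == 0:
        raise ValueError("both sexes need at least one length")
    mbar, fbar = m.mean(), f.mean()
    if fbar >= mbar:
        return float(fbar / mbar - 1.0)
    return float(-(mbar / fbar - 1.0))


@dataclass
class SDIResult:
    sdi: float
    mean_male: float
    mean_female: float
    ci_low: float
    ci_high: float
    n_male: int
    n_female: int
    n_boot: int


def sdi_bootstrap_ci(male_lengths: np.ndarray, female_lengths: np.ndarray,
                     n_boot: int = 10000, level: float = 0.95,
                     seed: int = 0) -> SDIResult:
    """Percentile bootstrap CI for the compressed SDI (stratified by sex)."""
    m = np.asarray(male_lengths, dtype=float)
    f = np.asarray(female_lengths, dtype=float)
    if len(m) < 5 or len(f) < 5:
        raise ValueError("need n >= 5 per sex for a bootstrap CI")
    rng = np.random.default_rng(seed)
    mi = rng.integers(0, len(m), size=(n_boot, len(m)))
    fi = rng.integers(0, len(f), size=(n_boot, len(f)))
    mbar = m[mi].mean(axis=1)
    fbar = f[fi].mean(axis=1)
    boot = np.where(fbar >= mbar, fbar / mbar - 1.0, -(mbar / fbar - 1.0))
    alpha = 1.0 - level
    lo, hi = np.quantile(boot, [alpha / 2, 1.0 - alpha / 2])
    return SDIResult(
        sdi=sdi_compressed(m, f), mean_male=float(m.mean()),
        mean_female=float(f.mean()), ci_low=float(lo), ci_high=float(hi),
        n_male=len(m), n_female=len(f), n_boot=n_boot,
    )


def size_dimorphism_test(metadata: pd.DataFrame) -> tuple[float, float]:
    """Two-sample t-test on log carapace length between the sexes."""
    males = metadata.loc[metadata["sex"] == "M", "carapace_length"].dropna()
    females = metadata.loc[metadata["sex"] == "F", "carapace_length"].dropna()
    if len(males) < 2 or len(females) < 2:
        raise ValueError("need >= 2 measured specimens per sex")
    t, p = stats.ttest_ind(np.log(males), np.log(females))
    return float(t), float(p)


def sex_shape_analysis(
    aligned: AlignedSample,
    metadata: pd.DataFrame,
    repeatable_pcs: int,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[AnovaResult, AssignmentResult]:
    """Shape dimorphism for one view: Procrustes ANOVA plus jackknife CVA.

    Terms enter in the order log CS, subspecies, sex, CS x sex,
    subspecies x sex; the CVA assigns specimens to sex from the repeatable
    PCs of the aligned sample. ``metadata`` must be row-aligned with the
    sample and contain sexed specimens only.
    """
    sexed = metadata["sex"].isin(["M", "F"])
    if not sexed.all():
        raise ValueError("sex_shape_analysis expects sexed specimens only")
    data = pd.DataFrame({
        "log_cs": np.log(aligned.centroid_sizes),
        "subspecies": metadata["subspecies"].to_numpy(),
        "sex": metadata["sex"].to_numpy(),
    })
    anova = procrustes_anova(
        aligned.flat(), data,
        ["log_cs", "subspecies", "sex", "log_cs:sex", "subspecies:sex"],
        n_perm=n_perm, seed=seed,
    )
    pcs = tangent_pca(aligned, repeatable_count=repeatable_pcs)
    assignment = cva_jackknife(pcs.repeatable_scores(), data["sex"].to_numpy())
    return anova, assignment
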