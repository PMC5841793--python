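"""Maturity proxies and the maturity inclusion filter.

Three proxies for reproductive maturity are evaluated against each other:
major growth ring count (MGR), carapace length, and an ordinal carapace
ossification score (1 = open fontanelles, 2 = fontanelles closed / sutures
visible, 3 = partially fused, 4 = fully fused). The working rule: growth is
informative only below the MGR threshold (default 8), above which log length
plateaus; fontanelle closure (score >= 2) marks the same transition.

Specimens enter downstream shape datasets iff mature: modern specimens need
MGR >= threshold or a closed carapace; fossils (where rings rarely preserve)
need a closed carapace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

MGR_THRESHOLD_DEFAULT = 8


@dataclass
class SegmentFit:
    """OLS of log length on MGR within one segment of the growth record."""

    n: int
    slope: float
    r_squared_adj: float
    p: float


@dataclass
class MaturityReport:
    lm_below: SegmentFit
    lm_above: SegmentFit
    anova_length: tuple[float, float]   # (F, p) ossification classes vs log length
    anova_mgr: tuple[float, float]      # (F, p) ossification classes vs MGR
    pairwise_length_p: pd.DataFrame     # FDR-adjusted t-test p between classes
    pairwise_mgr_p: pd.DataFrame
    threshold_mgr: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "quantity": [
                "lm_r2_below", "lm_p_below", "lm_slope_below", "n_below",
                "lm_r2_above", "lm_p_above", "lm_slope_above", "n_above",
                "anova_length_F", "anova_length_p",
                "anova_mgr_F", "anova_mgr_p", "threshold_mgr",
            ],
            "value": [
                self.lm_below.r_squared_adj, self.lm_below.p,
                self.lm_below.slope, self.lm_below.n,
                self.lm_above.r_squared_adj, self.lm_above.p,
                self.lm_above.slope, self.lm_above.n,
                *self.anova_length, *self.anova_mgr, self.threshold_mgr,
            ],
        })


def _segment_fit(mgr: np.ndarray, log_len: np.ndarray) -> SegmentFit:
    x = sm.add_constant(mgr)
    fit = sm.OLS(log_len, x).fit()
    return SegmentFit(n=len(mgr), slope=float(fit.params[1]),
                      r_squared_adj=float(fit.rsquared_adj),
                      p=float(fit.pvalues[1]))


def _pairwise_t(values: np.ndarray, classes: np.ndarray,
                levels: list[int]) -> pd.DataFrame:
    pairs = list(combinations(levels, 2))
    raw = []
    for a, b in pairs:
        t, p = stats.ttest_ind(values[classes == a], values[classes == b])
        raw.append(p)
    adj = multipletests(raw, method="fdr_bh")[1]
    mat = pd.DataFrame(np.ones((len(levels), len(levels))),
                       index=levels, columns=levels)
    for (a, b), p in zip(pairs, adj):
        mat.loc[a, b] = p
        mat.loc[b, a] = p
    return mat


def proxy_analysis(metadata: pd.DataFrame,
                   mgr_threshold: int = MGR_THRESHOLD_DEFAULT) -> MaturityReport:
    """Evaluate the concordance of the three maturity proxies.

    Fits log length ~ MGR separately at-or-below and above the threshold
    (the boundary value is included in the lower segment), runs one-way
    ANOVAs of log length and MGR across ossification classes, and all
    pairwise t-tests between classes with Benjamini-Hochberg adjustment.
    """
    df = metadata.dropna(subset=["mgr", "carapace_length", "ossification"]).copy()
    if len(df) < 10:
        raise ValueError("too few specimens with all three proxies recorded")
    mgr = df["mgr"].to_numpy(float)
    log_len = np.log(df["carapace_length"].to_numpy(float))
    oss = df["ossification"].to_numpy(int)

    below = mgr <= mgr_threshold
    lm_below = _segment_fit(mgr[below], log_len[below])
    lm_above = _segment_fit(mgr[~below], log_len[~below])

    levels = sorted(set(oss.tolist()))
    usable = [lv for lv in levels if np.sum(oss == lv) >= 2]
    if len(usable) < len(levels):
        warnings.warn(
            f"ossification classes with < 2 members dropped: {sorted(set(levels) - set(usable))}")
    groups_len = [log_len[oss == lv] for lv in usable]
    groups_mgr = [mgr[oss == lv] for lv in usable]
    f_len, p_len = stats.f_oneway(*groups_len)
    f_mgr, p_mgr = stats.f_oneway(*groups_mgr)

    return MaturityReport(
        lm_below=lm_below, lm_above=lm_above,
        anova_length=(float(f_len), float(p_len)),
        anova_mgr=(float(f_mgr), float(p_mgr)),
        pairwise_length_p=_pairwise_t(log_len, oss, usable),
        pairwise_mgr_p=_pairwise_t(mgr, oss, usable),
        threshold_mgr=mgr_threshold,
    )


def maturity_filter(metadata: pd.DataFrame,
                    mgr_threshold: int = MGR_THRESHOLD_DEFAULT) -> np.ndarray:
    """Boolean mask of specimens judged reproductively mature.

    Modern: MGR known and >= threshold, or ossification >= 2 (fontanelles
    closed). Fossil (holocene/pleistocene): ossification >= 2. Specimens
    with neither proxy known fail, with a warning listing their ids.
    """
    mgr = pd.to_numeric(metadata["mgr"], errors="coerce")
    oss = pd.to_numeric(metadata["ossification"], errors="coerce")
    era = metadata["era"].astype(str)
    closed = oss >= 2
    ringed = mgr >= mgr_threshold
    is_modern = era == "modern"
    mask = np.where(is_modern, (ringed.fillna(False) | closed.fillna(False)),
                    closed.fillna(False))
    unknown = mgr.isna() & oss.isna()
    if unknown.any():
        ids = metadata.loc[unknown, "specimen_id"].tolist()
        warnings.warn(f"specimens with no maturity proxies fail the filter: {ids}")
    return np.asarray(mask, dtype=bool)
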