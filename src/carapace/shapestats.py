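"""Shape statistics: permutation Procrustes ANOVA and friends.

The workhorse is :func:`procrustes_anova`: sequential (Type I) sums of
squares over all shape coordinates jointly, with significance from residual
randomization (RRPP) -- residuals of each term's reduced model are permuted
across specimens, the term statistic is recomputed, and the p-value is the
proportion of permuted F statistics at least as large as the observed one
(observed permutation included).

Also here: Benjamini-Hochberg-adjusted pairwise group tests, measurement
error / intraclass repeatability from replicate digitizations, jackknifed
canonical-variates assignment, BIC-ranked Gaussian mixture clustering, and
morphological disparity with bootstrap rarefaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# design encoding


def _encode_single(data: pd.DataFrame, name: str) -> np.ndarray:
    col = data[name]
    if pd.api.types.is_numeric_dtype(col):
        return np.asarray(col, dtype=float)[:, None]
    dummies = pd.get_dummies(col.astype(str), drop_first=True)
    if dummies.shape[1] == 0:
        raise ValueError(f"term {name!r} has zero degrees of freedom")
    return dummies.to_numpy(dtype=float)


def encode_term(data: pd.DataFrame, term: str) -> np.ndarray:
    """Encode a term name into design columns.

    A plain column name becomes a covariate (numeric) or dummy block
    (categorical, first level dropped); ``a:b`` becomes the elementwise
    product block of the two encodings (an interaction).
    """
    parts = term.split(":")
    block = _encode_single(data, parts[0])
    for part in parts[1:]:
        other = _encode_single(data, part)
        block = np.concatenate(
            [block[:, [i]] * other for i in range(block.shape[1])], axis=1
        )
    return block


@dataclass
class AnovaResult:
    """Sequential shape-ANOVA table with permutation p-values."""

    terms: list[str]
    ss: np.ndarray
    df: np.ndarray
    r_squared: np.ndarray
    f: np.ndarray
    p: np.ndarray
    n_perm: int
    total_ss: float
    residual_ss: float
    residual_df: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "term": self.terms, "df": self.df, "SS": self.ss,
            "R2": self.r_squared, "F": self.f, "p": self.p,
        })
        resid = pd.DataFrame({
            "term": ["Residual"], "df": [self.residual_df],
            "SS": [self.residual_ss],
            "R2": [self.residual_ss / self.total_ss if self.total_ss > 0 else np.nan],
            "F": [np.nan], "p": [np.nan],
        })
        return pd.concat([df, resid], ignore_index=True)


def _rss(q: np.ndarray, y: np.ndarray, total: float) -> float:
    qty = q.T @ y
    return total - float(np.sum(qty**2))


def procrustes_anova(
    shapes: np.ndarray,
    data: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> AnovaResult:
    """Sequential multivariate shape ANOVA with RRPP permutation p-values.

    ``shapes`` is the (n_specimens, n_coords) flattened aligned-coordinate
    matrix; ``terms`` are evaluated in the order given (Type I).
    """
    y = np.asarray(shapes, dtype=float)
    n = len(y)
    if len(data) != n:
        raise ValueError("shapes and data are not row-aligned")
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} is low; p-values will be coarse")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ones = np.ones((n, 1))
    xs = [ones]
    for t in terms:
        xs.append(np.concatenate([xs[-1], encode_term(data, t)], axis=1))
    qs, ranks = [], []
    for x in xs:
        q, r = np.linalg.qr(x)
        keep = np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(r).max())
        qs.append(q[:, keep])
        ranks.append(int(keep.sum()))
    dfs = np.diff(ranks)
    if np.any(dfs == 0):
        bad = [terms[i] for i in range(len(terms)) if dfs[i] == 0]
        raise ValueError(f"terms with zero df (aliased with earlier terms): {bad}")

    y2 = float(np.sum(y**2))
    rss_all = [_rss(q, y, y2) for q in qs]
    total_ss = rss_all[0]
    ss = -np.diff(rss_all)
    resid_ss = rss_all[-1]
    resid_df = n - ranks[-1]
    if resid_df <= 0:
        raise ValueError("model saturates the data; no residual df")
    f_obs = (ss / dfs) / (resid_ss / resid_df)

    # RRPP: one specimen permutation per iteration, applied to each term's
    # reduced-model residuals; F denominators recomputed on the permuted data.
    counts = np.ones(len(terms))  # observed permutation counts for each term
    fitted = [q @ (q.T @ y) for q in qs[:-1]]
    resid = [y - f for f in fitted]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        for k in range(len(terms)):
            y_star = fitted[k] + resid[k][perm]
            t2 = float(np.sum(y_star**2))
            rss_red = _rss(qs[k], y_star, t2)
            rss_fullk = _rss(qs[k + 1], y_star, t2)
            ss_star = rss_red - rss_fullk
            rss_full = _rss(qs[-1], y_star, t2)
            f_star = (ss_star / dfs[k]) / (rss_full / resid_df)
            if f_star >= f_obs[k] - 1e-12:
                counts[k] += 1
    p = counts / (n_perm + 1)

    return AnovaResult(
        terms=list(terms), ss=ss, df=dfs,
        r_squared=ss / total_ss if total_ss > 0 else np.zeros_like(ss),
        f=f_obs, p=p, n_perm=n_perm, total_ss=total_ss,
        residual_ss=resid_ss, residual_df=resid_df,
    )


def pairwise_group_tests(
    shapes: np.ndarray,
    groups: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    covariate_terms: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """FDR-adjusted pairwise Procrustes-ANOVA p-values between groups.

    Each unordered pair of groups is tested on its subset, with any stated
    covariate terms entered before the group term; Benjamini-Hochberg
    adjustment is applied across all pairs. Returns a symmetric DataFrame
    with unit diagonal.
    """
    groups = pd.Series(np.asarray(groups).astype(str), name="group")
    shapes = np.asarray(shapes, dtype=float)
    sizes = groups.value_counts()
    levels = [g for g in sorted(sizes.index) if sizes[g] >= min_group_size]
    dropped = sorted(set(sizes.index) - set(levels))
    if dropped:
        warnings.warn(f"groups below minimum size excluded: {dropped}")
    if len(levels) < 2:
        raise ValueError("need at least 2 groups of sufficient size")

    rng = np.random.default_rng(seed)
    pairs, raw_p = [], []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            sel = groups.isin([levels[i], levels[j]]).to_numpy()
            sub = pd.DataFrame({"group": groups[sel].to_numpy()})
            terms = []
            if covariates is not None and covariate_terms:
                for t in covariate_terms:
                    for base in t.split(":"):
                        if base not in sub.columns:
                            sub[base] = np.asarray(covariates[base])[sel]
                terms = list(covariate_terms)
            res = procrustes_anova(shapes[sel], sub, terms + ["group"],
                                   n_perm=n_perm, seed=rng)
            pairs.append((levels[i], levels[j]))
            raw_p.append(res.p[-1])
    adj = multipletests(raw_p, method="fdr_bh")[1]

    mat = pd.DataFrame(np.ones((len(levels), len(levels))),
                       index=levels, columns=levels)
    for (a, b), p in zip(pairs, adj):
        mat.loc[a, b] = p
        mat.loc[b, a] = p
    return mat


@dataclass
class RepeatabilityResult:
    """Measurement error and intraclass repeatability from replicates."""

    me_percent: float
    icc: float
    ms_among: float
    ms_within: float
    n_reps: float
    balanced: bool


def repeatability(shapes: np.ndarray,
                  specimen_ids: np.ndarray | list[str]) -> RepeatabilityResult:
    """One-way Procrustes ANOVA on specimen identity over replicate digitizations.

    Variance components follow the standard one-way random-effects layout:
    ``s2_among = (MS_among - MS_within) / n0`` (floored at zero) with ``n0``
    the Sokal-Rohlf effective replicate count for unbalanced designs,
    ``s2_within = MS_within``; ICC = s2_among / (s2_among + s2_within) and
    ME% = 100 * (1 - ICC).
    """
    y = np.asarray(shapes, dtype=float)
    ids = pd.Series(np.asarray(specimen_ids).astype(str))
    counts = ids.value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("need >= 2 specimens each with >= 2 replicates")
    n_total = len(y)
    a = len(counts)
    grand = y.mean(axis=0)
    ss_among = 0.0
    ss_within = 0.0
    for g, cnt in counts.items():
        sub = y[(ids == g).to_numpy()]
        mu = sub.mean(axis=0)
        ss_among += cnt * float(np.sum((mu - grand) ** 2))
        ss_within += float(np.sum((sub - mu) ** 2))
    ms_among = ss_among / (a - 1)
    ms_within = ss_within / (n_total - a)
    balanced = counts.nunique() == 1
    if balanced:
        n0 = float(counts.iloc[0])
    else:
        n0 = (n_total - float(np.sum(counts**2)) / n_total) / (a - 1)
        warnings.warn("unbalanced replicate counts; using Sokal-Rohlf n0")
    s2_among = max(0.0, (ms_among - ms_within) / n0)
    s2_within = ms_within
    denom = s2_among + s2_within
    icc = s2_among / denom if denom > 0 else 1.0
    return RepeatabilityResult(
        me_percent=100.0 * (1.0 - icc), icc=icc, ms_among=ms_among,
        ms_within=ms_within, n_reps=n0, balanced=balanced,
    )


@dataclass
class AssignmentResult:
    """Confusion matrix and accuracy of a group assignment test."""

    confusion: pd.DataFrame
    accuracy: float
    jackknifed: bool


def _cva_axes(x: np.ndarray, labels: np.ndarray,
              levels: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Canonical axes (columns) and group centroids in CV space."""
    from scipy.linalg import eigh

    n, p = x.shape
    g = len(levels)
    grand = x.mean(axis=0)
    w = np.zeros((p, p))
    b = np.zeros((p, p))
    means = {}
    for lv in levels:
        sub = x[labels == lv]
        mu = sub.mean(axis=0)
        means[lv] = mu
        w += (sub - mu).T @ (sub - mu)
        b += len(sub) * np.outer(mu - grand, mu - grand)
    w /= n - g
    try:
        vals, vecs = eigh(b, w)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular pooled within-group covariance") from exc
    order = np.argsort(vals)[::-1][: g - 1]
    axes = vecs[:, order]  # columns normalized so v' W v = 1 => Mahalanobis metric
    centroids = np.stack([means[lv] @ axes for lv in levels])
    return axes, centroids


def cva_jackknife(pc_scores: np.ndarray,
                  groups: np.ndarray | list[str]) -> AssignmentResult:
    """Leave-one-out CVA assignment by Mahalanobis distance to group centroids.

    Each specimen is dropped, the canonical axes are recomputed from the
    rest, and the specimen is assigned to the nearest centroid in CV space
    (ties broken by stable group order).
    """
    x = np.asarray(pc_scores, dtype=float)
    labels = np.asarray(groups).astype(str)
    levels = sorted(set(labels))
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    n, p = x.shape
    min_group = min(np.sum(labels == lv) for lv in levels)
    if min_group <= p:
        p_new = max(1, min_group - 1)
        warnings.warn(
            f"group size {min_group} <= {p} variables; reducing to first {p_new} PCs")
        x = x[:, :p_new]

    confusion = pd.DataFrame(0, index=levels, columns=levels, dtype=int)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        if min(np.sum(labels[keep] == lv) for lv in levels) < 2:
            raise ValueError("a group would empty during jackknife")
        axes, centroids = _cva_axes(x[keep], labels[keep], levels)
        z = x[i] @ axes
        d = np.linalg.norm(centroids - z, axis=1)
        assigned = levels[int(np.argmin(d))]  # argmin is stable: first minimum
        confusion.loc[labels[i], assigned] += 1
    accuracy = float(np.trace(confusion.to_numpy())) / n
    return AssignmentResult(confusion=confusion, accuracy=accuracy, jackknifed=True)


COVARIANCE_FAMILIES = ("spherical", "diag", "full")


@dataclass
class MixtureFit:
    """One Gaussian-mixture fit; ``bic = 2 loglik - n_params ln(n)`` (higher better)."""

    k: int
    covariance_family: str
    bic: float
    loglik: float
    assignments: np.ndarray
    informative: bool
    delta_bic_to_best_multigroup: float = np.nan


def mixture_bic_select(pc_scores: np.ndarray, k_max: int = 4,
                       seed: int = 0) -> tuple[list[MixtureFit], MixtureFit]:
    """Fit Gaussian mixtures for k = 1..k_max across covariance families.

    Models with a single-member cluster are flagged uninformative and passed
    over when choosing the best model. Returns (all fits, best fit).
    """
    x = np.asarray(pc_scores, dtype=float)
    if len(x) < 10:
        raise ValueError("need n >= 10 for mixture selection")
    fits: list[MixtureFit] = []
    for k in range(1, k_max + 1):
        for fam in COVARIANCE_FAMILIES:
            gm = GaussianMixture(
                n_components=k, covariance_type=fam, n_init=10,
                init_params="k-means++", random_state=seed, reg_covar=1e-6,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(x)
            labels = gm.predict(x)
            sizes = np.bincount(labels, minlength=k)
            informative = bool(np.all(sizes > 1))
            fits.append(MixtureFit(
                k=k, covariance_family=fam, bic=float(-gm.bic(x)),
                loglik=float(gm.score(x) * len(x)), assignments=labels,
                informative=informative,
            ))
    multi = [f.bic for f in fits if f.k > 1]
    best_multi = max(multi) if multi else np.nan
    for f in fits:
        f.delta_bic_to_best_multigroup = f.bic - best_multi
    candidates = [f for f in fits if f.informative] or fits
    best = max(candidates, key=lambda f: f.bic)
    return fits, best


def disparity(pc_scores: np.ndarray, method: str = "variance") -> float:
    """Morphological disparity of a sample in (repeatable-) PC space.

    Default ``variance``: sum of squared distances to the sample mean over
    N - 1 (the Procrustes-variance convention; equals the trace of the
    unbiased score covariance). ``mean_distance``: mean Euclidean distance
    to the sample mean.
    """
    x = np.asarray(pc_scores, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if len(x) < 2:
        raise ValueError("disparity undefined for n < 2")
    d2 = np.sum((x - x.mean(axis=0)) ** 2, axis=1)
    if method == "variance":
        return float(d2.sum() / (len(x) - 1))
    if method == "mean_distance":
        return float(np.sqrt(d2).mean())
    raise ValueError(f"unknown disparity method {method!r}")


@dataclass
class DisparityCurve:
    """Rarefied disparity of the modern sample plus fossil-augmented values."""

    sample_sizes: np.ndarray
    mean_disparity: np.ndarray
    ci_upper: np.ndarray          # one-tailed 95% bound (bootstrap 95th pctile)
    augmented: dict[str, float]
    augmented_n: dict[str, int]
    exceeds: dict[str, bool]
    n_boot: int
    method: str = "variance"

    def bound_at(self, n: int) -> float:
        return float(np.interp(n, self.sample_sizes, self.ci_upper))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n": self.sample_sizes, "mean_disparity": self.mean_disparity,
            "ci_upper_95": self.ci_upper,
        })


def disparity_rarefaction(
    modern_scores: np.ndarray,
    fossil_sets: dict[str, np.ndarray] | None = None,
    n_boot: int = 1000,
    sizes: np.ndarray | None = None,
    seed: int = 0,
    level: float = 0.95,
    method: str = "variance",
) -> DisparityCurve:
    """Bootstrap rarefaction of modern disparity with fossil-augmented values.

    For each sample size the modern scores are resampled with replacement
    ``n_boot`` times and disparity recomputed; the one-tailed bound is the
    ``level`` percentile. Each fossil set is pooled with the full modern
    sample, its disparity computed, and compared to the bound interpolated
    at the pooled sample size.
    """
    x = np.asarray(modern_scores, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    rng = np.random.default_rng(seed)
    if sizes is None:
        sizes = np.arange(10, 201, 10)
    sizes = np.asarray(sizes, dtype=int)

    means = np.empty(len(sizes))
    uppers = np.empty(len(sizes))
    n_modern = len(x)
    for si, size in enumerate(sizes):
        idx = rng.integers(0, n_modern, size=(n_boot, size))
        samples = x[idx]                                  # (n_boot, size, p)
        mu = samples.mean(axis=1, keepdims=True)
        d2 = np.sum((samples - mu) ** 2, axis=(1, 2))
        if method == "variance":
            vals = d2 / (size - 1)
        elif method == "mean_distance":
            vals = np.sqrt(np.sum((samples - mu) ** 2, axis=2)).mean(axis=1)
        else:
            raise ValueError(f"unknown disparity method {method!r}")
        means[si] = vals.mean()
        uppers[si] = np.quantile(vals, level)

    augmented: dict[str, float] = {}
    augmented_n: dict[str, int] = {}
    exceeds: dict[str, bool] = {}
    for name, scores in (fossil_sets or {}).items():
        f = np.asarray(scores, dtype=float)
        if f.ndim == 1:
            f = f[:, None]
        if len(f) == 0:
            warnings.warn(f"fossil set {name!r} is empty; skipped")
            continue
        pooled = np.concatenate([x, f], axis=0)
        val = disparity(pooled, method=method)
        augmented[name] = val
        augmented_n[name] = len(pooled)
        bound = float(np.interp(len(pooled), sizes, uppers))
        exceeds[name] = bool(val > bound)

    return DisparityCurve(
        sample_sizes=sizes, mean_disparity=means, ci_upper=uppers,
        augmented=augmented, augmented_n=augmented_n, exceeds=exceeds,
        n_boot=n_boot, method=method,
    )
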