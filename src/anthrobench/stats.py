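"""Comparative error statistics for height/weight estimator groups.

Per-image error statistics, median-across-images summaries with percentile
bootstrap confidence intervals, a k-way Friedman omnibus test on within-image
ranks, and all-pairs two-sided Wilcoxon signed-rank tests with Bonferroni
correction.

Two accuracy notions are distinguished for multi-rater groups.  With
estimate h~_{i,j} from rater j on image i and truth h_i:

* individual accuracy (per image):  median_j |h~_{i,j} - h_i|
* crowd accuracy (per image):       |median_j(h~_{i,j}) - h_i|

For single-estimate groups (mesh chain, experts, baseline) the two
coincide.  Summaries report the median across images, in absolute units and
as a percent of the per-image true value; medians are used because rater
responses are not normally distributed within or across images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .errors import ConfigurationError

ATTRIBUTES = ("height", "weight")

_EST_COL = {"height": "height_est_cm", "weight": "weight_est_kg"}
_TRUTH_ATTR = {"height": "true_height_cm", "weight": "true_weight_kg"}


@dataclass
class ErrorSample:
    """Per-image errors for one (group, attribute, setting) cell.

    ``data`` has columns image_id, abs_error, pct_error (one row per image);
    ``coverage`` counts images excluded for having no usable estimates.
    """

    group: str
    attribute: str
    setting: str
    data: pd.DataFrame
    coverage: dict | None = None


@dataclass(frozen=True)
class ErrorSummary:
    group: str
    attribute: str
    setting: str
    median_abs: float
    median_pct: float
    ci_low: float
    ci_high: float
    n_images: int


@dataclass(frozen=True)
class PairwiseTestResult:
    group_a: str
    group_b: str
    attribute: str
    n: int
    statistic: float
    p_value: float
    corrected_alpha: float
    significant_005: bool  # below the Bonferroni-corrected threshold
    significant_0005: bool  # below one tenth of the corrected threshold
    degenerate: bool = False


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    p_value: float
    n_images: int
    k_groups: int
    dropped_images: int
    method: str


# ---------------------------------------------------------------------------
# Per-image accuracy


def _per_image_frame(estimates, truth, attribute: str) -> pd.DataFrame:
    if attribute not in ATTRIBUTES:
        raise ConfigurationError(f"attribute must be one of {ATTRIBUTES}")
    tmap = {p.participant_id: getattr(p, _TRUTH_ATTR[attribute]) for p in truth}
    rows = []
    for r in estimates:
        est = getattr(r, _EST_COL[attribute])
        if est is None or (isinstance(est, float) and np.isnan(est)):
            continue
        if r.participant_id not in tmap:
            raise ConfigurationError(
                f"estimate for {r.image_id} references unknown participant {r.participant_id}"
            )
        rows.append((r.image_id, float(est), float(tmap[r.participant_id])))
    return pd.DataFrame(rows, columns=["image_id", "est", "truth"])


def _accuracy(
    estimates,
    truth,
    attribute: str,
    mode: str,
    group: str = "",
    setting: str = "all",
    images=None,
    pooling: str = "per_image",
) -> ErrorSample:
    df = _per_image_frame(estimates, truth, attribute)
    coverage = None
    if images is not None:
        expected = {img.image_id for img in images}
        seen = set(df["image_id"])
        missing = expected - seen
        coverage = {"expected": len(expected), "with_estimates": len(expected) - len(missing)}
        if missing:
            warnings.warn(
                f"{len(missing)} image(s) have no usable {attribute} estimates and are excluded"
            )
    if df.empty:
        data = pd.DataFrame(columns=["image_id", "abs_error", "pct_error"])
        return ErrorSample(group, attribute, setting, data, coverage)

    if mode == "individual" and pooling == "pooled":
        # alternative reading: pool all (image, rater) errors without the
        # per-image median; exposed for sensitivity analysis only
        df["abs_error"] = (df["est"] - df["truth"]).abs()
        df["pct_error"] = df["abs_error"] / df["truth"] * 100.0
        data = df[["image_id", "abs_error", "pct_error"]].reset_index(drop=True)
        return ErrorSample(group, attribute, setting, data, coverage)

    g = df.groupby("image_id", sort=True)
    if mode == "individual":
        abs_err = g.apply(lambda d: (d["est"] - d["truth"]).abs().median(), include_groups=False)
    elif mode == "crowd":
        abs_err = g.apply(lambda d: abs(d["est"].median() - d["truth"].iloc[0]), include_groups=False)
    else:
        raise ConfigurationError(f"unknown accuracy mode {mode!r}")
    truth_per_image = g["truth"].first()
    data = pd.DataFrame(
        {
            "image_id": abs_err.index,
            "abs_error": abs_err.values,
            "pct_error": (abs_err / truth_per_image).values * 100.0,
        }
    ).reset_index(drop=True)
    return ErrorSample(group, attribute, setting, data, coverage)


def individual_accuracy(
    estimates, truth, attribute: str, group: str = "", setting: str = "all",
    images=None, pooling: str = "per_image",
) -> ErrorSample:
    """Per image, the median over raters of the absolute error."""
    return _accuracy(estimates, truth, attribute, "individual", group, setting, images, pooling)


def crowd_accuracy(
    estimates, truth, attribute: str, group: str = "", setting: str = "all", images=None
) -> ErrorSample:
    """Per image, the absolute error of the median-aggregated estimate."""
    return _accuracy(estimates, truth, attribute, "crowd", group, setting, images)


# ---------------------------------------------------------------------------
# Summaries with bootstrap CIs


def bootstrap_median_ci(
    values: np.ndarray, n_boot: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap CI of the median, resampling with replacement."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        m = float(np.median(values)) if len(values) else np.nan
        return m, m
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    meds = np.median(values[idx], axis=1)
    lo, hi = np.quantile(meds, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def summarize(
    sample: ErrorSample, n_boot: int = 1000, level: float = 0.95, seed: int = 0
) -> ErrorSummary:
    """Median across images plus a percentile bootstrap CI of that median.

    Resampling is at the image level (images are the unit of analysis).
    Order-invariant: per-image rows are sorted by image_id before use.
    """
    if sample.data.empty:
        raise ConfigurationError("cannot summarize an empty error sample")
    data = sample.data.sort_values("image_id")
    abs_err = data["abs_error"].to_numpy(dtype=float)
    pct_err = data["pct_error"].to_numpy(dtype=float)
    if len(abs_err) < 2:
        warnings.warn("fewer than 2 images: confidence interval is degenerate")
    lo, hi = bootstrap_median_ci(abs_err, n_boot=n_boot, level=level, seed=seed)
    return ErrorSummary(
        group=sample.group,
        attribute=sample.attribute,
        setting=sample.setting,
        median_abs=float(np.median(abs_err)),
        median_pct=float(np.median(pct_err)),
        ci_low=lo,
        ci_high=hi,
        n_images=len(abs_err),
    )


def summaries_to_df(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": s.group,
                "attribute": s.attribute,
                "setting": s.setting,
                "median_abs": s.median_abs,
                "median_pct": s.median_pct,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "n_images": s.n_images,
            }
            for s in summaries
        ]
    )


# ---------------------------------------------------------------------------
# Group matrix helpers


def error_matrix(samples: dict[str, ErrorSample]) -> pd.DataFrame:
    """Align per-image errors of several groups into an images x groups frame.

    Rows are image_ids, columns group names; cells are absolute errors, NaN
    where a group lacks an estimate for that image.
    """
    cols = {}
    for name, sample in samples.items():
        cols[name] = sample.data.set_index("image_id")["abs_error"]
    return pd.DataFrame(cols)


def _complete_case(matrix: pd.DataFrame) -> tuple[np.ndarray, int]:
    full = matrix.dropna()
    return full.to_numpy(dtype=float), len(matrix) - len(full)


def _friedman_statistic(data: np.ndarray) -> float:
    """Friedman chi-square on within-row average ranks, with tie correction.

    Matches scipy.stats.friedmanchisquare (cross-checked in the test suite);
    kept as a standalone routine so the permutation null can reuse it
    vectorised.
    """
    n, k = data.shape
    ranks = sps.rankdata(data, axis=1)
    col_sums = ranks.sum(axis=0)
    chisq = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3 * n * (k + 1)
    # tie correction
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1 - ties / (n * k * (k * k - 1))
    if c <= 0:
        return 0.0
    return float(chisq / c)


def friedman(
    errors_by_group: pd.DataFrame | np.ndarray,
    p_method: str = "chisq",
    n_perm: int = 10000,
    seed: int = 0,
) -> FriedmanResult:
    """k-way Friedman omnibus test on the images x groups error matrix.

    Rows with missing cells are dropped (complete-case).  The p-value comes
    from the chi-square approximation with k-1 degrees of freedom (adequate
    for dozens of images) or, with ``p_method='permutation'``, from
    within-row permutations of the observations.
    """
    if isinstance(errors_by_group, pd.DataFrame):
        data, dropped = _complete_case(errors_by_group)
    else:
        data = np.asarray(errors_by_group, dtype=float)
        dropped = int(np.isnan(data).any(axis=1).sum())
        data = data[~np.isnan(data).any(axis=1)]
    if data.ndim != 2 or data.shape[1] < 2:
        raise ConfigurationError("friedman needs at least 2 groups")
    if data.shape[0] < 1:
        raise ConfigurationError("friedman needs at least 1 complete image row")
    n, k = data.shape
    stat = _friedman_statistic(data)
    if p_method == "chisq":
        p = float(sps.chi2.sf(stat, k - 1))
    elif p_method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permuted(data, axis=1)
            if _friedman_statistic(perm) >= stat - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
    else:
        raise ConfigurationError(f"unknown p_method {p_method!r}")
    return FriedmanResult(stat, p, n, k, dropped, p_method)


def bonferroni_threshold(alpha: float, k_groups: int) -> float:
    """Per-test threshold alpha / C(k, 2) for all-pairs testing."""
    n_pairs = k_groups * (k_groups - 1) // 2
    if n_pairs < 1:
        raise ConfigurationError("need at least 2 groups for pairwise testing")
    return alpha / n_pairs


def pairwise_wilcoxon(
    errors_by_group: pd.DataFrame,
    attribute: str = "",
    alpha: float = 0.05,
    zero_tol: float = 1e-9,
) -> list[PairwiseTestResult]:
    """All-pairs two-sided Wilcoxon signed-rank tests on per-image errors.

    For k groups, all k(k-1)/2 pairs are tested on paired (complete-case)
    per-image error differences; zero differences (absolute value at or
    below ``zero_tol``, the package's geometric epsilon) are dropped before
    ranking.  The exact null distribution is used for n <= 25 without ties,
    the tie-corrected normal approximation otherwise.  Significance flags
    use the Bonferroni-corrected threshold alpha / n_pairs, and a ten-times
    stricter flag for the second star level.
    """
    groups = list(errors_by_group.columns)
    if len(groups) < 2:
        raise ConfigurationError("need at least 2 groups")
    thr = bonferroni_threshold(alpha, len(groups))
    results = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            pair = errors_by_group[[ga, gb]].dropna()
            d = (pair[ga] - pair[gb]).to_numpy(dtype=float)
            d = d[np.abs(d) > zero_tol]
            if len(d) == 0:
                results.append(
                    PairwiseTestResult(ga, gb, attribute, 0, 0.0, 1.0, thr, False, False, True)
                )
                continue
            has_ties = len(np.unique(np.abs(d))) < len(d)
            method = "exact" if (len(d) <= 25 and not has_ties) else "approx"
            res = sps.wilcoxon(
                d, zero_method="wilcox", alternative="two-sided", method=method, correction=False
            )
            p = float(res.pvalue)
            results.append(
                PairwiseTestResult(
                    group_a=ga,
                    group_b=gb,
                    attribute=attribute,
                    n=len(d),
                    statistic=float(res.statistic),
                    p_value=p,
                    corrected_alpha=thr,
                    significant_005=p < thr,
                    significant_0005=p < thr / 10.0,
                )
            )
    return results


def pairwise_to_df(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": r.group_a,
                "group_b": r.group_b,
                "attribute": r.attribute,
                "n": r.n,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "corrected_alpha": r.corrected_alpha,
                "significant_005": r.significant_005,
                "significant_0005": r.significant_0005,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Closed forms


def folded_normal_median(mu: float, sigma: float) -> float:
    """Median of |X| for X ~ Normal(mu, sigma).

    Governs the error of a constant estimator against a normal population.
    """
    if sigma < 0:
        raise ConfigurationError("sigma must be non-negative")
    if sigma == 0:
        return abs(mu)

    def cdf(m):
        return sps.norm.cdf((m - mu) / sigma) - sps.norm.cdf((-m - mu) / sigma)

    hi = abs(mu) + 10 * sigma
    return float(brentq(lambda m: cdf(m) - 0.5, 0.0, hi, xtol=1e-12))


def mixture_folded_median(components) -> float:
    """Median of |X| where X is a finite mixture of normals.

    ``components`` is an iterable of (weight, mu, sigma); weights are
    normalised.  Used as the large-cohort closed form for the pooled
    baseline error of a gendered cohort.
    """
    comps = [(float(w), float(mu), float(sd)) for w, mu, sd in components]
    total = sum(w for w, _, _ in comps)
    if total <= 0:
        raise ConfigurationError("mixture weights must sum to a positive value")

    def cdf(m):
        acc = 0.0
        for w, mu, sd in comps:
            if sd == 0:
                acc += w * (1.0 if abs(mu) <= m else 0.0)
            else:
                acc += w * (sps.norm.cdf((m - mu) / sd) - sps.norm.cdf((-m - mu) / sd))
        return acc / total

    hi = max(abs(mu) + 10 * max(sd, 1e-12) for _, mu, sd in comps)
    return float(brentq(lambda m: cdf(m) - 0.5, 0.0, hi, xtol=1e-12))
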