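"""Visual grading characteristics (VGC) analysis of paired ordinal ratings.

VGC compares image-quality ratings between two imaging conditions with a
non-parametric, rank-invariant construction: sweeping a threshold t over the
ordinal scale, the fraction of test-condition ratings >= t is plotted
against the fraction of reference-condition ratings >= t.  The area under
this curve (AUC_VGC) measures the separation: 0.5 means the two conditions
are rated alike, > 0.5 means the test condition is rated higher.

With trapezoidal integration the area is identical to the tie-corrected
pairwise exceedance statistic

    AUC = [ #(test > ref) + 0.5 * #(test = ref) ] / (n_test * n_ref)

over all test x reference rating pairs pooled across readers and cases —
the Mann-Whitney AUC with half credit for ties.  A binormal estimate (ML
latent-normal fit with shared cut-points) is available as an alternative
smooth estimator.

Uncertainty comes from bootstrap resampling honouring the paired design:
a drawn case contributes both of its condition ratings.  In the
fixed-reader mode every original reader stays in each replicate and only
cases are resampled (conclusions apply to these readers); in the
random-reader mode readers are resampled with replacement before cases
(conclusions generalise to a reader population).  A difference is declared
significant when the 95% percentile CI excludes 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from .ratings import RatingSet

__all__ = [
    "OrientedRatings", "VGCResult",
    "orient_ratings", "vgc_curve", "auc_trapezoidal", "auc_binormal",
    "bootstrap_vgc", "per_reader_auc", "proportion_table",
]


@dataclass
class OrientedRatings:
    """Paired ratings re-coded so that larger always means better quality.

    Ratings are stored as (n_cases, n_readers) matrices aligned between the
    two conditions; ``test`` / ``reference`` expose the pooled 1D views used
    by the curve and AUC computations.
    """

    test_matrix: np.ndarray
    reference_matrix: np.ndarray
    scale_size: int
    case_ids: list
    reader_ids: list

    def __post_init__(self) -> None:
        if self.test_matrix.shape != self.reference_matrix.shape:
            raise ValueError("test and reference matrices must be aligned")
        for m in (self.test_matrix, self.reference_matrix):
            if m.min() < 1 or m.max() > self.scale_size:
                raise ValueError("oriented ratings must lie in 1..scale_size")

    @property
    def test(self) -> np.ndarray:
        return self.test_matrix.ravel()

    @property
    def reference(self) -> np.ndarray:
        return self.reference_matrix.ravel()

    @property
    def n_cases(self) -> int:
        return self.test_matrix.shape[0]

    @property
    def n_readers(self) -> int:
        return self.test_matrix.shape[1]


def orient_ratings(ratings: RatingSet, question_id: str) -> OrientedRatings:
    """Extract one question's paired ratings, oriented so larger = better.

    Five-step criterion scales are coded 1 = "confident the criterion is
    fulfilled" (best), so they are reversed (raw r -> 6 - r); three-step
    acceptability scales are coded 1 = unacceptable .. 3 = fully acceptable
    and are kept as-is.
    """
    sub = ratings.data[ratings.data["question_id"] == question_id]
    if sub.empty:
        raise ValueError(f"no ratings for question {question_id!r}")
    scales = sub["scale_size"].unique()
    if len(scales) != 1:
        raise ValueError(f"question {question_id!r} mixes scale sizes {sorted(scales)}")
    scale = int(scales[0])
    if scale not in (3, 5):
        raise ValueError(f"unsupported scale size {scale}")

    mats = {}
    pivots = {}
    for cond in ratings.conditions:
        part = sub[sub["condition"] == cond]
        pivots[cond] = part.pivot(index="case_id", columns="reader_id", values="rating")
    ref_p, test_p = pivots[ratings.reference], pivots[ratings.test]
    # align and check pairing
    test_p = test_p.reindex(index=ref_p.index, columns=ref_p.columns)
    for name, p in (("reference", ref_p), ("test", test_p)):
        if p.isna().any().any():
            r, c = np.argwhere(p.isna().values)[0]
            raise ValueError(f"missing {name} rating for (case, reader) = "
                             f"({p.index[r]!r}, {p.columns[c]!r}) on {question_id!r}")
    for cond, p in (("reference", ref_p), ("test", test_p)):
        raw = p.values.astype(int)
        mats[cond] = (scale + 1 - raw) if scale == 5 else raw
    return OrientedRatings(test_matrix=mats["test"], reference_matrix=mats["reference"],
                           scale_size=scale, case_ids=list(ref_p.index),
                           reader_ids=list(ref_p.columns))


def vgc_curve(oriented: OrientedRatings) -> np.ndarray:
    """VGC operating points: for each threshold t from scale_size down to 1,
    x = fraction of reference ratings >= t, y = fraction of test ratings >= t,
    with (0, 0) prepended (the t = 1 point is (1, 1))."""
    test, ref = oriented.test, oriented.reference
    pts = [(0.0, 0.0)]
    for t in range(oriented.scale_size, 0, -1):
        pts.append((float(np.mean(ref >= t)), float(np.mean(test >= t))))
    return np.array(pts)


def _category_counts(values: np.ndarray, scale_size: int) -> np.ndarray:
    return np.bincount(values.astype(int) - 1, minlength=scale_size).astype(float)


def _auc_from_counts(test_counts: np.ndarray, ref_counts: np.ndarray) -> float:
    """Tie-corrected pairwise AUC from per-category histograms."""
    ref_below = np.concatenate([[0.0], np.cumsum(ref_counts)[:-1]])
    wins = float(np.dot(test_counts, ref_below))
    ties = float(np.dot(test_counts, ref_counts))
    n = test_counts.sum() * ref_counts.sum()
    return (wins + 0.5 * ties) / n


def auc_trapezoidal(oriented: OrientedRatings) -> float:
    """Trapezoidal area under the VGC curve."""
    pts = vgc_curve(oriented)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def per_reader_auc(oriented: OrientedRatings) -> np.ndarray:
    """Diagnostic: trapezoidal AUC computed within each reader separately."""
    k = oriented.scale_size
    return np.array([
        _auc_from_counts(_category_counts(oriented.test_matrix[:, r], k),
                         _category_counts(oriented.reference_matrix[:, r], k))
        for r in range(oriented.n_readers)
    ])


def auc_binormal(oriented: OrientedRatings) -> float:
    """Binormal AUC: ML fit of a latent-normal ordinal model.

    Reference ratings are modelled as N(0, 1) and test ratings as N(mu,
    sigma) cut by shared ascending thresholds; the fitted AUC is
    Phi(mu / sqrt(1 + sigma^2)).  Requires at least two categories in use.
    """
    k = oriented.scale_size
    tc = _category_counts(oriented.test, k)
    rc = _category_counts(oriented.reference, k)
    pooled = tc + rc
    if np.count_nonzero(pooled) < 2:
        raise ValueError("binormal fit needs at least two rating categories in use")

    # initial cut-points from pooled empirical quantiles (clipped away from 0/1)
    cum = np.cumsum(pooled)[:-1] / pooled.sum()
    cum = np.clip(cum, 1e-3, 1 - 1e-3)
    c0 = norm.ppf(cum)
    # enforce strict ascent in the starting point
    for i in range(1, len(c0)):
        c0[i] = max(c0[i], c0[i - 1] + 1e-3)

    def unpack(theta):
        c = np.empty(k - 1)
        c[0] = theta[0]
        if k > 2:
            c[1:] = theta[0] + np.cumsum(np.exp(theta[1:k - 1]))
        mu = theta[k - 1]
        sigma = np.exp(theta[k])
        return c, mu, sigma

    def cell_probs(c, mu, sigma):
        z = np.concatenate([[-np.inf], (c - mu) / sigma, [np.inf]])
        return np.clip(np.diff(norm.cdf(z)), 1e-300, None)

    def nll(theta):
        c, mu, sigma = unpack(theta)
        p_ref = cell_probs(c, 0.0, 1.0)
        p_test = cell_probs(c, mu, sigma)
        return -(np.dot(rc, np.log(p_ref)) + np.dot(tc, np.log(p_test)))

    theta0 = np.concatenate([[c0[0]], np.log(np.maximum(np.diff(c0), 1e-3)),
                             [0.0], [0.0]])
    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"maxiter": 20000, "xatol": 1e-8, "fatol": 1e-10})
    if not np.isfinite(res.fun):
        raise ValueError("binormal fit failed to converge")
    _, mu, sigma = unpack(res.x)
    return float(norm.cdf(mu / np.sqrt(1.0 + sigma ** 2)))


@dataclass
class VGCResult:
    question_id: str
    auc: float
    ci_low: float
    ci_high: float
    mode: str                  # "fixed_reader" | "random_reader"
    estimator: str             # estimator of the point estimate
    n_boot: int
    seed: int
    significant: bool
    boot_aucs: np.ndarray | None = None


def _bootstrap_aucs(oriented: OrientedRatings, mode: str, n_boot: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Vectorised bootstrap of the trapezoidal AUC.

    fixed_reader: resample cases with replacement, keep all readers.
    random_reader: resample readers with replacement, then cases.
    A drawn case contributes both its test and reference ratings (paired).
    """
    nc, nr = oriented.n_cases, oriented.n_readers
    k = oriented.scale_size
    case_idx = rng.integers(0, nc, size=(n_boot, nc))
    if mode == "fixed_reader":
        t = oriented.test_matrix[case_idx]               # (B, nc, nr)
        r = oriented.reference_matrix[case_idx]
    elif mode == "random_reader":
        reader_idx = rng.integers(0, nr, size=(n_boot, nr))
        t = oriented.test_matrix[case_idx[:, :, None], reader_idx[:, None, :]]
        r = oriented.reference_matrix[case_idx[:, :, None], reader_idx[:, None, :]]
    else:
        raise ValueError("mode must be 'fixed_reader' or 'random_reader'")
    t = t.reshape(n_boot, -1)
    r = r.reshape(n_boot, -1)
    offsets = (np.arange(n_boot) * k)[:, None]
    tc = np.bincount((t - 1 + offsets).ravel(), minlength=n_boot * k) \
           .reshape(n_boot, k).astype(float)
    rc = np.bincount((r - 1 + offsets).ravel(), minlength=n_boot * k) \
           .reshape(n_boot, k).astype(float)
    ref_below = np.concatenate([np.zeros((n_boot, 1)), np.cumsum(rc, axis=1)[:, :-1]], axis=1)
    wins = (tc * ref_below).sum(axis=1)
    ties = (tc * rc).sum(axis=1)
    n_pairs = tc.sum(axis=1) * rc.sum(axis=1)
    return (wins + 0.5 * ties) / n_pairs


def bootstrap_vgc(ratings: RatingSet, question_id: str, mode: str = "fixed_reader",
                  n_boot: int = 2000, seed: int = 0,
                  estimator: str = "trapezoidal") -> VGCResult:
    """AUC_VGC point estimate with a 95% percentile bootstrap CI.

    Replicate AUCs are always trapezoidal; ``estimator`` selects how the
    point estimate itself is computed ("trapezoidal" or "binormal").
    """
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    oriented = orient_ratings(ratings, question_id)
    if oriented.n_cases < 2:
        raise ValueError("bootstrap needs at least 2 cases")
    if estimator == "trapezoidal":
        point = auc_trapezoidal(oriented)
    elif estimator == "binormal":
        point = auc_binormal(oriented)
    else:
        raise ValueError("estimator must be 'trapezoidal' or 'binormal'")
    rng = np.random.default_rng(seed)
    aucs = _bootstrap_aucs(oriented, mode, n_boot, rng)
    ci_low, ci_high = np.percentile(aucs, [2.5, 97.5])
    return VGCResult(question_id=question_id, auc=point,
                     ci_low=float(ci_low), ci_high=float(ci_high),
                     mode=mode, estimator=estimator, n_boot=n_boot, seed=seed,
                     significant=bool(ci_low > 0.5 or ci_high < 0.5),
                     boot_aucs=aucs)


def proportion_table(ratings: RatingSet, question_ids=None) -> pd.DataFrame:
    """Proportion of each raw answer category per (question, condition),
    pooled over readers and cases.  Rows: (question_id, condition);
    columns: category 1..scale_size (absent categories get 0)."""
    data = ratings.data
    if question_ids is not None:
        data = data[data["question_id"].isin(question_ids)]
    if data.empty:
        raise ValueError("no ratings selected")
    max_scale = int(data["scale_size"].max())
    counts = (data.groupby(["question_id", "condition"])["rating"]
                  .value_counts().unstack(fill_value=0)
                  .reindex(columns=range(1, max_scale + 1), fill_value=0))
    props = counts.div(counts.sum(axis=1), axis=0)
    return props
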