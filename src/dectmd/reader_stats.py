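"""Multi-reader diagnostic accuracy for clustered two-dataset comparisons.

Readers grade each patient on a 5-point confidence scale on two image
datasets ("conventional" and "optimal"); a rating of 3-5 is a positive
call. Accuracy metrics are compared between datasets with binomial GEE
(logit link, exchangeable working correlation clustered on patient, robust
sandwich SE); confidence-rating shifts use a proportional-odds model with a
cluster-robust (Huber-White) sandwich variance; inter-rater agreement uses
Cohen's and Fleiss' kappa with large-sample standard errors.

Ratings tables are pandas DataFrames with columns
``reader_id, group, patient_id, dataset, rating, truth`` where dataset is
"conventional"/"optimal" and truth is "pdac"/"no_pdac".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats import inter_rater

__all__ = [
    "ConfusionCounts",
    "MetricValue",
    "DiagnosticSummary",
    "ComparisonResult",
    "KappaResult",
    "METRICS",
    "binarize",
    "confusion",
    "metrics",
    "pool",
    "gee_compare",
    "ordinal_compare",
    "cohen_kappa",
    "fleiss_kappa",
    "kappa_z_test",
]

RATING_COLUMNS = ("reader_id", "group", "patient_id", "dataset", "rating", "truth")
METRICS = ("sensitivity", "specificity", "ppv", "npv", "accuracy")
POSITIVE_THRESHOLD = 3


def binarize(rating: int) -> bool:
    """Positive call iff the 5-point confidence rating is 3-5."""
    r = int(rating)
    if r != rating or not 1 <= r <= 5:
        raise ValueError(f"rating must be an integer in 1..5, got {rating!r}")
    return r >= POSITIVE_THRESHOLD


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricValue:
    """One diagnostic metric as numerator/denominator plus integer percent."""

    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def proportion(self) -> float:
        return self.numerator / self.denominator if self.defined else np.nan

    @property
    def percent(self) -> int | None:
        # Half-up rounding to match how printed percentages are conventionally formed.
        if not self.defined:
            return None
        return int(np.floor(100.0 * self.numerator / self.denominator + 0.5))

    def __str__(self) -> str:
        if not self.defined:
            return "undefined"
        return f"{self.percent} ({self.numerator}/{self.denominator})"


@dataclass(frozen=True)
class DiagnosticSummary:
    sensitivity: MetricValue
    specificity: MetricValue
    ppv: MetricValue
    npv: MetricValue
    accuracy: MetricValue

    def __getitem__(self, metric: str) -> MetricValue:
        return getattr(self, metric)


@dataclass(frozen=True)
class ComparisonResult:
    """Dataset comparison on one metric or rating stratum."""

    metric: str
    estimate: float | None  # difference on the linear-predictor (logit) scale
    robust_se: float | None
    p_two_sided: float | None
    nc: bool = False
    nc_reason: str | None = None


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    undefined: bool = False


def _validate_ratings(df: pd.DataFrame) -> None:
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ratings table missing column(s) {missing}")
    if df.duplicated(subset=["reader_id", "patient_id", "dataset"]).any():
        raise ValueError("duplicate (reader, patient, dataset) rows in ratings table")


def confusion(ratings: pd.DataFrame) -> ConfusionCounts:
    """Cross binarized calls with truth over a nonempty ratings subset."""
    if len(ratings) == 0:
        raise ValueError("cannot tally an empty ratings subset")
    call = ratings["rating"].map(binarize).to_numpy(bool)
    truth = (ratings["truth"] == "pdac").to_numpy(bool)
    return ConfusionCounts(
        tp=int((call & truth).sum()),
        fp=int((call & ~truth).sum()),
        tn=int((~call & ~truth).sum()),
        fn=int((~call & truth).sum()),
    )


def metrics(counts: ConfusionCounts) -> DiagnosticSummary:
    """Sensitivity, specificity, PPV, NPV and accuracy from a 2x2 table.

    Each metric carries its numerator/denominator so the printed
    ``percent (num/den)`` form can be reproduced exactly; a metric with a
    zero denominator is flagged undefined rather than raising.
    """
    c = counts
    return DiagnosticSummary(
        sensitivity=MetricValue(c.tp, c.tp + c.fn),
        specificity=MetricValue(c.tn, c.tn + c.fp),
        ppv=MetricValue(c.tp, c.tp + c.fp),
        npv=MetricValue(c.tn, c.tn + c.fn),
        accuracy=MetricValue(c.tp + c.tn, c.total),
    )


def pool(per_reader: list[ConfusionCounts]) -> ConfusionCounts:
    """Componentwise sum of per-reader confusion counts."""
    if not per_reader:
        raise ValueError("nothing to pool")
    out = ConfusionCounts()
    for c in per_reader:
        out = out + c
    return out


def _metric_outcome(df: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Subset rows and attach the binary outcome relevant to ``metric``.

    sensitivity: positive call among truth-positive rows; specificity:
    negative call among truth-negative rows; accuracy: correct call among
    all rows; PPV/NPV condition on the call (truth-positive among called
    positive / truth-negative among called negative) — clustering stays at
    the patient level even though the conditioning set then differs
    between datasets.
    """
    call = df["rating"].map(binarize)
    truth = df["truth"] == "pdac"
    if metric == "sensitivity":
        sub, outcome = df[truth], call[truth].astype(int)
    elif metric == "specificity":
        sub, outcome = df[~truth], (~call[~truth]).astype(int)
    elif metric == "accuracy":
        sub, outcome = df, (call == truth).astype(int)
    elif metric == "ppv":
        sub, outcome = df[call], truth[call].astype(int)
    elif metric == "npv":
        sub, outcome = df[~call], (~truth[~call]).astype(int)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    out = sub.copy()
    out["outcome"] = outcome
    return out


def _identical_across_datasets(sub: pd.DataFrame) -> bool:
    piv = sub.pivot_table(
        index=["reader_id", "patient_id"], columns="dataset", values="outcome",
        aggfunc="first",
    )
    if {"conventional", "optimal"} - set(piv.columns):
        return False
    both = piv.dropna()
    return len(both) == len(piv) and bool((both["conventional"] == both["optimal"]).all())


def gee_compare(
    ratings: pd.DataFrame,
    metric: str,
    corstruct: str = "exchangeable",
    maxiter: int = 100,
    tol: float = 1e-8,
) -> ComparisonResult:
    """Compare one diagnostic metric between datasets with binomial GEE.

    Fits ``outcome ~ dataset`` (logit link) with the chosen working
    correlation clustered on patient and reports the robust-sandwich Wald
    two-sided p for the dataset effect (optimal vs conventional, on the
    log-odds scale). Mirrors a standard clustered multi-reader analysis:
    the result is flagged not-calculable (nc) when the outcomes are
    identical across datasets, when either dataset attains 100% on the
    metric, or when the fit fails to converge.
    """
    _validate_ratings(ratings)
    sub = _metric_outcome(ratings, metric)
    for ds in ("conventional", "optimal"):
        part = sub[sub["dataset"] == ds]
        if len(part) == 0:
            return ComparisonResult(metric, None, None, None, True, f"no {ds} rows")
        if part["outcome"].mean() == 1.0:
            return ComparisonResult(metric, None, None, None, True, f"{ds} at 100%")
    if _identical_across_datasets(sub):
        return ComparisonResult(metric, None, None, None, True, "identical outcomes")
    if sub["outcome"].nunique() == 1:
        return ComparisonResult(metric, None, None, None, True, "constant outcome")

    exog = sm.add_constant((sub["dataset"] == "optimal").astype(float).rename("optimal"))
    cov = {
        "exchangeable": sm.cov_struct.Exchangeable,
        "independence": sm.cov_struct.Independence,
    }[corstruct]()
    model = sm.GEE(
        sub["outcome"].to_numpy(float),
        exog,
        groups=sub["patient_id"].to_numpy(),
        family=sm.families.Binomial(),
        cov_struct=cov,
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=maxiter, ctol=tol)
        if not getattr(res, "converged", True):
            return ComparisonResult(metric, None, None, None, True, "non-convergence")
    except Exception as err:  # separation, singular working cov, ...
        return ComparisonResult(metric, None, None, None, True, f"fit failed: {err}")
    est = float(res.params.iloc[1])
    se = float(res.bse.iloc[1])
    p = float(2 * stats.norm.sf(abs(est / se)))
    return ComparisonResult(metric, est, se, p)


def ordinal_compare(ratings: pd.DataFrame, truth_stratum: str) -> ComparisonResult:
    """Compare 5-point confidence ratings between datasets in one truth stratum.

    Proportional-odds (ordinal logistic) model on the rating with a
    dataset indicator, variance corrected by a patient-level Huber-White
    cluster sandwich. ``truth_stratum`` is "pdac" or "no_pdac". A positive
    estimate means the optimal dataset shifts ratings upward.
    """
    _validate_ratings(ratings)
    sub = ratings[ratings["truth"] == truth_stratum]
    name = f"ratings[{truth_stratum}]"
    if sub.empty or sub["dataset"].nunique() < 2:
        return ComparisonResult(name, None, None, None, True, "missing dataset arm")
    if sub["rating"].nunique() < 2:
        return ComparisonResult(name, None, None, None, True, "degenerate rating distribution")
    y = pd.Categorical(sub["rating"], categories=sorted(sub["rating"].unique()), ordered=True)
    x = (sub["dataset"] == "optimal").astype(float).to_frame("optimal")
    model = OrderedModel(y, x, distr="logit")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="bfgs", maxiter=200, disp=False)
        score_obs = model.score_obs(res.params)
        bread = np.linalg.inv(-model.hessian(res.params))
    except Exception as err:
        return ComparisonResult(name, None, None, None, True, f"fit failed: {err}")
    groups = sub["patient_id"].to_numpy()
    meat = np.zeros((score_obs.shape[1],) * 2)
    for g in np.unique(groups):
        s_g = score_obs[groups == g].sum(axis=0)
        meat += np.outer(s_g, s_g)
    n_g = len(np.unique(groups))
    meat *= n_g / (n_g - 1)  # small-sample cluster correction
    cov = bread @ meat @ bread
    est = float(np.asarray(res.params)[0])  # exog coefficients precede thresholds
    se = float(np.sqrt(cov[0, 0]))
    p = float(2 * stats.norm.sf(abs(est / se)))
    return ComparisonResult(name, est, se, p)


def _calls_constant(*call_arrays: np.ndarray) -> bool:
    merged = np.concatenate([np.asarray(c) for c in call_arrays])
    return np.unique(merged).size < 2


def cohen_kappa(calls_a, calls_b) -> KappaResult:
    """Unweighted Cohen kappa between two raters' paired calls.

    Standard error from the Fleiss-Cohen-Everitt large-sample variance
    (as implemented in statsmodels). Constant calls by both raters leave
    kappa undefined.
    """
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("need two equal-length nonempty call vectors")
    if _calls_constant(a, b):
        return KappaResult(np.nan, np.nan, undefined=True)
    cats = np.unique(np.concatenate([a, b]))
    table = np.array([[np.sum((a == ca) & (b == cb)) for cb in cats] for ca in cats])
    res = inter_rater.cohens_kappa(table, return_results=True)
    return KappaResult(float(res.kappa), float(np.sqrt(res.var_kappa)))


def fleiss_kappa(calls: np.ndarray) -> KappaResult:
    """Fleiss kappa for m >= 2 raters over N items.

    ``calls`` is an (N, m) array of categorical calls (one column per
    rater). The point estimate follows the standard multi-rater
    chance-corrected agreement; the SE is the Fleiss (1971) large-sample
    formula based on the category marginals.
    """
    arr = np.asarray(calls)
    if arr.ndim != 2 or arr.shape[1] < 2 or arr.shape[0] == 0:
        raise ValueError("need an (N items, m>=2 raters) array of calls")
    if _calls_constant(arr.ravel()):
        return KappaResult(np.nan, np.nan, undefined=True)
    n_items, m = arr.shape
    cats = np.unique(arr)
    counts = np.stack([(arr == c).sum(axis=1) for c in cats], axis=1)
    kappa = float(inter_rater.fleiss_kappa(counts, method="fleiss"))
    p_j = counts.sum(axis=0) / (n_items * m)
    p_e = float(np.sum(p_j**2))
    num = p_e - (2 * m - 3) * p_e**2 + 2 * (m - 2) * float(np.sum(p_j**3))
    var = 2.0 / (n_items * m * (m - 1)) * num / (1 - p_e) ** 2
    return KappaResult(kappa, float(np.sqrt(max(var, 0.0))))


def kappa_z_test(k1: float, se1: float, k2: float, se2: float) -> tuple[float, float]:
    """Two-sided z-test for equality of two asymptotically normal kappas."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("kappa standard errors must be positive")
    z = (k1 - k2) / np.hypot(se1, se2)
    return float(z), float(2 * stats.norm.sf(abs(z)))
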