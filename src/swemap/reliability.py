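"""Test-retest reliability and regional statistics.

The reliability metric is the two-way random-effects, absolute-agreement,
single-measure intraclass correlation coefficient ICC(2,1).  With a table
``X`` of n targets x k sessions, a two-way ANOVA without replication gives
mean squares for rows (MSR), columns (MSC) and error (MSE), and

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).

The 95% confidence interval follows the F-based absolute-agreement
single-measure construction of McGraw & Wong, implemented directly from
the formulas.  The standard error of measurement is, by default,

    SEm = SD(X) * sqrt(1 - ICC)

with the SD taken over all n*k entries (an ANOVA-based sqrt(MSE) variant
is available behind a flag).  ICC estimates are banded qualitatively as
poor (<= 0.2), fair (0.21-0.4), moderate (0.41-0.6), good (0.61-0.8) and
very good (> 0.8).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .parameterization import ParameterizedMap, subject_profiles

__all__ = [
    "ReliabilityResult",
    "RegionalReliability",
    "PairedTResult",
    "AssociationBin",
    "two_way_mean_squares",
    "icc_2_1",
    "sem_measure",
    "classify_icc",
    "whole_muscle_reliability",
    "regional_reliability",
    "paired_t",
    "regional_contrast",
    "spearman_rho",
    "regional_association",
    "normalized_mehs",
    "benjamini_hochberg",
]

logger = logging.getLogger(__name__)

BANDS = ("poor", "fair", "moderate", "good", "very_good")
DOMAINS = ("inter_regional", "inter_subject")


def _clean_table(X) -> tuple[np.ndarray, int]:
    """Drop rows with any missing entry; return (table, n_dropped)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("measurement table must be 2D (targets x sessions)")
    keep = np.all(np.isfinite(X), axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d row(s) with missing entries", n_dropped)
    return X[keep], n_dropped


def two_way_mean_squares(X) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the two-way ANOVA without replication."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 targets and 2 sessions")
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    return (
        float(ss_rows / (n - 1)),
        float(ss_cols / (k - 1)),
        float(max(ss_err, 0.0) / ((n - 1) * (k - 1))),
    )


@dataclass
class ReliabilityResult:
    icc: float
    ci95: tuple[float, float]
    sem: float
    band: str | None
    anova: tuple[float, float, float, int, int]  # MSR, MSC, MSE, n, k
    status: str = "ok"  # "ok" | "undefined"
    n_dropped: int = 0


def _icc_ci(icc: float, msr: float, msc: float, mse: float, n: int, k: int,
            alpha: float = 0.05) -> tuple[float, float]:
    """McGraw & Wong F-based CI for the absolute-agreement single-measure ICC."""
    if mse == 0 and msc == 0:
        return (icc, icc)
    if mse > 0:
        fj = msc / mse
        a = k * icc * fj + n * (1 + (k - 1) * icc) - k * icc
        vn = (k - 1) * (n - 1) * a**2
        vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd
    else:
        v = float(k - 1)  # limit of the Satterthwaite df as MSE -> 0
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    return (float(min(lower, upper)), float(max(lower, upper)))


def icc_2_1(X, alpha: float = 0.05, sem_method: str = "sd") -> ReliabilityResult:
    """ICC(2,1) with 95% CI, SEm and qualitative band.

    Rows with missing entries are dropped (listwise) with a logged count.
    An all-constant table has no between-target variance to agree on and
    yields an explicit ``status="undefined"`` result.
    """
    X, n_dropped = _clean_table(X)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 complete targets and 2 sessions")
    n, k = X.shape
    msr, msc, mse = two_way_mean_squares(X)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    anova = (msr, msc, mse, n, k)
    # an (exactly) constant table has no between-target variance to agree
    # on; detect it before floating-point residue in the sums of squares
    # can masquerade as signal
    if np.ptp(X) == 0 or denom == 0:
        return ReliabilityResult(
            icc=float("nan"), ci95=(float("nan"), float("nan")), sem=float("nan"),
            band=None, anova=anova, status="undefined", n_dropped=n_dropped,
        )
    icc = (msr - mse) / denom
    ci = _icc_ci(icc, msr, msc, mse, n, k, alpha)
    sem = sem_measure(X, icc, method=sem_method)
    return ReliabilityResult(
        icc=float(icc), ci95=ci, sem=sem, band=classify_icc(icc), anova=anova,
        n_dropped=n_dropped,
    )


def sem_measure(X, icc: float, method: str = "sd") -> float:
    """Standard error of measurement.

    ``sd`` (default): SD over all table entries times sqrt(1 - ICC);
    ``anova``: sqrt(MSE), the within-target error SD of the two-way model.
    """
    X, _ = _clean_table(X)
    if method == "sd":
        sd = float(np.std(X, ddof=1))
        return sd * math.sqrt(max(0.0, 1.0 - icc))
    if method == "anova":
        _, _, mse = two_way_mean_squares(X)
        return math.sqrt(mse)
    raise ValueError("sem method must be 'sd' or 'anova'")


def classify_icc(value: float) -> str:
    """Qualitative band: poor <=0.2 < fair <=0.4 < moderate <=0.6 < good
    <=0.8 < very_good."""
    if not np.isfinite(value):
        raise ValueError("cannot classify a non-finite ICC")
    if value <= 0.2:
        return "poor"
    if value <= 0.4:
        return "fair"
    if value <= 0.6:
        return "moderate"
    if value <= 0.8:
        return "good"
    return "very_good"


# ---------------------------------------------------------------------------
# whole-muscle and regional reliability
# ---------------------------------------------------------------------------


def whole_muscle_reliability(
    maps_session1: list[ParameterizedMap], maps_session2: list[ParameterizedMap]
) -> ReliabilityResult:
    """ICC(2,1) of the per-subject whole-muscle (count-weighted) mean SWV."""
    if len(maps_session1) != len(maps_session2):
        raise ValueError("sessions must contain the same subjects in the same order")
    if len(maps_session1) < 2:
        raise ValueError("need at least 2 subjects")
    X = np.array(
        [[a.whole_muscle_mean(), b.whole_muscle_mean()]
         for a, b in zip(maps_session1, maps_session2)]
    )
    return icc_2_1(X)


@dataclass
class RegionalReliability:
    domain: str
    results: list[ReliabilityResult]
    labels: list  # subject index (inter_regional) or cell index (inter_subject)
    icc_median: float
    icc_iqr: tuple[float, float]
    sem_median: float
    sem_iqr: tuple[float, float]
    n_undefined: int


def _summaries(results: list[ReliabilityResult], domain: str, labels: list) -> RegionalReliability:
    ok = [r for r in results if r.status == "ok" and np.isfinite(r.icc)]
    n_undefined = len(results) - len(ok)
    if n_undefined:
        logger.info("%d regional reliability estimate(s) undefined and excluded", n_undefined)
    if not ok:
        raise ValueError("no defined regional reliability estimates")
    iccs = np.array([r.icc for r in ok])
    sems = np.array([r.sem for r in ok])
    return RegionalReliability(
        domain=domain,
        results=results,
        labels=labels,
        icc_median=float(np.median(iccs)),
        icc_iqr=(float(np.percentile(iccs, 25)), float(np.percentile(iccs, 75))),
        sem_median=float(np.median(sems)),
        sem_iqr=(float(np.percentile(sems, 25)), float(np.percentile(sems, 75))),
        n_undefined=n_undefined,
    )


def regional_reliability(
    maps_session1: list[ParameterizedMap],
    maps_session2: list[ParameterizedMap],
    domain: str,
) -> RegionalReliability:
    """Regional test-retest reliability, summarized as median and IQR.

    ``inter_regional``: one ICC per subject over that subject's cells
    (can a region be re-identified within a subject-muscle?).
    ``inter_subject``: one ICC per cell over subjects (can a region's
    value rank subjects consistently?).
    """
    if domain not in DOMAINS:
        raise ValueError(f"domain must be one of {DOMAINS}")
    if len(maps_session1) != len(maps_session2):
        raise ValueError("sessions must contain the same subjects in the same order")
    results: list[ReliabilityResult] = []
    labels: list = []
    if domain == "inter_regional":
        for i, (a, b) in enumerate(zip(maps_session1, maps_session2)):
            X = np.column_stack([a.means.ravel(), b.means.ravel()])
            labels.append(i)
            results.append(_try_icc(X))
    else:
        shape = maps_session1[0].shape
        m1 = np.stack([m.means for m in maps_session1])
        m2 = np.stack([m.means for m in maps_session2])
        for cell in np.ndindex(shape):
            X = np.column_stack([m1[(slice(None),) + cell], m2[(slice(None),) + cell]])
            labels.append(cell)
            results.append(_try_icc(X))
    return _summaries(results, domain, labels)


def _try_icc(X) -> ReliabilityResult:
    Xc, n_dropped = _clean_table(X)
    if Xc.shape[0] < 2:
        return ReliabilityResult(
            icc=float("nan"), ci95=(float("nan"), float("nan")), sem=float("nan"),
            band=None, anova=(float("nan"),) * 3 + (Xc.shape[0], Xc.shape[1]),
            status="undefined", n_dropped=n_dropped,
        )
    return icc_2_1(Xc)


# ---------------------------------------------------------------------------
# contrasts and associations
# ---------------------------------------------------------------------------


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float
    status: str = "ok"  # "ok" | "degenerate"


def paired_t(pre, post) -> PairedTResult:
    """Two-sided paired t-test on subject-level scalars.

    Zero-variance differences make the statistic undefined; this is
    reported explicitly rather than as an arbitrary number.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1D arrays of equal length")
    n = len(pre)
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    d = post - pre
    sd = float(np.std(d, ddof=1))
    mean_d = float(d.mean())
    # sd below float rounding of the differences is a constant shift
    if sd <= 1e-12 * abs(mean_d):
        return PairedTResult(t=float("nan"), df=n - 1, p=float("nan"),
                             mean_diff=mean_d, status="degenerate")
    t = mean_d / (sd / math.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return PairedTResult(t=float(t), df=n - 1, p=float(p), mean_diff=mean_d)


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


@dataclass
class BinContrast:
    bin: int
    result: PairedTResult
    p_adjusted: float | None = None


def regional_contrast(
    pre_maps: list[ParameterizedMap],
    post_maps: list[ParameterizedMap],
    axis: str,
    adjust: bool = False,
) -> list[BinContrast]:
    """Per-bin paired t-tests of pre vs post axis profiles across subjects.

    P-values are unadjusted by default; ``adjust=True`` adds
    Benjamini-Hochberg adjusted values alongside.
    """
    pre = subject_profiles(pre_maps, axis)
    post = subject_profiles(post_maps, axis)
    out = []
    for b in range(pre.shape[1]):
        keep = np.isfinite(pre[:, b]) & np.isfinite(post[:, b])
        if keep.sum() < 2:
            res = PairedTResult(float("nan"), int(keep.sum()) - 1, float("nan"),
                                float("nan"), status="degenerate")
        else:
            res = paired_t(pre[keep, b], post[keep, b])
        out.append(BinContrast(bin=b, result=res))
    if adjust:
        ps = np.array([c.result.p for c in out])
        finite = np.isfinite(ps)
        adj = np.full(len(ps), np.nan)
        if finite.any():
            adj[finite] = benjamini_hochberg(ps[finite])
        for c, a in zip(out, adj):
            c.p_adjusted = None if np.isnan(a) else float(a)
    return out


def spearman_rho(x, y, method: str = "t_approx") -> tuple[float, float]:
    """Spearman rank correlation on mid-ranks (ties averaged).

    ``t_approx`` (default): two-sided p from t = rho sqrt((n-2)/(1-rho^2)).
    ``exact``: full permutation null (n <= 10 only; costly at n = 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("constant input has no rank correlation")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "exact":
        if n > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        from itertools import permutations

        a = (rx - rx.mean()) / (np.std(rx) * n)
        b = ry - ry.mean()
        b /= np.std(b)
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in permutations(range(n)):
            total += 1
            if abs(float(a @ b[list(perm)])) >= target:
                count += 1
        return rho, count / total
    if method != "t_approx":
        raise ValueError("method must be 't_approx' or 'exact'")
    if abs(rho) >= 1.0:
        return (1.0 if rho > 0 else -1.0), 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return rho, float(p)


@dataclass
class AssociationBin:
    bin: int
    rho: float
    p: float
    significant: bool
    status: str = "ok"  # "ok" | "insufficient_n"


def regional_association(
    maps: list[ParameterizedMap], covariate, axis: str, alpha: float = 0.05
) -> list[AssociationBin]:
    """Per-bin Spearman association of axis-profile SWV with a covariate
    across subjects.  Significance is unadjusted (p < alpha).  Bins with
    fewer than 4 complete subjects are flagged rather than tested."""
    cov = np.asarray(covariate, dtype=float)
    prof = subject_profiles(maps, axis)
    if len(cov) != prof.shape[0]:
        raise ValueError("covariate length must match the number of subjects")
    out = []
    for b in range(prof.shape[1]):
        keep = np.isfinite(prof[:, b]) & np.isfinite(cov)
        if keep.sum() < 4:
            out.append(AssociationBin(b, float("nan"), float("nan"), False,
                                      status="insufficient_n"))
            continue
        rho, p = spearman_rho(prof[keep, b], cov[keep])
        out.append(AssociationBin(b, rho, p, bool(p < alpha)))
    return out


def normalized_mehs(forces_n, body_mass_kg: float) -> float:
    """Normalized maximum eccentric hamstring strength (N/kg): the median
    of the six per-repetition force maxima divided by body mass."""
    forces = np.asarray(forces_n, dtype=float)
    if forces.shape != (6,):
        raise ValueError("six repetitions required")
    if body_mass_kg <= 0:
        raise ValueError("body mass must be positive")
    return float(np.median(forces) / body_mass_kg)
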