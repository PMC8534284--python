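"""Covariate-adjusted differential abundance between case and control.

The primary path is a moderated linear-model fit in the limma style: per
feature, ordinary least squares on a design of intercept + group + sex +
centred age, followed by empirical-Bayes shrinkage of the residual
variances toward a common prior fitted by moment matching of a scaled
inverse chi-square distribution. A univariate path (t-test or
Mann-Whitney U, gated per feature by Shapiro-Wilk normality) is available
as an alternative. False-discovery control is Benjamini-Hochberg or the
more conservative Benjamini-Yekutieli step-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import FeatureMatrix, SampleMetadata

__all__ = [
    "build_design",
    "choose_test",
    "moderated_fit",
    "univariate_fit",
    "adjust_fdr",
    "summarize_classes",
]


def build_design(metadata: SampleMetadata) -> pd.DataFrame:
    """Design matrix: intercept, group (case=1), sex (M=1), centred age.

    Age is mean-centred so the intercept stays interpretable as the
    control-female baseline at the cohort mean age.
    """
    t = metadata.table
    design = pd.DataFrame(
        {
            "intercept": 1.0,
            "group": (t["group"] == "case").astype(float),
            "sex": (t["sex"] == "M").astype(float),
            "age": t["age"].astype(float) - t["age"].astype(float).mean(),
        },
        index=t.index,
    )
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return design


def choose_test(values_by_group: Sequence[np.ndarray]) -> str:
    """Pick "t" vs "mann-whitney" from per-group Shapiro-Wilk normality.

    Returns ``"t"`` only when Shapiro-Wilk accepts normality (p >= 0.05)
    in every group.
    """
    for g in values_by_group:
        g = np.asarray(g, dtype=float)
        if g.size < 3:
            raise ValueError("each group needs >= 3 observations for the normality gate")
    for g in values_by_group:
        if stats.shapiro(np.asarray(g, dtype=float)).pvalue < 0.05:
            return "mann-whitney"
    return "t"


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (vectorised)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # starting value, exact as x -> 0 or inf
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(-dif / y < 1e-8):
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: float) -> Tuple[float, float]:
    """Moment-match a scaled inverse chi-square prior to residual variances.

    Matching is done on z = log(s2), whose mean and variance under the
    hierarchical model are analytic in digamma/trigamma terms. Returns
    (d0, s0_squared); d0 = inf when the observed spread of log-variances
    is no larger than expected from the residual degrees of freedom alone.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = len(e)
    evar = np.sum((e - emean) ** 2) / (n - 1) if n > 1 else 0.0
    evar = evar - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * float(_trigamma_inverse(np.array([evar]))[0])
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_fit(
    matrix: FeatureMatrix,
    design: pd.DataFrame,
    alpha: float = 0.05,
    fdr_method: str = "BY",
    coef: str = "group",
    prior_df: Optional[float] = None,
) -> pd.DataFrame:
    """Per-feature moderated linear model for the group effect.

    For every feature the design is fitted by ordinary least squares; the
    group coefficient is the log fold change (log2 when the matrix holds
    log2 values). Residual variances are shrunk toward the fitted prior:

        s2_post = (d0 * s0^2 + d * s^2) / (d0 + d)

    and the moderated t = coef / (se_unscaled * sqrt(s2_post)) is referred
    to a t distribution with d0 + d degrees of freedom. ``prior_df``
    overrides the fitted d0 (0 recovers ordinary per-feature t-tests).

    Returns a DataFrame indexed by feature with columns
    ``log_fold_change``, ``t_moderated``, ``p_raw``, ``p_adjusted``,
    ``test_used``, ``significant``.
    """
    if matrix.scale_state not in ("log", "log-pareto"):
        raise ValueError("moderated_fit expects a log or log-pareto matrix")
    if matrix.has_missing():
        raise ValueError("matrix contains missing values; impute first")
    if list(design.index) != matrix.sample_ids:
        design = design.loc[matrix.sample_ids]
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    Y = matrix.values.to_numpy(dtype=float)
    n, k = X.shape
    d = n - k
    if d <= 0:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # k x p
    resid = Y - X @ beta
    s2 = np.sum(resid**2, axis=0) / d
    j = list(design.columns).index(coef)
    se_unscaled = np.sqrt(xtx_inv[j, j])

    if prior_df is None:
        d0, s0_sq = fit_variance_prior(s2, d)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_sq = fit_variance_prior(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d

    lfc = beta[j]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = lfc / (se_unscaled * np.sqrt(s2_post))
    if np.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p_raw = np.where(np.isnan(t_mod), 1.0, p_raw)
    t_mod = np.where(np.isnan(t_mod), 0.0, t_mod)
    p_adj = adjust_fdr(p_raw, method=fdr_method)
    return pd.DataFrame(
        {
            "log_fold_change": lfc,
            "t_moderated": t_mod,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "test_used": "moderated",
            "significant": p_adj < alpha,
        },
        index=pd.Index(matrix.feature_ids, name="feature_id"),
    )


def univariate_fit(
    matrix: FeatureMatrix,
    metadata: SampleMetadata,
    alpha: float = 0.05,
    fdr_method: str = "BY",
) -> pd.DataFrame:
    """Per-feature two-group test, t or Mann-Whitney by normality gate."""
    if matrix.has_missing():
        raise ValueError("matrix contains missing values; impute first")
    control = metadata.samples_in_group("control")
    case = metadata.samples_in_group("case")
    rows = []
    for fid in matrix.feature_ids:
        col = matrix.values[fid]
        a = col.loc[case].to_numpy(dtype=float)
        b = col.loc[control].to_numpy(dtype=float)
        if np.std(a) == 0 and np.std(b) == 0:
            test, stat, p = "t", 0.0, 1.0
        else:
            test = choose_test([a, b])
            if test == "t":
                res = stats.ttest_ind(a, b)
            else:
                res = stats.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append((fid, float(a.mean() - b.mean()), stat, p, test))
    out = pd.DataFrame(
        rows, columns=["feature_id", "log_fold_change", "t_moderated", "p_raw", "test_used"]
    ).set_index("feature_id")
    out["p_adjusted"] = adjust_fdr(out["p_raw"].to_numpy(), method=fdr_method)
    out["significant"] = out["p_adjusted"] < alpha
    return out[
        ["log_fold_change", "t_moderated", "p_raw", "p_adjusted", "test_used", "significant"]
    ]


def adjust_fdr(p_values: Iterable[float], method: str = "BY") -> np.ndarray:
    """Step-up FDR adjustment: BH, or BY with the c(m) = sum(1/i) inflation."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "BY": "fdr_by"}.get(method.upper())
    if key is None:
        raise ValueError(f"unknown FDR method {method!r}; use 'BH' or 'BY'")
    return multipletests(p, method=key)[1]


@dataclass
class ClassSummary:
    """Significant-feature counts per biochemical class and the top set."""

    counts: Dict[str, int]
    top_features: List[str]
    n_significant: int


def summarize_classes(
    results: pd.DataFrame,
    annotations: Dict[str, str],
    lfc_cutoff: float = 1.5,
    p_cutoff: float = 0.01,
) -> ClassSummary:
    """Count significant features per biochemical class.

    Features lacking an annotation are counted as "unannotated". Also
    reports the top-metabolite subset at |log fold change| > ``lfc_cutoff``
    and adjusted p < ``p_cutoff``.
    """
    sig = results[results["significant"].astype(bool)]
    counts: Dict[str, int] = {}
    for fid in sig.index:
        cls = annotations.get(fid, "unannotated")
        counts[cls] = counts.get(cls, 0) + 1
    top = sig[
        (sig["log_fold_change"].abs() > lfc_cutoff) & (sig["p_adjusted"] < p_cutoff)
    ].index.tolist()
    return ClassSummary(counts=counts, top_features=top, n_significant=len(sig))
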