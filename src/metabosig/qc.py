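"""Feature-level quality control, normalisation, imputation, and
ion-mobility CCS calibration.

Pooled-QC filtering follows the standard untargeted-metabolomics recipe:
a feature is kept only if (i) its intensity tracks the concentration of a
pooled-QC dilution series (Pearson r >= 0.70) and (ii) its precision over
repeated pooled-QC injections is acceptable (RSD < 25%). Normalisation is
log2 followed by Pareto scaling; missing values are imputed by k-nearest-
neighbour averaging on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .containers import FeatureMatrix, QCSeries

__all__ = [
    "log_transform",
    "pareto_scale",
    "knn_impute",
    "dilution_correlation_filter",
    "rsd_filter",
    "combine_qc_reports",
    "apply_qc_filter",
    "CCSCalibration",
    "ccs_calibrate",
    "ccs_error",
]


def log_transform(matrix: FeatureMatrix) -> FeatureMatrix:
    """Log2-transform a raw-scale matrix; missing entries stay missing.

    Raises ``ValueError`` naming the offending cell if any observed value
    is <= 0 (log undefined).
    """
    if matrix.scale_state != "raw":
        raise ValueError(f"expected raw-scale matrix, got {matrix.scale_state!r}")
    vals = matrix.values.to_numpy(dtype=float)
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            "non-positive value "
            f"{vals[i, j]!r} at sample {matrix.sample_ids[i]!r}, "
            f"feature {matrix.feature_ids[j]!r}: log2 undefined"
        )
    out = pd.DataFrame(
        np.log2(vals), index=matrix.values.index, columns=matrix.values.columns
    )
    return FeatureMatrix(out, scale_state="log")


def pareto_scale(matrix: FeatureMatrix) -> FeatureMatrix:
    """Mean-centre each feature and divide by sqrt(sample standard deviation).

    Pareto scaling sits between no scaling and unit-variance scaling: high-
    variance features are shrunk but keep more leverage than under
    autoscaling. Constant features map to all-zero columns.
    """
    if matrix.scale_state != "log":
        raise ValueError(f"expected log-scale matrix, got {matrix.scale_state!r}")
    if matrix.has_missing():
        raise ValueError("matrix contains missing values; impute before Pareto scaling")
    vals = matrix.values.to_numpy(dtype=float)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1) if vals.shape[0] > 1 else np.zeros(vals.shape[1])
    centred = vals - mean
    scaled = np.zeros_like(centred)
    nonconst = sd > 0
    scaled[:, nonconst] = centred[:, nonconst] / np.sqrt(sd[nonconst])
    out = pd.DataFrame(scaled, index=matrix.values.index, columns=matrix.values.columns)
    return FeatureMatrix(out, scale_state="log-pareto")


def knn_impute(matrix: FeatureMatrix, k: int = 10) -> FeatureMatrix:
    """Impute missing cells by nearest-neighbour averaging across samples.

    Each missing cell is replaced by the mean of the feature over the k
    nearest samples, with distances computed on mutually observed features
    (NaN-aware Euclidean). Observed cells are never altered. Features with
    zero observations are rejected.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    all_missing = matrix.values.columns[matrix.values.isna().all(axis=0)].tolist()
    if all_missing:
        raise ValueError(f"features with no observed values: {all_missing}")
    if not matrix.has_missing():
        return matrix.copy()
    imputer = KNNImputer(n_neighbors=min(k, matrix.n_samples - 1), weights="uniform")
    filled = imputer.fit_transform(matrix.values.to_numpy(dtype=float))
    out = pd.DataFrame(filled, index=matrix.values.index, columns=matrix.values.columns)
    return FeatureMatrix(out, scale_state=matrix.scale_state)


def _qc_report_frame(feature_ids: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(
        index=pd.Index(feature_ids, name="feature_id"),
        columns=["dilution_r", "rsd_pct", "passed", "reason"],
    )


def dilution_correlation_filter(qc: QCSeries, threshold: float = 0.70) -> pd.DataFrame:
    """Flag features whose intensity does not track the dilution series.

    Pearson correlation of intensity against dilution fraction is computed
    per feature; a feature fails iff r < threshold (strict) or r is
    undefined (constant intensities). Returns a QC report frame with
    columns ``dilution_r``, ``passed``, ``reason``.
    """
    ids = sorted(qc.dilution_intensities)
    report = _qc_report_frame(ids)
    for fid in ids:
        pts = qc.dilution_intensities[fid]
        if len(pts) < 3:
            raise ValueError(
                f"feature {fid!r} has {len(pts)} dilution points; >= 3 required"
            )
        d = np.array([p[0] for p in pts], dtype=float)
        y = np.array([p[1] for p in pts], dtype=float)
        if np.std(d) == 0 or np.std(y) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(d, y)[0, 1])
        report.loc[fid, "dilution_r"] = r
        if np.isnan(r):
            report.loc[fid, ["passed", "reason"]] = False, "dilution_r_undefined"
        elif r < threshold:
            report.loc[fid, ["passed", "reason"]] = False, "dilution_r_below_threshold"
        else:
            report.loc[fid, ["passed", "reason"]] = True, ""
    return report


def rsd_filter(qc: QCSeries, threshold_pct: float = 25.0) -> pd.DataFrame:
    """Flag features with poor precision over pooled-QC replicates.

    RSD = 100 * sd / mean over replicate injections; a feature passes iff
    RSD < threshold (strict). A non-positive mean makes the RSD undefined
    and the feature fails.
    """
    ids = sorted(qc.replicate_intensities)
    report = _qc_report_frame(ids)
    for fid in ids:
        reps = np.asarray(qc.replicate_intensities[fid], dtype=float)
        if reps.size < 3:
            raise ValueError(f"feature {fid!r} has {reps.size} replicates; >= 3 required")
        mean = reps.mean()
        if mean <= 0:
            report.loc[fid, ["rsd_pct", "passed", "reason"]] = np.nan, False, "rsd_undefined"
            continue
        rsd = 100.0 * reps.std(ddof=1) / mean
        report.loc[fid, "rsd_pct"] = rsd
        if rsd < threshold_pct:
            report.loc[fid, ["passed", "reason"]] = True, ""
        else:
            report.loc[fid, ["passed", "reason"]] = False, "rsd_at_or_above_threshold"
    return report


def combine_qc_reports(dilution: pd.DataFrame, rsd: pd.DataFrame) -> pd.DataFrame:
    """Merge the two per-feature filters; a feature passes iff it passes both."""
    ids = sorted(set(dilution.index) | set(rsd.index))
    report = _qc_report_frame(ids)
    report["dilution_r"] = dilution["dilution_r"].reindex(ids)
    report["rsd_pct"] = rsd["rsd_pct"].reindex(ids)
    def _flags(rep: pd.DataFrame) -> pd.Series:
        raw = rep["passed"].reindex(ids)
        return pd.Series([bool(v) if pd.notna(v) else False for v in raw], index=ids)

    d_pass = _flags(dilution)
    r_pass = _flags(rsd)
    report["passed"] = d_pass & r_pass
    reasons = []
    for fid in ids:
        parts = []
        if not d_pass.loc[fid]:
            parts.append(str(dilution["reason"].get(fid, "missing_from_dilution_series")))
        if not r_pass.loc[fid]:
            parts.append(str(rsd["reason"].get(fid, "missing_from_replicates")))
        reasons.append(";".join(p for p in parts if p))
    report["reason"] = reasons
    return report


def apply_qc_filter(matrix: FeatureMatrix, report: pd.DataFrame) -> FeatureMatrix:
    """Drop matrix features that failed QC; features without a QC record are kept."""
    failed = set(report.index[~report["passed"].astype(bool)])
    keep = [f for f in matrix.feature_ids if f not in failed]
    return matrix.subset_features(keep)


@dataclass
class CCSCalibration:
    """Power-law drift-time -> CCS calibration, ln(CCS') = x ln(dt') + ln(A).

    ``x`` is the dimensionless exponent; ``A`` the scale factor in the CCS
    unit (Angstrom^2 for normalised drift times). Fitted by ordinary least
    squares in log-log space.
    """

    x: float
    A: float
    fit_points: List[Tuple[float, float]]
    residual_sd: float

    def predict(self, dt_prime: float) -> float:
        """Predicted reduced CCS at a reduced drift time; dt' = 1 returns A."""
        if dt_prime <= 0:
            raise ValueError("drift time must be positive")
        return self.A * dt_prime**self.x


def ccs_calibrate(calibrants: Sequence[Tuple[float, float]]) -> CCSCalibration:
    """Fit the log-linear travelling-wave CCS calibration to calibrant ions.

    ``calibrants`` holds (reduced drift time dt', reduced CCS') pairs for
    species of known cross section (e.g. poly-DL-alanine oligomers). At
    least two distinct positive drift times are required.
    """
    pts = [(float(d), float(c)) for d, c in calibrants]
    if any(d <= 0 or c <= 0 for d, c in pts):
        raise ValueError("calibrant drift times and CCS values must be positive")
    if len({d for d, _ in pts}) < 2:
        raise ValueError("need >= 2 calibrants with distinct drift times")
    ld = np.log([d for d, _ in pts])
    lc = np.log([c for _, c in pts])
    slope, intercept = np.polyfit(ld, lc, 1)
    resid = lc - (slope * ld + intercept)
    dof = len(pts) - 2
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    return CCSCalibration(
        x=float(slope), A=float(math.exp(intercept)), fit_points=pts, residual_sd=residual_sd
    )


def ccs_error(observed_ccs: float, theoretical_ccs: float) -> float:
    """Signed percent deviation of an observed CCS from its theoretical value."""
    if theoretical_ccs <= 0:
        raise ValueError("theoretical CCS must be positive")
    return 100.0 * (observed_ccs - theoretical_ccs) / theoretical_ccs
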