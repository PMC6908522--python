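"""Quality control and variance-stabilizing normalization.

Per-study matrices pass three steps before differential expression: a QC
summary (per-sample medians/IQRs, outlier flags, raw-vs-log scale guess),
an affine between-sample calibration against a median reference profile,
and the generalized-log transform

    h(y) = log2( (y + sqrt(y^2 + c^2)) / 2 )

which is finite for all real y (including small negatives produced by
calibration) and converges to log2(y) for y >> c. Full maximum-likelihood
VSN is deliberately replaced by this affine-calibration + glog procedure:
it targets the same additive + multiplicative noise model with a fully
specified, closed-form fit; see docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionStudy
from .errors import ConfigurationError, NormalizationError

logger = logging.getLogger(__name__)

# log2 microarray data rarely exceeds ~20; a matrix maximum below this is
# taken as evidence the data are already on a log-like scale.
LOG_SCALE_MAX = 30.0


@dataclass
class QcReport:
    """Per-sample summary statistics and outlier flags for one study."""

    study_id: str
    sample_median: pd.Series
    sample_iqr: pd.Series
    fraction_missing: pd.Series
    outlier_flags: list[str]
    scale_guess: str  # "raw" or "log-like"


def qc_summary(study: ExpressionStudy) -> QcReport:
    """Summarize per-sample distributions and flag outlying samples.

    A sample is flagged when its median lies outside
    ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]`` of all sample medians. The scale guess
    is "log-like" when the matrix maximum is below 30.
    """
    values = study.values
    med = values.median(axis=0)
    q3 = values.quantile(0.75, axis=0)
    q1 = values.quantile(0.25, axis=0)
    iqr = q3 - q1
    frac_missing = values.isna().mean(axis=0)

    m_q1, m_q3 = med.quantile(0.25), med.quantile(0.75)
    m_iqr = m_q3 - m_q1
    lo, hi = m_q1 - 1.5 * m_iqr, m_q3 + 1.5 * m_iqr
    flags = list(med.index[(med < lo) | (med > hi)])

    max_val = float(np.nanmax(values.to_numpy(dtype=float)))
    guess = "log-like" if max_val < LOG_SCALE_MAX else "raw"
    return QcReport(
        study_id=study.study_id,
        sample_median=med,
        sample_iqr=iqr,
        fraction_missing=frac_missing,
        outlier_flags=flags,
        scale_guess=guess,
    )


def drop_missing_features(study: ExpressionStudy) -> ExpressionStudy:
    """Drop features with any missing value study-wide (count logged)."""
    mask = study.values.notna().all(axis=1)
    dropped = int((~mask).sum())
    if dropped:
        logger.info("study %s: dropped %d features with missing values",
                    study.study_id, dropped)
        return study.with_values(study.values.loc[mask], study.scale)
    return study


def calibrate_samples(study: ExpressionStudy, trim: float = 0.2,
                      n_trim_iter: int = 3) -> ExpressionStudy:
    """Affine between-sample calibration against a median reference.

    The reference profile is the per-feature median across samples. For each
    sample j the model ``y_ij ~= a_j + b_j * ref_i`` is fit by least squares
    over features whose reference value lies within the [5th, 95th]
    percentile band, and values are replaced by ``(y - a_j) / b_j``.

    The fit is made resistant to truly differential features by iterative
    residual trimming (a least-trimmed-squares surrogate): after each
    ordinary fit the ``trim`` fraction of features with the largest absolute
    residuals is excluded and the fit repeated. Without trimming, a minority
    of strongly shifted genes drags the slope and imprints a spurious
    group-coherent shift on every other gene.
    """
    if study.scale != "raw":
        raise NormalizationError(
            f"study {study.study_id!r}: calibration expects raw scale, "
            f"got {study.scale!r}"
        )
    values = study.values.to_numpy(dtype=float)
    ref = np.median(values, axis=1)
    lo, hi = np.percentile(ref, [5, 95])
    band = (ref >= lo) & (ref <= hi)
    r = ref[band]
    if r.size < 2 or np.ptp(r) == 0:
        raise NormalizationError(
            f"study {study.study_id!r}: degenerate reference profile "
            "(constant within the percentile band)"
        )
    def affine_fit(rr: np.ndarray, yy: np.ndarray) -> tuple[float, float]:
        r_mean = rr.mean()
        r_var = ((rr - r_mean) ** 2).sum()
        if r_var == 0:
            return np.nan, np.nan
        b = ((rr - r_mean) * (yy - yy.mean())).sum() / r_var
        return yy.mean() - b * r_mean, b

    out = np.empty_like(values)
    for j, sample in enumerate(study.samples):
        y = values[band, j]
        keep = np.ones(r.size, dtype=bool)
        a = b = np.nan
        for _ in range(max(1, n_trim_iter)):
            a, b = affine_fit(r[keep], y[keep])
            if not np.isfinite(b):
                break
            resid = np.abs(y - (a + b * r))
            cut = np.quantile(resid, 1.0 - trim)
            keep = resid <= cut
            if keep.sum() < 2:
                break
        if not np.isfinite(b) or b <= 0:
            raise NormalizationError(
                f"study {study.study_id!r}: degenerate calibration fit for "
                f"sample {sample!r} (slope {b!r})"
            )
        out[:, j] = (values[:, j] - a) / b
    frame = pd.DataFrame(out, index=study.features, columns=study.samples)
    return study.with_values(frame, "raw")


def auto_glog_c(values: np.ndarray, eps: float = 1e-8) -> float:
    """Auto-select the glog constant c = sigma_additive / sigma_multiplicative.

    The additive noise scale is the scaled MAD of per-feature-centered
    intensities among the bottom-decile features (where additive noise
    dominates); the multiplicative scale is the median per-feature SD of
    log intensities among the top-decile features (where it dominates).
    Their ratio is the intensity at which the two noise regimes cross —
    the canonical glog tuning. Floored at a machine-safe epsilon.
    """
    gene_med = np.median(values, axis=1)
    low = values[gene_med <= np.quantile(gene_med, 0.1)]
    resid = (low - np.median(low, axis=1, keepdims=True)).ravel()
    sigma_add = 1.4826 * np.median(np.abs(resid))
    high = values[gene_med >= np.quantile(gene_med, 0.9)]
    with np.errstate(invalid="ignore"):
        log_high = np.log(np.maximum(high, eps))
    sigma_mult = float(np.median(log_high.std(axis=1)))
    if sigma_mult <= 0:
        return float(max(sigma_add, eps))
    return float(max(sigma_add / sigma_mult, eps))


def glog_transform(study: ExpressionStudy, c: float | str = "auto") -> ExpressionStudy:
    """Apply the generalized log2 transform; output scale is ``glog2``."""
    values = study.values.to_numpy(dtype=float)
    if c == "auto":
        c_val = auto_glog_c(values)
    else:
        c_val = float(c)
        if c_val <= 0:
            raise ConfigurationError(f"glog constant c must be positive, got {c}")
    h = np.log2((values + np.sqrt(values ** 2 + c_val ** 2)) / 2.0)
    frame = pd.DataFrame(h, index=study.features, columns=study.samples)
    out = study.with_values(frame, "glog2")
    logger.info("study %s: glog2 transform with c=%.6g", study.study_id, c_val)
    return out


def normalize_study(study: ExpressionStudy, c: float | str = "auto",
                    force_glog: bool = False) -> ExpressionStudy:
    """QC -> calibration -> glog; pass-through for log-like input.

    When the QC scale guess is log-like (and ``force_glog`` is off) the
    matrix is assumed pre-normalized and passed through unchanged on the
    ``glog2`` scale; the skip is logged.
    """
    study = drop_missing_features(study)
    report = qc_summary(study)
    if study.scale == "glog2" or (report.scale_guess == "log-like" and not force_glog):
        if study.scale != "glog2":
            logger.info("study %s: log-like input, skipping calibration+glog",
                        study.study_id)
            return study.with_values(study.values, "glog2")
        return study
    return glog_transform(calibrate_samples(study), c=c)
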