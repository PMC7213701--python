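"""Agreement statistics between estimated and reference interval series.

Bland–Altman bias and limits of agreement, RMSE, grouped summary tables in
the layout of clinical QT studies (mean ± sd of RR/HR/QT/QTc per category),
and ordinary-least-squares trends against gestational age with prediction
bounds for flagging outlying subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError, InvalidArgumentError

__all__ = [
    "PairedIntervalSeries",
    "AgreementReport",
    "TrendResult",
    "bland_altman",
    "rmse",
    "group_summary",
    "linear_trend",
]

#: Classic limits-of-agreement multiplier (95% of normal differences).
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedIntervalSeries:
    """Per-beat estimated and reference intervals for one subject/group.

    Differences are always oriented estimate − reference.
    """

    estimate_ms: np.ndarray
    reference_ms: np.ndarray
    group: str = "normal"
    subject_id: str | None = None
    ga_weeks: float | None = None

    def __post_init__(self):
        est = np.asarray(self.estimate_ms, dtype=float)
        ref = np.asarray(self.reference_ms, dtype=float)
        if est.shape != ref.shape or est.ndim != 1:
            raise InvalidArgumentError("estimate and reference must be equal-length 1-D arrays")
        if est.size and (np.any(est <= 0) or np.any(ref <= 0)):
            raise InvalidArgumentError("intervals must be positive")
        object.__setattr__(self, "estimate_ms", est)
        object.__setattr__(self, "reference_ms", ref)

    @property
    def n(self) -> int:
        return int(self.estimate_ms.size)

    @property
    def differences(self) -> np.ndarray:
        return self.estimate_ms - self.reference_ms


@dataclass(frozen=True)
class AgreementReport:
    """Bland–Altman summary of one paired series (estimate − reference)."""

    n: int
    bias_ms: float
    sd_ms: float
    loa_low_ms: float
    loa_high_ms: float
    pct_within_loa: float
    rmse_ms: float
    flags: tuple[str, ...] = ()


def bland_altman(pairs: PairedIntervalSeries) -> tuple[AgreementReport, pd.DataFrame]:
    """Bland–Altman agreement of an estimate series against a reference.

    Bias is the mean difference; the standard deviation uses the n − 1
    denominator; limits of agreement are bias ± 1.96·sd; ``pct_within_loa``
    counts pairs strictly inside the limits.  Zero-variance series collapse
    the limits onto the bias and report 100% within, flagged.

    Returns the report plus the (mean, difference) scatter table for
    plotting.
    """
    if pairs.n < 2:
        raise InvalidArgumentError(f"need at least 2 pairs, got {pairs.n}")
    d = pairs.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    flags: tuple[str, ...] = ()
    if sd == 0.0:
        lo = hi = bias
        pct = 100.0
        flags = ("zero_variance",)
    else:
        lo = bias - LOA_MULTIPLIER * sd
        hi = bias + LOA_MULTIPLIER * sd
        pct = 100.0 * float(np.mean((d > lo) & (d < hi)))
    scatter = pd.DataFrame(
        {
            "mean_ms": (pairs.estimate_ms + pairs.reference_ms) / 2.0,
            "difference_ms": d,
        }
    )
    report = AgreementReport(
        n=pairs.n,
        bias_ms=bias,
        sd_ms=sd,
        loa_low_ms=lo,
        loa_high_ms=hi,
        pct_within_loa=pct,
        rmse_ms=rmse(pairs),
        flags=flags,
    )
    return report, scatter


def rmse(pairs: PairedIntervalSeries) -> float:
    """Root mean square of the estimate − reference differences."""
    if pairs.n < 1:
        raise InvalidArgumentError("need at least 1 pair for RMSE")
    return float(np.sqrt(np.mean(pairs.differences**2)))


_SUMMARY_COLUMNS = {
    "group",
    "rr_ms",
    "hr_bpm",
    "qt_est_ms",
    "qt_ref_ms",
    "qtc_est_ms",
    "qtc_ref_ms",
}


def group_summary(
    beats: pd.DataFrame, vocabulary: list[str] | None = None
) -> pd.DataFrame:
    """Per-group summary table of paired QT/QTc measurements.

    ``beats`` holds one row per beat with columns ``group, rr_ms, hr_bpm,
    qt_est_ms, qt_ref_ms, qtc_est_ms, qtc_ref_ms``.  The output mirrors the
    clinical comparison-table layout: beat count, mean ± sd of RR, HR, and of
    reference and estimated QT/QTc, plus RMSE columns.  Groups with a single
    beat report sd 0 and are flagged.  If ``vocabulary`` is given, labels
    outside it raise a configuration error.
    """
    missing = _SUMMARY_COLUMNS - set(beats.columns)
    if missing:
        raise InvalidArgumentError(f"beat table missing columns: {sorted(missing)}")
    if beats.empty:
        raise InvalidArgumentError("beat table is empty")
    if vocabulary is not None:
        unknown = set(beats["group"]) - set(vocabulary)
        if unknown:
            raise ConfigurationError(f"unknown group labels: {sorted(unknown)}")
    rows = []
    for group, g in beats.groupby("group", sort=True):
        n = len(g)
        sd = lambda s: float(np.std(s, ddof=1)) if n > 1 else 0.0
        qt_pairs = PairedIntervalSeries(g["qt_est_ms"].to_numpy(), g["qt_ref_ms"].to_numpy())
        qtc_pairs = PairedIntervalSeries(g["qtc_est_ms"].to_numpy(), g["qtc_ref_ms"].to_numpy())
        rows.append(
            {
                "group": group,
                "n_beats": n,
                "rr_mean_ms": float(g["rr_ms"].mean()),
                "rr_sd_ms": sd(g["rr_ms"]),
                "hr_mean_bpm": float(g["hr_bpm"].mean()),
                "hr_sd_bpm": sd(g["hr_bpm"]),
                "qt_ref_mean_ms": float(g["qt_ref_ms"].mean()),
                "qt_ref_sd_ms": sd(g["qt_ref_ms"]),
                "qt_est_mean_ms": float(g["qt_est_ms"].mean()),
                "qt_est_sd_ms": sd(g["qt_est_ms"]),
                "qt_rmse_ms": rmse(qt_pairs),
                "qtc_ref_mean_ms": float(g["qtc_ref_ms"].mean()),
                "qtc_ref_sd_ms": sd(g["qtc_ref_ms"]),
                "qtc_est_mean_ms": float(g["qtc_est_ms"].mean()),
                "qtc_est_sd_ms": sd(g["qtc_est_ms"]),
                "qtc_rmse_ms": rmse(qtc_pairs),
                "flags": "single_beat" if n == 1 else "",
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrendResult:
    """OLS fit of interval means against gestational age, with prediction bounds."""

    slope: float
    intercept: float
    r_squared: float
    level: float
    fitted: np.ndarray
    pred_low: np.ndarray
    pred_high: np.ndarray
    outlier: np.ndarray


def linear_trend(x, y, level: float = 0.95) -> TrendResult:
    """Least-squares linear trend with per-point prediction intervals.

    Prediction (not confidence-of-mean) intervals are used because individual
    subjects are classified against the bounds: a point strictly outside its
    prediction interval at the given level is flagged as an outlier.
    Requires at least 3 points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise InvalidArgumentError(f"need at least 3 points, got {x.size}")
    if not 0 < level < 1:
        raise InvalidArgumentError(f"level must be in (0, 1), got {level}")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    pred = fit.get_prediction(X)
    bounds = pred.conf_int(obs=True, alpha=1.0 - level)
    low, high = bounds[:, 0], bounds[:, 1]
    outlier = (y < low) | (y > high)
    return TrendResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared) if np.isfinite(fit.rsquared) else 0.0,
        level=level,
        fitted=np.asarray(fit.fittedvalues, dtype=float),
        pred_low=low,
        pred_high=high,
        outlier=outlier,
    )
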