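"""Agreement statistics between two activation series or raters.

Implements the intraclass correlation for a two-way model with
absolute-agreement, average-measures definition

    ICC = (MS_rows - MS_err) / (MS_rows + (MS_cols - MS_err) / n)

with the F-based confidence interval of McGraw & Wong (single-measures
bounds via a Satterthwaite-approximated denominator df, then stepped up
with the Spearman-Brown relation), Bland-Altman bias and +/-1.96 SD limits
of agreement, Pearson r, the within-condition coefficient of variation,
and the method-by-time interaction F from a fully-within two-factor
repeated-measures ANOVA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "icc_agreement",
    "bland_altman",
    "within_cv",
    "method_by_time_interaction",
    "pearson",
    "compare_series",
]


def _two_way_mean_squares(matrix: np.ndarray) -> tuple[float, float, float, int, int]:
    """(MS_rows, MS_cols, MS_error, n_rows, n_cols) of a complete two-way table."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D subjects x raters matrix")
    n, k = m.shape
    if n < 3 or k < 2:
        raise ValueError(f"need >= 3 rows and >= 2 columns, got {n} x {k}")
    if np.isnan(m).any():
        raise ValueError("matrix must be complete (no missing cells)")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_rows, ms_cols, ms_err, n, k


def icc_agreement(
    matrix: np.ndarray, alpha: float = 0.05, form: str = "absolute"
) -> tuple[float, tuple[float, float]]:
    """Average-measures ICC of a subjects x raters matrix with 95% CI.

    ``form='absolute'`` penalizes systematic rater offsets (the
    absolute-agreement coefficient); ``form='consistency'`` ignores them.
    A matrix with zero between-subject variance has no defined ICC and
    raises rather than returning NaN.
    """
    msr, msc, mse, n, k = _two_way_mean_squares(matrix)
    if msr == 0:
        raise ValueError("between-subject variance is zero; ICC undefined")
    if form == "consistency":
        icc = (msr - mse) / msr
        f_obs = msr / mse if mse > 0 else np.inf
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        return float(icc), (float(1 - 1 / fl), float(1 - 1 / fu))
    if form != "absolute":
        raise ValueError(f"unknown form {form!r}")

    icc_k = (msr - mse) / (msr + (msc - mse) / n)
    # single-measures coefficient and its Satterthwaite F interval
    icc_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if icc_1 >= 1.0:  # degenerate perfect agreement: no error variance
        return float(icc_k), (float(icc_k), float(icc_k))
    a = k * icc_1 / (n * (1 - icc_1))
    b = 1 + k * icc_1 * (n - 1) / (n * (1 - icc_1))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo1 = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi1 = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    sb = lambda r: r * k / (1 + (k - 1) * r)  # noqa: E731 - Spearman-Brown step-up
    return float(icc_k), (float(sb(lo1)), float(sb(hi1)))


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    diffs: np.ndarray
    means: np.ndarray


def bland_altman(a: np.ndarray, b: np.ndarray) -> BlandAltman:
    """Bias and +/-1.96 x sample-SD limits of agreement for paired values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    if len(a) < 2:
        raise ValueError(f"need >= 2 pairs, got {len(a)}")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        diffs=d,
        means=(a + b) / 2.0,
    )


def within_cv(values: np.ndarray) -> float:
    """Coefficient of variation, percent: 100 x sample SD / mean."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError(f"need >= 2 values, got {len(v)}")
    mean = v.mean()
    if mean <= 0:
        raise ValueError(f"CV undefined for non-positive mean ({mean:g})")
    return float(100.0 * v.std(ddof=1) / mean)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation of paired values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need >= 3 aligned pairs")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(a, b)[0, 1])


def method_by_time_interaction(
    series_a: np.ndarray, series_b: np.ndarray
) -> tuple[float, float]:
    """Interaction F and p of a method x time within-subject ANOVA.

    Inputs are ``subjects x minutes`` matrices for the two methods on a
    common minute grid (truncate to common minutes first if unbalanced;
    mismatched shapes raise).  The interaction is tested against the
    method x time x subject residual with no sphericity correction.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError(
            "series must be subjects x minutes matrices of identical shape; "
            "truncate both methods to their common minute grid"
        )
    n, t = a.shape
    if n < 2 or t < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 time points, got {n} x {t}")
    y = np.stack([a, b])  # (method, subject, time)
    grand = y.mean()
    m_m = y.mean(axis=(1, 2))
    m_s = y.mean(axis=(0, 2))
    m_t = y.mean(axis=(0, 1))
    m_mt = y.mean(axis=1)
    m_ms = y.mean(axis=2)
    m_st = y.mean(axis=0)

    ss_mt = n * np.sum((m_mt - m_m[:, None] - m_t[None, :] + grand) ** 2)
    resid = (
        y
        - m_mt[:, None, :]
        - m_ms[:, :, None]
        - m_st[None, :, :]
        + m_m[:, None, None]
        + m_s[None, :, None]
        + m_t[None, None, :]
        - grand
    )
    ss_err = np.sum(resid**2)
    df_mt = (2 - 1) * (t - 1)
    df_err = (2 - 1) * (t - 1) * (n - 1)
    ms_mt = ss_mt / df_mt
    ms_err = ss_err / df_err
    # perfectly parallel curves leave both mean squares at rounding level;
    # their ratio would be numerical noise
    floor = 1e-12 * float(np.mean((y - grand) ** 2))
    if ms_err <= floor:
        return (0.0, 1.0) if ms_mt <= floor else (np.inf, 0.0)
    f = float(ms_mt / ms_err)
    p = float(stats.f.sf(f, df_mt, df_err))
    return f, p


@dataclass
class AgreementReport:
    """Agreement summary for one pair of methods/raters."""

    icc: float
    icc_ci: tuple[float, float]
    bias: float
    loa_low: float
    loa_high: float
    pearson_r: float
    n_pairs: int
    cv_by_condition: dict = field(default_factory=dict)
    interaction_f: float | None = None
    interaction_p: float | None = None
    diffs: list = field(default_factory=list)
    means: list = field(default_factory=list)

    def to_json(self, **kwargs) -> str:
        payload = {
            "icc": self.icc,
            "icc_ci": list(self.icc_ci),
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "pearson_r": self.pearson_r,
            "n_pairs": self.n_pairs,
            "cv_by_condition": self.cv_by_condition,
            "interaction_f": self.interaction_f,
            "interaction_p": self.interaction_p,
            "diffs": self.diffs,
            "means": self.means,
        }
        return json.dumps(payload, indent=2, **kwargs)


def compare_series(a: np.ndarray, b: np.ndarray, cv_by_condition: dict | None = None) -> AgreementReport:
    """Pooled pairwise agreement between two aligned value series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ba = bland_altman(a, b)
    icc, ci = icc_agreement(np.column_stack([a, b]))
    return AgreementReport(
        icc=icc,
        icc_ci=ci,
        bias=ba.bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        pearson_r=pearson(a, b),
        n_pairs=len(a),
        cv_by_condition=cv_by_condition or {},
        diffs=ba.diffs.tolist(),
        means=ba.means.tolist(),
    )
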