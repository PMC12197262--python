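"""Statistics for group comparison and observer agreement, from formulas.

Implements the analysis surface applied to per-image CA/COID measurements:

* two-sample Student's t (pooled variance by default, Welch by flag), with
  the two-sided p-value computed through the regularized incomplete beta
  function;
* one-sample Kolmogorov–Smirnov normality with sample-estimated mean/SD,
  whose p-value is calibrated by seeded parametric Monte Carlo (the
  Lilliefors correction) since the naive KS p is anti-conservative when
  parameters are estimated;
* Pearson correlation with the t-transform p-value;
* the coefficient of variation (CoV, %) for repeatability, averaged across
  subjects;
* ICC(2,1) — two-way random effects, absolute agreement, single measure —
  from the two-way ANOVA decomposition, with the mean squares returned for
  audit.

Measurement tables are plain pandas DataFrames with the columns
``image_id, group, examiner_id, session_id, ca_px2, coid`` and optionally
``ca_mm2_device``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import special

from .errors import DegenerateDataError, ParameterError

__all__ = [
    "GroupComparison",
    "IccComponents",
    "students_t",
    "ks_normality",
    "pearson_r",
    "cov_percent",
    "icc_2_1",
    "cohort_compare",
    "load_measurement_table",
    "inter_observer",
    "intra_observer",
]

TABLE_COLUMNS = ("image_id", "group", "examiner_id", "session_id", "ca_px2", "coid")


@dataclass(frozen=True)
class GroupComparison:
    """Two-group summary in the layout of a comparison-table row."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    dof: float
    p_value: float

    def as_row(self, label: str = "") -> str:
        p = "<0.001" if self.p_value < 0.001 else f"{self.p_value:.3f}"
        return (
            f"{label}\t{self.mean_a:,.2f}\t{self.sd_a:,.2f}"
            f"\t{self.mean_b:,.2f}\t{self.sd_b:,.2f}\t{p}"
        )


def _t_sf_two_sided(t: float, dof: float) -> float:
    """Two-sided p for a t statistic via the regularized incomplete beta."""
    if not np.isfinite(t):
        return 0.0
    if t == 0.0:
        return 1.0
    x = dof / (dof + t * t)
    return float(special.betainc(dof / 2.0, 0.5, x))


def students_t(
    a: Iterable[float], b: Iterable[float], pooled: bool = True
) -> GroupComparison:
    """Two-sample t-test (pooled variance by default; Welch if ``pooled=False``)."""
    a = np.asarray(list(a), dtype=np.float64)
    b = np.asarray(list(b), dtype=np.float64)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise DegenerateDataError(f"need >= 2 observations per group, got {na}, {nb}")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0 and ma == mb:
        raise DegenerateDataError("both groups constant and equal: t undefined")
    if pooled:
        dof = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / dof
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        se = np.sqrt(va / na + vb / nb)
        dof = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = (ma - mb) / se if se > 0 else np.inf * np.sign(ma - mb)
    return GroupComparison(
        mean_a=float(ma),
        sd_a=float(np.sqrt(va)),
        n_a=na,
        mean_b=float(mb),
        sd_b=float(np.sqrt(vb)),
        n_b=nb,
        t_statistic=float(t),
        dof=float(dof),
        p_value=_t_sf_two_sided(float(t), float(dof)),
    )


# ---------------------------------------------------------------------------
# Kolmogorov–Smirnov normality with Lilliefors Monte-Carlo calibration

_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _ks_statistic_normal(x: np.ndarray) -> float:
    """D = sup |F_n − Φ((x − x̄)/s)| with sample-estimated mean and SD."""
    n = len(x)
    s = x.std(ddof=1)
    if s == 0:
        raise DegenerateDataError("zero-variance sample: KS statistic undefined")
    z = np.sort((x - x.mean()) / s)
    cdf = special.ndtr(z)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    return float(max(d_plus, d_minus))


def _null_distribution(n: int, reps: int, seed: int) -> np.ndarray:
    """Null D distribution for sample size n (cached per (n, reps, seed))."""
    key = (n, reps, seed)
    if key in _NULL_CACHE:
        return _NULL_CACHE[key]
    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    chunk = max(1, int(5e6) // n)
    i = np.arange(1, n + 1)
    pos = 0
    while pos < reps:
        m = min(chunk, reps - pos)
        z = rng.standard_normal((m, n))
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
        z.sort(axis=1)
        cdf = special.ndtr(z)
        d_plus = np.max(i / n - cdf, axis=1)
        d_minus = np.max(cdf - (i - 1) / n, axis=1)
        out[pos : pos + m] = np.maximum(d_plus, d_minus)
        pos += m
    out.sort()
    _NULL_CACHE[key] = out
    return out


def ks_normality(
    x: Iterable[float], n_reps: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """One-sample KS test against a normal with estimated parameters.

    Because the mean and SD are estimated from the sample, the p-value is
    calibrated by parametric resampling under the normal null (``n_reps``
    simulated samples of the same size, seeded), following Lilliefors.

    Returns ``(D, p)`` where ``p = (1 + #{D_null >= D}) / (n_reps + 1)``.
    """
    x = np.asarray(list(x), dtype=np.float64)
    if len(x) < 4:
        raise ParameterError(f"need n >= 4 for the normality test, got {len(x)}")
    d = _ks_statistic_normal(x)
    null = _null_distribution(len(x), n_reps, seed)
    n_ge = len(null) - np.searchsorted(null, d, side="left")
    return d, float((1 + n_ge) / (n_reps + 1))


def pearson_r(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Sample Pearson r with the two-sided p from t = r·sqrt((n−2)/(1−r²))."""
    x = np.asarray(list(x), dtype=np.float64)
    y = np.asarray(list(y), dtype=np.float64)
    if len(x) != len(y):
        raise ParameterError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    if n < 3:
        raise ParameterError(f"need n >= 3 for a correlation p-value, got {n}")
    xd, yd = x - x.mean(), y - y.mean()
    sx = np.sqrt((xd**2).sum())
    sy = np.sqrt((yd**2).sum())
    if sx == 0 or sy == 0:
        raise DegenerateDataError("zero variance: correlation undefined")
    r = float(np.clip((xd * yd).sum() / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return r, _t_sf_two_sided(float(t), n - 2)


def cov_percent(
    replicates: Mapping[object, Iterable[float]] | Iterable[Iterable[float]],
) -> float:
    """Mean across subjects of CoV_i = 100·SD_i/mean_i over each subject's replicates.

    SD uses the n−1 denominator.  Subjects with fewer than two replicates are
    ignored; at least one subject must have two or more.
    """
    if isinstance(replicates, Mapping):
        groups = list(replicates.values())
    else:
        groups = [list(g) for g in replicates]
    covs = []
    for g in groups:
        g = np.asarray(list(g), dtype=np.float64)
        if len(g) < 2:
            continue
        mean = g.mean()
        if mean == 0:
            raise DegenerateDataError("subject mean of 0: CoV undefined")
        covs.append(100.0 * g.std(ddof=1) / mean)
    if not covs:
        raise ParameterError("need >= 2 replicates for at least one subject")
    return float(np.mean(covs))


@dataclass(frozen=True)
class IccComponents:
    """Mean squares of the two-way ANOVA behind ICC(2,1)."""

    msr: float  # between-subjects (rows)
    msc: float  # between-raters (columns)
    mse: float  # residual


def icc_2_1(data: np.ndarray | pd.DataFrame) -> tuple[float, IccComponents]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``data`` is a complete subjects × raters matrix.  Returns the coefficient

        (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

    together with the ANOVA mean squares for audit.
    """
    m = np.asarray(data, dtype=np.float64)
    if m.ndim != 2:
        raise ParameterError(f"expected a 2-D subjects × raters matrix, got ndim={m.ndim}")
    if np.isnan(m).any():
        raise ParameterError("missing cells are not allowed (no imputation)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ParameterError(f"need >= 2 subjects and >= 2 raters, got {n} x {k}")
    if np.ptp(m) == 0:
        raise DegenerateDataError("constant matrix: ICC undefined")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((m - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise DegenerateDataError("degenerate variance decomposition: ICC undefined")
    icc = (msr - mse) / denom
    return float(icc), IccComponents(float(msr), float(msc), float(mse))


# ---------------------------------------------------------------------------
# Measurement tables

def load_measurement_table(path: str | os.PathLike) -> pd.DataFrame:
    """Load and validate a per-image measurement CSV.

    Requires the columns ``image_id, group, examiner_id, session_id,
    ca_px2, coid``; ``(image_id, examiner_id, session_id)`` must be unique
    and ``group`` nonempty on every row.
    """
    df = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"measurement table missing columns: {missing}")
    key = ["image_id", "examiner_id", "session_id"]
    if df.duplicated(subset=key).any():
        raise ParameterError(f"duplicate {tuple(key)} rows in measurement table")
    if df["group"].isna().any() or (df["group"].astype(str).str.len() == 0).any():
        raise ParameterError("every row must have a nonempty group")
    return df


def cohort_compare(
    table: pd.DataFrame, metric: str = "ca_px2", pooled: bool = True
) -> GroupComparison:
    """Diabetic-vs-healthy comparison of one metric, as a table-style row.

    Group a is ``diabetic``, group b is ``healthy``; both must be present
    with at least two observations each.
    """
    if metric not in table.columns:
        raise ParameterError(f"metric column {metric!r} not in table")
    groups = set(table["group"].unique())
    for g in ("diabetic", "healthy"):
        if g not in groups:
            raise ParameterError(f"group {g!r} absent from table")
    a = table.loc[table["group"] == "diabetic", metric].dropna().to_numpy()
    b = table.loc[table["group"] == "healthy", metric].dropna().to_numpy()
    return students_t(a, b, pooled=pooled)


def _rating_matrix(table: pd.DataFrame, metric: str, col: str) -> pd.DataFrame:
    piv = table.pivot_table(index="image_id", columns=col, values=metric)
    if piv.isna().any().any():
        raise ParameterError(
            f"incomplete {col} design: every image needs a value for every {col}"
        )
    return piv


def inter_observer(table: pd.DataFrame, metric: str = "ca_px2") -> dict:
    """Inter-observer agreement: examiners as raters over images.

    Returns ``{"icc", "components", "cov_percent", "n_subjects", "n_raters"}``.
    """
    piv = _rating_matrix(table, metric, "examiner_id")
    icc, comp = icc_2_1(piv.to_numpy())
    cov = cov_percent(piv.to_numpy().tolist())
    return {
        "icc": icc,
        "components": comp,
        "cov_percent": cov,
        "n_subjects": piv.shape[0],
        "n_raters": piv.shape[1],
    }


def intra_observer(
    table: pd.DataFrame, metric: str = "ca_px2", examiner_id: str = "E2"
) -> dict:
    """Intra-observer repeatability: one examiner's sessions as raters."""
    sub = table[table["examiner_id"] == examiner_id]
    if sub.empty:
        raise ParameterError(f"no rows for examiner {examiner_id!r}")
    piv = _rating_matrix(sub, metric, "session_id")
    if piv.shape[1] < 2:
        raise ParameterError(
            f"examiner {examiner_id!r} has fewer than two sessions"
        )
    icc, comp = icc_2_1(piv.to_numpy())
    cov = cov_percent(piv.to_numpy().tolist())
    return {
        "icc": icc,
        "components": comp,
        "cov_percent": cov,
        "n_subjects": piv.shape[0],
        "n_raters": piv.shape[1],
    }
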