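"""Group-level statistics: paired t-tests and linear-regression R².

The cohort analysis compares ROI metrics between structures or weeks with
a classical paired-samples t-test and quantifies the association between
tracer-uptake ratios and mean T2* with ordinary least squares. Two-sided
tests at alpha = 0.05 throughout, no multiple-testing correction (a
deliberate mirror of conventional small-cohort reporting; see the methods
note for the caveat). Missing patients are dropped pairwise per test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class PairedSample:
    """Two metric vectors aligned by patient; incomplete pairs are dropped."""

    labels: list[str]
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("paired vectors must be 1-D and the same length")
        keep = np.isfinite(a) & np.isfinite(b)
        self.labels = [l for l, k in zip(self.labels, keep) if k]
        self.a, self.b = a[keep], b[keep]
        if self.a.size < 2:
            raise ValueError("need at least 2 complete pairs")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def paired_t_test(sample: PairedSample) -> tuple[float, float, int]:
    """Classical paired t: t = mean(d) / (std(d)/sqrt(n)), df = n - 1.

    Identical pairs give t = 0, p = 1. Zero-variance differences with a
    nonzero mean give a signed infinite t with p = 0.
    """
    d = sample.a - sample.b
    n = d.size
    df = n - 1
    sd = float(np.std(d, ddof=1))
    md = float(np.mean(d))
    if sd == 0:
        if md == 0:
            return 0.0, 1.0, df
        return float(np.sign(md) * np.inf), 0.0, df
    t = md / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), p, df


def linear_regression_r2(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares of y on x; R² = 1 - SSres/SStot.

    The p-value is the two-sided t-test on the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    if np.ptp(y) == 0:
        # SStot = 0: the flat fit is perfect but explains no variance
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                                p_value=1.0, n=int(x.size))
    res = sps.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue**2), p_value=float(res.pvalue),
                            n=int(x.size))


def suv_max(image, mask) -> float:
    """Maximum voxel value within a non-empty ROI."""
    image.geometry.require_compatible(mask.geometry, "SUV image vs mask")
    if mask.is_empty:
        raise ValueError(f"mask {mask.label!r} is empty; SUVmax undefined")
    return float(np.max(image.values[mask.mask]))


def correlation_endpoints(endpoints: pd.DataFrame, week: int) -> pd.DataFrame:
    """The study's regression endpoints at one week.

    ``endpoints`` is a per-patient long table with columns
    ``patient, week, structure, fmiso_ratio, fdg_ratio, t2star_mean`` where
    the ratios are SUVmax(structure)/SUVmean(NT) of the same session. Per
    structure (GTV-T, GTV-LN) this computes OLS R² of the FMISO ratio
    against mean T2*, and — when FDG ratios are present at that week, i.e.
    at baseline — of the FMISO ratio against the FDG ratio.
    """
    rows = []
    sub = endpoints[endpoints["week"] == week]
    for structure in ("GTV-T", "GTV-LN"):
        s = sub[sub["structure"] == structure]
        for yvar, pair in (("t2star_mean", "FMISO-vs-T2*"),
                           ("fdg_ratio", "FMISO-vs-FDG")):
            if yvar not in s.columns:
                continue
            data = s[["fmiso_ratio", yvar]].dropna()
            if len(data) == 0 and yvar == "fdg_ratio":
                continue  # FDG not acquired at this week
            if len(data) < 3:
                rows.append({"week": week, "structure": structure, "pair": pair,
                             "n": len(data), "slope": np.nan, "intercept": np.nan,
                             "r_squared": np.nan, "p_value": np.nan,
                             "error": "insufficient complete cases"})
                continue
            reg = linear_regression_r2(data["fmiso_ratio"].to_numpy(),
                                       data[yvar].to_numpy())
            rows.append({"week": week, "structure": structure, "pair": pair,
                         "n": reg.n, "slope": reg.slope, "intercept": reg.intercept,
                         "r_squared": reg.r_squared, "p_value": reg.p_value,
                         "error": ""})
    return pd.DataFrame(rows)
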