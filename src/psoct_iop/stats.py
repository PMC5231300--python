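"""Dose-response statistics for metric-vs-IOP series.

The study design yields, per animal, one scalar metric value per IOP level;
points are pooled across animals and evaluated with rank statistics chosen
for monotone (not necessarily linear) relations:

* Spearman's rho with the conventional strength bands (|rho| >= 0.70 strong,
  0.50-0.70 moderate, 0.30-0.50 weak, else negligible), p-value from the
  two-sided t approximation.
* Ordinary least-squares regression for effect sizes (slope per mmHg).
* Wilcoxon rank-sum for the superior/inferior hemifield comparison.
* Conversion between effective birefringence in deg/um and the dimensionless
  refractive-index difference: ``dn = b * lambda_um / 360``.

The scleral response is summarised by two independent fits below/above a
breakpoint (default 45 mmHg): a dynamic phase followed by a plateau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    UndefinedCorrelationError,
)

STRENGTH_BANDS = (
    (0.70, "strong"),
    (0.50, "moderate"),
    (0.30, "weak"),
    (0.0, "negligible"),
)


def classify_strength(rho: float) -> str:
    """Map |rho| to a strength class; bands are closed on the left."""
    a = abs(rho)
    for lo, name in STRENGTH_BANDS:
        if a >= lo:
            return name
    return "negligible"


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    strength_class: str


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    n: int


@dataclass
class IOPSeries:
    """Paired (IOP, metric value) observations, optionally labelled by animal."""

    iop: np.ndarray
    values: np.ndarray
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.iop = np.asarray(self.iop, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.iop.shape != self.values.shape or self.iop.ndim != 1:
            raise InvalidInputError("iop and values must be 1-D and paired")
        if np.any((self.iop < 0) | (self.iop > 200)):
            raise InvalidInputError("IOP outside the plausible 0-200 mmHg range")

    def dropna(self) -> "IOPSeries":
        ok = np.isfinite(self.iop) & np.isfinite(self.values)
        return IOPSeries(self.iop[ok], self.values[ok], self.animal_id)

    def restrict(self, lo: float, hi: float) -> "IOPSeries":
        ok = (self.iop >= lo) & (self.iop <= hi)
        return IOPSeries(self.iop[ok], self.values[ok], self.animal_id)


def spearman(series: IOPSeries) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    The p-value is the two-sided t approximation
    ``t = rho * sqrt((n-2) / (1-rho**2))`` on n-2 degrees of freedom.
    """
    s = series.dropna()
    n = s.iop.size
    if n < 4:
        raise InsufficientDataError(f"Spearman needs >= 4 pairs, got {n}")
    if np.unique(s.iop).size < 2 or np.unique(s.values).size < 2:
        raise UndefinedCorrelationError("correlation undefined for a constant variable")
    res = sps.spearmanr(s.iop, s.values)
    rho = float(res.statistic)
    p = float(res.pvalue)
    if abs(rho) == 1.0:
        p = 0.0 if np.isnan(p) else p
    return CorrelationResult(rho, p, n, classify_strength(rho))


def ols_fit(series: IOPSeries) -> RegressionResult:
    """Ordinary least-squares fit of metric value vs IOP."""
    s = series.dropna()
    n = s.iop.size
    if n < 2 or np.unique(s.iop).size < 2:
        raise InsufficientDataError("OLS needs >= 2 distinct IOP values")
    res = sps.linregress(s.iop, s.values)
    return RegressionResult(float(res.slope), float(res.intercept), n)


def wilcoxon_ranksum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration for small tie-free samples (both n <= 20), otherwise the
    normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("rank-sum test needs >= 3 values per sample")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def birefringence_to_dimensionless(b: float, wavelength_nm: float = 840.0) -> float:
    """Convert effective birefringence (deg/um) to a dimensionless dn.

    One full wave (360 deg) over one wavelength corresponds to dn = 1, hence
    ``dn = b * lambda_um / 360``. Works equally for per-mmHg slopes.
    """
    if wavelength_nm <= 0:
        raise InvalidInputError("wavelength must be positive")
    return b * (wavelength_nm * 1e-3) / 360.0


def dimensionless_to_birefringence(dn: float, wavelength_nm: float = 840.0) -> float:
    """Inverse of :func:`birefringence_to_dimensionless`."""
    if wavelength_nm <= 0:
        raise InvalidInputError("wavelength must be positive")
    return dn * 360.0 / (wavelength_nm * 1e-3)


def two_phase_summary(
    series: IOPSeries, breakpoint: float = 45.0
) -> tuple[RegressionResult | None, RegressionResult | None]:
    """Independent OLS fits below/above a breakpoint IOP.

    Points at the breakpoint belong to the lower (dynamic) phase. A side with
    fewer than 2 distinct IOP values yields None.
    """
    s = series.dropna()
    below = IOPSeries(s.iop[s.iop <= breakpoint], s.values[s.iop <= breakpoint])
    above = IOPSeries(s.iop[s.iop > breakpoint], s.values[s.iop > breakpoint])
    out = []
    for side in (below, above):
        try:
            out.append(ols_fit(side))
        except InsufficientDataError:
            out.append(None)
    return out[0], out[1]
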