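"""From fitted free-donor fractions to reporter phosphorylation and
kinase/phosphatase balance.

The reporter interconverts between its unphosphorylated and phosphorylated
forms with first-order rates k_PKA and k_phosphatase.  At steady state
k_PKA [AKAR] = k_phosphatase [pAKAR], so the species ratio

    [AKAR] / [pAKAR] = k_phosphatase / k_PKA

is read directly from the phosphorylated fraction f_pAKAR.  f_pAKAR itself
is interpolated between calibration endpoints: the free-donor fraction
measured when the reporter is fully dephosphorylated (kinase inhibited or a
non-phosphorylatable mutant) and when it is fully phosphorylated
(forskolin + phosphodiesterase and phosphatase inhibitors):

    f_pAKAR = (P_free(AKAR) - P_free(experiment))
              / (P_free(AKAR) - P_free(pAKAR))

Only the rate *ratio* is identified at steady state; the ratio is therefore
reported only for measurement windows that pass a steadiness check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationEndpoints",
    "KineticState",
    "SteadinessResult",
    "f_pakar",
    "rate_ratio",
    "kinetic_state",
    "steady_state_check",
    "bonferroni_alpha",
    "compare_conditions",
]

#: Absolute excursion of f_pAKAR outside [0, 1] tolerated (fit noise near an
#: endpoint); larger excursions indicate a calibration error and raise.
CLIP_TOLERANCE = 0.05


@dataclass(frozen=True)
class CalibrationEndpoints:
    """Free-donor fractions of the fully de-/phosphorylated reporter."""

    p_free_akar: float    # unphosphorylated endpoint, (0, 1]
    p_free_pakar: float   # fully phosphorylated endpoint, [0, 1)

    def __post_init__(self) -> None:
        if not 0.0 < self.p_free_akar <= 1.0:
            raise ValueError("p_free_akar must lie in (0, 1]")
        if not 0.0 <= self.p_free_pakar < 1.0:
            raise ValueError("p_free_pakar must lie in [0, 1)")
        if not self.p_free_akar > self.p_free_pakar:
            raise ValueError(
                "phosphorylation increases FRET: p_free_akar must exceed "
                "p_free_pakar")


@dataclass(frozen=True)
class KineticState:
    """Phosphorylated fraction and steady-state rate ratio of one ROI."""

    f_pakar: float
    rate_ratio: float  # k_phosphatase / k_PKA; inf at f_pakar = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_pakar <= 1.0:
            raise ValueError("f_pakar must lie in [0, 1]")
        if self.rate_ratio < 0:
            raise ValueError("rate_ratio must be >= 0")


def f_pakar(p_free_exp: float, endpoints: CalibrationEndpoints,
            clip_tolerance: float = CLIP_TOLERANCE) -> float:
    """Phosphorylated reporter fraction from a measured free-donor fraction.

    Affine, order-reversing interpolation between the calibration
    endpoints.  Values pushed outside [0, 1] by fit noise are clipped with
    a warning if within ``clip_tolerance``; larger excursions raise, since
    they indicate endpoints that do not bracket the measurement.
    """
    span = endpoints.p_free_akar - endpoints.p_free_pakar
    f = (endpoints.p_free_akar - p_free_exp) / span
    if f < -clip_tolerance or f > 1.0 + clip_tolerance:
        raise ValueError(
            f"f_pAKAR = {f:.4f} is outside [0, 1] by more than "
            f"{clip_tolerance}; check the calibration endpoints")
    if -1e-9 <= f < 0.0 or 1.0 < f <= 1.0 + 1e-9:
        return float(min(max(f, 0.0), 1.0))  # float epsilon, not fit noise
    if f < 0.0 or f > 1.0:
        warnings.warn(
            f"f_pAKAR = {f:.4f} clipped into [0, 1] (fit noise near an "
            "endpoint)", stacklevel=2)
        f = min(max(f, 0.0), 1.0)
    return float(f)


def rate_ratio(f: float) -> float:
    """Steady-state k_phosphatase / k_PKA from the phosphorylated fraction.

    (1 - f) / f; strictly decreasing on (0, 1], with the f = 0 limit
    reported as +inf (no phosphorylation means the kinase term is
    unidentified) and f = 1 giving 0.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"f must lie in [0, 1], got {f}")
    if f == 0.0:
        return float("inf")
    return (1.0 - f) / f


def kinetic_state(p_free_exp: float, endpoints: CalibrationEndpoints,
                  **kwargs) -> KineticState:
    f = f_pakar(p_free_exp, endpoints, **kwargs)
    return KineticState(f_pakar=f, rate_ratio=rate_ratio(f))


@dataclass(frozen=True)
class SteadinessResult:
    """Outcome of the steady-state check over a measurement window."""

    steady: bool
    slope: float          # drift per frame (units of the input series)
    slope_ci: tuple       # 95% CI on the slope
    p_value: float


def steady_state_check(series, window=None, alpha: float = 0.05,
                       ) -> SteadinessResult:
    """Test whether a fitted-fraction series has reached steady state.

    Steady state holds when the lifetime (equivalently the fitted fraction)
    is constant; the check fits an ordinary least-squares line over the
    window and flags the window steady when the (1 - alpha) confidence
    interval on the slope contains zero.  Rate ratios should only be
    interpreted for steady windows.
    """
    v = np.asarray(series, dtype=float)
    if window is not None:
        v = v[window]
    if v.size < 3:
        raise ValueError("steadiness check needs at least 3 frames")
    x = np.arange(v.size, dtype=float)
    res = stats.linregress(x, v)
    if np.isnan(res.stderr):  # zero residual variance (constant series)
        return SteadinessResult(steady=res.slope == 0.0,
                                slope=float(res.slope),
                                slope_ci=(float(res.slope), float(res.slope)),
                                p_value=1.0 if res.slope == 0.0 else 0.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, v.size - 2)
    lo = res.slope - tcrit * res.stderr
    hi = res.slope + tcrit * res.stderr
    return SteadinessResult(steady=bool(lo <= 0.0 <= hi),
                            slope=float(res.slope),
                            slope_ci=(float(lo), float(hi)),
                            p_value=float(res.pvalue))


def bonferroni_alpha(familywise_alpha: float, n_comparisons: int) -> float:
    """Per-comparison significance threshold under Bonferroni correction."""
    if not 0.0 < familywise_alpha < 1.0:
        raise ValueError("familywise_alpha must lie in (0, 1)")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return familywise_alpha / n_comparisons


def compare_conditions(groups: dict, reference: str,
                       familywise_alpha: float = 0.05,
                       n_comparisons: int | None = None):
    """Welch t-tests of each group against a reference, Bonferroni-corrected.

    Unpaired two-sided Student t-tests assuming unequal variances
    (Welch-Satterthwaite degrees of freedom) compare every non-reference
    group with ``reference``; the per-comparison threshold is
    ``familywise_alpha / n_comparisons`` (defaulting to the number of
    comparisons performed).  Returns a pandas DataFrame with one row per
    comparison: group, n, t, df, p_value, corrected_alpha, significant.
    """
    import pandas as pd

    if reference not in groups:
        raise KeyError(f"reference group {reference!r} not in groups")
    for name, values in groups.items():
        if len(np.asarray(values)) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    others = [g for g in groups if g != reference]
    if n_comparisons is None:
        n_comparisons = len(others)
    alpha = bonferroni_alpha(familywise_alpha, n_comparisons)
    ref = np.asarray(groups[reference], dtype=float)
    rows = []
    for name in others:
        x = np.asarray(groups[name], dtype=float)
        res = stats.ttest_ind(x, ref, equal_var=False)
        rows.append({
            "group": name, "reference": reference, "n": x.size,
            "n_reference": ref.size, "t": float(res.statistic),
            "df": float(res.df), "p_value": float(res.pvalue),
            "corrected_alpha": alpha,
            "significant": bool(res.pvalue < alpha),
        })
    return pd.DataFrame(rows)
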