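"""Fluorescence recovery after photobleaching (FRAP) analysis.

A diffusible reporter bleached in a small region (a spine head or a stretch
of dendrite) is replenished by diffusion from the surrounding cytoplasm;
the recovery time constant tau measures that exchange.  Traces are
normalized against the pre-bleach baseline, replicate acquisitions are
averaged, and the post-bleach recovery is fit with a single exponential
whose plateau is left free (no assumption of full return to baseline):

    F(t) = plateau - amplitude * exp(-t / tau)

with t measured from the first post-bleach sample, excluding the bleach
pulse itself so finite pulse widths do not distort tau.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

__all__ = [
    "FRAPTrace",
    "FRAPFit",
    "TauSummary",
    "normalize_trace",
    "average_acquisitions",
    "fit_frap",
    "summarize_taus",
]

TAU_BOUNDS_MS = (1.0, 10_000.0)


@dataclass(frozen=True)
class FRAPTrace:
    """One FRAP acquisition: fluorescence vs time around a bleach step."""

    time: np.ndarray          # ms, strictly increasing
    fluorescence: np.ndarray  # arbitrary units or normalized
    bleach_time: float = 0.0  # ms
    acquisition_id: int = 0
    roi_class: str = "spine"  # {"spine", "dendrite"}

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("time and fluorescence must be matching 1-D arrays")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if not t[0] <= self.bleach_time <= t[-1]:
            raise ValueError("bleach_time must lie inside the recorded interval")
        if not np.any(t < self.bleach_time):
            raise ValueError("at least one pre-bleach sample required")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "fluorescence", f)

    @property
    def pre_bleach(self) -> np.ndarray:
        return self.fluorescence[self.time < self.bleach_time]

    @property
    def post_mask(self) -> np.ndarray:
        return self.time >= self.bleach_time


def normalize_trace(trace: FRAPTrace) -> FRAPTrace:
    """Divide by the mean of the pre-bleach samples (baseline -> 1.0).

    Idempotent: renormalizing a normalized trace changes nothing.
    """
    baseline = trace.pre_bleach.mean()
    if baseline <= 0:
        raise ValueError("pre-bleach baseline must be positive")
    return replace(trace, fluorescence=trace.fluorescence / baseline)


def average_acquisitions(traces) -> FRAPTrace:
    """Pointwise mean of replicate acquisitions on an identical grid."""
    traces = list(traces)
    if not traces:
        raise ValueError("no traces to average")
    first = traces[0]
    for tr in traces[1:]:
        if (tr.time.shape != first.time.shape
                or not np.allclose(tr.time, first.time)
                or tr.bleach_time != first.bleach_time):
            raise ValueError("acquisitions must share time grid and bleach time")
    mean_f = np.mean([tr.fluorescence for tr in traces], axis=0)
    return replace(first, fluorescence=mean_f)


@dataclass(frozen=True)
class FRAPFit:
    """Single-exponential recovery fit of one averaged trace.

    ``plateau`` is the free asymptote (may sit below baseline);
    ``amplitude`` the recovered span; ``identifiable`` is False when the
    recovery amplitude is indistinguishable from the residual noise or tau
    pinned at a bound, in which case tau should not be interpreted.
    """

    tau: float         # ms
    amplitude: float
    plateau: float
    rsq: float
    identifiable: bool
    roi_class: str = "spine"

    def __post_init__(self) -> None:
        if self.identifiable and self.tau <= 0:
            raise ValueError("identifiable fits must have tau > 0")


def _recovery(t, plateau, amplitude, tau):
    return plateau - amplitude * np.exp(-t / tau)


def fit_frap(trace: FRAPTrace, min_post_samples: int = 5) -> FRAPFit:
    """Least-squares single-exponential fit of the post-bleach recovery.

    Only samples at or after the bleach are used; the first post-bleach
    sample defines t = 0 of recovery.  tau is initialized from the time at
    which the trace crosses 63% of the first-to-last post-bleach span and
    bounded to [1 ms, 10 s].
    """
    post = trace.post_mask
    if post.sum() < min_post_samples:
        raise ValueError(
            f"need >= {min_post_samples} post-bleach samples, got {post.sum()}")
    t = trace.time[post] - trace.time[post][0]
    f = trace.fluorescence[post]

    f_first, f_last = f[0], float(f[-min(10, f.size):].mean())
    span = f_last - f_first
    if abs(span) > 0:
        target = f_first + 0.63 * span
        crossed = np.nonzero((f - target) * np.sign(span) >= 0)[0]
        tau0 = float(t[crossed[0]]) if crossed.size else float(t[-1] / 3)
    else:
        tau0 = float(t[-1] / 3)
    tau0 = float(np.clip(tau0, *TAU_BOUNDS_MS))

    try:
        popt, _ = optimize.curve_fit(
            _recovery, t, f, p0=[f_last, span, tau0],
            bounds=([-np.inf, -np.inf, TAU_BOUNDS_MS[0]],
                    [np.inf, np.inf, TAU_BOUNDS_MS[1]]),
            ftol=1e-13, xtol=1e-13, gtol=1e-13, max_nfev=20_000)
        converged = True
    except RuntimeError:
        popt, converged = (f_last, span, tau0), False
    plateau, amplitude, tau = (float(v) for v in popt)

    resid = f - _recovery(t, plateau, amplitude, tau)
    ss_res = float(resid @ resid)
    ss_tot = float(((f - f.mean()) ** 2).sum())
    rsq = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    resid_sd = float(np.sqrt(ss_res / max(t.size - 3, 1)))

    at_bound = (tau <= TAU_BOUNDS_MS[0] * (1 + 1e-6)
                or tau >= TAU_BOUNDS_MS[1] * (1 - 1e-6))
    identifiable = (converged and not at_bound
                    and amplitude >= max(2.0 * resid_sd, 1e-6))
    return FRAPFit(tau=tau, amplitude=amplitude, plateau=plateau, rsq=rsq,
                   identifiable=identifiable, roi_class=trace.roi_class)


@dataclass(frozen=True)
class TauSummary:
    """Per-ROI-class summary of recovery time constants."""

    roi_class: str
    n: int
    n_excluded: int         # flagged (unidentifiable) fits, not summarized
    mean: float             # ms
    sem: float | None       # None when n < 2
    taus: np.ndarray        # sorted identifiable taus (ECDF x)
    ecdf: np.ndarray        # cumulative probabilities (ECDF y)


def summarize_taus(fits) -> dict[str, TauSummary]:
    """Mean, SEM and empirical CDF of tau per ROI class.

    Unidentifiable fits are excluded from the summary but counted.  A class
    with no identifiable fit is an error.
    """
    by_class: dict[str, list[FRAPFit]] = {}
    for fit in fits:
        by_class.setdefault(fit.roi_class, []).append(fit)
    out = {}
    for roi_class, class_fits in sorted(by_class.items()):
        good = [f.tau for f in class_fits if f.identifiable]
        if not good:
            raise ValueError(
                f"class {roi_class!r} has no identifiable fits to summarize")
        taus = np.sort(np.asarray(good))
        sem = (float(taus.std(ddof=1) / np.sqrt(taus.size))
               if taus.size > 1 else None)
        out[roi_class] = TauSummary(
            roi_class=roi_class, n=taus.size,
            n_excluded=len(class_fits) - taus.size,
            mean=float(taus.mean()), sem=sem, taus=taus,
            ecdf=np.arange(1, taus.size + 1) / taus.size)
    return out
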