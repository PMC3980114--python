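"""Two-state fluorescence decay model for 2pFLIM-FRET measurements.

A FRET biosensor's donor population is a mixture of two species: free donors
with lifetime ``tau_free`` and donors undergoing FRET with the shorter
lifetime ``tau_fret``.  After pulsed excitation the fluorescence decays as

    F(t) = F0 * (P_free * exp(-t/tau_free) + P_FRET * exp(-t/tau_fret))

with the amplitude fractions summing to one.  Photon arrival times measured
by time-correlated single photon counting (TCSPC) are binned into 64 or 256
channels over one laser period (12.5 ns at 80 MHz); the measured histogram is
the decay convolved with the instrument response function (IRF) and shifted
by the offset arrival time ``t0`` (the laser-to-detector delay).

Because the laser is an 80 MHz pulse train, photons emitted more than one
period after their excitation pulse appear in the next period's histogram.
All sampled curves here therefore treat the time axis as circular over the
period: exponential tails wrap, and convolution with the IRF is periodic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DecayParams",
    "IRFCurve",
    "PhotonHistogram",
    "eval_decay",
    "convolve_irf",
    "mean_lifetime",
    "empirical_mean_lifetime",
    "periodic_component",
    "expected_counts",
    "LASER_PERIOD_NS",
]

#: One period of the 80 MHz pulsed excitation laser, in ns.
LASER_PERIOD_NS = 12.5


@dataclass(frozen=True)
class DecayParams:
    """Parameters of the two-state (free / FRET) donor decay.

    Attributes
    ----------
    f0 : float
        Peak amplitude (expected photons per channel scale), >= 0.
    p_free : float
        Amplitude fraction of free donors, in [0, 1].  The FRET fraction is
        derived as ``p_fret = 1 - p_free`` so the sum constraint is
        structural.
    tau_free, tau_fret : float
        Lifetimes (ns) of the free and FRET-undergoing donor; FRET shortens
        the lifetime, so ``tau_fret < tau_free`` is required.
    t0 : float
        Offset arrival time (ns), the delay between laser-pulse detection and
        photon detection; shifts the decay origin within the period.
    """

    f0: float
    p_free: float
    tau_free: float = 2.6
    tau_fret: float = 1.1
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.f0) or self.f0 < 0:
            raise ValueError(f"f0 must be finite and >= 0, got {self.f0}")
        if not 0.0 <= self.p_free <= 1.0:
            raise ValueError(f"p_free must lie in [0, 1], got {self.p_free}")
        if self.tau_free <= 0 or self.tau_fret <= 0:
            raise ValueError("lifetimes must be strictly positive")
        if not self.tau_fret < self.tau_free:
            raise ValueError(
                f"tau_fret ({self.tau_fret}) must be < tau_free ({self.tau_free})"
            )
        if self.t0 < 0:
            raise ValueError(f"t0 must be >= 0, got {self.t0}")

    @property
    def p_fret(self) -> float:
        """Amplitude fraction of FRET-undergoing donors (1 - p_free)."""
        return 1.0 - self.p_free

    def with_p_fret(self, p_fret: float) -> "DecayParams":
        return replace(self, p_free=1.0 - p_fret)


def _channel_centers(n_channels: int, channel_width: float) -> np.ndarray:
    # channel i covers [i*w, (i+1)*w); its center is (i + 0.5)*w
    return (np.arange(n_channels) + 0.5) * channel_width


@dataclass(frozen=True)
class IRFCurve:
    """Sampled instrument response function on the TCSPC channel grid.

    Values are normalized to sum to one on construction; the grid must tile
    exactly one laser period.
    """

    values: np.ndarray
    channel_width: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("IRF values must be a non-empty 1-D array")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("IRF values must be finite and non-negative")
        total = values.sum()
        if total <= 0:
            raise ValueError("IRF must contain positive mass")
        if self.channel_width <= 0:
            raise ValueError("channel_width must be positive")
        object.__setattr__(self, "values", values / total)

    @property
    def n_channels(self) -> int:
        return self.values.size

    @property
    def period(self) -> float:
        return self.n_channels * self.channel_width

    @property
    def channel_centers(self) -> np.ndarray:
        return _channel_centers(self.n_channels, self.channel_width)

    @property
    def mean_time(self) -> float:
        """First moment of the IRF (ns); the mean detection delay it adds."""
        return float(np.dot(self.channel_centers, self.values))

    @property
    def mean_delay(self) -> float:
        """Mean shift (ns) the discrete periodic convolution applies.

        Channel index 0 shifts by zero; indices are unwrapped circularly
        around zero so an IRF peak just before the period edge counts as a
        small negative delay, not a full period.
        """
        period = self.period
        shift = np.arange(self.n_channels) * self.channel_width
        shift = np.mod(shift + period / 2, period) - period / 2
        return float(np.dot(shift, self.values))

    @classmethod
    def delta(cls, n_channels: int, period: float = LASER_PERIOD_NS,
              channel: int = 0) -> "IRFCurve":
        """Unit impulse IRF (all mass in one channel)."""
        values = np.zeros(n_channels)
        values[channel] = 1.0
        return cls(values, period / n_channels)

    @classmethod
    def gaussian(cls, n_channels: int, sigma: float, center: float = 0.25,
                 period: float = LASER_PERIOD_NS) -> "IRFCurve":
        """Gaussian IRF of width ``sigma`` ns centered at ``center`` ns.

        Sampled on the circular period so no mass is lost at the edges;
        emulates the sharp response measured from second-harmonic generation
        of urea crystals.
        """
        width = period / n_channels
        centers = _channel_centers(n_channels, width)
        # circular distance to the Gaussian center
        d = np.mod(centers - center + period / 2, period) - period / 2
        values = np.exp(-0.5 * (d / sigma) ** 2)
        return cls(values, width)


@dataclass(frozen=True)
class PhotonHistogram:
    """Binned photon counts over one laser period (one ROI or pixel)."""

    counts: np.ndarray
    channel_width: float
    period: float = field(default=LASER_PERIOD_NS)
    allowed_n_channels: tuple = (64, 256)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D array")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integer-valued")
        counts = np.asarray(np.round(counts), dtype=np.int64)
        if self.allowed_n_channels and counts.size not in self.allowed_n_channels:
            raise ValueError(
                f"n_channels must be one of {self.allowed_n_channels}, "
                f"got {counts.size}"
            )
        if not np.isclose(counts.size * self.channel_width, self.period):
            raise ValueError("n_channels * channel_width must equal the period")
        object.__setattr__(self, "counts", counts)

    @property
    def n_channels(self) -> int:
        return self.counts.size

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def channel_centers(self) -> np.ndarray:
        return _channel_centers(self.n_channels, self.channel_width)


def eval_decay(params: DecayParams, t) -> np.ndarray | float:
    """Evaluate the two-state decay at time ``t`` (ns, relative to ``t0``).

    Returns ``f0 * (p_free * exp(-t/tau_free) + p_fret * exp(-t/tau_fret))``
    for t >= 0 and zero before the offset (t < 0).
    """
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        out = params.f0 * (
            params.p_free * np.exp(-t / params.tau_free)
            + params.p_fret * np.exp(-t / params.tau_fret)
        )
    out = np.where(t < 0, 0.0, out)
    return out if out.ndim else float(out)


def convolve_irf(model_curve: np.ndarray, irf: IRFCurve,
                 mode: str = "wrap") -> np.ndarray:
    """Convolve a sampled model curve with the IRF on the shared grid.

    ``mode="wrap"`` (default) performs periodic convolution over the laser
    period, matching the physics of an 80 MHz pulse train in which slow-tail
    photons wrap into the next period.  ``mode="truncate"`` keeps only the
    first period of the linear convolution (useful for tests).
    """
    curve = np.asarray(model_curve, dtype=float)
    if curve.ndim != 1 or curve.size != irf.n_channels:
        raise ValueError(
            f"model curve has {curve.shape} samples; expected "
            f"({irf.n_channels},) matching the IRF grid"
        )
    full = np.convolve(curve, irf.values)
    out = full[: curve.size].copy()
    if mode == "wrap":
        out[: curve.size - 1] += full[curve.size:]
    elif mode != "truncate":
        raise ValueError(f"unknown convolution mode {mode!r}")
    return out


def mean_lifetime(params: DecayParams, weighting: str = "photon") -> float:
    """Mean lifetime of the two-state mixture (ns).

    ``weighting="amplitude"`` averages lifetimes by species (amplitude)
    fractions; ``weighting="photon"`` (default) weights by emitted photons,
    which is what the empirical mean arrival time of the histogram, minus
    t0, estimates.
    """
    pf, pd_ = params.p_free, params.p_fret
    tf, td = params.tau_free, params.tau_fret
    amp = pf * tf + pd_ * td
    if weighting == "amplitude":
        return amp
    if weighting == "photon":
        return (pf * tf**2 + pd_ * td**2) / amp
    raise ValueError(f"unknown weighting {weighting!r}")


def _binned_exponential(tau: float, t0: float, n_channels: int,
                        channel_width: float) -> np.ndarray:
    """Per-channel bin integral of the wrapped unit-amplitude exponential.

    The decay starts at ``t0`` (mod the period) and its tail wraps around
    with the geometric pile-up of previous pulses.  Bin integration (rather
    than point sampling at channel centers) keeps sub-channel shifts of
    ``t0`` identifiable: a fractional shift moves edge mass between the
    channels straddling the rise, whereas a point-sampled curve would only
    rescale each component.  Units are mean amplitude per channel.
    """
    period = n_channels * channel_width
    t0 = t0 % period
    scale = tau / (1.0 - np.exp(-period / tau))

    def cumulative(t: np.ndarray) -> np.ndarray:
        # integral from 0 to t of exp(-((s - t0) mod period)/tau), t in [0, P]
        def integral(x):  # from the decay start, x in [0, period]
            return scale * (1.0 - np.exp(-x / tau))

        head = integral(period)  # full-period mass
        return np.where(
            t <= t0,
            integral(period - t0 + t) - integral(period - t0),
            head - integral(period - t0) + integral(t - t0))

    edges = np.arange(n_channels + 1) * channel_width
    return np.diff(cumulative(edges)) / channel_width


def periodic_component(tau: float, t0: float, irf: IRFCurve) -> np.ndarray:
    """Expected channel profile of a unit-amplitude exponential component.

    The exponential with lifetime ``tau`` is wrapped over the laser period
    (geometric pile-up of previous pulses), bin-integrated on the channel
    grid starting at the offset arrival time ``t0``, and convolved
    periodically with the IRF.
    """
    g = _binned_exponential(tau, t0, irf.n_channels, irf.channel_width)
    return convolve_irf(g, irf, mode="wrap")


def expected_counts(params: DecayParams, irf: IRFCurve,
                    total: float | None = None) -> np.ndarray:
    """Expected photon counts per channel under the full forward model.

    The two wrapped exponential components are weighted by the amplitude
    fractions, shifted by ``t0`` and convolved with the IRF.  If ``total``
    is given the curve is rescaled so its sum equals ``total`` (expected
    photon budget); otherwise the peak-amplitude scale ``f0`` applies.
    """
    curve = params.f0 * (
        params.p_free * periodic_component(params.tau_free, params.t0, irf)
        + params.p_fret * periodic_component(params.tau_fret, params.t0, irf)
    )
    if total is not None:
        if total < 0:
            raise ValueError("total must be >= 0")
        s = curve.sum()
        curve = curve * (total / s) if s > 0 else np.zeros_like(curve)
    return curve


def _component_circular_stats(tau: float, t0: float, n_channels: int,
                              channel_width: float) -> tuple[float, float]:
    """Discrete circular mean arrival time and mass of one wrapped component.

    Computed on the same grid and wrap convention as the forward model, so
    the two-component unwrap in :func:`empirical_mean_lifetime` inverts the
    delta-IRF expected-counts model exactly.
    """
    period = n_channels * channel_width
    dt = np.mod(_channel_centers(n_channels, channel_width) - t0, period)
    g = _binned_exponential(tau, t0, n_channels, channel_width)
    mass = g.sum()
    return float(np.dot(dt, g) / mass), float(mass)


def empirical_mean_lifetime(hist: PhotonHistogram, t0: float,
                            lifetimes: tuple[float, float] | None = None,
                            ) -> float:
    """Count-weighted mean arrival time relative to ``t0`` (ns).

    Photons detected before ``t0`` are treated as wrapped from the previous
    pulse (one period is added) rather than discarded.  An empty histogram
    returns NaN (a masked value for map use, not an exception).

    The raw circular mean underestimates the true mean lifetime because the
    slow component's tail wraps past the end of the 12.5 ns period.  When
    ``lifetimes=(tau_free, tau_fret)`` is supplied, a closed-form two-state
    unwrap calibrated to those lifetimes is applied: the circular mean is an
    affine function of the component photon weights, so the weights — and
    from them the photon-weighted mean lifetime — are recovered exactly in
    the expected-counts limit, without any fitting.
    """
    if not 0.0 <= t0 <= hist.period:
        raise ValueError(f"t0 must lie within the period, got {t0}")
    total = hist.total
    if total == 0:
        return float("nan")
    dt = np.mod(hist.channel_centers - t0, hist.period)
    m = float(np.dot(dt, hist.counts) / total)
    if lifetimes is None:
        return m
    tau_free, tau_fret = lifetimes
    if not 0 < tau_fret < tau_free:
        raise ValueError("lifetimes must satisfy 0 < tau_fret < tau_free")
    est = _unwrap_circular_mean(m, t0, hist.n_channels, hist.channel_width,
                                tau_free, tau_fret)
    return est[0]


def _unwrap_circular_mean(m: float, t0: float, n_channels: int,
                          channel_width: float, tau_free: float,
                          tau_fret: float) -> tuple[float, float]:
    """Map a circular mean arrival time to (mean lifetime, p_fret).

    Solves the two-state mixture whose discrete circular mean equals ``m``:
    the circular photon weight of the free component is linear in ``m``;
    converting through the discrete component masses yields the amplitude
    fraction and the analytic photon-weighted mean lifetime.  Weights are
    clipped to [0, 1] (noise can push the mean past a pure component).
    """
    m_free, s_free = _component_circular_stats(tau_free, t0, n_channels,
                                               channel_width)
    m_fret, s_fret = _component_circular_stats(tau_fret, t0, n_channels,
                                               channel_width)
    w = np.clip((m - m_fret) / (m_free - m_fret), 0.0, 1.0)
    # circular photon weight -> amplitude fractions via the component masses
    a_free = w / s_free
    a_fret = (1.0 - w) / s_fret
    p_fret = a_fret / (a_free + a_fret)
    p_free = 1.0 - p_fret
    amp = p_free * tau_free + p_fret * tau_fret
    tau_mean = (p_free * tau_free**2 + p_fret * tau_fret**2) / amp
    return float(tau_mean), float(p_fret)
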