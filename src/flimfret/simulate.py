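"""Synthetic-data generators for the FLIM-FRET / FRAP analysis pipeline.

Everything the pipeline consumes can be simulated here with known ground
truth: TCSPC photon histograms (Poisson-counted two-state decays with IRF
blur and time offset), drug-step reporter kinetics with per-compartment
rates, pixel-wise FLIM image stacks, and FRAP recovery traces.

The reporter kinetics deliberately include the measurement caveat of FRET
biosensors: the histogram reflects the phosphorylated fraction p(t) of the
reporter, which relaxes with rate (k_pka + k_phos) and therefore lags a step
change in the underlying kinase or phosphatase activity.

Every generator takes an explicit seed and returns ground truth next to the
data, so downstream recovery can always be checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import DecayParams, IRFCurve, PhotonHistogram, expected_counts

__all__ = [
    "KineticRates",
    "Epoch",
    "CompartmentScenario",
    "FRAPSimConfig",
    "FlimTimecourse",
    "FRAPSimResult",
    "simulate_histogram",
    "simulate_reporter_kinetics",
    "simulate_flim_timecourse",
    "simulate_flim_image",
    "simulate_frap",
    "forskolin_h89_schedule",
    "agonist_scenario",
    "default_scenario",
]

ALLOWED_EPOCHS = frozenset({"baseline", "forskolin", "h89", "agonist"})
ALLOWED_COMPARTMENTS = frozenset(
    {"cytoplasm", "nucleus", "dendrite", "spine", "soma"}
)


@dataclass(frozen=True)
class KineticRates:
    """First-order phosphorylation / dephosphorylation rates (1/s).

    ``k_pka`` drives reporter phosphorylation, ``k_phos`` (phosphatase)
    reverses it; at steady state k_pka * (1 - p) = k_phos * p.
    """

    k_pka: float
    k_phos: float

    def __post_init__(self) -> None:
        for name, k in (("k_pka", self.k_pka), ("k_phos", self.k_phos)):
            if not np.isfinite(k) or k < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {k}")

    @property
    def p_inf(self) -> float:
        """Steady-state phosphorylated fraction k_pka / (k_pka + k_phos)."""
        total = self.k_pka + self.k_phos
        if total == 0:
            raise ValueError("steady state undefined when both rates are zero")
        return self.k_pka / total


@dataclass(frozen=True)
class Epoch:
    """One drug epoch: a named interval with constant kinetic rates."""

    name: str
    duration: float
    rates: KineticRates

    def __post_init__(self) -> None:
        if self.name not in ALLOWED_EPOCHS:
            raise ValueError(
                f"unknown epoch {self.name!r}; allowed: {sorted(ALLOWED_EPOCHS)}"
            )
        if self.duration <= 0:
            raise ValueError("epoch duration must be positive")


@dataclass(frozen=True)
class CompartmentScenario:
    """A multi-compartment drug-application experiment.

    Each compartment has its own epoch schedule (epochs tile the simulated
    interval without gaps).  The reporter's phosphorylated fraction p(t)
    maps affinely onto the FRET amplitude fraction between the calibration
    endpoints: p=0 gives the fully dephosphorylated reporter
    (p_free = p_free_akar) and p=1 the fully phosphorylated one
    (p_free = p_free_pakar).
    """

    compartments: dict[str, tuple[Epoch, ...]]
    p_free_akar: float = 0.85
    p_free_pakar: float = 0.45
    photons_per_frame: float = 1e5
    frame_interval: float = 10.0
    tau_free: float = 2.6
    tau_fret: float = 1.1
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not self.compartments:
            raise ValueError("scenario needs at least one compartment")
        for name, epochs in self.compartments.items():
            if name not in ALLOWED_COMPARTMENTS:
                raise ValueError(
                    f"unknown compartment {name!r}; allowed: "
                    f"{sorted(ALLOWED_COMPARTMENTS)}"
                )
            if not epochs:
                raise ValueError(f"compartment {name!r} has no epochs")
        if not 0.0 <= self.p_free_pakar < self.p_free_akar <= 1.0:
            raise ValueError(
                "endpoints must satisfy 0 <= p_free_pakar < p_free_akar <= 1"
            )
        if self.photons_per_frame <= 0:
            raise ValueError("photon budget must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")

    def p_fret_of(self, p: np.ndarray | float) -> np.ndarray | float:
        """Affine map from phosphorylated fraction p to FRET amplitude fraction."""
        lo = 1.0 - self.p_free_akar   # p = 0 endpoint
        hi = 1.0 - self.p_free_pakar  # p = 1 endpoint
        return lo + np.asarray(p, dtype=float) * (hi - lo)


def simulate_histogram(params: DecayParams, irf: IRFCurve, n_photons: float,
                       seed: int, mode: str = "poisson") -> PhotonHistogram:
    """Draw one TCSPC histogram from the forward model.

    The expected curve is the IRF-reconvolved, offset-shifted two-state
    decay scaled to ``n_photons`` expected total counts.  ``mode="poisson"``
    draws independent per-channel Poisson counts; ``mode="multinomial"``
    fixes the total at exactly ``n_photons``.
    """
    if n_photons < 0:
        raise ValueError("n_photons must be >= 0")
    rng = np.random.default_rng(seed)
    n_ch = irf.n_channels
    if n_photons == 0:
        counts = np.zeros(n_ch, dtype=np.int64)
    else:
        mu = expected_counts(params, irf, total=n_photons)
        if mode == "poisson":
            counts = rng.poisson(mu)
        elif mode == "multinomial":
            counts = rng.multinomial(int(round(n_photons)), mu / mu.sum())
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return PhotonHistogram(counts, irf.channel_width, period=irf.period,
                           allowed_n_channels=())


def simulate_reporter_kinetics(epochs, p_init: float, t_grid) -> np.ndarray:
    """Phosphorylated reporter fraction p(t) over a piecewise-constant schedule.

    Within each epoch, dp/dt = k_pka (1 - p) - k_phos p relaxes in closed
    form: p(t) = p_inf + (p_start - p_inf) exp(-(k_pka + k_phos) t), with
    p_inf = k_pka / (k_pka + k_phos).  Epochs are integrated sequentially;
    times beyond the last epoch continue its kinetics.
    """
    if not 0.0 <= p_init <= 1.0:
        raise ValueError("p_init must lie in [0, 1]")
    epochs = tuple(epochs)
    if not epochs:
        raise ValueError("at least one epoch required")
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("time grid must be non-negative")
    p = np.empty_like(t)
    t_start, p_start = 0.0, float(p_init)
    edges = np.cumsum([e.duration for e in epochs])
    for i, epoch in enumerate(epochs):
        t_end = edges[i] if i < len(epochs) - 1 else np.inf
        sel = (t >= t_start) & (t < t_end)
        k_sum = epoch.rates.k_pka + epoch.rates.k_phos
        if k_sum == 0:
            p[sel] = p_start
            p_end = p_start
        else:
            p_inf = epoch.rates.k_pka / k_sum
            p[sel] = p_inf + (p_start - p_inf) * np.exp(
                -k_sum * (t[sel] - t_start))
            p_end = p_inf + (p_start - p_inf) * np.exp(
                -k_sum * (edges[i] - t_start))
        t_start, p_start = edges[i], p_end
    return p


@dataclass(frozen=True)
class FlimTimecourse:
    """Simulated frames for one compartment, with ground truth alongside."""

    compartment: str
    times: np.ndarray            # frame times, s
    histograms: tuple            # PhotonHistogram per frame
    p_true: np.ndarray           # phosphorylated fraction per frame
    p_fret_true: np.ndarray      # FRET amplitude fraction per frame
    epoch_names: tuple           # epoch label per frame
    scenario: CompartmentScenario


def _epoch_labels(epochs, times) -> tuple:
    edges = np.cumsum([e.duration for e in epochs])
    idx = np.searchsorted(edges, times, side="right")
    idx = np.minimum(idx, len(epochs) - 1)
    return tuple(epochs[i].name for i in idx)


def simulate_flim_timecourse(scenario: CompartmentScenario, irf: IRFCurve,
                             seed: int) -> dict[str, FlimTimecourse]:
    """Simulate per-compartment FLIM frame series for a drug scenario.

    Frames are taken every ``frame_interval`` seconds across the tiled
    epochs.  The reporter starts at the steady state of the first epoch, so
    baseline frames are flat in expectation; drug epochs then relax toward
    their own steady state with rate (k_pka + k_phos) — the reporter lag.
    """
    ss = np.random.SeedSequence(seed)
    out: dict[str, FlimTimecourse] = {}
    for comp_seed, (name, epochs) in zip(ss.spawn(len(scenario.compartments)),
                                         sorted(scenario.compartments.items())):
        total = sum(e.duration for e in epochs)
        times = np.arange(0.0, total, scenario.frame_interval)
        p_init = epochs[0].rates.p_inf
        p = simulate_reporter_kinetics(epochs, p_init, times)
        p_fret = np.asarray(scenario.p_fret_of(p))
        frame_seeds = comp_seed.generate_state(len(times)) % (2**31)
        hists = tuple(
            simulate_histogram(
                DecayParams(f0=1.0, p_free=1.0 - pf,
                            tau_free=scenario.tau_free,
                            tau_fret=scenario.tau_fret, t0=scenario.t0),
                irf, scenario.photons_per_frame, int(s))
            for pf, s in zip(p_fret, frame_seeds)
        )
        out[name] = FlimTimecourse(name, times, hists, p, p_fret,
                                   _epoch_labels(epochs, times), scenario)
    return out


def simulate_flim_image(phantom: np.ndarray,
                        region_params: dict[int, DecayParams | None],
                        photons_per_pixel: float, irf: IRFCurve,
                        seed: int,
                        background_label: int = 0) -> np.ndarray:
    """Per-pixel TCSPC histograms for a labeled 2-D phantom.

    Returns a counts array of shape (ny, nx, n_channels).  Pixels of the
    background label get zero counts (autofluorescence-free); every other
    label must map to valid decay parameters.  Labels present in the phantom
    but missing from ``region_params`` are rejected.
    """
    phantom = np.asarray(phantom)
    if phantom.ndim != 2:
        raise ValueError("phantom must be a 2-D label map")
    if photons_per_pixel <= 0:
        raise ValueError("photons_per_pixel must be positive")
    rng = np.random.default_rng(seed)
    stack = np.zeros(phantom.shape + (irf.n_channels,), dtype=np.int64)
    for label in np.unique(phantom):
        if label == background_label:
            continue
        if label not in region_params or region_params[label] is None:
            raise ValueError(f"phantom label {label} has no decay parameters")
        mu = expected_counts(region_params[label], irf,
                             total=photons_per_pixel)
        sel = phantom == label
        stack[sel] = rng.poisson(mu, size=(int(sel.sum()), irf.n_channels))
    return stack


@dataclass(frozen=True)
class FRAPSimConfig:
    """Generative settings for a FRAP experiment.

    Defaults follow the acquisition protocol used for the diffusible
    reporter: 1 s of baseline, an instantaneous bleach step removing
    30-50% of the fluorescence (40% by default), then 10 s of recovery
    sampled every 2 ms, with Gaussian noise of 2% of baseline and 4
    acquisitions averaged per region.
    """

    tau_true: float = 500.0      # recovery time constant, ms
    bleach_frac: float = 0.40    # fractional fluorescence lost at the step
    noise_sd: float = 0.02       # Gaussian noise, fraction of baseline
    dt: float = 2.0              # sample interval, ms
    t_pre: float = 1000.0        # pre-bleach duration, ms
    t_post: float = 10000.0      # post-bleach duration, ms
    n_acquisitions: int = 4
    plateau_frac: float = 1.0    # asymptotic recovered fraction of the loss
    roi_class: str = "spine"
    noise_model: str = "gaussian"  # or "poisson" (counts ~ baseline/noise_sd^2)

    def __post_init__(self) -> None:
        if self.tau_true <= 0:
            raise ValueError("tau_true must be positive")
        if not 0.0 <= self.bleach_frac < 1.0:
            raise ValueError("bleach_frac must lie in [0, 1)")
        if self.dt <= 0 or self.t_pre <= 0 or self.t_post <= 0:
            raise ValueError("dt and durations must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_acquisitions < 1:
            raise ValueError("n_acquisitions must be >= 1")
        if not 0.0 <= self.plateau_frac <= 1.0:
            raise ValueError("plateau_frac must lie in [0, 1]")


def frap_recovery_curve(config: FRAPSimConfig, t: np.ndarray) -> np.ndarray:
    """Noiseless normalized fluorescence; bleach step at t = 0."""
    floor = 1.0 - config.bleach_frac
    plateau = floor + config.plateau_frac * config.bleach_frac
    f = np.ones_like(t)
    post = t >= 0
    f[post] = plateau - (plateau - floor) * np.exp(-t[post] / config.tau_true)
    return f


@dataclass(frozen=True)
class FRAPSimResult:
    """Simulated FRAP acquisitions plus the generative ground truth."""

    traces: tuple                # FRAPTrace per acquisition
    config: FRAPSimConfig

    @property
    def tau_true(self) -> float:
        return self.config.tau_true


def simulate_frap(config: FRAPSimConfig, seed: int) -> FRAPSimResult:
    """Simulate ``n_acquisitions`` replicate FRAP traces.

    Baseline fluorescence is 1.0 (already normalized units); the bleach is a
    step at t = 0 down to (1 - bleach_frac), recovering toward the plateau
    with time constant ``tau_true``.  Noise is Gaussian per sample (traces
    are line-scan averages); a Poisson mode of matched baseline variance is
    available.
    """
    from .frap import FRAPTrace  # deferred: frap imports nothing from here

    rng = np.random.default_rng(seed)
    t = np.concatenate([
        np.arange(-config.t_pre, 0.0, config.dt),
        np.arange(0.0, config.t_post + config.dt / 2, config.dt),
    ])
    clean = frap_recovery_curve(config, t)
    traces = []
    for i in range(config.n_acquisitions):
        if config.noise_sd == 0:
            f = clean.copy()
        elif config.noise_model == "gaussian":
            f = clean + rng.normal(0.0, config.noise_sd, size=t.size)
        elif config.noise_model == "poisson":
            n0 = 1.0 / config.noise_sd**2  # baseline counts matching the sd
            f = rng.poisson(clean * n0) / n0
        else:
            raise ValueError(f"unknown noise model {config.noise_model!r}")
        traces.append(FRAPTrace(time=t.copy(), fluorescence=f,
                                bleach_time=0.0, acquisition_id=i,
                                roi_class=config.roi_class))
    return FRAPSimResult(traces=tuple(traces), config=config)


def forskolin_h89_schedule() -> tuple[Epoch, ...]:
    """Baseline -> forskolin (adenylate cyclase activation, net PKA up)
    -> H89 (PKA inhibition, phosphatase-driven return to baseline)."""
    return (
        Epoch("baseline", 120.0, KineticRates(k_pka=0.001, k_phos=0.05)),
        Epoch("forskolin", 240.0, KineticRates(k_pka=0.15, k_phos=0.05)),
        Epoch("h89", 300.0, KineticRates(k_pka=0.0, k_phos=0.05)),
    )


def default_scenario(**overrides) -> CompartmentScenario:
    """Single-compartment forskolin / H89 scenario (demo default)."""
    return CompartmentScenario(
        compartments={"cytoplasm": forskolin_h89_schedule()}, **overrides)


def agonist_scenario(**overrides) -> CompartmentScenario:
    """Agonist step with fast cytoplasmic and slow nuclear reporter kinetics.

    Both compartments share the same steady-state target under the agonist,
    but the nuclear rates are tenfold slower, so the nucleus reaches
    half-maximal response later — spatially compartmentalized kinetics.
    """
    baseline = Epoch("baseline", 120.0, KineticRates(k_pka=0.001, k_phos=0.05))
    return CompartmentScenario(
        compartments={
            "cytoplasm": (baseline,
                          Epoch("agonist", 600.0,
                                KineticRates(k_pka=0.08, k_phos=0.04))),
            "nucleus": (baseline,
                        Epoch("agonist", 600.0,
                              KineticRates(k_pka=0.008, k_phos=0.004))),
        }, **overrides)
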