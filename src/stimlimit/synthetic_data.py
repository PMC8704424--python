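"""Synthetic electrochemistry records and RGC population recordings.

The generators emulate the statistical structure the analysis pipeline
assumes, so every stage can be exercised end-to-end without instrument
data:

* a linear electrode circuit (access resistance in series with a specific
  polarization capacitance, plus a voltammetric pseudocapacitance profile
  with Gaussian redox peaks) produces cyclic-voltammetry traces and
  biphasic-pulse voltage transients with closed-form ground truth;
* a heterogeneous cell population couples a logistic per-trial spiking
  probability (midpoint = the cell's charge threshold) to a saturating
  spike-count curve anchored at a designed count at threshold, with
  homogeneous-Poisson spontaneous firing and a short/long latency mixture
  for evoked spikes.

Every routine takes an explicit seed and is bit-reproducible from
(parameters, seed). Calibration presets live in ``presets/*.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .electrochem import (
    CVScan,
    ElectrodeGeometry,
    VoltageTransient,
    disk_area,
)
from .errors import InvalidParameterError
from .spike_analysis import StimulusProtocol, StimulusPulse, TrialResponse

__all__ = [
    "RedoxPeak",
    "CVProfile",
    "ElectrodeCircuitParams",
    "LatencyMixture",
    "DiameterPopulation",
    "PopulationParams",
    "SyntheticCell",
    "gen_cv_trace",
    "gen_voltage_transient",
    "gen_transient_family",
    "gen_cell_population",
    "gen_recording",
    "load_preset",
    "circuit_from_preset",
    "population_from_preset",
]


# ---------------------------------------------------------------------------
# Electrode circuit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RedoxPeak:
    """Gaussian pseudocapacitance peak: c(V) += height·exp(−(V−center)²/2w²)."""

    center_V: float
    width_V: float
    height_F_cm2: float


@dataclass(frozen=True)
class CVProfile:
    """Sweep-direction-specific pseudocapacitance c(V), F/cm²."""

    baseline_F_cm2: float
    peaks: tuple[RedoxPeak, ...] = ()

    def capacitance(self, v: np.ndarray) -> np.ndarray:
        c = np.full_like(np.asarray(v, dtype=float), self.baseline_F_cm2)
        for p in self.peaks:
            c = c + p.height_F_cm2 * np.exp(-0.5 * ((v - p.center_V) / p.width_V) ** 2)
        return c

    def integral(self, v_low: float, v_high: float, n: int = 20001) -> float:
        """∫ c(V) dV over the window (C/cm²), fine trapezoid."""
        v = np.linspace(v_low, v_high, n)
        return float(np.trapezoid(self.capacitance(v), v))


@dataclass(frozen=True)
class ElectrodeCircuitParams:
    """Linear R + series-C electrode model with a CV pseudocapacitance.

    ``c_specific_F_cm2`` is the polarization capacitance per geometric
    area governing pulse transients; the anodic/cathodic CV profiles
    govern slow voltammetry (they may differ, as oxide electrodes do).
    """

    access_resistance_ohm: float
    c_specific_F_cm2: float
    cv_anodic: CVProfile
    cv_cathodic: CVProfile
    noise_sd_V: float = 0.0
    cv_noise_sd_A: float = 0.0

    def __post_init__(self) -> None:
        if self.c_specific_F_cm2 <= 0:
            raise InvalidParameterError("polarization capacitance must be positive")
        if self.noise_sd_V < 0 or self.cv_noise_sd_A < 0:
            raise InvalidParameterError("noise sd must be >= 0")

    def designed_csc_mC_cm2(
        self, vertices: tuple[float, float] = (-0.6, 0.8)
    ) -> tuple[float, float]:
        """Ground-truth (anodic, cathodic) CSC in mC/cm² over the window."""
        lo, hi = vertices
        return (
            self.cv_anodic.integral(lo, hi) * 1e3,
            self.cv_cathodic.integral(lo, hi) * 1e3,
        )

    def designed_cic_mC_cm2(self, anodic_limit_V: float = 0.8) -> float:
        """Ground-truth CIC of the purely capacitive pulse response."""
        return self.c_specific_F_cm2 * anodic_limit_V * 1e3


def gen_cv_trace(
    circuit: ElectrodeCircuitParams,
    geometry: ElectrodeGeometry,
    scan_rate_V_per_s: float = 0.2,
    vertices: tuple[float, float] = (-0.6, 0.8),
    n_cycles: int = 3,
    seed: int = 0,
    dv_V: float = 0.01,
) -> CVScan:
    """Triangular-sweep cyclic voltammogram of the circuit.

    i(t) = sign(dV/dt)·ν·A·c_dir(V) + noise, sampled at 10 mV potential
    increments by default. Each vertex is duplicated a microsecond apart so
    that the instantaneous current-sign flip does not smear into the
    trapezoidal CSC integral.
    """
    if scan_rate_V_per_s <= 0:
        raise InvalidParameterError("scan rate must be positive")
    lo, hi = vertices
    if lo < -0.6 - 1e-9 or hi > 0.8 + 1e-9:
        import warnings

        warnings.warn("sweep vertices extend outside the water window")
    rng = np.random.default_rng(seed)
    area = disk_area(geometry)

    n_steps = int(round((hi - lo) / dv_V))
    up_v = np.linspace(lo, hi, n_steps + 1)
    down_v = up_v[::-1]
    dt = dv_V / scan_rate_V_per_s
    eps = 1e-6 * dt

    pot: list[np.ndarray] = []
    cur: list[np.ndarray] = []
    times: list[np.ndarray] = []
    t0 = 0.0
    for _ in range(n_cycles):
        for v_seg, sign in ((up_v, 1.0), (down_v, -1.0)):
            prof = circuit.cv_anodic if sign > 0 else circuit.cv_cathodic
            i_seg = sign * scan_rate_V_per_s * area * prof.capacitance(v_seg)
            t_seg = t0 + eps + np.arange(len(v_seg)) * dt
            pot.append(v_seg)
            cur.append(i_seg)
            times.append(t_seg)
            t0 = t_seg[-1]

    current = np.concatenate(cur)
    if circuit.cv_noise_sd_A > 0:
        current = current + rng.normal(0.0, circuit.cv_noise_sd_A, size=current.size)
    return CVScan(
        time_s=np.concatenate(times),
        potential_V=np.concatenate(pot),
        current_A=current,
        scan_rate_V_per_s=scan_rate_V_per_s,
        vertex_low_V=lo,
        vertex_high_V=hi,
    )


def gen_voltage_transient(
    circuit: ElectrodeCircuitParams,
    geometry: ElectrodeGeometry,
    pulse: StimulusPulse,
    seed: int = 0,
    *,
    fs_hz: float = 5e5,
    interphase_gap_s: float = 0.5e-3,
    pre_s: float = 2e-3,
    post_s: float = 2e-3,
) -> VoltageTransient:
    """Voltage transient of the R + series-C circuit to a biphasic pulse.

    V(t) = I(t)·R_access + Q(t)/(c_s·A) + noise. Sampling defaults to
    500 kHz so the 10 μs polarization read-out after each phase is
    resolved; the default 0.5 ms interphase gap puts that read-out in a
    zero-current segment, where the series-capacitor model is exact.
    """
    if pulse.amplitude_A < 0:
        raise InvalidParameterError("pulse amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    dt = 1.0 / fs_hz
    pw = pulse.phase_width_s
    total = pre_s + 2 * pw + interphase_gap_s + post_s
    t = np.arange(0.0, total, dt)

    i = np.zeros_like(t)
    t_on = pre_s
    i[(t >= t_on) & (t < t_on + pw)] = pulse.amplitude_A
    t_c = t_on + pw + interphase_gap_s
    i[(t >= t_c) & (t < t_c + pw)] = -pulse.amplitude_A

    # cumulative trapezoidal charge
    q = np.concatenate(([0.0], np.cumsum(0.5 * (i[1:] + i[:-1]) * np.diff(t))))
    cap = circuit.c_specific_F_cm2 * disk_area(geometry)
    v = i * circuit.access_resistance_ohm + q / cap
    if circuit.noise_sd_V > 0:
        v = v + rng.normal(0.0, circuit.noise_sd_V, size=v.size)
    return VoltageTransient(
        time_s=t, command_current_A=i, measured_potential_V=v, phase_width_s=pw
    )


def gen_transient_family(
    circuit: ElectrodeCircuitParams,
    geometry: ElectrodeGeometry,
    phase_width_s: float,
    currents_A: Sequence[float],
    seed: int = 0,
) -> list[VoltageTransient]:
    """Transients at strictly increasing currents (hence per-phase charges)."""
    if np.any(np.diff(currents_A) <= 0):
        raise InvalidParameterError("currents must be strictly increasing")
    return [
        gen_voltage_transient(
            circuit,
            geometry,
            StimulusPulse(phase_width_s=phase_width_s, amplitude_A=float(I)),
            seed=seed + k,
        )
        for k, I in enumerate(currents_A)
    ]


# ---------------------------------------------------------------------------
# RGC population model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatencyMixture:
    """Evoked-spike latency mixture: gamma-distributed short-latency
    component plus a uniform long-latency component."""

    short_mean_s: float = 0.010
    short_shape: float = 2.0
    long_range_s: tuple[float, float] = (0.1, 0.4)
    short_weight: float = 0.6

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        short = rng.random(n) < self.short_weight
        out = np.empty(n)
        n_short = int(short.sum())
        scale = self.short_mean_s / self.short_shape
        out[short] = rng.gamma(self.short_shape, scale, size=n_short)
        out[~short] = rng.uniform(*self.long_range_s, size=n - n_short)
        return out


@dataclass(frozen=True)
class DiameterPopulation:
    """Generative parameters for cells stimulated by one electrode size.

    Thresholds (logistic midpoints) and count parameters are log-normal
    across cells, parameterized by median and log-space dispersion;
    spontaneous rates are gamma-distributed. ``count_at_threshold`` is the
    designed mean evoked count on responding trials at the midpoint, the
    anchor of the dynamic-range calibration.
    """

    diameter_um: float
    p_resp: float
    threshold_median_nC: float
    threshold_dispersion: float = 0.35
    slope_frac: float = 0.1
    count_at_threshold: float = 2.0
    count_at_threshold_dispersion: float = 0.2
    count_max_median: float = 4.0
    count_max_dispersion: float = 0.25
    spont_rate_mean_hz: float = 0.15
    spont_rate_shape: float = 2.0
    train_threshold_factor: float = 1.0
    train_gain_factor: float = 1.0
    cic_limit_nC: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_resp <= 1.0:
            raise InvalidParameterError("p_resp must lie in [0, 1]")
        if self.threshold_median_nC <= 0 or self.count_max_median <= 0:
            raise InvalidParameterError("medians must be positive")
        if not 0.0 < self.train_threshold_factor <= 1.0:
            raise InvalidParameterError("train threshold factor must be in (0, 1]")
        if self.train_gain_factor < 1.0:
            raise InvalidParameterError("train spike-gain factor must be >= 1")


@dataclass(frozen=True)
class PopulationParams:
    """Full population description across electrode diameters."""

    diameters: tuple[DiameterPopulation, ...]
    latency: LatencyMixture = LatencyMixture()
    max_distance_um: float = 25.0

    def for_diameter(self, diameter_um: float) -> DiameterPopulation:
        for d in self.diameters:
            if d.diameter_um == diameter_um:
                return d
        raise InvalidParameterError(f"no parameters for diameter {diameter_um} μm")


@dataclass(frozen=True)
class SyntheticCell:
    """One drawn cell: a realization of the population distributions."""

    cell_id: str
    diameter_um: float
    responsive: bool
    midpoint_nC: float
    slope_nC: float
    count_at_threshold: float
    count_max: float
    spont_rate_hz: float
    distance_um: float
    train_threshold_factor: float
    train_gain_factor: float
    cic_limit_nC: float
    latency: LatencyMixture

    def spike_probability(self, q_nC: float, is_train: bool = False) -> float:
        """Logistic per-trial probability of any evoked spiking."""
        if not self.responsive:
            return 0.0
        factor = self.train_threshold_factor if is_train else 1.0
        q0 = self.midpoint_nC * factor
        # recruitment steepness scales with the protocol's midpoint
        slope = self.slope_nC * factor
        return float(1.0 / (1.0 + np.exp(-(q_nC - q0) / slope)))

    def mean_count(self, q_nC: float, is_train: bool = False) -> float:
        """Designed mean evoked count on responding trials: a ramp from the
        count at threshold to the (train-scaled) maximum at the CIC limit."""
        q0 = self.midpoint_nC * (self.train_threshold_factor if is_train else 1.0)
        m_max = self.count_max * (self.train_gain_factor if is_train else 1.0)
        q_sat = self.cic_limit_nC
        if not np.isfinite(q_sat) or q_sat <= q0:
            return m_max
        frac = np.clip((q_nC - q0) / (q_sat - q0), 0.0, 1.0)
        return float(self.count_at_threshold + (m_max - self.count_at_threshold) * frac)


def gen_cell_population(
    params: PopulationParams,
    n_cells: int,
    seed: int = 0,
) -> list[SyntheticCell]:
    """Draw ``n_cells`` per diameter, independently across cells.

    Cell k of diameter d is reproducible from (params, seed, index): each
    cell gets its own spawned random substream.
    """
    if n_cells < 1:
        raise InvalidParameterError("n_cells must be >= 1")
    cells: list[SyntheticCell] = []
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(params.diameters) * n_cells)
    k = 0
    for dp in params.diameters:
        for idx in range(n_cells):
            rng = np.random.default_rng(streams[k])
            k += 1
            responsive = bool(rng.random() < dp.p_resp)
            midpoint = float(
                dp.threshold_median_nC
                * np.exp(rng.normal(0.0, dp.threshold_dispersion))
            )
            m0 = float(
                dp.count_at_threshold
                * np.exp(rng.normal(0.0, dp.count_at_threshold_dispersion))
            )
            m_max = float(
                dp.count_max_median * np.exp(rng.normal(0.0, dp.count_max_dispersion))
            )
            spont = float(
                rng.gamma(
                    dp.spont_rate_shape,
                    dp.spont_rate_mean_hz / dp.spont_rate_shape,
                )
            )
            cells.append(
                SyntheticCell(
                    cell_id=f"d{dp.diameter_um:g}um_c{idx:03d}",
                    diameter_um=dp.diameter_um,
                    responsive=responsive,
                    midpoint_nC=midpoint,
                    slope_nC=dp.slope_frac * midpoint,
                    count_at_threshold=m0,
                    count_max=max(m_max, m0),
                    spont_rate_hz=spont,
                    distance_um=float(rng.uniform(0.0, params.max_distance_um)),
                    train_threshold_factor=dp.train_threshold_factor,
                    train_gain_factor=dp.train_gain_factor,
                    cic_limit_nC=dp.cic_limit_nC,
                    latency=params.latency,
                )
            )
    return cells


def gen_recording(
    cell: SyntheticCell,
    protocol: StimulusProtocol,
    charge_levels_nC: Sequence[float],
    seed: int = 0,
    *,
    baseline_span_s: float = 2.0,
    post_span_s: float = 0.5,
) -> dict[float, list[TrialResponse]]:
    """Simulate the full stimulus series for one cell.

    For each charge level and repeat: spontaneous spikes as a homogeneous
    Poisson process over [−baseline, +post]; with logistic probability
    p(Q) the trial responds, in which case the evoked count is
    1 + Poisson(max(m(Q) − 1, 0)) — so the probability of ≥1 evoked spike
    is exactly p(Q) — with latencies drawn from the short/long mixture.
    """
    if np.any(np.asarray(charge_levels_nC) <= 0):
        raise InvalidParameterError("charge levels must be positive")
    out: dict[float, list[TrialResponse]] = {}
    for li, q in enumerate(charge_levels_nC):
        trials = []
        for rep in range(protocol.n_repeats):
            rng = np.random.default_rng(
                np.random.SeedSequence((int(seed), li, rep))
            )
            span = baseline_span_s + post_span_s
            n_spont = rng.poisson(cell.spont_rate_hz * span)
            spont = rng.uniform(-baseline_span_s, post_span_s, size=n_spont)
            spikes = [spont]
            if rng.random() < cell.spike_probability(q, protocol.is_train):
                m = cell.mean_count(q, protocol.is_train)
                n_ev = 1 + rng.poisson(max(m - 1.0, 0.0))
                spikes.append(cell.latency.draw(rng, n_ev))
            trials.append(
                TrialResponse(
                    spike_times_s=np.concatenate(spikes),
                    trial=rep,
                    baseline_span_s=baseline_span_s,
                )
            )
        out[float(q)] = trials
    return out


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def load_preset(name: str) -> dict:
    """Load a calibration preset shipped with the package."""
    path = resources.files("stimlimit") / "presets" / f"{name}.yaml"
    if not path.is_file():
        available = sorted(
            p.name.removesuffix(".yaml")
            for p in (resources.files("stimlimit") / "presets").iterdir()
        )
        raise InvalidParameterError(f"unknown preset {name!r}; available: {available}")
    return yaml.safe_load(path.read_text())


def circuit_from_preset(name: str = "fig2_electrode") -> ElectrodeCircuitParams:
    cfg = load_preset(name)

    def profile(d: Mapping) -> CVProfile:
        return CVProfile(
            baseline_F_cm2=float(d["baseline_F_cm2"]),
            peaks=tuple(
                RedoxPeak(float(p["center_V"]), float(p["width_V"]), float(p["height_F_cm2"]))
                for p in d.get("peaks", [])
            ),
        )

    return ElectrodeCircuitParams(
        access_resistance_ohm=float(cfg["access_resistance_ohm"]),
        c_specific_F_cm2=float(cfg["c_specific_F_cm2"]),
        cv_anodic=profile(cfg["cv_anodic"]),
        cv_cathodic=profile(cfg["cv_cathodic"]),
        noise_sd_V=float(cfg.get("noise_sd_V", 0.0)),
        cv_noise_sd_A=float(cfg.get("cv_noise_sd_A", 0.0)),
    )


def population_from_preset(name: str = "fig7_population") -> PopulationParams:
    cfg = load_preset(name)
    lat = cfg.get("latency", {})
    latency = LatencyMixture(
        short_mean_s=float(lat.get("short_mean_s", 0.010)),
        short_shape=float(lat.get("short_shape", 2.0)),
        long_range_s=tuple(lat.get("long_range_s", (0.1, 0.4))),
        short_weight=float(lat.get("short_weight", 0.6)),
    )
    diams = tuple(
        DiameterPopulation(
            diameter_um=float(d["diameter_um"]),
            p_resp=float(d["p_resp"]),
            threshold_median_nC=float(d["threshold_median_nC"]),
            threshold_dispersion=float(d.get("threshold_dispersion", 0.35)),
            slope_frac=float(d.get("slope_frac", 0.15)),
            count_at_threshold=float(d.get("count_at_threshold", 2.0)),
            count_at_threshold_dispersion=float(
                d.get("count_at_threshold_dispersion", 0.2)
            ),
            count_max_median=float(d.get("count_max_median", 4.0)),
            count_max_dispersion=float(d.get("count_max_dispersion", 0.25)),
            spont_rate_mean_hz=float(d.get("spont_rate_mean_hz", 0.3)),
            spont_rate_shape=float(d.get("spont_rate_shape", 2.0)),
            train_threshold_factor=float(d.get("train_threshold_factor", 1.0)),
            train_gain_factor=float(d.get("train_gain_factor", 1.0)),
            cic_limit_nC=float(d.get("cic_limit_nC", float("nan"))),
        )
        for d in cfg["diameters"]
    )
    return PopulationParams(
        diameters=diams,
        latency=latency,
        max_distance_um=float(cfg.get("max_distance_um", 25.0)),
    )
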