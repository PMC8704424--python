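"""Electrochemical characterization of stimulation microelectrodes.

Charge storage capacity (CSC) is integrated from slow cyclic voltammetry
within the water window; charge injection capacity (CIC) is extracted from
biphasic-pulse voltage transients by separating the ohmic access voltage
``V_a`` from the residual electrode polarization (``E_ma`` anodic, ``E_mc``
cathodic) and finding the largest per-phase charge that keeps both
polarizations inside the water window.

Units: SI internally (s, V, A, m); charge densities are reported in mC/cm²
and per-electrode charges in nC only at the result boundary, matching the
conventions of the electrode literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    BelowResolutionError,
    FormatError,
    InvalidGeometryError,
    InvalidParameterError,
    ProtocolError,
    ResolutionError,
)

__all__ = [
    "ElectrodeGeometry",
    "ElectrochemLimits",
    "CVScan",
    "VoltageTransient",
    "PolarizationMeasurement",
    "ChargeCapacityResult",
    "disk_area",
    "max_injectable_charge",
    "compute_csc",
    "measure_polarization",
    "compute_cic",
]

UM_TO_CM = 1e-4
C_PER_CM2_TO_MC_PER_CM2 = 1e3
C_TO_NC = 1e9


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeGeometry:
    """A disk stimulating electrode on the array plane.

    Parameters
    ----------
    diameter_um:
        Disk diameter in μm. The study's electrodes are 10, 20 and 30 μm.
    center_um:
        (x, y) position on the array plane, μm. Only used for bookkeeping.
    label:
        Free-form identifier.
    """

    diameter_um: float
    center_um: tuple[float, float] = (0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise InvalidGeometryError(
                f"electrode diameter must be positive, got {self.diameter_um}"
            )

    @property
    def radius_m(self) -> float:
        return 0.5 * self.diameter_um * 1e-6

    @property
    def area_cm2(self) -> float:
        """Geometric (planar) disk area in cm²."""
        return disk_area(self)


@dataclass(frozen=True)
class ElectrochemLimits:
    """Water-window potential limits and the polarization sampling delay.

    Defaults are the reversibility limits of sputtered iridium oxide:
    −0.6 V (cathodal) to +0.8 V (anodal) vs. Ag/AgCl, with the residual
    polarization read 10 μs after the end of each current phase.
    """

    anodic_limit_V: float = 0.8
    cathodic_limit_V: float = -0.6
    sample_delay_s: float = 10e-6

    def __post_init__(self) -> None:
        if not (self.cathodic_limit_V < 0 < self.anodic_limit_V):
            raise InvalidParameterError(
                "water window must straddle 0 V: "
                f"({self.cathodic_limit_V}, {self.anodic_limit_V})"
            )
        if not self.sample_delay_s > 0:
            raise InvalidParameterError("sample_delay_s must be positive")


@dataclass
class CVScan:
    """One cyclic-voltammetry record.

    ``time_s``, ``potential_V`` and ``current_A`` are parallel arrays;
    ``scan_rate_V_per_s`` is the nominal triangular sweep rate and the
    vertices are the sweep turning potentials.
    """

    time_s: np.ndarray
    potential_V: np.ndarray
    current_A: np.ndarray
    scan_rate_V_per_s: float
    vertex_low_V: float
    vertex_high_V: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.potential_V = np.asarray(self.potential_V, dtype=float)
        self.current_A = np.asarray(self.current_A, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise FormatError("CV scan time axis must be strictly increasing")


@dataclass
class VoltageTransient:
    """Measured electrode potential in response to a biphasic current pulse.

    ``command_current_A`` is the signed current command (anodic positive);
    ``measured_potential_V`` is the working-vs-reference potential.
    """

    time_s: np.ndarray
    command_current_A: np.ndarray
    measured_potential_V: np.ndarray
    phase_width_s: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.command_current_A = np.asarray(self.command_current_A, dtype=float)
        self.measured_potential_V = np.asarray(self.measured_potential_V, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise FormatError("transient time axis must be strictly increasing")

    @property
    def dt_s(self) -> float:
        return float(np.median(np.diff(self.time_s)))

    @property
    def charge_per_phase_C(self) -> float:
        """Per-phase charge integrated from the anodic command segment."""
        i = self.command_current_A
        pos = np.clip(i, 0.0, None)
        return float(np.trapezoid(pos, self.time_s))


@dataclass(frozen=True)
class PolarizationMeasurement:
    """Access voltage and residual polarizations extracted from a transient."""

    access_voltage_V: float
    anodic_polarization_V: float
    cathodic_polarization_V: float

    def within(self, limits: ElectrochemLimits) -> bool:
        return (
            self.anodic_polarization_V <= limits.anodic_limit_V
            and self.cathodic_polarization_V >= limits.cathodic_limit_V
        )


@dataclass(frozen=True)
class ChargeCapacityResult:
    """Per-electrode electrochemical limits at the reporting boundary."""

    csc_anodic_mC_cm2: float
    csc_cathodic_mC_cm2: float
    cic_mC_cm2: float
    max_charge_per_phase_nC: float
    status: str = "ok"


# ---------------------------------------------------------------------------
# Geometry arithmetic
# ---------------------------------------------------------------------------

def disk_area(geometry: ElectrodeGeometry) -> float:
    """Geometric disk area π·d²/4 in cm²."""
    d_cm = geometry.diameter_um * UM_TO_CM
    return float(np.pi * d_cm**2 / 4.0)


def max_injectable_charge(
    geometry: ElectrodeGeometry,
    cic_density_mC_cm2: float,
    *,
    sig_figs: int | None = None,
) -> float:
    """Safe charge per phase, in nC: CIC density × geometric area.

    ``sig_figs`` optionally rounds the result to a number of significant
    figures for presentation (2 reproduces conventional reporting).
    """
    if cic_density_mC_cm2 < 0:
        raise InvalidParameterError("cic_density_mC_cm2 must be >= 0")
    q_nC = cic_density_mC_cm2 * 1e-3 * disk_area(geometry) * C_TO_NC
    if sig_figs is not None:
        if q_nC == 0:
            return 0.0
        exp = int(np.floor(np.log10(abs(q_nC))))
        q_nC = round(q_nC, sig_figs - 1 - exp)
    return float(q_nC)


# ---------------------------------------------------------------------------
# Charge storage capacity (cyclic voltammetry)
# ---------------------------------------------------------------------------

def _cycle_bounds(potential: np.ndarray) -> list[tuple[int, int]]:
    """Split a triangular potential trace into full cycles.

    A cycle is two consecutive sweeps (two sign changes of dV/dt). Returns
    index bounds [start, stop) for each complete cycle.
    """
    dv = np.diff(potential)
    direction = np.sign(dv)
    direction[direction == 0] = 1
    turns = np.nonzero(np.diff(direction) != 0)[0] + 1
    bounds: list[tuple[int, int]] = []
    start = 0
    # every second turning point closes a cycle relative to `start`
    for k in range(1, len(turns), 2):
        stop = turns[k] + 1
        bounds.append((start, min(stop, len(potential))))
        start = turns[k]
    return bounds


def compute_csc(
    scan: CVScan,
    geometry: ElectrodeGeometry,
    limits: ElectrochemLimits | None = None,
) -> tuple[float, float]:
    """Anodic and cathodic charge storage capacity, mC/cm².

    CSC is the time integral of (respectively) the positive and negative
    current, restricted to samples whose potential lies inside the water
    window, normalized by geometric area. With multiple complete cycles the
    first (conditioning) cycle is discarded and the rest averaged; with a
    single or partial cycle the whole trace is integrated and a warning
    issued for the partial case.
    """
    limits = limits or ElectrochemLimits()
    area = disk_area(geometry)

    bounds = _cycle_bounds(scan.potential_V)
    if not bounds:
        warnings.warn("CV scan holds less than one full cycle; integrating as-is")
        bounds = [(0, len(scan.time_s))]
    elif len(bounds) >= 2:
        bounds = bounds[1:]

    tol = 1e-9  # guard against float drift at the sweep vertices
    in_window = (scan.potential_V >= limits.cathodic_limit_V - tol) & (
        scan.potential_V <= limits.anodic_limit_V + tol
    )
    i_pos = np.where(in_window, np.clip(scan.current_A, 0.0, None), 0.0)
    i_neg = np.where(in_window, np.clip(-scan.current_A, 0.0, None), 0.0)

    q_a = []
    q_c = []
    for start, stop in bounds:
        t = scan.time_s[start:stop]
        q_a.append(np.trapezoid(i_pos[start:stop], t))
        q_c.append(np.trapezoid(i_neg[start:stop], t))

    csc_a = float(np.mean(q_a)) / area * C_PER_CM2_TO_MC_PER_CM2
    csc_c = float(np.mean(q_c)) / area * C_PER_CM2_TO_MC_PER_CM2
    return csc_a, csc_c


# ---------------------------------------------------------------------------
# Polarization from voltage transients
# ---------------------------------------------------------------------------

def _current_edges(i: np.ndarray) -> np.ndarray:
    """Indices k where the command current steps between samples k and k+1."""
    di = np.diff(i)
    scale = max(np.max(np.abs(i)), 1.0e-30)
    return np.nonzero(np.abs(di) > 1e-9 * scale)[0]


def measure_polarization(
    transient: VoltageTransient,
    limits: ElectrochemLimits | None = None,
) -> PolarizationMeasurement:
    """Extract V_a, E_ma and E_mc from a biphasic pulse transient.

    The access voltage is the near-instantaneous potential step across each
    current edge; each edge's step is scaled by |I_phase / ΔI| before
    averaging so that the double-amplitude anodic→cathodic edge of a
    gap-free pulse contributes on the same footing as onset/offset edges.
    Residual polarizations are the baseline-referenced potentials read
    ``sample_delay`` after the end of the anodic (E_ma) and cathodic (E_mc)
    phase; the baseline is the mean potential over 1 ms before pulse onset.
    """
    limits = limits or ElectrochemLimits()
    t = transient.time_s
    i = transient.command_current_A
    v = transient.measured_potential_V

    i_amp = float(np.max(np.abs(i)))
    if i_amp == 0.0:
        return PolarizationMeasurement(0.0, 0.0, 0.0)

    dt = transient.dt_s
    if dt > limits.sample_delay_s:
        raise ResolutionError(
            f"sampling interval {dt:.3g}s exceeds sample delay "
            f"{limits.sample_delay_s:.3g}s"
        )

    edges = _current_edges(i)
    if edges.size == 0:
        raise ProtocolError("no current pulse found in command trace")

    onset = edges[0] + 1
    t_on = t[onset]
    base_mask = (t >= t_on - 1e-3) & (t < t_on)
    if not np.any(base_mask):
        base_mask = t < t_on
    if not np.any(base_mask):
        raise ProtocolError("no pre-pulse baseline samples before pulse onset")
    baseline = float(np.mean(v[base_mask]))

    # access voltage: per-edge potential step, normalized per phase current
    steps = []
    for k in edges:
        dv = abs(v[k + 1] - v[k])
        di = abs(i[k + 1] - i[k])
        steps.append(dv * i_amp / di)
    v_a = float(np.mean(steps))

    # phase ends: last sample of the positive and of the negative segment
    pos = i > 0.5 * i_amp
    neg = i < -0.5 * i_amp
    e_ma = 0.0
    e_mc = 0.0
    for mask, which in ((pos, "anodic"), (neg, "cathodic")):
        if not np.any(mask):
            continue
        t_end = t[np.nonzero(mask)[0][-1]]
        t_read = t_end + limits.sample_delay_s
        k = int(np.searchsorted(t, t_read))
        if k >= len(t):
            raise ResolutionError(
                f"transient ends before {which} polarization read-out point"
            )
        val = float(v[k]) - baseline
        if which == "anodic":
            e_ma = val
        else:
            e_mc = val
    return PolarizationMeasurement(v_a, e_ma, e_mc)


# ---------------------------------------------------------------------------
# Charge injection capacity
# ---------------------------------------------------------------------------

def compute_cic(
    transients: Sequence[VoltageTransient],
    geometry: ElectrodeGeometry,
    limits: ElectrochemLimits | None = None,
) -> tuple[float, str]:
    """CIC density (mC/cm²) from a family of increasing-amplitude transients.

    Each transient yields (E_ma, E_mc); the CIC is the per-phase charge of
    the largest transient whose polarizations stay inside the water window,
    refined by linear interpolation in charge towards the first failing
    transient (taking, when both limits are crossed, the smaller crossing).

    Returns ``(density, status)`` with status ``"ok"`` or ``"unbounded"``
    (no transient exceeded the limits — the value is a lower bound).
    """
    limits = limits or ElectrochemLimits()
    if len(transients) < 2:
        raise InvalidParameterError("need at least 2 transients to bracket the CIC")

    charges = np.array([tr.charge_per_phase_C for tr in transients])
    if np.any(np.diff(charges) <= 0):
        raise InvalidParameterError(
            "per-phase charge must be strictly increasing across the family"
        )

    pols = [measure_polarization(tr, limits) for tr in transients]
    passing = np.array([p.within(limits) for p in pols])

    if not passing.any():
        raise BelowResolutionError(
            "smallest transient already polarizes beyond the water window"
        )

    area = disk_area(geometry)
    if passing.all():
        return (
            float(charges[-1]) / area * C_PER_CM2_TO_MC_PER_CM2,
            "unbounded",
        )

    last_pass = int(np.nonzero(passing)[0][-1])
    first_fail = last_pass + 1
    q0, q1 = charges[last_pass], charges[first_fail]
    p0, p1 = pols[last_pass], pols[first_fail]

    crossings = []
    if p1.anodic_polarization_V > limits.anodic_limit_V:
        de = p1.anodic_polarization_V - p0.anodic_polarization_V
        frac = (limits.anodic_limit_V - p0.anodic_polarization_V) / de
        crossings.append(q0 + frac * (q1 - q0))
    if p1.cathodic_polarization_V < limits.cathodic_limit_V:
        de = p1.cathodic_polarization_V - p0.cathodic_polarization_V
        frac = (limits.cathodic_limit_V - p0.cathodic_polarization_V) / de
        crossings.append(q0 + frac * (q1 - q0))
    q_star = min(crossings)
    return float(q_star) / area * C_PER_CM2_TO_MC_PER_CM2, "ok"
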