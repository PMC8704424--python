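"""Evoked-response statistics for loose-patch stimulation recordings.

Per-trial spike-time tables are reduced to peristimulus time histograms,
spontaneous-corrected evoked spike counts, boolean response probabilities,
and per-cell metrics: the charge threshold (charge at which a cell spikes
on 50% of trials, by lowest-crossing linear interpolation between tested
levels), the half-max charge of the spike-count curve, and the dynamic
range in dB — the ratio of the maximal evoked count within the electrode's
charge-injection limit to the count at threshold.

Spontaneous activity is estimated from a ≥2 s pre-stimulus baseline and
subtracted from counts; response probability is a per-trial boolean (any
spike in the evoked window) and is deliberately not rate-corrected, since
a boolean cannot be. The two definitions are kept distinct throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.signal as sps

from .electrochem import ElectrodeGeometry, disk_area
from .errors import BaselineError, InputError, InvalidParameterError, ResolutionError

__all__ = [
    "StimulusPulse",
    "StimulusProtocol",
    "TrialResponse",
    "ResponseCurve",
    "PSTH",
    "SpikeDetectionParams",
    "CellMetrics",
    "detect_spikes",
    "count_evoked",
    "build_psth",
    "response_curve",
    "estimate_threshold",
    "estimate_half_max",
    "dynamic_range",
    "analyze_cell",
    "population_summary",
]

EVOKED_WINDOW_S = (0.0, 0.5)   # post-stimulus analysis window
BASELINE_SPAN_S = 2.0          # pre-stimulus spontaneous-rate window
LATENCY_SPLIT_S = 0.1          # short/long latency cut for descriptive stats


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusPulse:
    """Charge-balanced biphasic current pulse (anodic phase first)."""

    phase_width_s: float
    amplitude_A: float
    polarity: str = "anodic_first"

    def __post_init__(self) -> None:
        if self.phase_width_s <= 0:
            raise InvalidParameterError("phase_width_s must be positive")

    @property
    def charge_per_phase_C(self) -> float:
        return self.amplitude_A * self.phase_width_s

    @property
    def charge_per_phase_nC(self) -> float:
        return self.charge_per_phase_C * 1e9


@dataclass(frozen=True)
class StimulusProtocol:
    """Single pulses (n_pulses=1) or 500 Hz trains of 20 pulses, delivered
    every 10 s and repeated five times."""

    pulse: StimulusPulse
    n_pulses: int = 1
    frequency_hz: float = 500.0
    n_repeats: int = 5
    inter_trial_s: float = 10.0
    protocol_id: str = ""

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise InvalidParameterError("n_pulses must be >= 1")

    @property
    def train_duration_s(self) -> float:
        return 0.0 if self.n_pulses == 1 else self.n_pulses / self.frequency_hz

    @property
    def is_train(self) -> bool:
        return self.n_pulses > 1


@dataclass
class TrialResponse:
    """Spike times of one trial, in seconds relative to stimulus onset
    (negative times are pre-stimulus baseline)."""

    spike_times_s: np.ndarray
    trial: int = 0
    baseline_span_s: float = BASELINE_SPAN_S

    def __post_init__(self) -> None:
        self.spike_times_s = np.sort(np.asarray(self.spike_times_s, dtype=float))


@dataclass
class ResponseCurve:
    """Per-charge-level response statistics for one cell and protocol.

    ``table`` columns: charge_nC, response_probability, mean_evoked_spikes,
    sd_evoked_spikes, n_trials, in_cic.
    """

    table: pd.DataFrame
    cic_limit_nC: float
    cell_id: str = ""
    diameter_um: float = float("nan")

    def within_cic(self) -> pd.DataFrame:
        return self.table[self.table["in_cic"]]


@dataclass
class PSTH:
    """Trial-averaged peristimulus spike rate on fixed bins."""

    bin_edges_s: np.ndarray
    rate_hz: np.ndarray
    n_trials: int
    normalized: bool = False

    @property
    def bin_width_s(self) -> np.ndarray:
        return np.diff(self.bin_edges_s)

    def post_stimulus_count(self) -> float:
        """Σ rate·Δt over post-stimulus bins == mean post-stimulus count."""
        post = self.bin_edges_s[:-1] >= 0
        return float(np.sum(self.rate_hz[post] * self.bin_width_s[post]))


@dataclass(frozen=True)
class CellMetrics:
    """Per-cell analysis output."""

    cell_id: str
    diameter_um: float
    protocol_id: str
    threshold_nC: float
    threshold_status: str
    half_max_nC: float
    half_max_status: str
    dynamic_range_dB: float
    dynamic_range_status: str


# ---------------------------------------------------------------------------
# Spike detection (raw-trace plumbing)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeDetectionParams:
    band_hz: tuple[float, float] = (100.0, 4000.0)
    mad_k: float = 5.0
    refractory_s: float = 1e-3
    artifact_pad_s: float = 0.5e-3


def detect_spikes(
    trace: np.ndarray,
    fs_hz: float,
    *,
    params: SpikeDetectionParams | None = None,
    baseline_end_s: float | None = None,
    blank_windows_s: Sequence[tuple[float, float]] = (),
) -> np.ndarray:
    """Threshold-crossing spike times (s) from a raw loose-patch trace.

    Band-pass filters the trace, estimates noise from the baseline segment
    as a MAD-based robust σ, detects |x| crossings of k·σ, merges events
    closer than the refractory period, and removes events inside stimulus
    artifact blanking windows (each padded by ``artifact_pad_s``).
    """
    params = params or SpikeDetectionParams()
    if fs_hz < 10e3:
        raise ResolutionError(f"sampling rate {fs_hz} Hz below the 10 kHz minimum")
    x = np.asarray(trace, dtype=float)
    if x.size == 0:
        return np.array([])
    if np.ptp(x) > 0 and (np.mean(x == x.max()) + np.mean(x == x.min())) > 0.01:
        import warnings

        warnings.warn("trace appears clipped/saturated; detection may be unreliable")

    lo, hi = params.band_hz
    sos = sps.butter(2, [lo, min(hi, 0.45 * fs_hz)], btype="bandpass", fs=fs_hz, output="sos")
    y = sps.sosfiltfilt(sos, x)

    n_base = int(baseline_end_s * fs_hz) if baseline_end_s is not None else y.size
    base = y[: max(n_base, 16)]
    sigma = 1.4826 * np.median(np.abs(base - np.median(base)))
    if sigma == 0.0:
        return np.array([])

    above = np.abs(y) > params.mad_k * sigma
    onsets = np.nonzero(above & ~np.roll(above, 1))[0]
    if above.size and above[0]:
        onsets = np.union1d(onsets, [0])

    merged: list[int] = []
    n_refr = int(round(params.refractory_s * fs_hz))
    for k in onsets:
        if not merged or k - merged[-1] >= n_refr:
            merged.append(int(k))
    # peak-align each event within one refractory period of its onset
    out = np.array(
        [(k + int(np.argmax(np.abs(y[k : k + n_refr])))) / fs_hz for k in merged]
    )

    for t0, t1 in blank_windows_s:
        out = out[(out < t0 - params.artifact_pad_s) | (out > t1 + params.artifact_pad_s)]
    return out


# ---------------------------------------------------------------------------
# Counting and PSTHs
# ---------------------------------------------------------------------------

def count_evoked(
    trial: TrialResponse,
    window_s: tuple[float, float] = EVOKED_WINDOW_S,
) -> float:
    """Spontaneous-corrected evoked spike count (may be negative).

    evoked = (spikes in window) − baseline_rate × window_duration, with the
    baseline rate taken over the ``baseline_span_s`` seconds preceding the
    stimulus. Suppression below baseline is preserved, not clipped.
    """
    if trial.baseline_span_s < BASELINE_SPAN_S:
        raise BaselineError(
            f"baseline span {trial.baseline_span_s}s < required {BASELINE_SPAN_S}s"
        )
    t = trial.spike_times_s
    w0, w1 = window_s
    n_post = int(np.sum((t >= w0) & (t < w1)))
    n_base = int(np.sum((t >= -trial.baseline_span_s) & (t < 0)))
    base_rate = n_base / trial.baseline_span_s
    return n_post - base_rate * (w1 - w0)


def responded(trial: TrialResponse, window_s: tuple[float, float] = EVOKED_WINDOW_S) -> bool:
    """Boolean response: any spike in the evoked window."""
    t = trial.spike_times_s
    return bool(np.any((t >= window_s[0]) & (t < window_s[1])))


def build_psth(
    trials: Sequence[TrialResponse],
    bin_width_s: float = 0.01,
    t_range_s: tuple[float, float] = (-0.05, 0.5),
    *,
    normalize_to: float | None = None,
) -> PSTH:
    """Trial-averaged PSTH on uniform bins over ``t_range_s``.

    ``normalize_to`` divides rates by a supplied maximum (e.g. the maximal
    rate in a dataset) for heat-map display; conservation then no longer
    holds in absolute units.
    """
    if len(trials) == 0:
        raise InputError("build_psth requires at least one trial")
    t0, t1 = t_range_s
    edges = np.arange(t0, t1 + 0.5 * bin_width_s, bin_width_s)
    counts = np.zeros(len(edges) - 1)
    for tr in trials:
        counts += np.histogram(tr.spike_times_s, bins=edges)[0]
    rate = counts / (len(trials) * bin_width_s)
    normalized = False
    if normalize_to is not None and normalize_to > 0:
        rate = rate / normalize_to
        normalized = True
    return PSTH(bin_edges_s=edges, rate_hz=rate, n_trials=len(trials), normalized=normalized)


# ---------------------------------------------------------------------------
# Response curves and per-cell metrics
# ---------------------------------------------------------------------------

def response_curve(
    trials_by_level: Mapping[float, Sequence[TrialResponse]],
    cic_limit_nC: float,
    *,
    cell_id: str = "",
    diameter_um: float = float("nan"),
    window_s: tuple[float, float] = EVOKED_WINDOW_S,
) -> ResponseCurve:
    """Reduce grouped trials to a per-charge-level response table.

    Keys of ``trials_by_level`` are charge per phase in nC. Levels above
    the CIC limit are retained but flagged ``in_cic=False`` and excluded
    from dynamic-range computations downstream.
    """
    if len(trials_by_level) < 2:
        raise InputError("need at least 2 charge levels for a response curve")
    rows = []
    for q in sorted(trials_by_level):
        trials = trials_by_level[q]
        if len(trials) == 0:
            raise InputError(f"charge level {q} nC has no trials")
        counts = [count_evoked(tr, window_s) for tr in trials]
        prob = float(np.mean([responded(tr, window_s) for tr in trials]))
        rows.append(
            {
                "charge_nC": float(q),
                "response_probability": prob,
                "mean_evoked_spikes": float(np.mean(counts)),
                "sd_evoked_spikes": float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0,
                "n_trials": len(trials),
                "in_cic": q <= cic_limit_nC + 1e-12,
            }
        )
    table = pd.DataFrame(rows)
    return ResponseCurve(
        table=table, cic_limit_nC=cic_limit_nC, cell_id=cell_id, diameter_um=diameter_um
    )


def _lowest_crossing(x: np.ndarray, y: np.ndarray, level: float) -> float | None:
    """First linear-interpolated crossing of y(x) rising through `level`."""
    for i in range(len(x) - 1):
        if y[i] < level <= y[i + 1]:
            return float(x[i] + (level - y[i]) / (y[i + 1] - y[i]) * (x[i + 1] - x[i]))
    return None


def estimate_threshold(curve: ResponseCurve) -> tuple[float, str]:
    """Charge threshold (nC): 50% response probability, lowest crossing.

    Returns ``(threshold, status)`` with status ``"ok"``,
    ``"left-censored"`` (lowest tested level already at/above 0.5) or
    ``"no-threshold"`` (never reaches 0.5 within the CIC; NaN value).
    """
    tab = curve.within_cic()
    if len(tab) == 0:
        return float("nan"), "no-threshold"
    q = tab["charge_nC"].to_numpy()
    p = tab["response_probability"].to_numpy()
    if p[0] >= 0.5:
        return float(q[0]), "left-censored"
    thr = _lowest_crossing(q, p, 0.5)
    if thr is None:
        return float("nan"), "no-threshold"
    return thr, "ok"


def estimate_half_max(curve: ResponseCurve) -> tuple[float, str]:
    """Charge (nC) at which the evoked-count curve first reaches half of
    its within-CIC maximum, by lowest-crossing interpolation."""
    tab = curve.within_cic()
    if len(tab) < 2:
        return float("nan"), "undefined"
    q = tab["charge_nC"].to_numpy()
    m = tab["mean_evoked_spikes"].to_numpy()
    peak = float(np.max(m))
    if peak <= 0:
        return float("nan"), "undefined"
    half = 0.5 * peak
    if m[0] >= half:
        return float(q[0]), "ok"
    hm = _lowest_crossing(q, m, half)
    if hm is None:  # unreachable when peak > 0, kept defensive
        return float("nan"), "undefined"
    return hm, "ok"


def dynamic_range(
    curve: ResponseCurve,
    *,
    mode: str = "interpolated",
) -> tuple[float, str]:
    """Dynamic range in dB: 10·log₁₀(max within-CIC count / count at threshold).

    The count at threshold is obtained by linear interpolation of the count
    curve at the threshold charge (``mode="interpolated"``, default) or at
    the nearest tested level (``mode="nearest"``). A non-positive count at
    threshold gives status ``"undefined"``.
    """
    thr, status = estimate_threshold(curve)
    if status == "no-threshold":
        return float("nan"), "no-threshold"
    tab = curve.within_cic()
    q = tab["charge_nC"].to_numpy()
    m = tab["mean_evoked_spikes"].to_numpy()
    peak = float(np.max(m))
    if mode == "interpolated":
        at_thr = float(np.interp(thr, q, m))
    elif mode == "nearest":
        at_thr = float(m[np.argmin(np.abs(q - thr))])
    else:
        raise InvalidParameterError(f"unknown dynamic-range mode {mode!r}")
    if at_thr <= 0:
        return float("nan"), "undefined"
    return 10.0 * np.log10(peak / at_thr), "ok"


def analyze_cell(
    trials_by_level: Mapping[float, Sequence[TrialResponse]],
    cic_limit_nC: float,
    *,
    cell_id: str = "",
    diameter_um: float = float("nan"),
    protocol_id: str = "",
    window_s: tuple[float, float] = EVOKED_WINDOW_S,
) -> CellMetrics:
    """Full per-cell reduction: threshold, half-max and dynamic range."""
    curve = response_curve(
        trials_by_level,
        cic_limit_nC,
        cell_id=cell_id,
        diameter_um=diameter_um,
        window_s=window_s,
    )
    thr, thr_status = estimate_threshold(curve)
    hm, hm_status = estimate_half_max(curve)
    dr, dr_status = dynamic_range(curve)
    return CellMetrics(
        cell_id=cell_id,
        diameter_um=diameter_um,
        protocol_id=protocol_id,
        threshold_nC=thr,
        threshold_status=thr_status,
        half_max_nC=hm,
        half_max_status=hm_status,
        dynamic_range_dB=dr,
        dynamic_range_status=dr_status,
    )


# ---------------------------------------------------------------------------
# Population summaries
# ---------------------------------------------------------------------------

def _box_stats(x: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "q25": float(np.percentile(x, 25)),
        "q75": float(np.percentile(x, 75)),
        "p9": float(np.percentile(x, 9)),
        "p91": float(np.percentile(x, 91)),
        "n": int(len(x)),
    }


def population_summary(cells: Sequence[CellMetrics]) -> pd.DataFrame:
    """Per (diameter, protocol) summary of thresholds and dynamic ranges.

    Box statistics (mean, median, 25–75% quartiles, 9–91% whiskers) over
    cells with a threshold; responsive fraction over all cells tested;
    charge-density thresholds (median threshold / geometric area, mC/cm²).
    """
    if len(cells) == 0:
        raise InputError("population_summary requires at least one cell")
    df = pd.DataFrame([c.__dict__ for c in cells])
    out_rows = []
    for (diam, proto), grp in df.groupby(["diameter_um", "protocol_id"]):
        resp = grp[grp["threshold_status"].isin(["ok", "left-censored"])]
        row: dict[str, object] = {
            "diameter_um": diam,
            "protocol_id": proto,
            "n_tested": len(grp),
            "n_responsive": len(resp),
            "responsive_fraction": len(resp) / len(grp),
        }
        if len(resp) == 0:
            import warnings

            warnings.warn(f"no responsive cells for {diam} μm / {proto!r}; group omitted")
            continue
        thr = resp["threshold_nC"].to_numpy()
        for k, v in _box_stats(thr).items():
            row[f"threshold_nC_{k}"] = v
        area = disk_area(ElectrodeGeometry(diameter_um=float(diam)))
        row["threshold_density_mC_cm2_median"] = float(np.median(thr)) * 1e-6 / area
        dr = resp[resp["dynamic_range_status"] == "ok"]["dynamic_range_dB"].to_numpy()
        if len(dr):
            for k, v in _box_stats(dr).items():
                row[f"dynamic_range_dB_{k}"] = v
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def latency_split(
    trials: Sequence[TrialResponse],
    split_s: float = LATENCY_SPLIT_S,
    window_s: tuple[float, float] = EVOKED_WINDOW_S,
) -> dict[str, float]:
    """Mean short-/long-latency evoked spike counts per trial (descriptive)."""
    short = long = 0
    for tr in trials:
        t = tr.spike_times_s
        in_win = (t >= window_s[0]) & (t < window_s[1])
        short += int(np.sum(in_win & (t < split_s)))
        long += int(np.sum(in_win & (t >= split_s)))
    n = max(len(trials), 1)
    return {"short_per_trial": short / n, "long_per_trial": long / n}
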