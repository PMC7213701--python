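"""Synthetic fetal-ECG generator with exact ground-truth fiducials.

Each beat is a sum of Gaussian waves (P, Q, R, S, T) placed relative to the
R peak, on a flat isoelectric baseline, at fetal rates (default 140 bpm with
beat-to-beat variability).  The T wave's centre is derived from a QT rule
QT = c · RR_s^(1/3) (so the Fridericia-corrected truth is constant at c),
and the true T-end is defined as the T-Gaussian centre plus 2.5 widths — an
explicit artifact convention, since "end" of a smooth Gaussian is otherwise
arbitrary.  Optional additive white noise and a baseline sinusoid emulate
the noise floor and respiration drift of abdominal recordings; a surrogate
"reference" T-end series is the truth plus seeded Gaussian jitter, standing
in for scalp-ECG/Doppler annotations.

Everything is driven by a single integer seed: the same config and seed
reproduce the samples and fiducials bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from . import agreement, core_model, signal_processing
from .errors import InvalidArgumentError
from .signal_processing import BeatAnnotations, EcgRecord

__all__ = [
    "GaussianWave",
    "SimulationConfig",
    "SimulatedRecord",
    "simulate_record",
    "benchmark_detector",
    "default_waves",
]


@dataclass(frozen=True)
class GaussianWave:
    """One ECG wave: amplitude · exp(−(t − centre)²/(2·width²))."""

    amplitude: float
    center_ms: float | None  # offset from the R peak; None = derived (T wave)
    width_ms: float


def default_waves() -> dict[str, GaussianWave]:
    """Default fetal morphology: dominant narrow R, low-amplitude T and P."""
    return {
        "P": GaussianWave(amplitude=0.10, center_ms=-90.0, width_ms=12.0),
        "Q": GaussianWave(amplitude=-0.10, center_ms=-35.0, width_ms=5.0),
        "R": GaussianWave(amplitude=1.00, center_ms=0.0, width_ms=7.0),
        "S": GaussianWave(amplitude=-0.20, center_ms=22.0, width_ms=6.0),
        "T": GaussianWave(amplitude=0.20, center_ms=None, width_ms=16.0),
    }


#: True T-end sits this many T-widths beyond the T-Gaussian centre.
T_END_WIDTHS = 2.5


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated record.

    Defaults mirror the normal fetal cohort the estimator targets: 1 kHz
    sampling, mean 140 bpm with 5 bpm beat-to-beat sd, and a QT rule whose
    Fridericia-corrected value is the constant ``qtc_truth_ms`` (325 ms).
    ``reference_jitter_ms`` is the sd of the jitter applied to the true
    T-ends to fabricate a surrogate reference series.
    """

    fs_hz: float = 1000.0
    n_beats: int = 100
    hr_bpm: float = 140.0
    hr_sd_bpm: float = 5.0
    qtc_truth_ms: float = 325.0
    waves: dict[str, GaussianWave] = field(default_factory=default_waves)
    noise_white_sd: float = 0.0
    baseline_amp: float = 0.0
    baseline_freq_hz: float = 0.3
    reference_jitter_ms: float = 0.0
    lead_in_ms: float = 400.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.fs_hz <= 0:
            problems.append("fs_hz must be positive")
        if self.n_beats < 1:
            problems.append("n_beats must be >= 1")
        if not (60.0 <= self.hr_bpm <= 250.0):
            problems.append("hr_bpm must lie in [60, 250]")
        if self.hr_sd_bpm < 0:
            problems.append("hr_sd_bpm must be >= 0")
        if self.qtc_truth_ms <= 0:
            problems.append("qtc_truth_ms must be positive")
        for name, w in self.waves.items():
            if w.width_ms <= 0:
                problems.append(f"wave {name}: width_ms must be positive")
        if self.noise_white_sd < 0 or self.baseline_amp < 0:
            problems.append("noise amplitudes must be >= 0")
        if self.reference_jitter_ms < 0:
            problems.append("reference_jitter_ms must be >= 0")
        if problems:
            raise InvalidArgumentError("invalid simulation config: " + "; ".join(problems))


@dataclass(frozen=True)
class SimulatedRecord:
    """A simulated trace with its exact truth and surrogate reference."""

    record: EcgRecord
    truth: BeatAnnotations  # r/q/t_end indices, source="truth"
    reference_t_end_ms: np.ndarray  # absolute times, truth + jitter
    config: SimulationConfig

    @property
    def n_beats(self) -> int:
        return self.truth.n_beats

    def rr_ms(self) -> np.ndarray:
        return self.truth.rr_ms(self.record.fs_hz)

    def truth_t_end_offset_ms(self) -> np.ndarray:
        """True T-end offsets from each R peak, in ms."""
        return (self.truth.t_end_idx - self.truth.r_idx) / self.record.fs_hz * 1000.0


def _true_qt_ms(rr_ms: float, qtc_truth_ms: float) -> float:
    """Invert Fridericia: QT = c · (RR in s)^(1/3)."""
    return qtc_truth_ms * (rr_ms / 1000.0) ** (1.0 / 3.0)


def simulate_record(config: SimulationConfig | None = None) -> SimulatedRecord:
    """Generate one record with exact fiducials and a surrogate reference.

    Per beat: RR is drawn from N(60000/hr, ·) via a per-beat heart rate
    N(hr_bpm, hr_sd_bpm) clipped to [60, 250] bpm and rounded to whole
    samples so the truth fiducials are exact grid points.  Waves are summed
    at their per-beat positions; the T centre is placed so that the true
    T-end (centre + 2.5 widths) equals the QT-rule value minus the Q offset.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs_hz
    ms_per_sample = 1000.0 / fs

    hr = np.clip(rng.normal(cfg.hr_bpm, cfg.hr_sd_bpm, size=cfg.n_beats), 60.0, 250.0)
    rr_samples = np.round(60000.0 / hr / ms_per_sample).astype(np.int64)

    r_idx = np.empty(cfg.n_beats, dtype=np.int64)
    r_idx[0] = int(round(cfg.lead_in_ms / ms_per_sample))
    r_idx[1:] = r_idx[0] + np.cumsum(rr_samples[:-1])
    n_samples = int(r_idx[-1] + rr_samples[-1])

    q_wave = cfg.waves.get("Q")
    q_offset_ms = -q_wave.center_ms if (q_wave and q_wave.center_ms is not None) else 35.0
    t_wave = cfg.waves["T"]

    x = np.zeros(n_samples, dtype=float)
    t_end_idx = np.empty(cfg.n_beats, dtype=np.int64)
    q_idx = np.empty(cfg.n_beats, dtype=np.int64)

    def add_gaussian(center_idx: float, amp: float, width_ms: float) -> None:
        w = width_ms / ms_per_sample
        lo = max(int(center_idx - 5 * w), 0)
        hi = min(int(center_idx + 5 * w) + 1, n_samples)
        if hi <= lo:
            return
        tt = np.arange(lo, hi, dtype=float)
        x[lo:hi] += amp * np.exp(-0.5 * ((tt - center_idx) / w) ** 2)

    for i in range(cfg.n_beats):
        r = r_idx[i]
        rr_ms_i = rr_samples[i] * ms_per_sample
        qt_ms = _true_qt_ms(rr_ms_i, cfg.qtc_truth_ms)
        t_end_offset_ms = qt_ms - q_offset_ms
        for name, wave in cfg.waves.items():
            if name == "T" and wave.center_ms is None:
                center_ms = t_end_offset_ms - T_END_WIDTHS * wave.width_ms
            else:
                center_ms = wave.center_ms
            add_gaussian(r + center_ms / ms_per_sample, wave.amplitude, wave.width_ms)
        t_center_ms = (
            t_end_offset_ms - T_END_WIDTHS * t_wave.width_ms
            if t_wave.center_ms is None
            else t_wave.center_ms
        )
        t_end_idx[i] = r + int(round((t_center_ms + T_END_WIDTHS * t_wave.width_ms) / ms_per_sample))
        q_idx[i] = r - int(round(q_offset_ms / ms_per_sample))

    if cfg.baseline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        tt = np.arange(n_samples) / fs
        x += cfg.baseline_amp * np.sin(2 * np.pi * cfg.baseline_freq_hz * tt + phase)
    if cfg.noise_white_sd > 0:
        x += rng.normal(0.0, cfg.noise_white_sd, size=n_samples)

    truth = BeatAnnotations(r_idx=r_idx, q_idx=q_idx, t_end_idx=t_end_idx, source="truth")
    truth_t_end_ms = t_end_idx * ms_per_sample
    jitter = (
        rng.normal(0.0, cfg.reference_jitter_ms, size=cfg.n_beats)
        if cfg.reference_jitter_ms > 0
        else np.zeros(cfg.n_beats)
    )
    record = EcgRecord(fs_hz=fs, samples=x, label="sim_fecg")
    return SimulatedRecord(
        record=record,
        truth=truth,
        reference_t_end_ms=truth_t_end_ms + jitter,
        config=cfg,
    )


def benchmark_detector(
    sim: SimulatedRecord,
    detector: str | Callable = "tangent",
    against: str = "truth",
) -> tuple[agreement.AgreementReport, pd.DataFrame]:
    """Run a T-end method over a simulated record and score the agreement.

    ``detector`` is ``"tangent"`` (tangent rule on the trace), ``"model"``
    (the RR-driven band-median estimator), ``"truth"`` (the generator's own
    fiducials, for self-checks), or a callable
    ``f(sim) -> t_end_offsets_ms`` returning one offset per beat with a
    successor R (NaN for failures).  ``against`` selects ``"truth"`` or the
    jittered ``"reference"`` series.  Beats where the method fails are
    excluded from the pairing and counted in the per-beat table.

    Returns the Bland–Altman report on T-end offsets (estimate − reference)
    plus the per-beat table.
    """
    fs = sim.record.fs_hz
    r_idx = sim.truth.r_idx
    n_pairs = sim.n_beats - 1  # last beat has no RR
    if n_pairs < 2:
        raise InvalidArgumentError("need at least 3 beats to benchmark")

    if callable(detector):
        est_offsets = np.asarray(detector(sim), dtype=float)
        name = getattr(detector, "__name__", "custom")
    elif detector == "tangent":
        t_idx, reasons = signal_processing.tangent_t_ends(sim.record, r_idx)
        est_offsets = np.where(t_idx >= 0, (t_idx - r_idx[:-1]) / fs * 1000.0, np.nan)
        name = "tangent"
    elif detector == "model":
        rr = sim.rr_ms()
        est_offsets = np.empty(n_pairs)
        for i in range(n_pairs):
            curve = core_model.repolarization_curve(rr[i])
            band = core_model.compute_k(curve)
            try:
                est_offsets[i] = core_model.t_end_from_curve(curve, band).t_end_ms
            except Exception:
                est_offsets[i] = np.nan
        name = "model"
    elif detector == "truth":
        est_offsets = sim.truth_t_end_offset_ms()[:-1]
        name = "truth"
    else:
        raise InvalidArgumentError(f"unknown detector {detector!r}")

    if est_offsets.shape != (n_pairs,):
        raise InvalidArgumentError(
            f"detector returned {est_offsets.shape}, expected ({n_pairs},)"
        )
    if against == "truth":
        ref_offsets = sim.truth_t_end_offset_ms()[:-1]
    elif against == "reference":
        ref_offsets = (sim.reference_t_end_ms[:-1] - r_idx[:-1] / fs * 1000.0)
    else:
        raise InvalidArgumentError(f"against must be 'truth' or 'reference', got {against!r}")

    table = pd.DataFrame(
        {
            "beat_index": np.arange(n_pairs),
            "estimate_ms": est_offsets,
            "reference_ms": ref_offsets,
            "missing": ~np.isfinite(est_offsets),
            "detector": name,
        }
    )
    ok = np.isfinite(est_offsets)
    if ok.sum() < 2:
        raise InvalidArgumentError(f"detector {name!r} produced fewer than 2 estimates")
    pairs = agreement.PairedIntervalSeries(est_offsets[ok], ref_offsets[ok])
    report, _ = agreement.bland_altman(pairs)
    return report, table
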