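"""Paired-pulse EPSC analysis.

Measures evoked excitatory postsynaptic current (EPSC) amplitudes on paired
stimulation sweeps, computes the paired-pulse ratio (PPR = A2/A1; >1 means
facilitation, <1 depression), averages 20 successive sweeps per
interstimulus interval (ISI), and applies the recording-stability rejection
rule: if input or series resistance varies by more than 20% over the
experiment, the whole experiment (cell) is rejected.

EPSCs are treated as inward (negative) current deflections; amplitudes are
reported as magnitudes in pA. At short ISIs where the second response rides
on the decay of the first, the second baseline is taken immediately before
stimulus 2, which removes the residual first-pulse current to first order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["SweepPair", "PPRResult", "measure_amplitude", "compute_ppr", "qc_filter"]


@dataclass
class SweepPair:
    """One paired-pulse sweep with QC metadata.

    ``time_ms`` and ``current_pA`` are equal-length 1-D arrays; ``t1``/``t2``
    are the stimulus times (ms) with ``isi = t2 - t1``; ``r_input`` and
    ``r_series`` are the access/input resistances (MΩ) at sweep time.
    """

    time_ms: np.ndarray
    current_pA: np.ndarray
    t1: float
    t2: float
    r_input: float | None = None
    r_series: float | None = None
    sweep_id: int = 0
    overlap_flag: bool = False

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        if self.t1 >= self.t2:
            raise ValueError("t1 must precede t2")
        if self.time_ms[0] > self.t1 or self.time_ms[-1] < self.t2:
            raise ValueError("trace does not cover both stimuli")

    @property
    def isi(self) -> float:
        return self.t2 - self.t1


@dataclass
class PPRResult:
    isi: float
    a1: np.ndarray  # per accepted sweep, pA
    a2: np.ndarray
    ppr_per_sweep: np.ndarray = field(init=False)
    mean_ppr: float = field(init=False)  # mean of per-sweep ratios
    ppr_of_means: float = field(init=False)  # ratio of mean amplitudes
    n_accepted: int = field(init=False)

    def __post_init__(self) -> None:
        self.a1 = np.asarray(self.a1, dtype=float)
        self.a2 = np.asarray(self.a2, dtype=float)
        self.ppr_per_sweep = self.a2 / self.a1
        self.mean_ppr = float(np.mean(self.ppr_per_sweep))
        self.ppr_of_means = float(np.mean(self.a2) / np.mean(self.a1))
        self.n_accepted = len(self.a1)


def _window_mean(t: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    sel = (t >= lo) & (t < hi)
    if not sel.any():
        raise ValueError(f"empty window [{lo}, {hi}) ms")
    return float(y[sel].mean())


def measure_amplitude(
    pair: SweepPair,
    baseline_window_ms: float = 5.0,
    peak_window_ms: float = 20.0,
) -> tuple[float, float]:
    """Baseline-subtracted amplitudes |extremum - baseline| of both EPSCs.

    Baseline 1 is the mean current over ``baseline_window_ms`` before
    stimulus 1. Baseline 2 is the mean over a short (<= 1 ms, and never
    reaching back past stimulus 1's response) window immediately before
    stimulus 2 — the local-baseline correction for overlapping responses.
    The peak is the sample of largest absolute deviation from baseline
    within ``peak_window_ms`` after each stimulus.
    """
    t, y = pair.time_ms, pair.current_pA
    if pair.t2 + peak_window_ms > t[-1] + (t[1] - t[0]):
        raise ValueError("peak window truncated by trace end")

    b1 = _window_mean(t, y, pair.t1 - baseline_window_ms, pair.t1)
    w2 = min(1.0, baseline_window_ms, pair.isi / 4)
    b2 = _window_mean(t, y, pair.t2 - w2, pair.t2)

    amps = []
    for t0, b in ((pair.t1, b1), (pair.t2, b2)):
        sel = (t >= t0) & (t < t0 + peak_window_ms)
        seg = y[sel] - b
        amps.append(float(np.abs(seg).max()) if seg.size else 0.0)
    return amps[0], amps[1]


def compute_ppr(
    sweeps: list[SweepPair],
    baseline_window_ms: float = 5.0,
    peak_window_ms: float = 20.0,
) -> PPRResult:
    """Per-ISI PPR: each sweep measured individually, then ratios averaged.

    The reported statistic is the mean of per-sweep A2/A1 ratios; the
    ratio of mean amplitudes is also computed for comparison (the two agree
    in the noise-free limit).
    """
    if not sweeps:
        raise ValueError("no accepted sweeps")
    isis = {round(s.isi, 6) for s in sweeps}
    if len(isis) != 1:
        raise ValueError(f"sweeps span multiple ISIs: {sorted(isis)}")
    a = np.array([measure_amplitude(s, baseline_window_ms, peak_window_ms) for s in sweeps])
    return PPRResult(isi=sweeps[0].isi, a1=a[:, 0], a2=a[:, 1])


def qc_filter(sweeps: list[SweepPair], max_rel_variation: float = 0.20) -> dict:
    """Whole-experiment stability QC on resistance metadata.

    For each resistance type the relative variation is
    ``(max - min) / first-sweep value``; the experiment is rejected if either
    strictly exceeds ``max_rel_variation`` (a variation of exactly 20% is
    accepted). Missing metadata flags the experiment as un-QC'able.

    Returns ``{"accepted": list[SweepPair], "rejected": bool, "report": dict}``.
    """
    report: dict = {}
    for attr, name in (("r_input", "input"), ("r_series", "series")):
        vals = [getattr(s, attr) for s in sweeps]
        if any(v is None or not np.isfinite(v) for v in vals):
            raise ValueError(f"missing {name} resistance metadata; experiment un-QC'able")
        vals = np.asarray(vals, dtype=float)
        rel = float((vals.max() - vals.min()) / vals[0])
        report[f"{name}_rel_variation"] = rel
    rejected = any(v > max_rel_variation for v in report.values())
    if rejected:
        logger.warning("experiment rejected: resistance variation %s", report)
    report["rejected"] = rejected
    return {"accepted": [] if rejected else list(sweeps), "rejected": rejected, "report": report}
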