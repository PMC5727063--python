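"""Two-stage resistive-pulse extraction from current traces.

Stage one finds candidate events on the baseline-subtracted *depth*
signal (baseline minus current, so downward spikes are positive): a
60 pA threshold marks the current-decrease onset, a 10 pA rising edge
bounds the region containing the pulse, and the deepest sample in the
region is the peak; events whose depth never reaches the onset
threshold are discarded.  Stage two refines the boundaries by locating
where the signal rises above / falls below 5 sigma of the local noise
and attaches 256-sample margins on both sides, which defines the onset
time t_s (0.256 ms before the 5-sigma crossing at 1 MHz) and endpoint
t_e; the dwell time is t_d = t_e - t_s.

The baseline is removed by independent linear fits to consecutive
0.5 s segments, with candidate-event samples masked out of the fits so
deep pulses do not bias the base level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace_io import CurrentTrace, Histogram2D

__all__ = [
    "DetectionConfig",
    "BaselineModel",
    "DetectedPulse",
    "estimate_baseline",
    "detect_events",
    "refine_boundaries",
    "detect_pulses",
    "extract_windows",
    "build_histogram2d",
    "pulse_table",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Detection thresholds (SI units)."""

    baseline_segment: float = 0.5         # s per linear baseline fit
    onset_threshold: float = 60e-12       # A, minimum accepted pulse depth
    rising_edge: float = 10e-12           # A, bounds the pulse region
    sigma_factor: float = 5.0             # boundary crossing level in sigma
    margin_samples: int = 256             # samples prepended/appended
    window_half_width: float = 20e-3      # s, event-overlay window
    run_length: int = 3                   # consecutive samples to confirm a 5-sigma run
    onset_run: int = 2                    # consecutive samples above onset to accept
    merge_gap_samples: int | None = None  # region-merge gap; None: margin_samples

    def __post_init__(self) -> None:
        if not (self.onset_threshold > self.rising_edge > 0):
            raise ValueError("need onset_threshold > rising_edge > 0")
        if not (self.sigma_factor > 0):
            raise ValueError("sigma_factor must be positive")
        if self.margin_samples < 0:
            raise ValueError("margin_samples must be >= 0")
        if self.run_length < 1 or self.onset_run < 1:
            raise ValueError("run lengths must be >= 1")


@dataclass
class BaselineModel:
    """Per-segment linear baseline fits."""

    boundaries: np.ndarray   # segment start indices, plus final length
    intercepts: np.ndarray
    slopes: np.ndarray
    sampling_rate: float

    def evaluate(self, n_samples: int | None = None) -> np.ndarray:
        """Baseline value at every sample index."""
        n = int(self.boundaries[-1]) if n_samples is None else n_samples
        out = np.empty(n)
        for k in range(len(self.intercepts)):
            lo, hi = int(self.boundaries[k]), min(int(self.boundaries[k + 1]), n)
            idx = np.arange(lo, hi)
            out[lo:hi] = self.intercepts[k] + self.slopes[k] * idx / self.sampling_rate
        return out


@dataclass
class DetectedPulse:
    """One extracted resistive pulse (depth convention: positive down)."""

    pulse_id: int
    t_s: float
    t_e: float
    peak_time: float
    I_p: float
    samples: np.ndarray      # baseline-subtracted depth over [t_s, t_e]
    sigma: float
    sampling_rate: float
    truncated: bool = False
    source: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def t_d(self) -> float:
        return self.t_e - self.t_s


def _candidate_mask(depth: np.ndarray, config: "DetectionConfig") -> np.ndarray:
    """Samples inside confirmed candidate regions, grown by the margin.

    Masking only confirmed events (not every sample past the rising
    edge) keeps noise-only stretches unclipped, so baseline and sigma
    estimates stay unbiased.
    """
    mask = np.zeros(len(depth), dtype=bool)
    for event in detect_events(depth, config):
        lo = max(0, event.start - config.margin_samples)
        hi = min(len(depth), event.end + 1 + config.margin_samples)
        mask[lo:hi] = True
    return mask


def estimate_baseline(trace: CurrentTrace, config: DetectionConfig = DetectionConfig()
                      ) -> BaselineModel:
    """Fit the base level by segment-wise linear regression.

    Two passes: a first fit on all samples gives a rough depth signal,
    whose candidate regions (depth above the rising edge) are masked out
    of the second fit.  Traces shorter than one segment fall back to a
    single whole-trace fit with a warning.
    """
    n = len(trace)
    seg_len = int(round(config.baseline_segment * trace.sampling_rate))
    if seg_len < 2 or n < seg_len:
        warnings.warn(
            "trace shorter than one baseline segment; fitting the whole trace",
            stacklevel=2,
        )
        seg_len = n
    n_seg = max(1, n // seg_len)
    boundaries = np.array([k * seg_len for k in range(n_seg)] + [n])
    idx_all = np.arange(n)
    t_all = idx_all / trace.sampling_rate
    y = trace.samples

    def fit(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        inter = np.empty(n_seg)
        slope = np.empty(n_seg)
        for k in range(n_seg):
            lo, hi = int(boundaries[k]), int(boundaries[k + 1])
            m = mask[lo:hi]
            if m.sum() < 2:         # pulse fills the segment; fall back to all samples
                m = np.ones(hi - lo, dtype=bool)
            coef = np.polyfit(t_all[lo:hi][m], y[lo:hi][m], 1)
            slope[k], inter[k] = coef[0], coef[1]
        return inter, slope

    inter, slope = fit(np.ones(n, dtype=bool))
    model = BaselineModel(boundaries, inter, slope, trace.sampling_rate)
    depth = model.evaluate(n) - y
    mask = ~_candidate_mask(depth, config)
    inter, slope = fit(mask)
    return BaselineModel(boundaries, inter, slope, trace.sampling_rate)


@dataclass(frozen=True)
class CandidateEvent:
    start: int       # first sample with depth > rising edge
    end: int         # last sample with depth > rising edge (inclusive)
    peak: int        # index of maximum depth (earliest on ties)
    depth: float


def detect_events(depth: np.ndarray, config: DetectionConfig = DetectionConfig()
                  ) -> list[CandidateEvent]:
    """Find candidate events in a baseline-subtracted depth signal.

    A crossing of the onset threshold flags an event; its region extends
    while the depth stays above the rising edge; events whose depth
    never holds the onset threshold for ``onset_run`` consecutive
    samples are discarded (single-sample noise excursions past 60 pA
    are not pulses).  Confirmed events closer than the merge gap are
    joined, so noise dips that fragment a pulse's shallow tails do not
    double-count it.
    """
    above = depth > config.rising_edge
    if not np.any(above):
        return []
    padded = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1
    events: list[CandidateEvent] = []
    gap = config.merge_gap_samples
    if gap is None:
        gap = config.margin_samples
    for s, e in zip(starts, ends):
        seg = depth[s:e + 1]
        deep = (seg > config.onset_threshold).view(np.int8)
        if deep.size < config.onset_run:
            continue
        conv = np.convolve(deep, np.ones(config.onset_run, dtype=int), "valid")
        if not np.any(conv == config.onset_run):
            continue
        peak_rel = int(np.argmax(seg))          # argmax returns the earliest maximum
        event = CandidateEvent(int(s), int(e), int(s + peak_rel),
                               float(seg[peak_rel]))
        if events and event.start - events[-1].end <= gap:
            prev = events[-1]
            peak, depth_max = (prev.peak, prev.depth) \
                if prev.depth >= event.depth else (event.peak, event.depth)
            events[-1] = CandidateEvent(prev.start, event.end, peak, depth_max)
        else:
            events.append(event)
    return events


def _quiet_mask(depth: np.ndarray, config: DetectionConfig) -> np.ndarray:
    """Samples outside any confirmed candidate region (grown by the
    margin), usable for noise estimation without truncation bias."""
    return ~_candidate_mask(depth, config)


def _local_sigma(depth: np.ndarray, event: CandidateEvent,
                 config: DetectionConfig, sampling_rate: float,
                 quiet: np.ndarray | None = None) -> float:
    """Robust noise scale near an event: scaled MAD over event-free samples
    of the surrounding segment."""
    if quiet is None:
        quiet = _quiet_mask(depth, config)
    half = int(round(config.baseline_segment * sampling_rate / 2))
    lo = max(0, event.peak - half)
    hi = min(len(depth), event.peak + half)
    seg = depth[lo:hi][quiet[lo:hi]]
    if seg.size < 16:
        seg = depth[quiet] if np.any(quiet) else depth
    return float(1.4826 * np.median(np.abs(seg - np.median(seg))))


def _runs_below(flags: np.ndarray, run_length: int) -> np.ndarray:
    """Indices where a run of ``run_length`` consecutive True values starts."""
    if flags.size < run_length:
        return np.array([], dtype=int)
    conv = np.convolve(flags.view(np.int8), np.ones(run_length, dtype=int), "valid")
    return np.flatnonzero(conv == run_length)


def refine_boundaries(trace: CurrentTrace, depth: np.ndarray,
                      event: CandidateEvent,
                      config: DetectionConfig = DetectionConfig(),
                      pulse_id: int = 0, source: str = "",
                      quiet: np.ndarray | None = None) -> DetectedPulse:
    """Refine event boundaries to the 5-sigma crossings plus margins.

    Scanning outward from the peak, the boundary crossing is the first
    sample beyond which the depth stays below ``sigma_factor * sigma``
    for at least ``run_length`` consecutive samples; the stored t_s/t_e
    prepend/append ``margin_samples``.  Boundaries clipped by the trace
    edge are flagged as truncated.
    """
    sigma = _local_sigma(depth, event, config, trace.sampling_rate, quiet)
    # noise-free traces leave only float residue in sigma; fall back to a
    # fixed boundary level well below the rising edge
    if sigma > 1e-3 * config.rising_edge:
        level = config.sigma_factor * sigma
    else:
        level = config.rising_edge / 2.0
    below = np.abs(depth) < level

    # onset: last quiet run that ends before the peak
    left = below[:event.peak]
    starts = _runs_below(left, config.run_length)
    onset = int(starts[-1] + config.run_length) if starts.size else 0
    # offset: first quiet run after the peak
    right = below[event.peak + 1:]
    starts = _runs_below(right, config.run_length)
    offset = int(event.peak + starts[0]) if starts.size else len(depth) - 1

    truncated = False
    s_idx = onset - config.margin_samples
    e_idx = offset + config.margin_samples
    if s_idx < 0:
        s_idx, truncated = 0, True
    if e_idx > len(depth) - 1:
        e_idx, truncated = len(depth) - 1, True
    fs = trace.sampling_rate
    return DetectedPulse(
        pulse_id=pulse_id,
        t_s=s_idx / fs,
        t_e=e_idx / fs,
        peak_time=event.peak / fs,
        I_p=float(depth[event.peak]),
        samples=depth[s_idx:e_idx + 1].copy(),
        sigma=sigma,
        sampling_rate=fs,
        truncated=truncated,
        source=source,
    )


def detect_pulses(trace: CurrentTrace, config: DetectionConfig = DetectionConfig(),
                  source: str = "") -> list[DetectedPulse]:
    """Full two-stage extraction: baseline, candidates, refined pulses."""
    model = estimate_baseline(trace, config)
    depth = model.evaluate(len(trace)) - trace.samples
    quiet = _quiet_mask(depth, config)
    pulses = []
    for k, event in enumerate(detect_events(depth, config)):
        pulses.append(refine_boundaries(trace, depth, event, config,
                                        pulse_id=k, source=source, quiet=quiet))
    return pulses


@dataclass
class PulseWindows:
    """Fixed-length, peak-aligned depth segments."""

    windows: np.ndarray       # (n_pulses, window_len)
    valid: np.ndarray         # boolean validity mask, same shape
    truncated: np.ndarray     # per-pulse truncation flag
    sampling_rate: float


def extract_windows(trace: CurrentTrace, pulses: list[DetectedPulse],
                    window_half_width: float = 20e-3,
                    depth: np.ndarray | None = None,
                    config: DetectionConfig = DetectionConfig()) -> PulseWindows:
    """Collect +-window_half_width of depth signal around each peak.

    Windows are peak-aligned and fixed-length (2*half*fs + 1 samples);
    samples beyond the trace edges are zero with ``valid`` False and the
    pulse flagged truncated, never silently padded.
    """
    fs = trace.sampling_rate
    if depth is None:
        model = estimate_baseline(trace, config)
        depth = model.evaluate(len(trace)) - trace.samples
    half = int(round(window_half_width * fs))
    width = 2 * half + 1
    n = len(pulses)
    windows = np.zeros((n, width))
    valid = np.zeros((n, width), dtype=bool)
    truncated = np.zeros(n, dtype=bool)
    for i, p in enumerate(pulses):
        peak = int(round(p.peak_time * fs))
        lo, hi = peak - half, peak + half + 1
        src_lo, src_hi = max(0, lo), min(len(depth), hi)
        dst_lo = src_lo - lo
        windows[i, dst_lo:dst_lo + (src_hi - src_lo)] = depth[src_lo:src_hi]
        valid[i, dst_lo:dst_lo + (src_hi - src_lo)] = True
        truncated[i] = (lo < 0) or (hi > len(depth))
    return PulseWindows(windows, valid, truncated, fs)


def build_histogram2d(windows: PulseWindows, current_bin: float = 1e-12,
                      time_bin: float = 1e-4) -> Histogram2D:
    """Overlay histogram of window samples, binned at 1 pA x 0.1 ms.

    Counts are conserved: every valid sample lands in exactly one bin.
    """
    if windows.windows.shape[0] < 1:
        raise ValueError("need at least one window")
    half = (windows.windows.shape[1] - 1) // 2
    t_rel = (np.arange(windows.windows.shape[1]) - half) / windows.sampling_rate
    t_all = np.broadcast_to(t_rel, windows.windows.shape)[windows.valid]
    i_all = windows.windows[windows.valid]

    def edges(values: np.ndarray, width: float) -> np.ndarray:
        lo = np.floor(values.min() / width) * width
        hi = np.ceil(values.max() / width) * width
        if hi <= lo:
            hi = lo + width
        k = int(round((hi - lo) / width))
        return lo + width * np.arange(k + 1)

    t_edges = edges(t_all, time_bin)
    i_edges = edges(i_all, current_bin)
    counts, _, _ = np.histogram2d(t_all, i_all, bins=[t_edges, i_edges])
    return Histogram2D(counts.astype(int), t_edges, i_edges)


def pulse_table(pulses: list[DetectedPulse]) -> pd.DataFrame:
    """Tabulate detected pulses (SI units) for :func:`trace_io.write_pulse_table`."""
    return pd.DataFrame(
        {
            "pulse_id": [p.pulse_id for p in pulses],
            "t_s": [p.t_s for p in pulses],
            "t_e": [p.t_e for p in pulses],
            "peak_time": [p.peak_time for p in pulses],
            "I_p": [p.I_p for p in pulses],
            "t_d": [p.t_d for p in pulses],
            "source": [p.source for p in pulses],
        }
    )
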