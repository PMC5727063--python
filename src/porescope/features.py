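"""Waveform descriptors of resistive pulses and the 60-vector feature catalog.

Every descriptor operates on the *normalized* pulse: depth divided by
the peak depth I_p (apex = 1) and time mapped onto [0, 1] between the
pulse onset t_s and endpoint t_e.  Descriptors are therefore invariant
to depth scaling and time translation of the raw pulse.

The apex bluntness is

    beta_apex = 1/(m t_d^2) * sum_i (t_i - t_s - t_ave)^2

where t_i are the m times at which the pulse crosses the level Y_th
percent down from its apex and t_ave is the mean of t_i - t_s.  In
normalized time this is the population variance of the crossing times:
0 for a needle, up to 0.25 for a flat top (when m = 2).

The level convention is apex-referenced: crossings are found at
I_norm = 1 - Y_th/100 of the normalized depth.  A baseline-referenced
convention (crossings at I_norm = Y_th/100) is available through the
``convention`` flag of :func:`crossing_times`.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pulse_detect import DetectedPulse

__all__ = [
    "NormalizedPulse",
    "FeatureRecord",
    "FeatureVectorSpec",
    "normalize",
    "crossing_times",
    "bluntness",
    "onset_angle",
    "areas",
    "inertia",
    "compute_features",
    "default_catalog",
    "catalog_hash",
    "build_feature_vectors",
    "feature_matrix",
    "SCALAR_FEATURES",
]

#: Y_th levels (percent down from the apex) at which bluntness is reported
DEFAULT_Y_TH = (15.0, 30.0, 50.0)
#: partitions for area/inertia descriptors
DEFAULT_PARTITIONS = 50
#: resampling length of the current vector in composed feature vectors
CURRENT_VECTOR_LEN = 64
#: Y_th ladder of the crossing-time vector (first/last crossing per level)
CROSSING_LADDER = tuple(range(5, 100, 5))

SCALAR_FEATURES = ("I_p", "t_d", "beta_apex_15", "beta_apex_30", "beta_apex_50",
                   "theta", "A", "r_m", "I_m", "I_w")


@dataclass
class NormalizedPulse:
    """Depth-normalized pulse: ``i_norm`` has apex 1, ``t_norm`` spans [0, 1]."""

    i_norm: np.ndarray
    t_norm: np.ndarray

    def __post_init__(self) -> None:
        self.i_norm = np.asarray(self.i_norm, dtype=float)
        self.t_norm = np.asarray(self.t_norm, dtype=float)
        if self.i_norm.shape != self.t_norm.shape or self.i_norm.ndim != 1:
            raise ValueError("i_norm and t_norm must be 1-D arrays of equal length")
        if self.i_norm.size < 3:
            raise ValueError("normalized pulse needs at least three samples")
        if not np.all(np.diff(self.t_norm) > 0):
            raise ValueError("t_norm must be strictly increasing")
        if not math.isclose(float(self.i_norm.max()), 1.0, rel_tol=1e-9):
            raise ValueError("normalized pulse must have apex 1")

    @property
    def apex_index(self) -> int:
        return int(np.argmax(self.i_norm))   # earliest sample on ties

    @property
    def apex_position(self) -> float:
        """Normalized time of the apex, measured from the onset."""
        return float(self.t_norm[self.apex_index])


def normalize(pulse: DetectedPulse) -> NormalizedPulse:
    """Normalize a detected pulse: I_norm = depth/I_p, t_norm in [0, 1]."""
    if pulse.I_p <= 0:
        raise ValueError("cannot normalize a pulse of non-positive depth")
    if pulse.t_e <= pulse.t_s:
        raise ValueError("pulse endpoint must follow its onset")
    seg = np.asarray(pulse.samples, dtype=float)
    return NormalizedPulse(seg / seg.max(), np.linspace(0.0, 1.0, seg.size))


def crossing_times(np_pulse: NormalizedPulse, y_th: float,
                   convention: str = "apex") -> tuple[int, np.ndarray, float]:
    """Times at which the pulse crosses the Y_th level.

    Returns ``(m, t_i, t_ave)`` in normalized time; crossings are found
    by linear interpolation between bracketing samples.  ``convention``
    selects the level: ``"apex"`` (default) puts it Y_th percent below
    the apex (level = 1 - Y_th/100); ``"baseline"`` puts it Y_th percent
    above the baseline (level = Y_th/100).
    """
    if not (0 < y_th < 100):
        raise ValueError("y_th must lie in (0, 100)")
    if convention == "apex":
        level = 1.0 - y_th / 100.0
    elif convention == "baseline":
        level = y_th / 100.0
    else:
        raise ValueError(f"unknown level convention: {convention!r}")
    d = np_pulse.i_norm - level
    t = np_pulse.t_norm
    crossings = []
    sign_change = np.flatnonzero(d[:-1] * d[1:] < 0)
    for k in sign_change:
        frac = d[k] / (d[k] - d[k + 1])
        crossings.append(t[k] + frac * (t[k + 1] - t[k]))
    exact = np.flatnonzero(d == 0)
    for k in exact:
        # count an exact touch once; skip if part of a sign change already found
        crossings.append(float(t[k]))
    t_i = np.sort(np.array(crossings))
    if t_i.size == 0:
        raise ValueError(f"pulse never crosses the Y_th = {y_th} level")
    return int(t_i.size), t_i, float(np.mean(t_i))


def bluntness(np_pulse: NormalizedPulse, y_th: float,
              convention: str = "apex") -> float:
    """Apex bluntness beta_apex: population variance of the normalized
    crossing times at the Y_th level."""
    m, t_i, t_ave = crossing_times(np_pulse, y_th, convention)
    return float(np.mean((t_i - t_ave) ** 2))


def onset_angle(np_pulse: NormalizedPulse) -> float:
    """Onset angle theta = arctan(1/r) with r the normalized apex position.

    A symmetric pulse (r = 0.5) gives arctan(2); the apex at the very
    end (r -> 1) gives pi/4; r = 0 gives pi/2.
    """
    r = np_pulse.apex_position
    return math.atan2(1.0, r)


def areas(np_pulse: NormalizedPulse, n_partitions: int = DEFAULT_PARTITIONS
          ) -> tuple[float, float, float, float, np.ndarray]:
    """Partition-averaged pulse areas.

    The normalized time axis is split into ``n_partitions`` equal
    sections with mean height h_i each; A = sum(h_i)/n.  A_L and A_R
    split A at the apex (the partition containing the apex contributes
    proportionally), so A = A_L + A_R holds to machine precision.
    Returns ``(A, A_L, A_R, r_m, h)``.
    """
    if n_partitions < 2:
        raise ValueError("n_partitions must be >= 2")
    h = _partition_heights(np_pulse, n_partitions)
    dt = 1.0 / n_partitions
    areas_i = h * dt
    a_total = float(np.sum(areas_i))
    r = np_pulse.apex_position
    k = min(int(r / dt), n_partitions - 1)
    frac = (r - k * dt) / dt
    a_left = float(np.sum(areas_i[:k]) + frac * areas_i[k])
    a_right = a_total - a_left
    if a_right == 0:
        raise ZeroDivisionError("A_R = 0: area ratio r_m undefined")
    return a_total, a_left, a_right, a_left / a_right, h


def _partition_heights(np_pulse: NormalizedPulse, n: int) -> np.ndarray:
    """Mean I_norm over n equal t_norm sections.

    Integrates the piecewise-linear pulse exactly by merging the sample
    grid with the section boundaries, so single-sample features are not
    lost to resampling.
    """
    edges = np.linspace(0.0, 1.0, n + 1)
    grid = np.union1d(np_pulse.t_norm, edges)
    vals = np.interp(grid, np_pulse.t_norm, np_pulse.i_norm)
    seg = np.diff(grid) * (vals[:-1] + vals[1:]) / 2.0
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    F = cum[np.searchsorted(grid, edges)]
    return np.diff(F) * n


def _width_above(np_pulse: NormalizedPulse, levels: np.ndarray) -> np.ndarray:
    """Exact Lebesgue width of {t: I_norm(t) >= level} for the
    piecewise-linear pulse, vectorized over levels."""
    t, i = np_pulse.t_norm, np_pulse.i_norm
    dt = np.diff(t)
    lo = np.minimum(i[:-1], i[1:])
    hi = np.maximum(i[:-1], i[1:])
    span = hi - lo
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        frac = (hi[None, :] - levels[:, None]) / span[None, :]
    flat = span == 0
    frac[:, flat] = (hi[None, flat] >= levels[:, None]).astype(float)
    return np.clip(frac, 0.0, 1.0) @ dt


def inertia(np_pulse: NormalizedPulse, n_partitions: int = DEFAULT_PARTITIONS
            ) -> tuple[float, float]:
    """Waveform inertia about the two axes.

    I_m = sum_i t_i^2 A_lat,i over time partitions (t_i the partition
    center, A_lat,i = h_i * dt its area); I_w = sum_i h_i^2 A_long,i
    over height partitions (A_long,i the area of the horizontal band at
    height h_i: band width times the time the pulse spends above it).
    Both are non-negative.
    """
    if n_partitions < 2:
        raise ValueError("n_partitions must be >= 2")
    h = _partition_heights(np_pulse, n_partitions)
    dt = 1.0 / n_partitions
    t_centers = (np.arange(n_partitions) + 0.5) * dt
    i_m = float(np.sum(t_centers ** 2 * h * dt))

    dh = 1.0 / n_partitions
    h_centers = (np.arange(n_partitions) + 0.5) * dh
    widths = _width_above(np_pulse, h_centers)
    i_w = float(np.sum(h_centers ** 2 * widths * dh))
    return i_m, i_w


@dataclass
class FeatureRecord:
    """Scalar descriptors of one pulse plus crossing diagnostics."""

    I_p: float
    t_d: float
    beta: dict[float, float]          # Y_th -> beta_apex
    theta: float
    A: float
    A_L: float
    A_R: float
    r_m: float
    I_m: float
    I_w: float
    crossings: dict[float, dict]      # Y_th -> {m, t_i, t_ave}
    label: str = ""
    pulse_id: int = 0
    source: str = ""

    def scalar(self, name: str) -> float:
        if name.startswith("beta_apex_"):
            return self.beta[float(name.rsplit("_", 1)[1])]
        return getattr(self, name)


def compute_features(pulse: DetectedPulse, y_th_levels=DEFAULT_Y_TH,
                     n_partitions: int = DEFAULT_PARTITIONS,
                     label: str = "") -> tuple[FeatureRecord, NormalizedPulse]:
    """Compute the full descriptor set of one detected pulse."""
    np_pulse = normalize(pulse)
    beta = {}
    crossings = {}
    for y in y_th_levels:
        m, t_i, t_ave = crossing_times(np_pulse, y)
        beta[float(y)] = float(np.mean((t_i - t_ave) ** 2))
        crossings[float(y)] = {"m": m, "t_i": t_i, "t_ave": t_ave}
    a_total, a_left, a_right, r_m, _ = areas(np_pulse, n_partitions)
    i_m, i_w = inertia(np_pulse, n_partitions)
    record = FeatureRecord(
        I_p=pulse.I_p, t_d=pulse.t_d, beta=beta, theta=onset_angle(np_pulse),
        A=a_total, A_L=a_left, A_R=a_right, r_m=r_m, I_m=i_m, I_w=i_w,
        crossings=crossings, label=label, pulse_id=pulse.pulse_id,
        source=pulse.source,
    )
    return record, np_pulse


# ---------------------------------------------------------------------------
# feature-vector catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVectorSpec:
    """Composition of one named feature vector."""

    name: str
    scalar: str                       # one of SCALAR_FEATURES
    with_current: bool = False        # append resampled I_norm (len 64)
    with_crossings: bool = False      # append first/last crossing ladder
    with_diff: bool = False           # append first difference of I_norm

    @property
    def length(self) -> int:
        n = 1
        if self.with_current:
            n += CURRENT_VECTOR_LEN
        if self.with_crossings:
            n += 2 * len(CROSSING_LADDER)
        if self.with_diff:
            n += CURRENT_VECTOR_LEN - 1
        return n


#: augmentation modes pairing each scalar with the current/time vectors
_MODES = (
    ("", dict()),
    ("+curr", dict(with_current=True)),
    ("+cross", dict(with_crossings=True)),
    ("+curr+cross", dict(with_current=True, with_crossings=True)),
    ("+dcurr", dict(with_diff=True)),
    ("+curr+cross+dcurr", dict(with_current=True, with_crossings=True, with_diff=True)),
)


def default_catalog() -> list[FeatureVectorSpec]:
    """The default catalog: 10 scalar descriptors x 6 augmentation modes
    = 60 named feature vectors."""
    catalog = []
    for scalar in SCALAR_FEATURES:
        for suffix, kwargs in _MODES:
            catalog.append(FeatureVectorSpec(name=scalar + suffix, scalar=scalar,
                                             **kwargs))
    return catalog


def catalog_hash(catalog: list[FeatureVectorSpec]) -> str:
    """Stable hash identifying a catalog composition (reported with results)."""
    payload = json.dumps(
        [
            [s.name, s.scalar, s.with_current, s.with_crossings, s.with_diff]
            for s in catalog
        ]
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _resampled_current(np_pulse: NormalizedPulse, n: int = CURRENT_VECTOR_LEN
                       ) -> np.ndarray:
    grid = np.linspace(0.0, 1.0, n)
    return np.interp(grid, np_pulse.t_norm, np_pulse.i_norm)


def _crossing_vector(np_pulse: NormalizedPulse) -> np.ndarray:
    """First and last crossing time per ladder level (apex convention);
    levels never reached fall back to the apex position."""
    out = np.empty(2 * len(CROSSING_LADDER))
    r = np_pulse.apex_position
    for k, y in enumerate(CROSSING_LADDER):
        try:
            _, t_i, _ = crossing_times(np_pulse, float(y))
            out[2 * k] = t_i[0]
            out[2 * k + 1] = t_i[-1]
        except ValueError:
            out[2 * k] = out[2 * k + 1] = r
    return out


def build_feature_vectors(record: FeatureRecord, np_pulse: NormalizedPulse,
                          catalog: list[FeatureVectorSpec] | None = None
                          ) -> dict[str, np.ndarray]:
    """Assemble every catalog vector for one pulse; reproducibly ordered."""
    if catalog is None:
        catalog = default_catalog()
    current = crossings = diff = None
    out: dict[str, np.ndarray] = {}
    for spec in catalog:
        if spec.scalar not in SCALAR_FEATURES:
            raise KeyError(f"unknown scalar feature: {spec.scalar!r}")
        parts = [np.array([record.scalar(spec.scalar)])]
        if spec.with_current:
            if current is None:
                current = _resampled_current(np_pulse)
            parts.append(current)
        if spec.with_crossings:
            if crossings is None:
                crossings = _crossing_vector(np_pulse)
            parts.append(crossings)
        if spec.with_diff:
            if diff is None:
                diff = np.diff(current if current is not None
                               else _resampled_current(np_pulse))
            parts.append(diff)
        vec = np.concatenate(parts)
        assert vec.size == spec.length
        out[spec.name] = vec
    return out


def feature_matrix(records: list[tuple[FeatureRecord, NormalizedPulse]]
                   ) -> pd.DataFrame:
    """Scalar feature table (one row per pulse) with labels when known."""
    rows = []
    for record, _ in records:
        row = {"pulse_id": record.pulse_id, "label": record.label,
               "source": record.source or "-"}
        for name in SCALAR_FEATURES:
            row[name] = record.scalar(name)
        rows.append(row)
    return pd.DataFrame(rows)
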