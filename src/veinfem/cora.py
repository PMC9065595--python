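"""CORA (CORrelation and Analysis) rating of time-history curve pairs.

CORA scores the similarity of a simulated against a measured curve on a
0-1 scale by combining a corridor rating (fraction of samples inside
inner/outer corridors around the reference) with a cross-correlation
rating split into shape (correlation at the optimal time shift), phase
(size of that shift) and size (squared-area ratio) sub-ratings.  Totals
map onto ISO/TR 9790 biofidelity labels from *unacceptable* to
*excellent*.

Parameter presets are explicit, named settings objects; the
``"giordano"`` preset is the configuration commonly used for brain
displacement validation (cross-correlation only, corridor weight zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CoraSettings",
    "CurvePair",
    "CoraScore",
    "PRESETS",
    "cora_score",
    "biofidelity_label",
    "batch_score",
    "BIOFIDELITY_BINS",
]


@dataclass(frozen=True)
class CoraSettings:
    """All CORA parameters, made explicit.

    Corridor half-widths are fractions of the reference peak (a_0 inner,
    b_0 outer); the evaluation interval starts where |reference| first
    exceeds ``a_thres`` x peak and ends where it last exceeds
    ``b_thres`` x peak; allowed time shifts span ``d_min``..``d_max``
    fractions of the interval length.  Weights: total =
    w_corridor * corridor + w_cross * (w_shape * shape + w_size * size
    + w_phase * phase).
    """

    a_0: float = 0.05
    b_0: float = 0.5
    a_thres: float = 0.03
    b_thres: float = 0.075
    d_min: float = 0.01
    d_max: float = 0.12
    k_shape: float = 1.0
    k_size: float = 1.0
    k_phase: float = 1.0
    w_corridor: float = 0.5
    w_cross: float = 0.5
    w_shape: float = 0.5
    w_size: float = 0.25
    w_phase: float = 0.25


PRESETS: dict[str, CoraSettings] = {
    "default": CoraSettings(),
    # cross-correlation-only configuration used for brain displacement
    # rating (corridors need multiple repeat experiments to be defined)
    "giordano": CoraSettings(w_corridor=0.0, w_cross=1.0),
}


@dataclass
class CurvePair:
    """Reference and test curves resampled onto a common uniform base."""

    t: np.ndarray  # ms, uniform
    ref: np.ndarray  # mm
    test: np.ndarray  # mm

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ref = np.asarray(self.ref, dtype=float)
        self.test = np.asarray(self.test, dtype=float)
        if not (self.t.shape == self.ref.shape == self.test.shape):
            raise ValueError("t, ref, test must share shape")
        if self.t.size < 3:
            raise ValueError("need at least 3 samples")
        steps = np.diff(self.t)
        if np.any(steps <= 0):
            raise ValueError("time must be strictly increasing")

    @classmethod
    def from_samples(cls, t_ref, y_ref, t_test, y_test) -> "CurvePair":
        """Linear resampling to the coarser curve's uniform step over the overlap."""
        t_ref = np.asarray(t_ref, dtype=float)
        t_test = np.asarray(t_test, dtype=float)
        if np.any(np.diff(t_ref) <= 0) or np.any(np.diff(t_test) <= 0):
            raise ValueError("time bases must be strictly increasing")
        lo = max(t_ref[0], t_test[0])
        hi = min(t_ref[-1], t_test[-1])
        if hi <= lo:
            raise ValueError("curves do not overlap in time")
        step = max(np.median(np.diff(t_ref)), np.median(np.diff(t_test)))
        n = max(3, int(np.floor((hi - lo) / step)) + 1)
        t = lo + step * np.arange(n)
        t = t[t <= hi + 1e-12]
        return cls(t, np.interp(t, t_ref, y_ref), np.interp(t, t_test, y_test))


@dataclass
class CoraScore:
    corridor: float
    phase: float
    size: float
    shape: float
    total: float
    shift_ms: float = 0.0
    settings: CoraSettings = field(default_factory=CoraSettings)

    def as_dict(self) -> dict[str, float]:
        return {
            "corridor": self.corridor,
            "phase": self.phase,
            "size": self.size,
            "shape": self.shape,
            "total": self.total,
            "shift_ms": self.shift_ms,
        }


def _clip01(x: float) -> float:
    return float(min(1.0, max(0.0, x)))


def cora_score(pair: CurvePair, settings: CoraSettings | str = "giordano") -> CoraScore:
    """Rate a test curve against a reference curve.

    Raises for a reference with zero variance over the evaluation
    interval (the normalised correlation is undefined).
    """
    if isinstance(settings, str):
        settings = PRESETS[settings]
    t, ref, test = pair.t, pair.ref, pair.test
    dt = float(np.mean(np.diff(t)))
    peak = float(np.max(np.abs(ref)))
    if peak == 0 or float(np.ptp(ref)) == 0:
        raise ValueError("reference has zero variance over the interval")

    above_a = np.abs(ref) >= settings.a_thres * peak
    above_b = np.abs(ref) >= settings.b_thres * peak
    i0 = int(np.argmax(above_a))
    i1 = int(len(ref) - 1 - np.argmax(above_b[::-1]))
    if i1 - i0 < 2:
        i0, i1 = 0, len(ref) - 1
    r = ref[i0:i1 + 1]
    s = test[i0:i1 + 1]
    n = r.size
    interval = (n - 1) * dt
    if float(np.ptp(r)) == 0:
        raise ValueError("reference has zero variance over the interval")

    # corridor rating: inner +-a_0*peak scores 1, outer +-b_0*peak scores 0
    dev = np.abs(s - r)
    inner = settings.a_0 * peak
    outer = settings.b_0 * peak
    with np.errstate(invalid="ignore"):
        per_sample = np.where(
            dev <= inner, 1.0, np.where(dev >= outer, 0.0, (outer - dev) / (outer - inner))
        )
    corridor = _clip01(float(per_sample.mean()))

    # cross-correlation at integer-sample shifts within +-d_max*interval
    max_shift = int(np.floor(settings.d_max * interval / dt))
    shifts = np.arange(-max_shift, max_shift + 1)
    best_k, best_m = -np.inf, 0
    for m in shifts:
        if m >= 0:
            a, b = r[m:], s[: n - m] if m else s
        else:
            a, b = r[: n + m], s[-m:]
        if a.size < 3:
            continue
        denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
        if denom == 0:
            continue
        k = float(np.sum(a * b) / denom)
        if k > best_k + 1e-15 or (abs(k - best_k) <= 1e-15 and abs(m) < abs(best_m)):
            best_k, best_m = k, m
    if not np.isfinite(best_k):
        raise ValueError("cross-correlation undefined for this pair")

    shape = _clip01(max(0.0, best_k) ** settings.k_shape)

    delta = abs(best_m) * dt
    lo = settings.d_min * interval
    hi = settings.d_max * interval
    if delta <= lo:
        phase = 1.0
    elif delta >= hi:
        phase = 0.0
    else:
        phase = (hi - delta) / (hi - lo)
    phase = _clip01(phase**settings.k_phase)

    m = best_m
    if m >= 0:
        a, b = r[m:], s[: n - m] if m else s
    else:
        a, b = r[: n + m], s[-m:]
    area_r = float(np.sum(a * a))
    area_t = float(np.sum(b * b))
    if max(area_r, area_t) == 0:
        size = 0.0
    else:
        size = (min(area_r, area_t) / max(area_r, area_t)) ** settings.k_size
    size = _clip01(size)

    wsub = settings.w_shape + settings.w_size + settings.w_phase
    cross = (settings.w_shape * shape + settings.w_size * size + settings.w_phase * phase) / wsub
    wtot = settings.w_corridor + settings.w_cross
    total = _clip01((settings.w_corridor * corridor + settings.w_cross * cross) / wtot)
    return CoraScore(corridor, phase, size, shape, total, shift_ms=best_m * dt,
                     settings=settings)


#: ISO/TR 9790 biofidelity bins: label applies above its threshold.
BIOFIDELITY_BINS: tuple[tuple[float, str], ...] = (
    (0.86, "excellent"),
    (0.65, "good"),
    (0.44, "fair"),
    (0.26, "marginal"),
)


def biofidelity_label(total: float, bins=BIOFIDELITY_BINS) -> str:
    """Map a total CORA score onto a biofidelity label (configurable bins)."""
    if not (0 <= total <= 1):
        raise ValueError("score must lie in [0, 1]")
    for threshold, label in bins:
        if total > threshold:
            return label
    if total == 1.0:
        return bins[0][1]
    return "unacceptable"


def batch_score(
    pairs,
    group_keys: tuple[str, ...] = (),
    settings: CoraSettings | str = "giordano",
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Score many curve pairs and average totals per group.

    ``pairs`` is an iterable of ``(meta, CurvePair)`` where ``meta`` is a
    dict of grouping metadata (axis, velocity, plane...).  Returns the
    per-curve table and, if ``group_keys`` given, per-group mean ratings.
    """
    rows = []
    for meta, pair in pairs:
        try:
            score = cora_score(pair, settings)
        except ValueError as exc:
            warnings.warn(f"pair skipped: {exc}", stacklevel=2)
            continue
        rows.append({**meta, **score.as_dict()})
    table = pd.DataFrame(rows)
    if table.empty or not group_keys:
        return table, None
    means = table.groupby(list(group_keys))["total"].mean().reset_index()
    return table, means
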