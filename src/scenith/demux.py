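"""Fluorescent-barcode demultiplexing of pooled inhibitor conditions.

The four inhibitor conditions are pooled into one tube after labeling each
with two amine-reactive dyes applied at a high or a low dilution (roughly a
100-fold intensity separation).  Each dye channel therefore shows a bimodal
log-intensity distribution; the 2x2 grid of (hi, lo) levels across the two
channels encodes the condition.

The split on each channel is a deterministic two-class partition of the
log10 intensities minimizing within-class variance (the 1-D analogue of
2-means / Otsu thresholding, computed exhaustively over sorted split points —
no random initialization).  Events falling inside a guard band around either
threshold are left unassigned, mimicking the conservative cluster gates an
operator would draw by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conditions import Condition
from .errors import ConfigError, DemuxError
from .events import ChannelMap, EventTable, validate_channels

Level = str  # "hi" | "lo"

#: Default condition encoding; the dye-to-condition orientation is a
#: convention and fully user-overridable.
DEFAULT_PLAN_MAPPING: dict[tuple[Level, Level], Condition] = {
    ("hi", "hi"): Condition.CONTROL,
    ("hi", "lo"): Condition.GLUCOSE_INHIBITED,
    ("lo", "hi"): Condition.MITO_INHIBITED,
    ("lo", "lo"): Condition.DOUBLE_INHIBITED,
}


@dataclass(frozen=True)
class BarcodePlan:
    """Bijection from (level on dye A, level on dye B) to condition."""

    mapping: dict[tuple[Level, Level], Condition] = field(
        default_factory=lambda: dict(DEFAULT_PLAN_MAPPING)
    )
    expected_ratio: float = 100.0  # hi:lo intensity ratio of the two dilutions

    def __post_init__(self) -> None:
        keys = set(self.mapping)
        expected_keys = {(a, b) for a in ("hi", "lo") for b in ("hi", "lo")}
        if keys != expected_keys:
            raise ConfigError(
                f"barcode plan must map exactly the four hi/lo combinations, got {keys}"
            )
        if set(self.mapping.values()) != set(Condition):
            raise ConfigError(
                "barcode plan must be a bijection onto the four conditions, got "
                f"{[c.value for c in self.mapping.values()]}"
            )
        if self.expected_ratio <= 1:
            raise ConfigError("expected hi:lo ratio must exceed 1")


@dataclass(frozen=True)
class ThresholdFit:
    """Two-class split of one barcode channel, in log10 intensity units."""

    threshold: float  # log10 a.u., midpoint of the two class centers
    center_lo: float
    center_hi: float
    n_dropped_nonpositive: int

    @property
    def separation(self) -> float:
        return self.center_hi - self.center_lo


@dataclass
class DemuxResult:
    """Per-event condition assignment for one pooled tube."""

    labels: np.ndarray  # object array of Condition or None (unassigned)
    threshold_a: ThresholdFit
    threshold_b: ThresholdFit
    counts: dict[Condition, int]
    n_unassigned: int
    warnings: list[str] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return int(self.labels.shape[0])

    @property
    def unassigned_fraction(self) -> float:
        return self.n_unassigned / self.n_events


def fit_barcode_threshold(
    intensities: np.ndarray,
    guard: float = 0.1,
    min_events: int = 50,
) -> ThresholdFit:
    """Fit the hi/lo split of one barcode channel.

    Parameters
    ----------
    intensities
        Raw channel intensities; non-positive values are dropped (log10).
    guard
        Half-width (log10 units) of the unassigned band; the fit fails unless
        the two class centers are separated by more than ``2 * guard``.
    min_events
        Minimum positive events required *per class*, i.e. at least
        ``2 * min_events`` positive events overall.

    Returns
    -------
    ThresholdFit
        Threshold at the midpoint of the two class centers (log10 scale).
    """
    if guard < 0:
        raise ConfigError(f"guard must be >= 0, got {guard}")
    x = np.asarray(intensities, dtype=np.float64).ravel()
    positive = x[x > 0]
    n_dropped = x.size - positive.size
    if x.size and n_dropped > 0.5 * x.size:
        raise DemuxError(
            f"{n_dropped}/{x.size} barcode intensities non-positive (>50%)"
        )
    if positive.size < 2 * min_events:
        raise DemuxError(
            f"need at least {2 * min_events} positive events to fit a barcode "
            f"threshold, got {positive.size}"
        )

    logx = np.sort(np.log10(positive))
    n = logx.size
    # Exhaustive search over the n-1 split points of the sorted sample for the
    # partition minimizing total within-class variance; O(n) via prefix sums.
    csum = np.cumsum(logx)
    csq = np.cumsum(logx**2)
    k = np.arange(1, n)  # size of the low class
    total = csum[-1]
    sum_lo = csum[:-1]
    sum_hi = total - sum_lo
    ss_lo = csq[:-1] - sum_lo**2 / k
    ss_hi = (csq[-1] - csq[:-1]) - sum_hi**2 / (n - k)
    within = ss_lo + ss_hi
    best = int(np.argmin(within))
    center_lo = float(sum_lo[best] / k[best])
    center_hi = float(sum_hi[best] / (n - k[best]))
    if center_hi - center_lo <= 2 * guard:
        raise DemuxError(
            "no hi/lo structure: fitted class centers separated by "
            f"{center_hi - center_lo:.4f} log10 <= 2*guard ({2 * guard:.4f})"
        )
    threshold = 0.5 * (center_lo + center_hi)
    return ThresholdFit(
        threshold=threshold,
        center_lo=center_lo,
        center_hi=center_hi,
        n_dropped_nonpositive=int(n_dropped),
    )


def _levels(
    intensities: np.ndarray, fit: ThresholdFit, guard: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-event level ("hi" iff log10 >= threshold; tie goes to hi) and a
    validity mask (positive intensity, outside the guard band)."""
    x = np.asarray(intensities, dtype=np.float64)
    valid = x > 0
    logx = np.full(x.shape, -np.inf)
    np.log10(x, out=logx, where=valid)
    hi = logx >= fit.threshold
    # strictly inside the guard band -> unassigned; guard 0 keeps everything
    valid &= np.abs(logx - fit.threshold) >= guard
    return hi, valid


def assign_conditions(
    table: EventTable,
    cmap: ChannelMap,
    plan: BarcodePlan | None = None,
    guard: float = 0.1,
    min_events: int = 50,
    min_events_condition: int = 100,
    hard_floor: int = 25,
) -> DemuxResult:
    """Assign every event of a pooled tube to a condition (or unassigned).

    Thresholds are fitted independently on the two barcode channels; each
    event's (hi/lo, hi/lo) level pair is looked up in the plan.  Events with a
    non-positive barcode intensity or within ``guard`` log10 of either
    threshold are unassigned and excluded from all downstream MFI work.
    """
    plan = plan or BarcodePlan()
    binding = validate_channels(table, cmap)
    if binding.barcode_a is None or binding.barcode_b is None:
        raise ConfigError("channel map has no barcode channels; cannot demultiplex")
    a = table.values[:, binding.barcode_a]
    b = table.values[:, binding.barcode_b]
    fit_a = fit_barcode_threshold(a, guard=guard, min_events=min_events)
    fit_b = fit_barcode_threshold(b, guard=guard, min_events=min_events)

    hi_a, ok_a = _levels(a, fit_a, guard)
    hi_b, ok_b = _levels(b, fit_b, guard)
    assigned = ok_a & ok_b

    labels = np.full(table.n_events, None, dtype=object)
    counts: dict[Condition, int] = {}
    warnings: list[str] = []
    for (level_a, level_b), condition in plan.mapping.items():
        mask = assigned & (hi_a == (level_a == "hi")) & (hi_b == (level_b == "hi"))
        labels[mask] = condition
        counts[condition] = int(mask.sum())
    n_unassigned = int((~assigned).sum())

    for condition, count in counts.items():
        if count < hard_floor:
            raise DemuxError(
                f"condition {condition.value} received {count} events "
                f"(< hard floor {hard_floor})"
            )
        if count < min_events_condition:
            warnings.append(
                f"condition {condition.value} received only {count} events "
                f"(< {min_events_condition})"
            )
    return DemuxResult(
        labels=labels,
        threshold_a=fit_a,
        threshold_b=fit_b,
        counts=counts,
        n_unassigned=n_unassigned,
        warnings=warnings,
    )
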