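"""Geometric MFIs and the metabolic-dependence calculus.

The assay reads out protein synthesis (clicked ncAA fluorescence) under four
inhibitor conditions and converts the per-population MFIs into four
percentage metrics::

    dMFI                    = MFI(DMSO) - MFI(2DG+Oligo)
    glucose dependence      = 100 * (MFI(DMSO) - MFI(2DG))   / dMFI
    mitochondrial dependence= 100 * (MFI(DMSO) - MFI(Oligo)) / dMFI
    glycolytic capacity     = 100 - mitochondrial dependence
    FAO/AAO capacity        = 100 - glucose dependence

The MFI statistic is the geometric mean (fluorescence is approximately
log-normal); an arithmetic mean is available by configuration.  Out-of-range
values are reported raw and flagged, never silently clamped: a negative
mitochondrial dependence is a real phenomenon (MITA — oligomycin paradoxically
*increasing* translation), and clamping would hide it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .conditions import CONDITION_ORDER, Condition
from .errors import LowResolutionError, MetricError

# QC flags
FLAG_MITA = "MITA"
FLAG_NEGATIVE_GLUCOSE_DEP = "NEGATIVE_GLUCOSE_DEP"
FLAG_LOW_RESOLUTION = "LOW_RESOLUTION"
FLAG_OUT_OF_RANGE = "OUT_OF_RANGE"
FLAG_LOW_N = "LOW_N"

#: Replicate-aggregation policies.
POLICY_MEAN_FIRST = "mean_of_gmfi_before_formula"
POLICY_PROFILE_FIRST = "profile_per_replicate_then_mean"

#: Columns of the tidy MFI table.
MFI_COLUMNS = (
    "population",
    "condition",
    "replicate_id",
    "gmfi",
    "n_events",
    "n_nonpositive_dropped",
    "log_sd",
)


@dataclass(frozen=True)
class GMFIResult:
    gmfi: float
    n_events: int  # events entering the geometric mean (positive values)
    n_dropped: int  # non-positive values excluded
    log_sd: float  # SD of ln(intensity); feeds the resolution floor
    low_n: bool  # fewer events than the warn level

    @property
    def standard_error(self) -> float:
        """Delta-method SE of the geometric mean: gMFI * sd(log)/sqrt(n)."""
        return self.gmfi * self.log_sd / math.sqrt(self.n_events)


def geometric_mfi(
    values: Iterable[float],
    min_events: int = 100,
    min_events_error: int = 25,
    statistic: str = "geometric",
) -> GMFIResult:
    """Geometric (default) or arithmetic MFI of a population's intensities.

    Non-positive values cannot enter a log mean and are dropped with an
    accounting; fewer than ``min_events_error`` remaining events is an error,
    fewer than ``min_events`` sets the low-n flag.
    """
    x = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=np.float64).ravel()
    positive = x[x > 0]
    n_dropped = int(x.size - positive.size)
    if positive.size < min_events_error:
        raise MetricError(
            f"only {positive.size} positive events (< {min_events_error}); "
            "MFI would be unreliable"
        )
    logs = np.log(positive)
    if statistic == "geometric":
        gmfi = float(np.exp(logs.mean()))
    elif statistic == "arithmetic":
        gmfi = float(positive.mean())
    else:
        raise MetricError(f"unknown MFI statistic {statistic!r}")
    log_sd = float(logs.std(ddof=1)) if positive.size > 1 else 0.0
    return GMFIResult(
        gmfi=gmfi,
        n_events=int(positive.size),
        n_dropped=n_dropped,
        log_sd=log_sd,
        low_n=positive.size < min_events,
    )


@dataclass(frozen=True)
class DependenceProfile:
    """The four dependence metrics for one population/sample, unclamped."""

    glucose_dependence: float  # %
    mitochondrial_dependence: float  # %
    glycolytic_capacity: float  # %
    faoaao_capacity: float  # %
    delta_mfi: float  # a.u., MFI(DMSO) - MFI(2DG+Oligo)
    flags: frozenset[str] = frozenset()

    def clamped(self) -> "DependenceProfile":
        """Reporting-layer convenience: metrics clamped to [0, 100].

        The complement identities are preserved by clamping the dependences
        and recomputing the capacities.
        """
        g = min(max(self.glucose_dependence, 0.0), 100.0)
        m = min(max(self.mitochondrial_dependence, 0.0), 100.0)
        return DependenceProfile(
            glucose_dependence=g,
            mitochondrial_dependence=m,
            glycolytic_capacity=100.0 - m,
            faoaao_capacity=100.0 - g,
            delta_mfi=self.delta_mfi,
            flags=self.flags,
        )


def dependence_profile(
    mfi_dmso: float,
    mfi_2dg: float,
    mfi_oligo: float,
    mfi_both: float,
    resolution_floor: float | None = None,
    extra_flags: Iterable[str] = (),
) -> DependenceProfile:
    """Compute the four dependence metrics from the four condition MFIs.

    Parameters
    ----------
    mfi_dmso, mfi_2dg, mfi_oligo, mfi_both
        (Geometric) MFIs under control, 2-DG, oligomycin and double inhibition.
    resolution_floor
        Optional absolute floor (a.u.) on the dynamic range ``dMFI``; below it
        the LOW_RESOLUTION flag is set.  The pipeline defaults this to 3x the
        pooled within-condition gMFI standard error.

    Raises
    ------
    LowResolutionError
        If ``dMFI <= 0``: the formulas' shared denominator vanishes, the
        profile is undefined, and we report rather than divide.
    """
    delta = mfi_dmso - mfi_both
    if delta <= 0:
        raise LowResolutionError(
            f"undefined profile: dMFI = MFI(DMSO) - MFI(2DG+Oligo) = {delta:g} <= 0"
        )
    glucose = 100.0 * (mfi_dmso - mfi_2dg) / delta
    mito = 100.0 * (mfi_dmso - mfi_oligo) / delta
    flags = set(extra_flags)
    if mito < 0:
        flags.add(FLAG_MITA)
    if glucose < 0:
        flags.add(FLAG_NEGATIVE_GLUCOSE_DEP)
    if resolution_floor is not None and delta < resolution_floor:
        flags.add(FLAG_LOW_RESOLUTION)
    metrics = (glucose, mito, 100.0 - mito, 100.0 - glucose)
    if any(v < 0 or v > 100 for v in metrics):
        flags.add(FLAG_OUT_OF_RANGE)
    return DependenceProfile(
        glucose_dependence=glucose,
        mitochondrial_dependence=mito,
        glycolytic_capacity=100.0 - mito,
        faoaao_capacity=100.0 - glucose,
        delta_mfi=delta,
        flags=frozenset(flags),
    )


@dataclass(frozen=True)
class FoldChangeRecord:
    population: str
    stimulation: str
    fold_change: float


def fold_change(
    mfi_stimulated: float,
    mfi_medium: float,
    population: str = "",
    stimulation: str = "",
) -> FoldChangeRecord:
    """Fold change of ncAA incorporation vs the unstimulated (Medium) control.

    Both MFIs are taken from the uninhibited (DMSO) condition, within donor;
    averaging across donors happens downstream.
    """
    if not (mfi_stimulated > 0 and mfi_medium > 0):
        raise MetricError(
            f"fold change needs positive MFIs, got "
            f"({mfi_stimulated:g}, {mfi_medium:g})"
        )
    return FoldChangeRecord(
        population=population,
        stimulation=stimulation,
        fold_change=mfi_stimulated / mfi_medium,
    )


def seahorse_glycolytic_capacity(
    ecar_basal: float, ecar_oligo: float
) -> tuple[float, list[str]]:
    """Extracellular-flux glycolytic capacity: oligomycin ECAR minus basal ECAR.

    Units mpH/min.  A negative capacity is physiologically suspect and is
    returned with a warning flag rather than an error.
    """
    if not (math.isfinite(ecar_basal) and math.isfinite(ecar_oligo)):
        raise MetricError("ECAR inputs must be finite")
    capacity = ecar_oligo - ecar_basal
    warnings = ["NEGATIVE_CAPACITY"] if capacity < 0 else []
    return capacity, warnings


def _pooled_se(group: pd.DataFrame) -> float:
    """Pooled gMFI standard error across the four conditions (delta method)."""
    ses = group["gmfi"] * group["log_sd"] / np.sqrt(group["n_events"])
    return float(np.sqrt(np.mean(ses**2)))


def aggregate_replicates(
    mfi_table: pd.DataFrame,
    policy: str = POLICY_MEAN_FIRST,
    resolution_floor: float | None = None,
    auto_floor_factor: float = 3.0,
) -> pd.DataFrame:
    """Collapse an MFI table into one dependence profile per population.

    ``mfi_table`` is tidy with columns population, condition, replicate_id,
    gmfi, n_events, n_nonpositive_dropped and (optionally) log_sd; conditions
    are the serialized labels.  Two policies:

    * ``mean_of_gmfi_before_formula`` (default): average replicate gMFIs per
      condition, then evaluate the formulas once.  Ratios of averaged
      differences are less noisy than averaged ratios.
    * ``profile_per_replicate_then_mean``: one profile per replicate id
      present in all four conditions, then average the metrics.

    When ``resolution_floor`` is None and log_sd is available, the floor
    defaults to ``auto_floor_factor`` x the pooled within-condition gMFI
    standard error of the population.
    """
    if policy not in (POLICY_MEAN_FIRST, POLICY_PROFILE_FIRST):
        raise MetricError(f"unknown aggregation policy {policy!r}")
    required = {"population", "condition", "gmfi"}
    if not required.issubset(mfi_table.columns):
        raise MetricError(f"MFI table must have columns {sorted(required)}")
    table = mfi_table.copy()
    table["condition"] = table["condition"].map(
        lambda c: c.value if isinstance(c, Condition) else str(c)
    )
    condition_labels = [c.value for c in CONDITION_ORDER]

    rows = []
    for population, group in table.groupby("population", sort=True):
        present = set(group["condition"])
        missing = [c for c in condition_labels if c not in present]
        if missing:
            raise LowResolutionError(
                f"population {population!r}: undefined profile, missing "
                f"condition(s) {missing}"
            )
        floor = resolution_floor
        if floor is None and {"log_sd", "n_events"}.issubset(group.columns):
            floor = auto_floor_factor * _pooled_se(group)
        extra = {FLAG_LOW_N} if bool(group.get("low_n", pd.Series(dtype=bool)).any()) else set()

        if policy == POLICY_MEAN_FIRST:
            means = group.groupby("condition")["gmfi"].mean()
            profile = dependence_profile(
                means[condition_labels[0]],
                means[condition_labels[1]],
                means[condition_labels[2]],
                means[condition_labels[3]],
                resolution_floor=floor,
                extra_flags=extra,
            )
        else:
            per_rep = group.pivot_table(
                index="replicate_id", columns="condition", values="gmfi"
            ).dropna()
            if per_rep.empty:
                raise MetricError(
                    f"population {population!r}: no replicate present in all "
                    "four conditions"
                )
            profiles = [
                dependence_profile(
                    rep[condition_labels[0]],
                    rep[condition_labels[1]],
                    rep[condition_labels[2]],
                    rep[condition_labels[3]],
                    resolution_floor=floor,
                    extra_flags=extra,
                )
                for _, rep in per_rep.iterrows()
            ]
            glucose = float(np.mean([p.glucose_dependence for p in profiles]))
            mito = float(np.mean([p.mitochondrial_dependence for p in profiles]))
            profile = DependenceProfile(
                glucose_dependence=glucose,
                mitochondrial_dependence=mito,
                glycolytic_capacity=100.0 - mito,
                faoaao_capacity=100.0 - glucose,
                delta_mfi=float(np.mean([p.delta_mfi for p in profiles])),
                flags=frozenset().union(*[p.flags for p in profiles]),
            )
        rows.append(
            {
                "population": population,
                "glucose_dependence": profile.glucose_dependence,
                "mitochondrial_dependence": profile.mitochondrial_dependence,
                "glycolytic_capacity": profile.glycolytic_capacity,
                "faoaao_capacity": profile.faoaao_capacity,
                "delta_mfi": profile.delta_mfi,
                "flags": ";".join(sorted(profile.flags)),
            }
        )
    return pd.DataFrame(rows)


def mfi_table_from_events(
    intensities_by_group: dict[tuple[str, str, str], np.ndarray],
    min_events: int = 100,
    min_events_error: int = 25,
    statistic: str = "geometric",
) -> pd.DataFrame:
    """Build a tidy MFI table from per-(population, condition, replicate)
    intensity vectors.  Keys are (population, condition label, replicate_id)."""
    rows = []
    for (population, condition, replicate_id), values in sorted(
        intensities_by_group.items()
    ):
        try:
            res = geometric_mfi(
                values,
                min_events=min_events,
                min_events_error=min_events_error,
                statistic=statistic,
            )
        except MetricError as err:
            raise MetricError(
                f"population {population!r}, condition {condition!r}, "
                f"replicate {replicate_id!r}: {err}"
            ) from err
        rows.append(
            {
                "population": population,
                "condition": condition,
                "replicate_id": replicate_id,
                "gmfi": res.gmfi,
                "n_events": res.n_events,
                "n_nonpositive_dropped": res.n_dropped,
                "log_sd": res.log_sd,
                "low_n": res.low_n,
            }
        )
    return pd.DataFrame(rows, columns=list(MFI_COLUMNS) + ["low_n"])
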