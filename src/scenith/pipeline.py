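"""End-to-end run orchestration: events in, tidy result tables out.

``run_pipeline`` wires the stages — read, demultiplex (pooled runs), gate,
quantify, profile, multivariate summary — and writes::

    mfi_table.csv     one row per sample x population x condition x replicate
    profiles.csv      one row per sample x population with the four metrics
    stats.csv         vs-control tests when the donor design supports them
    pca_scores.csv    sample scores (when >= 2 complete samples)
    pca_loadings.csv  feature loadings
    report.json       seed, versions, per-table event accounting, QC flags

Everything is deterministic given config + inputs + seed.  Outputs are
written only after every stage succeeded, so a failing run leaves no partial
results behind.
"""

from __future__ import annotations

import json
import platform
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conditions import Condition
from .config import RunConfig
from .demux import assign_conditions
from .errors import ConfigError, LowResolutionError, ScenithError
from .events import EventTable, read_event_table, validate_channels
from .gating import UNGATED, apply_gates
from .metrics import (
    FLAG_LOW_RESOLUTION,
    aggregate_replicates,
    mfi_table_from_events,
)
from .stats import build_profile_matrix, compare_to_control, pca_profiles

PROFILE_METRICS = (
    "glucose_dependence",
    "mitochondrial_dependence",
    "glycolytic_capacity",
    "faoaao_capacity",
    "delta_mfi",
)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, ScenithError):
                raise type(exc)(f"[stage {name}] {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    tables: list[EventTable] | None = None,
) -> dict:
    """Run the full pipeline and write result tables to ``outdir``.

    ``tables`` may be passed directly (e.g. fresh simulator output); otherwise
    the files named in ``config.inputs`` are read.  Returns the report dict.
    """
    outdir = Path(outdir)
    cmap = config.channels.to_channel_map()
    gates = config.gate_list()

    if tables is None:
        with _stage("read"):
            if not config.inputs.files:
                raise ConfigError("no input files configured and no tables passed")
            tables = []
            for entry in config.inputs.files:
                table = read_event_table(entry.path, entry.format)
                for key in ("condition", "sample_id", "donor_id", "tissue",
                            "stimulation", "replicate_id"):
                    override = getattr(entry, key)
                    if override is not None:
                        table.meta[key] = override
                tables.append(table)

    if config.inputs.pooled:
        if config.barcode is None or cmap.barcode_a is None:
            raise ConfigError(
                "pooled inputs need barcode channels and a barcode plan"
            )
        with _stage("config"):
            plan = config.barcode.to_plan()

    mfi_groups: dict[str, dict[tuple[str, str, str], list[np.ndarray]]] = (
        defaultdict(lambda: defaultdict(list))
    )
    sample_meta: dict[str, dict[str, str]] = {}
    accounting = []
    demux_warnings: list[str] = []
    gate_warnings: list[str] = []

    for i, table in enumerate(tables):
        with _stage("validate"):
            binding = validate_channels(table, cmap)
        sample_id = table.meta.get("sample_id", f"sample{i + 1}")
        replicate_id = table.meta.get("replicate_id", "r1")
        sample_meta.setdefault(
            sample_id,
            {
                "sample_id": sample_id,
                "donor_id": table.meta.get("donor_id", sample_id),
                "tissue": table.meta.get("tissue", ""),
                "stimulation": table.meta.get("stimulation", "Medium"),
            },
        )

        if config.inputs.pooled:
            with _stage("demux"):
                demux = assign_conditions(
                    table,
                    cmap,
                    plan,
                    guard=config.barcode.guard,
                    min_events=config.barcode.min_events,
                    min_events_condition=config.barcode.min_events_condition,
                    hard_floor=config.barcode.hard_floor,
                )
            conditions = demux.labels
            n_unassigned = demux.n_unassigned
            demux_warnings += [f"{sample_id}: {w}" for w in demux.warnings]
        else:
            with _stage("demux"):
                label = table.meta.get("condition")
                if label is None:
                    raise ConfigError(
                        f"table {i} ({sample_id}): unpooled input without a "
                        "condition label (set it in the file metadata or config)"
                    )
                condition = Condition.from_label(label)
            conditions = np.full(table.n_events, condition, dtype=object)
            n_unassigned = 0

        with _stage("gate"):
            if gates:
                gated = apply_gates(table, cmap, gates)
                pops = gated.labels
                gate_warnings += [f"{sample_id}: {w}" for w in gated.warnings]
            else:
                pops = np.full(table.n_events, "all", dtype=object)

        ncaa = table.values[:, binding.ncaa_signal]
        usable = np.array(
            [c is not None for c in conditions], dtype=bool
        ) & (pops != UNGATED)
        n_dropped_ungated = int(
            ((pops == UNGATED) & np.array([c is not None for c in conditions])).sum()
        )
        for pop in np.unique(pops[usable]):
            mask = usable & (pops == pop)
            for cond in Condition:
                sel = mask & (conditions == cond)
                if sel.any():
                    mfi_groups[sample_id][(str(pop), cond.value, replicate_id)].append(
                        ncaa[sel]
                    )
        accounting.append(
            {
                "table": i,
                "sample_id": sample_id,
                "read": table.n_events,
                "assigned": int(table.n_events - n_unassigned - n_dropped_ungated),
                "unassigned": int(n_unassigned),
                "dropped_ungated": n_dropped_ungated,
            }
        )

    with _stage("mfi"):
        mfi_frames = []
        for sample_id, groups in sorted(mfi_groups.items()):
            flat = {
                key: np.concatenate(chunks) for key, chunks in groups.items()
            }
            frame = mfi_table_from_events(
                flat,
                min_events=config.metrics.min_events,
                min_events_error=config.metrics.min_events_error,
                statistic=config.metrics.statistic,
            )
            frame.insert(0, "sample_id", sample_id)
            mfi_frames.append(frame)
        if not mfi_frames:
            raise ConfigError("no usable events in any input")
        mfi_table = pd.concat(mfi_frames, ignore_index=True)

    with _stage("profile"):
        profile_rows = []
        for sample_id, frame in mfi_table.groupby("sample_id"):
            for population, group in frame.groupby("population"):
                base = {
                    **sample_meta[sample_id],
                    "population": population,
                }
                try:
                    prof = aggregate_replicates(
                        group,
                        policy=config.metrics.aggregation,
                        resolution_floor=config.metrics.resolution_floor,
                        auto_floor_factor=config.metrics.auto_floor_factor,
                    ).iloc[0]
                except LowResolutionError as err:
                    # dynamic range collapsed for this population only: keep
                    # the run alive, report an undefined profile
                    profile_rows.append(
                        {
                            **base,
                            **{m: np.nan for m in PROFILE_METRICS},
                            "flags": FLAG_LOW_RESOLUTION,
                            "note": str(err),
                        }
                    )
                    continue
                row = {**base, **{m: prof[m] for m in PROFILE_METRICS},
                       "flags": prof["flags"], "note": ""}
                if config.metrics.clamp:
                    g = float(np.clip(row["glucose_dependence"], 0, 100))
                    m = float(np.clip(row["mitochondrial_dependence"], 0, 100))
                    row.update(
                        glucose_dependence=g,
                        mitochondrial_dependence=m,
                        glycolytic_capacity=100 - m,
                        faoaao_capacity=100 - g,
                    )
                profile_rows.append(row)
        profiles = pd.DataFrame(profile_rows)

    pca_result = None
    stats_frame = None
    with _stage("stats"):
        usable_profiles = profiles[profiles["note"] == ""]
        if config.stats.pca and usable_profiles["sample_id"].nunique() >= 2:
            matrix = build_profile_matrix(usable_profiles)
            try:
                pca_result = pca_profiles(
                    matrix,
                    n_components=config.stats.n_components,
                    scale=config.stats.scale,
                )
            except ScenithError:
                pca_result = None  # e.g. all features constant on tiny runs
        if config.stats.compare_stimulations:
            stim = usable_profiles.drop_duplicates(["sample_id"])[
                ["sample_id", "donor_id", "stimulation"]
            ]
            levels = set(stim["stimulation"])
            if (
                config.stats.control in levels
                and len(levels) >= 2
                and stim.groupby("stimulation")["donor_id"].nunique().min() >= 3
            ):
                frames = []
                for (population, metric) in [
                    (p, m)
                    for p in sorted(usable_profiles["population"].unique())
                    for m in ("glucose_dependence", "mitochondrial_dependence")
                ]:
                    sub = usable_profiles[
                        usable_profiles["population"] == population
                    ][["donor_id", "stimulation", metric]]
                    try:
                        res = compare_to_control(
                            sub.rename(columns={metric: "value"}),
                            control=config.stats.control,
                            group="stimulation",
                            donor="donor_id",
                            n_mc=config.stats.n_mc,
                            seed=config.seed,
                        )
                    except ScenithError:
                        continue
                    res.insert(0, "metric", metric)
                    res.insert(0, "population", population)
                    frames.append(res)
                if frames:
                    stats_frame = pd.concat(frames, ignore_index=True)

    report = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "pooled": config.inputs.pooled,
        "n_tables": len(tables),
        "event_accounting": accounting,
        "demux_warnings": demux_warnings,
        "gate_warnings": gate_warnings,
        "profile_flags": {
            f"{r['sample_id']}/{r['population']}": r["flags"]
            for r in profile_rows
            if r["flags"]
        },
        "pca": None
        if pca_result is None
        else {
            "explained_variance_fraction": [
                float(v) for v in pca_result.explained_variance_fraction
            ],
            "dropped_samples": list(pca_result.dropped_samples),
            "dropped_features": list(pca_result.dropped_features),
        },
    }

    # all stages succeeded: write everything
    outdir.mkdir(parents=True, exist_ok=True)
    mfi_table.to_csv(outdir / "mfi_table.csv", index=False)
    profiles.to_csv(outdir / "profiles.csv", index=False)
    if stats_frame is not None:
        stats_frame.to_csv(outdir / "stats.csv", index=False)
    if pca_result is not None:
        pca_result.scores.rename_axis("sample_id").to_csv(outdir / "pca_scores.csv")
        pca_result.loadings.rename_axis("feature").to_csv(
            outdir / "pca_loadings.csv"
        )
    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
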