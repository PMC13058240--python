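"""Wiring of the analysis stages into reproducible, logged runs.

``analyze_experiment`` is the in-memory composition gate -> threshold ->
classify -> analyze; ``run_pipeline`` adds file I/O around it, driven by a
plain-text manifest (``RunConfig``), and stamps every output with the
software version and a hash of the resolved configuration so a run can be
reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import Trajectory, aggregate_trends, carrying_capacity, fit_frequency_trend
from .errors import ValidationError
from .events_io import (
    CultureKind,
    EventTable,
    ODSeries,
    PlateSeries,
    SampleMeta,
    read_event_table,
    read_od_series,
    read_plate_counts,
)
from .frequency import (
    classify_events,
    correlate_methods,
    estimate_frequency,
    plate_frequency,
)
from .gating import (
    DEFAULT_AREA_GATE,
    DEFAULT_CELL_GATE,
    PolygonGate,
    RangeGate,
    gate_cells,
    load_gates,
)
from .thresholding import build_roc, select_threshold

__all__ = ["RunConfig", "load_run_config", "analyze_experiment", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated run description parsed from a manifest file."""

    root: Path
    focal: str
    event_entries: list  # (Path, SampleMeta)
    plate_entries: list = field(default_factory=list)
    od_entries: list = field(default_factory=list)
    column_map: dict = field(default_factory=dict)
    polygon: PolygonGate = None
    area: RangeGate = None
    criterion: str = "closest_topleft"
    mode: str = "general"
    out_dir: Optional[Path] = None
    raw: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_run_config(path, out_dir=None) -> RunConfig:
    """Parse and validate a manifest; referenced files must exist."""
    path = Path(path)
    root = path.parent
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "events" not in doc:
        raise ValidationError(f"manifest {path} must define an 'events' list")

    def entries(section):
        out = []
        for item in doc.get(section) or []:
            p = root / item["path"]
            if not p.exists():
                raise ValidationError(f"manifest references missing file: {p}")
            out.append((p, SampleMeta(**item["meta"])))
        return out

    gate_doc = doc.get("gate") or {}
    polygon = DEFAULT_CELL_GATE
    if isinstance(gate_doc.get("polygon"), list):
        polygon = PolygonGate(vertices=np.asarray(gate_doc["polygon"], float), name="manifest")
    elif gate_doc.get("polygon") not in (None, "default"):
        gates_file = gate_doc.get("file")
        if gates_file is None:
            raise ValidationError("named gate requires a 'file' entry in the gate section")
        polygon = load_gates(root / gates_file)[gate_doc["polygon"]]
    area = DEFAULT_AREA_GATE
    if gate_doc.get("area") is not None:
        low, high = gate_doc["area"]
        area = RangeGate(low=float(low), high=float(high))

    thr = doc.get("threshold") or {}
    return RunConfig(
        root=root,
        focal=doc.get("focal") or doc.get("competitors", ["A"])[0],
        event_entries=entries("events"),
        plate_entries=entries("plates"),
        od_entries=entries("od"),
        column_map=doc.get("column_map")
        or {k: k for k in ("event_id", "intensity_dye", "intensity_auto", "area", "true_label")},
        polygon=polygon,
        area=area,
        criterion=thr.get("criterion", "closest_topleft"),
        mode=thr.get("mode", "general"),
        out_dir=Path(out_dir) if out_dir else None,
        raw=doc,
    )


def derive_thresholds(
    monocultures: Sequence[EventTable],
    criterion: str = "closest_topleft",
) -> dict:
    """Per-stained-competitor general thresholds from gated monocultures.

    For each competitor X with stained monocultures, intensities are pooled
    over time and compared against the pooled unstained monocultures of its
    coculture partner (every other competitor present).
    """
    stained: dict = {}
    unstained: dict = {}
    for t in monocultures:
        comp = t.meta.competitor_a
        if t.meta.culture_kind is CultureKind.MONOCULTURE_STAINED:
            stained.setdefault(comp, []).append(t.intensity_dye)
        elif t.meta.culture_kind is CultureKind.MONOCULTURE_UNSTAINED:
            unstained.setdefault(comp, []).append(t.intensity_dye)
    if not stained:
        raise ValidationError("no stained monocultures available for thresholding")
    reports: dict = {}
    for comp, chunks in stained.items():
        partners = [c for c in unstained if c != comp] or list(unstained)
        if not partners:
            raise ValidationError(f"no unstained control available for competitor {comp!r}")
        control = np.concatenate([np.concatenate(unstained[p]) for p in partners])
        roc = build_roc(np.concatenate(chunks), control)
        reports[comp] = select_threshold(roc, criterion)
    return reports


def analyze_experiment(
    monocultures: Sequence[EventTable],
    cocultures: Sequence[EventTable],
    plate_series: Sequence[PlateSeries] = (),
    od_series: Sequence[ODSeries] = (),
    focal: Optional[str] = None,
    criterion: str = "closest_topleft",
    polygon: PolygonGate = None,
    area: RangeGate = None,
) -> dict:
    """Run gate -> threshold -> classify -> analyze on in-memory tables.

    Returns a report dict with the per-competitor threshold reports, the
    per-sample frequency table (stained fraction and focal-competitor
    frequency with Wilson CIs), per-replicate and per-condition trends,
    carrying capacities, and the fluorescence-versus-plate correlation when
    plate series are supplied.
    """
    gated_monos = [gate_cells(t, polygon, area) for t in monocultures]
    gated_cocs = [gate_cells(t, polygon, area) for t in cocultures]
    thresholds = derive_thresholds(gated_monos, criterion)

    if focal is None:
        focal = gated_cocs[0].meta.competitor_a if gated_cocs else next(iter(thresholds))

    freq_rows = []
    for t in gated_cocs:
        meta = t.meta
        stained_comp = meta.stained_competitor
        if stained_comp not in thresholds:
            raise ValidationError(
                f"no threshold for stained competitor {stained_comp!r} in {meta.sample_id}"
            )
        n_st, n_un = classify_events(t, thresholds[stained_comp].threshold)
        est = estimate_frequency(n_st, n_st + n_un, meta=meta)
        f_focal = est.freq_stained if stained_comp == focal else 1.0 - est.freq_stained
        freq_rows.append(
            {
                "sample_id": meta.sample_id,
                "initial_ratio": meta.initial_ratio,
                "stained_competitor": stained_comp,
                "predator_present": meta.predator_present,
                "replicate": meta.replicate,
                "time_h": meta.time_h,
                "n_gated": est.n_gated,
                "n_stained": est.n_stained,
                "freq_stained": est.freq_stained,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "freq_focal": f_focal,
            }
        )
    frequencies = pd.DataFrame(freq_rows)

    trends = []
    condition_trends = pd.DataFrame()
    if not frequencies.empty:
        grouped: dict = {}
        for (ratio, stained_comp, predator, rep), grp in frequencies.groupby(
            ["initial_ratio", "stained_competitor", "predator_present", "replicate"],
            dropna=False,
        ):
            grp = grp.sort_values("time_h")
            if len(grp) < 2:
                logger.warning("skipping single-point trajectory for replicate %s", rep)
                continue
            n_focal = np.where(
                stained_comp == focal,
                grp["n_stained"].to_numpy(float),
                grp["n_gated"].to_numpy(float) - grp["n_stained"].to_numpy(float),
            )
            traj = Trajectory(
                condition=(ratio, stained_comp, predator),
                replicate=int(rep),
                time_h=grp["time_h"].to_numpy(float),
                freq=grp["freq_focal"].to_numpy(float),
                n_focal=n_focal,
                n_total=grp["n_gated"].to_numpy(float),
            )
            est = fit_frequency_trend(traj)
            trends.append(est)
            grouped.setdefault(traj.condition, []).append(est)
        if grouped:
            condition_trends = aggregate_trends(grouped, statistic="s_logit")

    report: dict = {
        "focal": focal,
        "thresholds": thresholds,
        "frequencies": frequencies,
        "replicate_trends": trends,
        "condition_trends": condition_trends,
        "gating": [t.provenance[-1] for t in gated_monos + gated_cocs if t.provenance],
    }

    if plate_series:
        by_id = {row["sample_id"]: row for row in freq_rows}
        pairs = []
        plate_rows = []
        for series in plate_series:
            est = plate_frequency(series, focal)
            sid = series.meta.sample_id if series.meta else ""
            plate_rows.append(
                {
                    "sample_id": sid,
                    "valid": est.valid,
                    "freq_focal_plate": est.freq_stained,
                    "n_colonies": est.n_gated,
                }
            )
            if est.valid and sid in by_id:
                pairs.append((by_id[sid]["freq_focal"], est.freq_stained))
        report["plate_frequencies"] = pd.DataFrame(plate_rows)
        if len(pairs) >= 3:
            report["method_correlation"] = correlate_methods(pairs)

    if od_series:
        per_culture, per_condition = carrying_capacity(od_series)
        report["carrying_capacity"] = per_culture
        report["carrying_capacity_by_condition"] = per_condition

    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline described by a run configuration.

    Reads every referenced file, runs :func:`analyze_experiment`, and — when
    ``out_dir`` is set — writes the frequency table, trend tables, threshold
    reports and a structured ``run.json`` log (software version, config
    hash, gating counts, plate-rule decisions) into it.
    """
    events = [
        read_event_table(p, config.column_map, meta) for p, meta in config.event_entries
    ]
    monocultures = [t for t in events if t.meta.culture_kind is not CultureKind.COCULTURE]
    cocultures = [t for t in events if t.meta.culture_kind is CultureKind.COCULTURE]
    plates = [read_plate_counts(p, meta) for p, meta in config.plate_entries]
    ods = [read_od_series(p, meta) for p, meta in config.od_entries]

    report = analyze_experiment(
        monocultures,
        cocultures,
        plate_series=plates,
        od_series=ods,
        focal=config.focal,
        criterion=config.criterion,
        polygon=config.polygon,
        area=config.area,
    )
    report["version"] = __version__
    report["config_hash"] = config.config_hash()

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stamp = {"version": __version__, "config_hash": report["config_hash"]}
        report["frequencies"].to_csv(out / "frequencies.csv", index=False)
        if len(report["condition_trends"]):
            report["condition_trends"].to_csv(out / "condition_trends.csv", index=False)
        if "plate_frequencies" in report:
            report["plate_frequencies"].to_csv(out / "plate_frequencies.csv", index=False)
        if "carrying_capacity" in report:
            report["carrying_capacity"].to_csv(out / "carrying_capacity.csv", index=False)
        log = {
            **stamp,
            "thresholds": {k: v.to_dict() for k, v in report["thresholds"].items()},
            "n_event_tables": len(events),
            "n_frequency_rows": len(report["frequencies"]),
            "gating": report["gating"],
        }
        if "method_correlation" in report:
            log["method_correlation"] = report["method_correlation"].to_dict()
        with open(out / "run.json", "w", encoding="utf-8") as fh:
            json.dump(log, fh, indent=2, default=str)
    return report
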