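"""Synthetic competition-assay data with ground-truth labels.

The generator emulates the statistical structure the assay rests on:

* Stained cells carry a log-normally distributed dye load that halves with
  every cell division — per cell, dye = LogNormal(stain_log_mean,
  stain_log_sd) * 2**(-(g + eps)) with g the generations elapsed and a
  per-cell jitter eps ~ Normal(0, dilution_noise_sd) standing in for
  asynchronous division. An independent autofluorescence draw adds on the
  linear scale (detector counts are additive).
* Unstained cells show only log-normal autofluorescence, with a per-
  competitor additive shift of the log-mean for inter-competitor
  differences.
* Coculture frequencies follow discrete selection,
  f_g = w^g f0 / (w^g f0 + (1 - f0)), optionally modulated by per-interval
  predation survival multipliers; logit(f_g) - logit(f0) = g ln(w) exactly.
* Colony counts are Poisson draws around density * 10^(-dilution) *
  plated-volume equivalent, split binomially between the two morphotypes;
  OD curves are logistic growth plus normal measurement noise.

The default configuration is the ``paperlike`` preset: 2000 events per
sample, six 2-h time points over 10 h, cocultures at initial ratios
0.1/0.5/0.9 for both staining assignments, with and without predation, in
triplicate, with ~0.8 generations per 2-h interval. Intensity parameters
are chosen so that the t = 0 stained and unstained distributions overlap
slightly — the regime where the choice of threshold actually matters — and
are synthetic, not fitted to any instrument.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .events_io import (
    CultureKind,
    EventTable,
    ODSeries,
    PlateSeries,
    SampleMeta,
    write_event_table,
    write_od_series,
    write_plate_counts,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "paperlike_config",
    "simulate_intensities",
    "propagate_frequency",
    "logistic_od",
    "simulate_experiment",
    "write_dataset",
]

#: Serial-dilution series of the default plating design (log10 factors).
DEFAULT_DILUTION_EXPONENTS = (3.79, 4.50, 5.19, 5.89, 6.59, 7.29)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic competition experiment.

    Intensities are in arbitrary detector units on the natural-log scale;
    ``dilution_noise_sd`` is in generations; ``relative_fitness_w`` is the
    per-generation fitness of competitor A relative to B;
    ``predator_mortality`` maps competitors to per-interval survival
    multipliers applied when a predator is present;
    ``plated_volume_equivalent`` is the expected colony count of an undiluted
    plate.
    """

    seed: int = 0
    competitor_a: str = "A"
    competitor_b: str = "B"
    n_events_per_sample: int = 2000
    time_points_h: tuple = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    generations_per_interval: Mapping[str, float] = None  # default set in __post_init__
    stain_log_mean: float = 12.7
    stain_log_sd: float = 1.4
    dilution_noise_sd: float = 0.25
    autofluor_log_mean: float = 3.9
    autofluor_log_sd: float = 1.0
    autofluor_offset: Mapping[str, float] = None
    relative_fitness_w: float = 0.85
    initial_ratios: tuple = (0.1, 0.5, 0.9)
    predator_levels: tuple = (False, True)
    predator_mortality: Optional[Mapping[str, float]] = None
    n_replicates: int = 3
    ch2_log_mean: float = 5.0
    ch2_log_sd: float = 0.8
    area_log_mean: float = 3.0
    area_log_sd: float = 0.35
    od0: float = 0.01
    od_growth_rate: float = 1.2
    od_capacity: float = 0.42
    od_capacity_ratio_slope: float = 0.08
    od_noise_sd: float = 0.005
    plate_dilution_exponents: tuple = DEFAULT_DILUTION_EXPONENTS
    plated_volume_equivalent: float = 2.0e7

    def __post_init__(self) -> None:
        if self.generations_per_interval is None:
            self.generations_per_interval = {self.competitor_a: 0.8, self.competitor_b: 0.8}
        elif not isinstance(self.generations_per_interval, Mapping):
            g = float(self.generations_per_interval)
            self.generations_per_interval = {self.competitor_a: g, self.competitor_b: g}
        if self.autofluor_offset is None:
            self.autofluor_offset = {self.competitor_a: 0.0, self.competitor_b: 0.4}
        if self.predator_mortality is None:
            self.predator_mortality = {self.competitor_a: 0.9, self.competitor_b: 0.75}
        self.validate()

    def validate(self) -> None:
        if self.n_events_per_sample < 1:
            raise ValidationError("n_events_per_sample must be >= 1")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        for sd in (
            self.stain_log_sd, self.dilution_noise_sd, self.autofluor_log_sd,
            self.ch2_log_sd, self.area_log_sd, self.od_noise_sd,
        ):
            if sd < 0:
                raise ValidationError("standard deviations must be >= 0")
        if self.relative_fitness_w <= 0:
            raise ValidationError("relative_fitness_w must be > 0")
        if any(not 0.0 < r < 1.0 for r in self.initial_ratios):
            raise ValidationError("initial_ratios must lie in (0, 1)")
        if any(g < 0 for g in self.generations_per_interval.values()):
            raise ValidationError("generations_per_interval must be >= 0")
        if any(not 0 < s <= 1 for s in self.predator_mortality.values()):
            raise ValidationError("predator_mortality multipliers must lie in (0, 1]")
        if len(self.time_points_h) < 1 or any(np.diff(self.time_points_h) <= 0):
            raise ValidationError("time_points_h must be non-empty and strictly increasing")

    @property
    def competitors(self) -> tuple:
        return (self.competitor_a, self.competitor_b)


def paperlike_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The named preset mirroring the published assay design."""
    return SimulationConfig(seed=seed, **overrides)


@dataclass
class SimulatedDataset:
    """Ground-truth-labelled synthetic experiment."""

    config: SimulationConfig
    monocultures: list  # EventTable
    cocultures: list  # EventTable
    plate_series: list  # PlateSeries
    od_series: list  # ODSeries
    truth: pd.DataFrame


def simulate_intensities(
    kind: str,
    generations_elapsed: float,
    n: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    competitor: Optional[str] = None,
) -> np.ndarray:
    """Draw dye-channel intensities for ``n`` cells of one class.

    Stained cells: log-normal initial dye load halved once per elapsed
    generation (with per-cell generation jitter) plus an additive
    autofluorescence draw. Unstained cells: autofluorescence only.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    offset = config.autofluor_offset.get(competitor, 0.0) if competitor else 0.0
    auto = rng.lognormal(config.autofluor_log_mean + offset, config.autofluor_log_sd, n)
    if kind == "unstained":
        return auto
    if kind != "stained":
        raise ValidationError(f"kind must be 'stained' or 'unstained', got {kind!r}")
    eps = rng.normal(0.0, config.dilution_noise_sd, n) if config.dilution_noise_sd else 0.0
    dye = rng.lognormal(config.stain_log_mean, config.stain_log_sd, n)
    dye *= np.exp2(-(generations_elapsed + eps))
    return dye + auto


def propagate_frequency(f0: float, w: float, generations: float) -> float:
    """Discrete selection: f_g = w^g f0 / (w^g f0 + (1 - f0)).

    ``w`` is the focal type's per-generation relative fitness. The identity
    logit(f_g) = logit(f0) + g ln(w) makes logit trajectories exactly linear.
    """
    if not 0.0 < f0 < 1.0:
        raise ValidationError("f0 must lie in (0, 1)")
    if w <= 0:
        raise ValidationError("w must be > 0")
    wg = w**generations
    return wg * f0 / (wg * f0 + (1.0 - f0))


def _apply_survival(f: float, survival_focal: float, survival_other: float) -> float:
    num = survival_focal * f
    return num / (num + survival_other * (1.0 - f))


def logistic_od(t: np.ndarray, od0: float, r: float, capacity: float) -> np.ndarray:
    """Logistic growth curve OD(t) with intrinsic rate r and plateau K."""
    t = np.asarray(t, float)
    e = np.exp(r * t)
    return capacity * od0 * e / (capacity + od0 * (e - 1.0))


def _event_frame(
    dye: np.ndarray,
    labels: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = dye.size
    ch2 = rng.lognormal(config.ch2_log_mean, config.ch2_log_sd, n)
    area = rng.lognormal(config.area_log_mean, config.area_log_sd, n)
    perm = rng.permutation(n)
    return pd.DataFrame(
        {
            "event_id": np.arange(n, dtype=np.int64),
            "intensity_dye": dye[perm],
            "intensity_auto": ch2[perm],
            "area": area[perm],
            "true_label": labels[perm],
        }
    )


def simulate_experiment(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full synthetic experiment, deterministic given the seed.

    Emits stained and unstained monoculture event tables for both
    competitors at every time point, coculture event tables for every
    (ratio, staining assignment, predator level, replicate, time point)
    cell of the design, a dilution plate series per coculture sample, one OD
    series per culture, and a ground-truth table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    a, b = config.competitors
    n = config.n_events_per_sample
    times = list(config.time_points_h)

    monocultures: list = []
    for comp in (a, b):
        for stained in (True, False):
            for i, t in enumerate(times):
                g = config.generations_per_interval[comp] * i
                kind = "stained" if stained else "unstained"
                dye = simulate_intensities(kind, g, n, config, rng, competitor=comp)
                meta = SampleMeta(
                    sample_id=f"mono_{comp}_{kind}_t{t:g}",
                    culture_kind=(
                        CultureKind.MONOCULTURE_STAINED
                        if stained
                        else CultureKind.MONOCULTURE_UNSTAINED
                    ),
                    competitor_a=comp,
                    stained_competitor=comp if stained else None,
                    time_h=t,
                )
                labels = np.full(n, kind)
                monocultures.append(
                    EventTable(meta=meta, events=_event_frame(dye, labels, config, rng))
                )

    cocultures: list = []
    plate_series: list = []
    od_series: list = []
    truth_rows: list = []

    for ratio in config.initial_ratios:
        for stained_comp in (a, b):
            for predator in config.predator_levels:
                for rep in range(1, config.n_replicates + 1):
                    culture = f"co_r{ratio:g}_s{stained_comp}_p{int(predator)}_rep{rep}"
                    # frequency of focal competitor A propagated interval by interval
                    f = ratio
                    freqs_a = [f]
                    for _ in times[1:]:
                        f = propagate_frequency(
                            f, config.relative_fitness_w,
                            config.generations_per_interval[a],
                        )
                        if predator:
                            f = _apply_survival(
                                f,
                                config.predator_mortality[a],
                                config.predator_mortality[b],
                            )
                        freqs_a.append(f)
                    for i, t in enumerate(times):
                        f_a = freqs_a[i]
                        f_stained = f_a if stained_comp == a else 1.0 - f_a
                        g_stained = config.generations_per_interval[stained_comp] * i
                        n_st = int(rng.binomial(n, f_stained))
                        dye = np.empty(n)
                        unstained_comp = b if stained_comp == a else a
                        if n_st > 0:
                            dye[:n_st] = simulate_intensities(
                                "stained", g_stained, n_st, config, rng,
                                competitor=stained_comp,
                            )
                        if n - n_st > 0:
                            dye[n_st:] = simulate_intensities(
                                "unstained", 0.0, n - n_st, config, rng,
                                competitor=unstained_comp,
                            )
                        labels = np.array(["stained"] * n_st + ["unstained"] * (n - n_st))
                        meta = SampleMeta(
                            sample_id=f"{culture}_t{t:g}",
                            culture_kind=CultureKind.COCULTURE,
                            competitor_a=a,
                            competitor_b=b,
                            stained_competitor=stained_comp,
                            initial_ratio=ratio,
                            predator_present=predator,
                            replicate=rep,
                            time_h=t,
                        )
                        cocultures.append(
                            EventTable(meta=meta, events=_event_frame(dye, labels, config, rng))
                        )
                        # plate counts: Poisson totals thinned binomially
                        dil = np.asarray(config.plate_dilution_exponents, float)
                        expected = config.plated_volume_equivalent * 10.0 ** (-dil)
                        tot = rng.poisson(expected)
                        focal_counts = rng.binomial(tot, f_a)
                        plate_series.append(
                            PlateSeries(
                                meta=meta,
                                plates=pd.DataFrame(
                                    {
                                        "dilution_exponent": dil,
                                        a: focal_counts.astype(np.int64),
                                        b: (tot - focal_counts).astype(np.int64),
                                    }
                                ),
                            )
                        )
                        truth_rows.append(
                            {
                                "sample_id": meta.sample_id,
                                "initial_ratio": ratio,
                                "stained_competitor": stained_comp,
                                "predator_present": predator,
                                "replicate": rep,
                                "time_h": t,
                                "generations": g_stained,
                                "freq_focal_true": f_a,
                                "freq_stained_true": f_stained,
                                "n_stained_realized": n_st,
                                "freq_stained_realized": n_st / n,
                            }
                        )
                    # one OD series per culture
                    capacity = config.od_capacity + config.od_capacity_ratio_slope * (1.0 - ratio)
                    od = logistic_od(np.asarray(times), config.od0, config.od_growth_rate, capacity)
                    od = np.maximum(od + rng.normal(0.0, config.od_noise_sd, od.size), 0.0)
                    od_meta = SampleMeta(
                        sample_id=culture,
                        culture_kind=CultureKind.COCULTURE,
                        competitor_a=a,
                        competitor_b=b,
                        stained_competitor=stained_comp,
                        initial_ratio=ratio,
                        predator_present=predator,
                        replicate=rep,
                    )
                    od_series.append(
                        ODSeries(
                            meta=od_meta,
                            points=pd.DataFrame({"time_h": times, "od600": od}),
                        )
                    )

    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(
        config=config,
        monocultures=monocultures,
        cocultures=cocultures,
        plate_series=plate_series,
        od_series=od_series,
        truth=truth,
    )


def write_dataset(dataset: SimulatedDataset, outdir) -> Path:
    """Write a simulated dataset in the package's on-disk formats.

    Produces ``events/``, ``plates/`` and ``od/`` directories of delimited
    text, ``truth.csv`` and a ``manifest.yaml`` that the pipeline consumes.
    Returns the manifest path. Identical seeds give byte-identical trees.
    """
    out = Path(outdir)
    (out / "events").mkdir(parents=True, exist_ok=True)
    (out / "plates").mkdir(exist_ok=True)
    (out / "od").mkdir(exist_ok=True)
    manifest: dict = {
        "competitors": list(dataset.config.competitors),
        "focal": dataset.config.competitor_a,
        "column_map": {
            "event_id": "event_id",
            "intensity_dye": "intensity_dye",
            "intensity_auto": "intensity_auto",
            "area": "area",
            "true_label": "true_label",
        },
        "gate": {"polygon": "default", "area": [2.0, 150.0]},
        "threshold": {"criterion": "closest_topleft", "mode": "general"},
        "events": [],
        "plates": [],
        "od": [],
    }
    for table in dataset.monocultures + dataset.cocultures:
        rel = f"events/{table.meta.sample_id}.csv"
        write_event_table(table, out / rel)
        manifest["events"].append({"path": rel, "meta": table.meta.to_dict()})
    for series in dataset.plate_series:
        rel = f"plates/{series.meta.sample_id}.csv"
        write_plate_counts(series, out / rel)
        manifest["plates"].append({"path": rel, "meta": series.meta.to_dict()})
    for series in dataset.od_series:
        rel = f"od/{series.meta.sample_id}.csv"
        write_od_series(series, out / rel)
        manifest["od"].append({"path": rel, "meta": series.meta.to_dict()})
    dataset.truth.to_csv(out / "truth.csv", index=False)
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path
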