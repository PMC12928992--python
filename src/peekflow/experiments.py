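"""End-to-end experiment presets: device comparison, inter-laboratory
comparison, and the accuracy/precision grid.

Each experiment draws a population of PEEK tubing specimens whose true
conductances follow the published per-colour/per-laboratory reference
distributions, characterizes them by simulated water displacement (the
reference route), then simulates the configured grid of flow-meter
measurements and summarises them with the agreement/precision/accuracy
statistics.  A single integer seed makes the whole bundle reproducible; each
stream gets a deterministic child seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as pkstats
from .conductance import QCThresholds, measure, measurements_to_frame
from .reference import TubingSpec, build_reference_interval, displacement_resistance
from .rig import (
    CircuitConfig,
    FaultSpec,
    SensorSpec,
    simulate_displacement_series,
    simulate_measurement,
)
from .tables import load_reference_table

log = logging.getLogger("peekflow")

EXPERIMENTS = ("device_comparison", "interlab", "accuracy_grid")

#: reservoir heights exercised by the validation campaign (cm)
DEFAULT_HEIGHTS_CM = (10.0, 15.0, 25.0, 45.0)


class ConfigError(ValueError):
    """Invalid experiment configuration (raised before any simulation)."""


@dataclass
class ExperimentConfig:
    """One experiment run: grid, replication, sensor model and thresholds."""

    experiment: str = "accuracy_grid"
    labs: tuple = ("DRF", "UQAM")
    devices: dict = field(default_factory=lambda: {
        "DRF": ["X1", "X2", "X3"], "UQAM": ["U1", "U2"],
    })
    colors: tuple = ("yellow", "blue", "orange")
    heights_cm: tuple = DEFAULT_HEIGHTS_CM
    replicates: int = 5
    n_sample_ids: int = 4
    seed: int = 0
    backpressure_kpa: float = 0.2
    duration_s: float = 600.0
    sample_rate_hz: float = 1.0
    temperature_c: float = 25.0
    relative_accuracy: float = 0.0025
    noise_sd_kpa: float = 0.005
    displacement_volume_noise: float = 0.01
    n_ref_determinations: int = 3
    faults: list = field(default_factory=list)
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ConfigError(f"unknown experiment {self.experiment!r}")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if not self.labs:
            raise ConfigError("at least one lab required")
        for lab in self.labs:
            if lab not in self.devices or not self.devices[lab]:
                raise ConfigError(f"no devices configured for lab {lab!r}")
        if any(h <= 0 for h in self.heights_cm):
            raise ConfigError("heights must be positive")

    def sensor(self) -> SensorSpec:
        return SensorSpec(
            relative_accuracy=self.relative_accuracy,
            noise_sd_kpa=self.noise_sd_kpa,
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        try:
            faults = [FaultSpec(**f) for f in raw.pop("faults", [])]
            cfg = cls(**raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        cfg.faults = faults
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["thresholds"].pop("k_max_by_color", None)
        d.pop("thresholds")
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def child_seed(root_seed: int, *key: int) -> int:
    """Deterministic child seed (< 2^31) for one simulated stream."""
    ss = np.random.SeedSequence([int(root_seed), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2**31))


def device_comparison_config(seed: int = 0, replicates: int = 15) -> ExperimentConfig:
    """Three devices, one blue tubing pair, 25 cm, one laboratory."""
    return ExperimentConfig(
        experiment="device_comparison",
        labs=("DRF",),
        devices={"DRF": ["X1", "X2", "X3"]},
        colors=("blue",),
        heights_cm=(25.0,),
        replicates=replicates,
        n_sample_ids=1,
        seed=seed,
    )


def interlab_config(seed: int = 0, replicates: int = 5) -> ExperimentConfig:
    """Two labs, three colours, heights 10/25/45 cm, two pairs per colour."""
    return ExperimentConfig(
        experiment="interlab",
        labs=("DRF", "UQAM"),
        devices={"DRF": ["X1"], "UQAM": ["U1"]},
        colors=("yellow", "blue", "orange"),
        heights_cm=(10.0, 25.0, 45.0),
        replicates=replicates,
        n_sample_ids=2,
        seed=seed,
    )


def accuracy_grid_config(seed: int = 0, replicates: int = 5,
                         n_sample_ids: int = 4) -> ExperimentConfig:
    """Full grid: colours x devices x heights, 15 cm measured only at DRF."""
    return ExperimentConfig(
        experiment="accuracy_grid",
        labs=("DRF", "UQAM"),
        devices={"DRF": ["X1", "X2", "X3"], "UQAM": ["U1", "U2"]},
        colors=("yellow", "blue", "orange"),
        heights_cm=DEFAULT_HEIGHTS_CM,
        replicates=replicates,
        n_sample_ids=n_sample_ids,
        seed=seed,
    )


def _draw_tubing(config: ExperimentConfig, lab: str, color: str, tag: str,
                 index: int, ref_row: pd.Series) -> TubingSpec:
    """One specimen: true conductance from the published colour/lab
    distribution, reference resistance from simulated water displacement."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 101, hash_id(lab), hash_id(color),
                                hash_id(tag), index])
    )
    mean = float(ref_row["mean"])
    sd = float(ref_row["cv_pct"]) / 100.0 * mean
    k_true = float(np.clip(rng.normal(mean, sd),
                           float(ref_row["min"]), float(ref_row["max"])))
    r_true = 1.0 / k_true
    k_reps = []
    for rep in range(config.n_ref_determinations):
        series = simulate_displacement_series(
            r_true=r_true,
            temperature_c=config.temperature_c,
            seed=child_seed(config.seed, 102, hash_id(lab), hash_id(color),
                            hash_id(tag), index, rep),
            volume_noise_rel=config.displacement_volume_noise,
        )
        k_reps.append(displacement_resistance(series)["k_ref"])
    spec = TubingSpec(
        tubing_id=f"{tag}{index + 1}", color=color, lab=lab,
        r_ref=1.0 / float(np.mean(k_reps)), n_ref=len(k_reps),
    )
    spec.k_true = k_true  # underlying truth, kept for closed-loop diagnostics
    spec.k_ref_reps = k_reps
    return spec


def hash_id(s: str) -> int:
    """Stable small integer from a label (for seed derivation)."""
    return sum(ord(c) * (i + 1) for i, c in enumerate(str(s))) % 9973


def build_population(config: ExperimentConfig) -> dict:
    """Tubing specimens per (lab, color): internal tubing per device plus
    sample specimens, each with displacement-measured reference values."""
    table = load_reference_table().set_index(["color", "lab"])
    pop = {}
    for lab in config.labs:
        for color in config.colors:
            row = table.loc[(color, lab)]
            internals = {
                dev: _draw_tubing(config, lab, color, f"int_{dev}_", i, row)
                for i, dev in enumerate(config.devices[lab])
            }
            samples = [
                _draw_tubing(config, lab, color, "s", i, row)
                for i in range(config.n_sample_ids)
            ]
            pop[(lab, color)] = {"internal": internals, "samples": samples}
    return pop


def _heights_for(config: ExperimentConfig, lab: str):
    # the 15 cm rung was exercised in one laboratory only
    if config.experiment == "accuracy_grid" and lab != "DRF":
        return [h for h in config.heights_cm if h != 15.0]
    return config.heights_cm


def run_experiment(config: ExperimentConfig, out=None) -> dict:
    """Run one experiment; returns {"measurements", "summaries", "log"}.

    ``measurements`` is a tidy DataFrame (one row per determination with QC
    provenance), ``summaries`` a dict of DataFrames produced by the stats
    module, ``log`` the QC rejection log.  With ``out`` set, everything is
    also written as CSV/JSON under that directory.
    """
    pop = build_population(config)
    sensor = config.sensor()
    measurements = []
    rejections = []
    idx = 0
    for lab in config.labs:
        for device in config.devices[lab]:
            for color in config.colors:
                group = pop[(lab, color)]
                internal = group["internal"][device]
                for sample in group["samples"]:
                    for height in _heights_for(config, lab):
                        for rep in range(config.replicates):
                            idx += 1
                            cfg = CircuitConfig(
                                height_cm=height,
                                r_tubing=1.0 / internal.k_true,
                                r_sample=1.0 / sample.k_true,
                                backpressure_kpa=config.backpressure_kpa,
                                temperature_c=config.temperature_c,
                                duration_s=config.duration_s,
                                sample_rate_hz=config.sample_rate_hz,
                            )
                            stream, phase = simulate_measurement(
                                cfg, sensor, sensor, config.faults,
                                seed=child_seed(config.seed, 7, idx),
                                meta={
                                    "device": device, "lab": lab,
                                    "tubing_internal": internal.tubing_id,
                                    "tubing_sample": sample.tubing_id,
                                    "height_cm": height,
                                    "k_ref": sample.k_ref,
                                    "k_true": sample.k_true,
                                },
                            )
                            m = measure(
                                stream, phase, r_tubing=internal.r_ref,
                                thresholds=config.thresholds,
                                color=color, lab=lab,
                            )
                            measurements.append(m)
                            if not m.valid:
                                entry = (
                                    f"rejected lab={lab} device={device} "
                                    f"color={color} sample={sample.tubing_id} "
                                    f"h={height} rep={rep}: "
                                    f"{','.join(sorted(m.qc_flags))}"
                                )
                                rejections.append(entry)
                                log.info(entry)
    frame = measurements_to_frame(measurements)
    summaries = summarize(config, frame, pop)
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "measurements.csv", index=False)
        for name, df in summaries.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "run_log.json").write_text(json.dumps(
            {"config": {"experiment": config.experiment, "seed": config.seed},
             "rejections": rejections}, indent=1))
    return {"measurements": frame, "summaries": summaries, "log": rejections,
            "population": pop}


def summarize(config: ExperimentConfig, frame: pd.DataFrame, pop: dict) -> dict:
    """Experiment-appropriate summary tables, from valid measurements only."""
    valid = frame[frame["valid"]]
    out = {}
    if config.experiment == "device_comparison":
        rows, pair_rows = [], []
        groups = {
            dev: g["K25"].to_numpy()
            for dev, g in valid.groupby("device", sort=True)
        }
        for dev, values in groups.items():
            k_ref = valid.loc[valid["device"] == dev, "K_ref"].iloc[0]
            prec = pkstats.precision_summary(values)
            rows.append({
                "device": dev, "n": prec.n, "mean": float(np.mean(values)),
                "relative_bias_pct": pkstats.relative_bias(values, k_ref),
                "cv_pct": prec.cv_pct, "range_5_95": prec.range_5_95,
                "stderr": prec.stderr,
            })
        devs = sorted(groups)
        for i, a in enumerate(devs):
            for b in devs[i + 1:]:
                agr = pkstats.compare_groups(groups[a], groups[b])
                pair_rows.append({"pair": f"{a}-{b}",
                                  **dataclasses.asdict(agr)})
        out["by_device"] = pd.DataFrame(rows)
        out["pairwise"] = pd.DataFrame(pair_rows)
    elif config.experiment == "interlab":
        rows = []
        for (color, height), g in valid.groupby(["color", "height_cm"],
                                                sort=True):
            by_lab = {lab: lg["K25"].to_numpy()
                      for lab, lg in g.groupby("lab")}
            if len(by_lab) < 2:
                continue
            a, b = (by_lab[lab] for lab in sorted(by_lab))
            row = {"color": color, "height_cm": height,
                   "n_a": len(a), "n_b": len(b),
                   "mean_diff_pct": pkstats.mean_difference_pct(a, b)}
            if min(len(a), len(b)) >= 5:
                ks = pkstats.ks_two_sample(a, b)
                row.update(ks_stat=ks["statistic"], ks_p=ks["p"])
            for lab, v in by_lab.items():
                if len(v) >= 3:
                    row[f"cv_pct_{lab}"] = pkstats.precision_summary(v).cv_pct
            rows.append(row)
        out["by_color_height"] = pd.DataFrame(rows)
    else:  # accuracy_grid
        prec_rows, acc_rows = [], []
        for (lab, color, height), g in valid.groupby(
                ["lab", "color", "height_cm"], sort=True):
            if len(g) < 3:
                continue
            prec = pkstats.precision_summary(g["K25"].to_numpy())
            prec_rows.append({
                "lab": lab, "color": color, "height_cm": height, "n": prec.n,
                "range_5_95": prec.range_5_95, "stderr": prec.stderr,
                "cv_pct": prec.cv_pct,
            })
        for (lab, color), g in valid.groupby(["lab", "color"], sort=True):
            # full range spans every individual reference determination of
            # every specimen, the conservative band the campaign used
            refs = [k for s in pop[(lab, color)]["samples"]
                    for k in s.k_ref_reps]
            interval = build_reference_interval(refs, color, lab)
            acc = pkstats.accuracy_summary(g, interval)
            acc_rows.append({
                "lab": lab, "color": color, "n": len(g),
                "inclusion_rate_pct": acc.inclusion_rate_pct,
                "outlier_rate_pct": acc.outlier_rate_pct,
                "weighted_bias_pct": acc.weighted_bias_pct,
            })
        out["precision"] = pd.DataFrame(prec_rows)
        out["accuracy"] = pd.DataFrame(acc_rows)
    return out


def validate_dataset(measurements) -> dict:
    """Rejection report for a measurement table (DataFrame or CSV path).

    Returns totals, the overall rejection rate in percent, per-flag counts,
    and a list of malformed rows (listed, not fatal).
    """
    if not isinstance(measurements, pd.DataFrame):
        measurements = pd.read_csv(measurements)
    required = {"K25", "valid", "flags"}
    missing = required - set(measurements.columns)
    if missing:
        raise ConfigError(f"measurement table missing columns: {sorted(missing)}")
    malformed = measurements.index[measurements["K25"].isna()].tolist()
    ok = measurements.drop(index=malformed)
    total = len(ok)
    rejected = ok[~ok["valid"].astype(bool)]
    by_reason: dict[str, int] = {}
    for flags in rejected["flags"].fillna(""):
        for flag in str(flags).split(";"):
            if flag:
                by_reason[flag] = by_reason.get(flag, 0) + 1
    return {
        "total": total,
        "rejected": int(len(rejected)),
        "rejection_rate_pct": 100.0 * len(rejected) / total if total else 0.0,
        "by_reason": by_reason,
        "malformed_rows": malformed,
    }
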