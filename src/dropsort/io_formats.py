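"""Readers/writers, configuration round-tripping, and fixture generation.

Formats are deliberately plain: frame streams as CSV with the wavelength
grid in the header (``time_s, I_450.0, ...``), droplet ground truth as
JSONL (one record per line, streaming-friendly), events as CSV, and all
configuration as YAML with unknown keys rejected.  Floats are written with
``repr`` so a write/read round trip is value-exact.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import sorter_physics, stream_sim
from .controller import PulseSettings, TimingModel
from .sigproc import DropletEvent, Gate, SpectralStream
from .stream_sim import DetectorModel, DropletRecord, SimConfig

__all__ = [
    "FrameFormatError",
    "read_frames",
    "write_frames",
    "read_truth",
    "write_truth",
    "write_events",
    "read_gate",
    "write_gate",
    "RunConfig",
    "make_fixture",
    "FIXTURE_NAMES",
]


class FrameFormatError(ValueError):
    """Malformed frame CSV; the message names the offending row."""


def write_frames(stream: SpectralStream, path) -> None:
    """Write a frame stream as CSV: header declares the wavelength grid."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["time_s"] + [f"I_{w}" for w in stream.wavelengths])
        for t, row in zip(stream.times, stream.intensities):
            writer.writerow([repr(float(t))] + [repr(float(v)) for v in row])


def read_frames(path) -> SpectralStream:
    """Read a frame CSV back into a stream; errors carry the row number."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FrameFormatError(f"{path}: empty file, missing header") from None
        if not header or header[0] != "time_s":
            raise FrameFormatError(f"{path}: header must start with 'time_s'")
        try:
            grid = np.array([float(c[2:]) for c in header[1:]], dtype=float)
        except ValueError:
            raise FrameFormatError(f"{path}: malformed wavelength header") from None
        times, rows = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != grid.size + 1:
                raise FrameFormatError(
                    f"{path}: row {lineno} has {len(row)} fields, "
                    f"expected {grid.size + 1}"
                )
            try:
                values = [float(v) for v in row]
            except ValueError:
                raise FrameFormatError(
                    f"{path}: row {lineno} contains a non-numeric cell"
                ) from None
            times.append(values[0])
            rows.append(values[1:])
    intensities = (
        np.array(rows, dtype=float) if rows else np.empty((0, grid.size))
    )
    return SpectralStream(
        times=np.array(times, dtype=float), intensities=intensities, wavelengths=grid
    )


def write_truth(train: Sequence[DropletRecord], path) -> None:
    """Ground-truth droplet records as JSONL, one record per line."""
    with Path(path).open("w") as fh:
        for rec in train:
            d = dataclasses.asdict(rec)
            fh.write(json.dumps(d) + "\n")


def read_truth(path) -> list[DropletRecord]:
    train = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line:
                train.append(DropletRecord(**json.loads(line)))
    return train


def write_events(events: Sequence[DropletEvent], path) -> None:
    """Detected events as CSV with the standard column set."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["event_id", "start_s", "end_s", "wavelength_nm",
             "intensity_rfu", "prominence_rfu", "gated"]
        )
        for i, ev in enumerate(events):
            writer.writerow([
                i, repr(ev.start_time), repr(ev.end_time),
                repr(ev.peak.wavelength), repr(ev.peak.intensity),
                repr(ev.peak.prominence), int(ev.gated),
            ])


def write_gate(gate: Gate, path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(
            {
                "wavelength_min": gate.wavelength_min,
                "wavelength_max": gate.wavelength_max,
                "intensity_min": gate.intensity_min,
                "intensity_max": (
                    None if np.isinf(gate.intensity_max) else gate.intensity_max
                ),
                "noise_level": gate.noise_level,
            },
            fh, sort_keys=False,
        )


def read_gate(path) -> Gate:
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    _reject_unknown(raw, {"wavelength_min", "wavelength_max", "intensity_min",
                          "intensity_max", "noise_level"}, "gate")
    if raw.get("intensity_max") is None:
        raw["intensity_max"] = float("inf")
    return Gate(**raw)


def _reject_unknown(raw: dict, allowed: set[str], what: str) -> None:
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown {what} keys: {sorted(unknown)}")


@dataclasses.dataclass
class RunConfig:
    """Merged run configuration: simulator, detector, timing, pulse, seed.

    Round-trips losslessly through YAML; unknown keys are rejected so a
    typo in a config file fails loudly instead of silently using a
    default.
    """

    sim: SimConfig
    detector: DetectorModel = dataclasses.field(default_factory=DetectorModel)
    timing: TimingModel = dataclasses.field(default_factory=TimingModel)
    pulse: PulseSettings = dataclasses.field(default_factory=PulseSettings)
    sort_voltage: float = 40.0
    sort_flow: float = 60.0
    seed: int = 0

    def to_yaml(self, path) -> None:
        det = dataclasses.asdict(self.detector)
        det["wavelength_grid"] = [float(w) for w in det["wavelength_grid"]]
        det["dark_spectrum"] = [float(v) for v in det["dark_spectrum"]]
        sim = dataclasses.asdict(self.sim)
        sim["media"] = self.sim.media.value
        sim["substrate"] = self.sim.substrate.value
        payload = {
            "sim": sim,
            "detector": det,
            "timing": dataclasses.asdict(self.timing),
            "pulse": dataclasses.asdict(self.pulse),
            "sort_voltage": self.sort_voltage,
            "sort_flow": self.sort_flow,
            "seed": self.seed,
        }
        with Path(path).open("w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        _reject_unknown(
            raw, {"sim", "detector", "timing", "pulse", "sort_voltage",
                  "sort_flow", "seed"}, "run-config",
        )
        sim_raw = dict(raw.get("sim", {}))
        _reject_unknown(
            sim_raw, {f.name for f in dataclasses.fields(SimConfig)}, "sim"
        )
        det_raw = dict(raw.get("detector", {}))
        _reject_unknown(
            det_raw, {f.name for f in dataclasses.fields(DetectorModel)}, "detector"
        )
        timing_raw = dict(raw.get("timing", {}))
        _reject_unknown(
            timing_raw, {f.name for f in dataclasses.fields(TimingModel)}, "timing"
        )
        pulse_raw = dict(raw.get("pulse", {}))
        _reject_unknown(
            pulse_raw, {f.name for f in dataclasses.fields(PulseSettings)}, "pulse"
        )
        return cls(
            sim=SimConfig(**sim_raw),
            detector=DetectorModel(**det_raw),
            timing=TimingModel(**timing_raw),
            pulse=PulseSettings(**pulse_raw),
            sort_voltage=float(raw.get("sort_voltage", 40.0)),
            sort_flow=float(raw.get("sort_flow", 60.0)),
            seed=int(raw.get("seed", 0)),
        )


FIXTURE_NAMES = (
    "calibration_5_50uM",
    "mixed_pos_neg",
    "mutant_library",
    "efficiency_grid",
)


def make_fixture(name: str, outdir, seed: int = 0) -> list[Path]:
    """Generate a named, seeded test fixture on disk; returns the paths.

    * ``calibration_5_50uM`` — two frame streams of fluorescein standard
      droplets (5 uM and 50 uM, 500 droplets each) for gate calibration;
      their peak histograms separate cleanly at default noise.
    * ``mixed_pos_neg`` — one stream of 5 uM positives mixed 1:9 with
      0 uM (dye-only) negatives, plus its JSONL ground truth.
    * ``mutant_library`` — a right-skewed single-spore library stream
      after incubation, plus ground truth.
    * ``efficiency_grid`` — the 7 x 20 x (N = 10) sorter characterisation
      table as CSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    detector = DetectorModel()
    written: list[Path] = []
    if name == "calibration_5_50uM":
        for conc in (5.0, 50.0):
            train = stream_sim.generate_calibration_train(
                n_droplets=500, droplet_rate=2.0, positive_conc_uM=conc,
                positive_fraction=1.0, seed=seed,
            )
            stream = stream_sim.synthesize_stream(
                train, detector, droplet_rate=2.0, seed=seed + int(conc)
            )
            p = outdir / f"calibration_{int(conc)}uM.csv"
            write_frames(stream, p)
            written.append(p)
    elif name == "mixed_pos_neg":
        train = stream_sim.generate_calibration_train(
            n_droplets=500, droplet_rate=2.0, positive_conc_uM=5.0,
            positive_fraction=0.1, seed=seed,
        )
        stream = stream_sim.synthesize_stream(
            train, detector, droplet_rate=2.0, seed=seed
        )
        p1, p2 = outdir / "mixed_frames.csv", outdir / "mixed_truth.jsonl"
        write_frames(stream, p1)
        write_truth(train, p2)
        written += [p1, p2]
    elif name == "mutant_library":
        cfg = SimConfig(
            session_length=120.0, droplet_rate=2.0, incubation_time=96.0,
            seed=seed,
        )
        train = stream_sim.generate_droplet_train(cfg)
        stream = stream_sim.synthesize_stream(
            train, detector, droplet_rate=cfg.droplet_rate, seed=seed
        )
        p1, p2 = outdir / "library_frames.csv", outdir / "library_truth.jsonl"
        write_frames(stream, p1)
        write_truth(train, p2)
        written += [p1, p2]
    elif name == "efficiency_grid":
        grid = sorter_physics.efficiency_grid(rng=seed)
        p = outdir / "efficiency_grid.csv"
        grid.to_csv(p, index=False)
        written.append(p)
    else:
        raise ValueError(
            f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
        )
    return written
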