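"""Reading and writing gait-lab signals and AMAP artifacts.

The interchange convention is a wide CSV (one column per channel) plus a
JSON sidecar that declares everything the CSV cannot: sampling rate,
channel-to-muscle map, which belt carries which leg, subject id. All
internal time is seconds; sample ``i`` covers the half-open interval
``[i/rate, (i+1)/rate)``, so recordings sampled at different rates (EMG at
2000 Hz, forces at 1000 Hz, say) coexist without resampling.

Report CSVs are written with shortest round-trip float repr so that
``read_report(write_report(x)) == x`` bit-exactly.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError

__all__ = [
    "EmgRecording",
    "GrfRecording",
    "read_trial",
    "write_trial",
    "write_report",
    "read_report",
    "write_components",
    "read_components",
]

VALID_LEGS = ("left", "right", "paretic", "nonparetic")


@dataclass
class EmgRecording:
    """Multi-channel surface EMG for one leg.

    Parameters
    ----------
    signals : (n_channels, n_samples) float array
        Raw EMG in volts or arbitrary units.
    rate_hz : float
        Sampling frequency, > 0.
    channel_names : sequence of str
        Ordered muscle labels, unique, one per channel.
    leg : str
        One of ``left|right|paretic|nonparetic``.
    subject_id : str
        Opaque identifier.
    """

    signals: np.ndarray
    rate_hz: float
    channel_names: tuple[str, ...]
    leg: str = "left"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        self.channel_names = tuple(self.channel_names)
        if self.rate_hz <= 0:
            raise SchemaError(f"rate_hz must be positive, got {self.rate_hz}")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise SchemaError(f"duplicate channel names: {self.channel_names}")
        if self.signals.shape[0] != len(self.channel_names):
            raise SchemaError(
                f"{self.signals.shape[0]} channels but "
                f"{len(self.channel_names)} channel names"
            )
        if self.leg not in VALID_LEGS:
            raise SchemaError(f"leg must be one of {VALID_LEGS}, got {self.leg!r}")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        """Start time (s) of each sample's half-open interval."""
        return np.arange(self.n_samples) / self.rate_hz

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.signals[self.channel_names.index(name)]
        except ValueError:
            raise SchemaError(f"no channel named {name!r}") from None


@dataclass
class GrfRecording:
    """Bilateral ground reaction forces from a split-belt force treadmill.

    ``vertical`` and ``anterior`` map a leg id to its force trace in
    newtons; positive anterior force is propulsive (forward).
    """

    vertical: dict[str, np.ndarray]
    anterior: dict[str, np.ndarray]
    rate_hz: float
    belt_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise SchemaError(f"rate_hz must be positive, got {self.rate_hz}")
        if set(self.vertical) != set(self.anterior):
            raise SchemaError("vertical and anterior must cover the same legs")
        self.vertical = {k: np.asarray(v, dtype=float) for k, v in self.vertical.items()}
        self.anterior = {k: np.asarray(v, dtype=float) for k, v in self.anterior.items()}
        for leg in self.vertical:
            if self.vertical[leg].shape != self.anterior[leg].shape:
                raise SchemaError(f"vertical/anterior length mismatch for leg {leg!r}")

    @property
    def legs(self) -> tuple[str, ...]:
        return tuple(self.vertical)

    def contralateral(self, leg: str) -> str:
        others = [k for k in self.vertical if k != leg]
        if leg not in self.vertical or len(others) != 1:
            raise SchemaError(f"cannot resolve contralateral leg of {leg!r}")
        return others[0]

    def times(self, leg: str) -> np.ndarray:
        return np.arange(len(self.vertical[leg])) / self.rate_hz


def _read_csv_matrix(path: Path, columns: Sequence[str]) -> np.ndarray:
    """Read named columns from a CSV, with a row-indexed parse error."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    sub = df[list(columns)]
    for col in columns:
        vals = pd.to_numeric(sub[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy() & sub[col].notna().to_numpy())
        if sub[col].isna().any():
            bad = np.append(bad, np.flatnonzero(sub[col].isna().to_numpy()))
        if bad.size:
            raise ParseError(
                f"{path}: non-numeric sample in column {col!r} at row {int(bad.min())}"
            )
    return sub.to_numpy(dtype=float).T


def read_trial(
    emg_path: str | Path, grf_path: str | Path, sidecar_path: str | Path
) -> tuple[EmgRecording, GrfRecording]:
    """Load one walking trial: wide EMG CSV + wide GRF CSV + JSON sidecar.

    The sidecar declares::

        {"emg": {"rate_hz": 2000, "channels": ["SO", ...],
                 "leg": "left", "subject_id": "S01"},
         "grf": {"rate_hz": 1000, "belt_map": {"belt1": "left",
                                               "belt2": "right"}}}

    GRF CSV columns are named ``<belt>_vertical`` / ``<belt>_anterior``.
    """
    sidecar_path = Path(sidecar_path)
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{sidecar_path}: invalid JSON ({exc})") from exc
    for key in ("emg", "grf"):
        if key not in meta:
            raise SchemaError(f"{sidecar_path}: missing {key!r} section")
    emg_meta, grf_meta = meta["emg"], meta["grf"]
    for key in ("rate_hz", "channels"):
        if key not in emg_meta:
            raise SchemaError(f"{sidecar_path}: emg section missing {key!r}")
    channels = list(emg_meta["channels"])
    if len(set(channels)) != len(channels):
        raise SchemaError(f"{sidecar_path}: duplicate channels in sidecar: {channels}")

    signals = _read_csv_matrix(Path(emg_path), channels)
    emg = EmgRecording(
        signals=signals,
        rate_hz=float(emg_meta["rate_hz"]),
        channel_names=tuple(channels),
        leg=emg_meta.get("leg", "left"),
        subject_id=str(emg_meta.get("subject_id", "")),
    )

    belt_map: Mapping[str, str] = grf_meta.get("belt_map", {})
    if not belt_map:
        raise SchemaError(f"{sidecar_path}: grf section missing belt_map")
    cols = []
    for belt in belt_map:
        cols += [f"{belt}_vertical", f"{belt}_anterior"]
    mat = _read_csv_matrix(Path(grf_path), cols)
    vertical, anterior = {}, {}
    for i, (belt, leg) in enumerate(belt_map.items()):
        vertical[leg] = mat[2 * i]
        anterior[leg] = mat[2 * i + 1]
    grf = GrfRecording(
        vertical=vertical,
        anterior=anterior,
        rate_hz=float(grf_meta["rate_hz"]),
        belt_map=dict(belt_map),
    )
    return emg, grf


def write_trial(
    emg: EmgRecording,
    grf: GrfRecording,
    emg_path: str | Path,
    grf_path: str | Path,
    sidecar_path: str | Path,
) -> None:
    """Write a trial in the CSV+sidecar convention read by :func:`read_trial`."""
    emg_path, grf_path = Path(emg_path), Path(grf_path)
    with emg_path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(emg.channel_names)
        for row in emg.signals.T:
            w.writerow([repr(float(v)) for v in row])
    belt_map = grf.belt_map or {leg: leg for leg in grf.legs}
    cols, arrays = [], []
    for belt, leg in belt_map.items():
        cols += [f"{belt}_vertical", f"{belt}_anterior"]
        arrays += [grf.vertical[leg], grf.anterior[leg]]
    with grf_path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for row in np.column_stack(arrays):
            w.writerow([repr(float(v)) for v in row])
    sidecar = {
        "emg": {
            "rate_hz": emg.rate_hz,
            "channels": list(emg.channel_names),
            "leg": emg.leg,
            "subject_id": emg.subject_id,
        },
        "grf": {"rate_hz": grf.rate_hz, "belt_map": belt_map},
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def write_report(report, path: str | Path) -> None:
    """Write an :class:`~amap.scoring.AmapReport` as tidy CSV + JSON summary.

    The CSV has one row per muscle x region x component with the z-score
    and outlier flag; ``<path>.json`` carries the per-muscle totals, the
    window half-width and identification. Floats are written with
    shortest round-trip repr so a re-read is value-identical.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["muscle", "region", "component", "z", "outlier"])
        for component in report.components:
            zdf = report.z[component]
            odf = report.outlier[component]
            for muscle in zdf.index:
                for region in zdf.columns:
                    w.writerow(
                        [
                            muscle,
                            region,
                            component,
                            repr(float(zdf.at[muscle, region])),
                            str(bool(odf.at[muscle, region])),
                        ]
                    )
    summary = {
        "subject_id": report.subject_id,
        "speed_band": report.speed_band,
        "window_halfwidth": report.window_halfwidth,
        "totals": {
            comp: {m: repr(float(v)) for m, v in report.totals[comp].items()}
            for comp in report.components
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(summary, indent=2))


def read_report(path: str | Path):
    """Inverse of :func:`write_report` (bit-exact for finite floats)."""
    from .scoring import AmapReport, REGIONS

    path = Path(path)
    rows = list(csv.DictReader(path.open()))
    summary = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    components = tuple(summary["totals"])
    muscles = list(dict.fromkeys(r["muscle"] for r in rows))
    regions = list(dict.fromkeys(r["region"] for r in rows)) or list(REGIONS)
    z, outlier = {}, {}
    for comp in components:
        zdf = pd.DataFrame(np.nan, index=muscles, columns=regions, dtype=float)
        odf = pd.DataFrame(False, index=muscles, columns=regions, dtype=bool)
        for r in rows:
            if r["component"] == comp:
                zdf.at[r["muscle"], r["region"]] = float(r["z"])
                odf.at[r["muscle"], r["region"]] = r["outlier"] == "True"
        z[comp], outlier[comp] = zdf, odf
    totals = pd.DataFrame(
        {comp: {m: float(v) for m, v in summary["totals"][comp].items()} for comp in components}
    ).reindex(index=muscles, columns=list(components))
    return AmapReport(
        z=z,
        outlier=outlier,
        totals=totals,
        window_halfwidth=float(summary["window_halfwidth"]),
        subject_id=summary.get("subject_id", ""),
        speed_band=summary.get("speed_band"),
    )


def write_components(cm, path: str | Path) -> None:
    """Write a ComponentMatrix as tidy CSV + JSON metadata sidecar."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["muscle", "region", "timing", "amplitude"])
        for muscle in cm.timing.index:
            for region in cm.timing.columns:
                w.writerow(
                    [
                        muscle,
                        region,
                        repr(float(cm.timing.at[muscle, region])),
                        repr(float(cm.amplitude.at[muscle, region])),
                    ]
                )
    meta = {
        "subject_id": cm.subject_id,
        "leg": cm.leg,
        "n_strides": cm.n_strides,
        "speed_mps": cm.speed_mps,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_components(path: str | Path):
    """Inverse of :func:`write_components` (bit-exact for finite floats)."""
    from .scoring import ComponentMatrix

    path = Path(path)
    rows = list(csv.DictReader(path.open()))
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    muscles = list(dict.fromkeys(r["muscle"] for r in rows))
    regions = list(dict.fromkeys(r["region"] for r in rows))
    timing = pd.DataFrame(0.0, index=muscles, columns=regions)
    amplitude = pd.DataFrame(0.0, index=muscles, columns=regions)
    for r in rows:
        timing.at[r["muscle"], r["region"]] = float(r["timing"])
        amplitude.at[r["muscle"], r["region"]] = float(r["amplitude"])
    return ComponentMatrix(
        timing=timing,
        amplitude=amplitude,
        n_strides=int(meta.get("n_strides", 1)),
        subject_id=str(meta.get("subject_id", "")),
        speed_mps=meta.get("speed_mps"),
        leg=str(meta.get("leg", "left")),
    )
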