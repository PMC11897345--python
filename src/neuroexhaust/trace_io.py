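"""Data model and on-disk trace-bundle format for patch-clamp sweep sets.

A recording is a :class:`SweepRecording`: an ordered set of equal-length
sweeps acquired under a :class:`ProtocolDescriptor` (step current injection,
voltage steps, or gap-free). Voltages are mV, currents pA, capacitance pF;
protocol metadata uses seconds and Hz. Units are fixed — no inference.

Bundles are plain-text directories: ``meta.json`` plus one
``sweep_NNN.csv`` (``time_s,value``) per sweep, so recordings survive
version control and diffing. An equivalent single-file HDF5 container is
provided for bulk storage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "ClampMode",
    "ProtocolDescriptor",
    "SweepRecording",
    "build_step_protocol",
    "apply_junction_correction",
    "read_bundle",
    "write_bundle",
    "read_bundle_h5",
    "write_bundle_h5",
]


class ClampMode(str, Enum):
    CURRENT_CLAMP = "current_clamp"
    VOLTAGE_CLAMP = "voltage_clamp"
    GAP_FREE = "gap_free"


@dataclass(frozen=True)
class ProtocolDescriptor:
    """Command protocol for one acquisition.

    Parameters
    ----------
    mode
        Clamp mode. ``current_clamp`` commands are pA, ``voltage_clamp``
        commands are mV. ``gap_free`` records continuously at the holding
        level with no steps.
    holding_level
        Holding potential (mV, VC) or holding current (pA, CC; 0 allowed).
    step_levels
        Ordered command amplitudes, strictly increasing. One sweep per level.
    step_duration, pre_duration, post_duration
        Segment lengths in seconds. For gap-free protocols ``step_duration``
        is the total recording length and pre/post are 0.
    sampling_rate
        Acquisition rate in Hz.
    """

    mode: ClampMode
    holding_level: float
    step_levels: tuple[float, ...]
    step_duration: float
    pre_duration: float
    post_duration: float
    sampling_rate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", ClampMode(self.mode))
        object.__setattr__(self, "step_levels", tuple(float(v) for v in self.step_levels))
        if self.step_duration <= 0:
            raise ValueError("step_duration must be > 0")
        if self.pre_duration < 0 or self.post_duration < 0:
            raise ValueError("pre/post durations must be >= 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.mode is ClampMode.GAP_FREE:
            if len(self.step_levels) != 0:
                raise ValueError("gap_free protocols have no step levels")
        else:
            if len(self.step_levels) == 0:
                raise ValueError("stepped protocols need at least one level")
            diffs = np.diff(self.step_levels)
            if len(diffs) and not np.all(diffs > 0):
                raise ValueError("step_levels must be strictly increasing")

    @property
    def n_sweeps(self) -> int:
        return 1 if self.mode is ClampMode.GAP_FREE else len(self.step_levels)

    @property
    def sweep_duration(self) -> float:
        """Total sweep length in seconds."""
        return self.pre_duration + self.step_duration + self.post_duration

    @property
    def samples_per_sweep(self) -> int:
        return int(round(self.sweep_duration * self.sampling_rate))

    @property
    def step_onset(self) -> float:
        """Step onset time in seconds from sweep start."""
        return self.pre_duration

    @property
    def step_offset(self) -> float:
        return self.pre_duration + self.step_duration

    def time(self) -> np.ndarray:
        """Sample times in seconds (implicit: index / sampling_rate)."""
        return np.arange(self.samples_per_sweep) / self.sampling_rate

    def to_dict(self) -> dict:
        return {
            "mode": self.mode.value,
            "holding_level": self.holding_level,
            "step_levels": list(self.step_levels),
            "step_duration": self.step_duration,
            "pre_duration": self.pre_duration,
            "post_duration": self.post_duration,
            "sampling_rate": self.sampling_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolDescriptor":
        return cls(
            mode=ClampMode(d["mode"]),
            holding_level=float(d["holding_level"]),
            step_levels=tuple(d["step_levels"]),
            step_duration=float(d["step_duration"]),
            pre_duration=float(d["pre_duration"]),
            post_duration=float(d["post_duration"]),
            sampling_rate=float(d["sampling_rate"]),
        )


def build_step_protocol(
    start_level: float,
    stop_level: float,
    increment: float,
    step_duration: float,
    pre_duration: float = 0.25,
    post_duration: float = 0.25,
    sampling_rate: float = 20_000.0,
    mode: ClampMode | str = ClampMode.CURRENT_CLAMP,
    holding_level: float = 0.0,
) -> ProtocolDescriptor:
    """Build a step protocol with levels ``start, start+inc, ..., stop``.

    The span ``stop_level - start_level`` must be an integer multiple of
    ``increment`` so both ends are included exactly; otherwise a
    ``ValueError`` is raised. The standard current-clamp protocol is 2-s
    steps of 5 pA from −20 to +60 pA (17 sweeps); the standard
    voltage-clamp protocol is 1-s steps of 10 mV from −80 to +60 mV
    (15 sweeps) from a −80 mV holding potential.
    """
    if increment <= 0:
        raise ValueError("increment must be > 0")
    if stop_level < start_level:
        raise ValueError("stop_level must be >= start_level")
    span = stop_level - start_level
    n_steps = span / increment
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(
            f"level range {start_level}..{stop_level} is not divisible by "
            f"increment {increment}; both ends must be included exactly"
        )
    n = int(round(n_steps)) + 1
    levels = tuple(start_level + i * increment for i in range(n))
    return ProtocolDescriptor(
        mode=ClampMode(mode),
        holding_level=holding_level,
        step_levels=levels,
        step_duration=step_duration,
        pre_duration=pre_duration,
        post_duration=post_duration,
        sampling_rate=sampling_rate,
    )


@dataclass
class SweepRecording:
    """One cell's acquisition: ordered sweeps plus protocol and labels.

    ``sweeps`` hold mV for current-clamp and pA for voltage-clamp /
    gap-free recordings. ``metadata`` is a free-form dict used e.g. by the
    synthetic generator to embed ground-truth parameters.
    """

    cell_id: str
    protocol: ProtocolDescriptor
    sweeps: list[np.ndarray]
    genotype: str = "control"
    treatment: str | None = None
    junction_potential_applied: bool = False
    junction_potential_mv: float = 0.0
    capacitance_pf: float | None = None
    days_in_vitro: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sweeps = [np.asarray(s, dtype=float) for s in self.sweeps]
        n = self.protocol.n_sweeps
        if len(self.sweeps) != n:
            raise ValueError(
                f"recording has {len(self.sweeps)} sweeps but protocol "
                f"declares {n} levels"
            )
        lengths = {s.shape[0] for s in self.sweeps}
        if len(lengths) > 1:
            raise ValueError(f"sweeps have unequal lengths: {sorted(lengths)}")
        expected = self.protocol.samples_per_sweep
        (got,) = lengths
        if abs(got - expected) > 1:  # allow one-sample rounding at the edge
            raise ValueError(
                f"sweep length {got} inconsistent with protocol "
                f"({expected} samples = {self.protocol.sweep_duration} s x "
                f"{self.protocol.sampling_rate} Hz)"
            )
        if self.capacitance_pf is not None and self.capacitance_pf <= 0:
            raise ValueError("capacitance must be positive")

    @property
    def sampling_rate(self) -> float:
        return self.protocol.sampling_rate

    def time(self) -> np.ndarray:
        return np.arange(self.sweeps[0].shape[0]) / self.sampling_rate


def apply_junction_correction(
    rec: SweepRecording, jp_mv: float = 12.0, sign: int = -1
) -> SweepRecording:
    """Correct recorded/command voltages for the liquid junction potential.

    The standard correction for a positive pipette-to-bath junction
    potential subtracts ``jp_mv`` from every voltage (``sign=-1``); the
    sign is configurable. In current clamp the recorded samples shift; in
    voltage clamp the command levels (holding + steps) shift and the
    current samples are untouched. The correction is applied at most once,
    guarded by ``junction_potential_applied``.
    """
    if rec.junction_potential_applied:
        raise ValueError(
            f"junction correction already applied to {rec.cell_id!r} "
            f"({rec.junction_potential_mv:+g} mV); refusing double application"
        )
    if sign not in (-1, 1):
        raise ValueError("sign must be -1 or +1")
    shift = sign * jp_mv
    if rec.protocol.mode is ClampMode.CURRENT_CLAMP:
        sweeps = [s + shift for s in rec.sweeps]
        protocol = rec.protocol
    else:
        # voltage commands live in the protocol; samples are currents
        sweeps = [s.copy() for s in rec.sweeps]
        protocol = replace(
            rec.protocol,
            holding_level=rec.protocol.holding_level + shift,
            step_levels=tuple(v + shift for v in rec.protocol.step_levels),
        )
    return replace(
        rec,
        protocol=protocol,
        sweeps=sweeps,
        junction_potential_applied=True,
        junction_potential_mv=float(sign * jp_mv),
        metadata=dict(rec.metadata),
    )


# ---------------------------------------------------------------------------
# bundle I/O


def _meta_dict(rec: SweepRecording) -> dict:
    return {
        "cell_id": rec.cell_id,
        "genotype": rec.genotype,
        "treatment": rec.treatment,
        "protocol": rec.protocol.to_dict(),
        "units": {
            "sweeps": "mV" if rec.protocol.mode is ClampMode.CURRENT_CLAMP else "pA",
            "time": "s",
        },
        "junction_potential_applied": rec.junction_potential_applied,
        "junction_potential_mv": rec.junction_potential_mv,
        "capacitance_pf": rec.capacitance_pf,
        "days_in_vitro": rec.days_in_vitro,
        "metadata": rec.metadata,
    }


def _rec_from_meta(meta: dict, sweeps: list[np.ndarray]) -> SweepRecording:
    return SweepRecording(
        cell_id=meta["cell_id"],
        protocol=ProtocolDescriptor.from_dict(meta["protocol"]),
        sweeps=sweeps,
        genotype=meta.get("genotype", "control"),
        treatment=meta.get("treatment"),
        junction_potential_applied=meta.get("junction_potential_applied", False),
        junction_potential_mv=meta.get("junction_potential_mv", 0.0),
        capacitance_pf=meta.get("capacitance_pf"),
        days_in_vitro=meta.get("days_in_vitro"),
        metadata=meta.get("metadata", {}),
    )


def write_bundle(rec: SweepRecording, path: str | Path) -> Path:
    """Write a recording as a bundle directory (meta.json + sweep CSVs)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "meta.json", "w") as fh:
        json.dump(_meta_dict(rec), fh, indent=1)
    t = rec.time()
    for i, sweep in enumerate(rec.sweeps):
        out = np.column_stack([t, sweep])
        np.savetxt(
            path / f"sweep_{i:03d}.csv",
            out,
            delimiter=",",
            header="time_s,value",
            comments="",
            fmt="%.17g",
        )
    return path


def read_bundle(path: str | Path) -> SweepRecording:
    """Read a bundle directory written by :func:`write_bundle`."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"bundle {path} has no meta.json")
    with open(meta_path) as fh:
        meta = json.load(fh)
    protocol = ProtocolDescriptor.from_dict(meta["protocol"])
    files = sorted(path.glob("sweep_*.csv"))
    if len(files) != protocol.n_sweeps:
        raise ValueError(
            f"bundle {path}: {len(files)} sweep files but protocol declares "
            f"{protocol.n_sweeps} levels"
        )
    sweeps = []
    for f in files:
        arr = np.loadtxt(f, delimiter=",", skiprows=1, ndmin=2)
        t = arr[:, 0]
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{f}: time column is not strictly increasing")
        sweeps.append(arr[:, 1])
    return _rec_from_meta(meta, sweeps)


def write_bundle_h5(rec: SweepRecording, path: str | Path) -> Path:
    """Single-file HDF5 container with the same schema as the bundle dir."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.attrs["meta_json"] = json.dumps(_meta_dict(rec))
        for i, sweep in enumerate(rec.sweeps):
            fh.create_dataset(f"sweep_{i:03d}", data=sweep)
    return path


def read_bundle_h5(path: str | Path) -> SweepRecording:
    import h5py

    with h5py.File(path, "r") as fh:
        meta = json.loads(fh.attrs["meta_json"])
        keys = sorted(k for k in fh.keys() if k.startswith("sweep_"))
        sweeps = [fh[k][()] for k in keys]
    protocol = ProtocolDescriptor.from_dict(meta["protocol"])
    if len(sweeps) != protocol.n_sweeps:
        raise ValueError("sweep count mismatch in HDF5 bundle")
    return _rec_from_meta(meta, sweeps)
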