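"""Reference-data model: per-snapshot QM forces and SR electrostatics.

A force-matching reference data set holds, for each stored configuration
("snapshot") of a QM/MM trajectory: the total forces on the QM atoms, the
electrostatic potential and field generated by the QM charge density at the
positions of the short-range (SR) MM atoms, and the positions of both sets
of atoms.

Two on-disk containers are supported:

* a JSON file laid out as a top-level array whose first element is a header
  object ``{"units": ..., "qm_atom_ids": [...]}`` followed by one object per
  snapshot with keys ``{"step", "qm": {"ids","positions","forces"},
  "sr": {"ids","positions","potential","field"}, "box"}``.  Concatenated
  one-object-per-line (JSON-lines) input is also accepted.  This schema is a
  documented dialect of the producer's per-snapshot JSON stream.
* an HDF5 file with one group per snapshot plus root attributes for the
  unit system and the QM atom ids.  Snapshot access through the HDF5
  backend is lazy: reading snapshot ``l`` does not load the others.

Files declare their unit system in metadata; when absent, Hartree atomic
units are assumed (the natural output units of a QM engine).  Everything is
converted to internal units (nm, kJ/mol, e) on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import h5py
import numpy as np

from .units import conversion_factors

__all__ = [
    "Snapshot",
    "FMDataSet",
    "read_fm_trajectory",
    "write_fm_trajectory",
]

#: unit system assumed for files that do not declare one
DEFAULT_FILE_UNITS = "au"


class RefDataError(ValueError):
    """Malformed or inconsistent reference data."""


@dataclass
class Snapshot:
    """One reference configuration.

    Positions in nm, forces in kJ mol^-1 nm^-1, potential in kJ mol^-1 e^-1,
    field in kJ mol^-1 nm^-1 e^-1.  ``sr_indices`` are global (1-based,
    topology-file convention) atom indices of the SR atoms; SR membership
    may differ between snapshots.
    """

    index: int
    qm_positions: np.ndarray      # (n_qm, 3)
    qm_forces: np.ndarray         # (n_qm, 3)
    sr_indices: np.ndarray        # (n_sr,)
    sr_positions: np.ndarray      # (n_sr, 3)
    sr_potential: np.ndarray      # (n_sr,)
    sr_field: np.ndarray          # (n_sr, 3)
    box: Optional[np.ndarray] = None  # (3,) orthorhombic box lengths, or None

    def __post_init__(self) -> None:
        self.qm_positions = np.atleast_2d(np.asarray(self.qm_positions, float))
        self.qm_forces = np.atleast_2d(np.asarray(self.qm_forces, float))
        self.sr_indices = np.asarray(self.sr_indices, int).reshape(-1)
        self.sr_positions = np.asarray(self.sr_positions, float).reshape(-1, 3)
        self.sr_potential = np.asarray(self.sr_potential, float).reshape(-1)
        self.sr_field = np.asarray(self.sr_field, float).reshape(-1, 3)
        if self.box is not None:
            self.box = np.asarray(self.box, float).reshape(3)
        self.validate()

    @property
    def n_qm(self) -> int:
        return self.qm_positions.shape[0]

    @property
    def n_sr(self) -> int:
        return self.sr_positions.shape[0]

    def validate(self) -> None:
        if self.qm_positions.shape != self.qm_forces.shape:
            raise RefDataError(
                f"snapshot {self.index}: qm_positions {self.qm_positions.shape} "
                f"and qm_forces {self.qm_forces.shape} differ"
            )
        n_sr = self.sr_positions.shape[0]
        for name in ("sr_indices", "sr_potential"):
            if getattr(self, name).shape[0] != n_sr:
                raise RefDataError(
                    f"snapshot {self.index}: {name} length "
                    f"{getattr(self, name).shape[0]} != {n_sr} SR atoms"
                )
        if self.sr_field.shape != (n_sr, 3):
            raise RefDataError(
                f"snapshot {self.index}: sr_field shape {self.sr_field.shape}"
            )
        for name in ("qm_positions", "qm_forces", "sr_positions",
                     "sr_potential", "sr_field"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise RefDataError(f"snapshot {self.index}: non-finite {name}")

    def scaled(self, factors: dict) -> "Snapshot":
        """Return a copy with unit conversion factors applied."""
        return Snapshot(
            index=self.index,
            qm_positions=self.qm_positions * factors["length"],
            qm_forces=self.qm_forces * factors["force"],
            sr_indices=self.sr_indices,
            sr_positions=self.sr_positions * factors["length"],
            sr_potential=self.sr_potential * factors["potential"],
            sr_field=self.sr_field * factors["field"],
            box=None if self.box is None else self.box * factors["length"],
        )


class _HDF5Backend:
    """Lazy per-snapshot access; memory use independent of L."""

    def __init__(self, path, factors: dict):
        self._file = h5py.File(path, "r")
        self._keys = sorted(
            (k for k in self._file if k.startswith("snapshot_")),
            key=lambda k: int(k.rsplit("_", 1)[1]),
        )
        self._factors = factors

    def __len__(self) -> int:
        return len(self._keys)

    def get(self, l: int) -> Snapshot:
        g = self._file[self._keys[l]]
        box = g.attrs.get("box")
        return Snapshot(
            index=int(g.attrs.get("step", l)),
            qm_positions=g["qm_positions"][()],
            qm_forces=g["qm_forces"][()],
            sr_indices=g["sr_indices"][()],
            sr_positions=g["sr_positions"][()],
            sr_potential=g["sr_potential"][()],
            sr_field=g["sr_field"][()],
            box=box,
        ).scaled(self._factors)

    def close(self) -> None:
        self._file.close()


@dataclass
class FMDataSet:
    """An ordered collection of snapshots with a constant QM atom set.

    ``qm_atom_ids`` are global 1-based atom indices, identical for every
    snapshot; the SR set may vary.  Values are stored in internal units.
    """

    snapshots: Sequence[Snapshot] = field(default_factory=list)
    qm_atom_ids: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    units: str = "internal"
    _backend: Optional[_HDF5Backend] = None

    def __post_init__(self) -> None:
        self.qm_atom_ids = np.asarray(self.qm_atom_ids, int).reshape(-1)

    def __len__(self) -> int:
        if self._backend is not None:
            return len(self._backend)
        return len(self.snapshots)

    def get_snapshot(self, l: int) -> Snapshot:
        if not 0 <= l < len(self):
            raise IndexError(f"snapshot index {l} out of range [0, {len(self)})")
        if self._backend is not None:
            return self._backend.get(l)
        return self.snapshots[l]

    def __getitem__(self, l: int) -> Snapshot:
        return self.get_snapshot(l)

    def __iter__(self) -> Iterator[Snapshot]:
        for l in range(len(self)):
            yield self.get_snapshot(l)

    @property
    def n_qm(self) -> int:
        return self.get_snapshot(0).n_qm

    def validate(self) -> None:
        if len(self) < 1:
            raise RefDataError("data set must contain at least one snapshot")
        n_qm = self.n_qm
        if self.qm_atom_ids.size and self.qm_atom_ids.size != n_qm:
            raise RefDataError(
                f"{self.qm_atom_ids.size} QM atom ids but {n_qm} QM atoms"
            )
        for snap in self:
            if snap.n_qm != n_qm:
                raise RefDataError(
                    f"snapshot {snap.index}: {snap.n_qm} QM atoms, expected {n_qm}"
                )

    def to_memory(self) -> "FMDataSet":
        """Materialize a lazily backed data set into memory."""
        if self._backend is None:
            return self
        return FMDataSet(
            snapshots=[self.get_snapshot(l) for l in range(len(self))],
            qm_atom_ids=self.qm_atom_ids,
            units=self.units,
        )

    def close(self) -> None:
        if self._backend is not None:
            self._backend.close()


# ---------------------------------------------------------------------------
# JSON container

def _snapshot_to_obj(snap: Snapshot, qm_ids: np.ndarray, inv: dict) -> dict:
    obj = {
        "step": int(snap.index),
        "qm": {
            "ids": [int(i) for i in qm_ids],
            "positions": (snap.qm_positions / inv["length"]).tolist(),
            "forces": (snap.qm_forces / inv["force"]).tolist(),
        },
        "sr": {
            "ids": [int(i) for i in snap.sr_indices],
            "positions": (snap.sr_positions / inv["length"]).tolist(),
            "potential": (snap.sr_potential / inv["potential"]).tolist(),
            "field": (snap.sr_field / inv["field"]).tolist(),
        },
    }
    if snap.box is not None:
        obj["box"] = (snap.box / inv["length"]).tolist()
    return obj


def _snapshot_from_obj(obj: dict, l: int) -> Snapshot:
    try:
        qm = obj["qm"]
        sr = obj.get("sr", {})
        return Snapshot(
            index=int(obj.get("step", l)),
            qm_positions=qm["positions"],
            qm_forces=qm["forces"],
            sr_indices=sr.get("ids", []),
            sr_positions=np.asarray(sr.get("positions", []), float).reshape(-1, 3),
            sr_potential=sr.get("potential", []),
            sr_field=np.asarray(sr.get("field", []), float).reshape(-1, 3),
            box=obj.get("box"),
        )
    except (KeyError, TypeError) as exc:
        raise RefDataError(f"malformed snapshot record {l}: {exc}") from exc


def _load_json_objects(path) -> list:
    text = Path(path).read_text()
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        # concatenated one-object-per-line stream
        data = [json.loads(line) for line in text.splitlines() if line.strip()]
    if isinstance(data, dict):  # single-snapshot or wrapped layout
        data = data.get("snapshots", [data])
    if not isinstance(data, list):
        raise RefDataError(f"{path}: unrecognized JSON layout")
    return data


def _read_json(path) -> FMDataSet:
    objects = _load_json_objects(path)
    units = DEFAULT_FILE_UNITS
    qm_ids: list = []
    if objects and isinstance(objects[0], dict) and "qm" not in objects[0]:
        header = objects.pop(0)
        units = header.get("units", units)
        qm_ids = header.get("qm_atom_ids", [])
    factors = conversion_factors(units)
    snaps = [_snapshot_from_obj(o, l).scaled(factors) for l, o in enumerate(objects)]
    if not qm_ids and snaps and objects:
        qm_ids = objects[0].get("qm", {}).get("ids", [])
    ds = FMDataSet(snapshots=snaps, qm_atom_ids=np.asarray(qm_ids, int),
                   units="internal")
    ds.validate()
    return ds


def _write_json(ds: FMDataSet, path, file_units: str) -> None:
    inv = conversion_factors(file_units)
    qm_ids = ds.qm_atom_ids
    lines = [json.dumps({"units": file_units,
                         "qm_atom_ids": [int(i) for i in qm_ids]})]
    for l in range(len(ds)):
        lines.append(json.dumps(_snapshot_to_obj(ds.get_snapshot(l), qm_ids, inv)))
    Path(path).write_text("[\n" + ",\n".join(lines) + "\n]\n")


# ---------------------------------------------------------------------------
# HDF5 container

def _write_hdf5(ds: FMDataSet, path, file_units: str) -> None:
    inv = conversion_factors(file_units)
    with h5py.File(path, "w") as f:
        f.attrs["units"] = file_units
        f.attrs["qm_atom_ids"] = np.asarray(ds.qm_atom_ids, int)
        for l in range(len(ds)):
            snap = ds.get_snapshot(l)
            g = f.create_group(f"snapshot_{l:06d}")
            g.attrs["step"] = int(snap.index)
            g.create_dataset("qm_positions", data=snap.qm_positions / inv["length"])
            g.create_dataset("qm_forces", data=snap.qm_forces / inv["force"])
            g.create_dataset("sr_indices", data=snap.sr_indices)
            g.create_dataset("sr_positions", data=snap.sr_positions / inv["length"])
            g.create_dataset("sr_potential", data=snap.sr_potential / inv["potential"])
            g.create_dataset("sr_field", data=snap.sr_field / inv["field"])
            if snap.box is not None:
                g.attrs["box"] = snap.box / inv["length"]


def _read_hdf5(path, lazy: bool = True) -> FMDataSet:
    with h5py.File(path, "r") as f:
        units = f.attrs.get("units", DEFAULT_FILE_UNITS)
        qm_ids = np.asarray(f.attrs.get("qm_atom_ids", []), int)
    factors = conversion_factors(str(units))
    backend = _HDF5Backend(path, factors)
    ds = FMDataSet(snapshots=[], qm_atom_ids=qm_ids, units="internal",
                   _backend=backend)
    if not lazy:
        ds = ds.to_memory()
        backend.close()
    return ds


# ---------------------------------------------------------------------------
# public API

def _detect_format(path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    if suffix in (".json", ".js", ".jsonl"):
        return "json"
    raise ValueError(f"cannot detect container format from extension {suffix!r}")


def read_fm_trajectory(path, format: str = "auto", lazy: bool = True) -> FMDataSet:
    """Read a reference data set from a JSON or HDF5 container.

    The HDF5 backend is lazy by default: snapshots are read from disk on
    access so that peak memory is independent of the number of snapshots.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    if fmt == "json":
        return _read_json(path)
    if fmt == "hdf5":
        return _read_hdf5(path, lazy=lazy)
    raise ValueError(f"unknown format {fmt!r}")


def write_fm_trajectory(dataset: FMDataSet, path, format: str = "auto",
                        file_units: str = "au") -> None:
    """Write a reference data set; readable back by :func:`read_fm_trajectory`."""
    dataset.validate()
    fmt = _detect_format(path, format)
    if fmt == "json":
        _write_json(dataset, path, file_units)
    elif fmt == "hdf5":
        _write_hdf5(dataset, path, file_units)
    else:
        raise ValueError(f"unknown format {fmt!r}")
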