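"""Trajectory, configuration and manifest I/O.

The native trajectory container is an HDF5 file with datasets
``positions[T,N,3]``, ``velocities[T,N,3]``, ``species[N]``, ``chain_id[N]``,
``time[T]`` and ``box[3]``, tagged with the reduced-unit convention.
Extended-XYZ import/export (columns: species tag H/C, position, velocity)
is provided for interoperability; it does not carry chain ids, which are
reassigned as contiguous blocks on import.
"""
from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import yaml

from .md import (COLD, HOT, SPECIES_TAGS, TAG_TO_SPECIES, SimulationBox,
                 Trajectory)

logger = logging.getLogger("activeblend.io")

UNITS_TAG = "reduced LJ (sigma, epsilon, tau; kB=1, m=1)"
_DATASETS = ("positions", "velocities", "species", "chain_id", "time", "box")


class TrajectoryFormatError(RuntimeError):
    """File does not conform to the documented trajectory schema."""


def write_trajectory(traj: Trajectory, path) -> None:
    """Write the native HDF5 container (lossless)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=traj.positions)
        f.create_dataset("velocities", data=traj.velocities)
        f.create_dataset("species", data=traj.species.astype(np.int8))
        f.create_dataset("chain_id", data=traj.chain_id.astype(np.int32))
        f.create_dataset("time", data=traj.times)
        f.create_dataset("box", data=traj.box.lengths)
        f.attrs["units"] = UNITS_TAG
        f.attrs["format_version"] = 1


def read_trajectory(path) -> Trajectory:
    """Read the native HDF5 container, validating the schema."""
    try:
        with h5py.File(path, "r") as f:
            missing = [d for d in _DATASETS if d not in f]
            if missing:
                raise TrajectoryFormatError(
                    f"missing dataset(s): {', '.join(missing)}")
            species = f["species"][...]
            if not np.isin(species, [COLD, HOT]).all():
                raise TrajectoryFormatError(
                    "species labels must be hot/cold "
                    f"({HOT}/{COLD}); found {np.unique(species)}")
            return Trajectory(
                positions=f["positions"][...],
                velocities=f["velocities"][...],
                times=f["time"][...],
                species=species.astype(np.int8),
                chain_id=f["chain_id"][...].astype(np.int32),
                box=SimulationBox(f["box"][...]),
            )
    except OSError as exc:
        raise TrajectoryFormatError(f"unreadable trajectory file: {exc}") from exc


def write_xyz(traj: Trajectory, path) -> None:
    """Extended-XYZ export: species tag H/C, position, velocity (6 decimals)."""
    L = traj.box.lengths
    lattice = f"{L[0]:.6f} 0.0 0.0 0.0 {L[1]:.6f} 0.0 0.0 0.0 {L[2]:.6f}"
    with open(path, "w") as f:
        for t in range(len(traj)):
            f.write(f"{traj.n_particles}\n")
            f.write(f'Lattice="{lattice}" '
                    'Properties=species:S:1:pos:R:3:vel:R:3 '
                    f"Time={traj.times[t]:.6f}\n")
            for i in range(traj.n_particles):
                tag = SPECIES_TAGS[int(traj.species[i])]
                p = traj.positions[t, i]
                v = traj.velocities[t, i]
                f.write(f"{tag} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} "
                        f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")


def read_xyz(path, chain_length: int = 40) -> Trajectory:
    """Extended-XYZ import.

    Chain ids are not stored in the format; they are reassigned as
    contiguous blocks of ``chain_length`` particles within each species.
    """
    frames_p, frames_v, times = [], [], []
    species = None
    box = None
    try:
        with open(path) as f:
            lines = f.read().splitlines()
        k = 0
        while k < len(lines):
            if not lines[k].strip():
                k += 1
                continue
            n = int(lines[k].strip())
            header = lines[k + 1]
            t = 0.0
            for token in header.split():
                if token.startswith("Time="):
                    t = float(token[5:])
                if token.startswith('Lattice="'):
                    pass
            if 'Lattice="' in header:
                lat = header.split('Lattice="', 1)[1].split('"', 1)[0].split()
                diag = np.array([float(lat[0]), float(lat[4]), float(lat[8])])
                box = SimulationBox(diag)
            rows = lines[k + 2:k + 2 + n]
            if len(rows) < n:
                raise TrajectoryFormatError("truncated frame")
            sp = np.empty(n, dtype=np.int8)
            p = np.empty((n, 3))
            v = np.empty((n, 3))
            for i, row in enumerate(rows):
                parts = row.split()
                if parts[0] not in TAG_TO_SPECIES:
                    raise TrajectoryFormatError(
                        f"unknown species tag {parts[0]!r} (expected H or C)")
                sp[i] = TAG_TO_SPECIES[parts[0]]
                p[i] = [float(x) for x in parts[1:4]]
                v[i] = [float(x) for x in parts[4:7]]
            if species is None:
                species = sp
            elif not np.array_equal(species, sp):
                raise TrajectoryFormatError("species labels change between frames")
            frames_p.append(p)
            frames_v.append(v)
            times.append(t)
            k += 2 + n
    except (ValueError, IndexError) as exc:
        raise TrajectoryFormatError(f"malformed extended-XYZ file: {exc}") from exc
    if not frames_p or box is None:
        raise TrajectoryFormatError("no complete frames with a Lattice header")
    chain_id = np.empty(species.size, dtype=np.int32)
    next_chain = 0
    for code in (HOT, COLD):
        idx = np.nonzero(species == code)[0]
        chain_id[idx] = next_chain + np.arange(idx.size) // chain_length
        next_chain += int(np.ceil(idx.size / chain_length))
    return Trajectory(positions=np.stack(frames_p),
                      velocities=np.stack(frames_v),
                      times=np.asarray(times), species=species,
                      chain_id=chain_id, box=box)


# ---------------------------------------------------------------------------
# Configs and manifests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationSettings:
    """Parsed [system]/[thermostats]/[run] configuration."""

    M: int
    N: int = 40
    density: float = 0.85
    box_aspect: tuple[float, float, float] = (1.0, 1.0, 1.0)
    Tc: float = 1.0
    Th: float = 3.0
    zeta: float = 1.5
    dt: float = 0.005
    duration: float = 100.0
    sample_interval: float = 25.0
    seed: int = 0


def load_config(path) -> SimulationSettings:
    """Load a TOML or YAML run configuration."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
    else:
        data = tomllib.loads(path.read_text())
    system = data.get("system", {})
    thermo = data.get("thermostats", {})
    run = data.get("run", {})
    return SimulationSettings(
        M=int(system["M"]),
        N=int(system.get("N", 40)),
        density=float(system.get("density", 0.85)),
        box_aspect=tuple(system.get("box_aspect", (1.0, 1.0, 1.0))),
        Tc=float(thermo.get("Tc", 1.0)),
        Th=float(thermo.get("Th", 3.0)),
        zeta=float(thermo.get("zeta", 1.5)),
        dt=float(run.get("dt", 0.005)),
        duration=float(run.get("duration", 100.0)),
        sample_interval=float(run.get("sample_interval", 25.0)),
        seed=int(run.get("seed", 0)),
    )


@dataclass
class ManifestEntry:
    Th: float
    path: Path


@dataclass
class RunManifest:
    """Per-Th trajectory ensemble plus the shared global parameters."""

    entries: list[ManifestEntry]
    Tc: float = 1.0
    zeta: float = 1.5
    M: int | None = None
    N: int = 40
    density: float = 0.85

    def __post_init__(self):
        ths = [e.Th for e in self.entries]
        if len(set(ths)) != len(ths):
            raise ValueError("Th values in a manifest must be unique")
        for e in self.entries:
            if not Path(e.path).exists():
                raise FileNotFoundError(f"trajectory not found: {e.path}")


def load_manifest(path) -> RunManifest:
    data = yaml.safe_load(Path(path).read_text())
    base = Path(path).parent
    entries = [ManifestEntry(Th=float(e["Th"]),
                             path=(base / e["path"]).resolve())
               for e in data["entries"]]
    g = data.get("globals", {})
    return RunManifest(entries=entries, Tc=float(g.get("Tc", 1.0)),
                       zeta=float(g.get("zeta", 1.5)),
                       M=g.get("M"), N=int(g.get("N", 40)),
                       density=float(g.get("density", 0.85)))


def write_profile_tsv(profile, path) -> None:
    """Tidy tabular text: z_center, value, stderr, count."""
    frame = profile.to_frame()
    with open(path, "w") as f:
        f.write(f"# {profile.name} [{profile.units}] ({UNITS_TAG})\n")
        frame.to_csv(f, sep="\t", index=False)
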