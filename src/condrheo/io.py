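"""Readers and writers for on-disk formats, plus run configuration.

Formats:

* FASTA sequences (protein or RNA, auto-detected) via Biopython;
* stress logs as TSV with the fixed header
  ``time sxx syy szz sxy sxz syz`` (lossless round trip at 17 significant
  digits, columns matched by name);
* trajectories as extended XYZ (box + tilt on the comment line) or a
  LAMMPS-dump-compatible dialect with unwrapped ``xu yu zu`` columns
  (1-based particle ids on disk, 0-based in memory);
* run configuration as TOML, schema-checked, with the resolved config
  written next to the outputs of every run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .engine import StressLog, Trajectory

__all__ = [
    "read_sequences",
    "read_stress_log",
    "write_stress_log",
    "read_trajectory_xyz",
    "write_trajectory_xyz",
    "read_trajectory_dump",
    "write_trajectory_dump",
    "RunConfig",
]

STRESS_HEADER = ["time", "sxx", "syy", "szz", "sxy", "sxz", "syz"]

_PROTEIN = set("ACDEFGHIKLMNPQRSTVWY")
_RNA = set("ACGU")


def read_sequences(path) -> list[dict]:
    """Labeled sequences from FASTA with protein/RNA alphabet detection."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        letters = set(seq)
        if letters <= _RNA:
            alphabet = "rna"
        elif letters <= _PROTEIN:
            alphabet = "protein"
        else:
            bad = sorted(letters - (_PROTEIN | _RNA))
            raise ValueError(
                f"record {rec.id!r}: unknown or mixed alphabet "
                f"(letters {bad})")
        out.append({"id": rec.id, "sequence": seq, "alphabet": alphabet})
    return out


def write_stress_log(path, log: StressLog) -> None:
    df = pd.DataFrame(
        np.column_stack([log.times, log.components]), columns=STRESS_HEADER)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_stress_log(path, volume: float = 1.0,
                    temperature: float = 1.0) -> StressLog:
    """Stress samples from TSV; columns are matched by header name."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in STRESS_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"stress log missing column(s) {missing}")
    return StressLog(times=df["time"].to_numpy(),
                     components=df[STRESS_HEADER[1:]].to_numpy(),
                     volume=volume, temperature=temperature)


def write_trajectory_xyz(path, traj: Trajectory,
                         types: list[str] | None = None) -> None:
    """Extended XYZ: comment line carries time, box and tilt per frame."""
    n = traj.positions.shape[1]
    names = types or ["A"] * n
    with open(path, "w") as fh:
        for f in range(len(traj.times)):
            fh.write(f"{n}\n")
            bx = traj.box
            fh.write(f"time={traj.times[f]:.17g} "
                     f"box={bx[0]:.17g},{bx[1]:.17g},{bx[2]:.17g} "
                     f"tilt={traj.tilts[f]:.17g}\n")
            for i in range(n):
                x, y, z = traj.positions[f, i]
                fh.write(f"{names[i]} {x:.10f} {y:.10f} {z:.10f}\n")


def read_trajectory_xyz(path) -> Trajectory:
    times, frames, tilts = [], [], []
    box = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i])
        except ValueError as exc:
            raise ValueError(f"truncated frame at line {i + 1}") from exc
        if i + 1 + n >= len(lines) + 1:
            raise ValueError(f"truncated frame {frame_no} (expected {n} atoms)")
        meta = dict(kv.split("=") for kv in lines[i + 1].split())
        times.append(float(meta.get("time", frame_no)))
        box = np.array([float(v) for v in meta["box"].split(",")])
        tilts.append(float(meta.get("tilt", 0.0)))
        pos = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise ValueError(f"truncated frame {frame_no} at atom {k}")
            pos[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(pos)
        i += 2 + n
        frame_no += 1
    return Trajectory(times=np.array(times), positions=np.array(frames),
                      box=box, tilts=np.array(tilts),
                      indices=np.arange(frames[0].shape[0]))


def write_trajectory_dump(path, traj: Trajectory,
                          type_ids: np.ndarray | None = None) -> None:
    """LAMMPS-dump dialect with id, type and unwrapped xu yu zu columns."""
    n = traj.positions.shape[1]
    tid = (np.ones(n, dtype=int) if type_ids is None
           else np.asarray(type_ids) + 1)
    with open(path, "w") as fh:
        for f in range(len(traj.times)):
            bx = traj.box
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{traj.times[f]:.17g}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{n}\n")
            if traj.tilts[f] != 0.0:
                fh.write("ITEM: BOX BOUNDS xy xz yz pp pp pp\n")
                fh.write(f"0 {bx[0]:.17g} {traj.tilts[f]:.17g}\n")
                fh.write(f"0 {bx[1]:.17g} 0\n")
                fh.write(f"0 {bx[2]:.17g} 0\n")
            else:
                fh.write("ITEM: BOX BOUNDS pp pp pp\n")
                for a in range(3):
                    fh.write(f"0 {bx[a]:.17g}\n")
            fh.write("ITEM: ATOMS id type xu yu zu\n")
            for i in range(n):
                x, y, z = traj.positions[f, i]
                fh.write(f"{i + 1} {tid[i]} {x:.10f} {y:.10f} {z:.10f}\n")


def read_trajectory_dump(path) -> Trajectory:
    """Read the dump dialect; wrapped-only coordinate columns are flagged."""
    times, frames, tilts = [], [], []
    box = None
    wrapped_only = False
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].startswith("ITEM: TIMESTEP"):
            i += 1
            continue
        try:
            t = float(lines[i + 1])
            n = int(lines[i + 3])
            bounds_header = lines[i + 4]
            tilt = 0.0
            dims = []
            for a in range(3):
                parts = lines[i + 5 + a].split()
                dims.append(float(parts[1]) - float(parts[0]))
                if "xy" in bounds_header and a == 0 and len(parts) > 2:
                    tilt = float(parts[2])
            cols = lines[i + 8].replace("ITEM: ATOMS", "").split()
            if not {"xu", "yu", "zu"} <= set(cols):
                wrapped_only = True
                xc, yc, zc = (cols.index("x"), cols.index("y"),
                              cols.index("z"))
            else:
                xc, yc, zc = (cols.index("xu"), cols.index("yu"),
                              cols.index("zu"))
            idc = cols.index("id")
            pos = np.empty((n, 3))
            for k in range(n):
                parts = lines[i + 9 + k].split()
                pid = int(parts[idc]) - 1
                pos[pid] = [float(parts[xc]), float(parts[yc]),
                            float(parts[zc])]
        except (IndexError, ValueError) as exc:
            raise ValueError(
                f"truncated dump frame {len(frames)}") from exc
        box = np.array(dims)
        times.append(t)
        tilts.append(tilt)
        frames.append(pos)
        i += 9 + n
    traj = Trajectory(times=np.array(times), positions=np.array(frames),
                      box=box, tilts=np.array(tilts),
                      indices=np.arange(frames[0].shape[0]))
    traj.wrapped_only = wrapped_only
    return traj


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_SCHEMA: dict[str, set[str]] = {
    "model": {"kind", "epsilon", "sigma", "cutoff", "k_bond", "r0",
              "parameter_table", "sequences"},
    "topology": {"n_chains", "beads_per_chain"},
    "state": {"temperature", "density", "slab", "elongation"},
    "integrator": {"dt", "thermostat", "damping", "stress_stride"},
    "gk": {"p", "m", "modes_per_decade", "n_blocks", "channel_mode"},
    "os": {"gamma0", "omegas", "n_periods", "samples_per_period"},
    "bt": {"radius", "epsilon", "lambda", "msd_lags"},
    "age": {"cutoff", "partners", "stride", "strength_factor", "larks"},
    "phase_diagram": {"temperatures", "n_bins", "beta"},
    "run": {"seed", "n_steps", "equilibration_steps", "output_dir"},
}


@dataclass
class RunConfig:
    """Validated run configuration (TOML on disk)."""

    sections: dict

    def __getitem__(self, key):
        return self.sections[key]

    def get(self, section: str, key: str, default=None):
        return self.sections.get(section, {}).get(key, default)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        cls._validate(data)
        return cls(sections=data)

    @staticmethod
    def _validate(data: dict) -> None:
        for section, keys in data.items():
            if section not in _SCHEMA:
                raise ValueError(f"unknown config section [{section}]")
            unknown = set(keys) - _SCHEMA[section]
            if unknown:
                raise ValueError(
                    f"unknown key(s) {sorted(unknown)} in section [{section}]")

    @property
    def seed(self) -> int:
        return int(self.get("run", "seed", 0))

    def write_resolved(self, out_dir) -> Path:
        """Record the fully resolved configuration next to the outputs."""
        out = Path(out_dir) / "resolved_config.json"
        out.parent.mkdir(parents=True, exist_ok=True)
        out.write_text(json.dumps(self.sections, indent=2, default=str))
        return out
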