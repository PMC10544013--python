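"""Plain-text serialization: multi-frame XYZ chains, tabular trajectories.

All formats are whitespace-delimited text with full-precision decimals
(%.17g) so write-then-read round-trips bit-exactly; files ending in
``.gz`` are compressed and decompressed transparently.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dna import BasePairTrajectory, IonTrajectory
from .model import ChainConformation

__all__ = [
    "write_chain_xyz",
    "read_chain_xyz",
    "write_bp_trajectory",
    "read_bp_trajectory",
    "write_ion_trajectory",
    "read_ion_trajectory",
    "write_sidecar",
    "read_sidecar",
]

_FMT = "%.17g"


def _open(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_chain_xyz(chains, path, delta: float = None, lz: float | None = None) -> None:
    """Write conformations as multi-frame XYZ-style text.

    Each frame: a bead-count line, a comment line carrying ``delta`` and
    (optionally) ``lz``, then one ``W x y z`` line per bead.
    """
    chains = [chains] if isinstance(chains, ChainConformation) else list(chains)
    with _open(path, "w") as fh:
        for chain in chains:
            d = delta if delta is not None else chain.delta
            meta = f"delta={_FMT % d}"
            if lz is not None:
                meta += f" lz={_FMT % lz}"
            fh.write(f"{chain.beads.shape[0]}\n{meta}\n")
            for b in chain.beads:
                fh.write("W " + " ".join(_FMT % v for v in b) + "\n")


def read_chain_xyz(path) -> tuple[list[ChainConformation], dict]:
    """Read a multi-frame XYZ chain file; returns (chains, metadata)."""
    chains: list[ChainConformation] = []
    meta: dict = {}
    with _open(path, "r") as fh:
        while True:
            head = fh.readline()
            if not head.strip():
                break
            count = int(head)
            comment = fh.readline().strip()
            for token in comment.split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = float(v)
            beads = np.empty((count, 3))
            for i in range(count):
                parts = fh.readline().split()
                beads[i] = [float(x) for x in parts[1:4]]
            chains.append(ChainConformation(beads=beads, delta=meta.get("delta", 1.0)))
    return chains, meta


def write_bp_trajectory(traj: BasePairTrajectory, path) -> None:
    """One row per base pair per frame: frame, bp, x, y, z, hx, hy, hz."""
    with _open(path, "w") as fh:
        fh.write(f"# box {_FMT % traj.box[0]} {_FMT % traj.box[1]} {_FMT % traj.box[2]}\n")
        fh.write(f"# n_bp {traj.n_bp}\n")
        fh.write("frame bp x y z hx hy hz\n")
        for f in range(traj.n_frames):
            for i in range(traj.n_bp):
                row = np.concatenate([traj.centers[f, i], traj.orientations[f, i]])
                fh.write(f"{f} {i} " + " ".join(_FMT % v for v in row) + "\n")


def read_bp_trajectory(path) -> BasePairTrajectory:
    with _open(path, "r") as fh:
        text = fh.read()
    box = None
    for line in text.splitlines():
        if line.startswith("# box"):
            box = tuple(float(v) for v in line.split()[2:5])
    df = pd.read_csv(_io.StringIO(text), sep=r"\s+", comment="#", float_precision="round_trip")
    n_frames = df["frame"].nunique()
    n_bp = df["bp"].nunique()
    df = df.sort_values(["frame", "bp"])
    centers = df[["x", "y", "z"]].to_numpy().reshape(n_frames, n_bp, 3)
    orients = df[["hx", "hy", "hz"]].to_numpy().reshape(n_frames, n_bp, 3)
    return BasePairTrajectory(centers=centers, orientations=orients, box=box)


def write_ion_trajectory(traj: IonTrajectory, path) -> None:
    """Same framing as the base-pair format with a species column.

    DNA atoms are written with the reserved species label ``DNA``.
    """
    with _open(path, "w") as fh:
        fh.write(f"# box {_FMT % traj.box[0]} {_FMT % traj.box[1]} {_FMT % traj.box[2]}\n")
        fh.write("frame species x y z\n")
        for f in range(traj.n_frames):
            for xyz in traj.dna_atoms[f]:
                fh.write(f"{f} DNA " + " ".join(_FMT % v for v in xyz) + "\n")
            for sp in sorted(traj.ions):
                for xyz in traj.ions[sp][f]:
                    fh.write(f"{f} {sp} " + " ".join(_FMT % v for v in xyz) + "\n")


def read_ion_trajectory(path) -> IonTrajectory:
    with _open(path, "r") as fh:
        text = fh.read()
    box = None
    for line in text.splitlines():
        if line.startswith("# box"):
            box = tuple(float(v) for v in line.split()[2:5])
    df = pd.read_csv(_io.StringIO(text), sep=r"\s+", comment="#", float_precision="round_trip")
    frames = sorted(df["frame"].unique())
    species = [s for s in df["species"].unique() if s != "DNA"]
    dna = []
    ions: dict[str, list[np.ndarray]] = {sp: [] for sp in species}
    for f in frames:
        sub = df[df["frame"] == f]
        dna.append(sub[sub["species"] == "DNA"][["x", "y", "z"]].to_numpy())
        for sp in species:
            ions[sp].append(sub[sub["species"] == sp][["x", "y", "z"]].to_numpy())
    return IonTrajectory(ions=ions, dna_atoms=dna, box=box)


def write_sidecar(data: dict, path) -> None:
    """YAML sidecar with run metadata (parameters, seed, acceptance)."""
    with _open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_sidecar(path) -> dict:
    with _open(path, "r") as fh:
        return yaml.safe_load(fh)
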