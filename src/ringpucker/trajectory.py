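"""Trajectory containers and I/O for multi-frame XYZ and CPMD-style files.

Two on-disk dialects are supported:

``xyz``
    Standard multi-frame XYZ: an atom-count line, a comment line, then one
    ``element x y z`` record per atom, repeated per frame.  Coordinates in Å.

``cpmd``
    A whitespace trajectory in the layout CPMD writes: one line per atom per
    frame, first column the integer MD step, the next three columns the
    position in Bohr, any further columns (velocities) ignored.  The file
    stores no element symbols, so a topology (ordered element list) must be
    supplied.  Frames are delimited by a change of the step value.

All in-memory coordinates are Å.  Parsing is strict: a malformed block raises
:class:`~ringpucker.errors.TrajectoryParseError` naming the offending line —
frames are never silently dropped, because downstream populations are ratios
over frame counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import ConfigurationError, TrajectoryParseError

#: CODATA 2018 Bohr radius in Å.
BOHR_TO_ANGSTROM = 0.529177210903


@dataclass(frozen=True)
class Frame:
    """A single trajectory snapshot (coordinates in Å)."""

    index: int
    elements: tuple[str, ...]
    coords: np.ndarray  # shape (n_atoms, 3), Å
    time_or_step: float | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must have shape (n, 3), got {coords.shape}")
        if len(self.elements) != coords.shape[0]:
            raise ValueError(
                f"frame {self.index}: {len(self.elements)} elements "
                f"but {coords.shape[0]} coordinate rows"
            )
        if coords.shape[0] < 5:
            raise ValueError(f"frame {self.index}: need at least 5 atoms")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"frame {self.index}: non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """An ordered sequence of frames sharing one element sequence."""

    frames: list[Frame]
    source_dialect: str = "xyz"  # {"xyz", "cpmd"}
    length_unit_of_source: str = "angstrom"  # {"angstrom", "bohr"}

    def __post_init__(self) -> None:
        if self.source_dialect not in ("xyz", "cpmd"):
            raise ValueError(f"unknown dialect {self.source_dialect!r}")
        if self.length_unit_of_source not in ("angstrom", "bohr"):
            raise ValueError(f"unknown unit {self.length_unit_of_source!r}")
        if self.frames:
            ref = self.frames[0].elements
            for f in self.frames[1:]:
                if f.elements != ref:
                    raise ValueError(
                        f"frame {f.index}: element sequence differs from frame "
                        f"{self.frames[0].index}"
                    )
            idx = [f.index for f in self.frames]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def elements(self) -> tuple[str, ...]:
        return self.frames[0].elements

    def coords_array(self) -> np.ndarray:
        """Stack all frame coordinates into an (n_frames, n_atoms, 3) array."""
        return np.stack([f.coords for f in self.frames])


@dataclass(frozen=True)
class RingSpec:
    """Five ring-atom indices plus the ring's chemistry and symmetry.

    ``atom_indices`` follow the cyclic ring order starting at the heteroatom
    (for furan: O1, C2, C3, C4, C5 with C2/C5 the alpha and C3/C4 the beta
    carbons).  ``bond_types[i]`` labels the bond between ring positions
    ``i`` and ``(i+1) % 5``.  ``symmetry_perm`` is the involution of ring
    positions generated by the ring's mirror plane; for furan it fixes the
    oxygen and swaps the alpha pair and the beta pair.
    """

    atom_indices: tuple[int, int, int, int, int]
    bond_types: tuple[str, str, str, str, str] = ("CO", "CC", "CC", "CC", "CO")
    symmetry_perm: tuple[int, int, int, int, int] = (0, 4, 3, 2, 1)
    include_updown_equivalence: bool = True
    position_names: tuple[str, str, str, str, str] = ("O", "Cα", "Cβ", "Cβ", "Cα")

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.atom_indices)
        object.__setattr__(self, "atom_indices", idx)
        if len(set(idx)) != 5:
            raise ConfigurationError(f"ring atom indices must be 5 distinct, got {idx}")
        if any(i < 0 for i in idx):
            raise ConfigurationError("ring atom indices must be non-negative")
        perm = tuple(int(p) for p in self.symmetry_perm)
        object.__setattr__(self, "symmetry_perm", perm)
        if sorted(perm) != [0, 1, 2, 3, 4]:
            raise ConfigurationError(f"symmetry_perm must permute 0..4, got {perm}")
        if any(perm[perm[i]] != i for i in range(5)):
            raise ConfigurationError(f"symmetry_perm must be an involution, got {perm}")
        bt = tuple(str(b) for b in self.bond_types)
        object.__setattr__(self, "bond_types", bt)
        if len(bt) != 5:
            raise ConfigurationError("need exactly 5 bond types")

    @classmethod
    def furan(cls, atom_indices: Sequence[int] = (0, 1, 2, 3, 4)) -> "RingSpec":
        """Default furan ring: O-first ordering, Cs mirror, up/down equivalence."""
        return cls(atom_indices=tuple(atom_indices))

    @classmethod
    def from_dict(cls, d: dict) -> "RingSpec":
        """Build from a nested key-value config mapping."""
        kwargs: dict = {"atom_indices": tuple(d["atom_indices"])}
        for key in ("bond_types", "symmetry_perm", "position_names"):
            if key in d:
                kwargs[key] = tuple(d[key])
        if "include_updown_equivalence" in d:
            kwargs["include_updown_equivalence"] = bool(d["include_updown_equivalence"])
        return cls(**kwargs)

    def check_bounds(self, frame: Frame) -> None:
        if max(self.atom_indices) >= frame.n_atoms:
            raise ConfigurationError(
                f"ring index {max(self.atom_indices)} out of bounds for "
                f"{frame.n_atoms}-atom frame"
            )

    def ring_coords(self, frame: Frame) -> np.ndarray:
        """Return the (5, 3) coordinates of the ring atoms in ring order."""
        self.check_bounds(frame)
        return frame.coords[list(self.atom_indices)]


# ---------------------------------------------------------------------------
# readers / writers


def _read_xyz(path: Path) -> list[Frame]:
    with open(path) as fh:
        lines = fh.readlines()
    frames: list[Frame] = []
    ln = 0
    n_lines = len(lines)
    while ln < n_lines:
        if not lines[ln].strip():  # tolerate trailing blank lines
            ln += 1
            continue
        header_line = ln
        try:
            natoms = int(lines[ln].split()[0])
        except (ValueError, IndexError):
            raise TrajectoryParseError(
                f"{path}: line {ln + 1}: expected an atom-count header in frame "
                f"{len(frames) + 1}, got {lines[ln].rstrip()!r}"
            ) from None
        ln += 2  # skip comment line
        elements: list[str] = []
        coords = np.empty((natoms, 3))
        for a in range(natoms):
            if ln >= n_lines:
                raise TrajectoryParseError(
                    f"{path}: frame {len(frames) + 1} (starting at line "
                    f"{header_line + 1}) truncated: expected {natoms} atom "
                    f"records, found {a}"
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise TrajectoryParseError(
                    f"{path}: line {ln + 1}: malformed atom record in frame "
                    f"{len(frames) + 1}: {lines[ln].rstrip()!r}"
                )
            try:
                coords[a] = [float(x) for x in parts[1:4]]
            except ValueError:
                raise TrajectoryParseError(
                    f"{path}: line {ln + 1}: non-numeric coordinate in frame "
                    f"{len(frames) + 1}: {lines[ln].rstrip()!r}"
                ) from None
            elements.append(parts[0])
            ln += 1
        try:
            frames.append(
                Frame(index=len(frames), elements=tuple(elements), coords=coords)
            )
        except ValueError as exc:  # e.g. non-finite coordinates
            raise TrajectoryParseError(f"{path}: {exc}") from exc
    if not frames:
        raise TrajectoryParseError(f"{path}: no frames found")
    return frames


def _read_cpmd(path: Path, topology: Sequence[str]) -> list[Frame]:
    natoms = len(topology)
    frames: list[Frame] = []
    block: list[np.ndarray] = []
    block_step: int | None = None
    block_start_line = 1

    def flush(end_line: int) -> None:
        nonlocal block, block_step
        if block_step is None:
            return
        if len(block) != natoms:
            raise TrajectoryParseError(
                f"{path}: frame {len(frames) + 1} (step {block_step}, lines "
                f"{block_start_line}-{end_line}): expected {natoms} atom lines "
                f"per topology, found {len(block)}"
            )
        frames.append(
            Frame(
                index=len(frames),
                elements=tuple(topology),
                coords=np.array(block) * BOHR_TO_ANGSTROM,
                time_or_step=float(block_step),
            )
        )
        block = []

    lineno = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            try:
                step = int(float(parts[0]))
                xyz = np.array([float(x) for x in parts[1:4]])
                if xyz.shape != (3,):
                    raise ValueError
            except (ValueError, IndexError):
                raise TrajectoryParseError(
                    f"{path}: line {lineno}: malformed record {line.rstrip()!r}"
                ) from None
            if block_step is not None and step != block_step:
                flush(lineno - 1)
                block_start_line = lineno
            block_step = step
            block.append(xyz)
            if len(block) > natoms:
                raise TrajectoryParseError(
                    f"{path}: line {lineno}: more than {natoms} consecutive lines "
                    f"with step {step}; topology and file disagree"
                )
    flush(lineno)
    if not frames:
        raise TrajectoryParseError(f"{path}: no frames found")
    return frames


def read_trajectory(
    path: str | Path,
    dialect: str = "xyz",
    topology: Sequence[str] | None = None,
) -> Trajectory:
    """Read a trajectory file; coordinates are returned in Å.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"xyz"`` for standard multi-frame XYZ (Å) or ``"cpmd"`` for the
        step-indexed Bohr dialect.
    topology:
        Ordered element symbols; required for ``cpmd`` (that dialect stores
        no element information).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "xyz":
        frames = _read_xyz(path)
        unit = "angstrom"
    elif dialect == "cpmd":
        if topology is None:
            raise ConfigurationError(
                "cpmd dialect stores no element symbols: a topology element "
                "list is required"
            )
        frames = _read_cpmd(path, list(topology))
        unit = "bohr"
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    return Trajectory(frames=frames, source_dialect=dialect, length_unit_of_source=unit)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as standard multi-frame XYZ (Å, 8 decimals)."""
    if len(traj) == 0:
        raise ValueError("refusing to write an empty trajectory")
    path = Path(path)
    with open(path, "w") as fh:
        for frame in traj:
            fh.write(f"{frame.n_atoms}\n")
            step = "" if frame.time_or_step is None else f" step {frame.time_or_step:g}"
            fh.write(f"frame {frame.index}{step}\n")
            for el, (x, y, z) in zip(frame.elements, frame.coords):
                fh.write(f"{el} {x:.8f} {y:.8f} {z:.8f}\n")
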