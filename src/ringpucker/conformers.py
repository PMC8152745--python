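"""The pseudorotation wheel of a five-membered ring and its symmetry classes.

A five-ring has 20 canonical puckered conformers arranged every 18° around
the pseudorotation wheel: 10 envelopes (E, one flap atom out of plane) and
10 twists (T, two adjacent atoms on opposite sides), alternating.  With the
phase origin anchored at envelope-at-O flap-up (see :mod:`.puckering`), the
wheel position at phase 18·k carries an envelope for even k and a twist for
odd k.

For a ring with mirror symmetry (furan: the plane through O perpendicular to
the ring), conformers related by the mirror — and, physically, by flipping
the ring over (up/down equivalence) — are indistinguishable, which reduces
the 20 wheel points to 6 unique classes with orbit sizes {2, 4, 4, 4, 4, 2}:
envelope O, twist O–Cα, envelope Cα, twist Cα–β, envelope Cβ, twist Cβ–β.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .puckering import PuckerState
from .trajectory import RingSpec

WHEEL_STEP_DEG = 18.0


@dataclass(frozen=True)
class CanonicalConformer:
    """One of the 20 pure wheel conformations."""

    kind: str  # {"envelope", "twist"}
    anchor: tuple[int, ...]  # (atom,) for E, (atom, atom) bond for T
    sign: str  # {"up", "down"}: flap side for E, side of the first bond atom for T
    wheel_psi: float  # degrees, multiple of 18

    @property
    def wheel_index(self) -> int:
        return int(round(self.wheel_psi / WHEEL_STEP_DEG)) % 20


@dataclass(frozen=True)
class ConformerClass:
    """A symmetry-unique set of canonical conformers."""

    label: str
    members: tuple[CanonicalConformer, ...]

    @property
    def orbit_size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ConformerAssignment:
    """Classification of a single frame."""

    frame: int
    planar: bool
    canonical: CanonicalConformer | None
    cls: ConformerClass | None

    def __post_init__(self) -> None:
        if self.planar != (self.canonical is None):
            raise ValueError("planar assignments carry no conformer, and vice versa")
        if (self.canonical is None) != (self.cls is None):
            raise ValueError("canonical conformer and class must be set together")


def build_wheel() -> list[CanonicalConformer]:
    """The 20 canonical conformers, ordered by wheel phase 0°, 18°, …, 342°.

    Derived from the displacement pattern z_j ∝ cos(ψ + 4πj/5): at ψ = 36·m
    the pattern is an envelope with flap atom ``m mod 5`` (up for even m),
    at ψ = 18 + 36·m a twist about the bond ``(m, m+1) mod 5`` with the first
    bond atom up for even m.
    """
    wheel: list[CanonicalConformer] = []
    for k in range(20):
        psi = k * WHEEL_STEP_DEG
        if k % 2 == 0:
            m = k // 2
            wheel.append(
                CanonicalConformer(
                    kind="envelope",
                    anchor=(m % 5,),
                    sign="up" if m % 2 == 0 else "down",
                    wheel_psi=psi,
                )
            )
        else:
            m = (k - 1) // 2
            wheel.append(
                CanonicalConformer(
                    kind="twist",
                    anchor=(m % 5, (m + 1) % 5),
                    sign="up" if m % 2 == 0 else "down",
                    wheel_psi=psi,
                )
            )
    return wheel


def _reflection_offset(perm: tuple[int, ...]) -> int | None:
    """If perm is the ring reflection j → (c − j) mod 5, return c; else None."""
    for c in range(5):
        if all(perm[j] == (c - j) % 5 for j in range(5)):
            return c
    return None


def _bond_label(i: int, j: int, names: tuple[str, ...]) -> str:
    a, b = names[i], names[j]
    if a.startswith("C") and b.startswith("C"):
        b = b[1:]  # Cα–β rather than Cα–Cβ
    return f"{a}–{b}"


def class_label(conf: CanonicalConformer, ring: RingSpec, with_sign: bool = False) -> str:
    names = ring.position_names
    if conf.kind == "envelope":
        base = f"envelope {names[conf.anchor[0]]}"
    else:
        base = f"twist {_bond_label(conf.anchor[0], conf.anchor[1], names)}"
    if with_sign:
        base += f" ({conf.sign})"
    return base


def reduce_by_symmetry(
    wheel: list[CanonicalConformer], ring: RingSpec
) -> list[ConformerClass]:
    """Partition the wheel into orbits of the ring's symmetry group.

    The group is generated by (a) the mirror permutation of ring positions,
    acting on the wheel as ψ → −ψ − 144·c where the permutation is
    j → (c − j) mod 5, and (b) if ``ring.include_updown_equivalence``, the
    ring flip ψ → ψ + 180°.  Classes are labelled by their lowest-wheel-index
    member; when up/down conformers are *not* identified, the flap side is
    appended to keep labels unique.
    """
    perm = ring.symmetry_perm
    generators: list[callable] = []
    if perm != (0, 1, 2, 3, 4):
        c = _reflection_offset(perm)
        if c is None:
            raise ConfigurationError(
                f"symmetry permutation {perm} is not a ring reflection; only "
                "reflections j → (c − j) mod 5 (or the identity) are ring "
                "symmetries of a 5-cycle"
            )
        generators.append(lambda k, c=c: (-k - 8 * c) % 20)  # ψ → −ψ − 144 c
    if ring.include_updown_equivalence:
        generators.append(lambda k: (k + 10) % 20)  # ψ → ψ + 180

    by_index = {conf.wheel_index: conf for conf in wheel}
    if len(by_index) != 20:
        raise ConfigurationError("wheel must contain all 20 canonical positions")

    seen: set[int] = set()
    classes: list[ConformerClass] = []
    for k in range(20):
        if k in seen:
            continue
        orbit = {k}
        frontier = [k]
        while frontier:
            cur = frontier.pop()
            for g in generators:
                nxt = g(cur)
                if nxt not in orbit:
                    orbit.add(nxt)
                    frontier.append(nxt)
        seen |= orbit
        members = tuple(by_index[i] for i in sorted(orbit))
        label = class_label(
            members[0], ring, with_sign=not ring.include_updown_equivalence
        )
        classes.append(ConformerClass(label=label, members=members))
    # positions the symmetry does not merge can share a chemical name
    # (e.g. both alpha carbons); disambiguate by wheel phase
    labels = [c.label for c in classes]
    for i, cls in enumerate(classes):
        if labels.count(cls.label) > 1:
            classes[i] = ConformerClass(
                label=f"{cls.label} ψ={cls.members[0].wheel_psi:g}°",
                members=cls.members,
            )
    return classes


def classify_frame(
    state: PuckerState,
    classes: list[ConformerClass],
    planarity_threshold: float,
) -> ConformerAssignment:
    """Assign a frame to the planar class or its nearest wheel conformer.

    Frames with ``S < planarity_threshold`` (degrees) are planar.  Otherwise
    the canonical conformer nearest in circular distance to ψ wins; an exact
    midpoint tie (9° from both neighbours) goes to the lower wheel phase.
    """
    if planarity_threshold < 0:
        raise ConfigurationError("planarity threshold must be ≥ 0")
    if state.S < planarity_threshold:
        return ConformerAssignment(frame=state.frame, planar=True, canonical=None, cls=None)
    # nearest multiple of 18°; exact midpoint ties go to the lower wheel_psi
    lo = int(np.floor(state.psi / WHEEL_STEP_DEG)) % 20
    hi = (lo + 1) % 20
    d_lo = _circdist(state.psi, lo * WHEEL_STEP_DEG)
    d_hi = _circdist(state.psi, hi * WHEEL_STEP_DEG)
    if abs(d_lo - d_hi) < 1e-12:
        k = min(lo, hi)
    else:
        k = lo if d_lo < d_hi else hi
    for cls in classes:
        for member in cls.members:
            if member.wheel_index == k:
                return ConformerAssignment(
                    frame=state.frame, planar=False, canonical=member, cls=cls
                )
    raise ConfigurationError(
        f"wheel position {k} is not covered by the supplied classes"
    )


def _circdist(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def wheel_table(classes: list[ConformerClass], ring: RingSpec):
    """Flat per-conformer table (label, kind, anchor, sign, wheel_psi, orbit size)."""
    import pandas as pd

    rows = []
    for cls in classes:
        for conf in cls.members:
            rows.append(
                {
                    "wheel_psi": conf.wheel_psi,
                    "kind": conf.kind,
                    "anchor": "-".join(str(a) for a in conf.anchor),
                    "sign": conf.sign,
                    "class": cls.label,
                    "orbit_size": cls.orbit_size,
                }
            )
    return pd.DataFrame(rows).sort_values("wheel_psi").reset_index(drop=True)
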