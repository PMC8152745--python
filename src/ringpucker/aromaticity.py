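"""Geometric aromaticity indices: HOMA and the Bird I5.

Both indices are functions of the five ring bond lengths of a single frame.

HOMA (harmonic oscillator model of aromaticity)::

    HOMA = 1 − (1/5) Σ_i α_t(i) (R_opt,t(i) − R_i)²

with per-bond-type force parameters α (Å⁻²) and optimal aromatic lengths
R_opt (Å).  HOMA = 1 iff every bond sits at its optimum; it is unbounded
below (strong alternation drives it negative).

Bird I5, built on Gordy bond orders ``N = a/R² − b``::

    V  = (100 / N̄) · sqrt( Σ_i (N_i − N̄)² / 5 )
    I5 = 100 · (1 − V / V_K)

where N̄ is the mean bond order and V_K the reference spread of the
corresponding non-delocalised (Kekulé) ring family — 35 for five-membered
heterocycles.  I5 = 100 iff all bond orders are equal; it is not clamped
below zero.

The shipped default constants are the common literature parameterisation for
CC and CO bonds; they are configuration, not constants of nature, and every
output should echo the values actually used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .trajectory import Frame, RingSpec


@dataclass(frozen=True)
class AromaticityParams:
    """Per-bond-type constants for HOMA and Bird I5."""

    homa_alpha: dict = field(default_factory=lambda: {"CC": 257.7, "CO": 157.38})
    homa_ropt: dict = field(default_factory=lambda: {"CC": 1.388, "CO": 1.265})
    gordy_a: dict = field(default_factory=lambda: {"CC": 6.80, "CO": 5.75})
    gordy_b: dict = field(default_factory=lambda: {"CC": 1.71, "CO": 1.85})
    v_k: float = 35.0

    def __post_init__(self) -> None:
        for name in ("homa_alpha", "homa_ropt", "gordy_a", "gordy_b"):
            d = getattr(self, name)
            if any(v <= 0 for v in d.values()):
                raise ConfigurationError(f"{name} entries must be strictly positive")
        if self.v_k <= 0:
            raise ConfigurationError("v_k must be strictly positive")

    def _lookup(self, table: dict, bond_type: str) -> float:
        try:
            return table[bond_type]
        except KeyError:
            raise ConfigurationError(
                f"no constants for bond type {bond_type!r}; known: {sorted(table)}"
            ) from None

    @classmethod
    def from_dict(cls, d: dict) -> "AromaticityParams":
        base = cls()
        kwargs = {}
        for name in ("homa_alpha", "homa_ropt", "gordy_a", "gordy_b"):
            merged = dict(getattr(base, name))
            merged.update(d.get(name, {}))
            kwargs[name] = merged
        kwargs["v_k"] = float(d.get("v_k", base.v_k))
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "homa_alpha": dict(self.homa_alpha),
            "homa_ropt": dict(self.homa_ropt),
            "gordy_a": dict(self.gordy_a),
            "gordy_b": dict(self.gordy_b),
            "v_k": self.v_k,
        }


@dataclass(frozen=True)
class AromaticityRecord:
    """Per-frame bond lengths and index values."""

    frame: int
    bond_lengths: np.ndarray  # Å, ring-bond order (i, i+1 mod 5)
    homa: float
    i5: float


def ring_bond_lengths_batch(ring_coords: np.ndarray) -> np.ndarray:
    """Bond lengths R_i = |r_{i+1} − r_i| from (..., 5, 3) ring coordinates."""
    rc = np.asarray(ring_coords, dtype=float)
    return np.linalg.norm(np.roll(rc, -1, axis=-2) - rc, axis=-1)


def ring_bond_lengths(frame: Frame, ring: RingSpec) -> np.ndarray:
    """Five ring bond lengths (Å) of a frame in ring-bond order."""
    return ring_bond_lengths_batch(ring.ring_coords(frame))


def _per_bond(params_table: dict, bond_types, params: AromaticityParams) -> np.ndarray:
    return np.array([params._lookup(params_table, t) for t in bond_types])


def homa(bond_lengths, bond_types, params: AromaticityParams | None = None) -> float:
    """HOMA of one ring geometry; 1 at the all-optimal geometry."""
    params = params or AromaticityParams()
    r = np.asarray(bond_lengths, dtype=float)
    if np.any(r <= 0):
        raise ValueError("bond lengths must be positive")
    alpha = _per_bond(params.homa_alpha, bond_types, params)
    ropt = _per_bond(params.homa_ropt, bond_types, params)
    return float(1.0 - np.mean(alpha * (ropt - r) ** 2, axis=-1))


def gordy_bond_orders(bond_lengths, bond_types, params: AromaticityParams | None = None) -> np.ndarray:
    """Empirical Gordy bond orders N = a/R² − b per ring bond."""
    params = params or AromaticityParams()
    r = np.asarray(bond_lengths, dtype=float)
    a = _per_bond(params.gordy_a, bond_types, params)
    b = _per_bond(params.gordy_b, bond_types, params)
    return a / r**2 - b


def bird_i5(bond_lengths, bond_types, params: AromaticityParams | None = None) -> float:
    """Bird I5 of one ring geometry; 100 at equalised bond orders."""
    params = params or AromaticityParams()
    r = np.asarray(bond_lengths, dtype=float)
    if np.any(r <= 0):
        raise ValueError("bond lengths must be positive")
    n = gordy_bond_orders(r, bond_types, params)
    nbar = np.mean(n, axis=-1)
    v = (100.0 / nbar) * np.sqrt(np.mean((n - nbar[..., None]) ** 2, axis=-1))
    return float(100.0 * (1.0 - v / params.v_k))


def compute_aromaticity(
    traj, ring: RingSpec, params: AromaticityParams | None = None
) -> list[AromaticityRecord]:
    """HOMA and Bird I5 for every frame (vectorised over the trajectory)."""
    params = params or AromaticityParams()
    coords = traj.coords_array()[:, list(ring.atom_indices), :]
    r = ring_bond_lengths_batch(coords)  # (n_frames, 5)
    alpha = _per_bond(params.homa_alpha, ring.bond_types, params)
    ropt = _per_bond(params.homa_ropt, ring.bond_types, params)
    homa_vals = 1.0 - np.mean(alpha * (ropt - r) ** 2, axis=-1)
    a = _per_bond(params.gordy_a, ring.bond_types, params)
    b = _per_bond(params.gordy_b, ring.bond_types, params)
    n = a / r**2 - b
    nbar = n.mean(axis=-1)
    v = (100.0 / nbar) * np.sqrt(np.mean((n - nbar[:, None]) ** 2, axis=-1))
    i5_vals = 100.0 * (1.0 - v / params.v_k)
    return [
        AromaticityRecord(frame=f.index, bond_lengths=r[i], homa=float(homa_vals[i]), i5=float(i5_vals[i]))
        for i, f in enumerate(traj)
    ]
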