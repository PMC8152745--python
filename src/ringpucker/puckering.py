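"""Ring-puckering coordinates for five-membered rings.

Two descriptions of the out-of-plane deformation are computed per frame:

* the torsion-based Zefirov–Palyulin–Dashevskaya (ZPD) pair ``(S, ψ)``,
  obtained by projecting the five endocyclic torsions onto the pseudorotation
  cosine basis ``cos(4πj/5)`` — ``S`` is the torsional amplitude in degrees,
  ``ψ`` the phase angle on the conformational wheel;
* the classical Cremer–Pople pair ``(q2, φ2)`` for N = 5, obtained from the
  out-of-plane displacements ``z_j`` relative to the Cremer–Pople mean plane —
  ``q2`` in Å.

Phase origin.  ``ψ = 0`` (and ``φ2 = 0``) is anchored at the envelope
conformation with the first ring atom (the heteroatom) as the flap, displaced
to the +z side ("envelope-at-O, flap up").  For ``φ2`` this holds by
construction of the Cremer–Pople transform; for ``ψ`` a calibration offset
``ψ_ref`` is computed once from a constructed canonical envelope-at-O geometry
and subtracted from the raw torsional phase.

Sign convention for dihedrals: IUPAC — looking along the central bond from
atom 2 to atom 3, a clockwise rotation carrying the 1-2 bond onto the 3-4
bond is positive.  Results lie in (−180°, 180°].
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import DegenerateGeometryError
from .trajectory import Frame, RingSpec

_J = np.arange(5)
#: pseudorotation basis angles 4πj/5 for j = 0..4, in radians
_BASIS = 4.0 * np.pi * _J / 5.0
#: mean-plane basis angles 2πj/5
_PLANE = 2.0 * np.pi * _J / 5.0


@dataclass(frozen=True)
class PuckerState:
    """Per-frame puckering descriptors (angles in degrees, lengths in Å)."""

    frame: int
    torsions: np.ndarray  # τ0..τ4, degrees
    S: float  # ZPD torsional amplitude, degrees
    psi: float  # ZPD phase, [0, 360)
    q2: float  # Cremer–Pople amplitude, Å
    phi2: float  # Cremer–Pople phase, [0, 360)
    z: np.ndarray  # out-of-plane displacements, Å, sum ≈ 0


# ---------------------------------------------------------------------------
# dihedral primitive


def dihedral_batch(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> np.ndarray:
    """Signed dihedrals in degrees for stacked point quadruples (..., 3)."""
    b1 = p1 - p2  # near bond, pointing away from the axis
    b2 = p3 - p2  # central bond
    b3 = p4 - p3  # far bond
    n2 = np.linalg.norm(b2, axis=-1, keepdims=True)
    if np.any(n2 < 1e-12):
        raise DegenerateGeometryError("zero-length central bond in dihedral")
    b2u = b2 / n2
    # components of b1, b3 perpendicular to the central bond
    v = b1 - np.sum(b1 * b2u, axis=-1, keepdims=True) * b2u
    w = b3 - np.sum(b3 * b2u, axis=-1, keepdims=True) * b2u
    nv = np.linalg.norm(v, axis=-1)
    nw = np.linalg.norm(w, axis=-1)
    if np.any(nv < 1e-10) or np.any(nw < 1e-10):
        raise DegenerateGeometryError(
            "three consecutive points are collinear; dihedral undefined"
        )
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b2u, v) * w, axis=-1)
    return np.degrees(np.arctan2(y, x))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, IUPAC convention.

    Positive when, viewed from p2 towards p3, the far bond p3→p4 is rotated
    clockwise from the near bond p2→p1.  Range (−180, 180].
    """
    return float(
        dihedral_batch(
            *(np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
        )
    )


# ---------------------------------------------------------------------------
# endocyclic torsions


def endocyclic_torsions_batch(ring_coords: np.ndarray) -> np.ndarray:
    """Five endocyclic torsions per frame from (..., 5, 3) ring coordinates.

    τ_j is the dihedral over ring atoms (j, j+1, j+2, j+3) mod 5, so τ_0 is
    the torsion about the bond between ring positions 1 and 2.
    """
    rc = np.asarray(ring_coords, dtype=float)
    quads = [(j, (j + 1) % 5, (j + 2) % 5, (j + 3) % 5) for j in range(5)]
    taus = [
        dihedral_batch(rc[..., a, :], rc[..., b, :], rc[..., c, :], rc[..., d, :])
        for a, b, c, d in quads
    ]
    return np.stack(taus, axis=-1)


def endocyclic_torsions(frame: Frame, ring: RingSpec) -> np.ndarray:
    """τ0..τ4 (degrees) for one frame; τ_j spans ring atoms j..j+3 mod 5."""
    try:
        return endocyclic_torsions_batch(ring.ring_coords(frame))
    except DegenerateGeometryError as exc:
        raise DegenerateGeometryError(f"frame {frame.index}: {exc}") from exc


# ---------------------------------------------------------------------------
# ZPD (S, psi)


def zpd_components(torsions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cosine/sine projections (A, B) of torsions onto the m=2 basis."""
    t = np.asarray(torsions, dtype=float)
    a = (2.0 / 5.0) * np.sum(t * np.cos(_BASIS), axis=-1)
    b = -(2.0 / 5.0) * np.sum(t * np.sin(_BASIS), axis=-1)
    return a, b


@lru_cache(maxsize=1)
def psi_reference() -> float:
    """Raw torsional phase of the canonical envelope-at-O (flap up) geometry.

    Computed once from a regular pentagon (circumradius of a typical
    five-ring) carrying the pure envelope-at-O displacement pattern
    ``z_j ∝ cos(4πj/5)`` at small amplitude, so that subtracting this
    constant anchors ψ = 0 on envelope-at-O up.
    """
    radius = 1.17  # Å, typical five-membered-ring circumradius
    q = 0.01  # Å, small amplitude: linear regime
    ring = _pentagon_with_pucker(radius, q, phase_deg=0.0)
    a, b = zpd_components(endocyclic_torsions_batch(ring))
    return float(np.degrees(np.arctan2(b, a))) % 360.0


def mean_plane_normal(ring_coords: np.ndarray) -> np.ndarray:
    """Unit normal of the Cremer–Pople mean plane (defines the '+' side)."""
    rc = np.asarray(ring_coords, dtype=float)
    centred = rc - rc.mean(axis=-2, keepdims=True)
    rp = np.sum(centred * np.sin(_PLANE)[:, None], axis=-2)
    rpp = np.sum(centred * np.cos(_PLANE)[:, None], axis=-2)
    normal = np.cross(rp, rpp)
    norm = np.linalg.norm(normal, axis=-1, keepdims=True)
    if np.any(norm < 1e-10):
        raise DegenerateGeometryError("ring atoms (nearly) collinear")
    return normal / norm


def impose_pucker(planar_ring: np.ndarray, q2: float | np.ndarray, phase_deg: float | np.ndarray) -> np.ndarray:
    """Displace a planar ring along its mean-plane normal with the pure
    pseudorotation pattern ``z_j = √(2/5)·q2·cos(phase + 4πj/5)``, so that
    Cremer–Pople analysis of the result reads back exactly (q2, phase)."""
    ring = np.asarray(planar_ring, dtype=float)
    nhat = mean_plane_normal(ring)
    z = np.sqrt(2.0 / 5.0) * np.asarray(q2)[..., None] * np.cos(
        np.radians(np.asarray(phase_deg))[..., None] + _BASIS
    )
    return ring + z[..., :, None] * nhat


def _pentagon_with_pucker(radius: float, q2: float, phase_deg: float) -> np.ndarray:
    """Regular pentagon with a pure m=2 pucker imposed along its mean-plane normal."""
    theta = 2.0 * np.pi * _J / 5.0
    xy = radius * np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    flat = np.concatenate([xy, np.zeros((5, 1))], axis=-1)
    return impose_pucker(flat, q2, phase_deg)


def zpd_pucker(torsions: np.ndarray, psi_ref: float | None = None) -> tuple[float, float]:
    """ZPD puckering amplitude S (degrees) and phase ψ ∈ [0, 360).

    Projects the five endocyclic torsions onto the pseudorotation basis:
    ``A = (2/5) Σ τ_j cos(4πj/5)``, ``B = −(2/5) Σ τ_j sin(4πj/5)``,
    ``S = √(A² + B²)``, ``ψ = atan2(B, A) − ψ_ref (mod 360)``.

    ``psi_ref`` defaults to the calibrated envelope-at-O anchor
    (:func:`psi_reference`); pass ``0.0`` for the raw, uncalibrated phase.
    A planar ring (S = 0) reports ψ = 0 by convention.
    """
    t = np.asarray(torsions, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite torsions")
    if psi_ref is None:
        psi_ref = psi_reference()
    a, b = zpd_components(t)
    s = float(np.hypot(a, b))
    if s < 1e-12:
        return 0.0, 0.0
    psi = (float(np.degrees(np.arctan2(b, a))) - psi_ref) % 360.0
    return s, psi


def zpd_pucker_batch(torsions: np.ndarray, psi_ref: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`zpd_pucker` over an (n, 5) torsion array."""
    if psi_ref is None:
        psi_ref = psi_reference()
    a, b = zpd_components(torsions)
    s = np.hypot(a, b)
    psi = (np.degrees(np.arctan2(b, a)) - psi_ref) % 360.0
    psi = np.where(s < 1e-12, 0.0, psi)
    return s, psi


# ---------------------------------------------------------------------------
# Cremer–Pople for N = 5


def cremer_pople_batch(ring_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(q2, φ2, z) per frame from (..., 5, 3) ring coordinates.

    The mean plane passes through the ring centroid with normal
    ``R' × R''``, where ``R' = Σ r_j sin(2πj/5)`` and
    ``R'' = Σ r_j cos(2πj/5)`` over centred positions.  Then
    ``q2 cos φ2 = √(2/5) Σ z_j cos(4πj/5)`` and
    ``q2 sin φ2 = −√(2/5) Σ z_j sin(4πj/5)``.
    """
    rc = np.asarray(ring_coords, dtype=float)
    centred = rc - rc.mean(axis=-2, keepdims=True)
    rp = np.sum(centred * np.sin(_PLANE)[:, None], axis=-2)
    rpp = np.sum(centred * np.cos(_PLANE)[:, None], axis=-2)
    normal = np.cross(rp, rpp)
    norm = np.linalg.norm(normal, axis=-1, keepdims=True)
    if np.any(norm < 1e-10):
        raise DegenerateGeometryError(
            "ring atoms (nearly) collinear: mean plane undefined"
        )
    nhat = normal / norm
    z = np.sum(centred * nhat[..., None, :], axis=-1)
    qc = np.sqrt(2.0 / 5.0) * np.sum(z * np.cos(_BASIS), axis=-1)
    qs = -np.sqrt(2.0 / 5.0) * np.sum(z * np.sin(_BASIS), axis=-1)
    q2 = np.hypot(qc, qs)
    phi2 = np.degrees(np.arctan2(qs, qc)) % 360.0
    phi2 = np.where(q2 < 1e-12, 0.0, phi2)
    return q2, phi2, z


def cremer_pople_5(frame: Frame, ring: RingSpec) -> tuple[float, float, np.ndarray]:
    """Cremer–Pople (q2 in Å, φ2 in degrees, z displacements) for one frame."""
    try:
        q2, phi2, z = cremer_pople_batch(ring.ring_coords(frame))
    except DegenerateGeometryError as exc:
        raise DegenerateGeometryError(f"frame {frame.index}: {exc}") from exc
    return float(q2), float(phi2), z


# ---------------------------------------------------------------------------
# trajectory-level driver


def compute_pucker_states(traj, ring: RingSpec) -> list[PuckerState]:
    """Puckering descriptors for every frame of a trajectory."""
    coords = traj.coords_array()[:, list(ring.atom_indices), :]
    taus = endocyclic_torsions_batch(coords)
    s, psi = zpd_pucker_batch(taus)
    q2, phi2, z = cremer_pople_batch(coords)
    return [
        PuckerState(
            frame=f.index,
            torsions=taus[i],
            S=float(s[i]),
            psi=float(psi[i]),
            q2=float(q2[i]),
            phi2=float(phi2[i]),
            z=z[i],
        )
        for i, f in enumerate(traj)
    ]
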