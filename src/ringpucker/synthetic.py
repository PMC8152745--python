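"""Seeded synthetic thermal ensembles of a furan-like five-membered ring.

The generator emulates the statistical structure of a configurational
ensemble from finite-temperature MD of an isolated aromatic five-ring,
without integrating any dynamics:

* the single out-of-plane pucker mode is excited with 2D-Gaussian components,
  so the Cremer–Pople amplitude ``q2`` is Rayleigh-distributed with scale
  ``σ_q · sqrt(T/T_ref) · γ`` (γ < 1 for the deuterated preset — heavier
  substituents stiffen the out-of-plane motion);
* the pseudorotation phase is drawn from a mixture of a uniform component
  (free pseudorotation, the protiated default) and von Mises components at
  configurable centres (phase localisation, the deuterated behaviour);
* isotropic Gaussian coordinate jitter of scale ``σ_b`` produces the
  bond-length fluctuations that drive the spread of the aromaticity indices.

Identical parameters (including the seed) yield a bit-identical trajectory.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.optimize import fsolve, least_squares

from .errors import RingClosureError
from .trajectory import Frame, Trajectory

#: typical gas-phase furan ring: O–Cα, Cα=Cβ, Cβ–Cβ, Cβ=Cα, Cα–O (Å)
FURAN_BOND_LENGTHS = (1.362, 1.361, 1.431, 1.361, 1.362)
#: interior angles at O, Cα, Cβ, Cβ, Cα that close the pentagon exactly
FURAN_RING_ANGLES = (106.5, 110.720865, 106.029136, 106.029136, 110.720865)

_ISOTOPE_PRESETS = {
    # gamma: sigma_q multiplier; kappa/uniform weight: phase localisation
    "protiated": {"gamma": 1.0, "vm_kappa": 2.0, "phase_mixture": 1.0},
    "deuterated": {"gamma": 0.9, "vm_kappa": 2.0, "phase_mixture": 0.3},
}


@dataclass(frozen=True)
class GeneratorParams:
    """Full parameterisation of one synthetic ensemble.

    ``phase_mixture`` is the weight of the *uniform* phase component; the
    remaining weight goes to the von Mises mixture at ``vm_centers``.
    ``temperature_scale`` multiplies the thermal scales (use
    :meth:`for_conditions` to derive it as sqrt(T / T_ref)).
    """

    n_frames: int = 1000
    seed: int = 0
    ref_bond_lengths: tuple = FURAN_BOND_LENGTHS
    ref_angles: tuple = FURAN_RING_ANGLES
    sigma_q: float = 0.04  # Å, Rayleigh scale of q2 at T_ref, protiated
    phase_mixture: float = 1.0  # weight of the uniform-phase component
    vm_centers: tuple = (0.0, 180.0)  # degrees
    vm_kappa: float = 2.0
    sigma_b: float = 0.02  # Å, isotropic coordinate jitter at T_ref
    temperature_scale: float = 1.0
    isotope_preset: str = "protiated"

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be ≥ 1")
        if self.sigma_q < 0 or self.sigma_b < 0:
            raise ValueError("sigma_q and sigma_b must be ≥ 0")
        if not 0.0 <= self.phase_mixture <= 1.0:
            raise ValueError("phase_mixture must lie in [0, 1]")
        if self.isotope_preset not in _ISOTOPE_PRESETS:
            raise ValueError(
                f"unknown isotope preset {self.isotope_preset!r}; "
                f"known: {sorted(_ISOTOPE_PRESETS)}"
            )
        if self.temperature_scale < 0:
            raise ValueError("temperature_scale must be ≥ 0")

    @property
    def sigma_q_effective(self) -> float:
        """Rayleigh scale of q2 actually sampled (thermal + isotope factors)."""
        gamma = _ISOTOPE_PRESETS[self.isotope_preset]["gamma"]
        return self.sigma_q * self.temperature_scale * gamma

    @property
    def sigma_b_effective(self) -> float:
        return self.sigma_b * self.temperature_scale

    @classmethod
    def for_conditions(
        cls,
        temperature: float = 300.0,
        isotope: str = "protiated",
        t_ref: float = 300.0,
        **overrides,
    ) -> "GeneratorParams":
        """Preset for a (temperature, isotopomer) study condition."""
        preset = _ISOTOPE_PRESETS[isotope]
        kwargs = {
            "temperature_scale": float(np.sqrt(temperature / t_ref)),
            "isotope_preset": isotope,
            "vm_kappa": preset["vm_kappa"],
            "phase_mixture": preset["phase_mixture"],
        }
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sigma_q_effective"] = self.sigma_q_effective
        d["sigma_b_effective"] = self.sigma_b_effective
        return d


# ---------------------------------------------------------------------------
# planar reference ring


def _walk(lengths, angles_deg) -> tuple[np.ndarray, np.ndarray]:
    """Turtle-walk a planar polygon; returns the 5 vertices and the
    misclosure vector (where the walk re-lands relative to the start)."""
    p = np.zeros(2)
    heading = 0.0
    pts = [p.copy()]
    for j in range(5):
        p = p + lengths[j] * np.array([np.cos(heading), np.sin(heading)])
        pts.append(p.copy())
        heading += np.pi - np.radians(angles_deg[(j + 1) % 5])
    return np.array(pts[:5]), pts[5] - pts[0]


def _interior_angles(xy: np.ndarray) -> np.ndarray:
    prev = np.roll(xy, 1, axis=0) - xy
    nxt = np.roll(xy, -1, axis=0) - xy
    cosang = np.sum(prev * nxt, axis=1) / (
        np.linalg.norm(prev, axis=1) * np.linalg.norm(nxt, axis=1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def build_reference_ring(
    ref_bond_lengths=FURAN_BOND_LENGTHS, ref_angles=FURAN_RING_ANGLES
) -> Frame:
    """Planar reference ring in the xy-plane, heteroatom first.

    The ring is laid out from the supplied bond lengths and interior angles;
    a closure gap above 1e-3 Å means the internal coordinates are
    inconsistent and raises :class:`RingClosureError`.  Any smaller residual
    is redistributed by a least-squares refinement of the vertex coordinates
    against the target lengths and angles.
    """
    lengths = np.asarray(ref_bond_lengths, dtype=float)
    angles = np.asarray(ref_angles, dtype=float)
    if lengths.shape != (5,) or angles.shape != (5,):
        raise ValueError("need exactly 5 bond lengths and 5 interior angles")
    if np.any(lengths <= 0):
        raise ValueError("bond lengths must be positive")
    xy0, gapvec = _walk(lengths, angles)
    gap = float(np.linalg.norm(gapvec))
    if gap > 1e-3:
        raise RingClosureError(
            f"ring does not close: gap {gap:.6f} Å exceeds 1e-3 Å; "
            "bond lengths and interior angles are inconsistent"
        )

    def residuals(x: np.ndarray) -> np.ndarray:
        xy = x.reshape(5, 2)
        r = np.linalg.norm(np.roll(xy, -1, axis=0) - xy, axis=1)
        ang = _interior_angles(xy)
        # angle residuals weighted to comparable magnitude (1° ≈ 0.02 Å here)
        return np.concatenate([r - lengths, np.radians(ang - angles)])

    sol = least_squares(residuals, xy0.ravel(), method="trf", xtol=1e-15, ftol=1e-15)
    xy = sol.x.reshape(5, 2)
    xy = xy - xy.mean(axis=0)
    # orient with the heteroatom on the +y axis, mirror axis vertical
    angle = np.arctan2(xy[0, 1], xy[0, 0])
    rot = np.pi / 2 - angle
    c, s = np.cos(rot), np.sin(rot)
    xy = xy @ np.array([[c, s], [-s, c]])
    coords = np.concatenate([xy, np.zeros((5, 1))], axis=1)
    return Frame(index=0, elements=("O", "C", "C", "C", "C"), coords=coords)


def symmetric_ring_angles(lengths, apex_angle: float) -> tuple[float, ...]:
    """Interior angles closing a mirror-symmetric pentagon.

    For bond lengths of the symmetric pattern (a, b, c, b, a) and a chosen
    apex angle at position 0, solve for the remaining two angles
    (θ1 = θ4, θ2 = θ3) such that the pentagon closes exactly.
    """
    lengths = np.asarray(lengths, dtype=float)
    if not (
        np.isclose(lengths[0], lengths[4]) and np.isclose(lengths[1], lengths[3])
    ):
        raise ValueError("lengths must follow the symmetric pattern (a, b, c, b, a)")

    def eqs(x):
        t1, t2 = x
        _, gapvec = _walk(lengths, [apex_angle, t1, t2, t2, t1])
        return gapvec

    guess = np.array([(540.0 - apex_angle) / 4.0] * 2)
    sol, info, ier, msg = fsolve(eqs, guess, full_output=True)
    if ier != 1:
        raise RingClosureError(f"could not close symmetric pentagon: {msg}")
    t1, t2 = sol
    return (apex_angle, float(t1), float(t2), float(t2), float(t1))


# ---------------------------------------------------------------------------
# ensemble sampling

_BASIS = 4.0 * np.pi * np.arange(5) / 5.0


def sample_frames(params: GeneratorParams) -> Trajectory:
    """Draw a seeded synthetic ensemble as a Trajectory (Å, xyz dialect).

    Per frame: the Cremer–Pople amplitude q2 is the modulus of a 2D Gaussian
    of scale :attr:`GeneratorParams.sigma_q_effective` (Rayleigh), the phase
    φ2 comes from the uniform / von Mises mixture, the displacement pattern
    ``z_j = sqrt(2/5) · q2 · cos(φ2 + 4πj/5)`` is imposed along the ring
    normal of the planar reference, and isotropic Gaussian jitter of scale
    ``sigma_b_effective`` is added to every coordinate.
    """
    rng = np.random.default_rng(params.seed)
    ref = build_reference_ring(params.ref_bond_lengths, params.ref_angles)
    n = params.n_frames

    ab = rng.normal(scale=1.0, size=(n, 2))
    q2 = params.sigma_q_effective * np.hypot(ab[:, 0], ab[:, 1])

    uniform_phase = rng.uniform(0.0, 360.0, size=n)
    centers = np.asarray(params.vm_centers, dtype=float)
    which = rng.integers(len(centers), size=n)
    vm_phase = np.degrees(
        rng.vonmises(np.radians(centers[which]), params.vm_kappa, size=n)
    ) % 360.0
    use_uniform = rng.random(n) < params.phase_mixture
    phase = np.where(use_uniform, uniform_phase, vm_phase)

    from .puckering import mean_plane_normal

    nhat = mean_plane_normal(ref.coords)  # pucker displaces along the CP normal
    z = np.sqrt(2.0 / 5.0) * q2[:, None] * np.cos(np.radians(phase)[:, None] + _BASIS)
    coords = np.broadcast_to(ref.coords, (n, 5, 3)).copy()
    coords += z[:, :, None] * nhat
    if params.sigma_b_effective > 0:
        coords += rng.normal(scale=params.sigma_b_effective, size=(n, 5, 3))

    frames = [
        Frame(index=i, elements=ref.elements, coords=coords[i]) for i in range(n)
    ]
    return Trajectory(frames=frames, source_dialect="xyz", length_unit_of_source="angstrom")


def planar_fraction_law(q2_threshold: float, sigma_eff: float) -> float:
    """Analytic planar fraction P(q2 < c) = 1 − exp(−c²/(2σ²)) (Rayleigh CDF)."""
    if sigma_eff == 0:
        return 1.0
    return 1.0 - float(np.exp(-(q2_threshold**2) / (2.0 * sigma_eff**2)))
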