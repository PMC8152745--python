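# Methods

`ringpucker` quantifies the out-of-plane dynamics and aromaticity of a
five-membered ring (furan and its isotopomers being the motivating case) over
a configurational ensemble — typically frames of a finite-temperature MD
trajectory — and reduces them to the standard reporting artifacts of the
field: per-frame puckering coordinates, conformer-class populations,
distribution summaries and occupancy maps.

## Puckering coordinates

For ring atoms indexed j = 0..4 in cyclic order starting at the heteroatom,
two descriptions of non-planarity are computed per frame.

**Torsion-based (ZPD) pair (S, ψ).** The five endocyclic torsions
τ_j (dihedral over atoms j, j+1, j+2, j+3 mod 5, IUPAC sign convention,
degrees) of a puckered five-ring follow, to good accuracy, a single
pseudorotation mode

    τ_j ≈ S · cos(ψ_raw + 4πj/5).

Because the cosine basis is orthogonal over five equally spaced samples, the
projection

    A = (2/5) Σ_j τ_j cos(4πj/5),   B = −(2/5) Σ_j τ_j sin(4πj/5)
    S = √(A² + B²),                  ψ_raw = atan2(B, A)

is exact for pure-mode torsion vectors (recovered to 1e-9; tested). S is
reported as this torsional Fourier amplitude in degrees; no additional
dimensionless rescaling is applied (a multiplicative calibration would cancel
out of every histogram, threshold and population in a scale-consistent way,
so only cross-study comparison would need it).

**Phase origin.** ψ = 0 is anchored on the envelope conformation with the
heteroatom as flap, displaced to the positive side of the mean plane
("envelope-at-O, up"). The raw torsional phase of that conformer, ψ_ref, is
computed once at startup from a constructed canonical geometry (a regular
pentagon of circumradius 1.17 Å carrying the pure envelope displacement
pattern at small amplitude; ψ_ref = 306.0° for that ring) and subtracted:
ψ = (ψ_raw − ψ_ref) mod 360. A planar frame (S = 0) reports ψ = 0 by
convention.

**Cremer–Pople pair (q2, φ2).** The classical displacement-based coordinates
for N = 5: positions are centred on the ring centroid, the mean plane is
defined by the normal of R' × R'' with R' = Σ r_j sin(2πj/5),
R'' = Σ r_j cos(2πj/5), the out-of-plane displacements z_j (Σ z_j = 0 by
construction) are projected as

    q2 cos φ2 = √(2/5) Σ z_j cos(4πj/5),
    q2 sin φ2 = −√(2/5) Σ z_j sin(4πj/5).

q2 is in Å. With the shared phase origin, ψ tracks φ2 with a residual of
about 1° (sd) on thermal ensembles, and S tracks q2 with rank correlation
> 0.99; the effective gearing for the furan geometry is ≈ 120° of S per Å of
q2. This concordance is asserted in the test suite, which operationalizes the
accepted view that the scheme choice is immaterial for common heterocycles.

## Conformer wheel and symmetry classes

The 20 canonical conformers live every 18° on the pseudorotation wheel,
envelopes (E) and twists (T) alternating. From the displacement pattern
z_j ∝ cos(ψ + 4πj/5): at ψ = 36·m the pattern is an envelope with flap atom
m mod 5 (up for even m); at ψ = 18 + 36·m a twist about bond (m, m+1) mod 5.

A ring with a mirror plane (furan: fixes O, swaps the α and the β carbons)
induces an equivalence on the wheel. The implemented group is generated by
(a) the mirror acting on anchors, ψ → −ψ − 144·c for the reflection
j → (c − j) mod 5, and (b) optionally the up/down flip ψ → ψ + 180°. For
furan with up/down equivalence this reduces 20 conformers to 6 classes with
orbit sizes {2, 4, 4, 4, 4, 2}: envelope O, twist O–Cα, envelope Cα,
twist Cα–β, envelope Cβ, twist Cβ–β.

One subtlety is documented by a dedicated test: *relabeling* the atoms of a
fixed geometry by the mirror permutation maps ψ → 180° − ψ, not −ψ, because
reversing the traversal direction flips the measured mean-plane normal. With
up/down equivalence enabled both maps generate the same four-element group,
so classifications are invariant under relabeling either way.

**Classification.** A frame with S below the planarity threshold is planar;
otherwise it is assigned to the nearest wheel position in circular distance
(an exact 9° midpoint tie goes to the numerically lower wheel phase — a
deterministic, measure-zero rule). The threshold is a required parameter with
a documented default of **S < 5°**. No authoritative cutoff exists for
"planar": reported planar populations are threshold-dependent, and every
output file echoes the threshold used. Comparisons across runs are only
meaningful at a common threshold.

## Aromaticity indices

Both indices are per-frame functions of the five ring bond lengths
(instantaneous geometry, not time-averaged — distribution ranges only exist
for per-frame evaluation).

* HOMA = 1 − (1/5) Σ α_t(i) (R_opt,t(i) − R_i)², with per-bond-type
  constants; 1 at the all-optimal geometry, unbounded below.
* Bird I5 = 100·(1 − V/V_K), where V = (100/N̄)·√(Σ(N_i − N̄)²/5) is the
  relative spread of Gordy bond orders N = a/R² − b and V_K = 35 is the
  five-membered-ring reference spread; 100 at equalized orders, not clamped
  below zero.

Shipped defaults (overridable; every summary records the values used):
α_CC = 257.7 Å⁻², R_opt,CC = 1.388 Å; α_CO = 157.38 Å⁻², R_opt,CO = 1.265 Å;
Gordy a_CC = 6.80, b_CC = 1.71; a_CO = 5.75, b_CO = 1.85. These are the
common literature parameterisation for CC/CO bonds; index values are
meaningless without their parameterisation pinned, which is why they are
configuration rather than constants.

"Range" in summaries is max − min over frames; the median of an even count
is the midpoint of the two central order statistics.

## Synthetic thermal ensembles

The generator produces the statistical structure the analysis assumes,
without integrating dynamics:

* **Pucker mode.** The (q2 cos φ2, q2 sin φ2) components are drawn from an
  isotropic 2D Gaussian of scale σ_eff, so q2 is Rayleigh(σ_eff) and the
  planar fraction under a q2 threshold c is exactly 1 − exp(−c²/2σ_eff²) —
  the quantitative backbone of the end-to-end population tests.
* **Phase.** Mixture of a uniform component (weight w, free pseudorotation)
  and von Mises components at configurable centres (phase localisation).
* **Bond fluctuation.** Isotropic Gaussian coordinate jitter of scale σ_b,
  which spreads the bond lengths and therefore the aromaticity indices.
* **Conditions.** σ_eff = σ_q · √(T/T_ref) · γ. The thermal factor √(T/T_ref)
  is applied to both σ_q and σ_b: classical equipartition scales every
  harmonic fluctuation amplitude the same way, and the temperature trend of
  the mean indices is carried precisely by the bond-length fluctuation.
  γ < 1 is the isotope stiffening factor of the out-of-plane mode.

Defaults, chosen once as realistic scales for an isolated aromatic five-ring
and kept fixed: σ_q = 0.04 Å and σ_b = 0.02 Å at T_ref = 300 K; reference
geometry R(CO) = 1.362 Å, R(Cα–Cβ) = 1.361 Å, R(Cβ–Cβ) = 1.431 Å with
interior angles (106.50, 110.72, 106.03, 106.03, 110.72)° that close the
pentagon exactly (these are typical literature values for furan, not claimed
from any specific study). With the default 5° threshold these scales put the
room-temperature planar population in the ≈ 35–40% regime and give planar
populations of roughly 94% at 50 K and 23% at 500 K. Isotope presets are
phenomenological: protiated (γ = 1, uniform phase) versus deuterated
(γ = 0.9, uniform weight 0.3, κ = 2 at centres 0°/180°); they reproduce the
qualitative contrasts (lower mean S, phase localisation) rather than any
mass-weighted dynamical model, because no quantitative isotope scaling is
available to implement.

**What the generator does not emulate:** time correlation (frames are iid),
anharmonicity and mode coupling, realistic vibrational eigenvectors (jitter
is white), hydrogen atoms (frames carry the five ring atoms only — no
computed quantity depends on substituents), and any electronic-structure
response. Passing tests therefore validate the *analysis machinery* and its
statistical laws, not the physics of any particular simulation.

**Reference-ring construction.** The planar reference is laid out by a
turtle walk from bond lengths and interior angles; a closure gap above
1e-3 Å is an error (inconsistent internal coordinates), a smaller residual
is redistributed by least-squares refinement of the vertex coordinates
against the target lengths and angles (angle residuals in radians, making
1° ≈ 0.02 Å — comparable magnitude to the length residuals). A helper solves
the closing angles for mirror-symmetric custom bond lengths.

## Numerical and I/O choices

* Bohr → Å conversion fixed at 0.529177210903 (CODATA 2018).
* Degenerate geometry (collinear mid-bond, collinear ring) raises; frames
  with non-finite coordinates are rejected, never skipped — populations are
  ratios, and silent exclusion would bias them. Malformed trajectory blocks
  abort with the offending line and frame named.
* S = 0 frames report ψ = 0; phases are folded to [0, 360).
* Trajectory XYZ output uses 8 decimals (round-trips to < 1e-6 Å); analysis
  tables use a fixed 6-decimal format so identical inputs give byte-identical
  outputs.
* Default binning: S histogram at 1°, ψ in 36 bins of 10° (resolving the 18°
  wheel spacing); histogram frequencies are per-bin fractions, not densities.
* ψ binning is circular: 359.9° falls in the last bin, never out of range.

## Problem sizes

The test suite uses ensembles of 300–10⁵ frames depending on the statistical
claim (10⁵ for the 1%-level Rayleigh-moment and planar-fraction laws, 10⁴
for rank-correlation and isotope significance tests, a few hundred for
invariance checks); the acceptance script uses 10⁴–10⁵ frames per quantity.
The full suite and the script each complete in well under a minute on a
single core.

## Known limitations

* The ZPD amplitude is reported on its natural torsional scale (degrees);
  comparing absolute S values across studies may require a single
  multiplicative constant.
* Conformer populations are hard-threshold counts; near-threshold frames are
  not fractionally weighted.
* Only N = 5 rings are supported — the basis functions and the wheel are
  specific to five-membered rings.
* The cpmd trajectory dialect delimits frames by step-value change, so files
  with duplicated step values (e.g. restart overlaps) must be cleaned first.
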