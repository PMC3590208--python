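# Methods

`fftdock` implements initial-stage rigid-body protein–protein docking:
an exhaustive FFT search over the 6D space of relative placements of a
moving ligand against a stationary receptor, followed by proximity
clustering, knowledge-based soft filtering, and optional rescoring by a
Generalized Born (GBSA) solvation model.  This note records the model,
the numerical choices, the parameters that matter, and what the shipped
synthetic fixtures can and cannot demonstrate.

## Search model

A pose is a pair (r, t): a rotation of the ligand about its geometric
center and a displacement of that center.  Rotations are sampled
deterministically on a covering grid of SO(3) (below); for each rotation,
all translations on a cubic grid are scored at once by FFT
cross-correlation.  The grid spacing defaults to h = 1.2 Å and the grid
is sized to hold the receptor sphere and ligand sphere side by side, so
periodic wraparound can never alias a contacting pose.

Only translations inside a *band* around the receptor are kept: a node
belongs to the band if a sphere of the ligand's circumradius centered
there overlaps the receptor. The band is computed once by convolving the
receptor occupancy with a ball kernel (one FFT pair); on globular
receptors it covers well under half the grid. Planes of the ligand grid
that are identically zero are skipped in the forward transform, and the
inverse transform only evaluates planes that intersect the band; both
shortcuts are exact.

### Affinity channels

Three channels are correlated per rotation and combined linearly with
per-complex-type weights (w_sc, w_el, w_ip):

* **Shape complementarity (SC).** Double skin-layer scoring: the
  receptor's *grown skin* is a shell of chargeless pseudo-atoms sampled
  on an offset surface (stand-off d_float = 1.0 Å, pseudo-atom radius
  1.1 Å, ~1 sample/Å² merged at 1.0 Å), and the ligand skin is its
  surface-atom layer (plus atoms within 3.0 Å of it in the improved
  mode).  Skin atoms carry positive real weights, core atoms positive
  imaginary weights; with complex fields f_A, g_B the real part of the
  correlation is skin–skin − core–core overlap and the imaginary part is
  the skin–core clash magnitude, subtracted with weight λ_sc.
  Atoms are rendered as Gaussians with σ = radius/2: wide enough that
  the floating skin overlaps ligand surface atoms across the ~1 Å native
  gap, narrow enough that the contact geometry stays sharp at h = 1.2 Å.
  In the improved mode receptor skin weights are modulated by local
  curvature — the fraction `occ` of a 3 Å probe ball inside the molecule
  (0.5 at a flat surface) enters as 1 + κ(0.5 − occ) — and core weights
  grow linearly with burial depth (distance to the nearest surface atom,
  slope 0.5/Å, capped at 2.5×), so deep interpenetration costs more than
  grazing overlap.
* **Electrostatics (EL).** The receptor's potential is evaluated on the
  grid from its Gaussian-smeared charges (σ = radius/2, each Gaussian
  normalized to its charge) through a distance-dependent dielectric
  ε(r) = 4r clamped below 1 Å, i.e. kernel 1/(4·max(r,1)²), applied by
  FFT convolution.  The ligand's smeared charge density is correlated
  against this potential; the score sign is chosen so that
  opposite-charge contact is positive.
* **Interface propensity (IP).** Each residue type carries the natural
  log of its relative interface frequency, spanning −0.38 (ASP) to 0.83
  (TRP).  The receptor skin-band indicator is correlated with a ligand
  field carrying per-atom propensities on skin atoms.  A companion
  indicator–indicator correlation estimates the skin-overlap volume; a
  pose whose overlap falls below `ip_overlap_min` (default 1.0 grid
  units, about a third of a genuine pocket contact on the reference
  fixture) is assigned a fixed small-interface penalty value instead.

The two IP correlations share one complex FFT (propensity in the real
part, the indicator in the imaginary part), so each rotation costs three
forward and three inverse transforms.

### Calibrated constants

The published protocol trained its weights on a benchmark that is out of
scope here, and printed neither the trained values nor the skin-clash
weight.  The defaults below were calibrated **once** on the shipped
pocket-and-plug fixture and then frozen:

| parameter | default | role |
|---|---|---|
| w_skin / w_core | 1.0 / 9.0 | real skin and imaginary core weights |
| λ_sc | 1.0 | skin–core clash weight; per overlapping pair the clash term (w_skin·w_core·λ = 9) stays an order of magnitude below the core–core term (w_core² = 81) |
| σ (SC/IP/EL) | radius/2 | soft-ball atom rendering |
| ip_overlap_min | 1.0 | small-interface cut, smeared-overlap units |
| w_sc, w_el, w_ip | per type | (1.0, 0.3, 0.4) antibody, (1.0, 0.4, 0.2) enzyme, (1.0, 0.3, 0.3) other |

λ_sc matters most: a small ligand whose atoms are all skin (no core) is
otherwise free to burrow into the receptor, because core–core repulsion
never triggers.

## Rotation sampling

The sample set is a product construction: a Fibonacci-spiral point set
on the sphere supplies the image of the z-axis (the β, γ Euler pair) at
angular spacing δ, crossed with 2π/δ uniform twist angles α (z-y-z
composition), then de-duplicated at angular distance δ/2 keeping earlier
samples.  The identity is always sample 0.  Measured covering radius is
≈ 0.7δ (Monte-Carlo over 10⁴ random rotations), and the count grows as
1/δ³ while staying below the independent Euler-angle grid of the same
resolution (5088 vs 6912 at δ = 15°).  Angular distance between
rotations is arccos((tr(R₁ᵀR₂) − 1)/2).

## Clustering

Poses are processed in descending score order; for each pose, m counts
retained poses with better (pre-penalty) score whose ligand centers lie
within 5 Å.  The first matching tier applies: m ≥ 8 → −95%, m ≥ 4 →
−90%, m ≥ 1 → −85% of the score magnitude.  The lowest tier triggers at
a single better neighbor so that *all but the best pose of a cluster*
are penalized, and the reductions are deliberately heavy: the filter
stage rescales scores after clustering and would otherwise re-crowd the
top of the list with duplicates of the strongest basin.  Counting on
pre-penalty scores makes the result independent of processing order;
the stage is exactly deterministic (no thread-order effects) and changes
only the ordering, never the pose set.

## Filters

Seven soft filters act on the top 2000 poses; each verdict adds or
subtracts a fraction of the pose's score magnitude (default −30%
penalty, +10% reward), so no single filter is fatal.  Interface
extraction runs through the packing-grid/octree machinery, with a
vectorized distance-matrix path for small inputs (both paths return
identical pair sets; the tree path is exercised explicitly in tests).

1. *Interface propensity*: area-weighted propensity sum over interface
   quadrature points of both molecules, I = (P_A+P_B) + β(N_A+N_B);
   reward above T_hi, penalize below T_lo (placeholders 150 / 5 Å²·l_p).
2. *Residue–residue contacts*: Cβ–Cβ (Cα for Gly; ideal tetrahedral
   reconstruction when Cβ is absent) contacts under 6 Å scored with a
   symmetric log contact-preference matrix; penalize when the
   preferred/avoided ratio leaves the configured range.  All-preferred
   contact sets are in range by convention.
3. *Lennard-Jones*: softened 12-6 energy (repulsive term × 0.5 for
   unbound inputs, 12 Å cutoff, Lorentz–Berthelot mixing of per-element
   Amber-style parameters); penalize if positive.
4. *Steric clashes*: count pairs closer than 0.6·(r_i+r_j); penalize
   above 5.
5. *Interface area*: buried quadrature area outside [100, 5000] Å².
6. *Glycine motifs* (enzyme runs): surface G-X-Y / Y-X-G tripeptides
   (X polar, Y non-polar) touching the interface; reward proportional to
   the count, penalize when below threshold.
7. *Antibody CDR contacts* (antibody runs): antigen atom counts within
   5 Å of CDR-L1∪H1, CDR-L3 and CDR-H3 must each reach their configured
   minimum (default ≥ 1).

CDR loops are located from sequence anchors (Cys before L1/L3/H1/H3,
Trp after L1/H1, FGxG after L3, WGxG after H3, fixed framework offsets
between loops); both a light-pattern chain and a separate heavy-pattern
chain are required, so heavy-chain-only antibodies are deliberately not
recognized.  Complex typing: antibody if CDRs are found on either
molecule; else enzyme if a molecule has ≥ 200 residues with ≥ 8% surface
glycines; else other.

## Surface machinery

Surface detection and quadrature use deterministic Fibonacci sphere
sampling: an atom is surface if any point on its probe-inflated sphere
escapes all neighbor spheres; quadrature covers each accessible sphere
at a target density (default 1/Å²), discards buried points, and gives
every survivor an equal share of its sphere's area, so patch weights sum
to the exposed area (single-sphere total area accurate to < 2% at the
default density).  Points carry outward normals, the parent atom, and a
propensity label averaged over atoms within 4 Å.

## GB rescoring

Solvation free energy Gsol = Gcav + Gvdw + Gpol with:

* Gcav = p·V + γ·SASA, p = 0.008 kcal/(mol·Å³), γ = 0.0072
  kcal/(mol·Å²).  The volume uses the spherical-sector form
  V = (1/3)Σ a_k (x_k − c_parent)·n_k, which is exactly rigid-motion
  invariant and exactly additive for separated molecules; the naive
  divergence sum over absolute positions amplifies quadrature
  non-closure by the lever arm to the origin.
* Gvdw = Σ σ_i·SASA_i with bundled per-element solvation parameters;
  buried atoms contribute nothing.
* Gpol from Generalized Born theory with the Still interpolation
  f_GB = √(r² + R_iR_j·exp(−r²/4R_iR_j)), self-terms included; effective
  Born radii from the Coulomb-field surface integral
  1/R_i = (1/4π)Σ a_k (x_k−c_i)·n_k/|x_k−c_i|⁴ evaluated on the van der
  Waals surface quadrature (probe 0), floored at the intrinsic radius.
  A single ion recovers the Born equation exactly.  Beyond an
  analytically chosen distance (per-pair relative error ≤ ε_tol/10,
  default ε_tol = 10⁻³) the Coulomb limit f_GB → r is used.

Component energies for the two molecules are precomputed; each rescored
pose gets fresh quadrature and Born radii for the posed union.  The
rescoring criterion is ΔGsol + the direct intra-complex Coulomb energy
(ε_in = 1): pure ΔGsol alone *rewards* burying like charges and
*penalizes* salt bridges, because Born self-energies scale with the
square of the local net charge — adding the vacuum Coulomb term is the
standard GBSA treatment and restores physical charge complementarity.
Enzyme-type runs skip the rescoring stage by default, where the glycine
filter already carries the signal.

Numerical caveat: sphere-sampling directions are fixed in the lab frame,
so ΔGsol under joint rigid motion of the complex is reproducible only to
quadrature orientation noise (~1–2%), not to machine precision.

## Evaluation

The receptor never moves, so predicted and native ligand placements are
compared directly without superposition.  IRMSD is the RMSD over native-
interface ligand backbone atoms (N, CA, C, O within 10 Å of any receptor
atom in the native pose); a hit is IRMSD ≤ 5 Å.  fnat is the recovered
fraction of native residue contacts (any-atom distance < 5 Å, the CAPRI
convention — the contact threshold is a documented package choice).
CAPRI classes: high (fnat ≥ 0.5, IRMSD ≤ 1), medium (≥ 0.3, ≤ 2),
acceptable (≥ 0.1, ≤ 4), else incorrect.  Rank statistics report the
top/best hit per complex, counts of complexes with the top hit in the
standard rank ranges, and the rate-of-success curve H(k)/H(k_max).

## Synthetic fixtures

`make_pocket_plug` builds the reference test system: a ~120-atom lattice
sphere receptor, a plug shaped as an ellipsoid with an off-axis bump
(anisotropic, so only the native orientation fits), and a cavity carved
as the inflated plug, giving complementary van der Waals surfaces with a
1 Å native gap.  Opposite charges are planted across the interface and
each molecule is then neutralized (proteins carry little net charge;
monopoles would dominate every electrostatic limit).  Residue names
cycle through a motif covering high- and low-propensity types, glycine
and charged residues, so every filter has signal.  Atom radii are drawn
in 1.5–1.9 Å from the seed.  The standard conditions used by the
validation suite are seed 7, 30° rotational sampling and a 32³ grid —
sizes chosen so the complete pipeline runs in minutes on one core.

What passing on these fixtures shows: the FFT scoring is exact (verified
against direct correlation), the geometric filters agree with
brute-force enumeration, the GB model satisfies its closed-form limits,
and the assembled pipeline recovers a planted complementary pose and
keeps the top of its ranked list spatially diverse.  What it does not
show: performance on real protein complexes — the fixtures have no
backbone geometry, no side chains, no conformational change on binding,
and far smoother score landscapes than real interfaces; the trained
thresholds of the original protocol remain placeholders.

## Known limitations

* Flexibility is handled only through soft scoring (reduced LJ
  repulsion, floating skin); there is no refinement stage.
* The propensity and contact-preference tables anchor only their
  published extreme values; intermediate entries are synthetic
  interpolations (see `data/propensity_synthetic.txt`).
* Small quadrature orientation noise breaks exact frame invariance of
  the GB energies (see above).
* The filter thresholds and channel weights are honest placeholders,
  configurable per run; they have not been trained on any benchmark.
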