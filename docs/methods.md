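# Methods

`orientscan` scores rigid-body orientations of a two-body protein complex
by long-range polar energetics. The motivating application is the T-cell
receptor (TCR) over a peptide–MHC: after the bound complex is pulled apart
by ~8 Å along the receptor's long axis, the remaining electrostatic
landscape as a function of rotation about that axis forms a funnel that
pre-orients the receptor before contacts form. The package reproduces that
protocol on arbitrary prepared two-body PDB inputs and on bundled synthetic
fixtures with known ground truth.

## The model

### Bodies, frame and poses

Chains are assigned to a MOBILE body (the receptor) and a FIXED body (the
target, e.g. MHC heavy chain + β2-microglobulin + peptide). The scan frame
takes local +x as the mobile body's principal axis — the largest-eigenvalue
eigenvector of its unweighted gyration tensor — sign-fixed to point from
the fixed-body centroid toward the mobile-body centroid. For an
immunoglobulin variable-domain dimer this is the long axis orthogonal to
the binding plane. A pose is (separation s, angle θ): rotate the mobile
body right-handedly by θ about the axis through its own centroid along x,
then translate it by s along +x. Rotations are applied as exact orthogonal
matrices; intra-body geometry is preserved to machine precision.

Design choices where the construction was open:

* y is the projection of the global +z off the x axis (global +y as a
  fallback when nearly parallel): deterministic and independent of atom
  order, at the cost of full-frame equivariance (only the x axis is
  equivariant under a global rotation of the input — the scan itself only
  depends on x).
* The rotation center is the mobile-body center of geometry, which keeps
  the body on-axis during the scan.
* A body whose top two gyration eigenvalues coincide (no unique principal
  axis) is a hard error; `axis_mode="centroid-line"` uses the normalized
  centroid-difference vector instead. A collinear body is fine — its
  principal axis is unambiguous.

### Parameterization

A bundled CHARMM-style all-atom residue-template table
(`data/residue_templates.json`) supplies partial charges, Lennard-Jones
types and covalent bonds for the 20 standard amino acids plus charged
terminal patches (NH3+/COO−, applied to true chain termini only; a config
flag selects neutral termini). Charges derive from the CHARMM22 protein
topology mapped onto PDB v3.3 atom names, with minor atom-type
simplifications that preserve each residue's exact formal charge;
Lennard-Jones well depths and Rmin/2 follow the matching nonbonded table.
Intrinsic radii are element-based Bondi-style radii (H 1.2, C 1.7, N 1.55,
O 1.5, S 1.8 Å) and the descreening scale factors are the standard
element-wise values (H 0.85, C 0.72, N 0.79, O 0.85, S 0.96).

Histidine defaults to the neutral Nε2–H tautomer. Missing heavy atoms are a
hard error (no rebuilding); `allow_missing` downgrades this to a warning
and drops the affected charges with a logged net-charge delta. Missing
hydrogens are rebuilt from template connectivity at idealized local
geometry (tetrahedral/trigonal completion, staggered torsions, X–H bond
lengths 1.09/1.01/0.96/1.34 Å for C/N/O/S); positions are deterministic
functions of the heavy atoms. HETATM records, waters and secondary altlocs
are discarded. Structures are assumed prepared/minimized; no internal
minimization is performed.

### Energy terms

All energies are in kcal/mol, distances in Å, charges in e, with
k = 332.0716 kcal·Å/(mol·e²), ε_protein = 1, ε_solvent = 80 by default.

* **Coulomb** — Σ_{i<j} k q_i q_j / (ε_p r_ij) · S(r), with the CHARMM
  energy-shift factor S(r) = (1 − (r/r_c)²)², r_c = 12 Å.
* **GB polar solvation** — the Generalized Born energy
  −τ/2 Σ_{i,j} q_i q_j / f_GB with τ = k (1/ε_p − 1/ε_s) and the Still
  interpolation f_GB = sqrt(r² + R_i R_j exp(−r²/(4 R_i R_j))); self terms
  (f = R_i) are always included in the full sum.
* **Lennard-Jones** — 12-6 with Lorentz–Berthelot combination, switched to
  zero over [10, 12] Å.
* **Non-polar solvation** — γ·SASA with γ = 0.015 kcal/(mol·Å²), probe
  1.4 Å, Shrake–Rupley sampling on a fixed 256-point golden-spiral set.
  SASA is evaluated in a body-fixed principal-axis frame so that, like the
  strictly pairwise terms, it is invariant under global rigid motion of the
  input (the property that motivates non-grid continuum models).

**Truncation of the GB pair terms.** The off-diagonal GB pair terms are
attenuated by the same shift factor S(r) as the Coulomb term (self terms
are never truncated). This is deliberate: the GB pair term is the solvent
screening of the Coulomb interaction, and truncating one without the other
flips the sign of every screened interaction beyond ~4 Å — a
charge-complementary interface would then appear as a rotational energy
*maximum* at scan separations. With the consistent shift the effective
pair interaction is q_i q_j (k/r − τ/f_GB) S(r): physically signed at
every distance, smoothly zero at the cutoff, and in line with how
CHARMM-family nonbonded routines truncate continuum pair sums. The flag
`EnergyModel.gb_pair_shift` restores the untruncated sum if set to False.

Rigid bodies make intra-body bonded and nonbonded energies constant, so
1-2/1-3/1-4 exclusions are unnecessary: the package only ever reports
inter-body Coulomb/LJ, the GB energy (whose radii do change with pose),
and SASA differences.

### Born radii

The paper-level protocol needs per-atom Born radii but not a specific
estimator, so the estimator is pluggable (`gb_radii_method`):

* `pairwise_descreening` (default) — Hawkins–Cramer–Truhlar-style analytic
  integral over scaled neighbor spheres, 1/R_i = 1/ρ_i − Σ_j H(r_ij, S_j ρ_j).
  An isolated atom recovers its intrinsic radius exactly (no offset is
  subtracted by default); buried atoms get larger radii; the inverse radius
  is floored so fully buried atoms cap at 1000 Å.
* `fixed_intrinsic` — radii equal intrinsic radii; a fast degraded mode.
* `external` — radii supplied by the caller.

Radii are re-estimated at every pose (they change as one body descreens
the other); all decomposition identities are estimator-agnostic. The
operational definition — charge a single atom in the otherwise uncharged
system, evaluate the engine's solvation energy ΔG_i, and invert
R_i = −τ q_i²/(2 ΔG_i) — is exposed as `born_radius_from_engine` and
round-trips the estimator's radii to machine precision.

### Decomposition and correlations

Pair energies are split half-and-half between their two atoms (the
standard MM-GBSA convention; the per-atom sum over "all j" double-counts
unless halved), GB self terms belong wholly to their atom, so atom shares
sum exactly to each term's total. Sub-group rotation-profile vectors W_sel
are sums of inter-body (Coulomb + GB) shares over the selection, aligned
index-for-index with the system profile. The canonical groups are MHC
(including β2-microglobulin), PEPTIDE, CDR3, and CDR12 — the mobile body
without CDR3, i.e. CDR1 + CDR2 + framework. CDR boundary definitions vary
between numbering schemes, so loop ranges are required as input, never
guessed.

A selection's contribution is the inner product of the centered,
normalized vectors, c = Ŵ_syst · Ŵ_sel (a Pearson coefficient). Poses
masked in either vector are dropped from both; vectors with zero variance
or fewer than three usable poses are an error, not a NaN. The windowed
variant restricts poses to ±30° of the primary and secondary minima.
Group correlations over a partition are not additive and are only
guaranteed to lie in [−1, 1].

### Scans, clash masking and minima

The default protocol is separation 8 Å, step 5° (72 poses), energies
reported relative to the profile minimum with the offset recorded. At each
pose the closest inter-body residue pair (via a KD-tree minimum-distance
search) is probed: the pose is masked when that pair's LJ energy exceeds
+10 kcal/mol or any inter-body atom pair is closer than 1.0 Å (both
configurable; no numeric criterion is canonical). A profile whose every
pose is masked is a hard error.

A local minimum is an unmasked pose strictly below its circular unmasked
neighbors; equal-value plateaus collapse to the member with the smallest
|angle|. The **primary** minimum is the deepest local minimum with
|angle| < 90°, the **secondary** the deepest outside that window; the
boundary is excluded from the primary window so a 90° optimum is reported
as secondary. The gap is E(secondary) − E(primary) and the primary is
flagged global when it attains the profile minimum. Landscapes run the
same scan over a list of separations, reporting fully-clashed rows as
absent rather than aborting.

### Rigid pulling

The pulling profile translates the mobile body from the bound pose in
0.1 Å steps and reports the full effective interaction energy: inter-body
Coulomb + LJ, the change in total GB solvation relative to the isolated
bodies (which contains mutual desolvation through the per-pose radii), and
the change in γ·SASA. The plateau is the value at the largest
displacement; the well depth is plateau − E(0); a barrier is recorded when
the interior maximum exceeds both the plateau and E(0) by a 0.05 kcal/mol
tolerance (guarding against SASA discretization ripple).

## Synthetic fixtures

Fixtures are built from real ALA/GLY/ASP/LYS residues at idealized
heavy-atom geometry (internal-coordinate construction), written as valid
PDB files and loaded through the ordinary pipeline — no special-case
parameterization. Seeded jitter makes regeneration bitwise reproducible.
The charged side-chain tips are deliberately oriented toward the interface
and, for the ridge, interdigitate slightly in the bound pose, because with
a 12 Å consistent cutoff only near-interface atoms carry signal at 6–12 Å
scan separations — the same reason real interfaces dominate the paper-level
profiles.

* `charge_ridge` — complementary rings of LYS/ASP tips (one swapped pair
  breaks the ring symmetry so the optimum is unique); the construction
  angle is the ground truth for funnel recovery, and amplitude decreases
  strictly with separation.
* `c2_dimer` — the mobile partner of each residue is its exact
  diag(1,−1,−1) image, so the body has bitwise C2 symmetry about the scan
  axis; its profile must be 180°-periodic with a zero primary/secondary
  gap. Perturbing a single charge by +0.1 e destroys the periodicity.
* `mini_complex` — six mobile residues (four interface "loops" labeled
  CDR1/2/3 plus a two-residue framework stalk), a four-residue MHC-like
  chain and a two-residue peptide chain; net-neutral bodies; the
  end-to-end path (load → scan → decompose → correlate) runs in seconds.
* `barrier_complex` — a ladder of salt bridges whose diagonal neighbors
  repel: short-range attraction, mid-range desolvation + like-charge
  repulsion, hence a pulling barrier at ~4 Å whose position is validated
  against a 0.01 Å dense scan.

What the fixtures do **not** emulate: real protein folds and packing,
conformational flexibility, realistic charge anisotropy of a TCR/pMHC
interface, bulged peptides, or crystal-structure noise. Passing tests
therefore demonstrate the correctness of the energy model, decomposition
identities, geometry and search machinery — not the biological accuracy of
predictions on deposited structures, which additionally depends on input
preparation and the Born-radius estimator.

## Numerical choices

* Pair singularity threshold 1e-6 Å (overlapping atoms are an error, not
  an infinity); Born-radius cap 1000 Å.
* Angle grids are exact multiples of the step, normalized to (−180°, 180°];
  a step that does not divide 360° is rejected.
* Profile energies are offset to the unmasked minimum; correlations are
  offset-invariant, and the offset is stored for absolute recovery.
* Sample standard deviations use the n−1 denominator; a single observation
  reports SD 0.
* Problem sizes used by the test-suite and the acceptance script — 72-pose
  scans of ~150–330-atom fixtures, 20-atom oracle systems, 0.1 Å pulls to
  20 Å with a windowed 0.01 Å refinement — were chosen so every property is
  exercised at full protocol resolution while the whole pipeline remains a
  few minutes of single-core work.

## Known limitations

* The Born-radius estimator is a pairwise-descreening surrogate, not the
  self-consistent volume-based model used in the original study; absolute
  polar energies differ even though every decomposition identity and
  protocol-level property is preserved.
* mmCIF, non-natural amino acids, pKa prediction and N-terminal proline
  patches are unsupported.
* Full-frame equivariance under global rotations holds for the x axis
  only (see above); profiles themselves are invariant.
* The SASA estimator is exactly rigid-motion invariant but only ~0.5%
  accurate in absolute area at 256 points, and contributes small
  deterministic ripple (~0.01–0.05 kcal/mol) to pulling profiles.
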