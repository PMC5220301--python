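# Methods

This note documents the models, estimators, numerical choices and
limitations behind each analysis stage, and what the synthetic fixtures do
and do not establish about real data.

## Coordinate model and units

Structures are parsed from PDB via Biopython into a light hierarchy
(Atom → Residue → chain → Structure) with **all lengths in nm** (PDB
Ångström are converted on read/write); energies are kcal/mol, areas nm².
Alternate locations resolve to the highest-occupancy conformer; waters and
hetero groups are dropped unless requested; multi-MODEL files become
coordinate frames over one shared topology. Residues keep author (PDB)
numbering so literature residue identifiers (94, 95, 101, 107, …) map
directly. Van der Waals radii are a united-atom heavy-atom table
(C 0.170, N 0.155, O 0.152, S 0.180, H 0.120 nm) so that hydrogen-free
docking/MD output can be analysed; element masses are standard atomic
weights.

Superposition uses the Kabsch SVD construction with the determinant
correction, so the returned transform is always a proper rotation; inputs
with fewer than three points or collinear geometry are rejected.

Secondary structure is assigned from backbone φ/ψ dihedrals: helix for
φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°] in runs of ≥ 4 residues; strand for
extended φ/ψ in runs of ≥ 3; otherwise coil. This deliberately captures
only the helix/strand-vs-loop distinction the viability filters need — it
is not a DSSP replacement (no hydrogen-bond pattern analysis), and a
user-supplied assignment always overrides it.

## Solvent-accessible surface area

Shrake–Rupley with a deterministic golden-section spiral lattice
(default 960 points/atom, probe 0.14 nm): per-atom area is the exposed
fraction of lattice points times 4π(r+probe)². Determinism makes results
bit-reproducible, and because the same lattice is used for a monomer alone
and inside the complex, added occluders can only bury points — so
ΔSASA = SASA(A) + SASA(B) − SASA(AB) is non-negative for *every* geometry,
not just in expectation. Against the exact two-intersecting-spheres cap
formula the engine is accurate to ~0.3% at 960 points; the mean error over
overlap geometries decreases with the point count, though the pointwise
error at a single geometry can fluctuate within the lattice resolution.
A residue is counted interfacial when it buries > 0.01 nm² (the sampling
noise floor at the default density, configurable). Relative exposure
divides per-residue area by a Gly-X-Gly theoretical maximum table; the
exposure threshold (default 0.25) is inclusive.

## Interface descriptors

* **Hydrogen bonds**: donor–acceptor heavy-atom distance ≤ 0.3 nm and, when
  explicit hydrogens exist, donor–H···acceptor deviation ≤ 20°. Without
  hydrogens the angle term is dropped and the report flags the heavy-atom
  fallback — docking output commonly lacks protons, and silently changing
  criteria would make counts incomparable.
* **Hydrophobic contacts**: the number of monomer-A carbons within 0.38 nm
  of any monomer-B carbon. This is deliberately the literal atom-level,
  A-sided definition (a symmetric variant is available by flag); the
  asymmetry matters only for heterodimers.
* **d_COM**: Euclidean distance between mass-weighted monomer centres.
* **Relative orientation δ**: monomer A is superposed onto the reference's
  monomer A, and δ is the axis-angle magnitude of the residual rotation
  taking the reference's B onto the observed B. δ(reference) = 0 and a
  rigid rotation of B by θ gives δ = θ. The exact published definition of
  this quantity is not standardised; this axis-angle construction is the
  package's documented choice, with frame 0 as the default per-trajectory
  reference.
* **Salt bridges**: basic-group N (Lys NZ; Arg NE/NH1/NH2; His ring N only
  when flagged protonated) within 0.4 nm of acidic-group O (Asp OD1/2,
  Glu OE1/2), inter-monomer only, deduplicated per residue pair.
* **π-stacks**: ring-centroid distance ≤ 0.55 nm; the inter-normal angle
  (folded to [0°, 90°]) classifies parallel (≤ 30°) vs t-shaped.
* **Quasi-symmetry**: Jaccard overlap of the two monomers' interfacial
  residue-index sets — 1 for a perfect C2 interface, 0 for disjoint
  contributions. Defined for homodimers only.
* **Ensemble summaries** use a centred running window (truncated at the
  ends) plus mean ± sd over frames.

## Pose clustering and viability filters

Pose distance is interface RMSD: superpose monomer A (Cα), measure Cα RMSD
over monomer B, minimised over the two monomer-label assignments so a
label-swapped symmetric pose is distance 0. Clustering is greedy leader in
descending density order with a configurable radius (default 0.4 nm); the
representative minimises summed intra-cluster RMSD with ties broken by
lowest pose index for determinism. Enrichment is cluster size over
ensemble size; clusters under 5% are minor and excluded, with an explicit
`promote_minor` override representing the manual promotion of a minor
cluster a curator may choose. The original docking package's own
clustering is unpublished; greedy leader is a transparent stand-in with
the same enrichment rule.

The filters evaluate cluster representatives:

1. **interface composition** — the interfacial residue set must intersect
   the hotspot/reactive-surface list, and at least one interfacial residue
   must be helix or strand ("not made up solely of flexible loops");
2. **effector exposure** — mean relative SASA of the designated
   effector-loop range, in the dimer, ≥ the exposure cutoff for *both*
   protomers (the range is a configuration value, default 25–40, the
   switch-I convention for Ras-family numbering);
3. **membrane competence** — the anchor directions (C-terminal anchor Cα
   minus own-monomer centre of mass) of the two protomers must have a
   positive dot product, and both anchors must be exposed. A
   best-fit-plane half-space test was considered and rejected: for
   elongated dimers the anchors lie essentially in the best-fit plane and
   the sign test is ill-conditioned; the direction-dot-product form tests
   the same physical requirement (both anchors can reach one membrane
   face) robustly.

An audit table records every cluster, every verdict and its reason.

## PMF integration and standard-state Kd

W(r) = −∫ F dr by trapezoid, anchored at the far edge and shifted so the
mean over the reference window (default r ≥ 4.6 nm) is zero; the reference
must be flat to 0.2 kcal/mol or the estimate aborts with advice to extend
the profile. Pointwise errors propagate the per-point force standard
errors through the *entire* linear construction, including the
re-referencing — adjacent trapezoid segments share grid points, so
propagation is at the point level; the error is therefore ≈ 0 inside the
reference window and grows away from it, and the resulting 2-SE band has
close to nominal coverage against known synthetic truths.

The association constant is the 1-D radial configurational integral
`Ka = C° ∫_bound 4πr² e^(−W/RT) dr` with C° = 1/1.661 nm⁻³ (one molecule
per 1 M volume), Kd = 1/Ka and **ΔG_bind = RT ln(Kd/1 M)**
(R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹, default T = 300 K). The literature
sometimes prints the relation with the opposite sign inside the
exponential; the convention here is the one that reproduces the standard
printed pairs (5 mM ↔ ≈ −3.1 kcal/mol; 107 mM ↔ −1.3 kcal/mol at 300 K).
The volume element 4πr² can be disabled by flag for comparison with
no-Jacobian conventions. The bound window defaults to the grid's left edge
up to the thermal boundary of the principal well — the point past the
deepest minimum where W returns to −RT, located by linear interpolation so
the window edge does not snap to the grid. Only the Kd (the ratio
k_off/k_on) is computed; individual rate constants are not constrained by
a PMF alone.

Note the window choice matters for shallow wells: with a well of order
1 kcal/mol and noisy forces, the data-driven −RT crossing itself becomes
noisy, which the W-error band does not represent; for uncertainty
statements the window should be fixed (e.g. from the mean profile) and the
band applied at fixed window, which is how the acceptance checks proceed.

## Alanine scanning

Mutation is side-chain truncation past Cβ (Gly/Pro skipped with a reason,
Ala is a no-op). The interaction energy is a fixed-parameter pairwise sum
over inter-monomer atoms within 1.2 nm (CHARMM-style switching from
1.0 nm): Coulomb between formal side-chain charges (±1 e spread over the
terminal group atoms) with distance-dependent dielectric ε = 4r, plus 12-6
Lennard-Jones with minima at the sum of vdW radii and geometric-mean well
depths (C 0.10, N 0.16, O 0.20, S 0.25, H 0.02 kcal/mol). ΔΔE =
E_mut − E_wt, so a stabilising side chain scores positive. The scan is
rigid (no relaxation after mutation) and the energies are not calibrated
free energies: the deliverable is the *ranking* of interfacial residues,
which in the synthetic system correctly puts the planted bridge partners
at the top.

## Ripley's K statistics

K̂(r) = area/(n(n−1)) · Σ_i Σ_{j≠i} w_ij 1[d_ij ≤ r] with Ripley isotropic
edge weights — the reciprocal of the fraction of the circle of radius
d_ij centred on point i lying inside the rectangular window, computed from
the per-edge arcs with corner-overlap correction. The n(n−1) pair
normalisation makes the estimator unbiased under complete spatial
randomness (a 1/n² normalisation is biased low by (n−1)/n, measurable at
a few SE over hundreds of patterns). L(r) − r = √(K/π) − r, with
max L(r) − r as the clustering summary. Radii beyond a quarter of the
shorter window side draw a validity warning. The default EM-scale grid is
1–240 nm in 1 nm steps; calibration checks use a floor of ~30 nm, below
which expected pair counts (~tens) are too discrete for normal-theory
bands.

Group comparison is a permutation bootstrap on the difference of
n-weighted mean max L(r) − r, two-sided, with
p = (1 + #{|T*| ≥ |T|})/(n_boot + 1), hence floored at 1/(n_boot+1). The
weighting by pattern point count follows the EM convention of weighting
cells by their gold count. Null calibration on CSR replicates gives ~5%
rejections at the 5% level.

Generators: homogeneous Poisson (CSR) and the Thomas cluster process
(Poisson parents, Poisson(μ) offspring displaced by an isotropic Gaussian;
offspring outside the window discarded — edge effects from unobserved
parents just outside the window are accepted as negligible at the sizes
used).

## Coevolution scoring

MI with average-product correction over sequence-weighted (80% identity
clusters), pseudocounted (λ = 0.5/symbol) pair frequencies; columns with
gap fraction > 0.5 are masked; corrected scores are z-standardised over
unmasked pairs so one threshold (> 2.0, strict) transfers across
alignments. This is a deliberate stand-in for heavier coupling inference
(no pseudolikelihood/DCA); precomputed coupling tables from external tools
are accepted in the same container, where missing pairs stay absent rather
than zero. Column→residue mapping matches the ungapped alignment consensus
against the chain sequence (offset scanned or supplied; > 5% mismatch
aborts). A hotspot requires both score > cutoff *and* relative SASA ≥ the
exposure cutoff — a high-scoring buried residue is not a surface hotspot.

## Synthetic fixtures: what they show and what they do not

Helices are built from ideal internal coordinates (NeRF chain extension at
φ = −57°, ψ = −47°, standard bond lengths/angles), giving exactly
assignable dihedrals; planted charged/aromatic residues sit at
literature-style positions and their minimal side chains are placed
*geometrically* (atoms spaced along the Cβ→contact-point line, rings as
regular polygons) to realise planned contact distances exactly. Pose
ensembles are rigid placements of one monomer (helix + coil effector-loop
stand-in + anchor tail) around another: four viable seed arrangements,
one with anchors flipped to opposite faces (fails filter iii), one with a
loop-only contact (fails filter i), plus uniform far scatter; jittered
with ~0.05 nm RMS so clusters are tight relative to the 0.4 nm radius.
Mean-force profiles sample the analytic derivative of a Gaussian well
(center 3.6 nm, width 0.25 nm by default) with optional i.i.d. Gaussian
noise; the true Kd comes from the same documented integral evaluated on
the analytic curve at fine quadrature, so inverse construction (bisection
on depth for a target Kd, e.g. 5 mM) is exact to the quadrature.

Passing on these fixtures establishes the *estimators and bookkeeping*:
detectors match brute-force oracles, clustering recovers planted
memberships, the filters fire for the geometric reasons planted, Kd
integrates correctly, the K-function is unbiased. It does **not**
establish robustness to real structural data — rotamer physics, missing
atoms and alternate conformers beyond altloc selection, MSA phylogeny
(sequences here are i.i.d. given the planted states, so sequence
weighting is exercised only trivially), or inhomogeneous point intensity
in EM fields. Thresholds are all configuration values precisely so they
can be recalibrated on real systems.

## Problem sizes in the test and acceptance runs

Chosen as the smallest sizes at which each statistical claim is
well-posed: 100-pose ensembles with six planted clusters; 500 × 60 MSAs,
20 replicates; 141-point force grids, 100 noise seeds; 200 CSR patterns of
n ≈ 400 for K-estimator calibration and 20 meta-replicates × 199
bootstrap resamples for null calibration; 1,000 random rigid two-body
configurations for the ΔSASA positivity sweep.
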