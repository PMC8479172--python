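# Methods

This document defines the synthetic model, the analysis algorithms, the
numerical choices, and the scope limits of `hingelatch`.  All quantities
below that are stated as measured were computed with this code (seeds 0–7
of the default benchmark and the test suites); nothing here is an empirical
claim about any real molecular system.

## 1. Synthetic model

The generator manufactures coordinate time series that carry exactly the
statistical structure the analyses assume.  It does not integrate any
equations of motion.

**Layout.**  Residues are numbered consecutively: a static domain
("TM", default residues 1–60, a coil of radius 8 Å rising 1 Å/residue), a
mobile domain ("PP", default 61–100), and a peptide (default 101–108, a
strand in the interface groove).  Each residue carries backbone atoms
N, H, Cα, C, O, Cβ at idealized local offsets, plus any extra side-chain
atoms (acceptors, hydroxyl donors) the declared H-bonds require.

**Mobile-domain geometry.**  The mobile domain is a flat spiral fan around
its first residue (the pivot): residue *i* of the domain sits at radius
ρ = 3·min(i,1) + 1.2 i and winding angle φ = 0.7 i from the pivot, lifted
6 Å above the pivot plane.  Under a rotation about the vertical axis
through the pivot, every mobile residue is displaced in exact proportion
to its distance from the pivot, while distance measured from any *other*
candidate mixes in the winding angle and decorrelates.  This is what makes
the hinge identifiable: in the default benchmark, the pivot's
distance–displacement Pearson r is ≈ 0.999 while a candidate 5 residues
away scores ≈ 0.6.  The pivot residue itself does not rotate (it is the
fulcrum, shared by both domains).

**Per-frame assembly order.**  Rigid template → hinge rotation of the
mobile domain → correlated-block latent displacements → peptide unbinding
drift → H-bond acceptor placement → isotropic Gaussian noise
(σ = 0.05 Å per coordinate by default).  Replica *r* uses the random
substream seeded with `seed + r`, so replicas are independent but
individually reproducible.

**H-bond schedules.**  Each programmed bond follows a two-state Markov
chain with stationary occupancy `p_on` and nominal mean on-dwell
`mean_dwell_on` (default 10 ns).  The chain is discretized *exactly*: with
total rate k = k_on + k_off, the per-step transition probabilities are
p(off→on) = p_on·(1 − e^{−k·dt}) and p(on→off) = (1 − p_on)·(1 − e^{−k·dt}).
This preserves the stationary occupancy and the relaxation time exactly;
mean dwell times stretch when k_off·dt is not small (e.g. ≈ 1.6 ns
realized at p_on = 0.91, dwell 1 ns, dt 0.1 ns).  The naive per-rate form
1 − e^{−k_i·dt} was rejected because it biases the stationary occupancy
(measured 0.869 at a programmed 0.91).

When a bond is scheduled on, its acceptor is placed with donor–acceptor
distance drawn uniformly from [2.7, 3.2] Å and donor–hydrogen–acceptor
angle from [155°, 175°] — decisively inside the detection criterion; when
off, the acceptor is parked 5.5 Å away along the D–H axis, decisively
outside.  With the default noise the detector reproduces the programmed
schedule frame-for-frame (measured agreement 100 % at 5000 frames).

**Charges and Lennard-Jones parameters.**  Atoms carry alternating ±0.4 e
charges (net charge 0 or ±0.4 e depending on parity of the atom count) and
per-element LJ parameters of force-field-like magnitude
(ε, r_min/2): H (0.046, 0.2245), C (0.070, 2.0), N (0.20, 1.85),
O (0.12, 1.70) kcal/mol, Å.  The near-zero polar-hydrogen radius follows
standard force-field convention; without it, programmed H-bond contacts
(H···acceptor ≈ 2 Å) register as steric clashes and the interaction energy
diverges.  These parameters make the energetics stage *runnable and
well-scaled* on synthetic systems (benchmark peptide–protein energies of
order −25 to −35 kcal/mol); they are not a fitted force field.

**Reference conditions.**  TIGHT: six bonds at occupancies 0.78–0.92
(except one at 0.32), hinge mean 0°, sd 1.5°, interdomain correlation
block at ρ = 0.9.  LOOSE: occupancies 0.16–0.68, hinge mean 10°, sd 4°,
block at ρ = 0.5.  Group A are the three bonds whose joint loss marks
partial unbinding; group B keep a partially bound peptide attached.

## 2. Analyses

**H-bond criterion.**  Present when donor–acceptor distance < 3.5 Å
(strict) *and* donor–hydrogen–acceptor angle > 130° (strict), minimized
over the acceptor set of the bond.  A hydrogen more than 1.6 Å from its
donor triggers an atom-assignment warning.

**Binding-state machine.**  Three states, starting FULLY_BOUND.  With
window w = ⌈persistence_ns / dt⌉ frames: → PARTIALLY_BOUND at the first
frame where every group-A bond has been absent for > w frames (a run of
≥ w+1) while a group-B bond is present; → UNBOUND (absorbing) when all six
bonds have been absent for > w frames.  Return from partial to full
requires `allow_rebinding=True`.  All "bound frames only" analyses use the
FULLY_BOUND mask intersected with a post-equilibration mask.

**Stable core / rigid clusters.**  Average-linkage hierarchical clustering
of the inter-residue distance-fluctuation matrix (SD of each pairwise Cα
distance over frames, pooled over replicas); the core is the cluster with
the lowest mean internal fluctuation.  Singleton clusters are ineligible
(no internal fluctuation to measure) unless every cluster is a singleton;
exact ties resolve to the lowest residue id with a warning.

**Superposition.**  Kabsch via SVD with determinant correction; collinear
alignment sets are rejected.  Recovery of random rigid transforms is exact
to < 1e-8 Å RMSD (measured 0.0 over 100 random transforms).

**Hinge scan.**  For each candidate residue, the Pearson correlation
between (distance from the candidate Cα to each mobile-residue Cα in the
reference average) and (that residue's backbone RMSD between the two
condition averages).  A true pivot shows displacement ∝ distance, r → 1.
Candidates default to the low-RMSD quartile of the declared interface
residues, with per-residue RMSDs floored at twice the median coordinate
standard error (rmsf/√n over both averages): displacements below that are
statistically indistinguishable from zero, so such residues tie exactly
and are kept or dropped together instead of being split by estimation
noise.  The mobile set must contain ≥ 10 residues.

**Energetics.**  E_elec = 332.0636·q_i·q_j/(ε_r·r_ij) kcal/mol;
E_LJ = ε_ij[(r_min,ij/r)^12 − 2(r_min,ij/r)^6] with ε_ij = √(ε_i ε_j) and
r_min,ij = r_min,i/2 + r_min,j/2.  No cutoff or switching; an optional
residue-level center-of-mass prefilter reproduces the shortcut of
evaluating only residues within a stated radius.  Atom pairs closer than
0.1 Å abort the calculation (overlapping atoms indicate a broken system).
Jack-knife check: for i.i.d. replicas, sd(leave-one-out means)
= sd(replicas)/(n−1); large deviations of the reported ratio from 1/(n−1)
flag non-exchangeable replicas.

**PCA and correlations.**  Cartesian PCA diagonalizes the pooled 3N
coordinate covariance (economy SVD; eigenvalue_k = s_k²/F).  Fewer frames
than 3N triggers a rank-deficiency warning.  RMSIP over the first k
eigenvectors measures shared essential subspace.  Cross-correlations are
C_ij = ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) over core-aligned pooled frames;
zero-variance nodes get zero off-diagonal correlation with a warning.

**Networks.**  Edge wherever |C_ij| ≥ 0.7 (motion vectors within 45°),
weight −ln|C_ij| (so the threshold edge weighs −ln 0.7 ≈ 0.3567).
Communities: greedy modularity maximization with |C| edge strength,
labelled deterministically by lowest member id.  Betweenness:
shortest-path counting, endpoints excluded, unnormalized.  Suboptimal
paths: per source–sink pair, Yen's k-shortest simple paths, globally
merged, sorted by (weight, lexicographic sequence), truncated to k.
Community summary graphs use radius R_i = N_i/3 and inter-community
weight −ln|max C| (simplified) or −ln|max C|/4 (structure overlay);
communities with no external edge are pruned.

## 3. Numerical and statistical choices

- dt defaults to 0.1 ns/frame; default equilibration exclusion 5 ns;
  default persistence window 5 ns (50 frames).
- The benchmark sizes (108 residues, 2 replicas × 800 frames × 2
  conditions) are scaled so that the full pipeline runs in ~10 s while all
  recovery margins remain > 2.5 estimated standard errors; the generator
  accepts arbitrary sizes.
- Occupancy-recovery checks use 1 ns dwell bonds at 5000 frames: the
  time-average sd of a two-state occupancy is ≈ √(p(1−p)·2τ/T), which at
  the default 10 ns dwell would exceed the ±0.03 tolerance regardless of
  implementation quality.
- Exact-arithmetic anchor points used in the tests: LJ minimum value −ε at
  r = r_min; Coulomb −100.0 kcal/mol for ±1 e at 3.320636 Å; jack-knife
  ratio 1/(n−1); community radius 9 for N = 27; overlay/simplified weight
  ratio 4.

## 4. Scope and limitations

- The generator is a statistical mock, not physics: no bonded terms, no
  thermostat, no solvent, no excluded volume beyond the overlap guard.
  Conclusions about real systems require real trajectories.
- The binding-state machine assumes trajectories start bound and treats
  UNBOUND as absorbing by default; systems with genuine rebinding need
  `allow_rebinding=True` and careful window choice.
- The hinge scan assumes an approximately rigid mobile domain rotating
  about a single pivot; distributed or shear-type hinges will not produce
  r near 1 for any candidate.
- Energies are plain pairwise nonbonded sums: no polarization, no PME, no
  entropy.  They rank residues and compare conditions; they are not
  binding free energies.
- Correlation networks use linear (Pearson) correlations of Cartesian
  fluctuations; purely orthogonal or nonlinear couplings are invisible.
- The KDE projection densities use Scott's-rule bandwidth; with the
  benchmark's strongly bimodal TIGHT/LOOSE clouds the tail fractions are
  descriptive, not calibrated probabilities.
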