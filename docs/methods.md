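# Methods

This note records the model, the numerical choices, and what the
synthetic training data do and do not exercise.  Symbols follow the
README.

## Energy model

**Base frames and the orientation space.**  A nucleobase is a rigid
body with a local right-handed frame: origin C1', x-axis along
C1'->N9 (purines) or C1'->N1 (pyrimidines), z-axis along the cross
product of the glycosidic bond with the first in-ring bond, y = z x x.
The relative placement of two bases is parameterised by the
origin-origin distance r, the inter-origin direction expressed in each
frame, and a twist omega about the inter-origin axis.  The omega
convention (the literature leaves it open): project both x-axes onto
the plane normal to the i->j direction and take the signed angle from
i's projection to j's, right-handed about i->j.  Under this convention
omega is *invariant* under exchanging the two bases (both the angle
order and the axis flip, which cancels); the direction vectors swap.
Frames are exactly recoverable from (frame_i, orientation), which the
tests verify to 1e-8.

**DDM.**  Each base is reduced to four fixed pseudo-atoms
T1=(2.158, 3.826, 1.427), T2=(-0.789, -0.329, -1.273),
T3=(4.520, -3.006, 1.586), T4=(6.018, 1.903, -1.638) in its own frame
(identical for all four base types).  A pair configuration is the 4x4
matrix of cross distances between the two pseudo-atom sets, and
DDM(A, B) is the RMS of the element-wise differences of the two
matrices.  This distance-difference reading (rather than a direct sum
of cross distances, which would not vanish for congruent
configurations) makes DDM a rotation-invariant pseudo-metric that is
zero at identity — the property the kernel density below requires.
Measured over clash-free random placements (r in 3-15 A, uniform
rotations) it correlates with all-atom superposition RMSD at
Pearson r ~ 0.95; the exact value depends on the sampling
distribution.

**Base-base density and energy.**  f'(x) = sum_i w(x_i) h(DDM(x, x_i))
with the flat-top kernel h(d) = 1 for d <= 0.15 A and
exp(-0.5 ((d-0.15)/0.1)^2) beyond.  For non-local pairs (sequence
separation > 2) the weight is w(x_i) = exp(-E_QM(c_i)/4.32 kcal/mol)/f(c_i),
where c_i is the observation's nearest orientation-cluster center
(k-medoids under DDM, k = 80 capped at the observation count on small
corpora) and f(c_i) the unweighted density there, floored at 1e-6 to
keep weights bounded at sparse centers.  Local separations use unit
weights.  E_0 = -ln f'(x)/f_ref with f_ref = f'_max e^{target}, so the
table minimum equals the target exactly (-8 non-local, -4 local);
positive values clip to zero and only negatives are stored.

The 6D table axes are 50 radial bins of 0.3 A, 45 twist bins of 8 deg,
and a sphere codebook for each direction (2000 vectors by default;
tables are codebook-size agnostic in their normalisation, and the test
suite uses 300 for speed).  The density is evaluated at the
representative configuration of every cell occupied by an observation
plus two surrounding (r, omega) shells; cells further from all data
carry kernel mass below e^{-10} of a populated cell and would clip to
zero anyway.  Lookup interpolates bilinearly in (r, omega) at the
nearest codebook cells — continuous in r and omega, with documented
jumps across codebook-cell boundaries (interpolating over the irregular
spherical cells would complicate lookup for little gain at this
resolution).

**Polar terms.**  A base-oxygen contact is described by the four
distances from the oxygen to the base pseudo-atoms; oxygen-oxygen
contacts (O2'/OP only) by the six pairwise distances of the four
defining atoms (each oxygen plus its covalent parent, e.g.
C2'-O2'...OP-P), a superposition-free representation that carries the
angular dependence implicitly.  Densities use Gaussian kernels of
width 0.16 (base-oxygen) and 0.1 (oxygen-oxygen) over the RMS
difference of the representations.  Tables store -ln f/f_ref with the
minimum normalised exactly to -3 / -3 / -2 / -1.5 (base-oxygen,
O2'-O2', O2'-OP, OP-OP); gates apply at query time: logistic decays
1 - 1/(1+e^{(3.7-d_min)/0.08}) resp. 1 - 1/(1+e^{(3.3-d)/0.07}), and for
base-oxygen a quadratic angular score that is 1 at the corpus median
angle and 0 at the 3%/97%-trimmed bounds.  The angle is measured at
the oxygen between its covalent parent and the nearest base N/O atom
(when several are in range the nearest is used).  The repulsive branch
is kept (not clipped), but the raw log-ratio is capped at +3: with a
desk-scale corpus the KDE tail would otherwise assign essentially
unbounded penalties to any unfamiliar geometry, which both distorts
refinement and serves no statistical purpose.  Empty-density queries
return the cap.

**Rotamers, torsions, internal terms.**  Ribose conformers are the
eight sugar atoms expressed in the base frame; the rotamer energy is
-ln f/f_max with a 0.15-width kernel over the RMS atom distance, f_max
taken over the library conformers, and small negative excursions
clipped at zero.  Coupled torsion statistics use 10-degree bins for
eps, zeta, alpha, beta, gamma, with the sugar improper nu split into
the two pucker regions at -25 deg (C3'-endo sugars sit near -35,
C2'-endo near -10 under the improper convention used here).  The
histograms are blurred with a circular Gaussian of one bin width —
keeping the binned statistics kernel-smoothed like every other density,
and avoiding hard 10-degree steps that would make the closure search's
landscape needlessly blocky — and then add-one smoothed so every
conditional slice is a proper distribution and energies stay finite.  The internal energy of a backbone step applies
softened harmonics (quadratic within |u|<=1, linear beyond, C1 at the
crossover) to the O5'-C5' bond (mean 1.422 A, k=5) and to the
P-O5'-C5' and O5'-C5'-C4' angles (means 120.7 and 111.1 deg, k=0.1),
plus the three negative-log conditional torsion terms.

**Clash.**  r0 per atom-type pair is the 5th percentile ("lower"
interpolation) of observed pair distances below 5 A, with covalent
neighbours within three bonds excluded; for base (sp2) atoms r0 is
additionally resolved on a 1 A grid in the base frame where at least
10 observations fall in a cell.  Percentile estimates are clamped at
element-pair hard-core ceilings (O-O 2.5, N-O 2.6, C-C 3.0, ... see
`stats.ELEMENT_R0_CAP`), which also serve as fallbacks for unobserved
pairs: a small corpus can simply never show two types close together,
and an unclamped percentile would then penalise perfectly normal
geometry.  The penalty is the printed piecewise form: zero at and above
r0, a constant plateau (k_clash*0.4)^4 within 0.4 A below r0, and a
linear continuation below; the plateau joins the linear branch
continuously at r0-0.4, while the onset at r0 is a step by
construction of that functional form.  k_clash = 3 (the supported
range is 2-5).

## Sampler

The NuTree spans all residues: candidate edges are WC pairs, then
non-WC pairs, then sequence-neighbour steps in 5'->3' order (typed
wc/nwc/loop by the pairing context), then inter-chain jumps; cycles
become constraints whose energies are still counted.  This ordering
reproduces the canonical GCAA-tetraloop tree (loop runs hang off their
5' side; the 4-5 step carries only a phosphate, no edge).  The root is
the first residue of the longest WC helix.  Move sets per edge type are
built by two-level k-medoids (60 x 60) of the observed edge transforms
under an RMS rigid-probe metric, padded by resampling on small corpora.

Node moves: uniform rotamer swap or a rigid jitter of one residue
(<0.2 A, <2 deg).  Edge moves transport the downstream subtree rigidly
(local jitter or move-set jump, 50/50).  Every step whose two riboses
moved relative to each other gets its phosphate rebuilt by the
125-evaluation hierarchical search over the observed (eps, zeta) torus
(50 k-means representatives, 50 sub-representatives of the best, then
25 local points: a coarse window plus a recentring 1-degree descent);
closures beyond an 8 A C3'-C5' reach are
flagged and carry a fixed 100 penalty.  Delta energies recompute only
pair terms whose relative geometry changed plus the touched
rotamer/internal terms; the suite checks agreement with full
recomputation to 1e-6 over a thousand mixed moves.

Annealing follows a geometric schedule (refinement: T 0.5 -> 0.01,
factor 0.9; prediction: 2.5 -> 0.01, factor 0.95) with per-round step
counts 400/2000/4000 per WC/NWC/other edge, scaled uniformly by
`steps_scale` for desk-size runs.  The clash and internal weights ramp
linearly from 0.05 to 1 over the first 60% of rounds.  The sampler
returns the lowest full-weight-energy conformation visited; runs are
bit-reproducible for a fixed seed.

## Synthetic training data

The packaged corpus contains five 8-bp A-form duplexes, two 8-nt
hairpins (GCAA- and UUCG-type loops), a docked two-duplex "ribose
zipper" (the only source of O2'-O2' hydrogen bonds), and one noisy
decoy copy of each at sigma = 0.5 A.  The duplex is built by a
deterministic least-squares placement of a rigid idealized nucleotide
(C3'-endo sugar rebuilt at pseudorotation phase 18 deg, amplitude
39 deg; covalent geometry from the bundled chemical component
dictionary; A-form torsions and standard fiber rise/twist 2.81 A /
32.7 deg) under Watson-Crick hydrogen-bond, backbone-closure and
steric restraints; hairpin loops and the zipper docking are closed by
the same machinery.  The decoy copies emulate the conformational
spread a real structure database shows around recurring motifs —
without them the kernel densities have support only on a measure-zero
set and any perturbed structure reads as pure repulsion, which is a
property of degenerate sampling, not of the method.

What passing tests therefore show: the statistics pipeline, the
normalisation contracts, the sampler's correctness (rigidity,
incremental energies, Metropolis behaviour) and that refinement pulls
1 A decoys of a corpus motif back toward it.  What they cannot show:
transferability to RNA families outside the corpus, performance of the
full-size schedules, or the accuracy of real quantum-chemistry
reweighting (the shipped table is a synthetic stand-in assigned by an
analytic contact rule).

## Scales used in the shipped runs

The test-suite and the acceptance script run with a 300-vector
codebook, cluster counts capped at the per-type observation count, and
refinement at `steps_scale = 0.002` with 20 seeds on the 8-nt
tetraloop; these sizes keep a full run on one CPU in the tens of
minutes while preserving every contract above.  The correlation
measurement uses 10,000 sampled configuration pairs.

## Known limitations

* Electrostatics, ions and solvation are only implicit in the
  statistics; protruding, solvent-exposed bases are outside the
  model.
* Base pairs are fixed inputs: the sampler refines around the given
  pairing and cannot break or form pairs.
* Modified nucleotides and insertion codes are rejected.
* The 6D lookup is nearest-cell in the two direction axes; energies
  jump (by design) across sphere-codebook cell boundaries.
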