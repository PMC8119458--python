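# briq

Knowledge-based refinement of near-native RNA 3D models: an
orientation-dependent statistical potential for nucleobases and backbone
oxygens, coupled to a nucleobase-centric fold-tree (NuTree) Monte Carlo
simulated-annealing sampler.

## The problem

Models of RNA 3D structure produced by fragment assembly or homology
modelling are typically a few Angstroms from the native structure, with
most base pairs identified but the detailed base-pair geometry and the
backbone imperfect.  Pushing such models closer to experimental accuracy
requires an energy function whose minimum actually sits at the native
structure, and a sampler able to exploit it without derivatives.

RNA interactions are dominated by strongly orientation-dependent
base-base pairing and stacking.  `briq` therefore scores a structure as

    E = E_bb + E_bo + E_oo + E_rot + E_internal + E_clash

* **E_bb** — base-base term.  Each base carries a local frame (origin at
  C1', x along the glycosidic bond, z normal to it); the relative
  placement of two bases is a point in a six-dimensional rigid-body
  space (distance r on a 0.3 A grid up to 15 A, twist omega on an 8 deg
  grid, and the two inter-origin directions resolved on a 2000-vector
  sphere codebook).  The density of corpus observations in this space is
  estimated with a flat-top kernel over the DDM metric (RMS deviation of
  the 4x4 cross-distance matrices of four fixed pseudo-atoms per base),
  reweighted for non-local pairs by tabulated quantum-chemistry pair
  energies (scale 4.32 kcal/mol), and converted to an energy
  E = -ln f'(x)/f_ref with the table minimum normalised to -8 (non-local)
  or -4 (local) and repulsive values clipped to zero.
* **E_bo / E_oo** — base-oxygen and oxygen-oxygen hydrogen-bond terms:
  negative-log kernel densities over reduced distance representations,
  gated by logistic distance decays (midpoints 3.7 / 3.3 A) and, for
  base-oxygen, a quadratic angular score; minima normalised to -3
  (base-oxygen and O2'-O2'), -2 (O2'-OP) and -1.5 (OP-OP).
* **E_rot** — ribose rotamer term: kernel density over library
  conformers expressed in the base frame.
* **E_internal** — softened-harmonic restraints on the one flexible
  O5'-C5' linkage (mean 1.422 A, k=5) and its two flanking angles
  (120.7 deg, 111.1 deg, k=0.1), plus coupled backbone-torsion
  statistics -ln P(eps,zeta|nu) - ln P(alpha|zeta,beta) - ln P(beta,gamma|nu).
* **E_clash** — piecewise penalty below statistical minimum-approach
  radii (5th percentile of observed close approaches), with k_clash=3.

Sampling runs on the NuTree: one node per residue, typed edges (WC
helix / non-WC / loop neighbours, WC and non-WC pairs, jumps) carrying
rigid transforms.  Node moves perturb one base or swap its ribose
rotamer; edge moves rigidly transport the downstream subtree, either by
small adjustments or by jumps drawn from 60x60 hierarchically clustered
move sets (3600 representative transforms per edge type).  Phosphates
between repositioned riboses are rebuilt by a hierarchical
epsilon-zeta search (50 representatives -> 50 sub-representatives -> a
5x5 local grid; exactly 125 internal-energy evaluations).  Energy
changes are computed incrementally and accepted by the Metropolis rule
under a geometric cooling schedule with the clash/internal weights
ramped from 0.05 to 1.

Everything is trained from plain PDB coordinate files; the package
ships a synthetic-corpus generator (idealized A-form duplexes,
hairpins, a ribose-zipper dimer and noisy decoy copies) so all tables
can be built and every stage exercised without downloads.  The
tabulated quantum-chemistry energies are consumed as an input; a
clearly-labelled synthetic stand-in is generated from an analytic
contact rule.

## Worked example

```bash
# write the synthetic corpus and build all tables
briq make-fixtures --out fx --with-tables --codebook-size 300

# score a model: one line per energy family
briq score fx/hairpin-GCGCAAGC.pdb --tables fx/tables.h5
```

prints:

```
E_bb	-94.5702
E_bo	0.0854
E_oo	-2.7503
E_rot	0.0003
E_internal	89.6056
E_clash	54.0371
total	46.4079
```

The deep negative `E_bb` reflects the stem pairs and stacks of the
GCAA-type tetraloop sitting in the wells of the orientation tables;
`E_rot` is ~0 because the fixture riboses are the library's densest
conformers, and the positive internal/clash baseline comes from the
smoothed torsion statistics and tight loop contacts of the small
corpus (it is common to all conformations, so differences still drive
refinement).

```bash
# refine a perturbed model (pairing file: sequence, dot-bracket, NWC list)
briq refine --model decoy.pdb --pairing fx/hairpin-GCGCAAGC.pairing \
            --tables fx/tables.h5 --seed 7 --n-models 5 \
            --steps-scale 0.003 --out refined/
```

writes `refined/model_*.pdb` and `refined/best.pdb` (lowest-energy
model) and logs per-round temperature, acceptance rate and best energy.

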