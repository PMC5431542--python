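# Methods

`kinpocket` implements the trajectory-analysis layer used to characterise
how EGFR kinase-domain mutants (L858R, exon-19 deletion) reshape the
inhibitor binding pocket and its hydration: pocket-compaction and
side-chain distance metrics, interaction detectors (hydrogen bonds,
halogen bonds, heavy-atom contacts, salt bridges), and identity-agnostic
buried-water residence times.  It does not run molecular dynamics; it
consumes pre-computed coordinate frames.  All distances are in Å and
times in ps throughout.

## Input model and assumptions

A trajectory is a topology (one atom record per atom, masses from
standard atomic weights) plus an ordered stack of coordinate frames with
a uniform time step `dt` (default 10 ps, the typical save interval for
production MD).  Frames are assumed to be *pre-imaged*: no
periodic-boundary treatment is applied anywhere, so trajectories from
periodic simulations must be unwrapped/imaged before analysis.  PDB is
the interchange format (multi-model for trajectories); DCD is accepted
as an optional compact alternative.  Altloc records keep the
highest-occupancy conformer (ties resolve to the first listed,
conventionally "A").  Residue numbering is taken verbatim from the input
file, because the residues of interest (R858, E758, K745, C797) are
conventionally cited in author numbering.

Atom groups are named by a small selection language
(`resid/resname/name/element/chain/heavy/hydrogen/backbone/sidechain/
water/all` with `and/or/not`).  Backbone means N/CA/C/O (+OXT) of
non-water residues; side chain is everything else in a non-water residue.
Which residues constitute "the αC-helix" or "the hinge" is a
configuration input, not a constant: published kinase analyses rarely
state the exact ranges, and they differ between constructs.

## Metrics

**Pocket size.** Per-frame distance between the mass-weighted centres of
the αC-helix selection and the hinge selection.  True atomic masses are
used (not a geometric centroid).  Compaction of the active-state pocket
appears as a multi-Å downward shift of this distance (reported shifts in
EGFR are on the order of 27 Å → 20.5 Å between wild type and the
exon-19 deletion).

**Side-chain pair distances / salt bridges.** The distance between two
side chains is the *minimum* over all cross pairs of their heavy
side-chain atoms — the standard salt-bridge convention, and the one that
makes a "< 3.5 Å" formation criterion meaningful.  Salt-bridge occupancy
is the fraction of frames strictly below the cutoff (default 3.5 Å).

**Contacts.** The number of heavy-atom cross pairs within (≤) 6.5 Å.
Hydrogens are filtered inside the counter.  "Within" is read as ≤; at a
measure-zero boundary the choice is immaterial in practice.

**Hydrogen bonds.** Donor–acceptor distance strictly < 3.0 Å and
donor–H–acceptor angle strictly > 120°.  Donors are N/O atoms with at
least one covalently bonded hydrogen; acceptors are N/O/F.  Covalent
bonds are inferred geometrically (H within 1.2 Å of the donor in a
designated bonding frame — frame 0 by convention) because PDB
trajectories rarely carry connectivity.  Multiple hydrogens on one donor
are each evaluated; records are deduplicated per (donor, acceptor)
keeping the widest angle.  A donor with no resolvable hydrogen is
skipped with a logged warning.  On a topology with no hydrogens at all
the detector degrades to an explicit distance-only mode (records carry
no angle, the output header is flagged) rather than silently returning
nothing — heavy-atom-only PDBs are common.

**Halogen bonds.** No universally agreed criterion exists for detection
in trajectories; the package adopts the standard σ-hole geometry:
X···acceptor ≤ 3.5 Å with a C–X···acceptor angle ≥ 140°, X ∈ {F, Cl,
Br, I}, the bonded carbon being the nearest carbon within 2.0 Å.  Raw
X···A distances are additionally exportable as a per-frame series so
that bond *lengths* can be tracked across systems even when a pair sits
above the detection cutoff.

**RMSD/RMSF.** Superposition is least-squares (Kabsch via SVD with
reflection correction, unweighted over the fit selection; at least three
non-collinear fit atoms are required).  RMSD is measured against the
starting structure (frame 0) after fitting each frame to it.  RMSF fits
every frame to frame 0, then measures each atom's root-mean-square
deviation about its *mean aligned position*.  Fitting to frame 0 rather
than to a running average was chosen for determinism; for
well-converged trajectories the two agree closely.  For an atom with iid
isotropic Gaussian jitter of width σ per coordinate, RMSF → σ√3, which
is the closed form the test suite checks at 10⁴ frames.

**Distributions.** Scalar series are histogrammed with left-closed,
right-open bins of width 0.1 Å (default) whose edges sit on multiples of
the bin width, normalised to sum to 1.  Because the edges are aligned,
the probability mass below an aligned threshold (e.g. < 3.5 Å) equals
the exact frame count below it.

## Hydration sites and residence times

A *bridging water* is a water whose oxygen is simultaneously within the
proximity cutoff (default 3.5 Å) of at least one ligand-anchor atom and
one protein-anchor atom.  The site is *occupied* in a frame iff at least
one water bridges it.  This dual-proximity definition makes the
occupancy a property of the site: which water supplies it is irrelevant,
so a water exchanging with another leaves the clock running
(identity-agnostic residence).  Only the oxygen is used as the water's
position — water hydrogens are rotationally labile in most water models.

Residence is summarised three ways, because "residence time" is used
ambiguously in the literature: the **total** occupied time
(occupied-frame count × dt), the **longest contiguous interval**, and
the list of maximal occupied intervals.  A gap tolerance (default 0
frames) optionally bridges short vacancies when merging intervals;
bridged gap frames never count toward totals.  An **exchange event** is
a change of the occupying-water id set between two consecutively
occupied frames.

Water-mediated interaction records combine the detectors: for each
bridging water, hydrogen bonds to the protein anchor and to the ligand
anchor (both donation directions; water O–H bonding resolved by residue
membership) plus halogen bonds from ligand halogens to the water oxygen.
A *bridge* is reported when at least one qualifying interaction exists
on each side.

## The synthetic generator

Desk-scale verification of MD analysis code needs trajectories whose
answers are known exactly, so the generator builds a toy scene — a
static hinge, a breathing helix, a glutamate/arginine salt-bridge pair,
a fluorinated ligand, scheduled waters, and a Gaussian probe atom — and
records every planted quantity as machine-readable ground truth:

* **Two-state pair**: the arginine side chain is placed so the minimum
  side-chain heavy-atom distance to the glutamate is exactly the bound
  (2.9 Å) or unbound (12 Å) value, switching by a two-state Markov chain
  with stationary bound probability `p_bound` (default 0.4) and
  transition probabilities scaled by `switching_rate` (default 0.5).
  The defaults mirror the regime reported for the L858R salt bridge
  (~40% occupancy against a ~12 Å separated state in the wild type).
  Because consecutive frames are correlated, recovery tests use a
  chain-aware confidence interval with effective sample size
  n·(1−λ)/(1+λ), λ = 1 − switching_rate; `switching_rate = 1` gives an
  iid sequence and the plain binomial CI.
* **Pocket breathing**: the helix group's COM is placed at
  mean + amplitude·sin(2πi/period) from the hinge COM (defaults
  20.5 ± 0.8 Å, period 500 frames), so per-frame pocket distances are
  planted exactly.
* **Hydration schedule**: explicit `(start, end, water_id)` intervals
  place the named water at a site where the default geometry satisfies
  both bond criteria by construction (water-O···carboxylate 2.8 Å at
  180°; F···O 3.0 Å with a collinear C–F axis).  Off-schedule waters are
  parked ≥ 10 Å from both anchors.  The default schedule occupies half
  the trajectory through four exchange events — at the default study
  scale (10,000 frames × 10 ps = 100 ns, the production length typical
  of this kind of simulation) that is 50 ns total with a 25 ns longest
  interval, the order of magnitude reported for tightly bound waters.
* **Thermal noise**: iid Gaussian jitter (σ = 0.5 Å) on a dedicated
  probe atom, giving the RMSF closed form σ√3.  Noise is iid per frame
  (no autocorrelation) precisely so the closed form holds.
* **Rigid-body motion**: a random global rotation (≤ 5°) and translation
  (≤ 1 Å per axis) per frame, applied to all atoms last.  Every distance
  metric must be invariant to it and superposition must remove it.

All randomness flows from one seeded generator; identical spec + seed
gives bit-identical coordinates.  The two glutamates flanking the helix
(the salt-bridge partner and the hydration anchor) are intentionally
static and excluded from the breathing "helix" selection so that planted
salt-bridge distances and site geometry remain exact while the helix
moves; selections are configuration, so this is purely a
scene-construction convenience.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: no force field, no energetics, no solvent
box or periodic boundaries, no correlated protein motions beyond the
single sinusoid, no sub-frame kinetics, and idealised bond geometries
instead of thermalised ones.  The tests demonstrate that the *analysis*
is correct, not that any particular biological conclusion follows.

## Numerical choices

* Kabsch collinearity is rejected when the second singular value of the
  centred reference fit coordinates is ≤ 10⁻¹⁰ of the largest.
* Strict-vs-inclusive boundaries follow the stated criteria: hydrogen
  bond and salt bridge use strict `<` / `>`, contacts and halogen bonds
  use `≤` / `≥`.
* CSV outputs print at 6 significant digits; identical inputs give
  byte-identical tables (the run report additionally records wall time,
  which naturally varies).
* PDB coordinate precision is 10⁻³ Å; fixture round trips are tested at
  that tolerance, and planted geometries keep ≥ 0.2 Å margins from every
  detection cutoff so that write/read rounding cannot flip a
  classification.
* Problem sizes: property tests run at 10⁴ frames where a closed form or
  CI is asserted (sampling error ≲ 0.5%), 200 random frames of ≤ 50
  atoms for oracle-equivalence scans, and the end-to-end check analyses
  the written 10,000-frame fixture twice to confirm determinism.

## Known limitations

* No PBC imaging, no PSF/PRMTOP/GRO input, no NetCDF/mdcrd; convert
  Amber trajectories to multi-model PDB or DCD first.
* Hydrogen-bond detection without explicit hydrogens is distance-only;
  angles cannot be recovered from heavy atoms alone.
* The halogen-bond criterion is a geometric convention; systems near the
  cutoff boundary should also be inspected via the raw distance series.
* One trajectory per invocation: pooling replicate simulations (and how
  to average their statistics) is left to the consumer.
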