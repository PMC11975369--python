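# Methods

This note records the models, conventions and numerical choices behind
`tcrchassis`, and what the synthetic fixtures do and do not establish
about real trajectories.

## Coordinate and time conventions

Coordinates are in Å, times in ns, and the first production frame is
t = 0; intervals quoted as, e.g., 500–1000 ns are offsets from the
production start.  Trajectory frames are assumed evenly spaced (the
standard saving rate for this class of simulation is 20 ps, so a 500 ns
interval holds 25,000 frames).  Residue selections address the
*sequentially renumbered* structure: within each chain residues are
renumbered 1..N in file order with insertion codes collapsed, and the
old→new map is returned so any numbering discrepancy against a
published selection is auditable.

## Contacts and occupancy

An instantaneous residue contact exists when any heavy-atom pair
across the two residues is within the cutoff.  The default cutoff is
4.0 Å; hydrogens are excluded so results do not depend on H-placement.
Atom-pair bookkeeping is also available (`mode="atom"`), since crystal
contact counts are sometimes quoted per atom pair; residue-pair
accounting is the default.  Detection uses a k-d tree and is tested
frame-by-frame against an O(N²) distance-matrix oracle.

Occupancy is tabulated two ways: an average over a stated interval and
in rolling windows.  Windows are 40 ns with a 20 ns stride (50%
overlap); the overlap fraction is a package choice, and "maximum
instantaneous occupancy" in the dual high-occupancy criterion is
interpreted as the maximum *windowed* occupancy.  The criterion itself
— average occupancy > 0.50 AND max windowed occupancy > 0.80, strict
inequalities — and the interval are configurable.  The Hamming trace
takes the first 40 ns window as its reference and a presence threshold
of 0.5 within a window; both defaults are package choices.  H may
decrease when a contact re-forms.

## Buried surface area

SASA is Shrake–Rupley point sampling with a deterministic golden-spiral
point set (default 960 points/atom; two-sphere closed-form agreement is
~0.3% and halving/doubling the point count moves totals by <1%), probe
radius 1.4 Å, and Chothia-style heavy-atom radii (C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80, Se 1.90 Å; overridable).  BSA is differenced
SASA per residue (isolated part minus complex), full residue (main
chain + side chain).  "Interfacial residues" are those appearing in any
instantaneous contact during the interval analysed — a package
definition, since the quantity is conventionally plotted without one.
Trajectory BSA subsamples frames at a 1 ns stride by default.

## Triads, CDR3 distance, BOC

The reference triad of a variable-domain core is built from its Cα
coordinates at the reference frame: e3 = first principal axis (the
domain long axis), oriented toward the C-module by a hint vector;
e1 = third principal axis (the β-sheet normal), sign fixed by a hint or
by the largest-component-positive rule; e2 = e3 × e1 (right-handed by
construction).  At every other frame the triad is the reference triad
rotated by the core's rigid-body (Kabsch) fit, so arm identity is
stable; a core fitting worse than 3 Å RMSD triggers an unfolding
warning.  Absolute ∠eᵢ values are convention-dependent (any fixed
orthonormal convention preserves the printed angle *relations*), so
tests and acceptance checks use relative and recovery properties, not
absolute histograms.  Superposition is an unweighted least-squares
rigid fit (Kabsch via SVD), Cα-only by default, cross-checked against
an independent quaternion (Horn) implementation.

The CDR3 distance is the distance between the midpoints of the two
CDR3-base Cα pairs (E93/K97 on α, S94/E102 on β for the B7 preset).
BOC beads are unweighted Cα centroids of the domain cores and hinge
residues; the C-module bead is the midpoint of the Cα and Cβ beads;
∠TCRα is the three-bead angle at Hα between the Vα and Cα beads (the
hinge construction is drawn, not printed, in the source figures — the
three-bead angle is the package's definition).  "Centre of mass of Cα
atoms" is implemented as the unweighted centroid (identical, as all Cα
masses are equal).

## Reduced-coordinate PCA

The V-module reduction uses the two triad origins plus the three arm
tips of each triad (10 Å arms), making modes drawable as arrows; the
V–C reduction uses the six BOC beads.  Rows are mean-centred per
analysed interval (per-interval centring is the package default),
covariance uses n−1 normalisation, amplitudes are √eigenvalues, and
mode signs are fixed by making the largest-magnitude component
positive so overlaps and plots are reproducible.  Amplitude
uncertainty is the std over three overlapping sub-intervals spanning
0–60%, 20–80% and 40–100% of the interval (the 500–800/600–900/
700–1000 ns convention, generalised).  Per-bead asymmetry of mode m is
amplitude × ‖mode sub-vector on the bead‖, differenced α − β for the
matching V and H beads; positive means the α chain is the more mobile.

## Mechanics

Each restrained atom feels F = k·max(|x − c| − w, 0) toward its centre
(w = flat-bottom half-width, default 0).  Forces convert with
1 kcal/(mol·Å) = 69.48 pN (thermochemical calorie, from physical
constants at run time).  The scalar applied load is the mean over the
two molecular ends of the net restraint force projected on the
instantaneous end-to-end axis, outward positive — tension is positive
at both ends, compression negative; per-end values are also emitted
since the reduction to one number is a package choice.  Extension is
reported both as the *setting* (distance between restraint centres,
the number a simulation is labelled by) and as *realized* (atom-atom
distance).  Load and extension use the same 40/20 ns windowing as the
contacts, enabling joint force-vs-occupancy window tables.

## The synthetic generator

The toy complex has four 24-residue domain cores (2×3×4 grids, 4 Å
spacing) for Vα/Vβ/Cα/Cβ, two CDR3-base residues per V domain (rest
CDR3 distance 10 Å), one (α) and two (β) hinge residues, a 20-residue
partner slab that doubles as the MHC floor selection, a 4-residue
peptide ridge, and terminal restraint atoms 62 Å apart.  Prescribed
motions are exact by construction:

- **Hinge bending** rotates the whole V-module rigidly about the
  inter-hinge axis; because both hinge beads lie on the axis and each
  V bead sits directly above its hinge, both measured three-bead hinge
  angles equal the prescribed series exactly at zero noise.
- **Vα–Vβ motion** rotates Vβ about its reference-triad arms as
  R = Rot(e3, b)·Rot(e2, a), for which ∠e2 = |b| and ∠e3 = |a|
  exactly.  A pure rotation about e3 ("twist") gives
  ∠e1 = ∠e2 = |angle|, ∠e3 = 0.  The *scissor* drive sets
  a = a0 + s(t), b = a0 − s(t) (default baseline a0 = 10°), so ∠e2 and
  ∠e3 move in opposite directions while the CDR3 distance tracks s —
  reproducing the reciprocal scissoring signature the analysis must
  detect.  The fixtures use s amplitudes (8°) that keep a and b
  positive, so the folded angles remain linear in s.
- **Contacts** are realised geometrically: the probe (CB) atom of the
  pair's second residue is placed cutoff − 1 Å from the partner's CA
  when on, and parked 1.5 Å from its own CA (≥ 5 Å clearance) when
  off.  The margin is 1 Å on either side of the cutoff, ≈ 7σ of the
  distance noise at the default σ = 0.1 Å, so detected contact sets
  equal the schedule frame-for-frame.  Geometry (outer-column slab
  contacts, 4 Å peptide spacing) keeps every *unscheduled*
  cross-group residue pair > 1 Å clear of the cutoff under all default
  motions.
- **Noise** is i.i.d. isotropic Gaussian per atom per frame
  (default σ = 0.1 Å, a small fraction of a bond length).  Telegraph
  contact schedules use the exact two-state Markov propagator; the
  0.6-occupancy fixture uses rates 150/100 ns⁻¹, whose correlation
  time (4 ps) is a fifth of the frame spacing, making frames
  effectively independent so the binomial sampling band applies.

Everything is reproducible from seeds: each motion process can carry
its own seed, and processes without one draw from the master seed.

What the fixtures do **not** emulate: correlated thermal motion,
anisotropic fluctuations, solvent, force-field energetics, or
realistic contact geometry (probe atoms teleport across the cutoff).
Passing tests therefore demonstrate that the estimators recover known
kinematic and statistical structure at realistic noise levels — not
that any biological conclusion about a particular TCR is reproduced.

## Problem sizes and estimator choices

Test and acceptance fixtures use 600–10,000 frames (12–200 ns at the
20 ps spacing) and the 142-atom toy complex; these sizes give
sampling errors comfortably below the tolerances being asserted
(e.g. binomial σ ≈ 0.005 for occupancy at 10⁴ frames; hinge-mode
vertex noise ≈ 0.9° against a 2° tolerance with 1° histogram bins).
Sinusoidal rotation amplitude is recovered by least-squares projection
on the known |sin| waveform rather than a per-frame maximum, which
carries the positive bias of noise extremes.  Angles are computed via
arccos of clipped dot products; near 0° this is conditioning-limited
to ~10⁻⁵ degrees, which is the tolerance used for zero-angle
assertions (exact-recovery claims elsewhere hold to 10⁻⁶ or better).

## Known limitations

- The crystal-structure CDR3 check requires the 1BD2 coordinates,
  which must be supplied by the user (`data/README.md`); the package
  does not bundle them.
- The renumbering of 1BD2 is defined by the sequential rule; if a
  published selection used a different collapse of insertion codes,
  the returned old→new map is the audit trail.
- BSA per-residue values can be very slightly negative (|x| < 0.5 Å²)
  from point sampling; totals are sums over interface residues.
- `run_analysis` skips stages whose selections are absent (logged to
  stderr) rather than failing, so partial presets (e.g. geometry-only
  for real structures) are usable.
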