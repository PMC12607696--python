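# Methods

This note documents the models and procedures implemented in `memwire`, the
defaults chosen where the underlying methods are conventionally
under-specified, and what the synthetic test systems do and do not
establish.

## Conventions

Coordinates are stored in nm, times in ps, charges in elementary charge
units, masses in u.  Atom, residue and frame indices are 0-based everywhere;
1-based numbering appears only in GRO/PDB files.  Boxes are 3×3
lattice-vector matrices (GROMACS-reduced for triclinic cells); the membrane
normal is assumed to be the z lattice axis.  Molecules are kept whole on
ingest; `geometry.make_whole` re-joins molecules split across the boundary
by walking each molecule's atom order, and should be run before any
center-of-mass or graph computation on wrapped inputs.  Minimum-image
displacements use an orthorhombic fast path and, for triclinic cells,
fractional rounding followed by a 27-image search (exact for reduced cells).

## Water-wire detection

A frame's candidate nodes are the water oxygens (and, by default, AA
carboxylate oxygens, which may be interior nodes but never endpoints) inside
a cylinder coaxial with the protein COM axis.  Pairwise minimum-image O–O
distances up to the graph cutoff (1 nm; larger gaps are irrelevant to
proton transfer and are treated as non-edges) define a weighted graph.  The
source and sink are bulk waters — one per side, beyond the bulk margin —
and the path between them through a minimum spanning tree attains the
minimax gap: the classical MST property guarantees its largest edge is the
minimum, over all source–sink paths, of the path's largest edge.  The
property tests verify the implementation against exhaustive all-simple-path
enumeration on random graphs; the result is algorithm- and tie-independent,
so any correct MST yields the same `max_gap` (only the node path may
differ).

A wire is formed when `max_gap ≤ 0.33 nm`; formation frequency is the
formed-frame fraction, and lifetimes are maximal runs of consecutive formed
frames times the frame interval, with no interpolation between saved frames.
Disconnected endpoints give `max_gap = +∞`, preserving "no wire" semantics
rather than reporting an unmeasurable bridge.

Under-specified choices, made deterministic here:

- **Cylinder**: radius 1.5 nm; half-length 3.4 nm (past the bulk margin on
  both sides).  Both configurable; results are insensitive as long as the
  cylinder encloses the channel and genuine bulk on both sides.
- **Endpoints**: on each side, among waters with `|z − COM_z|` at or beyond
  the membrane half-width (1.7 nm) plus the bulk margin (1.0 nm), the one
  laterally nearest the axis, ties broken by lowest atom index.  For truly
  bulk endpoints the minimax gap is endpoint-robust; determinism matters
  only for reproducibility.
- **Unit assignment**: a formed wire is labeled by the helix pair whose
  inter-axis midline is laterally nearest the midpoint of the wire's largest
  gap (its constriction), or `cavity-axis` when the COM axis is nearer.
  Frames are counted once, by their minimax wire; concurrent channels can be
  planted and are then reported by their own constrictions in the frames
  where each provides the minimax path.

## Binding classification

Each interhelical site is a quadrilateral spanning the gap between two
consecutive TM helices, split into two triangles that share an edge.  The
anchor atoms default to the lowest- and highest-z residues of each helix
(appropriate for the synthetic protein; for real carriers the anchor
residues are user-specified configuration).  A probe is **bound** when any
consecutive segment of its tail chain intersects either triangle
(Möller–Trumbore, boundary-inclusive, ε = 1e-9, with tail positions mapped
to their minimum image about the triangle centroid) *and* the probe has
heavy-atom contacts (< 0.5 nm, strict) with residues of both flanking
helices.  **Deep** states have the head atom within 1.3 nm (3-D
minimum-image distance — the literal reading of a COM-distance criterion)
of the protein COM while bound at a site or cavity-bound.  **Cavity-bound**
states have every heavy atom inside a cylinder of radius 1.3 nm about the
COM axis spanning the cavity z-range (±1.9 nm by default) with the head
within the deep radius; this makes cavity ⇒ deep ⇒ head ≤ 1.3 nm an
invariant of every emitted state.  POPC is analyzed identically with the
phosphate as head atom.

Events are maximal runs of deep-and-bound frames per (probe, site);
the run-merging gap tolerance defaults to 0 frames (the conservative
choice — no merging), and events reaching the last frame are flagged
open-ended.  Contact frequencies are computed over all protein residues
(binding sites can recruit residues outside the flanking helices) and
normalized by the site's bound-frame count; they are monotone
non-increasing in the contact cutoff.

Replicate divergence reports the per-frame distance between the same probe
head atom in two protein-centered replicate runs and the first passage above
a threshold (default 4.8 nm).  Cardiolipin excursions are maximal intervals
with lateral COM distance above 3 nm from the protein COM axis.

## Leaflet-resolved enrichment

Lipids are assigned to leaflets by head-atom z against the bilayer midplane
(mean z of all POPC phosphates); exact ties go to the M leaflet.  The
protein is approximated as a cylinder whose C-leaflet radius is the
time-averaged largest lateral distance from the COM axis to the C-side
terminal residue of each helix, and whose M-leaflet radius is fixed at
2 nm.  Mole fractions use a pooled-count estimator — AA and AA+POPC head
counts summed over frames per annulus, then divided — rather than averaging
per-frame fractions: pooling is unbiased in sparse annuli and makes the
count-weighted bin average equal the global mole fraction as an exact
identity, which the tests assert to machine precision.  Empty annuli are
reported as undefined (NaN), never zero.  The enrichment ratio divides the
0–1 nm ring fraction by the bulk fraction; the bulk region defaults to the
outermost 0.5 nm of radii fully contained in the box under periodic
boundaries, and a zero bulk fraction raises rather than returning infinity.
Replicate profiles aggregate to a bin-wise mean and population standard
deviation (identical replicates give sd = 0).

## Reciprocal-space electrostatics

The field is the smooth part of an Ewald decomposition: charges are spread
onto the grid with 4th-order cardinal B-splines, the structure factor is
corrected by the Euler exponential-spline factors, each mode is multiplied
by `4π/V · exp(−k²/4β²)/k²`, and the inverse transform gives a periodic
potential whose grid mean is exactly zero (k = 0 excluded; net charge is
implicitly neutralized by a uniform background).  Short-range terms are
omitted by construction — they would be singular on a grid — so the output
is the smeared, long-range component only, and the output metadata restates
this.  Defaults: β = 2.5 nm⁻¹, grid spacing ≤ 0.12 nm (0.1 nm in the
validation fixtures), T = 310.15 K for the kT/e scale.  A direct k-space sum
(`direct_reciprocal_sum`, truncated where the Gaussian factor falls below
1e-10) serves as an independent reference: at 0.1 nm spacing the grid field
agrees with it to ~0.01 % on 20-charge fixtures, improving monotonically
under refinement.  Off-grid values use periodic tricubic B-spline
interpolation (exact at grid nodes).

Wire-averaged profiles evaluate the per-frame field at the wire's node
positions, subtract a per-frame bulk reference (mean potential over water
oxygens with `|z − COM_z| ≥ 2.2 nm` by default), and bin by z relative to
the protein COM; every 10th wire-containing frame is analyzed by default.
Per-wire maxima are reported separately from the binned profile because
different wires peak at different z, so the mean of maxima exceeds the
maximum of the mean profile.

## Synthetic systems

The generator emulates the study geometry at desk scale: 6 vertical
9-bead helices on a 0.9 nm ring (antiparallel, so C-side helix ends define
the outer surface), phosphate planes at ±1.7 nm, 48 POPC-like (3-bead,
neutral) and 8 AA-like (5-bead, head charge −1) lipids per leaflet on a
lateral lattice, single-bead water slabs at 2.0–2.9 nm from the midplane on
a 0.28 nm lattice with ±0.004 nm jitter, and +1 counter-ion beads in a far
corner of one slab keeping the total charge exactly zero.  The water slab's
outer edge stays more than the graph cutoff away from its periodic image so
the two reservoirs never connect around the box.  The jitter bound keeps
bulk O–O gaps below 0.30 nm, so a planted chain's spacing alone controls
the detected minimax gap; chain ends are snapped to water-lattice sites so
chain-to-bulk connectivity never exceeds the planted spacing.  Everything
is a pure function of (spec, seed): identical inputs give bit-identical
systems, trajectories and sidecar ground-truth records.

Planting semantics:

- **Wires**: per-frame presence flags; present frames place a single-file
  chain (spacing ≤ `gap_when_present`, default 0.30 nm) between a helix
  pair; absent frames park enough mid-chain waters in bulk that the
  narrowest crossing is ≥ `gap_when_absent` (default 0.50 nm).  A lateral
  kink and concurrent second channels are generator options.
- **Binding events**: during the event the AA head sits at the planted
  depth from the protein COM with one tail bead at the exact gap center
  (0.45 nm from both helix axes, inside the 0.5 nm contact cutoff) and the
  tail crossing the gap surface; outside the event the AA rests at its
  outermost membrane site, ≥ 1 nm from the protein surface.  Cavity events
  place all beads near the COM axis.
- **Enrichment**: occupied lattice sites are fixed; each frame the number
  of ring AA is Binomial(m_ring, fold·x₀) with
  x₀ = n_AA/(fold·m_ring + m_out), which makes the expected ring and
  off-ring mole fractions fold·x₀ and x₀, hence an expected ratio of
  exactly `fold`; recovery tests use 3-binomial-SE bands.

What the synthetic systems do **not** emulate: thermal motion (frames are
static except planted changes), realistic lipid/protein shapes and packing,
hydrogens and hydrogen-bond geometry (the wire criterion is O–O distance
only, matching the method), force-field energetics, and real charge
distributions (the default protein is neutral; charges are planted where a
test needs them).  Passing recovery tests therefore demonstrates
correctness of the geometric and statistical machinery under controlled
conditions — not that any particular biological system forms wires at a
given frequency.  Published trajectory-scale quantities are checked only at
the arithmetic level (run-time, composition-charge and equilibration sums in
the packaged metadata tables).

## Problem sizes and numerical choices

The default toy scale (≈ 3,300 waters, 112 lipids, 54 protein beads,
≤ 1,000 frames) was chosen so full-pipeline recovery runs complete in
seconds to tens of seconds; all algorithms are size-agnostic, and real
trajectories stream through the same per-frame path (binary formats via the
MDTraj adapter).  Edge ties in the MST are resolved by scipy's deterministic
sweep; the minimax value is tie-independent, which a dedicated relabeling
test asserts.  Degenerate gap triangles (area < 1e-6 nm²) raise with the
site named rather than returning an arbitrary answer.  Segment–triangle
boundary cases within 1e-9 are counted as intersections (boundary-inclusive)
— the convention only matters on a measure-zero set.  Contact cutoffs are
strict inequalities, matching a "distance < 0.5 nm" criterion.

## Known limitations

- Leaflet assignment by midplane crossing misclassifies lipids mid-flip;
  the fixtures contain no flip-flop, and none is expected on the source
  timescales.
- The C-leaflet surface radius uses the terminal helix residues' Cα-like
  atoms; heavily kinked helices would need user-specified anchors.
- `wire_potential_profile` recomputes the full grid per analyzed frame;
  for very long trajectories increase the stride or spacing.
- Only the reciprocal potential is computed; absolute barrier heights
  additionally depend on short-range and desolvation terms that grid
  estimators of this family do not capture.
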