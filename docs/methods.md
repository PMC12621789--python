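# Methods

This note records the geometric definitions, numerical choices, and the
design decisions behind `micurate`, in the order the pipelines apply
them. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Structure model

A complex is an ordered list of residues (chain id, author sequence
number, 3-letter name, ordered heavy atoms; hydrogens are kept when
present but every definition below is heavy-atom based). Chains are
tagged `binder` or `target` explicitly — with more than two chains there
is no safe automatic partition, so the caller must name the binder
chains. Alternate locations resolve to the highest occupancy, ties
broken by altloc letter. Waters and non-PTR heteroatoms are dropped by
default. Van der Waals radii are a fixed element table (C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80 Å). Internal bookkeeping is positional; author
numbering is preserved for all reporting, so PDB numbering gaps never
affect geometry.

The virtual Cβ used throughout (glycine, or any residue without an
explicit CB) is constructed from N/CA/C at ideal tetrahedral geometry,
1.522 Å from Cα, with the standard out-of-plane construction; it is
exactly rigid-motion equivariant, which makes every annotation invariant
under global superposition.

Phosphotyrosine follows the PTR chemical component: phosphorus P,
terminal oxygens O1P/O2P/O3P, and the bridging ester oxygen OH. Missing
terminal oxygens degrade gracefully (warning, smaller group); a missing
P is an incomplete-residue error.

## Solvent accessibility

SASA is Shrake–Rupley point sampling on a deterministic golden-spiral
sphere set (default 960 points per atom), so results are bit-for-bit
reproducible at fixed density. Two probes are used deliberately:

* the **hotspot gate** uses probe 2.8 Å in complex context, because the
  gate is paired with interface detection and a large probe suppresses
  narrow crevice area;
* the **RASA conditioning channel** uses the conventional 1.4 Å water
  probe, normalized by a fixed per-amino-acid theoretical maximum ASA
  (Tien-style values; PTR normalizes against tyrosine), clipped to
  [0, 1]. Residue types without a reference are reported as missing,
  never as zero.

Whether the curation SASA should be measured on the complex or on the
isolated target is genuinely open; complex context is the default and
`chain_alone` is available. The implementation is cross-checked in the
tests against a Monte-Carlo rejection oracle on small systems (2 %
agreement at 10 000 points) and against biotite's independent
implementation on a small fixture.

## Interface annotation

* Hotspot: target residue with min Cβ–Cβ distance to the binder ≤ 7.0 Å
  (boundary inclusive) **and** SASA ≥ 30 Å². The Cβ–Cβ reading is
  literal; the virtual Cβ covers glycine.
* Anti-hotspot: minimum heavy-atom distance from any of the residue's
  atoms to any binder atom > 10.0 Å (boundary exclusive). Since
  7 ≤ 10, hotspot and anti-hotspot are disjoint by construction and the
  annotation container enforces it.
* Super-hotspot value: for each hotspot, count binder Cα within 10 Å of
  its Cα, optionally add a uniform integer from {−1, 0, +1} (the "±1"
  jitter distribution is our choice; it is drawn from a seeded generator
  per structure so runs are reproducible), clamp to [0, 12], divide
  by 12. Non-hotspots get 0; jitter can move a value by at most 1/12.
* Mask downsampling: budget = ceil(0.20 × target length). `speckle`
  keeps a uniform random subset; `region` picks one seeded hotspot and
  grows by 3D nearest-neighbor order over hotspot Cβ until the budget is
  filled (the contiguous-patch geometry is unspecified upstream; the
  chosen patch is logged). Masks below budget pass through unchanged;
  the output is always a subset of the input.
* ORI: arithmetic mean of the hotspot residues' (virtual) Cβ, emitted
  as a pseudoatom in PDB output; a user-supplied point is passed
  through. The 75 % / 10 % hotspot / anti-hotspot inclusion rates are
  carried as configuration for dataset builders and not re-validated
  statistically here beyond seeded determinism.

## Packing quality and cropping

The SCN cone weighting (`w_dist = 1/(1+exp(d−9))`,
`w_ang = ((cosθ+0.5)/1.5)²` for cosθ > −0.5, self excluded, summed over
every other residue with a Cα) is the published Rosetta-style
side-chain-neighbor form; adopting a fully explicit formula makes the
metric oracle-checkable by brute force, which the tests do. The
SCN > 4.0 (well-packed) and SCN > 1.0 (folded, for trimming) thresholds
are used unchanged.

Curation applies four gates — `binder_FBSCN < 0.12`,
`interface_FBSCN < 0.13`, empty hotspot mask, binder > 170 residues —
and reports all violated reasons rather than failing fast. A complex
with zero interface residues has `interface_FBSCN = 0` by definition
(degenerate inputs give reject verdicts, not exceptions).

Trimming examines each binder terminus independently: take the terminal
window of `w = min(9, remaining)` residues, tolerance 0/1/2 for
`w ≤ 4 / ≤ 8 / > 8`; while the window's folded count is within
tolerance, remove **one** terminal residue and re-examine. Removing one
residue per step (rather than the whole window) makes the stopping point
well-defined and the operation idempotent; this was an open ambiguity
and is our choice. Trimming never leaves fewer than one residue, may
extend at most one window length (9 residues) past a supplied
hotspot-bound, and never touches target chains. Note a consequence of
the rule as stated: a short floppy tail directly adjacent to a
well-folded terminus may survive, because the terminal window already
contains more folded residues than the tolerance.

Radial cropping keeps every binder residue unconditionally and keeps a
target residue iff any heavy atom lies within 25 Å of the crop center's
(virtual) Cβ, the center drawn uniformly from the hotspot residues under
the seed. The upstream description of the radius ("within >25 Å") is
contradictory as written; we read it as *within 25 Å*, since retaining
only distant residues would defeat the purpose of limiting context while
preserving local geometry. The radius is configurable, and the retained
set is monotone in it.

## Conditioning tensor

Fixed 29-channel layout: 21 amino-acid one-hot slots (alphabetical
1-letter order + unknown), 3 secondary-structure slots, motif flag,
hotspot mask, anti-hotspot mask, super-hotspot value, RASA. PTR maps to
the unknown slot — the one-hot is a 20-type alphabet with no PTM slot —
with its identity recorded in metadata and, of course, in the structure
itself. Channel order is versioned in the TSV sidecar; unused channels
are zero-filled with the mask recorded, so tensors stay comparable
across runs. Secondary structure comes from a self-contained
dihedral-window rule (helix: (φ, ψ) ∈ [−100°, −30°] × [−80°, −5°] for
the residue and both neighbors; strand: φ ∈ [−180°, −80°],
ψ ∈ [80°, 180°] ∪ [−180°, −170°] for the residue and at least one
neighbor; otherwise coil, termini coil) — no external assigner, so the
pipeline has no tool dependency; the windows classify ideal helix
(−57°, −47°) and strand (−120°, 120°) geometry correctly. Features are
residue-level and geometry-free given their inputs; broadcasting copies
rows to atom slots bit-for-bit.

## Design filters

The hydrogen-bond criterion (donor–acceptor ≤ 3.5 Å heavy-atom,
antecedent–acceptor–donor ≥ 90°, D–H–A ≥ 120° when hydrogens exist) is
common structural-biology practice; it is not prescribed upstream and
every threshold is configurable. Donors are backbone N plus tabulated
side-chain N/O/S donors (any side-chain nitrogen qualifies, which also
covers synthetic donor groups); acceptors are backbone O plus tabulated
side-chain acceptors including the PTR phosphate oxygens. The acceptor's
antecedent is its nearest covalent heavy neighbor within the residue.
Each donor–acceptor pair counts once; intra-residue pairs are excluded.

Phosphate hydrogen bonds count binder-chain donors (backbone or side
chain) to *terminal* phosphate oxygens of a target-chain PTR. The
peptide total counts all binder↔target bonds in either direction and
includes the phosphate bonds (subset semantics — whether the ≤ 12 cap
includes them was unspecified); the side-chain/side-chain subset is
reported separately as the sequence-specificity signal.

pTyr RMSD superposes the predicted complex onto the design over matched
binder Cα (chain id + sequential position; mismatched lengths use the
common prefix with a warning, requiring ≥ 3 pairs), then measures RMSD
over the PTR's shared heavy atoms without further fitting. All shared
heavy atoms is the default; a phosphate-only selection (P, O1P, O2P,
O3P, OH) is available since the intended atom set was unspecified.
Superposition is a standard SVD Kabsch with proper-rotation correction;
degenerate (collinear) point sets are an error.

Gates: phosphate bonds ≥ 2, peptide total ≤ 12, pTyr RMSD < 5 Å, binder
length < 160. Confidence gates (min pLDDT, max iPAE, min iPTM, min PTM)
have **no defaults**: upstream gives directions ("high", "low") but no
numbers, so both threshold and metric must be supplied explicitly; a
supplied threshold whose metric is missing skips with a warning. The
filter is monotone: relaxing any threshold never turns a pass into a
fail.

## Synthetic fixtures

The generator emulates the two phosphopeptide binding modes the pipeline
must handle — a helical peptide with the phosphate engaged at a helix
terminus, and a strand peptide pairing with a sheet — using idealized
poly-alanine scaffolds built by natural-extension-reference-frame
construction from ideal bond lengths/angles (helix φ/ψ = −57°/−47°,
strand −120°/120°, extended −150°/150°, ω = 180°; verified rise
≈ 1.5 Å/residue and Cα–Cα ≈ 3.80 Å). The default binder is a 48-residue
three-helix bundle packed as a triangle with 9 Å axis spacing and the
inter-helix groove facing the peptide; this is the smallest idealized
topology that genuinely passes both FBSCN gates, the way a curated
training example would, while a lone helix or flat sheet — physically
under-packed — lands on the reject side of the same gates. The default
peptide is AAyAA with three contact residues at a 5.5 Å Cβ gap and two
phosphate pseudo-donors at 2.9 Å, i.e. a design that passes the
phosphate gate exactly at threshold.

Peptide placement is a deterministic grid search over tilt, axial
offset, and approach distance until exactly the requested number of
peptide residues are within 7 Å Cβ contact range with the nearest pair
at the requested separation (honesty is asserted in tests: exact contact
counts, donor distances within 0.2 Å). Infeasible requests (contacts at
separation > 7 Å) are an error. Pseudo-donor nitrogens are placed on the
nearest binder residue along the O→P extension so the antecedent angle
is ideal; side chains beyond Cβ are otherwise omitted (all in-scope
metrics are backbone/Cβ/phosphate-based). Disordered tails are extended
glycine segments pointing away from the complex, built so their SCN
falls below the folded threshold.

What the fixtures do **not** model: real rotamers, clash relaxation,
sequence diversity beyond the one-hot alphabet, crystallographic
disorder, or prediction noise. Passing tests therefore demonstrate that
the rules are implemented exactly and behave correctly on controlled
geometry — not that the thresholds themselves are optimal on
experimental structures.

## Problem sizes and determinism

All tests and the acceptance script run on fixtures of 20–70 residues
(hundreds of atoms), where every oracle (closed-form sphere area,
Monte-Carlo SASA, brute-force SCN and rotation search) is exact or
converged; the full suite plus the acceptance script complete in well
under a minute. Every stochastic step (super-hotspot jitter, mask
downsampling, crop-center choice) flows from one seed; PDB and TSV
writers emit no timestamps, so identical inputs give byte-identical
outputs, which the CLI tests assert across reruns.
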