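# micurate

Interface curation and design filtering for binder–target complexes, with
first-class support for phosphotyrosine (pTyr) peptide targets.

Generative binder-design pipelines need two kinds of deterministic,
geometry-level bookkeeping around the model itself: **curation** of
training complexes (which target residues count as interface hotspots,
how well-packed is the binder, which disordered tails and distant context
should be removed) and **filtering** of candidate designs (does the
binder actually engage the phosphate group, is the phosphotyrosine where
the design put it). `micurate` implements both as a reusable library plus
a small CLI, together with a deterministic generator of idealized
binder–phosphopeptide complexes so everything is testable without any
structure download.

## What it computes

**Interface annotation.** A target residue is a *hotspot* iff its
(virtual) Cβ lies within 7 Å of any binder Cβ **and** its
solvent-accessible surface area is ≥ 30 Å² (Shrake–Rupley, probe radius
2.8 Å). *Anti-hotspots* are target residues whose minimum heavy-atom
distance to the binder exceeds 10 Å. *Super-hotspot values* grade each
hotspot by cross-chain contact density: the number `n` of binder Cα
within 10 Å of its Cα (optionally jittered by ±1), capped at 12 and
normalized, `v = min(n, 12) / 12 ∈ [0, 1]`. Hotspot masks can be
downsampled to a coverage budget (default 20 % of the target) by
scattered *speckle* or contiguous *region* sampling, and the ORI noise
origin is placed at the geometric center of the hotspot mask.

**Packing quality.** The side-chain-neighbor count of residue *i* is a
cone-weighted Cα neighbor count along the Cα→Cβ direction **u**:

```
SCN_i = Σ_j  w_dist(d_ij) · w_ang(θ_ij)
w_dist = 1 / (1 + exp(d_ij − 9))
w_ang  = ((cos θ_ij + 0.5) / 1.5)²   if cos θ_ij > −0.5, else 0
```

with `d_ij` the Cα–Cα distance and `θ_ij` the angle between **u** and
the displacement to residue *j*. `binder_FBSCN` is the fraction of
binder residues with SCN > 4.0; `interface_FBSCN` is the same fraction
over binder interface residues (Cβ within 7 Å of a target Cβ). A complex
is **rejected** when `binder_FBSCN < 0.12`, `interface_FBSCN < 0.13`,
no hotspots were found, or the binder exceeds 170 residues. Disordered
binder tails are trimmed with a sliding 9-residue window (a residue is
"folded" iff SCN > 1.0; terminal residues are removed while the window
holds ≤ 0/1/2 folded residues for window lengths ≤ 4/≤ 8/> 8), and the
target is radially cropped to 25 Å around a randomly chosen hotspot (the
binder is always retained; targets are never trimmed or packing-scored).

**Conditioning features.** Each residue token gets a fixed 29-channel
row — amino-acid one-hot (20 + unknown; PTR uses the unknown slot with
its identity kept in metadata), helix/strand/coil tokens from a
self-contained dihedral-window rule, a motif flag, hotspot and
anti-hotspot masks, the super-hotspot value, and relative solvent
accessibility (SASA at probe 1.4 Å over a fixed per-type maximum).
Rows broadcast unchanged to every atom slot of their residue.

**Design filters.** Hydrogen bonds use a heavy-atom geometric criterion
(donor–acceptor ≤ 3.5 Å, antecedent–acceptor–donor angle ≥ 90°, plus
D–H–A ≥ 120° when explicit hydrogens exist). A design passes when it
makes ≥ 2 hydrogen bonds to the phosphotyrosine's phosphate group, at
most 12 total hydrogen bonds to the peptide, has a pTyr RMSD < 5 Å
between designed and predicted complexes after Kabsch superposition on
the binder Cα, a binder under 160 residues, and satisfies any
explicitly supplied prediction-confidence gates (pLDDT, iPAE, iPTM,
PTM — no silent defaults).

## Worked example

```python
from micurate import (FixtureSpec, assemble_complex, sasa_per_residue,
                      detect_hotspots, scn_per_residue, curation_verdict,
                      detect_hbonds, count_phosphate_hbonds, ptyr_rmsd)

cx = assemble_complex(FixtureSpec())        # 48-res helix bundle + AAyAA peptide
sasa = sasa_per_residue(cx, probe_radius=2.8)
hot = detect_hotspots(cx, sasa)
report = curation_verdict(cx, scn_per_residue(cx), hot)
bonds = detect_hbonds(cx)
print(int(hot.sum()), report.verdict,
      round(report.binder_fbscn, 3), round(report.interface_fbscn, 2),
      count_phosphate_hbonds(bonds, cx), round(ptyr_rmsd(cx, cx), 6))
```

prints

```
3 accept 0.292 0.25 2 0.0
```

i.e. the three peptide residues placed in contact range are detected as
hotspots, the bundle passes both FBSCN folding gates (29.2 % of binder
residues and 25 % of interface residues pack above SCN 4.0), the two
pseudo-donors placed 2.9 Å from the phosphate register as phosphate
hydrogen bonds, and the phosphotyrosine RMSD of a structure against
itself is zero.

The same pipelines are exposed as a CLI:

```
micurate fixture  --out fix --tail-len 4
micurate curate   fix/fixture.pdb --binder-chains A --out curated --seed 7
micurate featurize fix/fixture.pdb --binder-chains A --out features
micurate filter   fix/fixture.pdb --predicted fix/fixture.pdb \
                  --binder-chains A --out filtered
```

Exit codes distinguish gate rejection (3) from errors (1); every run
writes a manifest echoing all thresholds and seeds.

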