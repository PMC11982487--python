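# Methods

This note documents the models, algorithms, parameters and design choices
behind `shortloop`, and what the synthetic-fixture tests do and do not
demonstrate about real structures.

## Structure model and chemistry tables

Structures are parsed with gemmi into a minimal chain → residue → atom
model. Author residue numbering is preserved end to end, so outputs read
"Ala99" or "Thr75" exactly as deposited; internal indices are 0-based and
never serialized. Only the first MODEL of a multi-model file is used.
Alternate locations are collapsed per atom name to the highest-occupancy
copy (positional first on ties); the policy is deliberately simple and
testable, and no assumption is made that occupancies per group sum to 1.
Waters and hetero compounds are kept on side lists and excluded from
occupancy grids by default (`include_hetero` flips this for ligands).

Van der Waals radii are a Bondi-style per-element set (C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80, H 1.20 Å; 1.70 Å default with a warning for unknown
elements). Hydrogens are excluded from occupancy grids by default because
these heavy-atom radii are calibrated for implicit hydrogens.

Residue size uses Zamyatnin-style mean residue volumes (Gly 60.1, Ala 88.6,
Thr 116.1, Glu 138.4, Val 140.0, Met 162.9, Phe 189.9, Tyr 193.6,
Trp 227.8 Å³, …). Note Val sits exactly at the default sensitive-residue
size threshold (≤ 140 Å³) and is therefore admissible.

The hydrophobic set defaults to {Ala, Val, Leu, Ile, Pro, Phe, Met, Trp,
Tyr, Cys}. This is intentionally broader than a Kyte–Doolittle > 0 cut:
in loop context Pro and Tyr act as hydrophobic packing partners of buried
small residues, which a strict scale would exclude. The set is
configurable. Common non-standard residues (MSE, SEP, PTR, …) inherit the
chemistry of their standard parent and are flagged non-standard.

## Secondary structure

A minimal DSSP-style assigner separates loop from regular structure —
nothing finer is needed downstream. Backbone N–H…O=C bonds are scored with
the Kabsch–Sander electrostatic model

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)   [kcal/mol]

with a bond recorded when E < −0.5 kcal/mol and a 5.2 Å N…O shortcut.
Missing amide hydrogens are built 1.0 Å from N along the preceding
C→O direction (deposited hydrogens win); prolines and chain-start residues
have no donor, and a degenerate C≡O geometry disables the donor with a log
message. Two consecutive i→i+4 turns mark residues i+1…i+4 as helix
(3₁₀/π variants are merged into H); Kabsch–Sander parallel/antiparallel
bridge patterns between residues ≥ 3 apart mark strand, isolated bridges
included; helix wins where both apply; everything else is coil. The
assignment depends only on interatomic distances, hence is rigid-body
invariant and deterministic.

A per-chain HEC string file (`ss_override`) can bypass assignment entirely,
e.g. to reuse states from another tool.

## Loops and hydrophobic runs

Maximal coil runs are segmented per chain; runs touching a chain terminus
are flagged terminal and carry a single flank. Short loops are runs of
`loop_min_len`–`loop_max_len` residues (default 5–7, soft bounds exposed on
the CLI) with regular flanks of ≥ `min_flank_len` (default 3) on both
sides; the flank minimum suppresses single-residue secondary-structure
noise. Hydrophobic runs are maximal consecutive-hydrophobic stretches in
the loop window extended `flank_extension` (default 2) residues into each
flank, because the hydrophobic context of a loop frequently includes
flank-adjacent residues; runs that never touch the loop are dropped.

## Cavity detection

A dual-probe voxel grid in the KVFinder family. Defaults: spacing 0.6 Å,
probe_in 1.4 Å (water), probe_out 4.0 Å, minimum reported cavity 5 Å³,
box padding probe_out + 2·spacing. For each probe, a voxel is occupied if
its centre lies within (vdw + probe) of any heavy atom. Bulk solvent is
found by flood-filling the probe_out-free space from the box boundary
(6-connectivity) and sweeping it by the probe_out radius (Euclidean
distance transform). Cavities are the probe_in-free voxels outside the
swept region, split into 6-connected components (6-neighbourhoods avoid
diagonal leakage); volume is exactly voxel count × spacing³. A pocket
whose mouth is too narrow for the 4 Å probe counts as a cavity — that is
the point of the dual probe: probe_out defines "bulk", not geometry
textbook enclosure.

Lining residues are those with any heavy atom within `contact_distance`
(default 5 Å) of a cavity voxel centre; a component with an empty lining is
suppressed with a warning. Cavities are ordered by decreasing volume, ids
assigned after ordering, so output is deterministic.

Numerical behaviour worth knowing:

- Volumes converge with resolution: halving 0.6 → 0.3 Å moves hollow-shell
  volumes < 1% in our tests (< 5% asserted).
- The grid origin follows the model bounding box. Comparisons that change
  the box (adding an atom outside it, changing probe_out with default
  padding) shift voxel alignment and can move volumes by a voxel or two.
  Monotonicity invariants are therefore stated — and tested — at fixed
  grid (explicit `padding`, additions inside the box).
- Grid volumes agree with an independent Monte-Carlo point-sampling oracle
  of probe-accessible interior volume to well within 10% on hollow shells
  of inner radius 4–8 Å.

## Sensitive residues and mutation proposals

A residue is sensitive iff (a) it belongs to a retained short loop,
(b) both immediate sequence neighbours are hydrophobic, (c) its own
side-chain volume is ≤ `max_sidechain_volume` (140 Å³ — the smallest round
value admitting Ala, Thr and Glu, the classic cases of this strategy; the
Glu case shows "small side chain" is not sharply defined, hence the knob),
and (d) it lines a cavity of ≥ `min_cavity_volume` (100 Å³, comfortably
below the 150–884 Å³ range of published examples). Ranking is
cavity_volume / sidechain_volume, descending — large void behind a small
residue first; the score is scale-free and invariant under rigid motions.

Proposals mutate to each configured target (default Phe, Tyr, Trp, Met)
strictly larger than the wild type on the volume scale. The graft keeps
the backbone fixed, superimposes the target's ideal heavy-atom geometry
(CCD templates via biotite) on N/CA/C, and scans a small chi grid
(chi1 ∈ {−60°, 60°, 180°}; chi2 ∈ {−90°, 90°} for aromatics, else three
staggered values; chi3 staggered; higher chis extended). Glycine sites get
their Cβ from the template. Clashes are heavy-atom pairs (new side chain
vs everything outside the residue) with centre distance < 0.7·(r₁+r₂); the
first rotamer with the fewest clashes wins (grid order breaks ties), and a
best rotamer above `clash_cap` (10) marks the proposal infeasible but keeps
it in the report. The hard-sphere model is crude but deterministic; real
mutant refinement (minimization, MD) is deliberately out of scope — this
tool ranks candidates for external refinement and ΔΔG screening.

The residual cavity of a mutant is re-measured by running detection on the
mutated model and summing cavities that intersect the wild-type cavity's
bounding box dilated by probe_in — robust to the cavity shrinking,
splitting or shifting. Proposals are sorted by (clash count, residual
volume), so the cleanest, most-filling mutation comes first.

External stability scores join on (chain, residue number, wild-type,
mutant) from a TSV with the convention ΔΔG = ΔG(mutant) − ΔG(wild-type),
negative = predicted stabilization. They are annotations only.

## Synthetic fixtures: what they emulate, what they do not

All fixtures are deterministic and serialize to valid PDB.

- **Ideal helix / extended chain**: backbones built by natural-extension
  (NeRF) placement with ideal bond geometry; helix torsions (−57°, −47°),
  ω = 180°. Side chains beyond Cβ come from the same ideal templates used
  for grafting, so identity grafts are exact fixed points.
- **Helix-loop-helix**: two ideal helices joined by a linker with fixed
  "random-coil" torsions. The torsion pattern at the boundaries (coil ψ on
  the first loop residue, coil φ with helical ψ on the last) breaks the
  helical turn ladder precisely at the designed residues, so the assigned
  coil run coincides exactly with the designed loop for lengths ≥ 3. The
  specific coil torsion cycle was chosen so no accidental i→i+4 turns form
  at the boundaries across loop lengths 5–12.
- **Hollow shell**: carbon-typed single-atom glycine "residues" on a
  Fibonacci lattice of radius inner_radius + 1.7 Å. The lattice is
  densified until the largest hole clearance sits 1.0 Å below the water
  probe's reach, which both seals the void analytically and keeps the
  occupied slab around the surface thicker than a voxel step, so no
  discretized path leaks through. The enclosed probe-accessible volume is
  approximately (4/3)π(inner_radius − 1.4)³ and is measured independently
  by Monte-Carlo sampling. An aperture variant cuts a polar cap to open
  the void to bulk (caps ≥ ~60° admit the 4 Å probe: negative control).
- **Cavity pocket**: the end-to-end fixture. Serine helices flank the
  SVAVS loop, so the centre alanine is the only residue with hydrophobic
  neighbours on both sides — the "exactly one sensitive residue" outcome
  is a sequence-design fact. A sealed shell with a wide mouth
  (radius 4.8 Å) sits against that residue; the residue's own Cβ plugs the
  mouth (no water-probe path in or out), while a grafted large side chain
  grows through the mouth into the void. The mouth is aimed along the tip
  of the first Trp rotamer of the chi grid — the rotamer the graft scan
  visits first — so a clash-free, cavity-filling Trp proposal exists by
  construction. The mouth cannot be made probe-tight *and* ring-passable:
  any aperture a ~3.4 Å-wide aromatic ring can thread without hard-sphere
  clash also admits a 1.4 Å probe, which is why the plug design is used.

These fixtures are geometric, not physical: they have no packing quality,
no realistic rotamer distribution, no solvent, and pseudo-atom shells are
not protein. Passing tests therefore certify the algorithmic contracts
(volumes, monotonicity, determinism, criteria logic), not predictive
accuracy on real proteins. On real structures, cavity volumes further
depend on the conformer: published volumes in this problem area are
typically computed on MD-relaxed structures, so agreement on deposited
coordinates is expected only to within a generous tolerance (the bundled
urate-oxidase check uses ±25%, and requires downloading the PDB entry).

## Problem sizes and budgets

Default grids put a 30-residue fixture at ~10⁵–10⁶ voxels; a full screen of
the cavity-pocket fixture (detection + four mutant re-detections) takes a
few seconds on one core. The monotonicity sweep uses a coarser 0.8 Å grid
over 100 randomized fixtures as a test-size choice — the invariants are
grid-parameterized, and defaults are unchanged. The Monte-Carlo oracle
uses 10⁶ points (≈ 0.3% relative error at shell scale). A voxel budget
(4·10⁸, configurable) guards against accidentally fine grids on large
proteins; exceeding it raises a resolution error advising larger spacing.

## Known limitations

- The assigner collapses all helix types into H and does not classify
  turns/bends; per-residue agreement with full DSSP is not claimed, only
  loop-vs-regular separation.
- Hard-sphere clash counting ignores electrostatics, torsional strain and
  backbone relaxation; a zero-clash graft is a packing hypothesis, not a
  stability prediction.
- Cavity volumes on a single conformer can differ substantially from
  ensemble-averaged values.
- Multi-chain interfaces are screened as given; no symmetry expansion is
  performed (use the `--chain` flag to restrict).
- Acidic cavity-rescue mutations (new salt bridges/H-bonds) are a
  different stabilization mechanism and are intentionally not proposed.
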