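# Methods

`exthect` re-analyses the domain boundaries of the 28 human HECT E3
ubiquitin ligases. The catalytic HECT domain (~350 residues, bilobal, with
the catalytic cysteine in the C-lobe) is preceded in every solved structure
by at least one amphipathic α-helix (α1′) that packs against a hydrophobic
pocket of the N-lobe. Constructs cut at the annotated UniProt start lose
this helix and expose the pocket, which correlates with poor solubility.
The package quantifies that exposure on structures, detects the helix from
sequence, proposes extended boundaries from ortholog alignments, and
compares boundary annotations across sources.

## Structure preparation

Structures are read from PDB format (via gemmi) into a typed model. The
preparation protocol keeps a single chain, removes residues made of HETATM
records (waters, ions, ligands), and strips hydrogens. Selenomethionine
(MSE) is retained and treated as methionine for hydrophobicity, since it is
a modified standard residue rather than a ligand. Alternate locations
default to highest occupancy (ties broken by altloc letter); only the first
MODEL is kept; every dropped record class is counted in the structure's
provenance notes.

Hydrogens are deliberately not added back. Protonation output depends on
the placement tool and its settings and is not reproducible bit-exactly, so
the pipeline works at the heavy-atom level with two radii presets:

| preset | C | N | O | S | P | Se | default |
|---|---|---|---|---|---|---|---|
| `default-heavy` | 1.70 | 1.55 | 1.52 | 1.80 | 1.80 | 1.90 | 1.70 |
| `pymol-like` | 1.90 | 1.65 | 1.50 | 1.85 | 1.90 | 1.95 | 1.90 |

`pymol-like` is a united-atom style set whose enlarged carbon radius
absorbs the implicit hydrogens; it is the preset used when comparing
against areas measured on protonated structures. Unknown elements fall back
to the set default and are logged.

Hydrophobic residues are A, G, V, I, L, F, M, Y, W (binary set); side-chain
atoms are heavy atoms whose name is not N, CA, C, O or OXT, so glycine
contributes none.

## Solvent-accessible surface area

SASA is computed by Shrake–Rupley sphere sampling: each atom's accessible
sphere (vdW radius + probe, probe default 1.4 Å) carries a deterministic
golden-spiral lattice (default 960 points); a point is exposed when outside
every neighbour's accessible sphere; per-atom area is the exposed fraction
× 4π(r+p)². Neighbour search uses a KD-tree with the exact occlusion cutoff
(r_i + r_j + 2p); occluders are tested nearest-first with early exit, which
cannot change the result.

Lattice orientation. A world-fixed lattice makes areas change by ~1% under
rotation of the input. To make areas invariant under rigid-body motion, each
atom's lattice is oriented by a local frame: the eigenbasis of a smoothly
weighted covariance of neighbour displacements (weights (1−d/R)², support
R = 8 Å), signs fixed by the weighted third moment, handedness resolved
without ever flipping an axis whose third-moment sign is decisive. The
frame is a smooth, rotation-covariant function of the local geometry, so
areas are invariant to rigid motion to floating-point precision, and —
because the support is finite — deleting a segment farther than 8 Å cannot
perturb the sampling of untouched atoms. Where the frame is ambiguous
(isolated atoms, mirror-symmetric environments, degenerate neighbourhoods)
the ambiguity coincides with an occluder symmetry that leaves the sampled
count unchanged.

One consequence, verified by the tests: strict occlusion monotonicity
("adding an atom never increases any other atom's area"), exact for a
world-fixed lattice, holds here only up to single-lattice-point noise
(≤ ~0.5 Å² at 960 points), because a new neighbour within 8 Å can re-orient
nearby frames. The monotonicity test allows a 1 Å² tolerance for this.

Accuracy at 960 points, measured against closed-form values: isolated
spheres are exact to the lattice (<10⁻⁹ relative); intersecting two-sphere
systems agree with the spherical-cap formula to ≤0.6%; random three-sphere
systems agree with an independent Monte-Carlo estimator to <2%; totals at
960 vs 4000 points differ by <1%.

## Hydrophobic patch

The quantity of interest is the hydrophobic surface the α1′ helix protects.
Primary mode (differential): compute per-residue hydrophobic side-chain
SASA for the full structure and for the structure with the extension
segment deleted; the patch area is the sum of positive per-residue gains
above a noise floor `min_delta` (default 1 Å², below the sampling
resolution at 960 points). A second number, the truncated-total hydrophobic
side-chain SASA over a chosen residue subset, is always recorded because a
reported patch size could be read either way. The differential reading is
primary: a whole-domain truncated total is far larger than any plausible
patch.

Interface residues: hydrophobic residues inside the extension with a
side-chain heavy atom within 4.5 Å (a standard hydrophobic-contact
distance) of a hydrophobic side-chain heavy atom outside it, and the
converse set, both ordered by residue number.

## Amphipathic helix detection

The Eisenberg hydrophobic moment at the ideal α-helical twist
δ = 100°/residue:

    μH = |Σₙ H(aaₙ)·exp(i·n·δ)| / N

with the Eisenberg consensus scale by default; the binary
hydrophobic-set scale ("binary-hydrophobic") is available since the
boundary analysis reasons with a binary hydrophobic set. The window is 18 residues —
five exact turns, so a homogeneous window cancels identically (μH < 10⁻¹⁶),
giving a clean null. Windows with μH ≥ `mu_min` are merged when overlapping
by more than half a window; a merged segment records both its union span
and the span of its single best window (the less biased estimate of where
the helix is).

`mu_min` defaults to 0.5. No amphipathicity threshold exists in the
underlying boundary analysis ("obligate amphipathic" is qualitative), so
the default was calibrated once by Monte-Carlo — iid-uniform random
30-mers, 1000 replicates — to keep the per-sequence false-hit rate under
5% (measured 3.6%); designed amphipathic helices score ~0.64.

Secondary structure from coordinates uses backbone dihedrals: H for
φ ∈ (−100°, −30°), ψ ∈ (−80°, −5°); E for φ ∈ (−170°, −70°),
ψ ∈ (90°, 180°]; labels require runs of ≥4 candidates; chain breaks
(CA–CA > 4.5 Å) and missing backbone atoms force coil. This is a geometric
stand-in for the external secondary-structure predictions used on
sequences without structures; it is not a predictor.

## Alignment analysis and boundary proposal

Alignments are consumed, not computed (recomputing ClustalW/T-Coffee is out
of scope); FASTA, Clustal and Stockholm are read through Biopython, '.'
gaps normalized. Column conservation is the modal-residue frequency among
non-gap entries — the simple statistic matching "absolute conservation"
shading in alignment viewers; columns with gap fraction > 0.5 are flagged
unused. Column-to-residue maps assign the k-th non-gap column of a row to
`first_residue_number + k`.

Boundary proposal per sequence: scan the ungapped residues in
`[uniprot_start − search_span, uniprot_start)` (span default 120 residues,
enough for up to four upstream helices) for amphipathic windows; a window
qualifies when its alignment columns average conservation ≥ `c_min`
(default 0.5); the proposal is the best-window start of the most
N-terminal qualifying segment, never inside the annotated domain. Statuses:
`extended`, `unchanged` (no amphipathic window), `insufficient_signal`
(windows present but unconserved).

Family-level boundary: one protein gets one proposed boundary from an
ortholog alignment, taken as the median extension length
(uniprot_start − proposed_start) over rows with status `extended`. The
median across ~30 orthologs is robust: individual rows fail at realistic
divergence (at 80% helix conservation ~60% of rows recover the planted
start within ±3 residues), while the family-level proposal recovered the
planted start in 50/50 seeded replicates at that level, and per-row
recovery rises monotonically with conservation (~25%/~60%/~93% at
0.6/0.8/1.0).

## Boundary comparison

The packaged 28-member table (UniProt vs MSA-derived vs AlphaFold spans)
is transcribed verbatim from the published comparison; "N/A" marks the
members absent from the AlphaFold database. Derived quantities: per-protein
extension lengths (uniprot start − extended start; negative values are
flagged anomalous, not corrected — HECTD1's MSA start lies inside its
UniProt domain, likely a typo in the source), MSA-vs-AlphaFold start
differences and exact agreements, and the median extension (44 residues —
the "~50 conserved residues" claim).

Residue classification is a three-region model: `extension` for
[extended start, uniprot start), `core` for the UniProt span, `outside`
elsewhere. A handful of published mutation-location labels contradict this
model (positions N-terminal of even the extended start, or labelled
"N-lobe" while numerically upstream of the UniProt start); the fixtures
transcribe the tables verbatim and the discrepancies are pinned in a test
rather than silently reconciled.

## Synthetic data

The generators provide every input class with exact ground truth:

* **Ideal helices** are built by internal-coordinate chain extension at
  φ=−57°, ψ=−47° (standard bond lengths/angles), which realizes the
  canonical geometry (rise ≈ 1.5 Å/residue, twist ≈ 100°, CA radius
  ≈ 2.3 Å) — the `SyntheticHelixSpec` geometry fields describe and
  validate the result rather than parameterize it, because a cylinder-parametric build
  cannot produce correct backbone dihedrals. A single CB pseudo side chain
  per non-Gly residue points radially outward. Auto-designed sequences put
  hydrophobics (L,F,I,L,W,V) at one helical face (wheel offsets
  0,3,7,10,14,17 of an 18-residue period) and charged/polar residues
  opposite — charged residues on the polar face raise the moment exactly as
  in natural amphipathic helices.
* **Helix–slab complexes** pack the hydrophobic face against a two-layer
  slab of single-atom hydrophobic pseudo-residues (default vertical
  clearance 3.6 Å, a close C–C contact). The recorded burial truth is
  computed by an *independent* Monte-Carlo SASA estimator (random sphere
  sampling, brute-force distance prefilter, 2×10⁴ points/atom — <1%
  standard error) run on the full complex and the slab alone; the engine
  and the oracle share no code. Planted interface contacts are recorded by
  brute-force all-pairs distances.
* **Ortholog-style MSAs** plant a conserved amphipathic 18-mer a known
  offset upstream of a conserved "domain" core. Per-position consensus
  retention: `conservation_level` inside the planted helix, 0.9 in the
  core, 0.25 in the linker; gaps and rare insertion columns at
  `indel_rate` (default 0.02) in the linker only; row 0 is an intact query
  whose numbering can be parameterized. Truth records every row's planted
  helix start and core start in its own numbering.
* **Sphere systems** with closed-form areas (spherical-cap formula) for
  radii 1.52/1.70/1.80 Å and separations 2.5/3.0/4.0/10.0 Å.

What the synthetic data does not emulate: real side-chain rotamers and
packing, sequence evolution beyond iid substitution around a conserved
motif, alignment errors from real aligners, and the size/heterogeneity of
real HECT domains. Passing the synthetic recovery tests therefore shows the
machinery is correct and calibrated, not that real ortholog sets will
behave as cleanly.

## Real-structure reproduction

The patch protocol applied to deposited structures (AREL1 6JX5 chain A,
extension 439–482; WWP1 1ND7 chain A, extension 547–587; `pymol-like`
preset) reproduces the reported patch areas (~627 Å² and ~698 Å²) and the
AREL1 interface residues. These checks need the PDB entries: they read a
local cache (`data/pdb/` or `~/.cache/exthect/pdb/`) and fall back to a
download; with neither available they fail with a clear message rather
than pass vacuously. The extension spans are the published extended starts
up to one before the UniProt start; the exact helix extents are otherwise
only shown in the source's figures.

## Problem sizes and numerical choices

Defaults used by the test-suite and the acceptance script: 960 lattice
points (4000 for convergence checks), 2×10⁴ Monte-Carlo points per atom in
the burial oracle, ~340-atom synthetic complexes, 30-row alignments, 50
recovery replicates, 20 replicates per conservation level for the
monotonicity check. These sizes put every Monte-Carlo estimate well inside
the tolerances asserted against it while keeping a full run to a few
minutes. All randomness flows through seeded NumPy generators; every
generator is bit-reproducible for a fixed seed.

## Known limitations

* SASA only — no molecular (Connolly) surface; tools that report molecular
  surface will differ systematically, which is part of why the
  real-structure patch tolerance is generous (±15%).
* No patch contiguity analysis; the patch is a sum over residues, not a
  connected surface component.
* The secondary-structure assigner is a dihedral rule, deliberately
  simple; it under-calls termini of helices (first/last residues lack
  φ or ψ).
* The three-region residue classifier cannot represent mutation positions
  upstream of the extended start; such positions classify `outside`.
* mmCIF input, structure download beyond the thin cache helper, hydrogen
  placement, energetics and phylogenetics are out of scope.
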