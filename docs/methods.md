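# Methods

This note records the models, algorithms and numerical choices behind
`structmap`, the defaults that matter, what the synthetic fixtures do and
do not emulate, and the known limitations.

## Structure model

PDB parsing is delegated to gemmi; the package keeps its own light
hierarchy (models → residues → atoms) keyed by author numbering
`(chain, seq_num, icode)` so figures show deposited residue numbers.
Coordinates are orthogonal Å everywhere; fractional coordinates appear
only inside the symmetry machinery. Records with malformed mandatory
columns are dropped with a warning rather than aborting the parse; a file
with no ATOM records is a hard error.

Altloc handling: the highest-occupancy conformer of each atom is kept for
all geometry; the residue is flagged as alternate-bearing, which drives
the gray-star marker. Hydrogens are retained in the model but excluded
from every distance and surface computation — most X-ray depositions lack
them, and including them only when present would make annotations depend
on deposition style.

Space groups P 1, P 2, P 21, C 2, P 21 21 21 and P 43 21 2 are built in
as symop-triplet tables parsed by the package's own triplet parser; any
other Hermann–Mauguin symbol is resolved through gemmi's reference
tables, and explicit triplet lists can be supplied for arbitrary groups.
Symmetry expansion uses one shell of neighbouring cells (27 total): with
a 5 Å contact cutoff and physically sized cells, images beyond the
adjacent cells cannot contribute.

## Secondary structure

Deposited HELIX/SHEET records are authoritative when present (geometry
then contributes only turns); otherwise assignment is fully geometric, in
the hydrogen-bond-energy style: the amide H is placed 1.01 Å from N
opposite the preceding carbonyl, a bond is
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol,
consecutive 4-turns (and 3-turns) produce helices, parallel/antiparallel
bridge patterns produce strands, and residues covered by isolated n-turns
become turns. Chains shorter than four residues are coil. Only one helix
glyph class is rendered; 3₁₀ and π helices are not distinguished.

## Solvent accessibility

Shrake–Rupley numerical SASA with element van-der-Waals radii, probe
1.4 Å and 960 sphere points per atom by default. The sphere point set is
a fixed golden-spiral lattice, so results are deterministic; coordinates
are first rotated into a canonical principal-axes frame (axis signs fixed
by the third coordinate moment) so per-atom areas are invariant under
rigid motion of the input, not just reproducible. An isolated atom
reproduces the analytic sphere area to well under 1%.

Relative accessibility divides the residue sum by a theoretical
per-residue maximum (Tien-style table; unknown residue types fall back to
the glycine reference with a warning) and is clamped to [0, 1]. Class
cutoffs 0.10 (buried) and 0.40 (intermediate/accessible) are common
practice; the three-class scheme itself is fixed but both cutoffs are
config keys. Het atoms occlude but are excluded from protein residue
sums.

## Hydropathy

Kyte–Doolittle values smoothed with an odd sliding window (default 9),
windows shrinking at the termini. Classes: hydrophobic above +0.5,
hydrophilic below −0.5, neutral between. Scale, window and cutoffs are
configurable; unknown letters score 0 with a warning.

## Contacts and markers

A contact is a minimum heavy-atom distance; altloc duplicates and
hydrogens never contribute. Detection includes distances up to and
including 5.0 Å; the *close* class is strictly below 3.2 Å, by a literal
reading of the distance-class legend. Assembly contacts are computed on
the biological assembly built from REMARK 350 (protein pairs across
chains, protein–ligand pairs anywhere). Crystallographic contacts are
computed from the deposited asymmetric unit against all symmetry images
in the 27-cell shell — crystal packing is a property of the lattice, not
of the assembly. Waters are always dropped; other hetero-compounds
participate only if on the keep list (heme, NAD(P)(H), FAD, nucleotides,
common metals, …), which the user may extend.

Special positions: a residue is flagged when any atom lies within eps
(default 1.0 Å, configurable; inclusive comparison) of its own image
under a non-identity operator.

Markers follow the figure legend vocabulary: crystallographic
protein:protein contact → italic partner-chain letter (red if close,
black if far; we interpret the letter as the partner chain identifier);
crystallographic protein:ligand → italic ligand symbol; assembly
protein:ligand → upright symbol on light-yellow background; assembly
protein:protein → blue frame; both crystallographic and
non-crystallographic contacts → orange background; special position →
italic hash; non-standard residue → X with legend footnote; alternate
conformers → gray star. Each distinct ligand compound takes the next
symbol from the ordered palette (colon, caret, then =, ~, $, %, &, +;
ASCII-safe so the PostScript writer stays 7-bit); past eight compounds
symbols recycle with a numeric suffix in the legend.

## Conservation

The per-column score blends exact identity with physicochemical-group
agreement: score = w_id·f_id + (1 − w_id)·f_grp, w_id = 0.7, groups
[ILVMFWYC][KRH][DE][STNQ][G][P][A], gaps excluded from denominators.
This is a documented stand-in with the right endpoints (1.0 exactly when
a column is identical; monotone under adding query-identical rows) rather
than a published formula. Column boxing uses the same groups: a column is
*identical* when one residue type fills every non-gap row and *similar*
when the best group reaches 70% of non-gap rows (threshold
configurable). Scores enter structures and viewers as 100·score in the
B-factor column, two decimals, sentinel −1.00 for unscored residues.

Homology search and alignment are deliberately out of scope: the MSA is
an input. The query row must match the chain sequence (≤ 5% mismatches;
modified residues compare via their parent one-letter code).

## Superposition and the sausage profile

Kabsch superposition (SVD with determinant correction; never a
reflection) over Cα pairs taken from the sequence alignment — pairing is
sequence-based by design, keeping the pipeline deterministic and
self-contained rather than depending on a structure-alignment engine.
Homologs with fewer than three pairs are skipped with a warning.
Degenerate (collinear) point sets are flagged but still solved. By
default all pairs are used; an optional single trim round refits after
dropping pairs deviating more than 3σ, which is how a localized
displacement is recovered essentially exactly instead of being partially
absorbed into the fit.

The per-residue profile is the root-mean-square of deviations over the
homologs aligned at that residue (an arithmetic mean is available behind
a config switch). Residues aligned in no homolog receive the maximum
observed value — rendered thick and white — and are marked by
`n_pairs = 0` in the TSV. Tube radius is linear and clamped:
r = r_min + (r_max − r_min)·min(d, d_cap)/d_cap with defaults
r_min = 0.3 Å, r_max = 2.0 Å, d_cap = 5 Å.

## Rendering

Layout produces a device-independent primitive list (text runs at fixed
monospace pitch, boxes, strand-arrow polygons, parametric helix
squiggles) in PostScript points, so tests assert on primitives rather
than pixels and vector output is byte-identical across reruns
(timestamps suppressed; PDF metadata stripped). PostScript comes from
the package's own writer — helix squiggles are expanded by a prolog
procedure, keeping documents with hundreds of thousands of glyphs small —
while PDF/PNG/TIFF go through matplotlib. Page sizes: US letter, A4, A3,
A0 and Tapestry (exactly 800 × 3300 mm).

The MSA panel is run-based: maximal column runs of one similarity class
become single box/text primitives, so cost scales with rows × class runs
rather than rows × columns. A 2500 × 4500 alignment with per-row
secondary structure lays out and exports to multi-page Tapestry
PostScript in well under a minute on one CPU, single-threaded; this is
also the problem size the acceptance script exercises. Raster export
writes one file per page (page 1 at the requested path, later pages
suffixed `_pN`).

## Viewer scenes

Scenes are plain-text PyMOL `.pml` scripts plus the coordinate files they
reference, bundled into a zip; no binary session files are generated, so
every artifact is testable text. Conservation coloring is
`spectrum b, white_red, minimum=0, maximum=100` over the score-loaded
B-factor channel — the color ramp is affine in score with exact white and
red endpoints. Sausage radii are set per residue with explicit
`set cartoon_tube_radius` commands, so the script is directly checkable
against the computed radii. Seven preset toggles (surface, assembly, NMR
models, disulfides, ligands + contacting residues, strictly conserved
residues, site markers) are emitted as named selections defined before
any reference. A conservative lint (command allowlist, balanced
delimiters, no references to undefined objects) runs over every generated
script in the tests.

External properties use the same channel convention: a modified PDB whose
B-factor (or occupancy) column carries the value, with a REMARK header
`... <KEYWORD> MIN <v> MAX <v> [CHANNEL ...] [GRANULARITY ...]`.
Values are clamped to [MIN, MAX] with a count of clamped entries, then
normalized to [0, 1]; the property renders as an extra color-bar track in
the sequence panel and as a ramp-colored 3D scene. MIN ≥ MAX or a missing
header is an error.

## Synthetic fixtures

All test inputs are generated from first principles: backbones are built
by internal-coordinate (NeRF) chain extension with ideal bond geometry,
so helices (φ=−57°, ψ=−47°) and strands (φ=−139°, ψ=135°) are exact;
contact fixtures place chains and ligands so the *minimum* heavy-atom
distance equals the requested value (bisection along an outward
direction, exact to 1e-6 Å in memory; PDB text then quantizes
coordinates at 1e-3 Å); crystal fixtures position a small chain inside a
cubic cell of the requested space group; homolog fixtures apply known
per-residue displacements, optional coordinate noise and a random rigid
transform; MSAs mutate a query to a controlled identity level, and the
capacity alignment (2500 × 4500 with a 30% conserved block) is generated
with numpy. Everything is seeded and byte-reproducible.

What the fixtures do not emulate: real side-chain packing (chains are
backbone-only unless specified), ligand geometry beyond single atoms,
insertion codes, chain breaks, real B-factor distributions, and the
statistics of real homolog ensembles. Passing tests therefore demonstrate
correctness of the geometry, scoring and rendering machinery under known
ground truth — not robustness to every pathology of deposited PDB files.

## Other numerical choices

- Distance queries use KD-trees; outer cutoff comparisons are inclusive
  (≤ 5.0 Å), the close-class comparison strict (< 3.2 Å).
- Disulfide pairing is greedy closest-first, each cysteine in at most one
  bridge; the SSBOND union never duplicates a geometric detection.
- Conservation and marker assignment are pure functions of their inputs;
  reruns of the whole pipeline produce byte-identical vector output.
- The acceptance script derives all sub-seeds from `--seed` and keeps
  them below 2³¹.

## Known limitations

mmCIF is not parsed. Only the first biomolecule of REMARK 350 is built.
The geometric secondary-structure assignment is a compact
hydrogen-bond-energy method, not a full DSSP reimplementation (no
π-helix class, no β-bulge handling). Sequence-based Cα pairing cannot
superpose homologs whose alignment is wrong, and no sequence-independent
structural alignment is attempted. The similarity score is the package's
own documented formula, not a reproduction of any server's unpublished
one.
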