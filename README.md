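# structmap

Per-residue structural annotation, conservation mapping and
publication-quality figure generation for protein structures.

Structural biologists routinely need to read a crystal (or NMR, or model)
structure together with an alignment of its homologs and answer, residue by
residue: what is the secondary structure, how buried is it, is it
hydrophobic, does it touch a ligand or a neighbouring chain, is that contact
biological or a crystal-packing artifact, how conserved is it in sequence,
and how much does its position vary across homologous structures?
`structmap` computes all of these from a PDB file (plus an optional MSA and
homolog structures) and renders them as annotated flat figures, a Stockholm
alignment, and interactive PyMOL scenes.

## What it computes

- **Secondary structure** — deposited HELIX/SHEET records when present;
  otherwise a backbone hydrogen-bond-energy assignment (an H-bond is a
  C=O···H–N pair with electrostatic energy
  E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol;
  consecutive 4-turns give helices, bridge ladders give strands, isolated
  n-turns give turns).
- **Solvent accessibility** — Shrake–Rupley numerical SASA (probe 1.4 Å,
  960 deterministic sphere points per atom), classified per residue against
  theoretical maxima: buried < 0.10 ≤ intermediate < 0.40 ≤ accessible.
- **Hydropathy** — Kyte–Doolittle sliding-window mean (window 9), classes
  hydrophobic (> +0.5), neutral, hydrophilic (< −0.5).
- **Contacts** — minimum heavy-atom distances up to and including 5 Å;
  *close* is strictly < 3.2 Å, *far* is 3.2–5 Å. Assembly (biological)
  contacts are found on the REMARK 350 assembly; crystallographic contacts
  by expanding the asymmetric unit through its space-group operators over
  the 27 neighbouring cells. Residues on special positions (own symmetry
  image within 1 Å) and disulfides (SG–SG ≤ 2.5 Å or SSBOND) are flagged.
- **Conservation** — per query column,
  `score = w_id·f_id + (1 − w_id)·f_grp` with `w_id = 0.7`, where `f_id`
  is the fraction of rows carrying the query residue and `f_grp` the
  fraction in its physicochemical group; score 1 ⇔ strictly conserved.
- **Structural deviation** — homologs are superposed on the query by the
  Kabsch algorithm over MSA-paired Cα atoms; the per-residue
  root-mean-square deviation across homologs drives the radius of the
  "Sausage" tube (linear from 0.3 Å to 2.0 Å, capped at 5 Å deviation).

Outputs: a sequence panel (SS glyphs, accessibility/hydropathy bars,
contact-marker rows), an MSA panel (identical columns boxed red, similar
yellow, per-row SS glyphs), Stockholm 1.0 with `#=GR SS` lines, TSV contact
and deviation reports, and two PyMOL scene bundles — **Cartoon** (ribbon
colored white→red by conservation) and **Sausage** (deviation-radius tube,
same coloring). Figures export to PostScript, PDF, PNG and TIFF at US
letter, A4, A3, A0 and Tapestry (0.8 × 3.3 m) page sizes; alignments up to
2500 sequences × 4500 columns render on a single CPU. External per-residue
or per-atom properties can be supplied in a modified PDB (values in the
B-factor or occupancy column, a REMARK header declaring keyword, MIN and
MAX) and are normalized and displayed as an extra color bar and a colored
3D scene.

## Worked example

The package ships a deterministic fixture generator, so a complete run
needs no external data:

```
$ structmap fixtures --seed 1 --out fix
$ structmap run --pdb fix/query.pdb --msa fix/alignment.fasta \
      --homologs fix/homologs --out results --format ps --format pdf
produced:
  [cartoon] results/cartoon/cartoon.pml
  [cartoon] results/cartoon/cartoon.zip
  [contacts] results/contacts.tsv
  [deviation_profile] results/deviation_profile.tsv
  [msa_panel] results/msa_panel.ps
  [msa_panel] results/msa_panel.pdf
  [sausage] results/sausage/sausage.pml
  [sausage] results/sausage/sausage.zip
  [sequence_panel] results/sequence_panel.ps
  [sequence_panel] results/sequence_panel.pdf
  [stockholm] results/alignment.sto
  [superposed] results/superposed/homolog1_on_query.pdb
  [superposed] results/superposed/homolog2_on_query.pdb
skipped:
```

The fixture places a heme iron exactly 3.0 Å from residue 3, which the
contact report recovers as a *close* protein:ligand contact (< 3.2 Å):

```
$ head -3 results/contacts.tsv
chain	seq_num	icode	kind	crystallographic	partner	min_dist	dist_class
A	3		prot_lig	0	LIG:HEM:A:201	3.000	close
A	4		prot_lig	0	LIG:HEM:A:201	3.417	far
```

The fixture homologs carry a known 2 Å displacement at residue 5; the
deviation profile (mean Cα rmsd over the superposed homologs, plus the
resulting tube radius in Å) shows exactly that residue standing out:

```
$ head -8 results/deviation_profile.tsv
index	mean_rmsd	n_pairs	radius
0	0.330	2	0.412
1	0.261	2	0.389
2	0.177	2	0.360
3	0.178	2	0.360
4	1.860	2	0.933
5	0.213	2	0.372
6	0.106	2	0.336
```

(The fixture adds 0.05 Å coordinate noise to every homolog residue, hence
the small baseline and the ~1.9 Å recovered displacement at index 4.)

Stages degrade gracefully: without `--msa` only the sequence panel and
contact report are produced and the MSA panel, Cartoon and Sausage stages
are reported as skipped; a structure without CRYST1 skips the
crystallographic-contact stage the same way.

## Configuration

Every threshold above (SASA probe and point count, accessibility and
hydropathy cutoffs, contact distances, special-position tolerance, ligand
keep-list, conservation weights, sausage radius mapping, palette) lives in
one YAML-overridable config; see `structmap/config.py` and
`docs/methods.md` for the rationale behind each default.
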