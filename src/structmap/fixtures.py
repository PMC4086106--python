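"""Deterministic synthetic fixtures: structures, crystals, MSAs, homologs.

Everything here is generated from first principles (internal-coordinate
chain building, explicit geometric placement) so that tests know the
ground truth exactly.  All randomness flows from an explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import (Atom, Model, Residue, SSERecord, Structure, UnitCell,
                    write_pdb)

# ideal backbone geometry (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.8


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               length: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom D bonded to C, with
    bond angle B-C-D and torsion A-B-C-D given in degrees."""
    ang, tor = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-length * math.cos(ang),
                   length * math.sin(ang) * math.cos(tor),
                   length * math.sin(ang) * math.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_backbone(n: int, phi: float, psi: float, omega: float = 180.0,
                   ) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C/O coordinates for an n-residue chain with uniform
    (phi, psi) dihedrals."""
    res: list[dict[str, np.ndarray]] = []
    N = np.zeros(3)
    CA = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANG_N_CA_C)
    C = CA + np.array([-BOND_CA_C * math.cos(ang), BOND_CA_C * math.sin(ang), 0.0])
    res.append({"N": N, "CA": CA, "C": C})
    for i in range(1, n):
        prev = res[-1]
        N = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANG_CA_C_N, psi)
        CA = place_atom(prev["CA"], prev["C"], N, BOND_N_CA, ANG_C_N_CA, omega)
        C = place_atom(prev["C"], N, CA, BOND_CA_C, ANG_N_CA_C, phi)
        res.append({"N": N, "CA": CA, "C": C})
    # carbonyl O: anti to the next N (trans peptide)
    for i, r in enumerate(res):
        tor = psi + 180.0
        r["O"] = place_atom(r["N"], r["CA"], r["C"], BOND_C_O, ANG_CA_C_O, tor)
    return res


def make_chain(n: int, phi: float = -57.0, psi: float = -47.0,
               chain_id: str = "A", names: Optional[Sequence[str]] = None,
               start_num: int = 1) -> list[Residue]:
    """A poly-residue chain (default ideal alpha-helix dihedrals)."""
    bb = build_backbone(n, phi, psi)
    names = list(names) if names else ["ALA"] * n
    out = []
    for i, coords in enumerate(bb):
        atoms = [Atom(k, "C" if k.startswith("C") else k[0], v)
                 for k, v in coords.items()]
        out.append(Residue(chain_id, start_num + i, "", names[i], False, atoms))
    return out


def make_structure(residues: Sequence[Residue], cell: Optional[UnitCell] = None,
                   **kw) -> Structure:
    return Structure(models=[Model(list(residues))], cell=cell, **kw)


def helix_structure(n: int = 12, **kw) -> Structure:
    """Ideal alpha helix (phi=-57, psi=-47), no deposited SS records."""
    return make_structure(make_chain(n, -57.0, -47.0, **kw))


def extended_structure(n: int = 12, **kw) -> Structure:
    """Fully extended chain (phi=psi=180)."""
    return make_structure(make_chain(n, 180.0, 180.0, **kw))


def single_atom_residue(chain_id: str, num: int, name: str, atom_name: str,
                        element: str, pos, is_het: bool = False) -> Residue:
    return Residue(chain_id, num, "", name, is_het,
                   [Atom(atom_name, element, np.asarray(pos, dtype=float))])


# ---------------------------------------------------------------------------
# PDB-text fixtures


def five_residue_pdb(cryst: bool = True, spacegroup: str = "P 1") -> str:
    st = make_structure(make_chain(5),
                        cell=UnitCell(30, 30, 30, 90, 90, 90, spacegroup)
                        if cryst else None)
    return write_pdb(st)


def nmr_pdb(n_models: int = 3, n_res: int = 5, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    base = make_chain(n_res)
    models = []
    for m in range(n_models):
        residues = []
        for r in base:
            atoms = [Atom(a.name, a.element, a.pos + rng.normal(0, 0.2, 3))
                     for a in r.atoms]
            residues.append(Residue(r.chain_id, r.seq_num, r.icode, r.name,
                                    False, atoms))
        models.append(Model(residues))
    return write_pdb(Structure(models=models))


def biomt_pdb(n_ops: int = 4, n_res: int = 5) -> str:
    """One chain plus REMARK 350 rotations about z producing n_ops copies."""
    st = make_structure(make_chain(n_res))
    body = write_pdb(st)
    lines = ["REMARK 350 BIOMOLECULE: 1",
             "REMARK 350 APPLY THE FOLLOWING TO CHAINS: A"]
    for k in range(n_ops):
        ang = 2 * math.pi * k / n_ops
        rot = np.array([[math.cos(ang), -math.sin(ang), 0],
                        [math.sin(ang), math.cos(ang), 0],
                        [0, 0, 1]])
        vec = np.zeros(3) if k == 0 else np.array([0.0, 0.0, 20.0 * k])
        for row in range(3):
            lines.append(
                f"REMARK 350   BIOMT{row+1:1d} {k+1:3d}"
                f"{rot[row,0]:10.6f}{rot[row,1]:10.6f}{rot[row,2]:10.6f}"
                f"{vec[row]:15.5f}")
    return "\n".join(lines) + "\n" + body


def cys_pair_structure(distance: float = 2.03, ssbond: bool = False) -> Structure:
    """Two Cys residues with SG atoms at an exact separation."""
    r1 = Residue("A", 1, "", "CYS", False, [
        Atom("CA", "C", np.array([0.0, 0.0, 0.0])),
        Atom("SG", "S", np.array([1.8, 0.0, 0.0]))])
    r2 = Residue("A", 4, "", "CYS", False, [
        Atom("CA", "C", np.array([1.8 + distance + 1.8, 0.0, 0.0])),
        Atom("SG", "S", np.array([1.8 + distance, 0.0, 0.0]))])
    kw = {}
    if ssbond:
        kw["ssbond_records"] = [(("A", 1, ""), ("A", 4, ""))]
    return make_structure([r1, r2], **kw)


def two_chain_contact_structure(distance: float = 4.2,
                                ligand_distance: Optional[float] = None,
                                ligand_name: str = "HEM") -> Structure:
    """Two short chains whose closest heavy-atom pair sits at ``distance``;
    optionally a ligand atom at ``ligand_distance`` from residue A3."""
    a = make_chain(3, chain_id="A")
    b = make_chain(3, chain_id="B")
    # shift chain B along +x so the closest pair is exactly `distance`
    coords_a = np.array([at.pos for r in a for at in r.atoms])
    coords_b = np.array([at.pos for r in b for at in r.atoms])
    xmax = coords_a[:, 0].max()
    # chain B closest atom is its min-x atom; align along x only
    i_b = np.argmin(coords_b[:, 0])
    i_a = np.argmax(coords_a[:, 0])
    target = coords_a[i_a] + np.array([distance, 0.0, 0.0])
    shift = target - coords_b[i_b]
    for r in b:
        for at in r.atoms:
            at.pos = at.pos + shift
    residues = a + b
    if ligand_distance is not None:
        ref = a[2].atom("CA").pos
        lig = single_atom_residue("A", 201, ligand_name, "FE", "FE",
                                  ref + np.array([0.0, ligand_distance, 0.0]),
                                  is_het=True)
        residues = residues + [lig]
    st = make_structure(residues)
    st.het_names = {ligand_name} if ligand_distance is not None else set()
    return st


def crystal_structure(spacegroup: str = "P 1", cell_len: float = 20.0,
                      n_res: int = 3, offset: Sequence[float] = (4.0, 6.0, 5.0),
                      ) -> Structure:
    """A small chain placed inside a cubic cell for crystal-contact tests."""
    residues = make_chain(n_res)
    off = np.asarray(offset, dtype=float)
    for r in residues:
        for a in r.atoms:
            a.pos = a.pos + off
    return make_structure(
        residues, cell=UnitCell(cell_len, cell_len, cell_len, 90, 90, 90,
                                spacegroup))


def special_position_structure(eps_offset: float = 0.0) -> Structure:
    """P 2 crystal with one atom on (or ``eps_offset`` Å off) the 2-fold
    axis at x=z=0."""
    cell = UnitCell(20, 20, 20, 90, 90, 90, "P 2")
    on_axis = single_atom_residue("A", 1, "GLY", "CA", "C",
                                  [eps_offset, 5.0, 0.0])
    general = single_atom_residue("A", 2, "GLY", "CA", "C", [6.0, 5.0, 7.0])
    return make_structure([on_axis, general], cell=cell)


# ---------------------------------------------------------------------------
# MSAs

AA = "ACDEFGHIKLMNPQRSTVWY"

GROUP_OF = {}
for grp in ("ILVMFWYC", "KRH", "DE", "STNQ", "G", "P", "A"):
    for ch in grp:
        GROUP_OF[ch] = grp


def mutate_sequence(seq: str, identity: float, rng,
                    conservative: bool = False) -> str:
    """Mutate a fraction (1 - identity) of positions; ``conservative``
    draws replacements from the same physicochemical group."""
    n = len(seq)
    k = round(n * (1 - identity))
    idx = rng.choice(n, size=k, replace=False)
    out = list(seq)
    for i in idx:
        cur = out[i]
        if conservative:
            pool = [c for c in GROUP_OF.get(cur, AA) if c != cur] or list(AA)
        else:
            pool = [c for c in AA if c != cur]
        out[i] = pool[rng.integers(len(pool))]
    return "".join(out)


def random_sequence(n: int, rng) -> str:
    return "".join(AA[i] for i in rng.integers(len(AA), size=n))


def generate_msa(query: str, n_homologs: int = 5, identity: float = 0.6,
                 seed: int = 0, names: Optional[list[str]] = None,
                 conservative: bool = False):
    """Gapless MSA of the query plus mutated homologs at a controlled
    identity level.  Returns (names, rows, query_index)."""
    rng = np.random.default_rng(seed)
    rows = [query]
    for _ in range(n_homologs):
        rows.append(mutate_sequence(query, identity, rng, conservative))
    nm = names or ["query"] + [f"homolog{i+1}" for i in range(n_homologs)]
    return nm, rows, 0


def generate_capacity_msa(n_rows: int, n_cols: int, seed: int = 0,
                          conserved_fraction: float = 0.3):
    """Large synthetic MSA with contiguous conserved stretches (efficient
    numpy generation; used for the capacity exercise)."""
    rng = np.random.default_rng(seed)
    letters = np.frombuffer(AA.encode(), dtype=np.uint8)
    query = letters[rng.integers(len(letters), size=n_cols)]
    mat = np.tile(query, (n_rows, 1))
    # mutate the non-conserved span uniformly
    n_cons = int(n_cols * conserved_fraction)
    var = slice(n_cons, n_cols)
    nvar = n_cols - n_cons
    mut = letters[rng.integers(len(letters), size=(n_rows - 1, nvar))]
    mask = rng.random((n_rows - 1, nvar)) < 0.7
    block = mat[1:, var]
    block[mask] = mut[mask]
    mat[1:, var] = block
    rows = [bytes(r).decode() for r in mat]
    names = ["query"] + [f"seq{i:04d}" for i in range(1, n_rows)]
    return names, rows, 0


# ---------------------------------------------------------------------------
# homolog structures


def random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def perturb_homolog(structure: Structure, displacements: dict[int, float]
                    | None = None, noise: float = 0.0, seed: int = 0,
                    rigid: bool = True) -> Structure:
    """Copy of a structure with optional per-residue CA displacement
    (Å, by 1-based position in the chain), coordinate noise, and a random
    rigid transform; ground truth for superposition tests."""
    rng = np.random.default_rng(seed)
    out = structure.copy()
    residues = out.model.residues
    for i, r in enumerate(residues, start=1):
        d = (displacements or {}).get(i, 0.0)
        if d:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            for a in r.atoms:
                a.pos = a.pos + direction * d
        if noise:
            for a in r.atoms:
                a.pos = a.pos + rng.normal(0, noise, 3)
    if rigid:
        R = random_rotation(rng)
        t = rng.uniform(-20, 20, 3)
        for r in residues:
            for a in r.atoms:
                a.pos = R @ a.pos + t
    return out


# ---------------------------------------------------------------------------
# file-set generation (CLI `structmap fixtures`)


@dataclass
class FixtureSpec:
    n_res: int = 20
    spacegroup: str = "P 21 21 21"
    cell_len: float = 40.0
    ligand_distance: float = 3.0
    n_homolog_seqs: int = 5
    n_homolog_structs: int = 2
    msa_identity: float = 0.6
    displaced_residue: int = 5
    displacement: float = 2.0


def generate_fixtures(seed: int, spec: FixtureSpec | dict | None = None,
                      out_dir: str | Path = ".") -> dict[str, Path]:
    """Write a deterministic, self-consistent fixture file set: a query
    PDB (crystal cell, ligand at a set distance, SS records), an MSA
    containing the query, and perturbed homolog structures with a known
    displacement."""
    if spec is None:
        spec = FixtureSpec()
    elif isinstance(spec, dict):
        spec = FixtureSpec(**spec)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    names3 = {v: k for k, v in
              {"ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
               "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
               "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
               "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y",
               "VAL": "V"}.items()}
    seq = random_sequence(spec.n_res, rng)
    chain = make_chain(spec.n_res, names=[names3[c] for c in seq])
    off = np.array([spec.cell_len / 3] * 3)
    for r in chain:
        for a in r.atoms:
            a.pos = a.pos + off
    ref = chain[min(6, spec.n_res - 1)].atom("CA").pos
    prot_coords = np.array([a.pos for r in chain for a in r.atoms])
    lig_pos = _place_at_min_distance(prot_coords, ref,
                                     spec.ligand_distance)
    lig = single_atom_residue("A", 201, "HEM", "FE", "FE", lig_pos,
                              is_het=True)
    query = make_structure(
        list(chain) + [lig],
        cell=UnitCell(spec.cell_len, spec.cell_len, spec.cell_len,
                      90, 90, 90, spec.spacegroup),
        helix_sheet_records=[SSERecord("helix", "A", (1, ""),
                                       (spec.n_res, ""))],
        het_names={"HEM"})

    files: dict[str, Path] = {}
    qpath = out_dir / "query.pdb"
    qpath.write_text(_pdb_with_records(query))
    files["query"] = qpath

    nm, rows, _ = generate_msa(seq, spec.n_homolog_seqs, spec.msa_identity,
                               seed=int(rng.integers(2**31)))
    msa_path = out_dir / "alignment.fasta"
    msa_path.write_text("".join(f">{n}\n{r}\n" for n, r in zip(nm, rows)))
    files["msa"] = msa_path

    hom_dir = out_dir / "homologs"
    hom_dir.mkdir(exist_ok=True)
    for i in range(spec.n_homolog_structs):
        hom = perturb_homolog(
            query, {spec.displaced_residue: spec.displacement},
            noise=0.05, seed=int(rng.integers(2**31)))
        p = hom_dir / f"homolog{i+1}.pdb"
        p.write_text(write_pdb(hom))
        files[f"homolog{i+1}"] = p
    files["homolog_dir"] = hom_dir
    return files


def _place_at_min_distance(coords: np.ndarray, ref: np.ndarray,
                           target: float) -> np.ndarray:
    """A point whose minimum distance to ``coords`` is exactly ``target``,
    found along the outward direction from the coordinate centroid through
    ``ref`` (bisection on the monotone min-distance function)."""
    direction = ref - coords.mean(axis=0)
    direction = direction / np.linalg.norm(direction)

    def min_dist(t: float) -> float:
        p = ref + direction * t
        return float(np.linalg.norm(coords - p, axis=1).min())

    lo, hi = 0.0, target + 1.0
    while min_dist(hi) < target:
        hi *= 2
    for _ in range(80):
        mid = (lo + hi) / 2
        if min_dist(mid) < target:
            lo = mid
        else:
            hi = mid
    return ref + direction * hi


def _pdb_with_records(st: Structure) -> str:
    """write_pdb plus HELIX/SSBOND header records for deposited metadata."""
    header = []
    for i, rec in enumerate(st.helix_sheet_records, 1):
        if rec.kind == "helix":
            header.append(
                f"HELIX  {i:3d} {i:3d} ALA {rec.chain_id}{rec.start[0]:5d} "
                f"ALA {rec.chain_id}{rec.end[0]:5d}  1"
                f"{rec.end[0]-rec.start[0]+1:36d}")
    for i, (k1, k2) in enumerate(st.ssbond_records, 1):
        header.append(
            f"SSBOND {i:3d} CYS {k1[0]}{k1[1]:5d}    CYS {k2[0]}{k2[1]:5d}")
    return "\n".join(header) + ("\n" if header else "") + write_pdb(st)
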