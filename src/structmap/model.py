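"""Structure model: PDB parsing, unit cell, space-group symmetry, assemblies.

Coordinates are orthogonal Ångström throughout; fractional coordinates are
used only inside the symmetry machinery.  Residues are keyed by their
author numbering ``(chain_id, seq_num, icode)`` exactly as deposited.
"""

from __future__ import annotations

import copy
import logging
import string
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Optional

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: residue key = (chain_id, author seq number, insertion code)
ResidueKey = tuple[str, int, str]

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

#: modified residues mapped to their parent one-letter code (figures show X)
MODIFIED_TO_ONE = {
    "MSE": "M", "MSO": "M", "MHO": "M", "SME": "M",
    "CSO": "C", "CSD": "C", "OCS": "C", "CME": "C",
    "SEP": "S", "TPO": "T", "PTR": "Y", "KCX": "K", "MLY": "K",
    "HYP": "P", "PCA": "Q", "FME": "M",
}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class StructureError(ValueError):
    """Raised for unusable coordinate input (e.g. no ATOM records)."""


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray            # shape (3,), orthogonal Å
    occupancy: float = 1.0
    bfactor: float = 0.0
    altloc: str = ""

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    name: str
    is_het: bool
    atoms: list[Atom] = field(default_factory=list)
    has_altloc: bool = False

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    @property
    def one_letter(self) -> str:
        if self.name in THREE_TO_ONE:
            return THREE_TO_ONE[self.name]
        return MODIFIED_TO_ONE.get(self.name, "X")

    @property
    def is_nonstandard(self) -> bool:
        return self.name not in STANDARD_AA

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    spacegroup: str = "P 1"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise StructureError("unit cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise StructureError("unit cell angles must lie in (0, 180)")

    @property
    def orth_matrix(self) -> np.ndarray:
        """Fractional -> orthogonal Å (standard PDB convention)."""
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        cosal, cosbe, cosga = np.cos([al, be, ga])
        singa = np.sin(ga)
        v = np.sqrt(1 - cosal**2 - cosbe**2 - cosga**2 + 2 * cosal * cosbe * cosga)
        return np.array([
            [self.a, self.b * cosga, self.c * cosbe],
            [0.0, self.b * singa, self.c * (cosal - cosbe * cosga) / singa],
            [0.0, 0.0, self.c * v / singa],
        ])

    @property
    def frac_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orth_matrix)

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.frac_matrix.T

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return frac @ self.orth_matrix.T


@dataclass(frozen=True)
class SymmetryOp:
    """Symmetry operator in the fractional basis: x' = rot @ x + trans."""
    rot: tuple[tuple[Fraction, ...], ...]
    trans: tuple[Fraction, ...]

    @property
    def rot_array(self) -> np.ndarray:
        return np.array(self.rot, dtype=float)

    @property
    def trans_array(self) -> np.ndarray:
        return np.array(self.trans, dtype=float)

    @property
    def is_identity(self) -> bool:
        return (self.rot_array == np.eye(3)).all() and (self.trans_array == 0).all()

    def triplet(self) -> str:
        axes = "xyz"
        parts = []
        for i in range(3):
            term = ""
            for j in range(3):
                c = self.rot[i][j]
                if c == 0:
                    continue
                sign = "-" if c < 0 else ("+" if term else "")
                mag = abs(c)
                coef = "" if mag == 1 else f"{mag}*"
                term += f"{sign}{coef}{axes[j]}"
            t = self.trans[i] % 1
            if t != 0:
                term += f"+{t}"
            parts.append(term or "0")
        return ",".join(parts)

    def compose(self, other: "SymmetryOp") -> "SymmetryOp":
        """self ∘ other, translation reduced mod 1."""
        r1, r2 = np.array(self.rot, object), np.array(other.rot, object)
        t1, t2 = np.array(self.trans, object), np.array(other.trans, object)
        rot = r1 @ r2
        trans = r1 @ t2 + t1
        return SymmetryOp(
            tuple(tuple(Fraction(x) for x in row) for row in rot),
            tuple(Fraction(x) % 1 for x in trans),
        )


IDENTITY_OP = SymmetryOp(
    tuple(tuple(Fraction(int(i == j)) for j in range(3)) for i in range(3)),
    (Fraction(0), Fraction(0), Fraction(0)),
)


@dataclass
class Model:
    """One coordinate model (X-ray structures have one, NMR several)."""
    residues: list[Residue] = field(default_factory=list)

    @property
    def chains(self) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for r in self.residues:
            out.setdefault(r.chain_id, []).append(r)
        return out

    def protein_residues(self, chain_id: Optional[str] = None) -> list[Residue]:
        return [r for r in self.residues
                if not r.is_het and (chain_id is None or r.chain_id == chain_id)]

    def ligand_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_het and not r.is_water]

    def find(self, key: ResidueKey) -> Optional[Residue]:
        for r in self.residues:
            if r.key == key:
                return r
        return None


@dataclass
class SSERecord:
    """A deposited HELIX or SHEET record."""
    kind: str                   # "helix" | "strand"
    chain_id: str
    start: tuple[int, str]      # (seq_num, icode)
    end: tuple[int, str]


@dataclass
class Structure:
    models: list[Model]
    cell: Optional[UnitCell] = None
    assembly_transforms: list[np.ndarray] = field(default_factory=list)
    ssbond_records: list[tuple[ResidueKey, ResidueKey]] = field(default_factory=list)
    helix_sheet_records: list[SSERecord] = field(default_factory=list)
    het_names: set[str] = field(default_factory=set)
    name: str = "structure"

    def __post_init__(self) -> None:
        if not self.assembly_transforms:
            self.assembly_transforms = [np.eye(4)]

    @property
    def model(self) -> Model:
        """The first (representative) model."""
        return self.models[0]

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.model.protein_residues(chain_id))

    def copy(self) -> "Structure":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# parsing


def _prefilter_pdb_text(text: str) -> str:
    """Drop ATOM/HETATM records whose mandatory columns are malformed."""
    kept = []
    for line in text.splitlines():
        if line[:6] in ("ATOM  ", "HETATM"):
            ok = len(line) >= 54
            if ok:
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                    int(line[22:26])
                except ValueError:
                    ok = False
            if not ok:
                logger.warning("skipping malformed coordinate record: %r", line[:30])
                continue
        kept.append(line)
    return "\n".join(kept) + "\n"


def _convert_residue(chain_name: str, res: gemmi.Residue) -> Residue:
    """Collapse altlocs to the highest-occupancy conformer per atom name."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in res:
        by_name.setdefault(a.name, []).append(a)
    has_altloc = any(len(v) > 1 or (v[0].altloc not in ("", "\x00")) for v in by_name.values())
    atoms = []
    for name, alts in by_name.items():
        best = max(alts, key=lambda a: a.occ)
        altloc = best.altloc if best.altloc != "\x00" else ""
        atoms.append(Atom(
            name=name,
            element=best.element.name,
            pos=np.array([best.pos.x, best.pos.y, best.pos.z]),
            occupancy=best.occ,
            bfactor=best.b_iso,
            altloc=altloc,
        ))
    return Residue(
        chain_id=chain_name,
        seq_num=res.seqid.num,
        icode=res.seqid.icode.strip(),
        name=res.name,
        is_het=(res.het_flag == "H"),
        atoms=atoms,
        has_altloc=has_altloc,
    )


def parse_pdb(source, name: str = "structure") -> Structure:
    """Parse a PDB-format text stream, path or string into a :class:`Structure`.

    A valid CRYST1 record yields ``cell``; MODEL/ENDMDL blocks become
    separate models; SSBOND, HELIX/SHEET and REMARK 350 (BIOMT) records are
    captured for the annotation, contact and assembly stages.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text and len(text) < 4096:
            with open(text) as fh:
                text = fh.read()
    st = gemmi.read_pdb_string(_prefilter_pdb_text(text))

    models = []
    for gm in st:
        residues = []
        for ch in gm:
            for res in ch:
                residues.append(_convert_residue(ch.name, res))
        if residues:
            models.append(Model(residues))
    if not models or not any(not r.is_het for m in models for r in m.residues):
        raise StructureError("empty structure: no ATOM records")

    cell = None
    has_cryst1 = any(ln.startswith("CRYST1") for ln in text.splitlines())
    if has_cryst1 and st.cell.a > 0 and st.cell.is_crystal():
        try:
            cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                            st.cell.alpha, st.cell.beta, st.cell.gamma,
                            st.spacegroup_hm or "P 1")
        except StructureError:
            logger.warning("invalid CRYST1 record ignored")

    transforms = []
    for asm in st.assemblies:
        for gen in asm.generators:
            for oper in gen.operators:
                t = np.eye(4)
                t[:3, :3] = np.array(oper.transform.mat.tolist())
                t[:3, 3] = np.array(oper.transform.vec.tolist())
                transforms.append(t)
        break  # first biomolecule only

    ssbonds = []
    for con in st.connections:
        if con.type != gemmi.ConnectionType.Disulf:
            continue
        p1, p2 = con.partner1, con.partner2
        ssbonds.append((
            (p1.chain_name, p1.res_id.seqid.num, p1.res_id.seqid.icode.strip()),
            (p2.chain_name, p2.res_id.seqid.num, p2.res_id.seqid.icode.strip()),
        ))

    sse_records = []
    for h in st.helices:
        sse_records.append(SSERecord(
            "helix", h.start.chain_name,
            (h.start.res_id.seqid.num, h.start.res_id.seqid.icode.strip()),
            (h.end.res_id.seqid.num, h.end.res_id.seqid.icode.strip())))
    for sheet in st.sheets:
        for strand in sheet.strands:
            sse_records.append(SSERecord(
                "strand", strand.start.chain_name,
                (strand.start.res_id.seqid.num, strand.start.res_id.seqid.icode.strip()),
                (strand.end.res_id.seqid.num, strand.end.res_id.seqid.icode.strip())))

    het_names = {r.name for m in models for r in m.residues if r.is_het}

    return Structure(models=models, cell=cell, assembly_transforms=transforms,
                     ssbond_records=ssbonds, helix_sheet_records=sse_records,
                     het_names=het_names, name=name)


# ---------------------------------------------------------------------------
# writing


def write_pdb(structure: Structure, stream=None) -> str:
    """Serialize to PDB text (B-factor column fixed two decimals).

    The B-factor column may carry a repurposed per-residue property
    (conservation score, external data); the sentinel -1.00 marks unscored
    residues.
    """
    lines = []
    if structure.cell is not None:
        c = structure.cell
        lines.append(
            f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
            f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} {c.spacegroup:<11s}"
        )
    multi = len(structure.models) > 1
    serial = 0
    for imodel, model in enumerate(structure.models, start=1):
        if multi:
            lines.append(f"MODEL     {imodel:4d}")
        for res in model.residues:
            rec = "HETATM" if res.is_het else "ATOM  "
            for a in res.atoms:
                serial += 1
                nm = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                lines.append(
                    f"{rec}{serial % 100000:5d} {nm:<4s}{a.altloc or ' ':1s}"
                    f"{res.name:>3s} {res.chain_id:1s}{res.seq_num:4d}"
                    f"{res.icode or ' ':1s}   "
                    f"{a.pos[0]:8.3f}{a.pos[1]:8.3f}{a.pos[2]:8.3f}"
                    f"{a.occupancy:6.2f}{a.bfactor:6.2f}          "
                    f"{a.element:>2s}"
                )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# space-group symmetry

#: built-in operator tables (symop triplets) for the supported groups
BUILTIN_SPACEGROUPS: dict[str, list[str]] = {
    "P 1": ["x,y,z"],
    "P 2": ["x,y,z", "-x,y,-z"],
    "P 21": ["x,y,z", "-x,y+1/2,-z"],
    "C 2": ["x,y,z", "-x,y,-z", "x+1/2,y+1/2,z", "-x+1/2,y+1/2,-z"],
    "P 21 21 21": ["x,y,z", "-x+1/2,-y,z+1/2", "x+1/2,-y+1/2,-z", "-x,y+1/2,-z+1/2"],
    "P 43 21 2": [
        "x,y,z", "-x,-y,z+1/2", "-y+1/2,x+1/2,z+3/4", "y+1/2,-x+1/2,z+1/4",
        "-x+1/2,y+1/2,-z+3/4", "x+1/2,-y+1/2,-z+1/4", "y,x,-z", "-y,-x,-z+1/2",
    ],
}


def parse_triplet(triplet: str) -> SymmetryOp:
    """Parse one symop triplet string such as ``-x,y+1/2,-z``."""
    rows, trans = [], []
    parts = triplet.lower().replace(" ", "").split(",")
    if len(parts) != 3:
        raise ValueError(f"bad symop triplet {triplet!r}")
    for part in parts:
        row = [Fraction(0)] * 3
        t = Fraction(0)
        # tokenize into signed terms
        for term in _split_terms(part):
            sign = Fraction(1)
            body = term
            if body[0] in "+-":
                sign = Fraction(-1) if body[0] == "-" else Fraction(1)
                body = body[1:]
            if body and body[-1] in "xyz":
                axis = "xyz".index(body[-1])
                coef = body[:-1].rstrip("*")
                row[axis] += sign * (Fraction(coef) if coef else Fraction(1))
            else:
                t += sign * Fraction(body)
        rows.append(tuple(row))
        trans.append(t % 1)
    return SymmetryOp(tuple(rows), tuple(trans))


def _split_terms(expr: str) -> list[str]:
    terms, cur = [], ""
    for ch in expr:
        if ch in "+-" and cur and cur[-1] != "/":
            terms.append(cur)
            cur = ch
        else:
            cur += ch
    if cur:
        terms.append(cur)
    return terms


def symmetry_ops(spacegroup: str,
                 extra_triplets: Optional[Iterable[str]] = None) -> list[SymmetryOp]:
    """Return the symmetry operators of a space group, identity first.

    Built-in groups are resolved from our own triplet tables; other
    Hermann–Mauguin symbols fall back to gemmi's reference tables; a caller
    may also supply explicit symop triplet strings (``extra_triplets``)
    for an arbitrary user-provided group.
    """
    if extra_triplets is not None:
        ops = [parse_triplet(t) for t in extra_triplets]
    elif spacegroup in BUILTIN_SPACEGROUPS:
        ops = [parse_triplet(t) for t in BUILTIN_SPACEGROUPS[spacegroup]]
    else:
        sg = gemmi.find_spacegroup_by_name(spacegroup)
        if sg is None:
            raise ValueError(
                f"unknown space group {spacegroup!r}; built-in groups: "
                + ", ".join(sorted(BUILTIN_SPACEGROUPS))
                + "; other Hermann-Mauguin symbols or explicit symop triplets accepted")
        ops = [parse_triplet(op.triplet()) for op in sg.operations()]
    identity = [o for o in ops if o.is_identity]
    if not identity:
        ops.insert(0, IDENTITY_OP)
    else:
        ops = identity[:1] + [o for o in ops if not o.is_identity]
    return ops


@dataclass
class SymmetryImage:
    """One symmetry-related copy of the asymmetric unit."""
    op: SymmetryOp
    shift: tuple[int, int, int]       # lattice translation in cell units
    coords: np.ndarray                # (n_atoms, 3) orthogonal Å


def expand_symmetry(structure: Structure, shell: int = 1,
                    coords: Optional[np.ndarray] = None,
                    ) -> Optional[list[SymmetryImage]]:
    """Generate all symmetry images of the asymmetric unit within ``shell``
    unit-cell layers (shell 1 → the 27 surrounding cells), excluding the
    identity-with-zero-shift copy.

    Returns ``None`` ("not applicable") when the structure has no cell, so
    the crystallographic stages can degrade gracefully.
    """
    if structure.cell is None:
        return None
    if shell < 1:
        raise ValueError("shell must be >= 1")
    cell = structure.cell
    if coords is None:
        coords = np.array([a.pos for r in structure.model.residues
                           for a in r.heavy_atoms()])
    frac = cell.fractionalize(coords)
    ops = symmetry_ops(cell.spacegroup)
    rng = range(-shell, shell + 1)
    images = []
    for op in ops:
        base = frac @ op.rot_array.T + op.trans_array
        for i in rng:
            for j in rng:
                for k in rng:
                    if op.is_identity and i == j == k == 0:
                        continue
                    shifted = base + np.array([i, j, k], dtype=float)
                    images.append(SymmetryImage(
                        op, (i, j, k), cell.orthogonalize(shifted)))
    return images


# ---------------------------------------------------------------------------
# biological assembly


def build_assembly(structure: Structure) -> Structure:
    """Apply the REMARK 350 BIOMT transforms to produce the biological
    assembly.  Generated copies receive fresh chain identifiers; with no
    REMARK 350 the assembly equals the deposited coordinates."""
    out = structure.copy()
    transforms = structure.assembly_transforms
    model = structure.models[0]
    used = set(model.chains)
    pool = (c for c in string.ascii_uppercase + string.ascii_lowercase
            + string.digits if c not in used)
    new_residues: list[Residue] = []
    for it, t in enumerate(transforms):
        if abs(np.linalg.det(t[:3, :3])) < 1e-12:
            logger.warning("non-invertible BIOMT matrix %d skipped", it + 1)
            continue
        is_ident = np.allclose(t, np.eye(4), atol=1e-9)
        remap: dict[str, str] = {}
        for res in model.residues:
            r = copy.deepcopy(res)
            if not is_ident:
                if res.chain_id not in remap:
                    remap[res.chain_id] = next(pool, res.chain_id)
                r.chain_id = remap[res.chain_id]
                for a in r.atoms:
                    a.pos = t[:3, :3] @ a.pos + t[:3, 3]
            new_residues.append(r)
    out.models = [Model(new_residues)]
    out.assembly_transforms = [np.eye(4)]
    return out
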