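"""Per-residue annotation: secondary structure, solvent accessibility,
hydropathy and disulfide bridges.

Secondary structure comes from deposited HELIX/SHEET records when present
(turns are always geometric); otherwise a backbone hydrogen-bond-energy
assignment in the Kabsch–Sander style is computed from coordinates.
Accessibility is Shrake–Rupley numerical SASA classified against
theoretical per-residue maxima; hydropathy is a Kyte–Doolittle sliding
window.  Hydrogens are ignored in every distance and surface computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .model import Residue, ResidueKey, Structure

logger = logging.getLogger(__name__)

# Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

# theoretical maximum SASA per residue type (Ų), Tien et al. style table
MAX_ACC = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

# van der Waals radii (Å) by element; unknown elements fall back to default
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "FE": 2.00, "ZN": 1.39, "MG": 1.73, "CA": 2.00, "MN": 2.00,
    "NA": 2.27, "K": 2.75, "CU": 1.40, "NI": 1.63, "CO": 2.00,
}
DEFAULT_VDW = 1.80


@dataclass
class SSE:
    kind: str                   # helix | strand | turn
    chain_id: str
    start: tuple[int, str]      # (seq_num, icode)
    end: tuple[int, str]


@dataclass
class ResidueAnnotation:
    key: ResidueKey
    ss: str = "coil"            # H | E | T | coil
    sasa: float = 0.0
    rel_acc: float = 0.0
    acc_class: str = "buried"
    hyd: float = 0.0
    hyd_class: str = "neutral"
    is_nonstandard: bool = False
    has_altloc: bool = False
    in_ssbond: bool = False


# ---------------------------------------------------------------------------
# secondary structure


def _backbone(residues: Sequence[Residue]):
    """Extract N, CA, C, O coordinate arrays; NaN rows where atoms miss."""
    n = len(residues)
    out = {k: np.full((n, 3), np.nan) for k in ("N", "CA", "C", "O")}
    for i, r in enumerate(residues):
        for k in out:
            a = r.atom(k)
            if a is not None:
                out[k][i] = a.pos
    return out


def _hbond_matrix(bb, energy_cutoff: float) -> np.ndarray:
    """hb[i, j] True when the amide H of residue i donates to C=O of j.

    Electrostatic model: the amide H sits 1.01 Å from N opposite the
    previous carbonyl; E = 0.084*332*(1/rON + 1/rCH - 1/rOH - 1/rCN)
    kcal/mol and a bond is E below the cutoff.
    """
    N, CA, C, O = bb["N"], bb["CA"], bb["C"], bb["O"]
    n = len(N)
    H = np.full((n, 3), np.nan)
    for i in range(1, n):
        co = C[i - 1] - O[i - 1]
        norm = np.linalg.norm(co)
        if norm > 0 and np.isfinite(norm):
            H[i] = N[i] + co / norm * 1.01
    hb = np.zeros((n, n), dtype=bool)
    q = 0.084 * 332.0
    for i in range(1, n):
        if not np.isfinite(H[i]).all():
            continue
        for j in range(n):
            if abs(i - j) < 2:
                continue
            if not (np.isfinite(O[j]).all() and np.isfinite(C[j]).all()):
                continue
            r_on = np.linalg.norm(N[i] - O[j])
            r_ch = np.linalg.norm(H[i] - C[j])
            r_oh = np.linalg.norm(H[i] - O[j])
            r_cn = np.linalg.norm(N[i] - C[j])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue
            e = q * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if e < energy_cutoff:
                hb[i, j] = True
    return hb


def _geometric_states(residues: Sequence[Residue],
                      energy_cutoff: float = -0.5) -> list[str]:
    """Per-residue H/E/T/coil states from backbone hydrogen bonding."""
    n = len(residues)
    if n < 4:
        return ["coil"] * n
    bb = _backbone(residues)
    hb = _hbond_matrix(bb, energy_cutoff)

    # n-turns: hbond from NH(i+k) to CO(i)
    turns = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
    for k in turns:
        for i in range(n - k):
            if hb[i + k, i]:
                turns[k][i] = True

    states = ["coil"] * n
    # alpha helix: consecutive 4-turns at i-1 and i -> residues i..i+3
    for i in range(1, n - 4):
        if turns[4][i - 1] and turns[4][i]:
            for j in range(i, i + 4):
                states[j] = "H"
    # 3-10 style: consecutive 3-turns, rendered with the same helix glyph
    for i in range(1, n - 3):
        if turns[3][i - 1] and turns[3][i]:
            for j in range(i, i + 3):
                if states[j] == "coil":
                    states[j] = "H"

    # bridges -> strand
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[j, i - 1] and hb[i + 1, j]) or (hb[i, j - 1] and hb[j + 1, i])
            anti = (hb[i, j] and hb[j, i]) or (hb[j + 1, i - 1] and hb[i + 1, j - 1])
            if para or anti:
                for k in (i, j):
                    if states[k] == "coil":
                        states[k] = "E"

    # isolated n-turns -> turn
    for k, arr in turns.items():
        for i in np.where(arr)[0]:
            for j in range(i + 1, min(i + k, n)):
                if states[j] == "coil":
                    states[j] = "T"
    return states


def assign_secondary_structure(structure: Structure,
                               fallback: str = "geometric",
                               energy_cutoff: float = -0.5) -> list[SSE]:
    """Secondary structure elements for every protein chain of the first
    model.  Deposited HELIX/SHEET records are authoritative when present
    (geometry still contributes turns); otherwise the assignment is fully
    geometric.  Chains shorter than 4 residues are all coil."""
    sses: list[SSE] = []
    model = structure.model
    for chain_id, _ in sorted(model.chains.items()):
        residues = model.protein_residues(chain_id)
        if not residues:
            continue
        states = ["coil"] * len(residues)
        index = {(r.seq_num, r.icode): i for i, r in enumerate(residues)}
        deposited = [rec for rec in structure.helix_sheet_records
                     if rec.chain_id == chain_id]
        geo = (_geometric_states(residues, energy_cutoff)
               if (fallback == "geometric" and len(residues) >= 4)
               else ["coil"] * len(residues))
        if deposited:
            for rec in deposited:
                if rec.start not in index or rec.end not in index:
                    logger.warning("HELIX/SHEET record outside chain %s skipped",
                                   chain_id)
                    continue
                s, e = index[rec.start], index[rec.end]
                code = "H" if rec.kind == "helix" else "E"
                for i in range(s, e + 1):
                    states[i] = code
            # geometry contributes turns only
            for i, st in enumerate(geo):
                if st == "T" and states[i] == "coil":
                    states[i] = "T"
        else:
            states = geo
        sses.extend(_runs_to_sses(residues, states, chain_id))
    return sses


def _runs_to_sses(residues, states, chain_id) -> list[SSE]:
    out = []
    i = 0
    kinds = {"H": "helix", "E": "strand", "T": "turn"}
    while i < len(states):
        if states[i] in kinds:
            j = i
            while j + 1 < len(states) and states[j + 1] == states[i]:
                j += 1
            out.append(SSE(kinds[states[i]], chain_id,
                           (residues[i].seq_num, residues[i].icode),
                           (residues[j].seq_num, residues[j].icode)))
            i = j + 1
        else:
            i += 1
    return out


def sse_states(structure: Structure, sses: Optional[list[SSE]] = None,
               **kw) -> dict[ResidueKey, str]:
    """Flatten an SSE list into a per-residue state map (H/E/T/coil)."""
    if sses is None:
        sses = assign_secondary_structure(structure, **kw)
    states: dict[ResidueKey, str] = {}
    code = {"helix": "H", "strand": "E", "turn": "T"}
    for chain_id, _ in structure.model.chains.items():
        residues = structure.model.protein_residues(chain_id)
        order = {(r.seq_num, r.icode): i for i, r in enumerate(residues)}
        for r in residues:
            states[r.key] = "coil"
        for sse in sses:
            if sse.chain_id != chain_id or sse.start not in order:
                continue
            for i in range(order[sse.start], order.get(sse.end, order[sse.start]) + 1):
                states[residues[i].key] = code[sse.kind]
    return states


# ---------------------------------------------------------------------------
# solvent accessibility (Shrake-Rupley)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate coordinates into a canonical principal-axes frame so that
    the fixed sphere point set yields rigid-transform-invariant areas
    (axis signs fixed by the third coordinate moment)."""
    if len(coords) < 2:
        return coords - coords.mean(axis=0) if len(coords) else coords
    c = coords - coords.mean(axis=0)
    _, vecs = np.linalg.eigh(c.T @ c)
    proj = c @ vecs
    for i in range(3):
        m3 = (proj[:, i] ** 3).sum()
        if abs(m3) < 1e-9:
            m3 = proj[np.argmax(np.abs(proj[:, i])), i]
        if m3 < 0:
            vecs[:, i] = -vecs[:, i]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return c @ vecs


def atom_sasa(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
              n_points: int = 960) -> np.ndarray:
    """Shrake-Rupley SASA per atom (Ų).

    Each atom's solvent-extended sphere (vdW + probe) is sampled with a
    fixed golden-spiral point set; points inside any neighbour's extended
    sphere are occluded.  Deterministic for a given ``n_points`` and
    invariant under rigid motion (coordinates are canonicalized to a
    principal-axes frame before sampling).
    """
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 92:
        raise ValueError("need at least 92 sphere points")
    coords = _canonical_frame(np.asarray(coords, dtype=float))
    n = len(coords)
    ext = radii + probe
    pts = sphere_points(n_points)
    tree = cKDTree(coords)
    out = np.zeros(n)
    max_ext = ext.max() if n else 0.0
    for i in range(n):
        neighbors = [j for j in tree.query_ball_point(coords[i], ext[i] + max_ext)
                     if j != i and np.linalg.norm(coords[j] - coords[i]) < ext[i] + ext[j]]
        surface = coords[i] + pts * ext[i]
        free = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((surface - coords[j]) ** 2, axis=1)
            free &= d2 > ext[j] ** 2
        out[i] = free.sum() / n_points * 4 * np.pi * ext[i] ** 2
    return out


def compute_sasa(structure: Structure, probe: float = 1.4,
                 n_points: int = 960,
                 include_het_sums: bool = False) -> dict[ResidueKey, float]:
    """Per-residue SASA (Ų) of the first model.

    Hydrogens are ignored; het atoms act as occluders and are excluded
    from the protein residue sums unless ``include_het_sums``.
    """
    atoms, owners = [], []
    for res in structure.model.residues:
        for a in res.heavy_atoms():
            atoms.append(a)
            owners.append(res)
    if not atoms:
        return {}
    coords = np.array([a.pos for a in atoms])
    radii = np.array([vdw_radius(a.element) for a in atoms])
    per_atom = atom_sasa(coords, radii, probe=probe, n_points=n_points)
    out: dict[ResidueKey, float] = {}
    for res in structure.model.residues:
        if res.is_het and not include_het_sums:
            continue
        out[res.key] = 0.0
    for a_sasa, res in zip(per_atom, owners):
        if res.key in out:
            out[res.key] += a_sasa
    return out


def relative_accessibility(residue_name: str, sasa: float) -> float:
    """sasa / theoretical max for the residue type, clamped to [0, 1]."""
    ref = MAX_ACC.get(residue_name)
    if ref is None:
        logger.warning("no reference max SASA for %s; using GLY", residue_name)
        ref = MAX_ACC["GLY"]
    return float(np.clip(sasa / ref, 0.0, 1.0))


def classify_accessibility(rel_acc: float, buried_max: float = 0.10,
                           intermediate_max: float = 0.40) -> str:
    if rel_acc < buried_max:
        return "buried"
    if rel_acc < intermediate_max:
        return "intermediate"
    return "accessible"


# ---------------------------------------------------------------------------
# hydropathy


def hydropathy_profile(sequence: str, window: int = 9,
                       hydrophobic_min: float = 0.5,
                       hydrophilic_max: float = -0.5,
                       ) -> tuple[np.ndarray, list[str]]:
    """Sliding-window mean of the Kyte-Doolittle scale with shrunken
    windows at the termini; returns (values, classes)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    vals = []
    for ch in sequence:
        v = KYTE_DOOLITTLE.get(ch.upper())
        if v is None:
            logger.warning("unknown residue letter %r scored 0", ch)
            v = 0.0
        vals.append(v)
    vals = np.array(vals)
    half = window // 2
    n = len(vals)
    prof = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        prof[i] = vals[lo:hi].mean() if hi > lo else 0.0
    classes = ["hydrophobic" if v > hydrophobic_min
               else "hydrophilic" if v < hydrophilic_max
               else "neutral" for v in prof]
    return prof, classes


# ---------------------------------------------------------------------------
# disulfides


def detect_disulfides(structure: Structure, cutoff: float = 2.5,
                      ) -> list[tuple[ResidueKey, ResidueKey]]:
    """Disulfide bridges: union of SSBOND records and geometric Cys SG–SG
    pairs within ``cutoff``; each Cys joins at most one bridge (closest
    wins)."""
    model = structure.model
    cys = [r for r in model.residues
           if r.name == "CYS" and r.atom("SG") is not None]
    candidates: list[tuple[float, ResidueKey, ResidueKey]] = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = float(np.linalg.norm(cys[i].atom("SG").pos - cys[j].atom("SG").pos))
            if d <= cutoff:
                candidates.append((d, cys[i].key, cys[j].key))
    for k1, k2 in structure.ssbond_records:
        r1, r2 = model.find(k1), model.find(k2)
        if r1 is None or r2 is None:
            logger.warning("SSBOND names missing residue %s-%s; dropped", k1, k2)
            continue
        a1, a2 = r1.atom("SG"), r2.atom("SG")
        d = (float(np.linalg.norm(a1.pos - a2.pos))
             if a1 is not None and a2 is not None else cutoff)
        candidates.append((d, k1, k2))
    candidates.sort(key=lambda t: t[0])
    taken: set[ResidueKey] = set()
    bridges = []
    for _, k1, k2 in candidates:
        if k1 in taken or k2 in taken or k1 == k2:
            continue
        taken.update((k1, k2))
        bridges.append(tuple(sorted((k1, k2))))
    return sorted(bridges)


# ---------------------------------------------------------------------------
# combined annotation


def annotate_residues(structure: Structure, config: Optional[dict] = None,
                      ) -> dict[ResidueKey, ResidueAnnotation]:
    """Full per-residue annotation of the first model's protein residues."""
    from .config import default_config
    cfg = config or default_config()
    states = sse_states(structure,
                        fallback=cfg["ss"]["fallback"],
                        energy_cutoff=cfg["ss"]["hbond_energy_cutoff"])
    sasa = compute_sasa(structure, probe=cfg["sasa"]["probe"],
                        n_points=cfg["sasa"]["points"])
    bridges = detect_disulfides(structure)
    in_bridge = {k for pair in bridges for k in pair}
    out: dict[ResidueKey, ResidueAnnotation] = {}
    for chain_id in sorted(structure.model.chains):
        residues = structure.model.protein_residues(chain_id)
        if not residues:
            continue
        seq = "".join(r.one_letter for r in residues)
        hyd, hyd_cls = hydropathy_profile(
            seq, window=cfg["hyd"]["window"],
            hydrophobic_min=cfg["hyd"]["hydrophobic_min"],
            hydrophilic_max=cfg["hyd"]["hydrophilic_max"])
        for i, r in enumerate(residues):
            s = sasa.get(r.key, 0.0)
            rel = relative_accessibility(r.name, s)
            out[r.key] = ResidueAnnotation(
                key=r.key,
                ss=states.get(r.key, "coil"),
                sasa=s,
                rel_acc=rel,
                acc_class=classify_accessibility(
                    rel, cfg["acc"]["buried_max"], cfg["acc"]["intermediate_max"]),
                hyd=float(hyd[i]),
                hyd_class=hyd_cls[i],
                is_nonstandard=r.is_nonstandard,
                has_altloc=r.has_altloc,
                in_ssbond=r.key in in_bridge,
            )
    return out
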