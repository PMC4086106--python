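"""Contact detection and marker assignment.

Contacts are minimum heavy-atom distances: ``close`` strictly below
3.2 Å, included up to and including 5.0 Å.  Assembly contacts are
computed on the biological assembly; crystallographic contacts on the
deposited asymmetric unit against its symmetry images.  Residues sitting
on special positions (own image within eps) are flagged separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .config import DEFAULTS
from .model import ResidueKey, Structure, expand_symmetry

logger = logging.getLogger(__name__)

CLOSE_MAX = 3.2      # Å, strict upper bound of the close class
CUTOFF = 5.0         # Å, inclusive detection cutoff

#: ordered symbol palette for ligand compounds (first two match the
#: published legend: colon for the first compound, caret for the second)
LIGAND_PALETTE = [":", "^", "=", "~", "$", "%", "&", "+"]


@dataclass(frozen=True)
class Contact:
    kind: str                 # prot_prot | prot_lig
    crystallographic: bool
    residue: ResidueKey
    partner: str              # chain id (prot) or "LIG:chain:num" (ligand)
    min_dist: float

    @property
    def dist_class(self) -> str:
        return "close" if self.min_dist < CLOSE_MAX else "far"


@dataclass
class MarkerSet:
    cryst_pp_letter: Optional[tuple[str, str]] = None   # (letter, red|black)
    special_position_hash: bool = False
    cryst_lig_symbols: list[tuple[str, str]] = field(default_factory=list)
    assembly_lig_symbols: list[tuple[str, str]] = field(default_factory=list)
    pp_blue_frame: bool = False
    both_orange_background: bool = False
    nonstandard_X: bool = False
    altloc_star: bool = False


def classify_distance(d: float) -> str:
    return "close" if d < CLOSE_MAX else "far"


def _atom_table(model, keep_het: set[str]):
    """Flat heavy-atom table: coords, owning residue, chain, ligand flag.

    Waters are always dropped; het residues not on the keep list are
    dropped entirely (neither partners nor occluders here)."""
    coords, keys, chains, is_lig, lig_ids = [], [], [], [], []
    for r in model.residues:
        if r.is_het and (r.is_water or r.name not in keep_het):
            continue
        for a in r.heavy_atoms():
            coords.append(a.pos)
            keys.append(r.key)
            chains.append(r.chain_id)
            is_lig.append(r.is_het)
            lig_ids.append(f"LIG:{r.name}:{r.chain_id}:{r.seq_num}"
                           if r.is_het else "")
    return (np.array(coords).reshape(-1, 3), keys, chains,
            np.array(is_lig, dtype=bool), lig_ids)


def find_assembly_contacts(assembly: Structure, cutoff: float = CUTOFF,
                           keep_het: Optional[set[str]] = None,
                           ) -> list[Contact]:
    """Non-crystallographic contacts within the biological assembly:
    protein residue pairs from *different* chains and protein↔ligand
    pairs (any chain), with any heavy-atom distance ≤ cutoff."""
    keep = set(keep_het) if keep_het is not None else set(DEFAULTS["ligands"]["keep"])
    coords, keys, chains, is_lig, lig_ids = _atom_table(assembly.model, keep)
    if len(coords) == 0:
        return []
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    best: dict[tuple, float] = {}
    for i, j in pairs:
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d > cutoff:
            continue
        li, lj = is_lig[i], is_lig[j]
        if li and lj:
            continue
        if not li and not lj:
            if chains[i] == chains[j]:
                continue
            for a, b in ((i, j), (j, i)):
                k = ("prot_prot", keys[a], chains[b])
                if d < best.get(k, np.inf):
                    best[k] = d
        else:
            p, l = (i, j) if lj else (j, i)
            k = ("prot_lig", keys[p], lig_ids[l])
            if d < best.get(k, np.inf):
                best[k] = d
    return sorted(
        (Contact(kind, False, res, partner, d)
         for (kind, res, partner), d in best.items()),
        key=lambda c: (c.residue, c.partner))


def find_crystal_contacts(structure: Structure, cutoff: float = CUTOFF,
                          shell: int = 1,
                          keep_het: Optional[set[str]] = None,
                          ) -> tuple[list[Contact], str]:
    """Crystallographic contacts of the deposited asymmetric unit against
    every symmetry image within ``shell`` cell layers.

    Returns ``(contacts, status)`` with status ``"ok"`` or
    ``"not applicable"`` (no unit cell)."""
    keep = set(keep_het) if keep_het is not None else set(DEFAULTS["ligands"]["keep"])
    coords, keys, chains, is_lig, lig_ids = _atom_table(structure.model, keep)
    if len(coords) == 0:
        return [], "ok"
    images = expand_symmetry(structure, shell=shell, coords=coords)
    if images is None:
        return [], "not applicable"
    if cutoff <= 0:
        return [], "ok"
    tree = cKDTree(coords)
    best: dict[tuple, float] = {}
    for img in images:
        itree = cKDTree(img.coords)
        sparse = tree.sparse_distance_matrix(itree, cutoff, output_type="coo_matrix")
        for i, j, d in zip(sparse.row, sparse.col, sparse.data):
            if d > cutoff or is_lig[i]:
                continue
            if is_lig[j]:
                kind, partner = "prot_lig", lig_ids[j]
            else:
                kind, partner = "prot_prot", chains[j]
            k = (kind, keys[i], partner)
            d = float(d)
            if d < best.get(k, np.inf):
                best[k] = d
    contacts = sorted(
        (Contact(kind, True, res, partner, d)
         for (kind, res, partner), d in best.items()),
        key=lambda c: (c.residue, c.partner))
    return contacts, "ok"


def detect_special_positions(structure: Structure, eps: float = 1.0,
                             shell: int = 1) -> list[ResidueKey]:
    """Residues with any atom within ``eps`` of its *own* image under a
    non-identity symmetry operation (e.g. sitting on a 2-fold axis)."""
    if structure.cell is None:
        return []
    coords, keys, _, _, _ = _atom_table(structure.model,
                                        set(DEFAULTS["ligands"]["keep"]))
    if len(coords) == 0:
        return []
    images = expand_symmetry(structure, shell=shell, coords=coords)
    flagged: set[ResidueKey] = set()
    for img in images:
        d = np.linalg.norm(img.coords - coords, axis=1)
        for i in np.where(d <= eps)[0]:
            flagged.add(keys[i])
    return sorted(flagged)


def ligand_symbol_map(contacts: list[Contact]) -> dict[str, tuple[str, str]]:
    """Assign each distinct ligand compound the next palette symbol, in
    first-appearance order; beyond the palette, symbols recycle with a
    numeric suffix in the legend."""
    compounds: list[str] = []
    for c in contacts:
        if c.kind != "prot_lig":
            continue
        name = c.partner.split(":")[1]
        if name not in compounds:
            compounds.append(name)
    out = {}
    for i, name in enumerate(compounds):
        sym = LIGAND_PALETTE[i % len(LIGAND_PALETTE)]
        suffix = i // len(LIGAND_PALETTE)
        legend = name if suffix == 0 else f"{name} ({suffix + 1})"
        out[name] = (sym, legend)
    return out


def assign_markers(assembly_contacts: list[Contact],
                   crystal_contacts: list[Contact],
                   special_positions: list[ResidueKey],
                   disulfides: list[tuple[ResidueKey, ResidueKey]],
                   annotations: Optional[dict] = None,
                   ) -> dict[ResidueKey, MarkerSet]:
    """Deterministic mapping from contacts/flags to the figure marker
    vocabulary (see the sequence-panel legend)."""
    symbols = ligand_symbol_map(crystal_contacts + assembly_contacts)
    markers: dict[ResidueKey, MarkerSet] = {}

    def m(key: ResidueKey) -> MarkerSet:
        return markers.setdefault(key, MarkerSet())

    for c in crystal_contacts:
        ms = m(c.residue)
        color = "red" if c.dist_class == "close" else "black"
        if c.kind == "prot_prot":
            prev = ms.cryst_pp_letter
            # closest partner wins the letter; red beats black
            if prev is None or (color == "red" and prev[1] == "black"):
                ms.cryst_pp_letter = (c.partner, color)
        else:
            sym = symbols[c.partner.split(":")[1]][0]
            if (sym, color) not in ms.cryst_lig_symbols:
                ms.cryst_lig_symbols.append((sym, color))
    for c in assembly_contacts:
        ms = m(c.residue)
        if c.kind == "prot_prot":
            ms.pp_blue_frame = True
        else:
            color = "red" if c.dist_class == "close" else "black"
            sym = symbols[c.partner.split(":")[1]][0]
            if (sym, color) not in ms.assembly_lig_symbols:
                ms.assembly_lig_symbols.append((sym, color))
    cryst_residues = {c.residue for c in crystal_contacts}
    noncryst_residues = {c.residue for c in assembly_contacts}
    for key in cryst_residues & noncryst_residues:
        m(key).both_orange_background = True
    for key in special_positions:
        m(key).special_position_hash = True
    for ann in (annotations or {}).values():
        if ann.is_nonstandard:
            m(ann.key).nonstandard_X = True
        if ann.has_altloc:
            m(ann.key).altloc_star = True
    return markers


def write_contact_tsv(contacts: list[Contact], stream=None) -> str:
    """Machine-readable contact report."""
    lines = ["chain\tseq_num\ticode\tkind\tcrystallographic\tpartner\t"
             "min_dist\tdist_class"]
    for c in contacts:
        ch, num, ic = c.residue
        lines.append(f"{ch}\t{num}\t{ic}\t{c.kind}\t"
                     f"{int(c.crystallographic)}\t{c.partner}\t"
                     f"{c.min_dist:.3f}\t{c.dist_class}")
    text = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(text)
    return text
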