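"""3D scene generation: "Cartoon" and "Sausage" PyMOL scripts.

Scenes are written as plain-text ``.pml`` command scripts plus the
coordinate files they reference, bundled into a zip.  Conservation
scores travel through the B-factor channel of the written PDB files
(the same convention used for external per-residue/per-atom properties),
colored with a white→red linear ramp; the sausage tube radius is set
per residue from the deviation profile.
"""

from __future__ import annotations

import re
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .contacts import Contact
from .model import Structure, parse_pdb, write_pdb
from .superpose import DeviationProfile

WHITE = np.array([1.0, 1.0, 1.0])
RED = np.array([1.0, 0.0, 0.0])


def ramp_color(score: float) -> tuple[float, float, float]:
    """Affine white→red ramp: color(s) = white + s·(red − white)."""
    s = min(max(float(score), 0.0), 1.0)
    return tuple(WHITE + s * (RED - WHITE))


@dataclass
class SceneBundle:
    script_path: Path
    files: list[Path] = field(default_factory=list)
    presets: list[str] = field(default_factory=list)
    zip_path: Optional[Path] = None

    def all_exist(self) -> bool:
        return all(p.exists() for p in [self.script_path] + list(self.files))


#: the seven preset toggles exposed as named scenes in every script
PRESETS = ["surface", "assembly", "nmr_models", "disulfides",
           "ligands_contacts", "strictly_conserved", "sites"]

ALLOWED_COMMANDS = {
    "load", "hide", "show", "color", "spectrum", "set", "select",
    "deselect", "disable", "enable", "bg_color", "alter", "rebuild",
    "scene", "orient", "zoom", "group", "delete", "set_name", "python",
    "print", "as",
}


def lint_script(text: str) -> list[str]:
    """Grammar-level lint: every command on the allowlist, balanced
    parentheses and quotes, and every referenced object defined by an
    earlier load/select/group.  Returns a list of problems (empty=ok)."""
    problems = []
    defined: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cmd = re.split(r"[ ,(]", line, 1)[0]
        if cmd not in ALLOWED_COMMANDS:
            problems.append(f"line {lineno}: unknown command {cmd!r}")
            continue
        if line.count("(") != line.count(")"):
            problems.append(f"line {lineno}: unbalanced parentheses")
        if line.count('"') % 2:
            problems.append(f"line {lineno}: unbalanced quotes")
        if cmd == "load":
            name = None
            parts = [p.strip() for p in line[4:].split(",")]
            name = parts[1] if len(parts) > 1 else Path(parts[0]).stem
            defined.add(name)
        elif cmd == "select":
            parts = line[6:].split(",", 1)
            defined.add(parts[0].strip())
        elif cmd in ("enable", "disable", "delete"):
            target = line.split(None, 1)[1].strip().rstrip(",")
            if target not in defined and not target.startswith(("all",)):
                problems.append(
                    f"line {lineno}: {cmd} references undefined {target!r}")
    return problems


def _scored_b_selection(obj: str) -> str:
    return f"({obj} and b > -0.5)"


def _script_header(out: list[str], pdb_file: str, obj: str) -> None:
    out.append(f"load {pdb_file}, {obj}")
    out.append("bg_color white")
    out.append("hide everything")


def _conservation_coloring(out: list[str], obj: str) -> None:
    # B channel carries 100*score; sentinel -1 residues stay gray
    out.append(f"color grey80, {obj}")
    out.append(f"spectrum b, white_red, {_scored_b_selection(obj)}, "
               f"minimum=0, maximum=100")


def _preset_blocks(out: list[str], obj: str,
                   strictly_conserved: Optional[list[int]] = None,
                   ligand_contact_resi: Optional[list[int]] = None,
                   has_assembly: bool = False) -> list[str]:
    presets = []
    out.append(f"select preset_surface, {obj}")
    out.append("show surface, preset_surface")
    out.append("disable preset_surface")
    presets.append("surface")
    if has_assembly:
        out.append(f"select preset_assembly, {obj}_assembly")
        out.append("disable preset_assembly")
        presets.append("assembly")
    out.append(f"select preset_nmr_models, {obj}")
    out.append("disable preset_nmr_models")
    presets.append("nmr_models")
    out.append(f"select preset_disulfides, {obj} and resn CYS and name SG")
    out.append("show sticks, preset_disulfides")
    out.append("disable preset_disulfides")
    presets.append("disulfides")
    lig = f"{obj} and hetatm"
    resi = "+".join(str(i) for i in (ligand_contact_resi or [])) or "0"
    out.append(f"select preset_ligands_contacts, ({lig}) or "
               f"({obj} and resi {resi})")
    out.append("show sticks, preset_ligands_contacts")
    out.append("color cyan, preset_ligands_contacts and hetatm")
    out.append(f"color palegreen, preset_ligands_contacts and not hetatm")
    out.append("disable preset_ligands_contacts")
    presets.append("ligands_contacts")
    resi = "+".join(str(i) for i in (strictly_conserved or [])) or "0"
    out.append(f"select preset_strictly_conserved, {obj} and resi {resi}")
    out.append("disable preset_strictly_conserved")
    presets.append("strictly_conserved")
    out.append(f"select preset_sites, {obj} and resi 0")
    out.append("disable preset_sites")
    presets.append("sites")
    return presets


def _bundle(out_dir: Path, name: str, lines: list[str],
            files: list[Path], presets: list[str]) -> SceneBundle:
    script = out_dir / f"{name}.pml"
    script.write_text("\n".join(lines) + "\n", newline="\n")
    zip_path = out_dir / f"{name}.zip"
    with zipfile.ZipFile(zip_path, "w") as zf:
        zf.write(script, script.name)
        for f in files:
            zf.write(f, f.name)
    return SceneBundle(script, files, presets, zip_path)


def build_cartoon_scene(scored: Structure, profile, out_dir,
                        name: str = "cartoon",
                        strictly_conserved_resi: Optional[list[int]] = None,
                        ligand_contact_resi: Optional[list[int]] = None,
                        homolog_files: Optional[list[Path]] = None,
                        ) -> SceneBundle:
    """Conservation-colored ribbon of the query.

    ``scored`` must carry 100·score in the B-factor channel (sentinel
    -1.00 for unscored residues); the white→red ramp spans score 0..1.
    """
    if profile is None:
        raise ValueError("cartoon scene requires conservation scores")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_file = out_dir / f"{name}_query.pdb"
    pdb_file.write_text(write_pdb(scored))
    obj = "query"
    lines: list[str] = []
    _script_header(lines, pdb_file.name, obj)
    lines.append(f"show cartoon, {obj}")
    _conservation_coloring(lines, obj)
    files = [pdb_file]
    for hf in homolog_files or []:
        lines.append(f"load {Path(hf).name}, {Path(hf).stem}")
        lines.append(f"disable {Path(hf).stem}")
        files.append(Path(hf))
    presets = _preset_blocks(lines, obj,
                             strictly_conserved_resi, ligand_contact_resi)
    return _bundle(out_dir, name, lines, files, presets)


def build_sausage_scene(scored: Structure, profile: DeviationProfile,
                        radii: np.ndarray, out_dir,
                        name: str = "sausage",
                        query_chain: Optional[str] = None,
                        ligand_contacts: Optional[list[Contact]] = None,
                        strictly_conserved_resi: Optional[list[int]] = None,
                        homolog_files: Optional[list[Path]] = None,
                        ) -> SceneBundle:
    """Cα-trace tube whose per-residue radius encodes the mean Cα
    deviation across superposed homologs, colored by conservation."""
    if profile is None or radii is None:
        raise ValueError("sausage scene requires a deviation profile")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_file = out_dir / f"{name}_query.pdb"
    pdb_file.write_text(write_pdb(scored))
    obj = "query"
    residues = scored.model.protein_residues(query_chain)
    lines: list[str] = []
    _script_header(lines, pdb_file.name, obj)
    lines.append(f"show cartoon, {obj}")
    lines.append(f"set cartoon_tube_radius, 0.3, {obj}")
    lines.append(f"as cartoon, {obj}")
    lines.append(f"set cartoon_trace_atoms, 1, {obj}")
    for res, r in zip(residues, radii):
        lines.append(f"set cartoon_tube_radius, {r:.2f}, "
                     f"{obj} and chain {res.chain_id} and resi {res.seq_num}")
    _conservation_coloring(lines, obj)
    lig_resi = sorted({c.residue[1] for c in (ligand_contacts or [])
                       if c.kind == "prot_lig"})
    files = [pdb_file]
    for hf in homolog_files or []:
        lines.append(f"load {Path(hf).name}, {Path(hf).stem}")
        lines.append(f"disable {Path(hf).stem}")
        files.append(Path(hf))
    presets = _preset_blocks(lines, obj, strictly_conserved_resi, lig_resi)
    return _bundle(out_dir, name, lines, files, presets)


# ---------------------------------------------------------------------------
# external-property channel


@dataclass
class ExternalProperty:
    keyword: str
    vmin: float
    vmax: float
    channel: str = "bfactor"          # bfactor | occupancy
    granularity: str = "residue"      # residue | atom
    values: dict = field(default_factory=dict)   # residue key or (key, atom) -> raw
    clamped: int = 0

    def normalized(self) -> dict:
        span = self.vmax - self.vmin
        return {k: (min(max(v, self.vmin), self.vmax) - self.vmin) / span
                for k, v in self.values.items()}


_REMARK_RE = re.compile(
    r"^REMARK\s+\d+\s+(?:EXTERNAL\s+PROPERTY\s+)?(?P<kw>\S+)\s+"
    r"MIN\s+(?P<vmin>-?[\d.eE+]+)\s+MAX\s+(?P<vmax>-?[\d.eE+]+)"
    r"(?:\s+CHANNEL\s+(?P<chan>BFACTOR|OCCUPANCY))?"
    r"(?:\s+GRANULARITY\s+(?P<gran>RESIDUE|ATOM))?", re.I)


def read_external_property(stream) -> tuple[ExternalProperty, Structure]:
    """Read the modified-PDB external-property dialect: a REMARK header
    declaring keyword, min and max (optionally channel and granularity),
    with the property values in the B-factor or occupancy column.

    Out-of-range values are clamped (counted in ``clamped``); values are
    normalized to [0, 1] by (v − vmin)/(vmax − vmin).
    """
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        text = str(stream)
        if "\n" not in text:
            text = Path(text).read_text()
    meta = None
    for line in text.splitlines():
        m = _REMARK_RE.match(line)
        if m:
            meta = m
            break
    if meta is None:
        raise ValueError("external property header required "
                         "(REMARK with keyword, MIN and MAX)")
    vmin, vmax = float(meta["vmin"]), float(meta["vmax"])
    if vmin >= vmax:
        raise ValueError("property MIN must be below MAX")
    channel = (meta["chan"] or "bfactor").lower()
    granularity = (meta["gran"] or "residue").lower()
    st = parse_pdb(text)
    prop = ExternalProperty(meta["kw"], vmin, vmax, channel, granularity)
    for res in st.model.residues:
        vals = [a.bfactor if channel == "bfactor" else a.occupancy
                for a in res.atoms]
        if granularity == "residue":
            v = vals[0]
            if v < vmin or v > vmax:
                prop.clamped += 1
            prop.values[res.key] = v
        else:
            for a, v in zip(res.atoms, vals):
                if v < vmin or v > vmax:
                    prop.clamped += 1
                prop.values[(res.key, a.name)] = v
    return prop, st


def render_external_property(prop: ExternalProperty, target: str,
                             structure: Optional[Structure] = None,
                             out_dir=None):
    """``flat_bar``: a color-bar track for the sequence panel
    (label, {residue key: hex color}).  ``scene``: a SceneBundle coloring
    residues/atoms by the white→red ramp over the normalized value."""
    norm = prop.normalized()
    if target == "flat_bar":
        colors = {}
        for k, v in norm.items():
            key = k[0] if isinstance(k[0], tuple) else k
            r, g, b = ramp_color(v)
            colors[key] = f"#{int(r*255):02x}{int(g*255):02x}{int(b*255):02x}"
        return (prop.keyword, colors)
    if target != "scene":
        raise ValueError("target must be flat_bar or scene")
    out_dir = Path(out_dir or ".")
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_file = out_dir / "external_property.pdb"
    pdb_file.write_text(write_pdb(structure))
    lines: list[str] = []
    _script_header(lines, pdb_file.name, "extprop")
    lines.append("show cartoon, extprop")
    for k, v in sorted(norm.items(), key=str):
        r, g, b = ramp_color(v)
        if isinstance(k[0], tuple):
            (chain, num, _), atom = k
            sel = f"extprop and chain {chain} and resi {num} and name {atom}"
        else:
            chain, num, _ = k
            sel = f"extprop and chain {chain} and resi {num}"
        lines.append(f"color [{r:.3f}, {g:.3f}, {b:.3f}], {sel}")
    script = out_dir / "external_property.pml"
    script.write_text("\n".join(lines) + "\n")
    return SceneBundle(script, [pdb_file], ["property"], None)
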