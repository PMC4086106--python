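"""Pipeline orchestration: parse → annotate → contacts → conservation →
superposition → figures and scenes, with graceful degradation.

Optional inputs that are absent (unit cell, MSA, homolog structures,
external property) skip their stages with a recorded reason instead of
failing; the run report lists every produced file and every skipped
stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import annotate as an
from . import contacts as ct
from . import msa as msamod
from . import render, scenes, superpose
from .config import default_config, load_config
from .model import Structure, build_assembly, parse_pdb, write_pdb

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    query_pdb: str | Path
    msa_path: Optional[str | Path] = None
    msa_dialect: str = "fasta"
    query_name: Optional[str] = None        # row name in the MSA
    homolog_dir: Optional[str | Path] = None
    property_pdb: Optional[str | Path] = None
    out_dir: str | Path = "structmap_out"
    chain: Optional[str] = None             # default: first chain
    page: str = "A4"
    formats: tuple[str, ...] = ("ps",)
    residues_per_line: int = 60
    config_path: Optional[str | Path] = None
    overrides: Optional[dict] = None


@dataclass
class RunReport:
    produced: dict[str, list[Path]] = field(default_factory=dict)
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def add(self, group: str, paths) -> None:
        self.produced.setdefault(group, []).extend(
            Path(p) for p in (paths if isinstance(paths, (list, tuple)) else [paths]))

    def skip(self, stage: str, reason: str) -> None:
        self.skipped.append((stage, reason))
        logger.info("stage %s skipped: %s", stage, reason)

    def summary(self) -> str:
        lines = ["produced:"]
        for group in sorted(self.produced):
            for p in self.produced[group]:
                lines.append(f"  [{group}] {p}")
        lines.append("skipped:")
        for stage, reason in self.skipped:
            lines.append(f"  {stage}: {reason}")
        return "\n".join(lines)


def run(rc: RunConfig) -> RunReport:
    cfg = load_config(rc.config_path, rc.overrides)
    out_dir = Path(rc.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    structure = parse_pdb(rc.query_pdb, name=Path(str(rc.query_pdb)).stem)
    chain = rc.chain or sorted(structure.model.chains)[0]
    residues = structure.model.protein_residues(chain)
    annotations = an.annotate_residues(structure, cfg)
    sses = an.assign_secondary_structure(
        structure, fallback=cfg["ss"]["fallback"],
        energy_cutoff=cfg["ss"]["hbond_energy_cutoff"])

    # contacts
    keep = set(cfg["ligands"]["keep"])
    assembly = build_assembly(structure)
    assembly_contacts = ct.find_assembly_contacts(
        assembly, cutoff=cfg["contacts"]["cutoff"], keep_het=keep)
    crystal_contacts, status = ct.find_crystal_contacts(
        structure, cutoff=cfg["contacts"]["cutoff"],
        shell=cfg["contacts"]["shell"], keep_het=keep)
    if status != "ok":
        report.skip("crystal_contacts", status)
    specials = ct.detect_special_positions(
        structure, eps=cfg["contacts"]["special_position_eps"],
        shell=cfg["contacts"]["shell"])
    disulfides = an.detect_disulfides(structure)
    markers = ct.assign_markers(assembly_contacts, crystal_contacts,
                                specials, disulfides, annotations)
    tsv = out_dir / "contacts.tsv"
    with open(tsv, "w") as fh:
        ct.write_contact_tsv(assembly_contacts + crystal_contacts, fh)
    report.add("contacts", tsv)

    # external property (optional; adds a flat track + its own scene)
    extra_tracks = []
    ext_prop = None
    if rc.property_pdb is not None:
        try:
            ext_prop, ext_struct = scenes.read_external_property(
                str(rc.property_pdb))
            extra_tracks.append(
                scenes.render_external_property(ext_prop, "flat_bar"))
            bundle = scenes.render_external_property(
                ext_prop, "scene", ext_struct, out_dir / "external")
            report.add("external_property",
                       [bundle.script_path] + list(bundle.files))
        except (ValueError, OSError) as exc:
            report.skip("external_property", str(exc))

    # group 1: sequence panel
    seq_residues = [(r.key, r.one_letter) for r in residues]
    symbols = ct.ligand_symbol_map(crystal_contacts + assembly_contacts)
    legend = [f"{sym}  {name}" for name, (sym, name_leg) in symbols.items()
              for sym, name_leg in [symbols[name]]]
    doc1 = render.layout_sequence_panel(
        seq_residues, annotations, markers,
        residues_per_line=rc.residues_per_line, page=rc.page,
        palette=cfg["render"]["palette"], extra_tracks=extra_tracks,
        title=f"{structure.name} chain {chain}", legend=legend)
    for fmt in rc.formats:
        files = render.export(doc1, out_dir / f"sequence_panel.{fmt}", fmt,
                              dpi=cfg["render"]["dpi"])
        report.add("sequence_panel", files)

    # MSA-dependent stages
    if rc.msa_path is None:
        for stage in ("msa_panel", "stockholm", "cartoon", "sausage"):
            report.skip(stage, "no MSA provided")
        return report

    msa = msamod.read_msa(str(rc.msa_path), rc.msa_dialect, rc.query_name)
    msamod.validate_query_row(msa, structure, chain,
                              cfg["msa"]["max_mismatch"])
    profile = msamod.conservation_scores(
        msa, identity_weight=cfg["msa"]["identity_weight"],
        similarity_threshold=cfg["msa"]["similarity_threshold"])
    classes = msamod.column_similarity(msa, cfg["msa"]["similarity_threshold"])

    # homolog structures (for per-row SS and the sausage)
    homolog_devs = []
    homolog_files = []
    row_ss: dict[str, str] = {}
    q_states = [getattr(annotations.get(r.key), "ss", "coil")
                for r in residues]
    row_ss[msa.query_name] = msamod.gapped_ss_string(
        msa, msa.query_name, q_states)
    if rc.homolog_dir is not None:
        for p in sorted(Path(rc.homolog_dir).glob("*.pdb")):
            if p.stem not in msa.names:
                report.skip(f"homolog:{p.name}", "no matching MSA row")
                continue
            hom = parse_pdb(p, name=p.stem)
            pairing = superpose.msa_pairing(msa, msa.query_name, p.stem)
            res = superpose.superpose_homolog(
                structure, hom, pairing, query_chain=chain,
                trim_sigma=3.0 if cfg["sausage"]["trim"] else None)
            if res is None:
                report.skip(f"homolog:{p.name}", "fewer than 3 aligned pairs")
                continue
            moved, devs = res
            homolog_devs.append(devs)
            hp = out_dir / "superposed" / f"{p.stem}_on_query.pdb"
            hp.parent.mkdir(exist_ok=True)
            hp.write_text(write_pdb(moved))
            homolog_files.append(hp)
            report.add("superposed", hp)
            h_sses = an.assign_secondary_structure(hom)
            h_states = [s for s in _chain_states(hom, h_sses)]
            row_ss[p.stem] = msamod.gapped_ss_string(msa, p.stem, h_states)

    # group 2: MSA panel
    stars = {structure.name if structure.name in msa.names else msa.query_name:
             [c for i, c in enumerate(profile.query_positions)
              if residues[i].has_altloc]}
    doc2 = render.layout_msa_panel(
        msa.names, msa.rows, classes, row_ss=row_ss, stars=stars,
        page=rc.page, palette=cfg["render"]["palette"])
    for fmt in rc.formats:
        files = render.export(doc2, out_dir / f"msa_panel.{fmt}", fmt,
                              dpi=cfg["render"]["dpi"])
        report.add("msa_panel", files)

    # Stockholm export
    sto = out_dir / "alignment.sto"
    with open(sto, "w") as fh:
        msamod.write_stockholm(msa, row_ss, fh)
    report.add("stockholm", sto)

    # group 3: Cartoon
    scored = msamod.map_profile_to_structure(profile, structure, chain)
    strict_resi = [residues[i].seq_num
                   for i in range(len(residues))
                   if i < len(profile.is_strict) and profile.is_strict[i]]
    lig_resi = sorted({c.residue[1] for c in assembly_contacts
                       if c.kind == "prot_lig"})
    cartoon = scenes.build_cartoon_scene(
        scored, profile, out_dir / "cartoon",
        strictly_conserved_resi=strict_resi,
        ligand_contact_resi=lig_resi, homolog_files=homolog_files)
    report.add("cartoon", [cartoon.script_path, cartoon.zip_path])

    # group 4: Sausage (needs homolog structures)
    if not homolog_devs:
        report.skip("sausage", "no homolog structures superposed")
        return report
    dev = superpose.deviation_profile(structure, homolog_devs,
                                      query_chain=chain,
                                      mean=cfg["sausage"]["mean"])
    radii = superpose.sausage_radii(dev, cfg["sausage"]["r_min"],
                                    cfg["sausage"]["r_max"],
                                    cfg["sausage"]["d_cap"])
    dev_tsv = out_dir / "deviation_profile.tsv"
    with open(dev_tsv, "w") as fh:
        superpose.write_deviation_tsv(dev, radii, fh)
    report.add("deviation_profile", dev_tsv)
    sausage = scenes.build_sausage_scene(
        scored, dev, radii, out_dir / "sausage", query_chain=chain,
        ligand_contacts=assembly_contacts,
        strictly_conserved_resi=strict_resi, homolog_files=homolog_files)
    report.add("sausage", [sausage.script_path, sausage.zip_path])
    return report


def _chain_states(structure: Structure, sses) -> list[str]:
    states_map = an.sse_states(structure, sses)
    chain = sorted(structure.model.chains)[0]
    return [states_map.get(r.key, "coil")
            for r in structure.model.protein_residues(chain)]
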