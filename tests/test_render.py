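"""Figure layout and export: blocks, glyphs, boxes, formats, page sizes."""

import math

import pytest
from PIL import Image

from structmap import fixtures as fx
from structmap.annotate import annotate_residues
from structmap.contacts import MarkerSet
from structmap.model import parse_pdb
from structmap.msa import MSA, column_similarity
from structmap.render import (Box, HelixGlyph, Polygon, Text, export,
                              layout_msa_panel, layout_sequence_panel,
                              page_size_pt)


def _flat(doc):
    return [p for page in doc.pages for p in page.prims]


def _sequence_inputs(n=130):
    st = fx.helix_structure(n)
    ann = annotate_residues(st)
    residues = [(r.key, r.one_letter) for r in st.model.residues]
    return residues, ann


class TestPageSizes:
    @pytest.mark.parametrize("name,mm", [
        ("letter", (215.9, 279.4)), ("A4", (210, 297)), ("A3", (297, 420)),
        ("A0", (841, 1189)), ("tapestry", (800, 3300)),
    ])
    def test_sizes_in_points(self, name, mm):
        w, h = page_size_pt(name)
        assert w == pytest.approx(mm[0] * 72 / 25.4)
        assert h == pytest.approx(mm[1] * 72 / 25.4)

    def test_us_letter_alias(self):
        assert page_size_pt("US letter") == page_size_pt("letter")

    def test_tapestry_is_0p8_by_3p3_m(self):
        w, h = page_size_pt("tapestry")
        assert w * 25.4 / 72 / 1000 == pytest.approx(0.8)
        assert h * 25.4 / 72 / 1000 == pytest.approx(3.3)

    def test_unknown_size_rejected(self):
        with pytest.raises(ValueError, match="A4"):
            page_size_pt("B5")


class TestSequencePanel:
    def test_block_count_ceiling(self):
        residues, ann = _sequence_inputs(130)
        doc = layout_sequence_panel(residues, ann, residues_per_line=60)
        seq_texts = [p for p in _flat(doc)
                     if isinstance(p, Text) and p.pitch and len(p.text) > 5]
        assert len(seq_texts) == math.ceil(130 / 60) == 3

    def test_every_residue_appears_once(self):
        residues, ann = _sequence_inputs(130)
        doc = layout_sequence_panel(residues, ann, residues_per_line=60)
        seq = "".join(p.text for p in _flat(doc)
                      if isinstance(p, Text) and p.pitch and len(p.text) > 5)
        assert seq == "".join(c for _, c in residues)

    def test_accessible_residue_blue_bar_cell(self):
        residues, ann = _sequence_inputs(20)
        doc = layout_sequence_panel(residues, ann)
        boxes = [p for p in _flat(doc) if isinstance(p, Box) and p.fill]
        accessible_color = "#2060ff"
        has_accessible = any(a.acc_class == "accessible"
                             for a in ann.values())
        assert has_accessible == any(b.fill == accessible_color
                                     for b in boxes)

    def test_helix_glyph_split_across_blocks(self):
        residues, ann = _sequence_inputs(130)  # helix spans every line
        doc = layout_sequence_panel(residues, ann, residues_per_line=60)
        squiggles = [p for p in _flat(doc) if isinstance(p, HelixGlyph)]
        assert len(squiggles) >= 3  # one continuation per block

    def test_markers_rendered(self):
        residues, ann = _sequence_inputs(20)
        markers = {
            residues[4][0]: MarkerSet(cryst_pp_letter=("A", "red")),
            residues[6][0]: MarkerSet(special_position_hash=True),
            residues[8][0]: MarkerSet(assembly_lig_symbols=[(":", "red")]),
            residues[9][0]: MarkerSet(pp_blue_frame=True,
                                      both_orange_background=True),
        }
        doc = layout_sequence_panel(residues, ann, markers)
        flat = _flat(doc)
        texts = [p for p in flat if isinstance(p, Text)]
        assert any(p.text == "A" and p.style == "italic" for p in texts)
        assert any(p.text == "#" for p in texts)
        assert any(p.text == ":" for p in texts)
        boxes = [p for p in flat if isinstance(p, Box)]
        assert any(b.stroke == "#1040c0" for b in boxes)      # blue frame
        assert any(b.fill == "#ffa040" for b in boxes)        # orange bg
        assert any(b.fill == "#ffff90" for b in boxes)        # light yellow

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            layout_sequence_panel([], {})

    def test_deterministic_layout(self):
        residues, ann = _sequence_inputs(50)
        d1 = layout_sequence_panel(residues, ann)
        d2 = layout_sequence_panel(residues, ann)
        assert repr(_flat(d1)) == repr(_flat(d2))


class TestMsaPanel:
    def _small(self):
        names = ["query", "homolog1", "homolog2"]
        rows = ["LIVKDE", "LIVKDE", "LLVRDE"]
        msa = MSA(names, rows, 0)
        return names, rows, column_similarity(msa)

    def test_identical_column_red_box(self):
        names, rows, classes = self._small()
        doc = layout_msa_panel(names, rows, classes)
        boxes = [p for p in _flat(doc) if isinstance(p, Box)]
        assert any(b.fill == "#e80000" for b in boxes)

    def test_white_text_on_identical_runs(self):
        names, rows, classes = self._small()
        doc = layout_msa_panel(names, rows, classes)
        assert any(isinstance(p, Text) and p.color == "#ffffff"
                   for p in _flat(doc))

    def test_none_class_has_no_box(self):
        names = ["a", "b"]
        rows = ["LD", "DK"]
        doc = layout_msa_panel(names, rows, ["none", "none"])
        assert not any(isinstance(p, Box) for p in _flat(doc))

    def test_ss_glyph_line_for_annotated_rows(self):
        names, rows, classes = self._small()
        doc = layout_msa_panel(names, rows, classes,
                               row_ss={"query": "HHHHHH"})
        assert any(isinstance(p, HelixGlyph) for p in _flat(doc))

    def test_gray_stars(self):
        names, rows, classes = self._small()
        doc = layout_msa_panel(names, rows, classes,
                               stars={"query": [2]})
        assert any(isinstance(p, Text) and p.text == "*"
                   and p.color == "#808080" for p in _flat(doc))

    def test_long_alignment_paginates(self):
        names = [f"s{i}" for i in range(300)]
        rows = ["ACDEFGHIKL" * 30] * 300
        msa = MSA(names, rows, 0)
        doc = layout_msa_panel(names, rows, column_similarity(msa))
        assert len(doc.pages) > 1
        # every row/column drawn exactly once across pages
        total = sum(len(p.text) for pg in doc.pages for p in pg.prims
                    if isinstance(p, Text) and p.pitch)
        assert total == 300 * 300


class TestExport:
    @pytest.fixture
    def doc(self):
        residues, ann = _sequence_inputs(30)
        return layout_sequence_panel(residues, ann)

    def test_ps_magic_and_pages(self, doc, tmp_path):
        out = tmp_path / "fig.ps"
        export(doc, out, "ps")
        text = out.read_text()
        assert text.startswith("%!PS")
        assert f"%%Pages: {len(doc.pages)}" in text

    def test_pdf_magic(self, doc, tmp_path):
        out = tmp_path / "fig.pdf"
        export(doc, out, "pdf")
        assert out.read_bytes()[:5] == b"%PDF-"

    def test_png_dimensions_match_page_and_dpi(self, doc, tmp_path):
        out = tmp_path / "fig.png"
        export(doc, out, "png", dpi=150)
        img = Image.open(out)
        assert img.size[0] == pytest.approx(doc.width / 72 * 150, abs=1)
        assert img.size[1] == pytest.approx(doc.height / 72 * 150, abs=1)

    def test_tiff_decodable(self, doc, tmp_path):
        out = tmp_path / "fig.tiff"
        export(doc, out, "tiff", dpi=72)
        assert Image.open(out).format == "TIFF"

    def test_unsupported_format_lists_choices(self, doc, tmp_path):
        with pytest.raises(ValueError, match="ps, pdf, png, tiff"):
            export(doc, tmp_path / "x.svg", "svg")

    def test_low_dpi_rejected(self, doc, tmp_path):
        with pytest.raises(ValueError, match="dpi"):
            export(doc, tmp_path / "x.png", "png", dpi=30)

    def test_ps_byte_identical_reruns(self, tmp_path):
        residues, ann = _sequence_inputs(40)
        outs = []
        for i in range(2):
            doc = layout_sequence_panel(residues, ann)
            out = tmp_path / f"f{i}.ps"
            export(doc, out, "ps")
            outs.append(out.read_bytes())
        assert outs[0] == outs[1]
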