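"""Flat-figure rendering: sequence panel and MSA panel.

Layout produces a device-independent :class:`RenderDocument` (pages of
drawing primitives in PostScript points, origin bottom-left), which the
export step serializes to PostScript (own writer, deterministic,
timestamp-free), or to PDF/PNG/TIFF through matplotlib.

The layout is run-based: consecutive columns sharing a class are drawn
as one primitive, which keeps very large alignments (thousands of rows
by thousands of columns) tractable in memory and time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .config import DEFAULTS
from .contacts import MarkerSet
from .model import ResidueKey

# page sizes in millimetres
PAGE_SIZES_MM: dict[str, tuple[float, float]] = {
    "letter": (215.9, 279.4),
    "A4": (210.0, 297.0),
    "A3": (297.0, 420.0),
    "A0": (841.0, 1189.0),
    "tapestry": (800.0, 3300.0),
}
PAGE_ALIASES = {"us letter": "letter", "usletter": "letter"}

MM_TO_PT = 72.0 / 25.4


def page_size_pt(name: str) -> tuple[float, float]:
    key = PAGE_ALIASES.get(name.strip().lower(), name.strip())
    if key not in PAGE_SIZES_MM and key.lower() in PAGE_SIZES_MM:
        key = key.lower()
    if key not in PAGE_SIZES_MM:
        if key.upper() in PAGE_SIZES_MM:
            key = key.upper()
        else:
            raise ValueError(f"unknown page size {name!r}; choose from "
                             + ", ".join(PAGE_SIZES_MM))
    w, h = PAGE_SIZES_MM[key]
    return w * MM_TO_PT, h * MM_TO_PT


@dataclass(slots=True)
class Text:
    x: float
    y: float
    text: str
    size: float = 8.0
    color: str = "#000000"
    style: str = "normal"       # normal | italic | bold
    pitch: float = 0.0          # fixed char advance; 0 = natural


@dataclass(slots=True)
class Box:
    x: float
    y: float
    w: float
    h: float
    fill: Optional[str] = None
    stroke: Optional[str] = None
    linewidth: float = 0.5


@dataclass(slots=True)
class PolyLine:
    points: list[tuple[float, float]]
    color: str = "#000000"
    linewidth: float = 1.0


@dataclass(slots=True)
class HelixGlyph:
    """Parametric helix squiggle: a sine wave over [x, x+w] at mid-line y.

    Stored compactly (four floats) and expanded only at draw time — a
    PostScript procedure in the prolog, a sampled polyline elsewhere —
    so documents with hundreds of thousands of helix glyphs stay small.
    """
    x: float
    y: float
    w: float
    h: float
    color: str = "#d00000"

    def points(self, step: float = 2.5) -> list[tuple[float, float]]:
        n = max(int(self.w / step), 4)
        return [(self.x + self.w * i / n,
                 self.y + self.h / 2 * math.sin(2 * math.pi * i / n * 1.5))
                for i in range(n + 1)]


@dataclass(slots=True)
class Polygon:
    points: list[tuple[float, float]]
    fill: str = "#000000"


Primitive = object


@dataclass
class Page:
    width: float
    height: float
    prims: list = field(default_factory=list)


@dataclass
class RenderDocument:
    pages: list[Page]
    page_size: str = "A4"

    @property
    def width(self) -> float:
        return self.pages[0].width if self.pages else 0.0

    @property
    def height(self) -> float:
        return self.pages[0].height if self.pages else 0.0


# ---------------------------------------------------------------------------
# shared layout helpers

MARGIN = 40.0
FONT = 8.0
PITCH = FONT * 0.6
ROW_H = FONT * 1.15


def _runs(classes: Sequence[str], lo: int, hi: int):
    """Yield (start, end_exclusive, class) runs of classes[lo:hi]."""
    i = lo
    while i < hi:
        j = i + 1
        while j < hi and classes[j] == classes[i]:
            j += 1
        yield i, j, classes[i]
        i = j


def _clip_runs(runs: list[tuple[int, int, str]], lo: int, hi: int):
    """Intersect precomputed (start, end, class) runs with [lo, hi)."""
    from bisect import bisect_right
    starts = [r[0] for r in runs]
    i = max(bisect_right(starts, lo) - 1, 0)
    out = []
    while i < len(runs) and runs[i][0] < hi:
        s, e, cls = runs[i]
        if e > lo:
            out.append((max(s, lo), min(e, hi), cls))
        i += 1
    return out


def _helix_squiggle(x: float, y: float, w: float, h: float) -> HelixGlyph:
    """Sinusoidal squiggle spanning [x, x+w] at mid-height y."""
    return HelixGlyph(x, y, w, h)


def _strand_arrow(x: float, y: float, w: float, h: float) -> Polygon:
    head = min(w * 0.35, 6.0)
    b = h * 0.28
    return Polygon([(x, y - b), (x + w - head, y - b), (x + w - head, y - h / 2),
                    (x + w, y), (x + w - head, y + h / 2),
                    (x + w - head, y + b), (x, y + b)], "#d0a000")


# ---------------------------------------------------------------------------
# sequence panel


def layout_sequence_panel(residues: Sequence[tuple[ResidueKey, str]],
                          annotations: dict,
                          markers: Optional[dict[ResidueKey, MarkerSet]] = None,
                          residues_per_line: int = 60,
                          page: str = "A4",
                          palette: Optional[dict[str, str]] = None,
                          extra_tracks: Optional[list[tuple[str, dict]]] = None,
                          title: str = "",
                          legend: Optional[list[str]] = None,
                          ) -> RenderDocument:
    """Sequence panel: per line block a secondary-structure glyph track,
    the sequence row (deposited numbering), accessibility and hydropathy
    bars, and the contact-marker rows below.

    ``residues`` is the ordered list of (residue key, one-letter code);
    non-standard residues are expected pre-mapped to ``X`` by the caller
    or shown via their ``is_nonstandard`` annotation.
    """
    if not residues:
        raise ValueError("empty sequence")
    if residues_per_line < 10:
        raise ValueError("residues_per_line must be >= 10")
    markers = markers or {}
    pal = dict(DEFAULTS["render"]["palette"])
    if palette:
        pal.update(palette)
    extra_tracks = extra_tracks or []
    pw, ph = page_size_pt(page)
    label_w = 42.0
    x0 = MARGIN + label_w
    pitch = PITCH
    usable = pw - x0 - MARGIN
    rpl = min(residues_per_line, max(10, int(usable / pitch)))

    keys = [k for k, _ in residues]
    letters = []
    for k, c in residues:
        ann = annotations.get(k)
        letters.append("X" if (ann is not None and ann.is_nonstandard) else c)
    ss = [getattr(annotations.get(k), "ss", "coil") for k in keys]
    acc = [getattr(annotations.get(k), "acc_class", "buried") for k in keys]
    hyd = [getattr(annotations.get(k), "hyd_class", "neutral") for k in keys]
    n = len(keys)
    n_blocks = math.ceil(n / rpl)

    # per-block height: ss + seq + 2 bars + 2 marker rows + extra tracks
    block_h = (ROW_H * 2 + 7.0 * 2 + ROW_H * 2
               + 7.0 * len(extra_tracks) + 14.0)
    pages: list[Page] = []
    cur = Page(pw, ph)
    y = ph - MARGIN - (ROW_H * 2 if title else 0)
    if title:
        cur.prims.append(Text(MARGIN, ph - MARGIN - FONT, title, FONT + 2,
                              "#000000", "bold"))

    acc_color = {"accessible": pal["acc_accessible"],
                 "intermediate": pal["acc_intermediate"],
                 "buried": pal["acc_buried"]}
    hyd_color = {"hydrophobic": pal["hyd_hydrophobic"],
                 "neutral": pal["hyd_neutral"],
                 "hydrophilic": pal["hyd_hydrophilic"]}

    for b in range(n_blocks):
        lo, hi = b * rpl, min((b + 1) * rpl, n)
        if y - block_h < MARGIN:
            pages.append(cur)
            cur = Page(pw, ph)
            y = ph - MARGIN
        top = y
        # --- SS glyph track
        gy = top - ROW_H / 2
        for s, e, cls in _runs(ss, lo, hi):
            gx = x0 + (s - lo) * pitch
            gw = (e - s) * pitch
            if cls == "H":
                cur.prims.append(_helix_squiggle(gx, gy, gw, FONT))
            elif cls == "E":
                cur.prims.append(_strand_arrow(gx, gy, gw, FONT))
            elif cls == "T":
                cur.prims.append(Text(gx, gy - FONT * 0.35, "T" * (e - s),
                                      FONT - 1, "#009000", "bold", pitch))
        y = top - ROW_H
        # --- sequence row with backgrounds and frames
        seq_y = y - ROW_H + FONT * 0.2
        for i in range(lo, hi):
            ms = markers.get(keys[i])
            if ms is None:
                continue
            cx = x0 + (i - lo) * pitch
            if ms.both_orange_background:
                cur.prims.append(Box(cx, seq_y - 1, pitch, ROW_H,
                                     fill=pal["orange_bg"]))
            if ms.pp_blue_frame:
                cur.prims.append(Box(cx, seq_y - 1, pitch, ROW_H,
                                     stroke=pal["blue_frame"]))
        cur.prims.append(Text(MARGIN, seq_y, str(keys[lo][1]), FONT, "#000000"))
        cur.prims.append(Text(x0, seq_y, "".join(letters[lo:hi]), FONT,
                              "#000000", "normal", pitch))
        # altloc gray stars above the sequence letters
        for i in range(lo, hi):
            ms = markers.get(keys[i])
            if ms is not None and ms.altloc_star:
                cur.prims.append(Text(x0 + (i - lo) * pitch, seq_y + FONT,
                                      "*", FONT, pal["gray_star"], "bold"))
        y = seq_y - 4
        # --- accessibility and hydropathy bars
        for classes, cmap in ((acc, acc_color), (hyd, hyd_color)):
            for s, e, cls in _runs(classes, lo, hi):
                cur.prims.append(Box(x0 + (s - lo) * pitch, y - 6,
                                     (e - s) * pitch, 5, fill=cmap[cls],
                                     stroke="#000000", linewidth=0.3))
            y -= 7
        # --- external property tracks
        for label, colors in extra_tracks:
            for i in range(lo, hi):
                col = colors.get(keys[i])
                if col:
                    cur.prims.append(Box(x0 + (i - lo) * pitch, y - 6,
                                         pitch, 5, fill=col))
            cur.prims.append(Text(MARGIN, y - 6, label[:8], FONT - 2,
                                  "#404040"))
            y -= 7
        # --- marker row 1: crystallographic letters / special hash
        my = y - ROW_H + FONT * 0.2
        for i in range(lo, hi):
            ms = markers.get(keys[i])
            if ms is None:
                continue
            cx = x0 + (i - lo) * pitch
            if ms.cryst_pp_letter is not None:
                letter, color = ms.cryst_pp_letter
                cur.prims.append(Text(cx, my, letter[:1],
                                      FONT, pal["close_contact"]
                                      if color == "red" else
                                      pal["far_contact"], "italic"))
            if ms.special_position_hash:
                cur.prims.append(Text(cx, my, "#", FONT, "#000000", "italic"))
        y = my - 2
        # --- marker row 2: ligand symbols (italic = crystallographic,
        #     upright on light-yellow = assembly)
        ly = y - ROW_H + FONT * 0.2
        for i in range(lo, hi):
            ms = markers.get(keys[i])
            if ms is None:
                continue
            cx = x0 + (i - lo) * pitch
            if ms.assembly_lig_symbols:
                cur.prims.append(Box(cx, ly - 1, pitch, ROW_H,
                                     fill=pal["light_yellow_bg"]))
                sym, color = ms.assembly_lig_symbols[0]
                cur.prims.append(Text(cx, ly, sym, FONT,
                                      pal["close_contact"] if color == "red"
                                      else pal["far_contact"], "normal"))
            elif ms.cryst_lig_symbols:
                sym, color = ms.cryst_lig_symbols[0]
                cur.prims.append(Text(cx, ly, sym, FONT,
                                      pal["close_contact"] if color == "red"
                                      else pal["far_contact"], "italic"))
        y = ly - 14
    if legend:
        for line in legend:
            if y - ROW_H < MARGIN:
                pages.append(cur)
                cur = Page(pw, ph)
                y = ph - MARGIN
            cur.prims.append(Text(MARGIN, y - FONT, line, FONT - 1, "#202020"))
            y -= ROW_H
    pages.append(cur)
    return RenderDocument(pages, page)


# ---------------------------------------------------------------------------
# MSA panel


def layout_msa_panel(names: Sequence[str], rows: Sequence[str],
                     column_classes: Sequence[str],
                     row_ss: Optional[dict[str, str]] = None,
                     stars: Optional[dict[str, Iterable[int]]] = None,
                     page: str = "A4",
                     palette: Optional[dict[str, str]] = None,
                     font_size: float = FONT,
                     ) -> RenderDocument:
    """MSA panel: identical columns as white-on-red boxes, similar
    columns bold on yellow, a secondary-structure glyph line above every
    row that carries one, gray stars above flagged (altloc) columns.

    Run-based: boxes span maximal column runs of one class and the full
    row band, so cost scales with rows × class runs, not rows × columns.
    """
    row_ss = row_ss or {}
    stars = stars or {}
    pal = dict(DEFAULTS["render"]["palette"])
    if palette:
        pal.update(palette)
    n_rows, n_cols = len(rows), len(rows[0]) if rows else 0
    pw, ph = page_size_pt(page)
    pitch = font_size * 0.6
    row_h = font_size * 1.15
    label_w = min(80.0, max(len(nm) for nm in names) * (font_size - 2) * 0.6 + 6)
    x0 = MARGIN + label_w
    cols_per_line = max(10, int((pw - x0 - MARGIN) / pitch))
    n_blocks = math.ceil(n_cols / cols_per_line)

    pages: list[Page] = []
    classes = list(column_classes)
    # precompute maximal runs once; clip per column window below
    ss_runs_full = {name: list(_runs(ss, 0, len(ss)))
                    for name, ss in row_ss.items()}
    for b in range(n_blocks):
        lo = b * cols_per_line
        hi = min(lo + cols_per_line, n_cols)
        runs = list(_runs(classes, lo, hi))
        r = 0
        while r < n_rows:
            cur = Page(pw, ph)
            y = ph - MARGIN
            cur.prims.append(Text(MARGIN, y - font_size,
                                  f"columns {lo + 1}-{hi}", font_size, "#404040"))
            y -= row_h * 2
            # how many rows fit on this page (each row may carry an SS line)
            while r < n_rows and y - row_h * 2 > MARGIN:
                name, row = names[r], rows[r]
                ss = row_ss.get(name)
                if ss is not None:
                    gy = y - row_h / 2
                    for s, e, cls in _clip_runs(ss_runs_full[name], lo, hi):
                        gx, gw = x0 + (s - lo) * pitch, (e - s) * pitch
                        if cls == "H":
                            cur.prims.append(_helix_squiggle(gx, gy, gw,
                                                             font_size))
                        elif cls == "E":
                            cur.prims.append(_strand_arrow(gx, gy, gw,
                                                           font_size))
                        elif cls == "T":
                            cur.prims.append(Text(gx, gy - font_size * 0.35,
                                                  "T" * (e - s), font_size - 1,
                                                  "#009000", "bold", pitch))
                    y -= row_h
                ty = y - row_h + font_size * 0.2
                # class boxes behind this row
                for s, e, cls in runs:
                    if cls == "identical":
                        cur.prims.append(Box(x0 + (s - lo) * pitch, ty - 1,
                                             (e - s) * pitch, row_h,
                                             fill=pal["identical_box"]))
                    elif cls == "similar":
                        cur.prims.append(Box(x0 + (s - lo) * pitch, ty - 1,
                                             (e - s) * pitch, row_h,
                                             fill=pal["similar_box"]))
                cur.prims.append(Text(MARGIN, ty, name[:13], font_size - 2,
                                      "#000000"))
                # text split by class runs (white on red, bold on yellow)
                for s, e, cls in runs:
                    color = "#ffffff" if cls == "identical" else "#000000"
                    style = "bold" if cls == "similar" else "normal"
                    cur.prims.append(Text(x0 + (s - lo) * pitch, ty,
                                          row[s:e], font_size, color, style,
                                          pitch))
                for col in stars.get(name, ()):
                    if lo <= col < hi:
                        cur.prims.append(Text(x0 + (col - lo) * pitch,
                                              ty + font_size, "*", font_size,
                                              pal["gray_star"], "bold"))
                y -= row_h
                r += 1
            pages.append(cur)
    return RenderDocument(pages, page)


# ---------------------------------------------------------------------------
# export

FORMATS = ("ps", "pdf", "png", "tiff")


def export(document: RenderDocument, path, fmt: str, dpi: int = 150) -> list:
    """Serialize a document; returns the list of files written.

    PostScript uses the package's own deterministic writer; PDF is a
    multi-page matplotlib PdfPages (creation date suppressed); PNG/TIFF
    rasterize one file per page (page 1 at ``path``, later pages
    suffixed ``_pN``).
    """
    from pathlib import Path as _P
    fmt = fmt.lower()
    if fmt not in FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; choose from "
                         + ", ".join(FORMATS))
    if fmt in ("png", "tiff") and dpi < 72:
        raise ValueError("dpi must be >= 72 for raster formats")
    path = _P(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "ps":
        with open(path, "w") as fh:
            _write_postscript(document, fh)
        return [path]
    return _export_matplotlib(document, path, fmt, dpi)


def _hex_rgb(color: str) -> tuple[float, float, float]:
    c = color.lstrip("#")
    return tuple(int(c[i:i + 2], 16) / 255.0 for i in (0, 2, 4))


_PS_FONT = {"normal": "Courier", "bold": "Courier-Bold",
            "italic": "Courier-Oblique"}


def _ps_escape(s: str) -> str:
    return s.replace("\\", r"\\").replace("(", r"\(").replace(")", r"\)")


def _write_postscript(doc: RenderDocument, fh) -> None:
    w, h = doc.width, doc.height
    fh.write("%!PS-Adobe-3.0\n")
    fh.write(f"%%BoundingBox: 0 0 {math.ceil(w)} {math.ceil(h)}\n")
    fh.write(f"%%HiResBoundingBox: 0 0 {w:.6f} {h:.6f}\n")
    fh.write(f"%%Pages: {len(doc.pages)}\n")
    fh.write("%%Creator: structmap\n%%EndComments\n")
    fh.write("/mono {/Courier findfont exch scalefont setfont} def\n")
    # squiggle procedure: x y w h squig -> sine polyline, expanded in PS
    fh.write(
        "/squig { /sh exch def /sw exch def /sy exch def /sx exch def\n"
        " newpath sx sy moveto\n"
        " 1 1 24 { /i exch def\n"
        "  sx sw i mul 24 div add\n"
        "  sy sh 2 div i 540 mul 24 div sin mul add lineto } for\n"
        " stroke } def\n")
    for ipage, page in enumerate(doc.pages, 1):
        fh.write(f"%%Page: {ipage} {ipage}\n")
        last_color = last_font = None
        for p in page.prims:
            if isinstance(p, Text):
                font = (_PS_FONT.get(p.style, "Courier"), p.size)
                if font != last_font:
                    fh.write(f"/{font[0]} findfont {p.size:.1f} scalefont setfont\n")
                    last_font = font
                if p.color != last_color:
                    r, g, bcol = _hex_rgb(p.color)
                    fh.write(f"{r:.3f} {g:.3f} {bcol:.3f} setrgbcolor\n")
                    last_color = p.color
                if p.pitch and abs(p.pitch - p.size * 0.6) > 1e-6:
                    extra = p.pitch - p.size * 0.6
                    fh.write(f"{p.x:.2f} {p.y:.2f} moveto {extra:.3f} 0 "
                             f"({_ps_escape(p.text)}) ashow\n")
                else:
                    fh.write(f"{p.x:.2f} {p.y:.2f} moveto "
                             f"({_ps_escape(p.text)}) show\n")
            elif isinstance(p, Box):
                if p.fill:
                    r, g, bcol = _hex_rgb(p.fill)
                    fh.write(f"{r:.3f} {g:.3f} {bcol:.3f} setrgbcolor\n")
                    fh.write(f"{p.x:.2f} {p.y:.2f} {p.w:.2f} {p.h:.2f} "
                             f"rectfill\n")
                    last_color = None
                if p.stroke:
                    r, g, bcol = _hex_rgb(p.stroke)
                    fh.write(f"{r:.3f} {g:.3f} {bcol:.3f} setrgbcolor "
                             f"{p.linewidth:.2f} setlinewidth\n")
                    fh.write(f"{p.x:.2f} {p.y:.2f} {p.w:.2f} {p.h:.2f} "
                             f"rectstroke\n")
                    last_color = None
            elif isinstance(p, HelixGlyph):
                if p.color != last_color:
                    r, g, bcol = _hex_rgb(p.color)
                    fh.write(f"{r:.3f} {g:.3f} {bcol:.3f} setrgbcolor\n")
                    last_color = p.color
                fh.write(f"{p.x:.2f} {p.y:.2f} {p.w:.2f} {p.h:.2f} squig\n")
            elif isinstance(p, PolyLine):
                r, g, bcol = _hex_rgb(p.color)
                fh.write(f"{r:.3f} {g:.3f} {bcol:.3f} setrgbcolor "
                         f"{p.linewidth:.2f} setlinewidth newpath\n")
                x, y = p.points[0]
                fh.write(f"{x:.2f} {y:.2f} moveto\n")
                for x, y in p.points[1:]:
                    fh.write(f"{x:.2f} {y:.2f} lineto\n")
                fh.write("stroke\n")
                last_color = None
            elif isinstance(p, Polygon):
                r, g, bcol = _hex_rgb(p.fill)
                fh.write(f"{r:.3f} {g:.3f} {bcol:.3f} setrgbcolor newpath\n")
                x, y = p.points[0]
                fh.write(f"{x:.2f} {y:.2f} moveto\n")
                for x, y in p.points[1:]:
                    fh.write(f"{x:.2f} {y:.2f} lineto\n")
                fh.write("closepath fill\n")
                last_color = None
        fh.write("showpage\n")
    fh.write("%%EOF\n")


def _draw_page_mpl(ax, page: Page) -> None:
    import matplotlib.patches as mpatches
    from matplotlib.lines import Line2D
    for p in page.prims:
        if isinstance(p, Text):
            ax.text(p.x, p.y, p.text, fontsize=p.size, color=p.color,
                    family="monospace",
                    style="italic" if p.style == "italic" else "normal",
                    weight="bold" if p.style == "bold" else "normal")
        elif isinstance(p, Box):
            ax.add_patch(mpatches.Rectangle(
                (p.x, p.y), p.w, p.h,
                facecolor=p.fill if p.fill else "none",
                edgecolor=p.stroke if p.stroke else "none",
                linewidth=p.linewidth, fill=p.fill is not None))
        elif isinstance(p, HelixGlyph):
            xs, ys = zip(*p.points())
            ax.add_line(Line2D(xs, ys, color=p.color, linewidth=1.0))
        elif isinstance(p, PolyLine):
            xs, ys = zip(*p.points)
            ax.add_line(Line2D(xs, ys, color=p.color, linewidth=p.linewidth))
        elif isinstance(p, Polygon):
            ax.add_patch(mpatches.Polygon(p.points, closed=True,
                                          facecolor=p.fill, edgecolor="none"))


def _export_matplotlib(doc: RenderDocument, path, fmt: str, dpi: int) -> list:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.backends.backend_pdf import PdfPages
    w_in, h_in = doc.width / 72.0, doc.height / 72.0
    written = []

    def make_fig(page):
        fig = plt.figure(figsize=(w_in, h_in))
        ax = fig.add_axes([0, 0, 1, 1])
        ax.set_xlim(0, doc.width)
        ax.set_ylim(0, doc.height)
        ax.axis("off")
        _draw_page_mpl(ax, page)
        return fig

    if fmt == "pdf":
        with PdfPages(path, metadata={"CreationDate": None,
                                      "Creator": "structmap",
                                      "Producer": "structmap"}) as pdf:
            for page in doc.pages:
                fig = make_fig(page)
                pdf.savefig(fig)
                plt.close(fig)
        return [path]
    for i, page in enumerate(doc.pages):
        out = path if i == 0 else path.with_name(
            f"{path.stem}_p{i + 1}{path.suffix}")
        fig = make_fig(page)
        fig.savefig(out, dpi=dpi, format="tif" if fmt == "tiff" else fmt)
        plt.close(fig)
        written.append(out)
    return written
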