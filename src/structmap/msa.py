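"""MSA handling: reading, column similarity classes, conservation scores,
mapping onto structures, and Stockholm export.

The conservation score of a query column blends exact identity with
physicochemical-group agreement:

    score = w_id * f_id + (1 - w_id) * f_grp

where ``f_id`` is the fraction of non-gap rows carrying the query residue,
``f_grp`` the fraction in the query residue's group, and ``w_id`` defaults
to 0.7.  A column is strictly conserved iff ``f_id == 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Optional

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import ResidueKey, Structure

GAP = "-."

#: physicochemical groups used for "similar" columns and f_grp
SIMILARITY_GROUPS = ["ILVMFWYC", "KRH", "DE", "STNQ", "G", "P", "A"]
GROUP_OF: dict[str, str] = {}
for _g in SIMILARITY_GROUPS:
    for _c in _g:
        GROUP_OF[_c] = _g


class MSAError(ValueError):
    pass


@dataclass
class MSA:
    names: list[str]
    rows: list[str]
    query_index: int = 0

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise MSAError("an alignment needs at least 2 rows")
        n = len(self.rows[0])
        for name, row in zip(self.names, self.rows):
            if len(row) != n:
                raise MSAError(f"ragged alignment: row {name!r} has length "
                               f"{len(row)}, expected {n}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def query_row(self) -> str:
        return self.rows[self.query_index]

    @property
    def query_name(self) -> str:
        return self.names[self.query_index]

    def query_columns(self) -> list[int]:
        """Alignment columns where the query has a residue."""
        return [i for i, c in enumerate(self.query_row) if c not in GAP]


def read_msa(stream, dialect: str = "fasta",
             query: Optional[str | int] = None) -> MSA:
    """Read a FASTA or Clustal alignment; the query row is located by
    name (or taken as an explicit index; default: first row)."""
    if dialect not in ("fasta", "clustal"):
        raise MSAError(f"unknown MSA dialect {dialect!r}")
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        text = str(stream)
        if not text.lstrip().startswith((">", "CLUSTAL")):
            with open(text) as fh:
                text = fh.read()
    if dialect == "fasta":
        records = list(SeqIO.parse(StringIO(text), "fasta"))
        if len(records) < 2:
            raise MSAError("an alignment needs at least 2 rows")
        n = len(records[0].seq)
        for r in records:
            if len(r.seq) != n:
                raise MSAError(f"ragged alignment: row {r.id!r} has length "
                               f"{len(r.seq)}, expected {n}")
        names = [r.id for r in records]
        rows = [str(r.seq).upper() for r in records]
    else:
        aln = AlignIO.read(StringIO(text), "clustal")
        names = [r.id for r in aln]
        rows = [str(r.seq).upper() for r in aln]
    qi = 0
    if isinstance(query, int):
        qi = query
    elif isinstance(query, str):
        if query not in names:
            raise MSAError(f"query {query!r} not found in alignment")
        qi = names.index(query)
    return MSA(names, rows, qi)


# ---------------------------------------------------------------------------
# column classes and conservation


def column_similarity(msa: MSA, threshold: float = 0.7) -> list[str]:
    """Per-column class: ``identical`` when one residue type fills every
    non-gap row, ``similar`` when the best physicochemical group reaches
    the threshold fraction of non-gap rows, else ``none``."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    out = []
    for col in range(msa.n_cols):
        letters = [row[col] for row in msa.rows if row[col] not in GAP]
        if not letters:
            out.append("none")
            continue
        if len(set(letters)) == 1:
            out.append("identical")
            continue
        counts: dict[str, int] = {}
        for c in letters:
            g = GROUP_OF.get(c, c)
            counts[g] = counts.get(g, 0) + 1
        if max(counts.values()) / len(letters) >= threshold:
            out.append("similar")
        else:
            out.append("none")
    return out


@dataclass
class ConservationProfile:
    """Per query residue (degapped query order)."""
    scores: np.ndarray                 # in [0, 1]
    column_classes: list[str]          # identical | similar | none
    is_strict: np.ndarray              # score == 1 via full identity
    query_positions: list[int] = field(default_factory=list)  # MSA columns


def conservation_scores(msa: MSA, identity_weight: float = 0.7,
                        similarity_threshold: float = 0.7,
                        ) -> ConservationProfile:
    """Blended identity/group conservation per query residue."""
    w = identity_weight
    classes_all = column_similarity(msa, similarity_threshold)
    cols = msa.query_columns()
    scores, strict, classes = [], [], []
    for col in cols:
        q = msa.query_row[col]
        letters = [row[col] for row in msa.rows if row[col] not in GAP]
        n = len(letters)
        f_id = sum(1 for c in letters if c == q) / n
        grp = GROUP_OF.get(q, q)
        f_grp = sum(1 for c in letters if GROUP_OF.get(c, c) == grp) / n
        scores.append(w * f_id + (1 - w) * f_grp)
        strict.append(f_id == 1.0)
        classes.append(classes_all[col])
    return ConservationProfile(np.array(scores), classes,
                               np.array(strict, dtype=bool), cols)


def validate_query_row(msa: MSA, structure: Structure, chain_id: str,
                       max_mismatch: float = 0.05) -> None:
    """The degapped query row must match the chain sequence (modified
    residues compare via their parent one-letter code)."""
    degapped = "".join(c for c in msa.query_row if c not in GAP)
    chain_seq = structure.chain_sequence(chain_id)
    if len(degapped) != len(chain_seq):
        raise MSAError(
            f"query row length {len(degapped)} != chain {chain_id} length "
            f"{len(chain_seq)}")
    mism = sum(1 for a, b in zip(degapped, chain_seq) if a != b and b != "X")
    if mism / max(len(chain_seq), 1) > max_mismatch:
        raise MSAError(
            f"query row disagrees with chain {chain_id} at {mism} positions")


def map_profile_to_structure(profile: ConservationProfile,
                             structure: Structure, chain_id: str,
                             ) -> Structure:
    """Copy of the structure with every atom's B-factor replaced by
    100·score (two decimals); unscored residues carry the sentinel
    -1.00."""
    out = structure.copy()
    residues = out.model.protein_residues(chain_id)
    scores = {i: s for i, s in enumerate(profile.scores)}
    for model in out.models:
        for r in model.residues:
            for a in r.atoms:
                a.bfactor = -1.00
    for model in out.models:
        prot = model.protein_residues(chain_id)
        for i, r in enumerate(prot):
            if i in scores:
                b = round(100.0 * float(scores[i]), 2)
                for a in r.atoms:
                    a.bfactor = b
    return out


# ---------------------------------------------------------------------------
# Stockholm


def write_stockholm(msa: MSA, ss_annotations: Optional[dict[str, str]] = None,
                    stream=None) -> str:
    """Stockholm 1.0 with ``#=GR <name> SS`` lines for annotated rows and
    ``#=GC SS_cons`` from the query's annotation.  SS strings are
    alignment-length, gap-aware (``-`` under gaps), H/E/T/C alphabet."""
    ss_annotations = ss_annotations or {}
    records = []
    for name, row in zip(msa.names, msa.rows):
        rec = SeqRecord(Seq(row), id=name, name=name, description=name)
        if name in ss_annotations:
            ss = ss_annotations[name]
            if len(ss) != len(row):
                raise MSAError(
                    f"SS annotation for {name!r} has length {len(ss)}, "
                    f"row has {len(row)}")
            rec.letter_annotations["secondary_structure"] = ss
        records.append(rec)
    aln = MultipleSeqAlignment(records)
    qname = msa.query_name
    if qname in ss_annotations:
        aln.column_annotations["secondary_structure"] = \
            ss_annotations[qname].replace("-", ".")
    out = StringIO()
    AlignIO.write(aln, out, "stockholm")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def read_stockholm(stream) -> tuple[MSA, dict[str, str]]:
    """Read back a Stockholm file (names, rows, per-row SS)."""
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        text = str(stream)
        if "# STOCKHOLM" not in text:
            with open(text) as fh:
                text = fh.read()
    aln = AlignIO.read(StringIO(text), "stockholm")
    names = [r.id for r in aln]
    rows = [str(r.seq).upper() for r in aln]
    ss = {r.id: r.letter_annotations["secondary_structure"]
          for r in aln if "secondary_structure" in r.letter_annotations}
    return MSA(names, rows, 0), ss


def gapped_ss_string(msa: MSA, row_name: str,
                     states: list[str]) -> str:
    """Spread per-residue SS states (H/E/T/coil) of a row's degapped
    sequence across its aligned row, '-' under gaps, C for coil."""
    row = msa.rows[msa.names.index(row_name)]
    it = iter(states)
    out = []
    for c in row:
        if c in GAP:
            out.append("-")
        else:
            s = next(it, "coil")
            out.append(s if s in "HET" else "C")
    return "".join(out)
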