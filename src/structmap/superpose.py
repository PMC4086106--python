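"""Alignment-guided rigid superposition and per-residue Cα deviation.

Homolog structures are fitted onto the query with the Kabsch algorithm
over Cα pairs taken from the sequence alignment.  The per-residue mean
deviation (root-mean-square over homologs by default) drives the radius
of the "sausage" tube depiction, linearly mapped and clamped between
r_min and r_max.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import Structure
from .msa import GAP, MSA

logger = logging.getLogger(__name__)


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rigid transform (R, t) minimizing Σ|R·q + t − p|².

    Returns (rotation, translation, rmsd).  The rotation is always a
    proper rotation (det +1): a reflection is never used, so mirrored
    inputs fit with a positive residual.  Collinear/degenerate sets are
    flagged with a warning but still solved.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be N x 3")
    n = len(P)
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    if not (np.isfinite(P).all() and np.isfinite(Q).all()):
        raise ValueError("coordinates must be finite")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = Q0.T @ P0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-8 * max(S[0], 1.0):
        logger.warning("degenerate (collinear) point set in superposition")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    diff = (Q0 @ R.T) - P0
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return R, t, rmsd


def msa_pairing(msa: MSA, query_name: str, homolog_name: str,
                ) -> list[tuple[int, int]]:
    """(query_residue_index, homolog_residue_index) for every alignment
    column where both rows have a residue, in degapped coordinates."""
    qrow = msa.rows[msa.names.index(query_name)]
    hrow = msa.rows[msa.names.index(homolog_name)]
    pairs = []
    qi = hi = 0
    for qc, hc in zip(qrow, hrow):
        qgap, hgap = qc in GAP, hc in GAP
        if not qgap and not hgap:
            pairs.append((qi, hi))
        if not qgap:
            qi += 1
        if not hgap:
            hi += 1
    return pairs


def _ca_coords(structure: Structure, chain_id: Optional[str] = None):
    residues = structure.model.protein_residues(chain_id)
    keys, coords = [], []
    for i, r in enumerate(residues):
        a = r.atom("CA")
        if a is not None:
            keys.append(i)
            coords.append(a.pos)
    return keys, np.array(coords).reshape(-1, 3)


def superpose_homolog(query: Structure, homolog: Structure,
                      pairing: list[tuple[int, int]],
                      query_chain: Optional[str] = None,
                      homolog_chain: Optional[str] = None,
                      trim_sigma: Optional[float] = None,
                      ) -> Optional[tuple[Structure, dict[int, float]]]:
    """Fit the homolog onto the query over the paired Cα atoms.

    Returns (transformed homolog copy, {query residue index: |Δ| Å}),
    or None (with a warning) when fewer than 3 pairs exist.  With
    ``trim_sigma`` set, one refit round drops pairs deviating more than
    that many standard deviations."""
    qidx, qca = _ca_coords(query, query_chain)
    hidx, hca = _ca_coords(homolog, homolog_chain)
    qpos = {k: i for i, k in enumerate(qidx)}
    hpos = {k: i for i, k in enumerate(hidx)}
    usable = [(q, h) for q, h in pairing if q in qpos and h in hpos]
    if len(usable) < 3:
        logger.warning("homolog skipped: only %d aligned CA pairs", len(usable))
        return None
    P = qca[[qpos[q] for q, _ in usable]]
    Q = hca[[hpos[h] for _, h in usable]]
    R, t, _ = kabsch(P, Q)
    if trim_sigma is not None:
        dev = np.linalg.norm((Q @ R.T + t) - P, axis=1)
        keep = dev <= dev.mean() + trim_sigma * dev.std()
        if keep.sum() >= 3 and keep.sum() < len(usable):
            R, t, _ = kabsch(P[keep], Q[keep])
    moved = homolog.copy()
    for model in moved.models:
        for r in model.residues:
            for a in r.atoms:
                a.pos = R @ a.pos + t
    dev = np.linalg.norm((Q @ R.T + t) - P, axis=1)
    return moved, {q: float(d) for (q, _), d in zip(usable, dev)}


@dataclass
class DeviationProfile:
    mean_rmsd: np.ndarray      # Å per query residue
    n_pairs: np.ndarray        # homologs contributing per residue
    unaligned_max_rule: bool = True


def deviation_profile(query: Structure,
                      homolog_deviations: list[dict[int, float]],
                      query_chain: Optional[str] = None,
                      mean: str = "rms") -> DeviationProfile:
    """Per-residue deviation across homologs.

    ``rms`` (default): sqrt(mean of squared deviations) over the homologs
    aligned at that residue; ``arithmetic`` is available behind the
    switch.  Residues aligned in no homolog get the maximum observed
    value (rendered thick and white)."""
    if not homolog_deviations:
        raise ValueError("sausage requires homolog structures")
    n = len(query.model.protein_residues(query_chain))
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for devs in homolog_deviations:
        for i, d in devs.items():
            if 0 <= i < n:
                sums[i] += d ** 2 if mean == "rms" else d
                counts[i] += 1
    vals = np.zeros(n)
    mask = counts > 0
    if mean == "rms":
        vals[mask] = np.sqrt(sums[mask] / counts[mask])
    else:
        vals[mask] = sums[mask] / counts[mask]
    vmax = vals[mask].max() if mask.any() else 0.0
    vals[~mask] = vmax
    return DeviationProfile(vals, counts)


def sausage_radii(profile: DeviationProfile, r_min: float = 0.3,
                  r_max: float = 2.0, d_cap: float = 5.0) -> np.ndarray:
    """Linear, clamped mapping of mean deviation to tube radius:
    radius = r_min + (r_max − r_min) · min(d, d_cap)/d_cap."""
    if not r_min < r_max:
        raise ValueError("r_min must be < r_max")
    d = np.minimum(profile.mean_rmsd, d_cap)
    return r_min + (r_max - r_min) * d / d_cap


def write_deviation_tsv(profile: DeviationProfile, radii: np.ndarray,
                        stream=None) -> str:
    lines = ["index\tmean_rmsd\tn_pairs\tradius"]
    for i, (d, n, r) in enumerate(zip(profile.mean_rmsd, profile.n_pairs,
                                      radii)):
        lines.append(f"{i}\t{d:.3f}\t{n}\t{r:.3f}")
    text = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(text)
    return text
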