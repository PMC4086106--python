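"""Default configuration for every tunable threshold, in one place.

All values can be overridden from a YAML file (``load_config``) or with
CLI flags; module functions take them as keyword arguments with these
defaults.
"""

from __future__ import annotations

import copy
from typing import Any

import yaml

DEFAULTS: dict[str, Any] = {
    "sasa": {
        "probe": 1.4,           # Å, water-sized probe
        "points": 960,          # sphere points per atom
    },
    "acc": {
        "buried_max": 0.10,     # rel. accessibility below -> buried
        "intermediate_max": 0.40,
    },
    "hyd": {
        "window": 9,            # sliding-window length (odd)
        "hydrophobic_min": 0.5,
        "hydrophilic_max": -0.5,
    },
    "ss": {
        "fallback": "geometric",   # geometric | none
        "hbond_energy_cutoff": -0.5,  # kcal/mol
    },
    "contacts": {
        "cutoff": 5.0,          # Å, inclusive outer bound
        "close_max": 3.2,       # Å, strict upper bound of the "close" class
        "special_position_eps": 1.0,   # Å
        "shell": 1,             # symmetry expansion: layers of unit cells
    },
    "ligands": {
        # common hetero-compounds kept automatically; user-extensible
        "keep": [
            "HEM", "HEC", "NDP", "NAP", "NAD", "NAI", "FAD", "FMN",
            "ATP", "ADP", "AMP", "GTP", "GDP", "PLP", "SAM", "COA",
            "SF4", "FES", "ZN", "MG", "MN", "FE", "CA", "NA", "K",
            "CU", "CO", "NI", "MO", "CL",
        ],
    },
    "msa": {
        "similarity_threshold": 0.7,   # group fraction for "similar" columns
        "identity_weight": 0.7,        # w_id in the conservation score
        "top_n": 20,                   # homologs shown by default
        "max_mismatch": 0.05,          # query row vs chain sequence
    },
    "sausage": {
        "r_min": 0.3,           # Å tube radius at zero deviation
        "r_max": 2.0,           # Å tube radius at/above d_cap
        "d_cap": 5.0,           # Å deviation mapped to r_max
        "mean": "rms",          # rms | arithmetic
        "trim": False,          # one-round >3 sigma pair trimming
    },
    "render": {
        "residues_per_line": 60,
        "page": "A4",
        "dpi": 150,
        "palette": {
            "identical_box": "#e80000",
            "similar_box": "#ffe050",
            "blue_frame": "#1040c0",
            "orange_bg": "#ffa040",
            "light_yellow_bg": "#ffff90",
            "gray_star": "#808080",
            "acc_accessible": "#2060ff",
            "acc_intermediate": "#40d0e0",
            "acc_buried": "#ffffff",
            "hyd_hydrophobic": "#ff90c0",
            "hyd_neutral": "#ffffff",
            "hyd_hydrophilic": "#40d0e0",
            "close_contact": "#e80000",
            "far_contact": "#000000",
        },
    },
}


def default_config() -> dict[str, Any]:
    return copy.deepcopy(DEFAULTS)


def load_config(path=None, overrides: dict | None = None) -> dict[str, Any]:
    """Defaults, optionally updated from a YAML file and an override dict."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def _deep_update(base: dict, upd: dict) -> None:
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
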