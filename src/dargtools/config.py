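"""Flat, namespaced configuration for the pipeline.

The config file is a flat YAML mapping whose keys are dotted namespaces
(``voting.rg.k: 6``, ``null.n_perm: 10000``).  Defaults mirror the printed
analysis parameters: the radial-glia voting rule is 6 of 9 genes at a
normalized threshold of 1, astroglial progenitors 7 of 10 at 0.5, neural
progenitors 5 of 7 at 0.5, IFN-alpha/beta signaling 3 of 6 at 0.5, NOTCH1
signaling 13 of 16 in presence/absence mode; the permutation null uses
10,000 random gene sets; DARG-high gene-count gates are >6 (WM) and >4 (GM).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config", "config_hash", "signature_params"]

DEFAULTS: dict[str, object] = {
    "seed": 0,
    # core
    "normalize.scale_factor": 10_000.0,
    "normalize.log_base": 2.0,
    "filter.min_unique_genes": 100,
    # voting rules (k out of n genes at threshold theta)
    "voting.rg.k": 6,
    "voting.rg.theta": 1.0,
    "voting.rg.mode": "threshold",
    "voting.astro.k": 7,
    "voting.astro.theta": 0.5,
    "voting.astro.mode": "threshold",
    "voting.npc.k": 5,
    "voting.npc.theta": 0.5,
    "voting.npc.mode": "threshold",
    "voting.ifn.k": 3,
    "voting.ifn.theta": 0.5,
    "voting.ifn.mode": "threshold",
    "voting.notch1.k": 13,
    "voting.notch1.theta": 0.0,
    "voting.notch1.mode": "presence",
    # AUC scoring and permutation null
    "auc.top_fraction": 0.05,
    "null.n_perm": 10_000,
    "null.quantile": 0.95,
    # DARG-high calling
    "darg.wm_gene_threshold": 6,
    "darg.gm_gene_threshold": 4,
    "darg.vote_mode": "presence",
    # module matching
    "match.alpha": 0.05,
    "match.scaling": "ochiai",
    # statistics
    "stats.n_bins": 20,
    # simulation (cmd_simulate)
    "sim.grid_w": 60,
    "sim.grid_h": 60,
    "sim.n_genes": 10_000,
    "sim.n_rg_genes": 20,
    "sim.n_infl_genes": 20,
    "sim.log2_fold_change": 2.0,
    "sim.lc_radius": 8.0,
    "sim.lr_width": 5.0,
    "sim.plwm_width": 7.0,
    "sim.darg_rate.LC": 0.01,
    "sim.darg_rate.LR": 0.06,
    "sim.darg_rate.PLWM": 0.03,
    "sim.darg_rate.NAWM": 0.005,
    "sim.sample_id": "sim",
    "sim.group": "MS",
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge defaults, a config file and explicit overrides; unknown keys are
    rejected with the accepted key list in the error."""
    cfg = dict(DEFAULTS)
    supplied: dict[str, object] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        supplied.update(loaded)
    if overrides:
        supplied.update(overrides)
    unknown = sorted(set(supplied) - set(DEFAULTS))
    if unknown:
        raise ValueError(
            f"unknown config keys {unknown}; accepted keys: {sorted(DEFAULTS)}"
        )
    for key, value in supplied.items():
        default = DEFAULTS[key]
        if isinstance(default, bool):
            cfg[key] = bool(value)
        elif isinstance(default, int) and not isinstance(value, bool):
            cfg[key] = int(value)
        elif isinstance(default, float):
            cfg[key] = float(value)
        else:
            cfg[key] = value
    if cfg["null.n_perm"] < 1:
        raise ValueError("null.n_perm must be >= 1")
    if not (0.0 < cfg["null.quantile"] < 1.0):
        raise ValueError("null.quantile must lie in (0, 1)")
    if not (0.0 < cfg["auc.top_fraction"] <= 1.0):
        raise ValueError("auc.top_fraction must lie in (0, 1]")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def signature_params(cfg: dict) -> dict[str, dict]:
    """Extract per-signature voting parameters (voting.<name>.*) from a config."""
    out: dict[str, dict] = {}
    for key, value in cfg.items():
        parts = key.split(".")
        if len(parts) == 3 and parts[0] == "voting":
            out.setdefault(parts[1], {})[parts[2]] = value
    return out
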