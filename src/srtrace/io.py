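"""Trial-table I/O, run configuration, and report serialization.

One flat delimited-text trial format serves both synthetic and real-style
data: header ``subject,graphset,stage,trial,node,target,rt_ms,correct`` with
1-based node/target labels and RT in milliseconds.  Validation is strict and
line-numbered; malformed rows are rejected, never silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .graphs import N_NODES
from .rt_model import TRIAL_COLUMNS

log = logging.getLogger(__name__)


class TrialTableError(ValueError):
    pass


def read_trials(path: str | Path, n_nodes: int = N_NODES) -> pd.DataFrame:
    """Read and validate a trial table (CSV, or TSV by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"{path}: missing columns {missing}")
    # line numbers: header is line 1
    lines = df.index.to_numpy() + 2
    for col in ("trial", "node", "target"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = lines[vals.isna().to_numpy() | (vals.to_numpy() % 1 != 0)]
        if len(bad):
            raise TrialTableError(f"{path}: non-integer {col} at line {bad[0]}")
        df[col] = vals.astype(int)
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad = lines[rt.isna().to_numpy() | (rt.to_numpy() <= 0)]
    if len(bad):
        raise TrialTableError(f"{path}: non-positive or non-numeric rt_ms at line {bad[0]}")
    df["rt_ms"] = rt.astype(float)
    for col, hi in (("node", n_nodes), ("target", n_nodes)):
        v = df[col].to_numpy()
        bad = lines[(v < 1) | (v > hi)]
        if len(bad):
            raise TrialTableError(f"{path}: {col} outside 1..{hi} at line {bad[0]}")
    if df["correct"].dtype == object:
        df["correct"] = df["correct"].astype(str).str.lower().isin(("true", "1", "t", "yes"))
    df["correct"] = df["correct"].astype(bool)
    mono = df.groupby(["subject", "graphset", "stage"])["trial"].apply(
        lambda t: bool((t.diff().dropna() > 0).all()))
    if not mono.all():
        key = mono[~mono].index[0]
        raise TrialTableError(f"{path}: trial index not strictly increasing for {key}")
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def derive_seed(master_seed: int, label: str) -> int:
    """Deterministic component seed below 2^31 from a master seed and a stable label."""
    h = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    data: str = ""
    out_dir: str = "srtrace_out"
    models: list[str] = field(default_factory=lambda: ["baseline", "recency", "combined_sr_td"])
    seed: int = 0
    n_restarts: int = 2
    em_max_iter: int = 10
    run_signatures: bool = True
    run_cluster_analysis: bool = False
    include_targets: bool = True
    include_nuisance: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


def _round_floats(obj, sig: int = 10):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), sig)
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), sig)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_json(obj: dict, path: str | Path) -> None:
    """JSON with floats at 10 significant digits for stable regression output."""
    with open(path, "w") as fh:
        json.dump(_round_floats(obj), fh, indent=1, sort_keys=True)
        fh.write("\n")


def fit_result_record(result, model_id: str) -> dict:
    """JSON-serializable record of an EM fit."""
    group = result.group
    return {
        "model": model_id,
        "group_mean_unconstrained": dict(zip(group.names, group.group_mean)),
        "group_mean_natural": group.natural_means(),
        "stage_coef_unconstrained": dict(zip(group.names, group.stage_coef)),
        "em_iterations": result.n_iter,
        "em_converged": bool(result.converged),
        "subjects": [
            {
                "subject": f.subject,
                "graphset": f.graphset,
                "stage": f.stage,
                "params_natural": f.params_natural,
                "laplace_nlml": f.laplace_nlml,
                "converged": bool(f.converged),
            }
            for f in result.fits
        ],
    }
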