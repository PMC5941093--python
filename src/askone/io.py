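"""Cohort readers/writers, schema validation, and run manifests.

The on-disk cohort is a CSV with one row per child::

    child_id, age_months, sex, family_asd,
    m1..m20,                 # yes(1)/no(0) answers to the checklist items
    f1..f20,                 # follow-up confirmations (blank if not triggered)
    asq_<domain>_<1..6>,     # item scores in {0, 5, 10}
    text                     # the parental narrative (optional column)

Narratives may alternatively live in a separate CSV (``child_id,text``) or
JSON-lines file. Every stochastic command records its seed in a JSON run
manifest alongside config and file digests, so any artifact is reproducible
from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import math
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .instruments import (
    ASQ_DOMAINS,
    N_MCHAT_ITEMS,
    AsqCutoffs,
    InputValidationError,
    MChatKey,
    administer_interspersed,
    derive_outcomes,
    score_asq,
)
from .synthetic import SyntheticCohort

__all__ = [
    "COHORT_COLUMNS",
    "cohort_to_frame",
    "save_cohort",
    "load_cohort",
    "score_cohort_frame",
    "load_narratives",
    "write_manifest",
]

_M_COLS = [f"m{i + 1}" for i in range(N_MCHAT_ITEMS)]
_F_COLS = [f"f{i + 1}" for i in range(N_MCHAT_ITEMS)]
_ASQ_COLS = [f"asq_{dom}_{k + 1}" for dom in ASQ_DOMAINS for k in range(6)]

COHORT_COLUMNS = (
    ["child_id", "age_months", "sex", "family_asd"] + _M_COLS + _F_COLS + _ASQ_COLS
)


def cohort_to_frame(cohort: SyntheticCohort, include_text: bool = True) -> pd.DataFrame:
    """Flatten a synthetic cohort into the CSV schema (latent risk excluded)."""
    rows = []
    for c in cohort.children:
        row: dict = {
            "child_id": c.child_id,
            "age_months": c.age_months,
            "sex": c.sex,
            "family_asd": int(c.family_asd),
        }
        for i in range(N_MCHAT_ITEMS):
            row[f"m{i + 1}"] = int(c.answers_yes[i])
            row[f"f{i + 1}"] = (
                int(c.followup_confirmed[i]) if i in c.followup_confirmed else ""
            )
        for dom in ASQ_DOMAINS:
            for k in range(6):
                row[f"asq_{dom}_{k + 1}"] = int(c.asq_items[dom][k])
        if include_text:
            row["text"] = c.text
        rows.append(row)
    return pd.DataFrame(rows)


def save_cohort(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def _fail(row: int, col: str, msg: str):
    raise InputValidationError(f"row {row + 1}, column {col!r}: {msg}")


def load_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; errors name the offending row/column."""
    df = pd.read_csv(path, dtype={"child_id": str}, keep_default_na=True)
    extra_m = [c for c in df.columns if c.startswith("m") and c[1:].isdigit()]
    if sorted(extra_m) != sorted(_M_COLS):
        unexpected = sorted(set(extra_m) - set(_M_COLS))
        missing = sorted(set(_M_COLS) - set(extra_m))
        raise InputValidationError(
            f"checklist columns malformed: unexpected {unexpected}, missing {missing}"
        )
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise InputValidationError(f"missing required columns: {missing}")
    for r in range(len(df)):
        for col in _M_COLS:
            v = df.at[r, col]
            if pd.isna(v) or v not in (0, 1):
                _fail(r, col, f"binary answer required, got {v!r}")
        for i, col in enumerate(_F_COLS):
            v = df.at[r, col]
            if not (pd.isna(v) or v in (0, 1) or v == ""):
                _fail(r, col, f"blank or binary confirmation required, got {v!r}")
        for col in _ASQ_COLS:
            v = df.at[r, col]
            if pd.isna(v) or v not in (0, 5, 10):
                _fail(r, col, f"item score must be 0/5/10, got {v!r}")
        v = df.at[r, "family_asd"]
        if pd.isna(v) or v not in (0, 1):
            _fail(r, "family_asd", f"binary flag required, got {v!r}")
    return df


def _row_followup(row: pd.Series) -> dict[int, bool]:
    out = {}
    for i, col in enumerate(_F_COLS):
        v = row[col]
        if not (isinstance(v, float) and math.isnan(v)) and v != "":
            out[i] = bool(int(v))
    return out


def score_cohort_frame(
    df: pd.DataFrame,
    key: MChatKey | None = None,
    cutoffs: AsqCutoffs | None = None,
) -> pd.DataFrame:
    """Score every child: outcome labels plus the eight per-measure flags."""
    key = key or MChatKey.default()
    cutoffs = cutoffs or AsqCutoffs.default()
    rows = []
    for r in range(len(df)):
        row = df.iloc[r]
        responses = [int(row[c]) for c in _M_COLS]
        mchat = administer_interspersed(responses, key, _row_followup(row))
        items = {
            dom: tuple(int(row[f"asq_{dom}_{k + 1}"]) for k in range(6))
            for dom in ASQ_DOMAINS
        }
        asq = score_asq(items, cutoffs)
        out = {
            "child_id": row["child_id"],
            "family_asd": bool(int(row["family_asd"])),
            "mchat_initial_count": mchat.initial_count,
            "mchat_tier": mchat.tier,
            "mchat_final_score": mchat.final_score,
            "mchat_r_risk": mchat.tier in ("medium", "high"),
            "mchat_rf_risk": mchat.at_risk_rf,
            "asq_global_risk": asq.global_risk,
        }
        for dom in ASQ_DOMAINS:
            out[f"asq_{dom}_refer"] = asq.domain_class[dom] == "refer"
        out.update(derive_outcomes(mchat, asq))
        rows.append(out)
    return pd.DataFrame(rows)


def load_narratives(path) -> pd.DataFrame:
    """Narratives from CSV (child_id,text) or JSON lines ({child_id, text})."""
    path = Path(path)
    if path.suffix in (".jsonl", ".json"):
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(json.loads(line))
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, dtype={"child_id": str})
    if not {"child_id", "text"} <= set(df.columns):
        raise InputValidationError("narratives need 'child_id' and 'text' columns")
    return df[["child_id", "text"]]


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_path,
    command: str,
    seed: int | None,
    config: dict | None = None,
    inputs: list | None = None,
    outputs: list | None = None,
) -> dict:
    """Record command, seed, config hash and file digests as JSON."""
    manifest = {
        "command": command,
        "package_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config or {}, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "inputs": {str(p): _digest(p) for p in (inputs or [])},
        "outputs": {str(p): _digest(p) for p in (outputs or [])},
    }
    with open(out_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
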