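"""Readers, writers and provenance helpers for the CLI pipeline.

Conventions: aggregated 2x2 input is a CSV with columns
``stratum,a,b,c,d`` (``stratum`` optional, implying a single table); rows
are exposure (exposed first), columns outcome (case first).  Decimal
commas are accepted on read (published tables in some locales print
"0,7126"); all output uses decimal points.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .glm import SubjectData
from .tables import ContingencyTable2x2, EffectEstimate, StratifiedTables

__all__ = [
    "parse_number",
    "read_tables_csv",
    "read_subjects_csv",
    "table_to_subjects",
    "estimates_frame",
    "write_manifest",
    "load_config",
]


def parse_number(value) -> float:
    """Parse a number accepting both '.' and ',' as the decimal separator."""
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    s = str(value).strip()
    if "," in s and "." not in s:
        s = s.replace(",", ".")
    try:
        return float(s)
    except ValueError as exc:
        raise ValidationError(f"cannot parse number {value!r}") from exc


def read_tables_csv(path) -> StratifiedTables:
    """Read stratified (or single) 2x2 counts from CSV."""
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"a", "b", "c", "d"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    strata = []
    for i, row in df.iterrows():
        label = str(row["stratum"]) if "stratum" in df.columns else f"stratum{i}"
        try:
            cells = {k: int(parse_number(row[k])) for k in "abcd"}
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, line {i + 2}: {exc}") from exc
        strata.append((label, ContingencyTable2x2(**cells)))
    return StratifiedTables(strata)


def read_subjects_csv(path, outcome: str, exposure: str) -> SubjectData:
    """Read subject-level records; validates the declared binary columns."""
    df = pd.read_csv(path)
    for col in (outcome, exposure):
        if col not in df.columns:
            raise ValidationError(
                f"{path}: required column {col!r} not found "
                f"(columns: {list(df.columns)})")
    return SubjectData(df, outcome=outcome, exposure=exposure)


def table_to_subjects(table: ContingencyTable2x2,
                      outcome: str = "outcome",
                      exposure: str = "exposure") -> pd.DataFrame:
    """Expand a 2x2 table into one subject-level row per count.

    Exact: collapsing the result with the same orientation recovers the
    table, so GLMs can be fitted to aggregated data without approximation.
    """
    blocks = [(1, 1, table.a), (1, 0, table.b), (0, 1, table.c), (0, 0, table.d)]
    e = np.concatenate([np.full(n, ev, dtype=int) for ev, yv, n in blocks])
    y = np.concatenate([np.full(n, yv, dtype=int) for ev, yv, n in blocks])
    return pd.DataFrame({exposure: e, outcome: y})


def estimates_frame(estimates: Iterable[tuple[str, EffectEstimate]]) -> pd.DataFrame:
    """Tidy frame of labelled estimates (measure, point, se_log, CI, method)."""
    return pd.DataFrame([
        {"method": label, "measure": e.measure, "point": e.point,
         "se_log": e.se_log, "ci_low": e.ci_low, "ci_high": e.ci_high,
         "level": e.level}
        for label, e in estimates
    ])


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def write_manifest(outdir: Union[str, Path], config: dict) -> Path:
    """Write a provenance manifest (config + hash + versions) to outdir."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "versions": {
            "prevratio": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n",
                    encoding="utf-8")
    return path
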