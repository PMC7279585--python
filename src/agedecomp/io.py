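"""Bit-stable CSV serialization and run configuration.

All tables are written as UTF-8 CSV with '.' decimal separator, no
thousands separators, and counts serialized as integers where integral,
so identical inputs produce byte-identical outputs across runs.
"""
from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd
import yaml

from .core import ValidationError
from .simulate import PANEL_COLUMNS, validate_panel

__all__ = [
    "RunConfig",
    "write_table",
    "read_panel",
    "write_panel",
    "write_panel_inputs",
]


def _fmt(x) -> str:
    """Stable scalar formatting: integral floats as integers, else 12 s.f."""
    if isinstance(x, float):
        if x == int(x) and abs(x) < 1e15:
            return str(int(x))
        return format(x, ".12g")
    return str(x)


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a DataFrame as a deterministic CSV; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(_fmt)
    out.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")
    return path


def write_panel(panel: pd.DataFrame, path) -> Path:
    """Write a StratumPanel as tidy CSV (canonical column order)."""
    validate_panel(panel)
    return write_table(panel[PANEL_COLUMNS], path)


def read_panel(path) -> pd.DataFrame:
    """Read and validate a tidy StratumPanel CSV."""
    panel = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValidationError(f"panel file {path} missing columns {missing}")
    panel = panel[PANEL_COLUMNS]
    validate_panel(panel)
    return panel


def write_panel_inputs(panel: pd.DataFrame, outdir) -> dict:
    """Export a panel as the three ingest input CSVs.

    Returns a dict with paths for ``deaths``, ``population`` and
    ``income_map``.  The population table is deduplicated across causes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    deaths = panel[["location", "sex", "cause", "year", "age_group", "deaths"]]
    pop = panel.drop_duplicates(["location", "sex", "year", "age_group"])[
        ["location", "sex", "year", "age_group", "population"]
    ]
    imap = panel.drop_duplicates("location")[["location", "income_category"]]
    return {
        "deaths": write_table(deaths, outdir / "deaths.csv"),
        "population": write_table(pop, outdir / "population.csv"),
        "income_map": write_table(imap, outdir / "income_map.csv"),
    }


@dataclass
class RunConfig:
    """Flat run configuration shared by the CLI subcommands."""

    deaths: str | None = None
    population: str | None = None
    income_map: str | None = None
    baseline_year: int = 1990
    scale: float = 1.0
    percent_digits: int = 1
    seed: int = 0
    outdir: str = "out"

    def __post_init__(self):
        if self.percent_digits < 0:
            raise ValidationError("percent_digits must be >= 0")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a flat key-value YAML mapping."""
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**d)
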