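"""Readers, writers and run configuration.

All tables are comma-separated UTF-8 CSV with a mandatory header and ``.`` as
the decimal mark.  The long-format schema is
``participant_id,region,modality,value``; results are tidy CSVs that
round-trip numeric fields at full precision (repr-level floats).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datagen import DEFAULT_MODALITIES, RegionalTable
from .simulation import SimulationSummary, SubsampleSummary
from .strategies import CorrelationEstimate

__all__ = [
    "RunConfig",
    "read_regional_table",
    "write_regional_table",
    "write_results",
    "read_results",
    "write_manifest",
]

ESTIMATE_COLUMNS = ["method", "region", "estimate", "ci_low", "ci_high", "p", "n_units"]


@dataclass
class RunConfig:
    """Validated configuration of one simulation-study run."""

    scenario: str
    n: int
    reps: int
    seed: int
    strategies: tuple[str, ...] = ("1.1", "1.2", "2", "3")
    variance_structure: str = "by_modality"
    fixture: str | None = None
    out_dir: str | None = None
    verbosity: int = 0

    def __post_init__(self):
        from .simulation import STRATEGIES
        if self.n < 1 or self.reps < 1:
            raise ValueError("n and reps must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        bad = set(self.strategies) - set(STRATEGIES)
        if bad:
            raise ValueError(f"unknown strategies {sorted(bad)}")
        if self.variance_structure not in ("by_modality", "by_region_modality"):
            raise ValueError("variance_structure must be by_modality or by_region_modality")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_regional_table(path: str | Path,
                        modalities: tuple[str, ...] | None = DEFAULT_MODALITIES,
                        ) -> RegionalTable:
    """Read and validate a long-format regional CSV.

    Reports duplicated (participant, region, modality) cells, unknown
    modality labels (pass ``modalities=None`` to accept any) and unbalanced
    designs with explicit messages.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in RegionalTable.COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    non_numeric = pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()
    if non_numeric.any():
        rows = (df.index[non_numeric] + 2).tolist()[:5]  # header is line 1
        raise ValueError(f"{path}: non-numeric value(s) at line(s) {rows}")
    df["value"] = pd.to_numeric(df["value"])
    if df["value"].isna().any():
        rows = (df.index[df["value"].isna()] + 2).tolist()[:5]
        raise ValueError(f"{path}: missing value(s) at line(s) {rows}")
    try:
        return RegionalTable.from_frame(df, modalities=modalities)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_regional_table(table: RegionalTable, path: str | Path,
                         force: bool = False) -> Path:
    path = _check_target(path, force)
    table.to_frame().to_csv(path, index=False)
    return path


def _check_target(path: str | Path, force: bool) -> Path:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True (or --force) to overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    return path


def _estimates_frame(estimates: list[CorrelationEstimate]) -> pd.DataFrame:
    rows = [{
        "method": e.method, "region": e.region, "estimate": e.estimate,
        "ci_low": e.ci_low, "ci_high": e.ci_high, "p": e.p_value,
        "n_units": e.n_units,
    } for e in estimates]
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)


def write_results(results, path: str | Path, force: bool = False) -> Path:
    """Write estimates or simulation summaries as a tidy CSV.

    Accepts a list of :class:`CorrelationEstimate`, of
    :class:`SimulationSummary` or of :class:`SubsampleSummary`; an empty list
    produces a header-only estimates file.  Floats are written at full
    precision so a reload round-trips exactly.
    """
    path = _check_target(path, force)
    items = list(results)
    if not items:
        df = pd.DataFrame(columns=ESTIMATE_COLUMNS)
    elif isinstance(items[0], CorrelationEstimate):
        df = _estimates_frame(items)
    elif isinstance(items[0], (SimulationSummary, SubsampleSummary)):
        df = pd.DataFrame([dataclasses.asdict(s) for s in items])
    else:
        raise TypeError(f"cannot serialize results of type {type(items[0]).__name__}")
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), float_precision="round_trip")


def write_manifest(path: str | Path, config: RunConfig | dict,
                   fixture_path: str | Path | None = None,
                   force: bool = True, **extra) -> Path:
    """Emit a JSON run manifest: config, seed, fixture hash and versions —
    enough to reproduce the run bit-for-bit."""
    import scipy

    import mapcorr

    path = _check_target(path, force)
    cfg = config.to_dict() if isinstance(config, RunConfig) else dict(config)
    if fixture_path is not None:
        digest = hashlib.sha256(Path(fixture_path).read_bytes()).hexdigest()
    else:
        from importlib import resources
        ref = resources.files("mapcorr") / "fixtures" / "default.yaml"
        digest = hashlib.sha256(ref.read_bytes()).hexdigest()
    manifest = {
        "config": cfg,
        "fixture_sha256": digest,
        "versions": {
            "mapcorr": mapcorr.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        **extra,
    }
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
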