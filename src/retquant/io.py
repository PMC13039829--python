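"""File I/O helpers shared by the command-line pipelines.

All writers are deterministic: JSON is dumped with sorted keys and no
timestamps, CSV floats use a fixed general format, and TIFF stacks are
written without time metadata, so identical inputs reproduce byte-identical
outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

FLOAT_FORMAT = "%.10g"


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def write_json(obj: Any, path: str | Path) -> None:
    def default(o: Any):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(
        json.dumps(obj, sort_keys=True, indent=2, default=default) + "\n"
    )


def write_csv(df: pd.DataFrame, path: str | Path, *, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=FLOAT_FORMAT, lineterminator="\n")


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Multi-page TIFF, one page per channel/slice."""
    tifffile.imwrite(path, np.asarray(stack))


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def read_erg_trace_csv(path: str | Path):
    """Read one ERG trace: CSV with ``time_ms``/``voltage_uV`` columns and a
    YAML side-car (same stem, ``.yaml``) holding flash time, intensity,
    adaptation and group."""
    from .erg import ErgTrace

    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_ms", "voltage_uV"):
        if col not in df.columns:
            raise KeyError(f"missing column: {col!r}")
    meta_path = path.with_suffix(".yaml")
    meta = read_yaml(meta_path) if meta_path.exists() else {}
    return ErgTrace(
        time_ms=df["time_ms"].to_numpy(),
        voltage_uV=df["voltage_uV"].to_numpy(),
        flash_time_ms=float(meta.get("flash_time_ms", 0.0)),
        flash_intensity_log_photons_per_um2=float(meta.get("flash_intensity", np.nan)),
        adaptation=str(meta.get("adaptation", "dark")),
        group=str(meta.get("group", "")),
    )


def write_erg_trace_csv(trace, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_ms": trace.time_ms, "voltage_uV": trace.voltage_uV})
    write_csv(df, path)
    meta = {
        "flash_time_ms": float(trace.flash_time_ms),
        "flash_intensity": float(trace.flash_intensity_log_photons_per_um2),
        "adaptation": trace.adaptation,
        "group": trace.group,
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def read_count_matrix_tsv(path: str | Path, groups: Mapping[str, str]):
    """Proteins x samples TSV (first column protein ids) into a matrix."""
    from .prot.matrix import SpectralCountMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return SpectralCountMatrix(counts=df, groups=dict(groups), normalized=False)


def write_count_matrix_tsv(matrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, lineterminator="\n")
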