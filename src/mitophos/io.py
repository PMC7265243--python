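"""Table readers/writers, column mapping and run manifests.

All on-disk tables are UTF-8 TSV with Unix newlines; positions are 1-based.
A column-mapping configuration translates MaxQuant-style headers
("Localization prob", "Sequence window", "Reporter intensity corrected N",
"Reverse", "Potential contaminant") to the package's canonical column
names; boolean columns accept the MaxQuant "+"/"" convention.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .phospho import TMT6_CHANNELS, DataError, intensity_column

__all__ = [
    "MAXQUANT_COLUMN_MAP",
    "read_design_table",
    "read_protein_table",
    "read_site_table",
    "write_results",
    "write_table",
]

logger = logging.getLogger(__name__)


def _package_version() -> str:
    try:
        return version("mitophos")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


#: MaxQuant "Phospho (STY)Sites"-style headers -> canonical names.
MAXQUANT_COLUMN_MAP: dict[str, str] = {
    "Protein": "protein_id",
    "Position": "position",
    "Amino acid": "residue",
    "Localization prob": "localization_prob",
    "Sequence window": "sequence_window",
    "Reverse": "is_reverse",
    "Potential contaminant": "is_contaminant",
    **{
        f"Reporter intensity corrected {i}": intensity_column(ch)
        for i, ch in enumerate(TMT6_CHANNELS)
    },
}

SITE_REQUIRED = (
    "protein_id",
    "position",
    "residue",
    "localization_prob",
    "sequence_window",
    "is_contaminant",
    "is_reverse",
)
PROTEIN_REQUIRED = ("protein_id", "is_contaminant", "is_reverse")

_BOOL_COLUMNS = ("is_contaminant", "is_reverse")
_NUMERIC_SITE = ("position", "localization_prob")


def _coerce_bool(series: pd.Series) -> pd.Series:
    """Accept +/"" (MaxQuant) as well as True/False/1/0 spellings."""
    def conv(v) -> bool:
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return False
        s = str(v).strip()
        return s in {"+", "1", "True", "true"}
    return series.map(conv)


def _coerce_numeric(df: pd.DataFrame, columns: list[str], path: str | Path) -> None:
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        original_na = df[col].isna()
        bad = converted.isna() & ~original_na
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"{path}: malformed number in column {col!r} at data row {row}: "
                f"{df[col].iloc[row]!r}"
            )
        df[col] = converted


def _read_tsv(
    path: str | Path,
    required: tuple[str, ...],
    column_map: dict[str, str] | None,
    numeric: tuple[str, ...],
) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    intensity_cols = [c for c in df.columns if c.startswith("intensity_")]
    if not intensity_cols:
        raise DataError(f"{path}: no intensity_<channel> columns found")
    for col in _BOOL_COLUMNS:
        df[col] = _coerce_bool(df[col])
    _coerce_numeric(df, list(numeric) + intensity_cols, path)
    logger.info("read %d rows from %s", len(df), path)
    return df


def read_site_table(
    path: str | Path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a phospho-site table; extra columns are preserved but ignored.

    ``column_map`` translates foreign headers (e.g. MaxQuant's) to canonical
    names before validation; see :data:`MAXQUANT_COLUMN_MAP`.
    """
    df = _read_tsv(path, SITE_REQUIRED, column_map, _NUMERIC_SITE)
    if "site_id" not in df.columns:
        df["site_id"] = df["protein_id"].astype(str) + "_" + df["position"].astype(str)
    return df


def read_protein_table(
    path: str | Path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a protein-level quantitation table."""
    return _read_tsv(path, PROTEIN_REQUIRED, column_map, ())


def read_design_table(path: str | Path) -> pd.DataFrame:
    """Read a channel-design table (channel, group, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"channel": str})
    missing = [c for c in ("channel", "group", "replicate") if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV deterministically: fixed column order, 6 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a JSON-serialisable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Write named result tables plus a run manifest into ``out_dir``.

    The manifest records the package version, a hash of the run
    configuration and the seed, so any run is reproducible from the
    manifest alone.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        write_table(df, path)
        written.append(path)
    manifest = {
        "package": "mitophos",
        "version": _package_version(),
        "config": config or {},
        "config_hash": config_hash(config or {}),
        "seed": seed,
        "tables": [p.name for p in written],
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    written.append(manifest_path)
    return written
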