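"""Schema-checked CSV/TSV/YAML readers and writers.

All tables move through pandas; writers pin column order, float format and
line endings so identical inputs reproduce byte-identical files (the
end-to-end determinism contract of the pipeline).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .errors import SchemaError
from .profiles import DepthProfile

SPOT_COLUMNS = ["profile_id", "treatment", "timepoint_h", "depth_um",
                "delta_c13_permil"]
MEASUREMENT_COLUMNS = ["sample_id", "treatment", "timepoint_h",
                       "delta_c13_permil", "sd_permil", "n"]
ACIDWASH_COLUMNS = ["sample_id", "treatment", "timepoint_h", "delta_pre",
                    "delta_post"]
INTENSITY_COLUMNS = ["metabolite", "timepoint", "incubation", "replicate",
                     "mz_offset", "intensity"]

FLOAT_FORMAT = "%.10g"


def require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}; "
                          f"found {list(df.columns)}")


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a table with deterministic formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT,
              lineterminator="\n")
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
    return path


def read_spot_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    require_columns(df, SPOT_COLUMNS, path)
    return df


def spot_table_to_profiles(df: pd.DataFrame) -> list[DepthProfile]:
    """Group a spot table into per-profile :class:`DepthProfile` objects."""
    profiles = []
    for pid, grp in df.groupby("profile_id", sort=True):
        grp = grp.sort_values("depth_um")
        profiles.append(DepthProfile(
            profile_id=str(pid),
            depths_um=grp["depth_um"].to_numpy(),
            deltas=grp["delta_c13_permil"].to_numpy(),
            timepoint_h=float(grp["timepoint_h"].iloc[0]),
            treatment=str(grp["treatment"].iloc[0]),
        ))
    return profiles


def read_acidwash_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    require_columns(df, ACIDWASH_COLUMNS, path)
    return df


def read_intensity_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    require_columns(df, INTENSITY_COLUMNS, path)
    return df


def read_peptide_table(path) -> pd.DataFrame:
    from .proteomics import PEPTIDE_COLUMNS

    df = pd.read_csv(path)
    require_columns(df, PEPTIDE_COLUMNS, path)
    return df


def read_map_table(path, value_col: str) -> pd.DataFrame:
    """Read a two-column protein map (TSV or CSV by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    require_columns(df, ["protein_id", value_col], path)
    return df
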