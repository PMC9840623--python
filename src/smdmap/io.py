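"""Table and image I/O for the localization pipeline.

The localization-table dialect is delimited text with header
``frame,x_nm,y_nm,amplitude,background,sigma_x_nm,sigma_y_nm,pair_id``;
only frame and the coordinates are mandatory, unknown extra columns are
preserved on round-trip.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

REQUIRED_COLUMNS = ["frame", "x_nm", "y_nm"]
STANDARD_COLUMNS = ["frame", "x_nm", "y_nm", "amplitude", "background",
                    "sigma_x_nm", "sigma_y_nm", "pair_id"]


class SchemaError(ValueError):
    pass


def read_localizations(path, dialect: str = "csv") -> pd.DataFrame:
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    table = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"localization table missing required "
                          f"column(s): {', '.join(missing)}")
    table["frame"] = table["frame"].astype(int)
    return table


def write_localizations(table: pd.DataFrame, path, dialect: str = "csv") -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"localization table missing required "
                          f"column(s): {', '.join(missing)}")
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    # standard columns first, extras preserved after
    cols = [c for c in STANDARD_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, sep=sep, index=False)


def write_stack(stack: np.ndarray, path) -> None:
    """Write frames as multi-frame 16-bit grayscale TIFF."""
    data = np.clip(np.rint(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data)


def read_stack(path) -> np.ndarray:
    return tifffile.imread(path)


def write_map_tiff(array: np.ndarray, path) -> None:
    """Write a diffusivity or count map as 32-bit float TIFF (NaN = masked)."""
    tifffile.imwrite(path, np.asarray(array, np.float32))
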