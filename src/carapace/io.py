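"""TPS landmark file and specimen metadata I/O.

The TPS dialect accepted here is the one produced by the tpsDig family of
digitizers: records start with ``LM=n``, followed by ``n`` whitespace-
separated ``x y`` lines, then optional ``IMAGE=``, ``ID=``, ``SCALE=`` lines.
``CURVES=``/``POINTS=`` blocks are tolerated and ignored (semilandmark roles
come from the scheme registry, not from the file). Missing points may be
encoded as ``-999 -999`` or as non-numeric tokens (``NA NA``); they are
carried as a mask, never as sentinel coordinates, and written back out as
``-999 -999``.

Metadata is a delimited table with a header; unknown columns are tolerated,
and a user-supplied column-name mapping adapts foreign headers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schemes import LandmarkScheme

SEXES = ("M", "F", "unknown")
SUBSPECIES = ("bauri", "carolina", "major", "triunguis", "none")
ERAS = ("modern", "holocene", "pleistocene")

#: canonical metadata column names
METADATA_COLUMNS = [
    "specimen_id", "sex", "subspecies", "latitude", "longitude",
    "carapace_length", "mgr", "ossification", "era", "site",
]


class TpsParseError(ValueError):
    pass


class SchemaMismatchError(ValueError):
    pass


@dataclass
class LandmarkConfiguration:
    """One specimen in one view: ordered 2-D points plus a missing mask."""

    specimen_id: str
    view: str
    coords: np.ndarray  # (n_points, 2); masked entries are NaN
    scale: float | None = None
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    image: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(len(self.coords), dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if len(self.missing_mask) != len(self.coords):
            raise ValueError("missing_mask length mismatch")

    @property
    def n_points(self) -> int:
        return len(self.coords)

    def is_complete(self) -> bool:
        return not self.missing_mask.any()


_MISSING_SENTINEL = -999.0


def _is_missing_pair(tokens: list[str]) -> bool:
    try:
        x, y = float(tokens[0]), float(tokens[1])
    except ValueError:
        return True
    return x == _MISSING_SENTINEL and y == _MISSING_SENTINEL


def read_tps(path, scheme: LandmarkScheme | None = None) -> list[LandmarkConfiguration]:
    """Read a TPS file into a list of configurations, in record order.

    Coordinates are multiplied through by ``SCALE=`` when present. If a
    ``scheme`` is given, every record's point count is checked against it.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    configs: list[LandmarkConfiguration] = []
    i, n_lines = 0, len(lines)
    record_no = 0
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = re.match(r"(?i)^LM\s*=\s*(\d+)$", line)
        if m is None:
            raise TpsParseError(f"{path}: line {i + 1}: expected 'LM=n', got {line!r}")
        n_pts = int(m.group(1))
        record_no += 1
        i += 1
        coords = np.full((n_pts, 2), np.nan)
        mask = np.zeros(n_pts, dtype=bool)
        for k in range(n_pts):
            while i < n_lines and not lines[i].strip():
                i += 1
            if i >= n_lines:
                raise TpsParseError(f"{path}: record {record_no}: truncated coordinates")
            tokens = lines[i].split()
            if len(tokens) != 2:
                raise TpsParseError(f"{path}: line {i + 1}: malformed coordinate line")
            if _is_missing_pair(tokens):
                mask[k] = True
            else:
                try:
                    coords[k] = [float(tokens[0]), float(tokens[1])]
                except ValueError as exc:
                    raise TpsParseError(f"{path}: line {i + 1}: {exc}") from None
            i += 1
        # trailing key=value lines until the next LM=
        specimen_id, image, scale = f"record_{record_no}", None, None
        skip_curve_points = 0
        while i < n_lines:
            line = lines[i].strip()
            if re.match(r"(?i)^LM\s*=", line):
                break
            if not line:
                i += 1
                continue
            kv = re.match(r"(?i)^([A-Z]+)\s*=\s*(.*)$", line)
            if kv:
                key, value = kv.group(1).upper(), kv.group(2).strip()
                if key == "ID":
                    specimen_id = value
                elif key == "IMAGE":
                    image = value
                elif key == "SCALE":
                    try:
                        scale = float(value)
                    except ValueError:
                        raise TpsParseError(f"{path}: line {i + 1}: bad SCALE") from None
                elif key == "POINTS":
                    skip_curve_points = int(value)
                # CURVES= and any other keys: ignored
            else:
                if skip_curve_points > 0:
                    skip_curve_points -= 1
                else:
                    raise TpsParseError(f"{path}: line {i + 1}: unexpected line {line!r}")
            i += 1
        if scale is not None:
            coords = coords * scale
            coords[mask] = np.nan
        if scheme is not None and n_pts != scheme.n_points:
            raise SchemaMismatchError(
                f"{path}: record {record_no} (ID={specimen_id}) has {n_pts} points, "
                f"scheme {scheme.view!r} expects {scheme.n_points}"
            )
        view = scheme.view if scheme is not None else "unknown"
        configs.append(
            LandmarkConfiguration(
                specimen_id=specimen_id, view=view, coords=coords,
                scale=scale, missing_mask=mask, image=image,
            )
        )
    return configs


def write_tps(configs: list[LandmarkConfiguration], path) -> None:
    """Write configurations as TPS records (6-decimal coordinates)."""
    with open(path, "w") as fh:
        for cfg in configs:
            fh.write(f"LM={cfg.n_points}\n")
            for k in range(cfg.n_points):
                if cfg.missing_mask[k]:
                    fh.write("-999 -999\n")
                else:
                    fh.write(f"{cfg.coords[k, 0]:.6f} {cfg.coords[k, 1]:.6f}\n")
            if cfg.image:
                fh.write(f"IMAGE={cfg.image}\n")
            fh.write(f"ID={cfg.specimen_id}\n")


class MetadataValidationError(ValueError):
    pass


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Type and validate a metadata table in canonical column layout."""
    out = df.copy()
    if "specimen_id" not in out.columns:
        raise MetadataValidationError("metadata lacks a specimen_id column")
    out["specimen_id"] = out["specimen_id"].astype(str)
    bad_id = out["specimen_id"].isin(["", "nan", "None"])
    if bad_id.any():
        out = out[~bad_id]
    for col, default in [("sex", "unknown"), ("subspecies", "none"),
                         ("era", "modern"), ("site", "")]:
        if col not in out.columns:
            out[col] = default
        out[col] = out[col].fillna(default).astype(str)
    bad_sex = ~out["sex"].isin(SEXES)
    if bad_sex.any():
        raise MetadataValidationError(f"invalid sex values: {sorted(out.loc[bad_sex, 'sex'].unique())}")
    bad_ssp = ~out["subspecies"].isin(SUBSPECIES)
    if bad_ssp.any():
        raise MetadataValidationError(
            f"invalid subspecies values: {sorted(out.loc[bad_ssp, 'subspecies'].unique())}")
    bad_era = ~out["era"].isin(ERAS)
    if bad_era.any():
        raise MetadataValidationError(f"invalid era values: {sorted(out.loc[bad_era, 'era'].unique())}")
    for col in ("latitude", "longitude", "carapace_length", "mgr", "ossification"):
        if col not in out.columns:
            out[col] = np.nan
        out[col] = pd.to_numeric(out[col], errors="coerce")
    length = out["carapace_length"]
    bad_len = length.notna() & (length <= 0)
    if bad_len.any():
        raise MetadataValidationError(
            f"non-positive carapace_length in rows: {out.index[bad_len].tolist()}")
    oss = out["ossification"]
    bad_oss = oss.notna() & ~oss.isin([1, 2, 3, 4])
    if bad_oss.any():
        raise MetadataValidationError(
            f"ossification outside 1-4 in rows: {out.index[bad_oss].tolist()}")
    return out.reset_index(drop=True)


def read_metadata(path, column_map: dict[str, str] | None = None,
                  sep: str = ",") -> pd.DataFrame:
    """Read a delimited metadata table.

    ``column_map`` maps foreign header names to canonical ones (e.g.
    ``{"CL_mm": "carapace_length"}``); unknown columns are ignored but kept.
    """
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    return validate_metadata(df)


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
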