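"""Reading and writing landmark tables.

The canonical interchange format is a long CSV with one row per landmark:

    individual,biotype,lineage,site,dental_formula,session,side,landmark,x,y,z

(``z`` omitted for 2D data).  A column-mapping dict lets the reader absorb
differently named columns from externally produced tables.  A minimal TPS
reader (``LM=`` / ``ID=`` dialect) is provided for 2D fixtures.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .landmarks import Configuration, ConfigurationSet, LandmarkScheme, default_scheme, plain_scheme

__all__ = ["LONG_COLUMNS", "read_long_table", "write_long_table", "read_tps"]

LONG_COLUMNS = (
    "individual",
    "biotype",
    "lineage",
    "site",
    "dental_formula",
    "session",
    "side",
    "landmark",
    "x",
    "y",
    "z",
)

_REQUIRED = ("individual", "session", "side", "landmark", "x", "y")
_META_OPTIONAL = ("biotype", "lineage", "site", "dental_formula")


def _infer_scheme(n_points: int, dims: int) -> LandmarkScheme:
    if n_points == 33 and dims == 3:
        return default_scheme()
    return plain_scheme(n_points, dims)


def read_long_table(
    path,
    colmap: Mapping[str, str] | None = None,
    scheme: LandmarkScheme | None = None,
) -> ConfigurationSet:
    """Read a long-format coordinate table into a :class:`ConfigurationSet`.

    Parameters
    ----------
    path
        CSV file (or ``.xlsx``, read through openpyxl) with one row per
        (individual, side, session, landmark).
    colmap
        Optional mapping from canonical column names to the file's column
        names, e.g. ``{"individual": "SpecimenID"}``.
    scheme
        Landmark scheme; inferred when omitted (the 33-point 3D arch
        scheme for 33-point data, otherwise fixed landmarks only).

    Raises
    ------
    ValueError
        On duplicated (individual, side, session, landmark) rows,
        non-numeric coordinates, or landmark-count mismatch vs the scheme.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, float_precision="round_trip")
    if colmap:
        df = df.rename(columns={v: k for k, v in colmap.items()})

    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    has_z = "z" in df.columns and df["z"].notna().any()
    coord_cols = ["x", "y", "z"] if has_z else ["x", "y"]

    for col in coord_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            rownum = int(bad.idxmax()) + 2  # header + 1-based
        elif df[col].isna().any():
            rownum = int(df[col].isna().idxmax()) + 2
        else:
            df[col] = vals
            continue
        raise ValueError(f"non-numeric coordinate in column {col!r} at file row {rownum}")

    key_cols = ["individual", "side", "session", "landmark"]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        first = df.loc[dup, key_cols].iloc[0]
        raise ValueError(
            "duplicated landmark row for (individual={individual!r}, side={side!r}, "
            "session={session}, landmark={landmark})".format(**first.to_dict())
        )

    dims = len(coord_cols)
    n_points_seen = df.groupby(["individual", "side", "session"])["landmark"].size()
    if scheme is None:
        scheme = _infer_scheme(int(n_points_seen.mode().iloc[0]), dims)
    bad_counts = n_points_seen[n_points_seen != scheme.n_points]
    if not bad_counts.empty:
        key = bad_counts.index[0]
        raise ValueError(
            f"configuration (individual={key[0]!r}, side={key[1]!r}, session={key[2]}) "
            f"has {int(bad_counts.iloc[0])} landmarks, scheme expects {scheme.n_points}"
        )

    configs: list[Configuration] = []
    # canonical ordering: configurations sorted by key, rows by landmark index
    for (ind, side, session), grp in sorted(
        df.groupby(["individual", "side", "session"]), key=lambda kv: kv[0]
    ):
        grp = grp.sort_values("landmark")
        lm = grp["landmark"].to_numpy()
        if not np.array_equal(lm, np.arange(1, scheme.n_points + 1)):
            raise ValueError(
                f"configuration (individual={ind!r}, side={side!r}, session={session}) "
                f"landmark indices are not 1..{scheme.n_points}"
            )
        first = grp.iloc[0]

        def _meta(col):
            v = first[col] if col in grp.columns else None
            return None if v is None or (isinstance(v, float) and np.isnan(v)) or v == "" else str(v)

        configs.append(
            Configuration(
                coords=grp[coord_cols].to_numpy(dtype=float),
                individual=str(ind),
                side=str(side),
                replicate=int(session),
                biotype=_meta("biotype"),
                lineage=_meta("lineage"),
                site=_meta("site"),
                formula=_meta("dental_formula"),
            )
        )
    return ConfigurationSet(scheme, configs)


def write_long_table(cset: ConfigurationSet, path) -> None:
    """Write a :class:`ConfigurationSet` as the canonical long CSV.

    Full float precision (``repr`` round-trip); stable column order.
    """
    if len(cset) == 0:
        raise ValueError("refusing to write an empty configuration set")
    rows = []
    for c in sorted(cset.configs, key=lambda c: c.key):
        for j in range(c.n_points):
            row = {
                "individual": c.individual,
                "biotype": c.biotype,
                "lineage": c.lineage,
                "site": c.site,
                "dental_formula": c.formula,
                "session": c.replicate,
                "side": c.side,
                "landmark": j + 1,
                "x": repr(float(c.coords[j, 0])),
                "y": repr(float(c.coords[j, 1])),
            }
            if c.dims == 3:
                row["z"] = repr(float(c.coords[j, 2]))
            rows.append(row)
    cols = list(LONG_COLUMNS[:-1]) + (["z"] if cset.scheme.dims == 3 else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_tps(path) -> ConfigurationSet:
    """Read a TPS file (``LM=`` blocks with optional ``ID=`` lines).

    Returns 2D configurations; the scheme (fixed landmarks only) is
    inferred from the first block.  All blocks must share one LM count.
    """
    text = Path(path).read_text()
    configs: list[Configuration] = []
    n_points: int | None = None
    block_coords: list[list[float]] | None = None
    block_id: str | None = None
    n_blocks = 0

    def _flush():
        nonlocal block_coords, block_id, n_blocks
        if block_coords is None:
            return
        n_blocks += 1
        ident = block_id if block_id is not None else f"tps_{n_blocks}"
        configs.append(Configuration(coords=np.array(block_coords), individual=ident))
        block_coords, block_id = None, None

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            _flush()
            k = int(line.split("=", 1)[1])
            if n_points is None:
                n_points = k
            elif k != n_points:
                raise ValueError(f"inconsistent LM counts: expected {n_points}, got {k}")
            block_coords = []
        elif upper.startswith("ID="):
            block_id = line.split("=", 1)[1].strip()
        elif "=" in line and not line[0].isdigit() and not line[0] in "+-.":
            continue  # IMAGE=, SCALE= etc.
        else:
            if block_coords is None:
                raise ValueError("coordinate line outside an LM= block")
            parts = line.split()
            block_coords.append([float(parts[0]), float(parts[1])])
    _flush()
    if n_points is None:
        raise ValueError("no LM= blocks found")
    for c in configs:
        if c.n_points != n_points:
            raise ValueError(f"block {c.individual!r} has {c.n_points} points, expected {n_points}")
    return ConfigurationSet(plain_scheme(n_points, dims=2), configs)
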