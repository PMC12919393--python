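"""Domain types, delimited-file I/O and reference tables.

The in-memory container for a soil survey is a :class:`SoilDataset`, a thin
validated wrapper around a :class:`pandas.DataFrame` with one row per sample.
Concentrations are held in nine fixed element columns (mg kg^-1); the element
ordering is part of the package contract and is shared by every matrix-valued
stage (source apportionment, kriging, prediction).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

#: Fixed element ordering used for all matrix layouts (column index j).
ELEMENTS: tuple[str, ...] = ("Hg", "As", "Zn", "Pb", "Co", "Cd", "Ni", "Cr", "Cu")

#: Recognised land-use classes: coal mine, agricultural, residential,
#: forest, roadside.
LAND_USES: tuple[str, ...] = ("CM", "AG", "RD", "FT", "RS")

#: Mandatory non-element columns of the delimited sample table, in order.
SAMPLE_COLUMNS: tuple[str, ...] = (
    "sample_id", "land_use", "x", "y", "depth_class",
    "pH", "EC_uScm", "C_pct", "N_pct", "OM_pct", "CEC_cmolkg", "texture",
)

#: Continuous physicochemical covariates (used by the prediction stage).
COVARIATE_COLUMNS: tuple[str, ...] = ("pH", "EC_uScm", "C_pct", "N_pct", "OM_pct", "CEC_cmolkg")

_NUMERIC_COLUMNS = ("x", "y") + COVARIATE_COLUMNS


class SoilDataError(ValueError):
    """Raised when a sample table violates the documented schema."""


def _data_path(name: str):
    return importlib.resources.files("soilpte.data").joinpath(name)


@dataclass
class SoilDataset:
    """A validated sample-by-(covariate + element) table.

    Parameters
    ----------
    df:
        One row per sample with the documented columns.  Element columns are
        concentrations in mg kg^-1; optional ``<element>_below_mdl`` boolean
        columns flag censored values.
    mdl:
        Method detection limit per element, mg kg^-1.
    """

    df: pd.DataFrame
    mdl: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        validate_samples(self.df)
        for el, v in self.mdl.items():
            if el not in ELEMENTS:
                raise SoilDataError(f"MDL given for unknown element {el!r}")
            if v < 0:
                raise SoilDataError(f"negative MDL for {el}")

    # -- convenience accessors -------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def land_use(self) -> np.ndarray:
        return self.df["land_use"].to_numpy()

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) planar coordinates in metres."""
        return self.df[["x", "y"]].to_numpy(float)

    def concentrations(self) -> np.ndarray:
        """(n, 9) concentration matrix in the fixed element order."""
        return self.df[list(ELEMENTS)].to_numpy(float)

    def below_mdl(self) -> np.ndarray:
        """(n, 9) boolean censoring flags (all False when not recorded)."""
        out = np.zeros((self.n, len(ELEMENTS)), dtype=bool)
        for j, el in enumerate(ELEMENTS):
            col = f"{el}_below_mdl"
            if col in self.df.columns:
                out[:, j] = self.df[col].to_numpy(bool)
        return out

    def landuse_counts(self) -> dict[str, int]:
        return {lu: int((self.df["land_use"] == lu).sum()) for lu in LAND_USES}


def validate_samples(df: pd.DataFrame) -> None:
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    missing += [el for el in ELEMENTS if el not in df.columns]
    if missing:
        raise SoilDataError(f"missing mandatory column(s): {', '.join(missing)}")
    bad_lu = df.loc[~df["land_use"].isin(LAND_USES)]
    if len(bad_lu):
        row = bad_lu.index[0]
        raise SoilDataError(
            f"unknown land-use token {bad_lu['land_use'].iloc[0]!r} in row {row}"
        )
    for col in _NUMERIC_COLUMNS + ELEMENTS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() and not df[col].isna().any():
            row = int(vals.index[vals.isna()][0])
            raise SoilDataError(f"unparseable numeric value in column {col!r}, row {row}")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise SoilDataError(f"missing value in column {col!r}, row {row}")
    for el in ELEMENTS:
        vals = df[el].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise SoilDataError(f"non-finite concentration for {el}")
        if (vals < 0).any():
            row = int(np.flatnonzero(vals < 0)[0])
            raise SoilDataError(f"negative concentration for {el} in row {row}")


def read_samples(path: str | Path, sep: str = ",", mdl: Mapping[str, float] | None = None) -> SoilDataset:
    """Read a delimited sample table and validate it against the schema.

    Unparseable numeric cells raise :class:`SoilDataError` rather than
    propagating as silent NaNs.
    """
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "land_use": str,
                                           "depth_class": str, "texture": str})
    for el in ELEMENTS:
        col = f"{el}_below_mdl"
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return SoilDataset(df, dict(mdl) if mdl else {})


def write_samples(ds: SoilDataset, path: str | Path, sep: str = ",") -> None:
    """Write a dataset as delimited text readable by :func:`read_samples`.

    Numeric precision is 12 significant digits so a round trip preserves
    values far below the 1e-9 relative tolerance the contract promises.
    """
    ds.df.to_csv(path, sep=sep, index=False, float_format="%.12g")


@dataclass
class ReferenceTables:
    """Geochemical background values, toxic-response coefficients and
    soil-quality guidelines.

    ``background`` holds the local background value Bn (mg kg^-1) used by the
    contamination factor and the geo-accumulation index; ``toxic_response``
    holds the Hakanson toxic-response coefficient Tr per element.
    """

    background: dict[str, float]
    toxic_response: dict[str, float]
    guidelines: dict[str, dict[str, float]] = field(default_factory=dict)
    mdl: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            if el not in self.background:
                raise SoilDataError(f"background value missing for {el}")
            if self.background[el] <= 0:
                raise SoilDataError(f"non-positive background for {el}")
        for el, tr in self.toxic_response.items():
            if tr < 0:
                raise SoilDataError(f"negative toxic-response coefficient for {el}")


def load_reference_tables(path: str | Path | None = None,
                          merge_defaults: bool = True) -> ReferenceTables:
    """Load reference tables from YAML.

    By default the packaged tables supply any section or element the file
    does not override; with ``merge_defaults=False`` the file must be
    complete on its own (a missing element background is an error).
    """
    if merge_defaults:
        with _data_path("reference.yaml").open("r") as fh:
            base = yaml.safe_load(fh)
    else:
        if path is None:
            raise SoilDataError("merge_defaults=False requires a config path")
        base = {}
    if path is not None and not merge_defaults:
        with open(path) as fh:
            base = yaml.safe_load(fh) or {}
    elif path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section in ("background", "toxic_response", "mdl"):
            if section in user:
                merged = dict(base.get(section, {}))
                merged.update(user[section])
                base[section] = merged
        if "guidelines" in user:
            merged_g = dict(base.get("guidelines", {}))
            for name, table in user["guidelines"].items():
                row = dict(merged_g.get(name, {}))
                row.update(table)
                merged_g[name] = row
            base["guidelines"] = merged_g
    missing = [el for el in ELEMENTS if el not in base.get("background", {})]
    if missing:
        raise SoilDataError(f"background value missing for {', '.join(missing)}")
    return ReferenceTables(
        background={k: float(v) for k, v in base["background"].items()},
        toxic_response={k: float(v) for k, v in base.get("toxic_response", {}).items()},
        guidelines={n: {k: float(v) for k, v in t.items() if v is not None}
                    for n, t in base.get("guidelines", {}).items()},
        mdl={k: float(v) for k, v in base.get("mdl", {}).items()},
    )


def landuse_means(ds: SoilDataset) -> tuple[pd.DataFrame, pd.Series]:
    """Arithmetic mean concentration per land use, plus the study-area grand
    mean per element (mean over all samples; equal to the mean of land-use
    means under a balanced design).

    Returns
    -------
    (means, grand) where ``means`` is a land-use x element DataFrame and
    ``grand`` an element-indexed Series.
    """
    if ds.n == 0:
        raise SoilDataError("empty dataset")
    present = [lu for lu in LAND_USES if (ds.df["land_use"] == lu).any()]
    empties = [lu for lu in LAND_USES if lu not in present]
    if empties and len(present) < len(set(ds.df["land_use"]) | set(present)):
        pass  # unreachable; land uses validated at construction
    means = (
        ds.df.groupby("land_use", sort=False)[list(ELEMENTS)]
        .mean()
        .reindex(present)
    )
    grand = ds.df[list(ELEMENTS)].mean()
    return means, grand


def load_landuse_mean_table(path: str | Path | None = None) -> pd.DataFrame:
    """Land-use x element table of mean concentrations (mg kg^-1).

    Without ``path`` this returns the packaged study-design table used by the
    worked examples and the reproduction script.
    """
    src = path if path is not None else _data_path("landuse_mean_concentrations.csv")
    with importlib.resources.as_file(src) if path is None else _noop(src) as p:
        df = pd.read_csv(p, index_col=0)
    missing = [el for el in ELEMENTS if el not in df.columns]
    if missing:
        raise SoilDataError(f"mean table missing element(s): {', '.join(missing)}")
    return df[list(ELEMENTS)].astype(float)


class _noop:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False
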