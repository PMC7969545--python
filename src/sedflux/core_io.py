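"""Data model, validation and delimited-text I/O for sediment-core tables.

A core table is one CSV row per stratigraphic layer, depths in cm below the
sediment-water interface, with dry-mass information (bulk density and/or
areal dry mass), total :sup:`210`Pb and :sup:`226`Ra activities (Bq kg⁻¹) and
element concentrations (μg g⁻¹ dry sediment).  Units are fixed at this
boundary and never change inside the pipeline:

* concentrations: μg g⁻¹ dry sediment
* activities: Bq kg⁻¹
* areal dry mass: g cm⁻²
* mass accumulation rate (MAR): g m⁻² yr⁻¹
* fluxes: μg m⁻² yr⁻¹ (display-side conversion to mg m⁻² yr⁻¹ only)

Missing values are encoded as empty cells (NaN), never as 0 or sentinel
numbers: zero is a legal concentration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: Trace elements the pipeline knows about (concentration columns ``<el>_ug_g``).
ELEMENTS = ("V", "Cr", "Co", "Ni", "Cu", "Zn", "As", "Cd", "Pb", "Hg")

#: Organic-matter indicator columns, percent dry mass.
CNS_COLUMNS = {"C": "c_pct", "N": "n_pct", "S": "s_pct"}

MANDATORY_COLUMNS = ("depth_top_cm", "depth_bottom_cm")

OPTIONAL_COLUMNS = (
    "layer_id",
    "dbd_g_cm3",
    "dry_mass_g_cm2",
    "pb210_bq_kg",
    "pb210_sd",
    "ra226_bq_kg",
    "ra226_sd",
    "event_layer",
    "c_pct",
    "n_pct",
    "s_pct",
)


class SchemaError(ValueError):
    """A mandatory column could not be resolved in an input table."""


class ProfileError(ValueError):
    """A core profile violates a structural invariant."""


def element_column(element: str) -> str:
    """Canonical concentration column name for an element symbol."""
    return f"{element.lower()}_ug_g"


def lod_column(element: str) -> str:
    """Below-detection-limit flag column name for an element symbol."""
    return f"{element.lower()}_below_lod"


@dataclass(frozen=True)
class Finding:
    """One validation finding; findings are data, not exceptions."""

    level: str  # "error" or "warning"
    code: str
    message: str
    layer_ids: tuple[int, ...] = ()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f" (layers {list(self.layer_ids)})" if self.layer_ids else ""
        return f"[{self.level}] {self.code}: {self.message}{where}"


@dataclass
class LakeMetadata:
    """Static metadata of a study lake.

    Areas keep their customary field units (lake area in hectares, catchment
    in km²); :attr:`catchment_lake_ratio` reconciles them.
    """

    name: str
    coring_year: int
    elevation_m: float
    lake_area_ha: float
    catchment_area_km2: float
    notes: str = ""

    def __post_init__(self) -> None:
        if self.lake_area_ha <= 0:
            raise ValueError("lake_area_ha must be > 0")
        if self.catchment_area_km2 <= 0:
            raise ValueError("catchment_area_km2 must be > 0")
        if not 1900 <= self.coring_year <= 2100:
            raise ValueError("coring_year out of plausible range [1900, 2100]")

    @property
    def catchment_lake_ratio(self) -> float:
        """Dimensionless catchment-area / lake-area ratio (1 km² = 100 ha)."""
        return self.catchment_area_km2 * 100.0 / self.lake_area_ha


@dataclass
class CoreProfile:
    """Ordered per-layer record of a sediment core.

    Wraps a :class:`pandas.DataFrame` with the canonical column names listed
    in the module docstring.  Layers are half-open depth intervals
    ``[depth_top_cm, depth_bottom_cm)``; the layer midpoint is used wherever
    a single depth per layer is needed.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing mandatory column '{col}'")
        df = df.sort_values("depth_top_cm", kind="stable").reset_index(drop=True)
        if "layer_id" not in df.columns:
            df["layer_id"] = np.arange(len(df), dtype=int)
        df["layer_id"] = df["layer_id"].astype(int)
        if "event_layer" in df.columns:
            df["event_layer"] = df["event_layer"].fillna(False).astype(bool)
        else:
            df["event_layer"] = False
        self.data = df

    # -- basic geometry -------------------------------------------------

    @property
    def n_layers(self) -> int:
        return len(self.data)

    @property
    def layer_ids(self) -> np.ndarray:
        return self.data["layer_id"].to_numpy()

    @property
    def depth_top(self) -> np.ndarray:
        return self.data["depth_top_cm"].to_numpy(float)

    @property
    def depth_bottom(self) -> np.ndarray:
        return self.data["depth_bottom_cm"].to_numpy(float)

    @property
    def depth_mid(self) -> np.ndarray:
        return 0.5 * (self.depth_top + self.depth_bottom)

    @property
    def thickness(self) -> np.ndarray:
        return self.depth_bottom - self.depth_top

    def layer_mass(self) -> np.ndarray:
        """Areal dry mass per layer (g cm⁻²).

        Prefers an explicit ``dry_mass_g_cm2`` column; falls back to
        dry bulk density × thickness.  NaN where neither is available.
        """
        mass = np.full(self.n_layers, np.nan)
        if "dry_mass_g_cm2" in self.data.columns:
            mass = self.data["dry_mass_g_cm2"].to_numpy(float)
        if "dbd_g_cm3" in self.data.columns:
            fallback = self.data["dbd_g_cm3"].to_numpy(float) * self.thickness
            mass = np.where(np.isnan(mass), fallback, mass)
        return mass

    # -- chemistry ------------------------------------------------------

    @property
    def elements(self) -> tuple[str, ...]:
        """Elements with a concentration column present, in canonical order."""
        return tuple(el for el in ELEMENTS if element_column(el) in self.data.columns)

    def concentration(self, element: str) -> np.ndarray:
        col = element_column(element)
        if col not in self.data.columns:
            raise KeyError(f"no concentration column for element '{element}'")
        return self.data[col].to_numpy(float)

    def cns(self, which: str) -> np.ndarray:
        col = CNS_COLUMNS[which]
        if col not in self.data.columns:
            raise KeyError(f"no column for '{which}' ({col})")
        return self.data[col].to_numpy(float)

    def copy(self) -> "CoreProfile":
        return CoreProfile(self.data.copy())


@dataclass
class ThresholdTable:
    """Per-element sediment-quality thresholds (μg g⁻¹): LEL, ERL, TAS.

    LEL = low effect level, ERL = effect range-low (sediment quality
    guidelines); TAS = threshold for agricultural soils.  Any value may be
    missing for an element; a missing threshold yields a missing lookup,
    never zero.
    """

    data: pd.DataFrame  # index: element symbol; columns: lel, erl, tas

    KINDS = ("lel", "erl", "tas")

    def __post_init__(self) -> None:
        df = self.data.copy()
        for kind in self.KINDS:
            if kind not in df.columns:
                df[kind] = np.nan
            df[kind] = pd.to_numeric(df[kind], errors="coerce")
        neg = df[list(self.KINDS)].lt(0).any(axis=1)
        if neg.any():
            raise ValueError(
                f"negative thresholds for elements {list(df.index[neg])}"
            )
        self.data = df

    def lookup(self, element: str, kind: str) -> float:
        """Threshold value, or NaN when the element/kind is not tabulated."""
        kind = kind.lower()
        if kind not in self.KINDS:
            raise KeyError(f"unknown threshold kind '{kind}'")
        if element not in self.data.index:
            return float("nan")
        return float(self.data.loc[element, kind])

    def findings(self) -> list[Finding]:
        """Consistency findings; LEL > ERL is reported as a warning because
        the shipped defaults deliberately preserve the published Hg values
        (LEL 0.2 above ERL 0.15)."""
        out: list[Finding] = []
        both = self.data.dropna(subset=["lel", "erl"])
        odd = both[both["lel"] > both["erl"]]
        for el, row in odd.iterrows():
            out.append(
                Finding(
                    "warning",
                    "lel-above-erl",
                    f"{el}: LEL {row['lel']} exceeds ERL {row['erl']} "
                    "(documented guideline inconsistency)",
                )
            )
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_core_table(path: str | Path, schema: dict[str, str] | None = None) -> CoreProfile:
    """Read a delimited core table into a validated :class:`CoreProfile`.

    Parameters
    ----------
    path:
        CSV file, one row per layer.
    schema:
        Optional mapping of file column names to canonical names, e.g.
        ``{"Depth top": "depth_top_cm"}``.

    Raises
    ------
    SchemaError
        when a mandatory column cannot be resolved.
    ProfileError
        when the table violates a structural invariant (non-monotone or
        overlapping depths, negative measured values, no dry-mass data).
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=schema)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column '{col}' in {path}")
    profile = CoreProfile(df)
    errors = [f for f in validate_profile(profile) if f.level == "error"]
    if errors:
        raise ProfileError("; ".join(str(f) for f in errors))
    return profile


def write_core_table(profile: CoreProfile, path: str | Path) -> None:
    """Write a profile back to CSV (round-trips all text-representable fields)."""
    profile.data.to_csv(path, index=False)


def read_thresholds(path: str | Path | None = None) -> ThresholdTable:
    """Load a threshold table; with no path, the shipped default.

    The shipped defaults reproduce the published guideline columns exactly
    (e.g. As: LEL 6, ERL 33, TAS 5; Hg: LEL 0.2, ERL 0.15, TAS 0.5).
    """
    if path is None:
        with resources.files("sedflux.data").joinpath("sqg_thresholds.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    if "element" not in df.columns:
        raise SchemaError("threshold table needs an 'element' column")
    df = df.set_index("element")
    return ThresholdTable(df)


def read_config(path: str | Path) -> dict:
    """Read a YAML run configuration (lake metadata, cutoff/split years, seeds)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_profile(profile: CoreProfile) -> list[Finding]:
    """Validate a profile, returning findings; never mutates the input.

    Errors are invariant violations (bad geometry, negative measured values,
    missing dry-mass information).  Warnings flag data that downstream
    stages must treat specially (below-LOD values, missing radionuclides).
    """
    df = profile.data
    findings: list[Finding] = []

    top = profile.depth_top
    bottom = profile.depth_bottom
    ids = profile.layer_ids

    bad_interval = np.flatnonzero(~(top < bottom))
    if bad_interval.size:
        findings.append(
            Finding(
                "error",
                "bad-interval",
                "depth_top_cm must be < depth_bottom_cm",
                tuple(int(i) for i in ids[bad_interval]),
            )
        )
    if profile.n_layers > 1:
        overlap = np.flatnonzero(top[1:] < bottom[:-1] - 1e-9)
        if overlap.size:
            findings.append(
                Finding(
                    "error",
                    "overlapping-layers",
                    "layers overlap or are out of order",
                    tuple(int(i) for i in ids[overlap + 1]),
                )
            )

    numeric_cols = [
        c
        for c in df.columns
        if c.endswith("_ug_g")
        or c in ("pb210_bq_kg", "ra226_bq_kg", "pb210_sd", "ra226_sd",
                 "dbd_g_cm3", "dry_mass_g_cm2", "c_pct", "n_pct", "s_pct")
    ]
    for col in numeric_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        neg = np.flatnonzero(vals.to_numpy(float) < 0)
        if neg.size:
            findings.append(
                Finding(
                    "error",
                    "negative-value",
                    f"negative values in column '{col}'",
                    tuple(int(i) for i in ids[neg]),
                )
            )

    mass = profile.layer_mass()
    no_mass = np.flatnonzero(np.isnan(mass))
    if no_mass.size:
        findings.append(
            Finding(
                "error",
                "no-dry-mass",
                "neither dry_mass_g_cm2 nor dbd_g_cm3 available",
                tuple(int(i) for i in ids[no_mass]),
            )
        )

    if "pb210_bq_kg" not in df.columns or df["pb210_bq_kg"].isna().all():
        findings.append(
            Finding("warning", "no-pb210", "no total 210Pb activities; core cannot be dated")
        )
    if "ra226_bq_kg" not in df.columns or df["ra226_bq_kg"].isna().all():
        findings.append(
            Finding(
                "warning",
                "no-ra226",
                "no 226Ra activities; supported 210Pb must come from the "
                "deep-asymptote method",
            )
        )

    for el in profile.elements:
        col = lod_column(el)
        if col in df.columns and df[col].fillna(False).astype(bool).any():
            flagged = np.flatnonzero(df[col].fillna(False).astype(bool).to_numpy())
            findings.append(
                Finding(
                    "warning",
                    "below-lod",
                    f"{el} concentrations below detection limit",
                    tuple(int(i) for i in ids[flagged]),
                )
            )

    return findings
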