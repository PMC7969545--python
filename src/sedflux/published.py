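"""Published study values shipped as data: lake metadata and the printed
period-summary tables for the two Ecuadorian study lakes.

These tables hold the published pre-/post-1950 mean concentrations
(μg g⁻¹) and fluxes (mg m⁻² yr⁻¹), the post/pre Factor and the Recent
values (mean of the two topmost samples) per element, as printed.  They
are inputs for desk-reproducible worked examples (threshold exceedance
factors, between-lake ratios, Factor recomputation); the per-layer raw
data behind them are archived externally and are not required here.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core_io import LakeMetadata

#: Remote high-elevation Páramo lake.
FONDOCOCHA = LakeMetadata(
    name="Fondococha",
    coring_year=2014,
    elevation_m=4130.0,
    lake_area_ha=3.4,
    catchment_area_km2=0.6,
    notes="remote, oligotrophic, above the cloud-condensation level",
)

#: Peri-urban lake in the montane forest belt near the city.
LLAVIUCU = LakeMetadata(
    name="Llaviucu",
    coring_year=2014,
    elevation_m=3140.0,
    lake_area_ha=18.9,
    catchment_area_km2=47.7,
    notes="peri-urban, mesotrophic, below the cloud-condensation level; "
    "caged fishery 1978-1998",
)


def _load(name: str) -> pd.DataFrame:
    with resources.files("sedflux.data").joinpath(name).open() as fh:
        return pd.read_csv(fh).set_index("element")


def published_summary(lake: str) -> pd.DataFrame:
    """Printed period-summary table for ``fondococha`` or ``llaviucu``.

    Columns: conc_pre1950, conc_post1950, conc_factor, conc_recent,
    flux_pre1950, flux_post1950, flux_factor, flux_recent (fluxes in
    mg m⁻² yr⁻¹, display convention; the C row's fluxes are in
    g m⁻² yr⁻¹ after the printed ×1000 footnote is undone).
    """
    key = lake.strip().lower()
    if key not in ("fondococha", "llaviucu"):
        raise KeyError(f"unknown lake '{lake}'")
    return _load(f"{key}_summary.csv")
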