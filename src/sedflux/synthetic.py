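"""Forward simulator for sediment cores with known ground truth.

The simulator inverts the analysis chain: it lays down annual deposition
slabs with a prescribed mass-accumulation-rate (MAR) history, a constant
atmospheric supply of unsupported ²¹⁰Pb, and per-element concentrations
built from a background level plus an atmospheric flux component, then
discretizes the slab pile into layers of fixed thickness exactly as a
core slicer would.  Because the construction mirrors the apportionment
algebra (``C(t) = C_B + F_A(t)/MAR(t)``), the true background, erosion and
atmospheric flux components are known per layer and conserve exactly:
``F_B + F_V + F_A = F_tot`` before noise.

Unsupported ²¹⁰Pb of matter deposited at age ``t`` follows

    A(t) = 1000 · P / MAR(t) · exp(−λ t)     [Bq kg⁻¹]

with supply rate ``P`` (Bq m⁻² yr⁻¹); slab inventories are the exact
integrals of this expression, so the whole-core inventory converges to
``P/λ`` independent of the MAR history.

Two presets encode contrasting lake archetypes: ``remote-highland`` (low
MAR, post-1950 MAR doubling, Hg with a large atmospheric share, a few
elements with a slight post-1950 catchment depletion) and ``peri-urban``
(≈5× higher MAR, strong post-1950 atmospheric pulses for Pb/As/Hg and
occasional instantaneous flood layers at background composition).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from .chronology import PB210_LAMBDA
from .core_io import CoreProfile, element_column

#: Excess-210Pb concentration of event-layer material relative to ambient
#: freshly deposited matter (partial scavenging from the water column).
EVENT_PB_FRACTION = 0.2


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class ElementSpec:
    """Per-element generating parameters.

    ``atm_share_post`` is the target time-integrated share of the
    atmospheric component in the post-split total flux (fraction of 1; may
    be negative to emulate a catchment depleted in the element, which the
    apportionment then reports as negative F_A).  ``noise_cv`` is the
    coefficient of variation of multiplicative lognormal measurement
    noise, defaulting into the 7–16% replicate-RSD range typical of
    ICP-MS sediment digests.
    """

    background: float  # μg g⁻¹
    atm_share_post: float = 0.0
    noise_cv: float = 0.10


#: Normalized post-1950 atmospheric pulse shape (year, relative magnitude).
DEFAULT_PULSE_SHAPE = (
    (1950.0, 0.0),
    (1965.0, 0.8),
    (1975.0, 1.0),
    (1990.0, 0.55),
    (2000.0, 0.7),
    (2014.0, 0.9),
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete specification of a synthetic core."""

    name: str
    coring_year: int = 2014
    span_years: int = 260
    layer_thickness_cm: float = 0.5
    dry_bulk_density: float = 0.175  # g cm⁻³ at the surface
    dbd_gradient: float = 0.0  # g cm⁻³ per cm depth (compaction ramp)
    pb210_supply: float = 150.0  # Bq m⁻² yr⁻¹
    supported: float = 25.0  # Bq kg⁻¹
    mar_control_points: tuple[tuple[float, float], ...] = (
        (1754.0, 69.0),
        (1950.0, 69.0),
        (1951.0, 138.0),
        (1970.0, 138.0),
        (1985.0, 152.0),
        (1992.0, 100.0),
        (2014.0, 125.0),
    )
    elements: dict[str, ElementSpec] = field(default_factory=dict)
    pulse_shape: tuple[tuple[float, float], ...] = DEFAULT_PULSE_SHAPE
    event_layers: tuple[tuple[float, float], ...] = ()  # (year, thickness multiplier)
    split_year: float = 1950.0
    cutoff_year: float = 1900.0
    organic_base_pct: float = 8.0
    organic_pulse_gain_pct: float = 3.0
    pb_noise_cv: float = 0.05
    ra_noise_cv: float = 0.05
    apply_noise: bool = True

    def noise_free(self) -> "ScenarioConfig":
        return replace(self, apply_noise=False)

    def with_thickness(self, thickness_cm: float) -> "ScenarioConfig":
        return replace(self, layer_thickness_cm=thickness_cm)


@dataclass
class SyntheticTruth:
    """Ground truth recorded while generating a core.

    ``layers``: layer_id, year_true, mar_true (apparent, g m⁻² yr⁻¹),
    duration_yr, event_mass_frac.  ``components``: tidy per-element truth
    fluxes f_tot/f_b/f_v/f_a (μg m⁻² yr⁻¹, pre-noise).  ``mar_ref_true`` is
    the mean true MAR of non-event layers older than the scenario cutoff.
    """

    layers: pd.DataFrame
    components: pd.DataFrame
    supply: float
    supported: float
    mar_ref_true: float
    background: dict[str, float]

    def export(self, path) -> None:
        merged = self.components.merge(self.layers, on="layer_id")
        merged.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def simulate_mar_history(scenario: ScenarioConfig) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear MAR(t) on an annual calendar grid (oldest first)."""
    pts = np.asarray(scenario.mar_control_points, float)
    if (pts[:, 1] <= 0).any():
        raise ScenarioError("MAR control points must be strictly positive")
    years = np.arange(
        scenario.coring_year - scenario.span_years + 1, scenario.coring_year + 1, 1.0
    )
    if pts[0, 0] > years[0] or pts[-1, 0] < years[-1]:
        raise ScenarioError("MAR control points must cover the simulated span")
    mar = np.interp(years, pts[:, 0], pts[:, 1])
    return years, mar


def pulse_profile(scenario: ScenarioConfig, years: np.ndarray) -> np.ndarray:
    """Normalized atmospheric pulse shape evaluated on the year grid."""
    pts = np.asarray(scenario.pulse_shape, float)
    shape = np.interp(years, pts[:, 0], pts[:, 1], left=0.0, right=pts[-1, 1])
    shape[years < pts[0, 0]] = 0.0
    return shape


def simulate_atmospheric_flux(
    scenario: ScenarioConfig, years: np.ndarray, mar: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-element atmospheric flux series F_A(t) (μg m⁻² yr⁻¹).

    The pulse shape is scaled so the time-integrated post-split share of
    F_A in F_tot equals the element's target: with ``s`` the share and
    F_tot = C_B·MAR + F_A, ``ΣF_A = s/(1−s) · ΣC_B·MAR`` over post-split
    years.
    """
    shape = pulse_profile(scenario, years)
    post = years >= scenario.split_year
    out: dict[str, np.ndarray] = {}
    for el, spec in scenario.elements.items():
        s = spec.atm_share_post
        if s == 0.0 or not shape[post].sum() > 0:
            out[el] = np.zeros_like(years)
            continue
        if not -1.0 < s < 1.0:
            raise ScenarioError(f"{el}: atmospheric share must be in (−1, 1)")
        total_background = float(np.sum(spec.background * mar[post]))
        scale = (s / (1.0 - s)) * total_background / float(np.sum(shape[post]))
        out[el] = scale * shape
    return out


def simulate_concentrations(
    scenario: ScenarioConfig, years: np.ndarray, mar: np.ndarray
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Pre-noise annual concentration series C(t) = C_B + F_A(t)/MAR(t).

    Returns (concentrations, atmospheric fluxes); concentrations are
    clipped at zero (a strongly negative depletion cannot drive a
    concentration below zero).
    """
    f_a = simulate_atmospheric_flux(scenario, years, mar)
    conc = {
        el: np.clip(spec.background + f_a[el] / mar, 0.0, None)
        for el, spec in scenario.elements.items()
    }
    return conc, f_a


def unsupported_activity(
    supply: float, mar: float | np.ndarray, age: float | np.ndarray,
    decay_constant: float = PB210_LAMBDA,
) -> float | np.ndarray:
    """Closed-form unsupported ²¹⁰Pb activity A(t) = 1000·P/MAR·e^(−λt)."""
    return 1000.0 * supply / mar * np.exp(-decay_constant * age)


def simulate_pb210(
    scenario: ScenarioConfig, years: np.ndarray, mar: np.ndarray
) -> pd.DataFrame:
    """Annual slab table with exact unsupported-²¹⁰Pb inventories.

    Slab ``j`` holds material of ages ``[j, j+1)`` at coring; its
    inventory is the exact integral ``P(e^{−λj} − e^{−λ(j+1)})/λ``
    (Bq m⁻²), so the summed inventory approaches P/λ as the span grows,
    whatever the MAR history.
    """
    lam = PB210_LAMBDA
    p = scenario.pb210_supply
    if p <= 0:
        raise ScenarioError("210Pb supply must be > 0")
    age_start = scenario.coring_year - years  # 0 for the newest year
    inv = p * (np.exp(-lam * age_start) - np.exp(-lam * (age_start + 1.0))) / lam
    return pd.DataFrame(
        {
            "year": years,
            "age_start": age_start,
            "age_end": age_start + 1.0,
            "mass_g_cm2": mar / 1e4,
            "pb_inventory_bq_m2": inv,
        }
    )


# ---------------------------------------------------------------------------
# core assembly
# ---------------------------------------------------------------------------


def _slab_records(scenario: ScenarioConfig):
    """Deposition slabs, newest first: annual slabs plus event slabs."""
    years, mar = simulate_mar_history(scenario)
    conc, f_a = simulate_concentrations(scenario, years, mar)
    pb = simulate_pb210(scenario, years, mar)
    shape = pulse_profile(scenario, years)
    organic = scenario.organic_base_pct + scenario.organic_pulse_gain_pct * shape

    lam = PB210_LAMBDA
    events = {float(y): float(mult) for y, mult in scenario.event_layers}
    slabs = []
    order = np.argsort(-years)  # newest first
    for i in order:
        y = float(years[i])
        rec = {
            "year": y,
            "mass": float(pb["mass_g_cm2"].iloc[i]),
            "age_start": float(pb["age_start"].iloc[i]),
            "age_end": float(pb["age_end"].iloc[i]),
            "pb_inv": float(pb["pb_inventory_bq_m2"].iloc[i]),
            "event": False,
            "c_pct": float(organic[i]),
            "conc": {el: float(conc[el][i]) for el in conc},
            "f_a": {el: float(f_a[el][i]) for el in f_a},
        }
        if y in events:
            mult = events[y]
            ev_mass = mult * rec["mass"]
            ambient = unsupported_activity(
                scenario.pb210_supply, float(mar[i]), rec["age_start"], lam
            )
            slabs.append(
                {
                    "year": y,
                    "mass": ev_mass,
                    "age_start": rec["age_start"],
                    "age_end": rec["age_start"],  # instantaneous
                    "pb_inv": EVENT_PB_FRACTION * ambient * ev_mass * 10.0,
                    "event": True,
                    "c_pct": scenario.organic_base_pct,
                    "conc": {el: spec.background for el, spec in scenario.elements.items()},
                    "f_a": {el: 0.0 for el in scenario.elements},
                }
            )
        slabs.append(rec)
    return slabs


def _take_fraction(slab: dict, frac: float, supply: float) -> tuple[dict, dict]:
    """Split a slab into (top part with mass fraction ``frac``, remainder).

    Non-event slabs deposit mass uniformly in time, so a mass fraction
    maps linearly onto the age interval and the ²¹⁰Pb inventory is split
    with the exact exponential integral.
    """
    lam = PB210_LAMBDA
    if frac >= 1.0 - 1e-12:
        return slab, None
    a0, a1 = slab["age_start"], slab["age_end"]
    if slab["event"] or a1 <= a0:
        top = dict(slab, mass=slab["mass"] * frac, pb_inv=slab["pb_inv"] * frac)
        rest = dict(slab, mass=slab["mass"] * (1 - frac), pb_inv=slab["pb_inv"] * (1 - frac))
        return top, rest
    a_split = a0 + frac * (a1 - a0)
    inv_top = supply * (np.exp(-lam * a0) - np.exp(-lam * a_split)) / lam
    top = dict(slab, mass=slab["mass"] * frac, age_end=a_split, pb_inv=inv_top)
    rest = dict(
        slab,
        mass=slab["mass"] * (1 - frac),
        age_start=a_split,
        pb_inv=slab["pb_inv"] - inv_top,
    )
    return top, rest


def build_synthetic_core(
    scenario: ScenarioConfig, seed: int
) -> tuple[CoreProfile, SyntheticTruth]:
    """Discretize the slab pile into layers and emit profile plus truth.

    The observed profile gets measurement noise when the scenario says so
    (lognormal on concentrations, Gaussian counting noise on activities);
    event layers are *unflagged* in the profile (detection is the
    pipeline's job) but fully described in the truth tables.  All
    randomness is driven by ``seed``.
    """
    slabs = _slab_records(scenario)
    elements = list(scenario.elements)
    dm_target0 = scenario.layer_thickness_cm * scenario.dry_bulk_density
    if dm_target0 <= 0:
        raise ScenarioError("layer thickness × bulk density must be > 0")

    layers = []
    current = _new_accumulator(elements)
    depth_top = 0.0
    queue = list(slabs)
    while queue:
        dbd_here = scenario.dry_bulk_density + scenario.dbd_gradient * depth_top
        dm_target = scenario.layer_thickness_cm * dbd_here
        slab = queue.pop(0)
        space = dm_target - current["mass"]
        if slab["mass"] <= space + 1e-15:
            _accumulate(current, slab, elements)
        else:
            frac = space / slab["mass"]
            top, rest = _take_fraction(slab, frac, scenario.pb210_supply)
            _accumulate(current, top, elements)
            if rest is not None:
                queue.insert(0, rest)
        dbd_here = scenario.dry_bulk_density + scenario.dbd_gradient * depth_top
        dm_target = scenario.layer_thickness_cm * dbd_here
        if current["mass"] >= dm_target - 1e-12:
            layers.append(_finalize_layer(current, depth_top, scenario, elements))
            depth_top += scenario.layer_thickness_cm
            current = _new_accumulator(elements)
    # drop a trailing partial layer (less than half full)
    if current["mass"] > 0.5 * scenario.layer_thickness_cm * scenario.dry_bulk_density:
        layers.append(_finalize_layer(current, depth_top, scenario, elements))

    if len(layers) < 10:
        raise ScenarioError(
            f"scenario yields only {len(layers)} layers; "
            "check span, thickness and bulk density"
        )

    rng = np.random.default_rng(seed)
    profile_df, truth = _assemble_tables(layers, scenario, elements, rng)
    return CoreProfile(profile_df), truth


def _new_accumulator(elements):
    return {
        "mass": 0.0,
        "event_mass": 0.0,
        "pb_inv": 0.0,
        "age_mass": 0.0,  # Σ mass × mean slab age
        "duration": 0.0,
        "c_mass": 0.0,
        "conc_mass": {el: 0.0 for el in elements},
        "fa_time": {el: 0.0 for el in elements},
    }


def _accumulate(acc, slab, elements):
    m = slab["mass"]
    acc["mass"] += m
    acc["pb_inv"] += slab["pb_inv"]
    acc["age_mass"] += m * 0.5 * (slab["age_start"] + slab["age_end"])
    acc["c_mass"] += m * slab["c_pct"]
    dt = slab["age_end"] - slab["age_start"]
    if slab["event"]:
        acc["event_mass"] += m
    else:
        acc["duration"] += dt
        for el in elements:
            acc["fa_time"][el] += slab["f_a"][el] * dt
    for el in elements:
        acc["conc_mass"][el] += m * slab["conc"][el]


def _finalize_layer(acc, depth_top, scenario, elements):
    mass = acc["mass"]
    duration = max(acc["duration"], 1e-3)
    mar_true = mass * 1e4 / duration
    return {
        "depth_top": depth_top,
        "depth_bottom": depth_top + scenario.layer_thickness_cm,
        "mass": mass,
        "dbd": mass / scenario.layer_thickness_cm,
        "unsupported": acc["pb_inv"] / (mass * 10.0),
        "year_true": scenario.coring_year - acc["age_mass"] / mass,
        "mar_true": mar_true,
        "duration": duration,
        "event_frac": acc["event_mass"] / mass,
        "c_pct": acc["c_mass"] / mass,
        "conc": {el: acc["conc_mass"][el] / mass for el in elements},
        "f_a_true": {el: acc["fa_time"][el] / duration for el in elements},
    }


def _assemble_tables(layers, scenario, elements, rng):
    n = len(layers)
    lam = PB210_LAMBDA
    noisy = scenario.apply_noise

    pb_total_true = np.array([scenario.supported + l["unsupported"] for l in layers])
    if noisy:
        pb_obs = np.clip(
            pb_total_true * (1.0 + rng.normal(0.0, scenario.pb_noise_cv, n)), 0.0, None
        )
        pb_sd = scenario.pb_noise_cv * pb_total_true
        ra_obs = np.clip(
            scenario.supported * (1.0 + rng.normal(0.0, scenario.ra_noise_cv, n)),
            0.0,
            None,
        )
    else:
        pb_obs = pb_total_true
        pb_sd = np.zeros(n)
        ra_obs = np.full(n, float(scenario.supported))

    df = pd.DataFrame(
        {
            "layer_id": np.arange(n, dtype=int),
            "depth_top_cm": [l["depth_top"] for l in layers],
            "depth_bottom_cm": [l["depth_bottom"] for l in layers],
            "dbd_g_cm3": [l["dbd"] for l in layers],
            "dry_mass_g_cm2": [l["mass"] for l in layers],
            "pb210_bq_kg": pb_obs,
            "pb210_sd": pb_sd,
            "ra226_bq_kg": ra_obs,
            "event_layer": False,
        }
    )

    c_true = np.array([l["c_pct"] for l in layers])
    c_obs = c_true * _lognormal_factor(rng, 0.03, n) if noisy else c_true
    df["c_pct"] = c_obs
    df["n_pct"] = c_obs / 12.5 * (_lognormal_factor(rng, 0.05, n) if noisy else 1.0)
    df["s_pct"] = (0.4 + 0.05 * (c_obs - scenario.organic_base_pct)) * (
        _lognormal_factor(rng, 0.05, n) if noisy else 1.0
    )

    for el in elements:
        true_c = np.array([l["conc"][el] for l in layers])
        cv = scenario.elements[el].noise_cv
        obs = true_c * _lognormal_factor(rng, cv, n) if noisy else true_c
        df[element_column(el)] = obs

    layer_truth = pd.DataFrame(
        {
            "layer_id": np.arange(n, dtype=int),
            "year_true": [l["year_true"] for l in layers],
            "mar_true": [l["mar_true"] for l in layers],
            "duration_yr": [l["duration"] for l in layers],
            "event_mass_frac": [l["event_frac"] for l in layers],
        }
    )
    non_event = layer_truth["event_mass_frac"] == 0.0
    pre = non_event & (layer_truth["year_true"] < scenario.cutoff_year)
    mar_ref_true = float(layer_truth.loc[pre, "mar_true"].mean())

    comp_rows = []
    for el in elements:
        cb = scenario.elements[el].background
        for i, l in enumerate(layers):
            f_tot = l["conc"][el] * l["mar_true"]
            f_v = cb * (l["mar_true"] - mar_ref_true)
            comp_rows.append(
                {
                    "element": el,
                    "layer_id": i,
                    "f_tot_true": f_tot,
                    "f_b_true": cb * mar_ref_true,
                    "f_v_true": f_v,
                    "f_a_true": f_tot - cb * mar_ref_true - f_v,
                }
            )
    truth = SyntheticTruth(
        layers=layer_truth,
        components=pd.DataFrame(comp_rows),
        supply=scenario.pb210_supply,
        supported=scenario.supported,
        mar_ref_true=mar_ref_true,
        background={el: scenario.elements[el].background for el in elements},
    )
    return df, truth


def _lognormal_factor(rng, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, n)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_REMOTE_ELEMENTS = {
    "Hg": ElementSpec(0.094, atm_share_post=0.42, noise_cv=0.10),
    "Pb": ElementSpec(22.73, atm_share_post=0.12, noise_cv=0.07),
    "Cu": ElementSpec(24.67, atm_share_post=0.12, noise_cv=0.10),
    "As": ElementSpec(14.16, atm_share_post=0.20, noise_cv=0.12),
    "Zn": ElementSpec(76.29, atm_share_post=0.0, noise_cv=0.10),
    "Cr": ElementSpec(16.7, atm_share_post=-0.05, noise_cv=0.16),
    "Ni": ElementSpec(8.82, atm_share_post=-0.05, noise_cv=0.12),
    "Co": ElementSpec(9.0, atm_share_post=-0.03, noise_cv=0.12),
    "Cd": ElementSpec(0.42, atm_share_post=-0.04, noise_cv=0.14),
    "V": ElementSpec(60.0, atm_share_post=0.0, noise_cv=0.10),
}

_PERI_URBAN_ELEMENTS = {
    "Hg": ElementSpec(0.111, atm_share_post=0.40, noise_cv=0.10),
    "Pb": ElementSpec(76.82, atm_share_post=0.50, noise_cv=0.07),
    "Cu": ElementSpec(31.73, atm_share_post=0.28, noise_cv=0.10),
    "As": ElementSpec(25.87, atm_share_post=0.36, noise_cv=0.12),
    "Zn": ElementSpec(178.8, atm_share_post=0.22, noise_cv=0.10),
    "Cr": ElementSpec(27.1, atm_share_post=0.08, noise_cv=0.16),
    "Ni": ElementSpec(8.1, atm_share_post=0.08, noise_cv=0.12),
    "Co": ElementSpec(12.0, atm_share_post=0.20, noise_cv=0.12),
    "Cd": ElementSpec(2.11, atm_share_post=0.18, noise_cv=0.14),
    "V": ElementSpec(66.0, atm_share_post=0.07, noise_cv=0.10),
}

#: MAR ×5 relative to the remote preset, same temporal structure.
_PERI_MAR = tuple(
    (year, 5.0 * value)
    for year, value in ScenarioConfig.__dataclass_fields__[
        "mar_control_points"
    ].default
)

PRESETS = {
    "remote-highland": ScenarioConfig(
        name="remote-highland",
        elements=dict(_REMOTE_ELEMENTS),
    ),
    "peri-urban": ScenarioConfig(
        name="peri-urban",
        dry_bulk_density=0.25,
        supported=30.0,
        mar_control_points=_PERI_MAR,
        elements=dict(_PERI_URBAN_ELEMENTS),
        event_layers=((1930.0, 6.0), (1972.0, 8.0), (1998.0, 7.0)),
    ),
}


def preset(name: str) -> ScenarioConfig:
    """Look up a shipped scenario preset by name."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ScenarioError(
            f"unknown preset '{name}'; available: {sorted(PRESETS)}"
        ) from None


def scenario_from_dict(cfg: dict) -> ScenarioConfig:
    """Build a scenario from a parsed structured-text config.

    Accepts either ``{"preset": name, ...overrides}`` or a full scenario
    mapping with an ``elements`` sub-mapping of per-element parameters.
    """
    cfg = dict(cfg)
    base = preset(cfg.pop("preset")) if "preset" in cfg else None
    if "elements" in cfg:
        cfg["elements"] = {
            el: ElementSpec(**spec) for el, spec in cfg["elements"].items()
        }
    for key in ("mar_control_points", "event_layers", "pulse_shape"):
        if key in cfg:
            cfg[key] = tuple(tuple(map(float, p)) for p in cfg[key])
    if base is not None:
        return replace(base, **cfg)
    return ScenarioConfig(**cfg)
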