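"""Constant-rate-of-supply (CRS) ²¹⁰Pb chronology with missing-inventory
correction and mass-accumulation-rate (MAR) estimation.

The CRS model assumes a constant atmospheric supply of unsupported
(excess) ²¹⁰Pb to the sediment surface.  With ``I(m)`` the residual
unsupported inventory (Bq m⁻²) below the cumulative-dry-mass boundary
``m`` (g cm⁻²), the age of that boundary is

    t(m) = (1/λ) · ln( I(0) / I(m) )

and the mass accumulation rate at a depth with unsupported activity
``A`` (Bq kg⁻¹) is ``MAR = λ · I / A``.  λ defaults to ln(2)/22.3 yr⁻¹
(²¹⁰Pb half-life 22.3 yr).

Cores rarely reach radioactive equilibrium at their base; the inventory
missed below the core bottom is estimated by fitting a log-linear decay
of unsupported activity against cumulative dry mass over the deepest
``tail_k`` layers and integrating the fitted exponential to infinity.
Layers too old to date reliably are assigned years by ordinary
least-squares extrapolation of the deepest dated layers, mirroring
standard practice for ~250-year records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import CoreProfile

#: Default ²¹⁰Pb decay constant, yr⁻¹ (half-life 22.3 yr).
PB210_LAMBDA = np.log(2.0) / 22.3

#: Bq kg⁻¹ · g cm⁻² → Bq m⁻² (1e-3 Bq g⁻¹·g cm⁻² = 1e-3 Bq cm⁻² = 10 Bq m⁻²).
_INV_UNIT = 10.0

MEASURED = "measured-CRS"
EXTRAPOLATED = "extrapolated"


class ChronologyError(ValueError):
    pass


class EquilibriumWarning(UserWarning):
    """Raised when a profile shows no sign of reaching ²¹⁰Pb equilibrium."""


@dataclass
class ActivityProfile:
    """Per-layer unsupported ²¹⁰Pb activities on a cumulative dry-mass grid.

    ``data`` columns: layer_id, unsupported (Bq kg⁻¹), unsupported_sd,
    mass_top, mass_bottom (cumulative g cm⁻² at the layer boundaries),
    clipped (activity fell below the supported level and was clipped at 0).

    ``missing_inventory`` (Bq m⁻²) is the model-estimated inventory below
    the boundary indexed by ``tail_from`` (the first layer whose measured
    activity is no longer trusted; ``None`` means the core bottom): zero
    until :func:`correct_missing_inventory` sets it.  Measured activities
    at and below ``tail_from`` are excluded from inventory sums — near the
    detection limit the zero-clipped activities are pure positive-biased
    noise.
    """

    data: pd.DataFrame
    supported: float
    missing_inventory: float = 0.0
    tail_from: int | None = None

    @property
    def n_layers(self) -> int:
        return len(self.data)

    @property
    def mass_mid(self) -> np.ndarray:
        return 0.5 * (
            self.data["mass_top"].to_numpy(float)
            + self.data["mass_bottom"].to_numpy(float)
        )


@dataclass
class AgeDepthModel:
    """CRS (plus extrapolated) age-depth model.

    ``data`` columns per layer: layer_id, depth_mid_cm, year (calendar year
    at the layer mass midpoint), age_yr (years before coring),
    year_top / year_bottom (boundary years), mar_g_m2_yr, mar_sd_g_m2_yr,
    source_flag (``measured-CRS`` or ``extrapolated``).
    """

    data: pd.DataFrame
    coring_year: float
    decay_constant: float
    supported: float
    total_inventory: float  # Bq m⁻², including any missing-inventory estimate
    missing_inventory: float  # Bq m⁻²

    @property
    def n_dated(self) -> int:
        return int((self.data["source_flag"] == MEASURED).sum())

    def layer_duration(self) -> np.ndarray:
        """Years represented by each layer (top boundary year − bottom)."""
        return (
            self.data["year_top"].to_numpy(float)
            - self.data["year_bottom"].to_numpy(float)
        )

    def provenance(self) -> dict:
        return {
            "coring_year": float(self.coring_year),
            "decay_constant_yr": float(self.decay_constant),
            "supported_bq_kg": float(self.supported),
            "total_inventory_bq_m2": float(self.total_inventory),
            "missing_inventory_bq_m2": float(self.missing_inventory),
            "n_dated_layers": self.n_dated,
        }

    def export(self, path) -> None:
        cols = [
            "layer_id",
            "depth_mid_cm",
            "year",
            "age_yr",
            "mar_g_m2_yr",
            "mar_sd_g_m2_yr",
            "source_flag",
        ]
        self.data[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# supported level and unsupported activities
# ---------------------------------------------------------------------------


def estimate_supported(
    profile: CoreProfile, method: str = "ra226-mean", n_tail: int = 3
) -> float:
    """Estimate the supported ²¹⁰Pb level (Bq kg⁻¹).

    ``ra226-mean``: arithmetic mean of all available ²²⁶Ra activities —
    the default, since supported ²¹⁰Pb is in secular equilibrium with
    in-situ ²²⁶Ra.  ``deep-asymptote``: mean total ²¹⁰Pb of the deepest
    ``n_tail`` layers, for cores without ²²⁶Ra; warns if those layers do
    not look like an equilibrium asymptote.
    """
    df = profile.data
    if method == "ra226-mean":
        if "ra226_bq_kg" not in df.columns or df["ra226_bq_kg"].dropna().empty:
            raise ChronologyError("ra226-mean requires at least one 226Ra value")
        return float(df["ra226_bq_kg"].dropna().mean())
    if method == "deep-asymptote":
        if "pb210_bq_kg" not in df.columns:
            raise ChronologyError("deep-asymptote requires total 210Pb activities")
        pb = df["pb210_bq_kg"].dropna()
        if len(pb) < n_tail:
            raise ChronologyError(
                f"deep-asymptote requires ≥{n_tail} 210Pb values, got {len(pb)}"
            )
        tail = pb.to_numpy(float)[-n_tail:]
        surface = float(pb.to_numpy(float)[0])
        est = float(tail.mean())
        # an asymptote should be flat and far below the surface activity
        if est > 0.5 * surface or (tail.max() - tail.min()) > 0.5 * est:
            warnings.warn(
                "deepest layers do not look like 210Pb equilibrium; "
                "supported estimate may be biased high",
                EquilibriumWarning,
                stacklevel=2,
            )
        return est
    raise ChronologyError(f"unknown supported-210Pb method '{method}'")


def unsupported_profile(profile: CoreProfile, supported: float) -> ActivityProfile:
    """Subtract the supported level and build the cumulative dry-mass grid.

    Unsupported activity = max(total − supported, 0); clipped layers are
    flagged rather than dropped so the depth grid stays intact.
    """
    df = profile.data
    if "pb210_bq_kg" not in df.columns:
        raise ChronologyError("profile has no total 210Pb activities")
    mass = profile.layer_mass()
    if np.isnan(mass).any():
        raise ChronologyError("profile lacks dry-mass information on some layers")

    total = df["pb210_bq_kg"].to_numpy(float)
    sd = (
        df["pb210_sd"].to_numpy(float)
        if "pb210_sd" in df.columns
        else np.zeros_like(total)
    )
    raw = total - supported
    unsupported = np.clip(raw, 0.0, None)
    clipped = raw < 0

    mass_bottom = np.cumsum(mass)
    mass_top = mass_bottom - mass
    data = pd.DataFrame(
        {
            "layer_id": profile.layer_ids,
            "unsupported": unsupported,
            "unsupported_sd": np.nan_to_num(sd),
            "mass_top": mass_top,
            "mass_bottom": mass_bottom,
            "clipped": clipped,
        }
    )
    return ActivityProfile(data=data, supported=float(supported))


# ---------------------------------------------------------------------------
# inventories
# ---------------------------------------------------------------------------


def cumulative_residual_inventory(ap: ActivityProfile) -> np.ndarray:
    """Residual unsupported inventory I(m) at each layer boundary (Bq m⁻²).

    Returns ``n_layers + 1`` values, surface first.  Activities are
    layer-averaged, so each layer contributes activity × layer mass to the
    integral over cumulative dry mass (the trapezoidal sum for piecewise-
    constant layer means).  Any missing-inventory estimate is added below
    the trusted range: measured contributions from ``tail_from`` downward
    are replaced by the model estimate.
    """
    if ap.n_layers < 2:
        raise ChronologyError("need at least 2 layers to build an inventory")
    a = ap.data["unsupported"].to_numpy(float).copy()
    dm = (
        ap.data["mass_bottom"].to_numpy(float)
        - ap.data["mass_top"].to_numpy(float)
    )
    if ap.tail_from is not None:
        a[ap.tail_from :] = 0.0
    contrib = a * dm * _INV_UNIT
    below = np.concatenate([np.cumsum(contrib[::-1])[::-1], [0.0]])
    return below + ap.missing_inventory


def correct_missing_inventory(
    ap: ActivityProfile, tail_k: int = 4, fit_floor: float = 0.05
) -> ActivityProfile:
    """Estimate the unsupported inventory below the trusted depth range.

    Fits ln(unsupported) against cumulative dry mass at layer midpoints
    over the deepest ``tail_k`` layers whose activity is still well
    resolved (above twice its counting error and above ``fit_floor``
    times the profile maximum — near the detection limit the zero-clipped
    activities form a flat noise plateau with no decay-slope information).
    The fitted exponential is then integrated from the last reliable
    boundary to infinity and *replaces* the noise-floor measurements below
    it.  For a truncated core this is the classic missing-inventory
    estimate; for a core measured to equilibrium it also removes the
    positive bias the clipped noise floor would otherwise add.

    Robustness: the slope is a Theil–Sen estimate (a single layer whose
    activity departs from the exponential limb cannot wreck it), and when
    measured layers exist below the trusted boundary the tail estimate is
    capped by the inventory those near-zero activities could at most hold
    — an extrapolated exponential may not claim more ²¹⁰Pb than the deep
    core demonstrably lacks.  Returns a new profile with
    ``missing_inventory`` and ``tail_from`` set.
    """
    a = ap.data["unsupported"].to_numpy(float)
    sd = ap.data["unsupported_sd"].to_numpy(float)
    mid = ap.mass_mid
    reliable = (a > 0) & (a > 2.0 * sd)
    if not reliable.any():
        raise ChronologyError("no layer has resolvable unsupported activity")
    last_reliable = int(np.flatnonzero(reliable)[-1])

    floor = fit_floor * float(a.max())
    pos = np.flatnonzero(reliable & (a >= floor))
    if pos.size < tail_k:
        pos = np.flatnonzero(reliable)
    if pos.size < tail_k:
        raise ChronologyError(
            f"need ≥{tail_k} layers with resolvable unsupported activity "
            f"for the tail fit, got {pos.size}"
        )
    # widen the window beyond tail_k until it spans ≥1 e-fold of decay:
    # a short flat window yields a slope too unstable to extrapolate
    k = tail_k
    while k < pos.size and a[pos[-k]] < np.e * a[pos[-1]]:
        k += 1
    idx = pos[-k:]
    from scipy import stats as _stats

    slope, intercept, _, _ = _stats.theilslopes(np.log(a[idx]), mid[idx])
    if slope >= 0:
        raise ChronologyError(
            "tail activities are not decaying with mass; choose the tail "
            "manually or extend the core"
        )
    m_trust = float(ap.data["mass_bottom"].iloc[last_reliable])
    # ∫_{m_trust}^∞ exp(intercept + slope·m) dm = A(m_trust)/(−slope)
    missing = float(np.exp(intercept + slope * m_trust) / (-slope) * _INV_UNIT)
    tail_from = last_reliable + 1 if last_reliable + 1 < ap.n_layers else None
    if tail_from is not None:
        dm = (
            ap.data["mass_bottom"].to_numpy(float)
            - ap.data["mass_top"].to_numpy(float)
        )[tail_from:]
        cap = 2.0 * float(
            np.sum(np.maximum(a[tail_from:], sd[tail_from:]) * dm) * _INV_UNIT
        )
        missing = min(missing, cap)
    return replace(ap, missing_inventory=missing, tail_from=tail_from)


# ---------------------------------------------------------------------------
# CRS model
# ---------------------------------------------------------------------------


def crs_model(
    ap: ActivityProfile,
    coring_year: float,
    decay_constant: float = PB210_LAMBDA,
    profile: CoreProfile | None = None,
    max_age: float = 150.0,
    min_snr: float = 4.0,
    noise_floor_frac: float = 0.05,
) -> AgeDepthModel:
    """Build the CRS age-depth model from an activity profile.

    Ages are computed at layer mass midpoints, ``t = ln(I0/I)/λ``; layer
    MAR is ``λ·I(mid)/A`` converted to g m⁻² yr⁻¹.  Dating terminates at
    the first layer whose midpoint inventory vanishes, whose CRS age
    exceeds ``max_age`` (ages beyond ~150 yr rest on <1% of the
    inventory), or that sits in the deep noise floor — residual inventory
    below ``noise_floor_frac`` of the total *and* unsupported activity
    below ``min_snr`` times its counting error.  A low-activity layer
    higher up (e.g. an instantaneous event deposit diluting the excess
    ²¹⁰Pb) does not terminate dating: its boundary ages derive from the
    inventory, not from its own activity, and its inflated apparent MAR
    is exactly what downstream event-layer screening keys on.

    Layers below the termination point are left undated;
    :func:`extrapolate_ages` assigns them years.  ``profile`` supplies
    layer depths for the exported model; optional.
    """
    lam = float(decay_constant)
    inv = cumulative_residual_inventory(ap)
    I0 = inv[0]
    if I0 <= 0:
        raise ChronologyError("surface inventory is zero; cannot date")

    a = ap.data["unsupported"].to_numpy(float)
    sd = ap.data["unsupported_sd"].to_numpy(float)
    dm = ap.data["mass_bottom"].to_numpy(float) - ap.data["mass_top"].to_numpy(float)
    i_mid = inv[:-1] - 0.5 * a * dm * _INV_UNIT

    with np.errstate(divide="ignore", invalid="ignore"):
        age_mid = np.where(i_mid > 0, np.log(I0 / np.maximum(i_mid, 1e-300)) / lam, np.inf)
        age_top = np.where(inv[:-1] > 0, np.log(I0 / np.maximum(inv[:-1], 1e-300)) / lam, np.inf)
        age_bot = np.where(inv[1:] > 0, np.log(I0 / np.maximum(inv[1:], 1e-300)) / lam, np.inf)
        mar = np.where(a > 0, lam * i_mid / np.maximum(a, 1e-300) * 1000.0, np.nan)

    in_noise_floor = (i_mid < noise_floor_frac * I0) & ~(a > min_snr * sd)
    dated = (i_mid > 0) & (a > 0) & (age_mid <= max_age) & ~in_noise_floor
    # dating must be contiguous from the surface
    if not dated.all():
        first_bad = int(np.flatnonzero(~dated)[0])
        dated[first_bad:] = False
    if not dated.any():
        raise ChronologyError("no layer could be dated by CRS")

    # first-order MAR uncertainty from activity counting error only
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_sd = np.where(a > 0, sd / np.maximum(a, 1e-300), np.nan)
    mar_sd = np.abs(mar) * rel_sd

    n = ap.n_layers
    depth_mid = (
        profile.depth_mid if profile is not None else np.full(n, np.nan)
    )
    data = pd.DataFrame(
        {
            "layer_id": ap.data["layer_id"].to_numpy(),
            "depth_mid_cm": depth_mid,
            "age_yr": np.where(dated, age_mid, np.nan),
            "year": np.where(dated, coring_year - age_mid, np.nan),
            "year_top": np.where(dated, coring_year - age_top, np.nan),
            "year_bottom": np.where(dated, coring_year - age_bot, np.nan),
            "mar_g_m2_yr": np.where(dated, mar, np.nan),
            "mar_sd_g_m2_yr": np.where(dated, mar_sd, np.nan),
            "source_flag": np.where(dated, MEASURED, ""),
        }
    )
    return AgeDepthModel(
        data=data,
        coring_year=float(coring_year),
        decay_constant=lam,
        supported=ap.supported,
        total_inventory=float(I0),
        missing_inventory=float(ap.missing_inventory),
    )


def extrapolate_ages(
    model: AgeDepthModel, profile: CoreProfile, n_anchor: int = 4
) -> AgeDepthModel:
    """Assign years to undated deep layers by linear extrapolation.

    Ordinary least squares of calendar year against midpoint depth over the
    deepest ``n_anchor`` dated layers; extrapolated layers get the anchor
    layers' mean MAR and are flagged ``extrapolated``.  An extrapolated year
    is never allowed to be younger than the deepest dated layer.
    """
    df = model.data.copy()
    df["depth_mid_cm"] = profile.depth_mid
    dated = df["source_flag"] == MEASURED
    if int(dated.sum()) < n_anchor:
        raise ChronologyError(
            f"need ≥{n_anchor} dated layers to extrapolate, have {int(dated.sum())}"
        )
    if dated.all():
        return replace(model, data=df)

    anchors = df[dated].tail(n_anchor)
    slope, intercept = np.polyfit(
        anchors["depth_mid_cm"].to_numpy(float), anchors["year"].to_numpy(float), 1
    )
    anchor_mar = float(anchors["mar_g_m2_yr"].mean())
    oldest_dated = float(df.loc[dated, "year"].min())

    undated = ~dated
    depth = df.loc[undated, "depth_mid_cm"].to_numpy(float)
    year = np.minimum(intercept + slope * depth, oldest_dated)
    df.loc[undated, "year"] = year
    df.loc[undated, "age_yr"] = model.coring_year - year
    df.loc[undated, "mar_g_m2_yr"] = anchor_mar
    df.loc[undated, "source_flag"] = EXTRAPOLATED

    # boundary years for extrapolated layers from the same linear model
    top = profile.depth_top[undated.to_numpy()]
    bottom = profile.depth_bottom[undated.to_numpy()]
    df.loc[undated, "year_top"] = np.minimum(intercept + slope * top, oldest_dated)
    df.loc[undated, "year_bottom"] = np.minimum(
        intercept + slope * bottom, oldest_dated
    )

    if not df["age_yr"].is_monotonic_increasing:
        raise ChronologyError("extrapolated ages are not monotone with depth")
    return replace(model, data=df)


def build_chronology(
    profile: CoreProfile,
    coring_year: float,
    supported_method: str = "ra226-mean",
    decay_constant: float = PB210_LAMBDA,
    tail_k: int = 4,
    n_anchor: int = 4,
    max_age: float = 150.0,
) -> AgeDepthModel:
    """Convenience pipeline: supported level → unsupported activities →
    missing-inventory correction → CRS model → age extrapolation."""
    try:
        supported = estimate_supported(profile, supported_method)
    except ChronologyError:
        if supported_method == "ra226-mean":
            supported = estimate_supported(profile, "deep-asymptote")
        else:
            raise
    ap = unsupported_profile(profile, supported)
    try:
        ap = correct_missing_inventory(ap, tail_k=tail_k)
    except ChronologyError as exc:
        warnings.warn(
            f"missing-inventory correction skipped: {exc}",
            EquilibriumWarning,
            stacklevel=2,
        )
    model = crs_model(ap, coring_year, decay_constant, profile=profile, max_age=max_age)
    return extrapolate_ages(model, profile, n_anchor=n_anchor)
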