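"""Contamination assessment and analytical QA/QC.

Covers threshold-exceedance classification against sediment-quality
guidelines (LEL, ERL) and agricultural-soil thresholds (TAS), between-lake
comparison ratios, element-vs-organic-matter correlation screening, and
the laboratory QA utilities (recovery correction, limit of detection,
replicate relative standard deviation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CoreProfile, ThresholdTable, lod_column


class AssessmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# threshold exceedance
# ---------------------------------------------------------------------------


def exceedance_factor(
    conc: float, threshold: float, decimals: int | None = None
) -> float:
    """Concentration / threshold; NaN when the threshold is missing.

    ``decimals`` rounds for display (the raw value is what callers should
    keep); a missing threshold yields NaN, never zero.
    """
    if threshold is None or (isinstance(threshold, float) and np.isnan(threshold)):
        return float("nan")
    if threshold <= 0:
        raise AssessmentError("threshold must be > 0")
    factor = conc / threshold
    return round(factor, decimals) if decimals is not None else factor


def sqg_classify(
    summary: pd.DataFrame, thresholds: ThresholdTable
) -> pd.DataFrame:
    """Classify period concentrations against each threshold kind.

    ``summary`` is a period-summary table indexed by element with
    concentration columns (``conc_pre``, ``conc_post``, ``conc_recent`` —
    any column starting with ``conc`` except factors).  Returns a tidy
    table with one row per element × period × threshold kind: the factor
    and whether the value exceeds the threshold.  "Exceeds" means strictly
    greater than the threshold; exact ties classify as below (conservative
    boundary, reported via the factor of exactly 1).
    """
    period_cols = [
        c for c in summary.columns if c.startswith("conc") and "factor" not in c
    ]
    rows = []
    for el, row in summary.iterrows():
        for col in period_cols:
            conc = float(row[col])
            for kind in ThresholdTable.KINDS:
                thr = thresholds.lookup(str(el), kind)
                factor = exceedance_factor(conc, thr) if thr > 0 else float("nan")
                rows.append(
                    {
                        "element": el,
                        "period": col.replace("conc_", ""),
                        "concentration": conc,
                        "kind": kind.upper(),
                        "threshold": thr,
                        "factor": factor,
                        "exceeds": bool(conc > thr) if np.isfinite(thr) else False,
                    }
                )
    return pd.DataFrame(rows)


def between_lake_ratio(
    summary_a: pd.DataFrame, summary_b: pd.DataFrame
) -> pd.DataFrame:
    """Element-wise ratios a/b of period concentrations and fluxes.

    Operates on matching period-summary tables; the result is sorted by
    the post-period flux ratio (the customary presentation order).
    Zero-mean denominators produce missing ratios.
    """
    common = summary_a.index.intersection(summary_b.index)
    if common.empty:
        raise AssessmentError("summaries share no elements")
    cols = [
        c
        for c in ("conc_pre", "conc_post", "flux_pre", "flux_post")
        if c in summary_a.columns and c in summary_b.columns
    ]
    a = summary_a.loc[common, cols]
    b = summary_b.loc[common, cols]
    ratio = a / b.replace(0, np.nan)
    ratio.columns = [f"ratio_{c}" for c in cols]
    if "ratio_flux_post" in ratio.columns:
        ratio = ratio.sort_values("ratio_flux_post")
    return ratio


# ---------------------------------------------------------------------------
# correlation screening
# ---------------------------------------------------------------------------


def correlate_elements(
    profile: CoreProfile,
    targets: list[str] | None = None,
    refs: tuple[str, ...] = ("C", "N", "S"),
) -> pd.DataFrame:
    """Pearson correlation of element concentrations with C/N/S series.

    Complete-case pairs, two-sided p-values, no multiple-testing
    adjustment by default (apply Holm externally if desired).  Constant
    series yield NaN r with a flag.  Requires ≥3 paired observations.
    """
    targets = list(targets) if targets is not None else list(profile.elements)
    rows = []
    for el in targets:
        x_all = profile.concentration(el)
        for ref in refs:
            try:
                y_all = profile.cns(ref)
            except KeyError:
                continue
            ok = ~np.isnan(x_all) & ~np.isnan(y_all)
            n = int(ok.sum())
            if n < 3:
                raise AssessmentError(
                    f"{el} vs {ref}: need ≥3 paired observations, have {n}"
                )
            x, y = x_all[ok], y_all[ok]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append(
                    {"element": el, "ref": ref, "r": np.nan, "p": np.nan,
                     "n": n, "constant": True}
                )
                continue
            r, p = stats.pearsonr(x, y)
            rows.append(
                {"element": el, "ref": ref, "r": float(r), "p": float(p),
                 "n": n, "constant": False}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# QA/QC utilities
# ---------------------------------------------------------------------------


def qa_recovery_correct(conc, recovery_pct: float):
    """Divide concentrations by recovery/100.

    A constant recovery is a positive scaling, so temporal trends, ratios
    between layers and correlations are unchanged; this is why pipelines
    may run on uncorrected values.  Off by default in the CLI.
    """
    if recovery_pct <= 0:
        raise AssessmentError("recovery must be > 0")
    return np.asarray(conc, float) / (recovery_pct / 100.0)


def qa_lod(blanks: dict[str, list[float]], k: float = 3.0) -> dict[str, float]:
    """Limit of detection per element: mean(blanks) + k·sd(blanks).

    Blank values live in the digest domain (μg L⁻¹); convert with the
    digest mass/volume before comparing with sediment concentrations.
    """
    out = {}
    for el, vals in blanks.items():
        v = np.asarray(vals, float)
        if v.size < 2:
            raise AssessmentError(f"{el}: need ≥2 blanks for an LOD")
        out[el] = float(v.mean() + k * v.std(ddof=1))
    return out


def flag_below_lod(profile: CoreProfile, lod: dict[str, float]) -> CoreProfile:
    """Return a copy with ``<el>_below_lod`` flags for values under the LOD.

    ``lod`` must already be in sediment-concentration units (μg g⁻¹).
    Flagged values are kept, not substituted; downstream treatment is a
    configuration decision.
    """
    out = profile.copy()
    for el, limit in lod.items():
        if el not in out.elements:
            continue
        conc = out.concentration(el)
        out.data[lod_column(el)] = conc < limit
    return out


def qa_replicate_rsd(replicates: dict[str, list[list[float]]]) -> pd.DataFrame:
    """Relative standard deviation of replicate digests per element.

    RSD = 100·sd/mean per replicate set (sample sd, ddof=1); the
    element-level value is the mean across its sets.  Zero-mean sets are
    flagged with NaN.
    """
    rows = []
    for el, sets in replicates.items():
        rsds = []
        for vals in sets:
            v = np.asarray(vals, float)
            if v.size < 2:
                raise AssessmentError(f"{el}: replicate sets need ≥2 values")
            m = v.mean()
            rsds.append(100.0 * v.std(ddof=1) / m if m != 0 else np.nan)
        rows.append(
            {
                "element": el,
                "rsd_pct": float(np.nanmean(rsds)) if not all(np.isnan(r) for r in rsds) else np.nan,
                "n_sets": len(sets),
                "undefined_sets": int(sum(np.isnan(r) for r in rsds)),
            }
        )
    return pd.DataFrame(rows).set_index("element")
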