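"""Derived biomarkers: contributions, bilirubin metrics, energy metrics.

Relative contributions are percentages of the total fitted band area over
the 400-750 nm analysis window, aggregated per fluorophore report group.
From those, serum yields the bilirubin bichromophore metrics (main/secondary
band ratio, total bilirubin contribution, absolute 'real AF' emission) and
liver yields the energy-state metrics (NAD(P)H total, free/bound ratio,
optical redox ratio = flavins / (NAD(P)H bound + free + flavins)).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .model import DecompositionResults

#: Contribution (%) below which a bilirubin band is considered too weak for
#: a reliable band ratio (the ratio is withheld and flagged).
LOW_SIGNAL_PCT = 0.5

BILIRUBIN_MAIN = "bilirubin_517_530"
BILIRUBIN_SECONDARY = "bilirubin_570"
NADPH_BOUND = "nadph_bound"
NADPH_FREE = "nadph_free"
FLAVINS = "flavins"


@dataclasses.dataclass
class BilirubinMetrics:
    """Serum bilirubin bichromophore summary.

    ``band_ratio`` is the (517-530 nm)/(570 nm) area ratio; ``real_af_au``
    rescales the summed relative contribution by the measured total emission
    area of the raw spectrum (divided by 100 for presentation):
    real AF = (total % / 100) × total_area / 100.
    """

    band_ratio: float
    total_contribution_pct: float
    real_af_au: float
    low_signal: bool


@dataclasses.dataclass
class EnergyMetrics:
    """Liver energy-state summary derived from AF contributions."""

    nadph_total: float
    free_over_bound: float
    redox_ratio: float


def relative_contributions(fit: DecompositionResults) -> pd.Series:
    """Percent contribution of each fluorophore report group.

    100 × (summed fitted area of the group's bands) / (total fitted area);
    the result sums to 100 by construction.
    """
    total = float(fit.areas.sum())
    if total <= 0:
        raise ValueError("total fitted area is zero; no contributions defined")
    lib = fit.model.library
    out: dict[str, float] = {}
    i = 0
    for f in lib.fluorophores:
        area = float(fit.areas.iloc[i : i + len(f.bands)].sum())
        out[f.report_group] = out.get(f.report_group, 0.0) + 100.0 * area / total
        i += len(f.bands)
    return pd.Series(out, name="contribution_pct")


def contribution_table(
    rows: dict[str, pd.Series] | pd.DataFrame,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stack per-sample contribution Series into a tidy table.

    ``meta`` (indexed by sample_id) is joined on, typically carrying
    ``group`` and ``tissue`` columns.
    """
    df = pd.DataFrame(rows).T if isinstance(rows, dict) else rows.copy()
    df.index.name = "sample_id"
    if meta is not None:
        df = df.join(meta, how="left")
    return df


def bilirubin_metrics(
    row: pd.Series,
    total_area_au: float,
    main: str = BILIRUBIN_MAIN,
    secondary: str = BILIRUBIN_SECONDARY,
    low_signal_pct: float = LOW_SIGNAL_PCT,
) -> BilirubinMetrics:
    """Bilirubin band metrics from one serum contribution row.

    The band ratio is withheld (NaN, ``low_signal=True``) when either band
    contributes less than ``low_signal_pct`` percent — too weak to be
    reliable.
    """
    if total_area_au <= 0:
        raise ValueError("total_area_au must be positive")
    for key in (main, secondary):
        if key not in row.index:
            raise KeyError(f"contribution row lacks {key!r}")
    c_main = float(row[main])
    c_sec = float(row[secondary])
    total = c_main + c_sec
    low = (c_main < low_signal_pct) or (c_sec < low_signal_pct)
    ratio = float("nan") if low else c_main / c_sec
    real_af = (total / 100.0) * total_area_au / 100.0
    return BilirubinMetrics(
        band_ratio=ratio,
        total_contribution_pct=total,
        real_af_au=real_af,
        low_signal=low,
    )


def energy_metrics(
    row: pd.Series,
    bound: str = NADPH_BOUND,
    free: str = NADPH_FREE,
    flavins: str = FLAVINS,
) -> EnergyMetrics:
    """Liver energy metrics from one contribution row.

    nadph_total = bound + free + flavins; free_over_bound = free/bound;
    redox ratio = flavins / nadph_total.  The flavin term is included in the
    total because the optical reserve pool is the full coenzyme signal.
    """
    for key in (bound, free, flavins):
        if key not in row.index:
            raise KeyError(f"contribution row lacks {key!r}")
    c_b, c_f, c_fl = float(row[bound]), float(row[free]), float(row[flavins])
    if c_b <= 0:
        raise ValueError("NAD(P)H bound contribution must be positive")
    total = c_b + c_f + c_fl
    return EnergyMetrics(
        nadph_total=total,
        free_over_bound=c_f / c_b,
        redox_ratio=c_fl / total,
    )


def percent_change(a: float, b: float) -> float:
    """Signed percent change from ``a`` to ``b``: 100·(b − a)/a."""
    if a <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (b - a) / a


def energy_metrics_frame(contribs: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`energy_metrics` row-wise over a liver contribution table."""
    recs = {}
    cols = [NADPH_BOUND, NADPH_FREE, FLAVINS]
    for sid, row in contribs[cols].iterrows():
        m = energy_metrics(row)
        recs[sid] = {
            "nadph_total": m.nadph_total,
            "free_over_bound": m.free_over_bound,
            "redox_ratio": m.redox_ratio,
        }
    out = pd.DataFrame(recs).T
    out.index.name = "sample_id"
    return out


def bilirubin_metrics_frame(
    contribs: pd.DataFrame, total_areas: pd.Series
) -> pd.DataFrame:
    """Apply :func:`bilirubin_metrics` row-wise over a serum table.

    ``total_areas`` maps sample_id → measured raw emission area (a.u.).
    """
    recs = {}
    for sid, row in contribs.iterrows():
        m = bilirubin_metrics(row, float(total_areas[sid]))
        recs[sid] = {
            "band_ratio": m.band_ratio,
            "bilirubin_total_pct": m.total_contribution_pct,
            "real_af_au": m.real_af_au,
            "low_signal": m.low_signal,
        }
    out = pd.DataFrame(recs).T
    out.index.name = "sample_id"
    for c in ("band_ratio", "bilirubin_total_pct", "real_af_au"):
        out[c] = out[c].astype(float)
    out["low_signal"] = out["low_signal"].astype(bool)
    return out
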