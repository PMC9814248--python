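"""Damage metrics: normalized time series and scalar damage indices.

All intensities are normalized on the total P2p area at the same timepoint
(phosphorus occurs exactly once per nucleotide, so P2p is the internal
reference that cancels fluence and probed-volume drifts).  Per-region
percentages are quoted with respect to the total (non-gas) normalized area
of that region at the first timepoint.  Scalar indices are endpoint-based:

* strand-break index — fractional decrease, start to end, of the normalized
  backbone C-O-P component (C1s at 286 eV);
* base-damage index — fractional decrease of the summed condensed-phase
  nitrogen signal;
* waters per nucleotide — RSF-corrected O1s water area over RSF-corrected
  P2p area (one phosphorus per nucleotide).

Uncertainties propagate through the ratios assuming independence between
regions (separate scans); the P2p variance contribution is included,
cross-region covariances are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import RegionFitResult

__all__ = [
    "AreaSeries",
    "DamageReport",
    "load_rsf",
    "areas_table",
    "normalize_series",
    "normalize_series_table",
    "strand_break_index",
    "base_damage_index",
    "water_per_nucleotide",
    "water_per_nucleotide_table",
    "damage_report",
    "damage_report_table",
]

log = logging.getLogger(__name__)


class UndefinedIndexError(ValueError):
    """A damage index is undefined (vanishing start intensity)."""


def load_rsf(path=None) -> dict[str, float]:
    """Relative sensitivity factors; the shipped default is Scofield-derived."""
    if path is None:
        ref = resources.files("napxps.data") / "rsf.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(Path(path), sep="\t", comment="#")
    return dict(zip(df["line"], df["rsf"].astype(float)))


@dataclass
class AreaSeries:
    """Time-resolved normalized areas of one region.

    ``table`` is long-form with one row per (timepoint, component):
    columns ``timepoint_s, component, normalized_area, sigma_norm,
    percent_of_initial, sigma_percent, is_gas_phase``.
    """

    region_label: str
    table: pd.DataFrame
    condition: dict = field(default_factory=dict)

    @property
    def timepoints(self) -> np.ndarray:
        return np.sort(self.table["timepoint_s"].unique())

    def component(self, label: str) -> pd.DataFrame:
        sub = self.table[self.table["component"] == label]
        if sub.empty:
            raise KeyError(f"{self.region_label}: no component {label!r}")
        return sub.sort_values("timepoint_s").reset_index(drop=True)

    def endpoint_values(self, label: str):
        """(value, sigma) of normalized area at first and last timepoint."""
        sub = self.component(label)
        first, last = sub.iloc[0], sub.iloc[-1]
        return ((float(first["normalized_area"]), float(first["sigma_norm"])),
                (float(last["normalized_area"]), float(last["sigma_norm"])))

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.5))
        for label, sub in self.table.groupby("component"):
            sub = sub.sort_values("timepoint_s")
            ax.errorbar(sub["timepoint_s"], sub["percent_of_initial"],
                        yerr=sub["sigma_percent"], marker="o", ms=3,
                        capsize=2, label=label)
        ax.set_xlabel("time / s")
        ax.set_ylabel("% of initial total area (P2p-normalized)")
        ax.set_title(self.region_label)
        ax.legend(fontsize=8)
        return ax


def areas_table(fits: dict[str, list[RegionFitResult]]) -> pd.DataFrame:
    """Flatten fit results into a long-form raw-area table.

    Columns: ``region, timepoint_s, component, area, sigma, is_gas_phase``.
    This is the persisted interchange format between the fit and damage
    stages.
    """
    rows = []
    for region, frs in fits.items():
        for fr in frs:
            for c in fr.model.components:
                a, s = fr.component_areas[c.label]
                rows.append({
                    "region": region,
                    "timepoint_s": fr.spectrum.timepoint,
                    "component": c.label,
                    "area": a, "sigma": s,
                    "is_gas_phase": c.is_gas_phase,
                })
    return pd.DataFrame(rows)


def normalize_series_table(
    table: pd.DataFrame,
    reference_region: str = "P2p",
) -> dict[str, AreaSeries]:
    """Build P2p-normalized area series from a raw-area table.

    Timepoints without a reference-region entry are dropped with a warning.
    Gas-phase components are normalized too but excluded from the region
    totals used for the percent-of-initial scale.
    """
    if reference_region not in set(table["region"]):
        raise ValueError(f"no {reference_region} areas supplied")
    ref = {}
    for t, sub in table[table["region"] == reference_region].groupby("timepoint_s"):
        a_p = float(sub["area"].sum())
        s_p = float(np.sqrt((sub["sigma"] ** 2).sum()))
        if a_p <= 0:
            raise ValueError(f"{reference_region} total area <= 0 at t={t:g} s")
        ref[t] = (a_p, s_p)

    out: dict[str, AreaSeries] = {}
    for region, sub in table.groupby("region"):
        if region == reference_region:
            continue
        rows = []
        for _, row in sub.sort_values("timepoint_s").iterrows():
            t = row["timepoint_s"]
            if t not in ref:
                log.warning("dropping %s at t=%g s: no %s areas at that "
                            "timepoint", region, t, reference_region)
                continue
            a_p, s_p = ref[t]
            a, s = float(row["area"]), float(row["sigma"])
            norm = a / a_p
            if a > 0:
                sig = norm * np.sqrt((s / a) ** 2 + (s_p / a_p) ** 2)
            else:
                sig = s / a_p
            rows.append({
                "timepoint_s": t, "component": row["component"],
                "normalized_area": norm, "sigma_norm": sig,
                "is_gas_phase": bool(row["is_gas_phase"]),
            })
        if not rows:
            continue
        df = pd.DataFrame(rows)
        t0 = df["timepoint_s"].min()
        first = df[df["timepoint_s"] == t0]
        total0 = first.loc[~first["is_gas_phase"], "normalized_area"].sum()
        if total0 <= 0:
            raise ValueError(f"{region}: zero total area at the first timepoint")
        df["percent_of_initial"] = 100.0 * df["normalized_area"] / total0
        df["sigma_percent"] = 100.0 * df["sigma_norm"] / total0
        out[region] = AreaSeries(region_label=region, table=df,
                                 condition={"reference": reference_region})
    return out


def normalize_series(
    fits: dict[str, list[RegionFitResult]],
    reference_region: str = "P2p",
) -> dict[str, AreaSeries]:
    """Build P2p-normalized area series from per-region, per-timepoint fits."""
    for region, frs in fits.items():
        if not frs:
            raise ValueError(f"no fits supplied for region {region}")
    return normalize_series_table(areas_table(fits), reference_region)


def _endpoint_index(start, end):
    (a0, s0), (a1, s1) = start, end
    if a0 <= 0:
        raise UndefinedIndexError("start area <= 0: index undefined")
    value = (a0 - a1) / a0
    sigma = np.sqrt((s1 / a0) ** 2 + (a1 * s0 / a0**2) ** 2)
    return float(value), float(sigma)


def strand_break_index(series: AreaSeries, component: str = "C1s_286"):
    """Fractional start-to-end decrease of the backbone C1s 286 eV signal.

    Returns ``(value, sigma)``; 0 means no change, 0.5 means the normalized
    component area halved over the exposure.
    """
    return _endpoint_index(*series.endpoint_values(component))


def base_damage_index(series: AreaSeries):
    """Fractional start-to-end decrease of the total condensed-phase N1s signal."""
    labels = [lab for lab in series.table["component"].unique()
              if not series.table[series.table["component"] == lab]
              ["is_gas_phase"].iloc[0]]
    if not labels:
        raise ValueError("no condensed-phase nitrogen components in series")

    def summed(row_idx):
        vals = [series.endpoint_values(lab)[row_idx] for lab in labels]
        a = sum(v for v, _ in vals)
        s = float(np.sqrt(sum(sig**2 for _, sig in vals)))
        return a, s

    return _endpoint_index(summed(0), summed(1))


def water_per_nucleotide(
    o1s_fit: RegionFitResult,
    p2p_fit: RegionFitResult,
    rsf: dict[str, float] | None = None,
    water_component: str = "O1s_535",
):
    """Average number of water molecules per nucleotide.

    RSF-corrected water O1s area over RSF-corrected total P2p area; the
    conversion assumes one phosphorus per nucleotide (logged).  Returns
    ``(value, sigma)``.
    """
    rsf = rsf if rsf is not None else load_rsf()
    for key in ("O1s", "P2p"):
        if key not in rsf:
            raise KeyError(f"rsf table lacks an entry for {key}")
    if water_component not in o1s_fit.component_areas:
        raise KeyError(f"O1s fit has no component {water_component!r}")
    a_w, s_w = o1s_fit.component_areas[water_component]
    a_p = sum(a for a, _ in p2p_fit.component_areas.values())
    s_p = float(np.sqrt(sum(s**2 for _, s in p2p_fit.component_areas.values())))
    if a_p <= 0:
        raise ValueError("P2p total area <= 0")
    log.info("water per nucleotide assumes one phosphorus per nucleotide")
    value = (a_w / rsf["O1s"]) / (a_p / rsf["P2p"])
    if a_w > 0:
        sigma = value * np.sqrt((s_w / a_w) ** 2 + (s_p / a_p) ** 2)
    else:
        sigma = (s_w / rsf["O1s"]) / (a_p / rsf["P2p"])
    return float(value), float(sigma)


@dataclass
class DamageReport:
    """Scalar damage/hydration summary of one irradiation series."""

    strand_break_index: float
    strand_break_sigma: float
    base_damage_index: float
    base_damage_sigma: float
    water_per_nucleotide: float | None
    water_sigma: float | None
    end_start_ratios: dict[str, float]
    condition: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "strand_break_index": self.strand_break_index,
            "strand_break_sigma": self.strand_break_sigma,
            "base_damage_index": self.base_damage_index,
            "base_damage_sigma": self.base_damage_sigma,
            "water_per_nucleotide": self.water_per_nucleotide,
            "water_sigma": self.water_sigma,
            "end_start_ratios": self.end_start_ratios,
            "condition": self.condition,
        }


def water_per_nucleotide_table(
    table: pd.DataFrame,
    rsf: dict[str, float] | None = None,
    water_component: str = "O1s_535",
    timepoint: float | None = None,
):
    """Waters per nucleotide from a raw-area table (first timepoint by default)."""
    rsf = rsf if rsf is not None else load_rsf()
    for key in ("O1s", "P2p"):
        if key not in rsf:
            raise KeyError(f"rsf table lacks an entry for {key}")
    if timepoint is None:
        timepoint = float(table["timepoint_s"].min())
    at_t = table[table["timepoint_s"] == timepoint]
    wat = at_t[at_t["component"] == water_component]
    p2p = at_t[at_t["region"] == "P2p"]
    if wat.empty or p2p.empty:
        raise KeyError(
            f"need {water_component!r} and P2p areas at t={timepoint:g} s"
        )
    a_w, s_w = float(wat["area"].iloc[0]), float(wat["sigma"].iloc[0])
    a_p = float(p2p["area"].sum())
    s_p = float(np.sqrt((p2p["sigma"] ** 2).sum()))
    if a_p <= 0:
        raise ValueError("P2p total area <= 0")
    log.info("water per nucleotide assumes one phosphorus per nucleotide")
    value = (a_w / rsf["O1s"]) / (a_p / rsf["P2p"])
    if a_w > 0:
        sigma = value * np.sqrt((s_w / a_w) ** 2 + (s_p / a_p) ** 2)
    else:
        sigma = (s_w / rsf["O1s"]) / (a_p / rsf["P2p"])
    return float(value), float(sigma)


def damage_report_table(
    table: pd.DataFrame,
    rsf: dict[str, float] | None = None,
    condition: dict | None = None,
) -> DamageReport:
    """Assemble the scalar damage indices from a raw-area table."""
    series = normalize_series_table(table)
    sbi, sbi_s = strand_break_index(series["C1s"])
    bdi, bdi_s = base_damage_index(series["N1s"])
    wpn = wpn_s = None
    try:
        wpn, wpn_s = water_per_nucleotide_table(table, rsf=rsf)
    except (KeyError, ValueError):
        log.warning("water-per-nucleotide not computed (missing O1s water "
                    "or P2p areas)")
    ratios = {}
    for region, ser in series.items():
        for lab in ser.table["component"].unique():
            (a0, _), (a1, _) = ser.endpoint_values(lab)
            ratios[lab] = float(a1 / a0) if a0 > 0 else float("nan")
    return DamageReport(
        strand_break_index=sbi, strand_break_sigma=sbi_s,
        base_damage_index=bdi, base_damage_sigma=bdi_s,
        water_per_nucleotide=wpn, water_sigma=wpn_s,
        end_start_ratios=ratios,
        condition=condition or {},
    )


def damage_report(
    series: dict[str, AreaSeries],
    fits: dict[str, list[RegionFitResult]] | None = None,
    rsf: dict[str, float] | None = None,
    condition: dict | None = None,
) -> DamageReport:
    """Assemble the scalar indices from normalized series (and fits, for water)."""
    sbi, sbi_s = strand_break_index(series["C1s"])
    bdi, bdi_s = base_damage_index(series["N1s"])
    wpn = wpn_s = None
    if fits is not None and "O1s" in fits and "P2p" in fits:
        o1s = sorted(fits["O1s"], key=lambda f: f.spectrum.timepoint)[0]
        p2p = sorted(fits["P2p"], key=lambda f: f.spectrum.timepoint)[0]
        wpn, wpn_s = water_per_nucleotide(o1s, p2p, rsf=rsf)
    ratios = {}
    for region, ser in series.items():
        for lab in ser.table["component"].unique():
            (a0, _), (a1, _) = ser.endpoint_values(lab)
            ratios[lab] = float(a1 / a0) if a0 > 0 else float("nan")
    return DamageReport(
        strand_break_index=sbi, strand_break_sigma=sbi_s,
        base_damage_index=bdi, base_damage_sigma=bdi_s,
        water_per_nucleotide=wpn, water_sigma=wpn_s,
        end_start_ratios=ratios,
        condition=condition or {},
    )
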