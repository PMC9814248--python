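"""Peak-model registry: components, constraints, and region models.

The default registry encodes the standard core-level assignment scheme for
irradiated DNA films: four C1s components (hydrocarbon 285 eV; C-O/C-N
286-287 eV; C=O/C=N 288 eV; urea-like N-(C=O)-N 289 eV), two condensed-phase
N1s components plus the gas-phase N2 line, two condensed O1s components plus
gas-phase water, and the spin-orbit-split P2p doublet (2p3/2 / 2p1/2, 2:1
area ratio, 1.0 eV splitting) that serves as the internal reference — DNA
carries exactly one phosphorus per nucleotide.

Centers given as literature ranges are represented by the range midpoint
with widened bounds (+-0.75 eV instead of the default +-0.5 eV).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

__all__ = [
    "PeakComponent",
    "DoubletLink",
    "RegionModel",
    "default_region_models",
    "load_region_models",
    "dump_region_models",
]

# global width bounds (FWHM, eV); centers default to +-0.5 eV around the
# assigned value (+-0.75 eV for ranged literature entries)
GAUSS_FWHM_BOUNDS = (0.6, 2.5)
LORENTZ_FWHM_BOUNDS = (0.0, 0.6)
CENTER_HALFWIDTH = 0.5
CENTER_HALFWIDTH_RANGED = 0.75


@dataclass
class PeakComponent:
    """One Voigt component of a region model.

    ``center`` / ``center_bounds`` are binding energies in eV; widths are
    FWHM values in eV; ``area`` is in counts*eV.  ``is_gas_phase`` marks
    lines that report the atmosphere (gas-phase N2, water vapour) rather
    than the DNA film; they are fitted but excluded from damage metrics.
    """

    label: str
    center: float
    assigned_bonds: tuple[str, ...] = ()
    group: str = ""
    center_bounds: tuple[float, float] | None = None
    gaussian_width: float = 1.3
    lorentzian_width: float = 0.2
    gaussian_bounds: tuple[float, float] = GAUSS_FWHM_BOUNDS
    lorentzian_bounds: tuple[float, float] = LORENTZ_FWHM_BOUNDS
    area: float = 1.0
    is_gas_phase: bool = False

    def __post_init__(self):
        if self.center_bounds is None:
            self.center_bounds = (
                self.center - CENTER_HALFWIDTH,
                self.center + CENTER_HALFWIDTH,
            )
        lo, hi = self.center_bounds
        if not lo <= self.center <= hi:
            raise ValueError(
                f"{self.label}: center {self.center} outside bounds {self.center_bounds}"
            )
        if self.area < 0:
            raise ValueError(f"{self.label}: negative area")
        if self.gaussian_width < 0 or self.lorentzian_width < 0:
            raise ValueError(f"{self.label}: negative width")


@dataclass
class DoubletLink:
    """Ties a follower component to a primary one.

    The follower's area is ``area_ratio`` times the primary's and its center
    sits ``splitting`` eV above the primary's; widths are shared.  For a
    2p3/2 / 2p1/2 spin-orbit pair the statistical ratio is 1:2 relative to
    the 3/2 line.
    """

    primary: str
    follower: str
    area_ratio: float = 0.5
    splitting: float = 1.0

    def __post_init__(self):
        if self.area_ratio <= 0:
            raise ValueError("doublet area ratio must be positive")
        if self.primary == self.follower:
            raise ValueError("doublet must reference two distinct components")


@dataclass
class RegionModel:
    """Deconvolution model of one core-level region."""

    region_label: str
    components: list[PeakComponent]
    doublets: list[DoubletLink] = field(default_factory=list)
    share_gaussian_width: bool = False
    share_lorentzian_width: bool = False
    background: str = "shirley"

    def __post_init__(self):
        labels = [c.label for c in self.components]
        if len(set(labels)) != len(labels):
            raise ValueError(f"{self.region_label}: duplicate component labels")
        for d in self.doublets:
            for lab in (d.primary, d.follower):
                if lab not in labels:
                    raise ValueError(
                        f"{self.region_label}: doublet references unknown component {lab!r}"
                    )
        if self.background not in ("shirley", "linear"):
            raise ValueError(f"unknown background type {self.background!r}")

    def __getitem__(self, label: str) -> PeakComponent:
        for c in self.components:
            if c.label == label:
                return c
        raise KeyError(label)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.components]

    @property
    def follower_labels(self) -> set[str]:
        return {d.follower for d in self.doublets}

    def copy(self) -> "RegionModel":
        return RegionModel(
            region_label=self.region_label,
            components=[replace(c) for c in self.components],
            doublets=[replace(d) for d in self.doublets],
            share_gaussian_width=self.share_gaussian_width,
            share_lorentzian_width=self.share_lorentzian_width,
            background=self.background,
        )


def _comp(label, center, bonds, group, ranged=False, gas=False, area=1.0):
    hw = CENTER_HALFWIDTH_RANGED if ranged else CENTER_HALFWIDTH
    return PeakComponent(
        label=label,
        center=center,
        assigned_bonds=tuple(bonds),
        group=group,
        center_bounds=(center - hw, center + hw),
        is_gas_phase=gas,
        area=area,
    )


def default_region_models() -> dict[str, RegionModel]:
    """The standard DNA assignment scheme, one model per region.

    Multi-component regions share one Gaussian and one Lorentzian FWHM
    across their components: the Gaussian broadening is instrumental and
    identical within a scan, lifetime widths of one core level are
    comparable, and releasing every width independently makes heavily
    overlapping deconvolutions unidentifiable (the covariance turns
    rank-deficient and the reported area uncertainties lose calibration).
    """
    c1s = RegionModel(
        "C1s",
        [
            _comp("C1s_285", 285.0, ["C-C", "C-H"], "All"),
            _comp("C1s_286", 286.5, ["C-O", "C-N"], "All", ranged=True),
            _comp("C1s_288", 288.0, ["C=O", "C=N", "C-NH2"], "Bases"),
            _comp("C1s_289", 289.0, ["N-(C=O)-N"], "Bases"),
        ],
        share_gaussian_width=True,
        share_lorentzian_width=True,
    )
    n1s = RegionModel(
        "N1s",
        [
            _comp("N1s_399", 399.0, ["N=C", "-N="], "Bases", ranged=True),
            _comp("N1s_401", 401.0, ["NC3", "-NH2", "O=C-N-C=O"], "Bases", ranged=True),
            _comp("N1s_405", 405.5, ["N2"], "Nitrogen", ranged=True, gas=True),
        ],
        share_gaussian_width=True,
        share_lorentzian_width=True,
    )
    o1s = RegionModel(
        "O1s",
        [
            _comp("O1s_531", 531.0, ["C=O", "P=O"], "Bases, backbone"),
            _comp("O1s_532", 532.5, ["C-O-C", "C-O-P", "C-OH"], "Sugar, backbone",
                  ranged=True),
            _comp("O1s_535", 535.0, ["H2O"], "Water", ranged=True, gas=True),
        ],
        share_gaussian_width=True,
        share_lorentzian_width=True,
    )
    p2p = RegionModel(
        "P2p",
        [
            _comp("P2p_32", 133.0, ["P2p3/2"], "Backbone", area=1.0),
            _comp("P2p_12", 134.0, ["P2p1/2"], "Backbone", area=0.5),
        ],
        doublets=[DoubletLink(primary="P2p_32", follower="P2p_12",
                              area_ratio=0.5, splitting=1.0)],
    )
    return {"C1s": c1s, "N1s": n1s, "O1s": o1s, "P2p": p2p}


# ---------------------------------------------------------------------------
# serialization

def _model_to_dict(m: RegionModel) -> dict:
    return {
        "region_label": m.region_label,
        "share_gaussian_width": m.share_gaussian_width,
        "share_lorentzian_width": m.share_lorentzian_width,
        "background": m.background,
        "components": [
            {
                "label": c.label,
                "center": c.center,
                "center_bounds": list(c.center_bounds),
                "assigned_bonds": list(c.assigned_bonds),
                "group": c.group,
                "gaussian_width": c.gaussian_width,
                "lorentzian_width": c.lorentzian_width,
                "gaussian_bounds": list(c.gaussian_bounds),
                "lorentzian_bounds": list(c.lorentzian_bounds),
                "area": c.area,
                "is_gas_phase": c.is_gas_phase,
            }
            for c in m.components
        ],
        "doublets": [
            {"primary": d.primary, "follower": d.follower,
             "area_ratio": d.area_ratio, "splitting": d.splitting}
            for d in m.doublets
        ],
    }


def _model_from_dict(d: dict) -> RegionModel:
    comps = [
        PeakComponent(
            label=c["label"],
            center=c["center"],
            center_bounds=tuple(c["center_bounds"]) if c.get("center_bounds") else None,
            assigned_bonds=tuple(c.get("assigned_bonds", ())),
            group=c.get("group", ""),
            gaussian_width=c.get("gaussian_width", 1.3),
            lorentzian_width=c.get("lorentzian_width", 0.2),
            gaussian_bounds=tuple(c.get("gaussian_bounds", GAUSS_FWHM_BOUNDS)),
            lorentzian_bounds=tuple(c.get("lorentzian_bounds", LORENTZ_FWHM_BOUNDS)),
            area=c.get("area", 1.0),
            is_gas_phase=c.get("is_gas_phase", False),
        )
        for c in d["components"]
    ]
    doublets = [DoubletLink(**dd) for dd in d.get("doublets", [])]
    return RegionModel(
        region_label=d["region_label"],
        components=comps,
        doublets=doublets,
        share_gaussian_width=d.get("share_gaussian_width", False),
        share_lorentzian_width=d.get("share_lorentzian_width", False),
        background=d.get("background", "shirley"),
    )


def dump_region_models(models: dict[str, RegionModel], path) -> Path:
    """Serialize region models to YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    payload = {name: _model_to_dict(m) for name, m in models.items()}
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(payload, fh, indent=2)
        else:
            yaml.safe_dump(payload, fh, sort_keys=False)
    return path


def load_region_models(path) -> dict[str, RegionModel]:
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    return {name: _model_from_dict(d) for name, d in payload.items()}
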