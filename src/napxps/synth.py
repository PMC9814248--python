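"""Synthetic spectrum time series with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes for an irradiated DNA film monitored by XPS: each core-level region
is a sum of Voigt components at the standard assignment binding energies on
a Shirley-consistent step background, component areas decay (or grow) in
time under first-order kinetics, and counts are Poisson with a scale chosen
so the largest peak of a region reaches a target peak signal-to-noise
ratio.  The :class:`TruthRecord` retains every generating parameter, so any
downstream estimate can be checked against the programmed truth.

The three preset scenarios encode the qualitative experimental contrasts as
generator truth, not as measured values: the backbone C-O-P decay rate
(C1s 286 eV) under water atmosphere is exactly twice the nitrogen-atmosphere
rate, the total-nitrogen decay rate exactly three times, and the vacuum
rates sit slightly below the nitrogen ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .lineshapes import voigt_profile
from .peakmodel import RegionModel, default_region_models
from .spectra import Spectrum, SpectrumSeries

__all__ = ["DamageScenario", "TruthRecord", "generate_series", "preset_scenarios"]

#: Poisson means above this are considered unphysical for a counting channel
MAX_PEAK_COUNTS = 1e12

DEFAULT_WINDOWS = {
    "C1s": (280.0, 294.0),
    "N1s": (394.0, 410.0),
    "O1s": (525.0, 542.0),
    "P2p": (127.0, 140.0),
}

# default exposure: 10 timepoints over 2 h (spacing is a stated assumption,
# not a measured quantity)
DEFAULT_TIMEPOINTS = tuple(np.linspace(0.0, 7200.0, 10))

# Scofield RSF defaults used to convert a programmed waters-per-nucleotide
# number into an O1s water peak area (kept identical to data/rsf.tsv)
_RSF = {"C1s": 1.00, "N1s": 1.80, "O1s": 2.93, "P2p": 1.19}


@dataclass
class DamageScenario:
    """Generating conditions for one atmosphere.

    ``initial_areas`` are in units where the total P2p area at t = 0 is
    1.0 (the internal phosphorus reference); ``rates`` are first-order rate
    constants in 1/s (negative values grow).  ``snr`` is the peak
    signal-to-noise target of the largest peak per region
    (``None`` disables noise).  The background couples to the total region
    area: baseline and step height are fractions of the mean spectral
    density, so damage shrinks the background along with the peaks and the
    Shirley stage is exercised nontrivially.
    """

    condition: str = "vacuum"
    models: dict[str, RegionModel] = field(default_factory=default_region_models)
    initial_areas: dict[str, float] = field(default_factory=dict)
    rates: dict[str, float] = field(default_factory=dict)
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    grid_step: float = 0.05
    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS))
    snr: float | None = 100.0
    p2p_profile: tuple[float, ...] | None = None  # per-timepoint P2p total
    bg_base_frac: float = 0.5
    bg_step_frac: float = 0.4
    pressure_mbar: float = 1e-8

    def __post_init__(self):
        if any(a < 0 for a in self.initial_areas.values()):
            raise ValueError("initial areas must be >= 0")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.snr is not None and not (self.snr > 0):
            raise ValueError("snr must be positive (or None to disable noise)")

    def area_at(self, label: str, t: float) -> float:
        a0 = self.initial_areas.get(label, 0.0)
        k = self.rates.get(label, 0.0)
        return a0 * float(np.exp(-k * t))

    def p2p_total(self, i_time: int) -> float:
        if self.p2p_profile is not None:
            return self.p2p_profile[i_time]
        t = self.timepoints[i_time]
        return sum(self.area_at(c.label, t)
                   for c in self.models["P2p"].components)


@dataclass
class TruthRecord:
    """Everything needed to recompute the noiseless series bit-identically."""

    condition: str
    seed: int | None
    timepoints: list[float]
    rates: dict[str, float]
    initial_areas: dict[str, float]
    scales: dict[str, float]                      # counts per unit area, per region
    noiseless_areas: dict[str, dict[str, list[float]]]  # region -> label -> series
    centers: dict[str, float]
    gaussian_fwhm: dict[str, float]
    lorentzian_fwhm: dict[str, float]
    snr: float | None

    def normalized_area(self, label: str, i_time: int, region: str) -> float:
        return self.noiseless_areas[region][label][i_time]

    def to_json(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        return cls(**json.load(open(path)))


def _noiseless_region(sc: DamageScenario, region: str, i_time: int):
    """Unit-scale noiseless curve (area units) and per-component areas."""
    t = sc.timepoints[i_time]
    model = sc.models[region]
    lo, hi = sc.windows[region]
    x = np.arange(lo, hi + 0.5 * sc.grid_step, sc.grid_step)
    y = np.zeros_like(x)
    areas: dict[str, float] = {}
    followers = model.follower_labels
    for c in model.components:
        if c.label in followers:
            continue
        a = sc.area_at(c.label, t)
        if region == "P2p" and sc.p2p_profile is not None:
            a = a * sc.p2p_total(i_time) / max(sc.p2p_total(0), 1e-300)
        areas[c.label] = a
    for d in model.doublets:
        areas[d.follower] = d.area_ratio * areas[d.primary]
    for c in model.components:
        a = areas[c.label]
        if a > 0:
            y += voigt_profile(x, c.center, a, c.gaussian_width,
                               c.lorentzian_width)
    total = sum(areas.values())
    width = hi - lo
    density = total / width
    base = sc.bg_base_frac * density
    if total > 0:
        cum = cumulative_trapezoid(y, x, initial=0.0)
        bg = base + sc.bg_step_frac * density * cum / cum[-1]
    else:
        bg = np.full_like(x, base)
    return x, y + bg, y, areas


def generate_series(sc: DamageScenario, seed: int | None = None):
    """Generate a :class:`SpectrumSeries` plus its :class:`TruthRecord`.

    Deterministic for a fixed ``(scenario, seed)``.  The per-region count
    scale is fixed at the first timepoint so that the largest peak reaches
    the SNR target (``peak / sqrt(peak + background)``), then held constant
    so later timepoints genuinely lose intensity.
    """
    rng = np.random.default_rng(seed)
    spectra: list[Spectrum] = []
    noiseless: dict[str, dict[str, list[float]]] = {}

    # one global intensity scale (all regions share the detector scale, so
    # cross-region quantification stays meaningful); the tallest peak of the
    # first timepoint reaches the SNR target
    s_max, b_at_peak = 0.0, 0.0
    for region in sorted(sc.models):
        _, curve0, net0, _ = _noiseless_region(sc, region, 0)
        if float(net0.max()) > s_max:
            s_max = float(net0.max())
            b_at_peak = float(curve0[np.argmax(net0)] - net0.max())
    if s_max <= 0:
        raise ValueError("no signal in any region at the first timepoint")
    if sc.snr is None:
        scale = 1.0
    else:
        scale = sc.snr**2 * (s_max + b_at_peak) / s_max**2
        peak_counts = scale * s_max
        if peak_counts > MAX_PEAK_COUNTS:
            limit = sc.snr * np.sqrt(MAX_PEAK_COUNTS / peak_counts)
            raise ValueError(
                f"SNR {sc.snr:g} needs {peak_counts:.3g} peak counts; the "
                f"limiting SNR at this grid step is {limit:.3g}"
            )
    scales = {region: scale for region in sc.models}

    for region in sorted(sc.models):
        noiseless[region] = {c.label: [] for c in sc.models[region].components}

        for i_time, t in enumerate(sc.timepoints):
            x, curve, _, areas = _noiseless_region(sc, region, i_time)
            for lab, a in areas.items():
                noiseless[region][lab].append(a)
            lam = scale * curve
            counts = rng.poisson(lam).astype(float) if sc.snr is not None else lam
            spectra.append(Spectrum(
                region_label=region,
                binding_energy=x,
                counts=counts,
                timepoint=t,
                atmosphere=sc.condition,
                metadata={"scenario": sc.condition, "scale": scale},
            ))

    series = SpectrumSeries(
        spectra,
        condition={"atmosphere": sc.condition, "pressure_mbar": sc.pressure_mbar},
    )
    all_models = [c for m in sc.models.values() for c in m.components]
    truth = TruthRecord(
        condition=sc.condition,
        seed=seed,
        timepoints=list(sc.timepoints),
        rates=dict(sc.rates),
        initial_areas=dict(sc.initial_areas),
        scales=scales,
        noiseless_areas=noiseless,
        centers={c.label: c.center for c in all_models},
        gaussian_fwhm={c.label: c.gaussian_width for c in all_models},
        lorentzian_fwhm={c.label: c.lorentzian_width for c in all_models},
        snr=sc.snr,
    )
    return series, truth


# ---------------------------------------------------------------------------
# preset scenarios

_T_END = DEFAULT_TIMEPOINTS[-1]


def _per_second(k_times_t: float) -> float:
    return k_times_t / _T_END


#: programmed dimensionless decays k * t_end per condition and component.
#: H2O C1s_286 is exactly 2x N2's; H2O N decay exactly 3x N2's; vacuum sits
#: slightly below N2 with base damage clearly weaker than strand breaks.
_PRESET_KT = {
    "vacuum": {"C1s_285": 0.00, "C1s_286": 0.13, "C1s_288": 0.02, "C1s_289": 0.02,
               "N1s_399": 0.06, "N1s_401": 0.06,
               "O1s_531": 0.02, "O1s_532": 0.13},
    "N2":     {"C1s_285": 0.00, "C1s_286": 0.15, "C1s_288": 0.03, "C1s_289": 0.03,
               "N1s_399": 0.08, "N1s_401": 0.08,
               "O1s_531": 0.03, "O1s_532": 0.15},
    "H2O":    {"C1s_285": 0.01, "C1s_286": 0.30, "C1s_288": 0.10, "C1s_289": 0.08,
               "N1s_399": 0.24, "N1s_401": 0.24,
               "O1s_531": 0.06, "O1s_532": 0.30},
}

#: waters per nucleotide programmed into the O1s water component
_PRESET_WPN = {"vacuum": 0.25, "N2": 0.05, "H2O": 1.50}

_INITIAL_AREAS = {
    "C1s_285": 0.90, "C1s_286": 1.10, "C1s_288": 0.55, "C1s_289": 0.30,
    "N1s_399": 0.55, "N1s_401": 0.45,
    "O1s_531": 0.80, "O1s_532": 1.40,
    "P2p_32": 2.0 / 3.0, "P2p_12": 1.0 / 3.0,
}


def preset_scenarios(snr: float | None = 100.0) -> dict[str, DamageScenario]:
    """The three standard study conditions: vacuum, N2, and H2O."""
    out: dict[str, DamageScenario] = {}
    for cond in ("vacuum", "N2", "H2O"):
        init = dict(_INITIAL_AREAS)
        # O1s water component scaled to the programmed hydration level
        # (one phosphorus per nucleotide, Scofield RSFs)
        init["O1s_535"] = _PRESET_WPN[cond] * _RSF["O1s"] / _RSF["P2p"] * 1.0
        init["N1s_405"] = 0.25 if cond == "N2" else 0.0
        rates = {lab: _per_second(kt) for lab, kt in _PRESET_KT[cond].items()}
        out[cond] = DamageScenario(
            condition=cond,
            initial_areas=init,
            rates=rates,
            snr=snr,
            pressure_mbar=1e-8 if cond == "vacuum" else 10.0,
        )
    return out
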