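"""Spectrum containers and delimited-text / VAMAS-subset I/O.

A :class:`Spectrum` is one core-level region scan: a strictly ascending
binding-energy grid (eV) with nonnegative counts plus acquisition metadata.
The exchange format is plain delimited text: a ``# key: value`` header block
followed by two numeric columns (binding energy, counts).  A minimal
read-only subset of the VAMAS ISO 14976 format is supported for single-block
REGULAR scans.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumSeries",
    "SpectrumFormatError",
    "SpectrumValidationError",
    "WindowError",
    "read_spectrum",
    "write_spectrum",
    "extract_region",
    "write_report",
    "read_report",
]

KNOWN_REGIONS = ("C1s", "O1s", "N1s", "P2p")
ATMOSPHERES = ("vacuum", "N2", "H2O")
AL_KALPHA_EV = 1486.6

#: grid non-uniformity above which a warning (10 %) or an error (25 %) fires
GRID_WARN_FRAC = 0.10
GRID_ERROR_FRAC = 0.25


class SpectrumFormatError(ValueError):
    """Raised when a file cannot be parsed as a spectrum."""


class SpectrumValidationError(ValueError):
    """Raised when parsed data violate the Spectrum invariants."""


class WindowError(ValueError):
    """Raised when a requested binding-energy window misses the grid."""


@dataclass(frozen=True)
class Spectrum:
    """One core-level region scan on a binding-energy grid.

    Parameters
    ----------
    region_label : str
        Core-level name (``C1s``, ``O1s``, ``N1s``, ``P2p`` or user-defined).
    binding_energy : ndarray
        Strictly ascending grid, eV.
    counts : ndarray
        Nonnegative finite intensities, one per grid point.
    timepoint : float
        Seconds since the start of irradiation.
    atmosphere : str
        One of ``vacuum``, ``N2``, ``H2O``.
    excitation_energy : float
        Photon energy in eV (Al K-alpha by default).
    """

    region_label: str
    binding_energy: np.ndarray
    counts: np.ndarray
    timepoint: float = 0.0
    atmosphere: str = "vacuum"
    excitation_energy: float = AL_KALPHA_EV
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        be = np.asarray(self.binding_energy, dtype=float)
        ct = np.asarray(self.counts, dtype=float)
        if be.ndim != 1 or ct.ndim != 1:
            raise SpectrumValidationError("binding_energy and counts must be 1-D")
        if be.size != ct.size:
            raise SpectrumValidationError(
                f"grid length {be.size} != counts length {ct.size}"
            )
        if be.size < 2:
            raise SpectrumValidationError("a spectrum needs at least two points")
        if not np.all(np.isfinite(be)) or not np.all(np.isfinite(ct)):
            raise SpectrumValidationError("non-finite values in spectrum")
        order = np.argsort(be, kind="stable")
        be, ct = be[order], ct[order]
        d = np.diff(be)
        if np.any(d <= 0):
            i = int(np.argmax(d <= 0))
            raise SpectrumValidationError(
                f"binding-energy grid not strictly monotonic near {be[i]:g} eV"
            )
        bad = np.flatnonzero(ct < 0)
        if bad.size:
            raise SpectrumValidationError(
                f"negative counts at row {bad[0]} (BE = {be[bad[0]]:g} eV)"
            )
        spread = (d.max() - d.min()) / d.mean()
        if spread > GRID_ERROR_FRAC:
            raise SpectrumValidationError(
                f"grid spacing varies by {spread:.0%} (> {GRID_ERROR_FRAC:.0%})"
            )
        if spread > GRID_WARN_FRAC:
            warnings.warn(
                f"grid spacing varies by {spread:.0%}; Shirley integration "
                "assumes a near-uniform grid",
                stacklevel=2,
            )
        if self.atmosphere not in ATMOSPHERES:
            raise SpectrumValidationError(
                f"atmosphere {self.atmosphere!r} not in {ATMOSPHERES}"
            )
        object.__setattr__(self, "binding_energy", be)
        object.__setattr__(self, "counts", ct)

    @property
    def kinetic_energy(self) -> np.ndarray:
        """Kinetic-energy axis, derived on demand (never stored)."""
        return self.excitation_energy - self.binding_energy

    @property
    def step(self) -> float:
        return float(np.mean(np.diff(self.binding_energy)))

    def with_counts(self, counts: np.ndarray) -> "Spectrum":
        return replace(self, counts=np.asarray(counts, dtype=float))

    def __len__(self) -> int:
        return self.binding_energy.size


@dataclass
class SpectrumSeries:
    """Spectra grouped by region and sorted by timepoint.

    ``condition`` carries free-form metadata such as gas identity and
    pressure (mbar).
    """

    spectra: list[Spectrum]
    condition: dict = field(default_factory=dict)

    def __post_init__(self):
        self.spectra = sorted(
            self.spectra, key=lambda s: (s.region_label, s.timepoint)
        )
        for region in self.regions:
            tps = [s.timepoint for s in self.spectra if s.region_label == region]
            if np.any(np.diff(tps) <= 0):
                raise SpectrumValidationError(
                    f"duplicated or non-increasing timepoints in region {region}"
                )

    @property
    def regions(self) -> list[str]:
        return sorted({s.region_label for s in self.spectra})

    def timepoints(self, region: str) -> np.ndarray:
        return np.array(
            [s.timepoint for s in self.spectra if s.region_label == region]
        )

    def get(self, region: str, timepoint: float) -> Spectrum:
        for s in self.spectra:
            if s.region_label == region and s.timepoint == timepoint:
                return s
        raise KeyError(f"no spectrum for {region} at t = {timepoint}")

    def by_region(self, region: str) -> list[Spectrum]:
        return [s for s in self.spectra if s.region_label == region]

    def __len__(self) -> int:
        return len(self.spectra)


# ---------------------------------------------------------------------------
# delimited text I/O

_META_KEYS = {
    "region": ("region_label", str),
    "timepoint_s": ("timepoint", float),
    "atmosphere": ("atmosphere", str),
    "excitation_energy_ev": ("excitation_energy", float),
}


def read_spectrum(path, dialect: str = "tsv") -> Spectrum:
    """Read one spectrum from a delimited text or VAMAS-subset file.

    The text dialects expect an optional ``# key: value`` header block and
    two numeric columns (binding energy in eV, counts).  Row order is
    irrelevant: the grid is normalized to ascending order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "vamas-subset":
        return _read_vamas(path)
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    meta: dict[str, object] = {}
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = [p for p in line.replace(sep, " ").split() if p]
            if len(parts) < 2:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: expected two columns (BE, counts)"
                )
            try:
                be, ct = float(parts[0]), float(parts[1])
            except ValueError:
                if rows:
                    raise SpectrumFormatError(
                        f"{path}:{lineno}: non-numeric data row {line!r}"
                    )
                continue  # tolerated column-title line
            if ct < 0:
                raise SpectrumValidationError(
                    f"{path}:{lineno}: negative counts ({ct:g}) at BE {be:g} eV"
                )
            rows.append((be, ct))
    if len(rows) < 2:
        raise SpectrumFormatError(f"{path}: no numeric data rows found")
    arr = np.array(rows)
    kwargs: dict[str, object] = {}
    extra: dict[str, object] = {}
    for key, val in meta.items():
        if key in _META_KEYS:
            attr, conv = _META_KEYS[key]
            kwargs[attr] = conv(val)
        else:
            extra[key] = val
    kwargs.setdefault("region_label", path.stem)
    return Spectrum(
        binding_energy=arr[:, 0], counts=arr[:, 1], metadata=extra, **kwargs
    )


def write_spectrum(s: Spectrum, path, dialect: str = "tsv") -> Path:
    """Write a spectrum in the delimited-text exchange format."""
    path = Path(path)
    sep = "\t" if dialect == "tsv" else ","
    with open(path, "w") as fh:
        fh.write(f"# region: {s.region_label}\n")
        fh.write(f"# timepoint_s: {s.timepoint:.10g}\n")
        fh.write(f"# atmosphere: {s.atmosphere}\n")
        fh.write(f"# excitation_energy_ev: {s.excitation_energy:.10g}\n")
        for k, v in s.metadata.items():
            fh.write(f"# {k}: {v}\n")
        for be, ct in zip(s.binding_energy, s.counts):
            fh.write(f"{float(be)!r}{sep}{float(ct)!r}\n")
    return path


def _read_vamas(path: Path) -> Spectrum:
    """Minimal VAMAS (ISO 14976) reader: single-block REGULAR scans only.

    Anything else — MAP experiments, multiple blocks, IRREGULAR abscissae,
    extra corresponding variables — is rejected loudly.  The parser is
    positional per the standard's fixed header order for the simplest
    NORM-experiment file with no optional items.
    """
    lines = [ln.rstrip("\n") for ln in open(path)]
    it = iter(enumerate(lines, start=1))

    def nxt() -> str:
        try:
            _, ln = next(it)
        except StopIteration:
            raise SpectrumFormatError(f"{path}: truncated VAMAS file")
        return ln.strip()

    ident = nxt()
    if not ident.startswith("VAMAS Surface Chemical Analysis"):
        raise SpectrumFormatError(f"{path}: missing VAMAS format identifier")
    for _ in range(3):  # institution, instrument model, operator
        nxt()
    nxt()  # experiment identifier
    n_comment = int(nxt())
    for _ in range(n_comment):
        nxt()
    exp_mode = nxt()
    if exp_mode != "NORM":
        raise SpectrumFormatError(
            f"{path}: unsupported experiment mode {exp_mode!r} (NORM only)"
        )
    scan_mode = nxt()
    if scan_mode != "REGULAR":
        raise SpectrumFormatError(
            f"{path}: unsupported scan mode {scan_mode!r} (REGULAR only)"
        )
    n_regions = int(nxt())
    n_exp_var = int(nxt())
    for _ in range(n_exp_var):
        nxt(), nxt()  # label, unit
    n_incl = int(nxt())
    if n_incl != 0:
        raise SpectrumFormatError(f"{path}: parameter inclusion lists unsupported")
    n_manual = int(nxt())
    if n_manual != 0:
        raise SpectrumFormatError(f"{path}: manually entered items unsupported")
    n_fut_exp = int(nxt())
    n_fut = int(nxt())
    if n_fut_exp or n_fut:
        raise SpectrumFormatError(f"{path}: future upgrade entries unsupported")
    n_blocks = int(nxt())
    if n_regions != 1 or n_blocks != 1:
        raise SpectrumFormatError(
            f"{path}: only single-block files supported (found {n_blocks})"
        )
    block_id = nxt()
    nxt()  # sample identifier
    for _ in range(7):  # year month day hour minute second GMT-offset
        nxt()
    n_blk_comment = int(nxt())
    for _ in range(n_blk_comment):
        nxt()
    technique = nxt()
    if technique not in ("XPS", "ESCA"):
        raise SpectrumFormatError(f"{path}: unsupported technique {technique!r}")
    source_label = nxt()
    source_energy = float(nxt())
    for _ in range(3):  # source strength, width x, width y
        nxt()
    for _ in range(2):  # polar/azimuth incidence angles
        nxt()
    nxt()  # analyzer mode
    nxt()  # analyzer pass energy
    nxt()  # analyzer work function
    nxt()  # target bias
    for _ in range(2):  # analysis width x/y
        nxt()
    for _ in range(2):  # analyzer take-off polar/azimuth
        nxt()
    species = nxt()
    transition = nxt()
    nxt()  # charge of detected particle
    abscissa_label = nxt()
    abscissa_unit = nxt()
    start = float(nxt())
    increment = float(nxt())
    n_corr = int(nxt())
    if n_corr != 1:
        raise SpectrumFormatError(
            f"{path}: exactly one corresponding variable supported (found {n_corr})"
        )
    nxt(), nxt()  # corresponding variable label, unit
    nxt()  # signal mode
    nxt()  # dwell
    n_scans = nxt()
    nxt()  # time correction
    nxt()  # sample normal polar
    nxt()  # sample normal azimuth
    nxt()  # sample rotation
    n_add = int(nxt())
    if n_add != 0:
        raise SpectrumFormatError(f"{path}: additional numerical parameters unsupported")
    n_ord = int(nxt())
    vmin = float(nxt())
    vmax = float(nxt())
    counts = np.array([float(nxt()) for _ in range(n_ord)])
    axis = start + increment * np.arange(n_ord)
    if abscissa_label.lower().startswith("kinetic"):
        be = source_energy - axis
    else:
        be = axis
    if not (counts.min() >= vmin - 1e-9 and counts.max() <= vmax + 1e-9):
        raise SpectrumFormatError(f"{path}: ordinate range check failed")
    region = f"{species}{transition}".replace(" ", "") or block_id
    return Spectrum(
        region_label=region,
        binding_energy=be,
        counts=counts,
        excitation_energy=source_energy,
        metadata={"source_label": source_label, "n_scans": n_scans,
                  "abscissa_unit": abscissa_unit},
    )


# ---------------------------------------------------------------------------
# region windowing

def extract_region(s: Spectrum, window: Sequence[float], min_points: int = 8) -> Spectrum:
    """Restrict a spectrum to a closed binding-energy window.

    Raises :class:`WindowError` if the intersection is empty or holds fewer
    than ``min_points`` grid points.
    """
    lo, hi = sorted(float(w) for w in window)
    mask = (s.binding_energy >= lo) & (s.binding_energy <= hi)
    n = int(mask.sum())
    if n == 0:
        raise WindowError(
            f"window [{lo:g}, {hi:g}] eV does not intersect the "
            f"{s.region_label} grid "
            f"[{s.binding_energy[0]:g}, {s.binding_energy[-1]:g}] eV"
        )
    if n < min_points:
        raise WindowError(
            f"window [{lo:g}, {hi:g}] eV overlaps the grid by only {n} points "
            f"(minimum {min_points})"
        )
    return replace(s, binding_energy=s.binding_energy[mask], counts=s.counts[mask])


# ---------------------------------------------------------------------------
# tabular report output

def write_report(tables: Mapping[str, object], path, overwrite: bool = False) -> list[Path]:
    """Write analysis tables to ``path`` (a directory).

    ``tables`` maps a base name to either a :class:`pandas.DataFrame`
    (written as TSV with full float precision) or a JSON-serializable
    mapping (written as ``.json``).  Returns the list of files written.
    Round-trip safe: :func:`read_report` reproduces the values exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, obj in tables.items():
        if isinstance(obj, pd.DataFrame):
            target = path / f"{name}.tsv"
        else:
            target = path / f"{name}.json"
        if target.exists() and not overwrite:
            raise FileExistsError(
                f"{target} exists; pass overwrite=True to replace it"
            )
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(target, sep="\t", index=False, float_format=None)
        else:
            with open(target, "w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True)
                fh.write("\n")
        written.append(target)
    return written


def read_report(path) -> dict[str, object]:
    """Read back everything :func:`write_report` wrote under ``path``."""
    path = Path(path)
    out: dict[str, object] = {}
    for f in sorted(path.glob("*.tsv")):
        out[f.stem] = pd.read_csv(f, sep="\t")
    for f in sorted(path.glob("*.json")):
        out[f.stem] = json.load(open(f))
    return out
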