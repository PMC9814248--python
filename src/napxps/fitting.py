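"""Constrained Voigt deconvolution of core-level regions.

The public surface follows the fitted-model idiom: build a
:class:`RegionFitModel` from a :class:`~napxps.spectra.Spectrum` and a
:class:`~napxps.peakmodel.RegionModel`, call :meth:`~RegionFitModel.fit`,
and work with the returned :class:`RegionFitResult` (fitted parameters,
covariance, per-area uncertainties, residuals, ``summary()``, ``plot()``).

The fit is a bound-constrained least-squares problem on
``counts - background - sum(Voigt components)``.  By default the Shirley
step is fitted jointly with the peaks: its shape follows the cumulative
fitted peak sum and its two endpoint levels are profiled out by linear
least squares inside every residual evaluation (a one-shot background
estimated from the raw data and frozen during optimization — the older
common practice — remains available, but it folds peak tails into the
endpoint means and biases overlapping components).  Counting statistics
enter through Poisson weights ``1/sqrt(max(counts, 1))``, so the residual
variance is ~1 per point and the Gauss-Newton covariance is calibrated in
absolute counts.

Uncertainties follow the standard matrix-inversion route: the covariance of
the free parameters is the residual-variance estimate times the inverse
Gauss-Newton normal matrix ``(J^T J)^-1`` at the optimum; per-component
area sigmas are read off (areas are direct parameters; linked doublet
followers scale by their area ratio).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares

from .background import linear_background, shirley_background
from .lineshapes import voigt_profile
from .peakmodel import RegionModel
from .spectra import Spectrum

__all__ = ["RegionFitModel", "RegionFitResult", "FitWarning", "estimate_uncertainties"]


class FitWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# parameter packing


@dataclass(frozen=True)
class _ParamSpec:
    names: tuple[str, ...]          # "<label>.<kind>" or "shared.gaussian_width"
    lower: np.ndarray
    upper: np.ndarray

    @property
    def n(self) -> int:
        return len(self.names)


def _build_param_spec(m: RegionModel, vary_centers, vary_widths, vary_areas,
                      vary_lorentzian=None):
    if vary_lorentzian is None:
        vary_lorentzian = vary_widths
    names, lo, hi = [], [], []
    followers = m.follower_labels
    for c in m.components:
        if c.label in followers:
            continue
        if vary_centers:
            names.append(f"{c.label}.center")
            lo.append(c.center_bounds[0])
            hi.append(c.center_bounds[1])
        if vary_areas:
            names.append(f"{c.label}.area")
            lo.append(0.0)
            hi.append(np.inf)
        if vary_widths and not m.share_gaussian_width:
            names.append(f"{c.label}.gaussian_width")
            lo.append(c.gaussian_bounds[0])
            hi.append(c.gaussian_bounds[1])
        if vary_lorentzian and not m.share_lorentzian_width:
            names.append(f"{c.label}.lorentzian_width")
            lo.append(c.lorentzian_bounds[0])
            hi.append(c.lorentzian_bounds[1])
    c0 = next(c for c in m.components if c.label not in followers)
    if vary_widths and m.share_gaussian_width:
        names.append("sharedG.gaussian_width")
        lo.append(c0.gaussian_bounds[0])
        hi.append(c0.gaussian_bounds[1])
    if vary_lorentzian and m.share_lorentzian_width:
        names.append("sharedL.lorentzian_width")
        lo.append(c0.lorentzian_bounds[0])
        hi.append(c0.lorentzian_bounds[1])
    return _ParamSpec(tuple(names), np.array(lo), np.array(hi))


def _pack(m: RegionModel, spec: _ParamSpec) -> np.ndarray:
    vals = []
    for name in spec.names:
        label, kind = name.split(".")
        if label in ("sharedG", "sharedL"):
            c = next(c for c in m.components if c.label not in m.follower_labels)
            vals.append(getattr(c, kind))
        else:
            vals.append(getattr(m[label], kind))
    return np.array(vals, dtype=float)


def _unpack(m: RegionModel, spec: _ParamSpec, x: np.ndarray) -> RegionModel:
    out = m.copy()
    shared_gw = shared_lw = None
    for name, v in zip(spec.names, x):
        label, kind = name.split(".")
        if label == "sharedG":
            shared_gw = float(v)
        elif label == "sharedL":
            shared_lw = float(v)
        else:
            setattr(out[label], kind, float(v))
    if shared_gw is not None:
        for c in out.components:
            c.gaussian_width = shared_gw
    if shared_lw is not None:
        for c in out.components:
            c.lorentzian_width = shared_lw
    for d in out.doublets:
        p, f = out[d.primary], out[d.follower]
        f.area = d.area_ratio * p.area
        f.center = p.center + d.splitting
        f.gaussian_width = p.gaussian_width
        f.lorentzian_width = p.lorentzian_width
        f.center_bounds = (f.center - 1e-9, f.center + 1e-9)
    return out


def _model_curve(m: RegionModel, x: np.ndarray) -> np.ndarray:
    y = np.zeros_like(x)
    for c in m.components:
        if c.area > 0 and (c.gaussian_width > 0 or c.lorentzian_width > 0):
            y += voigt_profile(x, c.center, c.area, c.gaussian_width,
                               c.lorentzian_width)
    return y


# ---------------------------------------------------------------------------
# model / results


class RegionFitModel:
    """Bound-constrained Voigt deconvolution of one region scan.

    Parameters
    ----------
    spectrum : Spectrum
        The region scan to fit.
    region_model : RegionModel
        Components, bounds, and constraints (doublet links, shared widths).
    weighting : {"poisson", "none"}
        Residual weights; Poisson weights calibrate the covariance for
        counting noise.
    vary_centers, vary_widths, vary_areas : bool
        Release or freeze parameter classes; frozen parameters keep their
        values from ``region_model``.
    n_edge_points, background_tol, background_max_iter :
        Shirley background controls (endpoint means over ``n_edge_points``,
        fixed-point tolerance, iteration cap).
    reiterate_background : bool
        Fit the Shirley step jointly with the peaks: the step is shaped by
        the cumulative fitted peak sum and its two endpoint levels are
        profiled out by linear least squares at every residual evaluation.
        Enabled by default — the classic one-shot data Shirley folds peak
        tails into its endpoint means and measurably biases overlapping
        components.  Set to False for the frozen data-derived background.
    """

    def __init__(
        self,
        spectrum: Spectrum,
        region_model: RegionModel,
        *,
        weighting: str = "poisson",
        vary_centers: bool = True,
        vary_widths: bool = True,
        vary_areas: bool = True,
        vary_lorentzian_widths: bool | None = None,
        n_edge_points: int = 5,
        background_tol: float = 1e-6,
        background_max_iter: int = 100,
        reiterate_background: bool = True,
    ):
        self.spectrum = spectrum
        self.region_model = region_model.copy()
        if weighting not in ("poisson", "none"):
            raise ValueError(f"unknown weighting {weighting!r}")
        self.weighting = weighting
        self.vary_centers = vary_centers
        self.vary_widths = vary_widths
        self.vary_areas = vary_areas
        self.vary_lorentzian_widths = vary_lorentzian_widths
        self.n_edge_points = n_edge_points
        self.background_tol = background_tol
        self.background_max_iter = background_max_iter
        self.reiterate_background = reiterate_background
        self._spec = _build_param_spec(
            region_model, vary_centers, vary_widths, vary_areas,
            vary_lorentzian=vary_lorentzian_widths,
        )
        n_free = self._spec.n
        if n_free and n_free >= len(spectrum) / 3:
            raise ValueError(
                f"{n_free} free parameters for {len(spectrum)} grid points "
                "(need free parameters < points / 3)"
            )
        x = spectrum.binding_energy
        for c in region_model.components:
            if not (x[0] <= c.center <= x[-1]):
                raise ValueError(
                    f"component {c.label} at {c.center:g} eV lies outside the "
                    f"spectrum window [{x[0]:g}, {x[-1]:g}] eV"
                )

    # -- background ---------------------------------------------------------

    def _background(self, y: np.ndarray):
        kwargs = dict(
            x=self.spectrum.binding_energy,
            y=y,
            n_edge_points=self.n_edge_points,
        )
        if self.region_model.background == "linear":
            return linear_background(**kwargs)
        return shirley_background(
            **kwargs, tol=self.background_tol, max_iter=self.background_max_iter
        )

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        start_from: "RegionModel | RegionFitResult | None" = None,
        max_nfev: int | None = None,
        ftol: float = 1e-10,
        xtol: float = 1e-10,
    ) -> "RegionFitResult":
        """Run the bound-constrained least squares and return the results.

        ``start_from`` warm-starts from a previous fit (e.g. the preceding
        timepoint) or an explicit :class:`RegionModel`.
        """
        x = self.spectrum.binding_energy
        y = self.spectrum.counts
        if isinstance(start_from, RegionFitResult):
            start = start_from.model
        elif isinstance(start_from, RegionModel):
            start = start_from
        else:
            start = self.region_model
        p0 = np.clip(_pack(start, self._spec), self._spec.lower, self._spec.upper)
        # give a zero-area start something to climb from
        area_idx = [i for i, n in enumerate(self._spec.names) if n.endswith(".area")]
        net_guess = max(float(np.ptp(y)) * max(x[-1] - x[0], 1.0), 1e-6)
        for i in area_idx:
            if p0[i] == 0.0:
                p0[i] = 1e-3 * net_guess

        w = np.ones_like(y)
        if self.weighting == "poisson":
            w = 1.0 / np.sqrt(np.clip(y, 1.0, None))

        bg_result = self._background(y)
        bg = np.asarray(bg_result.background)
        ramp = (x - x[0]) / (x[-1] - x[0])

        def _profiled_bg(peaks: np.ndarray) -> np.ndarray:
            # model-aware Shirley, profiled out: for a given peak sum the
            # step shape is cum(peaks)/total and the background is linear
            # in its two endpoint levels, so solve them by 2x2 weighted
            # least squares inside every residual evaluation
            tot = cumulative_trapezoid(peaks, x, initial=0.0)
            c = tot / tot[-1] if tot[-1] > 0 else ramp
            b1, b2 = w * (1.0 - c), w * c
            r = w * (y - peaks)
            a11 = b1 @ b1
            a12 = b1 @ b2
            a22 = b2 @ b2
            det = a11 * a22 - a12 * a12
            if det <= 0:
                return bg
            v1, v2 = b1 @ r, b2 @ r
            lo = (a22 * v1 - a12 * v2) / det
            hi = (a11 * v2 - a12 * v1) / det
            return lo * (1.0 - c) + hi * c

        if self.reiterate_background:

            def residual(p):
                m = _unpack(self.region_model, self._spec, p)
                peaks = _model_curve(m, x)
                return w * (y - peaks - _profiled_bg(peaks))

        else:

            def residual(p):
                m = _unpack(self.region_model, self._spec, p)
                return w * (y - bg - _model_curve(m, x))

        res = least_squares(
            residual, p0,
            bounds=(self._spec.lower, self._spec.upper),
            method="trf", ftol=ftol, xtol=xtol, gtol=1e-12,
            max_nfev=max_nfev, x_scale="jac",
        )

        fitted = _unpack(self.region_model, self._spec, res.x)
        model_curve = _model_curve(fitted, x)
        if self.reiterate_background:
            bg = _profiled_bg(model_curve)
        residuals = y - bg - model_curve  # exact identity with input counts

        converged = bool(res.status > 0)
        if not converged:
            warnings.warn(
                f"{self.region_model.region_label}: fit did not converge "
                f"(status {res.status}: {res.message})", FitWarning, stacklevel=2,
            )
        notes = []
        at_bound = []
        for name, v, lo, hi in zip(self._spec.names, res.x,
                                   self._spec.lower, self._spec.upper):
            span = hi - lo
            tol = 1e-8 * (span if np.isfinite(span) else max(abs(v), 1.0))
            if (np.isfinite(lo) and abs(v - lo) <= tol and lo != 0.0) or \
                    (np.isfinite(hi) and abs(v - hi) <= tol):
                at_bound.append(name)
        if at_bound:
            notes.append("parameters at a bound: " + ", ".join(at_bound))
            warnings.warn(
                f"{self.region_model.region_label}: parameter(s) at a bound: "
                + ", ".join(at_bound), FitWarning, stacklevel=2,
            )

        n_bg = 2 if self.reiterate_background else 0
        dof = max(y.size - self._spec.n - n_bg, 1)
        chi2 = 2.0 * res.cost  # sum of squared weighted residuals
        red_chi2 = chi2 / dof
        cov, cov_notes = _covariance(res.jac, chi2, dof)
        notes.extend(cov_notes)

        areas = {}
        for c in fitted.components:
            sig = _area_sigma(c.label, fitted, self._spec, cov)
            areas[c.label] = (c.area, sig)

        return RegionFitResult(
            model=fitted,
            spectrum=self.spectrum,
            param_names=list(self._spec.names),
            params=pd.Series(res.x, index=list(self._spec.names)),
            background_curve=bg,
            background_converged=bg_result.converged,
            background_iterations=bg_result.n_iterations,
            residuals=residuals,
            component_areas=areas,
            covariance=cov,
            reduced_chi_square=float(red_chi2),
            converged=converged,
            n_iterations=int(res.nfev),
            notes=notes,
            weighting=self.weighting,
        )


def _covariance(jac: np.ndarray, chi2: float, dof: int):
    """Residual-variance-scaled inverse Gauss-Newton normal matrix."""
    notes: list[str] = []
    jtj = jac.T @ jac
    s2 = chi2 / dof
    if jtj.size == 0:
        return np.zeros((0, 0)), notes
    u, sv, vt = np.linalg.svd(jtj)
    rank = int(np.sum(sv > sv[0] * 1e-12)) if sv.size else 0
    if rank < jtj.shape[0]:
        notes.append(
            f"rank-deficient normal matrix (rank {rank} of {jtj.shape[0]}); "
            "pseudo-inverse used; degenerate directions involve parameters "
            f"{_degenerate_params(vt, sv)}"
        )
        warnings.warn(notes[-1], FitWarning, stacklevel=3)
        inv = np.linalg.pinv(jtj, rcond=1e-12)
    else:
        inv = vt.T @ np.diag(1.0 / sv) @ u.T
    cov = s2 * inv
    cov = 0.5 * (cov + cov.T)  # enforce exact symmetry
    return cov, notes


def _degenerate_params(vt, sv):
    if sv.size == 0:
        return []
    null = vt[sv <= sv[0] * 1e-12]
    idx = sorted({int(i) for row in null for i in np.argsort(-np.abs(row))[:2]})
    return idx


def _area_sigma(label: str, m: RegionModel, spec: _ParamSpec, cov: np.ndarray) -> float:
    name = f"{label}.area"
    names = list(spec.names)
    if name in names:
        i = names.index(name)
        return float(np.sqrt(max(cov[i, i], 0.0)))
    for d in m.doublets:
        if d.follower == label:
            pname = f"{d.primary}.area"
            if pname in names:
                i = names.index(pname)
                return float(d.area_ratio * np.sqrt(max(cov[i, i], 0.0)))
    return 0.0  # fixed parameter: no statistical uncertainty propagated


@dataclass
class RegionFitResult:
    """Fit results: fitted model, diagnostics, and uncertainty information.

    The stored arrays satisfy the exact identity
    ``model_curve + background_curve + residuals == spectrum.counts``.
    """

    model: RegionModel
    spectrum: Spectrum
    param_names: list[str]
    params: pd.Series
    background_curve: np.ndarray
    background_converged: bool
    background_iterations: int
    residuals: np.ndarray
    component_areas: dict[str, tuple[float, float]]
    covariance: np.ndarray
    reduced_chi_square: float
    converged: bool
    n_iterations: int
    notes: list[str] = field(default_factory=list)
    weighting: str = "poisson"

    @property
    def model_curve(self) -> np.ndarray:
        return _model_curve(self.model, self.spectrum.binding_energy)

    @property
    def bse(self) -> pd.Series:
        """Standard errors of the free parameters."""
        return pd.Series(np.sqrt(np.clip(np.diag(self.covariance), 0, None)),
                         index=self.param_names)

    def conf_int(self, nsigma: float = 1.0) -> pd.DataFrame:
        lo = self.params - nsigma * self.bse
        hi = self.params + nsigma * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def area_table(self) -> pd.DataFrame:
        rows = []
        for c in self.model.components:
            a, s = self.component_areas[c.label]
            rows.append({
                "component": c.label, "center_eV": c.center,
                "area": a, "area_sigma": s,
                "gaussian_fwhm_eV": c.gaussian_width,
                "lorentzian_fwhm_eV": c.lorentzian_width,
                "is_gas_phase": c.is_gas_phase,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Region fit: {m.region_label}   "
            f"t = {self.spectrum.timepoint:g} s, {self.spectrum.atmosphere}",
            f"converged: {self.converged}   nfev: {self.n_iterations}   "
            f"reduced chi2: {self.reduced_chi_square:.4g}",
            f"background: {m.background} "
            f"({self.background_iterations} iterations, "
            f"converged={self.background_converged})",
            "-" * 78,
            f"{'component':<12}{'center/eV':>10}{'area':>14}{'sigma':>12}"
            f"{'FWHM_G':>9}{'FWHM_L':>9}  flags",
        ]
        for c in m.components:
            a, s = self.component_areas[c.label]
            flags = []
            if c.is_gas_phase:
                flags.append("gas")
            if c.label in m.follower_labels:
                flags.append("linked")
            lines.append(
                f"{c.label:<12}{c.center:>10.2f}{a:>14.4g}{s:>12.3g}"
                f"{c.gaussian_width:>9.3f}{c.lorentzian_width:>9.3f}  "
                + ",".join(flags)
            )
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Spectrum, components, Shirley background, sum, and residuals."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        x = self.spectrum.binding_energy
        y = self.spectrum.counts
        ax.plot(x, y, ".", ms=3, color="0.3", label="data")
        ax.plot(x, self.background_curve, "k:", label="Shirley background")
        for c in self.model.components:
            if c.area > 0:
                ax.plot(x, self.background_curve
                        + voigt_profile(x, c.center, c.area, c.gaussian_width,
                                        c.lorentzian_width),
                        color="tab:blue", lw=0.8)
        ax.plot(x, self.background_curve + self.model_curve, color="tab:red",
                label="sum")
        offset = -0.15 * np.ptp(y)
        ax.plot(x, self.residuals + offset, color="0.6", lw=0.8,
                label="residuals (shifted)")
        ax.invert_xaxis()
        ax.set_xlabel("binding energy / eV")
        ax.set_ylabel("counts")
        ax.set_title(self.model.region_label)
        ax.legend(fontsize=8)
        return ax


def estimate_uncertainties(fr: RegionFitResult) -> dict[str, float]:
    """Per-component area standard deviations of a converged fit.

    Reads the covariance (residual-variance estimate times the inverse
    Gauss-Newton normal matrix) already attached to the result and maps it
    through the area parameterization: free areas are direct parameters,
    doublet followers scale by their link ratio.
    """
    if not fr.converged:
        warnings.warn("uncertainties requested for a non-converged fit",
                      FitWarning, stacklevel=2)
    return {label: sig for label, (_, sig) in fr.component_areas.items()}
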