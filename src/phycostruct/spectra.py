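"""Derivative analysis and constrained multi-Gaussian spectral deconvolution.

The visible absorbance band of a phycobiliprotein is a composite of
overlapping contributions from its chemically identical but conformationally
distinct chromophore sites.  The band is decomposed as a constant baseline
plus a sum of Gaussians in wavelength space,

    A(lambda) = b + sum_i  a_i * exp(-(lambda - c_i)^2 / (2 w_i^2)),

fitted by bounded nonlinear least squares from multiple seeded starts whose
centre initialisations come from the smoothed second-derivative minima.  The
component count can be fixed or selected automatically by an information
criterion (BIC by default; small-sample-corrected AIC available).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

logger = logging.getLogger(__name__)


class SpectrumParseError(ValueError):
    pass


class FitConvergenceError(RuntimeError):
    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class Spectrum:
    """Wavelength (nm, strictly increasing) / absorbance series."""

    wavelengths: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, float)
        self.absorbance = np.asarray(self.absorbance, float)
        if self.wavelengths.shape != self.absorbance.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and absorbance must be equal-length 1-D")
        if self.wavelengths.size == 0:
            raise ValueError("empty spectrum")
        if not np.all(np.isfinite(self.absorbance)) or not np.all(np.isfinite(self.wavelengths)):
            raise ValueError("non-finite values in spectrum")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def window(self, lo: float, hi: float) -> "Spectrum":
        m = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        return Spectrum(self.wavelengths[m], self.absorbance[m])

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass(frozen=True)
class GaussianComponent:
    center: float     # nm
    width: float      # sd, nm
    amplitude: float  # absorbance units

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((x - self.center) / self.width) ** 2)


@dataclass
class SpectrumModel:
    """Fitted sum-of-Gaussians, components sorted by ascending centre."""

    components: list[GaussianComponent]
    baseline: float
    rss: float
    aicc: float
    bic: float
    n_points: int
    restarts_used: int = 0

    @property
    def centers(self) -> list[float]:
        return [c.center for c in self.components]

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        y = np.full_like(x, self.baseline, dtype=float)
        for comp in self.components:
            y += comp(x)
        return y

    def component_areas(self) -> list[float]:
        """Integrated area of each component (amplitude * width * sqrt(2 pi))."""
        return [c.amplitude * c.width * math.sqrt(2.0 * math.pi)
                for c in self.components]


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_spectrum(path: str | Path) -> Spectrum:
    """Two-column wavelength/absorbance text (CSV or TSV, optional header).

    Descending wavelength order is accepted and sorted (with a warning);
    a non-numeric data cell raises with its line number.
    """
    path = Path(path)
    wl, ab = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", " ").replace("\t", " ").split() if p]
            if len(parts) < 2:
                raise SpectrumParseError(f"{path.name}:{lineno}: expected two columns")
            try:
                w, a = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise SpectrumParseError(
                    f"{path.name}:{lineno}: non-numeric value in {parts[:2]}") from None
            wl.append(w)
            ab.append(a)
    if not wl:
        raise SpectrumParseError(f"{path.name}: no data rows")
    wl_arr, ab_arr = np.array(wl), np.array(ab)
    order = np.argsort(wl_arr, kind="stable")
    if not np.array_equal(order, np.arange(len(wl_arr))):
        logger.warning("%s: wavelengths not ascending; sorting", path.name)
    return Spectrum(wl_arr[order], ab_arr[order])


# ---------------------------------------------------------------------------
# Derivative analysis
# ---------------------------------------------------------------------------

def derivative(spectrum: Spectrum, order: int = 2, window: int = 11) -> Spectrum:
    """Smoothed finite-difference derivative on the original grid."""
    if order not in (1, 2, 4):
        raise ValueError("derivative order must be 1, 2 or 4")
    if window <= order:
        raise ValueError("smoothing window must exceed the derivative order")
    if len(spectrum) <= window:
        raise ValueError("spectrum shorter than the smoothing window")
    if window % 2 == 0:
        window += 1
    poly = min(window - 1, max(3, order + 1))
    step = float(np.mean(np.diff(spectrum.wavelengths)))
    dy = savgol_filter(spectrum.absorbance, window_length=window,
                       polyorder=poly, deriv=order, delta=step)
    return Spectrum(spectrum.wavelengths, dy)


def _ranked_candidates(spectrum: Spectrum, window: int,
                       min_prominence: float) -> list[tuple[float, float]]:
    """(wavelength, depth) of negative 2nd-derivative minima, deepest first.

    ``min_prominence`` is a fraction of the deepest minimum; shallower
    minima (noise wiggles) are dropped.
    """
    d2 = derivative(spectrum, order=2, window=window)
    y = d2.absorbance
    raw = [(float(d2.wavelengths[i]), float(-y[i]))
           for i in range(1, len(y) - 1)
           if y[i] < 0.0 and y[i] <= y[i - 1] and y[i] < y[i + 1]]
    if not raw:
        return []
    deepest = max(d for _, d in raw)
    keep = [(w, d) for w, d in raw if d >= min_prominence * deepest]
    return sorted(keep, key=lambda t: -t[1])


def peak_candidates(spectrum: Spectrum, window: int = 11,
                    min_prominence: float = 0.05) -> list[float]:
    """Candidate band positions: negative local minima of the 2nd derivative.

    Returned in ascending wavelength order after pruning minima shallower
    than ``min_prominence`` times the deepest one.
    """
    return sorted(w for w, _ in _ranked_candidates(spectrum, window, min_prominence))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _pack(components: np.ndarray, baseline: float) -> np.ndarray:
    return np.concatenate([components.ravel(), [baseline]])


def _model(params: np.ndarray, x: np.ndarray, n: int) -> np.ndarray:
    y = np.full_like(x, params[-1])
    for k in range(n):
        a, c, w = params[3 * k:3 * k + 3]
        y = y + a * np.exp(-0.5 * ((x - c) / w) ** 2)
    return y


def _jacobian(params: np.ndarray, x: np.ndarray, n: int) -> np.ndarray:
    cols = []
    for k in range(n):
        a, c, w = params[3 * k:3 * k + 3]
        e = np.exp(-0.5 * ((x - c) / w) ** 2)
        cols.append(e)
        cols.append(a * e * (x - c) / w ** 2)
        cols.append(a * e * (x - c) ** 2 / w ** 3)
    cols.append(np.ones_like(x))
    return np.column_stack(cols)


def _aicc(rss: float, n_obs: int, k_params: int) -> float:
    rss = max(rss, 1e-300)
    aic = n_obs * math.log(rss / n_obs) + 2 * k_params
    denom = n_obs - k_params - 1
    return aic + (2 * k_params * (k_params + 1) / denom if denom > 0 else math.inf)


def _bic(rss: float, n_obs: int, k_params: int) -> float:
    rss = max(rss, 1e-300)
    return n_obs * math.log(rss / n_obs) + k_params * math.log(n_obs)


def fit_gaussians(spectrum: Spectrum,
                  n_components: int | str = "auto",
                  n_range: tuple[int, int] = (1, 4),
                  fit_window: tuple[float, float] = (450.0, 750.0),
                  center_bounds: tuple[float, float] | None = None,
                  width_bounds: tuple[float, float] = (2.0, 60.0),
                  restarts: int = 20,
                  seed: int = 0,
                  criterion: str = "bic",
                  derivative_window: int = 11) -> SpectrumModel:
    """Bounded multi-start least-squares deconvolution.

    Centre initialisations are drawn from the second-derivative candidate
    peaks, padded with quantiles of the fit window and jittered with a
    seeded generator; the best-RSS solution over ``restarts`` starts is
    returned.  With ``n_components="auto"`` every count in ``n_range`` is
    fitted and the information-criterion minimiser wins (Bayesian
    information criterion by default; its stronger complexity penalty is
    consistent for component-count selection, while ``criterion="aicc"``
    offers the small-sample-corrected Akaike alternative).
    """
    if criterion not in ("bic", "aicc"):
        raise ValueError("criterion must be 'bic' or 'aicc'")
    if n_components != "auto":
        n_components = int(n_components)
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
    spec = spectrum.window(*fit_window)
    if len(spec) < 8:
        raise ValueError("fit window contains too few points")
    x, y = spec.wavelengths, spec.absorbance
    lo, hi = (center_bounds if center_bounds is not None
              else (float(x[0]), float(x[-1])))
    try:
        ranked = _ranked_candidates(spec, window=derivative_window,
                                    min_prominence=0.05)
    except ValueError:
        ranked = []
    cands = [w for w, _ in ranked if lo <= w <= hi]
    if not cands:
        cands = [float(x[np.argmax(y)])]

    ymax = float(y.max())
    span = hi - lo

    def fit_n(n: int, rng: np.random.Generator) -> SpectrumModel | None:
        lower = np.concatenate([np.tile([0.0, lo, width_bounds[0]], n), [-ymax]])
        upper = np.concatenate([np.tile([2.0 * max(ymax, 1e-12), hi,
                                         width_bounds[1]], n), [ymax]])
        best = None
        used = 0
        for r in range(restarts):
            base_centers = [cands[k % len(cands)] for k in range(n)]
            extra = np.quantile(x, np.linspace(0.25, 0.75, n))
            centers = np.array([base_centers[k] if k < len(cands) else extra[k]
                                for k in range(n)], float)
            if r > 0:
                centers = centers + rng.normal(0.0, 0.03 * span, size=n)
            centers = np.clip(centers, lo + 1e-6, hi - 1e-6)
            widths = rng.uniform(0.5, 1.5, size=n) * 12.0 if r > 0 else np.full(n, 12.0)
            widths = np.clip(widths, *width_bounds)
            amps = np.clip(np.interp(centers, x, y), 1e-6, None)
            p0 = np.concatenate([np.column_stack([amps, centers, widths]).ravel(),
                                 [0.0]])
            p0 = np.clip(p0, lower + 1e-12, upper - 1e-12)
            try:
                sol = least_squares(
                    lambda p: _model(p, x, n) - y, p0,
                    jac=lambda p: _jacobian(p, x, n),
                    bounds=(lower, upper), method="trf",
                    xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400)
            except Exception:
                continue
            used += 1
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)
        if best is None:
            return None
        rss, params = best
        comps = sorted((GaussianComponent(amplitude=params[3 * k],
                                          center=params[3 * k + 1],
                                          width=params[3 * k + 2])
                        for k in range(n)), key=lambda c: c.center)
        k = 3 * n + 1
        return SpectrumModel(components=comps, baseline=float(params[-1]),
                             rss=rss, aicc=_aicc(rss, len(x), k),
                             bic=_bic(rss, len(x), k),
                             n_points=len(x), restarts_used=used)

    rng = np.random.default_rng(seed)
    if n_components == "auto":
        models = []
        for n in range(n_range[0], n_range[1] + 1):
            m = fit_n(n, rng)
            if m is not None:
                models.append(m)
        if not models:
            raise FitConvergenceError("no component count converged",
                                      {"n_range": n_range})
        return min(models, key=lambda m: getattr(m, criterion))
    model = fit_n(n_components, rng)
    if model is None:
        raise FitConvergenceError(
            f"all {restarts} restarts failed for n={n_components}",
            {"n_components": n_components, "candidates": cands})
    return model


def component_shifts(model_a: SpectrumModel, model_b: SpectrumModel) -> list[float]:
    """Per-component centre differences a - b (nm); negative = blue shift of a."""
    if len(model_a.components) != len(model_b.components):
        raise ValueError("models have different component counts")
    return [ca.center - cb.center
            for ca, cb in zip(model_a.components, model_b.components)]
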