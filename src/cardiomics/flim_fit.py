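"""Per-pixel biexponential decay fitting for TCSPC cubes.

The fitting strategy mirrors standard FLIM practice: photon histograms are
first pooled over a square spatial neighbourhood (binning) to reach a
workable photon budget, then each pixel's histogram is fitted from its peak
onward with the two-component model

    m(t) = c1 * exp(-t / tau1) + c2 * exp(-t / tau2),

reported as fractional amplitudes a_i = c_i / (c1 + c2) * 100 % and
lifetimes tau_i, with the amplitude-weighted mean lifetime
tau_m = (a1*tau1 + a2*tau2) / 100.

The optimiser uses variable projection: for any (tau1, tau2) the optimal
non-negative amplitudes of the weighted least-squares problem are solved
exactly, leaving a 2-parameter nonlinear search over the lifetimes.  The
model histogram integrates the decay over each timing bin and accounts for
periodic wrap-around of incomplete decays at the laser period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy.optimize import least_squares, nnls

from .flim_synth import AcquisitionSpec, DecayCube, ValidationError

__all__ = [
    "FitConfig",
    "BiexpFit",
    "ParamMaps",
    "spatial_bin",
    "fit_decay",
    "mean_lifetime",
    "fit_cube",
    "grid_search_objective",
]


@dataclass(frozen=True)
class FitConfig:
    """Configuration for per-pixel decay fitting.

    ``bin_size`` is the side of the square sliding-sum neighbourhood (5
    pools a 5x5 window, the convention used for 512x512 frames by vendor
    FLIM software).  ``fit_start`` is either an explicit bin index or
    "peak" to start at the histogram maximum (tail fit).  Pixels whose
    binned histogram holds fewer than ``min_total_counts`` photons are not
    fitted.  ``degenerate_rtol`` collapses fits with nearly equal lifetimes
    to a mono-exponential report.

    ``n_reweight`` controls the weighting of the least-squares objective:
    the first pass uses Neyman weights 1/max(counts, 1); subsequent passes
    refit with model-based weights 1/max(model, 1), which removes the
    low-count bias of pure Neyman weighting.  Set ``n_reweight=1`` for
    classic Neyman-weighted least squares.
    """

    bin_size: int = 5
    fit_start: int | str = "peak"
    tau_bounds: tuple[float, float] = (0.05, 10.0)
    noise_model: str = "poisson_weighted_ls"
    min_total_counts: float = 100.0
    include_wrap: bool = True
    degenerate_rtol: float = 0.01
    min_component_frac: float = 0.5  # % below which the minor component collapses
    max_nfev: int = 60
    n_reweight: int = 3

    def __post_init__(self) -> None:
        if self.bin_size < 1 or self.bin_size % 2 == 0:
            raise ValidationError("bin_size must be an odd positive neighbourhood side")
        if self.tau_bounds[0] <= 0 or self.tau_bounds[0] >= self.tau_bounds[1]:
            raise ValidationError("tau bounds must satisfy 0 < tau_min < tau_max")
        if self.noise_model not in ("poisson_weighted_ls", "poisson_mle"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")


@dataclass
class BiexpFit:
    """One pixel's fitted parameters (amplitudes in %, lifetimes in ns)."""

    a1: float = np.nan
    a2: float = np.nan
    tau1: float = np.nan
    tau2: float = np.nan
    tau_m: float = np.nan
    chi2_reduced: float = np.nan
    converged: bool = False
    valid: bool = False


@dataclass
class ParamMaps:
    """Per-pixel fitted parameter images for one channel.

    Pixels that were below the photon threshold or failed to converge are
    flagged invalid (``valid`` False, parameter images NaN) rather than
    silently zeroed.
    """

    a1: np.ndarray
    a2: np.ndarray
    tau1: np.ndarray
    tau2: np.ndarray
    tau_m: np.ndarray
    chi2_reduced: np.ndarray
    valid: np.ndarray
    channel: str = "broad"
    config: FitConfig = field(default_factory=FitConfig)


def spatial_bin(cube: DecayCube, bin_size: int) -> DecayCube:
    """Pool each pixel's histogram over a bin_size x bin_size sliding window.

    The frame shape is preserved; counts outside the frame contribute zero.
    """
    if bin_size == 1:
        return cube
    if bin_size < 1 or bin_size % 2 == 0:
        raise ValidationError("bin_size must be odd and >= 1")
    rows, cols = cube.spec.frame_shape
    if bin_size > min(rows, cols):
        raise ValidationError(f"bin_size {bin_size} exceeds frame {cube.spec.frame_shape}")
    counts = np.asarray(cube.counts)
    kernel_dtype = np.int64 if counts.dtype.kind in "iu" else np.float64
    summed = ndi.convolve(
        counts.astype(kernel_dtype),
        np.ones((bin_size, bin_size, 1), dtype=kernel_dtype),
        mode="constant",
        cval=0,
    )
    return DecayCube(counts=summed, spec=cube.spec, channel=cube.channel)


def _component_integrals(
    taus: np.ndarray, edges: np.ndarray, period: float, include_wrap: bool
) -> np.ndarray:
    """Bin integrals of exp(-t/tau) (optionally with periodic wrap) per tau.

    Returns an array of shape (len(taus), n_bins).
    """
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    e = np.exp(-edges[None, :] / taus[:, None])
    out = taus[:, None] * (e[:, :-1] - e[:, 1:])
    if include_wrap:
        out = out / (1.0 - np.exp(-period / taus))[:, None]
    return out


def _fit_window(hist: np.ndarray, config: FitConfig) -> int:
    if config.fit_start == "peak":
        return int(np.argmax(hist))
    return int(config.fit_start)


def fit_decay(
    hist: np.ndarray,
    spec: AcquisitionSpec,
    config: FitConfig | None = None,
    x0_taus: tuple[float, float] | None = None,
) -> BiexpFit:
    """Fit the two-component exponential model to one photon histogram.

    Non-convergence yields a flagged (``converged=False``) fit rather than
    an exception; histograms below ``min_total_counts`` yield an invalid
    fit.  ``x0_taus`` optionally warm-starts the lifetime search.
    """
    config = config or FitConfig()
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    if total < config.min_total_counts:
        return BiexpFit(valid=False)

    start = _fit_window(hist, config)
    y = hist[start:]
    if len(y) < 6:
        return BiexpFit(valid=False)
    edges = spec.bin_edges[start:]
    t_rel = edges[:-1] - edges[0]  # model times measured from the window start
    rel_edges = np.concatenate([t_rel, [t_rel[-1] + spec.bin_width]])
    period = spec.laser_period

    lo, hi = config.tau_bounds

    def amplitudes_for(taus: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = _component_integrals(taus, rel_edges, period, config.include_wrap).T
        c, _ = nnls(X * w[:, None], y * w)
        return c, X

    # moment-based initial guess: mean arrival time within the window
    tbar = float(np.sum(t_rel * y) / total) if total > 0 else 1.0
    tbar = min(max(tbar, 2 * lo), hi / 2)
    if x0_taus is None:
        x0_taus = (max(lo * 1.5, 0.4 * tbar), min(hi / 1.5, 2.5 * tbar))
    x0 = np.log(np.clip(x0_taus, lo * 1.001, hi * 0.999))

    w = 1.0 / np.sqrt(np.maximum(y, 1.0))  # Neyman weights, floored at one count
    converged = False
    try:
        for _pass in range(max(config.n_reweight, 1)):
            w_pass = w

            def residuals(log_taus: np.ndarray) -> np.ndarray:
                c, X = amplitudes_for(np.exp(log_taus), w_pass)
                return (X @ c - y) * w_pass

            sol = least_squares(
                residuals,
                x0,
                bounds=(np.log(lo), np.log(hi)),
                max_nfev=config.max_nfev,
                xtol=1e-10,
                ftol=1e-10,
            )
            converged = sol.status > 0
            x0 = sol.x
            taus = np.exp(sol.x)
            c, X = amplitudes_for(taus, w_pass)
            model = X @ c
            # refit with model-based weights: unbiased at low counts
            w = 1.0 / np.sqrt(np.maximum(model, 1.0))
    except Exception:  # pragma: no cover - optimiser failure path
        return BiexpFit(valid=False)

    resid = (model - y) * w_pass
    dof = max(len(y) - 4, 1)
    chi2 = float(resid @ resid) / dof

    if config.noise_model == "poisson_mle":
        # polish lifetimes against the Poisson deviance; amplitudes keep the
        # converged model-based weighting (a close ML surrogate)
        from scipy.optimize import minimize

        def deviance(log_taus: np.ndarray) -> float:
            cc, XX = amplitudes_for(np.exp(log_taus), w_pass)
            m = np.maximum(XX @ cc, 1e-12)
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(y > 0, y * np.log(y / m), 0.0)
            return float(2.0 * np.sum(m - y + term))

        res = minimize(
            deviance, np.log(taus), method="Nelder-Mead", options={"maxiter": 200, "xatol": 1e-6}
        )
        taus = np.exp(res.x)
        c, X = amplitudes_for(taus, w_pass)
        model = X @ c
        resid = (model - y) * w_pass
        chi2 = float(resid @ resid) / dof
        converged = converged and bool(res.success)

    order = np.argsort(taus)
    taus, c = taus[order], c[order]
    csum = c.sum()
    if csum <= 0:
        return BiexpFit(valid=False)
    a = c / csum * 100.0

    tau1, tau2 = float(taus[0]), float(taus[1])
    a1, a2 = float(a[0]), float(a[1])
    if (
        min(a1, a2) < config.min_component_frac
        or abs(tau2 - tau1) < config.degenerate_rtol * tau2
    ):
        # indistinguishable components: report mono-exponential
        tau = (a1 * tau1 + a2 * tau2) / 100.0
        tau1 = tau2 = tau
        a1, a2 = 100.0, 0.0

    tau_m = (a1 * tau1 + a2 * tau2) / 100.0
    return BiexpFit(
        a1=a1,
        a2=a2,
        tau1=tau1,
        tau2=tau2,
        tau_m=tau_m,
        chi2_reduced=chi2,
        converged=bool(converged),
        valid=True,
    )


def mean_lifetime(fit: BiexpFit) -> float:
    """Amplitude-weighted mean lifetime a1*tau1 + a2*tau2 (amplitudes as fractions of 1)."""
    if not fit.valid:
        return float("nan")
    return (fit.a1 * fit.tau1 + fit.a2 * fit.tau2) / 100.0


def fit_cube(
    cube: DecayCube,
    mask: np.ndarray | None = None,
    config: FitConfig | None = None,
) -> ParamMaps:
    """Spatially bin a cube and fit every in-mask pixel.

    ``mask`` restricts fitting (None fits everywhere); low-count and
    non-converged pixels are flagged invalid.  Deterministic given inputs.
    """
    config = config or FitConfig()
    binned = spatial_bin(cube, config.bin_size)
    rows, cols = cube.spec.frame_shape
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    else:
        mask = np.asarray(mask) > 0
        if mask.shape != (rows, cols):
            raise ValidationError(f"mask shape {mask.shape} does not match frame {(rows, cols)}")
    if not mask.any():
        warnings.warn("empty mask: returning all-invalid parameter maps")

    shape = (rows, cols)
    maps = {k: np.full(shape, np.nan) for k in ("a1", "a2", "tau1", "tau2", "tau_m", "chi2")}
    valid = np.zeros(shape, dtype=bool)

    counts = np.asarray(binned.counts, dtype=float)
    warm: tuple[float, float] | None = None
    for r, cidx in zip(*np.nonzero(mask)):
        fit = fit_decay(counts[r, cidx], cube.spec, config, x0_taus=warm)
        if fit.valid:
            maps["a1"][r, cidx] = fit.a1
            maps["a2"][r, cidx] = fit.a2
            maps["tau1"][r, cidx] = fit.tau1
            maps["tau2"][r, cidx] = fit.tau2
            maps["tau_m"][r, cidx] = fit.tau_m
            maps["chi2"][r, cidx] = fit.chi2_reduced
            valid[r, cidx] = fit.converged
            if fit.converged and fit.a2 > 0:
                warm = (fit.tau1, fit.tau2)  # neighbouring pixels are similar
    return ParamMaps(
        a1=maps["a1"],
        a2=maps["a2"],
        tau1=maps["tau1"],
        tau2=maps["tau2"],
        tau_m=maps["tau_m"],
        chi2_reduced=maps["chi2"],
        valid=valid,
        channel=cube.channel,
        config=config,
    )


def grid_search_objective(
    hist: np.ndarray,
    spec: AcquisitionSpec,
    config: FitConfig,
    tau_grid: np.ndarray,
    a1_grid: np.ndarray,
) -> float:
    """Best weighted-least-squares objective over a dense (tau1, tau2, a1) lattice.

    For each lattice point the overall amplitude scale is optimised in
    closed form.  Used as an independent check that the fitter's optimum is
    at least as good as an exhaustive coarse search.
    """
    hist = np.asarray(hist, dtype=float)
    start = _fit_window(hist, config)
    y = hist[start:]
    edges = spec.bin_edges[start:]
    rel_edges = edges - edges[0]
    w2 = 1.0 / np.maximum(y, 1.0)

    I = _component_integrals(tau_grid, rel_edges, spec.laser_period, config.include_wrap)
    best = np.inf
    f = a1_grid / 100.0
    for i, _t1 in enumerate(tau_grid):
        for j in range(i, len(tau_grid)):
            # shapes (n_f, n_bins): f * I1 + (1-f) * I2
            S = f[:, None] * I[i][None, :] + (1 - f)[:, None] * I[j][None, :]
            num = S @ (w2 * y)
            den = np.einsum("ab,b,ab->a", S, w2, S)
            A = np.clip(np.where(den > 0, num / np.maximum(den, 1e-300), 0.0), 0.0, None)
            # objective = sum w2*(A*S - y)^2 = A^2*den - 2A*num + sum w2 y^2
            const = float(np.sum(w2 * y * y))
            obj = A * A * den - 2 * A * num + const
            m = float(obj.min())
            if m < best:
                best = m
    return best


def fit_objective(hist: np.ndarray, spec: AcquisitionSpec, config: FitConfig, fit: BiexpFit) -> float:
    """Weighted-least-squares objective of a reported fit, on the fitter's window."""
    hist = np.asarray(hist, dtype=float)
    start = _fit_window(hist, config)
    y = hist[start:]
    edges = spec.bin_edges[start:]
    rel_edges = edges - edges[0]
    w2 = 1.0 / np.maximum(y, 1.0)
    taus = np.array([fit.tau1, fit.tau2 if fit.a2 > 0 else fit.tau1])
    I = _component_integrals(taus, rel_edges, spec.laser_period, config.include_wrap)
    shape = (fit.a1 / 100.0) * I[0] + (fit.a2 / 100.0) * I[1]
    num = float(np.sum(w2 * shape * y))
    den = float(np.sum(w2 * shape * shape))
    A = num / den if den > 0 else 0.0
    model = A * shape
    return float(np.sum(w2 * (model - y) ** 2))
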