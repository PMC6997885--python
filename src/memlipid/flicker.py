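"""GUV flicker spectroscopy: contour Fourier analysis and Helfrich fit.

A quasi-spherical vesicle observed at its equator fluctuates thermally;
writing the contour radius as r(phi) = R [1 + u(phi)] and expanding
u(phi) = sum_q u_q e^{i q phi}, the equatorial mode variances follow the
Helfrich spectrum

    <|u_q|^2> = (kB T / kappa) * sum_{l=q}^{l_max}
                (2l+1)/(4 pi) * (l-q)!/(l+q)! * [P_l^q(0)]^2
                / [ (l-1)(l+2) ( l(l+1) + sigma_bar ) ]

with kappa the bending rigidity (in kB T units here, so the prefactor
is 1/kappa), sigma_bar = sigma R^2 / kappa the reduced tension, and
P_l^q the associated Legendre function.  Fitting the measured spectrum
over modes q = 6..20 with free (kappa, sigma_bar) yields the bending
rigidity.  The model is exposed statsmodels-style:
``FlickerSpectrumModel(spectrum).fit()`` returns a
:class:`RigidityFitResults` with estimates, standard errors and a
``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import gammaln

__all__ = [
    "ContourSeries",
    "ModeSpectrum",
    "contour_to_radial",
    "fluctuation_spectrum",
    "helfrich_variance",
    "FlickerSpectrumModel",
    "RigidityFitResults",
    "fit_bending_rigidity",
]


@dataclass
class ContourSeries:
    """Closed 2D vesicle contours (one point set per video frame), in um."""

    frames: list
    pixel_size: float = 1.0
    temperature: float = 295.0

    def __post_init__(self) -> None:
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for f in self.frames:
            if f.ndim != 2 or f.shape[1] != 2 or f.shape[0] < 64:
                raise ValueError("each frame needs >= 64 (x, y) points")


@dataclass
class ModeSpectrum:
    modes: np.ndarray  # q = 2..q_max
    variance: np.ndarray  # <|u_q|^2>
    std_error: np.ndarray
    n_frames: int
    mean_radius: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.modes) <= 0):
            raise ValueError("modes must be strictly increasing")
        if np.any(self.variance < 0):
            raise ValueError("variances must be non-negative")


def _polygon_centroid(points: np.ndarray) -> np.ndarray:
    """Area centroid of a closed polygon (shoelace formula)."""
    x, y = points[:, 0], points[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    if abs(area) < 1e-12:
        raise ValueError("degenerate contour: zero enclosed area")
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return np.array([cx, cy])


def contour_to_radial(frame: np.ndarray, n_angles: int = 512) -> np.ndarray:
    """Normalized radial deviation u(phi) on a uniform angular grid.

    The contour is recentred on its area centroid, the radius r(phi) is
    linearly interpolated at ``n_angles`` uniform angles and returned as
    u = (r - rbar)/rbar (so sum(u) == 0 up to rounding).  Contours that
    are not star-shaped about their centroid (angle not monotonic along
    the path) are rejected.
    """
    pts = np.asarray(frame, dtype=float) - _polygon_centroid(np.asarray(frame))
    phi = np.unwrap(np.arctan2(pts[:, 1], pts[:, 0]))
    r = np.hypot(pts[:, 0], pts[:, 1])
    if np.all(np.diff(phi) < 0):  # clockwise traversal
        phi, r = phi[::-1], r[::-1]
    dphi = np.diff(phi)
    if np.any(dphi <= 0) or not (5.5 < phi[-1] - phi[0] < 7.0):
        raise ValueError("non-star-shaped contour")
    grid = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    # periodic linear interpolation
    phi0 = phi - phi[0]
    r_ext = np.concatenate([r, r[:1]])
    phi_ext = np.concatenate([phi0, [2.0 * np.pi]])
    r_grid = np.interp((grid - phi[0]) % (2.0 * np.pi), phi_ext, r_ext)
    rbar = r_grid.mean()
    return (r_grid - rbar) / rbar


def fluctuation_spectrum(
    series: ContourSeries,
    q_max: int = 20,
    n_angles: int = 512,
    noise_floor: float = 0.0,
) -> ModeSpectrum:
    """Per-mode fluctuation variances <|u_q|^2> for q = 2..q_max.

    u_q is the complex Fourier coefficient in the two-sided convention
    u(phi) = sum_q u_q e^{i q phi}; variances are averaged over frames
    with the standard error of that average.  An optional constant
    ``noise_floor`` is subtracted from every mode (clipped at zero).
    """
    if q_max >= n_angles / 2:
        raise ValueError("q_max must be below n_angles/2")
    qs = np.arange(2, q_max + 1)
    power = np.empty((len(series.frames), len(qs)))
    radii = np.empty(len(series.frames))
    for i, frame in enumerate(series.frames):
        u = contour_to_radial(frame * series.pixel_size, n_angles)
        coef = np.fft.rfft(u) / n_angles
        power[i] = np.abs(coef[qs]) ** 2
        radii[i] = np.hypot(*(frame * series.pixel_size
                              - _polygon_centroid(frame * series.pixel_size)).T).mean()
    n = len(series.frames)
    var = power.mean(axis=0) - noise_floor
    var = np.clip(var, 0.0, None)
    se = power.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(len(qs), np.nan)
    return ModeSpectrum(qs, var, se, n, float(radii.mean()))


def _log_double_factorial(n: np.ndarray) -> np.ndarray:
    """ln(n!!) for integer n >= -1."""
    n = np.asarray(n)
    k = n // 2
    even = k * np.log(2.0) + gammaln(k + 1.0)
    odd = gammaln(n + 1.0) - k * np.log(2.0) - gammaln(k + 1.0)
    return np.where(n % 2 == 0, even, odd)


def helfrich_variance(
    q: int | np.ndarray,
    kappa: float,
    sigma_bar: float,
    l_max: int = 100,
) -> float | np.ndarray:
    """Model equatorial mode variance <|u_q|^2> (kappa in kB T units).

    The sum over spherical-harmonic degree l runs from q to ``l_max``;
    only terms with l + q even contribute (P_l^q(0) vanishes otherwise).
    Evaluated in log-space so large l and q are safe.  Requires q >= 2
    (translation and dilation modes are excluded) and sigma_bar > -6.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if sigma_bar <= -6:
        raise ValueError("sigma_bar must exceed -6 (l=2 term diverges)")
    qs = np.atleast_1d(np.asarray(q, dtype=int))
    if np.any(qs < 2):
        raise ValueError("q must be >= 2")
    if l_max < qs.max():
        raise ValueError("l_max must be >= q")
    out = np.empty(len(qs))
    for i, qi in enumerate(qs):
        l = np.arange(qi, l_max + 1)
        l = l[(l + qi) % 2 == 0]
        l = l[l >= 2]
        # |P_l^q(0)| = (l+q-1)!! / (l-q)!!
        log_p = _log_double_factorial(l + qi - 1) - _log_double_factorial(l - qi)
        log_term = (
            np.log(2.0 * l + 1.0)
            - np.log(4.0 * np.pi)
            + gammaln(l - qi + 1.0)
            - gammaln(l + qi + 1.0)
            + 2.0 * log_p
            - np.log((l - 1.0) * (l + 2.0) * (l * (l + 1.0) + sigma_bar))
        )
        out[i] = np.exp(log_term).sum() / kappa
    return out if np.ndim(q) else float(out[0])


@dataclass
class RigidityFitResults:
    """Helfrich-spectrum fit: estimates, uncertainties and diagnostics."""

    kappa: float  # kB T
    sigma_bar: float
    kappa_se: float
    sigma_bar_se: float
    fit_modes: tuple[int, int]
    chi2: float
    dof: int
    n_frames: int
    model: "FlickerSpectrumModel" = field(repr=False)

    @property
    def reduced_chi2(self) -> float:
        return self.chi2 / self.dof if self.dof > 0 else float("nan")

    def predicted(self) -> np.ndarray:
        return helfrich_variance(
            self.model.fit_q, self.kappa, self.sigma_bar, self.model.l_max
        )

    def summary(self) -> str:
        lines = [
            "Helfrich flicker-spectrum fit",
            "=" * 46,
            f"modes fitted        q = {self.fit_modes[0]}..{self.fit_modes[1]}",
            f"frames              {self.n_frames}",
            f"kappa (kB T)        {self.kappa:10.3f} +/- {self.kappa_se:.3f}",
            f"reduced tension     {self.sigma_bar:10.3f} +/- {self.sigma_bar_se:.3f}",
            f"chi2 / dof          {self.chi2:10.3f} / {self.dof}",
            "=" * 46,
        ]
        return "\n".join(lines)


class FlickerSpectrumModel:
    """Weighted least-squares Helfrich model for a measured mode spectrum."""

    def __init__(
        self,
        spectrum: ModeSpectrum,
        q_min: int = 6,
        q_max: int = 20,
        l_max: int = 100,
    ) -> None:
        sel = (spectrum.modes >= q_min) & (spectrum.modes <= q_max)
        if sel.sum() < 3:
            raise ValueError("spectrum does not cover the requested mode range")
        if np.any(spectrum.variance[sel] <= 0):
            raise ValueError("fitted modes must have positive variance")
        self.spectrum = spectrum
        self.q_min, self.q_max, self.l_max = q_min, q_max, l_max
        self.fit_q = spectrum.modes[sel]
        self.y = spectrum.variance[sel]
        se = spectrum.std_error[sel]
        # fall back to unweighted residuals when standard errors are absent
        self.w = np.where(np.isfinite(se) & (se > 0), se, self.y * 0.05)

    def _residuals(self, params: np.ndarray) -> np.ndarray:
        kappa, sigma_bar = np.exp(params[0]), params[1]
        model = helfrich_variance(self.fit_q, kappa, sigma_bar, self.l_max)
        return (self.y - model) / self.w

    def fit(self, clamp_sigma: bool = False) -> RigidityFitResults:
        shape = helfrich_variance(self.fit_q, 1.0, 0.0, self.l_max)
        kappa0 = float(np.median(shape / self.y))
        x0 = np.array([np.log(max(kappa0, 1e-3)), 1.0])
        lower = [-np.inf, 0.0 if clamp_sigma else -5.9]
        res = optimize.least_squares(
            self._residuals, x0, bounds=(lower, [np.inf, np.inf]), xtol=1e-12
        )
        if not res.success:
            raise RuntimeError(f"Helfrich fit did not converge: {res.message}")
        if res.x[1] < 0 and not clamp_sigma:
            warnings.warn("fitted reduced tension negative; refitting with sigma_bar >= 0")
            return self.fit(clamp_sigma=True)
        kappa, sigma_bar = float(np.exp(res.x[0])), float(res.x[1])
        dof = len(self.y) - 2
        chi2 = float(2.0 * res.cost)
        # covariance from the weighted Jacobian, scaled by reduced chi2
        jtj = res.jac.T @ res.jac
        try:
            cov = np.linalg.inv(jtj) * max(chi2 / dof, 1.0) if dof > 0 else np.full((2, 2), np.nan)
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
        kappa_se = float(np.sqrt(cov[0, 0]) * kappa)  # delta method for log-param
        sigma_se = float(np.sqrt(cov[1, 1]))
        return RigidityFitResults(
            kappa=kappa,
            sigma_bar=sigma_bar,
            kappa_se=kappa_se,
            sigma_bar_se=sigma_se,
            fit_modes=(self.q_min, self.q_max),
            chi2=chi2,
            dof=dof,
            n_frames=self.spectrum.n_frames,
            model=self,
        )


def fit_bending_rigidity(
    spectrum: ModeSpectrum, q_min: int = 6, q_max: int = 20, l_max: int = 100
) -> RigidityFitResults:
    """Convenience wrapper: fit the Helfrich spectrum over [q_min, q_max]."""
    return FlickerSpectrumModel(spectrum, q_min, q_max, l_max).fit()
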