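"""Dean-Jett-Fox fitting of DNA-content histograms.

A population's per-cell nuclear DNA-content intensities, binned into a
50-bin histogram, decompose into a G1 normal peak at mu_G1, a G2/M normal
peak at mu_G2M (both with the same coefficient of variation) and an
S-phase compartment modeled as a second-order polynomial on
[mu_G1, mu_G2M] broadened by convolution with the shared-CV Gaussian.
The areas under the three fitted compartments give the G1/S/G2M
percentages.  A helper picks per-phase harvest times from a synchronized
release time course.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "DNAContentHistogram",
    "PhaseFractions",
    "DeanJettFox",
    "fit_dean_jett_fox",
    "pick_harvest_times",
]


@dataclass
class DNAContentHistogram:
    """Binned per-cell DNA-content intensities."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_cells: int

    @classmethod
    def from_intensities(cls, intensities, n_bins: int = 50
                         ) -> "DNAContentHistogram":
        vals = np.asarray(intensities, dtype=float)
        counts, edges = np.histogram(vals, bins=n_bins)
        return cls(bin_edges=edges, counts=counts, n_cells=len(vals))

    @property
    def centers(self):
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def width(self):
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass(frozen=True)
class PhaseFractions:
    """G1/S/G2M percentages (sum to 100)."""

    g1: float
    s: float
    g2m: float

    def as_tuple(self):
        return (self.g1, self.s, self.g2m)


_N_S_NODES = 64  # discretization of the broadened S-compartment integral


class DeanJettFox(BaseEstimator):
    """Bounded least-squares Dean-Jett-Fox fit of a DNA-content histogram.

    Parameters
    ----------
    constrain_ratio :
        Fix mu_G2M = 2 * mu_G1 (the theoretical DNA doubling); with it off
        both peak positions are free (bounded to a ratio in [1.7, 2.3]).
    n_bins :
        Histogram bins when fitting from raw intensities.

    Attributes
    ----------
    mu_g1_, mu_g2m_, cv_ : fitted peak positions and shared CV
    s_polynomial_ : coefficients (c0, c1, c2) of the S compartment
    amplitudes_ : (A_g1, A_g2m) peak amplitudes in counts/bin
    fractions_ : the fitted :class:`PhaseFractions`
    residual_ : root-mean-square residual in counts/bin
    """

    def __init__(self, constrain_ratio: bool = False, n_bins: int = 50,
                 min_cells: int = 500):
        self.constrain_ratio = constrain_ratio
        self.n_bins = n_bins
        self.min_cells = min_cells

    # -- model -------------------------------------------------------------

    @staticmethod
    def _s_compartment(x, mu1, mu2, cv, q):
        """Quadratic on [mu1, mu2] convolved with the shared-CV Gaussian.

        The quadratic is parameterized in the degree-2 Bernstein basis with
        non-negative coefficients ``q``, which keeps it non-negative and
        smooth on the whole interval — a free monomial quadratic can
        degenerate into a narrow spike that mimics the G1 peak.
        """
        t = np.linspace(mu1, mu2, _N_S_NODES)
        dt = t[1] - t[0]
        u = (t - mu1) / max(mu2 - mu1, 1e-9)
        poly = (q[0] * (1 - u) ** 2 + q[1] * 2 * u * (1 - u) + q[2] * u ** 2)
        sd = np.clip(cv * t, 1e-9, None)
        return (stats.norm.pdf(x[:, None], t[None, :], sd[None, :])
                * poly[None, :]).sum(axis=1) * dt

    def _model(self, x, theta):
        mu1, cv, a1, a2, q0, q1, q2 = theta[:7]
        mu2 = 2.0 * mu1 if self.constrain_ratio else theta[7]
        g1 = a1 * stats.norm.pdf(x, mu1, cv * mu1)
        g2 = a2 * stats.norm.pdf(x, mu2, cv * mu2)
        s = self._s_compartment(x, mu1, mu2, cv, (q0, q1, q2))
        return g1, s, g2

    # -- initialization ----------------------------------------------------

    @staticmethod
    def _find_peaks(hist: DNAContentHistogram):
        smooth = ndi.gaussian_filter1d(hist.counts.astype(float), 1.5)
        local_max = [i for i in range(1, len(smooth) - 1)
                     if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1]
                     and smooth[i] > 0]
        local_max.sort(key=lambda i: -smooth[i])
        centers = hist.centers
        if len(local_max) >= 2:
            # demand a plausible doubling between the two retained modes
            first = local_max[0]
            for j in local_max[1:]:
                ratio = max(centers[j], centers[first]) / \
                    max(min(centers[j], centers[first]), 1e-9)
                if 1.5 <= ratio <= 2.6:
                    return sorted([centers[first], centers[j]]), 2
        if local_max:
            mu1 = centers[local_max[0]]
            return [mu1, 2.0 * mu1], 1
        mu1 = centers[int(np.argmax(hist.counts))]
        return [mu1, 2.0 * mu1], 1

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        """Fit from raw per-cell intensities or a :class:`DNAContentHistogram`."""
        if isinstance(X, DNAContentHistogram):
            hist = X
        else:
            vals = np.asarray(X, dtype=float).ravel()
            if len(vals) < self.min_cells:
                raise ValueError(
                    f"need at least {self.min_cells} cells, got {len(vals)}")
            hist = DNAContentHistogram.from_intensities(vals, self.n_bins)
        if hist.n_cells < self.min_cells:
            raise ValueError("histogram holds too few cells for a stable fit")

        (mu1_0, mu2_0), n_modes = self._find_peaks(hist)
        if n_modes < 2 and not self.constrain_ratio:
            raise ValueError("single-mode histogram: set constrain_ratio "
                             "to assume mu_G2M = 2 mu_G1")

        x = hist.centers
        yc = hist.counts.astype(float)
        wbin = hist.width

        # rough G1 peak width from the half-maximum of the smoothed histogram
        smooth = ndi.gaussian_filter1d(yc, 1.5)
        i1 = int(np.argmin(np.abs(x - mu1_0)))
        half = 0.5 * smooth[i1]
        right = i1
        while right + 1 < len(x) and smooth[right + 1] > half:
            right += 1
        left = i1
        while left - 1 >= 0 and smooth[left - 1] > half:
            left -= 1
        sd0 = max(0.5 * (x[right] - x[left]) / 1.177, wbin)  # FWHM/2.355
        cv0 = float(np.clip(sd0 / mu1_0, 0.01, 0.15))

        # approximate per-bin Poisson noise scale for weighted least squares
        w_sig = np.sqrt(np.clip(yc, 1.0, None))
        peak1 = max(float(yc[i1]), 1.0)
        i2 = int(np.argmin(np.abs(x - mu2_0)))
        peak2 = max(float(yc[i2]), 0.0)
        a1_0 = peak1 * np.sqrt(2 * np.pi) * cv0 * mu1_0 / wbin
        a2_0 = max(peak2 * np.sqrt(2 * np.pi) * cv0 * mu2_0 / wbin, 1e-6)

        # stage 1 (the peaks): normals with a shared CV fitted on windows
        # around each peak, weighted toward the uncontaminated outer flanks
        win = (np.abs(x - mu1_0) <= 2.5 * sd0) | (np.abs(x - mu2_0)
                                                  <= 2.5 * sd0)
        if win.sum() < (5 if self.constrain_ratio else 6):
            win = np.ones_like(win, dtype=bool)

        def resid_peaks(p):
            mu1, cv, a1, a2 = p[:4]
            mu2 = 2.0 * mu1 if self.constrain_ratio else p[4]
            g1 = a1 * stats.norm.pdf(x[win], mu1, cv * mu1)
            g2 = a2 * stats.norm.pdf(x[win], mu2, cv * mu2)
            return ((g1 + g2) * wbin - yc[win]) / w_sig[win]

        p0 = [mu1_0, cv0, a1_0, a2_0]
        plo = [0.8 * mu1_0, 0.005, 0.0, 0.0]
        phi = [1.2 * mu1_0, 0.30, np.inf, np.inf]
        if not self.constrain_ratio:
            p0.append(mu2_0)
            plo.append(1.7 * 0.8 * mu1_0)
            phi.append(2.3 * 1.2 * mu1_0)
        stage1 = optimize.least_squares(resid_peaks, p0, bounds=(plo, phi),
                                        max_nfev=2000)
        mu1_1, cv_1, a1_1, a2_1 = stage1.x[:4]
        mu2_1 = 2.0 * mu1_1 if self.constrain_ratio else stage1.x[4]

        # stage 2 (the S compartment): Bernstein quadratic on the residual
        mid = (x > mu1_1 + 1.5 * cv_1 * mu1_1) & (x < mu2_1 - 1.5 * cv_1
                                                  * mu2_1)
        g1f = a1_1 * stats.norm.pdf(x, mu1_1, cv_1 * mu1_1)
        g2f = a2_1 * stats.norm.pdf(x, mu2_1, cv_1 * mu2_1)
        resid_mid = yc - (g1f + g2f) * wbin
        s_level = float(np.median(resid_mid[mid])) / wbin if mid.any() else 0.0
        s_level = max(s_level, 0.0)

        # stage 3: joint bounded refinement from the sequential solution
        theta0 = [mu1_1, cv_1, a1_1, a2_1, s_level, s_level, s_level]
        lo = [0.9 * mu1_1, 0.005, 0.0, 0.0, 0.0, 0.0, 0.0]
        hi = [1.1 * mu1_1, 0.30, np.inf, np.inf, np.inf, np.inf, np.inf]
        if not self.constrain_ratio:
            theta0.append(mu2_1)
            lo.append(1.7 * 0.9 * mu1_1)
            hi.append(2.3 * 1.1 * mu1_1)

        # densities are in counts per intensity unit; compare counts/bin
        def resid2(theta):
            if not self.constrain_ratio and not \
                    1.7 <= theta[7] / theta[0] <= 2.3:
                return np.full(len(x), 1e6)
            g1, s, g2 = self._model(x, theta)
            return ((g1 + s + g2) * wbin - yc) / w_sig

        sol = optimize.least_squares(resid2, theta0, bounds=(lo, hi),
                                     max_nfev=4000)
        if not sol.success and sol.cost > 10 * len(x) * max(yc.max(), 1.0):
            raise RuntimeError(
                f"Dean-Jett-Fox fit did not converge: {sol.message}; "
                f"final cost {sol.cost:.3g}")

        theta = sol.x
        mu1, cv, a1, a2, q0, q1, q2 = theta[:7]
        mu2 = 2.0 * mu1 if self.constrain_ratio else theta[7]
        # report the quadratic in monomial form c0 + c1 (t-mu1) + c2 (t-mu1)^2
        span = max(mu2 - mu1, 1e-9)
        c0 = q0
        c1 = 2.0 * (q1 - q0) / span
        c2 = (q0 - 2.0 * q1 + q2) / span ** 2

        # compartment areas on a fine grid over the histogram support only:
        # model mass outside the observed intensity range is unconstrained
        # by the data and must not count toward the fractions
        grid = np.linspace(hist.bin_edges[0], hist.bin_edges[-1], 1024)
        g1d, sd_, g2d = self._model(grid, theta)
        dg = grid[1] - grid[0]
        areas = np.array([g1d.sum(), sd_.sum(), g2d.sum()]) * dg
        total = areas.sum()
        if total <= 0:
            raise RuntimeError("degenerate fit: zero total area")
        frac = 100.0 * areas / total

        self.mu_g1_ = float(mu1)
        self.mu_g2m_ = float(mu2)
        self.cv_ = float(cv)
        self.amplitudes_ = (float(a1), float(a2))
        self.s_polynomial_ = (float(c0), float(c1), float(c2))
        self._s_bernstein_ = (float(q0), float(q1), float(q2))
        self.fractions_ = PhaseFractions(*map(float, frac))
        g1c, sc, g2c = self._model(x, theta)
        self.residual_ = float(np.sqrt(np.mean(
            ((g1c + sc + g2c) * wbin - yc) ** 2)))
        self.histogram_ = hist
        return self

    def predict(self, x):
        """Fitted counts-per-bin curve at intensities ``x``."""
        theta = [self.mu_g1_, self.cv_, *self.amplitudes_,
                 *self._s_bernstein_]
        if not self.constrain_ratio:
            theta.append(self.mu_g2m_)
        g1, s, g2 = self._model(np.asarray(x, dtype=float), theta)
        return (g1 + s + g2) * self.histogram_.width

    def to_dict(self) -> dict:
        return {
            "mu_g1": self.mu_g1_, "mu_g2m": self.mu_g2m_, "cv": self.cv_,
            "s_polynomial": list(self.s_polynomial_),
            "amplitudes": list(self.amplitudes_),
            "fractions": {"g1": self.fractions_.g1, "s": self.fractions_.s,
                          "g2m": self.fractions_.g2m},
            "residual": self.residual_,
        }


def fit_dean_jett_fox(hist, constrain_ratio: bool = False, n_bins: int = 50):
    """Fit the model; returns (fitted estimator, PhaseFractions)."""
    est = DeanJettFox(constrain_ratio=constrain_ratio, n_bins=n_bins).fit(hist)
    return est, est.fractions_


def pick_harvest_times(timecourse):
    """Per-phase harvest hour maximizing that phase's fitted fraction.

    ``timecourse`` is a list of (hours, PhaseFractions) pairs; ties go to
    the earliest hour.  Returns a dict with keys 'g1', 's', 'g2m'.
    """
    items = list(timecourse)
    if not items:
        raise ValueError("empty time course")
    items.sort(key=lambda hf: hf[0])
    out = {}
    for phase in ("g1", "s", "g2m"):
        best_h, best_f = items[0][0], getattr(items[0][1], phase)
        for h, f in items[1:]:
            if getattr(f, phase) > best_f:
                best_h, best_f = h, getattr(f, phase)
        out[phase] = best_h
    return out
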