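"""CN-correlation analysis of single-cell migration.

For each pair of adjacent movie frames the cell-centroid displacement
magnitude (CCD) and the nuclear-centroid displacement projected on the CCD
direction (NCD_par) define one CN correlation datum; its polar angle
``atan2(CCD, NCD_par)`` falls in [0, 180] degrees.  Pooled over cells, the
polar-angle histogram is a migration fingerprint that decomposes — by
univariate normal-mixture (UNM) fitting — into weighted signature
subcellular activities.  Two derived statistics summarize the profile:

* CMPI (cell migration potential index): the occurrence of low-angle
  (<= 75 deg) data times their mean NCD_par, a long-term motility
  estimator;
* the polarity histogram: per-step CCD directions relative to the
  movie-long net displacement orientation, whose concentration measures
  migratory persistence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .mixtures import SIGNATURE_ANGLES, DEFAULT_SD_DEG
from .simulate import CellMovie

__all__ = [
    "CNProfile",
    "UNMDecomposer",
    "CMPIResult",
    "PolarityHistogram",
    "compute_cn_data",
    "unm_decompose",
    "cmpi",
    "polarity_histogram",
    "convergence_check",
]

logger = logging.getLogger(__name__)

#: steps whose cell-centroid displacement is below this floor (µm) leave
#: the CCD direction undefined and are excluded from the profile
MOTION_FLOOR_UM = 1e-3


@dataclass
class CNProfile:
    """Pooled CN correlation data (one row per adjacent-frame pair)."""

    ccd: np.ndarray       # µm, >= 0
    ncd_par: np.ndarray   # µm, signed
    angle: np.ndarray     # degrees in [0, 180]
    cell_ids: np.ndarray  # provenance per datum
    interval: float = 1.0  # minutes
    n_excluded: int = 0    # sub-floor steps dropped

    def __len__(self) -> int:
        return len(self.angle)

    @staticmethod
    def concatenate(profiles: list["CNProfile"]) -> "CNProfile":
        if not profiles:
            raise ValueError("no profiles to concatenate")
        return CNProfile(
            ccd=np.concatenate([p.ccd for p in profiles]),
            ncd_par=np.concatenate([p.ncd_par for p in profiles]),
            angle=np.concatenate([p.angle for p in profiles]),
            cell_ids=np.concatenate([p.cell_ids for p in profiles]),
            interval=profiles[0].interval,
            n_excluded=sum(p.n_excluded for p in profiles),
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"ccd_um": self.ccd, "ncd_par_um": self.ncd_par,
                             "angle_deg": self.angle, "cell_id": self.cell_ids})


def compute_cn_data(movie: CellMovie, cell_id=0,
                    relative_to_cell: bool = False) -> CNProfile:
    """Build the CN profile of a movie from its centroid tracks.

    Per adjacent frame pair: ``ccd = |d_cell|``; ``u = d_cell / ccd``;
    ``ncd_par = d_nucleus . u`` (nucleus displacement in the lab frame
    projected on the CCD direction, so that a rigid translation of cell and
    nucleus sits at exactly 45 deg); ``angle = atan2(ccd, ncd_par)`` in
    degrees.  Steps with ``ccd`` below the motion floor are excluded and
    counted in ``n_excluded``.

    With ``relative_to_cell=True`` the nucleus displacement is taken
    relative to the cell centroid motion instead (the alternative reading
    of "relative" nuclear displacement); rigid translation then sits at
    90 deg.
    """
    if movie.nucleus_centroids is None:
        raise ValueError("nucleus channel is required")
    if movie.n_frames < 2:
        return CNProfile(np.empty(0), np.empty(0), np.empty(0),
                         np.empty(0, dtype=object), interval=1.0)
    d_cell = np.diff(movie.cell_centroids, axis=0)
    d_nuc = np.diff(movie.nucleus_centroids, axis=0)
    if relative_to_cell:
        d_nuc = d_nuc - d_cell
    ccd = np.hypot(d_cell[:, 0], d_cell[:, 1])
    keep = ccd >= MOTION_FLOOR_UM
    u = d_cell[keep] / ccd[keep, None]
    ncd_par = np.einsum("ij,ij->i", d_nuc[keep], u)
    angle = np.degrees(np.arctan2(ccd[keep], ncd_par))
    return CNProfile(
        ccd=ccd[keep],
        ncd_par=ncd_par,
        angle=angle,
        cell_ids=np.full(keep.sum(), cell_id, dtype=object),
        interval=movie.interval if movie.n_frames > 1 else 1.0,
        n_excluded=int((~keep).sum()),
    )


# ---------------------------------------------------------------------------
# univariate normal mixture decomposition
# ---------------------------------------------------------------------------

class UNMDecomposer(BaseEstimator):
    """EM fit of a univariate normal mixture anchored on signature angles.

    The polar-angle histogram of a CN profile is decomposed into ``k``
    normal components; each fitted component is then assigned to the
    nearest signature activity.  Angles are treated on the line [0, 180]
    (no circular wrap-around), matching the linear normal-mixture reading
    of the fingerprint.

    Parameters
    ----------
    k :
        Number of components.  ``None`` selects k over 2..6 by BIC.
    signatures :
        Mapping of activity label -> expected peak angle used for
        initialization and component assignment.
    n_restarts :
        EM restarts (signature-anchored, quantile and jittered inits);
        the best log-likelihood solution wins.
    tol, max_iter :
        EM convergence tolerance on the log-likelihood and iteration cap.
    sd_mode :
        How component spreads are handled: ``"fixed"`` (default) holds
        every sd at ``fixed_sd`` — the known angular spread of a signature
        activity — so only weights and peak positions are estimated;
        ``"shared"`` estimates one common sd; ``"free"`` estimates each
        sd separately (closely overlapping activities then become weakly
        identifiable at profile-sized n).
    fixed_sd :
        Component sd (deg) under ``sd_mode="fixed"``.
    min_sd :
        Lower bound (deg) on estimated standard deviations, guarding
        against degenerate spikes.

    Attributes
    ----------
    means_, sds_, weights_ : arrays of the fitted components (sorted by mean)
    labels_ : signature activity assigned to each component
    loglik_ : final log-likelihood
    k_ : number of components used
    n_ : number of angles fitted
    """

    def __init__(self, k: int | None = None, signatures: dict | None = None,
                 n_restarts: int = 20, tol: float = 1e-8, max_iter: int = 500,
                 sd_mode: str = "fixed", fixed_sd: float = DEFAULT_SD_DEG,
                 min_sd: float = 1.0, random_state: int = 0):
        self.k = k
        self.signatures = signatures
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.sd_mode = sd_mode
        self.fixed_sd = fixed_sd
        self.min_sd = min_sd
        self.random_state = random_state

    # -- EM core -----------------------------------------------------------

    @staticmethod
    def _loglik(x, w, mu, sd):
        comp = w[None, :] * stats.norm.pdf(x[:, None], mu[None, :], sd[None, :])
        dens = comp.sum(axis=1)
        return float(np.sum(np.log(np.clip(dens, 1e-300, None)))), comp, dens

    def _em(self, x, w, mu, sd):
        if self.sd_mode not in ("fixed", "shared", "free"):
            raise ValueError("sd_mode must be 'fixed', 'shared' or 'free'")
        prev = -np.inf
        ll = prev
        for _ in range(self.max_iter):
            ll, comp, dens = self._loglik(x, w, mu, sd)
            resp = comp / np.clip(dens[:, None], 1e-300, None)
            nk = resp.sum(axis=0)
            w = nk / len(x)
            mu = (resp * x[:, None]).sum(axis=0) / np.clip(nk, 1e-12, None)
            if self.sd_mode == "free":
                var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) \
                    / np.clip(nk, 1e-12, None)
                sd = np.sqrt(np.clip(var, self.min_sd**2, None))
            elif self.sd_mode == "shared":
                var = float((resp * (x[:, None] - mu[None, :]) ** 2).sum()
                            / len(x))
                sd = np.full(len(mu), max(np.sqrt(var), self.min_sd))
            if abs(ll - prev) < self.tol * (1.0 + abs(ll)):
                break
            prev = ll
        ll, _, _ = self._loglik(x, w, mu, sd)
        return ll, w, mu, sd

    def _inits(self, x, k, rng):
        from itertools import combinations

        sig = np.sort(np.array(list(self._signature_map().values())))
        sd0 = np.full(k, self.fixed_sd)
        inits = []
        # (a) signature-anchored: every k-subset of the signature angles,
        #     with weights started at each subset's nearest-angle supports
        if len(sig) >= k:
            for subset in combinations(range(len(sig)), k):
                mu = sig[list(subset)].astype(float)
                assign = np.argmin(np.abs(x[:, None] - mu[None, :]), axis=1)
                w = np.clip(np.bincount(assign, minlength=k), 1, None
                            ).astype(float)
                inits.append((w / w.sum(), mu, sd0.copy()))
        # (b) quantile-based
        qs = np.quantile(x, (np.arange(k) + 0.5) / k)
        inits.append((np.full(k, 1.0 / k), qs, sd0.copy()))
        # (c) jittered data-point draws
        while len(inits) < max(self.n_restarts, 2):
            mu0 = np.sort(rng.choice(x, size=k, replace=False)).astype(float)
            mu0 = mu0 + rng.normal(0, 3.0, k)
            inits.append((np.full(k, 1.0 / k), mu0, sd0.copy()))
        return inits

    def _signature_map(self) -> dict:
        return dict(self.signatures) if self.signatures else dict(SIGNATURE_ANGLES)

    def _fit_k(self, x, k, rng):
        best = None
        for w0, mu0, sd0 in self._inits(x, k, rng):
            try:
                ll, w, mu, sd = self._em(x, np.array(w0, float),
                                         np.array(mu0, float),
                                         np.array(sd0, float))
            except FloatingPointError:  # pragma: no cover
                continue
            if best is None or ll > best[0]:
                best = (ll, w, mu, sd)
        if best is None:
            raise RuntimeError("EM failed to converge from any initialization")
        return best

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if len(x) < 50:
            raise ValueError("need at least 50 angles for a mixture fit")
        sig_map = self._signature_map()
        if not sig_map:
            raise ValueError("signatures must be non-empty")
        rng = np.random.default_rng(self.random_state)
        if self.k is not None:
            if self.k > len(np.unique(x)):
                raise ValueError("k exceeds the number of distinct angles")
            ll, w, mu, sd = self._fit_k(x, self.k, rng)
            k = self.k
        else:
            best = None
            for kk in range(2, 7):
                ll, w, mu, sd = self._fit_k(x, kk, rng)
                bic = -2 * ll + (3 * kk - 1) * np.log(len(x))
                if best is None or bic < best[0]:
                    best = (bic, ll, w, mu, sd, kk)
            _, ll, w, mu, sd, k = best

        order = np.argsort(mu)
        self.weights_, self.means_, self.sds_ = w[order], mu[order], sd[order]
        self.loglik_ = ll
        self.k_ = k
        self.n_ = len(x)
        self.labels_ = self._assign_signatures(self.means_, sig_map)
        return self

    @staticmethod
    def _assign_signatures(means, sig_map):
        """One-to-one component-to-signature matching by angular distance.

        With at most one component per signature (Table-style reporting),
        an optimal assignment keeps e.g. a 132-degree side-protrusion peak
        from being pulled onto the retraction signature by a nearer but
        already-taken angle.  When components outnumber signatures the
        extras fall back to their nearest signature.
        """
        from scipy.optimize import linear_sum_assignment

        labels, angles = zip(*sorted(sig_map.items(), key=lambda kv: kv[1]))
        angles = np.array(angles, dtype=float)
        means = np.asarray(means, dtype=float)
        if len(means) <= len(angles):
            cost = np.abs(means[:, None] - angles[None, :])
            rows, cols = linear_sum_assignment(cost)
            out = [None] * len(means)
            for r, c in zip(rows, cols):
                out[r] = labels[c]
            return tuple(out)
        idx = [int(np.argmin(np.abs(angles - m))) for m in means]
        return tuple(labels[i] for i in idx)

    def predict(self, X):
        """Most responsible component index per angle."""
        x = np.asarray(X, dtype=float).ravel()
        _, comp, _ = self._loglik(x, self.weights_, self.means_, self.sds_)
        return np.argmax(comp, axis=1)

    def weight_near(self, angle: float) -> float:
        """Total fitted weight of the component(s) nearest a signature angle."""
        sig_map = self._signature_map()
        labels, angles = zip(*sorted(sig_map.items(), key=lambda kv: kv[1]))
        angles = np.array(angles)
        target = labels[int(np.argmin(np.abs(angles - angle)))]
        return float(sum(w for w, lbl in zip(self.weights_, self.labels_)
                         if lbl == target))

    def to_dict(self) -> dict:
        return {
            "components": [
                {"mean_angle": float(m), "sd": float(s), "weight": float(w),
                 "activity": lbl}
                for m, s, w, lbl in zip(self.means_, self.sds_,
                                        self.weights_, self.labels_)
            ],
            "loglik": float(self.loglik_),
            "k": int(self.k_),
            "n": int(self.n_),
        }


def unm_decompose(angles, signatures=None, k: int | None = None,
                  **kwargs) -> UNMDecomposer:
    """Functional wrapper: fit a :class:`UNMDecomposer` on polar angles."""
    if signatures is not None and not isinstance(signatures, dict):
        signatures = {f"sig_{a:g}": float(a) for a in signatures}
    return UNMDecomposer(k=k, signatures=signatures, **kwargs).fit(angles)


# ---------------------------------------------------------------------------
# CMPI and polarity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CMPIResult:
    """Low-angle occurrence, mean NCD_par over that subset, and their product."""

    occurrence: float   # fraction of data with angle <= cutoff
    mean_ncd: float     # µm over the low-angle subset (0 if empty)
    cmpi: float         # µm, occurrence * mean_ncd
    cutoff: float       # degrees
    n: int


def cmpi(profile: CNProfile, cutoff: float = 75.0,
         per_hour_sum: bool = False) -> CMPIResult:
    """Cell migration potential index of a CN profile.

    Only CN data at polar angles up to ``cutoff`` (default 75 deg) carry a
    nuclear displacement that effectively contributes to migration;
    CMPI = occurrence of such data x their mean NCD_par.  With
    ``per_hour_sum=True`` the raw low-angle NCD_par sum per hour of
    observation is reported instead (the two differ by 1/n normalization).
    """
    n = len(profile)
    if n == 0:
        raise ValueError("profile is empty")
    low = profile.angle <= cutoff
    occurrence = float(low.mean())
    mean_ncd = float(profile.ncd_par[low].mean()) if low.any() else 0.0
    if per_hour_sum:
        hours = n * profile.interval / 60.0
        value = float(profile.ncd_par[low].sum()) / hours
    else:
        value = occurrence * mean_ncd
    return CMPIResult(occurrence=occurrence, mean_ncd=mean_ncd, cmpi=value,
                      cutoff=cutoff, n=n)


@dataclass
class PolarityHistogram:
    """Signed per-step direction offsets from the movie-long orientation."""

    bin_edges: np.ndarray          # degrees over [-180, 180]
    counts: np.ndarray
    reference_direction: float     # degrees, lab frame
    relative_angles: np.ndarray    # degrees in [-180, 180)

    @property
    def circular_variance(self) -> float:
        """1 - mean resultant length of the relative step directions."""
        rad = np.deg2rad(self.relative_angles)
        return float(1.0 - np.hypot(np.cos(rad).mean(), np.sin(rad).mean()))


def polarity_histogram(movie: CellMovie, bin_width: float = 10.0,
                       min_step_um: float = MOTION_FLOOR_UM) -> PolarityHistogram:
    """Histogram of 1-frame CCD directions relative to the net displacement.

    The reference orientation is the movie-long displacement of the cell
    centroid; with zero net displacement it falls back to the trajectory's
    first principal axis (logged).
    """
    if movie.n_frames < 2:
        raise ValueError("need at least two frames")
    d = np.diff(movie.cell_centroids, axis=0)
    mags = np.hypot(d[:, 0], d[:, 1])
    d = d[mags >= min_step_um]
    net = movie.cell_centroids[-1] - movie.cell_centroids[0]
    if np.hypot(*net) < min_step_um:
        centered = movie.cell_centroids - movie.cell_centroids.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        net = vt[0]
        logger.warning("zero net displacement; polarity reference set to the "
                       "trajectory's first principal axis")
    ref = np.degrees(np.arctan2(net[1], net[0]))
    step_dirs = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    rel = ((step_dirs - ref + 180.0) % 360.0) - 180.0
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(rel, bins=edges)
    return PolarityHistogram(bin_edges=edges, counts=counts,
                             reference_direction=float(ref),
                             relative_angles=rel)


# ---------------------------------------------------------------------------
# homogeneity / convergence
# ---------------------------------------------------------------------------

def convergence_check(per_cell_values, threshold: float = 0.10):
    """Smallest accumulated n at which relative SEM falls below threshold.

    Scans prefixes of the per-cell value list (in the given order) and
    returns the first n >= 2 whose SEM is at most ``threshold`` of the
    absolute prefix mean; returns ``None`` if the series never converges.
    """
    vals = np.asarray(per_cell_values, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least two per-cell values")
    for n in range(2, len(vals) + 1):
        prefix = vals[:n]
        mean = prefix.mean()
        if mean == 0:
            raise ValueError("prefix mean is zero; relative SEM undefined")
        sem = prefix.std(ddof=1) / np.sqrt(n)
        if sem / abs(mean) <= threshold:
            return n
    return None


def relative_sem(values, n: int | None = None) -> float:
    """Relative SEM (fraction of the mean) of the first ``n`` values."""
    vals = np.asarray(values, dtype=float)
    if n is not None:
        vals = vals[:n]
    mean = vals.mean()
    if mean == 0:
        raise ValueError("mean is zero; relative SEM undefined")
    return float(vals.std(ddof=1) / np.sqrt(len(vals)) / abs(mean))
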