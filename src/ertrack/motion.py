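"""Mean-squared-displacement analysis and translation-state classification.

The confinement statistic is the per-trajectory MSD at lag τ = 1 s,

    MSD_τ = Σ_i [ (x_{i+1} − x_i)² + (y_{i+1} − y_i)² ] / n ,

averaged over all consecutive-frame displacement pairs.  Secretome mRNAs
engaged by ribosomes on the ER show confined motion, so a trajectory is
classified *translating* when MSD_τ=1s falls strictly below a cutoff
(default 0.055 µm²; ribosome tracks use an effective cutoff of 0.04 µm²).

The ensemble MSD grows as MSD(τ) = 2 n D_app τ + 4σ² for n spatial
dimensions (here n = 2) with localization error σ; D_app and σ are taken
from an ordinary least-squares line through the first few lag points.

Displacement distributions are decomposed into up to three diffusive
species by fitting the 2D displacement CDF

    CDF(r) = 1 − Σ_x A_x · exp(−r² / (4 D_x t)),   ΣA_x = 1, A_x ≥ 0,

to the empirical CDF of single-lag displacements r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .io_tracks import Trajectory

logger = logging.getLogger(__name__)

TRANSLATING = "translating"
NON_TRANSLATING = "non_translating"
UNCLASSIFIED = "unclassified"


@dataclass
class ClassificationConfig:
    """Thresholds and minimum data requirements for translation-state calls."""

    msd_threshold: float = 0.055  # µm², mRNA cutoff
    ribosome_threshold: float = 0.04  # µm², effective cutoff for ribosome tracks
    min_localizations: int = 10
    lag: float = 1.0  # s

    def __post_init__(self) -> None:
        if self.msd_threshold <= 0 or self.ribosome_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if self.min_localizations < 2:
            raise ValueError("min_localizations must be >= 2")
        if self.lag <= 0:
            raise ValueError("lag must be > 0")


@dataclass
class TrajectoryMsd:
    track_id: str
    msd_lag1: float  # µm²
    n_displacements: int
    label: str = UNCLASSIFIED

    def __post_init__(self) -> None:
        if self.msd_lag1 < 0:
            raise ValueError("msd_lag1 must be >= 0")


@dataclass
class EnsembleMsdFit:
    lag_times: np.ndarray  # s
    msd_values: np.ndarray  # µm²
    n_per_lag: np.ndarray
    d_app: float | None = None  # µm²/s
    sigma: float | None = None  # µm
    n_dimensions: int = 2
    n_fit_points: int = 0
    clamped: bool = False  # true when slope or intercept was clamped at 0


@dataclass
class CdfMixtureFit:
    fractions: np.ndarray  # descending-D order, sums to 1
    diffusion_coefficients: np.ndarray  # µm²/s, descending
    lag_t: float
    rss: float
    n_components_used: int
    merged: bool = False  # components closer than 2x in D were merged
    raw_fractions: np.ndarray | None = None
    raw_diffusion_coefficients: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.fractions < -1e-9):
            raise ValueError("fractions must be >= 0")
        if abs(self.fractions.sum() - 1) > 1e-6:
            raise ValueError("fractions must sum to 1")


@dataclass
class DisplacementSample:
    """Single-lag displacement magnitudes (µm, all >= 0)."""

    r: np.ndarray
    lag_t: float

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if np.any(self.r < 0):
            raise ValueError("displacements must be >= 0")
        if self.lag_t <= 0:
            raise ValueError("lag_t must be > 0")


# ---------------------------------------------------------------------------
# per-trajectory MSD and classification


def msd_lag1(traj: Trajectory, cfg: ClassificationConfig | None = None) -> TrajectoryMsd:
    """Mean squared displacement over all consecutive-frame pairs.

    Pairs separated by more than one frame (gaps) are skipped and counted;
    trajectories with fewer than ``cfg.min_localizations`` points are marked
    unclassified.
    """
    cfg = cfg or ClassificationConfig()
    frames = traj.frames
    xy = traj.xy
    dframe = np.diff(frames)
    good = dframe == 1
    n_gaps = int((~good).sum())
    if n_gaps:
        logger.warning("track %s: %d gap pair(s) skipped in MSD", traj.track_id, n_gaps)
    d = np.diff(xy, axis=0)[good]
    sq = (d**2).sum(axis=1)
    n_disp = len(sq)
    msd = float(sq.mean()) if n_disp else 0.0
    label = UNCLASSIFIED if len(traj) < cfg.min_localizations or n_disp == 0 else ""
    out = TrajectoryMsd(track_id=traj.track_id, msd_lag1=msd, n_displacements=n_disp)
    if label == UNCLASSIFIED:
        out.label = UNCLASSIFIED
    else:
        out.label = classify_translation(out, cfg, _checked=True)
    return out


def classify_translation(
    msd: TrajectoryMsd, cfg: ClassificationConfig | None = None, _checked: bool = False
) -> str:
    """Translating iff MSD_τ=1s < threshold (strict); ties are non-translating."""
    cfg = cfg or ClassificationConfig()
    if not _checked and msd.label == UNCLASSIFIED:
        return UNCLASSIFIED
    return TRANSLATING if msd.msd_lag1 < cfg.msd_threshold else NON_TRANSLATING


def classify_trajectories(
    trajs: list[Trajectory], cfg: ClassificationConfig | None = None
) -> list[TrajectoryMsd]:
    cfg = cfg or ClassificationConfig()
    return [msd_lag1(t, cfg) for t in trajs]


def translating_fraction(msds: list[TrajectoryMsd]) -> float:
    """Translating / total classified; unclassified tracks are excluded entirely."""
    classified = [m for m in msds if m.label != UNCLASSIFIED]
    if not classified:
        raise ValueError("no classified trajectories: cannot compute a translating fraction")
    return sum(m.label == TRANSLATING for m in classified) / len(classified)


# ---------------------------------------------------------------------------
# ensemble MSD and apparent diffusion coefficient


def ensemble_msd(trajs: list[Trajectory], max_lag: float, frame_interval: float | None = None) -> EnsembleMsdFit:
    """Population MSD: mean squared displacement over all pairs at each lag.

    Lags are integer multiples of the frame interval up to ``max_lag``; lags
    with no displacement pairs are omitted.
    """
    if not trajs:
        raise ValueError("no trajectories")
    if frame_interval is None:
        dts = np.concatenate([np.diff(t.times) for t in trajs])
        frame_interval = float(np.min(dts))
    n_lags = int(np.floor(max_lag / frame_interval + 1e-9))
    sums = np.zeros(n_lags)
    counts = np.zeros(n_lags, dtype=int)
    for tr in trajs:
        frames = tr.frames
        xy = tr.xy
        if np.all(np.diff(frames) == 1):  # gapless: vectorized per lag
            for k in range(1, min(n_lags, len(xy) - 1) + 1):
                sq = ((xy[k:] - xy[:-k]) ** 2).sum(axis=1)
                sums[k - 1] += sq.sum()
                counts[k - 1] += len(sq)
        else:  # pairs exactly k frames apart, robust to gaps
            idx = {f: i for i, f in enumerate(frames)}
            for k in range(1, n_lags + 1):
                for i, f in enumerate(frames):
                    j = idx.get(f + k)
                    if j is not None:
                        sums[k - 1] += ((xy[j] - xy[i]) ** 2).sum()
                        counts[k - 1] += 1
    have = counts > 0
    lags = (np.arange(1, n_lags + 1) * frame_interval)[have]
    msd = sums[have] / counts[have]
    return EnsembleMsdFit(lag_times=lags, msd_values=msd, n_per_lag=counts[have])


def fit_dapp(ensemble: EnsembleMsdFit, n_fit_points: int = 4) -> EnsembleMsdFit:
    """OLS line through the first ``n_fit_points`` of MSD(τ) = 2nDτ + 4σ².

    With n = 2 dimensions, D_app = slope/4 and σ = sqrt(intercept)/2.
    Negative slope or intercept is clamped at 0 and flagged — confined
    ensembles routinely produce a sub-linear curve whose tail pulls the
    intercept around.
    """
    if len(ensemble.lag_times) < n_fit_points:
        raise ValueError(
            f"need >= {n_fit_points} lag points, have {len(ensemble.lag_times)}"
        )
    tau = ensemble.lag_times[:n_fit_points]
    msd = ensemble.msd_values[:n_fit_points]
    slope, intercept = np.polyfit(tau, msd, 1)
    clamped = False
    if slope < 0:
        slope, clamped = 0.0, True
    if intercept < 0:
        intercept, clamped = 0.0, True
    n = ensemble.n_dimensions
    ensemble.d_app = float(slope / (2 * n))
    ensemble.sigma = float(np.sqrt(intercept) / 2)
    ensemble.n_fit_points = n_fit_points
    ensemble.clamped = clamped
    return ensemble


# ---------------------------------------------------------------------------
# displacement CDF mixture fit


def pooled_displacements(
    trajs: list[Trajectory], lag_frames: int = 1, frame_interval: float = 1.0
) -> DisplacementSample:
    """Pool single-lag displacement magnitudes across trajectories."""
    rs = []
    for tr in trajs:
        frames = tr.frames
        xy = tr.xy
        idx = {f: i for i, f in enumerate(frames)}
        for i, f in enumerate(frames):
            j = idx.get(f + lag_frames)
            if j is not None:
                rs.append(np.hypot(*(xy[j] - xy[i])))
    return DisplacementSample(r=np.array(rs), lag_t=lag_frames * frame_interval)


def _mixture_cdf(r: np.ndarray, weights: np.ndarray, log10_d: np.ndarray, t: float) -> np.ndarray:
    a = weights / weights.sum()
    d = 10.0**log10_d
    return 1.0 - np.sum(a[:, None] * np.exp(-(r[None, :] ** 2) / (4.0 * d[:, None] * t)), axis=0)


def _fit_k_components(
    r_sorted: np.ndarray, ecdf: np.ndarray, t: float, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Multi-start constrained least squares; returns (A desc-D, D desc, rss)."""
    # data-driven D scale: median r² / (4 t ln 2) is the single-species estimate
    d_med = np.median(r_sorted) ** 2 / (4 * t * np.log(2))
    d_med = max(d_med, 1e-6)
    starts = []
    # spread starts across decades around the data scale
    for spread in (0.0, 1.0, 2.0):
        center = np.log10(d_med)
        if k == 1:
            logd = np.array([center])
        else:
            logd = center + np.linspace(-spread, spread, k)
        starts.append((np.full(k, 1.0 / k), logd))
    for _ in range(4):
        starts.append(
            (rng.dirichlet(np.ones(k)), np.log10(d_med) + rng.uniform(-2.5, 2.5, size=k))
        )
    best = None
    lo = np.concatenate([np.full(k, 1e-9), np.full(k, -6.0)])
    hi = np.concatenate([np.full(k, 1.0), np.full(k, 3.0)])

    def resid(p):
        return _mixture_cdf(r_sorted, p[:k], p[k:], t) - ecdf

    for w0, logd0 in starts:
        p0 = np.concatenate([np.clip(w0, 1e-6, 1.0), np.clip(logd0, -5.9, 2.9)])
        try:
            sol = least_squares(resid, p0, bounds=(lo, hi), max_nfev=4000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-12:
            best = (rss, sol.x)
    if best is None:
        raise RuntimeError(
            f"CDF mixture fit with {k} component(s) failed to converge from any start"
        )
    rss, p = best
    a = p[:k] / p[:k].sum()
    d = 10.0 ** p[k:]
    order = np.argsort(d)[::-1]
    return a[order], d[order], rss


def fit_cdf_mixture(
    sample: DisplacementSample,
    n_components: int | None = 3,
    seed: int = 0,
    max_ecdf_points: int = 2000,
    merge_ratio: float = 2.0,
) -> CdfMixtureFit:
    """Fit CDF(r) = 1 − Σ A_x exp(−r²/4D_x t) to the empirical displacement CDF.

    The empirical CDF is evaluated on the sorted displacements (no binning);
    weights are optimized as nonnegative free parameters normalized inside
    the model, so ΣA = 1 and A ≥ 0 hold by construction, and D on a log
    scale with multiple starts.  When ``n_components`` is None the model
    among 1–3 components is selected by BIC.  Components whose D differ by
    less than ``merge_ratio`` are merged in the report (flagged): the
    mixture is not identifiable for nearly equal coefficients.
    """
    r = np.sort(sample.r)
    n = len(r)
    if n < 100:
        logger.warning("CDF fit on only %d displacements; >=100 recommended", n)
    if n < 10:
        raise ValueError("need at least 10 displacements")
    ecdf_full = np.arange(1, n + 1) / n
    if n > max_ecdf_points:  # thin evenly for speed; keeps the tails
        take = np.unique(np.linspace(0, n - 1, max_ecdf_points).round().astype(int))
        r_fit, ecdf = r[take], ecdf_full[take]
    else:
        r_fit, ecdf = r, ecdf_full
    rng = np.random.default_rng(seed)
    t = sample.lag_t

    if n_components is not None:
        if not 1 <= n_components <= 3:
            raise ValueError("n_components must be in 1..3")
        a, d, rss = _fit_k_components(r_fit, ecdf, t, n_components, rng)
    else:
        # parameters from the CDF least squares, model order by BIC on the
        # exact mixture likelihood of the raw displacements (ECDF residuals
        # are correlated, so an RSS-based criterion would overfit)
        best = None
        for k in (1, 2, 3):
            a_k, d_k, rss_k = _fit_k_components(r_fit, ecdf, t, k, rng)
            dens = np.sum(
                a_k[:, None] * (r[None, :] / (2 * d_k[:, None] * t))
                * np.exp(-(r[None, :] ** 2) / (4 * d_k[:, None] * t)), axis=0)
            ll = float(np.sum(np.log(np.maximum(dens, 1e-300))))
            bic = -2 * ll + (2 * k - 1) * np.log(n)
            if best is None or bic < best[0]:
                best = (bic, a_k, d_k, rss_k)
        _, a, d, rss = best

    raw_a, raw_d = a.copy(), d.copy()
    merged = False
    i = 0
    a, d = list(a), list(d)
    while i < len(d) - 1:
        if d[i + 1] > 0 and d[i] / d[i + 1] < merge_ratio:
            w = a[i] + a[i + 1]
            d[i] = float(np.exp((a[i] * np.log(d[i]) + a[i + 1] * np.log(max(d[i + 1], 1e-300))) / max(w, 1e-300)))
            a[i] = w
            del a[i + 1], d[i + 1]
            merged = True
        else:
            i += 1
    return CdfMixtureFit(
        fractions=np.array(a),
        diffusion_coefficients=np.array(d),
        lag_t=t,
        rss=rss,
        n_components_used=len(a),
        merged=merged,
        raw_fractions=raw_a,
        raw_diffusion_coefficients=raw_d,
    )


def evaluate_mixture_cdf(fit: CdfMixtureFit, r: np.ndarray) -> np.ndarray:
    """Model CDF at displacements ``r`` for a fitted (or constructed) mixture."""
    r = np.asarray(r, dtype=float)
    a = fit.fractions
    d = fit.diffusion_coefficients
    return 1.0 - np.sum(
        a[:, None] * np.exp(-(r[None, :] ** 2) / (4.0 * d[:, None] * fit.lag_t)), axis=0
    )
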