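"""Sloan neutral community model (NCM) fitting.

The NCM predicts, for a taxon with metacommunity mean relative abundance
p, the frequency with which it is detected across local communities of
size N coupled to the metacommunity by immigration rate m:

    freq(p) = 1 - BetaCDF(d; N*m*p, N*m*(1-p))

where d is the detection limit (one read, d = 1/N, by default). The
single free parameter Nm is estimated by least squares of observed
occurrence frequencies against this curve; fit quality is the
generalized R^2 = 1 - SSE/SST (which may be negative). Confidence
intervals for m and R^2 come from a taxon bootstrap, and each taxon is
partitioned as above / neutral / below the neutral prediction using a
binomial (Wilson score) band around the fitted curve.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .core import AbundanceMatrix, occupancy_and_mean_abundance
from .exceptions import FitError, InvalidInputError

_LOG_NM_LO, _LOG_NM_HI = np.log(1e-3), np.log(1e7)
_GRID_SIZE = 281


@dataclass
class NCMFit:
    """Result of a Sloan NCM fit.

    ``table`` holds the per-taxon view: metacommunity abundance p,
    observed and predicted frequency, the confidence band, and the
    above/neutral/below partition label.
    """

    nm: float
    m: float
    community_size: float
    detection_limit: float
    r_squared: float
    ci_m: tuple[float, float]
    ci_r_squared: tuple[float, float]
    n_bootstrap: int
    n_samples: int
    seed: int
    table: pd.DataFrame = field(repr=False)

    def partition_counts(self) -> pd.Series:
        return self.table["partition"].value_counts().reindex(
            ["above", "neutral", "below"], fill_value=0
        )

    def summary(self) -> dict:
        return {
            "m": self.m,
            "Nm": self.nm,
            "N": self.community_size,
            "detection_limit": self.detection_limit,
            "r_squared": self.r_squared,
            "ci_m": list(self.ci_m),
            "ci_r_squared": list(self.ci_r_squared),
            "n_taxa": int(len(self.table)),
            "n_samples": self.n_samples,
            "n_bootstrap": self.n_bootstrap,
            "partition_counts": self.partition_counts().to_dict(),
            "seed": self.seed,
        }

    def write_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)

    def write_table(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="taxon_id")


def predicted_frequency(p, nm: float, d: float):
    """Neutral expectation of detection frequency for abundance p.

    Vectorized over ``p``; p must lie strictly inside (0, 1), d in (0, 1),
    Nm > 0. Monotone non-decreasing in p for fixed Nm and d.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise InvalidInputError("p must lie strictly in (0, 1)")
    if not 0 < d < 1:
        raise InvalidInputError("detection limit d must be in (0, 1)")
    if nm <= 0:
        raise InvalidInputError("Nm must be positive")
    out = stats.beta.sf(d, nm * p, nm * (1.0 - p))
    return float(out) if out.ndim == 0 else out


def detection_probability(p, nm, big_n: float):
    """Exact finite-depth detection probability under the neutral model.

    The marginal read count of a taxon with latent Beta(Nm*p, Nm*(1-p))
    relative abundance, sampled to depth N, is Beta-binomial; this
    returns 1 - P(count = 0). It converges to
    ``predicted_frequency(p, Nm, 1/N)`` as the depth grows, but unlike
    the sharp detection threshold it is unbiased at finite read depth.
    """
    p = np.asarray(p, dtype=float)
    a = nm * p
    b = nm * (1.0 - p)
    log_p0 = gammaln(b + big_n) + gammaln(a + b) - gammaln(b) - gammaln(a + b + big_n)
    out = -np.expm1(log_p0)
    return float(out) if out.ndim == 0 else out


def _predict(p, nm, d: float, big_n: float, detection: str):
    if detection == "threshold":
        return stats.beta.sf(d, nm * p, nm * (1.0 - p))
    if detection == "betabinomial":
        return detection_probability(p, nm, big_n)
    raise InvalidInputError(f"unknown detection model {detection!r}")


def _sse(log_nm, p, freq, d, big_n, detection) -> float:
    pred = _predict(p, np.exp(log_nm), d, big_n, detection)
    return float(np.sum((freq - pred) ** 2))


def _grid_predictions(p, d, big_n, detection, grid):
    nm = np.exp(grid)[:, None]
    if detection == "threshold":
        return stats.beta.sf(d, nm * p, nm * (1.0 - p))
    return detection_probability(p[None, :], nm, big_n)


def _fit_log_nm(
    p: np.ndarray,
    freq: np.ndarray,
    d: float,
    big_n: float | None = None,
    detection: str = "threshold",
) -> float:
    """Global grid scan over log(Nm) followed by bounded local refinement."""
    grid = np.linspace(_LOG_NM_LO, _LOG_NM_HI, _GRID_SIZE)
    pred = _grid_predictions(p, d, big_n, detection, grid)
    sse = ((pred - freq) ** 2).sum(axis=1)
    g = int(np.argmin(sse))
    lo = grid[max(g - 1, 0)]
    hi = grid[min(g + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _sse, bounds=(lo, hi), args=(p, freq, d, big_n, detection), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success or not np.isfinite(res.x):
        raise FitError(f"Nm optimizer failed: {res.message}")
    return float(res.x)


def _parabolic_refine(grid: np.ndarray, sse: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Vertex of the parabola through the grid minimum and its neighbours."""
    g = np.clip(idx, 1, len(grid) - 2)
    y0 = sse[g - 1, np.arange(sse.shape[1])]
    y1 = sse[g, np.arange(sse.shape[1])]
    y2 = sse[g + 1, np.arange(sse.shape[1])]
    h = grid[1] - grid[0]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-300, 0.5 * h * (y0 - y2) / np.where(denom == 0, 1, denom), 0.0)
    return grid[g] + np.clip(shift, -h, h)


def fit_frequencies(p, freq, d: float) -> tuple[float, float]:
    """Fit Nm to pre-computed (abundance, frequency) points.

    Returns (Nm, r_squared). Used internally by :func:`fit_ncm`; exposed
    for fitting occupancy curves that do not come from a count matrix.
    """
    p = np.asarray(p, dtype=float)
    freq = np.asarray(freq, dtype=float)
    log_nm = _fit_log_nm(p, freq, d)
    nm = float(np.exp(log_nm))
    pred = predicted_frequency(p, nm, d)
    sse = float(np.sum((freq - pred) ** 2))
    sst = float(np.sum((freq - freq.mean()) ** 2))
    return nm, (1.0 - sse / sst if sst > 0 else float("-inf"))


def fit_ncm(
    m: AbundanceMatrix,
    n_bootstrap: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    community_size: float | None = None,
    detection_limit: float | None = None,
    size_stat: str = "mean",
    bootstrap_unit: str = "taxa",
    detection: str = "betabinomial",
) -> NCMFit:
    """Fit the Sloan NCM to an abundance matrix.

    N defaults to the mean sample read total (``size_stat='median'`` to
    override) and the detection limit to 1/N. Taxa with zero mean
    abundance or zero occurrence are excluded (their Beta parameters are
    undefined). Bootstrap resamples taxa (the points of the
    occupancy–abundance plot) with replacement, 1000 replicates by
    default, and reports percentile 2.5/97.5 intervals for m and R^2.

    ``detection`` selects how the model maps latent relative abundance
    to a detection event: ``betabinomial`` (default) uses the exact
    finite-depth Beta-binomial probability of at least one read, while
    ``threshold`` uses the classical sharp cutoff at ``d``
    (:func:`predicted_frequency`). The two agree closely for deeply
    sequenced taxa; the threshold form overestimates m at finite depth.
    """
    if m.n_samples < 10:
        warnings.warn("fewer than 10 samples: NCM fit will be weakly constrained")
    occ = occupancy_and_mean_abundance(m)
    keep = (occ["mean_relative_abundance"] > 0) & (occ["frequency"] > 0)
    occ = occ[keep]
    # frequency 1 is fine; p must stay strictly interior for the Beta
    occ = occ[occ["mean_relative_abundance"] < 1]
    if len(occ) < 20:
        warnings.warn("fewer than 20 taxa with nonzero abundance: fit may be unstable")
    p = occ["mean_relative_abundance"].to_numpy()
    freq = occ["frequency"].to_numpy()
    if len(np.unique(p)) < 3:
        raise InvalidInputError("need at least 3 distinct abundance values to fit")

    totals = m.counts.sum(axis=1)
    if community_size is None:
        community_size = float(np.median(totals) if size_stat == "median" else totals.mean())
    d = detection_limit if detection_limit is not None else 1.0 / community_size

    log_nm = _fit_log_nm(p, freq, d, community_size, detection)
    nm = float(np.exp(log_nm))
    pred = _predict(p, nm, d, community_size, detection)
    sse = float(np.sum((freq - pred) ** 2))
    sst = float(np.sum((freq - freq.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("-inf")

    ci_m, ci_r2 = _bootstrap_ci(
        p, freq, d, n_bootstrap, seed, community_size, m, bootstrap_unit, detection
    )

    band_lo, band_hi = _wilson_band(pred, m.n_samples, level)
    partition = _partition_labels(freq, band_lo, band_hi)

    table = pd.DataFrame(
        {
            "mean_relative_abundance": p,
            "frequency_observed": freq,
            "frequency_predicted": pred,
            "band_low": band_lo,
            "band_high": band_hi,
            "partition": partition,
        },
        index=occ.index,
    )
    return NCMFit(
        nm=nm,
        m=nm / community_size,
        community_size=community_size,
        detection_limit=d,
        r_squared=r2,
        ci_m=ci_m,
        ci_r_squared=ci_r2,
        n_bootstrap=n_bootstrap,
        n_samples=m.n_samples,
        seed=seed,
        table=table,
    )


def _bootstrap_ci(p, freq, d, n_bootstrap, seed, community_size, matrix, unit, detection):
    if n_bootstrap < 1:
        nan = (float("nan"), float("nan"))
        return nan, nan
    rng = np.random.default_rng(seed)
    n_taxa = len(p)
    grid = np.linspace(_LOG_NM_LO, _LOG_NM_HI, _GRID_SIZE)
    if unit == "taxa":
        # Resampling taxa = multinomial weights over the occupancy points;
        # the residual grid is shared, so all replicates reduce to one matmul.
        pred_grid = _grid_predictions(p, d, community_size, detection, grid)
        resid2 = (pred_grid - freq) ** 2  # (grid, taxa)
        weights = rng.multinomial(n_taxa, np.full(n_taxa, 1.0 / n_taxa), size=n_bootstrap).T
        sse_all = resid2 @ weights  # (grid, boot)
        best = np.argmin(sse_all, axis=0)
        log_nm_b = _parabolic_refine(grid, sse_all, best)
        sse_b = sse_all[best, np.arange(n_bootstrap)]
        mean_b = (freq @ weights) / n_taxa
        sst_b = ((freq[:, None] - mean_b) ** 2 * weights).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2_b = 1.0 - sse_b / sst_b
        m_b = np.exp(log_nm_b) / community_size
    elif unit == "samples":
        m_b, r2_b = [], []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, matrix.n_samples, matrix.n_samples)
            sub = AbundanceMatrix(
                matrix.counts[idx],
                [f"b{k}" for k in range(matrix.n_samples)],
                list(matrix.taxon_ids),
            )
            occ_b = occupancy_and_mean_abundance(sub)
            occ_b = occ_b[(occ_b["mean_relative_abundance"] > 0) & (occ_b["frequency"] > 0)]
            pb = occ_b["mean_relative_abundance"].to_numpy()
            fb = occ_b["frequency"].to_numpy()
            log_nm = _fit_log_nm(pb, fb, d, community_size, detection)
            predb = _predict(pb, np.exp(log_nm), d, community_size, detection)
            sseb = np.sum((fb - predb) ** 2)
            sstb = np.sum((fb - fb.mean()) ** 2)
            m_b.append(np.exp(log_nm) / community_size)
            r2_b.append(1.0 - sseb / sstb if sstb > 0 else np.nan)
        m_b, r2_b = np.asarray(m_b), np.asarray(r2_b)
    else:
        raise InvalidInputError(f"unknown bootstrap unit {unit!r}")
    ci_m = tuple(np.nanpercentile(m_b, [2.5, 97.5]))
    ci_r2 = tuple(np.nanpercentile(r2_b, [2.5, 97.5]))
    return (float(ci_m[0]), float(ci_m[1])), (float(ci_r2[0]), float(ci_r2[1]))


def _wilson_band(pred: np.ndarray, n: int, level: float) -> tuple[np.ndarray, np.ndarray]:
    """Wilson score interval around the fitted curve, n = number of samples."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    denom = 1.0 + z**2 / n
    center = (pred + z**2 / (2 * n)) / denom
    half = z * np.sqrt(pred * (1 - pred) / n + z**2 / (4 * n**2)) / denom
    return np.clip(center - half, 0, 1), np.clip(center + half, 0, 1)


def _partition_labels(freq, lo, hi, eps: float = 1e-9):
    # eps guards the saturated ends where the band collapses onto 0 or 1
    return np.where(freq > hi + eps, "above", np.where(freq < lo - eps, "below", "neutral"))


def partition_taxa(fit: NCMFit, level: float = 0.95) -> pd.Series:
    """Re-partition taxa around the fitted curve at a different band level."""
    pred = fit.table["frequency_predicted"].to_numpy()
    freq = fit.table["frequency_observed"].to_numpy()
    lo, hi = _wilson_band(pred, fit.n_samples, level)
    return pd.Series(_partition_labels(freq, lo, hi), index=fit.table.index, name="partition")
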