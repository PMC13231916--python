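"""Simulation-based model evaluation: pcVPC, NPDE and weighted residuals.

*Prediction-corrected visual predictive check* (pcVPC): the observed
dataset and ``n_sim`` datasets simulated under the model at the original
design (same subjects, doses and sampling times) are normalized by the
typical population prediction -- each value is multiplied by
(bin median of typical predictions) / (typical prediction at that
observation) -- and the empirical 5th/50th/95th percentiles per time bin
of the observations are compared with 90% prediction intervals of the
same percentiles across the simulated replicates.

*Normalized prediction distribution errors* (NPDE): per subject, the
observed vector and each simulated replicate are decorrelated with the
simulation mean and the lower-triangular Cholesky factor of the
simulation covariance; the decorrelated observation is then ranked
against the decorrelated simulations component-wise and the rank is
mapped through the standard-normal quantile function.  Under the true
model the pooled NPDE are approximately N(0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .population import PopulationParams, _rng
from .study import StudyDataset
from .estimate import (_ebe_mode, _predict_batch_factory,
                       _prepare_subjects, _subject_context)

__all__ = ["VPCResult", "pc_vpc", "npde", "iwres", "DEFAULT_BINS"]

#: Default time bins (h) following the protocol sampling windows.
DEFAULT_BINS = (0.0, 12.0, 48.0, 120.0, 240.0, np.inf)

PERCENTILES = (5.0, 50.0, 95.0)


@dataclass
class VPCResult:
    """Binned percentiles of observed data and simulated prediction bands."""

    bin_edges: np.ndarray
    bin_mid: np.ndarray
    n_per_bin: np.ndarray
    observed: pd.DataFrame     # rows: bins; columns p5, p50, p95
    band_lo: pd.DataFrame      # 5th percentile of each simulated percentile
    band_mid: pd.DataFrame     # median of each simulated percentile
    band_hi: pd.DataFrame      # 95th percentile of each simulated percentile
    n_sim: int = 0
    prediction_corrected: bool = True

    def median_within_band(self) -> np.ndarray:
        """Per bin: does the observed median lie inside its 90% band?"""
        return ((self.observed["p50"].to_numpy()
                 >= self.band_lo["p50"].to_numpy())
                & (self.observed["p50"].to_numpy()
                   <= self.band_hi["p50"].to_numpy()))

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"bin_lo": self.bin_edges[:-1],
                            "bin_hi": self.bin_edges[1:],
                            "n_obs": self.n_per_bin})
        for name, df in (("obs", self.observed), ("lo", self.band_lo),
                         ("mid", self.band_mid), ("hi", self.band_hi)):
            for col in df.columns:
                out[f"{name}_{col}"] = df[col].to_numpy()
        return out


def _base_seed(seed) -> int:
    """A concrete base seed; randomness is streamed per subject from it so
    results do not depend on subject ordering."""
    if seed is None:
        return int(np.random.default_rng().integers(2 ** 31))
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    return int(_rng(seed).integers(2 ** 31))


def _subject_rng(base: int, subject_id) -> np.random.Generator:
    return np.random.default_rng([base, int(subject_id)])


def _simulate_replicates(subjects, pop: PopulationParams, n_sim: int,
                         base: int):
    """Per subject: (n_sim, n_i) matrix of simulated observation vectors."""
    sims = []
    for sub in subjects:
        rng = _subject_rng(base, sub.subject_id)
        active = pop.omegas > 0
        eta = (rng.standard_normal((n_sim, int(active.sum())))
               * pop.omegas[active][None, :])
        predict = _predict_batch_factory(sub, pop, active)
        f = predict(eta)
        eps_p = rng.standard_normal(f.shape) * pop.sigma_prop
        eps_a = rng.standard_normal(f.shape) * pop.sigma_add
        sims.append(np.maximum(f * (1.0 + eps_p) + eps_a, 0.0))
    return sims


def _typical_predictions(subjects, pop: PopulationParams):
    preds = []
    for sub in subjects:
        active = pop.omegas > 0
        predict = _predict_batch_factory(sub, pop, active)
        preds.append(predict(np.zeros((1, int(active.sum()))))[0])
    return preds


def pc_vpc(data, pop: PopulationParams, n_sim: int = 1000,
           bins=DEFAULT_BINS, seed=None,
           prediction_corrected: bool = True) -> VPCResult:
    """Prediction-corrected visual predictive check.

    Simulates ``n_sim`` replicates of the dataset at its own design and
    compares binned observed percentiles with the simulated bands.  Bins
    holding fewer than 2 observations trigger a warning flag via
    ``n_per_bin`` (they are retained, with NaN percentiles if empty).
    """
    base = _base_seed(seed)
    subjects = _prepare_subjects(data)
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    bins = np.asarray(bins, dtype=float)

    times = np.concatenate([s.obs_times for s in subjects])
    y_obs = np.concatenate([s.dv for s in subjects])
    bin_idx = np.clip(np.digitize(times, bins) - 1, 0, bins.size - 2)

    pred = np.concatenate(_typical_predictions(subjects, pop))
    if prediction_corrected:
        factor = np.ones_like(pred)
        for b in range(bins.size - 1):
            m = bin_idx == b
            if m.any():
                factor[m] = np.median(pred[m]) / pred[m]
    else:
        factor = np.ones_like(pred)

    sims = _simulate_replicates(subjects, pop, n_sim, base)
    y_sim = np.concatenate([s.T for s in sims], axis=0)   # (n_obs, n_sim)

    yc_obs = y_obs * factor
    yc_sim = y_sim * factor[:, None]

    n_bins = bins.size - 1
    obs_pct = np.full((n_bins, 3), np.nan)
    sim_pct = np.full((n_sim, n_bins, 3), np.nan)
    n_per_bin = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        m = bin_idx == b
        n_per_bin[b] = int(m.sum())
        if n_per_bin[b] == 0:
            continue
        obs_pct[b] = np.percentile(yc_obs[m], PERCENTILES)
        sim_pct[:, b, :] = np.percentile(yc_sim[m], PERCENTILES, axis=0).T

    cols = ["p5", "p50", "p95"]
    def _df(a):
        return pd.DataFrame(a, columns=cols)

    mids = np.array([
        (bins[i] + min(bins[i + 1], times.max())) / 2.0 for i in range(n_bins)])
    return VPCResult(
        bin_edges=bins, bin_mid=mids, n_per_bin=n_per_bin,
        observed=_df(obs_pct),
        band_lo=_df(np.nanpercentile(sim_pct, 5.0, axis=0)),
        band_mid=_df(np.nanpercentile(sim_pct, 50.0, axis=0)),
        band_hi=_df(np.nanpercentile(sim_pct, 95.0, axis=0)),
        n_sim=n_sim, prediction_corrected=prediction_corrected)


def npde(data, pop: PopulationParams, n_sim: int = 1000,
         seed=None) -> pd.DataFrame:
    """Normalized prediction distribution errors, one row per observation.

    Ties between the observation and simulated values are broken with
    uniform jitter within half a rank (seeded).  A singular simulation
    covariance is ridge-regularized and flagged in the ``regularized``
    column.
    """
    base = _base_seed(seed)
    subjects = _prepare_subjects(data)
    rows = []
    for sub in subjects:
        rng = np.random.default_rng([base, int(sub.subject_id), 1])  # ties
        sims = _simulate_replicates([sub], pop, n_sim, base)[0]  # (K, n)
        y = sub.dv
        m = sims.mean(axis=0)
        E = sims - m[None, :]
        S = E.T @ E / max(n_sim - 1, 1)
        regularized = False
        try:
            L = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            S = S + 1e-8 * np.eye(S.shape[0]) * max(np.trace(S), 1.0)
            L = np.linalg.cholesky(S)
            regularized = True
        y_star = solve_triangular(L, y - m, lower=True)
        sim_star = solve_triangular(L, E.T, lower=True)    # (n, K)
        ranks = (sim_star < y_star[:, None]).sum(axis=1).astype(float)
        ties = np.isclose(sim_star, y_star[:, None]).sum(axis=1)
        ranks += np.where(ties > 0, rng.uniform(0, 0.5, size=ranks.size) * ties,
                          0.0)
        pde = (ranks + 0.5) / (n_sim + 1.0)
        vals = stats.norm.ppf(pde)
        for t, v, r in zip(sub.obs_times, vals, [regularized] * y.size):
            rows.append({"ID": sub.subject_id, "TIME": t, "npde": v,
                         "regularized": r})
    return pd.DataFrame(rows)


def iwres(data, pop: PopulationParams) -> pd.DataFrame:
    """Individual weighted residuals at the empirical-Bayes etas.

    IWRES = (obs - individual prediction) / sqrt(sigma_add^2 +
    (sigma_prop * prediction)^2).
    """
    subjects = _prepare_subjects(data)
    rows = []
    for sub in subjects:
        ctx, active = _subject_context(sub, pop)
        mode, _, _ = _ebe_mode(ctx)
        predict = _predict_batch_factory(sub, pop, active)
        f = predict(mode[None, :])[0]
        v = pop.sigma_add ** 2 + (pop.sigma_prop * f) ** 2
        res = (sub.dv - f) / np.sqrt(v)
        for t, r, fi in zip(sub.obs_times, res, f):
            rows.append({"ID": sub.subject_id, "TIME": t, "IPRED": fi,
                         "IWRES": r})
    return pd.DataFrame(rows)
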