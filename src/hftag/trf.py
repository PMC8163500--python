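"""Temporal response functions by normalized reverse correlation.

The TRF is the linear kernel k(l) mapping a stimulus envelope s(t) to the
neural response r(t) = sum_l k(l) s(t - l) + noise.  It is estimated in
the lag domain from the normal equations: the stimulus-response
cross-covariance divided by the stimulus autocovariance, with the
autocovariance pseudo-inverted after discarding trailing eigencomponents
(the ``tolerance`` hyperparameter: the fraction of eigenvalue mass
retained).  A second hyperparameter, ``sparseness``, zeroes kernel
coefficients whose jackknife stability |mean| / SE falls below the given
threshold.  Both are selected by leave-one-trial-out cross-validation of
predictive power (Pearson correlation between the predicted and recorded
held-out response), and predictive power is tested against a null
distribution built from re-estimating on mismatched stimulus/response
pairings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .permstats import PermutationResult, _add_one_p, cluster_permutation

__all__ = [
    "TRFHyperParams",
    "TRFModel",
    "estimate_trf",
    "jackknife_cv",
    "predictive_power_null",
    "compare_trf_conditions",
    "roi_average_kernels",
]


@dataclass(frozen=True)
class TRFHyperParams:
    """Regularization of the reverse-correlation estimate.

    tolerance : fraction (0, 1] of stimulus-autocovariance eigenvalue mass
        retained in the pseudo-inverse; 1 keeps every component.
    sparseness : jackknife-stability threshold >= 0; coefficients with
        |mean| / SE below it are zeroed.  0 disables shrinkage.
    """

    tolerance: float = 1.0
    sparseness: float = 0.0

    def __post_init__(self):
        if not 0 < self.tolerance <= 1:
            raise ValueError(f"tolerance must be in (0, 1], got {self.tolerance}")
        if self.sparseness < 0:
            raise ValueError(f"sparseness must be >= 0, got {self.sparseness}")


@dataclass(frozen=True)
class TRFModel:
    kernel: np.ndarray  # (n_channels, n_lags)
    lags: np.ndarray  # seconds
    sample_rate: float
    hyperparams: TRFHyperParams
    predictive_power: np.ndarray | None  # per-channel held-out Pearson r
    n_trials: int


def _lag_samples(lags: tuple, sample_rate: float) -> np.ndarray:
    lo = int(round(lags[0] * sample_rate))
    hi = int(round(lags[1] * sample_rate))
    return np.arange(lo, hi + 1)


def _design_matrix(envelope: np.ndarray, lag_samples: np.ndarray) -> np.ndarray:
    """(n_samples, n_lags) lagged copies X[t, j] = s(t - l_j), zero-padded."""
    n = envelope.shape[0]
    lmin, lmax = int(lag_samples[0]), int(lag_samples[-1])
    padded = np.concatenate([np.zeros(max(lmax, 0)), envelope,
                             np.zeros(max(-lmin, 0))])
    windows = np.lib.stride_tricks.sliding_window_view(padded, lmax - lmin + 1)
    return windows[:n, lmax - lag_samples]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("constant (zero-variance) envelope")
    return (x - x.mean()) / sd


def _reg_inverse(xtx: np.ndarray, tolerance: float) -> np.ndarray:
    """Pseudo-inverse keeping the leading eigencomponents holding a
    ``tolerance`` fraction of total eigenvalue mass."""
    evals, evecs = np.linalg.eigh(xtx)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    cum = np.cumsum(evals) / max(evals.sum(), 1e-300)
    n_keep = int(np.searchsorted(cum, tolerance - 1e-12) + 1)
    n_keep = min(n_keep, evals.size)
    keep = slice(0, n_keep)
    inv = evecs[:, keep] / np.maximum(evals[keep], 1e-300)
    return inv @ evecs[:, keep].T


def _accumulate(envelopes, responses, lag_samples):
    """Per-trial X^T X and X^T r, plus the prepared designs/responses."""
    xs, rs, xtx_i, xty_i = [], [], [], []
    for s, r in zip(envelopes, responses):
        s = _zscore(np.asarray(s, dtype=float))
        r = np.atleast_2d(np.asarray(r, dtype=float))
        if r.shape[1] != s.shape[0]:
            raise ValueError("envelope and response lengths differ")
        x = _design_matrix(s, lag_samples)
        xs.append(x)
        rs.append(r)
        xtx_i.append(x.T @ x)
        xty_i.append(x.T @ r.T)
    return xs, rs, np.stack(xtx_i), np.stack(xty_i)


def _solve(xtx, xty, hp: TRFHyperParams, jack_terms=None):
    """Kernel (n_channels, n_lags); optionally sparsified via jackknife.

    ``jack_terms``: (xtx_i, xty_i) per-trial contributions, needed when
    hp.sparseness > 0.
    """
    kernel = (_reg_inverse(xtx, hp.tolerance) @ xty).T
    if hp.sparseness > 0:
        if jack_terms is None or jack_terms[0].shape[0] < 2:
            raise ValueError("sparseness > 0 needs at least 2 trials for the "
                             "jackknife stability estimate")
        xtx_i, xty_i = jack_terms
        n = xtx_i.shape[0]
        jack = np.stack([
            (_reg_inverse(xtx - xtx_i[i], hp.tolerance) @ (xty - xty_i[i])).T
            for i in range(n)])
        jmean = jack.mean(axis=0)
        se = np.sqrt((n - 1) / n * np.sum((jack - jmean) ** 2, axis=0))
        stable = np.abs(jmean) >= hp.sparseness * np.maximum(se, 1e-300)
        kernel = np.where(stable, kernel, 0.0)
    return kernel


def _pearson_per_channel(pred: np.ndarray, actual: np.ndarray,
                         n_edge: int) -> np.ndarray:
    """Row-wise Pearson r, discarding ``n_edge`` samples at each end."""
    sl = slice(n_edge, pred.shape[1] - n_edge if n_edge else None)
    p = pred[:, sl] - pred[:, sl].mean(axis=1, keepdims=True)
    a = actual[:, sl] - actual[:, sl].mean(axis=1, keepdims=True)
    denom = np.sqrt((p**2).sum(axis=1) * (a**2).sum(axis=1))
    return (p * a).sum(axis=1) / np.where(denom == 0, 1.0, denom)


def estimate_trf(envelopes, responses, lags: tuple = (-0.050, 0.400),
                 sample_rate: float = 250.0,
                 hp: TRFHyperParams = TRFHyperParams(),
                 compute_power: bool = True) -> TRFModel:
    """Estimate the TRF from matched (envelope, response) trial lists.

    Envelopes are z-scored per trial; ``lags`` is the (min, max) lag range
    in seconds.  When ``compute_power`` is set (and at least 3 trials are
    given), per-channel predictive power is computed by leave-one-trial-out
    prediction, discarding one lag-range of samples at each trial edge.
    """
    lag_samples = _lag_samples(lags, sample_rate)
    xs, rs, xtx_i, xty_i = _accumulate(envelopes, responses, lag_samples)
    xtx, xty = xtx_i.sum(axis=0), xty_i.sum(axis=0)
    kernel = _solve(xtx, xty, hp, (xtx_i, xty_i))
    power = None
    if compute_power and len(xs) >= 3:
        power = _loo_power(xs, rs, xtx_i, xty_i, hp, lag_samples).mean(axis=0)
    return TRFModel(kernel=kernel, lags=lag_samples / sample_rate,
                    sample_rate=sample_rate, hyperparams=hp,
                    predictive_power=power, n_trials=len(xs))


def _loo_power(xs, rs, xtx_i, xty_i, hp, lag_samples,
               pairing=None) -> np.ndarray:
    """(n_folds, n_channels) held-out Pearson r under a given pairing.

    ``pairing`` maps envelope index -> response index (identity when None).
    """
    n = len(xs)
    pairing = np.arange(n) if pairing is None else np.asarray(pairing)
    xtx = xtx_i.sum(axis=0)
    if (pairing == np.arange(n)).all():
        xty_pairs = xty_i
    else:
        xty_pairs = np.stack([xs[i].T @ rs[pairing[i]].T for i in range(n)])
    xty = xty_pairs.sum(axis=0)
    n_edge = lag_samples.size
    out = np.zeros((n, rs[0].shape[0]))
    for f in range(n):
        kernel = _solve(xtx - xtx_i[f], xty - xty_pairs[f], hp,
                        (np.delete(xtx_i, f, axis=0),
                         np.delete(xty_pairs, f, axis=0)))
        pred = (xs[f] @ kernel.T).T
        out[f] = _pearson_per_channel(pred, rs[pairing[f]], n_edge)
    return out


def jackknife_cv(envelopes, responses, lags: tuple = (-0.050, 0.400),
                 sample_rate: float = 250.0,
                 grid: list | None = None) -> tuple:
    """Select hyperparameters by leave-one-trial-out predictive power.

    Returns ``(best_hp, cv_table)`` where the table holds the mean held-out
    correlation (over folds and channels) per grid point.  Ties go to the
    first grid entry, so list preferred (less regularized) points first.
    """
    if grid is None:
        grid = [TRFHyperParams(tolerance=t, sparseness=s)
                for t in (1.0, 0.99, 0.95, 0.85) for s in (0.0, 0.5, 1.0)]
    if len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    if len(envelopes) < 3:
        raise ValueError("jackknife cross-validation needs at least 3 trials")
    lag_samples = _lag_samples(lags, sample_rate)
    xs, rs, xtx_i, xty_i = _accumulate(envelopes, responses, lag_samples)
    rows = []
    for hp in grid:
        score = _loo_power(xs, rs, xtx_i, xty_i, hp, lag_samples).mean()
        rows.append({"tolerance": hp.tolerance, "sparseness": hp.sparseness,
                     "cv_score": score})
    table = pd.DataFrame(rows)
    return grid[int(table["cv_score"].idxmax())], table


def _sample_derangement(rng: np.random.Generator, n: int) -> np.ndarray:
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def predictive_power_null(envelopes, responses,
                          hp: TRFHyperParams = TRFHyperParams(),
                          lags: tuple = (-0.050, 0.400),
                          sample_rate: float = 250.0,
                          n_perm: int = 1000, seed: int = 0) -> PermutationResult:
    """Test observed predictive power against mismatched-pairing surrogates.

    Each permutation re-pairs every envelope with a non-matching response
    (a sampled derangement), re-estimates the TRF and re-scores held-out
    predictive power with the same leave-one-out procedure as the observed
    statistic.
    """
    n = len(envelopes)
    if n < 3:
        raise ValueError("need at least 3 trials for derangement pairings")
    lag_samples = _lag_samples(lags, sample_rate)
    xs, rs, xtx_i, xty_i = _accumulate(envelopes, responses, lag_samples)
    observed = float(_loo_power(xs, rs, xtx_i, xty_i, hp, lag_samples).mean())
    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm)
    for k in range(n_perm):
        pairing = _sample_derangement(rng, n)
        null[k] = _loo_power(xs, rs, xtx_i, xty_i, hp, lag_samples,
                             pairing=pairing).mean()
    return PermutationResult(observed_stat=observed, null_distribution=null,
                             p=_add_one_p(null, observed, "one_sided_greater"),
                             n_perm=n_perm, tail="one_sided_greater", seed=seed)


def compare_trf_conditions(models_a, models_b, adjacency,
                           threshold_p: float = 0.05, n_perm: int = 1000,
                           seed: int = 0):
    """Cluster permutation test between per-participant TRF model sets.

    ``models_a`` / ``models_b`` are paired lists of :class:`TRFModel`; the
    test runs over participants x channels x lag bins.
    """
    lags = models_a[0].lags
    for m in list(models_a) + list(models_b):
        if m.lags.shape != lags.shape or not np.allclose(m.lags, lags):
            raise ValueError("TRF models do not share a common lag axis")
    a = np.stack([m.kernel for m in models_a])
    b = np.stack([m.kernel for m in models_b])
    return cluster_permutation(a, b, adjacency, threshold_p=threshold_p,
                               n_perm=n_perm, seed=seed)


def roi_average_kernels(kernels: np.ndarray, roi_map: dict) -> np.ndarray:
    """Average (participants, channels, lags) kernels into ROIs.

    ``roi_map`` maps ROI name -> iterable of channel indices; ROIs are
    ordered by sorted name in the output (participants, ROIs, lags).
    """
    names = sorted(roi_map)
    return np.stack([kernels[:, list(roi_map[n]), :].mean(axis=1)
                     for n in names], axis=1)


def kernels_to_tsv(path, model: TRFModel) -> None:
    rows = []
    for ch in range(model.kernel.shape[0]):
        for j, lag in enumerate(model.lags):
            rows.append({"channel": ch, "lag_ms": 1000 * lag,
                         "weight": model.kernel[ch, j]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
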