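"""Two-condition comparison statistics for activation trajectories.

The scientific question: does enforcing the stability constraint change a
muscle's activation trajectory?  Each condition contributes an ensemble of
trials (one per kinematic perturbation replicate), time-normalized to 0-100%
of the movement.  Per muscle we compute

* the effect-size curve: difference between the two condition means, and its
  peak absolute value;
* a pointwise paired t curve over matched trial pairs;
* cluster-level inference by a seeded sign-flip permutation test (supra-
  threshold clusters of |t|, max-cluster-mass null), standing in for
  random-field-theory SPM;
* the joint significance rule: a muscle is flagged only if some cluster has
  p < alpha AND the peak effect size exceeds the threshold (0.1 by default —
  a difference smaller than that is within what is considered an excellent
  EMG match and is not physiologically meaningful).

Also provides the MAE agreement metric between an estimated and a reference
activation curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ActivationEnsemble",
    "ClusterResult",
    "effect_size_curve",
    "peak_effect_size",
    "paired_t_curve",
    "permutation_cluster_test",
    "significant_muscle",
    "mae",
    "time_normalize",
]

N_NORMALIZED = 101  # samples of the 0-100% movement grid
T_INF = np.inf  # sentinel for zero-variance, nonzero-mean differences


def time_normalize(curve: np.ndarray, n: int = N_NORMALIZED) -> np.ndarray:
    """Resample a 1-D trajectory onto n evenly spaced samples of 0-100%."""
    curve = np.asarray(curve, float)
    if curve.ndim != 1 or curve.size < 2:
        raise ValueError("curve must be 1-D with at least 2 samples")
    x_old = np.linspace(0.0, 1.0, curve.size)
    return np.interp(np.linspace(0.0, 1.0, n), x_old, curve)


@dataclass
class ActivationEnsemble:
    """Trials x timepoints activation matrices per muscle, for one condition."""

    condition: str
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = {k: np.atleast_2d(np.asarray(v, float)) for k, v in self.data.items()}
        n_t = {v.shape[1] for v in self.data.values()}
        if len(n_t) > 1:
            raise ValueError("all muscles must share one timepoint count")

    @property
    def muscle_names(self) -> list[str]:
        return list(self.data)

    def n_trials(self, muscle: str) -> int:
        return self.data[muscle].shape[0]

    def add_trial(self, activations: dict[str, np.ndarray], n: int = N_NORMALIZED) -> None:
        """Append one trial, time-normalizing each muscle's trajectory."""
        for m, curve in activations.items():
            row = time_normalize(curve, n)[None, :]
            self.data[m] = np.vstack([self.data[m], row]) if m in self.data else row

    def mean(self, muscle: str) -> np.ndarray:
        return self.data[muscle].mean(axis=0)


def _matched(a: ActivationEnsemble, b: ActivationEnsemble, muscle: str) -> tuple[np.ndarray, np.ndarray]:
    xa, xb = a.data[muscle], b.data[muscle]
    if xa.shape != xb.shape:
        raise ValueError(
            f"{muscle}: unmatched ensembles {xa.shape} vs {xb.shape} (paired design required)"
        )
    return xa, xb


def effect_size_curve(a: ActivationEnsemble, b: ActivationEnsemble, muscle: str) -> np.ndarray:
    """Pointwise difference of condition means, mean_a(t) - mean_b(t)."""
    xa, xb = _matched(a, b, muscle)
    return xa.mean(axis=0) - xb.mean(axis=0)


def peak_effect_size(a: ActivationEnsemble, b: ActivationEnsemble, muscle: str) -> float:
    return float(np.max(np.abs(effect_size_curve(a, b, muscle))))


def _t_from_diffs(d: np.ndarray) -> np.ndarray:
    """Paired t statistic per timepoint from a trials x timepoints difference
    matrix; zero-variance columns give 0 (zero mean) or +/-inf (nonzero)."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    degenerate = ~ok & (mean != 0)
    t[degenerate] = np.sign(mean[degenerate]) * T_INF
    return t


def paired_t_curve(a: ActivationEnsemble, b: ActivationEnsemble, muscle: str) -> np.ndarray:
    """Pointwise paired t statistic between matched trials of two conditions."""
    xa, xb = _matched(a, b, muscle)
    if xa.shape[0] < 2:
        raise ValueError("paired t needs at least 2 trials")
    return _t_from_diffs(xa - xb)


@dataclass(frozen=True)
class ClusterResult:
    clusters: list[tuple[int, int]]  # [start, stop) index ranges of |t| > threshold
    cluster_p: list[float]
    threshold: np.ndarray  # pointwise (1 - alpha) permutation threshold of |t|
    t_obs: np.ndarray

    @property
    def min_p(self) -> float:
        return min(self.cluster_p) if self.cluster_p else 1.0


def _clusters_above(tabs: np.ndarray, thr: np.ndarray) -> list[tuple[int, int]]:
    above = tabs > thr
    out = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, above.size))
    return out


def _cluster_masses(tabs: np.ndarray, thr: np.ndarray, clusters: list[tuple[int, int]]) -> list[float]:
    return [float(np.sum(tabs[s:e])) for s, e in clusters]


def permutation_cluster_test(
    a: ActivationEnsemble,
    b: ActivationEnsemble,
    muscle: str,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Sign-flip permutation cluster test of the paired-difference trajectory.

    Under the null (no condition effect) the paired differences are sign-
    symmetric, so random sign flips generate the null distribution of the t
    curve.  The pointwise (1-alpha) quantile of permuted |t| sets the cluster-
    forming threshold; the observed supra-threshold clusters are scored by
    their |t| mass against the permutation distribution of the maximal
    cluster mass.  p-values use (1 + #{perm >= obs}) / (1 + n_perm), which
    keeps the test level-valid at finite n_perm.  Deterministic given seed.
    """
    import warnings

    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low; p-values will be coarse")
    xa, xb = _matched(a, b, muscle)
    n = xa.shape[0]
    if n < 2:
        raise ValueError("need at least 2 matched trials")
    d = xa - xb
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    # vectorized t for all permutations: sum(d^2) is sign-invariant
    sum_d2 = np.sum(d * d, axis=0)
    means = signs @ d / n  # n_perm x T
    var = (sum_d2[None, :] / n - means**2) * (n / (n - 1))
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.where(var > 0, means / np.sqrt(var / n), np.where(means != 0, np.inf, 0.0))
    tabs_perm = np.abs(t_perm)
    finite = np.where(np.isfinite(tabs_perm), tabs_perm, np.nan)
    thr = np.nanquantile(finite, 1.0 - alpha, axis=0)
    thr = np.where(np.isnan(thr), np.inf, thr)

    t_obs = _t_from_diffs(d)
    tabs_obs = np.abs(t_obs)
    clusters = _clusters_above(tabs_obs, thr)
    if not clusters:
        return ClusterResult(clusters=[], cluster_p=[], threshold=thr, t_obs=t_obs)
    masses = _cluster_masses(tabs_obs, thr, clusters)
    # null distribution of the maximal cluster mass
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        cl = _clusters_above(tabs_perm[p], thr)
        if cl:
            null_max[p] = max(_cluster_masses(tabs_perm[p], thr, cl))
    pvals = [float((1 + np.sum(null_max >= m)) / (1 + n_perm)) for m in masses]
    return ClusterResult(clusters=clusters, cluster_p=pvals, threshold=thr, t_obs=t_obs)


def significant_muscle(
    a: ActivationEnsemble,
    b: ActivationEnsemble,
    muscle: str,
    alpha: float = 0.01,
    effect_threshold: float = 0.1,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[bool, dict]:
    """Joint significance rule: cluster p < alpha AND peak effect > threshold.

    Returns (flag, evidence) where evidence holds the peak effect size, the
    smallest cluster p-value and the cluster intervals.
    """
    peak = peak_effect_size(a, b, muscle)
    res = permutation_cluster_test(a, b, muscle, alpha=alpha, n_perm=n_perm, seed=seed)
    min_p = min(res.cluster_p) if res.cluster_p else 1.0
    flag = (min_p < alpha) and (peak > effect_threshold)
    evidence = {
        "peak_effect_size": peak,
        "min_cluster_p": min_p,
        "clusters": res.clusters,
        "alpha": alpha,
        "effect_threshold": effect_threshold,
    }
    return flag, evidence


def mae(estimated: np.ndarray, reference: np.ndarray) -> float:
    """Mean absolute error between two equal-length activation curves."""
    e = np.asarray(estimated, float)
    r = np.asarray(reference, float)
    if e.shape != r.shape:
        raise ValueError(f"length mismatch: {e.shape} vs {r.shape}")
    return float(np.mean(np.abs(e - r)))
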