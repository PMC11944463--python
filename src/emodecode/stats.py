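"""Group-level inference on smoothed accuracy timecourses.

Each analysis tests subject-mean decoding accuracy against chance (0.25 for
four classes) with a one-sample t statistic per timepoint, enhances the t map
with threshold-free cluster enhancement (TFCE, extent exponent E = 0.5,
height exponent H = 2, integration step dh = 0.1 in t units), and corrects
for multiple comparisons with the max-TFCE statistic under a one-tailed
sign-flip permutation null (default 10,000 iterations).  Only above-chance
decoding is meaningful, so negative t values contribute nothing to TFCE and
the test is one-tailed throughout.

For cohorts of up to 12 subjects an exhaustive mode enumerates all 2^n sign
assignments, giving exact permutation p-values (used as the oracle for the
Monte-Carlo path).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: cap applied in place of a signed-infinite t at zero-variance timepoints,
#: and as a symmetric clip for (near-degenerate) finite t beyond it; far
#: beyond any attainable significance, small enough to keep the TFCE
#: threshold loop bounded (1000 steps at dh = 0.1).
T_CAP = 100.0


@dataclass(frozen=True)
class StatConfig:
    alpha: float = 0.05
    n_iterations: int = 10_000
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    tfce_dh: float = 0.1
    seed: int = 0
    chance: float = 0.25
    exhaustive: bool = False

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not self.exhaustive and self.n_iterations < 100:
            raise ValueError("n_iterations must be >= 100")
        if self.tfce_dh <= 0:
            raise ValueError("tfce_dh must be > 0")


@dataclass
class ClusterStatResult:
    """TFCE permutation-test output for one (population x scheme) analysis."""

    times: np.ndarray
    group_mean_accuracy: np.ndarray
    t_map: np.ndarray
    tfce_map: np.ndarray
    p_corrected: np.ndarray
    sig_mask: np.ndarray
    clusters: pd.DataFrame
    config: StatConfig
    n_subjects: int
    extra: dict = field(default_factory=dict)


def one_sample_tmap(curves: np.ndarray, chance: float = 0.25) -> np.ndarray:
    """Per-timepoint one-sample t of (accuracy - chance) across subjects.

    ``curves`` is subjects x timepoints; sd uses the n-1 denominator.  At a
    zero-variance timepoint t is 0 if the mean deviation is 0, otherwise the
    signed cap ``T_CAP`` replaces the infinity.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=np.float64))
    n = curves.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    dev = curves - chance
    mean = dev.mean(axis=0)
    sd = dev.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    t[~ok] = np.sign(mean[~ok]) * T_CAP
    return np.clip(t, -T_CAP, T_CAP)


def _run_extents(supra: np.ndarray) -> np.ndarray:
    """Length of the contiguous suprathreshold run containing each point.

    ``supra`` is maps x timepoints boolean; rows are independent.  Rows are
    padded with a False column and flattened so every run is found with one
    diff, then run lengths are scattered back with ``np.repeat``.
    """
    n_maps, n_tp = supra.shape
    padded = np.zeros((n_maps, n_tp + 1), dtype=np.int8)
    padded[:, :n_tp] = supra
    flat = padded.ravel()
    d = np.diff(np.concatenate(([0], flat)))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    lengths = ends - starts
    out = np.zeros(flat.size, dtype=np.float64)
    out[flat.astype(bool)] = np.repeat(lengths, lengths)
    return out.reshape(n_maps, n_tp + 1)[:, :n_tp]


def tfce_maps(stat_maps: np.ndarray, E: float = 0.5, H: float = 2.0,
              dh: float = 0.1) -> np.ndarray:
    """TFCE of one or many 1-D statistic maps (positive tail only).

    tfce(p) = sum over thresholds h = dh, 2dh, ..., max(map) of
    e(p, h)^E * h^H * dh, where e(p, h) is the length in timepoints of the
    contiguous run containing p in the suprathreshold set {map >= h}.
    Negative values contribute 0.
    """
    stat_maps = np.asarray(stat_maps, dtype=np.float64)
    maps = np.atleast_2d(stat_maps)
    if not np.isfinite(maps).all():
        raise ValueError("statistic map contains non-finite values")
    out = np.zeros_like(maps)
    top = maps.max() if maps.size else 0.0
    # i*dh can exceed an exactly-equal map value by one ulp; the tolerance
    # keeps values sitting exactly on a threshold inside the suprathreshold set
    tol = 1e-9 * dh
    n_steps = int(np.floor(top / dh + 1e-9))
    for i in range(1, n_steps + 1):
        h = i * dh
        ext = _run_extents(maps >= h - tol)
        out += (ext**E) * (h**H) * dh
    return out if stat_maps.ndim > 1 else out[0]


def tfce_1d(stat_map: np.ndarray, E: float = 0.5, H: float = 2.0,
            dh: float = 0.1) -> np.ndarray:
    """TFCE of a single 1-D statistic map."""
    return tfce_maps(np.asarray(stat_map, dtype=np.float64), E, H, dh)


def _flip_tmaps(dev: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t maps for many sign assignments at once.

    Flipping signs leaves per-subject squares unchanged, so only the flipped
    mean is needed: var = (E[d^2] - m^2) * n/(n-1).
    """
    n, n_tp = dev.shape
    m = signs @ dev / n                        # iterations x timepoints
    msq = (dev**2).mean(axis=0)                # timepoints
    var = (msq - m**2) * (n / (n - 1))
    var = np.maximum(var, 0.0)
    sd = np.sqrt(var)
    t = np.zeros_like(m)
    ok = sd > 0
    t[ok] = m[ok] / (sd[ok] / np.sqrt(n))
    t[~ok] = np.sign(m[~ok]) * T_CAP
    return np.clip(t, -T_CAP, T_CAP)


def _all_sign_vectors(n: int) -> np.ndarray:
    bits = np.arange(2**n, dtype=np.int64)
    signs = ((bits[:, None] >> np.arange(n)) & 1).astype(np.float64)
    return 1.0 - 2.0 * signs


def permutation_test(curves: np.ndarray,
                     config: StatConfig = StatConfig()) -> ClusterStatResult:
    """One-tailed TFCE sign-flip permutation test of accuracy vs chance.

    Null distribution: for each iteration the deviation (accuracy - chance)
    of a random subject subset is sign-flipped, the t map and its TFCE are
    recomputed, and the maximum TFCE across timepoints is recorded.
    p_corrected(p) = (1 + #{null max >= tfce(p)}) / (n_iterations + 1);
    in exhaustive mode (all 2^n assignments, n <= 20) p = #{...} / 2^n.
    Deterministic under ``config.seed``.
    """
    config.validate()
    curves = np.atleast_2d(np.asarray(curves, dtype=np.float64))
    n, n_tp = curves.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    return _permutation_test_on_dev(curves, np.arange(n_tp, dtype=float),
                                    config)


def _permutation_test_on_dev(curves: np.ndarray, times: np.ndarray,
                             config: StatConfig) -> ClusterStatResult:
    n, n_tp = curves.shape
    dev = curves - config.chance
    t_obs = one_sample_tmap(curves, config.chance)

    if config.exhaustive:
        if n > 20:
            raise ValueError("exhaustive mode supports at most 20 subjects")
        signs = _all_sign_vectors(n)
        denom = signs.shape[0]
        add_one = 0
    else:
        rng = np.random.default_rng(config.seed)
        signs = rng.choice([-1.0, 1.0], size=(config.n_iterations, n))
        denom = config.n_iterations + 1
        add_one = 1

    all_maps = np.vstack([t_obs[None, :], _flip_tmaps(dev, signs)])
    tfce_all = tfce_maps(all_maps, config.tfce_E, config.tfce_H,
                         config.tfce_dh)
    tfce_obs = tfce_all[0]
    null_max = tfce_all[1:].max(axis=1)

    exceed = (null_max[:, None] >= tfce_obs[None, :]).sum(axis=0)
    p_corrected = (add_one + exceed) / denom
    p_corrected = np.minimum(p_corrected, 1.0)
    sig_mask = p_corrected <= config.alpha

    mean_acc = curves.mean(axis=0)
    result = ClusterStatResult(
        times=np.asarray(times, dtype=float),
        group_mean_accuracy=mean_acc,
        t_map=t_obs,
        tfce_map=tfce_obs,
        p_corrected=p_corrected,
        sig_mask=sig_mask,
        clusters=pd.DataFrame(),
        config=config,
        n_subjects=n,
    )
    result.clusters = summarize_clusters(result)
    return result


def permutation_test_timecourses(curves: np.ndarray, times: np.ndarray,
                                 config: StatConfig = StatConfig()
                                 ) -> ClusterStatResult:
    """As :func:`permutation_test` but with an explicit time axis (ms)."""
    config.validate()
    curves = np.atleast_2d(np.asarray(curves, dtype=np.float64))
    times = np.asarray(times, dtype=float)
    if curves.shape[1] != len(times):
        raise ValueError("times length must match the timepoint axis")
    if curves.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    return _permutation_test_on_dev(curves, times, config)


def summarize_clusters(result: ClusterStatResult) -> pd.DataFrame:
    """One row per maximal significant run: start/end ms, peak group-mean
    accuracy in percent, and the minimal corrected p inside the run."""
    mask = np.asarray(result.sig_mask, dtype=bool)
    rows = []
    d = np.diff(np.concatenate(([0], mask.astype(int), [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    for s, e in zip(starts, ends):
        rows.append(
            {
                "start_ms": result.times[s],
                "end_ms": result.times[e - 1],
                "peak_accuracy_pct": 100.0
                * float(result.group_mean_accuracy[s:e].max()),
                "min_p": float(result.p_corrected[s:e].min()),
            }
        )
    return pd.DataFrame(rows,
                        columns=["start_ms", "end_ms", "peak_accuracy_pct",
                                 "min_p"])
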