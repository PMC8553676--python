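"""Paired resampling statistics for within-participant condition contrasts.

The inferential layer of the study design: per-participant logMAR
differences between two conditions are tested with a sign-flipping
permutation test (exact enumeration for small cohorts, Monte Carlo
otherwise), summarized with percentile-bootstrap confidence intervals,
and adjusted for the two-family comparison with a Bonferroni factor.

Participants with a missing estimate in either condition are excluded
pairwise before any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Cohort size up to which the sign-flip null is enumerated exhaustively.
EXHAUSTIVE_LIMIT = 20


@dataclass
class PairedDifferences:
    """Per-participant differences (condition A - condition B) in logMAR.

    ``values`` may contain NaN for participants lacking an estimate in
    either condition; these are masked out pairwise. ``labels`` are
    optional participant identifiers aligned with ``values``.
    """

    values: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.labels:
            self.labels = [f"P{i:02d}" for i in range(self.values.size)]
        if len(self.labels) != self.values.size:
            raise ValueError("labels and values must have equal length")

    @property
    def complete(self) -> np.ndarray:
        """Differences of complete pairs only (NaN excluded)."""
        return self.values[~np.isnan(self.values)]

    @property
    def n_complete(self) -> int:
        return int(self.complete.size)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())


def _statistic(name: str):
    if name == "median":
        return lambda a, axis=-1: np.median(a, axis=axis)
    if name == "mean":
        return lambda a, axis=-1: np.mean(a, axis=axis)
    raise ValueError(f"statistic must be 'median' or 'mean', got {name!r}")


def _sign_matrix(n: int) -> np.ndarray:
    """All 2**n sign patterns as a (2**n, n) matrix of +-1."""
    codes = np.arange(2**n, dtype=np.uint64)[:, None]
    bits = (codes >> np.arange(n, dtype=np.uint64)[None, :]) & 1
    return bits.astype(np.int8) * 2 - 1


def permutation_test(
    diffs: PairedDifferences | np.ndarray,
    statistic: str = "median",
    n_permutations: int = 100_000,
    seed: int = 0,
    *,
    alternative: str = "two-sided",
    method: str = "auto",
) -> float:
    """Sign-flipping permutation test of the paired null (no condition effect).

    Each participant's difference is multiplied by +-1: under
    within-participant exchangeability of the two conditions, every sign
    pattern is equally likely. The null is enumerated exhaustively
    (``2**n`` patterns) for n <= 20 complete pairs, otherwise sampled with
    ``n_permutations`` Monte-Carlo draws including the identity
    permutation. Two-sided p is the proportion of permuted |statistic|
    at or above the observed |statistic|. ``method`` overrides the
    size-based choice ("exhaustive" or "montecarlo" instead of "auto"),
    useful for cross-checking the two routes against each other.
    """
    d = diffs.complete if isinstance(diffs, PairedDifferences) else np.asarray(diffs, float)
    d = d[~np.isnan(d)]
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    stat = _statistic(statistic)
    observed = float(stat(d))

    if method not in ("auto", "exhaustive", "montecarlo"):
        raise ValueError(f"unknown method {method!r}")
    exhaustive = n <= EXHAUSTIVE_LIMIT if method == "auto" else method == "exhaustive"
    if exhaustive:
        if n > EXHAUSTIVE_LIMIT:
            raise ValueError(f"exhaustive enumeration limited to n <= {EXHAUSTIVE_LIMIT}")
        signs = _sign_matrix(n)
        null = stat(signs * d[None, :], axis=1)
    else:
        rng = np.random.default_rng(int(seed) % (2**31))
        signs = rng.integers(0, 2, size=(n_permutations - 1, n)) * 2 - 1
        null = stat(signs * d[None, :], axis=1)
        null = np.concatenate([[observed], null])  # identity permutation

    tol = 1e-12 * max(1.0, np.abs(null).max())
    if alternative == "two-sided":
        p = np.mean(np.abs(null) >= abs(observed) - tol)
    elif alternative == "greater":
        p = np.mean(null >= observed - tol)
    elif alternative == "less":
        p = np.mean(null <= observed + tol)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(p)


def bootstrap_ci(
    diffs: PairedDifferences | np.ndarray,
    statistic: str = "median",
    level: float = 0.95,
    n_boot: int = 10_000,
    seed: int = 0,
    *,
    method: str = "percentile",
) -> tuple[float, float]:
    """Bootstrap confidence interval for the paired statistic.

    Participants are resampled with replacement; the default interval is
    the (alpha/2, 1-alpha/2) percentile pair of the recomputed statistic,
    always reported as [lower, upper]. ``method="bca"`` uses the
    bias-corrected-and-accelerated variant instead (via scipy).
    """
    d = diffs.complete if isinstance(diffs, PairedDifferences) else np.asarray(diffs, float)
    d = d[~np.isnan(d)]
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    stat = _statistic(statistic)
    rng = np.random.default_rng(int(seed) % (2**31))
    if method == "percentile":
        idx = rng.integers(0, n, size=(n_boot, n))
        boot = stat(d[idx], axis=1)
        alpha = 1.0 - level
        lo, hi = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0])
    elif method == "bca":
        from scipy.stats import bootstrap as _scipy_bootstrap

        if np.ptp(d) == 0:  # degenerate sample: BCa jackknife is undefined
            return float(d[0]), float(d[0])
        res = _scipy_bootstrap(
            (d,), stat, n_resamples=n_boot, confidence_level=level,
            method="BCa", rng=rng, vectorized=True, axis=-1,
        )
        lo, hi = res.confidence_interval.low, res.confidence_interval.high
    else:
        raise ValueError(f"method must be 'percentile' or 'bca', got {method!r}")
    return float(lo), float(hi)


def bonferroni(p: float, factor: int = 2) -> float:
    """Bonferroni adjustment: min(1, factor * p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return min(1.0, factor * p)


def most_outlying_index(diffs: PairedDifferences | np.ndarray) -> int:
    """Index of the most outlying difference (largest |d - median|).

    NaN entries are never selected.
    """
    d = diffs.values if isinstance(diffs, PairedDifferences) else np.asarray(diffs, float)
    finite = ~np.isnan(d)
    if finite.sum() < 1:
        raise ValueError("no complete pairs")
    med = np.median(d[finite])
    dev = np.where(finite, np.abs(d - med), -np.inf)
    return int(np.argmax(dev))


def exclude_outlier(diffs: PairedDifferences, index: int) -> PairedDifferences:
    """Remove one participant pairwise, returning a new difference set."""
    n = diffs.values.size
    if not 0 <= index < n:
        raise IndexError(f"index {index} out of range for {n} participants")
    keep = np.ones(n, dtype=bool)
    keep[index] = False
    return PairedDifferences(
        values=diffs.values[keep],
        labels=[l for i, l in enumerate(diffs.labels) if keep[i]],
    )


def compare_conditions(
    diffs: PairedDifferences,
    *,
    statistic: str = "median",
    n_permutations: int = 100_000,
    n_boot: int = 10_000,
    level: float = 0.95,
    bonferroni_factor: int = 2,
    seed: int = 0,
) -> dict:
    """One condition contrast: statistic, permutation p, Bonferroni p, CI.

    Returns a plain dict ready for tabulation or JSON serialization.
    """
    d = diffs.complete
    stat = _statistic(statistic)
    p = permutation_test(diffs, statistic, n_permutations, seed)
    ci = bootstrap_ci(diffs, statistic, level, n_boot, seed)
    return {
        "statistic": statistic,
        "estimate": float(stat(d)),
        "ci_low": ci[0],
        "ci_high": ci[1],
        "ci_level": level,
        "p_value": p,
        "p_bonferroni": bonferroni(p, bonferroni_factor),
        "bonferroni_factor": bonferroni_factor,
        "n_pairs": diffs.n_complete,
        "n_missing": diffs.n_missing,
    }
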