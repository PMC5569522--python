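"""Two-group negative-binomial differential coverage testing per window.

The model: the read count of pool *j* in window *w* is NB with mean
``mu_w * s_j`` and variance ``mu + phi * mu^2`` (phi = common dispersion
shared across windows). After proportional library-size normalization the
size factors are equal, and the two-group comparison reduces to the classic
exact conditional test: given the window total ``s = Y_A + Y_B``, the group-A
total follows the distribution induced by ``Y_A ~ NB(size n_A/phi)`` and
``Y_B ~ NB(size n_B/phi)`` with a common success probability (which cancels),
i.e. a negative hypergeometric; at phi = 0 this is Binomial(s, n_A/(n_A+n_B)).
The two-sided p-value sums the conditional probabilities of all outcomes no
more likely than the observed one (minimum-likelihood rule).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

from .windows import CountMatrix, Sample

_TIE_RTOL = 1e-12
PHI_GRID_LO = 1e-6
PHI_GRID_HI = 5.0


def normalize_libsizes(counts: CountMatrix) -> CountMatrix:
    """Scale each pool's column to the mean library size, keeping counts integer.

    Each column is multiplied by ``mean(library sizes) / library_size`` and
    rounded half-to-even. Columns with library size 0 are left as zeros.
    Scaling factors are recorded in ``norm_factors``.
    """
    lib = counts.library_sizes().astype(float)
    if lib.sum() == 0:
        raise ValueError("all-zero count matrix: nothing to normalize")
    nonzero = lib > 0
    target = lib[nonzero].mean()
    factors = np.where(nonzero, target / np.where(nonzero, lib, 1.0), 0.0)
    scaled = np.rint(counts.counts * factors[np.newaxis, :]).astype(np.int64)
    scaled[:, ~nonzero] = counts.counts[:, ~nonzero]
    samples = [
        replace(s, library_size=int(scaled[:, j].sum())) for j, s in enumerate(counts.samples)
    ]
    return CountMatrix(counts.grid, samples, scaled, norm_factors=factors)


@dataclass(frozen=True)
class DispersionEstimate:
    phi: float
    n_windows_used: int
    method: str = "conditional-ML grid + golden section"


def _conditional_neg_loglik(phi: float, group_counts: list[np.ndarray]) -> float:
    """Minus the summed within-group conditional NB log-likelihood.

    For a group with n pools, the likelihood of the pool counts conditional on
    their window total T is ``prod_i NB(y_i; r) / NB(T; n r)`` with r = 1/phi;
    the NB success probability cancels. phi-independent terms are dropped.
    """
    r = 1.0 / phi
    total = 0.0
    for y in group_counts:
        w, n = y.shape
        t = y.sum(axis=1)
        total += (
            gammaln(y + r).sum()
            - w * n * gammaln(r)
            - gammaln(t + n * r).sum()
            + w * gammaln(n * r)
        )
    return -total


def estimate_common_dispersion(counts: CountMatrix) -> DispersionEstimate:
    """Common NB dispersion by maximizing the conditional likelihood.

    Conditions on each group's per-window total, so the unknown window means
    drop out. Searched on a log grid over [1e-6, 5], then refined with a
    bounded scalar minimization between the best grid point's neighbours.
    All-zero windows carry no information and are excluded. Groups with a
    single pool have a degenerate conditional likelihood and are skipped;
    if no group has >= 2 pools, the dispersion is unidentifiable and the
    caller must supply phi explicitly.
    """
    keep = counts.counts.sum(axis=1) > 0
    group_counts = []
    for g in counts.groups:
        cols = counts.group_columns(g)
        if len(cols) >= 2:
            group_counts.append(counts.counts[np.ix_(keep, cols)].astype(float))
    if not group_counts:
        raise ValueError(
            "fewer than 2 pools in every group: cannot estimate dispersion; supply phi"
        )
    grid = np.logspace(np.log10(PHI_GRID_LO), np.log10(PHI_GRID_HI), 41)
    nll = np.array([_conditional_neg_loglik(p, group_counts) for p in grid])
    best = int(np.argmin(nll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    if best in (0, len(grid) - 1):
        phi = float(grid[best])
    else:
        res = optimize.minimize_scalar(
            _conditional_neg_loglik,
            bounds=(lo, hi),
            args=(group_counts,),
            method="bounded",
            options={"xatol": 1e-6},
        )
        phi = float(res.x)
    return DispersionEstimate(phi=phi, n_windows_used=int(keep.sum()))


def conditional_pmf(s: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """pmf of the group-A total over splits {0..s} of the window total s.

    Exact NB conditional distribution for dispersion phi; Binomial limit at
    phi = 0. Sums to 1 up to floating point.
    """
    if s < 0:
        raise ValueError("negative total")
    if phi < 0:
        raise ValueError("negative dispersion")
    y = np.arange(s + 1)
    if s == 0:
        return np.ones(1)
    if phi == 0.0:
        return stats.binom.pmf(y, s, n_a / (n_a + n_b))
    r_a, r_b = n_a / phi, n_b / phi
    # log Gamma(y+r)/(Gamma(r) y!) accumulated as sum(log((r+k)/(k+1))):
    # well-conditioned at any r (a gammaln-difference form loses ~1e-6 at the
    # huge r of small phi and breaks the exact ties the minimum-likelihood
    # rule relies on), and exactly symmetric when r_a == r_b
    k = np.arange(s)
    log_a = np.concatenate(([0.0], np.cumsum(np.log((r_a + k) / (k + 1)))))
    log_b = np.concatenate(([0.0], np.cumsum(np.log((r_b + k) / (k + 1)))))
    logw = log_a[y] + log_b[s - y]
    return np.exp(logw - logsumexp(logw))


def _pvalues_all_splits(pmf: np.ndarray) -> np.ndarray:
    """Minimum-likelihood two-sided p-value for every possible split at once."""
    order = np.argsort(pmf, kind="stable")
    sp = pmf[order]
    cum = np.cumsum(sp)
    # ties (within relative tolerance) share the cumulative mass of the group;
    # normalizing by the summed mass makes the modal split exactly p = 1
    hi = np.searchsorted(sp, sp * (1.0 + _TIE_RTOL), side="right") - 1
    p = np.minimum(cum[hi] / cum[-1], 1.0)
    out = np.empty_like(p)
    out[order] = p
    return out


def exact_test_pvalue_table(s: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """p-value of every possible split ``y_A in {0..s}`` of the total s."""
    return _pvalues_all_splits(conditional_pmf(s, n_a, n_b, phi))


def nb_exact_test(
    y_a: np.ndarray | list[int], y_b: np.ndarray | list[int], phi: float
) -> tuple[float, float]:
    """Exact conditional NB test of equal means between two groups of pools.

    Returns ``(p_value, log2_fold_change)`` where the fold change is B vs A
    on the per-pool scale with a 0.5 pseudo-count. ``p = 1`` when both totals
    are zero.
    """
    y_a = np.asarray(y_a)
    y_b = np.asarray(y_b)
    if (y_a < 0).any() or (y_b < 0).any():
        raise ValueError("negative counts")
    if phi < 0:
        raise ValueError("negative dispersion")
    n_a, n_b = len(y_a), len(y_b)
    ya, yb = int(y_a.sum()), int(y_b.sum())
    lfc = float(np.log2((yb / n_b + 0.5) / (ya / n_a + 0.5)))
    s = ya + yb
    if s == 0:
        return 1.0, lfc
    pmf = conditional_pmf(s, n_a, n_b, phi)
    p_obs = pmf[ya]
    p = float(min(1.0, pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum() / pmf.sum()))
    return p, lfc


def test_all_windows(
    counts: CountMatrix,
    phi: float | DispersionEstimate | None = None,
    group_a: str | None = None,
    group_b: str | None = None,
) -> pd.DataFrame:
    """Per-window exact test track.

    Returns a DataFrame in grid order with columns ``chrom, start, end,
    p_value, log2_fc, mean_a, mean_b``. Counts should already be normalized.
    p-values are cached per window total, so the cost scales with the number
    of distinct totals rather than the number of windows.
    """
    if phi is None:
        phi = estimate_common_dispersion(counts)
    if isinstance(phi, DispersionEstimate):
        phi = phi.phi
    groups = counts.groups
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise ValueError(f"need exactly 2 groups, have {groups}; pass group_a/group_b")
        group_a, group_b = groups
    cols_a = counts.group_columns(group_a)
    cols_b = counts.group_columns(group_b)
    n_a, n_b = len(cols_a), len(cols_b)
    ya = counts.counts[:, cols_a].sum(axis=1).astype(np.int64)
    yb = counts.counts[:, cols_b].sum(axis=1).astype(np.int64)
    s = ya + yb

    pvals = np.ones(len(s))
    cache: dict[int, np.ndarray] = {}
    for w in np.nonzero(s)[0]:
        sw = int(s[w])
        table = cache.get(sw)
        if table is None:
            table = _pvalues_all_splits(conditional_pmf(sw, n_a, n_b, phi))
            cache[sw] = table
        pvals[w] = table[ya[w]]

    df = counts.grid.to_frame()
    df["p_value"] = pvals
    df["log2_fc"] = np.log2((yb / n_b + 0.5) / (ya / n_a + 0.5))
    df["mean_a"] = ya / n_a
    df["mean_b"] = yb / n_b
    return df


test_all_windows.__test__ = False  # not a pytest case despite the name
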