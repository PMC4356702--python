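"""Two-group differential-expression screening and expression clustering.

The screen combines two gates, applied inclusively:

* a linear fold-change gate — per-gene ratio of treatment (RS) group mean to
  control (CK) group mean, called up at ``ratio ≥ fc_up`` (default 2) and
  down at ``ratio ≤ fc_down`` (default 0.5);
* a significance gate — a permutation false-discovery-rate Q-value computed
  from the SAM "relative difference"

  .. math:: d_i = \\frac{\\bar{x}^{RS}_i - \\bar{x}^{CK}_i}{s_i + s_0}

  on log2 intensities, where :math:`s_i` is the pooled standard error of the
  group-mean difference and :math:`s_0` is a small positive "fudge factor"
  that stabilises genes with near-zero variance.  :math:`s_0` is selected
  from the percentiles {0, 5, …, 95} of the :math:`s_i` distribution so that
  the spread of :math:`|d|` is as uniform as possible across the range of
  :math:`s_i` (coefficient of variation of bin-wise median absolute
  deviations), the original SAM recipe.

Q-values: for each threshold :math:`t` on :math:`|d|`, the estimated FDR is
``π0 · median over permutations of #{|d*| ≥ t} / #{|d| ≥ t}``; a gene's
Q-value is the minimum estimated FDR over the rejection regions that contain
the gene (thresholds at or below its own :math:`|d|`), clamped to [0, 1] —
monotone nonincreasing in :math:`|d|` by construction.  Group-label permutations are enumerated exhaustively whenever
the number of distinct assignments fits in the permutation budget (e.g. all
20 assignments of a 3 vs 3 design), otherwise sampled without replacement.
``π0`` (the null proportion) is fixed at 1 by default — conservative and
stable at small sample sizes — with an optional SAM-style quartile estimator.

Also here: agglomerative hierarchical clustering of genes or samples under
1 − Pearson correlation of log2 profiles with average linkage, used to
assess global expression patterns across conditions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .io import ExpressionMatrix

logger = logging.getLogger("starchnet")

__all__ = [
    "ScreenParams",
    "Dendrogram",
    "fold_change",
    "sam_d_statistic",
    "estimate_s0",
    "permutation_q_values",
    "screen_degs",
    "sam_screen",
    "hierarchical_cluster",
    "to_newick",
]

S0_PERCENTILES = np.arange(0, 100, 5)  # 0, 5, ..., 95

# d-statistic sentinel for a zero denominator with a nonzero mean difference
# (noiseless data, s0 = 0): keeps d finite with the correct sign while
# dominating every regular statistic.
D_SENTINEL = 1e12


def _safe_d(diff: np.ndarray, denom: np.ndarray) -> np.ndarray:
    d = np.zeros_like(diff)
    pos = denom > 0
    d[pos] = diff[pos] / denom[pos]
    degen = ~pos & (diff != 0)
    d[degen] = np.sign(diff[degen]) * D_SENTINEL
    return d


@dataclass
class ScreenParams:
    """Screening thresholds and permutation settings.

    fc_up / fc_down
        Inclusive linear fold-change bounds for up / down calls.
    q_max
        Inclusive Q-value gate (default 5%).
    n_permutations
        Permutation budget; exhaustive enumeration is used when the design
        admits no more distinct label assignments than this.
    s0_strategy
        ``"tusher"`` (percentile-grid selection), ``"zero"``, or a fixed
        nonnegative float.
    estimate_pi0
        Estimate the null proportion from the permuted statistics instead of
        the conservative default π0 = 1.
    """

    fc_up: float = 2.0
    fc_down: float = 0.5
    q_max: float = 0.05
    n_permutations: int = 1000
    s0_strategy: str | float = "tusher"
    estimate_pi0: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.fc_up > 1.0 > self.fc_down > 0.0):
            raise ConfigError(
                f"require fc_up > 1 > fc_down > 0, got fc_up={self.fc_up!r}, fc_down={self.fc_down!r}")
        if not 0.0 < self.q_max < 1.0:
            raise ConfigError(f"q_max must lie in (0, 1), got {self.q_max!r}")
        if self.n_permutations < 1:
            raise ConfigError(f"n_permutations must be ≥ 1, got {self.n_permutations!r}")
        if isinstance(self.s0_strategy, str):
            if self.s0_strategy not in ("tusher", "zero"):
                raise ConfigError(f"unknown s0_strategy {self.s0_strategy!r}")
        elif self.s0_strategy < 0:
            raise ConfigError(f"fixed s0 must be ≥ 0, got {self.s0_strategy!r}")


# ---------------------------------------------------------------------------
# fold change and the SAM statistic
# ---------------------------------------------------------------------------


def fold_change(matrix: ExpressionMatrix) -> pd.Series:
    """Per-gene linear ratio mean(RS) / mean(CK)."""
    ck = matrix.group_values("CK")
    rs = matrix.group_values("RS")
    if ck.shape[1] == 0 or rs.shape[1] == 0:
        raise InputError("both groups need at least one sample")
    return rs.mean(axis=1) / ck.mean(axis=1)


def _log2_arrays(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.log2(matrix.values.to_numpy(dtype=float))
    samples = matrix.sample_ids
    ck_idx = np.array([i for i, s in enumerate(samples) if matrix.groups[s] == "CK"])
    rs_idx = np.array([i for i, s in enumerate(samples) if matrix.groups[s] == "RS"])
    return X, ck_idx, rs_idx


def _diff_and_se(X: np.ndarray, ck_idx: np.ndarray, rs_idx: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Group-mean difference (RS − CK) and pooled standard error, per row."""
    n1, n2 = len(ck_idx), len(rs_idx)
    a, b = X[:, ck_idx], X[:, rs_idx]
    diff = b.mean(axis=1) - a.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
        + ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = ss / (n1 + n2 - 2)
    se = np.sqrt((1.0 / n1 + 1.0 / n2) * pooled_var)
    return diff, se


def sam_d_statistic(matrix: ExpressionMatrix, s0: float) -> pd.Series:
    """SAM relative difference on log2 intensities, per gene.

    Requires ≥2 samples per group so the pooled standard error is defined.
    """
    if s0 < 0:
        raise ConfigError(f"s0 must be ≥ 0, got {s0!r}")
    X, ck_idx, rs_idx = _log2_arrays(matrix)
    if len(ck_idx) < 2 or len(rs_idx) < 2:
        raise InputError(
            "SAM needs ≥2 samples per group; use the fold-change-only screen otherwise")
    diff, se = _diff_and_se(X, ck_idx, rs_idx)
    d = _safe_d(diff, se + s0)
    return pd.Series(d, index=matrix.values.index)


def _s0_objective(diff: np.ndarray, se: np.ndarray, s0: float, n_bins: int) -> float:
    """Coefficient of variation of bin-wise MAD(|d|) across SE quantile bins."""
    d = _safe_d(diff, se + s0)
    order = np.argsort(se, kind="stable")
    bins = np.array_split(order, n_bins)
    mads = []
    for b in bins:
        if len(b) == 0:
            continue
        db = d[b]
        mads.append(np.median(np.abs(db - np.median(db))) / 0.64)
    mads = np.asarray(mads)
    mean = mads.mean()
    if mean == 0:
        return math.inf
    return mads.std() / mean


def estimate_s0(matrix: ExpressionMatrix) -> float:
    """Select the fudge factor from SE-distribution percentiles {0, 5, …, 95}.

    Deterministic given the matrix; ties resolve to the smallest percentile.
    A degenerate all-zero SE distribution yields 0 with a logged warning.
    """
    X, ck_idx, rs_idx = _log2_arrays(matrix)
    if len(ck_idx) < 2 or len(rs_idx) < 2:
        raise InputError("s0 estimation needs ≥2 samples per group")
    diff, se = _diff_and_se(X, ck_idx, rs_idx)
    if np.all(se == 0):
        logger.warning("all per-gene standard errors are zero; s0 = 0")
        return 0.0
    n_bins = int(min(100, max(2, len(se) // 10)))
    candidates = np.percentile(se, S0_PERCENTILES)
    best_s0, best_obj = float(candidates[0]), math.inf
    for c in candidates:
        obj = _s0_objective(diff, se, float(c), n_bins)
        if obj < best_obj - 1e-15:
            best_obj, best_s0 = obj, float(c)
    return best_s0


def _resolve_s0(matrix: ExpressionMatrix, params: ScreenParams) -> float:
    if params.s0_strategy == "tusher":
        return estimate_s0(matrix)
    if params.s0_strategy == "zero":
        return 0.0
    return float(params.s0_strategy)


# ---------------------------------------------------------------------------
# permutation Q-values
# ---------------------------------------------------------------------------


def _label_assignments(n_samples: int, n_ck: int, n_permutations: int,
                       rng: np.random.Generator) -> tuple[list[tuple[int, ...]], bool]:
    """Distinct CK-index assignments: exhaustive when they fit the budget,
    otherwise sampled without replacement."""
    total = math.comb(n_samples, n_ck)
    if total <= n_permutations:
        return list(combinations(range(n_samples), n_ck)), True
    if total <= 200_000:
        all_combos = list(combinations(range(n_samples), n_ck))
        picked = rng.choice(total, size=n_permutations, replace=False)
        return [all_combos[i] for i in sorted(picked)], False
    # design too large to enumerate: draw random assignments, deduplicating
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    attempts = 0
    while len(out) < n_permutations and attempts < 20 * n_permutations:
        attempts += 1
        combo = tuple(sorted(map(int, rng.choice(n_samples, size=n_ck, replace=False))))
        if combo not in seen:
            seen.add(combo)
            out.append(combo)
    return out, False


def _exceedance_counts(sorted_abs: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """#{values ≥ t} for each threshold, given values sorted ascending."""
    return len(sorted_abs) - np.searchsorted(sorted_abs, thresholds, side="left")


def permutation_q_values(matrix: ExpressionMatrix, params: ScreenParams,
                         s0: float | None = None) -> pd.Series:
    """Permutation-FDR Q-value per gene (see module docstring for the rule)."""
    X, ck_idx, rs_idx = _log2_arrays(matrix)
    if len(ck_idx) < 2 or len(rs_idx) < 2:
        raise InputError("permutation Q-values need ≥2 samples per group")
    if s0 is None:
        s0 = _resolve_s0(matrix, params)

    n_samples = X.shape[1]
    n_ck = len(ck_idx)
    rng = np.random.default_rng(params.seed)
    assignments, _exhaustive = _label_assignments(
        n_samples, n_ck, params.n_permutations, rng)

    diff, se = _diff_and_se(X, ck_idx, rs_idx)
    d_obs = _safe_d(diff, se + s0)
    abs_obs = np.abs(d_obs)
    sorted_obs = np.sort(abs_obs)

    all_idx = np.arange(n_samples)
    perm_abs: list[np.ndarray] = []
    perm_d_all: list[np.ndarray] = []
    for combo in assignments:
        pck = np.asarray(combo)
        prs = np.setdiff1d(all_idx, pck)
        pdiff, pse = _diff_and_se(X, pck, prs)
        pd_stat = _safe_d(pdiff, pse + s0)
        perm_d_all.append(pd_stat)
        perm_abs.append(np.sort(np.abs(pd_stat)))

    # thresholds = distinct observed |d|, most stringent first
    thresholds = np.unique(abs_obs)[::-1]
    obs_counts = _exceedance_counts(sorted_obs, thresholds)
    perm_counts = np.vstack([_exceedance_counts(p, thresholds) for p in perm_abs])
    med_counts = np.median(perm_counts, axis=0)

    if params.estimate_pi0:
        pooled = np.concatenate(perm_d_all)
        q25, q75 = np.percentile(pooled, [25, 75])
        inside = np.count_nonzero((d_obs >= q25) & (d_obs <= q75))
        pi0 = min(1.0, inside / (0.5 * len(d_obs)))
        pi0 = max(pi0, 1e-12)
    else:
        pi0 = 1.0

    fdr = pi0 * med_counts / obs_counts
    # q(t) = min FDR over rejection regions containing genes at threshold t,
    # i.e. over thresholds ≤ t: running min from the loosest threshold up
    q_at_threshold = np.minimum.accumulate(fdr[::-1])[::-1]
    q_at_threshold = np.clip(q_at_threshold, 0.0, 1.0)

    # map each gene's |d| to its threshold's q
    pos = {t: k for k, t in enumerate(thresholds)}
    q = np.array([q_at_threshold[pos[a]] for a in abs_obs])
    return pd.Series(q, index=matrix.values.index)


# ---------------------------------------------------------------------------
# the compound screen
# ---------------------------------------------------------------------------


def screen_degs(ratios: pd.Series, q_values: pd.Series, params: ScreenParams,
                d_stat: pd.Series | None = None) -> pd.DataFrame:
    """Apply the compound screen and return the DEG table.

    ``call`` is ``up`` iff ``ratio ≥ fc_up`` and ``q ≤ q_max``; ``down`` iff
    ``ratio ≤ fc_down`` and ``q ≤ q_max``; else ``unchanged``.  All bounds
    are inclusive and applied with a relative tolerance of 1e-9 so that a
    ratio equal to the bound up to floating-point roundoff is not dropped
    (far below the 4-decimal precision ratios are reported at).
    """
    set_r, set_q = set(ratios.index), set(q_values.index)
    if set_r != set_q:
        sym = sorted(set_r.symmetric_difference(set_q))
        raise InputError(
            f"ratio/q-value gene sets differ; first {min(10, len(sym))} of "
            f"{len(sym)}: {sym[:10]}")
    q = q_values.reindex(ratios.index)
    rtol = 1e-9
    call = np.where(
        (ratios >= params.fc_up * (1 - rtol)) & (q <= params.q_max), "up",
        np.where((ratios <= params.fc_down * (1 + rtol)) & (q <= params.q_max),
                 "down", "unchanged"),
    )
    if d_stat is None:
        d = pd.Series(np.nan, index=ratios.index)
    else:
        d = d_stat.reindex(ratios.index)
    table = pd.DataFrame(
        {"ratio": ratios, "d_stat": d, "q_value": q, "call": call})
    table.index.name = "gene_id"
    return table


def sam_screen(matrix: ExpressionMatrix, params: ScreenParams) -> pd.DataFrame:
    """Run the full screen on a matrix: fold change, SAM d, Q-values, calls."""
    ratios = fold_change(matrix)
    s0 = _resolve_s0(matrix, params)
    d = sam_d_statistic(matrix, s0)
    q = permutation_q_values(matrix, params, s0=s0)
    return screen_degs(ratios, q, params, d_stat=d)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Agglomerative merge tree in the usual linkage-matrix encoding.

    ``merges`` has one row per merge: the two cluster ids joined (original
    items are 0..n−1, the t-th new cluster is n+t), the merge height, and the
    size of the new cluster.  ``leaf_order`` lists item labels as they appear
    along the tree's fringe.
    """

    merges: np.ndarray
    leaf_order: list[str]
    labels: list[str]


def _correlation_distance(X: np.ndarray) -> np.ndarray:
    """1 − Pearson correlation between rows; zero-variance rows correlate 0
    with everything (distance 1), with a logged warning."""
    sd = X.std(axis=1)
    zero = sd == 0
    if zero.any():
        logger.warning("%d zero-variance profile(s); correlations set to 0",
                       int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.corrcoef(X)
    C = np.atleast_2d(C)
    C[np.isnan(C)] = 0.0
    np.fill_diagonal(C, 1.0)
    D = 1.0 - C
    D = (D + D.T) / 2.0  # corrcoef is symmetric only up to rounding
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, None)


def hierarchical_cluster(matrix: ExpressionMatrix, axis: str = "samples") -> Dendrogram:
    """Average-linkage agglomeration under 1 − Pearson distance of log2
    profiles, over genes or samples.

    Deterministic: at equal merge distances the pair with the smallest
    cluster ids (creation order) merges first.
    """
    if axis not in ("genes", "samples"):
        raise InputError(f"axis must be 'genes' or 'samples', got {axis!r}")
    X = np.log2(matrix.values.to_numpy(dtype=float))
    labels = matrix.gene_ids if axis == "genes" else matrix.sample_ids
    if axis == "samples":
        X = X.T
    n = X.shape[0]
    if n < 2:
        raise InputError(f"need ≥2 items on axis {axis!r}")

    D = _correlation_distance(X)
    size = np.ones(n)
    cid = np.arange(n)            # cluster id currently held by each slot
    active = np.ones(n, dtype=bool)
    children: dict[int, tuple[int, int]] = {}
    merges = np.zeros((n - 1, 4))

    work = D.copy()
    np.fill_diagonal(work, np.inf)
    for step in range(n - 1):
        masked = np.where(np.outer(active, active), work, np.inf)
        np.fill_diagonal(masked, np.inf)
        mval = masked.min()
        cand = np.argwhere(np.isclose(masked, mval, rtol=0.0, atol=0.0))
        # lowest cluster-id pair wins ties
        best = min(
            ((tuple(sorted((cid[i], cid[j]))), (i, j)) for i, j in cand if i < j),
            key=lambda t: t[0],
        )
        (ca, cb), (i, j) = best
        ni, nj = size[i], size[j]
        new_id = n + step
        children[new_id] = (ca, cb)
        merges[step] = (ca, cb, mval, ni + nj)
        # Lance–Williams average-linkage update into slot i
        upd = (ni * work[i] + nj * work[j]) / (ni + nj)
        work[i], work[:, i] = upd, upd
        work[i, i] = np.inf
        active[j] = False
        size[i] = ni + nj
        cid[i] = new_id

    def fringe(c: int) -> list[int]:
        if c < n:
            return [c]
        a, b = children[c]
        return fringe(a) + fringe(b)

    leaf_order = [labels[i] for i in fringe(2 * n - 2)]
    return Dendrogram(merges=merges, leaf_order=leaf_order, labels=list(labels))


def to_newick(dendro: Dendrogram) -> str:
    """Serialize a dendrogram as Newick; branch lengths are height drops."""
    n = len(dendro.labels)
    heights = {i: 0.0 for i in range(n)}
    children = {}
    for t, (a, b, h, _) in enumerate(dendro.merges):
        children[n + t] = (int(a), int(b))
        heights[n + t] = float(h)

    def render(c: int, parent_h: float) -> str:
        bl = max(parent_h - heights[c], 0.0)
        if c < n:
            return f"{dendro.labels[c]}:{bl:.6g}"
        a, b = children[c]
        h = heights[c]
        return f"({render(a, h)},{render(b, h)}):{bl:.6g}"

    root = 2 * n - 2
    a, b = children[root]
    h = heights[root]
    return f"({render(a, h)},{render(b, h)});"
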