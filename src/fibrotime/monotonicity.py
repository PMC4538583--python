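"""Monotonic-trend classification of temporal expression profiles.

Each gene's 5-PD profile is correlated (Spearman, mid-ranks) with the
linearly increasing curve f(x) = x.  Replicates are incorporated by
resampling: each resample picks one replicate per PD uniformly at random,
yielding a correlation rho_r and an exact permutation p-value p_r; the gene's
statistic is c(i) = mean rho_r with p(i) = median p_r.  Classification:

    up          if c(i) > 0 and p(i) < alpha
    down        if c(i) < 0 and p(i) < alpha
    nonuniform  otherwise

For n <= 8 time points the p-value is exact: all n! permutations of the
observed series are enumerated and p = P(|rho_perm| >= |rho_obs|).  Because
the enumeration permutes the observed values themselves it remains exact
under ties.  With n = 5 only a perfectly ordered profile reaches p < 0.05
(p = 2/120), which is why genome-wide monotone gene counts are small.
"""

from __future__ import annotations

import dataclasses
import functools
import itertools
import math

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

MAX_EXACT_N = 8


@dataclasses.dataclass
class MonotonyConfig:
    """Settings of the replicate-resampling trend classifier.

    When the number of distinct resample paths (product of per-PD replicate
    counts, e.g. 3^5 = 243) does not exceed ``path_limit``, all paths are
    enumerated with equal weight, making c(i) and p(i) exact expectations of
    the resampling scheme; otherwise ``n_resamples`` random draws are used.
    Set ``enumerate_paths`` explicitly to force either mode.
    """

    n_resamples: int = 100
    alpha: float = 0.05
    seed: int = 0
    sidedness: str = "two-sided"
    path_limit: int = 1024
    enumerate_paths: bool | None = None

    def validate(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.sidedness != "two-sided":
            raise ValueError("only the two-sided test is implemented")


@functools.lru_cache(maxsize=None)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _rho_against_index(ranks: np.ndarray) -> np.ndarray:
    """Pearson correlation of (mid-)rank rows with the ascending index."""
    n = ranks.shape[-1]
    ref = np.arange(1.0, n + 1.0)
    refc = ref - ref.mean()
    rc = ranks - ranks.mean(axis=-1, keepdims=True)
    denom = np.sqrt((rc**2).sum(axis=-1) * (refc**2).sum())
    num = rc @ refc
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, num / denom, 0.0)
    return rho


@functools.lru_cache(maxsize=4096)
def _null_abs_rho(rank_key: tuple) -> np.ndarray:
    """Sorted |rho| over all permutations of a given rank multiset."""
    ranks = np.asarray(rank_key, dtype=float)
    perms = _perm_matrix(len(ranks))
    rhos = _rho_against_index(ranks[perms])
    return np.sort(np.abs(rhos))


def _p_from_null(null_sorted: np.ndarray, abs_rho: float) -> float:
    idx = np.searchsorted(null_sorted, abs_rho - 1e-12, side="left")
    return float(null_sorted.size - idx) / null_sorted.size


def exact_spearman_p(values, reference=None) -> tuple:
    """Spearman rho of a short series against the increasing curve, exact p.

    ``reference`` defaults to the ascending index 1..n.  For n <= 8 the
    p-value enumerates all n! permutations of the series (exact under ties);
    longer series fall back to the large-sample t approximation.  A constant
    series returns (0.0, 1.0) by convention.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 time points")
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        order = np.argsort(ref, kind="stable")
        if not np.array_equal(rankdata(ref), np.arange(1.0, n + 1.0)):
            raise ValueError("reference must be strictly increasing after sorting")
        x = x[order]
    if np.all(x == x[0]):
        return 0.0, 1.0
    ranks = rankdata(x)
    rho = float(_rho_against_index(ranks))
    if n > MAX_EXACT_N:
        return tuple(spearmanr(x, np.arange(n)))
    null = _null_abs_rho(tuple(np.sort(ranks)))
    return rho, _p_from_null(null, abs(rho))


@dataclasses.dataclass
class MonotonicityResult:
    """Per-gene averaged correlation c, combined p, and class label."""

    table: pd.DataFrame  # columns: c, p, class

    @property
    def classes(self) -> pd.Series:
        return self.table["class"]

    def counts(self) -> pd.Series:
        return self.classes.value_counts().reindex(
            ["up", "down", "nonuniform"], fill_value=0
        )


def _replicate_stack(values: pd.DataFrame, sample_meta: pd.DataFrame, cell_line: str):
    """Per-PD replicate value arrays for one cell line, PDs in ascending order."""
    sub = sample_meta[sample_meta["cell_line"] == cell_line]
    pds = sorted(sub["pd"].unique())
    if len(pds) < 3:
        raise ValueError(f"cell line {cell_line!r} has fewer than 3 time points")
    blocks = []
    for pd_label in pds:
        samples = sub[sub["pd"] == pd_label].index
        if len(samples) == 0:
            raise ValueError(f"no replicates at PD {pd_label}")
        blocks.append(values[list(samples)].to_numpy(dtype=float))
    return blocks, pds


def classify_genes(
    values: pd.DataFrame,
    sample_meta: pd.DataFrame,
    cell_line: str,
    config: MonotonyConfig | None = None,
) -> MonotonicityResult:
    """Classify every gene of one cell line as up / down / nonuniform.

    ``values`` is a genes x samples expression table (RPKM).  Deterministic
    given ``config.seed``.
    """
    config = config or MonotonyConfig()
    config.validate()
    blocks, _ = _replicate_stack(values, sample_meta, cell_line)
    n_pd = len(blocks)
    n_genes = values.shape[0]
    n_paths = math.prod(block.shape[1] for block in blocks)
    enumerate_all = (
        config.enumerate_paths
        if config.enumerate_paths is not None
        else n_paths <= config.path_limit
    )
    if enumerate_all:
        # every distinct one-replicate-per-PD path, equally weighted
        paths = np.array(
            list(itertools.product(*(range(b.shape[1]) for b in blocks))),
            dtype=np.intp,
        )
        picks = np.empty((n_genes, len(paths), n_pd))
        for t, block in enumerate(blocks):
            picks[:, :, t] = block[:, paths[:, t]]
    else:
        rng = np.random.default_rng(config.seed)
        # one replicate per PD per (gene, resample)
        picks = np.empty((n_genes, config.n_resamples, n_pd))
        for t, block in enumerate(blocks):
            idx = rng.integers(0, block.shape[1], size=(n_genes, config.n_resamples))
            picks[:, :, t] = np.take_along_axis(block, idx, axis=1)

    ranks = rankdata(picks, axis=-1)
    rho = _rho_against_index(ranks)
    constant = np.ptp(picks, axis=-1) == 0
    rho[constant] = 0.0

    pvals = np.empty_like(rho)
    sorted_vals = np.sort(picks, axis=-1)
    has_tie = (np.diff(sorted_vals, axis=-1) == 0).any(axis=-1)
    null_distinct = _null_abs_rho(tuple(np.arange(1.0, n_pd + 1.0)))
    plain = ~has_tie
    idx = np.searchsorted(null_distinct, np.abs(rho[plain]) - 1e-12, side="left")
    pvals[plain] = (null_distinct.size - idx) / null_distinct.size
    for gi, ri in zip(*np.nonzero(has_tie)):
        if constant[gi, ri]:
            pvals[gi, ri] = 1.0
        else:
            null = _null_abs_rho(tuple(np.sort(ranks[gi, ri])))
            pvals[gi, ri] = _p_from_null(null, abs(rho[gi, ri]))

    c = rho.mean(axis=1)
    p = np.median(pvals, axis=1)
    cls = np.where(
        (c > 0) & (p < config.alpha),
        "up",
        np.where((c < 0) & (p < config.alpha), "down", "nonuniform"),
    )
    table = pd.DataFrame({"c": c, "p": p, "class": cls}, index=values.index)
    return MonotonicityResult(table=table)


def compare_lines(res1: MonotonicityResult, res2: MonotonicityResult) -> dict:
    """Venn counts of monotone classes between the two cell lines.

    Returns disjoint gene sets: ``common_up``, ``common_down``, ``opposite``
    (up in one line, down in the other) and ``rest``.
    """
    i1, i2 = res1.table.index, res2.table.index
    if not i1.equals(i2):
        offending = list(i1.symmetric_difference(i2))
        raise ValueError(f"gene universes differ: {offending[:10]}")
    c1, c2 = res1.classes, res2.classes
    common_up = set(i1[(c1 == "up") & (c2 == "up")])
    common_down = set(i1[(c1 == "down") & (c2 == "down")])
    opposite = set(
        i1[((c1 == "up") & (c2 == "down")) | ((c1 == "down") & (c2 == "up"))]
    )
    rest = set(i1) - common_up - common_down - opposite
    return {
        "common_up": common_up,
        "common_down": common_down,
        "opposite": opposite,
        "rest": rest,
    }
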