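"""Fuzzy c-means clustering of concatenated two-line temporal profiles.

Profiles are the 5 per-PD replicate-mean RPKM values of cell line 1 followed
by the 5 of cell line 2, z-scored per gene over all 10 entries (joint
scaling, so the between-line offset survives).  Clustering is standard FCM
with Euclidean distance and fuzzifier m:

    u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1))
    v_k  = sum_i u_ik^m x_i / sum_i u_ik^m
    J    = sum_ik u_ik^m d_ik^2

iterated until |dJ| < tol, best of ``n_starts`` random initializations.  The
number of clusters is chosen by a vote of four fuzzy validity indexes:
partition coefficient (maximize), partition entropy (minimize), Xie-Beni
(minimize) and Fukuyama-Sugeno (minimize); modal vote, ties resolved toward
the smallest candidate.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd


@dataclasses.dataclass
class FcmConfig:
    m: float = 1.2
    max_iter: int = 500
    tol: float = 1e-8
    n_starts: int = 30
    c_range: tuple = (2, 10)
    seed: int = 0

    def validate(self) -> None:
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclasses.dataclass
class ProfileMatrix:
    """Z-scored genes x 10 profile matrix with raw per-PD means retained."""

    z: pd.DataFrame
    raw_means: pd.DataFrame
    lines: tuple
    dropped: list


@dataclasses.dataclass
class ClusteringResult:
    membership: pd.DataFrame  # genes x c, rows sum to 1
    centers: np.ndarray  # c x n_features
    hard: pd.Series  # argmax membership, clusters numbered from 1
    objective: float
    objective_history: np.ndarray  # per-iteration J of the winning start
    validity: pd.DataFrame | None = None
    chosen_c: int | None = None


def build_profiles(rpkm, sample_meta: pd.DataFrame, genes, lines=None) -> ProfileMatrix:
    """Per-PD replicate means for both lines, concatenated and z-scored.

    ``rpkm`` is an RPKM DataFrame (genes x samples) or ExpressionMatrix.
    Genes whose 10-point raw profile is constant are dropped with a warning
    (their z-score is undefined).
    """
    values = rpkm.values if hasattr(rpkm, "scale") else rpkm
    genes = [g for g in genes]
    if not genes:
        raise ValueError("gene subset is empty")
    if lines is None:
        lines = tuple(pd.unique(sample_meta["cell_line"]))
    cols = {}
    for line in lines:
        sub = sample_meta[sample_meta["cell_line"] == line]
        for pd_label in sorted(sub["pd"].unique()):
            samples = sub[sub["pd"] == pd_label].index
            cols[f"{line}:PD{pd_label}"] = values.loc[genes, samples].mean(axis=1)
    raw = pd.DataFrame(cols)
    sd = raw.std(axis=1, ddof=0)
    constant = sd <= 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} gene(s) with constant profiles"
        )
    raw = raw.loc[~constant]
    z = raw.sub(raw.mean(axis=1), axis=0).div(raw.std(axis=1, ddof=0), axis=0)
    return ProfileMatrix(
        z=z, raw_means=raw, lines=tuple(lines), dropped=list(sd.index[constant])
    )


def _fcm_single(X: np.ndarray, c: int, m: float, tol: float, max_iter: int, rng):
    n = X.shape[0]
    u = rng.dirichlet(np.ones(c), size=n)
    exponent = 2.0 / (m - 1.0)
    prev_j = None
    history = []
    for _ in range(max_iter):
        um = u**m
        v = (um.T @ X) / um.sum(axis=0)[:, None]
        d2 = np.square(X[:, None, :] - v[None, :, :]).sum(axis=2)
        zero = d2 <= 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-exponent / 2.0)
            u = inv / inv.sum(axis=1, keepdims=True)
        rows_with_zero = zero.any(axis=1)
        if rows_with_zero.any():
            u[rows_with_zero] = 0.0
            z = zero[rows_with_zero]
            u[rows_with_zero] = z / z.sum(axis=1, keepdims=True)
        j = float((u**m * d2).sum())
        history.append(j)
        if prev_j is not None and abs(prev_j - j) < tol:
            break
        prev_j = j
    return u, v, history[-1], np.array(history)


def fcm(X, c: int, config: FcmConfig | None = None) -> ClusteringResult:
    """Fuzzy c-means for a fixed cluster count; best of n_starts by lowest J."""
    config = config or FcmConfig()
    config.validate()
    if hasattr(X, "z"):
        data = X.z
    elif isinstance(X, pd.DataFrame):
        data = X
    else:
        data = pd.DataFrame(np.asarray(X, dtype=float))
    arr = data.to_numpy(dtype=float)
    n = arr.shape[0]
    if c < 2:
        raise ValueError("c must be >= 2")
    if c >= n:
        raise ValueError(f"c={c} must be smaller than the number of points ({n})")
    rng = np.random.default_rng(config.seed)
    best = None
    for _ in range(config.n_starts):
        start_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        u, v, j, history = _fcm_single(
            arr, c, config.m, config.tol, config.max_iter, start_rng
        )
        if best is None or j < best[2]:
            best = (u, v, j, history)
    u, v, j, history = best
    membership = pd.DataFrame(
        u, index=data.index, columns=[f"cluster_{k + 1}" for k in range(c)]
    )
    hard = pd.Series(u.argmax(axis=1) + 1, index=data.index, name="cluster")
    return ClusteringResult(
        membership=membership,
        centers=v,
        hard=hard,
        objective=j,
        objective_history=history,
    )


def validity_indexes(X, result: ClusteringResult, m: float) -> dict:
    """Partition coefficient/entropy, Xie-Beni and Fukuyama-Sugeno indexes."""
    data = X.z if hasattr(X, "z") else X
    arr = np.asarray(data, dtype=float)
    u = result.membership.to_numpy()
    v = result.centers
    n = arr.shape[0]
    um = u**m
    d2 = np.square(arr[:, None, :] - v[None, :, :]).sum(axis=2)
    j = float((um * d2).sum())
    pc = float((u**2).sum() / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        logu = np.where(u > 0, np.log(u), 0.0)
    pe = float(-(u * logu).sum() / n)
    center_d2 = np.square(v[:, None, :] - v[None, :, :]).sum(axis=2)
    np.fill_diagonal(center_d2, np.inf)
    xb = j / (n * center_d2.min())
    xbar = arr.mean(axis=0)
    vk_d2 = np.square(v - xbar).sum(axis=1)
    fs = float((um * (d2 - vk_d2[None, :])).sum())
    return {"pc": pc, "pe": pe, "xb": float(xb), "fs": fs}


def choose_c(X, config: FcmConfig | None = None) -> tuple:
    """Pick the cluster count by a vote of four validity indexes.

    Each index votes for the candidate c it optimizes; the modal vote wins,
    ties resolved toward the smallest c.  Returns (chosen_c, validity table,
    {c: ClusteringResult}).
    """
    config = config or FcmConfig()
    config.validate()
    lo, hi = config.c_range
    candidates = list(range(lo, hi + 1))
    if not candidates:
        raise ValueError("candidate c range is empty")
    data = X.z if hasattr(X, "z") else X
    n = len(data)
    candidates = [c for c in candidates if 2 <= c < n]
    if not candidates:
        raise ValueError("no feasible candidate c for this data size")
    rows, results = {}, {}
    for c in candidates:
        sub = dataclasses.replace(config, seed=config.seed + c)
        res = fcm(X, c, sub)
        rows[c] = validity_indexes(X, res, config.m)
        results[c] = res
    table = pd.DataFrame(rows).T
    table.index.name = "c"
    votes = [
        int(table["pc"].idxmax()),
        int(table["pe"].idxmin()),
        int(table["xb"].idxmin()),
        int(table["fs"].idxmin()),
    ]
    table["votes"] = [votes.count(c) for c in table.index]
    top = table["votes"].max()
    chosen = int(min(c for c in table.index if table.loc[c, "votes"] == top))
    result = results[chosen]
    result.validity = table
    result.chosen_c = chosen
    return chosen, table, results


def summarize_clusters(result: ClusteringResult, pm: ProfileMatrix) -> pd.DataFrame:
    """Per-cluster, per-line 5-point mean and SD of member z-scored profiles.

    SD uses the population convention (ddof=0) so single-member clusters stay
    finite; empty clusters yield all-NaN rows with a warning.
    """
    n_per_line = pm.z.shape[1] // len(pm.lines)
    c = result.membership.shape[1]
    rows = []
    for k in range(1, c + 1):
        members = result.hard.index[result.hard == k]
        if len(members) == 0:
            warnings.warn(f"cluster {k} is empty")
        for li, line in enumerate(pm.lines):
            block = pm.z.loc[members].iloc[:, li * n_per_line : (li + 1) * n_per_line]
            rec = {"cluster": k, "cell_line": line, "n_genes": len(members)}
            for t in range(n_per_line):
                col = block.iloc[:, t] if len(members) else pd.Series(dtype=float)
                rec[f"mean_{t}"] = float(col.mean()) if len(members) else np.nan
                rec[f"sd_{t}"] = float(col.std(ddof=0)) if len(members) else np.nan
            rows.append(rec)
    return pd.DataFrame(rows).set_index(["cluster", "cell_line"])
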