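"""Temporal profile construction and fuzzy c-means clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import fibrotime as ft
from fibrotime.clustering import validity_indexes


def _planted_blobs(seed=0, n_per=20, c=3, spread=0.05, sep=4.0, dim=10):
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=sep, size=(c, dim))
    X = np.vstack([rng.normal(centers[k], spread, size=(n_per, dim)) for k in range(c)])
    labels = np.repeat(np.arange(c), n_per)
    return pd.DataFrame(X), labels


@pytest.fixture(scope="module")
def meta_two_lines():
    rows = []
    for line in ("A", "B"):
        pds = (32, 42, 52, 62, 72) if line == "A" else (16, 26, 46, 64, 74)
        for p in pds:
            for r in (1, 2, 3):
                rows.append(
                    {"sample": f"{line}_PD{p}_R{r}", "cell_line": line, "pd": p, "replicate": r}
                )
    return pd.DataFrame(rows).set_index("sample")


class TestBuildProfiles:
    def test_toy_means_and_zscores_match_hand_arithmetic(self, meta_two_lines):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(
            rng.uniform(1, 100, size=(2, 30)),
            index=["g1", "g2"],
            columns=meta_two_lines.index,
        )
        pm = ft.build_profiles(values, meta_two_lines, ["g1", "g2"], lines=("A", "B"))
        # oracle: group means per (line, pd), then z-score over the 10 values
        for gene in ("g1", "g2"):
            means = []
            for line in ("A", "B"):
                sub = meta_two_lines[meta_two_lines.cell_line == line]
                for p in sorted(sub["pd"].unique()):
                    cols = sub[sub["pd"] == p].index
                    means.append(values.loc[gene, cols].mean())
            means = np.array(means)
            z = (means - means.mean()) / means.std(ddof=0)
            assert np.allclose(pm.z.loc[gene].to_numpy(), z, atol=1e-12)

    def test_rows_have_zero_mean_unit_sd(self, meta_two_lines):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(
            rng.uniform(1, 50, size=(5, 30)),
            index=[f"g{i}" for i in range(5)],
            columns=meta_two_lines.index,
        )
        pm = ft.build_profiles(values, meta_two_lines, list(values.index))
        assert np.allclose(pm.z.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(pm.z.std(axis=1, ddof=0), 1.0, atol=1e-9)

    def test_constant_profile_dropped_with_warning(self, meta_two_lines):
        values = pd.DataFrame(
            np.vstack([np.full(30, 7.0), np.arange(30.0)]),
            index=["flatgene", "okgene"],
            columns=meta_two_lines.index,
        )
        with pytest.warns(UserWarning):
            pm = ft.build_profiles(values, meta_two_lines, ["flatgene", "okgene"])
        assert list(pm.z.index) == ["okgene"]
        assert pm.dropped == ["flatgene"]

    def test_zscore_scale_invariance(self, meta_two_lines):
        base = np.tile(np.arange(30.0) + 1, (2, 1))
        values = pd.DataFrame(
            np.vstack([base[0], base[1] * 50]),
            index=["slow", "fast"],
            columns=meta_two_lines.index,
        )
        pm = ft.build_profiles(values, meta_two_lines, ["slow", "fast"])
        assert np.allclose(pm.z.loc["slow"], pm.z.loc["fast"], atol=1e-12)


class TestFcm:
    def test_memberships_near_one_for_separated_clumps(self):
        X, labels = _planted_blobs(seed=5, spread=0.02, sep=8.0)
        res = ft.fcm(X, 3, ft.FcmConfig(n_starts=10, seed=1))
        assert res.membership.to_numpy().max(axis=1).min() >= 0.99
        assert adjusted_rand_score(labels, res.hard) == 1.0

    def test_membership_rows_sum_to_one_and_objective_monotone(self):
        X, _ = _planted_blobs(seed=6, spread=1.0, sep=2.0)
        res = ft.fcm(X, 4, ft.FcmConfig(n_starts=5, seed=2))
        assert np.allclose(res.membership.sum(axis=1), 1.0, atol=1e-9)
        assert (np.diff(res.objective_history) <= 1e-9).all()

    def test_objective_consistent_with_definitions(self):
        X, _ = _planted_blobs(seed=7)
        cfg = ft.FcmConfig(n_starts=3, seed=3)
        res = ft.fcm(X, 3, cfg)
        u = res.membership.to_numpy()
        d2 = np.square(X.to_numpy()[:, None, :] - res.centers[None]).sum(axis=2)
        j = ((u**cfg.m) * d2).sum()
        assert j == pytest.approx(res.objective, abs=1e-9)

    def test_stationarity_one_extra_step_changes_j_below_tol(self):
        X, _ = _planted_blobs(seed=8)
        cfg = ft.FcmConfig(n_starts=3, seed=4, tol=1e-10)
        res = ft.fcm(X, 3, cfg)
        u = res.membership.to_numpy()
        arr = X.to_numpy()
        um = u**cfg.m
        v = (um.T @ arr) / um.sum(axis=0)[:, None]
        d2 = np.square(arr[:, None, :] - v[None]).sum(axis=2)
        inv = d2 ** (-1.0 / (cfg.m - 1.0))
        u2 = inv / inv.sum(axis=1, keepdims=True)
        j2 = ((u2**cfg.m) * d2).sum()
        assert abs(j2 - res.objective) < 1e-6

    def test_deterministic_given_seed(self):
        X, _ = _planted_blobs(seed=9)
        r1 = ft.fcm(X, 3, ft.FcmConfig(n_starts=4, seed=11))
        r2 = ft.fcm(X, 3, ft.FcmConfig(n_starts=4, seed=11))
        pd.testing.assert_frame_equal(r1.membership, r2.membership)

    def test_rejects_degenerate_c(self):
        X, _ = _planted_blobs(n_per=2)
        with pytest.raises(ValueError):
            ft.fcm(X, 1, ft.FcmConfig())
        with pytest.raises(ValueError):
            ft.fcm(X.iloc[:3], 3, ft.FcmConfig())

    def test_planted_three_clusters_recovered_exactly(self):
        X, labels = _planted_blobs(seed=10, n_per=20, spread=0.1, sep=5.0)
        res = ft.fcm(X, 3, ft.FcmConfig(m=1.2, n_starts=10, seed=12))
        assert adjusted_rand_score(labels, res.hard) == 1.0


class TestChooseC:
    def test_single_candidate_chosen_trivially(self):
        X, _ = _planted_blobs(seed=13)
        chosen, table, _ = ft.choose_c(X, ft.FcmConfig(n_starts=3, c_range=(3, 3), seed=5))
        assert chosen == 3
        assert list(table.index) == [3]

    def test_planted_three_clusters_selected(self):
        X, _ = _planted_blobs(seed=14, n_per=25, spread=0.1, sep=5.0)
        chosen, table, _ = ft.choose_c(
            X, ft.FcmConfig(n_starts=8, c_range=(2, 6), seed=6)
        )
        assert chosen == 3
        assert table.loc[3, "votes"] == table["votes"].max()

    def test_vote_tie_resolves_to_smallest(self):
        # synthetic validity table exercise through the public contract:
        # equal votes for 4 and 5 must yield 4; emulate by checking the rule
        # on a table built from choose_c internals
        X, _ = _planted_blobs(seed=15, n_per=15, spread=0.5, sep=2.0)
        chosen, table, _ = ft.choose_c(
            X, ft.FcmConfig(n_starts=4, c_range=(2, 5), seed=7)
        )
        top = table["votes"].max()
        assert chosen == min(c for c in table.index if table.loc[c, "votes"] == top)


class TestSummarize:
    def test_identical_profiles_have_zero_sd(self, meta_two_lines):
        row = np.arange(30.0) + 1
        values = pd.DataFrame(
            np.vstack([row, row, row * 2, -row, -row * 3]),
            index=[f"g{i}" for i in range(5)],
            columns=meta_two_lines.index,
        )
        pm = ft.build_profiles(values, meta_two_lines, list(values.index))
        res = ft.fcm(pm, 2, ft.FcmConfig(n_starts=5, seed=8))
        summary = ft.summarize_clusters(res, pm)
        sd_cols = [c for c in summary.columns if c.startswith("sd_")]
        assert (summary[sd_cols].to_numpy() < 1e-9).all()

    def test_summary_matches_groupby_oracle(self, meta_two_lines):
        rng = np.random.default_rng(16)
        values = pd.DataFrame(
            rng.uniform(1, 100, size=(12, 30)),
            index=[f"g{i}" for i in range(12)],
            columns=meta_two_lines.index,
        )
        pm = ft.build_profiles(values, meta_two_lines, list(values.index))
        res = ft.fcm(pm, 3, ft.FcmConfig(n_starts=5, seed=9))
        summary = ft.summarize_clusters(res, pm)
        for k in (1, 2, 3):
            members = res.hard.index[res.hard == k]
            if not len(members):
                continue
            blockA = pm.z.loc[members].iloc[:, :5]
            assert np.allclose(
                summary.loc[(k, "A")][[f"mean_{t}" for t in range(5)]].to_numpy(
                    dtype=float
                ),
                blockA.mean(axis=0),
                atol=1e-12,
            )


def test_fcm_matches_reference_r_implementation(tmp_path):
    """On well-separated data our FCM converges to the same fixed point as
    the R e1071 cmeans reference implementation (centers and memberships
    agree to near machine precision)."""
    import subprocess

    rng = np.random.default_rng(0)
    centers = np.array([[0.0] * 4, [4.0] * 4, [-4.0] * 4])
    X = np.vstack([rng.normal(c, 0.3, size=(20, 4)) for c in centers])
    x_csv = tmp_path / "x.csv"
    init_csv = tmp_path / "init.csv"
    np.savetxt(x_csv, X, delimiter=",")
    np.savetxt(init_csv, centers + 0.5, delimiter=",")
    r_code = (
        f'x <- as.matrix(read.csv("{x_csv}", header=FALSE)); '
        f'init <- as.matrix(read.csv("{init_csv}", header=FALSE)); '
        'res <- e1071::cmeans(x, centers=init, m=1.2, iter.max=500, method="cmeans"); '
        f'write.csv(res$centers, "{tmp_path}/centers.csv", row.names=FALSE); '
        f'write.csv(res$membership, "{tmp_path}/u.csv", row.names=FALSE)'
    )
    subprocess.run(["Rscript", "-e", r_code], check=True, capture_output=True)
    ref_centers = pd.read_csv(tmp_path / "centers.csv").to_numpy()
    ref_u = pd.read_csv(tmp_path / "u.csv").to_numpy()
    res = ft.fcm(pd.DataFrame(X), 3, ft.FcmConfig(n_starts=10, seed=0, tol=1e-10))
    from scipy.spatial.distance import cdist

    perm = cdist(res.centers, ref_centers).argmin(axis=1)
    assert sorted(perm) == [0, 1, 2]
    assert np.abs(res.centers - ref_centers[perm]).max() < 1e-8
    assert np.abs(res.membership.to_numpy() - ref_u[:, perm]).max() < 1e-8


def test_validity_indexes_prefer_true_structure():
    X, _ = _planted_blobs(seed=17, n_per=30, spread=0.1, sep=6.0, c=4)
    cfg = ft.FcmConfig(n_starts=6, seed=10)
    res3 = ft.fcm(X, 3, cfg)
    res4 = ft.fcm(X, 4, cfg)
    v3 = validity_indexes(X, res3, cfg.m)
    v4 = validity_indexes(X, res4, cfg.m)
    assert v4["xb"] < v3["xb"]
    assert v4["pc"] > v3["pc"]
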