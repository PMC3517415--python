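"""Zero handling, centering/normalization, centroid linkage and TreeView output.

The centroid-linkage implementation is checked against an independent naive
oracle: at every step it recomputes all centroid-pair distances from the raw
member lists with plain Python loops and applies the same tie-break rule.
"""

import numpy as np
import pandas as pd
import pytest

from starprofile import (
    ParameterError,
    build_program,
    center_and_normalize,
    centroid_hclust,
    cluster_expression,
    cut_tree,
    order_matrix,
    read_cdt,
    replace_zeros,
    sample_counts,
    star_table,
    write_cdt,
    write_gtr,
)
from starprofile import DEFAULT_LIBRARY_DEPTHS
from starprofile.simulate import SimConfig


# ---------------------------------------------------------------------------
# Naive oracle: brute-force centroid linkage
# ---------------------------------------------------------------------------

def _naive_distance(u, v):
    """Pearson correlation distance, definitional form (clamped at 0)."""
    mu, mv = sum(u) / len(u), sum(v) / len(v)
    uc = [x - mu for x in u]
    vc = [x - mv for x in v]
    nu = sum(x * x for x in uc) ** 0.5
    nv = sum(x * x for x in vc) ** 0.5
    if nu == 0 or nv == 0:
        return 1.0
    return max(1.0 - sum(a * b for a, b in zip(uc, vc)) / (nu * nv), 0.0)


def naive_centroid_linkage(X, ids):
    """O(n^3) reference: recompute every centroid pair distance at each step."""
    n = len(ids)
    clusters = {i: [i] for i in range(n)}
    reps = {i: ids[i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                ca = [sum(X[m][j] for m in clusters[a]) / len(clusters[a]) for j in range(len(X[0]))]
                cb = [sum(X[m][j] for m in clusters[b]) / len(clusters[b]) for j in range(len(X[0]))]
                d = _naive_distance(ca, cb)
                pair = tuple(sorted((reps[a], reps[b])))
                if best is None or (d, pair) < best[:2]:
                    best = (d, pair, a, b)
        d, _pair, a, b = best
        merges.append((a, b, d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        reps[next_id] = min(reps[a], reps[b])
        next_id += 1
    return merges


class TestReplaceZeros:
    def test_zero_becomes_floor(self):
        m = pd.DataFrame({"a": [0.0, 13.27]})
        out = replace_zeros(m)
        assert out["a"].tolist() == [0.0002, 13.27]

    def test_idempotent(self):
        m = pd.DataFrame({"a": [0.0, 5.0]})
        assert replace_zeros(replace_zeros(m)).equals(replace_zeros(m))

    def test_bad_eps_rejected(self):
        with pytest.raises(ParameterError):
            replace_zeros(pd.DataFrame({"a": [1.0]}), eps=0)


class TestCenterAndNormalize:
    def test_row_invariants_hold(self, rng):
        m = pd.DataFrame(rng.random((20, 7)) * 100)
        out = center_and_normalize(m)
        assert np.allclose(np.median(out, axis=1), 0.0, atol=1e-9)
        assert np.allclose((out**2).sum(axis=1), 1.0, atol=1e-9)

    def test_direct_small_example(self):
        m = pd.DataFrame([[1.0, 2, 3, 4, 5, 6, 7]])
        out = center_and_normalize(m).to_numpy()[0]
        centered = np.arange(-3.0, 4.0)
        expected = centered / np.sqrt((centered**2).sum())
        assert np.allclose(out, expected)

    def test_fixed_point(self, rng):
        m = pd.DataFrame(rng.random((5, 7)))
        once = center_and_normalize(m)
        again = center_and_normalize(once)
        assert np.allclose(once.to_numpy(), again.to_numpy(), atol=1e-12)

    def test_constant_row_dropped_with_warning(self, caplog):
        m = pd.DataFrame([[1.0, 1, 1, 1, 1, 1, 1], [1.0, 2, 3, 4, 5, 6, 7]])
        with caplog.at_level("WARNING"):
            out = center_and_normalize(m)
        assert len(out) == 1
        assert "constant" in caplog.text


class TestCentroidHclust:
    def test_identical_rows_merge_first_at_zero(self, rng):
        data = rng.random((5, 7))
        data[3] = data[1]
        m = pd.DataFrame(data, index=[f"g{i}" for i in range(5)])
        tree = centroid_hclust(m)
        a, b, h = tree.merges[0]
        assert {tree.ids[a], tree.ids[b]} == {"g1", "g3"}
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_single_item_rejected(self):
        with pytest.raises(ParameterError):
            centroid_hclust(pd.DataFrame([[1.0, 2, 3]]))

    @pytest.mark.parametrize("trial_block", range(5))
    def test_matches_naive_oracle(self, trial_block):
        """1,000 random instances (n <= 8): identical merges and heights."""
        rng = np.random.default_rng(500 + trial_block)
        for _ in range(200):
            n = int(rng.integers(3, 9))
            X = rng.standard_normal((n, 5))
            ids = [f"g{i}" for i in range(n)]
            m = pd.DataFrame(X, index=ids)
            tree = centroid_hclust(m, metric="pearson")
            expected = naive_centroid_linkage(X.tolist(), ids)
            for (a1, b1, h1), (a2, b2, h2) in zip(tree.merges, expected):
                assert {a1, b1} == {a2, b2}
                assert h1 == pytest.approx(h2, abs=1e-9)

    def test_row_order_invariance(self, rng):
        X = rng.standard_normal((8, 7))
        ids = [f"g{i}" for i in range(8)]
        m = pd.DataFrame(X, index=ids)
        tree1 = centroid_hclust(m)
        perm = rng.permutation(8)
        m2 = m.iloc[perm]
        tree2 = centroid_hclust(m2)
        # compare merges as sets of leaf-label groups
        def groups(tree):
            n = tree.n_leaves
            members = {i: frozenset([tree.ids[i]]) for i in range(n)}
            out = []
            for t, (a, b, h) in enumerate(tree.merges):
                members[n + t] = members[a] | members[b]
                out.append((members[n + t], round(h, 9)))
            return out

        assert groups(tree1) == groups(tree2)


class TestTreeOutputs:
    @pytest.fixture
    def clustered(self, rng):
        m = pd.DataFrame(
            rng.random((10, 7)) * 50,
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(7)],
        )
        return cluster_expression(m)

    def test_gtr_line_count_is_n_minus_one(self, clustered, tmp_path):
        processed, row_tree, col_tree = clustered
        path = tmp_path / "t.gtr"
        write_gtr(row_tree, str(path))
        assert len(path.read_text().splitlines()) == len(processed) - 1

    def test_cdt_roundtrip_is_exact(self, clustered, tmp_path):
        processed, row_tree, col_tree = clustered
        path = tmp_path / "t.cdt"
        write_cdt(processed, row_tree, col_tree, str(path))
        back = read_cdt(str(path))
        ordered = order_matrix(processed, row_tree, col_tree)
        assert list(back.index) == list(ordered.index)
        assert np.array_equal(back.to_numpy(), ordered.to_numpy())

    def test_emitted_matrix_keeps_processing_invariants(self, clustered, tmp_path):
        processed, row_tree, col_tree = clustered
        path = tmp_path / "t.cdt"
        write_cdt(processed, row_tree, col_tree, str(path))
        back = read_cdt(str(path)).to_numpy()
        assert np.allclose(np.median(back, axis=1), 0.0, atol=1e-9)
        assert np.allclose((back**2).sum(axis=1), 1.0, atol=1e-9)


@pytest.fixture(scope="module")
def archetype_run():
    cfg = SimConfig(
        n_genes=240,
        archetype_proportions={
            "maternal_decay": 0.1,
            "trochophore_spike": 0.1,
            "postlarval_rise": 0.1,
            "background": 0.7,
        },
        seed=61,
        benthic_shift=True,
    )
    programs = build_program(cfg)
    cm = sample_counts(programs, DEFAULT_LIBRARY_DEPTHS, seed=62)
    table, candidates = star_table(cm)
    return programs, table, candidates


class TestSyntheticRecovery:
    def test_archetypes_recovered_by_cutting_gene_tree(self, archetype_run):
        from sklearn.metrics import adjusted_rand_score

        programs, table, candidates = archetype_run
        truth = {p.gene_id: p.archetype for p in programs}
        dynamic = {"maternal_decay", "trochophore_spike", "postlarval_rise"}
        keep = [g for g in candidates.index if truth[g] in dynamic]
        processed, row_tree, _ = cluster_expression(candidates.loc[keep])
        labels = cut_tree(row_tree, 3)
        ari = adjusted_rand_score(
            [truth[g] for g in labels.index], labels.to_numpy()
        )
        assert ari >= 0.95

    def test_benthic_stages_join_first(self, archetype_run):
        """74VEL and 144PL pair up before joining any earlier stage."""
        _, _, candidates = archetype_run
        _, _, col_tree = cluster_expression(candidates)
        n = col_tree.n_leaves
        for a, b, _h in col_tree.merges:
            touched = {col_tree.ids[x] for x in (a, b) if x < n}
            if "74VEL" in touched or "144PL" in touched:
                assert touched == {"74VEL", "144PL"}
                break


def test_cut_tree_produces_requested_clusters(rng):
    m = pd.DataFrame(rng.standard_normal((9, 7)), index=[f"g{i}" for i in range(9)])
    tree = centroid_hclust(m)
    for k in (1, 3, 9):
        labels = cut_tree(tree, k)
        assert labels.nunique() == k
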