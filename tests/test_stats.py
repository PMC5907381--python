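"""Variance gate, omnibus + post-hoc comparisons, compact letters."""

import itertools

import numpy as np
import pytest

from damrhythm import compact_letters, compare_groups, dunn_test, variance_gate


class TestVarianceGate:
    def test_homoscedastic_normal_routes_parametric_untransformed(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(20):
            groups = {f"g{i}": rng.normal(10, 2, 40) for i in range(4)}
            gate = variance_gate(groups)
            hits += gate.path == "parametric" and gate.transform == "none"
        assert hits >= 17  # Bartlett false-alarms ~5%

    def test_variance_proportional_to_squared_mean_selects_log(self):
        # lognormal groups with very different scales: raw Bartlett fails,
        # log(x+1) equalizes the variances
        rng = np.random.default_rng(1)
        groups = {
            "low": np.exp(rng.normal(3.0, 0.5, 60)),
            "mid": np.exp(rng.normal(4.5, 0.5, 60)),
            "high": np.exp(rng.normal(6.0, 0.5, 60)),
        }
        gate = variance_gate(groups)
        assert gate.path == "parametric" and gate.transform == "log"

    def test_arcsine_reachable_for_proportions_only(self):
        rng = np.random.default_rng(2)
        # raw counts outside [0, 1] must never route to arcsine
        counts = {f"g{i}": rng.poisson(5 * 10**i, 50).astype(float) for i in range(3)}
        gate = variance_gate(counts)
        assert gate.transform != "arcsine"
        assert "arcsine" not in gate.bartlett_p
        # binomial proportions with equal trials but very different p: raw,
        # log and sqrt variances scale with p(1-p) or (1-p) while the
        # arcsine-sqrt variance is ~1/(4m) for every group
        m = 100
        props = {
            f"p{int(100 * p)}": rng.binomial(m, p, 100) / m for p in (0.1, 0.5, 0.9)
        }
        gate = variance_gate(props)
        assert gate.path == "parametric" and gate.transform == "arcsine"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            variance_gate({"a": [1.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="at least 2"):
            variance_gate({"a": [1.0, 2.0]})


class TestCompareGroups:
    def test_identical_groups_share_a_letter(self):
        res = compare_groups({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.letters == {"a": "a", "b": "a"}

    def test_one_shifted_group_separates(self):
        rng = np.random.default_rng(3)
        res = compare_groups(
            {
                "g1": rng.normal(0, 1, 30),
                "g2": rng.normal(0, 1, 30),
                "g3": rng.normal(40, 1, 30),
            }
        )
        letters = res.letters
        assert letters["g1"] == letters["g2"] != letters["g3"]

    def test_nan_observations_dropped_listwise(self):
        res = compare_groups(
            {"a": [1.0, 2.0, np.nan, 3.0], "b": [4.0, 5.0, 6.0]}
        )
        assert res.n == {"a": 3, "b": 3}

    def test_kruskal_statistic_equals_rank_permutation_oracle(self):
        groups = {"a": [1.2, 3.4, 0.1], "b": [5.5, 2.2, 6.1], "c": [9.0, 8.5]}
        res = compare_groups(groups, gate=_force_nonparametric(groups))
        h_obs, p_perm = kruskal_permutation_oracle(groups)
        assert res.test_used == "kruskal_wallis"
        assert res.statistic == pytest.approx(h_obs, rel=1e-12)
        # chi-square approximation should be in the vicinity of the exact
        # permutation p on this tiny fixture
        assert abs(res.p_value - p_perm) < 0.07

    def test_nonparametric_path_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        groups = {f"g{i}": rng.normal(i, 1, 12) for i in range(3)}
        gate = _force_nonparametric(groups)
        a = compare_groups(groups, gate=gate)
        b = compare_groups({k: np.exp(v / 3.0) for k, v in groups.items()}, gate=gate)
        assert a.statistic == pytest.approx(b.statistic)
        assert np.allclose(a.pairwise_p, b.pairwise_p, equal_nan=True)


def _force_nonparametric(groups):
    from damrhythm import GateResult

    return GateResult(path="nonparametric", transform="none")


def rank_everything(values):
    """Midranks by explicit sorting (no scipy)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def kruskal_h(labels, ranks, sizes):
    n = len(ranks)
    k = len(sizes)
    means = [0.0] * k
    for lab, r in zip(labels, ranks):
        means[lab] += r
    h = 0.0
    for g in range(k):
        mean = means[g] / sizes[g]
        h += sizes[g] * (mean - (n + 1) / 2) ** 2
    return 12.0 / (n * (n + 1)) * h


def kruskal_permutation_oracle(groups):
    """Exact permutation distribution of the KW statistic (no ties here)."""
    vals = [v for g in groups.values() for v in g]
    sizes = [len(g) for g in groups.values()]
    labels = [i for i, g in enumerate(groups.values()) for _ in g]
    ranks = rank_everything(vals)
    h_obs = kruskal_h(labels, ranks, sizes)
    count = total = 0
    seen = set()
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if kruskal_h(perm, ranks, sizes) >= h_obs - 1e-12:
            count += 1
    return h_obs, count / total


class TestDunn:
    def test_symmetric_with_nan_diagonal(self):
        rng = np.random.default_rng(5)
        groups = {f"g{i}": rng.normal(i, 1, 10) for i in range(3)}
        pmat = dunn_test(groups)
        assert np.allclose(pmat, pmat.T, equal_nan=True)
        assert np.all(np.isnan(np.diag(pmat)))

    def test_flags_a_far_shifted_group(self):
        rng = np.random.default_rng(6)
        groups = {
            "a": rng.normal(0, 1, 20),
            "b": rng.normal(0, 1, 20),
            "c": rng.normal(30, 1, 20),
        }
        pmat = dunn_test(groups)
        assert pmat[0, 1] > 0.05 and pmat[0, 2] < 0.01 and pmat[1, 2] < 0.01


def brute_force_min_letters(sig):
    """Smallest valid letter assignment by exhaustive search over letter
    sets encoded as vertex subsets."""
    k = sig.shape[0]
    subsets = [
        frozenset(c)
        for r in range(1, k + 1)
        for c in itertools.combinations(range(k), r)
        if not any(sig[i][j] for i, j in itertools.combinations(c, 2))
    ]
    for size in range(1, len(subsets) + 1):
        for combo in itertools.combinations(subsets, size):
            ok = all(any(i in c for c in combo) for i in range(k))
            if not ok:
                continue
            valid = True
            for i, j in itertools.combinations(range(k), 2):
                share = any(i in c and j in c for c in combo)
                if share == bool(sig[i][j]):
                    valid = False
                    break
            if valid:
                return size
    raise AssertionError("no valid assignment found")


class TestCompactLetters:
    def test_no_significant_pairs_all_share(self):
        sig = np.zeros((4, 4), dtype=bool)
        assert compact_letters(sig) == ["a"] * 4

    def test_all_pairs_significant_all_distinct(self):
        sig = ~np.eye(3, dtype=bool)
        assert compact_letters(sig) == ["a", "b", "c"]

    def test_chain_pattern(self):
        # a-b ns, b-c ns, a-c significant -> a / ab / b
        sig = np.zeros((3, 3), dtype=bool)
        sig[0, 2] = sig[2, 0] = True
        assert compact_letters(sig) == ["a", "ab", "b"]

    def test_asymmetric_matrix_rejected(self):
        sig = np.zeros((3, 3), dtype=bool)
        sig[0, 1] = True
        with pytest.raises(ValueError, match="symmetric"):
            compact_letters(sig)

    def test_random_matrices_match_brute_force_minimum(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            sig = np.zeros((5, 5), dtype=bool)
            for i, j in itertools.combinations(range(5), 2):
                sig[i, j] = sig[j, i] = rng.random() < 0.45
            letters = compact_letters(sig)
            # validity: share a letter iff not significant
            for i, j in itertools.combinations(range(5), 2):
                share = bool(set(letters[i]) & set(letters[j]))
                assert share != sig[i, j]
            n_letters = len(set("".join(letters)))
            assert n_letters == brute_force_min_letters(sig)

    def test_invariant_under_group_permutation(self):
        rng = np.random.default_rng(8)
        sig = np.zeros((4, 4), dtype=bool)
        for i, j in itertools.combinations(range(4), 2):
            sig[i, j] = sig[j, i] = rng.random() < 0.5
        base = compact_letters(sig)
        perm = np.array([2, 0, 3, 1])
        permuted = compact_letters(sig[np.ix_(perm, perm)])
        # same partition structure up to letter renaming
        for a, b in itertools.combinations(range(4), 2):
            share_base = bool(set(base[perm[a]]) & set(base[perm[b]]))
            share_perm = bool(set(permuted[a]) & set(permuted[b]))
            assert share_base == share_perm
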