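import itertools

import networkx as nx
import numpy as np
import pytest

from perturbnet import (
    AssociationSet,
    ClusterSupport,
    PAN,
    au_pvalue,
    cosine_matrix,
    filter_modules,
    fit_map,
    fit_null,
    hcluster,
    multiscale_bootstrap,
    permute_screen,
    profile_distance,
)
from perturbnet.errors import ConfigurationError, ValidationError
from perturbnet.modules import DEFAULT_SCALES, modules_frame


# ------------------------------------------------------------- distances


def _assoc_from_square(cc):
    cc = np.asarray(cc, dtype=float)
    n = cc.shape[0]
    iu, ju = np.triu_indices(n, 1)
    return AssociationSet([f"g{i}" for i in range(n)], cc[iu, ju])


def test_profile_distance_identical_and_anticorrelated_profiles():
    # genes 0/1 share one association profile; gene 2 mirrors gene 0 exactly
    cc = np.array(
        [
            [1.0, 0.5, -0.5, 0.3, -0.2],
            [0.5, 1.0, -0.5, 0.3, -0.2],
            [-0.5, -0.5, 1.0, -0.3, 0.2],
            [0.3, 0.3, -0.3, 1.0, 0.1],
            [-0.2, -0.2, 0.2, 0.1, 1.0],
        ]
    )
    d = profile_distance(_assoc_from_square(cc))
    assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert d[0, 2] == pytest.approx(2.0, abs=1e-12)  # exact anti-correlation
    assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)


def test_profile_distance_matches_hand_loop_oracle():
    rng = np.random.default_rng(17)
    cc = np.corrcoef(rng.standard_normal((6, 10)))
    assoc = _assoc_from_square(cc)
    d = profile_distance(assoc)
    full = assoc.square_cc()
    idx = np.arange(6)
    for u, v in itertools.combinations(range(6), 2):
        keep = (idx != u) & (idx != v)
        r = np.corrcoef(full[u, keep], full[v, keep])[0, 1]
        assert d[u, v] == pytest.approx(1 - r, abs=1e-10)


def test_profile_distance_rejects_constant_profile():
    cc = np.array(
        [
            [1.0, 0.5, 0.5, 0.5, 0.5],
            [0.5, 1.0, 0.2, -0.1, 0.3],
            [0.5, 0.2, 1.0, 0.7, -0.2],
            [0.5, -0.1, 0.7, 1.0, 0.4],
            [0.5, 0.3, -0.2, 0.4, 1.0],
        ]
    )
    with pytest.raises(ValidationError, match="g0"):
        profile_distance(_assoc_from_square(cc))


# ------------------------------------------------------------- clustering


def test_hcluster_merges_nearest_pair_first():
    dist = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
    dendro = hcluster(dist, ["A", "B", "C"])
    clusters = dendro.clusters()
    assert clusters[0][0] == frozenset({"A", "B"})
    assert clusters[-1][0] == frozenset({"A", "B", "C"})
    heights = [h for _, h in clusters]
    assert heights == sorted(heights)


def _naive_average_linkage(dist):
    """Brute-force agglomeration oracle returning merged member sets."""
    clusters = {i: frozenset([i]) for i in range(dist.shape[0])}
    out = []
    next_key = dist.shape[0]
    while len(clusters) > 1:
        best, pair = np.inf, None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if d < best - 1e-12:
                best, pair = d, (a, b)
        a, b = pair
        merged = clusters.pop(a) | clusters.pop(b)
        clusters[next_key] = merged
        next_key += 1
        out.append(merged)
    return out


def test_hcluster_agrees_with_bruteforce_agglomeration_oracle():
    rng = np.random.default_rng(23)
    for _ in range(3):
        x = rng.standard_normal((8, 5))
        dist = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        np.fill_diagonal(dist, 0.0)
        dendro = hcluster(dist, [str(i) for i in range(8)])
        got = [frozenset(int(g) for g in m) for m in dendro.cluster_sets()]
        assert got == _naive_average_linkage(dist)


def test_hcluster_rejects_bad_distance_matrices():
    with pytest.raises(ValidationError):
        hcluster(np.array([[0, 1.0], [2.0, 0]]), ["a", "b"])
    with pytest.raises(ValidationError):
        hcluster(np.zeros((2, 3)), ["a", "b"])
    with pytest.raises(ValidationError):
        hcluster(np.zeros((3, 3)), ["a", "b", "c"], linkage="single")


def test_dendrogram_member_sets_are_nested():
    rng = np.random.default_rng(31)
    x = rng.standard_normal((10, 4))
    dist = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
    np.fill_diagonal(dist, 0.0)
    sets = hcluster(dist, [str(i) for i in range(10)]).cluster_sets()
    for a, b in itertools.combinations(sets, 2):
        inter = a & b
        assert inter in (frozenset(), a, b)


# -------------------------------------------------------------- bootstrap

BLOCK_A = frozenset(f"a{i}" for i in range(6))
BLOCK_B = frozenset(f"b{i}" for i in range(6))


def test_bootstrap_stable_clusters_reach_unit_support(block_screen):
    """Clusters present in every replicate at every scale get bp == 1, p = 0."""
    supports = multiscale_bootstrap(block_screen, B=100, seed=9)
    by_set = {s.members: s for s in supports}
    for planted in (BLOCK_A, BLOCK_B):
        assert planted in by_set
        assert np.all(by_set[planted].bp == 1.0)
        assert by_set[planted].p_value == 0.0
    root = by_set[BLOCK_A | BLOCK_B]
    assert np.all(root.bp == 1.0) and root.p_value == 0.0


def test_bootstrap_is_deterministic_under_fixed_seed(small_sim):
    _, screen, _ = small_sim
    a = multiscale_bootstrap(screen, B=40, seed=123)
    b = multiscale_bootstrap(screen, B=40, seed=123)
    for sa, sb in zip(a, b):
        assert sa.members == sb.members
        np.testing.assert_array_equal(sa.hits, sb.hits)
        np.testing.assert_array_equal(sa.trials, sb.trials)


def test_bootstrap_counts_and_scales_are_well_formed(small_sim):
    _, screen, _ = small_sim
    supports = multiscale_bootstrap(screen, B=30, seed=4)
    assert len(supports) == screen.n_genes - 1  # one per internal node
    for s in supports:
        np.testing.assert_array_equal(s.scales, np.asarray(DEFAULT_SCALES))
        assert np.all(s.hits <= s.trials)
        assert np.all((s.bp >= 0) & (s.bp <= 1))
    with pytest.raises(ValidationError):
        multiscale_bootstrap(screen, B=0, seed=1)


# ---------------------------------------------------------- AU regression


def _support(bp, trials=1000, scales=None):
    scales = np.asarray(scales if scales is not None else DEFAULT_SCALES, dtype=float)
    bp = np.asarray(bp, dtype=float)
    return ClusterSupport(
        members=frozenset({"a", "b"}),
        scales=scales,
        hits=np.round(bp * trials),
        trials=np.full(scales.size, trials, dtype=float),
    )


def test_au_half_support_everywhere_gives_half_pvalue():
    sup = au_pvalue(_support(np.full(10, 0.5)))
    assert sup.v == pytest.approx(0.0, abs=1e-12)
    assert sup.c == pytest.approx(0.0, abs=1e-12)
    assert sup.au == pytest.approx(0.5)
    assert sup.p_value == pytest.approx(0.5)


def test_au_degenerate_supports_use_documented_fallbacks():
    assert au_pvalue(_support(np.ones(10))).p_value == 0.0
    assert au_pvalue(_support(np.zeros(10))).p_value == 1.0
    # fewer than two usable scales: fall back to BP at the scale nearest 1
    bp = np.zeros(10)
    bp[5] = 0.8  # scale 1.0
    sup = au_pvalue(_support(bp))
    assert sup.p_value == pytest.approx(1 - 0.8)


def test_au_rewards_support_rising_with_scale():
    rising = au_pvalue(_support([0.85, 0.88, 0.91, 0.93, 0.95, 0.96, 0.97, 0.98, 0.985, 0.99]))
    flat = au_pvalue(_support(np.full(10, 0.95)))
    assert rising.p_value < 0.01  # strong cluster under the scaling law
    assert rising.p_value < flat.p_value
    assert rising.c > 0  # positive curvature drives the AU > BP correction


def test_au_regression_recovers_planted_curve_parameters():
    from scipy import stats as st

    rng = np.random.default_rng(77)
    v_true, c_true = 1.2, 0.4
    scales = np.asarray(DEFAULT_SCALES)
    B = 10000
    bp_expected = 1 - st.norm.cdf(v_true * np.sqrt(scales) + c_true / np.sqrt(scales))
    hits = rng.binomial(B, bp_expected)
    sup = ClusterSupport(
        members=frozenset({"a"}),
        scales=scales,
        hits=hits.astype(float),
        trials=np.full(scales.size, B, dtype=float),
    )
    sup = au_pvalue(sup)
    assert sup.v == pytest.approx(v_true, abs=0.1)
    assert sup.c == pytest.approx(c_true, abs=0.1)
    assert sup.au == pytest.approx(1 - st.norm.cdf(v_true - c_true), abs=0.02)


# ---------------------------------------------------------------- filters


def _manual_support(members, p):
    sup = ClusterSupport(
        members=frozenset(members),
        scales=np.asarray(DEFAULT_SCALES),
        hits=np.zeros(10),
        trials=np.full(10, 100.0),
    )
    sup.p_value = p
    return sup


def _toy_pan():
    graph = nx.Graph()
    for g in "abcde":
        graph.add_node(g, mean_phenotype=1.0)
    for g in "fghij":
        graph.add_node(g, mean_phenotype=-1.0)
    for u, v in itertools.combinations("abcde", 2):
        graph.add_edge(u, v, sign="+", snr=20.0)
    return PAN(graph, cutoff=10.0)


def test_filter_predicates_are_sharp():
    pan = _toy_pan()
    supports = [
        _manual_support("abcde", 0.01),  # passes everything
        _manual_support("abcd", 0.001),  # too small (4 < 5)
        _manual_support("fghij", 0.06),  # p over threshold (and density 0)
        _manual_support("abcdef", 0.01),  # too big (6 > 0.5 * 10)
    ]
    mods = filter_modules(supports, pan, density_min=0.5)
    assert [m.genes for m in mods] == [frozenset("abcde")]
    assert mods[0].density == 1.0 and mods[0].mean_effect == pytest.approx(1.0)
    # density filter alone removes the significant-but-sparse cluster
    sparse = filter_modules([_manual_support("fghij", 0.01)], pan, density_min=0.5)
    assert sparse == []


def test_filter_effect_sign_and_config_validation():
    pan = _toy_pan()
    pos = _manual_support("abcde", 0.01)
    neg = _manual_support("fghij", 0.01)
    kept = filter_modules([pos, neg], pan, density_min=0.0, effect_sign="positive")
    assert [m.genes for m in kept] == [frozenset("abcde")]
    kept = filter_modules([pos, neg], pan, density_min=0.0, effect_sign="negative")
    assert [m.genes for m in kept] == [frozenset("fghij")]
    with pytest.raises(ConfigurationError):
        filter_modules([pos], pan, min_size=1)
    with pytest.raises(ConfigurationError):
        filter_modules([pos], pan, effect_sign="both")


def test_filter_nesting_links_and_order_invariance():
    pan = _toy_pan()
    supports = [
        _manual_support("abcde", 0.01),
        _manual_support("abc", 0.02),
        _manual_support("ab", 0.03),
        _manual_support("fgh", 0.01),
    ]
    mods = filter_modules(supports, pan, min_size=2, density_min=0.0)
    by_set = {m.genes: m for m in mods}
    child = by_set[frozenset("ab")]
    middle = by_set[frozenset("abc")]
    top = by_set[frozenset("abcde")]
    assert mods[child.parent] is middle  # smallest strictly-enclosing survivor
    assert mods[middle.parent] is top
    assert top.parent is None and by_set[frozenset("fgh")].parent is None
    rev = filter_modules(list(reversed(supports)), pan, min_size=2, density_min=0.0)
    assert {m.genes for m in rev} == {m.genes for m in mods}
    frame = modules_frame(mods)
    assert set(frame.columns) == {
        "module", "genes", "n_genes", "p_value", "density", "mean_effect", "parent"
    }


def test_end_to_end_planted_blocks_survive_all_filters(block_screen):
    """Full pipeline on a clean two-block screen keeps exactly the blocks."""
    rng = np.random.default_rng(11)
    assoc = cosine_matrix(block_screen)
    null = fit_null(permute_screen(block_screen, 3, rng, mode="per_column"))
    res = fit_map(assoc, null, tol=1e-4, max_iter=200)
    pan = res.infer_network(block_screen, cutoff=10.0)
    supports = multiscale_bootstrap(block_screen, B=100, seed=3)
    mods = filter_modules(supports, pan, min_size=5, max_frac=0.5, density_min=0.5)
    got = {m.genes for m in mods}
    assert BLOCK_A in got and BLOCK_B in got
    by_set = {m.genes: m for m in mods}
    assert by_set[BLOCK_A].mean_effect > 0 > by_set[BLOCK_B].mean_effect
    positive_only = filter_modules(
        supports, pan, min_size=5, max_frac=0.5, density_min=0.5, effect_sign="positive"
    )
    assert {m.genes for m in positive_only} == {BLOCK_A}
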