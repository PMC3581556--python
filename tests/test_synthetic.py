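import numpy as np
import pytest
from scipy import stats

from middomain.grid import build_presence_matrix
from middomain.synthetic import (
    SyntheticConfig,
    assign_guilds,
    bm_traits,
    make_domain,
    make_world,
    phylo_preferred_rows,
    sample_range_sizes,
    structured_ranges,
    yule_tree,
)


class TestMakeDomain:
    def test_full_rectangle(self):
        dom = make_domain(5, 4)
        assert dom.n_cells == 20

    def test_linear_domain(self):
        dom = make_domain(1, 21)
        assert dom.n_cells == 21 and dom.n_rows == 1

    def test_masked_domain_connected(self):
        rng = np.random.default_rng(0)
        dom = make_domain(10, 10, mask_fraction=0.6, rng=rng)
        assert dom.n_cells == 60
        assert dom.is_connected()

    def test_bad_args(self):
        with pytest.raises(ValueError):
            make_domain(0, 3)
        with pytest.raises(ValueError):
            make_domain(3, 3, mask_fraction=0.0)


class TestYuleTree:
    def test_two_tips_cherry(self):
        tree = yule_tree(2, 1.0, np.random.default_rng(0))
        assert tree.n_tips == 2
        assert tree.tip_depths[0] == pytest.approx(tree.tip_depths[1])

    def test_binary_internal_count(self):
        tree = yule_tree(50, 1.0, np.random.default_rng(1))
        internals = sum(1 for nd in tree.tree.preorder_node_iter() if not nd.is_leaf())
        assert internals == 49

    def test_ultrametric(self):
        tree = yule_tree(30, 2.0, np.random.default_rng(2))
        assert tree.is_ultrametric(tol=1e-9)

    def test_labels_unique(self):
        tree = yule_tree(20, 1.0, np.random.default_rng(3))
        assert len(set(tree.tips)) == 20


class TestBMTraits:
    def test_zero_rate_identical(self):
        tree = yule_tree(10, 1.0, np.random.default_rng(0))
        traits = bm_traits(tree, np.random.default_rng(1), n_traits=3, rate=0.0)
        assert np.allclose(traits.frame.std(axis=0), 0.0)

    def test_cherry_difference_variance(self):
        """Tip difference on a two-tip tree has variance 2 * rate * depth."""
        rng = np.random.default_rng(2)
        tree = yule_tree(2, 1.0, rng)
        depth = float(tree.tip_depths[0])
        rate = 0.5
        diffs = []
        for _ in range(4000):
            tm = bm_traits(tree, rng, n_traits=1, rate=rate)
            diffs.append(float(tm.frame.iloc[0, 0] - tm.frame.iloc[1, 0]))
        assert np.var(diffs) == pytest.approx(2 * rate * depth, rel=0.1)

    def test_phylogenetic_signal(self):
        """Sister tips are on average more similar than random tip pairs."""
        rng = np.random.default_rng(3)
        sister_d, random_d = [], []
        for _ in range(60):
            tree = yule_tree(12, 1.0, rng)
            tm = bm_traits(tree, rng, n_traits=1, rate=1.0)
            vals = tm.frame["t1"]
            for nd in tree.tree.preorder_node_iter():
                kids = nd.child_nodes()
                if len(kids) == 2 and all(k.is_leaf() for k in kids):
                    a, b = (k.taxon.label for k in kids)
                    sister_d.append(abs(vals[a] - vals[b]))
            tips = list(tree.tips)
            for _ in range(5):
                a, b = rng.choice(tips, 2, replace=False)
                random_d.append(abs(vals[a] - vals[b]))
        assert np.mean(sister_d) < np.mean(random_d)


class TestGuilds:
    def test_single_guild(self):
        tree = yule_tree(5, 1.0, np.random.default_rng(0))
        guilds = assign_guilds(tree, np.random.default_rng(1), n_guilds=1)
        assert set(guilds.assignments.values()) == {guilds.vocabulary[0]}

    def test_multinomial_frequencies(self):
        tree = yule_tree(600, 1.0, np.random.default_rng(2))
        # 10 independent assignments of 600 species each: 6000 draws total
        counts = np.zeros(6)
        for k in range(10):
            g = assign_guilds(tree, np.random.default_rng(10 + k), n_guilds=6)
            for lab in g.assignments.values():
                counts[g.vocabulary.index(lab)] += 1
        freq = counts / counts.sum()
        assert np.all(np.abs(freq - 1 / 6) < 0.02)

    def test_clade_conserved_monophyletic(self):
        tree = yule_tree(20, 1.0, np.random.default_rng(3))
        guilds = assign_guilds(tree, np.random.default_rng(4), n_guilds=4, scheme="clade-conserved")
        # each guild's tips form a connected (monophyletic) group: the MRCA
        # of the guild contains no other guild's tips
        for lab in set(guilds.assignments.values()):
            members = [sp for sp, g in guilds.assignments.items() if g == lab]
            mrca = tree.tree.mrca(taxon_labels=members)
            under = {lf.taxon.label for lf in mrca.leaf_iter()}
            assert under == set(members)

    def test_too_many_clades_errors(self):
        tree = yule_tree(3, 1.0, np.random.default_rng(5))
        with pytest.raises(ValueError):
            assign_guilds(tree, np.random.default_rng(6), n_guilds=5, scheme="clade-conserved")


class TestStructuredRanges:
    def test_zero_strength_uniform_seed_rows(self):
        """At strength 0 the placement reduces to the null model: single-cell
        ranges land uniformly over rows (KS test, alpha = 0.01)."""
        dom = make_domain(20, 5)
        rng = np.random.default_rng(0)
        rows = []
        for k in range(4000):
            rs = structured_ranges(dom, {"s": 1}, 0.0, rng)
            (cell,) = rs.ranges["s"]
            rows.append(dom.rows[cell])
        # discrete uniform over 20 rows: chi-square goodness of fit
        obs = np.bincount(rows, minlength=20)
        p = stats.chisquare(obs).pvalue
        assert p > 0.01

    def test_high_strength_confines_rows(self):
        dom = make_domain(30, 6)
        rng = np.random.default_rng(1)
        sizes = {f"s{i}": 12 for i in range(20)}
        tight = structured_ranges(dom, sizes, 10.0, rng)
        loose = structured_ranges(dom, sizes, 0.0, rng)
        spread_of = lambda rs: np.mean(
            [np.ptp([dom.rows[c] for c in cells]) for cells in rs.ranges.values()]
        )
        assert spread_of(tight) < spread_of(loose)

    def test_sizes_and_connectivity(self):
        dom = make_domain(12, 6)
        rng = np.random.default_rng(2)
        sizes = {"a": 5, "b": 20, "c": 36}
        rs = structured_ranges(dom, sizes, 2.0, rng)
        assert rs.sizes() == sizes
        for cells in rs.ranges.values():
            assert dom.is_connected(cells)

    def test_phylo_preferred_rows_cover_domain(self):
        tree = yule_tree(30, 1.0, np.random.default_rng(3))
        dom = make_domain(15, 4)
        rows = phylo_preferred_rows(tree, dom, np.random.default_rng(4))
        assert set(rows) == set(tree.tips)
        assert min(rows.values()) == 0 and max(rows.values()) == 14


class TestMakeWorld:
    def test_seed_determinism(self):
        w1 = make_world(SyntheticConfig(n_rows=6, n_cols=5, n_species=12, rng_seed=9))
        w2 = make_world(SyntheticConfig(n_rows=6, n_cols=5, n_species=12, rng_seed=9))
        assert w1.ranges.ranges == w2.ranges.ranges
        assert w1.traits.frame.equals(w2.traits.frame)
        assert w1.guilds.assignments == w2.guilds.assignments

    def test_all_parts_cross_resolvable(self):
        w = make_world(SyntheticConfig(n_rows=6, n_cols=5, n_species=15, rng_seed=1))
        pm = build_presence_matrix(w.ranges, w.domain)
        assert set(pm.species) == set(w.tree.tips) == set(w.guilds.species) == set(w.traits.species)

    def test_size_distribution_respected(self):
        rng = np.random.default_rng(0)
        sizes = sample_range_sizes(500, 800, rng, median_fraction=0.35, log_sd=0.7)
        vals = np.array(list(sizes.values()))
        assert vals.min() >= 1 and vals.max() <= 800
        assert 0.2 * 800 < np.median(vals) < 0.55 * 800
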