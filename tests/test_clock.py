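"""Dating machinery: rho/sigma, clock conversion, pruning likelihood vs
closed forms and exhaustive summation, clock-constrained ML, BIC, consensus."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitofounder.clock import (
    AgeEstimate,
    BicEntry,
    ClockModel,
    ClockNode,
    ConsensusInterval,
    PartitionScheme,
    RhoResult,
    SubstitutionModel,
    YEARS_PER_SUBSTITUTION,
    bic_select,
    consensus_interval,
    fit_clock_heights,
    jc69,
    load_correction_table,
    ml_age,
    rho_age,
    rho_sigma,
    tree_loglik,
)
from mitofounder.haplotree import ParsimonyTree, TreeNode, build_mp_tree
from mitofounder.mito_io import ReferenceGenome, ValidationError, Variant, VariantProfile


def leaf(name, n_mut, multiplicity=1):
    return TreeNode(
        name=name,
        edge_variants=tuple((100 + i, "A", "G") for i in range(n_mut)),
        sample_ids=tuple(f"{name}.{k}" for k in range(multiplicity)),
    )


def star_tree(mut_counts):
    root = TreeNode(name="root")
    root.children = [leaf(f"t{i}", m) for i, m in enumerate(mut_counts)]
    return ParsimonyTree(root)


class TestRhoSigma:
    def test_star_example(self):
        r = rho_sigma(star_tree([2, 2, 3, 1]))
        assert r.rho == pytest.approx(2.0)
        assert r.sigma**2 == pytest.approx(0.5)

    def test_all_tips_at_root(self):
        r = rho_sigma(star_tree([0, 0, 0]))
        assert r.rho == 0 and r.sigma == 0

    def test_caterpillar_example(self):
        # haplotypes {769}, {769,1000}, {769,2000} rooted at {}
        ps = [
            VariantProfile("s1", (Variant(769, "A", "G"),)),
            VariantProfile("s2", (Variant(769, "A", "G"), Variant(1000, "A", "G"))),
            VariantProfile("s3", (Variant(769, "A", "G"), Variant(2000, "A", "G"))),
        ]
        r = rho_sigma(build_mp_tree(ps))
        assert r.rho == pytest.approx(5 / 3)
        assert r.sigma**2 == pytest.approx(11 / 9)

    def test_star_identity_holds_exactly(self, rng):
        """sigma^2 == rho/n whenever every edge subtends a single tip."""
        for _ in range(50):
            counts = rng.poisson(5.0, size=rng.integers(2, 30))
            r = rho_sigma(star_tree(list(counts)))
            assert abs(r.sigma**2 - r.rho / r.n) < 1e-9

    def test_matches_path_walking_oracle(self, rng):
        """rho equals the mean root->tip path length computed independently,
        on random multifurcating mutation-labelled trees."""
        for trial in range(40):
            tree = _random_mutation_tree(rng)
            r = rho_sigma(tree)
            paths = _tip_path_lengths(tree.root, 0)
            assert r.rho == pytest.approx(np.mean(paths))
            assert r.n == len(paths)

    def test_multiplicity_honoured(self):
        root = TreeNode(name="root")
        root.children = [leaf("a", 2, multiplicity=3), leaf("b", 0, multiplicity=1)]
        r = rho_sigma(ParsimonyTree(root))
        assert r.n == 4
        assert r.rho == pytest.approx(6 / 4)

    def test_empty_clade_rejected(self):
        with pytest.raises(ValidationError):
            rho_sigma(ParsimonyTree(TreeNode(name="root")))


class TestClockConversion:
    def test_one_substitution_is_3624_years(self):
        est = rho_age(RhoResult("c", 10, 1.0, 0.0))
        assert est.age_years == pytest.approx(3624.0)

    def test_zero_rho(self):
        est = rho_age(RhoResult("c", 10, 0.0, 0.5))
        assert est.age_years == 0.0
        assert est.ci_low_years == 0.0
        assert est.ci_high_years == pytest.approx(1.96 * 0.5 * 3624)

    def test_ci_arithmetic(self):
        est = rho_age(RhoResult("c", 10, 2.0, 0.5))
        assert est.age_years == pytest.approx(2 * 3624)
        assert est.ci_low_years == pytest.approx((2 - 0.98) * 3624)
        assert est.ci_high_years == pytest.approx((2 + 0.98) * 3624)

    def test_correction_table(self, tmp_path):
        p = tmp_path / "corr.tsv"
        p.write_text("1\t5000\n2\t9000\n")
        clock = load_correction_table(p)
        assert clock.to_years(0) == 0
        assert clock.to_years(1) == pytest.approx(5000)
        assert clock.to_years(1.5) == pytest.approx(7000)
        # monotone nondecreasing on a grid
        xs = np.linspace(0, 3, 50)
        ys = [clock.to_years(x) for x in xs]
        assert all(b >= a for a, b in zip(ys, ys[1:]))

    def test_nonmonotone_table_rejected(self):
        with pytest.raises(ValidationError):
            ClockModel(correction_table=((1.0, 5000.0), (2.0, 4000.0)))


class TestSubstitutionModel:
    def test_rate_matrix_normalised(self):
        m = SubstitutionModel("TN93", (0.31, 0.31, 0.13, 0.25), 20, 18, 1)
        Q = m.rate_matrix
        pi = np.array(m.base_frequencies)
        assert np.allclose(Q.sum(axis=1), 0)
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_stationarity(self):
        m = SubstitutionModel("HKY85", (0.4, 0.2, 0.2, 0.2), 5, 5, 1)
        P = m.transition_probabilities(1000.0)
        for row in P:
            assert np.allclose(row, m.base_frequencies, atol=1e-6)

    def test_gamma_category_rates_mean_one(self):
        for shape in (0.2, 1.0, 5.0):
            m = jc69(gamma_shape=shape, n_categories=32)
            assert m.category_rates.mean() == pytest.approx(1.0, abs=1e-9)
            assert (np.diff(m.category_rates) > 0).all()

    def test_g6_mirror(self):
        m = jc69(gamma_shape=0.5, n_categories=6)
        assert len(m.category_rates) == 6


def two_tip(h):
    return ClockNode("r", [ClockNode("a"), ClockNode("b")], height=h)


class TestTreeLoglik:
    def test_identical_sequences_zero_heights(self):
        m = jc69()
        ll = tree_loglik({"a": "ACGT", "b": "ACGT"}, two_tip(0.0), m)
        assert ll == pytest.approx(4 * math.log(0.25))

    def test_jc69_closed_form_single_branch(self):
        m = jc69()
        h = 0.07
        t = 2 * h  # tip-to-tip distance through the root
        ll_match = tree_loglik({"a": "A", "b": "A"}, two_tip(h), m)
        assert ll_match == pytest.approx(
            math.log(0.25 * (0.25 + 0.75 * math.exp(-4 * t / 3)))
        )
        ll_mismatch = tree_loglik({"a": "A", "b": "C"}, two_tip(h), m)
        assert ll_mismatch == pytest.approx(
            math.log(0.25 * (0.25 - 0.25 * math.exp(-4 * t / 3)))
        )

    def test_matches_exhaustive_summation_four_tips(self, rng):
        """Pruning equals brute-force summation over all ancestral states on a
        4-tip tree, with TN93 + discrete gamma."""
        m = SubstitutionModel("TN93", (0.31, 0.31, 0.13, 0.25), 8, 4, 1,
                              gamma_shape=0.7, n_categories=4)
        x = ClockNode("x", [ClockNode("a"), ClockNode("b")], height=0.05)
        y = ClockNode("y", [ClockNode("c"), ClockNode("d")], height=0.11)
        root = ClockNode("r", [x, y], height=0.2)
        seqs = {n: "".join(rng.choice(list("ACGT"), size=5)) for n in "abcd"}
        ll = tree_loglik(seqs, root, m)
        assert ll == pytest.approx(_brute_force_loglik(seqs, m), rel=1e-9)

    def test_invariant_to_tip_reordering(self, rng):
        m = SubstitutionModel("HKY85", (0.3, 0.3, 0.2, 0.2), 4, 4, 1)
        x = ClockNode("x", [ClockNode("a"), ClockNode("b")], height=0.03)
        root = ClockNode("r", [x, ClockNode("c")], height=0.09)
        seqs = {"a": "ACGTAC", "b": "ACGTAA", "c": "GCGTAC"}
        ll1 = tree_loglik(seqs, root, m)
        x.children.reverse()
        root.children.reverse()
        ll2 = tree_loglik(seqs, root, m)
        assert ll1 == pytest.approx(ll2)

    def test_single_gamma_category_equals_no_gamma(self):
        seqs = {"a": "ACGTTGCA", "b": "ACGTTGCC"}
        ll_plain = tree_loglik(seqs, two_tip(0.04), jc69())
        ll_1cat = tree_loglik(seqs, two_tip(0.04), jc69(gamma_shape=1.0, n_categories=1))
        assert ll_plain == pytest.approx(ll_1cat)

    def test_invariant_sites_mixture(self):
        """p_inv splits the likelihood into invariant and variable classes."""
        m = jc69(p_invariant=0.3)
        h = 0.05
        t = 2 * h / (1 - 0.3)  # variable-class rate is rescaled to keep mean 1
        expect = math.log(
            0.3 * 0.25 + 0.7 * 0.25 * (0.25 + 0.75 * math.exp(-4 * t / 3))
        )
        ll = tree_loglik({"a": "A", "b": "A"}, two_tip(h), m)
        assert ll == pytest.approx(expect)

    def test_partitioned_logliks_add(self):
        seqs = {"a": "AAAACCCC", "b": "AAAACCCG"}
        parts = PartitionScheme((("p1", frozenset(range(1, 5))),
                                 ("p2", frozenset(range(5, 9)))))
        m = jc69()
        ll_joint = tree_loglik(seqs, two_tip(0.02), m, parts)
        ll_split = (tree_loglik({k: v[:4] for k, v in seqs.items()}, two_tip(0.02), m)
                    + tree_loglik({k: v[4:] for k, v in seqs.items()}, two_tip(0.02), m))
        assert ll_joint == pytest.approx(ll_split)


class TestFitClockHeights:
    def test_two_sequence_closed_form(self):
        L, k = 300, 30
        seqs = {"a": "A" * L, "b": "C" * k + "A" * (L - k)}
        fit = fit_clock_heights(seqs, two_tip(0.0), jc69())
        p = k / L
        d = -0.75 * math.log(1 - 4 * p / 3)
        assert fit.converged
        assert fit.tree.height == pytest.approx(d / 2, rel=1e-4)

    def test_identical_sequences_zero_heights(self):
        seqs = {"a": "ACGT" * 30, "b": "ACGT" * 30}
        fit = fit_clock_heights(seqs, two_tip(0.1), jc69())
        assert fit.tree.height == pytest.approx(0.0, abs=1e-6)

    def test_recovers_simulated_star_age(self):
        """Mean ML age over simulated star clades is within 2 Monte-Carlo
        standard errors of the true TMRCA, and relative bias is small."""
        from mitofounder.synthetic_data import (
            simulate_sequences, star_genealogy, synthetic_reference,
        )
        import mitofounder.clock as clk
        from mitofounder.mito_io import apply_mask, call_variants

        ref = synthetic_reference()
        T = 50_000.0
        ages = []
        for i in range(12):
            clade = simulate_sequences(star_genealogy(8, T), ref, seed=100 + i)
            m = SubstitutionModel(
                "TN93", base_frequencies=clk._empirical_frequencies(clade.sequences))
            profiles = [apply_mask(call_variants(s, ref, sample_id=n))
                        for n, s in clade.sequences.items()]
            tree = build_mp_tree(profiles)
            fit = fit_clock_heights(clade.sequences, tree, m,
                                    exclude_positions={16182, 16183, 16519}, seed=i)
            ages.append(fit.tree.height * 16569 * YEARS_PER_SUBSTITUTION)
        mean_age = np.mean(ages)
        mc_se = np.std(ages, ddof=1) / math.sqrt(len(ages))
        assert abs(mean_age - T) < 2 * mc_se + 0.05 * T
        assert abs(mean_age - T) / T < 0.1


class TestMlAge:
    def test_zero_height_zero_age(self):
        seqs = {"a": "ACGT" * 40, "b": "ACGT" * 40}
        fit = fit_clock_heights(seqs, two_tip(0.05), jc69())
        est = ml_age(fit, genome_length=160)
        assert est.age_years == pytest.approx(0.0, abs=1.0)

    def test_clock_constant_through_height(self):
        clock = ClockModel()
        # height such that height * L = 1 substitution
        assert clock.to_years(1.0) == pytest.approx(3624.0)

    def test_profile_ci_matches_grid_search(self):
        """2-tip toy: profile CI endpoints agree with a direct grid search of
        the log-likelihood curve within 1%."""
        L, k = 500, 25
        seqs = {"a": "A" * L, "b": "C" * k + "A" * (L - k)}
        m = jc69()
        fit = fit_clock_heights(seqs, two_tip(0.0), m)
        est = ml_age(fit, genome_length=L)
        assert not est.flagged
        # grid search: loglik as a function of height alone (no nuisances)
        hs = np.linspace(1e-5, 0.2, 4000)
        lls = np.array([tree_loglik(seqs, two_tip(h), m) for h in hs])
        keep = lls >= lls.max() - 1.92
        lo = hs[keep][0] * L * YEARS_PER_SUBSTITUTION / 1  # height->years
        hi = hs[keep][-1] * L * YEARS_PER_SUBSTITUTION
        assert est.ci_low_years == pytest.approx(lo, rel=0.01)
        assert est.ci_high_years == pytest.approx(hi, rel=0.01)


class TestBicSelect:
    def test_single_candidate_rank_one(self):
        seqs = {"a": "ACGTACGT" * 5, "b": "ACGTACGA" * 5}
        entries = bic_select(seqs, two_tip(0.0), [("JC69", False, False)])
        assert len(entries) == 1 and entries[0].kind == "JC69"

    def test_penalty_orders_nested_models(self):
        """With near-identical max likelihoods the smaller model wins BIC."""
        seqs = {"a": "ACGT" * 25, "b": "ACGT" * 25}  # identical: lnL equal at h=0
        entries = bic_select(seqs, two_tip(0.0),
                             [("JC69", False, False), ("K80", False, False)])
        assert entries[0].kind == "JC69"
        assert entries[0].bic < entries[1].bic

    def test_jc_data_prefers_jc(self, rng):
        """Data simulated under JC69: BIC picks JC69 over TN93 in >=90% of
        small replicates."""
        from mitofounder.synthetic_data import simulate_sequences, star_genealogy

        wins = 0
        n_rep = 50
        for i in range(n_rep):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            ref = ReferenceGenome("toy", seq)
            clade = simulate_sequences(star_genealogy(3, 40_000.0), ref,
                                       model=jc69(), hotspot_positions=set(), seed=i)
            top = ClockNode("r", [ClockNode(n) for n in clade.sequences])
            entries = bic_select(clade.sequences, top,
                                 [("JC69", False, False), ("TN93", False, False)])
            wins += entries[0].kind == "JC69"
        assert wins >= 0.9 * n_rep


class TestConsensus:
    def test_overlap(self):
        a = AgeEstimate("c", "rho", 65, 60, 70)
        b = AgeEstimate("c", "ml", 68, 63, 73)
        ci = consensus_interval([a, b])
        assert (ci.low, ci.high, ci.empty) == (63, 70, False)

    def test_idempotent(self):
        a = AgeEstimate("c", "rho", 65, 60, 70)
        ci = consensus_interval([a, a])
        assert (ci.low, ci.high) == (60, 70) and not ci.empty

    def test_disjoint_flagged(self):
        a = AgeEstimate("c", "rho", 15, 10, 20)
        b = AgeEstimate("c", "ml", 35, 30, 40)
        assert consensus_interval([a, b]).empty

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(st.floats(0, 100), st.floats(0, 100)).map(
                lambda t: AgeEstimate("c", "rho", (min(t) + max(t)) / 2, min(t), max(t))
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_commutative_associative(self, ests):
        ci1 = consensus_interval(ests)
        ci2 = consensus_interval(list(reversed(ests)))
        assert (ci1.low, ci1.high, ci1.empty) == (ci2.low, ci2.high, ci2.empty)
        if len(ests) > 2 and not ci1.empty:
            # fold pairwise: intersecting intermediate results is associative
            left = consensus_interval(ests[:2])
            folded = ConsensusInterval(
                max(left.low, min(e.ci_low_years for e in ests[2:])), ci1.high, False
            )
            assert ci1.low == max(e.ci_low_years for e in ests)


# ---------------------------------------------------------------------------
# helpers


def _random_mutation_tree(rng):
    counter = itertools.count()

    def grow(depth):
        node = TreeNode(
            name=f"n{next(counter)}",
            edge_variants=tuple((int(p), "A", "G")
                                for p in rng.choice(16000, size=rng.poisson(2)) + 1),
        )
        if depth >= 3 or rng.random() < 0.4:
            node.sample_ids = tuple(f"{node.name}.{k}"
                                    for k in range(rng.integers(1, 4)))
            return node
        for _ in range(rng.integers(2, 4)):
            node.children.append(grow(depth + 1))
        return node

    root = TreeNode(name="root")
    for _ in range(rng.integers(2, 4)):
        root.children.append(grow(1))
    return ParsimonyTree(root)


def _tip_path_lengths(root, acc):
    out = []

    def rec(node, acc):
        acc = acc + len(node.edge_variants)
        if node.is_tip:
            out.extend([acc] * len(node.sample_ids))
        for c in node.children:
            rec(c, acc)

    for c in root.children:
        rec(c, 0)
    return out


def _brute_force_loglik(seqs, model):
    """Exhaustive summation over ancestral states for the fixed 4-tip tree
    ((a,b)x,(c,d)y)r with heights x=0.05, y=0.11, r=0.2."""
    pi = np.array(model.base_frequencies)
    rates = model.category_rates
    hx, hy, hr = 0.05, 0.11, 0.2
    names = ["a", "b", "c", "d"]
    L = len(seqs["a"])
    enc = {b: i for i, b in enumerate("ACGT")}
    total = 0.0
    for site in range(L):
        obs = [enc[seqs[n][site]] for n in names]
        site_lik = 0.0
        for rate in rates:
            Pr_x = model.transition_probabilities((hr - hx) * rate)
            Pr_y = model.transition_probabilities((hr - hy) * rate)
            Px = model.transition_probabilities(hx * rate)
            Py = model.transition_probabilities(hy * rate)
            s = 0.0
            for r in range(4):
                for x in range(4):
                    for y in range(4):
                        s += (pi[r] * Pr_x[r, x] * Pr_y[r, y]
                              * Px[x, obs[0]] * Px[x, obs[1]]
                              * Py[y, obs[2]] * Py[y, obs[3]])
            site_lik += s / len(rates)
        total += math.log(site_lik)
    return total
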