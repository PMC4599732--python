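"""Signature splitting, contrast signatures, multi-signature queries, iteration."""

import numpy as np
import pytest

from sigrefine import (
    GeneSignature,
    GeneUniverse,
    IterationSpec,
    RankedList,
    RefinementConfig,
    ValidationError,
    average_ncs,
    classify_by_sign,
    combined_query,
    contrast_signature,
    make_optimal_signature,
    run_iterations,
    split_signature,
)


def perm_list(id, universe, rng):
    genes = np.asarray(universe.genes, dtype=object)
    return RankedList(id, universe, tuple(genes[rng.permutation(len(genes))]))


class TestConfig:
    def test_invalid_percentile_windows_rejected(self):
        with pytest.raises(ValidationError):
            RefinementConfig(hi_percentile=0.3, lo_percentile=0.7)
        with pytest.raises(ValidationError):
            RefinementConfig(min_support=0)
        with pytest.raises(ValidationError):
            RefinementConfig(contrast_quantile=0.6)


class TestSplitSignature:
    def test_agreeing_confounders_leave_signature_intact(self, make_universe):
        u = make_universe(20)
        seed_prl = RankedList("seed", u, u.genes)
        sig = make_optimal_signature(seed_prl, k=5)
        cons, inc = split_signature(sig, [seed_prl, seed_prl], RefinementConfig())
        assert not inc.up and not inc.down
        assert cons.up == sig.up and cons.down == sig.down

    def test_reversed_confounders_flag_everything(self, make_universe):
        u = make_universe(20)
        seed_prl = RankedList("seed", u, u.genes)
        sig = make_optimal_signature(seed_prl, k=5)  # k/N = 0.25 <= 0.30
        rev = seed_prl.reversed()
        cons, inc = split_signature(sig, [rev, rev], RefinementConfig())
        assert inc.up == sig.up and inc.down == sig.down
        assert not cons.up and not cons.down

    def test_min_support_counting(self):
        # seed: a,b up; i,j down. gene 'a' is pushed down by 2 of 3 confounders.
        genes = ("a", "b", "c", "d", "e", "f", "g", "h", "i", "j")
        u = GeneUniverse(genes)
        sig = GeneSignature("seed", frozenset({"a", "b"}), frozenset({"i", "j"}))

        def with_ranks(id, placements):
            rest = [g for g in genes if g not in placements]
            order = [None] * 10
            for g, r in placements.items():
                order[r - 1] = g
            it = iter(rest)
            order = [g if g is not None else next(it) for g in order]
            return RankedList(id, u, tuple(order))

        confs = [
            with_ranks("c1", {"a": 8, "b": 1, "i": 9, "j": 10}),
            with_ranks("c2", {"a": 9, "b": 2, "i": 10, "j": 8}),
            with_ranks("c3", {"a": 2, "b": 3, "i": 10, "j": 9}),
        ]
        cons, inc = split_signature(sig, confs, RefinementConfig(min_support=2))
        assert inc.up == {"a"}
        assert cons.up == {"b"}
        assert not inc.down and cons.down == {"i", "j"}

    def test_partition_is_exact_on_random_instances(self, make_universe):
        u = make_universe(50)
        rng = np.random.default_rng(0)
        for trial in range(10):
            seed_prl = perm_list("seed", u, rng)
            sig = make_optimal_signature(seed_prl, k=10)
            confs = [perm_list(f"c{i}", u, rng) for i in range(3)]
            cons, inc = split_signature(sig, confs, RefinementConfig())
            assert cons.up | inc.up == sig.up and not cons.up & inc.up
            assert cons.down | inc.down == sig.down and not cons.down & inc.down

    def test_lower_support_never_shrinks_the_inconsistent_set(self, make_universe):
        u = make_universe(50)
        rng = np.random.default_rng(1)
        seed_prl = perm_list("seed", u, rng)
        sig = make_optimal_signature(seed_prl, k=12)
        confs = [perm_list(f"c{i}", u, rng) for i in range(3)]
        prev_up, prev_down = None, None
        for support in (3, 2, 1):
            _, inc = split_signature(sig, confs, RefinementConfig(min_support=support))
            if prev_up is not None:
                assert prev_up <= inc.up and prev_down <= inc.down
            prev_up, prev_down = inc.up, inc.down

    def test_support_exceeding_confounders_rejected(self, make_universe):
        u = make_universe(20)
        prl = RankedList("seed", u, u.genes)
        sig = make_optimal_signature(prl, k=5)
        with pytest.raises(ValidationError, match="min_support"):
            split_signature(sig, [prl], RefinementConfig(min_support=2))


class TestContrastSignature:
    def test_agreeing_opposers_give_empty_signature(self, make_universe):
        u = make_universe(40)
        prl = RankedList("seed", u, u.genes)
        sig = contrast_signature(prl, [prl, prl], RefinementConfig())
        assert not sig.up and not sig.down

    def test_reversed_opposers_capture_the_quantile_tails(self, make_universe):
        u = make_universe(100)
        prl = RankedList("seed", u, u.genes)
        sig = contrast_signature(prl, [prl.reversed()], RefinementConfig())
        assert len(sig.up) == 25 and len(sig.down) == 25
        assert sig.up == set(prl.order[:25])
        assert sig.down == set(prl.order[-25:])

    def test_hand_enumerated_small_instance(self):
        genes = ("a", "b", "c", "d", "e", "f", "g", "h")
        u = GeneUniverse(genes)
        seed = RankedList("seed", u, genes)  # top 2 at q=0.25: a,b; bottom: g,h
        opp = RankedList("o", u, ("g", "c", "d", "e", "f", "h", "b", "a"))
        sig = contrast_signature(seed, [opp], RefinementConfig())
        # a,b sit above the 75% quantile of opp (ranks 8,7); g is top-2 in opp, h is not
        assert sig.up == {"a", "b"}
        assert sig.down == {"g"}

    def test_support_exceeding_opposers_rejected(self, make_universe):
        u = make_universe(20)
        prl = RankedList("seed", u, u.genes)
        with pytest.raises(ValidationError, match="contrast_support"):
            contrast_signature(prl, [prl], RefinementConfig(contrast_support=2))


@pytest.fixture(scope="module")
def planted_compendium():
    """12 drugs over 300 genes with a planted two-block signature.

    The seed signature has a primary block A (up g000-014 / down g285-299)
    and a shared secondary block B (up g015-029 / down g270-284).
    d00-d02 mimic A+B, d03-d04 (the confounders) share B but oppose A,
    d05-d06 reverse everything, d07-d11 are noise.
    """
    u = GeneUniverse(tuple(f"g{i:03d}" for i in range(300)))
    genes = np.asarray(u.genes, dtype=object)
    rng = np.random.default_rng(21)
    a_up, b_up = slice(0, 15), slice(15, 30)
    b_dn, a_dn = slice(270, 285), slice(285, 300)
    prls = {}
    for i in range(12):
        scores = rng.normal(0, 1, 300)
        if i < 3:  # full mimics of the seed response
            scores[a_up] += 5
            scores[b_up] += 5
            scores[a_dn] -= 5
            scores[b_dn] -= 5
        elif i < 5:  # confounders: share the B effect, oppose the A effect
            scores[a_up] -= 5
            scores[b_up] += 5
            scores[a_dn] += 5
            scores[b_dn] -= 5
        elif i < 7:  # full reversers
            scores[a_up] -= 5
            scores[b_up] -= 5
            scores[a_dn] += 5
            scores[b_dn] += 5
        prls[f"d{i:02d}"] = RankedList.from_score_vector(f"d{i:02d}", u, scores)
    sig = GeneSignature(
        "planted", frozenset(genes[:30]), frozenset(genes[-30:])
    )
    return u, sig, prls


class TestCombinedQuery:
    def test_scores_filtering_and_ordering(self, planted_compendium):
        _, sig, prls = planted_compendium
        cfg = RefinementConfig(n_perm=300, signature_k=30)
        res = combined_query([sig], prls, cfg, seed=0)
        mimics = {"d00", "d01", "d02"}
        assert mimics <= set(res.kept)
        assert not {"d05", "d06"} & set(res.kept)  # reversers never kept
        avg = res.table["avg_ncs"].to_numpy()
        assert np.all(np.diff(avg) <= 1e-12)
        # avg NCS is the exact mean of the per-signature NCS columns
        ncs_cols = [c for c in res.table.columns if c.startswith("ncs_")]
        assert np.allclose(res.table["avg_ncs"], res.table[ncs_cols].mean(axis=1))

    def test_kept_requires_every_signature(self, planted_compendium):
        u, sig, prls = planted_compendium
        genes = np.asarray(u.genes, dtype=object)
        # second signature orthogonal to the planted one: mimics fail it
        other = GeneSignature("other", frozenset(genes[100:120]), frozenset(genes[150:170]))
        cfg = RefinementConfig(n_perm=300, signature_k=30)
        both = combined_query([sig, other], prls, cfg, seed=0)
        assert len(both.kept) == 0

    def test_exclusions_removed_from_output(self, planted_compendium):
        _, sig, prls = planted_compendium
        cfg = RefinementConfig(n_perm=300, signature_k=30)
        res = combined_query([sig], prls, cfg, seed=0, exclude=["d00"])
        assert "d00" not in res.table.index


class TestAverageNcsAndClassification:
    def test_constant_scores_average_to_themselves(self):
        assert average_ncs([1.6, 1.6, 1.6]) == pytest.approx(1.6)

    @pytest.mark.parametrize(
        "ncs,label",
        [(1.14, "stabiliser"), (-1.63, "destabiliser"), (0.0, "neutral")],
    )
    def test_sign_rule(self, ncs, label):
        assert classify_by_sign(ncs) == label


class TestRunIterations:
    def test_zero_iterations_is_the_plain_seed_query(self, planted_compendium):
        _, _, prls = planted_compendium
        cfg = RefinementConfig(n_perm=300, signature_k=30)
        run = run_iterations("d00", prls, [], cfg, seed=0)
        sig = make_optimal_signature(prls["d00"], 30)
        plain = combined_query([sig], prls, cfg, seed=0, exclude=["d00"])
        assert run.final.table.equals(plain.table)

    def test_missing_confounder_is_reported(self, planted_compendium):
        _, _, prls = planted_compendium
        cfg = RefinementConfig(n_perm=300, signature_k=30)
        with pytest.raises(ValidationError, match="ghost"):
            run_iterations("d00", prls, [IterationSpec("split", ("ghost",))], cfg)

    def test_split_iteration_drops_the_confounder_class(self, planted_compendium):
        _, _, prls = planted_compendium
        cfg = RefinementConfig(n_perm=300, signature_k=30)
        run = run_iterations(
            "d00", prls, [IterationSpec("split", ("d03", "d04"))], cfg, seed=0
        )
        cons, inc = run.iterations[0].signatures
        # block A (opposed by the confounders) lands in the inconsistent part
        assert inc.up and inc.up <= {f"g{i:03d}" for i in range(15)}
        kept = set(run.final.kept)
        assert {"d01", "d02"} <= kept
        assert not {"d03", "d04", "d05", "d06"} & kept

    def test_seeded_rerun_is_byte_identical(self, planted_compendium):
        _, _, prls = planted_compendium
        cfg = RefinementConfig(n_perm=300, signature_k=30)
        spec = [IterationSpec("split", ("d03", "d04"))]
        a = run_iterations("d00", prls, spec, cfg, seed=3).audit_json()
        b = run_iterations("d00", prls, spec, cfg, seed=3).audit_json()
        assert a == b

    def test_contrast_iteration_appends_classification(self, planted_compendium):
        _, _, prls = planted_compendium
        cfg = RefinementConfig(n_perm=300, signature_k=30)
        specs = [
            IterationSpec("split", ("d03", "d04")),
            IterationSpec("contrast", ("d05", "d06")),
        ]
        run = run_iterations("d00", prls, specs, cfg, seed=0)
        assert "classification" in run.final.table.columns
        assert set(run.final.table["classification"]) <= {
            "stabiliser",
            "destabiliser",
            "neutral",
        }
        # kept drugs inherited from the filtering iteration
        assert set(run.final.kept) == set(run.iterations[0].result.kept)
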