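import numpy as np
import pandas as pd
import pytest

from micasm import assembly, synthio
from micasm.errors import DegenerateDataError, ValidationError
from micasm.io import CommunityTable, patristic_matrix

from conftest import abundance_vector


class TestBmntd:
    def test_identity_is_zero(self, four_leaf_D):
        names = list(four_leaf_D.index)
        x = abundance_vector(names, {"A": 0.5, "C": 0.5})
        assert assembly.bmntd(x, x, four_leaf_D) == 0.0

    def test_hand_value_cherry_pair(self, four_leaf_D):
        names = list(four_leaf_D.index)
        x = abundance_vector(names, {"A": 0.5, "B": 0.5})
        y = abundance_vector(names, {"C": 0.5, "D": 0.5})
        assert assembly.bmntd(x, y, four_leaf_D) == pytest.approx(4.0)

    def test_hand_value_singleton(self, four_leaf_D):
        names = list(four_leaf_D.index)
        x = abundance_vector(names, {"A": 1.0})
        y = abundance_vector(names, {"B": 0.5, "C": 0.5})
        assert assembly.bmntd(x, y, four_leaf_D) == pytest.approx(2.5)

    def test_empty_community_rejected(self, four_leaf_D):
        with pytest.raises(ValidationError):
            assembly.bmntd(np.zeros(4), np.ones(4) / 4, four_leaf_D)

    def test_permutation_invariance(self, four_leaf_D):
        rng = np.random.default_rng(0)
        D = four_leaf_D.to_numpy()
        for _ in range(20):
            x = rng.dirichlet(np.ones(4)) * (rng.random(4) < 0.7)
            y = rng.dirichlet(np.ones(4)) * (rng.random(4) < 0.7)
            if x.sum() == 0 or y.sum() == 0:
                continue
            perm = rng.permutation(4)
            a = assembly.bmntd(x, y, D)
            b = assembly.bmntd(x[perm], y[perm], D[np.ix_(perm, perm)])
            assert a == pytest.approx(b, abs=1e-12)


def _naive_bnti(x, y, D, n_null, seed):
    """Independent loop-based reimplementation used as an oracle."""
    def naive_bmntd(x, y, D):
        ix = [i for i in range(len(x)) if x[i] > 0]
        iy = [j for j in range(len(y)) if y[j] > 0]
        sx = sum(x[i] for i in ix)
        sy = sum(y[j] for j in iy)
        left = sum((x[i] / sx) * min(D[i][j] for j in iy) for i in ix)
        right = sum((y[j] / sy) * min(D[i][j] for i in ix) for j in iy)
        return 0.5 * (left + right)

    rng = np.random.default_rng(seed)
    obs = naive_bmntd(x, y, D)
    nulls = []
    for _ in range(n_null):
        perm = rng.permutation(len(x))
        Dp = D[np.ix_(perm, perm)]
        nulls.append(naive_bmntd(x, y, Dp))
    nulls = np.asarray(nulls)
    return (obs - nulls.mean()) / nulls.std(ddof=1)


class TestBnti:
    def test_matches_naive_reimplementation(self):
        tree = synthio.simulate_tree(4, seed=5)
        D = patristic_matrix(tree).to_numpy()
        x = np.array([0.6, 0.4, 0.0, 0.0])
        y = np.array([0.0, 0.2, 0.5, 0.3])
        res = assembly.bnti(x, y, D, n_null=999, seed=123)
        # the oracle permutes D rows/cols; the implementation permutes
        # taxon positions -- identical distributions, same rng stream
        expected = _naive_bnti(x, y, D, 999, 123)
        assert res.bnti == pytest.approx(expected, abs=1e-10)

    def test_standardized_deviate_definition(self):
        tree = synthio.simulate_tree(12, seed=2)
        D = patristic_matrix(tree).to_numpy()
        rng = np.random.default_rng(3)
        x = rng.dirichlet(np.ones(12)) * (rng.random(12) < 0.6)
        y = rng.dirichlet(np.ones(12)) * (rng.random(12) < 0.6)
        res = assembly.bnti(x, y, D, n_null=199, seed=1)
        assert res.bnti == pytest.approx(
            (res.observed - res.null_mean) / res.null_sd)

    def test_star_tree_degenerate(self):
        # equidistant tips: every shuffle yields the same betaMNTD
        D = np.full((5, 5), 2.0)
        np.fill_diagonal(D, 0.0)
        x = np.array([0.5, 0.5, 0, 0, 0])
        y = np.array([0, 0, 0.5, 0.5, 0])
        with pytest.raises(DegenerateDataError):
            assembly.bnti(x, y, D, n_null=99, seed=0)

    def test_n_null_floor(self):
        with pytest.raises(ValidationError):
            assembly.bnti(np.ones(3) / 3, np.ones(3) / 3, np.eye(3), n_null=10)


class TestRaupCrick:
    def test_identical_samples_give_minus_one(self):
        # obs BC = 0 sits below every null draw (totals large enough
        # that two null allocations never coincide exactly)
        x = np.array([1000, 2000, 500, 0, 0, 0], dtype=float)
        occ = np.full(6, 0.5)
        ab = np.ones(6) / 6
        rc = assembly.raup_crick_bray(x, x, occ, ab, n_null=199, seed=0)
        assert rc == -1.0

    def test_disjoint_samples_exceed_null(self):
        # richness 8+8 from a 20-taxon pool: a disjoint null pair has
        # probability C(12,8)/C(20,8) ~ 0.004, so disjointness is extreme
        p = 20
        x = np.zeros(p)
        y = np.zeros(p)
        x[:8] = 10
        y[8:16] = 10
        occ = np.full(p, 0.5)
        ab = np.ones(p) / p
        rc = assembly.raup_crick_bray(x, y, occ, ab, n_null=999, seed=1)
        assert rc > 0.95

    def test_two_taxon_pool_matches_enumeration(self):
        # richness-1 samples on a 2-taxon pool: the null has 4 outcomes
        occ = np.array([0.7, 0.3])
        ab = np.array([0.5, 0.5])
        x = np.array([10.0, 0.0])
        y = np.array([0.0, 10.0])
        q = occ[0] / occ.sum()
        p_same = q * q + (1 - q) * (1 - q)   # null BC = 0 (equal totals)
        p_diff = 1 - p_same                  # null BC = 1 = observed
        expected = 2 * (p_same + 0.5 * p_diff) - 1
        rc = assembly.raup_crick_bray(x, y, occ, ab, n_null=9999, seed=3)
        assert rc == pytest.approx(expected, abs=0.02)

    def test_extreme_antisymmetry(self):
        # observed below every null -> -1; above every null -> +1
        occ = np.full(8, 0.5)
        ab = np.ones(8) / 8
        x = np.zeros(8)
        y = np.zeros(8)
        x[:4] = 300
        y[4:] = 300
        low = assembly.raup_crick_bray(x, x, occ, ab, n_null=499, seed=5)
        high = assembly.raup_crick_bray(x, y, occ, ab, n_null=499, seed=5)
        assert low == -1.0
        assert high == pytest.approx(-low, abs=0.05)

    def test_pool_missing_taxa(self):
        x = np.array([1.0, 1.0])
        occ = np.array([0.5, 0.0])
        with pytest.raises(ValidationError):
            assembly.raup_crick_bray(x, x, occ, np.array([0.5, 0.5]),
                                     n_null=99, seed=0)


class TestClassifyPair:
    @pytest.mark.parametrize("bnti,rc,expected", [
        (2.5, 0.1, "variable_selection"),
        (-2.5, 0.1, "homogeneous_selection"),
        (-0.5, 0.97, "dispersal_limitation"),
        (0.5, -0.97, "homogenizing_dispersal"),
        (1.0, 0.2, "drift"),
    ])
    def test_rule(self, bnti, rc, expected):
        assert assembly.classify_pair(bnti, rc) == expected

    def test_inverted_convention_swaps_selection(self):
        assert assembly.classify_pair(2.5, 0.0, "inverted") == \
            "homogeneous_selection"

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            assembly.classify_pair(float("nan"), 0.0)


def _mini_table(n_otus=10):
    rng = np.random.default_rng(0)
    rows, meta = [], []
    for trt in ("Control", "T"):
        for rep in (1, 2):
            for b in (1, 2):
                sid = f"{trt}_r{rep}_B{b}"
                # sparse supports so the tip-shuffle null has spread
                counts = rng.integers(1, 8, n_otus) * (rng.random(n_otus) < 0.5)
                counts[rng.integers(n_otus)] += 5
                rows.append(pd.Series(counts,
                                      index=[f"OTU_{i}" for i in range(n_otus)],
                                      name=sid))
                meta.append((sid, trt, f"B{b}", rep, 5 * b))
    counts = pd.DataFrame(rows)
    md = pd.DataFrame(meta, columns=["sample_id", "treatment", "batch",
                                     "replicate", "day"]).set_index("sample_id")
    return CommunityTable(counts, md)


class TestProcessFractions:
    def test_forced_drift(self, monkeypatch):
        table = _mini_table()
        tree = synthio.simulate_tree(10, seed=0)
        D = patristic_matrix(tree)
        D.index = D.columns = [f"OTU_{i}" for i in range(10)]
        monkeypatch.setattr(
            assembly, "bnti",
            lambda *a, **k: assembly.BntiResult(0.0, 0.0, 0.0, 1.0, 99))
        monkeypatch.setattr(assembly, "raup_crick_bray",
                            lambda *a, **k: 0.0)
        pf = assembly.process_fractions(table, D, {"B1": 1, "B2": 2}, "T",
                                        n_null=99, seed=0)
        assert (pf.fractions["drift"] == 1.0).all()
        assert np.allclose(pf.fractions.sum(axis=1), 1.0)

    def test_fractions_sum_to_one(self):
        table = _mini_table()
        tree = synthio.simulate_tree(10, seed=1)
        D = patristic_matrix(tree)
        D.index = D.columns = [f"OTU_{i}" for i in range(10)]
        pf = assembly.process_fractions(table, D, {"B1": 1, "B2": 1}, "T",
                                        n_null=99, seed=1)
        assert np.allclose(pf.fractions.sum(axis=1), 1.0)
        assert len(pf.pairs) == 16  # 4 treatment x 4 control samples

    def test_variable_selection_monotone_in_strength(self):
        # stronger selection concentrates treated communities on the
        # tolerant clade, raising late-phase variable selection
        phases = {"B1": 1, "B2": 1, "B3": 2, "B4": 2,
                  "B5": 3, "B6": 3, "B7": 3}
        means = []
        for strength in (0.0, 0.5, 1.0):
            vs = []
            for seed in range(1, 6):
                cfg = synthio.SimConfig(
                    seed=seed, selection_strength=strength,
                    treatments=[synthio.Treatment("Control", {}),
                                synthio.Treatment("TCS", {"TCS": 1.0})])
                table, _, _ = synthio.simulate_experiment(cfg)
                tree = synthio.simulate_tree(
                    cfg.n_otus,
                    int(np.random.SeedSequence(cfg.seed).spawn(1)[0]
                        .generate_state(1)[0] % (2 ** 31)))
                D = patristic_matrix(tree)
                pf = assembly.process_fractions(table, D, phases, "TCS",
                                                n_null=99, seed=seed + 7)
                vs.append(pf.fractions.loc[3, "variable_selection"])
            means.append(np.mean(vs))
        assert means[0] <= means[1] <= means[2]
        assert means[2] > means[0]

    def test_unphased_batch_rejected(self):
        table = _mini_table()
        tree = synthio.simulate_tree(10, seed=1)
        D = patristic_matrix(tree)
        D.index = D.columns = [f"OTU_{i}" for i in range(10)]
        with pytest.raises(ValidationError, match="B2"):
            assembly.process_fractions(table, D, {"B1": 1}, "T",
                                       n_null=99, seed=0)
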