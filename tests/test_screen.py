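"""Block enumeration, fold change, rank AUC and the two-level screen."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryocm import screen as scr
from embryocm.config import RunConfig


def brute_force_auc(pos, neg) -> float:
    """Concordant-pair fraction with half credit for ties, direction-free."""
    total = 0.0
    for p in pos:
        for o in neg:
            if p > o:
                total += 1.0
            elif p == o:
                total += 0.5
    a = total / (len(pos) * len(neg))
    return max(a, 1 - a)


class TestLogFoldChange:
    def test_ratio_of_positive_means(self):
        assert scr.log_fold_change([8, 8], [2, 2]) == pytest.approx(2.0)
        assert scr.log_fold_change([4, 4], [4, 4]) == pytest.approx(0.0)

    def test_sentinel_when_one_class_at_or_below_zero(self):
        assert scr.log_fold_change([-1.0, 0.5], [3.0, 5.0]) == -99.0
        assert scr.log_fold_change([3.0, 5.0], [-1.0, 0.5]) == 99.0
        assert scr.log_fold_change([0.0, 0.0], [1.0, 1.0]) == -99.0

    def test_mutual_consumption_uses_absolute_means(self):
        # both classes net-negative: log2(|-8|/|-2|) = 2
        assert scr.log_fold_change([-8, -8], [-2, -2]) == pytest.approx(2.0)

    def test_both_zero_flagged_nan(self):
        assert math.isnan(scr.log_fold_change([0.0], [0.0]))

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            scr.log_fold_change([], [1.0])


class TestRocAuc:
    def test_two_discordant_pairs_of_42(self):
        from embryocm.synthetic import vectors_with_discordance

        p, o = vectors_with_discordance(6, 7, 2)
        assert scr.roc_auc(p, o) == pytest.approx(40 / 42)

    def test_perfect_separation(self):
        assert scr.roc_auc([10, 11, 12], [1, 2, 3]) == 1.0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n_p, n_o = rng.integers(1, 9, size=2)
            # integer values force ties regularly
            p = rng.integers(0, 6, size=n_p).astype(float)
            o = rng.integers(0, 6, size=n_o).astype(float)
            assert scr.roc_auc(p, o) == pytest.approx(brute_force_auc(p, o))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        p=st.lists(st.floats(0.1, 1e4), min_size=2, max_size=8),
        o=st.lists(st.floats(0.1, 1e4), min_size=2, max_size=8),
    )
    def test_invariant_under_monotone_transform(self, p, o):
        base = scr.roc_auc(p, o)
        logged = scr.roc_auc(np.log(p), np.log(o))
        assert base == pytest.approx(logged)


class TestVolcanoLevel1:
    def _block(self, n_p=6, n_o=7):
        return scr.BlockSpec(
            endpoint="D40",
            pregnant_ids=tuple(f"P{i}" for i in range(n_p)),
            open_ids=tuple(f"O{i}" for i in range(n_o)),
        )

    def test_null_feature_fails(self):
        rng = np.random.default_rng(1)
        p = rng.normal(10, 1, 6)
        o = rng.normal(10, 1, 7)
        rec = scr.volcano_level1(self._block(), p, o)
        assert not rec.passed

    def test_fold_change_gate_blocks_significant_small_effect(self):
        # 1.41-fold difference with tiny variance: p tiny but |logFC| = 0.5
        p = np.full(6, 2 ** 0.5 * 100) + np.linspace(-0.01, 0.01, 6)
        o = np.full(7, 100.0) + np.linspace(-0.01, 0.01, 7)
        rec = scr.volcano_level1(self._block(), p, o)
        assert abs(rec.log_fch) == pytest.approx(0.5, abs=1e-3)
        assert min(rec.p_param, rec.p_nonparam) < 0.001
        assert not rec.passed

    def test_qualitative_effect_passes_with_sentinel(self):
        rng = np.random.default_rng(2)
        p = -np.abs(rng.normal(0, 0.01, 6)) - 0.01
        o = rng.normal(50, 5, 7)
        rec = scr.volcano_level1(self._block(), p, o)
        assert rec.passed
        assert rec.log_fch == -99.0
        assert rec.significance == "significant"

    def test_tendency_band_flagged(self):
        # construct a contrast whose t-test p lands in [0.05, 0.10)
        p = np.array([10.0, 11, 12, 13, 30, 31])
        o = np.array([4.0, 5, 6, 7, 8, 9, 10])
        rec = scr.volcano_level1(self._block(), p, o)
        if rec.passed:
            assert rec.significance in ("significant", "tendency")

    def test_degenerate_identical_constant_groups(self):
        rec = scr.volcano_level1(self._block(3, 3), [5.0] * 3, [5.0] * 3)
        assert not rec.passed
        assert rec.p_param == 1.0


class TestRocLevel2:
    def _record(self, block, p, o):
        return scr.volcano_level1(block, p, o)

    def test_low_auc_rejected_despite_p(self):
        rec = scr.Level1Record(
            scr.BlockSpec("D40", pregnant_ids=("a",) * 10, open_ids=("b",) * 10),
            "F", -99.0, 0.01, 0.01, True, "significant",
        )
        # overlapping distributions -> AUC below the 0.700 gate
        p = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        o = [1.5, 2.5, 3.5, 4.5, 5.5, 6.5, 7.5, 8.5, 9.5, 10.5]
        assert scr.roc_auc(p, o) < 0.7
        assert scr.roc_level2(rec, p, o) is None

    def test_small_n_exception_admitted_and_flagged(self):
        block = scr.BlockSpec("D40", pregnant_ids=("a",) * 4, open_ids=("b",) * 4)
        rec = scr.Level1Record(block, "F", 2.0, 0.12, 0.04, True, "significant")
        p = [10.0, 11, 12, 13]
        o = [1.0, 2, 3, 4]
        hit = scr.roc_level2(rec, p, o)
        assert hit is not None and hit.small_n_exception
        # same p outside the exception window in a large block -> rejected
        big = scr.BlockSpec("D40", pregnant_ids=("a",) * 10, open_ids=("b",) * 10)
        rec2 = scr.Level1Record(big, "F", 2.0, 0.12, 0.04, True, "significant")
        assert scr.roc_level2(rec2, [10.0] * 10, [1.0] * 10) is None

    def test_hits_are_subset_of_level1_passers(self):
        rng = np.random.default_rng(3)
        block = scr.BlockSpec(
            "D40",
            pregnant_ids=tuple(f"P{i}" for i in range(6)),
            open_ids=tuple(f"O{i}" for i in range(6)),
        )
        for _ in range(50):
            p = rng.normal(rng.uniform(5, 15), 2, 6)
            o = rng.normal(10, 2, 6)
            rec = scr.volcano_level1(block, p, o)
            hit = scr.roc_level2(rec, p, o)
            if hit is not None:
                assert rec.passed


class TestScreenBlock:
    def test_matches_independent_per_feature_recomputation(self):
        rng = np.random.default_rng(4)
        n_p, n_o, m = 6, 7, 40
        cfg = RunConfig()
        p_ids = [f"P{i}" for i in range(n_p)]
        o_ids = [f"O{i}" for i in range(n_o)]
        block = scr.BlockSpec("D40", pregnant_ids=tuple(p_ids), open_ids=tuple(o_ids))
        vals = {}
        for s in p_ids + o_ids:
            vals[s] = rng.normal(rng.uniform(-5, 20), 5, m)
        net = pd.DataFrame({"feature_id": [f"F{i}" for i in range(m)], **vals})
        fast = {h.feature_id for h in scr.screen_block(block, net, cfg)}
        slow = set()
        for i in range(m):
            p = net.loc[i, p_ids].to_numpy(dtype=float)
            o = net.loc[i, o_ids].to_numpy(dtype=float)
            rec = scr.volcano_level1(block, p, o, feature_id=f"F{i}", config=cfg)
            if rec.passed and scr.roc_level2(rec, p, o, config=cfg) is not None:
                slow.add(f"F{i}")
        assert fast == slow

    def test_results_independent_of_block_order(self, toy_samples):
        rng = np.random.default_rng(5)
        m = 10
        net = pd.DataFrame(
            {
                "feature_id": [f"F{i}" for i in range(m)],
                **{s: rng.lognormal(3, 1, m) for s in toy_samples["sample_id"]},
            }
        )
        blocks = scr.enumerate_blocks(toy_samples, min_class=3)
        fwd = scr.screen_all(blocks, net)
        rev = scr.screen_all(list(reversed(blocks)), net)
        key = lambda h: (h.feature_id, str(h.block.constraint_key()))
        assert sorted(map(key, fwd)) == sorted(map(key, rev))


class TestEnumerateBlocks:
    def test_matches_brute_force_on_toy_cohort(self, toy_samples):
        cfg = RunConfig()
        blocks = scr.enumerate_blocks(toy_samples, min_class=2, config=cfg)
        # brute force: resolve the full constraint grid, filter, dedupe
        seen = {}
        for endpoint in ("D40", "D62", "Birth"):
            for cryo, breed, culture, age, s0, s24 in itertools.product(
                [None, "fresh", "frozen"], [None, "AV", "H"], [None, "BSA", "FCS"],
                [None, 7], cfg.stage0h_subsets, cfg.stage24h_subsets,
            ):
                b = scr.resolve_block(
                    toy_samples, endpoint, cryo=cryo, breed=breed,
                    culture=culture, stage0h=s0, stage24h=s24, age=age,
                )
                if b.n_pregnant < 2 or b.n_open < 2:
                    continue
                key = (endpoint, frozenset(b.pregnant_ids), frozenset(b.open_ids))
                if key not in seen or b.n_constraints < seen[key].n_constraints:
                    seen[key] = b
        assert len(blocks) == len(seen)
        got = {(b.endpoint, frozenset(b.pregnant_ids), frozenset(b.open_ids)) for b in blocks}
        assert got == set(seen)

    def test_zero_pregnant_cohort_yields_empty_list(self, toy_samples):
        samples = toy_samples.copy()
        samples[["D40", "D62", "Birth"]] = 0
        assert scr.enumerate_blocks(samples, min_class=1) == []

    def test_duplicate_resolutions_collapse_to_coarser_block(self):
        # single culture level: constraining culture resolves to the same
        # samples as leaving it free, so only the free block must remain
        rows = []
        for i in range(12):
            rows.append(
                {
                    "sample_id": f"S{i}", "cryo": "fresh", "breed": "AV",
                    "culture": "BSA", "bull": "b1", "stage0h": "B",
                    "stage24h": "FEB", "age": 7,
                    "D40": int(i < 6), "D62": int(i < 6), "Birth": int(i < 6),
                }
            )
        samples = pd.DataFrame(rows)
        blocks = scr.enumerate_blocks(samples, min_class=3, endpoints=("D40",))
        assert len(blocks) == 1
        assert blocks[0].n_constraints == 0


class TestAnnotation:
    LIB = pd.DataFrame(
        {
            "compound": ["citrate", "proline"],
            "exact_mass": [192.027, 115.0633],
            "ms2_mz_list": ["111.008;87.008;67.018", "70.065;68.05;43.055"],
        }
    )

    def _features(self, mz, ms2):
        return pd.DataFrame({"feature_id": ["X1"], "mz": [mz], "ms2": [ms2]})

    def test_exact_match_with_three_ions_validated(self):
        recs = scr.annotate_features(
            self._features(192.027, "111.008;87.008;67.018"), self.LIB
        )
        assert len(recs) == 1 and recs[0].validated
        assert recs[0].compound == "citrate"

    def test_precursor_error_over_10ppm_not_validated(self):
        mz = 192.027 * (1 + 12e-6)
        recs = scr.annotate_features(
            self._features(mz, "111.008;87.008;67.018"), self.LIB
        )
        assert all(not r.validated for r in recs)

    def test_two_of_three_ions_not_validated(self):
        recs = scr.annotate_features(
            self._features(192.027, "111.008;87.008"), self.LIB
        )
        assert len(recs) == 1 and not recs[0].validated
        assert recs[0].matched_ms2 == 2

    def test_empty_library_yields_no_annotations(self):
        assert scr.annotate_features(self._features(192.027, ""), self.LIB.iloc[:0]) == []
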