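"""TPM normalisation, counting rules and the exact two-library DE test."""

import math

import numpy as np
import pytest

from mirmodule import quant_de as qd
from mirmodule.annotate import FamilyReference
from mirmodule.preprocess import CleanTag
from mirmodule.reference import ac_pvalue_direct
from tests.conftest import random_seq


class TestTpm:
    @pytest.mark.parametrize("count,total,expected", [(0, 10**6, 0.0), (100, 10**6, 100.0)])
    def test_formula(self, count, total, expected):
        assert qd.tpm(count, total) == expected

    def test_category_share_matches_percentage(self):
        # a category holding 712,820 of 19,500,319 reads carries 3.66% of the
        # TPM mass (TPM / 10^4 = percent)
        assert round(qd.tpm(712_820, 19_500_319) / 10_000, 2) == 3.66

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            qd.tpm(1, 0)

    def test_tpm_sums_to_one_million_over_full_tag_set(self, pipeline_result):
        res = pipeline_result
        for lib in res.libraries:
            counts = [t.counts.get(lib, 0) for t in res.tags.values()]
            total = res.stats[lib].clean_reads
            assert math.isclose(qd.tpm_column(counts, total).sum(), 1e6, rel_tol=1e-12)


class TestFoldChange:
    def test_simple_ratio(self):
        assert qd.fold_change(4.0, 1.0) == 2.0

    @pytest.mark.parametrize("x", [0.5, 1.0, 37.2])
    def test_identity(self, x):
        assert qd.fold_change(x, x) == 0.0

    def test_floor_removes_singularity(self):
        assert qd.fold_change(50.0, 0.0) == pytest.approx(math.log2(50 / 0.01))

    def test_antisymmetry(self):
        assert qd.fold_change(8.0, 2.0) == -qd.fold_change(2.0, 8.0)


class TestDeTest:
    def test_symmetric_null_is_one(self):
        assert qd.de_test(7, 7, 10**6, 10**6) == pytest.approx(1.0, abs=1e-9)

    def test_strong_difference_is_small(self):
        assert qd.de_test(0, 20, 10**6, 10**6) < 1e-4

    def test_exchange_consistency(self):
        """Swapping libraries conditions the test on the other count, so
        p-values agree only asymptotically; at moderate counts they must
        be close, and Fisher's exact alternative is exactly symmetric."""
        p1 = qd.de_test(80, 130, 10**5, 2 * 10**5)
        p2 = qd.de_test(130, 80, 2 * 10**5, 10**5)
        assert p1 == pytest.approx(p2, rel=0.2)
        f1 = qd.fisher_de_test(3, 11, 10**5, 2 * 10**5)
        f2 = qd.fisher_de_test(11, 3, 2 * 10**5, 10**5)
        assert f1 == pytest.approx(f2, rel=1e-9)

    @pytest.mark.parametrize(
        "x,y,n1,n2",
        [(0, 20, 10**6, 10**6), (5, 9, 1000, 2000), (3, 3, 500, 500),
         (100, 140, 10**6, 2 * 10**6), (0, 0, 10**4, 10**4)],
    )
    def test_agrees_with_direct_tail_summation(self, x, y, n1, n2):
        assert qd.de_test(x, y, n1, n2) == pytest.approx(ac_pvalue_direct(x, y, n1, n2), rel=1e-9)

    def test_monotone_away_from_null(self):
        x, n1, n2 = 50, 10**6, 10**6
        ps_up = [qd.de_test(x, y, n1, n2) for y in range(50, 120, 5)]
        assert all(a >= b for a, b in zip(ps_up, ps_up[1:]))
        ps_down = [qd.de_test(x, y, n1, n2) for y in range(50, 0, -5)]
        assert all(a >= b for a, b in zip(ps_down, ps_down[1:]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            qd.de_test(-1, 5, 100, 100)

    def test_type_one_error_controlled_on_poisson_null(self):
        rng = np.random.default_rng(123)
        n1 = n2 = 10**6
        rates = rng.uniform(20, 500, size=1000)
        rejected = 0
        for mu in rates:
            x = rng.poisson(mu)
            y = rng.poisson(mu)
            rejected += qd.de_test(int(x), int(y), n1, n2) < 0.05
        assert rejected / len(rates) <= 0.08


class TestDdct:
    def test_no_change(self):
        assert qd.ddct(20, 18, 21, 19) == 1.0

    def test_fourfold_up(self):
        assert qd.ddct(18, 18, 20, 18) == 4.0  # ddCt = -2

    def test_fourfold_down(self):
        assert qd.ddct(22, 18, 20, 18) == 0.25  # ddCt = +2


class TestCounting:
    def _family(self, rng):
        s1, s2 = random_seq(rng, 21), random_seq(rng, 21)
        return FamilyReference(representatives={"miR1": ("miR1a", s1), "miR2": ("miR2a", s2)})

    def test_exact_tag_accrues_count(self, rng):
        fam = self._family(rng)
        seq = fam.representatives["miR1"][1]
        tags = {seq: CleanTag(seq, {"CA": 7, "NA": 0})}
        counts = qd.count_known(tags, fam, ["CA", "NA"])
        assert counts["miR1a"]["CA"] == 7

    def test_best_hit_only(self, rng):
        fam = self._family(rng)
        s1 = fam.representatives["miR1"][1]
        near = list(s1)
        near[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[near[5]]
        near = "".join(near)  # 1 mm from miR1a, ~random vs miR2a
        tags = {near: CleanTag(near, {"CA": 4})}
        counts = qd.count_known(tags, fam, ["CA"])
        assert counts["miR1a"]["CA"] == 4 and counts["miR2a"]["CA"] == 0

    def test_zero_count_record_retained(self, rng):
        fam = self._family(rng)
        counts = qd.count_known({}, fam, ["CA"])
        assert set(counts) == {"miR1a", "miR2a"}
        assert all(v["CA"] == 0 for v in counts.values())


class TestNovelMatching:
    def test_exact_match_counts(self, rng):
        m = random_seq(rng, 21)
        assert qd.matches_novel(m, m)

    def test_end_substitution_plus_overhang_counts(self, rng):
        m = random_seq(rng, 21)
        tag = list(m)
        tag[1] = {"A": "C", "C": "G", "G": "T", "T": "A"}[tag[1]]  # position 2
        tag = "G" + "".join(tag)  # 1 nt 5' overhang -> 2 end differences
        assert qd.matches_novel(tag, m)

    def test_middle_mismatch_rejected(self, rng):
        m = random_seq(rng, 21)
        tag = list(m)
        tag[9] = {"A": "C", "C": "G", "G": "T", "T": "A"}[tag[9]]  # position 10
        assert not qd.matches_novel("".join(tag), m)

    def test_four_end_differences_rejected(self, rng):
        m = random_seq(rng, 21)
        tag = "GG" + m[2:]  # may be 0-2 subs at the 5' end
        tag = tag + "AA"  # plus 2 overhang: only rejected if subs push over 3
        diffs = sum(1 for a, b in zip(tag[:2], m[:2]) if a != b) + 2
        assert qd.matches_novel(tag, m) == (diffs <= 3)


class TestCallDe:
    def _record(self, log2fc, p):
        r = qd.ExpressionRecord("m", "known", 10, 10, 10**5, 10**5)
        r.log2fc, r.p_value = log2fc, p
        return r

    def test_fold_change_gate(self):
        recs = qd.call_de([self._record(0.8, 0.001)])
        assert recs[0].status == "unDE"

    def test_pvalue_gate(self):
        recs = qd.call_de([self._record(2.0, 0.2)])
        assert recs[0].status == "unDE"

    def test_strict_tier_flagged(self):
        recs = qd.call_de([self._record(2.0, 0.001)])
        assert recs[0].status == "up" and recs[0].significant == "p<0.01"

    def test_bh_properties(self, pipeline_result):
        records = sorted(pipeline_result.known_records, key=lambda r: r.p_value)
        assert all(r.fdr >= r.p_value - 1e-12 for r in records)
        assert all(a.fdr <= b.fdr + 1e-12 for a, b in zip(records, records[1:]))

    def test_empty_input(self):
        assert qd.call_de([]) == []


def test_direction_recovery_on_synthetic_truth(small_dataset, pipeline_result):
    """Strong, well-covered effects are called in the right direction."""
    ds, res = small_dataset, pipeline_result
    truth_by_seq = {t.mature_seq: t for t in ds.truth}
    rep = dict(res.family_reference.sequences())
    rep.update({nm.mirna_id: nm.mature_seq for nm in res.novel})
    checked = correct = 0
    for r in res.known_records + res.novel_records:
        t = truth_by_seq.get(rep.get(r.mirna_id, ""))
        if t is None or abs(t.true_log2fc) < 2 or t.true_abundance_A < 50:
            continue
        checked += 1
        correct += r.status == t.direction
    assert checked > 0
    assert correct / checked >= 0.95
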