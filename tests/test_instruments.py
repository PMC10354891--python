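"""Instrument-selection cascade: each filter against an independent oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mrkit.instruments import (
    SelectionConfig,
    confounder_filter,
    filter_by_pvalue,
    find_proxy,
    ld_clump,
    per_snp_f,
    select_instruments,
)
from mrkit.sumstats import LdReference, SummaryDataset

from conftest import make_record, random_records


class TestPvalueFilter:
    def test_strict_inequality_at_boundary(self):
        recs = [
            make_record("a", pval=1e-6),
            make_record("b", pval=1e-5),
            make_record("c", pval=2e-5),
        ]
        kept = filter_by_pvalue(recs, 1e-5)
        assert [r.variant_id for r in kept] == ["a"]

    def test_threshold_one_keeps_everything(self, dataset):
        assert len(filter_by_pvalue(dataset, 1.0)) == len(dataset)

    def test_matches_loop_oracle_on_random_pvalues(self, rng):
        recs = [
            make_record(f"v{i}", pval=float(p))
            for i, p in enumerate(rng.uniform(1e-10, 1, 200) ** 3)
        ]
        threshold = 1e-4
        oracle = [r.variant_id for r in recs if r.pval < threshold]
        assert [r.variant_id for r in filter_by_pvalue(recs, threshold)] == oracle


class TestPerSnpF:
    def test_hand_arithmetic(self):
        assert per_snp_f(make_record(beta=0.02, se=0.004)) == pytest.approx(25.0)
        assert per_snp_f(make_record(beta=0.0)) == 0.0

    def test_equals_squared_z(self, rng):
        for _ in range(20):
            beta, se = rng.normal(), rng.uniform(0.01, 1)
            rec = make_record(beta=beta, se=se)
            assert per_snp_f(rec) == pytest.approx((beta / se) ** 2, rel=1e-14)


def brute_force_clump(records, ld, clump_r2, window):
    """Independent greedy re-implementation used as the oracle."""
    pool = sorted(records, key=lambda r: (r.pval, r.variant_id))
    out = []
    while pool:
        idx = pool[0]
        out.append(idx)
        pool = [
            r
            for r in pool[1:]
            if not (
                r.chrom == idx.chrom
                and abs(r.pos - idx.pos) <= window
                and ld.r2_between(idx.variant_id, r.variant_id) >= clump_r2
            )
        ]
    return out


class TestLdClump:
    def test_single_variant_is_its_own_index(self):
        rec = make_record("only")
        assert ld_clump([rec], None) == [rec]

    def test_weaker_of_correlated_pair_removed(self):
        a = make_record("a", pos=1_000_000, pval=1e-8)
        b = make_record("b", pos=1_001_000, pval=1e-6)
        ld = LdReference(["a", "b"], np.array([[1, 0.5], [0.5, 1]]))
        kept = ld_clump([a, b], ld, clump_r2=0.001, clump_window_bp=10_000_000)
        assert [r.variant_id for r in kept] == ["a"]

    def test_distant_or_uncorrelated_pairs_survive(self):
        a = make_record("a", chrom="1", pos=1_000_000, pval=1e-8)
        b = make_record("b", chrom="1", pos=20_000_000, pval=1e-6)  # outside window
        c = make_record("c", chrom="2", pos=1_000_000, pval=1e-7)  # other chromosome
        ld = LdReference(
            ["a", "b", "c"], np.array([[1, 0.9, 0.9], [0.9, 1, 0.9], [0.9, 0.9, 1]])
        )
        kept = ld_clump([a, b, c], ld, 0.001, 10_000_000)
        assert {r.variant_id for r in kept} == {"a", "b", "c"}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_and_pairwise_audit(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        recs = [
            make_record(
                f"v{i}",
                chrom=str(rng.integers(1, 3)),
                pos=int(rng.integers(1, 30_000_000)),
                pval=float(rng.uniform(1e-10, 1e-4)),
            )
            for i in range(n)
        ]
        a = rng.uniform(0, 1, (n, n))
        r2 = (a + a.T) / 2 * (rng.random((n, n)) < 0.5)
        r2 = (r2 + r2.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LdReference([r.variant_id for r in recs], r2)
        window, thr = 5_000_000, 0.2
        kept = ld_clump(recs, ld, thr, window)
        oracle = brute_force_clump(recs, ld, thr, window)
        assert [r.variant_id for r in kept] == [r.variant_id for r in oracle]
        # pairwise audit: no surviving pair violates the criterion
        for x, y in itertools.combinations(kept, 2):
            if x.chrom == y.chrom and abs(x.pos - y.pos) <= window:
                assert ld.r2_between(x.variant_id, y.variant_id) < thr

    def test_output_invariant_to_input_order(self, rng):
        recs = [
            make_record(f"v{i}", pos=int(rng.integers(1, 10**7)), pval=float(p))
            for i, p in enumerate(rng.uniform(0, 1e-4, 15))
        ]
        ld = None
        ordered = ld_clump(recs, ld, 0.001, 10_000_000)
        shuffled_in = list(recs)
        rng.shuffle(shuffled_in)
        assert [r.variant_id for r in ld_clump(shuffled_in, ld, 0.001, 10_000_000)] == [
            r.variant_id for r in ordered
        ]

    def test_variants_absent_from_reference_treated_independent(self):
        a = make_record("a", pos=1_000_000, pval=1e-8)
        b = make_record("b", pos=1_001_000, pval=1e-6)  # not in LD panel
        ld = LdReference(["a"], np.array([[1.0]]))
        kept = ld_clump([a, b], ld, 0.001, 10_000_000)
        assert {r.variant_id for r in kept} == {"a", "b"}


def _outcome_ds(ids):
    return SummaryDataset("out", "outcome", [make_record(v) for v in ids])


class TestFindProxy:
    def test_highest_r2_candidate_wins(self):
        ld = LdReference(
            ["m", "p1", "p2"],
            np.array([[1, 0.9, 0.85], [0.9, 1, 0], [0.85, 0, 1]]),
        )
        assert find_proxy("m", _outcome_ds(["p1", "p2"]), ld, 0.8) == "p1"

    def test_boundary_is_strict(self):
        ld = LdReference(["m", "p1"], np.array([[1, 0.8], [0.8, 1]]))
        assert find_proxy("m", _outcome_ds(["p1"]), ld, 0.8) is None

    def test_matches_scan_oracle_on_random_candidates(self, rng):
        n = 50
        ids = ["m"] + [f"p{i}" for i in range(n)]
        r2 = np.eye(n + 1)
        r2[0, 1:] = r2[1:, 0] = rng.uniform(0, 1, n)
        ld = LdReference(ids, r2)
        outcome = _outcome_ds(ids[1:])
        got = find_proxy("m", outcome, ld, 0.8)
        eligible = [(ld.r2_between("m", v), v) for v in ids[1:]]
        eligible = [(r, v) for r, v in eligible if r > 0.8]
        oracle = max(eligible, key=lambda t: (t[0], ))[1] if eligible else None
        if oracle is not None:
            # resolve exact-r2 ties the way the contract states
            best_r2 = max(r for r, _ in eligible)
            tied = sorted(v for r, v in eligible if r == best_r2)
            assert got in tied and got == tied[0]
        else:
            assert got is None

    def test_exposure_tiebreak_by_smaller_p(self):
        ld = LdReference(
            ["m", "p1", "p2"], np.array([[1, 0.9, 0.9], [0.9, 1, 0], [0.9, 0, 1]])
        )
        exposure = SummaryDataset(
            "exp",
            "exposure",
            [make_record("p1", pval=1e-6), make_record("p2", pval=1e-9)],
        )
        assert (
            find_proxy("m", _outcome_ds(["p1", "p2"]), ld, 0.8, exposure) == "p2"
        )


class TestConfounderFilter:
    ANN = pd.DataFrame(
        {
            "variant_id": ["rs332040", "rs332040", "rs17707300", "rsX"],
            "trait": ["worry or anxiety", "neuroticism", "body mass index", "height"],
            "category": ["psychiatric", "psychiatric", "obesity", "anthropometric"],
            "pval": [5.28e-22, 1.09e-14, 3.28e-25, 1e-3],
        }
    )

    def test_subthreshold_confounder_hit_removes_and_logs(self):
        recs = [make_record("rs332040"), make_record("rsClean")]
        kept, log = confounder_filter(recs, self.ANN, ["psychiatric"], 5e-8)
        assert [r.variant_id for r in kept] == ["rsClean"]
        assert set(log["trait"]) == {"worry or anxiety", "neuroticism"}
        assert (log["variant_id"] == "rs332040").all()

    def test_above_threshold_annotation_keeps_variant(self):
        recs = [make_record("rsX")]
        kept, log = confounder_filter(recs, self.ANN, ["anthropometric"], 5e-8)
        assert [r.variant_id for r in kept] == ["rsX"] and log.empty

    def test_category_not_configured_keeps_variant(self):
        recs = [make_record("rs17707300")]
        kept, _ = confounder_filter(recs, self.ANN, ["psychiatric"], 5e-8)
        assert [r.variant_id for r in kept] == ["rs17707300"]

    def test_matches_set_comprehension_oracle(self, rng):
        n = 100
        recs = [make_record(f"v{i}") for i in range(n)]
        cats = ["psychiatric", "obesity", "other"]
        ann = pd.DataFrame(
            {
                "variant_id": [f"v{rng.integers(n)}" for _ in range(150)],
                "trait": "t",
                "category": [cats[rng.integers(3)] for _ in range(150)],
                "pval": 10.0 ** rng.uniform(-12, 0, 150),
            }
        )
        chosen = ["psychiatric", "obesity"]
        thr = 5e-8
        removed = {
            row.variant_id
            for row in ann.itertuples()
            if row.category in chosen and row.pval < thr
        }
        kept, _ = confounder_filter(recs, ann, chosen, thr)
        assert {r.variant_id for r in kept} == {
            r.variant_id for r in recs if r.variant_id not in removed
        }


class TestSelectInstruments:
    def _strong(self, vid, chrom, pos, pval=1e-10):
        return make_record(vid, chrom=chrom, pos=pos, beta=0.1, se=0.01, pval=pval)

    def test_three_independent_signals_all_selected(self):
        exp_recs = [
            self._strong("a", "1", 1_000_000),
            self._strong("b", "2", 1_000_000),
            self._strong("c", "3", 1_000_000),
            make_record("weak", chrom="4", pval=0.5),
        ]
        exposure = SummaryDataset("e", "exposure", exp_recs)
        outcome = _outcome_ds(["a", "b", "c", "weak"])
        inst = select_instruments(exposure, outcome, None, None, SelectionConfig())
        assert sorted(inst.variant_ids) == ["a", "b", "c"]
        counts = list(inst.audit.values())
        assert counts == sorted(counts, reverse=True)  # monotone non-increasing
        assert all(f >= 10 for f in inst.f_stats.values())

    def test_no_variant_passes_p_filter(self):
        exposure = SummaryDataset(
            "e", "exposure", [make_record("a", pval=0.1), make_record("b", pval=0.2)]
        )
        inst = select_instruments(
            exposure, _outcome_ds(["a", "b"]), None, None, SelectionConfig()
        )
        assert inst.is_empty
        assert inst.audit["input"] == 2 and inst.audit["post_p_filter"] == 0

    def test_planted_proxy_substitution(self):
        exposure = SummaryDataset(
            "e",
            "exposure",
            [
                self._strong("missing", "1", 1_000_000, 1e-12),
                self._strong("partner", "1", 1_010_000, 1e-7),
            ],
        )
        outcome = _outcome_ds(["partner"])  # index variant absent from outcome
        r2 = np.array([[1, 0.95], [0.95, 1]])
        ld = LdReference(["missing", "partner"], r2)
        inst = select_instruments(exposure, outcome, ld, None, SelectionConfig())
        assert inst.variant_ids == ["partner"]
        assert inst.proxy_map == {"missing": "partner"}

    def test_f_screen_removes_weak_instrument(self):
        weak = make_record("weak", chrom="1", beta=0.005, se=0.002, pval=1e-6)
        assert per_snp_f(weak) < 10
        strong = self._strong("strong", "2", 1_000_000)
        exposure = SummaryDataset("e", "exposure", [weak, strong])
        inst = select_instruments(
            exposure, _outcome_ds(["weak", "strong"]), None, None, SelectionConfig()
        )
        assert inst.variant_ids == ["strong"]
        assert inst.audit["post_proxy"] == 2 and inst.audit["post_f"] == 1

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SelectionConfig(p_threshold=0)
        with pytest.raises(ValueError):
            SelectionConfig(clump_r2=0.9, proxy_r2=0.8)
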