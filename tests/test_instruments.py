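import dataclasses

import numpy as np
import pytest

from mrpipe import LdMatrix, clump, f_statistic, filter_weak, select_by_pvalue, select_instruments
from mrpipe.instruments import InstrumentError, exclude_outcome_associated

from conftest import make_record


def _records_with_pvals(pvals):
    return [
        make_record(snp_id=f"rs{i+1}", pos=1000 * (i + 1), pval=p)
        for i, p in enumerate(pvals)
    ]


class TestPvalueSelection:
    @pytest.mark.parametrize(
        "threshold,expected",
        [(5e-6, ["rs1", "rs2"]), (5e-8, ["rs1"]), (1e-5, ["rs1", "rs2", "rs3"])],
    )
    def test_thresholds(self, threshold, expected):
        recs = _records_with_pvals([1e-9, 1e-7, 9e-6])
        assert [r.snp_id for r in select_by_pvalue(recs, threshold)] == expected

    def test_bad_threshold(self):
        with pytest.raises(InstrumentError):
            select_by_pvalue([], 0.0)


class TestFStatistic:
    @pytest.mark.parametrize(
        "beta,se,expected",
        [(0.1, 0.05, 4.0), (0.0, 0.1, 0.0), (-0.2, 0.02, 100.0), (0.2, 0.02, 100.0)],
    )
    def test_values_and_sign_invariance(self, beta, se, expected):
        assert f_statistic(beta, se) == pytest.approx(expected)

    def test_filter_weak_boundary_inclusive(self):
        recs = [
            make_record(snp_id="a", beta=0.2, se=0.1),  # F = 4
            make_record(snp_id="b", beta=0.1, se=0.1 / np.sqrt(10)),  # F = 10
            make_record(snp_id="c", beta=1.0, se=0.1),  # F = 100
        ]
        assert [r.snp_id for r in filter_weak(recs)] == ["b", "c"]
        assert filter_weak(recs, f_min=1000.0) == []

    def test_filter_matches_per_record_recomputation(self, rng):
        recs = [
            make_record(snp_id=f"rs{i}", beta=float(rng.normal(0, 0.1)), se=float(rng.uniform(0.01, 0.1)))
            for i in range(50)
        ]
        got = filter_weak(recs, 10.0)
        expected = [r for r in recs if (r.beta / r.se) ** 2 >= 10.0]
        assert got == expected


def _brute_force_clump(records, ld, clump_r2, clump_kb):
    """Independent greedy reference: keep a SNP iff it conflicts with no
    better-ranked kept SNP."""
    ranked = sorted(records, key=lambda r: (r.pval, r.chrom, r.pos, r.snp_id))
    kept = []
    for rec in ranked:
        conflict = any(
            k.chrom == rec.chrom
            and abs(k.pos - rec.pos) <= clump_kb * 1000
            and ld.lookup(k.snp_id, rec.snp_id) >= clump_r2
            for k in kept
        )
        if not conflict:
            kept.append(rec)
    return {r.snp_id for r in kept}


def _block_world(rng, n_snp=30, n_blocks=3):
    """Random SNPs grouped into LD blocks with random within-block r²."""
    recs = []
    block_of = {}
    for i in range(n_snp):
        b = int(rng.integers(n_blocks))
        recs.append(
            make_record(
                snp_id=f"rs{i+1}",
                chrom=str(b + 1),
                pos=int(1_000_000 + rng.integers(0, 2_000_000)),
                pval=float(rng.uniform(1e-12, 1e-6)),
            )
        )
        block_of[f"rs{i+1}"] = b
    ids = [r.snp_id for r in recs]
    r2 = np.eye(n_snp)
    for i in range(n_snp):
        for j in range(i + 1, n_snp):
            if block_of[ids[i]] == block_of[ids[j]]:
                r2[i, j] = r2[j, i] = float(rng.uniform(0, 1))
    return recs, LdMatrix(snp_ids=tuple(ids), r2=r2)


class TestClump:
    def test_correlated_pair_keeps_best_pvalue(self, identity_ld):
        a = make_record(snp_id="a", pos=10_000, pval=1e-9)
        b = make_record(snp_id="b", pos=15_000, pval=1e-7)
        ld = LdMatrix(snp_ids=("a", "b"), r2=np.array([[1.0, 0.9], [0.9, 1.0]]))
        assert [r.snp_id for r in clump([a, b], ld)] == ["a"]

    def test_window_is_intra_chromosomal(self):
        a = make_record(snp_id="a", chrom="1", pos=10_000, pval=1e-9)
        b = make_record(snp_id="b", chrom="2", pos=10_000, pval=1e-7)
        ld = LdMatrix(snp_ids=("a", "b"), r2=np.array([[1.0, 0.9], [0.9, 1.0]]))
        assert len(clump([a, b], ld)) == 2

    def test_distance_beyond_window_retains_both(self, identity_ld):
        a = make_record(snp_id="a", pos=1_000, pval=1e-9)
        b = make_record(snp_id="b", pos=1_000 + 10_000 * 1000 + 1, pval=1e-7)
        ld = LdMatrix(snp_ids=("a", "b"), r2=np.array([[1.0, 0.9], [0.9, 1.0]]))
        assert len(clump([a, b], ld)) == 2

    def test_missing_ld_entry_is_error(self, identity_ld):
        recs = [make_record(snp_id="a"), make_record(snp_id="zzz", pos=2000)]
        ld = identity_ld(recs[:1])
        with pytest.raises(InstrumentError, match="zzz"):
            clump(recs, ld)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        recs, ld = _block_world(rng)
        got = {r.snp_id for r in clump(recs, ld, clump_r2=0.1, clump_kb=10_000)}
        assert got == _brute_force_clump(recs, ld, 0.1, 10_000)

    def test_row_order_invariance(self, rng):
        recs, ld = _block_world(rng)
        perm = list(rng.permutation(len(recs)))
        a = {r.snp_id for r in clump(recs, ld, 0.1)}
        b = {r.snp_id for r in clump([recs[i] for i in perm], ld, 0.1)}
        assert a == b

    def test_retained_count_monotone_in_window_and_r2(self, rng):
        recs, ld = _block_world(rng)
        sizes_kb = [len(clump(recs, ld, 0.3, kb)) for kb in (10, 1000, 10_000)]
        assert sizes_kb == sorted(sizes_kb, reverse=True)
        sizes_r2 = [len(clump(recs, ld, r2, 10_000)) for r2 in (0.8, 0.3, 0.01)]
        assert sizes_r2 == sorted(sizes_r2, reverse=True)


class TestSelectionFunnel:
    def test_audit_counts_reconcile(self, rng, identity_ld):
        recs = [
            make_record(
                snp_id=f"rs{i}",
                pos=1000 * i + 1,
                beta=float(rng.normal(0, 0.1)),
                se=float(rng.uniform(0.01, 0.05)),
                pval=float(10 ** rng.uniform(-12, 0)),
            )
            for i in range(40)
        ]
        inst = select_instruments(recs, identity_ld(recs), p_threshold=5e-6)
        a = inst.audit
        assert a["input"] == 40
        assert a["input"] - a["retained"] == (
            a["removed_pvalue"] + a["removed_clump"] + a["removed_weak"]
        )
        for r in inst.records:
            assert r.pval < 5e-6 and (r.beta / r.se) ** 2 >= 10

    def test_outcome_overlap_exclusion(self):
        inst = [make_record(snp_id="a"), make_record(snp_id="b", pos=2000)]
        outcome = [
            dataclasses.replace(inst[0], pval=1e-10),
            dataclasses.replace(inst[1], pval=0.2),
        ]
        kept = exclude_outcome_associated(inst, outcome, 5e-8)
        assert [r.snp_id for r in kept] == ["b"]
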