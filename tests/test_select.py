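import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitamr import (
    InstrumentSet,
    LDRecord,
    LDTable,
    SimulationConfig,
    VariantAssociation,
    exclude_annotated,
    filter_maf,
    filter_significance,
    find_proxy,
    ld_prune,
    ld_r2_from_dosages,
    restrict_to_regions,
    simulate_summary_stats,
    simulate_truth,
    variance_explained,
)
from vitamr.io import GeneRegion
from vitamr.select import ProxyPhaseError


def va(vid, pval=1e-10, eaf=0.3, beta=0.05, chrom="1", pos=1000, ea="A", oa="G"):
    return VariantAssociation(
        variant_id=vid, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=0.005, pval=pval,
    )


class TestSignificanceAndMAF:
    def test_boundary_p_is_dropped_strictly(self):
        out = filter_significance([va("a", pval=5e-8), va("b", pval=4.9e-8)])
        assert out.ids() == ["b"]
        assert out.provenance["a"].startswith("dropped:not_significant")

    def test_maf_boundaries(self):
        out = filter_maf([va("a", eaf=0.995), va("b", eaf=0.02), va("c", eaf=0.01)])
        assert out.ids() == ["b"]  # 0.005 and exactly-1% MAF both fail "more than 1%"

    def test_missing_eaf_dropped_with_reason(self):
        out = filter_maf([va("a", eaf=None)])
        assert out.ids() == [] and out.provenance["a"] == "dropped:missing_eaf"

    def test_filters_commute(self):
        records = [
            va("a", pval=1e-3), va("b", eaf=0.005), va("c"),
            va("d", pval=0.5, eaf=0.001), va("e", eaf=0.9),
        ]
        ab = filter_maf(filter_significance(records))
        ba = filter_significance(filter_maf(records))
        assert ab.ids() == ba.ids()

    def test_null_table_retains_almost_nothing(self):
        cfg = SimulationConfig(n_variants=500, causal_beta=0.0, target_r2=0.0005,
                               exposure_n=500, seed=5)
        truth = simulate_truth(cfg)
        exposure, _ = simulate_summary_stats(truth, cfg)
        kept = filter_significance(exposure)
        # expected count ~ J * threshold under the null; allow a tiny margin
        assert len(kept) <= 2


class TestLDPrune:
    def test_keeps_stronger_of_correlated_pair(self):
        ld = LDTable([LDRecord("a", "b", 0.9)])
        out = ld_prune([va("a", pval=1e-20), va("b", pval=1e-10)], ld)
        assert out.ids() == ["a"]

    def test_untabled_variants_all_kept(self):
        out = ld_prune([va("a"), va("b"), va("c")], LDTable())
        assert out.ids() == ["a", "b", "c"]

    def test_chain_keeps_ends(self):
        ld = LDTable([LDRecord("a", "b", 0.06), LDRecord("b", "c", 0.06)])
        out = ld_prune(
            [va("a", pval=1e-30), va("b", pval=1e-20), va("c", pval=1e-10)], ld
        )
        assert out.ids() == ["a", "c"]

    def test_self_pair_is_ignored(self):
        ld = LDTable([LDRecord("a", "a", 1.0)])
        assert ld_prune([va("a")], ld).ids() == ["a"]

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_greedy_output_is_maximal(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        ids = [f"v{i}" for i in range(n)]
        recs = [va(i, pval=float(rng.uniform(1e-30, 1e-8))) for i in ids]
        pairs = []
        for i in range(n):
            for k in range(i + 1, n):
                if rng.random() < 0.3:
                    pairs.append(LDRecord(ids[i], ids[k], float(rng.uniform(0, 1))))
        ld = LDTable(pairs)
        out = ld_prune(recs, ld, 0.05)
        kept = set(out.ids())
        # kept set is internally unlinked
        for a in kept:
            for b in kept:
                if a < b:
                    r2 = ld.r2(a, b)
                    assert r2 is None or r2 < 0.05
        # every pruned variant clashes with some kept variant
        for v in set(ids) - kept:
            assert any((ld.r2(v, k) or 0) >= 0.05 for k in kept)


class TestFindProxy:
    def _outcome(self, *vids, pal=()):
        out = {}
        for v in vids:
            ea, oa = ("A", "T") if v in pal else ("G", "T")
            out[v] = va(v, ea=ea, oa=oa, eaf=0.5 if v in pal else 0.3)
        return out

    def test_absent_target_with_good_partner(self):
        ld = LDTable([LDRecord("idx", "p1", 0.95, "A", "G")])
        proxy = find_proxy(va("idx"), ld, self._outcome("p1"))
        assert proxy is not None and proxy.variant_id == "p1"
        assert proxy.effect_allele == "G"  # phased with the index effect allele
        assert proxy.beta == va("idx").beta

    def test_below_threshold_returns_none(self):
        ld = LDTable([LDRecord("idx", "p1", 0.85, "A", "G")])
        assert find_proxy(va("idx"), ld, self._outcome("p1")) is None

    def test_highest_r2_candidate_wins(self):
        ld = LDTable([
            LDRecord("idx", "p1", 0.95, "A", "G"),
            LDRecord("idx", "p2", 0.99, "A", "G"),
        ])
        proxy = find_proxy(va("idx"), ld, self._outcome("p1", "p2"))
        assert proxy.variant_id == "p2"

    def test_intermediate_palindromic_candidate_skipped(self):
        ld = LDTable([LDRecord("idx", "p1", 0.99, "A", "A")])
        assert find_proxy(va("idx"), ld, self._outcome("p1", pal=("p1",))) is None

    def test_missing_phase_is_an_error(self):
        ld = LDTable([LDRecord("idx", "p1", 0.95)])
        with pytest.raises(ProxyPhaseError):
            find_proxy(va("idx"), ld, self._outcome("p1"))

    def test_own_exposure_record_preferred(self):
        ld = LDTable([LDRecord("idx", "p1", 0.95, "A", "G")])
        own = va("p1", beta=0.123, ea="G", oa="T")
        proxy = find_proxy(va("idx"), ld, self._outcome("p1"), exposure_table={"p1": own})
        assert proxy is own


class TestRegionsAndExclusions:
    GC = GeneRegion("GC", "4", 72_607_410, 72_669_758, window_bp=100_000)

    def test_inside_region_kept_chr_prefix_normalized(self):
        inside = va("a", chrom="chr4", pos=72_650_000)
        out = restrict_to_regions([inside], [self.GC])
        assert out.ids() == ["a"]

    def test_one_bp_outside_window_dropped(self):
        edge = va("a", chrom="4", pos=72_607_410 - 100_000)
        beyond = va("b", chrom="4", pos=72_607_410 - 100_001)
        out = restrict_to_regions([edge, beyond], [self.GC])
        assert out.ids() == ["a"]

    def test_empty_intersection_warns_not_raises(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="vitamr.select"):
            out = restrict_to_regions([va("a", chrom="1", pos=500)], [self.GC])
        assert len(out) == 0
        assert any("no instruments" in r.getMessage() for r in caplog.records)

    def test_exclusion_accounting(self):
        eleven = [va(f"v{i}") for i in range(9)] + [va("rs11723621"), va("rs6127099")]
        out = exclude_annotated(eleven, {"rs11723621": "", "rs6127099": ""})
        assert len(out) == 9
        assert out.provenance["rs11723621"] == "dropped:annotated"

    def test_empty_exclusion_is_identity_and_absent_id_noop(self):
        recs = [va("a"), va("b")]
        assert exclude_annotated(recs, {}).ids() == ["a", "b"]
        assert exclude_annotated(recs, {"zzz": ""}).ids() == ["a", "b"]


class TestVarianceExplained:
    def test_single_variant(self):
        assert variance_explained([va("a", eaf=0.5, beta=0.1)]) == pytest.approx(0.005)

    def test_empty_set_is_zero(self):
        assert variance_explained([]) == 0.0

    def test_missing_eaf_names_variant(self):
        with pytest.raises(ValueError, match="rsbad"):
            variance_explained([va("rsbad", eaf=None)])

    def test_recovers_simulation_target(self):
        cfg = SimulationConfig(n_variants=80, target_r2=0.04, seed=17)
        truth = simulate_truth(cfg)
        exposure, _ = simulate_summary_stats(truth, cfg)
        # estimated betas carry sampling noise; noise inflates the sum slightly
        assert variance_explained(exposure) == pytest.approx(0.04, abs=0.005)


class TestDosageR2:
    def test_identical_and_mirrored_vectors(self):
        a = [0.0, 1.0, 2.0, 1.0, 0.0]
        assert ld_r2_from_dosages(a, a) == pytest.approx(1.0)
        assert ld_r2_from_dosages(a, [2 - x for x in a]) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert ld_r2_from_dosages([0, 2, 0, 2], [0, 0, 2, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            ld_r2_from_dosages([1, 1, 1], [0, 1, 2])


class TestProvenance:
    def test_provenance_is_exhaustive(self):
        records = [va("a", pval=0.5), va("b", eaf=0.001), va("c"), va("d")]
        out = filter_maf(filter_significance(records))
        counts = out.counts()
        assert counts["input"] == 4
        assert counts["kept"] + counts["dropped"] == counts["input"]
        assert all(
            s == "kept" or s.startswith("dropped:") for s in out.provenance.values()
        )
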