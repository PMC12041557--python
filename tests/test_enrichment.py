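"""GO lifting, resampling enrichment and gene-list overlap."""

import numpy as np
import pytest
from scipy import stats

from famscan.enrichment import (AnnotationMap, chi_square_overlap,
                                filter_terms, lift_go_to_families,
                                sampling_enrichment)


def make_planted_instance(seed=0, n_background=400, n_focal=40,
                          p_focal=0.8, p_rest=0.1, n_noise_terms=20):
    """Background of families with one planted term plus uniform noise terms."""
    rng = np.random.default_rng(seed)
    families = [f"F{i:04d}" for i in range(n_background)]
    focal = set(families[:n_focal])
    mapping = {}
    for fam in families:
        terms = set()
        p = p_focal if fam in focal else p_rest
        if rng.random() < p:
            terms.add("GO:PLANTED")
        for j in range(n_noise_terms):
            if rng.random() < 0.3:
                terms.add(f"GO:N{j:03d}")
        if terms:
            mapping[fam] = frozenset(terms)
    return AnnotationMap(mapping, frozenset(families)), focal


class TestLift:
    def test_union_of_member_genes(self):
        genes = AnnotationMap({"g1": frozenset({"GO:1"})},
                              frozenset({"g1", "g2"}))
        fam = lift_go_to_families(genes, {"g1": "F", "g2": "F"})
        assert fam.mapping == {"F": frozenset({"GO:1"})}
        assert fam.background == {"F"}

    def test_no_annotations(self):
        genes = AnnotationMap({}, frozenset({"g1"}))
        fam = lift_go_to_families(genes, {"g1": "F"})
        assert fam.mapping == {}

    def test_matches_set_union_oracle(self, rng):
        genes = [f"g{i}" for i in range(500)]
        membership = {g: f"F{rng.integers(50)}" for g in genes}
        mapping = {}
        for g in genes:
            terms = {f"GO:{t}" for t in rng.choice(30, rng.integers(0, 4),
                                                   replace=False)}
            if terms:
                mapping[g] = frozenset(terms)
        ann = AnnotationMap(mapping, frozenset(genes))
        lifted = lift_go_to_families(ann, membership)
        oracle = {}
        for g, terms in mapping.items():
            oracle.setdefault(membership[g], set()).update(terms)
        assert {f: set(t) for f, t in lifted.mapping.items()} == oracle

    def test_family_size_filter_must_follow_lifting(self):
        """A term on 60 genes spread over 40 families survives a >=50 filter
        only at the gene level: lifting first, then filtering at the family
        level correctly drops it."""
        membership = {f"g{i}": f"F{i % 40}" for i in range(60)}
        gene_ann = AnnotationMap(
            {g: frozenset({"GO:X"}) for g in membership},
            frozenset(membership))
        assert len(filter_terms(gene_ann, 50).terms) == 1  # gene level: kept
        fam_ann = lift_go_to_families(gene_ann, membership)
        assert len(filter_terms(fam_ann, 50).terms) == 0   # family level: dropped


class TestFilterTerms:
    def test_boundary_at_threshold(self):
        m49 = {f"F{i}": frozenset({"GO:A"}) for i in range(49)}
        m50 = {f"F{i}": frozenset({"GO:A"}) for i in range(50)}
        bg = frozenset(f"F{i}" for i in range(50))
        assert filter_terms(AnnotationMap(m49, bg), 50).terms == frozenset()
        assert filter_terms(AnnotationMap(m50, bg), 50).terms == {"GO:A"}

    def test_min_one_is_identity(self, rng):
        mapping = {f"F{i}": frozenset({f"GO:{rng.integers(5)}"})
                   for i in range(20)}
        ann = AnnotationMap(mapping, frozenset(mapping))
        assert filter_terms(ann, 1).mapping == ann.mapping

    def test_matches_counting_oracle(self, rng):
        mapping = {}
        for i in range(100):
            ts = {f"GO:{t}" for t in rng.choice(10, rng.integers(1, 4),
                                                replace=False)}
            mapping[f"F{i}"] = frozenset(ts)
        ann = AnnotationMap(mapping, frozenset(mapping))
        out = filter_terms(ann, 25)
        counts = {}
        for ts in mapping.values():
            for t in ts:
                counts[t] = counts.get(t, 0) + 1
        assert out.terms == {t for t, c in counts.items() if c >= 25}


class TestSamplingEnrichment:
    def test_universal_term_is_degenerate(self):
        bg = [f"F{i}" for i in range(20)]
        ann = AnnotationMap({f: frozenset({"GO:ALL"}) for f in bg},
                            frozenset(bg))
        res = sampling_enrichment(bg[:5], ann, n_samples=100, seed=1)
        row = res.iloc[0]
        assert row["degenerate"]
        assert row["observed_proportion"] == 1.0 == row["null_mean"]
        assert row["p"] == 1.0

    def test_focal_equals_background_degenerate(self):
        bg = [f"F{i}" for i in range(10)]
        mapping = {f: frozenset({"GO:A"}) for f in bg[:6]}
        ann = AnnotationMap(mapping, frozenset(bg))
        res = sampling_enrichment(bg, ann, n_samples=50, seed=2)
        assert res["degenerate"].all()

    def test_seed_reproducibility(self):
        ann, focal = make_planted_instance(seed=3)
        a = sampling_enrichment(focal, ann, n_samples=200, seed=7)
        b = sampling_enrichment(focal, ann, n_samples=200, seed=7)
        assert np.array_equal(a["p"].to_numpy(), b["p"].to_numpy())

    def test_planted_term_ranks_first(self):
        ann, focal = make_planted_instance(seed=4)
        res = sampling_enrichment(focal, ann, n_samples=1000, seed=5)
        best = res.sort_values("q").iloc[0]
        assert best["term"] == "GO:PLANTED"
        assert best["q"] < 0.05
        assert best["direction"] == "over"

    def test_seed_stability_of_z(self):
        """Across seeds each Z varies only by resampling noise: for moderate
        |z| the sd across seeds stays below 0.15 at 1,000 samples; for the
        planted term (|z| ~ 12) the noise of the estimated null sd scales the
        spread with |z|, so stability is relative there."""
        ann, focal = make_planted_instance(seed=6)
        by_term = {}
        for seed in range(12):
            res = sampling_enrichment(focal, ann, n_samples=1000, seed=seed)
            for term, z in zip(res["term"], res["z"]):
                by_term.setdefault(term, []).append(float(z))
        planted = np.array(by_term.pop("GO:PLANTED"))
        assert np.std(planted) / np.abs(np.mean(planted)) < 0.08
        for term, zs in by_term.items():
            assert np.std(zs) < 0.15, term

    def test_null_pvalues_roughly_uniform(self):
        """Under no signal the per-repetition KS rejection rate stays nominal."""
        rejections = 0
        n_reps = 60
        for rep in range(n_reps):
            ann, focal = make_planted_instance(seed=100 + rep, p_focal=0.1,
                                               p_rest=0.1)
            res = sampling_enrichment(focal, ann, n_samples=400,
                                      seed=200 + rep)
            ps = res.loc[~res["degenerate"], "p"]
            if stats.kstest(ps, "uniform").pvalue < 0.01:
                rejections += 1
        assert rejections <= max(3, int(0.08 * n_reps))

    def test_focal_outside_background_rejected(self):
        ann, focal = make_planted_instance(seed=8)
        with pytest.raises(ValueError):
            sampling_enrichment({"NOT_A_FAMILY"}, ann, n_samples=10, seed=0)


class TestChiSquareOverlap:
    def test_proportional_table_is_null(self):
        bg = [f"g{i}" for i in range(90)]
        lst = set(bg[:30])                       # rows: 30 vs 60
        focal = set(bg[:10]) | set(bg[30:50])    # 10/30 in list, 20/60 out
        res = chi_square_overlap(lst, None, focal, bg)
        assert np.allclose(res.table, [[10, 20], [20, 40]])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.log2_fold == pytest.approx(0.0, abs=1e-12)

    def test_perfect_association(self):
        bg = [f"g{i}" for i in range(40)]
        half = set(bg[:20])
        res = chi_square_overlap(half, None, half, bg)
        assert res.direction == "over"
        assert res.chi2 == pytest.approx(40.0)   # n for a perfect 2x2 split
        assert res.p < 1e-9

    def test_fixed_table_matches_hand_formula(self):
        """[[30,70],[20,180]] over n=300 against sum((O-E)^2/E)."""
        bg = [f"g{i}" for i in range(300)]
        lst = set(bg[:100])
        focal = set(bg[:30]) | set(bg[100:120])
        res = chi_square_overlap(lst, None, focal, bg)
        table = np.array([[30.0, 70.0], [20.0, 180.0]])
        assert np.allclose(res.table, table)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2_hand = ((table - expected) ** 2 / expected).sum()
        assert res.chi2 == pytest.approx(chi2_hand, abs=1e-12)
        assert res.p == pytest.approx(float(stats.chi2.sf(chi2_hand, 1)),
                                      abs=1e-12)

    def test_background_harmonization(self):
        bg = [f"g{i}" for i in range(100)]
        list_bg = set(bg[:50])
        lst = set(bg[:25]) | {"外部gene"}        # extra gene outside study bg
        focal = set(bg[:10]) | set(bg[60:70])    # second half dropped by harmonization
        res = chi_square_overlap(lst, list_bg, focal, bg)
        assert res.n_background == 50
        assert res.table.sum() == 50

    def test_small_expected_flagged(self):
        bg = [f"g{i}" for i in range(30)]
        res = chi_square_overlap(set(bg[:1]), None, set(bg[:2]), bg)
        assert res.unreliable

    def test_statistic_symmetric_in_set_roles(self):
        bg = [f"g{i}" for i in range(200)]
        a = set(bg[:60]) | set(bg[100:120])
        b = set(bg[:40]) | set(bg[150:180])
        r1 = chi_square_overlap(a, None, b & set(bg), bg)
        r2 = chi_square_overlap(b, None, a & set(bg), bg)
        assert r1.chi2 == pytest.approx(r2.chi2, abs=1e-10)
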