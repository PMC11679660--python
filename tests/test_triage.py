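"""Exclusion cascade screens, linkage r2, power, and the bundled MAF table."""

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from hervtriage.triage import (
    TriageConfig,
    TriageDecision,
    VariantSummary,
    confirm_variants,
    dagger_screen,
    ddagger_screen,
    diamond_screen,
    geno_r2,
    linkage_clusters,
    load_common_variant_table,
    power_detectable_difference,
    rare_screen,
    somatic_flag,
    triage_variants,
)

#: variants whose control frequency is grossly discrepant with the external
#: database in the bundled 27-variant table (frozen regression expectation)
DISCREPANT = {
    "rs13030271", "rs13311049", "rs13311637", "rs611655",
    "rs61909780", "rs370565365", "rs3989120", "rs2750652",
}


@dataclass
class FakeResult:
    p_adj: float
    p_unadj: float


class TestConfirmVariants:
    def build(self, cells):
        results = {
            ("training", "blood"): {}, ("training", "tumor"): {},
            ("validation", "blood"): {}, ("validation", "tumor"): {},
        }
        for (s, t), mapping in cells.items():
            results[(s, t)] = mapping
        return results

    def test_confirmed_when_both_sets_significant_same_type(self):
        v = ("chr1", 1, "A", "T")
        results = self.build({
            ("training", "blood"): {v: FakeResult(1e-9, 1e-9)},
            ("validation", "blood"): {v: FakeResult(1e-8, 1e-8)},
        })
        confirmed, adj_only = confirm_variants(results, 1e-4)
        assert v in confirmed and not adj_only[v]

    def test_not_confirmed_when_validation_fails(self):
        v = ("chr1", 1, "A", "T")
        results = self.build({
            ("training", "blood"): {v: FakeResult(1e-9, 1e-9)},
            ("validation", "blood"): {v: FakeResult(0.2, 0.2)},
        })
        confirmed, _ = confirm_variants(results, 1e-4)
        assert v not in confirmed

    def test_adjusted_only_flagged(self):
        v = ("chr1", 1, "A", "T")
        results = self.build({
            ("training", "blood"): {v: FakeResult(1e-9, 0.3)},
            ("validation", "blood"): {v: FakeResult(1e-8, 0.2)},
        })
        confirmed, adj_only = confirm_variants(results, 1e-4)
        assert v in confirmed and adj_only[v]

    def test_missing_set_is_contract_error(self):
        with pytest.raises(ValueError):
            confirm_variants({("training", "blood"): {}}, 1e-4)


class TestDaggerScreen:
    @pytest.mark.parametrize(
        "train,valid,excluded",
        [
            (0.25, 0.26, False),  # near-identical
            (0.30, 0.05, True),   # gross inconsistency
            (0.20, 0.30, False),  # |diff| == 0.10 boundary: strict >
            (0.04, 0.09, True),   # ratio 2.25 outside [0.5, 2]
            (None, 0.2, False),   # not evaluable -> retain
        ],
    )
    def test_examples(self, train, valid, excluded):
        assert dagger_screen(train, valid) is excluded


class TestDdaggerScreen:
    def sig(self, *cells):
        return {c: True for c in cells}

    def test_crossed_pattern_excluded(self):
        assert ddagger_screen(
            self.sig(("training", "tumor"), ("validation", "blood"))
        )

    def test_same_type_confirmation_retained(self):
        assert not ddagger_screen(
            self.sig(("training", "blood"), ("validation", "blood"))
        )

    def test_all_significant_retained(self):
        assert not ddagger_screen(
            self.sig(*[(s, t) for s in ("training", "validation")
                       for t in ("blood", "tumor")])
        )

    def test_nothing_significant_retained(self):
        assert not ddagger_screen({})


class TestDiamondScreen:
    @pytest.mark.parametrize(
        "internal,external,tri,exclude,inconclusive",
        [
            (0.378, 0.000, False, True, False),   # external zero -> infinite fold
            (0.749, 0.415, False, False, False),  # ratio 1.80 within fold 2
            (0.730, 0.357, True, False, True),    # tri-allelic: flag only
            (0.50, None, False, False, False),    # absent external -> retain
            (0.321, 0.462, False, False, False),  # fold 0.69 within [0.5, 2]
        ],
    )
    def test_examples(self, internal, external, tri, exclude, inconclusive):
        assert diamond_screen(internal, external, tri) == (exclude, inconclusive)

    def test_bundled_table_regression(self):
        """Default thresholds flag exactly the eight discrepant variants."""
        table = load_common_variant_table()
        flagged = set()
        for _, row in table.iterrows():
            ext = row["maf_external"]
            excl, _ = diamond_screen(
                row["maf_control_internal"],
                None if pd.isna(ext) else float(ext),
                bool(row["tri_allelic"]),
            )
            if excl:
                flagged.add(row["name"])
        assert flagged == DISCREPANT


class TestRareScreen:
    @pytest.mark.parametrize(
        "case,internal,external,expected",
        [
            (0.12, 0.005, 0.002, "rare_enriched"),
            (0.08, 0.0, 0.0, "not_extracted"),
            (0.15, 0.0, 0.02, "extracted"),      # external above control bound
            (0.15, 0.0, None, "rare_enriched"),  # absent external counts as 0
            (0.10, 0.01, 0.011, "extracted"),
            (0.10, 0.005, 0.005, "rare_enriched"),  # 0.10 >= 10 x 0.005... holds
            (0.10, 0.005, 0.02, "extracted"),
        ],
    )
    def test_examples(self, case, internal, external, expected):
        assert rare_screen(case, internal, external) == expected

    def test_monotone_in_case_frequency(self, rng):
        order = {"not_extracted": 0, "extracted": 1, "rare": 2, "rare_enriched": 3}
        internal, external = 0.004, 0.008
        prev = -1
        for case in np.linspace(0.01, 0.9, 50):
            cls = rare_screen(float(case), internal, external)
            # classification can only move upward (or hold) as case MAF grows,
            # once past the extraction threshold
            if case >= 0.10:
                assert order[cls] >= prev
                prev = order[cls]


class TestSomaticFlag:
    @pytest.mark.parametrize(
        "blood,tumor,flagged",
        [(0.05, 0.09, True), (0.09, 0.09, False), (0.10, 0.05, False),
         (0.05, 0.07, True)],
    )
    def test_examples(self, blood, tumor, flagged):
        assert somatic_flag(blood, tumor) is flagged


class TestGenoR2:
    def test_identical_vectors(self):
        res = geno_r2([0, 1, 2, 1], [0, 1, 2, 1])
        assert res.r2 == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        res = geno_r2([0, 0, 1, 1], [1, 1, 0, 0])
        assert res.r2 == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        res = geno_r2([1, 1, 1, 1], [0, 1, 2, 0])
        assert not res.defined and res.r2 is None

    def test_matches_pearson_oracle_with_missingness(self, rng):
        for _ in range(10):
            a = rng.choice([0, 1, 2, -1], 200, p=[0.4, 0.3, 0.2, 0.1]).astype(float)
            b = rng.choice([0, 1, 2, -1], 200, p=[0.4, 0.3, 0.2, 0.1]).astype(float)
            res = geno_r2(a, b)
            ok = (a >= 0) & (b >= 0)
            if res.defined:
                r = np.corrcoef(a[ok], b[ok])[0, 1]
                assert res.r2 == pytest.approx(r * r, abs=1e-12)
                # symmetry
                assert geno_r2(b, a).r2 == pytest.approx(res.r2, abs=1e-12)

    def test_affine_recoding_invariance(self, rng):
        a = rng.binomial(2, 0.4, 100).astype(float)
        b = rng.binomial(2, 0.5, 100).astype(float)
        base = geno_r2(a, b).r2
        assert geno_r2(2 * a + 1, b).r2 == pytest.approx(base, abs=1e-12)

    def test_linkage_clusters_group_correlated_variants(self, rng):
        g1 = rng.binomial(2, 0.5, 300)
        g2 = g1.copy()
        g3 = rng.binomial(2, 0.5, 300)
        keys = ["v1", "v2", "v3"]
        clusters = linkage_clusters(
            np.column_stack([g1, g2, g3]), keys, r2_min=0.8
        )
        assert clusters.get("v1") == clusters.get("v2")
        assert "v3" not in clusters


class TestPower:
    def test_study_scale_value(self):
        assert power_detectable_difference(74, 0.10) == pytest.approx(
            0.818, abs=0.001
        )

    def test_vanishing_effect_approaches_alpha_side(self):
        assert power_detectable_difference(74, 1e-6) < 0.03

    def test_large_n_approaches_one(self):
        assert power_detectable_difference(10**6, 0.10) > 0.999


class TestCascade:
    def test_codes_computed_independently_and_unioned(self):
        s = VariantSummary(
            variant=("chr1", 1, "A", "T"),
            maf_case_blood=0.3, maf_case_tumor=0.3,
            maf_case_train=0.35, maf_case_valid=0.05,   # dagger
            maf_control_internal=0.5, maf_external=0.05,  # diamond
            significant={("training", "tumor"): True,
                         ("validation", "blood"): True},  # ddagger
        )
        [decision] = triage_variants([s], confirmed=set(), adjusted_only={})
        assert decision.status == "excluded"
        assert len(decision.exclusion_codes) == 3

    def test_confirmed_variant_carries_no_code(self):
        v = ("chr1", 2, "C", "G")
        s = VariantSummary(
            variant=v, maf_case_blood=0.3, maf_case_tumor=0.3,
            maf_case_train=0.3, maf_case_valid=0.31,
            maf_control_internal=0.5, maf_external=0.48,
            significant={(st, t): True for st in ("training", "validation")
                         for t in ("blood", "tumor")},
        )
        [decision] = triage_variants([s], confirmed={v}, adjusted_only={v: False})
        assert decision.status == "confirmed" and not decision.exclusion_codes

    def test_decision_invariants_enforced(self):
        with pytest.raises(ValueError):
            TriageDecision(variant=("x",), status="excluded")
        with pytest.raises(ValueError):
            TriageDecision(
                variant=("x",), status="confirmed",
                exclusion_codes={"diamond_db_discrepancy"},
            )
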