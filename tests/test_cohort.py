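"""Multiallelic splitting, cohort merge semantics, frequencies, and splits."""

import numpy as np
import pandas as pd
import pytest

from hervtriage import io as hio
from hervtriage.cohort import (
    MISSING,
    GenotypeMatrix,
    MergeError,
    RawSite,
    UndefinedFrequencyError,
    allele_frequency,
    merge_cohorts,
    split_multiallelic,
    stratified_split,
)


def site(chrom, pos, ref, alts, pairs, rsid="."):
    return RawSite(chrom, pos, ref, alts, rsid, np.array(pairs, dtype=np.int16))


def simple_matrix(ids, variants, genotypes, cohort="case", stype="blood"):
    samples = pd.DataFrame(
        {"cohort": cohort, "sample_type": stype},
        index=pd.Index(ids, name="sample_id"),
    )
    return GenotypeMatrix(
        samples=samples,
        variants=pd.DataFrame(variants),
        genotypes=np.array(genotypes, dtype=np.int8),
    )


def variant_row(pos, ref="A", alt="T", chrom="chr1"):
    return {
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "rsid": ".",
        "multiallelic_split": False, "alt_index": 1,
    }


class TestSplitMultiallelic:
    def test_biallelic_passthrough(self):
        variants, geno = split_multiallelic(
            [site("chr1", 100, "A", ["T"], [[0, 1]])]
        )
        assert len(variants) == 1
        assert not variants.loc[0, "multiallelic_split"]
        assert geno[0, 0] == 1

    def test_het_alt_alt_decomposes_to_one_copy_each(self):
        variants, geno = split_multiallelic(
            [site("chr1", 100, "C", ["T", "G"], [[1, 2]])]
        )
        assert list(variants["alt"]) == ["T", "G"]
        assert geno[0].tolist() == [1, 1]

    def test_split_records_share_rsid_and_flag(self):
        variants, _ = split_multiallelic(
            [site("chr2", 500, "C", ["T", "G"], [[0, 0]], rsid="rs10166768")]
        )
        assert list(variants["rsid"]) == ["rs10166768"] * 2
        assert variants["multiallelic_split"].all()

    def test_symbolic_alt_skipped(self):
        variants, _ = split_multiallelic(
            [site("chr1", 100, "A", ["<DEL>", "T"], [[0, 2]])]
        )
        assert list(variants["alt"]) == ["T"]

    def test_half_call_is_missing(self):
        _, geno = split_multiallelic(
            [site("chr1", 100, "A", ["T"], [[0, -1], [1, 1]])]
        )
        assert geno[:, 0].tolist() == [MISSING, 2]


class TestMergeCohorts:
    def case_and_control(self, missing_to_ref=True):
        case = simple_matrix(
            ["s1", "s2"],
            [variant_row(100), variant_row(200)],
            [[1, 2], [0, MISSING]],
        )
        ctrl = simple_matrix(
            ["c1", "c2"],
            [variant_row(100)],
            [[0], [1]],
            cohort="control", stype="control",
        )
        return merge_cohorts(case, ctrl, missing_to_ref=missing_to_ref)

    def test_unseen_variant_coded_ref_when_missing_to_ref(self):
        merged = self.case_and_control(True)
        j = merged.variants.index[merged.variants["pos"] == 200][0]
        ctrl_rows = merged.samples["cohort"] == "control"
        assert (merged.genotypes[ctrl_rows.to_numpy(), j] == 0).all()

    def test_unseen_variant_missing_otherwise(self):
        merged = self.case_and_control(False)
        j = merged.variants.index[merged.variants["pos"] == 200][0]
        ctrl_rows = merged.samples["cohort"] == "control"
        assert (merged.genotypes[ctrl_rows.to_numpy(), j] == MISSING).all()

    def test_explicit_missing_preserved_in_both_modes(self):
        for mode in (True, False):
            merged = self.case_and_control(mode)
            j = merged.variants.index[merged.variants["pos"] == 200][0]
            i = list(merged.samples.index).index("s2")
            assert merged.genotypes[i, j] == MISSING

    def test_variant_union_symmetric(self):
        case = simple_matrix(["s1"], [variant_row(100)], [[1]])
        ctrl = simple_matrix(
            ["c1"], [variant_row(300)], [[2]], cohort="control",
            stype="control",
        )
        ab = merge_cohorts(case, ctrl).variant_keys()
        ba = merge_cohorts(ctrl, case).variant_keys()
        assert list(ab) == list(ba)

    def test_conflicting_ref_raises(self):
        case = simple_matrix(["s1"], [variant_row(100, ref="A")], [[1]])
        ctrl = simple_matrix(
            ["c1"], [variant_row(100, ref="G")], [[0]],
            cohort="control", stype="control",
        )
        with pytest.raises(MergeError, match="chr1:100"):
            merge_cohorts(case, ctrl)


class TestAlleleFrequency:
    def test_worked_example(self):
        assert allele_frequency([0, 0, 1, 2, MISSING]) == pytest.approx(0.375)

    def test_all_hom_ref(self):
        assert allele_frequency([0, 0, 0]) == 0.0

    def test_all_missing_undefined(self):
        with pytest.raises(UndefinedFrequencyError):
            allele_frequency([MISSING, MISSING])

    def test_matches_allele_count_oracle_and_permutation(self, rng):
        codes = rng.choice([0, 1, 2, MISSING], size=500, p=[0.5, 0.3, 0.15, 0.05])
        # oracle: expand each genotype into two allele observations
        alleles = []
        for c in codes:
            if c != MISSING:
                alleles += [1] * c + [0] * (2 - c)
        assert allele_frequency(codes) == pytest.approx(np.mean(alleles))
        perm = rng.permutation(codes)
        assert allele_frequency(perm) == allele_frequency(codes)


class TestStratifiedSplit:
    def make_samples(self, n, stratum="all"):
        return pd.DataFrame(
            {"stratum": [stratum] * n},
            index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        )

    def test_138_samples_give_83_training(self):
        split = stratified_split(self.make_samples(138), "stratum", seed=0)
        assert len(split.training) == 83 and len(split.validation) == 55

    def test_exact_three_two_ratio(self):
        split = stratified_split(self.make_samples(10), "stratum", seed=0)
        assert len(split.training) == 6 and len(split.validation) == 4

    def test_deterministic_given_seed(self):
        a = stratified_split(self.make_samples(50), "stratum", n_trials=2, seed=9)
        b = stratified_split(self.make_samples(50), "stratum", n_trials=2, seed=9)
        assert a.training == b.training and a.chosen_trial == b.chosen_trial

    def test_partition_is_exact_and_disjoint(self):
        samples = self.make_samples(37)
        split = stratified_split(samples, "stratum", seed=1)
        assert set(split.training) | set(split.validation) == set(samples.index)
        assert not set(split.training) & set(split.validation)

    def test_per_stratum_deviation_bound(self, rng):
        n = 200
        samples = pd.DataFrame(
            {"g": rng.choice(["a", "b", "c"], n)},
            index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        )
        split = stratified_split(samples, "g", seed=3)
        in_train = samples.index.isin(split.training)
        for _, idx in samples.groupby("g").groups.items():
            mask = samples.index.isin(idx)
            n_s = mask.sum()
            assert abs(in_train[mask].mean() - 0.6) <= 1.0 / n_s


class TestVcfRoundTrip:
    def test_write_then_read_recovers_matrix(self, tmp_path):
        variants = pd.DataFrame(
            [variant_row(100), variant_row(250, ref="C", alt="G")]
        )
        geno = np.array([[0, 2], [1, MISSING], [2, 0]], dtype=np.int8)
        path = tmp_path / "cohort.vcf"
        hio.write_vcf(path, variants, geno, ["s1", "s2", "s3"])
        gm = hio.read_genotype_matrix(path, "case", "blood")
        assert list(gm.samples.index) == ["s1", "s2", "s3"]
        assert gm.variants["pos"].tolist() == [100, 250]
        np.testing.assert_array_equal(gm.genotypes, geno)
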