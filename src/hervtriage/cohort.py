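"""Cohort genotype handling: multiallelic splitting, merging, frequencies, splits.

Case and control cohorts are joint-called separately in this workflow, so
merging them requires a convention for variants present in only one file:
with ``missing_to_ref`` every unseen genotype becomes homozygous reference
(0/0), mirroring the bcftools merge option of the same name. Explicitly
missing genotypes (./.) stay missing in either mode.

Genotypes are additive dosage codes {0, 1, 2}; missing is -1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "rsid",
    "multiallelic_split",
    "alt_index",
]


@dataclass
class RawSite:
    """One VCF site before multiallelic decomposition.

    ``allele_pairs`` holds per-sample allele indices (n_samples, 2) with -1
    for a missing allele; index 0 is the reference, i >= 1 the i-th ALT.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alts: list[str]
    rsid: str
    allele_pairs: np.ndarray


@dataclass
class GenotypeMatrix:
    """Samples x biallelic variants with additive dosage codes.

    samples: DataFrame indexed by sample_id with at least columns
        ``cohort`` ({case, control}) and ``sample_type`` ({blood, tumor,
        control}); extra columns (sex, strata) pass through untouched.
    variants: DataFrame with columns chrom, pos, ref, alt, rsid,
        multiallelic_split, alt_index.
    genotypes: int8 array (n_samples, n_variants); -1 encodes missing.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.genotypes.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ValueError(
                f"genotype shape {self.genotypes.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.genotypes, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_keys(self) -> pd.Index:
        v = self.variants
        return pd.Index(list(zip(v["chrom"], v["pos"], v["ref"], v["alt"])))

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        idx = self.samples.index.get_indexer(sample_ids)
        if (idx < 0).any():
            raise KeyError("unknown sample id in subset request")
        return GenotypeMatrix(
            samples=self.samples.loc[sample_ids].copy(),
            variants=self.variants.copy(),
            genotypes=self.genotypes[idx],
        )


def split_multiallelic(sites: list[RawSite]) -> tuple[pd.DataFrame, np.ndarray]:
    """Decompose sites into biallelic records with recoded genotypes.

    One output record per (site, alt). For the record carrying alt *i*, a
    sample's code counts its copies of allele *i*; copies of other alts
    count as reference. A half-call (one missing allele) is treated as
    missing. Symbolic alleles (<DEL>, *) are skipped with a warning.
    Records from sites with >1 alt keep the site's rsID and are flagged
    ``multiallelic_split``.
    """
    rows = []
    columns = []
    for site in sites:
        real_alts = [
            (i, a)
            for i, a in enumerate(site.alts, start=1)
            if a and not a.startswith("<") and a != "*"
        ]
        if len(real_alts) < len(site.alts):
            log.warning(
                "skipping symbolic allele(s) at %s:%d", site.chrom, site.pos
            )
        multi = len(site.alts) > 1
        pairs = site.allele_pairs
        missing_mask = (pairs < 0).any(axis=1)
        for alt_index, alt in real_alts:
            if alt == site.ref:
                raise ValueError(
                    f"ref == alt ({site.ref}) at {site.chrom}:{site.pos}"
                )
            codes = (pairs == alt_index).sum(axis=1).astype(np.int8)
            codes[missing_mask] = MISSING
            rows.append(
                {
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "ref": site.ref,
                    "alt": alt,
                    "rsid": site.rsid,
                    "multiallelic_split": multi,
                    "alt_index": alt_index,
                }
            )
            columns.append(codes)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    genotypes = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((0, 0), dtype=np.int8)
    )
    return variants, genotypes


class MergeError(ValueError):
    """Raised when cohorts disagree on the reference allele at a site."""


def merge_cohorts(
    a: GenotypeMatrix, b: GenotypeMatrix, missing_to_ref: bool = True
) -> GenotypeMatrix:
    """Merge two cohorts on the union of their variants.

    Variant identity is (chrom, pos, ref, alt). For a variant absent from
    one cohort's file, that cohort's genotypes are 0 when missing_to_ref is
    true and missing otherwise. Explicit ./. genotypes stay missing either
    way. Cohorts reporting different REF alleles at the same position raise
    a MergeError naming the site.
    """
    _check_ref_consistency(a.variants, b.variants)
    keys_a, keys_b = a.variant_keys(), b.variant_keys()
    union = keys_a.union(keys_b, sort=False).sort_values()
    fill = 0 if missing_to_ref else MISSING

    def expand(gm: GenotypeMatrix, keys: pd.Index) -> np.ndarray:
        out = np.full((gm.n_samples, len(union)), fill, dtype=np.int8)
        pos = union.get_indexer(keys)
        out[:, pos] = gm.genotypes
        return out

    variants = pd.concat([a.variants, b.variants]).drop_duplicates(
        subset=["chrom", "pos", "ref", "alt"]
    )
    variants["_key"] = list(
        zip(variants["chrom"], variants["pos"], variants["ref"], variants["alt"])
    )
    variants = (
        variants.set_index("_key").loc[union].reset_index(drop=True)
    )
    samples = pd.concat([a.samples, b.samples])
    if samples.index.duplicated().any():
        raise MergeError("duplicate sample IDs across cohorts")
    genotypes = np.vstack([expand(a, keys_a), expand(b, keys_b)])
    return GenotypeMatrix(samples=samples, variants=variants, genotypes=genotypes)


def _check_ref_consistency(va: pd.DataFrame, vb: pd.DataFrame) -> None:
    refs_a = va.groupby(["chrom", "pos"])["ref"].agg(set)
    refs_b = vb.groupby(["chrom", "pos"])["ref"].agg(set)
    shared = refs_a.index.intersection(refs_b.index)
    for site in shared:
        if refs_a.loc[site] != refs_b.loc[site]:
            raise MergeError(
                f"conflicting REF alleles at {site[0]}:{site[1]}: "
                f"{sorted(refs_a.loc[site])} vs {sorted(refs_b.loc[site])}"
            )


class UndefinedFrequencyError(ValueError):
    """All genotypes missing: the allele frequency is undefined."""


def allele_frequency(codes: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Alternate-allele frequency over non-missing genotypes.

    Computed as (sum of dosage codes) / (2 x non-missing count), with no
    minor-allele folding: values above 0.5 are reported as-is.
    """
    codes = np.asarray(codes)
    if mask is not None:
        codes = codes[np.asarray(mask)]
    ok = codes != MISSING
    n = int(ok.sum())
    if n == 0:
        raise UndefinedFrequencyError("all genotypes missing")
    return float(codes[ok].sum()) / (2.0 * n)


@dataclass
class CohortSplit:
    """Outcome of the stratified multi-trial train/validation split."""

    training: list[str]
    validation: list[str]
    strata: pd.Series
    balance_scores: list[float]
    chosen_trial: int
    seed: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(
    samples: pd.DataFrame,
    strata: str | list[str],
    train_fraction: float = 0.6,
    n_trials: int = 10,
    seed: int = 0,
    balance_columns: list[str] | None = None,
) -> CohortSplit:
    """Stratified 3:2 train/validation split by multi-trial randomization.

    Each stratum contributes round(train_fraction * n_s) samples to
    training (round-half-up, so 138 samples at 0.6 give 83). Among
    ``n_trials`` seeded shuffles the trial minimizing the balance score is
    kept; the score is the maximum absolute deviation of the training
    fraction from ``train_fraction`` across strata and, when
    ``balance_columns`` are given, across the level-sets of those columns
    as well (letting the randomization also balance secondary attributes
    such as sex). Ties go to the earliest trial; fully deterministic for a
    fixed seed. Empty strata are skipped with a warning.
    """
    if isinstance(strata, str):
        strata = [strata]
    labels = samples[strata].astype(str).agg("|".join, axis=1)
    rng = np.random.default_rng(seed)
    best: tuple[float, int, list[str], list[str]] | None = None
    scores: list[float] = []
    for trial in range(n_trials):
        train: list[str] = []
        valid: list[str] = []
        for label, group in samples.groupby(labels, sort=True):
            n_s = len(group)
            if n_s == 0:
                log.warning("empty stratum %r skipped", label)
                continue
            n_train = _round_half_up(train_fraction * n_s)
            order = rng.permutation(n_s)
            ids = group.index.to_numpy()[order]
            train.extend(ids[:n_train])
            valid.extend(ids[n_train:])
        score = _balance_score(
            samples, labels, train, train_fraction, balance_columns
        )
        scores.append(score)
        if best is None or score < best[0]:
            best = (score, trial, train, valid)
    assert best is not None
    return CohortSplit(
        training=sorted(best[2]),
        validation=sorted(best[3]),
        strata=labels,
        balance_scores=scores,
        chosen_trial=best[1],
        seed=seed,
    )


def _balance_score(
    samples: pd.DataFrame,
    labels: pd.Series,
    train: list[str],
    target: float,
    balance_columns: list[str] | None,
) -> float:
    in_train = samples.index.isin(train)
    devs = []
    for _, group_mask in labels.groupby(labels).groups.items():
        mask = samples.index.isin(group_mask)
        if mask.sum():
            devs.append(abs(in_train[mask].mean() - target))
    for col in balance_columns or []:
        for _, idx in samples.groupby(col).groups.items():
            mask = samples.index.isin(idx)
            if mask.sum():
                devs.append(abs(in_train[mask].mean() - target))
    return max(devs) if devs else 0.0
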