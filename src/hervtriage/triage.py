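"""Multi-stage triage of candidate variants.

Variants that pass training/validation association are screened by a
cascade of exclusion rules before being reported:

* dagger (†): inconsistent case allele frequency between training and
  validation sets;
* double dagger (‡): a "crossed" significance pattern — significant only
  in one sample type in training and the other in validation, with no
  same-type confirmation;
* diamond (◊): gross discrepancy between the internal control frequency
  and an external reference frequency (tri-allelic variants are exempt
  and only flagged inconclusive, since their split records make external
  comparisons ambiguous).

Separately, a rare-variant screen extracts case-enriched variants absent
or rare in controls, a somatic flag marks blood-to-tumor frequency
shifts, and genotype-r2 identifies linked variant clusters.

Exclusion codes are computed independently and unioned, so the cascade is
order-independent for a fixed variant.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SETS = ("training", "validation")
SAMPLE_TYPES = ("blood", "tumor")

CODE_DAGGER = "dagger_inconsistent_maf"
CODE_DDAGGER = "ddagger_crossed_pattern"
CODE_DIAMOND = "diamond_db_discrepancy"

CODE_SYMBOLS = {
    CODE_DAGGER: "†",   # †
    CODE_DDAGGER: "‡",  # ‡
    CODE_DIAMOND: "◊",  # ◊
}


@dataclass
class TriageConfig:
    """Thresholds of the exclusion cascade and downstream screens.

    The qualitative rules ("inconsistent", "large variation") are pinned to
    defaults that are deliberately configurable: an absolute frequency
    difference > 0.10 combined (for the database screen) with a fold change
    > 2. Rare variants are case MAF >= 0.10 with control MAF <= 0.01, and
    enrichment means >= 10x the external frequency. The somatic flag
    requires a blood-to-tumor gain of at least 0.02, and linkage clusters
    form at r2 >= 0.8.
    """

    dagger_abs: float = 0.10
    dagger_fold: float = 2.0
    diamond_abs: float = 0.10
    diamond_fold: float = 2.0
    rare_case_maf: float = 0.10
    rare_control_maf: float = 0.01
    enrich_fold: float = 10.0
    somatic_delta: float = 0.02
    ld_r2: float = 0.8


@dataclass
class VariantSummary:
    """Per-variant frequencies and significance pattern feeding the cascade."""

    variant: tuple
    maf_case_blood: float | None = None
    maf_case_tumor: float | None = None
    maf_case_train: float | None = None
    maf_case_valid: float | None = None
    maf_control_internal: float | None = None
    maf_external: float | None = None
    tri_allelic: bool = False
    #: significance of the adjusted model per (set, sample_type)
    significant: dict = field(default_factory=dict)
    gene: str = ""


@dataclass
class TriageDecision:
    variant: tuple
    status: str  # confirmed / excluded / rare_candidate / somatic_candidate
    exclusion_codes: set = field(default_factory=set)
    adjusted_only: bool = False
    inconclusive_db: bool = False
    rare_class: str = "not_extracted"
    somatic: bool = False
    linkage_cluster: int | None = None

    def __post_init__(self) -> None:
        if self.status == "excluded" and not self.exclusion_codes:
            raise ValueError("excluded decisions need at least one code")
        if self.status == "confirmed" and self.exclusion_codes:
            raise ValueError("confirmed decisions must carry no code")

    @property
    def symbols(self) -> str:
        return "".join(
            CODE_SYMBOLS[c] for c in sorted(self.exclusion_codes)
        )


def confirm_variants(
    results: dict, threshold: float
) -> tuple[set, dict]:
    """Identify variants significant in training AND validation.

    ``results`` maps (set, sample_type) -> {variant: AssociationResult}.
    A variant is confirmed iff its adjusted-model p-value is below the
    threshold in training and validation for the same sample type.
    Returns (confirmed set, adjusted_only flags): adjusted_only marks
    confirmed variants significant after adjustment but not before, in
    both sets for the confirming sample type.
    """
    for s in SETS:
        if not any((s, t) in results for t in SAMPLE_TYPES):
            raise ValueError(f"association results missing for the {s} set")
    confirmed: set = set()
    adjusted_only: dict = {}
    variants = set()
    for cell in results.values():
        variants.update(cell.keys())
    for v in variants:
        for t in SAMPLE_TYPES:
            train = results.get(("training", t), {}).get(v)
            valid = results.get(("validation", t), {}).get(v)
            if train is None or valid is None:
                continue
            if _sig(train.p_adj, threshold) and _sig(valid.p_adj, threshold):
                confirmed.add(v)
                adj_only = not (
                    _sig(train.p_unadj, threshold)
                    and _sig(valid.p_unadj, threshold)
                )
                adjusted_only[v] = adjusted_only.get(v, True) and adj_only
    return confirmed, adjusted_only


def _sig(p: float, threshold: float) -> bool:
    return p == p and p < threshold  # NaN-safe


def dagger_screen(
    maf_train: float | None,
    maf_valid: float | None,
    t_abs: float = 0.10,
    t_rel: float = 2.0,
) -> bool:
    """Exclude on inconsistent case frequency between training and validation.

    Exclude iff |MAF_train - MAF_valid| > t_abs (strict), or the ratio
    falls outside [1/t_rel, t_rel] when both frequencies are positive.
    Returns False (retain, not evaluable) if either frequency is absent.
    """
    if maf_train is None or maf_valid is None:
        return False
    if abs(maf_train - maf_valid) > t_abs:
        return True
    if maf_train > 0 and maf_valid > 0:
        ratio = maf_train / maf_valid
        if ratio > t_rel or ratio < 1.0 / t_rel:
            return True
    return False


def ddagger_screen(significant: dict) -> bool:
    """Exclude on a crossed train/validation significance pattern.

    ``significant`` maps (set, sample_type) -> bool. Exclude iff the only
    significant cells pair one sample type in training with the other in
    validation (no same-type confirmation in either direction).
    """
    cells = {
        (s, t): bool(significant.get((s, t), False))
        for s in SETS
        for t in SAMPLE_TYPES
    }
    same_type = any(
        cells[("training", t)] and cells[("validation", t)]
        for t in SAMPLE_TYPES
    )
    if same_type:
        return False
    crossed = (
        cells[("training", "blood")] and cells[("validation", "tumor")]
    ) or (
        cells[("training", "tumor")] and cells[("validation", "blood")]
    )
    return crossed


def diamond_screen(
    maf_internal: float | None,
    maf_external: float | None,
    tri_allelic: bool = False,
    t_abs: float = 0.10,
    t_fold: float = 2.0,
) -> tuple[bool, bool]:
    """Exclude on internal-vs-external control frequency discrepancy.

    Returns (exclude, inconclusive). Exclude iff an external frequency is
    reported, |internal - external| > t_abs, and the fold change exceeds
    t_fold in either direction (an external frequency of exactly 0 counts
    as infinite fold change). Tri-allelic variants are never excluded here:
    a discrepant tri-allelic variant is retained but flagged inconclusive.
    """
    if maf_internal is None:
        raise ValueError("internal control frequency is required")
    if maf_external is None:
        return False, False
    discrepant = abs(maf_internal - maf_external) > t_abs
    if discrepant:
        if maf_external == 0.0 or maf_internal == 0.0:
            fold_exceeded = True
        else:
            ratio = maf_internal / maf_external
            fold_exceeded = ratio > t_fold or ratio < 1.0 / t_fold
        discrepant = fold_exceeded
    if discrepant and tri_allelic:
        return False, True
    return discrepant, False


def rare_screen(
    maf_case: float,
    maf_control_internal: float | None,
    maf_external: float | None,
    case_maf_min: float = 0.10,
    control_maf_max: float = 0.01,
    enrich_fold: float = 10.0,
) -> str:
    """Classify a candidate rare variant.

    Extraction requires case MAF >= case_maf_min. Among extracted
    variants, ``rare`` requires every available control frequency
    (internal and external; an absent external counts as 0) to be
    <= control_maf_max; ``rare_enriched`` additionally requires the case
    frequency to reach enrich_fold times the external frequency (or the
    external frequency to be absent/zero).
    """
    if maf_case is None:
        raise ValueError("case frequency is required")
    if maf_case < case_maf_min:
        return "not_extracted"
    internal = maf_control_internal if maf_control_internal is not None else 0.0
    external = maf_external if maf_external is not None else 0.0
    if internal > control_maf_max or external > control_maf_max:
        return "extracted"
    if external == 0.0 or maf_case >= enrich_fold * external:
        return "rare_enriched"
    return "rare"


def somatic_flag(
    maf_blood: float, maf_tumor: float, min_delta: float = 0.02
) -> bool:
    """Flag a blood-to-tumor frequency gain of at least ``min_delta``."""
    return (maf_tumor - maf_blood) >= min_delta


@dataclass
class LDResult:
    variant_a: tuple
    variant_b: tuple
    r2: float | None
    n_pairs: int
    defined: bool = True


def geno_r2(
    dosage_a: np.ndarray,
    dosage_b: np.ndarray,
    key_a: tuple = (),
    key_b: tuple = (),
) -> LDResult:
    """Genotype-level linkage: squared Pearson correlation of dosages.

    Computed over pairwise-complete samples (both genotypes non-missing,
    missing encoded as -1). Undefined (flagged) when fewer than two
    complete pairs remain or either vector is constant on that subset.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    n = int(ok.sum())
    if n < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return LDResult(key_a, key_b, None, n, defined=False)
    r = np.corrcoef(a, b)[0, 1]
    return LDResult(key_a, key_b, float(r * r), n)


def linkage_clusters(
    dosages: np.ndarray, keys: list, r2_min: float = 0.8
) -> dict:
    """Group variants whose pairwise geno-r2 reaches ``r2_min``.

    ``dosages`` is (n_samples, n_variants). Returns {key: cluster_id} for
    variants belonging to a cluster of size >= 2 (single-linkage over the
    r2 >= r2_min graph).
    """
    m = len(keys)
    parent = list(range(m))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(m):
        for j in range(i + 1, m):
            res = geno_r2(dosages[:, i], dosages[:, j])
            if res.defined and res.r2 >= r2_min:
                parent[find(i)] = find(j)
    roots: dict = {}
    assignment: dict = {}
    for i in range(m):
        roots.setdefault(find(i), []).append(i)
    cluster_id = 0
    for members in roots.values():
        if len(members) >= 2:
            for i in members:
                assignment[keys[i]] = cluster_id
            cluster_id += 1
    return assignment


def power_detectable_difference(
    n: int, p_alt: float, alpha: float = 0.05
) -> float:
    """Normal-approximation power to detect a proportion difference.

    Two-sided one-sample test of a proportion against zero with the
    variance taken at the alternative:
    power = Phi( p_alt / sqrt(p_alt (1 - p_alt) / n) - z_{1-alpha/2} ).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (0.0 < p_alt < 1.0):
        raise ValueError("p_alt must be in (0, 1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(p_alt / math.sqrt(p_alt * (1 - p_alt) / n) - z))


def triage_variants(
    summaries: list[VariantSummary],
    confirmed: set,
    adjusted_only: dict,
    config: TriageConfig | None = None,
) -> list[TriageDecision]:
    """Apply the full exclusion cascade to candidate variants.

    Exclusion codes are computed independently per rule and unioned; a
    variant with no code stays confirmed. Rare and somatic screens are
    annotated on every summary regardless of confirmation status.
    """
    cfg = config or TriageConfig()
    decisions = []
    for s in summaries:
        codes = set()
        inconclusive = False
        if dagger_screen(s.maf_case_train, s.maf_case_valid,
                         cfg.dagger_abs, cfg.dagger_fold):
            codes.add(CODE_DAGGER)
        if ddagger_screen(s.significant):
            codes.add(CODE_DDAGGER)
        if s.maf_control_internal is not None:
            excl, inconclusive = diamond_screen(
                s.maf_control_internal, s.maf_external, s.tri_allelic,
                cfg.diamond_abs, cfg.diamond_fold,
            )
            if excl:
                codes.add(CODE_DIAMOND)
        rare_class = "not_extracted"
        if s.maf_case_blood is not None:
            rare_class = rare_screen(
                s.maf_case_blood, s.maf_control_internal, s.maf_external,
                cfg.rare_case_maf, cfg.rare_control_maf, cfg.enrich_fold,
            )
        somatic = False
        if s.maf_case_blood is not None and s.maf_case_tumor is not None:
            somatic = somatic_flag(
                s.maf_case_blood, s.maf_case_tumor, cfg.somatic_delta
            )
        if codes:
            status = "excluded"
        elif s.variant in confirmed:
            status = "confirmed"
        elif rare_class in ("rare", "rare_enriched"):
            status = "rare_candidate"
        elif somatic:
            status = "somatic_candidate"
        else:
            status = "excluded" if codes else "not_confirmed"
        decisions.append(
            TriageDecision(
                variant=s.variant,
                status=status,
                exclusion_codes=codes,
                adjusted_only=bool(adjusted_only.get(s.variant, False)),
                inconclusive_db=inconclusive,
                rare_class=rare_class,
                somatic=somatic,
            )
        )
    return decisions


def load_common_variant_table() -> pd.DataFrame:
    """Bundled example table of 27 candidate common variants.

    Columns: name, gene, maf_case_blood, maf_case_tumor,
    maf_control_internal, maf_external (NaN when unreported), tri_allelic.
    Frequencies are proportions in [0, 1]. Used by examples and regression
    tests of the database-discrepancy screen.
    """
    ref = importlib.resources.files("hervtriage.data") / "common_variants_maf.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    df["tri_allelic"] = df["tri_allelic"].astype(bool)
    return df
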