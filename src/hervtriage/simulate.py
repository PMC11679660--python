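"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the study's data shapes: a reference panel of
ancestry-informative markers (AIMs) over K populations, admixed
case/control cohorts with planted per-allele log-odds effects, sex and
ancestry confounding, missing genotypes, rare case-enriched variants,
blood/tumor pairs with somatic frequency shifts, linked variant pairs,
and Alu sequences whose poly(A) tails are extended by planted spacer
substitutions.

Population allele frequencies follow a Balding-Nichols construction: a
common ancestral frequency is perturbed per population with a single
divergence parameter F, so F = 0 gives identical populations and F -> 1
maximally informative markers (clamped to the configured bounds).
Genotypes are g ~ Binomial(2, sum_k q_k p_km) given the individual's
admixture vector q (dominant-population model by default, symmetric
Dirichlet as an option); case status is Bernoulli on a
logit scale combining planted variant effects, a sex term and an
ancestry term (the latter two create genuine confounding). Defaults
mirror the study conditions: 138 cases, 2015 controls, 85 AIMs over
four reference populations, tail lengths drawn from 21-26 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .ancestry import DEFAULT_POPULATIONS, ReferencePanel, classify_ancestry
from .cohort import MISSING, VARIANT_COLUMNS, GenotypeMatrix
from .regions import CPGRecord, GenomicInterval
from .retroelements import AluElement


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    n_populations: int = 4
    n_aims: int = 85
    #: candidate markers drawn before keeping the n_aims with the largest
    #: cross-population frequency spread, mirroring how AIM panels are
    #: assembled by selection (85 informative markers out of 179 candidates)
    aim_candidate_pool: int | None = 179
    divergence: float = 0.15
    n_cases: int = 138
    n_controls: int = 2015
    n_variants: int = 200
    #: (variant index, per-allele log-odds) pairs planted into case status
    case_effect_variants: list = field(default_factory=list)
    missing_rate: float = 0.02
    baseline_logit: float = -1.0
    sex_effect: float = 0.5
    ancestry_effect: float = 1.5
    #: fraction of females; the case cohort can be imbalanced separately
    female_fraction: float = 0.5
    case_female_fraction: float | None = None
    #: admixture model for q: "dominant" draws a dominant population per
    #: individual with a Beta(2, 6) admixed fraction (human cohorts are
    #: mostly near-pure with an admixed minority); "dirichlet" draws
    #: symmetric Dirichlet vectors
    q_model: str = "dominant"
    dirichlet_alpha: tuple | None = None
    #: variants given strongly divergent frequencies so that ancestry
    #: confounds their unadjusted effect
    confounded_variants: list = field(default_factory=list)
    confounded_divergence: float = 0.5
    rare_variants: list = field(default_factory=list)
    rare_case_freq: float = 0.12
    rare_control_freq: float = 0.002
    somatic_variants: list = field(default_factory=list)
    somatic_shift: float = 0.05
    linked_pairs: list = field(default_factory=list)
    linked_flip_rate: float = 0.03
    freq_bounds: tuple = (0.01, 0.99)
    # annotation sizes
    n_genes: int = 10
    n_hervs: int = 40
    n_alus: int = 8
    tail_length_range: tuple = (21, 26)

    def __post_init__(self) -> None:
        if self.n_populations < 2:
            raise ConfigurationError("need K >= 2 populations")
        if not (0.0 <= self.divergence <= 1.0):
            raise ConfigurationError("divergence must lie in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        for idx, _ in self.case_effect_variants:
            if not (0 <= idx < self.n_variants):
                raise ConfigurationError(
                    f"effect on nonexistent variant index {idx}"
                )
        for idx in (*self.confounded_variants, *self.rare_variants,
                    *self.somatic_variants):
            if not (0 <= idx < self.n_variants):
                raise ConfigurationError(f"planted index {idx} out of range")

    @property
    def populations(self) -> tuple:
        return tuple(DEFAULT_POPULATIONS[: self.n_populations]) if (
            self.n_populations <= len(DEFAULT_POPULATIONS)
        ) else tuple(
            list(DEFAULT_POPULATIONS)
            + [f"POP{i}" for i in range(len(DEFAULT_POPULATIONS), self.n_populations)]
        )


@dataclass
class GroundTruth:
    sample_ids: list
    q: np.ndarray  # (n, K)
    labels: list
    effects: list  # (variant index, log-odds)
    confounded_variants: list
    rare_variants: list
    somatic_variants: list
    linked_pairs: list
    #: per planted tail variant: dict with sequence name, position, ref,
    #: alt, run length before/after
    polya_truth: list = field(default_factory=list)


def _balding_nichols(
    rng: np.random.Generator,
    n_markers: int,
    n_pops: int,
    divergence: float,
    bounds: tuple,
) -> np.ndarray:
    """Per-population frequencies (K, M) from a shared ancestral draw."""
    lo, hi = bounds
    ancestral = rng.uniform(0.1, 0.9, size=n_markers)
    if divergence == 0.0:
        freqs = np.tile(ancestral, (n_pops, 1))
    elif divergence == 1.0:
        freqs = rng.binomial(1, ancestral, size=(n_pops, n_markers)).astype(float)
    else:
        f = divergence
        a = ancestral * (1.0 - f) / f
        b = (1.0 - ancestral) * (1.0 - f) / f
        freqs = rng.beta(a, b, size=(n_pops, n_markers))
    return np.clip(freqs, lo, hi)


def simulate_panel(config: SimulationConfig) -> ReferencePanel:
    """Reference-panel AIM frequencies per population.

    When ``aim_candidate_pool`` is set, that many candidate markers are
    drawn and the ``n_aims`` with the largest cross-population frequency
    spread are kept — ancestry-informative markers are by construction a
    selected subset of candidate markers, not a random draw.
    """
    if config.n_aims < 1:
        raise ConfigurationError("need at least one AIM")
    pool = config.aim_candidate_pool or config.n_aims
    if pool < config.n_aims:
        raise ConfigurationError("candidate pool smaller than n_aims")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    candidates = _balding_nichols(
        rng, pool, config.n_populations, config.divergence,
        config.freq_bounds,
    )
    spread = np.ptp(candidates, axis=0)
    keep = np.sort(np.argsort(spread)[::-1][: config.n_aims])
    freqs = candidates[:, keep]
    return ReferencePanel(
        populations=list(config.populations),
        marker_ids=[f"aim_{i:04d}" for i in range(config.n_aims)],
        frequencies=freqs,
    )


def aim_variant_frame(panel: ReferencePanel) -> pd.DataFrame:
    """Synthetic variant records for the panel AIMs (rsID = marker ID)."""
    rows = [
        {
            "chrom": "chr22", "pos": 10_000 + 100 * i, "ref": "A", "alt": "G",
            "rsid": marker, "multiallelic_split": False, "alt_index": 1,
        }
        for i, marker in enumerate(panel.marker_ids)
    ]
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def draw_admixture(
    rng: np.random.Generator, n: int, k: int, config: SimulationConfig
) -> np.ndarray:
    if config.q_model == "dirichlet":
        alpha = np.asarray(
            config.dirichlet_alpha
            if config.dirichlet_alpha is not None
            else np.ones(k)
        )
        return rng.dirichlet(alpha, size=n)
    if config.q_model != "dominant":
        raise ConfigurationError(f"unknown q_model {config.q_model!r}")
    dominant = rng.integers(0, k, size=n)
    admixed_fraction = rng.beta(2.0, 6.0, size=n)
    rest = rng.dirichlet(np.ones(k), size=n)
    q = np.zeros((n, k))
    q[np.arange(n), dominant] = 1.0
    return (1.0 - admixed_fraction[:, None]) * q + admixed_fraction[:, None] * rest


@dataclass
class SimulatedCohort:
    cases_blood: GenotypeMatrix
    cases_tumor: GenotypeMatrix
    controls: GenotypeMatrix
    aim_genotypes_cases: np.ndarray
    aim_genotypes_controls: np.ndarray
    truth: GroundTruth


def _variant_frame(config: SimulationConfig,
                   positions: list | None) -> pd.DataFrame:
    if positions is None:
        positions = [("chr1", 100_000 + 500 * i) for i in range(config.n_variants)]
    bases = ["A", "C", "G", "T"]
    rows = []
    for i, (chrom, pos) in enumerate(positions):
        ref = bases[i % 4]
        alt = bases[(i + 1) % 4]
        rows.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "rsid": f"sim{i:05d}", "multiallelic_split": False,
                "alt_index": 1,
            }
        )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def simulate_cohort(
    panel: ReferencePanel,
    config: SimulationConfig,
    variant_positions: list | None = None,
) -> SimulatedCohort:
    """Admixed case/control genotypes with planted case-control structure.

    Individuals are drawn from the admixture model and assigned case or
    control status retrospectively (sampling continues until both quotas
    are filled), which preserves the planted per-allele odds ratios. Rare
    and somatic variants are planted by direct frequency override after
    status assignment; missingness is applied last.
    """
    if panel.n_populations != config.n_populations or panel.n_markers != config.n_aims:
        raise ConfigurationError("panel and config disagree on K or M")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    k = config.n_populations
    var_freqs = _balding_nichols(
        rng, config.n_variants, k, config.divergence, config.freq_bounds
    )
    if config.confounded_variants:
        conf_freqs = _balding_nichols(
            rng, len(config.confounded_variants), k,
            config.confounded_divergence, config.freq_bounds,
        )
        var_freqs[:, config.confounded_variants] = conf_freqs
    effects = np.zeros(config.n_variants)
    for idx, beta in config.case_effect_variants:
        effects[idx] = beta

    case_female = (
        config.case_female_fraction
        if config.case_female_fraction is not None
        else config.female_fraction
    )

    need = {"case": config.n_cases, "control": config.n_controls}
    collected = {"case": [], "control": []}
    max_rounds = 200
    for _ in range(max_rounds):
        if need["case"] <= 0 and need["control"] <= 0:
            break
        b = max(1024, 4 * (need["case"] + need["control"]))
        q = draw_admixture(rng, b, k, config)
        sex = rng.binomial(1, config.female_fraction, size=b)  # 1 = female
        aim_p = q @ panel.frequencies
        aims = rng.binomial(2, aim_p)
        var_p = q @ var_freqs
        geno = rng.binomial(2, var_p)
        logit = (
            config.baseline_logit
            + geno @ effects
            + config.sex_effect * sex
            + config.ancestry_effect * q[:, 1 % k]
        )
        y = rng.binomial(1, expit(logit))
        for status, flag in (("case", 1), ("control", 0)):
            idx = np.flatnonzero(y == flag)[: max(0, need[status])]
            for i in idx:
                collected[status].append((q[i], sex[i], aims[i], geno[i]))
            need[status] -= len(idx)
    if need["case"] > 0 or need["control"] > 0:
        raise ConfigurationError(
            "could not fill cohort quotas; check effect/baseline settings"
        )

    def stack(rows, prefix):
        q = np.stack([r[0] for r in rows])
        sex = np.array([r[1] for r in rows])
        aims = np.stack([r[2] for r in rows])
        geno = np.stack([r[3] for r in rows]).astype(np.int8)
        ids = [f"{prefix}{i:05d}" for i in range(len(rows))]
        return q, sex, aims, geno, ids

    q_ca, sex_ca, aims_ca, geno_ca, ids_ca = stack(collected["case"], "case")
    q_co, sex_co, aims_co, geno_co, ids_co = stack(collected["control"], "ctrl")

    # sex imbalance for cases is imposed by relabeling, not re-sampling,
    # so genotype-phenotype structure is untouched
    if case_female != config.female_fraction:
        sex_ca = rng.binomial(1, case_female, size=len(sex_ca))

    for idx in config.rare_variants:
        geno_ca[:, idx] = rng.binomial(2, config.rare_case_freq, size=len(ids_ca))
        geno_co[:, idx] = rng.binomial(2, config.rare_control_freq, size=len(ids_co))
    for i, j in config.linked_pairs:
        for geno in (geno_ca, geno_co):
            src = geno[:, i].copy()
            flip = rng.random(len(src)) < config.linked_flip_rate
            # redraw at the source column's own frequency so linkage noise
            # does not distort the cohort allele frequency
            redraw = rng.binomial(2, src.mean() / 2.0, size=len(src))
            geno[:, j] = np.where(flip, redraw, src)

    tumor = geno_ca.copy()
    for idx in config.somatic_variants:
        blood_freq = geno_ca[:, idx].mean() / 2.0
        shifted = min(0.99, blood_freq + config.somatic_shift)
        tumor[:, idx] = rng.binomial(2, shifted, size=tumor.shape[0])

    def mask(arr):
        if config.missing_rate > 0:
            m = rng.random(arr.shape) < config.missing_rate
            arr = arr.copy()
            arr[m] = MISSING
        return arr.astype(np.int8)

    geno_ca, geno_co, tumor = mask(geno_ca), mask(geno_co), mask(tumor)
    aims_ca, aims_co = mask(aims_ca), mask(aims_co)

    variants = _variant_frame(config, variant_positions)

    def matrix(ids, sex, geno, cohort, stype, q):
        samples = pd.DataFrame(
            {
                "cohort": cohort,
                "sample_type": stype,
                "sex": sex,
            },
            index=pd.Index(ids, name="sample_id"),
        )
        return GenotypeMatrix(samples=samples, variants=variants.copy(),
                              genotypes=geno)

    truth = GroundTruth(
        sample_ids=ids_ca + ids_co,
        q=np.vstack([q_ca, q_co]),
        labels=[
            classify_ancestry(qi, panel.populations)
            for qi in np.vstack([q_ca, q_co])
        ],
        effects=list(config.case_effect_variants),
        confounded_variants=list(config.confounded_variants),
        rare_variants=list(config.rare_variants),
        somatic_variants=list(config.somatic_variants),
        linked_pairs=list(config.linked_pairs),
    )
    return SimulatedCohort(
        cases_blood=matrix(ids_ca, sex_ca, geno_ca, "case", "blood", q_ca),
        cases_tumor=matrix(ids_ca, sex_ca, tumor, "case", "tumor", q_ca),
        controls=matrix(ids_co, sex_co, geno_co, "control", "control", q_co),
        aim_genotypes_cases=aims_ca,
        aim_genotypes_controls=aims_co,
        truth=truth,
    )


def simulate_annotations(
    config: SimulationConfig,
) -> tuple[list[CPGRecord], list[tuple[GenomicInterval, str, str]]]:
    """Gene models with DE statistics plus retroviral elements near them.

    Genes are laid out on a synthetic chromosome with alternating
    significant/non-significant differential-expression statistics;
    elements are scattered intronic to, flanking, and far from genes so
    that radius selection has known positives and negatives.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    genes: list[CPGRecord] = []
    span = 200_000
    for i in range(config.n_genes):
        start = 1_000_000 + i * span
        end = start + int(rng.integers(40_000, 80_000))
        n_exons = int(rng.integers(3, 8))
        bounds = np.sort(rng.choice(
            np.arange(start, end), size=2 * n_exons, replace=False
        ))
        exons = [
            GenomicInterval("chr1", int(bounds[2 * j]), int(bounds[2 * j + 1]),
                            "+" if i % 2 == 0 else "-")
            for j in range(n_exons)
        ]
        significant = i % 3 != 2  # every third gene fails the DE filter
        log2fc = float(rng.uniform(1.2, 3.0)) * (1 if i % 2 == 0 else -1)
        genes.append(
            CPGRecord(
                symbol=f"GENE{i:02d}",
                body=GenomicInterval("chr1", start, end,
                                     "+" if i % 2 == 0 else "-"),
                exons=exons,
                log2_fold_change=log2fc if significant else float(rng.uniform(0, 0.9)),
                adjusted_p=float(rng.uniform(1e-6, 0.04)) if significant
                else float(rng.uniform(0.06, 0.9)),
            )
        )
    families = ["MSTA", "MLT1A", "LTR12C", "MLT1J", "AluY", "AluSx"]
    elements = []
    for i in range(config.n_hervs):
        gene = genes[i % config.n_genes]
        mode = i % 4
        if mode == 0:  # intronic
            start = int(rng.integers(gene.body.start, gene.body.end - 600))
        elif mode == 1:  # upstream flank within radius
            start = gene.body.start - int(rng.integers(1_000, 19_000))
        elif mode == 2:  # downstream flank within radius
            start = gene.body.end + int(rng.integers(1_000, 19_000))
        else:  # far away, beyond any 20 kb radius
            start = 20_000_000 + i * 50_000
        length = int(rng.integers(400, 1_200))
        elements.append(
            (
                GenomicInterval("chr1", max(0, start), max(0, start) + length,
                                "+" if i % 2 == 0 else "-"),
                families[i % len(families)],
                "complete" if i % 10 == 0 else "soloLTR",
            )
        )
    return genes, elements


def simulate_retro_sequences(
    config: SimulationConfig,
) -> tuple[dict, list[AluElement], list[dict]]:
    """Alu sequences with annotated substructure and planted tail variants.

    Each Alu gets its own sequence (one FASTA record per element): left
    monomer, A-rich linker, right monomer, then a poly(A) tail of known
    length drawn from the configured range. Every second element carries a
    planted spacer variant — tail of the form A^a X A^b with a non-A base X
    and an X>A substitution — whose post-variant run length a + b + 1 is
    recorded as ground truth.
    """
    lo, hi = config.tail_length_range
    if lo < 1:
        raise ConfigurationError("tail lengths must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    bases = np.array(list("ACGT"))

    def random_seq(n, no_a_edges=False):
        s = "".join(rng.choice(bases, size=n))
        if no_a_edges:  # keep monomer edges from extending measured runs
            s = "C" + s[1:-1] + "G"
        return s

    sequences: dict[str, str] = {}
    alus: list[AluElement] = []
    truth: list[dict] = []
    for i in range(config.n_alus):
        name = f"alu_{i:03d}"
        left = random_seq(130, no_a_edges=True)
        linker = "A" * 5
        right = random_seq(130, no_a_edges=True)
        tail_len = int(rng.integers(lo, hi + 1))
        flank5 = random_seq(20, no_a_edges=True)
        flank3 = random_seq(20, no_a_edges=True)
        planted = i % 2 == 0
        if planted:
            spacer = str(rng.choice(["C", "G", "T"]))
            extra = int(rng.integers(5, 12))
            tail_seq = "A" * tail_len + spacer + "A" * extra
        else:
            tail_seq = "A" * tail_len
        seq = flank5 + left + linker + right + tail_seq + flank3
        off = len(flank5)
        element = GenomicInterval(name, off, off + len(left) + len(linker)
                                  + len(right) + len(tail_seq), "+")
        alu = AluElement(
            element=element,
            left_monomer=GenomicInterval(name, off, off + len(left), "+"),
            linker=GenomicInterval(name, off + len(left),
                                   off + len(left) + len(linker), "+"),
            right_monomer=GenomicInterval(
                name, off + len(left) + len(linker),
                off + len(left) + len(linker) + len(right), "+"),
            tail=GenomicInterval(
                name, off + len(left) + len(linker) + len(right),
                element.end, "+"),
            family="AluY" if i % 2 == 0 else "AluSx",
        )
        sequences[name] = seq
        alus.append(alu)
        if planted:
            pos = alu.tail.start + tail_len
            truth.append(
                {
                    "sequence": name,
                    "pos": pos,
                    "ref": spacer,
                    "alt": "A",
                    "run_before": tail_len,
                    "run_after": tail_len + extra + 1,
                }
            )
    return sequences, alus, truth
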