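"""Synthetic cohort generator.

Because the clinical study data this pipeline targets are private, every
stage is exercised on simulated cohorts that reproduce the statistical
structure the analysis assumes: Hardy-Weinberg genotypes at ~86 PRS loci,
a European core plus a few divergent-ancestry outliers (Balding-Nichols
allele frequencies), sibling pairs sharing a family ID, missing calls at
random, and ED/LD status drawn from a logistic model in the standardized
PRS plus the sICGT / cluster-region covariates.

Defaults mirror the published study conditions: 295 carriers out of 293
families (two sibling pairs), 183/295 BRCA1, sICGT prevalence 188/295,
BCCR/OCCR carrier-level prevalences 45/295 and 37/295, four divergent
outliers, and true model coefficients ln(1.62) per PRS standard deviation,
ln(3.45) for sICGT, ln(0.65) for BCCR and ln(0.32) for OCCR.  The intercept
default -0.4 puts the marginal ED fraction near the study's 162/295 under
those prevalences.

One global seed drives a named sub-stream per component (weights, genotypes,
divergence, missingness, reference, phenotypes) so components are
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .io_genotypes import (GenotypeTable, SampleRecord, SnpWeight,
                           write_phenotypes, write_population_labels,
                           write_tped, write_weights)
from .regions import classify_variant_region
from .scoring import harmonize, impute_missing, compute_prs, standardize

#: fixed sub-stream indices hashed with the global seed
_STREAMS = {"weights": 0, "genotypes": 1, "divergence": 2, "missing": 3,
            "reference": 4, "phenotypes": 5}

_NON_AMBIGUOUS_PAIRS = (("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                        ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"))
_AMBIGUOUS_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))

#: representative variant extents (1-based c. intervals) realising each
#: (in_bccr, in_occr) combination; the both-True BRCA1 case spans the
#: OCCR/BCCR boundary, the BRCA2 case sits in the genuinely overlapping part
_VARIANT_CANDIDATES = {
    "BRCA1": {(False, False): (100, 101), (True, False): (300, 300),
              (False, True): (2000, 2000), (True, True): (4050, 4350)},
    "BRCA2": {(False, False): (2500, 2500), (True, False): (300, 300),
              (False, True): (4000, 4000), (True, True): (7400, 7400)},
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Coefficients are log odds ratios on the ED-vs-LD scale; prevalences are
    carrier-level probabilities applied per family (relatives share the
    pathogenic variant and recruitment route).
    """

    n_samples: int = 295
    n_snps: int = 86
    maf_low: float = 0.05
    maf_high: float = 0.5
    allele_freqs: tuple[float, ...] | None = None

    intercept: float = -0.4
    log_or_prs: float = math.log(1.62)
    log_or_sicgt: float = math.log(3.45)
    log_or_bccr: float = math.log(0.65)
    log_or_occr: float = math.log(0.32)

    prev_sicgt: float = 188 / 295
    prev_bccr: float = 45 / 295
    prev_occr: float = 37 / 295
    frac_brca1: float = 183 / 295

    frac_sib_pairs: float = 4 / 295
    missing_rate: float = 0.02
    n_outliers: int = 4
    fst: float = 0.1
    n_ref_per_pop: int = 100

    #: additional non-PRS panel SNPs simulated alongside the weight loci so
    #: the ancestry MDS runs on ~342 overlapping SNPs as in the study design
    n_panel_extra: int = 244

    n_ambiguous: int = 0          # for generic (non-published-structure) weights
    published_structure: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("maf_low", "maf_high", "prev_sicgt", "prev_bccr",
                     "prev_occr", "frac_brca1", "frac_sib_pairs", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.fst < 1:
            raise ValueError("fst must be in (0, 1)")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed % (2 ** 31), _STREAMS[stream]])


# ---------------------------------------------------------------------------
# Weight tables
# ---------------------------------------------------------------------------

def simulate_weights(n_snps: int, n_ambiguous: int = 0,
                     rng: np.random.Generator | None = None,
                     sets: Sequence[frozenset[str]] | None = None) -> list[SnpWeight]:
    """Generic synthetic weight table.

    Per-SNP betas are drawn N(0, 0.05^2), a magnitude typical of published
    PRS loci; the first ``n_ambiguous`` SNPs get strand-ambiguous (A/T or
    C/G) allele pairs to exercise harmonization.  Unless ``sets`` is given,
    every SNP belongs to all three PRS sets.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if n_ambiguous > n_snps:
        raise ValueError("n_ambiguous > n_snps")
    weights = []
    for j in range(n_snps):
        pairs = _AMBIGUOUS_PAIRS if j < n_ambiguous else _NON_AMBIGUOUS_PAIRS
        eff, oth = pairs[int(rng.integers(len(pairs)))]
        membership = (frozenset(("overall", "ER+", "ER-")) if sets is None
                      else sets[j])
        weights.append(SnpWeight(
            snp_id=f"rs{100001 + j}", chrom=str(1 + j % 22), pos=1_000_000 + 10_000 * j,
            effect_allele=eff, other_allele=oth,
            beta=float(rng.normal(0.0, 0.05)), sets=membership,
        ))
    return weights


def published_structure_weights(rng: np.random.Generator | None = None
                                ) -> list[SnpWeight]:
    """Synthetic weight table mirroring the published PRS set-size structure.

    98 unique loci arranged so that the three SNP sets have the published
    pre-exclusion sizes (88 overall / 87 ER+ / 53 ER-) and the planted
    strand-ambiguous loci (including rs11571833, an A/T SNP) are exactly what
    the complementary-allele exclusion removes, leaving effective sizes
    77 / 77 / 50 with 86 unique retained loci, of which the overall and ER+
    sets share 76 of their 77.  Alleles and betas are synthetic; only the
    set/ambiguity bookkeeping mirrors the published tables.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    all3 = frozenset(("overall", "ER+", "ER-"))
    ove_erp = frozenset(("overall", "ER+"))
    blocks: list[tuple[int, frozenset[str], bool]] = [
        # (count, membership, ambiguous)
        (42, all3, False),
        (34, ove_erp, False),
        (1, frozenset(("overall",)), False),
        (1, frozenset(("ER+",)), False),
        (8, frozenset(("ER-",)), False),
        (9, ove_erp, True),
        (1, all3, True),
        (1, frozenset(("ER-",)), True),
    ]
    weights: list[SnpWeight] = []
    j = 0
    for count, membership, ambiguous in blocks:
        for _ in range(count):
            pairs = _AMBIGUOUS_PAIRS if ambiguous else _NON_AMBIGUOUS_PAIRS
            eff, oth = pairs[int(rng.integers(len(pairs)))]
            weights.append(SnpWeight(
                snp_id=f"rs{200001 + j}", chrom=str(1 + j % 22),
                pos=2_000_000 + 10_000 * j, effect_allele=eff, other_allele=oth,
                beta=float(rng.normal(0.0, 0.05)), sets=membership))
            j += 1
    # rs11571833: the BRCA2-resident A/T locus removed by the ambiguity rule
    weights.append(SnpWeight(
        snp_id="rs11571833", chrom="13", pos=32_972_626,
        effect_allele="A", other_allele="T",
        beta=float(rng.normal(0.0, 0.05)), sets=frozenset(("overall", "ER-"))))
    return weights


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

class GenotypeSim(NamedTuple):
    gt: GenotypeTable
    true_dosages: np.ndarray      # effect-allele counts before missingness
    family_ids: list[str]
    sib_pairs: list[tuple[str, str]]
    outlier_ids: list[str]
    base_freqs: np.ndarray        # effect-allele frequency per SNP (core pop)
    outlier_freqs: np.ndarray | None
    effect_alleles: np.ndarray
    other_alleles: np.ndarray


def balding_nichols_freqs(base: np.ndarray, fst: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Divergent-population allele frequencies p' ~ Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    ratio = (1.0 - fst) / fst
    return rng.beta(base * ratio, (1.0 - base) * ratio)


def _dosage_to_calls(dosages: np.ndarray, effect: np.ndarray,
                     other: np.ndarray) -> np.ndarray:
    """(n, m) integer dosages -> (n, m, 2) allele-letter calls."""
    n, m = dosages.shape
    calls = np.empty((n, m, 2), dtype="<U1")
    eff = np.broadcast_to(effect, (n, m))
    oth = np.broadcast_to(other, (n, m))
    calls[..., 0] = np.where(dosages >= 1, eff, oth)
    calls[..., 1] = np.where(dosages == 2, eff, oth)
    return calls


def simulate_genotypes(cfg: SimConfig,
                       weights: Sequence[SnpWeight] | None = None) -> GenotypeSim:
    """Draw the study genotype table.

    Unrelated individuals get Hardy-Weinberg genotypes at the core-population
    allele frequencies; each sibling pair is produced by simulating two
    parental genotypes and Mendelian transmission (and shares a family ID);
    the configured number of divergent-ancestry outliers draw from
    Balding-Nichols frequencies at the configured Fst; missing calls are
    applied MCAR.  Fully reproducible from the config seed.
    """
    rng = _rng(cfg, "genotypes")
    if weights is not None:
        effect = [w.effect_allele for w in weights]
        other = [w.other_allele for w in weights]
        snp_ids = [w.snp_id for w in weights]
        chrom = [w.chrom for w in weights]
        pos = [w.pos for w in weights]
        m_primary = len(weights)
    else:
        m_primary = cfg.n_snps
        pairs = [_NON_AMBIGUOUS_PAIRS[int(rng.integers(len(_NON_AMBIGUOUS_PAIRS)))]
                 for _ in range(m_primary)]
        effect = [p[0] for p in pairs]
        other = [p[1] for p in pairs]
        snp_ids = [f"rs{100001 + j}" for j in range(m_primary)]
        chrom = [str(1 + j % 22) for j in range(m_primary)]
        pos = [1_000_000 + 10_000 * j for j in range(m_primary)]

    # extra (non-PRS) panel SNPs carried only for the ancestry MDS
    for j in range(cfg.n_panel_extra):
        eff, oth = _NON_AMBIGUOUS_PAIRS[int(rng.integers(len(_NON_AMBIGUOUS_PAIRS)))]
        effect.append(eff)
        other.append(oth)
        snp_ids.append(f"panel{j + 1:04d}")
        chrom.append(str(1 + j % 22))
        pos.append(50_000_000 + 10_000 * j)
    effect = np.array(effect)
    other = np.array(other)
    m = m_primary + cfg.n_panel_extra

    if cfg.allele_freqs is not None:
        if len(cfg.allele_freqs) != m_primary:
            raise ValueError("allele_freqs length mismatch")
        base = np.concatenate([
            np.asarray(cfg.allele_freqs, dtype=float),
            rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.n_panel_extra)])
    else:
        base = rng.uniform(cfg.maf_low, cfg.maf_high, size=m)

    n = cfg.n_samples
    n_out = min(cfg.n_outliers, n)
    n_core = n - n_out
    n_pairs = min(int(round(cfg.frac_sib_pairs * n / 2.0)), n_core // 2)

    dosages = np.empty((n, m), dtype=np.int64)
    family_ids: list[str] = [""] * n
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    fam_counter = 0
    sib_pairs: list[tuple[str, str]] = []

    for pair in range(n_pairs):
        fam_counter += 1
        fam = f"F{fam_counter:04d}"
        father = rng.random((2, m)) < base
        mother = rng.random((2, m)) < base
        for child in range(2):
            i = 2 * pair + child
            from_father = father[rng.integers(0, 2, size=m), np.arange(m)]
            from_mother = mother[rng.integers(0, 2, size=m), np.arange(m)]
            dosages[i] = from_father.astype(np.int64) + from_mother.astype(np.int64)
            family_ids[i] = fam
        sib_pairs.append((sample_ids[2 * pair], sample_ids[2 * pair + 1]))

    n_unrel = n_core - 2 * n_pairs
    if n_unrel:
        dosages[2 * n_pairs:n_core] = rng.binomial(2, base, size=(n_unrel, m))
    for i in range(2 * n_pairs, n_core):
        fam_counter += 1
        family_ids[i] = f"F{fam_counter:04d}"

    outlier_freqs = None
    if n_out:
        outlier_freqs = balding_nichols_freqs(base, cfg.fst, _rng(cfg, "divergence"))
        dosages[n_core:] = rng.binomial(2, outlier_freqs, size=(n_out, m))
        for i in range(n_core, n):
            fam_counter += 1
            family_ids[i] = f"F{fam_counter:04d}"
    outlier_ids = sample_ids[n_core:]

    calls = _dosage_to_calls(dosages, effect, other)
    if cfg.missing_rate > 0:
        miss = _rng(cfg, "missing").random((n, m)) < cfg.missing_rate
        calls[miss] = "0"
    gt = GenotypeTable(sample_ids=sample_ids, snp_ids=snp_ids, calls=calls,
                       chrom=chrom, pos=pos)
    return GenotypeSim(gt=gt, true_dosages=dosages, family_ids=family_ids,
                       sib_pairs=sib_pairs, outlier_ids=outlier_ids,
                       base_freqs=base, outlier_freqs=outlier_freqs,
                       effect_alleles=effect, other_alleles=other)


def simulate_reference_panel(cfg: SimConfig, base_freqs: np.ndarray,
                             snp_ids: Sequence[str],
                             effect_alleles: Sequence[str],
                             other_alleles: Sequence[str],
                             outlier_freqs: np.ndarray | None = None
                             ) -> tuple[GenotypeTable, dict[str, str]]:
    """Labelled reference panel: EUR at the core frequencies, AFR at the
    outlier population's frequencies (so planted outliers have a home
    centroid), EAS at an independent Balding-Nichols draw.

    Allele letters must match the study panel's, otherwise identity-by-state
    distances between the panels would be meaningless.
    """
    rng = _rng(cfg, "reference")
    m = len(snp_ids)
    pop_freqs = {
        "EUR": np.asarray(base_freqs, dtype=float),
        "AFR": (outlier_freqs if outlier_freqs is not None
                else balding_nichols_freqs(base_freqs, cfg.fst, rng)),
        "EAS": balding_nichols_freqs(base_freqs, cfg.fst, rng),
    }
    effect = np.asarray(effect_alleles)
    other = np.asarray(other_alleles)
    tables, labels = [], {}
    sample_ids: list[str] = []
    for pop, freqs in pop_freqs.items():
        dosages = rng.binomial(2, freqs, size=(cfg.n_ref_per_pop, m))
        tables.append(_dosage_to_calls(dosages, effect, other))
        for i in range(cfg.n_ref_per_pop):
            sid = f"R{pop}{i + 1:03d}"
            sample_ids.append(sid)
            labels[sid] = pop
    gt = GenotypeTable(sample_ids=sample_ids, snp_ids=list(snp_ids),
                       calls=np.concatenate(tables, axis=0))
    return gt, labels


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(cfg: SimConfig, std_prs: np.ndarray,
                        sample_ids: Sequence[str] | None = None,
                        family_ids: Sequence[str] | None = None
                        ) -> list[SampleRecord]:
    """Draw ED/LD outcomes and covariates from the logistic model.

    Gene, sICGT and cluster-region status are drawn once per family (family
    members share the pathogenic variant and recruitment route); each
    sample's ED indicator is Bernoulli with
    logit = intercept + b_prs*PRS + b_sicgt*sICGT + b_bccr*BCCR + b_occr*OCCR.
    The variant c. interval is synthesised to realise the drawn region flags.
    ED samples get an integer age at diagnosis in [20, 34].

    If the draw produces a single-class cohort it is redrawn with a warning,
    fatally after 10 attempts.
    """
    std_prs = np.asarray(std_prs, dtype=float)
    n = std_prs.size
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    if family_ids is None:
        family_ids = [f"F{i + 1:04d}" for i in range(n)]
    if len(sample_ids) != n or len(family_ids) != n:
        raise ValueError("sample_ids/family_ids must align with std_prs")
    rng = _rng(cfg, "phenotypes")

    families = list(dict.fromkeys(family_ids))
    for attempt in range(10):
        fam_gene = {f: ("BRCA1" if rng.random() < cfg.frac_brca1 else "BRCA2")
                    for f in families}
        fam_sicgt = {f: bool(rng.random() < cfg.prev_sicgt) for f in families}
        fam_bccr = {f: bool(rng.random() < cfg.prev_bccr) for f in families}
        fam_occr = {f: bool(rng.random() < cfg.prev_occr) for f in families}

        logit = np.array([
            cfg.intercept + cfg.log_or_prs * std_prs[i]
            + cfg.log_or_sicgt * fam_sicgt[family_ids[i]]
            + cfg.log_or_bccr * fam_bccr[family_ids[i]]
            + cfg.log_or_occr * fam_occr[family_ids[i]]
            for i in range(n)])
        ed = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
        if 0 < ed.sum() < n or n < 2:
            break
        warnings.warn(f"single-class outcome on attempt {attempt + 1}; redrawing")
    else:
        raise RuntimeError("single-class outcome in 10 consecutive draws")

    records = []
    for i in range(n):
        fam = family_ids[i]
        gene = fam_gene[fam]
        flags = (fam_bccr[fam], fam_occr[fam])
        c_start, c_end = _VARIANT_CANDIDATES[gene][flags]
        assert classify_variant_region(gene, c_start, c_end) == flags
        records.append(SampleRecord(
            sample_id=sample_ids[i], family_id=fam,
            group="ED" if ed[i] else "LD", gene=gene, sicgt=fam_sicgt[fam],
            variant_c_start=c_start, variant_c_end=c_end,
            age_at_diagnosis=float(rng.integers(20, 35)) if ed[i] else None,
        ))
    return records


# ---------------------------------------------------------------------------
# Whole cohorts
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    cfg: SimConfig
    weights: list[SnpWeight]
    genotypes: GenotypeTable
    true_dosages: np.ndarray
    family_ids: list[str]
    sib_pairs: list[tuple[str, str]]
    outlier_ids: list[str]
    records: list[SampleRecord]
    std_prs_overall: np.ndarray
    reference: GenotypeTable
    ref_labels: dict[str, str]


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate a coherent full cohort: weights, genotypes, reference panel
    and phenotypes driven by the overall-set standardized PRS."""
    if cfg.published_structure:
        weights = published_structure_weights(_rng(cfg, "weights"))
    else:
        weights = simulate_weights(cfg.n_snps, cfg.n_ambiguous, _rng(cfg, "weights"))
    gsim = simulate_genotypes(cfg, weights)
    hd = impute_missing(harmonize(weights, gsim.gt))
    raw, _ = compute_prs(hd, "overall")
    std = standardize(raw)
    records = simulate_phenotypes(cfg, std, gsim.gt.sample_ids, gsim.family_ids)
    ref_gt, ref_labels = simulate_reference_panel(
        cfg, gsim.base_freqs, gsim.gt.snp_ids,
        gsim.effect_alleles, gsim.other_alleles, gsim.outlier_freqs)
    return SimulatedCohort(
        cfg=cfg, weights=weights, genotypes=gsim.gt,
        true_dosages=gsim.true_dosages, family_ids=gsim.family_ids,
        sib_pairs=gsim.sib_pairs, outlier_ids=gsim.outlier_ids,
        records=records, std_prs_overall=std,
        reference=ref_gt, ref_labels=ref_labels,
    )


def write_cohort(cfg: SimConfig, outdir: str | Path) -> dict[str, str]:
    """Write a simulated cohort as the pipeline's input file set.

    Emits weights.tsv, genotypes.tped/.tfam, phenotypes.tsv, a labelled
    reference panel, and a manifest JSON recording the full config and seed.
    Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(cfg)
    paths = {name: str(outdir / fname) for name, fname in [
        ("weights", "weights.tsv"), ("tped", "genotypes.tped"),
        ("tfam", "genotypes.tfam"), ("phenotypes", "phenotypes.tsv"),
        ("ref_tped", "reference.tped"), ("ref_tfam", "reference.tfam"),
        ("ref_labels", "reference_populations.tsv"),
        ("manifest", "manifest.json")]}
    write_weights(cohort.weights, paths["weights"])
    write_tped(cohort.genotypes, paths["tped"], paths["tfam"],
               family_ids=cohort.family_ids)
    write_phenotypes(cohort.records, paths["phenotypes"])
    write_tped(cohort.reference, paths["ref_tped"], paths["ref_tfam"])
    write_population_labels(cohort.ref_labels, paths["ref_labels"])
    Path(paths["manifest"]).write_text(json.dumps(
        {"seed": cfg.seed, "config": dataclasses.asdict(cfg)},
        indent=2, sort_keys=True) + "\n")
    return paths
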