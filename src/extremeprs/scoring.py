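"""Genotype harmonization, mean imputation, and polygenic risk scores.

The per-person score over a SNP set is ``PRS_i = sum_j beta_j * g_ij`` with
``g`` the number of effect alleles (0, 1 or 2) and ``beta`` the per-allele
log odds ratio.  The pipeline order is fixed: harmonize -> impute missing
genotypes to the per-SNP mean observed dosage -> score -> standardize to
mean 0 / variance 1 over the scored cohort.

Harmonization resolves allele orientation by allele identity, never by file
column order.  Strand-ambiguous (palindromic) SNPs -- allele pairs A/T or
C/G -- are excluded outright, because a strand flip cannot be detected for
them.  For the remaining SNPs, calls whose alleles match the weight alleles
are counted directly; calls matching only the base-complemented weight
alleles are counted on the flipped strand (provenance "flipped").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json

import numpy as np

from .io_genotypes import PRS_SETS, GenotypeTable, SnpWeight

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ScoringError(RuntimeError):
    """Fatal scoring failure (empty SNP set, degenerate PRS, ...)."""


@dataclass
class HarmonizedDosages:
    """Effect-allele dosage matrix plus the exclusion audit trail.

    ``dosages`` is (n_samples, n_retained_snps) float with NaN for missing
    calls; after :func:`impute_missing` it is complete and cells may be
    fractional.  ``provenance`` records per retained SNP whether the genotype
    alleles matched the weight alleles directly or on the complementary
    strand.  ``exclusions`` lists every weight SNP that was dropped, with one
    reason each: ``ambiguous``, ``unmatched``, ``allele-mismatch`` or
    ``all-missing``.
    """

    sample_ids: list[str]
    weights: list[SnpWeight]          # retained, aligned with dosage columns
    dosages: np.ndarray
    provenance: list[str]             # "direct" | "flipped" per retained SNP
    exclusions: list[tuple[str, str]] = field(default_factory=list)
    n_imputed: int = 0

    @property
    def snp_ids(self) -> list[str]:
        return [w.snp_id for w in self.weights]

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.dosages).any()

    def exclusions_to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            [{"snp_id": s, "reason": r} for s, r in self.exclusions],
            indent=2) + "\n")


@dataclass
class PrsResult:
    """Raw and standardized PRS per sample for each SNP set scored."""

    sample_ids: list[str]
    raw: dict[str, np.ndarray]
    std: dict[str, np.ndarray]
    effective_n: dict[str, int]
    n_imputed: int
    exclusions: list[tuple[str, str]]


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def harmonize(weights: Sequence[SnpWeight], gt: GenotypeTable) -> HarmonizedDosages:
    """Map genotype calls onto effect-allele dosages for each weight SNP.

    Nothing here is fatal: every dropped SNP lands in the exclusion report.
    """
    snp_to_col = {s: j for j, s in enumerate(gt.snp_ids)}
    retained: list[SnpWeight] = []
    provenance: list[str] = []
    columns: list[np.ndarray] = []
    exclusions: list[tuple[str, str]] = []

    for w in weights:
        if w.is_ambiguous:
            exclusions.append((w.snp_id, "ambiguous"))
            continue
        col = snp_to_col.get(w.snp_id)
        if col is None:
            exclusions.append((w.snp_id, "unmatched"))
            continue
        calls = gt.calls[:, col, :]                      # (n, 2)
        observed = calls[:, 0] != "0"
        alleles = set(calls[observed].ravel().tolist())
        direct = {w.effect_allele, w.other_allele}
        flipped = {COMPLEMENT[w.effect_allele], COMPLEMENT[w.other_allele]}
        if alleles <= direct:
            effect, prov = w.effect_allele, "direct"
        elif alleles <= flipped:
            effect, prov = COMPLEMENT[w.effect_allele], "flipped"
        else:
            exclusions.append((w.snp_id, "allele-mismatch"))
            continue
        dosage = (calls == effect).sum(axis=1).astype(float)
        dosage[~observed] = np.nan
        retained.append(w)
        provenance.append(prov)
        columns.append(dosage)

    dosages = (np.column_stack(columns) if columns
               else np.empty((gt.n_samples, 0)))
    return HarmonizedDosages(
        sample_ids=list(gt.sample_ids), weights=retained,
        dosages=dosages, provenance=provenance, exclusions=exclusions,
    )


def impute_missing(hd: HarmonizedDosages) -> HarmonizedDosages:
    """Replace missing dosages with the per-SNP mean observed dosage.

    A SNP missing in every sample cannot be imputed and is excluded with
    reason ``all-missing`` (with a warning).  Non-missing cells are untouched;
    imputed cells are left fractional.
    """
    dosages = hd.dosages.copy()
    nan = np.isnan(dosages)
    all_missing = nan.all(axis=0)
    if all_missing.any():
        for j in np.flatnonzero(all_missing):
            warnings.warn(f"SNP {hd.weights[j].snp_id} missing in all samples; excluded")
    keep = ~all_missing
    dosages = dosages[:, keep]
    nan = nan[:, keep]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_means = np.nanmean(dosages, axis=0)
    dosages[nan] = np.broadcast_to(col_means, dosages.shape)[nan]
    return HarmonizedDosages(
        sample_ids=hd.sample_ids,
        weights=[w for w, k in zip(hd.weights, keep) if k],
        dosages=dosages,
        provenance=[p for p, k in zip(hd.provenance, keep) if k],
        exclusions=hd.exclusions + [(hd.weights[j].snp_id, "all-missing")
                                    for j in np.flatnonzero(all_missing)],
        n_imputed=int(nan.sum()),
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def compute_prs(hd: HarmonizedDosages, set_name: str) -> tuple[np.ndarray, int]:
    """Raw PRS per sample for one SNP set; returns (scores, effective_N)."""
    if set_name not in PRS_SETS:
        raise ValueError(f"unknown PRS set {set_name!r}")
    if not hd.is_complete:
        raise ScoringError("dosage matrix has missing cells; impute first")
    member = np.array([set_name in w.sets for w in hd.weights])
    if not member.any():
        raise ScoringError(f"no retained SNPs in set {set_name!r}")
    betas = np.array([w.beta for w in hd.weights])[member]
    return hd.dosages[:, member] @ betas, int(member.sum())


def standardize(raw: np.ndarray) -> np.ndarray:
    """Z-score a raw PRS vector (sample sd, n-1 denominator)."""
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ScoringError("standardization needs >= 2 samples")
    sd = float(np.std(raw, ddof=1))
    if sd == 0.0:
        raise ScoringError("degenerate PRS: zero variance")
    return (raw - float(np.mean(raw))) / sd


def score_cohort(weights: Sequence[SnpWeight], gt: GenotypeTable,
                 sets: Sequence[str] = PRS_SETS) -> PrsResult:
    """Full scoring chain: harmonize -> impute -> score -> standardize."""
    hd = impute_missing(harmonize(weights, gt))
    raw: dict[str, np.ndarray] = {}
    std: dict[str, np.ndarray] = {}
    effective_n: dict[str, int] = {}
    for set_name in sets:
        raw[set_name], effective_n[set_name] = compute_prs(hd, set_name)
        std[set_name] = standardize(raw[set_name])
    return PrsResult(sample_ids=hd.sample_ids, raw=raw, std=std,
                     effective_n=effective_n, n_imputed=hd.n_imputed,
                     exclusions=hd.exclusions)
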