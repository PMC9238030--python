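"""Sample and SNP quality control.

The QC chain runs in the order: SNP call-rate filter -> sample call-rate
filter -> heterozygosity-outlier removal -> ancestry assignment by classical
multidimensional scaling (MDS) of identity-by-state (IBS) distances against a
labelled reference panel, with non-European samples flagged for exclusion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy import stats

from .io_genotypes import GenotypeTable


@dataclass
class QcConfig:
    """Quality-control thresholds.

    min_call_rate
        Minimum fraction of non-missing calls per SNP and per sample (0.95).
    het_alpha
        Tail probability of the heterozygosity-outlier rule before Bonferroni
        correction over the samples tested.
    mds_dims
        Number of MDS dimensions used for ancestry assignment.
    retained_population
        Reference population whose nearest-centroid members are kept.
    max_centroid_distance
        Optional cap: a study sample farther than this from every centroid is
        called "unassignable" (and flagged).
    """

    min_call_rate: float = 0.95
    het_alpha: float = 0.05
    mds_dims: int = 3
    retained_population: str = "EUR"
    max_centroid_distance: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.min_call_rate <= 1:
            raise ValueError("min_call_rate must be in (0, 1]")
        if not 0 < self.het_alpha < 0.5:
            raise ValueError("het_alpha must be in (0, 0.5)")
        if self.mds_dims < 2:
            raise ValueError("mds_dims must be >= 2")


@dataclass
class QcReport:
    """Accumulated QC decisions; every removed item has one primary reason."""

    snps_removed: dict[str, str] = field(default_factory=dict)
    samples_removed: dict[str, str] = field(default_factory=dict)
    het_bounds: tuple[float, float] | None = None
    mds_coordinates: dict[str, list[float]] | None = None
    ancestry_calls: dict[str, str] | None = None

    def merge(self, other: "QcReport") -> None:
        self.snps_removed.update(other.snps_removed)
        self.samples_removed.update(other.samples_removed)
        if other.het_bounds is not None:
            self.het_bounds = other.het_bounds
        if other.mds_coordinates is not None:
            self.mds_coordinates = other.mds_coordinates
        if other.ancestry_calls is not None:
            self.ancestry_calls = other.ancestry_calls

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "snps_removed": self.snps_removed,
            "samples_removed": self.samples_removed,
            "het_bounds": self.het_bounds,
            "mds_coordinates": self.mds_coordinates,
            "ancestry_calls": self.ancestry_calls,
        }, indent=2, sort_keys=True) + "\n")


class QcError(RuntimeError):
    """Fatal QC failure (e.g., the whole SNP panel removed)."""


# ---------------------------------------------------------------------------
# Call-rate filtering
# ---------------------------------------------------------------------------

def filter_call_rate(gt: GenotypeTable, cfg: QcConfig | None = None
                     ) -> tuple[GenotypeTable, QcReport]:
    """Drop SNPs, then samples, whose call rate falls below the threshold.

    SNP call rates are computed on the full table first and low-rate SNPs
    dropped; sample call rates are then computed on the retained SNPs only and
    low-rate samples dropped.  Both removals are listed in the report.
    """
    cfg = cfg or QcConfig()
    if gt.n_samples == 0 or gt.n_snps == 0:
        raise QcError("empty genotype table")
    report = QcReport()
    observed = ~gt.missing_mask

    snp_rate = observed.mean(axis=0)
    keep_snps = snp_rate >= cfg.min_call_rate
    for j in np.flatnonzero(~keep_snps):
        report.snps_removed[gt.snp_ids[j]] = (
            f"call_rate {snp_rate[j]:.4f} < {cfg.min_call_rate}")
    if not keep_snps.any():
        raise QcError("empty panel: all SNPs removed by call-rate filter")

    sample_rate = observed[:, keep_snps].mean(axis=1)
    keep_samples = sample_rate >= cfg.min_call_rate
    for i in np.flatnonzero(~keep_samples):
        report.samples_removed[gt.sample_ids[i]] = (
            f"call_rate {sample_rate[i]:.4f} < {cfg.min_call_rate}")
    if not keep_samples.any():
        raise QcError("all samples removed by call-rate filter")

    filtered = GenotypeTable(
        sample_ids=[s for s, k in zip(gt.sample_ids, keep_samples) if k],
        snp_ids=[s for s, k in zip(gt.snp_ids, keep_snps) if k],
        calls=gt.calls[np.ix_(keep_samples, keep_snps)].copy(),
        chrom=None if gt.chrom is None else [c for c, k in zip(gt.chrom, keep_snps) if k],
        pos=None if gt.pos is None else [p for p, k in zip(gt.pos, keep_snps) if k],
    )
    return filtered, report


# ---------------------------------------------------------------------------
# Heterozygosity outliers
# ---------------------------------------------------------------------------

class HetResult(NamedTuple):
    flagged: list[str]
    bounds: tuple[float, float]
    rates: np.ndarray


def heterozygosity_rates(gt: GenotypeTable) -> np.ndarray:
    """Per-sample fraction of heterozygous calls among non-missing calls."""
    observed = ~gt.missing_mask
    het = (gt.calls[..., 0] != gt.calls[..., 1]) & observed
    n_obs = observed.sum(axis=1)
    if (n_obs == 0).any():
        i = int(np.argmax(n_obs == 0))
        raise QcError(f"sample {gt.sample_ids[i]} has no observed calls")
    return het.sum(axis=1) / n_obs


def heterozygosity_outliers(gt: GenotypeTable, cfg: QcConfig | None = None) -> HetResult:
    """Flag samples with extreme heterozygosity.

    A normal distribution is fitted to the per-sample heterozygosity rates
    (sample mean, sample sd with n-1 denominator); samples outside the
    Bonferroni-corrected alpha/n and 1-alpha/n quantiles are flagged, with
    n the number of samples tested.
    """
    cfg = cfg or QcConfig()
    if gt.n_samples < 3:
        raise QcError("heterozygosity outlier detection needs >= 3 samples")
    rates = heterozygosity_rates(gt)
    mean, sd = float(np.mean(rates)), float(np.std(rates, ddof=1))
    if sd == 0.0:
        warnings.warn("heterozygosity rates have zero dispersion; no outliers flagged")
        return HetResult([], (mean, mean), rates)
    tail = cfg.het_alpha / gt.n_samples
    lo = float(stats.norm.ppf(tail, loc=mean, scale=sd))
    hi = float(stats.norm.ppf(1 - tail, loc=mean, scale=sd))
    flagged = [gt.sample_ids[i] for i in np.flatnonzero((rates < lo) | (rates > hi))]
    return HetResult(flagged, (lo, hi), rates)


# ---------------------------------------------------------------------------
# IBS distances and classical MDS
# ---------------------------------------------------------------------------

def _allele_counts(gt: GenotypeTable) -> np.ndarray:
    """(n_samples, n_snps, 4) int8 counts of A, C, G, T per call."""
    counts = np.zeros(gt.calls.shape[:2] + (4,), dtype=np.int8)
    for k, allele in enumerate("ACGT"):
        counts[..., k] = (gt.calls[..., 0] == allele).astype(np.int8)
        counts[..., k] += (gt.calls[..., 1] == allele).astype(np.int8)
    return counts


def ibs_distance_matrix(gt: GenotypeTable) -> np.ndarray:
    """Pairwise identity-by-state distance, d = 1 - shared/(2*loci compared).

    Shared alleles per locus (0, 1 or 2) is the multiset intersection of the
    two unordered allele pairs; only loci non-missing in both samples of a
    pair are compared.  A pair with no jointly observed locus is fatal.
    """
    n = gt.n_samples
    counts = _allele_counts(gt)
    observed = ~gt.missing_mask
    dist = np.zeros((n, n))
    for i in range(n):
        shared = np.minimum(counts[i][None, :, :], counts).sum(axis=2)  # (n, m)
        both = observed[i][None, :] & observed
        loci = both.sum(axis=1)
        if (loci == 0).any():
            j = int(np.argmax(loci == 0))
            raise QcError(
                f"samples {gt.sample_ids[i]} and {gt.sample_ids[j]} share no "
                "jointly observed locus")
        dist[i] = 1.0 - (shared * both).sum(axis=1) / (2.0 * loci)
    np.fill_diagonal(dist, 0.0)
    return (dist + dist.T) / 2.0


def classical_mds(D: np.ndarray, k: int) -> np.ndarray:
    """Torgerson scaling of a distance matrix into n x k coordinates.

    Double-centers -D^2/2, takes the top-k eigenvectors scaled by the square
    root of their eigenvalues (sorted descending).  Columns belonging to
    negative eigenvalues among the top k are zeroed with a warning.  For
    reproducibility each axis' sign is fixed so its first nonzero loading is
    positive.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("D must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("D must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1][:k]
    coords = np.zeros((n, k))
    for col, idx in enumerate(order):
        lam = eigval[idx]
        if lam <= 0:
            if lam < -1e-12 * max(1.0, abs(eigval).max()):
                warnings.warn(f"MDS axis {col + 1} has negative eigenvalue "
                              f"{lam:.3g}; column zeroed")
            continue
        axis = eigvec[:, idx] * np.sqrt(lam)
        nz = np.flatnonzero(np.abs(axis) > 1e-12)
        if nz.size and axis[nz[0]] < 0:
            axis = -axis
        coords[:, col] = axis
    return coords


# ---------------------------------------------------------------------------
# Ancestry assignment
# ---------------------------------------------------------------------------

class AncestryResult(NamedTuple):
    calls: dict[str, str]            # study sample -> population (or "unassignable")
    flagged: list[str]               # study samples not in the retained population
    coordinates: dict[str, list[float]]  # all samples (study + reference)
    shared_snps: list[str]


def assign_ancestry(study_gt: GenotypeTable, ref_gt: GenotypeTable,
                    ref_labels: dict[str, str], cfg: QcConfig | None = None
                    ) -> AncestryResult:
    """Assign each study sample the population of its nearest reference centroid.

    Study and reference panels are intersected to their shared SNPs, a joint
    IBS/MDS embedding is computed over the union of samples, and each study
    sample takes the label of the nearest reference-population centroid in the
    first ``mds_dims`` dimensions.  Samples not assigned to the retained
    population (EUR by default) are flagged for exclusion.
    """
    cfg = cfg or QcConfig()
    pops = sorted(set(ref_labels.values()))
    if len(pops) < 2:
        raise QcError("ancestry assignment needs >= 2 reference populations")
    missing = [s for s in ref_gt.sample_ids if s not in ref_labels]
    if missing:
        raise QcError(f"reference sample(s) without population label: {missing[:3]}")
    if study_gt.n_samples == 0:
        return AncestryResult({}, [], {}, [])

    shared = [s for s in study_gt.snp_ids if s in set(ref_gt.snp_ids)]
    if not shared:
        raise QcError("study and reference panels share no SNPs")
    study = study_gt.subset(snp_ids=shared)
    ref = ref_gt.subset(snp_ids=shared)

    overlap = set(study.sample_ids) & set(ref.sample_ids)
    if overlap:
        raise QcError(f"sample ID(s) present in both panels: {sorted(overlap)[:3]}")
    combined = GenotypeTable(
        sample_ids=study.sample_ids + ref.sample_ids,
        snp_ids=shared,
        calls=np.concatenate([study.calls, ref.calls], axis=0),
    )
    coords = classical_mds(ibs_distance_matrix(combined), cfg.mds_dims)
    n_study = study.n_samples

    centroids = {pop: coords[[n_study + i for i, s in enumerate(ref.sample_ids)
                              if ref_labels[s] == pop]].mean(axis=0)
                 for pop in pops}
    calls: dict[str, str] = {}
    flagged: list[str] = []
    for i, sid in enumerate(study.sample_ids):
        dists = {pop: float(np.linalg.norm(coords[i] - c)) for pop, c in centroids.items()}
        pop = min(dists, key=dists.get)
        if (cfg.max_centroid_distance is not None
                and dists[pop] > cfg.max_centroid_distance):
            pop = "unassignable"
        calls[sid] = pop
        if pop != cfg.retained_population:
            flagged.append(sid)
    coordinates = {sid: coords[i].tolist()
                   for i, sid in enumerate(combined.sample_ids)}
    return AncestryResult(calls, flagged, coordinates, shared)
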