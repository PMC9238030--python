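"""End-to-end orchestration: QC -> scoring -> annotation -> association.

``run_pipeline`` reads the weight/genotype/phenotype files, runs the QC chain
(call rate -> heterozygosity -> ancestry), scores the three PRSs, annotates
the BRCA1/2 cluster-region covariates, and fits the six gene-stratified
logistic models (2 genes x 3 PRS sets, one PRS term per model, covariates
standardized PRS + in_bccr + in_occr + sICGT) with family-clustered robust
variance.  It also computes the ED-vs-LD Welch tests per gene and PRS set,
the four pairwise Spearman correlations between standardized PRSs, a
Table-1-style descriptive summary and the recruitment-source allele-frequency
screen.  Every output is a pure function of (inputs, config), so repeated
runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import qc as qcmod
from .io_genotypes import (PRS_SETS, GenotypeTable, SampleRecord,
                           read_phenotypes, read_population_labels, read_tped,
                           read_weights)
from .regions import classify_variant_region
from .scoring import PrsResult, harmonize, score_cohort

log = logging.getLogger("extremeprs")

#: (PRS set pairs correlated per gene, mirroring the published figure layout)
CORRELATION_PAIRS = (("overall", "ER+"), ("overall", "ER-"))

MODEL_TERMS = ("intercept", "std_prs", "in_bccr", "in_occr", "sicgt")


class PipelineError(RuntimeError):
    """Fatal pipeline failure; the message names the failing stage."""


@dataclass
class RunConfig:
    """Paths, QC thresholds and analysis plan for one pipeline run."""

    weights: str
    tped: str
    tfam: str
    phenotypes: str
    outdir: str
    ref_tped: str | None = None
    ref_tfam: str | None = None
    ref_labels: str | None = None
    qc: qcmod.QcConfig = field(default_factory=qcmod.QcConfig)
    genes: tuple[str, ...] = ("BRCA1", "BRCA2")
    prs_sets: tuple[str, ...] = PRS_SETS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        qc_cfg = qcmod.QcConfig(**raw.pop("qc", {}))
        for key in ("genes", "prs_sets"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(qc=qc_cfg, **raw)

    def validate_paths(self) -> None:
        for name in ("weights", "tped", "tfam", "phenotypes",
                     "ref_tped", "ref_tfam", "ref_labels"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name} file not found: {value}")


@dataclass
class RunReport:
    """Everything one run computed, plus the paths it was written to."""

    qc_report: qcmod.QcReport
    prs: PrsResult
    association: dict[tuple[str, str], assoc.AssociationResult]
    welch: dict[tuple[str, str], assoc.WelchResult]
    correlations: dict[tuple[str, str, str], assoc.CorrelationResult]
    descriptives: pd.DataFrame
    allele_screen: pd.DataFrame | None
    n_input: int
    n_retained: int
    outdir: str


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def run_qc(gt: GenotypeTable, cfg: qcmod.QcConfig,
           ref_gt: GenotypeTable | None = None,
           ref_labels: dict[str, str] | None = None
           ) -> tuple[GenotypeTable, qcmod.QcReport]:
    """QC chain in the fixed order: call rate -> heterozygosity -> ancestry."""
    gt, report = qcmod.filter_call_rate(gt, cfg)

    het = qcmod.heterozygosity_outliers(gt, cfg)
    report.het_bounds = het.bounds
    if het.flagged:
        keep = [s for s in gt.sample_ids if s not in set(het.flagged)]
        for s in het.flagged:
            report.samples_removed[s] = "heterozygosity outlier"
        gt = gt.subset(sample_ids=keep)

    if ref_gt is not None:
        if ref_labels is None:
            raise PipelineError("ancestry stage: reference panel without labels")
        anc = qcmod.assign_ancestry(gt, ref_gt, ref_labels, cfg)
        report.ancestry_calls = anc.calls
        report.mds_coordinates = anc.coordinates
        if anc.flagged:
            for s in anc.flagged:
                report.samples_removed[s] = (
                    f"putative non-{cfg.retained_population} ancestry ({anc.calls[s]})")
            gt = gt.subset(sample_ids=[s for s in gt.sample_ids
                                       if s not in set(anc.flagged)])
    return gt, report


def annotate_records(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Phenotype records -> DataFrame with in_bccr / in_occr columns added."""
    rows = []
    for r in records:
        in_bccr, in_occr = classify_variant_region(
            r.gene, r.variant_c_start, r.variant_c_end)
        rows.append({"sample_id": r.sample_id, "family_id": r.family_id,
                     "group": r.group, "gene": r.gene, "sicgt": bool(r.sicgt),
                     "variant_c_start": r.variant_c_start,
                     "variant_c_end": r.variant_c_end,
                     "in_bccr": in_bccr, "in_occr": in_occr})
    return pd.DataFrame(rows)


def fit_models(pheno: pd.DataFrame, prs: PrsResult,
               genes: Sequence[str], prs_sets: Sequence[str]
               ) -> dict[tuple[str, str], assoc.AssociationResult]:
    """The gene-stratified logistic models, one PRS term per model."""
    results: dict[tuple[str, str], assoc.AssociationResult] = {}
    idx = {s: i for i, s in enumerate(prs.sample_ids)}
    for gene in genes:
        sub = pheno[pheno["gene"] == gene]
        if sub.empty:
            log.warning("no samples for gene %s; models skipped", gene)
            continue
        rows = np.array([idx[s] for s in sub["sample_id"]])
        y = (sub["group"] == "ED").to_numpy(dtype=float)
        covs = np.column_stack([
            sub["in_bccr"].to_numpy(dtype=float),
            sub["in_occr"].to_numpy(dtype=float),
            sub["sicgt"].to_numpy(dtype=float),
        ])
        for set_name in prs_sets:
            X = np.column_stack([np.ones(len(sub)),
                                 prs.std[set_name][rows], covs])
            fit = assoc.fit_logistic(y, X, colnames=list(MODEL_TERMS))
            results[(gene, set_name)] = assoc.cluster_robust_covariance(
                fit, sub["family_id"].to_numpy())
    return results


def descriptive_table(pheno: pd.DataFrame) -> pd.DataFrame:
    """Key characteristics of the analysed sample (total / ED / LD counts)."""
    def counts(mask: pd.Series | None, label: str) -> dict:
        sub = pheno if mask is None else pheno[mask]
        return {"characteristic": label, "total": len(sub),
                "ED": int((sub["group"] == "ED").sum()),
                "LD": int((sub["group"] == "LD").sum())}

    rows = [counts(None, "study sample"),
            counts(pheno["sicgt"], "sICGT"),
            counts(~pheno["sicgt"], "not sICGT")]
    for gene in sorted(pheno["gene"].unique()):
        g = pheno["gene"] == gene
        rows.append(counts(g, f"{gene} PV carriers"))
        rows.append(counts(g & pheno["in_bccr"], f"{gene} PV within BCCR"))
        rows.append(counts(g & pheno["in_occr"], f"{gene} PV within OCCR"))
    return pd.DataFrame(rows)


def simulate_and_associate(cfg, prs_set: str = "overall"
                           ) -> assoc.AssociationResult:
    """Simulate one cohort in memory and fit the pooled ED-vs-LD model.

    Light path for parameter-recovery and calibration studies: genotypes ->
    harmonize/impute/score/standardize -> phenotypes -> logistic fit with
    family-clustered robust variance, pooled over genes (the data-generating
    model has no gene effect).  No files are written and the ancestry stage
    is skipped.
    """
    from . import synth
    from .scoring import compute_prs, harmonize, impute_missing, standardize

    if cfg.published_structure:
        weights = synth.published_structure_weights(synth._rng(cfg, "weights"))
    else:
        weights = synth.simulate_weights(cfg.n_snps, cfg.n_ambiguous,
                                         synth._rng(cfg, "weights"))
    gsim = synth.simulate_genotypes(cfg, weights)
    hd = impute_missing(harmonize(weights, gsim.gt))
    raw, _ = compute_prs(hd, prs_set)
    std = standardize(raw)
    records = synth.simulate_phenotypes(cfg, std, gsim.gt.sample_ids,
                                        gsim.family_ids)
    pheno = annotate_records(records)
    y = (pheno["group"] == "ED").to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(pheno)), std,
                         pheno["in_bccr"].to_numpy(dtype=float),
                         pheno["in_occr"].to_numpy(dtype=float),
                         pheno["sicgt"].to_numpy(dtype=float)])
    fit = assoc.fit_logistic(y, X, colnames=list(MODEL_TERMS))
    return assoc.cluster_robust_covariance(fit, pheno["family_id"].to_numpy())


# ---------------------------------------------------------------------------
# The run
# ---------------------------------------------------------------------------

def _stage(name: str):
    """Context manager logging stage wall time and naming it on failure."""
    class _Stage:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                log.error("stage %s: FAILED after %.2fs: %s", name, dt, exc)
                if exc_type not in (PipelineError,):
                    raise PipelineError(f"stage {name} failed: {exc}") from exc
                return False
            log.info("stage %s: done in %.2fs", name, dt)
            return False
    return _Stage()


def run_pipeline(cfg: RunConfig) -> RunReport:
    cfg.validate_paths()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    failed_marker = outdir / "FAILED"
    try:
        with _stage("read-inputs"):
            weights = read_weights(cfg.weights)
            gt, stubs = read_tped(cfg.tped, cfg.tfam)
            records = read_phenotypes(cfg.phenotypes)
            family_of = {r.sample_id: r.family_id for r in records}
            n_input = gt.n_samples
            ref_gt = ref_labels = None
            if cfg.ref_tped is not None:
                ref_gt, _ = read_tped(cfg.ref_tped, cfg.ref_tfam)
                ref_labels = read_population_labels(cfg.ref_labels)

        with _stage("qc"):
            gt, qc_report = run_qc(gt, cfg.qc, ref_gt, ref_labels)
            qc_report.to_json(outdir / "qc_report.json")
            retained = [s for s in gt.sample_ids if s in family_of]
            dropped = gt.n_samples - len(retained)
            if dropped:
                log.warning("%d genotyped sample(s) have no phenotype row", dropped)
            gt = gt.subset(sample_ids=retained)
            log.info("retained %d of %d samples, %d SNP columns",
                     gt.n_samples, n_input, gt.n_snps)

        with _stage("allele-frequency-screen"):
            rec_by_id = {r.sample_id: r for r in records}
            source = np.array(["GC-HBOC" if rec_by_id[s].sicgt else "unselected"
                               for s in gt.sample_ids])
            allele_screen = None
            if np.unique(source).size == 2:
                allele_screen = assoc.compare_allele_frequencies(
                    harmonize(weights, gt), source)
                allele_screen.to_csv(outdir / "allele_frequency_screen.tsv",
                                     sep="\t", index=False, float_format="%.10g")
            else:
                log.warning("single recruitment source; allele screen skipped")

        with _stage("scoring"):
            prs = score_cohort(weights, gt, sets=cfg.prs_sets)
            prs_df = pd.DataFrame({"sample_id": prs.sample_ids})
            for set_name in cfg.prs_sets:
                prs_df[f"raw_{set_name}"] = prs.raw[set_name]
                prs_df[f"std_{set_name}"] = prs.std[set_name]
            prs_df.to_csv(outdir / "prs.tsv", sep="\t", index=False,
                          float_format="%.10g")
            Path(outdir / "prs_exclusions.json").write_text(json.dumps(
                [{"snp_id": s, "reason": r} for s, r in prs.exclusions],
                indent=2) + "\n")
            log.info("effective SNP set sizes: %s", prs.effective_n)

        with _stage("annotate"):
            pheno = annotate_records([rec_by_id[s] for s in gt.sample_ids])
            pheno.to_csv(outdir / "phenotypes_annotated.tsv", sep="\t",
                         index=False)

        with _stage("association"):
            models = fit_models(pheno, prs, cfg.genes, cfg.prs_sets)
            tables = []
            for (gene, set_name), res in models.items():
                t = res.table.copy()
                t.insert(0, "gene", gene)
                t.insert(1, "prs_set", set_name)
                t["n"] = res.n
                t["n_clusters"] = res.n_clusters
                t["converged"] = res.converged
                tables.append(t)
            pd.concat(tables, ignore_index=True).to_csv(
                outdir / "association.tsv", sep="\t", index=False,
                float_format="%.10g")

        with _stage("group-comparisons"):
            idx = {s: i for i, s in enumerate(prs.sample_ids)}
            welch: dict[tuple[str, str], assoc.WelchResult] = {}
            correlations: dict[tuple[str, str, str], assoc.CorrelationResult] = {}
            for gene in cfg.genes:
                sub = pheno[pheno["gene"] == gene]
                if sub.empty:
                    continue
                rows = np.array([idx[s] for s in sub["sample_id"]])
                ed = (sub["group"] == "ED").to_numpy()
                for set_name in cfg.prs_sets:
                    z = prs.std[set_name][rows]
                    if ed.sum() >= 2 and (~ed).sum() >= 2:
                        welch[(gene, set_name)] = assoc.welch_t_test(z[ed], z[~ed])
                for a, b in CORRELATION_PAIRS:
                    if a in cfg.prs_sets and b in cfg.prs_sets:
                        correlations[(gene, a, b)] = assoc.spearman_correlation(
                            prs.std[a][rows], prs.std[b][rows])
            pd.DataFrame([
                {"gene": g, "prs_set": s, "t": w.t, "df": w.df, "p": w.p}
                for (g, s), w in welch.items()
            ]).to_csv(outdir / "welch.tsv", sep="\t", index=False,
                      float_format="%.10g")
            pd.DataFrame([
                {"gene": g, "set_a": a, "set_b": b, "rho": c.rho,
                 "ci_low": c.ci95[0], "ci_high": c.ci95[1], "n": c.n}
                for (g, a, b), c in correlations.items()
            ]).to_csv(outdir / "correlations.tsv", sep="\t", index=False,
                      float_format="%.10g")

        with _stage("descriptives"):
            descriptives = descriptive_table(pheno)
            descriptives.to_csv(outdir / "descriptives.tsv", sep="\t", index=False)

        with _stage("write-manifest"):
            resolved = dataclasses.asdict(cfg)
            Path(outdir / "run_config.json").write_text(
                json.dumps(resolved, indent=2, sort_keys=True, default=str) + "\n")

        if failed_marker.exists():
            failed_marker.unlink()
        return RunReport(
            qc_report=qc_report, prs=prs, association=models, welch=welch,
            correlations=correlations, descriptives=descriptives,
            allele_screen=allele_screen, n_input=n_input,
            n_retained=gt.n_samples, outdir=str(outdir),
        )
    except Exception as exc:
        failed_marker.write_text(f"{exc}\n")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
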