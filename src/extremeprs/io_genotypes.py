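"""Readers and writers for the pipeline's text formats.

Genotypes travel as transposed-pedigree (TPED/TFAM) text, SNP weights and
phenotypes as tab-separated tables with a header.  All genomic coordinates are
1-based inclusive, matching the HGVS c. coordinates used for BRCA1/2 variants.

The TPED dialect: whitespace-delimited, four leading columns
(chromosome, snp_id, genetic distance in cM, position) followed by two allele
columns per sample; the cM column is read but ignored.  A missing call is
"0 0" -- a half-missing call (exactly one allele "0") is a parse error, since
an ambiguous call is worse than a missing one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ALLELES = frozenset("ACGT")
MISSING_ALLELE = "0"

#: The three published PRS SNP sets: overall breast cancer, estrogen-receptor
#: positive and estrogen-receptor negative disease.
PRS_SETS = ("overall", "ER+", "ER-")

GENES = ("BRCA1", "BRCA2")
GROUPS = ("ED", "LD")

WEIGHT_COLUMNS = ("snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "sets")
PHENOTYPE_COLUMNS = ("sample_id", "family_id", "group", "gene", "sicgt",
                     "variant_c_start", "variant_c_end", "age_at_diagnosis", "er_status")


class ParseError(ValueError):
    """Fatal error while parsing an input file; message names file and row."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpWeight:
    """One PRS locus: alleles, per-allele log odds ratio, set membership."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    sets: frozenset[str]

    def __post_init__(self) -> None:
        if self.effect_allele not in ALLELES:
            raise ValueError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in ALLELES:
            raise ValueError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not np.isfinite(self.beta):
            raise ValueError(f"{self.snp_id}: beta is not finite")
        if not self.sets:
            raise ValueError(f"{self.snp_id}: empty PRS-set membership")
        unknown = set(self.sets) - set(PRS_SETS)
        if unknown:
            raise ValueError(f"{self.snp_id}: unknown PRS set(s) {sorted(unknown)}")

    @property
    def is_ambiguous(self) -> bool:
        """True for strand-ambiguous (palindromic) allele pairs A/T and C/G."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class GenotypeTable:
    """Samples x SNPs unordered allele-pair calls.

    ``calls`` has shape (n_samples, n_snps, 2), dtype ``<U1``; a missing call
    stores ``"0"`` in both positions.  ``chrom``/``pos`` carry optional per-SNP
    map information so a table read from TPED round-trips bit-exactly.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray
    chrom: list[str] | None = None
    pos: list[int] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U1")
        n, m = len(self.sample_ids), len(self.snp_ids)
        if self.calls.shape != (n, m, 2):
            raise ValueError(f"calls shape {self.calls.shape} != ({n}, {m}, 2)")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample_ids")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate snp_ids")
        valid = np.isin(self.calls, list(ALLELES | {MISSING_ALLELE}))
        if not valid.all():
            bad = self.calls[~valid]
            raise ValueError(f"invalid allele symbol(s): {sorted(set(bad.tolist()))}")
        a_missing = self.calls[..., 0] == MISSING_ALLELE
        b_missing = self.calls[..., 1] == MISSING_ALLELE
        if (a_missing != b_missing).any():
            i, j = np.argwhere(a_missing != b_missing)[0]
            raise ValueError(
                f"half-missing call for sample {self.sample_ids[i]} at SNP {self.snp_ids[j]}"
            )
        if self.chrom is not None and len(self.chrom) != m:
            raise ValueError("chrom length mismatch")
        if self.pos is not None and len(self.pos) != m:
            raise ValueError("pos length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_snps): True where the call is missing."""
        return self.calls[..., 0] == MISSING_ALLELE

    def snp_index(self, snp_id: str) -> int:
        return self.snp_ids.index(snp_id)

    def subset(self, sample_ids: Sequence[str] | None = None,
               snp_ids: Sequence[str] | None = None) -> "GenotypeTable":
        """Row/column subset preserving the requested order."""
        rows = (np.arange(self.n_samples) if sample_ids is None
                else np.array([self.sample_ids.index(s) for s in sample_ids]))
        cols = (np.arange(self.n_snps) if snp_ids is None
                else np.array([self.snp_ids.index(s) for s in snp_ids]))
        return GenotypeTable(
            sample_ids=[self.sample_ids[i] for i in rows],
            snp_ids=[self.snp_ids[j] for j in cols],
            calls=self.calls[np.ix_(rows, cols)].copy(),
            chrom=None if self.chrom is None else [self.chrom[j] for j in cols],
            pos=None if self.pos is None else [self.pos[j] for j in cols],
        )


@dataclass
class SampleRecord:
    """Phenotype/covariate row for one carrier.

    ``group`` is "ED" (primary breast-cancer diagnosis before age 35) or "LD"
    (cancer-free survival to age 60).  ``sicgt`` flags selection by the
    GC-HBOC inclusion criteria for germline testing.  The pathogenic variant's
    extent is the 1-based inclusive coding-sequence interval
    [variant_c_start, variant_c_end].
    """

    sample_id: str
    family_id: str
    group: str | None = None
    gene: str | None = None
    sicgt: bool | None = None
    variant_c_start: int | None = None
    variant_c_end: int | None = None
    age_at_diagnosis: float | None = None
    er_status: str | None = None

    def __post_init__(self) -> None:
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"{self.sample_id}: unknown group {self.group!r}")
        if self.gene is not None and self.gene not in GENES:
            raise ValueError(f"{self.sample_id}: unknown gene {self.gene!r}")
        if (self.variant_c_start is not None and self.variant_c_end is not None
                and self.variant_c_start > self.variant_c_end):
            raise ValueError(f"{self.sample_id}: variant_c_start > variant_c_end")
        if (self.group == "ED" and self.age_at_diagnosis is not None
                and not self.age_at_diagnosis < 35):
            raise ValueError(
                f"{self.sample_id}: ED requires age at diagnosis < 35, "
                f"got {self.age_at_diagnosis}"
            )


# ---------------------------------------------------------------------------
# Weight tables
# ---------------------------------------------------------------------------

def read_weights(path: str | Path) -> list[SnpWeight]:
    """Read a tab-separated SNP weight table into :class:`SnpWeight` records.

    Required columns: snp_id, chrom, pos, effect_allele, other_allele, beta,
    sets (comma-separated subset of ``overall,ER+,ER-``).  Row order is
    preserved; any malformed row is a fatal :class:`ParseError` naming it.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(WEIGHT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    weights: list[SnpWeight] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # 1-based, after the header line
        snp_id = str(row["snp_id"])
        if snp_id in seen:
            raise ParseError(f"{path} row {rowno}: duplicate snp_id {snp_id}")
        seen.add(snp_id)
        try:
            beta = float(row["beta"])
        except (TypeError, ValueError):
            raise ParseError(f"{path} row {rowno}: non-numeric beta {row['beta']!r}") from None
        sets = frozenset(s.strip() for s in str(row["sets"]).split(",") if s.strip())
        try:
            weights.append(SnpWeight(
                snp_id=snp_id, chrom=str(row["chrom"]), pos=int(row["pos"]),
                effect_allele=str(row["effect_allele"]), other_allele=str(row["other_allele"]),
                beta=beta, sets=sets,
            ))
        except ValueError as exc:
            raise ParseError(f"{path} row {rowno}: {exc}") from None
    return weights


def write_weights(weights: Iterable[SnpWeight], path: str | Path) -> None:
    rows = [{
        "snp_id": w.snp_id, "chrom": w.chrom, "pos": w.pos,
        "effect_allele": w.effect_allele, "other_allele": w.other_allele,
        "beta": repr(w.beta),
        "sets": ",".join(s for s in PRS_SETS if s in w.sets),
    } for w in weights]
    pd.DataFrame(rows, columns=list(WEIGHT_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TPED / TFAM
# ---------------------------------------------------------------------------

def read_tped(tped_path: str | Path, tfam_path: str | Path
              ) -> tuple[GenotypeTable, list[SampleRecord]]:
    """Read transposed-pedigree genotypes.

    Returns the genotype table and one stub :class:`SampleRecord` per TFAM row
    carrying the sample and family IDs (phenotype fields are left unset; use
    :func:`read_phenotypes` for the full covariate table).
    """
    tped_path, tfam_path = Path(tped_path), Path(tfam_path)

    sample_ids: list[str] = []
    stubs: list[SampleRecord] = []
    for lineno, line in enumerate(tfam_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ParseError(f"{tfam_path} line {lineno}: expected >=2 columns")
        family_id, sample_id = fields[0], fields[1]
        sample_ids.append(sample_id)
        stubs.append(SampleRecord(sample_id=sample_id, family_id=family_id))
    n = len(sample_ids)
    if n == 0:
        raise ParseError(f"{tfam_path}: no samples")

    snp_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    columns: list[np.ndarray] = []
    for lineno, line in enumerate(tped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 4 + 2 * n:
            raise ParseError(
                f"{tped_path} line {lineno}: expected {4 + 2 * n} columns "
                f"({n} samples), got {len(fields)}"
            )
        chrom.append(fields[0])
        snp_ids.append(fields[1])
        try:
            pos.append(int(fields[3]))
        except ValueError:
            raise ParseError(f"{tped_path} line {lineno}: non-integer position "
                             f"{fields[3]!r}") from None
        pair = np.array(fields[4:], dtype="<U1").reshape(n, 2)
        bad = ~np.isin(pair, list(ALLELES | {MISSING_ALLELE}))
        if bad.any():
            raise ParseError(f"{tped_path} line {lineno}: invalid allele "
                             f"{pair[bad][0]!r}")
        half = (pair == MISSING_ALLELE).sum(axis=1) == 1
        if half.any():
            raise ParseError(f"{tped_path} line {lineno}: half-missing call for "
                             f"sample {sample_ids[int(np.argmax(half))]}")
        columns.append(pair)
    if not snp_ids:
        raise ParseError(f"{tped_path}: no SNPs")
    calls = np.stack(columns, axis=1)  # (n_samples, n_snps, 2)
    try:
        gt = GenotypeTable(sample_ids=sample_ids, snp_ids=snp_ids, calls=calls,
                           chrom=chrom, pos=pos)
    except ValueError as exc:
        raise ParseError(f"{tped_path}: {exc}") from None
    return gt, stubs


def write_tped(gt: GenotypeTable, tped_path: str | Path, tfam_path: str | Path,
               family_ids: Sequence[str] | None = None) -> None:
    """Write a genotype table as TPED/TFAM (missing call -> ``0 0``)."""
    if family_ids is None:
        family_ids = gt.sample_ids
    if len(family_ids) != gt.n_samples:
        raise ValueError("family_ids length mismatch")
    chrom = gt.chrom if gt.chrom is not None else ["1"] * gt.n_snps
    pos = gt.pos if gt.pos is not None else list(range(1, gt.n_snps + 1))
    with open(tped_path, "w") as fh:
        for j in range(gt.n_snps):
            alleles = " ".join(" ".join(pair) for pair in gt.calls[:, j, :])
            fh.write(f"{chrom[j]} {gt.snp_ids[j]} 0 {pos[j]} {alleles}\n")
    with open(tfam_path, "w") as fh:
        for fam, sid in zip(family_ids, gt.sample_ids):
            fh.write(f"{fam} {sid} 0 0 0 -9\n")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

_BOOL = {"0": False, "1": True, "true": True, "false": False}


def _parse_bool(value: str, context: str) -> bool:
    try:
        return _BOOL[str(value).strip().lower()]
    except KeyError:
        raise ParseError(f"{context}: invalid boolean {value!r}") from None


def read_phenotypes(path: str | Path) -> list[SampleRecord]:
    """Read the phenotype/covariate TSV into :class:`SampleRecord` rows."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "family_id", "group", "gene", "sicgt",
                "variant_c_start", "variant_c_end"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    records: list[SampleRecord] = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2
        if pd.isna(row["family_id"]) or not str(row["family_id"]).strip():
            raise ParseError(f"{path} row {rowno}: missing family_id")
        age = row.get("age_at_diagnosis")
        er = row.get("er_status")
        try:
            records.append(SampleRecord(
                sample_id=str(row["sample_id"]),
                family_id=str(row["family_id"]),
                group=str(row["group"]),
                gene=str(row["gene"]),
                sicgt=_parse_bool(row["sicgt"], f"{path} row {rowno}"),
                variant_c_start=int(row["variant_c_start"]),
                variant_c_end=int(row["variant_c_end"]),
                age_at_diagnosis=None if pd.isna(age) else float(age),
                er_status=None if (er is None or pd.isna(er)) else str(er),
            ))
        except ParseError:
            raise
        except ValueError as exc:
            raise ParseError(f"{path} row {rowno}: {exc}") from None
    return records


def write_phenotypes(records: Iterable[SampleRecord], path: str | Path) -> None:
    rows = [{
        "sample_id": r.sample_id, "family_id": r.family_id, "group": r.group,
        "gene": r.gene, "sicgt": int(bool(r.sicgt)),
        "variant_c_start": r.variant_c_start, "variant_c_end": r.variant_c_end,
        "age_at_diagnosis": "" if r.age_at_diagnosis is None else r.age_at_diagnosis,
        "er_status": "" if r.er_status is None else r.er_status,
    } for r in records]
    pd.DataFrame(rows, columns=list(PHENOTYPE_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_population_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample_id, population) -> mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "population"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns sample_id, population")
    return dict(zip(df["sample_id"], df["population"]))


def write_population_labels(labels: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(labels), "population": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)
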