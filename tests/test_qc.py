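import numpy as np
import pytest

import extremeprs as ep
from extremeprs import (QcConfig, QcError, assign_ancestry, classical_mds,
                        filter_call_rate, heterozygosity_outliers,
                        ibs_distance_matrix, GenotypeTable)
from extremeprs.synth import balding_nichols_freqs

from conftest import make_gt, random_gt


def hwe_calls(freqs, n, rng, a="A", b="G"):
    m = len(freqs)
    dosage = rng.binomial(2, freqs, size=(n, m))
    calls = np.empty((n, m, 2), dtype="<U1")
    calls[..., 0] = np.where(dosage >= 1, a, b)
    calls[..., 1] = np.where(dosage == 2, a, b)
    return calls


# ---------------------------------------------------------------------------
# Call-rate filtering
# ---------------------------------------------------------------------------

def test_complete_table_is_unchanged(rng):
    gt, _ = random_gt(rng, n=8, m=5)
    out, report = filter_call_rate(gt, QcConfig())
    assert out.sample_ids == gt.sample_ids and out.snp_ids == gt.snp_ids
    assert not report.snps_removed and not report.samples_removed


def test_snp_below_threshold_removed(rng):
    gt, _ = random_gt(rng, n=20, m=3)
    calls = gt.calls.copy()
    calls[:2, 1] = "0"  # SNP rs2 missing in 2/20 -> rate 0.90 < 0.95
    gt = GenotypeTable(gt.sample_ids, gt.snp_ids, calls)
    out, report = filter_call_rate(gt, QcConfig())
    assert out.snp_ids == ["rs1", "rs3"]
    assert list(report.snps_removed) == ["rs2"]
    assert not report.samples_removed


def test_call_rate_filter_matches_brute_force_recount(rng):
    gt, _ = random_gt(rng, n=50, m=40, missing_rate=0.10)
    cfg = QcConfig(min_call_rate=0.95)
    out, _ = filter_call_rate(gt, cfg)

    # independent recount: SNP rates on the full table, then sample rates
    obs = [[gt.calls[i, j, 0] != "0" for j in range(40)] for i in range(50)]
    keep_snps = [j for j in range(40)
                 if sum(obs[i][j] for i in range(50)) / 50 >= 0.95]
    keep_samples = [i for i in range(50)
                    if sum(obs[i][j] for j in keep_snps) / len(keep_snps) >= 0.95]
    assert out.snp_ids == [gt.snp_ids[j] for j in keep_snps]
    assert out.sample_ids == [gt.sample_ids[i] for i in keep_samples]


def test_call_rate_filter_idempotent(rng):
    gt, _ = random_gt(rng, n=50, m=40, missing_rate=0.10)
    once, _ = filter_call_rate(gt, QcConfig())
    twice, report = filter_call_rate(once, QcConfig())
    assert twice.sample_ids == once.sample_ids
    assert twice.snp_ids == once.snp_ids
    assert not report.snps_removed and not report.samples_removed


def test_all_snps_removed_is_fatal():
    gt = make_gt([["00", "00"], ["AA", "00"], ["00", "AG"]])
    with pytest.raises(QcError, match="empty panel"):
        filter_call_rate(gt, QcConfig())


# ---------------------------------------------------------------------------
# Heterozygosity outliers
# ---------------------------------------------------------------------------

def test_zero_dispersion_flags_nothing():
    gt = make_gt([["AG", "AG"], ["AG", "AG"], ["AG", "AG"]])
    with pytest.warns(UserWarning, match="zero dispersion"):
        res = heterozygosity_outliers(gt, QcConfig())
    assert res.flagged == []


def test_extreme_het_sample_is_the_only_flag(rng):
    """99 samples with het ~0.30 plus one fully heterozygous sample."""
    from scipy import stats
    m = 200
    rates = np.clip(rng.normal(0.30, 0.02, size=99), 0, 1)
    rows = []
    for r in rates:
        k = int(round(r * m))
        row = ["AG"] * k + ["AA"] * (m - k)
        rows.append(row)
    rows.append(["AG"] * m)  # het rate 1.0
    gt = make_gt(rows)
    res = heterozygosity_outliers(gt, QcConfig())
    assert res.flagged == ["S100"]
    # oracle: the fitted-normal Bonferroni bound is far below 1.0
    fitted = res.rates
    hi = stats.norm.ppf(1 - 0.05 / 100, np.mean(fitted), np.std(fitted, ddof=1))
    assert hi == pytest.approx(res.bounds[1])
    assert 1.0 > hi


def test_het_flag_rate_calibrated_under_null(rng):
    """With rates drawn from a normal, the per-cohort flag probability stays
    near the nominal Bonferroni level (<= ~2*alpha)."""
    n, m, reps = 60, 120, 500
    flagged_any = 0
    for _ in range(reps):
        rates = np.clip(rng.normal(0.3, 0.03, size=n), 0, 1)
        k = np.round(rates * m).astype(int)
        calls = np.empty((n, m, 2), dtype="<U1")
        calls[..., 0] = "A"
        calls[..., 1] = "A"
        for i in range(n):
            calls[i, :k[i], 1] = "G"
        gt = GenotypeTable([f"S{i}" for i in range(n)],
                           [f"rs{j}" for j in range(m)], calls)
        res = heterozygosity_outliers(gt, QcConfig())
        flagged_any += bool(res.flagged)
    assert flagged_any / reps <= 2.5 * 0.05


# ---------------------------------------------------------------------------
# IBS distances
# ---------------------------------------------------------------------------

def test_identical_samples_have_zero_distance(rng):
    gt, _ = random_gt(rng, n=1, m=10)
    dup = GenotypeTable(["S1", "S2"], gt.snp_ids,
                        np.concatenate([gt.calls, gt.calls], axis=0))
    D = ibs_distance_matrix(dup)
    assert D[0, 1] == 0.0


@pytest.mark.parametrize("a, b, expected", [
    ("AA", "GG", 1.0),   # no shared alleles
    ("AA", "AG", 0.5),   # one of two alleles shared
    ("AG", "AG", 0.0),
    ("AG", "GA", 0.0),   # unordered pairs
])
def test_single_locus_distances(a, b, expected):
    gt = make_gt([[a], [b]])
    assert ibs_distance_matrix(gt)[0, 1] == pytest.approx(expected)


def test_ibs_distance_is_a_bounded_symmetric_function(rng):
    gt, _ = random_gt(rng, n=15, m=30, missing_rate=0.1)
    D = ibs_distance_matrix(gt)
    assert np.allclose(D, D.T)
    assert (D >= 0).all() and (D <= 1).all()
    assert np.allclose(np.diag(D), 0)


def test_pair_with_no_joint_loci_is_fatal():
    gt = make_gt([["AA", "00"], ["00", "GG"]])
    with pytest.raises(QcError, match="jointly observed"):
        ibs_distance_matrix(gt)


# ---------------------------------------------------------------------------
# Classical MDS
# ---------------------------------------------------------------------------

def test_two_points_embed_at_plus_minus_one():
    D = np.array([[0.0, 2.0], [2.0, 0.0]])
    coords = classical_mds(D, 2)
    assert coords[:, 0] == pytest.approx([1.0, -1.0])
    assert coords[:, 1] == pytest.approx([0.0, 0.0])


def test_euclidean_configuration_distances_reproduced(rng):
    points = rng.normal(size=(12, 3))
    D = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    coords = classical_mds(D, 3)
    D2 = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    assert np.allclose(D, D2, atol=1e-9)


def test_mds_agrees_with_pcoa_oracle(rng):
    from skbio.stats.ordination import pcoa
    points = rng.normal(size=(10, 4))
    D = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    coords = classical_mds(D, 3)
    oracle = pcoa(D, number_of_dimensions=3).samples.to_numpy()
    # same embedding up to per-axis sign
    for k in range(3):
        assert (np.allclose(coords[:, k], oracle[:, k], atol=1e-8)
                or np.allclose(coords[:, k], -oracle[:, k], atol=1e-8))


def test_zero_distances_give_zero_coordinates():
    assert np.allclose(classical_mds(np.zeros((4, 4)), 2), 0.0)


def test_non_symmetric_distance_is_fatal():
    D = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValueError, match="symmetric"):
        classical_mds(D, 2)


# ---------------------------------------------------------------------------
# Ancestry assignment
# ---------------------------------------------------------------------------

def _two_pop_panels(rng, fst, n_ref=100, n_study=50, m=150):
    base = rng.uniform(0.1, 0.9, size=m)
    pa = balding_nichols_freqs(base, fst, rng)
    pb = balding_nichols_freqs(base, fst, rng)
    snp_ids = [f"rs{j}" for j in range(m)]
    ref = GenotypeTable(
        [f"A{i}" for i in range(n_ref)] + [f"B{i}" for i in range(n_ref)],
        snp_ids,
        np.concatenate([hwe_calls(pa, n_ref, rng), hwe_calls(pb, n_ref, rng)]))
    labels = {f"A{i}": "POPA" for i in range(n_ref)}
    labels.update({f"B{i}": "POPB" for i in range(n_ref)})
    study = GenotypeTable([f"S{i}" for i in range(n_study)], snp_ids,
                          hwe_calls(pa, n_study, rng))
    return study, ref, labels


def test_duplicated_reference_sample_gets_its_population(rng):
    study, ref, labels = _two_pop_panels(rng, fst=0.1, n_ref=40, n_study=1)
    clone = GenotypeTable(["X1"], ref.snp_ids, ref.calls[:1].copy())
    res = assign_ancestry(clone, ref, labels, QcConfig(retained_population="POPA"))
    assert res.calls == {"X1": "POPA"}
    assert res.flagged == []


def test_two_population_simulation_assignment_accuracy(rng):
    study, ref, labels = _two_pop_panels(rng, fst=0.1, n_ref=200, n_study=50)
    res = assign_ancestry(study, ref, labels, QcConfig(retained_population="POPA"))
    correct = sum(pop == "POPA" for pop in res.calls.values())
    assert correct / 50 >= 0.95


def test_assignment_accuracy_monotone_in_fst(rng):
    accs = []
    for fst in (0.01, 0.05, 0.1):
        study, ref, labels = _two_pop_panels(rng, fst=fst, n_ref=120, n_study=60)
        res = assign_ancestry(study, ref, labels,
                              QcConfig(retained_population="POPA"))
        accs.append(sum(p == "POPA" for p in res.calls.values()) / 60)
    assert accs[0] <= accs[1] <= accs[2]


def test_empty_study_set_returns_empty_calls(rng):
    study, ref, labels = _two_pop_panels(rng, fst=0.1, n_ref=20, n_study=1)
    empty = GenotypeTable([], study.snp_ids,
                          np.empty((0, study.n_snps, 2), dtype="<U1"))
    res = assign_ancestry(empty, ref, labels, QcConfig())
    assert res.calls == {} and res.flagged == []


def test_single_reference_population_is_fatal(rng):
    study, ref, labels = _two_pop_panels(rng, fst=0.1, n_ref=20, n_study=5)
    labels = {k: "POPA" for k in labels}
    with pytest.raises(QcError, match="2 reference populations"):
        assign_ancestry(study, ref, labels, QcConfig())
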