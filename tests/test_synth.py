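import numpy as np
import pandas as pd
import pytest

from l1burden.burden import compute_burden, polymorphic_loci
from l1burden.catalog import RcL1Catalog, RcL1Locus, read_catalog
from l1burden.genotypes import (
    GenotypeMatrix,
    build_genotype_matrix,
    load_deletion_vcf,
    load_mei_vcf,
    match_nonreference_loci,
    match_reference_loci,
)
from l1burden.synth import (
    SimulationConfig,
    activity_mixture_quantile,
    default_ha_set,
    generate_catalog,
    generate_cohort,
    generate_longitudinal,
    make_synthetic_study_catalog,
    simulate_run,
    write_caller_vcfs,
)


def roundtrip(matrix, catalog, tmp_path):
    del_path, mei_path = write_caller_vcfs(matrix, catalog, tmp_path)
    dels, samples = load_deletion_vcf(del_path)
    meis, _ = load_mei_vcf(mei_path)
    ref_m = match_reference_loci(dels, catalog)
    nonref_m = match_nonreference_loci(meis, catalog)
    return build_genotype_matrix(ref_m, nonref_m, catalog, samples)


def test_generated_catalog_is_seed_deterministic():
    cfg = SimulationConfig()
    a = generate_catalog(cfg, seed=5)
    b = generate_catalog(cfg, seed=5)
    assert a.to_frame().equals(b.to_frame())
    c = generate_catalog(cfg, seed=6)
    assert not a.to_frame().equals(c.to_frame())


def test_zero_tail_weight_bounds_activity():
    cfg = SimulationConfig(activity_tail_weight=0.0, activity_observed_fraction=1.0)
    cat = generate_catalog(cfg, seed=1)
    acts = [l.assay_activity_pct for l in cat if l.assay_activity_pct is not None]
    assert max(acts) <= cfg.activity_low_max


def test_empirical_activity_quantile_matches_analytic_mixture():
    cfg = SimulationConfig(n_reference_loci=5000, n_nonreference_loci=5000,
                           activity_observed_fraction=1.0)
    cat = generate_catalog(cfg, seed=9)
    acts = np.array([l.assay_activity_pct for l in cat if l.assay_activity_pct is not None])
    analytic = activity_mixture_quantile(0.75, cfg)
    assert np.quantile(acts, 0.75) == pytest.approx(analytic, rel=0.02)


def test_hwe_genotype_proportions():
    cat = RcL1Catalog([RcL1Locus("N1", "chr1", 100, 101, False, allele_frequency=0.3)])
    cfg = SimulationConfig(n_samples=10_000, genotype_missing_rate=0.0)
    matrix, _ = generate_cohort(cat, cfg, seed=13, ha_locus_ids=["N1"])
    counts = matrix.data["N1"].value_counts(normalize=True)
    # presence counts 0/1/2 at q=0.3: (1-q)^2, 2q(1-q), q^2
    assert counts[0.0] == pytest.approx(0.49, abs=0.01)
    assert counts[1.0] == pytest.approx(0.42, abs=0.01)
    assert counts[2.0] == pytest.approx(0.09, abs=0.01)


def test_allele_frequencies_converge_within_three_standard_errors(study_catalog):
    cat, poly = study_catalog
    cfg = SimulationConfig(n_samples=4000, genotype_missing_rate=0.0)
    matrix, _ = generate_cohort(cat, cfg, seed=21)
    freq = matrix.presence_frequency()
    for lid in poly[:20]:
        af = cat[lid].allele_frequency
        se = np.sqrt(af * (1 - af) / (2 * cfg.n_samples))
        assert abs(freq[lid] - af) <= 3 * se + 1e-12


def test_null_cohort_has_no_threshold_effect(study_catalog):
    cat, poly = study_catalog
    cfg = SimulationConfig(n_samples=4000, log_or=0.0, genotype_missing_rate=0.0)
    matrix, pheno = generate_cohort(cat, cfg, seed=3)
    ha = default_ha_set(cat, poly)
    b = compute_burden(matrix, ha, catalog=cat, exclude_sex_chromosomes=True)
    merged = b.merge(pheno, on="sample_id")
    above = merged["burden"] >= 9
    pd_rate_above = (merged.loc[above, "status"] == "PD").mean()
    pd_rate_below = (merged.loc[~above, "status"] == "PD").mean()
    assert pd_rate_above == pytest.approx(pd_rate_below, abs=0.04)
    assert (pheno["status"] == "PD").mean() == pytest.approx(cfg.case_fraction, abs=0.03)


def test_case_fraction_calibration_with_covariate_effects(study_catalog):
    cat, poly = study_catalog
    cfg = SimulationConfig(n_samples=3000, log_or=np.log(1.6), beta_age=0.03,
                           beta_sex=0.2, beta_famhist_first=0.8, case_fraction=0.5)
    _, pheno = generate_cohort(cat, cfg, seed=17)
    assert (pheno["status"] == "PD").mean() == pytest.approx(0.5, abs=0.03)


def test_cohort_determinism_and_stream_independence(study_catalog):
    cat, poly = study_catalog
    cfg = SimulationConfig(n_samples=200)
    m1, p1 = generate_cohort(cat, cfg, seed=99)
    m2, p2 = generate_cohort(cat, cfg, seed=99)
    assert m1.data.equals(m2.data) and p1.equals(p2)
    # dropping loci must not perturb the covariate stream
    small = cat.subset(cat.locus_ids[:50])
    ha_small = [lid for lid in default_ha_set(cat, poly) if lid in small]
    _, p3 = generate_cohort(small, cfg, seed=99, polymorphic_ids=None, ha_locus_ids=ha_small)
    assert p3[["sex", "age", "family_history"]].equals(p1[["sex", "age", "family_history"]])


def test_polymorphic_detection_recovers_catalog_set(study_catalog):
    cat, poly = study_catalog
    cfg = SimulationConfig(n_samples=600, genotype_missing_rate=0.0)
    matrix, _ = generate_cohort(cat, cfg, seed=29)
    assert polymorphic_loci(matrix) == set(poly)


def test_vcf_round_trip_exact(study_catalog, tmp_path):
    cat, _ = study_catalog
    cfg = SimulationConfig(n_samples=120, genotype_missing_rate=0.02)
    matrix, _ = generate_cohort(cat, cfg, seed=31)
    back = roundtrip(matrix, cat, tmp_path)
    assert back.data.columns.equals(matrix.data.columns)
    assert matrix.data.fillna(-9.0).equals(back.data.fillna(-9.0))


def test_fixed_present_matrix_writes_empty_deletion_vcf(tmp_path):
    cat = RcL1Catalog([RcL1Locus("R1", "chr1", 1000, 7019, True)])
    data = pd.DataFrame({"R1": [2.0, 2.0]}, index=pd.Index(["S1", "S2"], name="sample_id"))
    m = GenotypeMatrix(data=data, report=pd.DataFrame())
    del_path, _ = write_caller_vcfs(m, cat, tmp_path)
    body = [l for l in del_path.read_text().splitlines() if not l.startswith("#")]
    assert body == []


def test_single_het_insertion_record(tmp_path):
    cat = RcL1Catalog([RcL1Locus("N1", "chr5", 15000, 15001, False)])
    data = pd.DataFrame({"N1": [1.0]}, index=pd.Index(["S1"], name="sample_id"))
    m = GenotypeMatrix(data=data, report=pd.DataFrame())
    _, mei_path = write_caller_vcfs(m, cat, tmp_path)
    body = [l for l in mei_path.read_text().splitlines() if not l.startswith("#")]
    assert len(body) == 1
    fields = body[0].split("\t")
    assert fields[0] == "chr5" and fields[1] == "15001"
    assert "MEINFO=LINE1" in fields[7] and fields[9] == "0/1"


def test_longitudinal_noiseless_values_equal_cell_means():
    groups = pd.Series(["le8", "ge9"], index=["P0", "P1"])
    cfg = SimulationConfig(sigma_patient=0.0, sigma_residual=0.0)
    means = {("le8", 0): 1.0, ("le8", 12): 2.0, ("ge9", 0): 3.0, ("ge9", 12): 4.0,
             ("le8", 24): 0.0, ("le8", 36): 0.0, ("ge9", 24): 0.0, ("ge9", 36): 0.0}
    rec = generate_longitudinal(groups, cfg, seed=0, cell_means=means)
    got = rec.set_index(["patient_id", "visit_month"])["value"]
    assert got[("P0", 0)] == 1.0 and got[("P0", 12)] == 2.0
    assert got[("P1", 0)] == 3.0 and got[("P1", 12)] == 4.0


def test_longitudinal_intraclass_correlation():
    n = 500
    groups = pd.Series(["le8"] * n, index=[f"P{i}" for i in range(n)])
    cfg = SimulationConfig(sigma_patient=2.0, sigma_residual=1.0)
    rec = generate_longitudinal(groups, cfg, seed=7)
    wide = rec.pivot(index="patient_id", columns="visit_month", values="value")
    corr = wide.corr().to_numpy()
    off_diag = corr[np.triu_indices_from(corr, k=1)]
    assert off_diag.mean() == pytest.approx(4.0 / 5.0, abs=0.05)


def test_longitudinal_visit_missingness_and_determinism():
    groups = pd.Series(["le8"] * 200, index=[f"P{i}" for i in range(200)])
    cfg = SimulationConfig(visit_missing_rate=0.2)
    r1 = generate_longitudinal(groups, cfg, seed=11)
    r2 = generate_longitudinal(groups, cfg, seed=11)
    assert r1.equals(r2)
    assert len(r1) == pytest.approx(0.8 * 200 * 4, rel=0.1)


def test_simulate_run_writes_coherent_artifacts(tmp_path):
    cfg = SimulationConfig(n_samples=80)
    paths = simulate_run(cfg, seed=2, out_dir=tmp_path / "run")
    assert set(paths) == {"catalog", "pheno", "dels", "meis", "clinical", "config"}
    cat = read_catalog(paths["catalog"])
    assert len(cat) == 198
    pheno = pd.read_csv(paths["pheno"], sep="\t")
    assert len(pheno) == 80
    dels, samples = load_deletion_vcf(paths["dels"])
    assert samples == list(pheno["sample_id"])
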