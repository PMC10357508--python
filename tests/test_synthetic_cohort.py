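import numpy as np
import pytest

from coroflow.flow_solver import FluidProperties
from coroflow.geometry import StenosisSpec, make_stenosed_phantom
from coroflow.physiology import (BASELINE, HYPERAEMIC, INADEQUATE_GRADIENT,
                                 MESHING_FAILURE, RECONSTRUCTION_FAILURE,
                                 apply_exclusions, compute_cmvr)
from coroflow.synthetic_cohort import (CohortError, GeneratorConfig,
                                       forward_series_solve, generate_cohort,
                                       read_cohort, read_truth,
                                       sample_true_physiology, write_cohort)


def test_degenerate_dispersion_yields_exact_median():
    cfg = GeneratorConfig(cmvr_sigma_log={"male": 0.0, "female": 0.0},
                          ratio_sigma_log=0.0)
    rng = np.random.default_rng(0)
    for _ in range(5):
        truth = sample_true_physiology(cfg, "male", rng)
        assert truth["cmvr_hyper_wu"] == pytest.approx(680.0)
        assert truth["cmvr_base_wu"] == pytest.approx(1360.0)


def test_monte_carlo_medians_match_configuration():
    """Sample medians over 10,000 draws land within 3% of the configured
    sex-specific medians, preserving the female/male ratio."""
    cfg = GeneratorConfig()
    draws = {}
    for sex in ("male", "female"):
        rng = np.random.default_rng(2024)
        draws[sex] = np.array([
            sample_true_physiology(cfg, sex, rng)["cmvr_hyper_wu"]
            for _ in range(10_000)])
    assert np.median(draws["male"]) == pytest.approx(680.0, rel=0.03)
    assert np.median(draws["female"]) == pytest.approx(860.0, rel=0.03)
    ratio = np.median(draws["female"]) / np.median(draws["male"])
    assert ratio == pytest.approx(860.0 / 680.0, rel=0.05)


def test_dispersion_calibration_matches_observed_iqr():
    """The default lognormal sigmas reproduce the observed interquartile
    ranges (male 520-865, female 650-1205 WU) to ~10%."""
    cfg = GeneratorConfig()
    for sex, (lo, hi) in (("male", (520, 865)), ("female", (650, 1205))):
        rng = np.random.default_rng(77)
        x = np.array([sample_true_physiology(cfg, sex, rng)["cmvr_hyper_wu"]
                      for _ in range(20_000)])
        q25, q75 = np.percentile(x, [25, 75])
        assert q75 / q25 == pytest.approx(hi / lo, rel=0.10)


def test_forward_series_solve_degenerate_stenosis():
    """With a negligible epicardial resistance, Pa = 90 and CMVR = 900 WU
    give Q = 100 ml/min and Pd ~ Pa."""
    wide = make_stenosed_phantom(StenosisSpec(25.0, 30.0, 15.0, 10.0, 0.0),
                                 64)
    pd_mmhg, q = forward_series_solve(wide, 90.0, 900.0)
    assert q == pytest.approx(100.0, rel=1e-4)
    assert pd_mmhg == pytest.approx(90.0, rel=1e-4)


@pytest.mark.parametrize("cmvr,pa,sev", [
    (680.0, 92.0, 60.0), (1370.0, 85.0, 40.0), (300.0, 110.0, 75.0)])
def test_forward_solve_cmvr_identity(cmvr, pa, sev):
    """compute_cmvr on the forward-solved operating point reproduces the
    true CMVR to 1e-10 relative (defining identity of the circuit)."""
    geom = make_stenosed_phantom(StenosisSpec(1.5, 30, 15, 10, sev), 129)
    pd_mmhg, q = forward_series_solve(geom, pa, cmvr)
    assert abs(compute_cmvr(pd_mmhg, q) - cmvr) / cmvr < 1e-10


def test_forward_solve_monotone_in_severity():
    """At fixed CMVR, increasing severity lowers both Q and Pd."""
    qs, pds = [], []
    for sev in range(0, 91, 10):
        geom = make_stenosed_phantom(StenosisSpec(1.5, 30, 15, 10, sev), 129)
        pd_mmhg, q = forward_series_solve(geom, 92.0, 680.0)
        qs.append(q)
        pds.append(pd_mmhg)
    assert all(a > b for a, b in zip(qs, qs[1:]))
    assert all(a > b for a, b in zip(pds, pds[1:]))


def test_cohort_counts_and_determinism(tmp_path):
    cfg = GeneratorConfig(n_male=12, n_female=5, seed=99)
    cohort = generate_cohort(cfg)
    assert sum(c.sex == "male" for c in cohort.cases) == 12
    assert sum(c.sex == "female" for c in cohort.cases) == 5

    write_cohort(cohort, tmp_path / "a", "determinism test")
    write_cohort(generate_cohort(cfg), tmp_path / "b", "determinism test")
    for name in ("cohort.csv", "truth.json"):
        assert (tmp_path / "a" / name).read_bytes() == \
            (tmp_path / "b" / name).read_bytes()
    case = cohort.cases[0]
    pa = tmp_path / "a" / "cases" / case.case_id / "proj_a.csv"
    pb = tmp_path / "b" / "cases" / case.case_id / "proj_a.csv"
    assert pa.read_bytes() == pb.read_bytes()


def test_cohort_file_roundtrip(tmp_path):
    cfg = GeneratorConfig(n_male=4, n_female=2, seed=3)
    cohort = generate_cohort(cfg)
    write_cohort(cohort, tmp_path, "roundtrip")
    cases = read_cohort(tmp_path)
    truth = read_truth(tmp_path)
    assert len(cases) == 6
    assert set(truth) == {c.case_id for c in cases}
    for orig, back in zip(cohort.cases, cases):
        assert back.case_id == orig.case_id
        assert back.sex == orig.sex
        assert back.pressures[HYPERAEMIC].pd_mmhg == pytest.approx(
            orig.pressures[HYPERAEMIC].pd_mmhg, rel=1e-9)
        assert np.allclose(back.projections[0].half_width_mm,
                           orig.projections[0].half_width_mm, atol=1e-9)


def test_invalid_generator_configs_rejected():
    with pytest.raises(CohortError):
        GeneratorConfig(cmvr_hyper_median_wu={"male": -1, "female": 860})
    with pytest.raises(CohortError):
        GeneratorConfig(failure_rates={"bogus_category": 0.1})
    with pytest.raises(CohortError):
        GeneratorConfig(failure_rates={INADEQUATE_GRADIENT: 0.8,
                                       MESHING_FAILURE: 0.5})


def test_failure_injection_rates_recovered():
    """Consort category counts over 1,000 cases match the configured
    injection rates within 3-sigma binomial bounds."""
    rates = {INADEQUATE_GRADIENT: 0.06, RECONSTRUCTION_FAILURE: 0.04,
             MESHING_FAILURE: 0.03}
    # anatomy with comfortably large trans-lesional gradients, so the only
    # exclusions are the injected ones
    cfg = GeneratorConfig(n_male=700, n_female=300, seed=17,
                          severity_mean_pct=65.0, severity_sd_pct=5.0,
                          r0_mean_mm=1.2, r0_sd_mm=0.15,
                          projection_noise_sd_mm=0.0,
                          failure_rates=rates)
    cohort = generate_cohort(cfg, with_projections=False)
    results, consort, _ = apply_exclusions(cohort.cases)
    n = len(cohort.cases)
    for cat, rate in rates.items():
        sd = np.sqrt(n * rate * (1 - rate))
        assert abs(consort[cat] - n * rate) <= 3 * sd, (cat, consort[cat])


def test_noiseless_full_pipeline_recovery():
    """100 seeded cases, projections without noise: recovered hyperaemic
    CMVR within 2% of hidden truth (reduced-order backend)."""
    cfg = GeneratorConfig(n_male=70, n_female=30, seed=8,
                          projection_noise_sd_mm=0.0)
    cohort = generate_cohort(cfg)
    results, consort, _ = apply_exclusions(cohort.cases)
    assert len(results) >= 90          # mild natural gradient exclusions only
    errs = [abs(row["cmvr_hyper_wu"] - cohort.truth[row["case_id"]]
                ["cmvr_hyper_wu"]) / cohort.truth[row["case_id"]]
            ["cmvr_hyper_wu"] for _, row in results.iterrows()]
    assert max(errs) < 0.02


def test_noisy_pipeline_recovery_median_error():
    """Projection noise sd 0.05 mm: median CMVR error < 10% over 100
    cases."""
    cfg = GeneratorConfig(n_male=70, n_female=30, seed=9,
                          projection_noise_sd_mm=0.05)
    cohort = generate_cohort(cfg)
    results, _, _ = apply_exclusions(cohort.cases)
    errs = [abs(row["cmvr_hyper_wu"] - cohort.truth[row["case_id"]]
                ["cmvr_hyper_wu"]) / cohort.truth[row["case_id"]]
            ["cmvr_hyper_wu"] for _, row in results.iterrows()]
    assert np.median(errs) < 0.10


def test_hyperaemic_cmvr_not_above_baseline_without_noise():
    cfg = GeneratorConfig(n_male=50, n_female=50, seed=13,
                          ratio_sigma_log=0.0)
    cohort = generate_cohort(cfg, with_projections=False)
    for tr in cohort.truth.values():
        assert tr["cmvr_hyper_wu"] <= tr["cmvr_base_wu"]


def test_case_stream_independent_of_cohort_size():
    """Per-case substreams: the first cases coincide whatever the cohort
    size, so results are invariant to cohort ordering/extension."""
    a = generate_cohort(GeneratorConfig(n_male=3, n_female=0, seed=4),
                        with_projections=False)
    b = generate_cohort(GeneratorConfig(n_male=6, n_female=0, seed=4),
                        with_projections=False)
    for ca, cb in zip(a.cases, b.cases):
        assert ca.patient_id == cb.patient_id
        assert a.truth[ca.case_id]["cmvr_hyper_wu"] == \
            b.truth[cb.case_id]["cmvr_hyper_wu"]
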