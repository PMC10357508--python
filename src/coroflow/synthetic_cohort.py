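"""Virtual patient/artery generator with known ground-truth microvascular
resistance and self-consistent pressures.

Each virtual artery is a stenosed phantom in series with a microvascular
resistance: given proximal pressure Pa and a hidden true CMVR, the unique
operating point (Pd, Q) satisfies

    Pa - a*Q - b*Q**2 = Pd = CMVR_true * Q / 1000

with the phantom's viscous and separation-loss coefficients a, b.  The
generator draws sex-specific lognormal hyperaemic CMVR (right-skewed, as
observed clinically), baseline CMVR as a configurable multiple, covariates
at configurable prevalences, and writes two noisy angiographic-style
projections per artery, so the whole downstream pipeline (reconstruction ->
flow -> indices -> statistics) can be exercised against hidden truth.

Randomness: a single top-level seed spawns one independent substream per
case (``numpy.random.SeedSequence``); per-case results are therefore
invariant to cohort ordering, and the first draw of each case stream is the
hyperaemic CMVR (which external Monte-Carlo oracles can reproduce).

By default no covariate except sex influences CMVR, so subgroup analyses on
generated cohorts are type-I-error fixtures for everything but sex.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .flow_solver import (FluidProperties, expansion_coefficient,
                          viscous_coefficient)
from .geometry import (ProjectionView, StenosisSpec, VesselGeometry,
                       make_stenosed_phantom, project_geometry)
from .physiology import (BASELINE, CONVERGENCE_FAILURE, HYPERAEMIC,
                         INADEQUATE_GRADIENT, MESHING_FAILURE,
                         PressureRecord, RECONSTRUCTION_FAILURE)

ARTERIES = ("LAD", "RCA", "LCx", "Dx", "OM", "LMS")

#: observed artery frequencies (203 included arteries)
DEFAULT_ARTERY_PROBS = {
    "LAD": 103 / 203, "RCA": 45 / 203, "LCx": 26 / 203,
    "Dx": 17 / 203, "OM": 7 / 203, "LMS": 5 / 203,
}

#: cohort covariate prevalences (recruited-cohort defaults)
DEFAULT_PREVALENCES = {
    "white_caucasian": 0.90,
    "smoker": 0.63,
    "bmi_over_25": 0.64,
    "hypertension": 0.65,
    "dyslipidaemia": 0.76,
    "diabetes": 0.26,
    "lung_disease": 0.11,
    "valve_disease": 0.05,
    "prior_mi": 0.25,
    "lvsd": 0.20,
}


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition defaults for the virtual cohort.

    The sex-specific hyperaemic CMVR medians (680 male / 860 female, Wood
    units) and their lognormal dispersions (calibrated so the generated
    interquartile ratios match the observed 865/520 and 1205/650) define
    the reference conditions; the baseline-to-hyperaemic resistance ratio
    defaults to 2.0, consistent with the observed baseline medians.
    """

    n_male: int = 109
    n_female: int = 35
    cmvr_hyper_median_wu: dict = field(default_factory=lambda: {
        "male": 680.0, "female": 860.0})
    cmvr_sigma_log: dict = field(default_factory=lambda: {
        "male": 0.38, "female": 0.46})
    base_hyper_ratio: float = 2.0
    ratio_sigma_log: float = 0.10
    pa_mean_mmhg: float = 92.0
    pa_sd_mmhg: float = 10.0
    pa_min_mmhg: float = 60.0
    severity_mean_pct: float = 60.0
    severity_sd_pct: float = 15.0
    severity_range_pct: tuple = (10.0, 90.0)
    r0_mean_mm: float = 1.5
    r0_sd_mm: float = 0.25
    r0_range_mm: tuple = (0.8, 2.5)
    vessel_length_mm: float = 30.0
    stenosis_length_range_mm: tuple = (6.0, 14.0)
    n_samples: int = 128
    projection_noise_sd_mm: float = 0.05
    angles_a: tuple = (-30.0, 0.0)
    angles_b: tuple = (30.0, 20.0)
    age_mean: float = 65.0
    age_sd: float = 10.0
    prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    artery_probs: dict = field(default_factory=lambda: dict(DEFAULT_ARTERY_PROBS))
    failure_rates: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise CohortError("cohort sizes must be non-negative")
        for sex in ("male", "female"):
            if self.cmvr_hyper_median_wu[sex] <= 0:
                raise CohortError("CMVR medians must be positive")
            if self.cmvr_sigma_log[sex] < 0:
                raise CohortError("dispersions must be non-negative")
        if self.base_hyper_ratio <= 0:
            raise CohortError("baseline/hyperaemic ratio must be positive")
        bad = set(self.failure_rates) - {INADEQUATE_GRADIENT,
                                         RECONSTRUCTION_FAILURE,
                                         MESHING_FAILURE,
                                         CONVERGENCE_FAILURE}
        if bad:
            raise CohortError(f"unknown failure categories: {sorted(bad)}")
        rates = list(self.failure_rates.values())
        if any(not 0.0 <= r <= 1.0 for r in rates) or sum(rates) > 1.0:
            raise CohortError("failure rates must be probabilities summing "
                              "to at most 1")


@dataclass
class CaseRecord:
    """One virtual artery: identity, covariates, anatomy, pressures.

    The hidden ground truth lives in the cohort's separate truth table, not
    on the record, so pipeline code cannot peek at it.
    """

    case_id: str
    patient_id: str
    sex: str
    covariates: dict
    artery: str
    stenosis: StenosisSpec
    pressures: dict
    geometry: VesselGeometry | None = None
    projections: tuple | None = None
    injected_failure: str | None = None


@dataclass
class Cohort:
    cases: list
    truth: dict
    config: GeneratorConfig

    def __len__(self) -> int:
        return len(self.cases)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cases:
            row = {"case_id": c.case_id, "patient_id": c.patient_id,
                   "sex": c.sex, "artery": c.artery}
            row.update(c.covariates)
            row.update({
                "r0_mm": c.stenosis.r0_mm,
                "vessel_length_mm": c.stenosis.length_mm,
                "stenosis_centre_mm": c.stenosis.centre_mm,
                "stenosis_length_mm": c.stenosis.stenosis_length_mm,
                "stenosis_pct": c.stenosis.severity_pct,
                "pa_base_mmhg": c.pressures[BASELINE].pa_mmhg,
                "pd_base_mmhg": c.pressures[BASELINE].pd_mmhg,
                "pa_hyper_mmhg": c.pressures[HYPERAEMIC].pa_mmhg,
                "pd_hyper_mmhg": c.pressures[HYPERAEMIC].pd_mmhg,
                "injected_failure": c.injected_failure or "",
            })
            rows.append(row)
        return pd.DataFrame(rows)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def sample_true_physiology(cfg: GeneratorConfig, sex: str,
                           rng: np.random.Generator) -> dict:
    """Draw the hidden truth for one case: hyperaemic CMVR (lognormal with
    the sex-specific median), baseline CMVR (hyperaemic times the
    configured ratio with per-case lognormal noise) and per-state Pa.

    The hyperaemic CMVR is the *first* draw from ``rng`` — external oracles
    rely on this.
    """
    if sex not in ("male", "female"):
        raise CohortError(f"unknown sex {sex!r}")
    median = cfg.cmvr_hyper_median_wu[sex]
    sigma = cfg.cmvr_sigma_log[sex]
    cmvr_hyper = float(rng.lognormal(np.log(median), sigma))
    ratio = cfg.base_hyper_ratio
    if cfg.ratio_sigma_log > 0:
        ratio *= float(np.exp(rng.normal(0.0, cfg.ratio_sigma_log)))
    cmvr_base = cmvr_hyper * ratio
    pa = {state: _truncated_normal(rng, cfg.pa_mean_mmhg, cfg.pa_sd_mmhg,
                                   cfg.pa_min_mmhg, np.inf)
          for state in (BASELINE, HYPERAEMIC)}
    return {"cmvr_hyper_wu": cmvr_hyper, "cmvr_base_wu": cmvr_base,
            "pa_mmhg": pa}


def forward_series_solve(geom: VesselGeometry, pa_mmhg: float,
                         cmvr_true_wu: float,
                         fluid: FluidProperties | None = None,
                         K_e: float = 1.52) -> tuple[float, float]:
    """Operating point of the series stenosis + microvasculature circuit.

    Solves ``Pa - a*Q - b*Q^2 = CMVR*Q/1000`` for the unique positive Q in
    closed form and returns ``(Pd, Q)`` with ``Pd = CMVR*Q/1000`` exactly,
    so recomputing CMVR from (Pd, Q) reproduces the truth to round-off.
    """
    if pa_mmhg <= 0 or cmvr_true_wu <= 0:
        raise CohortError("Pa and CMVR must be positive")
    fluid = fluid or FluidProperties()
    a = viscous_coefficient(geom, fluid)
    b = expansion_coefficient(geom, fluid, K_e)
    c = cmvr_true_wu / 1000.0            # mmHg per ml/min
    lin = a + c
    # cancellation-free positive root of b*q^2 + (a+c)*q = Pa
    q = 2.0 * pa_mmhg / (lin + np.sqrt(lin * lin + 4.0 * b * pa_mmhg))
    assert q > 0.0, "series circuit must have a positive operating point"
    pd_distal = c * q
    assert 0.0 < pd_distal < pa_mmhg
    return float(pd_distal), float(q)


def _draw_covariates(cfg: GeneratorConfig, rng: np.random.Generator) -> dict:
    cov = {"age": round(_truncated_normal(rng, cfg.age_mean, cfg.age_sd,
                                          18.0, 100.0), 1)}
    white = rng.uniform() < cfg.prevalences["white_caucasian"]
    cov["ethnicity"] = "white" if white else "black_asian"
    for name, prev in cfg.prevalences.items():
        if name == "white_caucasian":
            continue
        cov[name] = bool(rng.uniform() < prev)
    return cov


def _draw_failure(cfg: GeneratorConfig, rng: np.random.Generator):
    # a single uniform against cumulative rates keeps categories exclusive
    u = rng.uniform()
    acc = 0.0
    for cat in (INADEQUATE_GRADIENT, RECONSTRUCTION_FAILURE,
                MESHING_FAILURE, CONVERGENCE_FAILURE):
        acc += cfg.failure_rates.get(cat, 0.0)
        if u < acc:
            return cat
    return None


def generate_case(cfg: GeneratorConfig, index: int, sex: str,
                  rng: np.random.Generator,
                  with_projections: bool = True) -> tuple[CaseRecord, dict]:
    """Build one virtual artery and its hidden truth."""
    truth = sample_true_physiology(cfg, sex, rng)
    covariates = _draw_covariates(cfg, rng)
    arteries = list(cfg.artery_probs)
    artery = arteries[rng.choice(len(arteries),
                                 p=list(cfg.artery_probs.values()))]
    sev = _truncated_normal(rng, cfg.severity_mean_pct, cfg.severity_sd_pct,
                            *cfg.severity_range_pct)
    r0 = _truncated_normal(rng, cfg.r0_mean_mm, cfg.r0_sd_mm,
                           *cfg.r0_range_mm)
    length = cfg.vessel_length_mm
    sten_len = float(rng.uniform(*cfg.stenosis_length_range_mm))
    centre = float(rng.uniform(length / 3.0, 2.0 * length / 3.0))
    spec = StenosisSpec(r0_mm=r0, length_mm=length, centre_mm=centre,
                        stenosis_length_mm=sten_len, severity_pct=sev)
    geom = make_stenosed_phantom(spec, cfg.n_samples)

    fluid = FluidProperties()
    pressures = {}
    for state in (BASELINE, HYPERAEMIC):
        key = "cmvr_base_wu" if state == BASELINE else "cmvr_hyper_wu"
        pd_mmhg, q = forward_series_solve(
            geom, truth["pa_mmhg"][state], truth[key], fluid)
        truth[f"q_{state}_ml_min"] = q
        pressures[state] = PressureRecord(
            pa_mmhg=truth["pa_mmhg"][state], pd_mmhg=pd_mmhg, state=state)

    injected = _draw_failure(cfg, rng)
    angles_b = cfg.angles_b
    if injected == INADEQUATE_GRADIENT:
        rec = pressures[HYPERAEMIC]
        pressures[HYPERAEMIC] = PressureRecord(
            pa_mmhg=rec.pa_mmhg,
            pd_mmhg=rec.pa_mmhg - float(rng.uniform(0.3, 1.5)),
            state=HYPERAEMIC)
    elif injected == RECONSTRUCTION_FAILURE:
        angles_b = (cfg.angles_a[0] + 10.0, cfg.angles_a[1])

    pid = f"P{index:04d}"
    case = CaseRecord(
        case_id=f"{pid}-{artery}", patient_id=pid, sex=sex,
        covariates=covariates, artery=artery, stenosis=spec,
        pressures=pressures, injected_failure=injected)

    needs_projections = with_projections or injected in (
        RECONSTRUCTION_FAILURE, MESHING_FAILURE)
    if needs_projections:
        noise = cfg.projection_noise_sd_mm
        proj_a = project_geometry(geom, cfg.angles_a, noise, rng, "A")
        proj_b = project_geometry(geom, angles_b, noise, rng, "B")
        if injected == MESHING_FAILURE:
            # corrupt a band of silhouette widths so the reconstructed
            # radius is non-physical even after smoothing/averaging
            k = proj_a.half_width_mm.size // 2
            proj_a.half_width_mm[k - 3:k + 4] = -5.0
            proj_b.half_width_mm[k - 3:k + 4] = -5.0
        case.projections = (proj_a, proj_b)
    else:
        case.geometry = geom

    tr = {"cmvr_hyper_wu": truth["cmvr_hyper_wu"],
          "cmvr_base_wu": truth["cmvr_base_wu"],
          "q_base_ml_min": truth[f"q_{BASELINE}_ml_min"],
          "q_hyper_ml_min": truth[f"q_{HYPERAEMIC}_ml_min"]}
    return case, tr


def generate_cohort(cfg: GeneratorConfig,
                    with_projections: bool = True) -> Cohort:
    """Generate the full cohort, deterministic under the configured seed.

    One artery per patient; males first, then females (case substreams are
    spawned per case, so any subset is reproducible independently).
    """
    n = cfg.n_male + cfg.n_female
    streams = np.random.SeedSequence(cfg.seed).spawn(n)
    cases, truth = [], {}
    for i in range(n):
        sex = "male" if i < cfg.n_male else "female"
        rng = np.random.default_rng(streams[i])
        case, tr = generate_case(cfg, i, sex, rng, with_projections)
        cases.append(case)
        truth[case.case_id] = tr
    return Cohort(cases=cases, truth=truth, config=cfg)


# --------------------------------------------------------------------- I/O
def write_cohort(cohort: Cohort, outdir, header_comment: str = "") -> None:
    """Write cohort CSV, per-case projection/geometry files and the hidden
    truth sidecar (separate JSON so the pipeline cannot see it)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = cohort.to_frame()
    with open(outdir / "cohort.csv", "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False, float_format="%.10g")
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    cases_dir = outdir / "cases"
    for case in cohort.cases:
        cdir = cases_dir / case.case_id
        cdir.mkdir(parents=True, exist_ok=True)
        if case.projections is not None:
            for view, tag in zip(case.projections, ("a", "b")):
                view.write(cdir / f"proj_{tag}.csv",
                           cdir / f"proj_{tag}.json", header_comment)
        else:
            case.geometry.to_csv(cdir / "geometry.csv", header_comment)


def read_cohort(outdir) -> list[CaseRecord]:
    """Load the cases written by :func:`write_cohort` (never the truth)."""
    outdir = Path(outdir)
    frame = pd.read_csv(outdir / "cohort.csv", comment="#")
    scalar_cols = {"case_id", "patient_id", "sex", "artery", "r0_mm",
                   "vessel_length_mm", "stenosis_centre_mm",
                   "stenosis_length_mm", "stenosis_pct", "pa_base_mmhg",
                   "pd_base_mmhg", "pa_hyper_mmhg", "pd_hyper_mmhg",
                   "injected_failure"}
    cases = []
    for _, row in frame.iterrows():
        spec = StenosisSpec(
            r0_mm=row["r0_mm"], length_mm=row["vessel_length_mm"],
            centre_mm=row["stenosis_centre_mm"],
            stenosis_length_mm=row["stenosis_length_mm"],
            severity_pct=row["stenosis_pct"])
        pressures = {
            BASELINE: PressureRecord(row["pa_base_mmhg"], row["pd_base_mmhg"],
                                     BASELINE),
            HYPERAEMIC: PressureRecord(row["pa_hyper_mmhg"],
                                       row["pd_hyper_mmhg"], HYPERAEMIC),
        }
        covariates = {k: row[k] for k in frame.columns
                      if k not in scalar_cols}
        injected = row["injected_failure"]
        injected = None if (pd.isna(injected) or injected == "") else injected
        case = CaseRecord(
            case_id=row["case_id"], patient_id=row["patient_id"],
            sex=row["sex"], covariates=covariates, artery=row["artery"],
            stenosis=spec, pressures=pressures, injected_failure=injected)
        cdir = outdir / "cases" / case.case_id
        if (cdir / "geometry.csv").exists():
            case.geometry = VesselGeometry.from_csv(cdir / "geometry.csv")
        else:
            case.projections = tuple(
                ProjectionView.read(cdir / f"proj_{t}.csv",
                                    cdir / f"proj_{t}.json")
                for t in ("a", "b"))
        cases.append(case)
    return cases


def read_truth(outdir) -> dict:
    """Hidden ground truth — for test harnesses and oracles only."""
    with open(Path(outdir) / "truth.json", encoding="utf-8") as fh:
        return json.load(fh)


def config_from_dict(d: dict) -> GeneratorConfig:
    """Build a GeneratorConfig from a (YAML-derived) plain dict, accepting
    partial overrides of the defaults."""
    known = set(GeneratorConfig.__dataclass_fields__)
    bad = set(d) - known
    if bad:
        raise CohortError(f"unknown generator config keys: {sorted(bad)}")
    kwargs = dict(d)
    for key in ("severity_range_pct", "r0_range_mm",
                "stenosis_length_range_mm", "angles_a", "angles_b"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return GeneratorConfig(**kwargs)


def config_to_dict(cfg: GeneratorConfig) -> dict:
    return asdict(cfg)
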