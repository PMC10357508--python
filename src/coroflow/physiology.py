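"""Physiological indices (FFR, CMVR, CFR) and case-exclusion accounting.

CMVR (coronary microvascular resistance) follows the hydraulic equivalent of
Ohm's law, ``CMVR = 1000 * Pd / Q`` with Pd in mmHg and Q in ml/min; the
factor 1000 converts ml/min to L/min so the result is in Wood units
(mmHg·min/L).  CFR is the hyperaemic-to-baseline flow ratio and FFR the
hyperaemic distal-to-proximal pressure ratio.

Cases that cannot yield indices are never dropped silently: every submitted
case receives exactly one consort entry (included, or one of four failure
categories: inadequate pressure gradient, reconstruction failure, meshing
failure, CFD convergence failure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .flow_solver import (ConvergenceError, FlowError, FluidProperties,
                          InadequateGradientError, SolverConfig, solve_flow)
from .geometry import (GeometryError, InsufficientSeparationError,
                       ReconstructionError, reconstruct_from_two_views)

logger = logging.getLogger(__name__)

BASELINE = "baseline"
HYPERAEMIC = "hyperaemic"

#: exclusion categories (consort taxonomy)
INADEQUATE_GRADIENT = "inadequate_gradient"
RECONSTRUCTION_FAILURE = "reconstruction_failure"
MESHING_FAILURE = "meshing_failure"
CONVERGENCE_FAILURE = "convergence_failure"
INCLUDED = "included"
CATEGORIES = (INADEQUATE_GRADIENT, RECONSTRUCTION_FAILURE, MESHING_FAILURE,
              CONVERGENCE_FAILURE, INCLUDED)

#: hyperaemic trans-lesional gradient below which flow is unidentifiable
#: (below pressure-wire drift tolerance), mmHg
DEFAULT_MIN_GRADIENT_MMHG = 2.0


class PhysiologyError(ValueError):
    pass


@dataclass(frozen=True)
class PressureRecord:
    """Invasive proximal/distal pressure pair for one physiological state."""

    pa_mmhg: float
    pd_mmhg: float
    state: str

    def __post_init__(self) -> None:
        if self.state not in (BASELINE, HYPERAEMIC):
            raise PhysiologyError(f"unknown state {self.state!r}")
        if not (0.0 < self.pd_mmhg <= self.pa_mmhg):
            raise PhysiologyError(
                f"need 0 < Pd <= Pa, got Pa={self.pa_mmhg}, Pd={self.pd_mmhg}")


@dataclass
class PhysioIndices:
    """Per-case indices: FFR, per-state CMVR in Wood units, CFR, and the
    absolute flows they derive from."""

    ffr: float
    cmvr_base_wu: float
    cmvr_hyper_wu: float
    cfr: float
    q_base_ml_min: float
    q_hyper_ml_min: float


@dataclass
class ExclusionEntry:
    case_id: str
    category: str
    detail: str = ""


def compute_ffr(p: PressureRecord) -> float:
    """Fractional flow reserve, hyperaemic Pd/Pa."""
    if p.state != HYPERAEMIC:
        raise PhysiologyError("FFR is defined on the hyperaemic record")
    if p.pa_mmhg <= 0:
        raise PhysiologyError("Pa must be positive")
    return p.pd_mmhg / p.pa_mmhg


def compute_cmvr(pd_mmhg: float, q_ml_min: float) -> float:
    """Microvascular resistance, 1000 * Pd / Q, in Wood units."""
    if q_ml_min <= 0:
        raise PhysiologyError(f"flow must be positive, got {q_ml_min}")
    return 1000.0 * pd_mmhg / q_ml_min


def compute_cfr(q_hyper_ml_min: float, q_base_ml_min: float) -> float:
    """Coronary flow reserve, hyperaemic / baseline flow."""
    if q_hyper_ml_min <= 0 or q_base_ml_min <= 0:
        raise PhysiologyError("flows must be positive")
    return q_hyper_ml_min / q_base_ml_min


def run_case(case, cfg: SolverConfig | None = None,
             fluid: FluidProperties | None = None,
             min_gradient_mmhg: float = DEFAULT_MIN_GRADIENT_MMHG,
             ) -> tuple[PhysioIndices | None, ExclusionEntry]:
    """Run one artery through reconstruction, flow solution and indices.

    The case must carry either a geometry or a pair of projections, plus
    baseline and hyperaemic :class:`PressureRecord` objects.  Any stage
    failure is mapped to its consort category and returned, never raised.
    """
    cfg = cfg or SolverConfig()
    fluid = fluid or FluidProperties()
    cid = case.case_id

    hyper = case.pressures[HYPERAEMIC]
    base = case.pressures[BASELINE]
    if hyper.pa_mmhg - hyper.pd_mmhg < min_gradient_mmhg:
        return None, ExclusionEntry(
            cid, INADEQUATE_GRADIENT,
            f"hyperaemic gradient {hyper.pa_mmhg - hyper.pd_mmhg:.2f} mmHg "
            f"< {min_gradient_mmhg} mmHg")

    geom = getattr(case, "geometry", None)
    if geom is None:
        try:
            geom = reconstruct_from_two_views(*case.projections)
        except (InsufficientSeparationError, ReconstructionError) as exc:
            return None, ExclusionEntry(cid, RECONSTRUCTION_FAILURE, str(exc))
        except GeometryError as exc:
            # reconstruction produced a lumen no mesh can be built on
            return None, ExclusionEntry(cid, MESHING_FAILURE, str(exc))

    if getattr(case, "injected_failure", None) == CONVERGENCE_FAILURE:
        # emulate a diverging CFD run: a one-iteration budget on the
        # iterative backend cannot reach any tolerance
        cfg = replace(cfg, backend="axisymmetric", max_iter=1)

    flows = {}
    for rec in (base, hyper):
        try:
            flows[rec.state] = solve_flow(
                geom, rec.pa_mmhg, rec.pd_mmhg, fluid, cfg)
        except InadequateGradientError as exc:
            return None, ExclusionEntry(cid, INADEQUATE_GRADIENT, str(exc))
        except ConvergenceError as exc:
            return None, ExclusionEntry(cid, CONVERGENCE_FAILURE, str(exc))
        except (FlowError, GeometryError, ValueError) as exc:
            return None, ExclusionEntry(cid, MESHING_FAILURE, str(exc))

    q_base = flows[BASELINE].q_ml_min
    q_hyper = flows[HYPERAEMIC].q_ml_min
    indices = PhysioIndices(
        ffr=compute_ffr(hyper),
        cmvr_base_wu=compute_cmvr(base.pd_mmhg, q_base),
        cmvr_hyper_wu=compute_cmvr(hyper.pd_mmhg, q_hyper),
        cfr=compute_cfr(q_hyper, q_base),
        q_base_ml_min=q_base,
        q_hyper_ml_min=q_hyper,
    )
    if indices.cmvr_base_wu < indices.cmvr_hyper_wu:
        # physiologically unusual (vasodilator failed to lower resistance);
        # logged but not excluded
        logger.warning("case %s: baseline CMVR %.0f WU below hyperaemic "
                       "%.0f WU", cid, indices.cmvr_base_wu,
                       indices.cmvr_hyper_wu)
    return indices, ExclusionEntry(cid, INCLUDED)


RESULT_COLUMNS = ["case_id", "patient_id", "sex", "artery", "ffr",
                  "stenosis_pct", "q_base_mlmin", "q_hyper_mlmin",
                  "cmvr_base_wu", "cmvr_hyper_wu", "cfr", "status"]


def result_row(case, indices: PhysioIndices, covariates: bool = True) -> dict:
    """One included-results CSV row for a solved case."""
    row = {
        "case_id": case.case_id,
        "patient_id": case.patient_id,
        "sex": case.sex,
        "artery": case.artery,
        "ffr": indices.ffr,
        "stenosis_pct": case.stenosis.severity_pct,
        "q_base_mlmin": indices.q_base_ml_min,
        "q_hyper_mlmin": indices.q_hyper_ml_min,
        "cmvr_base_wu": indices.cmvr_base_wu,
        "cmvr_hyper_wu": indices.cmvr_hyper_wu,
        "cfr": indices.cfr,
        "status": INCLUDED,
    }
    if covariates:
        row.update(case.covariates)
    return row


def apply_exclusions(cases, cfg: SolverConfig | None = None,
                     fluid: FluidProperties | None = None,
                     min_gradient_mmhg: float = DEFAULT_MIN_GRADIENT_MMHG,
                     covariates: bool = True):
    """Run a cohort of cases and assemble the included-results table plus
    the consort summary.

    Returns ``(results, consort, entries)`` where ``results`` is a DataFrame
    with one row per included artery (plus covariate columns when
    ``covariates``), ``consort`` maps category -> count (summing to the
    submitted case count) and ``entries`` is the per-case exclusion log.
    """
    rows = []
    entries = []
    consort = {cat: 0 for cat in CATEGORIES}
    for case in cases:
        indices, entry = run_case(case, cfg, fluid, min_gradient_mmhg)
        entries.append(entry)
        consort[entry.category] += 1
        if indices is None:
            continue
        rows.append(result_row(case, indices, covariates))
    results = pd.DataFrame(rows)
    assert sum(consort.values()) == len(list(entries)), \
        "consort counts must conserve the submitted case total"
    return results, consort, entries
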