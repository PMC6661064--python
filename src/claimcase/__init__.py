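"""claimcase: fracture case ascertainment from health-insurance claims.

A tested implementation of a claims-based algorithm for counting first-incident
peripheral fractures: ICD-10 site-group classification, deterministic patient
linkage from paired hashed identifiers, extraction of treatment (Dataset A) and
diagnosis-only (Dataset B) claims, hospital-acquired exclusion by date spread,
cross-facility first-visit resolution with a 14-day lookback, first-incidence
deduplication per fracture site group, and stratified month x age x site
reporting with small-cell suppression — plus a synthetic claims generator with
planted ground truth for end-to-end validation.
"""

from .aggregation import (
    PopulationTable,
    StratifiedTable,
    consistency_report,
    days_in_month_within,
    incidence_rates,
    load_population,
    render_report,
    suppress_small_cells,
    tabulate,
)
from .case_builder import (
    BLookupIndex,
    build_cases,
    candidate_events,
    dedupe_first_incidence,
    passes_date_spread,
    resolve_first_visit,
)
from .code_maps import (
    FRACTURE_PROCEDURE_CODES,
    SiteCodeMap,
    SiteGroup,
    classify_site,
    is_fracture_procedure,
    load_site_code_map,
)
from .config import KANTO_PREFECTURES, StudyConfig, load_config
from .extraction import Dataset, build_dataset_a, build_dataset_b, has_qualifying_diagnosis
from .io import ReadResult, read_claims, write_claims
from .linkage import LinkageResult, assign_patient_keys
from .model import (
    AgeBand,
    CandidateEvent,
    ClaimRecord,
    DiagnosisEntry,
    DiagnosisRole,
    FractureCase,
    ProcedureEntry,
    Setting,
    Sex,
)
from .synthetic import GroundTruth, SimParams, expected_cases, generate_cohort

__version__ = "0.1.0"


def run_pipeline(claims, config=None, code_map=None):
    """Convenience end-to-end run: linkage, extraction, case building.

    Returns ``(cases, linkage_result)``.
    """
    config = config or StudyConfig()
    link = assign_patient_keys(claims)
    linked = [c for c in claims if c.claim_id in link.keys]
    a = build_dataset_a(linked, link.keys, config, code_map)
    b = build_dataset_b(linked, a, link.keys, config, code_map)
    return build_cases(a, b, config, code_map), link
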