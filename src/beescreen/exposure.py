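"""Caste-resolved tier-1 honey-bee exposure and risk-quotient model.

Implements the screening-level (tier 1) exposure arithmetic used in
regulatory pollinator risk assessment for foliar spray applications:

* default mode — the estimated environmental concentration (EEC) in
  nectar and pollen is a residue unit dose (RUD, default 110 mg/kg per
  lb a.i./acre, the upper-bound tall-grass value from the Kenaga
  nomogram) times the application rate;
* empirical mode — measured peak residues in pollen, nectar, and royal
  jelly replace the RUD-based EEC;
* contact route — adults foraging at application time receive a direct
  spray dose proportional to the application rate (default 2.7 µg/bee
  per lb a.i./acre, the public BeeREX v1.0 default).

Dietary doses are consumption-weighted sums over a caste table of daily
food intake (mg/day of nectar, pollen, and jelly).  Risk quotients are
dose over endpoint:  AcuteRQ = EEC / acute LD50, ChronicRQ = EEC /
chronic NOED, screened against levels of concern (0.4 acute,
1.0 chronic).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .errors import MissingEndpointError, ModeMismatchError, UnknownUnitError

__all__ = [
    "KG_PER_HA_TO_LB_PER_ACRE",
    "DEFAULT_RUD",
    "DEFAULT_CONTACT_UNIT_DOSE",
    "DEFAULT_LOCS",
    "DEFAULT_CASTES",
    "ApplicationScenario",
    "EmpiricalResidues",
    "CasteDiet",
    "ToxicityProfile",
    "RQResult",
    "RQReport",
    "convert_rate",
    "default_eec",
    "contact_dose",
    "dietary_dose",
    "compute_rq_report",
    "backcalc_contact_unit_dose",
    "round_sig",
]

#: lb a.i./acre per kg a.i./ha (1 lb/acre = 1.12085 kg/ha).
KG_PER_HA_TO_LB_PER_ACRE = 0.892179

#: Tier-1 default residue unit dose for nectar and pollen, mg/kg per lb a.i./acre.
DEFAULT_RUD = 110.0

#: Direct-spray unit dose for adults, µg/bee per lb a.i./acre.
DEFAULT_CONTACT_UNIT_DOSE = 2.7

#: Levels of concern: acute routes screened at 0.4, chronic at 1.0.
DEFAULT_LOCS = {"acute": 0.4, "chronic": 1.0}

_UNITS = ("kg_per_ha", "lb_per_acre")


def convert_rate(rate: float, from_unit: str, to_unit: str) -> float:
    """Convert an application rate between kg a.i./ha and lb a.i./acre.

    Round-trips to within 1e-12 relative.
    """
    if from_unit not in _UNITS:
        raise UnknownUnitError(f"unknown rate unit: {from_unit!r}")
    if to_unit not in _UNITS:
        raise UnknownUnitError(f"unknown rate unit: {to_unit!r}")
    if rate < 0:
        raise ValueError("application rate must be >= 0")
    if from_unit == to_unit:
        return rate
    if from_unit == "kg_per_ha":
        return rate * KG_PER_HA_TO_LB_PER_ACRE
    return rate / KG_PER_HA_TO_LB_PER_ACRE


@dataclass(frozen=True)
class EmpiricalResidues:
    """Peak measured concentrations (mg/kg) feeding the empirical mode."""

    pollen_conc: float
    nectar_conc: float
    jelly_conc: float
    pollen_provenance: str = "measured"  # measured | loq_substituted
    nectar_provenance: str = "measured"
    jelly_provenance: str = "measured"

    def __post_init__(self):
        for name in ("pollen_conc", "nectar_conc", "jelly_conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ApplicationScenario:
    """A chemical's application rate and exposure mode.

    ``rud`` is the residue unit dose in mg/kg per lb a.i./acre and
    ``contact_unit_dose`` the direct-spray dose in µg/bee per lb
    a.i./acre; both apply to the rate expressed in lb a.i./acre.
    """

    chemical_id: str
    rate: float
    rate_unit: str = "kg_per_ha"
    mode: str = "default_rud"  # default_rud | empirical
    rud: float = DEFAULT_RUD
    contact_unit_dose: float = DEFAULT_CONTACT_UNIT_DOSE
    residues: EmpiricalResidues | None = None

    def __post_init__(self):
        if self.rate_unit not in _UNITS:
            raise UnknownUnitError(f"unknown rate unit: {self.rate_unit!r}")
        if self.mode not in ("default_rud", "empirical"):
            raise ValueError(f"unknown exposure mode: {self.mode!r}")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.rud <= 0 or self.contact_unit_dose <= 0:
            raise ValueError("rud and contact_unit_dose must be > 0")
        if self.mode == "empirical" and self.residues is None:
            raise ModeMismatchError(
                "empirical mode requires an attached EmpiricalResidues record"
            )

    @property
    def rate_lb_per_acre(self) -> float:
        return convert_rate(self.rate, self.rate_unit, "lb_per_acre")


@dataclass(frozen=True)
class CasteDiet:
    """Daily food consumption (mg/day) of one caste or life stage.

    ``in_rq_scope`` marks the castes whose maximum dose governs the
    single reported adult/larval risk quotient; out-of-scope castes are
    still computed and reported individually.
    """

    caste_id: str
    life_stage: str  # adult | larva
    nectar_mg_per_day: float = 0.0
    pollen_mg_per_day: float = 0.0
    jelly_mg_per_day: float = 0.0
    in_rq_scope: bool = True

    def __post_init__(self):
        if self.life_stage not in ("adult", "larva"):
            raise ValueError(f"unknown life stage: {self.life_stage!r}")
        for name in ("nectar_mg_per_day", "pollen_mg_per_day", "jelly_mg_per_day"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: Tier-1 caste consumption table (mg food per day).  The three castes in
#: RQ scope — nectar forager, nurse, and 5th-day worker larva — carry the
#: highest nectar-driven, pollen-driven, and larval dietary doses and are
#: the ones whose maxima appear in reported tier-1 tables.  The remaining
#: castes follow the public BeeREX v1.0 workbook and are reported but out
#: of scope by default; the queen's all-jelly diet in particular is never
#: allowed to govern the reported adult RQ.
DEFAULT_CASTES: tuple[CasteDiet, ...] = (
    CasteDiet("nectar_forager", "adult", nectar_mg_per_day=292.0, pollen_mg_per_day=0.041),
    CasteDiet("nurse", "adult", nectar_mg_per_day=140.0, pollen_mg_per_day=9.6),
    CasteDiet("worker_larva_5d", "larva", nectar_mg_per_day=120.0, pollen_mg_per_day=3.6),
    CasteDiet("cell_cleaner", "adult", nectar_mg_per_day=60.0, pollen_mg_per_day=6.65,
              in_rq_scope=False),
    CasteDiet("comb_builder", "adult", nectar_mg_per_day=60.0, pollen_mg_per_day=1.7,
              in_rq_scope=False),
    CasteDiet("pollen_forager", "adult", nectar_mg_per_day=43.5, pollen_mg_per_day=0.041,
              in_rq_scope=False),
    CasteDiet("winter_worker", "adult", nectar_mg_per_day=29.0, pollen_mg_per_day=2.0,
              in_rq_scope=False),
    CasteDiet("drone", "adult", nectar_mg_per_day=235.0, pollen_mg_per_day=0.0002,
              in_rq_scope=False),
    CasteDiet("queen", "adult", jelly_mg_per_day=525.0, in_rq_scope=False),
    CasteDiet("worker_larva_4d", "larva", nectar_mg_per_day=60.0, pollen_mg_per_day=1.8,
              in_rq_scope=False),
    CasteDiet("worker_larva_3d", "larva", jelly_mg_per_day=19.0, in_rq_scope=False),
    CasteDiet("worker_larva_2d", "larva", jelly_mg_per_day=9.4, in_rq_scope=False),
    CasteDiet("worker_larva_1d", "larva", jelly_mg_per_day=1.9, in_rq_scope=False),
    CasteDiet("queen_larva", "larva", jelly_mg_per_day=223.0, in_rq_scope=False),
    CasteDiet("drone_larva", "larva", nectar_mg_per_day=130.0, pollen_mg_per_day=3.6,
              in_rq_scope=False),
)


@dataclass(frozen=True)
class ToxicityProfile:
    """Endpoints (µg/bee acute; µg/bee/day chronic) selected for assessment.

    ``greater_than`` lists endpoints that were empirically unbounded
    ("greater than the highest dose tested"); per standard conservative
    practice the face value is still used in the quotient and the flag is
    propagated into the report.
    """

    adult_contact_ld50: float | None = None
    adult_oral_ld50: float | None = None
    adult_chronic_noed: float | None = None
    larval_acute_ld50: float | None = None
    larval_chronic_noed: float | None = None
    greater_than: frozenset[str] = frozenset()

    def __post_init__(self):
        for name in (
            "adult_contact_ld50",
            "adult_oral_ld50",
            "adult_chronic_noed",
            "larval_acute_ld50",
            "larval_chronic_noed",
        ):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")
        object.__setattr__(self, "greater_than", frozenset(self.greater_than))


@dataclass(frozen=True)
class RQResult:
    """One life-stage × route cell of the risk-quotient table."""

    life_stage: str
    route: str  # acute_contact | acute_dietary | chronic_dietary
    rq: float
    dose: float  # µg/bee (acute) or µg/bee/day (chronic)
    endpoint: float
    governing_caste: str | None
    eec_nectar: float
    eec_pollen: float
    eec_jelly: float
    loc: float
    verdict: str  # below_loc | at_or_above_loc
    conservative: bool = False  # endpoint was an unbounded ">" estimate


@dataclass(frozen=True)
class RQReport:
    """Machine twin of a tier-1 risk-quotient table for one chemical."""

    chemical_id: str
    mode: str
    results: tuple[RQResult, ...]
    out_of_scope_doses: Mapping[str, float] = field(default_factory=dict)

    def cell(self, life_stage: str, route: str) -> RQResult:
        for r in self.results:
            if r.life_stage == life_stage and r.route == route:
                return r
        raise KeyError((life_stage, route))

    @property
    def all_below_loc(self) -> bool:
        return all(r.verdict == "below_loc" for r in self.results)

    def to_records(self) -> list[dict]:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "chemical_id": self.chemical_id,
                    "mode": self.mode,
                    "life_stage": r.life_stage,
                    "route": r.route,
                    "dose": r.dose,
                    "endpoint": r.endpoint,
                    "rq": r.rq,
                    "rq_rounded": round_sig(r.rq, 2),
                    "governing_caste": r.governing_caste,
                    "loc": r.loc,
                    "verdict": r.verdict,
                    "conservative": r.conservative,
                }
            )
        return rows


def default_eec(scenario: ApplicationScenario) -> float:
    """EEC (mg/kg) in both nectar and pollen under the default RUD.

    EEC = RUD × application rate (lb a.i./acre).
    """
    if scenario.mode != "default_rud":
        raise ModeMismatchError("default_eec requires a scenario in default_rud mode")
    return scenario.rud * scenario.rate_lb_per_acre


def contact_dose(scenario: ApplicationScenario) -> float:
    """Direct-spray dose (µg/bee) to an adult foraging at application time."""
    return scenario.contact_unit_dose * scenario.rate_lb_per_acre


def dietary_dose(
    caste: CasteDiet,
    nectar_conc: float,
    pollen_conc: float,
    jelly_conc: float = 0.0,
) -> float:
    """Daily dietary dose (µg/bee/day) for one caste.

    dose = Σ_matrix consumption (mg/day) × concentration (mg/kg) / 1000.
    """
    for name, c in (("nectar", nectar_conc), ("pollen", pollen_conc), ("jelly", jelly_conc)):
        if c < 0:
            raise ValueError(f"{name} concentration must be >= 0")
    return (
        caste.nectar_mg_per_day * nectar_conc
        + caste.pollen_mg_per_day * pollen_conc
        + caste.jelly_mg_per_day * jelly_conc
    ) / 1000.0


def _matrix_concentrations(scenario: ApplicationScenario) -> tuple[float, float, float]:
    """(nectar, pollen, jelly) concentrations in mg/kg for the scenario.

    In default mode the RUD-based EEC applies to nectar and pollen; no
    default residue estimate exists for royal jelly, which is therefore
    zero unless measured residues are supplied.
    """
    if scenario.mode == "default_rud":
        eec = default_eec(scenario)
        return eec, eec, 0.0
    res = scenario.residues
    assert res is not None
    return res.nectar_conc, res.pollen_conc, res.jelly_conc


_ROUTE_ENDPOINTS = {
    ("adult", "acute_contact"): "adult_contact_ld50",
    ("adult", "acute_dietary"): "adult_oral_ld50",
    ("adult", "chronic_dietary"): "adult_chronic_noed",
    ("larva", "acute_dietary"): "larval_acute_ld50",
    ("larva", "chronic_dietary"): "larval_chronic_noed",
}


def compute_rq_report(
    scenario: ApplicationScenario,
    tox: ToxicityProfile,
    castes: Sequence[CasteDiet] = DEFAULT_CASTES,
    locs: Mapping[str, float] = DEFAULT_LOCS,
) -> RQReport:
    """Compute the full per-life-stage × route risk-quotient table.

    The reported dietary RQ for each life stage is the maximum over the
    in-scope castes of that stage (the governing caste is recorded); the
    acute contact RQ applies to adults only.  Verdicts compare RQ with
    the route's level of concern (below_loc iff RQ < LOC).
    """
    adults = [c for c in castes if c.life_stage == "adult" and c.in_rq_scope]
    larvae = [c for c in castes if c.life_stage == "larva" and c.in_rq_scope]
    if not adults or not larvae:
        raise ValueError("need at least one in-scope adult and one in-scope larval caste")

    nectar_c, pollen_c, jelly_c = _matrix_concentrations(scenario)
    results: list[RQResult] = []

    def _endpoint(life_stage: str, route: str) -> float:
        name = _ROUTE_ENDPOINTS[(life_stage, route)]
        value = getattr(tox, name)
        if value is None:
            raise MissingEndpointError(f"{life_stage}/{route} ({name})")
        return value

    def _add(life_stage: str, route: str, dose: float, caste_id: str | None):
        endpoint = _endpoint(life_stage, route)
        rq = dose / endpoint
        loc = locs["acute" if route.startswith("acute") else "chronic"]
        results.append(
            RQResult(
                life_stage=life_stage,
                route=route,
                rq=rq,
                dose=dose,
                endpoint=endpoint,
                governing_caste=caste_id,
                eec_nectar=nectar_c,
                eec_pollen=pollen_c,
                eec_jelly=jelly_c,
                loc=loc,
                verdict="below_loc" if rq < loc else "at_or_above_loc",
                conservative=_ROUTE_ENDPOINTS[(life_stage, route)] in tox.greater_than,
            )
        )

    # Acute contact: adults only (not applicable to comb-bound larvae).
    _add("adult", "acute_contact", contact_dose(scenario), None)

    for life_stage, group in (("adult", adults), ("larva", larvae)):
        doses = {
            c.caste_id: dietary_dose(c, nectar_c, pollen_c, jelly_c) for c in group
        }
        governing = max(doses, key=doses.get)
        for route in ("acute_dietary", "chronic_dietary"):
            _add(life_stage, route, doses[governing], governing)

    out_of_scope = {
        c.caste_id: dietary_dose(c, nectar_c, pollen_c, jelly_c)
        for c in castes
        if not c.in_rq_scope
    }
    return RQReport(
        chemical_id=scenario.chemical_id,
        mode=scenario.mode,
        results=tuple(results),
        out_of_scope_doses=out_of_scope,
    )


def backcalc_contact_unit_dose(
    rq: float, ld50: float, rate: float, rate_unit: str = "kg_per_ha"
) -> float:
    """Recover the contact unit dose (µg/bee per lb a.i./acre) implied by a
    published contact RQ, its LD50 and the application rate."""
    lb = convert_rate(rate, rate_unit, "lb_per_acre")
    if lb <= 0:
        raise ValueError("rate must be > 0 to back-calculate")
    return rq * ld50 / lb


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (presentation only)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))
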