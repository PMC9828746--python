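"""End-to-end assessment runs: config in, risk-quotient tables out.

Assembles application scenarios and toxicity profiles for a set of
chemicals, runs the tier-1 risk-quotient computation in default
(RUD-based) and/or empirical (measured-residue) exposure mode, and
renders the results as CSV, JSON and markdown, logging every constant
used (RUD, contact unit dose, unit conversion factor, caste table) for
auditability.

A bundled example study (three trisiloxane polyether surfactants) is
available via :func:`builtin_run`, making end-to-end runs possible
without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .exposure import (
    DEFAULT_CASTES,
    DEFAULT_CONTACT_UNIT_DOSE,
    DEFAULT_LOCS,
    DEFAULT_RUD,
    KG_PER_HA_TO_LB_PER_ACRE,
    ApplicationScenario,
    CasteDiet,
    EmpiricalResidues,
    RQReport,
    ToxicityProfile,
    compute_rq_report,
    round_sig,
)

__all__ = [
    "ChemicalEntry",
    "AssessmentRun",
    "load_run",
    "builtin_run",
    "builtin_residue_csv",
    "run_default_mode",
    "run_empirical_mode",
    "reports_to_frame",
    "render_report",
]

_DATA = resources.files("beescreen") / "data"


@dataclass(frozen=True)
class ChemicalEntry:
    """One chemical's inputs: rates, toxicity profile, optional residues."""

    chemical_id: str
    rate: float  # default-mode application rate
    rate_unit: str = "kg_per_ha"
    empirical_rate: float | None = None  # contact-route rate in empirical mode
    residues: EmpiricalResidues | None = None
    tox: ToxicityProfile = field(default_factory=ToxicityProfile)


@dataclass(frozen=True)
class AssessmentRun:
    """A full assessment: chemicals plus the constants the model uses."""

    chemicals: tuple[ChemicalEntry, ...]
    locs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_LOCS))
    rud: float = DEFAULT_RUD
    contact_unit_dose: float = DEFAULT_CONTACT_UNIT_DOSE
    castes: tuple[CasteDiet, ...] = DEFAULT_CASTES

    def __post_init__(self):
        if not self.chemicals:
            raise ValueError("an assessment run needs at least one chemical")

    def constants(self) -> dict:
        """Every constant entering the computation, for the report header."""
        return {
            "rud_mg_per_kg_per_lb_acre": self.rud,
            "contact_unit_dose_ug_per_bee_per_lb_acre": self.contact_unit_dose,
            "kg_per_ha_to_lb_per_acre": KG_PER_HA_TO_LB_PER_ACRE,
            "locs": dict(self.locs),
            "caste_table_mg_per_day": [
                {
                    "caste_id": c.caste_id,
                    "life_stage": c.life_stage,
                    "nectar": c.nectar_mg_per_day,
                    "pollen": c.pollen_mg_per_day,
                    "jelly": c.jelly_mg_per_day,
                    "in_rq_scope": c.in_rq_scope,
                }
                for c in self.castes
            ],
        }


def _entry_from_dict(d: Mapping, rud: float, contact: float) -> ChemicalEntry:
    res = None
    if "residues" in d and d["residues"] is not None:
        prov = d.get("residues_provenance", {})
        res = EmpiricalResidues(
            pollen_conc=float(d["residues"]["pollen"]),
            nectar_conc=float(d["residues"]["nectar"]),
            jelly_conc=float(d["residues"].get("jelly", 0.0)),
            pollen_provenance=prov.get("pollen", "measured"),
            nectar_provenance=prov.get("nectar", "measured"),
            jelly_provenance=prov.get("jelly", "measured"),
        )
    tox_d = d.get("tox", {})
    tox = ToxicityProfile(
        adult_contact_ld50=tox_d.get("adult_contact_ld50"),
        adult_oral_ld50=tox_d.get("adult_oral_ld50"),
        adult_chronic_noed=tox_d.get("adult_chronic_noed"),
        larval_acute_ld50=tox_d.get("larval_acute_ld50"),
        larval_chronic_noed=tox_d.get("larval_chronic_noed"),
        greater_than=frozenset(d.get("greater_than", ())),
    )
    return ChemicalEntry(
        chemical_id=str(d["chemical"]),
        rate=float(d["rate"]),
        rate_unit=str(d.get("rate_unit", "kg_per_ha")),
        empirical_rate=(
            float(d["empirical_rate"]) if d.get("empirical_rate") is not None else None
        ),
        residues=res,
        tox=tox,
    )


def load_run(path) -> AssessmentRun:
    """Load an assessment run from a YAML (or JSON) config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return _run_from_config(cfg)


def _run_from_config(cfg: Mapping) -> AssessmentRun:
    rud = float(cfg.get("rud", DEFAULT_RUD))
    contact = float(cfg.get("contact_unit_dose", DEFAULT_CONTACT_UNIT_DOSE))
    locs = {**DEFAULT_LOCS, **cfg.get("locs", {})}
    entries = tuple(_entry_from_dict(d, rud, contact) for d in cfg["chemicals"])
    return AssessmentRun(
        chemicals=entries, locs=locs, rud=rud, contact_unit_dose=contact
    )


def builtin_run() -> AssessmentRun:
    """The bundled three-surfactant example study."""
    with (_DATA / "trisiloxane_study.yaml").open() as fh:
        return _run_from_config(yaml.safe_load(fh))


def builtin_residue_csv():
    """Path-like handle on the bundled orchard residue summary CSV."""
    return _DATA / "orchard_residue_summary.csv"


def run_default_mode(run: AssessmentRun) -> list[RQReport]:
    """Risk quotients with RUD-based EECs at the default-mode rates."""
    reports = []
    for chem in run.chemicals:
        scenario = ApplicationScenario(
            chemical_id=chem.chemical_id,
            rate=chem.rate,
            rate_unit=chem.rate_unit,
            mode="default_rud",
            rud=run.rud,
            contact_unit_dose=run.contact_unit_dose,
        )
        reports.append(
            compute_rq_report(scenario, chem.tox, castes=run.castes, locs=run.locs)
        )
    return reports


def run_empirical_mode(run: AssessmentRun) -> list[RQReport]:
    """Risk quotients with measured residues; the contact route still uses
    the (empirical-study) application rate."""
    reports = []
    for chem in run.chemicals:
        if chem.residues is None:
            raise ValueError(
                f"{chem.chemical_id}: empirical mode requires measured residues"
            )
        rate = chem.empirical_rate if chem.empirical_rate is not None else chem.rate
        scenario = ApplicationScenario(
            chemical_id=chem.chemical_id,
            rate=rate,
            rate_unit=chem.rate_unit,
            mode="empirical",
            rud=run.rud,
            contact_unit_dose=run.contact_unit_dose,
            residues=chem.residues,
        )
        reports.append(
            compute_rq_report(scenario, chem.tox, castes=run.castes, locs=run.locs)
        )
    return reports


def reports_to_frame(reports: Sequence[RQReport]) -> pd.DataFrame:
    """Flatten reports into one row per chemical × life stage × route."""
    rows = [row for rep in reports for row in rep.to_records()]
    return pd.DataFrame(rows)


_ROUTE_LABEL = {
    "acute_contact": "Acute contact",
    "acute_dietary": "Acute dietary",
    "chronic_dietary": "Chronic dietary",
}


def _markdown_table(reports: Sequence[RQReport]) -> list[str]:
    chems = [r.chemical_id for r in reports]
    lines = ["| Exposure | " + " | ".join(f"{c} adults | {c} larvae" for c in chems) + " |"]
    lines.append("|" + " --- |" * (1 + 2 * len(chems)))
    for route in ("acute_contact", "acute_dietary", "chronic_dietary"):
        cells = []
        for rep in reports:
            for stage in ("adult", "larva"):
                if route == "acute_contact" and stage == "larva":
                    cells.append("NA")
                    continue
                r = rep.cell(stage, route)
                # unbounded ">" endpoints make the quotient an upper bound
                mark = "\\*" if r.conservative else ""
                cells.append(f"{round_sig(r.rq, 2):g}{mark}")
        lines.append(f"| {_ROUTE_LABEL[route]} | " + " | ".join(cells) + " |")
    return lines


def render_report(
    reports_by_mode: Mapping[str, Sequence[RQReport]],
    out_dir,
    locs: Mapping[str, float] = DEFAULT_LOCS,
    constants: Mapping | None = None,
) -> dict[str, Path]:
    """Write CSV, JSON and markdown outputs for completed runs.

    The markdown summary states that no acute or chronic risk is
    indicated only when every cell of every mode is below its level of
    concern; otherwise it lists the exceeding cells.
    """
    if not reports_by_mode or not any(reports_by_mode.values()):
        raise ValueError("render_report requires at least one completed run")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = pd.concat(
        [reports_to_frame(reps) for reps in reports_by_mode.values()],
        ignore_index=True,
    )
    csv_path = out / "rq.csv"
    frame.to_csv(csv_path, index=False)

    payload = {
        "constants": dict(constants) if constants is not None else {},
        "locs": dict(locs),
        "reports": frame.to_dict(orient="records"),
    }
    json_path = out / "rq.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True))

    exceed = frame[frame["verdict"] == "at_or_above_loc"]
    md = ["# Tier-1 pollinator risk quotients", ""]
    if constants:
        md += ["## Constants used", "", "```json",
               json.dumps(dict(constants), indent=2, sort_keys=True), "```", ""]
    for mode, reps in reports_by_mode.items():
        md += [f"## Mode: {mode}", ""]
        md += _markdown_table(list(reps))
        md += [""]
    if len(exceed) == 0:
        md.append(
            f"Summary: no acute or chronic risk indicated (all risk quotients "
            f"below the acute {locs['acute']} and chronic {locs['chronic']} "
            f"levels of concern)."
        )
    else:
        md.append("Summary: LEVEL-OF-CONCERN EXCEEDANCE in the following cells:")
        for _, row in exceed.iterrows():
            md.append(
                f"- {row['chemical_id']} {row['life_stage']} {row['route']} "
                f"({row['mode']}): RQ {row['rq']:.3g} >= LOC {row['loc']}"
            )
    md_path = out / "report.md"
    md_path.write_text("\n".join(md) + "\n")
    return {"csv": csv_path, "json": json_path, "markdown": md_path}
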