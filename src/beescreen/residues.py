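"""Residue-study post-processing: matrix groups, censoring, and peaks.

Converts replicate residue measurements (mg/kg) per bee-relevant matrix
and sampling day into the three empirical exposure inputs the tier-1
model consumes:

* pollen input  = peak over all pollen samples (forager pollen + bee bread),
* nectar input  = peak over all nectar samples (forager + stored nectar),
* jelly input   = peak larval concentration (surrogate for royal jelly).

Values below the analytical limits are censored; when an entire matrix
group is censored the limit of quantitation (LOQ) is substituted as a
conservative estimate (the default rule), with half-LOQ, MDL, and zero
available for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .errors import EmptyGroupError, UnknownRuleError

__all__ = [
    "MATRICES",
    "POLLEN_GROUP",
    "NECTAR_GROUP",
    "JELLY_SURROGATE_GROUP",
    "ResidueSample",
    "GroupPeak",
    "BeerexEmpiricalInputs",
    "substitute_censored",
    "peak_by_group",
    "read_residue_csv",
    "validate_controls",
]

MATRICES = (
    "forager_pollen",
    "bee_bread",
    "forager_nectar",
    "stored_nectar",
    "larvae",
    "wax",
    "whole_bees",
)

POLLEN_GROUP = ("forager_pollen", "bee_bread")
NECTAR_GROUP = ("forager_nectar", "stored_nectar")
JELLY_SURROGATE_GROUP = ("larvae",)

_RULES = ("loq", "mdl", "half_loq", "zero")


@dataclass(frozen=True)
class ResidueSample:
    """One replicate concentration for a matrix on a sampling day.

    ``conc`` is the measured value in mg/kg; censored samples (below the
    minimum detectable limit) carry ``censored=True`` and ``conc`` holds
    the bound they were censored at.  ``invalid`` marks matrices excluded
    from use (e.g. storage-instability failures); ``control`` marks
    untreated-plot samples, which never feed peaks.
    """

    matrix: str
    day: int
    conc: float
    loq: float
    mdl: float
    censored: bool = False
    replicate: int = 1
    control: bool = False
    invalid: bool = False

    def __post_init__(self):
        if self.matrix not in MATRICES:
            raise ValueError(f"unknown matrix: {self.matrix!r}")
        if self.mdl > self.loq:
            raise ValueError("MDL must be <= LOQ")
        if self.conc < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class GroupPeak:
    """Peak concentration for one matrix group."""

    value: float
    provenance: str  # measured_peak | loq_substituted
    source_matrix: str | None
    peak_day: int | None


@dataclass(frozen=True)
class BeerexEmpiricalInputs:
    """The three empirical exposure inputs with provenance."""

    pollen: GroupPeak
    nectar: GroupPeak
    jelly: GroupPeak

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.pollen.value, self.nectar.value, self.jelly.value)


def _substitute_value(sample: ResidueSample, rule: str) -> float:
    if rule == "loq":
        return sample.loq
    if rule == "mdl":
        return sample.mdl
    if rule == "half_loq":
        return sample.loq / 2.0
    if rule == "zero":
        return 0.0
    raise UnknownRuleError(f"unknown censoring rule: {rule!r}")


def substitute_censored(
    samples: Iterable[ResidueSample], rule: str = "loq"
) -> list[ResidueSample]:
    """Replace censored concentrations per ``rule``; measured samples are
    untouched.  The substituted value never exceeds the LOQ."""
    if rule not in _RULES:
        raise UnknownRuleError(f"unknown censoring rule: {rule!r}")
    out = []
    for s in samples:
        if s.censored:
            out.append(replace(s, conc=min(_substitute_value(s, rule), s.loq)))
        else:
            out.append(s)
    return out


def _group_peak(
    samples: Sequence[ResidueSample], group: Sequence[str], rule: str
) -> GroupPeak:
    members = [
        s for s in samples if s.matrix in group and not s.control and not s.invalid
    ]
    if not members:
        raise EmptyGroupError(f"no usable samples in matrix group {tuple(group)}")
    measured = [s for s in members if not s.censored]
    if measured:
        best = max(measured, key=lambda s: s.conc)
        return GroupPeak(best.conc, "measured_peak", best.matrix, best.day)
    # fully censored group: substitute (default: the LOQ, conservatively)
    substituted = substitute_censored(members, rule)
    best = max(substituted, key=lambda s: s.conc)
    return GroupPeak(best.conc, "loq_substituted" if rule == "loq" else f"{rule}_substituted",
                     best.matrix, best.day)


def peak_by_group(
    samples: Sequence[ResidueSample], rule: str = "loq"
) -> BeerexEmpiricalInputs:
    """Reduce a residue study to the three empirical exposure inputs.

    Each input is the maximum non-censored concentration over its matrix
    group across all sampling days; a fully censored group falls back to
    the substitution ``rule`` (LOQ by default).
    """
    if rule not in _RULES:
        raise UnknownRuleError(f"unknown censoring rule: {rule!r}")
    validate_controls(samples)
    return BeerexEmpiricalInputs(
        pollen=_group_peak(samples, POLLEN_GROUP, rule),
        nectar=_group_peak(samples, NECTAR_GROUP, rule),
        jelly=_group_peak(samples, JELLY_SURROGATE_GROUP, rule),
    )


def validate_controls(samples: Iterable[ResidueSample]) -> bool:
    """Check untreated-control samples are fully censored; warn otherwise."""
    bad = [s for s in samples if s.control and not s.censored]
    if bad:
        warnings.warn(
            f"{len(bad)} control-plot sample(s) show quantifiable residues; "
            "controls are excluded from peaks but this may indicate contamination",
            UserWarning,
            stacklevel=2,
        )
        return False
    return True


def read_residue_csv(path, chemical: str | None = None) -> list[ResidueSample]:
    """Read a residue-study CSV into samples.

    Expected columns: ``matrix, day, replicate, conc, loq, mdl`` and
    optionally ``control`` and ``invalid`` (0/1).  ``conc`` accepts the
    ``<X`` convention for values censored below the bound X.  A
    multi-chemical file (extra ``chemical`` column) can be filtered with
    ``chemical``.
    """
    df = pd.read_csv(path, comment="#")
    if chemical is not None:
        df = df[df["chemical"] == chemical]
    samples = []
    for row in df.itertuples(index=False):
        raw = str(row.conc).strip()
        censored = raw.startswith("<")
        conc = float(raw[1:]) if censored else float(raw)
        samples.append(
            ResidueSample(
                matrix=str(row.matrix),
                day=int(row.day),
                conc=conc,
                loq=float(row.loq),
                mdl=float(row.mdl),
                censored=censored,
                replicate=int(getattr(row, "replicate", 1)),
                control=bool(int(getattr(row, "control", 0))),
                invalid=bool(int(getattr(row, "invalid", 0))),
            )
        )
    return samples
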