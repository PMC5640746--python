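"""Readers, writers and validation for the three survey tables.

Three plain CSV tables (comma-separated, UTF-8, mandatory header, no index
column) carry the whole study: a service roster, a tie survey, and a patient
outcome table.  All readers validate eagerly and report offending rows by
number (1-based, excluding the header), because silent coercion of survey
data is how analysis sets drift.

Ordinal tie frequencies are encoded internally as ``never=0, sometimes=1,
often=2`` so that both dichotomization rules ("sometimes or often" vs
"often only") are simple threshold comparisons.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "SERVICE_TYPES",
    "RELATION_KINDS",
    "CLINICAL_KINDS",
    "FREQUENCY_LEVELS",
    "SEX_VALUES",
    "DIAGNOSES",
    "ValidationError",
    "ServiceNode",
    "TieRecord",
    "PatientRecord",
    "read_roster",
    "write_roster",
    "read_ties",
    "write_ties",
    "read_patients",
    "write_patients",
    "analysis_set",
    "participation_rate",
]

#: The nine service-type categories used for network composition.
SERVICE_TYPES: tuple[str, ...] = (
    "primary_care",
    "community_mental_health",
    "crisis_outreach",
    "rehabilitation",
    "social_services",
    "psychiatric_ward",
    "sheltered_housing",
    "nursing_home",
    "other",
)

#: Tie relation kinds collected by the survey.  The first three are clinical
#: and feed network construction; organizational ties are parsed but excluded.
RELATION_KINDS: tuple[str, ...] = (
    "referral_sent",
    "referral_received",
    "info_exchange",
    "organizational",
)
CLINICAL_KINDS: tuple[str, ...] = ("referral_sent", "referral_received", "info_exchange")

#: Ordinal contact-frequency levels over the previous six months.
FREQUENCY_LEVELS: dict[str, int] = {"never": 0, "sometimes": 1, "often": 2}

SEX_VALUES: tuple[str, ...] = ("male", "female")

#: Principal-diagnosis categories of the patient table.
DIAGNOSES: tuple[str, ...] = (
    "schizophrenia",
    "mood_disorder",
    "substance_use",
    "personality_disorder",
    "anxiety_disorder",
    "other",
)

N_ACSS_ITEMS = 31
ACSS_COLUMNS = tuple(f"acss_{i:02d}" for i in range(1, N_ACSS_ITEMS + 1))

ROSTER_COLUMNS = ("service_id", "network_id", "service_type", "participated")
TIE_COLUMNS = ("network_id", "reporter_id", "alter_id", "relation_kind", "frequency")
PATIENT_COLUMNS = (
    ("patient_id", "network_id", "recruitment_service_type")
    + ACSS_COLUMNS
    + (
        "six_employment",
        "six_accommodation",
        "six_family",
        "six_friends",
        "age",
        "sex",
        "honos",
        "diagnosis",
        "n_outpatient",
        "n_social",
        "n_residential",
    )
)


class ValidationError(ValueError):
    """Raised when a survey table violates its schema.

    ``errors`` lists one human-readable message per offending row.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class ServiceNode:
    """One service (agency) registered in a network.

    ``participated`` marks whether the service completed the tie survey;
    only participants' reports are trusted when building networks.
    """

    service_id: str
    network_id: str
    service_type: str
    participated: bool

    def __post_init__(self) -> None:
        if self.service_type not in SERVICE_TYPES:
            raise ValidationError(
                [f"unknown service_type {self.service_type!r} for service {self.service_id!r}"]
            )


@dataclass(frozen=True)
class TieRecord:
    """One reported directed contact between two services.

    ``frequency`` is the internal ordinal code (0=never, 1=sometimes,
    2=often).  ``reporter_id`` is the service filling in the survey;
    ``alter_id`` the service it reports about.
    """

    network_id: str
    reporter_id: str
    alter_id: str
    relation_kind: str
    frequency: int

    def __post_init__(self) -> None:
        errs = []
        if self.relation_kind not in RELATION_KINDS:
            errs.append(f"unknown relation_kind {self.relation_kind!r}")
        if self.frequency not in (0, 1, 2):
            errs.append(f"frequency code {self.frequency!r} outside 0..2")
        if self.reporter_id == self.alter_id:
            errs.append(f"self-tie {self.reporter_id!r} -> {self.alter_id!r}")
        if errs:
            raise ValidationError(errs)

    @property
    def frequency_label(self) -> str:
        return {v: k for k, v in FREQUENCY_LEVELS.items()}[self.frequency]


@dataclass
class PatientRecord:
    """One surveyed patient with outcomes and covariates.

    ``acss_items`` holds the 31 continuity items (1..5, ``None`` when
    missing).  ``complete`` is True only when every outcome item and
    covariate needed by the regression models is present; incomplete
    records stay in the parsed list but are excluded from the analysis
    set (listwise exclusion).
    """

    patient_id: str
    network_id: str
    recruitment_service_type: str
    acss_items: list[Optional[int]]
    six_employment: Optional[int]
    six_accommodation: Optional[int]
    six_family: Optional[int]
    six_friends: Optional[int]
    age: Optional[float]
    sex: Optional[str]
    honos: Optional[int]
    diagnosis: Optional[str]
    n_outpatient: Optional[int] = None
    n_social: Optional[int] = None
    n_residential: Optional[int] = None
    complete: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        errs = []
        if len(self.acss_items) != N_ACSS_ITEMS:
            errs.append(
                f"patient {self.patient_id!r}: expected {N_ACSS_ITEMS} continuity items, "
                f"got {len(self.acss_items)}"
            )
        for i, v in enumerate(self.acss_items, start=1):
            if v is not None and not (1 <= v <= 5):
                errs.append(f"patient {self.patient_id!r}: acss_{i:02d}={v} outside 1..5")
        if self.recruitment_service_type not in SERVICE_TYPES:
            errs.append(
                f"patient {self.patient_id!r}: unknown recruitment_service_type "
                f"{self.recruitment_service_type!r}"
            )
        for name, value, lo, hi in (
            ("six_employment", self.six_employment, 0, 2),
            ("six_accommodation", self.six_accommodation, 0, 2),
            ("six_family", self.six_family, 0, 1),
            ("six_friends", self.six_friends, 0, 1),
            ("honos", self.honos, 0, 48),
        ):
            if value is not None and not (lo <= value <= hi):
                errs.append(f"patient {self.patient_id!r}: {name}={value} outside {lo}..{hi}")
        if self.sex is not None and self.sex not in SEX_VALUES:
            errs.append(f"patient {self.patient_id!r}: unknown sex {self.sex!r}")
        if self.diagnosis is not None and self.diagnosis not in DIAGNOSES:
            errs.append(f"patient {self.patient_id!r}: unknown diagnosis {self.diagnosis!r}")
        if errs:
            raise ValidationError(errs)
        required = (
            list(self.acss_items)
            + [
                self.six_employment,
                self.six_accommodation,
                self.six_family,
                self.six_friends,
                self.age,
                self.sex,
                self.honos,
            ]
        )
        self.complete = all(v is not None for v in required)


def _read_rows(path: str | Path, required_columns: Sequence[str]) -> list[dict[str, str]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required_columns if c not in header]
        if missing:
            raise ValidationError([f"{path.name}: missing required column(s) {missing}"])
        return list(reader)


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean {text!r}")


def _opt_int(text: str) -> Optional[int]:
    t = text.strip()
    return int(t) if t else None


def read_roster(path: str | Path) -> list[ServiceNode]:
    """Read a service roster; row order is preserved.

    Raises :class:`ValidationError` naming each row with an unknown
    service type or a service id duplicated within its network.
    """
    rows = _read_rows(path, ROSTER_COLUMNS)
    nodes: list[ServiceNode] = []
    errors: list[str] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(rows, start=1):
        stype = row["service_type"].strip()
        if stype not in SERVICE_TYPES:
            errors.append(f"row {i}: unknown service_type {stype!r}")
            continue
        key = (row["network_id"].strip(), row["service_id"].strip())
        if key in seen:
            errors.append(f"row {i}: duplicate service_id {key[1]!r} in network {key[0]!r}")
            continue
        seen.add(key)
        try:
            nodes.append(
                ServiceNode(
                    service_id=key[1],
                    network_id=key[0],
                    service_type=stype,
                    participated=_parse_bool(row["participated"]),
                )
            )
        except (ValueError, ValidationError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError(errors)
    return nodes


def write_roster(nodes: Iterable[ServiceNode], path: str | Path) -> None:
    """Write the canonical roster CSV."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(ROSTER_COLUMNS)
        for n in nodes:
            writer.writerow([n.service_id, n.network_id, n.service_type, str(n.participated).lower()])


def read_ties(
    path: str | Path,
    roster: Sequence[ServiceNode],
    *,
    strict: bool = True,
) -> list[TieRecord] | tuple[list[TieRecord], list[str]]:
    """Read tie-survey records, resolving ids against ``roster``.

    Rejected rows: reporter or alter unknown in the row's network,
    reporter not a participating service, self-ties, missing or unknown
    frequency/relation values.  With ``strict=True`` (default) any bad row
    raises :class:`ValidationError`; with ``strict=False`` the valid
    records and the per-row error report are returned as a pair.
    """
    by_net: dict[str, dict[str, ServiceNode]] = {}
    for n in roster:
        by_net.setdefault(n.network_id, {})[n.service_id] = n

    rows = _read_rows(path, TIE_COLUMNS)
    records: list[TieRecord] = []
    errors: list[str] = []
    for i, row in enumerate(rows, start=1):
        net = row["network_id"].strip()
        reporter = row["reporter_id"].strip()
        alter = row["alter_id"].strip()
        kind = row["relation_kind"].strip()
        freq_text = row["frequency"].strip()
        services = by_net.get(net)
        if services is None:
            errors.append(f"row {i}: unknown network_id {net!r}")
            continue
        if reporter == alter:
            errors.append(f"row {i}: self-tie ({reporter!r})")
            continue
        if reporter not in services:
            errors.append(f"row {i}: unknown reporter_id {reporter!r} in network {net!r}")
            continue
        if alter not in services:
            errors.append(f"row {i}: unknown alter_id {alter!r} in network {net!r}")
            continue
        if not services[reporter].participated:
            errors.append(f"row {i}: reporter {reporter!r} did not participate in the survey")
            continue
        if kind not in RELATION_KINDS:
            errors.append(f"row {i}: unknown relation_kind {kind!r}")
            continue
        if not freq_text:
            errors.append(f"row {i}: missing frequency")
            continue
        if freq_text not in FREQUENCY_LEVELS:
            errors.append(f"row {i}: unknown frequency {freq_text!r}")
            continue
        records.append(
            TieRecord(
                network_id=net,
                reporter_id=reporter,
                alter_id=alter,
                relation_kind=kind,
                frequency=FREQUENCY_LEVELS[freq_text],
            )
        )
    if strict:
        if errors:
            raise ValidationError(errors)
        return records
    return records, errors


def write_ties(records: Iterable[TieRecord], path: str | Path) -> None:
    """Write the canonical tie-survey CSV (ordinal labels, not codes)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(TIE_COLUMNS)
        for r in records:
            writer.writerow([r.network_id, r.reporter_id, r.alter_id, r.relation_kind, r.frequency_label])


def read_patients(path: str | Path) -> list[PatientRecord]:
    """Read the patient table.

    Missing outcome items are tolerated (the record is flagged
    ``complete=False`` and dropped from the analysis set); values outside
    their documented ranges raise :class:`ValidationError`.
    """
    rows = _read_rows(path, PATIENT_COLUMNS)
    patients: list[PatientRecord] = []
    errors: list[str] = []
    for i, row in enumerate(rows, start=1):
        try:
            items = [_opt_int(row[c]) for c in ACSS_COLUMNS]
            age_text = row["age"].strip()
            patients.append(
                PatientRecord(
                    patient_id=row["patient_id"].strip(),
                    network_id=row["network_id"].strip(),
                    recruitment_service_type=row["recruitment_service_type"].strip(),
                    acss_items=items,
                    six_employment=_opt_int(row["six_employment"]),
                    six_accommodation=_opt_int(row["six_accommodation"]),
                    six_family=_opt_int(row["six_family"]),
                    six_friends=_opt_int(row["six_friends"]),
                    age=float(age_text) if age_text else None,
                    sex=row["sex"].strip() or None,
                    honos=_opt_int(row["honos"]),
                    diagnosis=row["diagnosis"].strip() or None,
                    n_outpatient=_opt_int(row["n_outpatient"]),
                    n_social=_opt_int(row["n_social"]),
                    n_residential=_opt_int(row["n_residential"]),
                )
            )
        except (ValueError, ValidationError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError(errors)
    return patients


def write_patients(patients: Iterable[PatientRecord], path: str | Path) -> None:
    """Write the canonical patient CSV (empty cell for missing values)."""

    def cell(v) -> str:
        if v is None:
            return ""
        if isinstance(v, float):
            return format(v, "g")
        return str(v)

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(PATIENT_COLUMNS)
        for p in patients:
            row = [p.patient_id, p.network_id, p.recruitment_service_type]
            row += [cell(v) for v in p.acss_items]
            row += [
                cell(p.six_employment),
                cell(p.six_accommodation),
                cell(p.six_family),
                cell(p.six_friends),
                cell(p.age),
                cell(p.sex),
                cell(p.honos),
                cell(p.diagnosis),
                cell(p.n_outpatient),
                cell(p.n_social),
                cell(p.n_residential),
            ]
            writer.writerow(row)


def analysis_set(patients: Sequence[PatientRecord]) -> list[PatientRecord]:
    """Complete records only (listwise exclusion of missing outcomes/covariates)."""
    return [p for p in patients if p.complete]


def participation_rate(n_responded: int, n_invited: int) -> float:
    """Survey participation as a percentage of those invited."""
    if n_invited <= 0:
        raise ValueError("n_invited must be positive")
    return 100.0 * n_responded / n_invited
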