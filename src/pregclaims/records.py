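"""Claims data model, code-list configuration and delimited-text I/O.

Three record streams make up an administrative-claims extract for this
pipeline: medical service records (inpatient DRG and outpatient TARMED
billing codes), outpatient pharmacy dispensations (WHO ATC coded), and
insurance enrollment spans.  All dates are calendar dates; interval
arithmetic everywhere in the package is in whole days.
"""

from __future__ import annotations

import csv
import datetime as dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import yaml

CODE_SYSTEMS = ("DRG", "TARMED")
TERM_STATUSES = ("full_term", "preterm", "unspecified")

#: ATC grammar: anatomical letter, 2-digit therapeutic level, then optional
#: pharmacological letter, chemical letter and 2-digit substance level.
ATC_PATTERN = re.compile(r"^[A-Z]\d{2}([A-Z]([A-Z](\d{2})?)?)?$")


class ConfigurationError(ValueError):
    """A configuration problem (missing column, inconsistent code lists)."""


class ServiceRecord(NamedTuple):
    person_id: str
    date: dt.date
    code_system: str  # "DRG" | "TARMED"
    code: str


class DispensationRecord(NamedTuple):
    person_id: str
    date: dt.date
    atc_code: str


class EnrollmentSpan(NamedTuple):
    person_id: str
    start: dt.date
    end: dt.date


@dataclass(frozen=True)
class RowDiagnostic:
    """A rejected input row: table name, 1-based data row number, message."""

    table: str
    row: int
    message: str


def is_valid_atc(code: str) -> bool:
    return bool(ATC_PATTERN.match(code.upper()))


@dataclass
class CodeConfig:
    """Code lists driving delivery identification and drug classification.

    The real Swiss DRG/TARMED delivery code values are proprietary; the
    default lists below are synthetic placeholders with the right shape
    (term-specific DRG codes, term-agnostic TARMED codes, caesarean DRGs).

    Attributes
    ----------
    delivery_codes
        code_system -> {code -> term status}.  DRG codes carry term
        information; TARMED codes are "unspecified".
    caesarean_codes, termination_codes
        Sets of (code_system, code).  Termination/miscarriage codes cause
        the surrounding pregnancy episode to be excluded.
    fertility_atc
        ATC prefixes of medications used in fertility treatment.
    adm_class_map
        Ordered (ATC prefix, class label) pairs; longest prefix wins, so
        A10A (insulins) and A10B (blood glucose-lowering drugs) take
        precedence over the bare A10 level.
    cluster_rule
        "anchor": delivery codes within 30 days of the cluster's first code
        join it (default).  "chain": within 30 days of the last joined code.
    tarmed_triggers_ignore_rule
        Whether a stray TARMED code 31-300 days after a delivery is treated
        like a stray DRG (default False: only DRG codes trigger the rule).
    post_delivery_enrollment_days
        Continuous-enrollment requirement after delivery (default 252 days,
        the 9-month convention used for the prepregnancy baseline).
    ci_method
        "clopper_pearson" (exact, default) or "wilson".
    """

    delivery_codes: dict[str, dict[str, str]]
    caesarean_codes: set[tuple[str, str]] = field(default_factory=set)
    termination_codes: set[tuple[str, str]] = field(default_factory=set)
    fertility_atc: set[str] = field(default_factory=set)
    adm_class_map: list[tuple[str, str]] = field(
        default_factory=lambda: [
            ("A10A", "insulin"),
            ("A10B", "blood_glucose_lowering"),
            ("A10", "other_adm"),
        ]
    )
    cluster_rule: str = "anchor"
    tarmed_triggers_ignore_rule: bool = False
    post_delivery_enrollment_days: int = 252
    ci_method: str = "clopper_pearson"

    def __post_init__(self) -> None:
        for system in self.delivery_codes:
            if system not in CODE_SYSTEMS:
                raise ConfigurationError(f"unknown code system {system!r}")
            for code, term in self.delivery_codes[system].items():
                if term not in TERM_STATUSES:
                    raise ConfigurationError(
                        f"term status {term!r} for delivery code {code!r}"
                    )
        overlap = {
            (s, c) for s, codes in self.delivery_codes.items() for c in codes
        } & self.termination_codes
        if overlap:
            raise ConfigurationError(
                f"codes listed as both delivery and termination: {sorted(overlap)}"
            )
        if self.cluster_rule not in ("anchor", "chain"):
            raise ConfigurationError(f"cluster_rule {self.cluster_rule!r}")
        if self.ci_method not in ("clopper_pearson", "wilson"):
            raise ConfigurationError(f"ci_method {self.ci_method!r}")

    # -- construction ------------------------------------------------------

    @classmethod
    def default(cls) -> "CodeConfig":
        """Synthetic default code lists (placeholder DRG/TARMED values)."""
        return cls(
            delivery_codes={
                "DRG": {
                    "O60A": "full_term",
                    "O60B": "full_term",
                    "O60C": "preterm",
                    "O01A": "full_term",  # caesarean, full term
                    "O01C": "preterm",  # caesarean, preterm
                },
                "TARMED": {"DEL01": "unspecified"},
            },
            caesarean_codes={("DRG", "O01A"), ("DRG", "O01C")},
            termination_codes={("DRG", "O40Z"), ("TARMED", "TERM01")},
            fertility_atc={"G03GA", "G03GB", "H01CA", "H01CC"},
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CodeConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "codes" in raw:
            raw = raw["codes"]
        kwargs: dict = {}
        if "delivery_codes" in raw:
            kwargs["delivery_codes"] = {
                sys: dict(codes) for sys, codes in raw["delivery_codes"].items()
            }
        else:
            raise ConfigurationError("config missing 'delivery_codes'")
        for key in ("caesarean_codes", "termination_codes"):
            if key in raw:
                kwargs[key] = {(s, c) for s, c in (tuple(x) for x in raw[key])}
        if "fertility_atc" in raw:
            kwargs["fertility_atc"] = set(raw["fertility_atc"])
        if "adm_class_map" in raw:
            kwargs["adm_class_map"] = [tuple(x) for x in raw["adm_class_map"]]
        for key in (
            "cluster_rule",
            "tarmed_triggers_ignore_rule",
            "post_delivery_enrollment_days",
            "ci_method",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "codes": {
                "delivery_codes": self.delivery_codes,
                "caesarean_codes": sorted(list(t) for t in self.caesarean_codes),
                "termination_codes": sorted(list(t) for t in self.termination_codes),
                "fertility_atc": sorted(self.fertility_atc),
                "adm_class_map": [list(t) for t in self.adm_class_map],
                "cluster_rule": self.cluster_rule,
                "tarmed_triggers_ignore_rule": self.tarmed_triggers_ignore_rule,
                "post_delivery_enrollment_days": self.post_delivery_enrollment_days,
                "ci_method": self.ci_method,
            }
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def is_delivery_code(self, system: str, code: str) -> bool:
        return code in self.delivery_codes.get(system, ())

    def term_status_of(self, system: str, code: str) -> str:
        return self.delivery_codes[system][code]


def classify_atc(atc_code: str, config: CodeConfig) -> str:
    """Map an ATC code to an antidiabetic class label.

    Longest-prefix, case-insensitive match against ``config.adm_class_map``;
    codes matching no prefix are ``non_adm``.
    """
    code = atc_code.upper()
    if not ATC_PATTERN.match(code):
        raise ValueError(f"malformed ATC code {atc_code!r}")
    best_label, best_len = "non_adm", -1
    for prefix, label in config.adm_class_map:
        p = prefix.upper()
        if code.startswith(p) and len(p) > best_len:
            best_label, best_len = label, len(p)
    return best_label


# ---------------------------------------------------------------------------
# Delimited-text readers and writers
# ---------------------------------------------------------------------------

_SERVICE_COLS = ("person_id", "date", "code_system", "code")
_DISPENSATION_COLS = ("person_id", "date", "atc_code")
_ENROLLMENT_COLS = ("person_id", "start", "end")


def _parse_date(value: str) -> dt.date:
    return dt.date.fromisoformat(value.strip())


def _check_header(reader: csv.DictReader, required: Sequence[str], table: str) -> None:
    have = set(reader.fieldnames or ())
    missing = [c for c in required if c not in have]
    if missing:
        raise ConfigurationError(
            f"{table} file is missing required column(s): {', '.join(missing)}"
        )


def read_services(path: str | Path) -> tuple[list[ServiceRecord], list[RowDiagnostic]]:
    records: list[ServiceRecord] = []
    diags: list[RowDiagnostic] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader, _SERVICE_COLS, "services")
        for i, row in enumerate(reader, start=1):
            try:
                date = _parse_date(row["date"])
            except (ValueError, TypeError):
                diags.append(RowDiagnostic("services", i, f"unparseable date {row.get('date')!r}"))
                continue
            system = (row["code_system"] or "").strip()
            if system not in CODE_SYSTEMS:
                diags.append(RowDiagnostic("services", i, f"unknown code_system {system!r}"))
                continue
            code = (row["code"] or "").strip()
            if not code:
                diags.append(RowDiagnostic("services", i, "empty code"))
                continue
            records.append(ServiceRecord(row["person_id"].strip(), date, system, code))
    records.sort(key=lambda r: (r.person_id, r.date, r.code_system, r.code))
    return records, diags


def read_dispensations(
    path: str | Path,
) -> tuple[list[DispensationRecord], list[RowDiagnostic]]:
    records: list[DispensationRecord] = []
    diags: list[RowDiagnostic] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader, _DISPENSATION_COLS, "dispensations")
        for i, row in enumerate(reader, start=1):
            try:
                date = _parse_date(row["date"])
            except (ValueError, TypeError):
                diags.append(
                    RowDiagnostic("dispensations", i, f"unparseable date {row.get('date')!r}")
                )
                continue
            atc = (row["atc_code"] or "").strip().upper()
            if not ATC_PATTERN.match(atc):
                diags.append(RowDiagnostic("dispensations", i, f"malformed ATC {atc!r}"))
                continue
            records.append(DispensationRecord(row["person_id"].strip(), date, atc))
    records.sort(key=lambda r: (r.person_id, r.date, r.atc_code))
    return records, diags


def read_enrollment(path: str | Path) -> tuple[list[EnrollmentSpan], list[RowDiagnostic]]:
    records: list[EnrollmentSpan] = []
    diags: list[RowDiagnostic] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader, _ENROLLMENT_COLS, "enrollment")
        for i, row in enumerate(reader, start=1):
            try:
                start = _parse_date(row["start"])
                end = _parse_date(row["end"])
            except (ValueError, TypeError):
                diags.append(RowDiagnostic("enrollment", i, "unparseable date"))
                continue
            if start > end:
                diags.append(RowDiagnostic("enrollment", i, f"start {start} after end {end}"))
                continue
            records.append(EnrollmentSpan(row["person_id"].strip(), start, end))
    records.sort(key=lambda r: (r.person_id, r.start, r.end))
    return records, diags


@dataclass
class ClaimsBundle:
    services: list[ServiceRecord]
    dispensations: list[DispensationRecord]
    enrollment: list[EnrollmentSpan]
    diagnostics: list[RowDiagnostic]


def read_claims(
    services_path: str | Path,
    dispensations_path: str | Path,
    enrollment_path: str | Path,
    config: CodeConfig | None = None,
) -> ClaimsBundle:
    """Read the three claims tables, collecting row-level diagnostics.

    Rows that cannot be parsed are rejected individually (with their data
    row number); a missing column raises :class:`ConfigurationError`.
    """
    services, d1 = read_services(services_path)
    dispensations, d2 = read_dispensations(dispensations_path)
    enrollment, d3 = read_enrollment(enrollment_path)
    return ClaimsBundle(services, dispensations, enrollment, d1 + d2 + d3)


def write_claims(
    records: Iterable[ServiceRecord | DispensationRecord | EnrollmentSpan],
    path: str | Path,
    kind: str | None = None,
) -> None:
    """Write one of the three record streams to CSV.

    Canonical column order, ISO-8601 dates, rows sorted deterministically.
    ``kind`` ("services" | "dispensations" | "enrollment") is required only
    for empty record lists, where the type cannot be inferred.
    """
    records = list(records)
    if records:
        kind = {
            ServiceRecord: "services",
            DispensationRecord: "dispensations",
            EnrollmentSpan: "enrollment",
        }[type(records[0])]
    elif kind is None:
        raise ValueError("kind must be given for an empty record list")
    cols = {
        "services": _SERVICE_COLS,
        "dispensations": _DISPENSATION_COLS,
        "enrollment": _ENROLLMENT_COLS,
    }[kind]
    records.sort(key=tuple)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for rec in records:
            writer.writerow([v.isoformat() if isinstance(v, dt.date) else v for v in rec])
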