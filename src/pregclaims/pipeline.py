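"""End-to-end orchestration: claims tables -> results tables + manifest."""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import pregclaims

from .deliveries import AuditEntry, DeliveryEvent, identify_deliveries, write_audit_log
from .exposure import ExposureProfile, GroupAssignment, classify_episodes
from .prevalence import cohort_summary, stratify_by_year
from .records import (
    ClaimsBundle,
    CodeConfig,
    DispensationRecord,
    EnrollmentSpan,
    ServiceRecord,
    read_claims,
)
from .timing import (
    DroppedEpisode,
    PregnancyEpisode,
    build_episode,
    filter_continuous_enrollment,
    write_episode_table,
)


@dataclass
class RunManifest:
    """Reproducibility record: identical inputs and config give an
    identical manifest up to the timestamp."""

    config_hash: str
    seed: int | None
    input_checksums: dict[str, str]
    row_counts: dict[str, int]
    version: str
    timestamp: str

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def _sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: CodeConfig) -> str:
    blob = json.dumps(
        {
            "delivery_codes": config.delivery_codes,
            "caesarean_codes": sorted(map(list, config.caesarean_codes)),
            "termination_codes": sorted(map(list, config.termination_codes)),
            "fertility_atc": sorted(config.fertility_atc),
            "adm_class_map": list(map(list, config.adm_class_map)),
            "cluster_rule": config.cluster_rule,
            "tarmed_triggers_ignore_rule": config.tarmed_triggers_ignore_rule,
            "post_delivery_enrollment_days": config.post_delivery_enrollment_days,
            "ci_method": config.ci_method,
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class PipelineResult:
    events: list[DeliveryEvent]
    episodes: list[PregnancyEpisode]
    dropped: list[DroppedEpisode]
    profiles: list[ExposureProfile]
    assignments: list[GroupAssignment]
    classification: pd.DataFrame
    prevalence_by_year: pd.DataFrame
    summary: pd.DataFrame
    audit: list[AuditEntry]
    manifest: RunManifest = field(default=None)  # type: ignore[assignment]

    @property
    def episode_frame(self) -> pd.DataFrame:
        rows = [
            {
                "episode_id": ep.episode_id,
                "person_id": ep.person_id,
                "delivery_year": ep.delivery_year,
                "caesarean": ep.caesarean,
                "maternal_age": ep.maternal_age_at_delivery,
            }
            for ep in self.episodes
        ]
        return pd.DataFrame(rows)


def run_pipeline(
    services: list[ServiceRecord],
    dispensations: list[DispensationRecord],
    enrollment: list[EnrollmentSpan],
    config: CodeConfig,
    birth_years: dict[str, int] | None = None,
    seed: int | None = None,
    input_checksums: dict[str, str] | None = None,
) -> PipelineResult:
    """Run delivery identification, episode building, enrollment filtering,
    exposure classification, and prevalence estimation over in-memory
    claims tables."""
    birth_years = birth_years or {}
    events, audit = identify_deliveries(services, config)
    episodes_all = [build_episode(ev, birth_years.get(ev.person_id)) for ev in events]
    episodes, dropped = filter_continuous_enrollment(
        episodes_all, enrollment, post_delivery_days=config.post_delivery_enrollment_days
    )
    profiles, assignments, classification = classify_episodes(episodes, dispensations, config)
    if len(classification):
        prevalence = stratify_by_year(classification, method=config.ci_method)
    else:
        prevalence = pd.DataFrame()
    ep_frame = pd.DataFrame(
        [
            {
                "delivery_year": ep.delivery_year,
                "caesarean": ep.caesarean,
                "maternal_age": ep.maternal_age_at_delivery,
            }
            for ep in episodes
        ]
    )
    summary = cohort_summary(ep_frame) if len(ep_frame) else pd.DataFrame()
    manifest = RunManifest(
        config_hash=config_hash(config),
        seed=seed,
        input_checksums=input_checksums or {},
        row_counts={
            "services": len(services),
            "dispensations": len(dispensations),
            "enrollment_spans": len(enrollment),
            "delivery_events": len(events),
            "episodes_kept": len(episodes),
            "episodes_dropped": len(dropped),
        },
        version=pregclaims.__version__,
        timestamp=dt.datetime.now(dt.timezone.utc).isoformat(),
    )
    return PipelineResult(
        events, episodes, dropped, profiles, assignments, classification,
        prevalence, summary, audit, manifest,
    )


def run_pipeline_from_files(
    services_path: str | Path,
    dispensations_path: str | Path,
    enrollment_path: str | Path,
    config: CodeConfig,
    persons_path: str | Path | None = None,
    seed: int | None = None,
) -> tuple[PipelineResult, ClaimsBundle]:
    bundle = read_claims(services_path, dispensations_path, enrollment_path, config)
    birth_years = None
    if persons_path is not None and Path(persons_path).exists():
        persons = pd.read_csv(persons_path)
        birth_years = dict(zip(persons["person_id"], persons["birth_year"].astype(int)))
    checksums = {
        "services": _sha256_file(services_path),
        "dispensations": _sha256_file(dispensations_path),
        "enrollment": _sha256_file(enrollment_path),
    }
    result = run_pipeline(
        bundle.services, bundle.dispensations, bundle.enrollment, config,
        birth_years=birth_years, seed=seed, input_checksums=checksums,
    )
    return result, bundle


def write_results(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_episode_table(result.episodes, outdir / "episodes.csv")
    result.classification.to_csv(outdir / "classification.csv", index=False)
    result.prevalence_by_year.to_csv(outdir / "prevalence_by_year.csv", index=False)
    result.summary.to_csv(outdir / "cohort_summary.csv", index=False)
    write_audit_log(result.audit, outdir / "audit_log.csv")
    dropped_rows = [
        {
            "episode_id": d.episode.episode_id,
            "person_id": d.episode.person_id,
            "delivery_date": d.episode.delivery_date.isoformat(),
            "first_uncovered_day": d.first_uncovered_day.isoformat(),
        }
        for d in result.dropped
    ]
    pd.DataFrame(
        dropped_rows,
        columns=["episode_id", "person_id", "delivery_date", "first_uncovered_day"],
    ).to_csv(outdir / "dropped_episodes.csv", index=False)
    if result.manifest is not None:
        result.manifest.to_json(outdir / "manifest.json")
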