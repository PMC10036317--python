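"""Estimator channels and session quality filtering.

Four estimator groups feed the comparative statistics: the mesh-based
measurement chain (``ai``), simulated expert and non-expert raters, and a
population ``baseline`` that predicts the gender-specific US-average height
and weight for every image regardless of content.  Non-expert sessions pass
through a catch-trial exclusion filter before their estimates are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mesh as meshmod
from .errors import ConfigurationError, AnthrobenchError

GROUPS = ("ai", "expert", "nonexpert", "baseline")


@dataclass(frozen=True)
class PopulationNorms:
    """US adult population averages used by the baseline estimator."""

    us_height_f: float = 161.0
    us_height_m: float = 175.0
    us_weight_f: float = 78.7
    us_weight_m: float = 90.8

    def __post_init__(self):
        for name in ("us_height_f", "us_height_m", "us_weight_f", "us_weight_m"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


@dataclass
class EstimateRecord:
    """One estimator's height/weight guess for one image.

    ``height_est_cm`` / ``weight_est_kg`` may be ``None`` (an estimator may
    decline one attribute); present values must be strictly positive.
    """

    image_id: str
    participant_id: str
    estimator_id: str
    group: str
    height_est_cm: float | None = None
    weight_est_kg: float | None = None

    def __post_init__(self):
        if self.height_est_cm is not None and self.height_est_cm <= 0:
            raise ConfigurationError(f"non-positive height estimate on {self.image_id}")
        if self.weight_est_kg is not None and self.weight_est_kg <= 0:
            raise ConfigurationError(f"non-positive weight estimate on {self.image_id}")


def records_to_df(records) -> pd.DataFrame:
    """Estimate table as a DataFrame (absent estimates become NaN)."""
    return pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "participant_id": r.participant_id,
                "estimator_id": r.estimator_id,
                "group": r.group,
                "height_est_cm": r.height_est_cm,
                "weight_est_kg": r.weight_est_kg,
            }
            for r in records
        ],
        columns=[
            "image_id",
            "participant_id",
            "estimator_id",
            "group",
            "height_est_cm",
            "weight_est_kg",
        ],
    ).astype({"height_est_cm": float, "weight_est_kg": float})


# ---------------------------------------------------------------------------
# Baseline channel


def baseline_estimate(
    gender: str, norms: PopulationNorms | None = None
) -> tuple[float, float]:
    """Gender-specific US-average (height_cm, weight_kg), constant per gender."""
    norms = norms or PopulationNorms()
    if gender == "female":
        return norms.us_height_f, norms.us_weight_f
    if gender == "male":
        return norms.us_height_m, norms.us_weight_m
    raise ConfigurationError(f"unknown gender {gender!r}")


def baseline_channel(images, participants, norms: PopulationNorms | None = None):
    """One baseline record per image, keyed by the participant's true gender."""
    norms = norms or PopulationNorms()
    by_id = {p.participant_id: p for p in participants}
    records = []
    for img in images:
        p = by_id[img.participant_id]
        h, w = baseline_estimate(p.gender, norms)
        records.append(
            EstimateRecord(
                image_id=img.image_id,
                participant_id=p.participant_id,
                estimator_id="baseline",
                group="baseline",
                height_est_cm=h,
                weight_est_kg=w,
            )
        )
    return records


# ---------------------------------------------------------------------------
# AI (mesh measurement) channel


class MeasurementChannelError(AnthrobenchError):
    def __init__(self, image_id: str, cause: Exception):
        super().__init__(f"measurement failed on image {image_id!r}: {cause}")
        self.image_id = image_id
        self.cause = cause


def ai_channel(
    meshes_by_participant: dict,
    images,
    participants,
    constants: meshmod.AnthropometryConstants | None = None,
):
    """Measure each image's mesh with the IPD-scaled chain; group ``ai``.

    ``meshes_by_participant`` maps participant_id to either a single raw
    AnthropometricMesh (reused for all of that participant's images) or a
    mapping image_id -> mesh for per-image fits.
    """
    constants = constants or meshmod.AnthropometryConstants()
    by_id = {p.participant_id: p for p in participants}
    records = []
    for img in images:
        p = by_id[img.participant_id]
        entry = meshes_by_participant[p.participant_id]
        m = entry[img.image_id] if isinstance(entry, dict) else entry
        try:
            bm = meshmod.measure(m, p.gender, constants)
        except AnthrobenchError as exc:
            raise MeasurementChannelError(img.image_id, exc) from exc
        records.append(
            EstimateRecord(
                image_id=img.image_id,
                participant_id=p.participant_id,
                estimator_id="ai",
                group="ai",
                height_est_cm=bm.height_cm,
                weight_est_kg=bm.weight_kg,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Catch-trial exclusion filter


@dataclass
class ExclusionReport:
    total: int = 0
    catch_failed: int = 0
    incomplete: int = 0
    valid: int = 0

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "catch_failed": self.catch_failed,
            "incomplete": self.incomplete,
            "valid": self.valid,
        }


def exclusion_filter(sessions) -> tuple[list, ExclusionReport]:
    """Drop sessions that failed any catch trial or did not finish.

    A session that both failed a catch trial and is incomplete is counted
    once, in the catch-failed bucket, matching the disjoint-bucket
    arithmetic of the study design (e.g. 325 - 65 - 24 = 236).
    """
    report = ExclusionReport(total=len(sessions))
    valid = []
    for s in sessions:
        if len(s.catch_results) != 4:
            raise ConfigurationError(
                f"session {s.rater_id!r} carries {len(s.catch_results)} catch results, expected 4"
            )
        if not all(s.catch_results):
            report.catch_failed += 1
        elif not s.completed:
            report.incomplete += 1
        else:
            valid.append(s)
    report.valid = len(valid)
    return valid, report


def baseline_error_study(
    attribute: str,
    n_cohorts: int = 1000,
    params=None,
    norms: PopulationNorms | None = None,
    seed: int = 0,
) -> float:
    """Expected cohort-level median absolute error of the baseline estimator.

    Draws ``n_cohorts`` cohorts from the gendered normals, applies the
    gender-specific US-average prediction to every member, takes each
    cohort's pooled median absolute error, and returns the mean across
    cohorts — the large-replication expectation of the single-cohort
    statistic (cm for height, kg for weight).
    """
    from .synthetic import CohortParams, generate_cohort  # local: avoids a cycle

    if attribute not in ("height", "weight"):
        raise ConfigurationError("attribute must be 'height' or 'weight'")
    params = params or CohortParams()
    norms = norms or PopulationNorms()
    seeds = np.random.SeedSequence(seed).generate_state(n_cohorts, dtype=np.uint64)
    medians = np.empty(n_cohorts)
    for i, s in enumerate(seeds):
        cohort = generate_cohort(params, seed=int(s & 0x7FFFFFFF))
        errs = []
        for p in cohort:
            h, w = baseline_estimate(p.gender, norms)
            truth = p.true_height_cm if attribute == "height" else p.true_weight_kg
            pred = h if attribute == "height" else w
            errs.append(abs(pred - truth))
        medians[i] = np.median(errs)
    return float(medians.mean())


def sessions_to_records(sessions) -> list:
    """Flatten sessions into one estimate-record list."""
    out = []
    for s in sessions:
        out.extend(s.responses)
    return out
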