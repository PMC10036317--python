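"""Synthetic study generator: cohorts, image designs, body meshes, rating sessions.

Everything the downstream pipeline consumes can be generated here, seeded
and reproducible.  The defaults encode the study conditions: a cohort of 33
women and 25 men with gendered normal height/weight distributions; 14
no-reference studio poses, 1 reference pose and 5 in-the-wild poses per
participant; ~22 non-expert raters per image; sessions of 58 images plus 4
catch trials, with catch failure and non-completion rates whose expected
counts are 65 and 24 out of 325.

The body mesh is a parametric humanoid built as a single surface of
revolution (lathe) of a smooth radius profile — ankles, calves, hips,
waist, shoulders, neck, prolate head — which is watertight by
construction.  It is solved so that, at true scale, the apex-to-sole-plane
distance equals the requested height exactly, the enclosed volume equals
weight / 1023 kg·m⁻³ (Brent root-find on a lateral body-scale factor), and
four eye-corner vertices are placed on the head so the pupil midpoints are
exactly one inter-pupillary distance apart.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .errors import ConfigurationError, GenerationError
from .estimators import EstimateRecord
from .mesh import AnthropometricMesh, AnthropometryConstants, mesh_volume

SETTINGS = ("studio_noref", "studio_ref", "wild")


# ---------------------------------------------------------------------------
# Cohort


@dataclass(frozen=True)
class CohortParams:
    """Gendered normal height/weight distributions and group sizes (cm/kg)."""

    mean_height_f: float = 161.1
    sd_height_f: float = 5.3
    mean_height_m: float = 176.1
    sd_height_m: float = 8.3
    mean_weight_f: float = 60.9
    sd_weight_f: float = 11.4
    mean_weight_m: float = 78.4
    sd_weight_m: float = 12.9
    n_female: int = 33
    n_male: int = 25

    def __post_init__(self):
        for name in (
            "mean_height_f",
            "mean_height_m",
            "mean_weight_f",
            "mean_weight_m",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        for name in ("sd_height_f", "sd_height_m", "sd_weight_f", "sd_weight_m"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.n_female < 0 or self.n_male < 0:
            raise ConfigurationError("cohort counts must be non-negative")


@dataclass(frozen=True)
class Participant:
    participant_id: str
    gender: str  # "female" | "male"
    true_height_cm: float
    true_weight_kg: float

    def __post_init__(self):
        if self.true_height_cm <= 0 or self.true_weight_kg <= 0:
            raise ConfigurationError("true height/weight must be strictly positive")


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws with rejection-resampling of non-positive values."""
    out = rng.normal(mean, sd, n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def generate_cohort(
    params: CohortParams | None = None, seed: int = 0
) -> list[Participant]:
    """Draw a cohort of participants from the gendered normals, reproducibly."""
    params = params or CohortParams()
    rng = np.random.default_rng(seed)
    hf = _positive_normal(rng, params.mean_height_f, params.sd_height_f, params.n_female)
    wf = _positive_normal(rng, params.mean_weight_f, params.sd_weight_f, params.n_female)
    hm = _positive_normal(rng, params.mean_height_m, params.sd_height_m, params.n_male)
    wm = _positive_normal(rng, params.mean_weight_m, params.sd_weight_m, params.n_male)
    cohort = []
    counter = itertools.count(1)
    for h, w in zip(hf, wf):
        cohort.append(Participant(f"P{next(counter):03d}", "female", float(h), float(w)))
    for h, w in zip(hm, wm):
        cohort.append(Participant(f"P{next(counter):03d}", "male", float(h), float(w)))
    return cohort


def cohort_to_df(cohort) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in cohort],
            "gender": [p.gender for p in cohort],
            "height_cm": [p.true_height_cm for p in cohort],
            "weight_kg": [p.true_weight_kg for p in cohort],
        }
    )


def cohort_from_df(df: pd.DataFrame) -> list[Participant]:
    return [
        Participant(str(r.participant_id), str(r.gender), float(r.height_cm), float(r.weight_kg))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Study design


@dataclass(frozen=True)
class StudyDesign:
    """Per-participant pose counts for the three capture settings."""

    studio_neutral: int = 8
    studio_dynamic: int = 6
    studio_reference: int = 1
    wild_static: int = 2
    wild_dynamic: int = 3

    def __post_init__(self):
        for name in (
            "studio_neutral",
            "studio_dynamic",
            "studio_reference",
            "wild_static",
            "wild_dynamic",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ImageRecord:
    image_id: str
    participant_id: str
    setting: str  # one of SETTINGS
    pose_class: str


_POSE_PLAN = (
    # (pose_class, setting, design attribute)
    ("studio_neutral", "studio_noref", "studio_neutral"),
    ("studio_dynamic", "studio_noref", "studio_dynamic"),
    ("studio_reference", "studio_ref", "studio_reference"),
    ("wild_static", "wild", "wild_static"),
    ("wild_dynamic", "wild", "wild_dynamic"),
)


def generate_design(
    participants, design: StudyDesign | None = None
) -> list[ImageRecord]:
    """Deterministically enumerate the image list implied by the design."""
    design = design or StudyDesign()
    images = []
    for p in participants:
        for pose_class, setting, attr in _POSE_PLAN:
            for k in range(getattr(design, attr)):
                images.append(
                    ImageRecord(
                        image_id=f"{p.participant_id}_{pose_class}_{k + 1:02d}",
                        participant_id=p.participant_id,
                        setting=setting,
                        pose_class=pose_class,
                    )
                )
    return images


def design_to_df(images) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "image_id": [i.image_id for i in images],
            "participant_id": [i.participant_id for i in images],
            "setting": [i.setting for i in images],
            "pose_class": [i.pose_class for i in images],
        }
    )


# ---------------------------------------------------------------------------
# Parametric body mesh

# Radius profile control points as fractions of total height: a smooth,
# vaguely human silhouette.  Only ratios matter; the lateral body scale is
# solved per mesh to hit the volume target.
_PROFILE_Z = np.array(
    [0.00, 0.04, 0.12, 0.25, 0.40, 0.52, 0.60, 0.72, 0.80, 0.850, 0.870, 0.900, 0.9333, 0.970, 0.990, 1.00]
)
_PROFILE_R = np.array(
    [0.050, 0.052, 0.062, 0.058, 0.075, 0.095, 0.082, 0.092, 0.098, 0.038, 0.032, 0.040, 0.0460, 0.036, 0.018, 0.00]
)
#: fraction of height where the head region begins; radii below are scaled
#: by the volume-solve factor, radii above (the head) stay fixed so the eye
#: landmark geometry is independent of body girth.
_HEAD_START = 0.865
#: eye ring height as a fraction of total height (widest part of the head).
_EYE_LEVEL = 0.9333
#: eye width (inner-to-outer corner, as a fraction of the IPD).
_EYE_WIDTH_FRAC = 0.6

_MIN_RESOLUTION = 16


def _build_lathe(
    radii_cm: np.ndarray,
    z_cm: np.ndarray,
    azimuths: np.ndarray,
    eye_ring: int,
    eye_azimuths: np.ndarray,
    eye_slots: np.ndarray,
    height_cm: float,
):
    """Vertices/faces of the closed lathe solid; returns landmark indices too.

    Ring k lives at ``z_cm[k]`` with radius ``radii_cm[k]``; a flat fan caps
    the sole at z=0 and an apex pole closes the top at z=height.  Azimuth phi
    is measured from +y (the face direction) toward +x (the model's left):
    vertex = (r sin phi, r cos phi, z).
    """
    n_az = len(azimuths)
    n_rings = len(z_cm)
    verts = [np.zeros(3)]  # sole centre
    ring_start = np.empty(n_rings, dtype=int)
    for k in range(n_rings):
        phi = azimuths.copy()
        if k == eye_ring:
            phi[eye_slots] = eye_azimuths
        ring_start[k] = len(verts)
        x = radii_cm[k] * np.sin(phi)
        y = radii_cm[k] * np.cos(phi)
        verts.extend(np.column_stack([x, y, np.full(n_az, z_cm[k])]))
    apex = len(verts)
    verts.append(np.array([0.0, 0.0, height_cm]))
    vertices = np.asarray(verts)

    faces = []
    j = np.arange(n_az)
    jn = (j + 1) % n_az
    # sole cap, outward normal -z
    faces.append(np.column_stack([np.zeros(n_az, dtype=int), ring_start[0] + jn, ring_start[0] + j]))
    # side wall
    for k in range(n_rings - 1):
        a = ring_start[k] + j
        b = ring_start[k] + jn
        c = ring_start[k + 1] + jn
        d = ring_start[k + 1] + j
        faces.append(np.column_stack([a, b, c]))
        faces.append(np.column_stack([a, c, d]))
    # apex fan
    last = ring_start[-1]
    faces.append(np.column_stack([last + j, last + jn, np.full(n_az, apex, dtype=int)]))
    # phi runs clockwise seen from +z, so flip winding for outward orientation
    return vertices, np.concatenate(faces)[:, [0, 2, 1]], ring_start, apex


def generate_body_mesh(
    height_cm: float,
    weight_kg: float,
    gender: str,
    resolution: int = 48,
    seed: int = 0,
    ipd_jitter_sd: float = 0.0,
    shape_jitter: float = 0.0,
    constants: AnthropometryConstants | None = None,
    raw_units_per_cm: float = 0.01,
) -> AnthropometricMesh:
    """Generate a watertight humanoid mesh hitting height/volume/IPD targets.

    At true scale the mesh satisfies: apex-to-sole-plane distance ==
    ``height_cm``; enclosed volume == ``weight_kg`` / 1023 kg·m⁻³ (to the
    root-finder tolerance, ~1e-9 relative); pupil-midpoint distance ==
    the gender-average IPD plus an optional per-individual jitter
    ``~ Normal(0, ipd_jitter_sd)``.  The mesh is emitted in arbitrary raw
    units (``raw_units_per_cm`` cm⁻¹, default 1 unit = 1 m) with the true
    scale recorded in ``true_cm_per_unit``.  With ``ipd_jitter_sd`` and
    ``shape_jitter`` at zero, the output is independent of ``seed``.
    """
    constants = constants or AnthropometryConstants()
    if height_cm <= 0 or weight_kg <= 0:
        raise ConfigurationError("height_cm and weight_kg must be strictly positive")
    if resolution < _MIN_RESOLUTION:
        raise ConfigurationError(
            f"resolution must be >= {_MIN_RESOLUTION} for a watertight mesh with eye landmarks"
        )
    rng = np.random.default_rng(seed)

    profile_r = _PROFILE_R.copy()
    if shape_jitter > 0:
        jitter = rng.normal(1.0, shape_jitter, len(profile_r) - 1)
        profile_r[:-1] = profile_r[:-1] * np.clip(jitter, 0.5, 1.5)

    ipd = constants.ipd_mean(gender)
    if ipd_jitter_sd > 0:
        ipd = ipd + rng.normal(0.0, ipd_jitter_sd)
        while ipd <= 2.0:  # reject anatomically impossible draws
            ipd = constants.ipd_mean(gender) + rng.normal(0.0, ipd_jitter_sd)

    profile = PchipInterpolator(_PROFILE_Z * height_cm, profile_r * height_cm)

    # ring heights: uniform, with a ring exactly at eye level and none at the apex
    n_rings = max(2 * resolution // 3, 24)
    z = np.linspace(0.0, height_cm, n_rings + 1)[:-1]
    z_eye = _EYE_LEVEL * height_cm
    z = z[np.abs(z - z_eye) > height_cm / (4 * n_rings)]
    z = np.sort(np.append(z, z_eye))
    eye_ring = int(np.searchsorted(z, z_eye))
    base_radii = profile(z)

    # eye-corner azimuths on the eye ring so pupil midpoints are IPD apart
    r_eye = float(base_radii[eye_ring])
    half_w = 0.5 * _EYE_WIDTH_FRAC * ipd
    sin_outer = (ipd / 2 + half_w) / r_eye
    if sin_outer > 0.95:
        raise GenerationError(
            f"height_cm={height_cm}: head too narrow for IPD {ipd:.2f} cm eye landmarks"
        )
    phi_inner = float(np.arcsin((ipd / 2 - half_w) / r_eye))
    phi_outer = float(np.arcsin(sin_outer))
    n_az = int(resolution)
    step = 2 * np.pi / n_az
    azimuths = step * np.arange(n_az)
    # left eye at +x (phi > 0), right eye mirrored across the sagittal plane;
    # snap the nearest free grid slots (never slot 0, the front midline) so
    # ring azimuths stay strictly increasing
    s_inner = max(1, round(phi_inner / step))
    s_outer = max(s_inner + 1, round(phi_outer / step))
    if s_outer >= n_az // 2:
        raise GenerationError("resolution too coarse to place distinct eye-corner vertices")
    targets = np.array([phi_inner, phi_outer, 2 * np.pi - phi_inner, 2 * np.pi - phi_outer])
    slots = np.array([s_inner, s_outer, n_az - s_inner, n_az - s_outer])

    # solve the lateral body-scale factor c so enclosed volume hits target
    target_cm3 = weight_kg / constants.body_density * 1e6
    body = z < _HEAD_START * height_cm

    def volume_at(c: float) -> float:
        radii = base_radii.copy()
        radii[body] *= c
        v, f, _, _ = _build_lathe(radii, z, azimuths, eye_ring, targets, slots, height_cm)
        return mesh_volume((v, f))

    c_lo, c_hi = 1e-3, 60.0
    v_lo, v_hi = volume_at(c_lo), volume_at(c_hi)
    if target_cm3 <= v_lo:
        raise GenerationError(
            f"weight_kg={weight_kg} infeasible at height_cm={height_cm}: "
            f"target volume {target_cm3:.1f} cm^3 below the template minimum {v_lo:.1f} cm^3"
        )
    if target_cm3 >= v_hi:
        raise GenerationError(
            f"weight_kg={weight_kg} infeasible at height_cm={height_cm}: "
            f"target volume exceeds the template maximum"
        )
    c = brentq(lambda x: volume_at(x) - target_cm3, c_lo, c_hi, xtol=1e-12, rtol=1e-15)

    radii = base_radii.copy()
    radii[body] *= c
    verts, faces, ring_start, apex = _build_lathe(
        radii, z, azimuths, eye_ring, targets, slots, height_cm
    )

    n_az_third = n_az // 3
    landmarks = {
        "left_eye_inner": int(ring_start[eye_ring] + slots[0]),
        "left_eye_outer": int(ring_start[eye_ring] + slots[1]),
        "right_eye_inner": int(ring_start[eye_ring] + slots[2]),
        "right_eye_outer": int(ring_start[eye_ring] + slots[3]),
        "head_apex": int(apex),
        "foot_a": int(ring_start[0] + 0),
        "foot_b": int(ring_start[0] + n_az_third),
        "foot_c": int(ring_start[0] + 2 * n_az_third),
    }
    return AnthropometricMesh(
        vertices=verts * raw_units_per_cm,
        faces=faces,
        landmarks=landmarks,
        units="raw",
        true_cm_per_unit=1.0 / raw_units_per_cm,
    )


# ---------------------------------------------------------------------------
# Rating sessions


@dataclass(frozen=True)
class RaterModel:
    """Additive (or lognormal-multiplicative) noise model for simulated raters."""

    group: str = "nonexpert"  # "expert" | "nonexpert"
    height_bias_cm: float = 0.0
    height_sd_cm: float = 7.0
    weight_bias_kg: float = 0.0
    weight_sd_kg: float = 11.0
    raters_per_image: int = 22
    noise_model: str = "additive"  # "additive" | "lognormal"

    def __post_init__(self):
        if self.height_sd_cm < 0 or self.weight_sd_kg < 0:
            raise ConfigurationError("rater SDs must be non-negative")
        if self.raters_per_image < 1:
            raise ConfigurationError("raters_per_image must be >= 1")
        if self.noise_model not in ("additive", "lognormal"):
            raise ConfigurationError(f"unknown noise_model {self.noise_model!r}")

    def draw(self, truth: float, bias: float, sd: float, rng: np.random.Generator) -> float:
        if self.noise_model == "additive":
            est = truth + bias + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        else:  # multiplicative: sd interpreted relative to the truth
            rel = sd / truth if truth > 0 else 0.0
            est = (truth + bias) * (np.exp(rng.normal(0.0, rel)) if rel > 0 else 1.0)
        return float(max(est, 1.0))


@dataclass
class Session:
    """One rater's pass through a 58-image set plus 4 catch trials."""

    rater_id: str
    group: str
    responses: list = field(default_factory=list)
    catch_results: tuple = (True, True, True, True)
    completed: bool = True

    def __post_init__(self):
        if len(self.catch_results) != 4:
            raise ConfigurationError("a session carries exactly 4 catch results")


def partition_image_sets(images, participants, seed: int = 0, max_sets_per_setting: int = 5):
    """Partition images into rating sets, one image per participant per set.

    Mirrors the study design: per setting, each participant contributes one
    image to each of up to ``max_sets_per_setting`` sets (the no-reference
    studio pool is subsampled; the single reference image forms one set).
    """
    rng = np.random.default_rng(seed)
    pids = [p.participant_id for p in participants]
    sets = []
    for setting in SETTINGS:
        per_pid = {pid: [] for pid in pids}
        for img in images:
            if img.setting == setting and img.participant_id in per_pid:
                per_pid[img.participant_id].append(img)
        counts = [len(v) for v in per_pid.values()]
        if not counts or min(counts) == 0:
            continue
        n_sets = min(min(counts), max_sets_per_setting)
        for pid in pids:
            pool = per_pid[pid]
            idx = rng.permutation(len(pool))[:n_sets]
            per_pid[pid] = [pool[i] for i in idx]
        for k in range(n_sets):
            sets.append([per_pid[pid][k] for pid in pids])
    return sets


def simulate_sessions(
    images,
    participants,
    rater_model: RaterModel | None = None,
    n_raters: int = 325,
    seed: int = 0,
    catch_fail_prob: float = 65 / 325,
    incomplete_prob: float = 24 / 325,
    deterministic_counts: tuple[int, int] | None = None,
    rater_prefix: str = "NE",
) -> list[Session]:
    """Simulate rating sessions: truth + bias + noise per the rater model.

    Each session draws a random image set (58 images for the default design)
    and 4 catch trials.  Catch failure and non-completion are stochastic by
    default; ``deterministic_counts=(n_catch_failed, n_incomplete)`` instead
    flags exactly those numbers of sessions (disjointly), reproducing the
    study's 325 - 65 - 24 = 236 arithmetic exactly.
    """
    if n_raters < 1:
        raise ConfigurationError("n_raters must be >= 1")
    rater_model = rater_model or RaterModel()
    rng = np.random.default_rng(seed)
    truth = {p.participant_id: p for p in participants}
    for img in images:
        if img.participant_id not in truth:
            raise ConfigurationError(f"image {img.image_id} references unknown participant")
    sets = partition_image_sets(images, participants, seed=int(rng.integers(2**31)))
    if not sets:
        raise ConfigurationError("no image sets could be formed from the provided images")

    if deterministic_counts is not None:
        n_fail, n_inc = deterministic_counts
        if n_fail + n_inc > n_raters:
            raise ConfigurationError("deterministic exclusion counts exceed n_raters")

    sessions = []
    for i in range(n_raters):
        image_set = sets[int(rng.integers(len(sets)))]
        if deterministic_counts is not None:
            failed = i < n_fail
            incomplete = (not failed) and i < n_fail + n_inc
        else:
            failed = bool(rng.random() < catch_fail_prob)
            incomplete = bool(rng.random() < incomplete_prob)
        if failed:
            catch = [True] * 4
            catch[int(rng.integers(4))] = False
            catch = tuple(catch)
        else:
            catch = (True, True, True, True)
        rater_id = f"{rater_prefix}{i + 1:04d}"
        n_resp = int(rng.integers(1, len(image_set))) if incomplete else len(image_set)
        responses = []
        for img in image_set[:n_resp]:
            p = truth[img.participant_id]
            responses.append(
                EstimateRecord(
                    image_id=img.image_id,
                    participant_id=img.participant_id,
                    estimator_id=rater_id,
                    group=rater_model.group,
                    height_est_cm=rater_model.draw(
                        p.true_height_cm, rater_model.height_bias_cm, rater_model.height_sd_cm, rng
                    ),
                    weight_est_kg=rater_model.draw(
                        p.true_weight_kg, rater_model.weight_bias_kg, rater_model.weight_sd_kg, rng
                    ),
                )
            )
        sessions.append(
            Session(
                rater_id=rater_id,
                group=rater_model.group,
                responses=responses,
                catch_results=catch,
                completed=not incomplete,
            )
        )
    return sessions


def simulate_expert_estimates(
    images,
    participants,
    rater_model: RaterModel | None = None,
    n_experts: int = 10,
    images_per_expert: int = 5,
    seed: int = 0,
    decline_weight_expert: bool = True,
) -> list[EstimateRecord]:
    """Simulate the expert panel: each expert rates a few wild images.

    Experts receive disjoint random subsets of distinct-participant images;
    optionally one expert declines to estimate weight (absent values).
    """
    rater_model = rater_model or RaterModel(
        group="expert", height_sd_cm=5.0, weight_sd_kg=9.0, raters_per_image=1
    )
    rng = np.random.default_rng(seed)
    truth = {p.participant_id: p for p in participants}
    wild = [img for img in images if img.setting == "wild"]
    # one image per participant, shuffled, dealt to experts in blocks
    per_pid: dict[str, list] = {}
    for img in wild:
        per_pid.setdefault(img.participant_id, []).append(img)
    chosen = [pool[int(rng.integers(len(pool)))] for pool in per_pid.values()]
    order = rng.permutation(len(chosen))
    chosen = [chosen[i] for i in order]
    decliner = int(rng.integers(n_experts)) if decline_weight_expert and n_experts else -1
    records = []
    for e in range(n_experts):
        block = chosen[e * images_per_expert : (e + 1) * images_per_expert]
        expert_id = f"EX{e + 1:02d}"
        for img in block:
            p = truth[img.participant_id]
            records.append(
                EstimateRecord(
                    image_id=img.image_id,
                    participant_id=img.participant_id,
                    estimator_id=expert_id,
                    group="expert",
                    height_est_cm=rater_model.draw(
                        p.true_height_cm, rater_model.height_bias_cm, rater_model.height_sd_cm, rng
                    ),
                    weight_est_kg=None
                    if e == decliner
                    else rater_model.draw(
                        p.true_weight_kg, rater_model.weight_bias_kg, rater_model.weight_sd_kg, rng
                    ),
                )
            )
    return records
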