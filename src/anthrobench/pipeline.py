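"""End-to-end orchestration: simulate -> measure -> analyze -> report.

A single master seed drives every stochastic stage through a documented
splitting scheme (``numpy.random.SeedSequence(master).generate_state``), so
re-running a configuration reproduces byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .estimators import (
    PopulationNorms,
    ai_channel,
    baseline_channel,
    exclusion_filter,
    records_to_df,
    sessions_to_records,
)
from .mesh import AnthropometryConstants
from .stats import (
    ATTRIBUTES,
    bonferroni_threshold,
    crowd_accuracy,
    error_matrix,
    friedman,
    individual_accuracy,
    pairwise_to_df,
    pairwise_wilcoxon,
    summaries_to_df,
    summarize,
)
from .synthetic import (
    CohortParams,
    RaterModel,
    StudyDesign,
    cohort_to_df,
    design_to_df,
    generate_body_mesh,
    generate_cohort,
    generate_design,
    simulate_expert_estimates,
    simulate_sessions,
)

#: analysis groups in reporting order (crowd/individual both derive from the
#: non-expert sessions)
ANALYSIS_GROUPS = ("ai", "expert", "crowd", "individual", "baseline")


@dataclass
class RunConfig:
    seed: int = 0
    cohort: CohortParams = field(default_factory=CohortParams)
    design: StudyDesign = field(default_factory=StudyDesign)
    nonexpert: RaterModel = field(default_factory=RaterModel)
    expert: RaterModel = field(
        default_factory=lambda: RaterModel(
            group="expert", height_sd_cm=5.0, weight_sd_kg=9.0, raters_per_image=1
        )
    )
    norms: PopulationNorms = field(default_factory=PopulationNorms)
    constants: AnthropometryConstants = field(default_factory=AnthropometryConstants)
    n_boot: int = 1000
    alpha: float = 0.05
    n_raters: int = 325
    #: (catch_failed, incomplete) flagged deterministically; None for stochastic
    deterministic_exclusions: tuple[int, int] | None = (65, 24)
    n_experts: int = 10
    images_per_expert: int = 5
    mesh_resolution: int = 48
    #: apply per-participant anatomical IPD jitter (gendered SDs) to meshes
    ipd_jitter: bool = True
    write_meshes: bool = False
    out_dir: str = "anthrobench_out"

    def __post_init__(self):
        if self.n_boot < 1:
            raise ConfigurationError("n_boot must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (
            ("cohort", CohortParams),
            ("design", StudyDesign),
            ("nonexpert", RaterModel),
            ("expert", RaterModel),
            ("norms", PopulationNorms),
            ("constants", AnthropometryConstants),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "deterministic_exclusions" in d and d["deterministic_exclusions"] is not None:
            d["deterministic_exclusions"] = tuple(d["deterministic_exclusions"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)


def stage_seeds(master: int, n: int = 12) -> list[int]:
    """Derive per-stage integer seeds (< 2^31) from one master seed."""
    state = np.random.SeedSequence(master).generate_state(n, dtype=np.uint64)
    return [int(s & 0x7FFFFFFF) for s in state]


# ---------------------------------------------------------------------------
# Analysis (reusable without the simulation stages)


def analyze(
    records,
    cohort,
    images,
    n_boot: int = 1000,
    alpha: float = 0.05,
    boot_seed: int = 0,
):
    """Error samples, summaries, and omnibus/pairwise tests for all groups.

    ``records`` is the flat estimate table (all groups).  The non-expert
    group contributes two analysis channels: ``crowd`` (error of the median
    estimate per image) and ``individual`` (median per-rater error per
    image); single-estimate groups use the same per-image statistic for
    both readings.  Omnibus and pairwise tests run on the in-the-wild
    complete-case matrix, the setting every group covers.
    """
    setting_of = {img.image_id: img.setting for img in images}
    settings = sorted({img.setting for img in images})
    by_group: dict[str, list] = {}
    for r in records:
        by_group.setdefault(r.group, []).append(r)

    def subset(recs, setting):
        return [r for r in recs if setting_of.get(r.image_id) == setting]

    samples = {}  # (group, attribute, setting) -> ErrorSample
    for setting in settings:
        for attribute in ATTRIBUTES:
            for group in ANALYSIS_GROUPS:
                source = {"crowd": "nonexpert", "individual": "nonexpert"}.get(group, group)
                recs = subset(by_group.get(source, []), setting)
                if not recs:
                    continue
                if group == "individual":
                    sample = individual_accuracy(
                        recs, cohort, attribute, group=group, setting=setting
                    )
                else:
                    sample = crowd_accuracy(recs, cohort, attribute, group=group, setting=setting)
                if not sample.data.empty:
                    samples[(group, attribute, setting)] = sample

    seeds = iter(stage_seeds(boot_seed, n=max(1, len(samples)) + 4))
    summaries = [
        summarize(s, n_boot=n_boot, seed=next(seeds))
        for s in (samples[k] for k in sorted(samples))
    ]

    friedman_results = {}
    pairwise_results = {}
    wild = "wild" if "wild" in settings else settings[-1]
    for attribute in ATTRIBUTES:
        cells = {
            g: samples[(g, attribute, wild)]
            for g in ANALYSIS_GROUPS
            if (g, attribute, wild) in samples
        }
        if len(cells) < 2:
            continue
        matrix = error_matrix(cells)
        friedman_results[attribute] = friedman(matrix)
        pairwise_results[attribute] = pairwise_wilcoxon(matrix, attribute=attribute, alpha=alpha)
    return samples, summaries, friedman_results, pairwise_results


# ---------------------------------------------------------------------------
# Reporting


def _stars(r) -> str:
    if r.significant_0005:
        return "**"
    if r.significant_005:
        return "*"
    return ""


def render_report(summaries, friedman_results=None, pairwise_results=None) -> str:
    """Markdown report: median-error table plus pairwise-significance matrices."""
    if not summaries:
        raise ConfigurationError("render_report needs at least one summary")
    lines = ["# Height/weight estimation error report", ""]
    lines.append("## Median errors (absolute and % of true value, 95% CI of the median)")
    lines.append("")
    lines.append("| group | setting | attribute | median abs | 95% CI | median % | n images |")
    lines.append("|---|---|---|---|---|---|---|")
    for s in summaries:
        unit = "cm" if s.attribute == "height" else "kg"
        lines.append(
            f"| {s.group} | {s.setting} | {s.attribute} | {s.median_abs:.2f} {unit} "
            f"| [{s.ci_low:.2f}, {s.ci_high:.2f}] | {s.median_pct:.2f}% | {s.n_images} |"
        )
    lines.append("")
    if friedman_results:
        lines.append("## Friedman omnibus tests (in-the-wild complete case)")
        lines.append("")
        for attr, fr in friedman_results.items():
            lines.append(
                f"- {attr}: chi2 = {fr.statistic:.3f}, k = {fr.k_groups}, "
                f"n = {fr.n_images} images, p = {fr.p_value:.3g}"
            )
        lines.append("")
    if pairwise_results:
        for attr, results in pairwise_results.items():
            if not results:
                continue
            thr = results[0].corrected_alpha
            lines.append(
                f"## Pairwise Wilcoxon, {attr} "
                f"(`*` p < {thr:g}, `**` p < {thr / 10:g}, Bonferroni-corrected)"
            )
            lines.append("")
            groups = []
            for r in results:
                for g in (r.group_a, r.group_b):
                    if g not in groups:
                        groups.append(g)
            cell = {(r.group_a, r.group_b): r for r in results}
            lines.append("| vs | " + " | ".join(groups[1:]) + " |")
            lines.append("|---|" + "---|" * (len(groups) - 1))
            for i, ga in enumerate(groups[:-1]):
                row = [ga]
                for gb in groups[1:]:
                    r = cell.get((ga, gb))
                    row.append("" if r is None else f"{_stars(r)} p={r.p_value:.3g}")
                lines.append("| " + " | ".join(row) + " |")
            lines.append("")
    return "\n".join(lines)


def plot_error_distributions(samples, attribute: str, path: str | Path) -> None:
    """Optional per-group error histogram figure (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = {k[0]: v for k, v in samples.items() if k[1] == attribute}
    fig, ax = plt.subplots(figsize=(7, 4))
    for group, sample in cells.items():
        ax.hist(sample.data["abs_error"], bins=30, alpha=0.5, label=group, density=True)
    ax.set_xlabel(f"absolute {attribute} error")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Full pipeline


def _log(verbose: bool, msg: str) -> None:
    if verbose:
        print(msg, file=sys.stderr)


def run_pipeline(config: RunConfig, verbose: bool = False) -> dict:
    """Run simulate -> measure -> analyze -> report; return the manifest.

    Writes cohort/design/estimate CSVs, summary and test tables, a Markdown
    report, and a manifest (config echo, versions, seed, SHA-256 of every
    output) into ``config.out_dir``.  Byte-identical on re-run with the
    same config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)

    _log(verbose, "stage 1/5: cohort + design")
    cohort = generate_cohort(config.cohort, seed=seeds[0])
    images = generate_design(cohort, config.design)

    _log(verbose, f"stage 2/5: body meshes for {len(cohort)} participants")
    mesh_seeds = stage_seeds(seeds[1], n=max(1, len(cohort)))
    meshes = {}
    for p, ms in zip(cohort, mesh_seeds):
        jitter = config.constants.ipd_sd(p.gender) if config.ipd_jitter else 0.0
        meshes[p.participant_id] = generate_body_mesh(
            p.true_height_cm,
            p.true_weight_kg,
            p.gender,
            resolution=config.mesh_resolution,
            seed=ms,
            ipd_jitter_sd=jitter,
            constants=config.constants,
        )
    if config.write_meshes:
        mesh_dir = out / "meshes"
        mesh_dir.mkdir(exist_ok=True)
        for pid, m in meshes.items():
            m.save(mesh_dir / f"{pid}.obj")

    _log(verbose, "stage 3/5: estimator channels")
    records = []
    records += ai_channel(meshes, images, cohort, config.constants)
    records += baseline_channel(images, cohort, config.norms)
    sessions = simulate_sessions(
        images,
        cohort,
        config.nonexpert,
        n_raters=config.n_raters,
        seed=seeds[2],
        deterministic_counts=config.deterministic_exclusions,
    )
    valid, report = exclusion_filter(sessions)
    records += sessions_to_records(valid)
    records += simulate_expert_estimates(
        images,
        cohort,
        config.expert,
        n_experts=config.n_experts,
        images_per_expert=config.images_per_expert,
        seed=seeds[3],
    )

    _log(verbose, f"stage 4/5: statistics ({len(records)} estimates)")
    samples, summaries, friedman_results, pairwise_results = analyze(
        records, cohort, images, n_boot=config.n_boot, alpha=config.alpha, boot_seed=seeds[4]
    )

    _log(verbose, "stage 5/5: writing outputs")
    files = {}

    def write_csv(name: str, df: pd.DataFrame):
        path = out / name
        df.to_csv(path, index=False)
        files[name] = path

    write_csv("cohort.csv", cohort_to_df(cohort))
    write_csv("design.csv", design_to_df(images))
    write_csv("estimates.csv", records_to_df(records))
    write_csv("summaries.csv", summaries_to_df(summaries))
    write_csv(
        "friedman.csv",
        pd.DataFrame(
            [
                {
                    "attribute": attr,
                    "statistic": fr.statistic,
                    "p_value": fr.p_value,
                    "n_images": fr.n_images,
                    "k_groups": fr.k_groups,
                    "dropped_images": fr.dropped_images,
                }
                for attr, fr in friedman_results.items()
            ]
        ),
    )
    write_csv(
        "pairwise.csv",
        pd.concat(
            [pairwise_to_df(r) for r in pairwise_results.values()],
            ignore_index=True,
        )
        if pairwise_results
        else pd.DataFrame(),
    )
    report_md = render_report(summaries, friedman_results, pairwise_results)
    (out / "report.md").write_text(report_md)
    files["report.md"] = out / "report.md"

    manifest = {
        "package": "anthrobench",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "session_filter": report.as_dict(),
        "corrected_alpha": bonferroni_threshold(config.alpha, len(ANALYSIS_GROUPS)),
        "outputs": {
            name: hashlib.sha256(path.read_bytes()).hexdigest() for name, path in files.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
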