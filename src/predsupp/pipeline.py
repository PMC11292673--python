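"""End-to-end orchestration: simulate -> first level -> group analyses -> report.

A single global seed deterministically spawns independent substreams per
stage and subject, so a config + seed pair reproduces every output bit for
bit, down to the posterior draws.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .design import DesignParams, assign_block_conditions, generate_experiment
from .glm import fit_first_level
from .paths import compare_path_models, make_specs, prepare_path_data
from .sdt import SDTModel
from .second_level import SecondLevelModel
from .simulate import GroundTruth, default_ground_truth, simulate_behavior, simulate_experiment_bold

log = logging.getLogger("predsupp")


@dataclass
class SamplerSettings:
    chains: int = 6
    iters: int = 2000
    warmup: int = 1000
    max_treedepth: int = 10


@dataclass
class PipelineConfig:
    """Fully serializable run configuration."""

    seed: int = 0
    n_subjects: int = 10
    out_dir: str = "predsupp_out"
    design: dict = field(default_factory=dict)       # DesignParams overrides
    truth: dict = field(default_factory=dict)        # GroundTruth overrides
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    granularity: str = "run"
    condition_sets: tuple[str, ...] = ("oddball",)
    run_sdt: bool = True
    run_paths: bool = True
    ar1_correction: bool = True
    write_raw: bool = False

    def design_params(self) -> DesignParams:
        return DesignParams(**self.design)

    def ground_truth(self) -> GroundTruth:
        over = dict(self.truth)
        if "amplitudes" in over:
            over["amplitudes"] = pd.DataFrame(over["amplitudes"]).T
        return default_ground_truth(**over)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["condition_sets"] = list(self.condition_sets)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sampler" in d and isinstance(d["sampler"], dict):
            d["sampler"] = SamplerSettings(**d["sampler"])
        if "condition_sets" in d:
            d["condition_sets"] = tuple(d["condition_sets"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)


def _stage_seed(master: int, label: str) -> int:
    # stable across processes, unlike the built-in string hash
    import zlib

    h = np.random.SeedSequence([master, zlib.crc32(label.encode())])
    return int(h.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.design_params()
    truth = config.ground_truth()
    report: dict = {"config": config.to_dict(), "stages": {}, "warnings": []}
    timings: dict[str, float] = {}

    def timed(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                log.info("stage %s started", name)
                return self_

            def __exit__(self_, *exc):
                timings[name] = round(time.perf_counter() - self_.t0, 3)
                log.info("stage %s finished in %.1fs", name, timings[name])

        return _T()

    # --- simulate designs and BOLD, fit first level per subject -------------
    estimates_frames = []
    behavior_frames = []
    with timed("simulate_and_first_level"):
        for s in range(config.n_subjects):
            seed_s = _stage_seed(config.seed, f"subject-{s}")
            design = generate_experiment(seed_s, params)
            design = assign_block_conditions(design, _stage_seed(seed_s, "blocks"))
            bold, nuis = simulate_experiment_bold(
                design, truth, _stage_seed(seed_s, "bold")
            )
            if config.write_raw:
                sub_dir = out / f"sub-{s:02d}"
                pio.write_events(design, sub_dir)
                pio.write_bold(bold, sub_dir)
                pio.write_bold(nuis, sub_dir, prefix="nuisance")
            for cset in config.condition_sets:
                est = fit_first_level(
                    design, bold, nuis, condition_set=cset,
                    ar1_correction=config.ar1_correction, subject=s,
                )
                est.insert(0, "condition_set", cset)
                estimates_frames.append(est)
            if config.run_sdt:
                beh = simulate_behavior(
                    design, truth, 1, _stage_seed(seed_s, "behavior")
                )
                beh["subject"] = s
                behavior_frames.append(beh)
    estimates = pd.concat(estimates_frames, ignore_index=True)
    estimates.to_csv(out / "estimates.csv", index=False)
    report["stages"]["first_level"] = {"rows": int(len(estimates))}

    sampler = config.sampler

    # --- second level -------------------------------------------------------
    grans = (
        ("run", "pooled") if config.granularity == "both" else (config.granularity,)
    )
    for cset in config.condition_sets:
        for gran in grans:
            label = (f"second_level_{cset}" if len(grans) == 1
                     else f"second_level_{cset}_{gran}")
            with timed(label):
                sub = estimates[estimates["condition_set"] == cset]
                model = SecondLevelModel(sub, condition_set=cset, granularity=gran)
                res = model.fit(
                    seed=_stage_seed(config.seed, f"second-{cset}-{gran}"),
                    chains=sampler.chains, iters=sampler.iters,
                    warmup=sampler.warmup, max_treedepth=sampler.max_treedepth,
                )
                contrasts = res.contrasts()
                suffix = cset if len(grans) == 1 else f"{cset}_{gran}"
                contrasts.to_json(out / f"contrasts_{suffix}.json",
                                  orient="records", indent=2)
                report["stages"][label] = {
                    "contrasts": json.loads(contrasts.to_json(orient="records")),
                }
                report["warnings"] += [f"{label}: {w}" for w in res.draws.warnings]
                if len(model.rois) > 1:
                    corr = res.roi_correlations()
                    corr.to_json(out / f"correlations_{suffix}.json",
                                 orient="records", indent=2)
                    report["stages"][label]["correlations"] = (
                        json.loads(corr.to_json(orient="records"))
                    )

    # --- behavior / SDT -----------------------------------------------------
    if config.run_sdt:
        with timed("sdt"):
            behavior = pd.concat(behavior_frames, ignore_index=True)
            behavior.to_csv(out / "behavior.csv", index=False)
            sdt_model = SDTModel(behavior)
            sdt_res = sdt_model.fit(
                seed=_stage_seed(config.seed, "sdt"),
                chains=sampler.chains, iters=sampler.iters,
                warmup=sampler.warmup, max_treedepth=sampler.max_treedepth,
            )
            sdt_summary = {
                "group": sdt_res.group_summary().as_dict(),
                "subjects": json.loads(
                    sdt_res.subject_summaries().to_json(orient="records")
                ),
                "position_accuracy": json.loads(
                    sdt_res.position_accuracy().to_json(orient="records")
                ),
            }
            (out / "sdt_summary.json").write_text(json.dumps(sdt_summary, indent=2))
            report["stages"]["sdt"] = {"group": sdt_summary["group"]}
            report["warnings"] += [f"sdt: {w}" for w in sdt_res.draws.warnings]

    # --- path analyses ------------------------------------------------------
    if config.run_paths and "oddball" in config.condition_sets:
        oddball = estimates[estimates["condition_set"] == "oddball"]
        for analysis in ("detection", "suppression"):
            with timed(f"paths_{analysis}"):
                path_gran = "run" if config.granularity == "both" else config.granularity
                data = prepare_path_data(oddball, analysis, granularity=path_gran)
                comparison = compare_path_models(
                    data, make_specs(analysis),
                    seed=_stage_seed(config.seed, f"paths-{analysis}"),
                    chains=sampler.chains, iters=sampler.iters,
                    warmup=sampler.warmup, max_treedepth=sampler.max_treedepth,
                )
                payload = comparison.as_dict()
                payload["betas"] = {
                    name: json.loads(res.beta_summaries().to_json(orient="records"))
                    for name, res in comparison.results.items()
                }
                (out / f"paths_{analysis}.json").write_text(
                    json.dumps(payload, indent=2)
                )
                report["stages"][f"paths_{analysis}"] = {
                    "winner": comparison.winner,
                    "directional": comparison.directional,
                    "waic": {k: v.as_dict() for k, v in comparison.waics.items()},
                }
                for name, res in comparison.results.items():
                    report["warnings"] += [
                        f"paths_{analysis}/{name}: {w}" for w in res.draws.warnings
                    ]

    report["timings"] = timings
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    (out / "report.md").write_text(_render_markdown(report))
    return report


def _render_markdown(report: dict) -> str:
    lines = ["# Pipeline report", ""]
    lines.append(f"Seed: {report['config']['seed']}; "
                 f"subjects: {report['config']['n_subjects']}")
    lines.append("")
    for stage, payload in report["stages"].items():
        lines.append(f"## {stage}")
        if "contrasts" in payload:
            lines.append("| ROI | contrast | MAP | HDI95 | PD | p | BF10 |")
            lines.append("|---|---|---|---|---|---|---|")
            for row in payload["contrasts"]:
                lines.append(
                    f"| {row['roi']} | {row['contrast']} | {row['map']:.2f} | "
                    f"[{row['hdi_lower']:.2f}, {row['hdi_upper']:.2f}] | "
                    f"{row['pd']:.3f} | {row['p']:.3f} | {row['bf10']:.3g} |"
                )
        if "waic" in payload:
            lines.append("| model | WAIC |")
            lines.append("|---|---|")
            for k, v in payload["waic"].items():
                lines.append(f"| {k} | {v['waic']:.1f} |")
            lines.append(f"Winner: **{payload.get('winner', 'n/a')}**")
        if "group" in payload:
            g = payload["group"]
            lines.append(
                f"Group d': MAP {g['map']:.2f}, "
                f"HDI95 [{g['hdi_lower']:.2f}, {g['hdi_upper']:.2f}]"
            )
        lines.append("")
    if report["warnings"]:
        lines.append("## Warnings")
        lines += [f"- {w}" for w in report["warnings"]]
    lines.append("")
    lines.append("## Timings (s)")
    for k, v in report.get("timings", {}).items():
        lines.append(f"- {k}: {v}")
    return "\n".join(lines) + "\n"
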