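"""Full-workflow orchestration: load → aggregate → calibrate → efficiency →
global-mean scoring → pre-checks → stability ranking → equivalence → target
comparison, with every table written as CSV and a JSON run manifest.

The stage order mirrors a reference-gene validation study: candidates are
first screened against the global mean, checked for non-differential and
equivalent expression between groups, then ranked by geNorm and NormFinder,
and finally the consequences of each normalizer choice for the target genes
are laid out side by side.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cq_data import CqDataset, load_dataset
from .efficiency import fit_standard_curve, fits_to_frame, load_dilution_series
from .errors import ConfigurationError, CqnormError
from .genorm import run_genorm
from .global_mean import global_mean_profile, score_candidates
from .group_stats import (
    differential_precheck,
    equivalence_test,
    log2_expression_from_aggregated,
    normality_check,
    variance_homogeneity,
)
from .normfinder import normfinder_rank
from .preprocess import aggregate_replicates, calibrate_plates, summarize_assays
from .quantification import cq_to_rq
from .target_analysis import compare_targets

logger = logging.getLogger(__name__)

ALL_STAGES = [
    "aggregate",
    "efficiency",
    "global_mean",
    "prechecks",
    "stability",
    "equivalence",
    "targets",
]


@dataclass
class PipelineConfig:
    """Paths, stage toggles and stage parameters for a full run."""

    cq_path: str
    samples_path: str
    panel_path: str
    outdir: str
    dilutions_path: str | None = None
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    dialect: dict = field(default_factory=dict)
    # preprocess
    sd_threshold: float = 0.3
    min_detected: int = 2
    calibrator_sample_id: str | None = None
    # quantification
    reference_point: str = "min_cq"
    default_amplification_factor: float = 2.0
    # global mean
    rule: str = "all_detected"
    cutoff: float = 35.0
    top_k: int = 4
    # stability
    v_threshold: float = 0.15
    # group stats
    transform: str = "log10_cq"
    alpha: float = 0.05
    fold_change_cutoff: float = 3.0
    ci_level: float = 0.90
    paired: bool = False
    case_group: str | None = None
    # targets
    normalizer_sets: dict = field(default_factory=dict)
    targets: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"stages: unknown stage names {sorted(unknown)}")
        for name, sets in (self.normalizer_sets or {}).items():
            clash = set(sets) & set(self.targets)
            if clash:
                raise ConfigurationError(
                    f"normalizer_sets[{name!r}]: targets {sorted(clash)} cannot "
                    "normalize themselves"
                )


def _write(frame: pd.DataFrame, outdir: Path, name: str, manifest: dict) -> None:
    path = outdir / name
    frame.to_csv(path, index=False, float_format="%.10g")
    manifest["outputs"][name] = int(len(frame))


def run_pipeline(config: PipelineConfig, dataset: CqDataset | None = None) -> dict:
    """Execute the enabled stages in order and return the run manifest.

    ``dataset`` can be supplied directly (e.g. from the simulator); otherwise
    the configured paths are loaded.  Partial outputs are retained on stage
    failure and the manifest records the failing stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {
            k: v for k, v in asdict(config).items() if k != "normalizer_sets"
        },
        "normalizer_sets": config.normalizer_sets,
        "stages_completed": [],
        "outputs": {},
    }

    try:
        if dataset is None:
            dataset = load_dataset(
                config.cq_path, config.samples_path, config.panel_path,
                dialect=config.dialect or None,
            )
        manifest["n_measurements"] = dataset.n_measurements

        agg = aggregate_replicates(
            dataset, sd_threshold=config.sd_threshold, min_detected=config.min_detected
        )
        if config.calibrator_sample_id:
            agg = calibrate_plates(agg, config.calibrator_sample_id)
            # the calibrator is a technical control, not an analysis sample
            agg = agg[agg["sample_id"] != config.calibrator_sample_id]
        if "aggregate" in config.stages:
            _write(agg, outdir, "aggregated.csv", manifest)
            _write(summarize_assays(agg), outdir, "cq_summaries.csv", manifest)
            manifest["stages_completed"].append("aggregate")

        panel = dataset.panel
        if "efficiency" in config.stages and config.dilutions_path:
            fits = [fit_standard_curve(s) for s in
                    load_dilution_series(config.dilutions_path)]
            fit_frame = fits_to_frame(fits)
            _write(fit_frame, outdir, "efficiency_fits.csv", manifest)
            eff = fit_frame.set_index("assay_id")["efficiency_percent"]
            pf = panel.frame.copy()
            pf["efficiency_percent"] = pf["assay_id"].map(eff).fillna(
                pf["efficiency_percent"]
            )
            panel = type(panel)(pf)
            manifest["stages_completed"].append("efficiency")

        candidates = panel.assays_with_role("reference_candidate")
        targets = config.targets or panel.assays_with_role("target")

        if "global_mean" in config.stages:
            profile = global_mean_profile(agg, rule=config.rule, cutoff=config.cutoff)
            prof_frame = pd.DataFrame(
                {
                    "sample_id": profile.mean_cq.index,
                    "global_mean_cq": profile.mean_cq.values,
                    "n_assays_used": profile.n_assays_used.values,
                }
            )
            _write(prof_frame, outdir, "global_mean_profile.csv", manifest)
            scores = score_candidates(agg, profile, candidates=candidates,
                                      top_k=config.top_k)
            _write(scores.table, outdir, "candidate_scores.csv", manifest)
            manifest["global_mean_top"] = scores.top
            manifest["stages_completed"].append("global_mean")

        samples = dataset.samples
        if "prechecks" in config.stages:
            cand_agg = agg[agg["assay_id"].isin(candidates)]
            pre = differential_precheck(
                cand_agg, samples, transform=config.transform, alpha=config.alpha,
                case_group=config.case_group,
            )
            _write(pre, outdir, "differential_precheck.csv", manifest)
            bart = variance_homogeneity(cand_agg, genes=candidates)
            (outdir / "variance_homogeneity.json").write_text(json.dumps(bart, indent=1))
            manifest["outputs"]["variance_homogeneity.json"] = 1
            norm = normality_check(cand_agg, samples)
            _write(norm, outdir, "normality_check.csv", manifest)
            manifest["stages_completed"].append("prechecks")

        rq = cq_to_rq(
            agg, panel, reference_point=config.reference_point,
            default_amplification_factor=config.default_amplification_factor,
        )
        if "stability" in config.stages:
            gn = run_genorm(rq, candidates, v_threshold=config.v_threshold)
            m_table = pd.DataFrame(
                {
                    "assay_id": gn.full_panel_m.index,
                    "full_panel_m": gn.full_panel_m.values,
                    "m_at_exclusion": gn.m_at_exclusion.reindex(
                        gn.full_panel_m.index
                    ).values,
                }
            )
            _write(m_table, outdir, "genorm_m.csv", manifest)
            gn.m_trajectory.to_csv(outdir / "genorm_m_trajectory.csv",
                                   index_label="step")
            manifest["outputs"]["genorm_m_trajectory.csv"] = len(gn.m_trajectory)
            if gn.v_series is not None:
                v_frame = gn.v_series.rename_axis("n").reset_index()
                _write(v_frame, outdir, "genorm_v.csv", manifest)
            manifest["genorm"] = {
                "final_pair": list(gn.final_pair),
                "ranking": gn.ranking,
                "recommended_n": gn.recommended_n,
            }
            nf_res = normfinder_rank(rq, candidates, samples)
            _write(nf_res.table, outdir, "normfinder.csv", manifest)
            _write(nf_res.pair_table, outdir, "normfinder_pairs.csv", manifest)
            manifest["normfinder"] = {
                "best_gene": nf_res.best_gene,
                "best_pair": list(nf_res.best_pair),
                "pair_stability": nf_res.pair_stability,
            }
            manifest["stages_completed"].append("stability")

        if "equivalence" in config.stages:
            cand_agg = agg[agg["assay_id"].isin(candidates)]
            eq = equivalence_test(
                log2_expression_from_aggregated(cand_agg), samples,
                fold_change_cutoff=config.fold_change_cutoff,
                ci_level=config.ci_level, paired=config.paired,
                case_group=config.case_group,
            )
            _write(eq, outdir, "equivalence.csv", manifest)
            manifest["stages_completed"].append("equivalence")

        if "targets" in config.stages and targets:
            sets = config.normalizer_sets
            if not sets:
                sets = {}
                if "genorm" in manifest:
                    pair = manifest["genorm"]["final_pair"]
                    sets["genorm_pair"] = pair
                if "normfinder" in manifest:
                    sets["normfinder_pair"] = manifest["normfinder"]["best_pair"]
                for c in candidates:
                    sets[c] = [c]
            comparison = compare_targets(
                rq, sets, targets, samples, alpha=config.alpha,
                case_group=config.case_group,
            )
            _write(comparison, outdir, "target_comparison.csv", manifest)
            manifest["stages_completed"].append("targets")

        manifest["status"] = "ok"
    except CqnormError as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = _next_stage(manifest, config)
        manifest["error"] = str(exc)
        logger.error("pipeline failed at %s: %s", manifest["failed_stage"], exc)
        _write_manifest(manifest, outdir)
        raise
    _write_manifest(manifest, outdir)
    return manifest


def _next_stage(manifest: dict, config: PipelineConfig) -> str:
    done = set(manifest["stages_completed"])
    for stage in config.stages:
        if stage not in done:
            return stage
    return "unknown"


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
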