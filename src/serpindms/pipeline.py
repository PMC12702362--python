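"""End-to-end orchestration: simulate -> score -> refine -> regions ->
predictors -> selection analysis, with every intermediate table written to an
output directory plus a JSON statistics report and a run log.

Stages are individually callable (the CLI exposes each as a subcommand); the
composed run equals the stage-by-stage run under one seed because every stage
is a pure function of its written inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .enrichment import EnrichmentModel, sample_pca
from .errors import ConfigurationError, ExportError, InputError
from .predictors import compare_conformations, stratified_comparison
from .selection import (
    conservation_regression,
    normalized_position_counts,
    quadrant_analysis,
    two_way_anova,
)
from .simulate import SimConfig, condition_label, simulate_screen
from .stability import (
    call_regions,
    lowess_smooth,
    positional_acceptance,
    refine_functional_stability,
)
from .variants import AMINO_ACIDS

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Either ``sim`` (a :class:`SimConfig`) or ``counts_path`` must be given.
    Thresholds default to the screen's published analysis settings: baseMean
    50, FDR 10%, class boundary 0, LOWESS window 20 points, stabilizing
    region threshold = 75th percentile of the LOWESS series.
    """

    outdir: str = "serpindms_run"
    seed: int = 0
    sim: SimConfig | None = None
    counts_path: str | None = None
    vep_path: str | None = None
    ddg_path: str | None = None
    conservation_path: str | None = None
    predictor_column_map: dict = field(default_factory=dict)
    base_mean_threshold: float = 50.0
    fdr: float = 0.10
    class_boundary: float = 0.0
    pseudocount: float = 0.5
    lowess_window: int = 20
    region_upper: str = "percentile"   # or "mean" or a number
    region_percentile: float = 75.0
    aggregate: str = "mean"
    selected_conditions: tuple[str, str] = ("sel0h", "sel48h")

    def __post_init__(self):
        if self.sim is None and self.counts_path is None:
            raise ConfigurationError("run config needs either sim or counts_path")
        if not 0 < self.fdr < 1:
            raise ConfigurationError(f"fdr must be in (0, 1), got {self.fdr}")
        if self.base_mean_threshold < 0:
            raise ConfigurationError("base_mean_threshold must be >= 0")
        if self.lowess_window < 2:
            raise ConfigurationError("lowess_window must be >= 2")
        if not 0 < self.region_percentile < 100:
            raise ConfigurationError("region_percentile must be in (0, 100)")
        for p in (self.counts_path, self.vep_path, self.ddg_path,
                  self.conservation_path):
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"referenced file does not exist: {p}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sim = data.pop("sim", None)
        if sim is not None:
            sim = sio.sim_config_from_dict(sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown run config fields: {sorted(unknown)}")
        if "selected_conditions" in data:
            data["selected_conditions"] = tuple(data["selected_conditions"])
        return cls(sim=sim, **data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = sio.sim_config_to_dict(self.sim)
        return json.loads(json.dumps(d))


def export_heatmap_matrix(
    scores: pd.Series, length: int | None = None, wt_seq: str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Position x amino-acid score grid for heatmap rendering.

    Returns ``(grid, wt_mask)``: 20 amino-acid rows by L position columns,
    NaN where a substitution is unscored (rendered white downstream) and a
    boolean mask flagging wild-type cells when ``wt_seq`` is given.

    Raises
    ------
    ExportError
        On duplicate variant keys.
    """
    if scores.index.has_duplicates:
        dup = scores.index[scores.index.duplicated()][0]
        raise ExportError(f"duplicate variant key {dup!r}")
    from .variants import parse_variant

    parsed = [parse_variant(v) for v in scores.index]
    if length is None:
        length = max(v.position for v in parsed)
    grid = pd.DataFrame(
        np.nan,
        index=pd.Index(list(AMINO_ACIDS), name="alt_aa"),
        columns=pd.RangeIndex(1, length + 1, name="position"),
    )
    for v, val in zip(parsed, scores.to_numpy(dtype=float)):
        grid.at[v.alt_aa, v.position] = val
    wt_mask = pd.DataFrame(False, index=grid.index, columns=grid.columns)
    if wt_seq is not None:
        for pos, aa in enumerate(wt_seq[:length], start=1):
            if aa in wt_mask.index:
                wt_mask.at[aa, pos] = True
    return grid, wt_mask


def heatmap_to_long(grid: pd.DataFrame) -> pd.Series:
    """Inverse of :func:`export_heatmap_matrix` (drops empty cells).

    The variant key omits the wild-type residue (unknown from the grid
    alone), so the index is ``(position, alt_aa)``.
    """
    long = grid.stack(future_stack=True).dropna()
    long.index.names = ["alt_aa", "position"]
    return long.reorder_levels(["position", "alt_aa"]).sort_index()


def _regression_dict(r) -> dict:
    return {"slope": r.slope, "intercept": r.intercept, "r2": r.r2,
            "pvalue": r.pvalue, "n": r.n}


def _comparison_dict(c) -> dict:
    s, m = c.stratified, c.mixed
    return {
        "n_high": s.n_high, "n_low": s.n_low,
        "mean_high": s.mean_high, "mean_low": s.mean_low,
        "ci_high": list(s.ci_high), "ci_low": list(s.ci_low),
        "difference": s.difference,
        "mixed_coefficient": m.coefficient, "mixed_se": m.se,
        "mixed_pvalue": m.pvalue, "ols_fallback": m.ols_fallback,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the result bundle under ``outdir``.

    Returns the statistics report (also written as ``stats.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("serpindms")
    root.addHandler(handler)
    stats: dict = {"version": __version__, "seed": config.seed,
                   "config": config.to_dict()}
    try:
        logger.info("resolved config: %s", json.dumps(config.to_dict(), sort_keys=True))

        # --- stage: simulate or load -------------------------------------
        vep = ddg = conservation = None
        truth = None
        if config.sim is not None:
            sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
            screen = simulate_screen(sim_cfg)
            counts, samples, truth = screen.counts, screen.samples, screen.truth
            vep = screen.predictors["vep_score"]
            ddg = screen.predictors[["ddg_active", "ddg_latent"]]
            conservation = screen.conservation
            sio.write_count_table(counts, outdir / "counts.tsv")
            sio.write_frame_csv(truth.variants, outdir / "ground_truth_variants.csv")
            sio.write_frame_csv(truth.positions, outdir / "ground_truth_positions.csv")
            sio.write_frame_csv(screen.predictors, outdir / "predictors.csv")
            sio.write_series_csv(conservation, outdir / "conservation.csv")
        else:
            counts, samples = sio.read_count_table(config.counts_path)
        if config.vep_path is not None:
            vep = sio.read_variant_table(
                config.vep_path, config.predictor_column_map
            )["score"]
        if config.ddg_path is not None:
            ddg = sio.read_variant_table(config.ddg_path, config.predictor_column_map)
        if config.conservation_path is not None:
            conservation = sio.read_conservation(config.conservation_path)

        # --- stage: enrichment scoring ------------------------------------
        cond_0h, cond_48h = config.selected_conditions
        results = {}
        for cond, tag in ((cond_0h, "0h"), (cond_48h, "48h")):
            model = EnrichmentModel(
                counts, samples, contrast=(cond, "input"),
                base_mean_threshold=config.base_mean_threshold,
                fdr=config.fdr, pseudocount=config.pseudocount,
            )
            res = model.fit()
            results[tag] = res
            sio.write_scores(res.frame, outdir / f"scores_{tag}.tsv")
            stats[f"screen_{tag}"] = {
                "n_scored": res.n_scored,
                "n_enriched": res.n_enriched,
                "n_depleted": res.n_depleted,
                "n_enriched_fdr": int((res.significant()["log2FoldChange"] > 0).sum()),
                "n_depleted_fdr": int((res.significant()["log2FoldChange"] <= 0).sum()),
            }
        pca = sample_pca(counts)
        sio.write_frame_csv(pca.coordinates, outdir / "sample_pca.csv")
        stats["pca_variance_fractions"] = [float(v) for v in
                                           pca.explained_variance_ratio]

        # --- stage: refinement + regions ----------------------------------
        refined = refine_functional_stability(
            results["0h"].scores, results["48h"].scores
        )
        stats["refined"] = {
            "n_refined": int(refined["refined"].sum()),
            "n_prolonged": int(
                (refined.loc[refined["refined"], "functional_stability_score"] > 0).sum()
            ),
            "n_reduced": int(
                (refined.loc[refined["refined"], "functional_stability_score"] <= 0).sum()
            ),
        }
        acceptance = positional_acceptance(refined, aggregate=config.aggregate)
        smooth = lowess_smooth(acceptance, window_points=config.lowess_window)
        regions = call_regions(
            smooth, upper=config.region_upper,
            upper_percentile=config.region_percentile,
        )
        profile = pd.DataFrame(
            {"mutational_acceptance": acceptance, "lowess": smooth,
             "region_class": regions.classes}
        )
        stats["regions"] = {
            "stabilizing": [list(iv) for iv in regions.stabilizing],
            "destabilizing": [list(iv) for iv in regions.destabilizing],
            "upper_threshold": regions.upper_threshold,
        }
        sio.write_regions_bed(
            {"stabilizing": regions.stabilizing,
             "destabilizing": regions.destabilizing},
            outdir / "regions.bed",
        )
        grid, wt_mask = export_heatmap_matrix(
            refined.loc[refined["refined"], "functional_stability_score"],
            length=config.sim.L if config.sim is not None else None,
            wt_seq=truth.wt_seq if truth is not None else None,
        )
        sio.write_frame_csv(grid, outdir / "heatmap_48h_refined.csv")
        sio.write_frame_csv(wt_mask, outdir / "heatmap_wt_mask.csv")

        # --- stage: predictor comparisons ---------------------------------
        inhibition = results["0h"].scores
        stability = refined.loc[refined["refined"], "functional_stability_score"]
        if vep is not None:
            comp = {
                "inhibition": stratified_comparison(
                    inhibition, vep, "inhibition", config.class_boundary, "VEP"),
                "stability": stratified_comparison(
                    stability, vep, "stability", config.class_boundary, "VEP"),
            }
            stats["vep"] = {k: _comparison_dict(v) for k, v in comp.items()}
        if ddg is not None:
            stats["ddg"] = {}
            for grouping, scores_ in (("inhibition", inhibition),
                                      ("stability", stability)):
                pair = compare_conformations(
                    scores_, ddg, grouping, config.class_boundary
                )
                stats["ddg"][grouping] = {
                    conf: _comparison_dict(c) for conf, c in pair.items()
                }

        # --- stage: selection analysis ------------------------------------
        if conservation is not None:
            npc0 = normalized_position_counts(inhibition)
            npc48 = normalized_position_counts(stability)
            reg0 = conservation_regression(npc0, conservation)
            reg48 = conservation_regression(npc48, conservation)
            quad = quadrant_analysis(npc0, npc48, conservation)
            aligned = quad.table
            anova2 = two_way_anova(
                aligned["inhibition_permissive"],
                aligned["stability_permissive"],
                aligned["conservation"],
            )
            profile = profile.join(
                aligned[["npc_0h", "npc_48h", "conservation", "quadrant"]],
                how="outer",
            )
            stats["selection"] = {
                "regression_0h": _regression_dict(reg0),
                "regression_48h": _regression_dict(reg48),
                "quadrant_means": quad.quadrant_means,
                "quadrant_medians": list(quad.medians),
                "anova_f": quad.anova_f,
                "anova_p": quad.anova_p,
                "tukey": quad.tukey.to_dict(orient="records"),
                "two_way": {
                    "f_inhibition": anova2.f_inhibition,
                    "p_inhibition": anova2.p_inhibition,
                    "f_stability": anova2.f_stability,
                    "p_stability": anova2.p_stability,
                    "f_interaction": anova2.f_interaction,
                    "p_interaction": anova2.p_interaction,
                    "df_denom": anova2.df_denom,
                },
            }
        profile.index.name = "position"
        sio.write_frame_csv(profile, outdir / "position_profile.csv")

        report = json.dumps(stats, indent=2, sort_keys=True, allow_nan=True)
        (outdir / "stats.json").write_text(report + "\n")
        logger.info("pipeline complete; %d stats keys", len(stats))
        return stats
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def default_run_config(seed: int = 0, outdir: str = "serpindms_run",
                       **sim_overrides) -> RunConfig:
    """Run configuration for the default synthetic screen."""
    return RunConfig(outdir=outdir, seed=seed,
                     sim=SimConfig(seed=seed, **sim_overrides))
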