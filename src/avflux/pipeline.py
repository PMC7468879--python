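"""End-to-end pipeline: simulate/load → preprocess → exchange →
multivariate → association, driven by one YAML config.

Each stage reads its inputs from, and writes its outputs to, the run
directory, so any stage can be re-run stand-alone on the previous stage's
on-disk outputs with identical results. A manifest records the seed, the
config, and a SHA-256 digest of every file written; it contains no
wall-clock information, so identical config + seed yields byte-identical
manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, chemometrics, exchange, preprocess, synthetic
from .data_model import (
    MetaboliteTable,
    OutcomeTable,
    read_bucket_table,
    read_metabolite_map,
    read_metabolite_table,
    read_outcomes,
    write_results,
)

logger = logging.getLogger("avflux")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending entity."""


@dataclass
class PipelineConfig:
    """Everything a run needs; see the README for a worked YAML example."""

    mode: str = "synthetic"  # or "data"
    seed: int = 0
    output_dir: str = "results"
    # data mode: paths to the four input CSVs
    samples: str | None = None
    buckets: str | None = None
    metabolite_map: str | None = None
    outcomes: str | None = None
    # synthetic mode: generator settings
    n_metabolites: int = 20
    n_animals: int = 5
    n_day_shifted: int = 8
    noise_sd: float = 0.10
    animal_sd: float = 0.15
    n_buckets: int = 594
    # analysis settings
    water_region: tuple[float, float] = (4.5, 5.1)
    alpha: float = 0.05
    folds: int = 7
    n_osc: int = 1
    n_perm_plsda: int = 200
    n_perm_splsda: int = 100
    vip_threshold: float = 0.8
    flow_weights: tuple[float, float] = (0.2, 0.8)
    n_components: int = 2
    keepX: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.mode not in ("synthetic", "data"):
            raise PipelineError(f"config: mode must be 'synthetic' or 'data', got {cfg.mode!r}")
        if cfg.mode == "data":
            for key in ("samples", "buckets", "metabolite_map", "outcomes"):
                p = getattr(cfg, key)
                if p is None:
                    raise PipelineError(f"config: data mode requires the {key!r} path")
                if not Path(p).exists():
                    raise PipelineError(f"config: input file not found: {p}")
        return cfg


def _sub_seeds(seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage sub-seeds below 2**31."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    """Synthetic mode: generate the four input tables plus ground truth."""
    gen = synthetic.GeneratorConfig.default(
        n_metabolites=cfg.n_metabolites,
        n_animals=cfg.n_animals,
        n_day_shifted=cfg.n_day_shifted,
        noise_sd=cfg.noise_sd,
        animal_sd=cfg.animal_sd,
        n_buckets=cfg.n_buckets,
    )
    s_conc, s_bucket, s_out = _sub_seeds(cfg.seed, 3)
    met, truth = synthetic.simulate_concentrations(gen, seed=s_conc)
    buckets, met_map = synthetic.embed_in_buckets(met, gen, seed=s_bucket)
    outcomes = synthetic.simulate_outcomes(truth, gen, seed=s_out)
    write_results(
        {
            "buckets": buckets,
            "metabolite_map": met_map,
            "outcomes": outcomes,
            "truth": truth.to_frame(),
        },
        out,
    )
    logger.info("simulate: %d samples × %d buckets, %d metabolites",
                buckets.n_samples, buckets.n_buckets, len(met.metabolite_names))


def stage_preprocess(cfg: PipelineConfig, out: Path) -> None:
    """Water exclusion, total-area normalization, metabolite quantification."""
    table = read_bucket_table(out / "buckets.csv", out / "buckets_samples.csv")
    met_map = read_metabolite_map(out / "metabolite_map.csv")
    region = preprocess.PpmRegion(*cfg.water_region)
    table = preprocess.exclude_region(table, region)
    table = preprocess.normalize_total_area(table)
    met = preprocess.quantify_metabolites(table, met_map)
    write_results({"buckets_normalized": table, "metabolites": met}, out)
    logger.info("preprocess: %d buckets kept, %d metabolites quantified",
                table.n_buckets, len(met.metabolite_names))


def stage_exchange(cfg: PipelineConfig, out: Path) -> None:
    """Per-organ exchange summaries, per-animal AUC exchanges, counts."""
    met = read_metabolite_table(out / "metabolites.csv", out / "metabolites_samples.csv")
    summaries = []
    aucs = []
    for organ in exchange.ORGANS:
        summaries.append(
            exchange.summarize_exchange(met, organ, alpha=cfg.alpha, weights=cfg.flow_weights)
        )
        aucs.append(exchange.per_animal_auc_exchange(met, organ, weights=cfg.flow_weights))
    summary = pd.concat(summaries, ignore_index=True)
    per_animal = pd.concat(aucs, ignore_index=True)
    counts = {
        mode: exchange.count_differential(summary, mode, alpha=cfg.alpha)
        for mode in ("fasting", "postprandial_auc")
    }
    write_results({"exchange_summary": summary, "per_animal_auc": per_animal}, out)
    (out / "differential_counts.json").write_text(json.dumps(counts, indent=2, sort_keys=True))
    logger.info("exchange: %d summary rows, counts %s", len(summary), counts)


def stage_multivariate(cfg: PipelineConfig, out: Path) -> None:
    """Multilevel (s)PLS-DA of day status on the normalized bucket matrix."""
    table = read_bucket_table(out / "buckets_normalized.csv", out / "buckets_normalized_samples.csv")
    X = table.intensities
    y = table.annotations["day"].to_numpy()
    animals = table.annotations["animal_id"].to_numpy()
    s_cv, s_perm1, s_perm2 = _sub_seeds(cfg.seed + 1, 3)

    split = chemometrics.multilevel_split(X, animals)
    Xw = chemometrics.pareto_scale(split.within)

    cv = chemometrics.cv_q2(Xw, y, folds=cfg.folds, groups=animals, seed=s_cv)
    ncomp = max(cfg.n_components, 1)

    def q2_stat(Xm, ym):
        return chemometrics.cv_q2(
            Xm, ym, folds=cfg.folds, n_components_grid=(ncomp,), groups=animals, seed=s_cv
        ).q2[ncomp]

    perm_q2 = chemometrics.permutation_test(
        Xw, y, q2_stat, n_perm=cfg.n_perm_plsda, seed=s_perm1, within_subject=animals
    )

    keepx = min(cfg.keepX, Xw.shape[1])
    model = chemometrics.splsda_fit(Xw, y, n_components=ncomp, keepX=keepx)
    auc = chemometrics.cv_auc(
        Xw, y, n_components=ncomp, keepX=keepx, folds=cfg.folds, groups=animals, seed=s_cv
    )

    def auc_stat(Xm, ym):
        return chemometrics.cv_auc(
            Xm, ym, n_components=ncomp, keepX=keepx, folds=cfg.folds, groups=animals, seed=s_cv
        )

    perm_auc = chemometrics.permutation_test(
        Xw, y, auc_stat, n_perm=cfg.n_perm_splsda, seed=s_perm2, within_subject=animals
    )

    kw = chemometrics.kruskal_wallis_fdr(Xw, y, alpha=cfg.alpha)
    kw["ppm_center"] = table.ppm_centers[kw["variable"].to_numpy()]
    vip_df = pd.DataFrame(
        {
            "variable": np.arange(Xw.shape[1]),
            "ppm_center": table.ppm_centers[: Xw.shape[1]],
            "vip": model.vip,
            "selected": model.vip > cfg.vip_threshold,
        }
    )
    stats_out = {
        "q2_grid": {str(k): v for k, v in cv.q2.items()},
        "chosen_n_components": cv.chosen_n_components,
        "q2": cv.q2.get(ncomp),
        "r2y": model.r2y,
        "cv_auc": auc,
        "perm_p_q2": perm_q2.p_value,
        "perm_p_auc": perm_auc.p_value,
        "n_vip_selected": int(np.sum(model.vip > cfg.vip_threshold)),
        "n_kw_significant": int(kw["significant"].sum()),
    }
    write_results({"vip": vip_df, "kw_fdr": kw}, out)
    (out / "multivariate_stats.json").write_text(json.dumps(stats_out, indent=2, sort_keys=True))
    logger.info("multivariate: Q2=%s AUC=%.3f perm p (Q2)=%.4f", stats_out["q2"], auc,
                perm_q2.p_value)


def stage_associate(cfg: PipelineConfig, out: Path) -> None:
    """Feature selection, HCA of condition means, outcome correlations."""
    met = read_metabolite_table(out / "metabolites.csv", out / "metabolites_samples.csv")
    outcomes = read_outcomes(out / "outcomes.csv")
    per_animal = pd.read_csv(out / "per_animal_auc.csv")

    selected = association.select_postprandial_features(met, alpha=cfg.alpha)
    means = association.condition_means(met)
    rows, cols = association.hca_heatmap(means)
    reports = []
    for outcome in ("HOMA_IR", "BW"):
        reports.append(association.correlate_outcomes(per_animal, outcomes, outcome))
    report = pd.concat(reports, ignore_index=True)
    top = association.top_k_report(report, k=10)
    write_results(
        {"selected_features": selected, "correlations": report, "top_correlations": top}, out
    )
    (out / "hca.json").write_text(
        json.dumps({"rows": rows.to_dict(), "columns": cols.to_dict()}, indent=2, sort_keys=True)
    )
    logger.info("associate: %d features selected, %d correlations",
                int(selected["selected"].sum()), len(report))


STAGES = [
    ("simulate", stage_simulate),
    ("preprocess", stage_preprocess),
    ("exchange", stage_exchange),
    ("multivariate", stage_multivariate),
    ("associate", stage_associate),
]


def _copy_inputs(cfg: PipelineConfig, out: Path) -> None:
    """Data mode: validate and re-write the inputs into the run directory."""
    table = read_bucket_table(cfg.buckets, cfg.samples)
    met_map = read_metabolite_map(cfg.metabolite_map)
    outcomes = read_outcomes(cfg.outcomes)
    write_results({"buckets": table, "metabolite_map": met_map, "outcomes": outcomes}, out)


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages (all by default) and write manifest.json.

    Returns the manifest: seed, config, and SHA-256 of every output file.
    Any stage error aborts with the stage name in the message.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    todo = stages or [name for name, _ in STAGES]
    for name, fn in STAGES:
        if name not in todo:
            continue
        if name == "simulate" and cfg.mode == "data":
            try:
                _copy_inputs(cfg, out)
            except Exception as err:
                raise PipelineError(f"stage load-inputs: {err}") from err
            continue
        try:
            fn(cfg, out)
        except Exception as err:
            raise PipelineError(f"stage {name}: {err}") from err

    files = {}
    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            files[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest = {
        "seed": cfg.seed,
        "mode": cfg.mode,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "stages": todo,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
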