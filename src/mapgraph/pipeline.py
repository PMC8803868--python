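"""End-to-end pipeline: generate → process → graph → zones/MI → ML.

A :class:`PipelineConfig` carries every stage's parameters with defaults
matching the analysis conventions (z threshold 3, triangular kernel
half-widths 9/18 µm, averaging bins 30/60 µm, ≥10 null graphs per map, the
random-forest and GLM protocols) plus a single global seed.  Runs are
idempotent: the same config and seed rewrite identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import graphs, io, maps, models, synthetic, zoning

log = logging.getLogger("mapgraph")


@dataclass
class PipelineConfig:
    """All stage parameters and toggles for one pipeline run."""

    out_dir: str = "run"
    cohort_dir: str | None = None            # existing cohort; None → generate
    seed: int = 0
    resolution: int = 20
    z_threshold: float = 3.0
    n_nulls: int = 10
    n_swaps_per_edge: int = 10
    feature_scheme: str = "g_bilateral"
    zone_template: str = "template7"         # template7 | template8
    functional_definition: str = "contiguous"
    n_mi_permutations: int = 200
    run_generate: bool = True
    run_process: bool = True
    run_graph: bool = True
    run_zones: bool = True
    run_classify: bool = True
    run_predict: bool = True
    with_trials: bool = False
    classifier: models.ClassifierConfig = field(default_factory=models.ClassifierConfig)
    glm: models.GLMSpec = field(default_factory=models.GLMSpec)
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("classifier"), dict):
            d["classifier"] = models.ClassifierConfig(**d["classifier"])
        if isinstance(d.get("glm"), dict):
            d["glm"] = models.GLMSpec(**d["glm"])
        if isinstance(d.get("cohort"), dict):
            d["cohort"] = synthetic.CohortConfig.from_dict(d["cohort"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns a dict of result artifacts.

    Every artifact is written under ``config.out_dir`` along with a
    provenance record (config hash, seed).  With all toggles off only the
    validated config echo is produced.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    config.save(out / "config.yaml")

    cohort = None
    if config.run_generate:
        log.info("stage generate: synthesising cohort")
        cc = config.cohort
        cc.seed = config.seed
        cc.resolution = config.resolution
        cohort = synthetic.generate_cohort(cc, with_trials=config.with_trials)
        io.write_cohort(cohort, out / "cohort")
        results["n_maps"] = len(cohort)
    elif config.cohort_dir is not None:
        cohort = io.read_cohort(config.cohort_dir)
        results["n_maps"] = len(cohort)

    needs_cohort = (
        config.run_process or config.run_graph or config.run_zones
        or config.run_classify or config.run_predict
    )
    if cohort is None and needs_cohort:
        raise FileNotFoundError(
            "stage process: no cohort available (enable generation or point "
            "cohort_dir at an existing cohort)"
        )
    if cohort is None:
        return results

    zmaps, profiles = [], []
    if config.run_process:
        log.info("stage process: z-scoring %d maps", len(cohort))
        for i, m in enumerate(cohort.maps):
            if cohort.trials:
                zm = maps.compute_zscore_map(cohort.trials[i])
            else:
                zm = maps.compute_zscore_map(
                    amplitudes=m.amplitudes,
                    noise_mean=cohort.config.noise.mean,
                    noise_sd=cohort.config.noise.sd,
                    threshold=config.z_threshold,
                )
            zmaps.append(zm)
            profiles.append(maps.project_profile(m, zm, mode="max_weight"))
        stats = [maps.active_site_stats(z, m) for z, m in zip(zmaps, cohort.maps)]
        pd.DataFrame(
            {
                "map_id": [m.metadata["map_id"] for m in cohort.maps],
                "condition": cohort.labels,
                "fraction_active": [s["fraction_active"] for s in stats],
                "cumulative_strength_nA": [
                    maps.cumulative_strength(p)[-1] for p in profiles
                ],
            }
        ).to_csv(out / "map_stats.csv", index=False)
        results["map_stats"] = str(out / "map_stats.csv")

    mgraphs, partitions = [], []
    if config.run_graph:
        log.info("stage graph: building graphs and features")
        feats = []
        rel_rows = []
        for i, m in enumerate(cohort.maps):
            g = graphs.build_correlation_graph(m)
            p = graphs.detect_modules(g, seed=config.seed + i)
            mgraphs.append(g)
            partitions.append(p)
            feats.append(graphs.assemble_features(g, p, scheme=config.feature_scheme))
            if config.n_nulls > 0:
                nulls = graphs.null_ensemble(
                    g, n_nulls=config.n_nulls,
                    n_swaps_per_edge=config.n_swaps_per_edge,
                    seed=config.seed + 7919 + i,
                )
                rel = graphs.relative_features(g, p, nulls, seed=config.seed + i)
                rel_rows.append(rel)
        feats = np.asarray(feats)
        io.write_feature_table(
            out / "features.csv",
            [m.metadata["map_id"] for m in cohort.maps],
            cohort.labels,
            config.feature_scheme,
            feats,
        )
        if rel_rows:
            pd.DataFrame(rel_rows).to_csv(out / "relative_metrics.csv", index=False)
        results["features"] = str(out / "features.csv")
        results["feature_matrix"] = feats

    if config.run_zones:
        if not mgraphs:
            raise RuntimeError("stage zones: graph stage must run first")
        log.info("stage zones: structural/functional MI")
        template = (
            zoning.TEMPLATE_8 if config.zone_template == "template8" else zoning.TEMPLATE_7
        )
        rows = []
        for i, (m, p) in enumerate(zip(cohort.maps, partitions)):
            sz = zoning.structural_zones(m.column_positions, m.geometry, template)
            fz = zoning.functional_zones(p, definition=config.functional_definition)
            mi = zoning.mi_chance(
                sz, fz, n_perm=config.n_mi_permutations, seed=config.seed + i
            )
            rows.append(
                {
                    "map_id": m.metadata["map_id"],
                    "condition": cohort.labels[i],
                    "nmi": mi.nmi,
                    "chance_lo": mi.chance_ci[0],
                    "chance_hi": mi.chance_ci[1],
                }
            )
        pd.DataFrame(rows).to_csv(out / "zone_mi.csv", index=False)
        results["zone_mi"] = str(out / "zone_mi.csv")

    if config.run_classify:
        if "feature_matrix" not in results:
            raise RuntimeError("stage classify: graph stage must run first")
        log.info("stage classify: random forest over conditions")
        cc = config.classifier
        cc.seed = config.seed
        ev = models.classify_conditions(results["feature_matrix"], cohort.labels, cc)
        (out / "classification.json").write_text(
            json.dumps(
                {
                    "summary": ev.summary(),
                    "classes": ev.classes,
                    "confusion": ev.confusion.tolist(),
                    "seed": config.seed,
                },
                indent=1,
            )
        )
        results["classification"] = ev

    if config.run_predict:
        if "feature_matrix" not in results:
            raise RuntimeError("stage predict: graph stage must run first")
        log.info("stage predict: behavioral GLM")
        gs = config.glm
        gs.seed = config.seed
        targets = np.array([b["target"] for b in cohort.behavior])
        ev = models.glm_predict(
            results["feature_matrix"], targets, cohort.group_codes, gs
        )
        (out / "glm.json").write_text(
            json.dumps(
                {
                    "summary": ev.summary(),
                    "coefficients": ev.coefficients.tolist(),
                    "rank_deficient": ev.extras.get("rank_deficient", False),
                    "seed": config.seed,
                },
                indent=1,
            )
        )
        results["glm"] = ev

    results.pop("feature_matrix", None)
    (out / "provenance.json").write_text(
        json.dumps({"config_hash": config.config_hash(), "seed": config.seed}, indent=1)
    )
    return results
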