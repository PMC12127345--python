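"""Full-pipeline orchestration: simulate -> rank -> model -> stats -> rlq -> sdm.

Driven by one structured (YAML) config with a global seed; each stage
consumes the previous stage's file outputs, so a run is reproducible and
byte-identical given the same config.  A manifest records the seed, the
config, and SHA-256 hashes of every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, OasisRiskError
from . import importance_ranking as ir
from . import rlq as rlq_mod
from . import survey_io as sio
from . import synthetic_data as syn
from . import trait_risk_model as trm
from . import trait_stats as ts
from . import trait_weighted_sdm as sdm

logger = logging.getLogger(__name__)

STAGES = ("simulate", "rank", "model", "stats", "rlq", "sdm")


def _validate_config(config: dict) -> None:
    """Validate every stage block before any stage runs."""
    unknown = set(config) - set(STAGES) - {"seed", "outdir"}
    if unknown:
        raise ConfigurationError(f"unknown config block(s): {sorted(unknown)}")
    if "stats" in config:
        alpha = config["stats"].get("alpha", 0.05)
        if not 0 < alpha < 1:
            raise ConfigurationError(f"stats.alpha must be in (0,1), got {alpha}")
    if "model" in config:
        alg = config["model"].get("algorithm", "forest")
        if alg not in {"forest", "boosting"}:
            raise ConfigurationError(f"model.algorithm must be forest|boosting, got {alg!r}")
    if "rank" in config:
        unit = config["rank"].get("unit", "quadrat")
        if unit not in ir.FREQUENCY_UNITS:
            raise ConfigurationError(f"rank.unit must be quadrat|plot, got {unit!r}")
    if "sdm" in config:
        ratio = config["sdm"].get("background_ratio", 10.0)
        if ratio <= 0:
            raise ConfigurationError("sdm.background_ratio must be positive")
    if "simulate" in config:
        syn.GeneratorConfig(**{**config["simulate"], "seed": int(config.get("seed", 0))})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run the configured stages in order; returns the manifest.

    Stages whose block is absent are skipped (downstream stages that need
    their outputs are skipped too, with a log message).
    """
    _validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("oasisrisk")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    outputs: dict[str, str] = {}

    try:
        traits = truth = survey = env = presences = ranking = None

        if "simulate" in config:
            logger.info("stage simulate: seed=%d", seed)
            gc = syn.GeneratorConfig(**{**config["simulate"], "seed": seed})
            traits, truth = syn.gen_traits(gc)
            survey = syn.gen_survey(traits, truth, gc)
            env = syn.gen_env(gc)
            presences = syn.gen_presences(traits, truth, env, gc)
            sio.write_survey(survey, outdir / "survey.csv")
            sio.write_traits(traits, outdir / "traits.csv")
            for name, layer in env.layers.items():
                sio.write_raster(layer, env.transform, outdir / f"{name}.asc", env.nodata_mask)
            presences.to_csv(outdir / "presences.csv", index=False)
            _write_json(
                {
                    "eta": truth.eta.round(10).to_dict(),
                    "true_risk": truth.true_risk.to_dict(),
                    "config": gc.to_dict(),
                },
                outdir / "truth.json",
            )
            outputs.update(
                {p.name: _sha256(p) for p in outdir.glob("*") if p.suffix in {".csv", ".asc", ".json"}}
            )
        else:
            paths = config.get("rank", {}) | config.get("sdm", {})
            if "survey" in config.get("rank", {}):
                survey = sio.read_survey(config["rank"]["survey"])
            if "traits" in paths:
                traits = sio.read_traits(paths["traits"])

        if "rank" in config:
            if survey is None:
                raise ConfigurationError("rank stage needs a survey (simulate block or rank.survey path)")
            logger.info("stage rank")
            ranking = ir.rank_and_classify(survey, unit=config["rank"].get("unit", "quadrat"))
            ranking.to_csv(outdir / "ranking.csv", index=False)
            ir.class_summary(ranking).to_csv(outdir / "class_summary.csv")
            if traits is not None:
                tally = ir.taxon_tally(traits)
                _write_json(
                    {k: (v.to_dict(orient="records") if isinstance(v, pd.DataFrame) else v)
                     for k, v in tally.items()},
                    outdir / "taxon_tally.json",
                )
            outputs["ranking.csv"] = _sha256(outdir / "ranking.csv")

        if "model" in config:
            if ranking is None or traits is None:
                logger.info("skipping model stage: no ranking/traits available")
            else:
                mc = config["model"]
                logger.info("stage model: algorithm=%s", mc.get("algorithm", "forest"))
                fm = trm.encode_features(traits, ranking)
                if mc.get("design", "observation") == "observation" and survey is not None:
                    fm = trm.expand_to_observations(fm, survey.records)
                train, test = trm.split_train_test(fm, mc.get("fraction", 0.7), seed)
                model = trm.fit_classifier(
                    train,
                    algorithm=mc.get("algorithm", "forest"),
                    hyperparams=mc.get("hyperparams"),
                    seed=seed,
                )
                report = trm.evaluate(model, test)
                _write_json(report.to_dict(), outdir / "report.json")
                imp = trm.permutation_importance(
                    model, test, n_repeats=mc.get("n_repeats", 50), seed=seed,
                    grouping=mc.get("grouping", "column"),
                )
                imp.to_csv(outdir / "importance.csv", index=False)
                outputs["report.json"] = _sha256(outdir / "report.json")
                outputs["importance.csv"] = _sha256(outdir / "importance.csv")

        if "stats" in config:
            if ranking is None or traits is None:
                logger.info("skipping stats stage: no ranking/traits available")
            else:
                sc = config["stats"]
                logger.info("stage stats")
                lab = ranking.set_index("species")["risk_level"]
                comps = []
                for t in sc.get("traits", ["sla", "hundred_grain_weight"]):
                    vals = traits.data.loc[lab.index, t]
                    comps.append(
                        ts.compare_trait_by_risk(
                            vals, lab.astype(str), alpha=sc.get("alpha", 0.05), trait_name=t
                        )
                    )
                ts.comparisons_table(comps).to_csv(outdir / "stats.csv", index=False)
                outputs["stats.csv"] = _sha256(outdir / "stats.csv")

        rlq_result = None
        if "rlq" in config:
            if presences is None or env is None or traits is None:
                logger.info("skipping rlq stage: no presences/env/traits available")
            else:
                logger.info("stage rlq")
                R, L, Q = rlq_mod.tables_from_points(presences, env, traits)
                rlq_result = rlq_mod.rlq_fit(R, L, Q, n_axes=config["rlq"].get("n_axes", 2))
                selected = rlq_mod.select_traits(rlq_result)
                _write_json(
                    {
                        "singular_values": rlq_result.singular_values.tolist(),
                        "total_coinertia": rlq_result.total_coinertia,
                        "env_scores": rlq_result.env_scores.round(10).to_dict(),
                        "trait_scores": rlq_result.trait_scores.round(10).to_dict(),
                        "selected_traits": selected["trait"].tolist(),
                    },
                    outdir / "rlq.json",
                )
                rlq_result.trait_scores.to_csv(outdir / "rlq_trait_scores.csv")
                rlq_result.env_scores.to_csv(outdir / "rlq_env_scores.csv")
                outputs["rlq.json"] = _sha256(outdir / "rlq.json")

        if "sdm" in config:
            if presences is None or env is None or traits is None or ranking is None:
                logger.info("skipping sdm stage: inputs missing")
            else:
                dc = config["sdm"]
                logger.info("stage sdm")
                high = ranking.loc[ranking["risk_level"] == "High", "species"]
                pres = presences[presences["species"].isin(high)].reset_index(drop=True)
                score = sdm.trait_score(traits, dc.get("select", ["sla"]))
                data = sdm.build_presence_set(
                    pres, score, env, dc.get("background_ratio", 10.0), seed=seed
                )
                train, test = sdm.split_presence_background(data, dc.get("fraction", 0.7), seed)
                fit = sdm.fit_weighted_maxent(train, penalty=dc.get("penalty", 0.01))
                surface = sdm.predict_surface(fit, env)
                sio.write_raster(surface, env.transform, outdir / "map.asc", env.nodata_mask)
                pos = sdm.predict_points(fit, test.presences)
                neg = sdm.predict_points(fit, test.background)
                roc = sdm.roc_auc(pos, neg)
                _write_json(
                    {
                        "auc": roc.auc,
                        "n_presence_test": len(pos),
                        "n_background_test": len(neg),
                        "coefficients": fit.coef.round(10).to_dict(),
                        "intercept": round(fit.intercept, 10),
                    },
                    outdir / "metrics.json",
                )
                pd.DataFrame({"threshold": roc.thresholds, "tpr": roc.tpr, "fpr": roc.fpr}).to_csv(
                    outdir / "roc.csv", index=False
                )
                outputs["metrics.json"] = _sha256(outdir / "metrics.json")
                outputs["map.asc"] = _sha256(outdir / "map.asc")

        manifest = {
            "version": __version__,
            "seed": seed,
            "config": config,
            "outputs": outputs,
        }
        _write_json(manifest, outdir / "manifest.json")
        return manifest
    except OasisRiskError:
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
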