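"""End-to-end reproduction pipeline: config -> cohort -> full report bundle.

`reproduce` regenerates, deterministically for a given seed, every
paper-shaped output of the analysis: the descriptive table, the
agreement and correlation reports, group means, the simple-regression
equations, the adjusted coefficient table with forest-plot data, and the
long-eye subgroup model.  Every JSON output embeds the config hash, the
seed and the package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Union

from . import __version__
from .cohort import GeneratorConfig, generate_cohort, load_config
from .exclusions import apply_exclusions
from .model import StiffnessElongationModel
from .records import write_cohort

__all__ = ["reproduce", "config_hash"]

logger = logging.getLogger(__name__)


def config_hash(config: GeneratorConfig) -> str:
    """Stable SHA-256 digest of the canonicalised config."""
    canon = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _jsonable(obj):
    """Recursively make an object JSON-safe (NaN/inf -> None, numpy -> python)."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float):
        return None if not math.isfinite(obj) else obj
    if hasattr(obj, "item"):  # numpy scalar
        return _jsonable(obj.item())
    return obj


def _write_json(path: Path, payload: dict, meta: dict) -> None:
    doc = {"meta": meta, **payload}
    path.write_text(json.dumps(_jsonable(doc), indent=2, sort_keys=True) + "\n")


def reproduce(
    config: Union[GeneratorConfig, str, Path],
    output_dir: Union[str, Path],
) -> dict:
    """Run the full pipeline and write the report bundle to ``output_dir``.

    Returns a manifest of written files.  Any stage failure removes the
    partially written outputs and re-raises with the stage name.
    """
    if not isinstance(config, GeneratorConfig):
        config = load_config(config)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "version": __version__,
    }
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "generate"
        cohort = generate_cohort(config)
        logger.info("generate: %d records", len(cohort))

        stage = "exclusions"
        retained, report = apply_exclusions(cohort)
        logger.info("exclusions: %d -> %d records", report.input_count, report.retained_count)
        path = outdir / "cohort.csv"
        write_cohort(retained, path)
        written.append(path)
        path = outdir / "exclusions.json"
        _write_json(path, {"exclusions": report.to_dict()}, meta)
        written.append(path)

        stage = "analysis"
        results = StiffnessElongationModel(retained).fit()
        full = results.to_dict()

        stage = "report"
        sections = {
            "descriptive_table.json": {"descriptives": full["descriptives"]},
            "agreement.json": {
                "pearson_al_vs_al_morgan": full["correlations"]["al_vs_al_morgan"],
                "bland_altman": full["bland_altman"],
            },
            "group_summary.json": {"group_means": full["group_means"]},
            "ser_delta_correlation.json": {
                "pearson_ser_vs_delta_al": full["correlations"]["ser_vs_delta_al"]
            },
            "simple_regressions.json": {"simple_regressions": full["simple_regressions"]},
            "adjusted_models.json": {
                "adjusted_models": full["adjusted_models"],
                "forest_data": [
                    {
                        "model": label,
                        "term": term,
                        "estimate": row["estimate"],
                        "ci_low": row["ci_low"],
                        "ci_high": row["ci_high"],
                    }
                    for label, model in full["adjusted_models"].items()
                    for term, row in model["terms"].items()
                    if term != "intercept"
                ],
            },
            "subgroup_model.json": {
                "subgroup_model": full["subgroup_model"],
                "note": full["subgroup_note"],
            },
            "diagnostics.json": {"diagnostics": full["diagnostics"]},
        }
        for fname, payload in sections.items():
            path = outdir / fname
            _write_json(path, payload, meta)
            written.append(path)
        path = outdir / "summary.txt"
        path.write_text(results.summary() + "\n")
        written.append(path)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        logger.error("pipeline failed at stage %r; partial outputs removed", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return {"stage": "complete", "files": [str(p) for p in written], "meta": meta}
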