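"""End-to-end pipeline: cohort -> baseline -> associations -> RCS -> WQS
(optionally the transcriptomic screen), driven by one declarative config.

Config layout (YAML or a dict), all sections optional except one data
source::

    input:
      raw_table: path/to/raw.csv        # or:
    simulate:
      n_participants: 5415
      seed: 7
    cohort:
      min_age: 40
    rcs:
      metal: pb
      n_knots: 4
    wqs:
      n_boot: 1000
      train_fraction: 0.8
      seed: 7
    transcriptomics:
      counts: path/to/counts.csv        # gene, NC, 10uM, 30uM
      eye_genes: path/to/eye_genes.txt  # one identifier per line
    output_dir: out/

Every run writes delimited artifacts plus ``manifest.json`` recording the
config snapshot, seeds, per-stage row counts, warnings, and a SHA-256
digest of each artifact.  A stage failure aborts with a stage-tagged error
but the manifest is still written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baseline, cohort as cohort_mod, exposure, plots, rcs, simulate, wqs
from . import transcriptomics as tx

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[stage: {stage}] {err}")
        self.stage = stage


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def run_pipeline(config, output_dir: str | Path | None = None) -> dict:
    """Run the configured stages; return the manifest dict.

    ``config`` is a mapping or a path to a YAML file.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    out = Path(output_dir or config.get("output_dir", "rvometals_out"))
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _jsonable(
            {k: v for k, v in config.items() if k != "output_dir"}
        ),
        "stages": {},
        "artifacts": {},
        "warnings": [],
    }

    def emit(name: str, df: pd.DataFrame):
        path = out / name
        df.to_csv(path, index=False)
        manifest["artifacts"][name] = _digest(path)

    try:
        try:
            if "input" in config:
                raw = cohort_mod.read_raw_table(config["input"]["raw_table"])
            else:
                sim_cfg = simulate.CohortSimConfig(**config.get("simulate", {}))
                raw, truth = simulate.simulate_cohort(sim_cfg)
                manifest["stages"]["simulate"] = {
                    "n_rows": len(raw),
                    "seed": sim_cfg.seed,
                    "intercept": truth.intercept,
                    "n_latent_cases": int(truth.table["outcome"].sum()),
                }
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("input", e) from e

        try:
            lod = cohort_mod.LODPolicy(
                lods=config.get("cohort", {}).get("lods", {})
            )
            analysis, flow = cohort_mod.build_analysis_cohort(
                raw,
                lod,
                min_age=config.get("cohort", {}).get("min_age", 40),
            )
            emit("cohort.csv", analysis)
            emit("flow_counts.csv", flow.to_frame())
            manifest["stages"]["cohort"] = _jsonable(flow)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("cohort", e) from e

        try:
            table1 = baseline.baseline_table(analysis)
            emit("baseline_table.csv", table1)
            plots.plot_metal_violins(analysis, out / "metal_violins.png")
            manifest["artifacts"]["metal_violins.png"] = _digest(
                out / "metal_violins.png"
            )
            manifest["stages"]["baseline"] = {"n_variables": len(table1)}
        except Exception as e:  # noqa: BLE001
            raise PipelineError("baseline", e) from e

        try:
            metals = tuple(config.get("metals", ("pb", "cd", "hg")))
            assoc = exposure.association_table(analysis, metals)
            emit("association_table.csv", assoc)
            manifest["stages"]["associations"] = {"n_models": len(assoc)}
        except Exception as e:  # noqa: BLE001
            raise PipelineError("associations", e) from e

        try:
            rcs_cfg = config.get("rcs", {})
            metal = rcs_cfg.get("metal", "pb")
            spec = rcs.RCSSpec(
                n_knots=rcs_cfg.get("n_knots", 4),
                reference_percentile=rcs_cfg.get("reference_percentile", 25.0),
            )
            curve = rcs.fit_rcs_curve(analysis, metal, spec=spec)
            emit("rcs_curve.csv", curve.grid)
            plots.plot_rcs_curve(curve, out / "rcs_curve.png", metal)
            manifest["artifacts"]["rcs_curve.png"] = _digest(out / "rcs_curve.png")
            manifest["stages"]["rcs"] = {
                "metal": metal,
                "nonlinearity_p": curve.nonlinearity_p,
            }
        except Exception as e:  # noqa: BLE001
            raise PipelineError("rcs", e) from e

        try:
            wqs_cfg = dict(config.get("wqs", {}))
            wqs_cfg.setdefault("metals", metals)
            result = wqs.WQS(analysis, wqs.WQSConfig(**wqs_cfg)).fit()
            emit("wqs_weights.csv", result.summary().reset_index(names="metal"))
            plots.plot_wqs_weights(result, out / "wqs_weights.png")
            manifest["artifacts"]["wqs_weights.png"] = _digest(
                out / "wqs_weights.png"
            )
            manifest["stages"]["wqs"] = {
                "score_coefficient": result.score_coefficient,
                "score_p": result.score_p,
                "n_boot_used": result.n_boot_used,
                "n_boot_failed": result.n_boot_failed,
            }
            if result.n_boot_failed:
                manifest["warnings"].append(
                    f"wqs: {result.n_boot_failed} bootstrap fits dropped"
                )
        except Exception as e:  # noqa: BLE001
            raise PipelineError("wqs", e) from e

        if "transcriptomics" in config:
            try:
                tcfg = config["transcriptomics"]
                counts = pd.read_csv(tcfg["counts"])
                eye = set(
                    Path(tcfg["eye_genes"]).read_text().split()
                )
                cands = tx.screen_candidates(counts, eye)
                emit(
                    "candidates.csv",
                    pd.DataFrame(
                        [
                            {
                                "gene": c.gene,
                                "monotone_direction": c.monotone_direction,
                                "abundance_pass": c.abundance_pass,
                                "annotation_pass": c.annotation_pass,
                                "selected": c.selected,
                            }
                            for c in cands
                        ]
                    ),
                )
                manifest["stages"]["transcriptomics"] = {
                    "n_genes": len(cands),
                    "n_selected": sum(c.selected for c in cands),
                }
            except Exception as e:  # noqa: BLE001
                raise PipelineError("transcriptomics", e) from e
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
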