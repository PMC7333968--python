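"""Workflow orchestration: convert → transform → markers → modification →
PERMANOVA/NMDS → ANOVA, with a JSON run manifest.

A run is configured by a plain dictionary (typically loaded from YAML),
executed stage by stage into an output directory of diff-able CSV/JSON
files, and described by a manifest recording input hashes, seeds and
parameters so the run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from trophfa import __version__
from trophfa.markers import arcsine_sqrt_transform, marker_summary
from trophfa.modification import modification_table
from trophfa.multivariate import centroid_shifts, euclidean_distances, nmds, permanova_oneway
from trophfa.profiles import FAProfileTable, concat_tables, read_profile_table, write_profile_table
from trophfa.synthetic import AssayConfig, generate_assay
from trophfa.univariate import anova_tukey

DEFAULT_STAGES = ("markers", "modify", "permanova", "nmds", "anova")


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _transform_values(table: FAProfileTable, transform: str) -> pd.DataFrame:
    if transform == "arcsine":
        return arcsine_sqrt_transform(table)
    if transform == "raw":
        return table.values
    raise ValueError(f"unknown transform {transform!r}; use 'arcsine' or 'raw'")


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the configured stages; return (and write) the run manifest.

    Config keys
    -----------
    ``seed`` (int, required) — master seed, logged and reused by every
    stochastic stage.  ``inputs`` — either ``{"consumers": path, "foods":
    path}`` or ``{"simulate": {...AssayConfig kwargs...}}``.  ``pairing`` —
    consumer→food treatment map (required for the ``modify`` stage).
    ``stages`` — subset of {markers, modify, permanova, nmds, anova}.
    ``params`` — ``trim_fraction`` (default 0.10), ``n_perm`` (default
    9999), ``transform`` ("arcsine"/"raw", default "arcsine"),
    ``anova_fa`` (labels to test; default the table's most abundant FA).

    Failures raise :class:`PipelineStageError` naming the stage; partial
    outputs and a manifest noting the failure are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if "seed" not in config:
        raise ValueError("config must set a seed")
    seed = int(config["seed"])
    params = dict(config.get("params", {}))
    trim = float(params.get("trim_fraction", 0.10))
    n_perm = int(params.get("n_perm", 9999))
    transform = params.get("transform", "arcsine")
    stages = list(config.get("stages", DEFAULT_STAGES))

    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "params": {"trim_fraction": trim, "n_perm": n_perm, "transform": transform},
        "stages": {},
        "inputs": {},
    }

    def finish(status: str) -> dict:
        manifest["status"] = status
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest

    def record(stage: str, outputs: dict) -> None:
        manifest["stages"][stage] = {"status": "ok", "outputs": outputs}

    # ---- inputs -------------------------------------------------------------
    inputs = config.get("inputs", {})
    try:
        if "simulate" in inputs:
            sim = dict(inputs["simulate"])
            assay = AssayConfig(**sim)
            foods, consumers, truth = generate_assay(assay, seed=seed)
            write_profile_table(foods, out / "foods.csv")
            write_profile_table(consumers, out / "consumers.csv")
            (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
            manifest["inputs"]["simulate"] = {"seed": seed}
            record("simulate", {"foods": "foods.csv", "consumers": "consumers.csv",
                                "truth": "truth.json"})
        else:
            consumers = read_profile_table(inputs["consumers"])
            foods = read_profile_table(inputs["foods"]) if "foods" in inputs else None
            for key in ("consumers", "foods"):
                if key in inputs:
                    manifest["inputs"][key] = {
                        "path": str(inputs[key]), "sha256": _sha256(Path(inputs[key]))
                    }
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001 - manifest must name the stage
        finish("failed")
        raise PipelineStageError("inputs", exc) from exc

    pairing = config.get("pairing")
    if pairing is None and foods is not None:
        shared = sorted(
            set(consumers.meta["treatment"]).intersection(foods.meta["treatment"])
        )
        pairing = {t: t for t in shared}

    def run_stage(stage: str):
        if stage == "markers":
            marker_summary(consumers).to_csv(out / "markers.csv")
            record("markers", {"markers": "markers.csv"})
        elif stage == "modify":
            if foods is None or not pairing:
                raise ValueError("modify stage needs a foods table and a pairing")
            mod = modification_table(consumers, foods, pairing, trim_fraction=trim)
            mod.to_csv(out / "modification.csv", index=False)
            record("modify", {"modification": "modification.csv"})
        elif stage == "permanova":
            table = consumers if foods is None else concat_tables([consumers, foods])
            groups = [
                f"{r}:{t}" for r, t in zip(table.meta["role"], table.meta["treatment"])
            ]
            dm = euclidean_distances(_transform_values(table, transform))
            res = permanova_oneway(dm, groups, n_perm=n_perm, seed=seed)
            res.to_frame().to_csv(out / "permanova.csv", index=False)
            record("permanova", {"permanova": "permanova.csv"})
        elif stage == "nmds":
            table = consumers if foods is None else concat_tables([consumers, foods])
            dm = euclidean_distances(_transform_values(table, transform))
            ord_res = nmds(dm, k=2, seed=seed)
            ord_res.coordinates.to_csv(out / "nmds_coordinates.csv")
            summary = {"stress": ord_res.stress, "converged": ord_res.converged,
                       "n_iter": ord_res.n_iter, "seed": seed}
            if foods is not None and pairing:
                groups = [
                    f"{r}:{t}" for r, t in zip(table.meta["role"], table.meta["treatment"])
                ]
                shift_pairing = {
                    f"consumer:{c}": f"food:{f}" for c, f in pairing.items()
                }
                shifts = centroid_shifts(ord_res.coordinates, groups, shift_pairing)
                shifts.to_csv(out / "centroid_shifts.csv", index=False)
            (out / "nmds_summary.json").write_text(json.dumps(summary, indent=2))
            record("nmds", {"coordinates": "nmds_coordinates.csv",
                            "summary": "nmds_summary.json"})
        elif stage == "anova":
            fa_list = params.get("anova_fa")
            if not fa_list:
                fa_list = [consumers.values.mean().idxmax()]
            trans = _transform_values(consumers, transform)
            rows = []
            for lab in fa_list:
                res = anova_tukey(trans[lab], consumers.meta["treatment"])
                rows.append({"fa": lab, "F": res.f_stat, "df_between": res.df_between,
                             "df_within": res.df_within, "p": res.p_value})
            pd.DataFrame(rows).to_csv(out / "anova.csv", index=False)
            record("anova", {"anova": "anova.csv"})
        else:
            raise ValueError(f"unknown stage {stage!r}")

    for stage in stages:
        try:
            run_stage(stage)
        except Exception as exc:  # noqa: BLE001
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            finish("failed")
            raise PipelineStageError(stage, exc) from exc

    return finish("ok")
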