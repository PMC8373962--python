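"""Orchestration of the headline workflow: cluster each water type, fit the
mixing model per cluster, run the diagnostics, and write a consolidated,
re-runnable set of CSV/JSON outputs plus a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import WardClusterer
from .datatypes import AnalysisConfig, SampleRecord, SourceProfile
from .diagnostics import (
    classify_nitrification,
    denitrification_assessment,
    exceedance_flags,
    nitrification_o18_range,
)
from .io import dump_config, validate_dataset
from .mixing import fit_mixing_model

logger = logging.getLogger(__name__)

__all__ = ["run_cluster_then_mix", "PipelineError"]


class PipelineError(RuntimeError):
    pass


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_cluster_then_mix(
    samples: list[SampleRecord],
    sources: list[SourceProfile],
    config: AnalysisConfig,
    out_dir: str | Path,
    input_paths: dict[str, str] | None = None,
) -> dict:
    """Run cluster → mix → diagnose and write all outputs to ``out_dir``.

    Returns the manifest dict.  The manifest is written even on partial
    failure; ``manifest["ok"]`` is True iff every stage completed and all
    R̂ values stayed at or below the configured threshold.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.rng_seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {
            name: _digest(Path(p)) for name, p in (input_paths or {}).items() if Path(p).exists()
        },
        "outputs": [],
        "warnings": [],
        "stages": [],
        "ok": False,
    }

    def emit(name: str, frame: pd.DataFrame) -> None:
        frame.to_csv(out / name, index=False)
        manifest["outputs"].append(name)

    try:
        violations = validate_dataset(samples, sources, config)
        manifest["stages"].append("validate")
        if violations:
            manifest["validation_errors"] = violations
            raise PipelineError(f"dataset not runnable: {violations}")

        dump_config(config, out / "config.json")
        manifest["outputs"].append("config.json")

        # --- clustering per water type ------------------------------------
        assign_rows, gvf_rows, tree_dump = [], [], {}
        groups: dict[str, list[SampleRecord]] = {}
        for wt in ("surface", "ground"):
            subset = [
                s for s in samples
                if s.water_type == wt and all(s.tracer(t) is not None for t in config.tracers)
            ]
            excluded = [
                s.sample_id for s in samples
                if s.water_type == wt and any(s.tracer(t) is None for t in config.tracers)
            ]
            if excluded:
                logger.info("%s: excluded samples with missing tracers: %s", wt, excluded)
            if len(subset) < 2:
                continue
            X = np.array([[s.tracer(t) for t in config.tracers] for s in subset])
            clusterer = WardClusterer(
                n_clusters=config.n_clusters(wt), standardize=config.standardize_features
            ).fit(X)
            result = clusterer.result([s.sample_id for s in subset])
            tree_dump[wt] = [list(m) for m in clusterer.tree_.merges]
            gvf_rows.append(
                {"scope": wt, "label": "partition", "gvf": result.partition_gvf}
            )
            for lab, g in result.per_group_gvf.items():
                gvf_rows.append({"scope": wt, "label": lab, "gvf": g})
            for s in subset:
                lab = result.assignments[s.sample_id]
                assign_rows.append(
                    {"sample_id": s.sample_id, "water_type": wt, "cluster_label": lab}
                )
                groups.setdefault(f"{wt}-{lab}", []).append(s)
        emit("assignments.csv", pd.DataFrame(assign_rows))
        emit("gvf.csv", pd.DataFrame(gvf_rows))
        (out / "linkage.json").write_text(json.dumps(tree_dump, indent=2) + "\n")
        manifest["outputs"].append("linkage.json")
        manifest["stages"].append("cluster")

        # --- mixing model per cluster -------------------------------------
        contrib_rows, diag_json = [], {}
        all_converged = True
        for label, members in sorted(groups.items()):
            posterior = fit_mixing_model(
                members,
                sources,
                mcmc=config.mcmc,
                tracers=config.tracers,
                sigma_prior_scale=config.sigma_prior_scale,
                group_label=label,
            )
            diag_json[label] = {
                "rhat": posterior.rhat,
                "acceptance": posterior.acceptance,
                "converged": posterior.converged,
            }
            if not posterior.converged:
                all_converged = False
                manifest["warnings"].append(f"group {label}: R-hat above threshold")
            for k, sid in enumerate(posterior.source_ids):
                pct = posterior.draws_P[:, k] * 100.0
                contrib_rows.append(
                    {
                        "group": label,
                        "source": sid,
                        "mean_pct": round(float(pct.mean()), 1),
                        "sd_pct": round(float(pct.std(ddof=0)), 1),
                    }
                )
            draws = pd.DataFrame(
                posterior.draws_P, columns=[f"P_{s}" for s in posterior.source_ids]
            )
            for j, t in enumerate(posterior.tracers):
                draws[f"sigma_{t}"] = posterior.draws_sigma[:, j]
            draws.insert(0, "chain", posterior.chain)
            draws.insert(1, "iteration", np.arange(len(draws)))
            emit(f"draws_{label}.csv", draws)
        emit("contributions.csv", pd.DataFrame(contrib_rows))
        (out / "diagnostics.json").write_text(json.dumps(diag_json, indent=2) + "\n")
        manifest["outputs"].append("diagnostics.json")
        manifest["stages"].append("mix")

        # --- biogeochemical diagnostics -----------------------------------
        h2o = [s.d18O_H2O for s in samples if s.d18O_H2O is not None]
        nitr_rows, corr_rows, exc_rows = [], [], []
        if h2o:
            window = nitrification_o18_range(min(h2o), max(h2o))
            for sid, status in classify_nitrification(samples, window).items():
                nitr_rows.append(
                    {"sample_id": sid, "status": status.value,
                     "lo": window.lo, "hi": window.hi}
                )
        scopes: dict[str, list[SampleRecord]] = dict(groups)
        for s in samples:
            if s.region:
                scopes.setdefault(f"region-{s.region}", []).append(s)
        for scope, members in sorted(scopes.items()):
            if len(members) < 3:
                continue
            for d in denitrification_assessment(members, alpha=config.alpha):
                corr_rows.append(
                    {"scope": scope, "pair": d.pair, "r": d.r, "p": d.p,
                     "n": d.n, "interpretation": d.interpretation.value}
                )
        for f in exceedance_flags(
            samples, config.who_no3_threshold, config.class_v_tn_threshold
        ):
            exc_rows.append(
                {"sample_id": f.sample_id,
                 "who_no3_exceeded": f.who_no3_exceeded,
                 "class_v_tn_exceeded": f.class_v_tn_exceeded,
                 "who_threshold": f.who_threshold,
                 "class_v_threshold": f.class_v_threshold}
            )
        emit("nitrification.csv", pd.DataFrame(nitr_rows))
        emit("correlations.csv", pd.DataFrame(corr_rows))
        emit("exceedance.csv", pd.DataFrame(exc_rows))
        manifest["stages"].append("diagnose")
        manifest["ok"] = all_converged
    finally:
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
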