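"""Markdown report and TSV table outputs for an end-to-end analysis run."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .pipeline import AnalysisResult
from .pls import y_loading_profile

__all__ = ["write_report", "cv_summary_table", "loading_profile_table"]


def loading_profile_table(result: AnalysisResult, subtests) -> pd.DataFrame:
    rows = []
    for mod, res in result.modality_results.items():
        prof = y_loading_profile(res.model, min(result.config.n_retained, res.model.n_components))
        rows.append({"modality": mod, **dict(zip(subtests, prof))})
    return pd.DataFrame(rows)


def cv_summary_table(result: AnalysisResult) -> pd.DataFrame:
    """Per (modality, subtest) LOOCV accuracy, with a Benjamini-Hochberg
    adjusted-p column as supplementary information."""
    rows = []
    for mod, res in result.modality_results.items():
        if res.cv is None:
            continue
        for subtest, r, p in zip(res.cv.subtests, res.cv.r, res.cv.p_value):
            rows.append({"modality": mod, "subtest": subtest, "r": r, "p_value": p})
    df = pd.DataFrame(rows)
    if not df.empty:
        ok = df["p_value"].notna()
        adj = np.full(len(df), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(df.loc[ok, "p_value"], method="fdr_bh")[1]
        df["p_bh"] = adj
    return df


def _fmt(df: pd.DataFrame) -> str:
    return df.to_string(index=False, float_format=lambda v: f"{v:.3f}") + "\n"


def write_report(
    result: AnalysisResult,
    subtests,
    out_dir: str | Path,
    ground_truth: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Write the report tables and a markdown summary; returns the report path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg: RunConfig = result.config
    stamp = f"config {cfg.hash()}" + (f", seed {seed}" if seed is not None else "")

    for mod, res in result.modality_results.items():
        res.selection.ranking.head(200).to_csv(out / f"vip_ranking_{mod}.tsv", sep="\t", index=False)
        res.explained.to_csv(out / f"explained_covariance_{mod}.tsv", sep="\t", index=False)
        if res.cv is not None:
            pred = pd.DataFrame(res.cv.predicted, columns=[f"pred_{s}" for s in res.cv.subtests])
            obs = pd.DataFrame(res.cv.observed, columns=[f"obs_{s}" for s in res.cv.subtests])
            pd.concat([obs, pred], axis=1).to_csv(out / f"cv_predictions_{mod}.tsv", sep="\t", index=False)

    shared_tab = pd.DataFrame({"region": result.shared.counts.index, "n_models": result.shared.counts.values})
    shared_tab = shared_tab.sort_values(["n_models", "region"], ascending=[False, True])
    shared_tab.to_csv(out / "shared_consensus.tsv", sep="\t", index=False)

    uniq_rows = [
        {"region": r, "subtest": s}
        for s, regions in result.unique.assignments.items()
        for r in regions
    ]
    pd.DataFrame(uniq_rows, columns=["region", "subtest"]).to_csv(
        out / "unique_regions.tsv", sep="\t", index=False
    )
    if result.variance is not None:
        result.variance.table.to_csv(out / "variance_decomposition.tsv", sep="\t", index=False)

    profiles = loading_profile_table(result, subtests)
    cv_table = cv_summary_table(result)

    lines = [f"# Multimodal PLS lesion-symptom mapping report", "", f"_{stamp}_", ""]
    lines += ["## Subtest loading profiles", "",
              "Relative contribution of each subtest to the latent decomposition, per modality:",
              "", "```", _fmt(profiles), "```", ""]
    comp_tab = pd.DataFrame(
        {
            "modality": list(result.modality_results),
            "components_to_50pct_covariance": [
                res.components_to_half_covariance for res in result.modality_results.values()
            ],
        }
    )
    lines += ["## Explained brain-behaviour covariance", "",
              "Smallest number of latent variables reaching 50% cumulative explained covariance:",
              "", "```", _fmt(comp_tab), "```", ""]
    lines += ["## Shared-region consensus", "",
              f"Regions passing VIP selection in >= {cfg.min_models_shared} models "
              f"(core: >= {cfg.min_models_core}):", "", "```",
              _fmt(shared_tab[shared_tab["n_models"] >= cfg.min_models_shared]), "```", ""]
    if not cv_table.empty:
        lines += ["## VIP-restricted LOOCV accuracy", "", "```", _fmt(cv_table), "```", ""]
    lines += ["## Unique regions per subtest", "", "```",
              _fmt(pd.DataFrame(uniq_rows, columns=["region", "subtest"])), "```", ""]
    if result.variance is not None:
        lines += ["## Shared + unique variance decomposition", "",
                  f"Stage 1: lesion % of shared predictors {result.shared_predictors}; "
                  "stage 2: MD of unique regions on stage-1 residuals.", "", "```",
                  _fmt(result.variance.table), "```", ""]
    if ground_truth:
        lines += ["## Ground-truth recovery", ""]
        gt_shared = set(ground_truth.get("shared_regions", []))
        found = set(result.shared.consensus())
        lines += [f"- planted shared regions recovered: "
                  f"{sorted(gt_shared & found)} (missed: {sorted(gt_shared - found)})"]
        for s, regions in ground_truth.get("unique_regions", {}).items():
            got = set(result.unique.assignments.get(s, []))
            lines += [f"- {s}: unique recovered {sorted(set(regions) & got)} "
                      f"(missed: {sorted(set(regions) - got)})"]
        lines += [""]
    path = out / "report.md"
    path.write_text("\n".join(lines))
    summary = {
        "config_hash": cfg.hash(),
        "seed": seed,
        "modalities": list(result.modality_results),
        "n_shared_consensus": int(len(result.shared.consensus())),
        "n_unique": {s: len(v) for s, v in result.unique.assignments.items()},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return path
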