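"""End-to-end orchestration: cohort I/O on disk and the full analysis.

``write_cohort``/``read_cohort`` persist a cohort as plain TSV (regional
modalities as subjects-by-regions tables, connectivity as per-subject
square matrices, behaviour as one table, ground truth as JSON).
``analyze`` chains modality-specific model fitting, cross-modality shared
consensus, unique-region calling, and the residual-variance regression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .atlas import devectorize_connectome
from .config import RunConfig
from .crossval import ModalityResult, run_all_modalities
from .dataset import (
    PAIRWISE_MODALITIES,
    AssembledDataset,
    assemble_dataset,
    read_behaviour_tsv,
    read_connectome_dir,
    read_feature_tsv,
    write_behaviour_tsv,
    write_connectome_dir,
    write_feature_tsv,
)
from .decompose import (
    SharedRegionSet,
    UniqueRegionMap,
    VarianceDecomposition,
    call_unique_regions,
    consensus_shared,
    residual_variance_analysis,
)
from .synthetic import SyntheticCohort

__all__ = ["AnalysisResult", "write_cohort", "read_cohort", "analyze"]


@dataclass
class AnalysisResult:
    """Everything the end-to-end analysis produces."""

    modality_results: dict[str, ModalityResult]
    shared: SharedRegionSet
    unique: UniqueRegionMap
    variance: VarianceDecomposition | None
    config: RunConfig
    shared_predictors: list[str] = field(default_factory=list)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_behaviour_tsv(cohort.behaviour, out / "behaviour.tsv")
    n_reg = cohort.spec.regions.n_regions
    for mod, mfm in cohort.modalities.items():
        if mfm.feature_kind == "pairwise":
            mats = {
                sid: devectorize_connectome(mfm.values[i], n_reg)
                for i, sid in enumerate(mfm.subject_ids)
            }
            write_connectome_dir(mats, out / mod)
        else:
            write_feature_tsv(mfm, out / f"{mod}.tsv")
    (out / "ground_truth.json").write_text(json.dumps(cohort.ground_truth, indent=1))
    cohort.spec.regions.table.to_csv(out / "regions.tsv", sep="\t", index=False)


def read_cohort(data_dir: str | Path, modalities: list[str] | None = None) -> AssembledDataset:
    data = Path(data_dir)
    behaviour = read_behaviour_tsv(data / "behaviour.tsv")
    regions = pd.read_csv(data / "regions.tsv", sep="\t")
    region_names = list(regions.sort_values("index")["name"])
    found: dict = {}
    for tsv in sorted(data.glob("*.tsv")):
        mod = tsv.stem
        if mod in ("behaviour", "regions"):
            continue
        if modalities is not None and mod not in modalities:
            continue
        found[mod] = read_feature_tsv(tsv, mod, "regional")
    for sub in sorted(p for p in data.iterdir() if p.is_dir()):
        mod = sub.name
        if modalities is not None and mod not in modalities:
            continue
        found[mod] = read_connectome_dir(sub, mod, region_names)
    if not found:
        raise ValueError(f"no modality data found under {data}")
    return assemble_dataset(found, behaviour)


def analyze(dataset: AssembledDataset, config: RunConfig | None = None) -> AnalysisResult:
    """Run the full pipeline on an assembled dataset."""
    config = RunConfig() if config is None else config
    results = run_all_modalities(
        dataset,
        n_components=config.n_components,
        n_retained=config.n_retained,
        vip_threshold=config.vip_threshold,
        n_top=config.n_top(),
        selection_mode=config.selection_mode,
        modalities=[m for m in config.modalities if m in dataset.modalities],
    )
    selections = {m: r.selection for m, r in results.items()}
    region_names = _region_names(dataset)
    if len(selections) >= 2:
        shared = consensus_shared(selections, config.min_models_shared, region_names)
    else:
        # single-modality run: no cross-modality consensus is defined;
        # report the one selection's regions as a count table of ones
        from .decompose import regions_of_selection

        only = next(iter(selections.values()))
        touched = sorted(regions_of_selection(only))
        flags = pd.DataFrame(True, index=touched, columns=list(selections))
        shared = SharedRegionSet(flags.sum(axis=1).astype(int), flags, config.min_models_shared)
    models = {m: r.model for m, r in results.items()}
    labels = {m: dataset.modalities[m].feature_labels for m in results}
    core = shared.consensus(config.min_models_core)
    unique = call_unique_regions(
        models,
        labels,
        region_names,
        subtests=dataset.behaviour.subtests,
        beta_threshold=config.beta_threshold,
        min_modalities=config.min_modalities_unique,
        n_components=config.n_components,
        shared_consensus=core,
    )
    variance = None
    shared_predictors: list[str] = []
    if "lesion" in dataset.modalities and "md" in dataset.modalities:
        mean_vip = _mean_vip(results, region_names)
        shared_predictors = shared.top_regions(config.n_shared_predictors, mean_vip)
        if shared_predictors and any(unique.assignments.values()):
            variance = residual_variance_analysis(
                dataset.behaviour,
                dataset.modalities["lesion"],
                dataset.modalities["md"],
                shared_predictors,
                unique.top_assignments(config.n_unique_predictors),
            )
    return AnalysisResult(results, shared, unique, variance, config, shared_predictors)


def _region_names(dataset: AssembledDataset) -> list[str]:
    for mfm in dataset.modalities.values():
        if mfm.feature_kind == "regional":
            return list(mfm.feature_labels)
    # pairwise only: recover region names from edge labels
    names: list[str] = []
    seen = set()
    for lab in next(iter(dataset.modalities.values())).feature_labels:
        for r in lab.split("|"):
            if r not in seen:
                seen.add(r)
                names.append(r)
    return names


def _mean_vip(results: dict[str, ModalityResult], region_names: list[str]) -> pd.Series:
    """Mean VIP per region across regional-modality rankings (edge VIPs are
    not mixed in; they live on a different feature grain)."""
    acc = pd.DataFrame(index=region_names)
    for mod, res in results.items():
        if mod in PAIRWISE_MODALITIES:
            continue
        rank = res.selection.ranking.set_index("feature")["vip"]
        acc[mod] = rank.reindex(region_names)
    if acc.empty or acc.shape[1] == 0:
        return pd.Series(0.0, index=region_names)
    return acc.mean(axis=1).fillna(0.0)
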