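"""Dissociating shared from unique lesion anatomy.

Three stages sit on top of the per-modality PLS models:

* **Cross-modality consensus** — a region counts toward the shared
  substrate when it passes VIP selection in many independent
  modality-specific models (default: >= 4 of 11; "core shared" >= 6).
  Edge-level selections from connectivity models are first summarized to
  regions by counting incident selected edges.
* **Unique-region calling** — within each modality and subtest, the
  absolute standardized regression coefficients are min-max rescaled to
  [0, 1] and thresholded at 0.2; a region is unique to a subtest when it
  exceeds the threshold for exactly that one subtest, consistently in at
  least two modalities. Uniqueness is called on coefficient magnitude:
  damage can impair and perfusion can facilitate, so what matters is
  involvement, not sign.
* **Residual-variance regression** — each subtest is regressed on
  proportional lesion of the top shared regions (stage 1); the stage-1
  residuals are regressed on mean-diffusivity values of that subtest's
  unique regions (stage 2), quantifying how much residual variance the
  unique anatomy explains on top of the shared anatomy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .crossval import VipSelection
from .dataset import SUBTESTS, BehaviourMatrix, ModalityFeatureMatrix
from .pls import PLSModel

__all__ = [
    "SharedRegionSet",
    "UniqueRegionMap",
    "VarianceDecomposition",
    "regions_of_selection",
    "consensus_shared",
    "call_unique_regions",
    "residual_variance_analysis",
]


@dataclass
class SharedRegionSet:
    """Per-region count of modality models in which it passed VIP selection."""

    counts: pd.Series = field(repr=False)  # index: region name
    per_modality: pd.DataFrame = field(repr=False)  # regions x modalities bool
    min_models: int

    def consensus(self, min_models: int | None = None) -> list[str]:
        t = self.min_models if min_models is None else min_models
        hits = self.counts[self.counts >= t]
        return list(hits.index)

    def top_regions(self, k: int, mean_vip: pd.Series | None = None) -> list[str]:
        """Top-k regions by model count; ties broken by mean VIP (when
        given) then by name for determinism."""
        df = pd.DataFrame({"count": self.counts})
        df["vip"] = mean_vip.reindex(df.index).fillna(0.0) if mean_vip is not None else 0.0
        df = df.sort_values(["count", "vip"], ascending=False, kind="mergesort")
        return list(df.index[:k])


@dataclass
class UniqueRegionMap:
    """Regions uniquely associated with one subtest each."""

    assignments: dict[str, list[str]]  # subtest -> region names
    support: pd.DataFrame = field(repr=False)  # region, subtest, modalities
    conflicts: list[str] = field(default_factory=list)
    overlap_with_shared: list[str] = field(default_factory=list)

    def top_assignments(self, k: int) -> dict[str, list[str]]:
        """Per subtest, the k unique regions with the broadest modality
        support (ties by name for determinism)."""
        counts = (
            self.support.groupby(["region", "subtest"])["modality"].nunique()
            if not self.support.empty
            else None
        )
        out: dict[str, list[str]] = {}
        for s, regions in self.assignments.items():
            if counts is None:
                out[s] = list(regions[:k])
                continue
            ranked = sorted(
                regions, key=lambda r: (-int(counts.get((r, s), 0)), r)
            )
            out[s] = ranked[:k]
        return out


@dataclass
class VarianceDecomposition:
    """Shared-model R^2 and unique-model residual delta-R^2 per subtest."""

    table: pd.DataFrame = field(repr=False)
    shared_predictors: list[str]
    unique_predictors: dict[str, list[str]]
    predictor_p_values: dict[str, pd.Series] = field(default_factory=dict)


def _edge_endpoints(label: str) -> tuple[str, str]:
    a, _, b = label.partition("|")
    return a, b


def regions_of_selection(selection: VipSelection) -> set[str]:
    """Region names touched by a selection; edges map to both endpoints."""
    if not selection.retained:
        return set()
    if "|" in selection.retained[0]:
        out: set[str] = set()
        for lab in selection.retained:
            a, b = _edge_endpoints(lab)
            out.update((a, b))
        return out
    return set(selection.retained)


def consensus_shared(
    selections: dict[str, VipSelection],
    min_models: int = 4,
    region_names: list[str] | None = None,
) -> SharedRegionSet:
    """Count, per region, the modality models whose VIP selection touched it."""
    if len(selections) < 2:
        raise ValueError("consensus needs selections from at least 2 modalities")
    if region_names is None:
        names: set[str] = set()
        for sel in selections.values():
            names.update(regions_of_selection(sel))
        region_names = sorted(names)
    flags = pd.DataFrame(False, index=region_names, columns=list(selections))
    for mod, sel in selections.items():
        for r in regions_of_selection(sel):
            if r in flags.index:
                flags.loc[r, mod] = True
    counts = flags.sum(axis=1).astype(int)
    return SharedRegionSet(counts, flags, min_models)


def _regional_abs_beta(
    model: PLSModel, feature_labels: list[str], region_names: list[str], n_components: int
) -> pd.DataFrame:
    """|standardized beta| per (region, subtest); edge features aggregate
    to regions by the maximum magnitude over incident edges."""
    B = np.abs(model.coefficients_std(min(n_components, model.n_components)))
    if feature_labels and "|" in feature_labels[0]:
        agg = pd.DataFrame(0.0, index=region_names, columns=range(B.shape[1]))
        for lab, row in zip(feature_labels, B):
            a, b = _edge_endpoints(lab)
            for r in (a, b):
                if r in agg.index:
                    agg.loc[r] = np.maximum(agg.loc[r].to_numpy(), row)
        return agg
    return pd.DataFrame(B, index=feature_labels, columns=range(B.shape[1]))


def call_unique_regions(
    models: dict[str, PLSModel],
    feature_labels: dict[str, list[str]],
    region_names: list[str],
    subtests: tuple[str, ...] = SUBTESTS,
    beta_threshold: float = 0.2,
    min_modalities: int = 2,
    n_components: int = 5,
    shared_consensus: list[str] | None = None,
    threshold_before_rescale: bool = False,
) -> UniqueRegionMap:
    """Call subtest-unique regions from per-modality coefficient maps.

    Default order of operations rescales |beta| to [0, 1] within each
    (modality, subtest) and then applies the 0.2 threshold, which makes
    the cut comparable across modalities with different units; the
    alternative order (threshold raw standardized betas at 0.2, then
    rescale) is available via ``threshold_before_rescale``.
    """
    votes: list[tuple[str, str, str]] = []  # (region, subtest, modality)
    for mod, model in models.items():
        beta = _regional_abs_beta(model, feature_labels[mod], region_names, n_components)
        if not (beta.to_numpy() > 0).any():
            warnings.warn(f"modality {mod}: all-zero coefficients; skipped")
            continue
        if threshold_before_rescale:
            above = beta.to_numpy() >= beta_threshold
        else:
            b = beta.to_numpy()
            lo, hi = b.min(axis=0, keepdims=True), b.max(axis=0, keepdims=True)
            span = np.where(hi > lo, hi - lo, 1.0)
            above = (b - lo) / span >= beta_threshold
        unique_mask = above & (above.sum(axis=1, keepdims=True) == 1)
        rows, cols = np.nonzero(unique_mask)
        for i, j in zip(rows, cols):
            votes.append((beta.index[i], subtests[j], mod))

    support = pd.DataFrame(votes, columns=["region", "subtest", "modality"])
    assignments: dict[str, list[str]] = {s: [] for s in subtests}
    conflicts: list[str] = []
    overlap: list[str] = []
    shared_set = set(shared_consensus or [])
    if not support.empty:
        tally = support.groupby(["region", "subtest"])["modality"].nunique().unstack(fill_value=0)
        for region, row in tally.iterrows():
            winners = [s for s in row.index if row[s] >= min_modalities]
            if len(winners) > 1:
                conflicts.append(str(region))
                continue
            if len(winners) == 1:
                if region in shared_set:
                    overlap.append(str(region))
                    continue
                assignments[winners[0]].append(str(region))
    for s in assignments:
        assignments[s].sort()
    return UniqueRegionMap(assignments, support, conflicts, sorted(overlap))


def _ols_r2(y: np.ndarray, X: np.ndarray) -> tuple[float, pd.Series, sm.regression.linear_model.RegressionResultsWrapper]:
    Xc = sm.add_constant(X, has_constant="add")
    cond = np.linalg.cond(Xc)
    if cond > 1e8:
        warnings.warn(f"ill-conditioned design (cond={cond:.2g}); pseudoinverse fit")
        fit = sm.OLS(y, Xc).fit(method="pinv")
    else:
        fit = sm.OLS(y, Xc).fit()
    pvals = pd.Series(fit.pvalues[1:])
    return float(fit.rsquared), pvals, fit


def residual_variance_analysis(
    behaviour: BehaviourMatrix,
    lesion: ModalityFeatureMatrix,
    md: ModalityFeatureMatrix,
    shared_regions: list[str],
    unique_map: UniqueRegionMap | dict[str, list[str]],
) -> VarianceDecomposition:
    """Two-stage shared + unique variance decomposition.

    Stage 1 regresses each subtest on proportional lesion of the shared
    regions (damage is expected to impair performance); stage 2 regresses
    the stage-1 residuals on MD of the subtest's unique regions (MD
    indexes microstructural integrity). Reports R^2, delta-R^2 and
    per-unique-predictor two-sided p-values.
    """
    unique = unique_map.assignments if isinstance(unique_map, UniqueRegionMap) else unique_map
    lesion_pos = {f: i for i, f in enumerate(lesion.feature_labels)}
    md_pos = {f: i for i, f in enumerate(md.feature_labels)}
    missing = [r for r in shared_regions if r not in lesion_pos]
    if missing:
        raise ValueError(f"shared regions absent from lesion features: {missing}")
    Xs = lesion.values[:, [lesion_pos[r] for r in shared_regions]]
    rows = []
    pvals: dict[str, pd.Series] = {}
    for subtest in behaviour.subtests:
        y = behaviour.column(subtest)
        r2_shared, _, fit = _ols_r2(y, Xs)
        resid = np.asarray(fit.resid)
        uniq = [r for r in unique.get(subtest, []) if r in md_pos]
        dropped = sorted(set(unique.get(subtest, [])) - set(uniq))
        if dropped:
            warnings.warn(f"{subtest}: unique regions missing from MD features: {dropped}")
        if uniq:
            Xu = md.values[:, [md_pos[r] for r in uniq]]
            r2_unique, pv, _ = _ols_r2(resid, Xu)
            pv.index = uniq
            pvals[subtest] = pv
        else:
            r2_unique = np.nan
        rows.append(
            {
                "subtest": subtest,
                "shared_r2": r2_shared,
                "unique_delta_r2": r2_unique,
                "n_shared": len(shared_regions),
                "n_unique": len(uniq),
            }
        )
    return VarianceDecomposition(
        pd.DataFrame(rows), list(shared_regions), {s: list(unique.get(s, [])) for s in behaviour.subtests}, pvals
    )
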