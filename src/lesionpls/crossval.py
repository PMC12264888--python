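"""Modality-specific model fitting, LOOCV prediction, and VIP-restricted
regression of the four subtest scores.

Model accuracy follows the standard protocol for this analysis family:
each subject is held out in turn, the PLS model is refit on the remaining
n-1 subjects (centring/scaling re-estimated inside the fold), the held-out
subject is predicted, and Pearson's r between the n out-of-fold
predictions and the observed scores summarizes accuracy per subtest.

VIP-restricted regression comes in two selection modes. ``"paper"``
selects the high-VIP features once on the full data and then
cross-validates the restricted matrix; ``"nested"`` re-selects inside
every fold, which is leakage-free and is the default headline. Both are
reported so the selection optimism is visible rather than hidden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import PAIRWISE_MODALITIES, AssembledDataset, ModalityFeatureMatrix
from .pls import PLSModel, fit_plsr, vip_scores

__all__ = [
    "CvResult",
    "VipSelection",
    "ModalityResult",
    "loocv_predict",
    "select_vip_regions",
    "vip_restricted_cv",
    "run_all_modalities",
    "default_n_top",
]


@dataclass
class CvResult:
    """Out-of-fold predictions and per-subtest accuracy."""

    subtests: tuple[str, ...]
    observed: np.ndarray = field(repr=False)
    predicted: np.ndarray = field(repr=False)
    r: np.ndarray
    p_value: np.ndarray
    n_components: int
    flags: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return self.observed.shape[0]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subtest": list(self.subtests), "r": self.r, "p_value": self.p_value}
        )


@dataclass
class VipSelection:
    """Ranked features by VIP and the retained high-importance subset."""

    modality: str
    ranking: pd.DataFrame = field(repr=False)  # feature, vip, rank
    retained: list[str]
    n_top: int
    vip_threshold: float

    @property
    def retained_indices(self) -> list[int]:
        pos = dict(zip(self.ranking["feature"], self.ranking.index))
        return sorted(pos[f] for f in self.retained)


@dataclass
class ModalityResult:
    modality: str
    model: PLSModel = field(repr=False)
    selection: VipSelection
    cv: CvResult | None
    explained: pd.DataFrame = field(repr=False)
    components_to_half_covariance: int | None


def _pearson_with_p(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    if np.std(obs) == 0 or np.std(pred) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(obs, pred)
    return float(r), float(p)


def loocv_predict(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    subtests: tuple[str, ...] | None = None,
    scale: bool = True,
) -> CvResult:
    """Leave-one-out cross-validated prediction of every response column."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, k = Y.shape
    if n < 4:
        raise ValueError(f"LOOCV needs at least 4 subjects, got {n}")
    subtests = tuple(f"response_{j}" for j in range(k)) if subtests is None else subtests
    pred = np.empty_like(Y)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        a = min(n_components, min(n - 2, X.shape[1]))
        model = fit_plsr(X[mask], Y[mask], a, scale=scale)
        pred[i] = model.predict(X[i : i + 1])[0]
        mask[i] = True
    r = np.empty(k)
    p = np.empty(k)
    flags = []
    for j in range(k):
        if np.std(Y[:, j]) == 0:
            r[j] = p[j] = np.nan
            flags.append(f"constant observed column: {subtests[j]}")
        else:
            r[j], p[j] = _pearson_with_p(Y[:, j], pred[:, j])
    return CvResult(tuple(subtests), Y, pred, r, p, n_components, flags)


def default_n_top(modality: str) -> int:
    """Retained-feature budget: 50 for connectivity models, 30 otherwise."""
    return 50 if modality in PAIRWISE_MODALITIES else 30


def select_vip_regions(
    model: PLSModel,
    modality: str,
    feature_labels: list[str],
    n_top: int | None = None,
    vip_threshold: float = 1.5,
    n_components: int | None = None,
) -> VipSelection:
    """Rank features by VIP and keep the top-N above the threshold.

    Ties are broken by feature index for determinism. An empty retained
    set is legitimate (all VIP below threshold) and is reported as such.
    """
    n_top = default_n_top(modality) if n_top is None else n_top
    vip = vip_scores(model, n_components)
    order = np.lexsort((np.arange(len(vip)), -vip))
    ranking = pd.DataFrame(
        {
            "feature": [feature_labels[i] for i in order],
            "vip": vip[order],
            "rank": np.arange(1, len(vip) + 1),
        }
    )
    eligible = order[vip[order] > vip_threshold]
    retained = [feature_labels[i] for i in eligible[:n_top]]
    return VipSelection(modality, ranking, retained, n_top, vip_threshold)


def _indices_of(labels: list[str], subset: list[str]) -> list[int]:
    pos = {f: i for i, f in enumerate(labels)}
    return sorted(pos[f] for f in subset)


def vip_restricted_cv(
    X: np.ndarray,
    Y: np.ndarray,
    modality: str,
    feature_labels: list[str],
    mode: str = "nested",
    n_components_fit: int = 20,
    n_components_cv: int = 5,
    n_top: int | None = None,
    vip_threshold: float = 1.5,
    subtests: tuple[str, ...] | None = None,
) -> CvResult | None:
    """LOOCV restricted to the highest-VIP features.

    ``mode="paper"`` performs the selection once on the full data set;
    ``mode="nested"`` re-selects within each training fold so the held-out
    subject never influences its own feature set. Returns ``None`` (with a
    warning) when the selection is empty and no model can be evaluated.
    """
    if mode not in ("paper", "nested"):
        raise ValueError(f"unknown selection mode {mode!r}")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, k = Y.shape
    if n < 4:
        raise ValueError(f"LOOCV needs at least 4 subjects, got {n}")
    subtests = tuple(f"response_{j}" for j in range(k)) if subtests is None else subtests

    def fit_and_select(Xt: np.ndarray, Yt: np.ndarray) -> list[int]:
        a = min(n_components_fit, Xt.shape[0] - 1, Xt.shape[1])
        model = fit_plsr(Xt, Yt, a)
        sel = select_vip_regions(model, modality, feature_labels, n_top, vip_threshold,
                                 n_components=min(n_components_cv, model.n_components))
        return _indices_of(feature_labels, sel.retained)

    if mode == "paper":
        idx = fit_and_select(X, Y)
        if not idx:
            warnings.warn(f"{modality}: empty VIP selection; restricted CV not evaluable")
            return None
        a = min(n_components_cv, len(idx))
        return loocv_predict(X[:, idx], Y, a, subtests)

    pred = np.empty_like(Y)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        idx = fit_and_select(X[mask], Y[mask])
        if not idx:
            warnings.warn(f"{modality}: empty VIP selection in fold {i}; not evaluable")
            return None
        a = min(n_components_cv, len(idx), n - 2)
        model = fit_plsr(X[mask][:, idx], Y[mask], a)
        pred[i] = model.predict(X[i : i + 1, idx])[0]
        mask[i] = True
    r = np.empty(k)
    p = np.empty(k)
    flags = []
    for j in range(k):
        if np.std(Y[:, j]) == 0:
            r[j] = p[j] = np.nan
            flags.append(f"constant observed column: {subtests[j]}")
        else:
            r[j], p[j] = _pearson_with_p(Y[:, j], pred[:, j])
    return CvResult(tuple(subtests), Y, pred, r, p, n_components_cv, flags)


def run_all_modalities(
    dataset: AssembledDataset | dict[str, ModalityFeatureMatrix],
    behaviour=None,
    n_components: int = 20,
    n_retained: int = 5,
    vip_threshold: float = 1.5,
    n_top: dict[str, int] | None = None,
    selection_mode: str = "nested",
    run_cv: bool = True,
    modalities: list[str] | None = None,
) -> dict[str, ModalityResult]:
    """Fit one independent PLS model per modality and summarize each.

    For every modality this fits the full model, ranks features by VIP
    over the retained components, optionally runs the VIP-restricted
    LOOCV, and records the smallest number of components whose cumulative
    explained brain-behaviour covariance reaches 50%.
    """
    if isinstance(dataset, AssembledDataset):
        mods = dataset.modalities
        behaviour = dataset.behaviour
    else:
        mods = dataset
        if behaviour is None:
            raise ValueError("behaviour matrix required when passing a raw modality dict")
    if modalities is not None:
        unknown = [m for m in modalities if m not in mods]
        for m in unknown:
            warnings.warn(f"modality {m!r} not in dataset; skipped")
        mods = {m: mods[m] for m in modalities if m in mods}
    Y = behaviour.scores
    results: dict[str, ModalityResult] = {}
    for mod, mfm in mods.items():
        X = mfm.values
        a = min(n_components, X.shape[0] - 1, X.shape[1])
        model = fit_plsr(X, Y, a)
        a_ret = min(n_retained, model.n_components)
        budget = None if n_top is None else n_top.get(mod)
        selection = select_vip_regions(
            model, mod, mfm.feature_labels, budget, vip_threshold, n_components=a_ret
        )
        explained = model.explained_covariance()
        cum = explained["cumulative_covariance"].to_numpy()
        reach = np.nonzero(cum >= 0.5)[0]
        to_half = int(reach[0]) + 1 if reach.size else None
        cv = None
        if run_cv:
            cv = vip_restricted_cv(
                X, Y, mod, mfm.feature_labels, mode=selection_mode,
                n_components_fit=n_components, n_components_cv=n_retained,
                n_top=budget, vip_threshold=vip_threshold, subtests=behaviour.subtests,
            )
        results[mod] = ModalityResult(mod, model, selection, cv, explained, to_half)
    return results
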