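"""Subject-aligned feature and behaviour containers plus TSV input/output.

All downstream modelling assumes one fixed subject order shared by every
modality and the behaviour table; :func:`assemble_dataset` is the single
place where that alignment happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import vectorize_connectome, edge_labels

__all__ = [
    "SUBTESTS",
    "SUBTEST_MAXIMA",
    "PAIRWISE_MODALITIES",
    "REGIONAL_MODALITIES",
    "ALL_MODALITIES",
    "ModalityFeatureMatrix",
    "BehaviourMatrix",
    "AssembledDataset",
    "assemble_dataset",
    "read_feature_tsv",
    "write_feature_tsv",
    "read_behaviour_tsv",
    "write_behaviour_tsv",
    "read_connectome_dir",
    "write_connectome_dir",
]

# WAB-R subtests in Table-2 order, with their maximum scores.
SUBTESTS = ("spontaneous_speech", "naming", "repetition", "auditory_comprehension")
SUBTEST_MAXIMA = {
    "spontaneous_speech": 20.0,
    "naming": 10.0,
    "repetition": 10.0,
    "auditory_comprehension": 10.0,
}

PAIRWISE_MODALITIES = ("sc", "fc")
REGIONAL_MODALITIES = (
    "lesion",
    "i3mT1",
    "palf",
    "vbm_gm",
    "vbm_wm",
    "fmri",
    "fa",
    "md",
    "cbf",
)
ALL_MODALITIES = ("lesion", "i3mT1", "sc", "fc", "palf", "vbm_gm", "vbm_wm", "fmri", "fa", "md", "cbf")


@dataclass
class ModalityFeatureMatrix:
    """Subjects-by-features matrix for one neuroimaging modality.

    ``feature_kind`` is ``"regional"`` (one column per region) or
    ``"pairwise"`` (one column per region pair, upper-triangle order).
    """

    modality: str
    values: np.ndarray = field(repr=False)
    feature_kind: str
    feature_labels: list[str] = field(repr=False)
    subject_ids: list[str] = field(repr=False)
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x features)")
        if self.feature_kind not in ("regional", "pairwise"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        n, p = self.values.shape
        if len(self.feature_labels) != p:
            raise ValueError(f"{len(self.feature_labels)} labels for {p} features")
        if len(self.subject_ids) != n:
            raise ValueError(f"{len(self.subject_ids)} subject ids for {n} rows")
        if not np.isfinite(self.values).all():
            bad = [self.feature_labels[j] for j in np.unique(np.where(~np.isfinite(self.values))[1])]
            raise ValueError(f"non-finite values in modality {self.modality}: columns {bad[:10]}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def reordered(self, subject_ids: list[str]) -> "ModalityFeatureMatrix":
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        rows = [pos[s] for s in subject_ids]
        return ModalityFeatureMatrix(
            self.modality, self.values[rows], self.feature_kind,
            self.feature_labels, list(subject_ids), self.units,
        )


@dataclass
class BehaviourMatrix:
    """Subjects-by-4 WAB-R subtest scores (bounded by the subtest maxima)."""

    scores: np.ndarray = field(repr=False)
    subject_ids: list[str] = field(repr=False)
    subtests: tuple[str, ...] = SUBTESTS

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(self.subtests):
            raise ValueError("scores must be subjects x n_subtests")
        if len(self.subject_ids) != self.scores.shape[0]:
            raise ValueError("subject id / row count mismatch")
        for j, name in enumerate(self.subtests):
            mx = SUBTEST_MAXIMA.get(name)
            col = self.scores[:, j]
            if not np.isfinite(col).all():
                raise ValueError(f"non-finite scores in {name}")
            if mx is not None and ((col < 0) | (col > mx)).any():
                raise ValueError(f"{name} scores outside [0, {mx}]")

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    def column(self, subtest: str) -> np.ndarray:
        return self.scores[:, self.subtests.index(subtest)]

    def reordered(self, subject_ids: list[str]) -> "BehaviourMatrix":
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        rows = [pos[s] for s in subject_ids]
        return BehaviourMatrix(self.scores[rows], list(subject_ids), self.subtests)


@dataclass
class AssembledDataset:
    """Modalities and behaviour on one shared, identically ordered subject list."""

    modalities: dict[str, ModalityFeatureMatrix]
    behaviour: BehaviourMatrix
    subject_ids: list[str]
    dropped: dict[str, list[str]] = field(default_factory=dict)


def assemble_dataset(
    modalities: dict[str, ModalityFeatureMatrix], behaviour: BehaviourMatrix
) -> AssembledDataset:
    """Intersect subjects across all inputs and align row order everywhere.

    Subjects missing from any modality are dropped from all of them (cohort
    definition requires complete multimodal data); the assembly report lists
    who was dropped from where. Fails if fewer than 3 subjects remain.
    """
    tables: dict[str, list[str]] = {m: mfm.subject_ids for m, mfm in modalities.items()}
    tables["behaviour"] = behaviour.subject_ids
    for name, ids in tables.items():
        if len(set(ids)) != len(ids):
            dups = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate subject ids in {name}: {dups}")
    common = set(behaviour.subject_ids)
    for ids in tables.values():
        common &= set(ids)
    if not common:
        raise ValueError("no subjects shared across all inputs")
    # keep behaviour's order for the surviving subjects
    order = [s for s in behaviour.subject_ids if s in common]
    if len(order) < 3:
        raise ValueError(f"only {len(order)} subjects remain after intersection; need >= 3")
    dropped = {name: sorted(set(ids) - common) for name, ids in tables.items()}
    dropped = {k: v for k, v in dropped.items() if v}
    aligned = {m: mfm.reordered(order) for m, mfm in modalities.items()}
    return AssembledDataset(aligned, behaviour.reordered(order), order, dropped)


# ---------------------------------------------------------------------------
# TSV input/output


def write_feature_tsv(mfm: ModalityFeatureMatrix, path: str | Path) -> None:
    df = pd.DataFrame(mfm.values, columns=mfm.feature_labels)
    df.insert(0, "subject_id", mfm.subject_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_feature_tsv(
    path: str | Path, modality: str, feature_kind: str = "regional", units: str = ""
) -> ModalityFeatureMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "subject_id":
        raise ValueError(f"{path}: first column must be subject_id")
    ids = df["subject_id"].astype(str).tolist()
    labels = list(df.columns[1:])
    return ModalityFeatureMatrix(modality, df[labels].to_numpy(float), feature_kind, labels, ids, units)


def write_behaviour_tsv(behaviour: BehaviourMatrix, path: str | Path) -> None:
    df = pd.DataFrame(behaviour.scores, columns=list(behaviour.subtests))
    df.insert(0, "subject_id", behaviour.subject_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_behaviour_tsv(path: str | Path) -> BehaviourMatrix:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("subject_id",) + SUBTESTS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    ids = df["subject_id"].astype(str).tolist()
    return BehaviourMatrix(df[list(SUBTESTS)].to_numpy(float), ids)


def write_connectome_dir(
    matrices: dict[str, np.ndarray], out_dir: str | Path
) -> None:
    """Write per-subject square connectivity matrices as TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, A in matrices.items():
        np.savetxt(out / f"{sid}.tsv", A, delimiter="\t", fmt="%.6g")


def read_connectome_dir(
    path: str | Path, modality: str, region_names: list[str], units: str = ""
) -> ModalityFeatureMatrix:
    """Assemble a pairwise feature matrix from per-subject square TSVs."""
    files = sorted(Path(path).glob("*.tsv"))
    if not files:
        raise ValueError(f"no connectome TSVs under {path}")
    ids, rows = [], []
    for f in files:
        A = np.loadtxt(f, delimiter="\t")
        if A.shape != (len(region_names), len(region_names)):
            raise ValueError(f"{f}: expected {len(region_names)}x{len(region_names)}, got {A.shape}")
        vec, _ = vectorize_connectome(A)
        ids.append(f.stem)
        rows.append(vec)
    return ModalityFeatureMatrix(
        modality, np.vstack(rows), "pairwise", edge_labels(region_names), ids, units
    )
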