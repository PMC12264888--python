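"""Homotopic region tables, parcellation volumes, and region-level feature extraction.

The analyses in this package operate on region-level feature matrices built
from a homotopic parcellation: every region in the left hemisphere has a
mirror ("homotope") in the right hemisphere. The default table has 384
regions (192 per hemisphere), matching the scale of homotopic whole-brain
atlases used in connectome-based lesion-symptom mapping.

Volumetric inputs (lesion masks, parcellation labels) are handled through
nibabel; everything downstream works on plain subjects-by-regions arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "RegionTable",
    "default_region_table",
    "synthetic_parcellation",
    "region_damage_from_mask",
    "vectorize_connectome",
    "devectorize_connectome",
    "edge_labels",
    "tiv_normalize",
    "palf_ratio",
]


@dataclass(frozen=True)
class RegionTable:
    """Table of parcellation regions with hemisphere and homotope links.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per region with columns ``region_id`` (integer label in the
        parcellation volume), ``name``, ``hemisphere`` (``"left"`` or
        ``"right"``), ``homotope_id`` (region_id of the mirror region) and
        ``index`` (0-based column position in feature matrices).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"region_id", "name", "hemisphere", "homotope_id", "index"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"region table missing columns: {sorted(missing)}")
        hemis = set(t["hemisphere"])
        if hemis != {"left", "right"}:
            raise ValueError(f"expected hemispheres left/right, got {sorted(hemis)}")
        n_left = (t["hemisphere"] == "left").sum()
        n_right = (t["hemisphere"] == "right").sum()
        if n_left != n_right:
            raise ValueError(f"unbalanced hemispheres: {n_left} left vs {n_right} right")
        if sorted(t["index"]) != list(range(len(t))):
            raise ValueError("region indices must be a permutation of 0..n-1")
        if t["region_id"].duplicated().any():
            raise ValueError("duplicate region_ids")
        # homotope map must be an involution crossing hemispheres
        by_id = t.set_index("region_id")
        for rid, row in by_id.iterrows():
            mate = by_id.loc[row["homotope_id"]]
            if mate["hemisphere"] == row["hemisphere"]:
                raise ValueError(f"region {rid} homotope is in the same hemisphere")
            if mate["homotope_id"] != rid:
                raise ValueError(f"homotope mapping not symmetric at region {rid}")

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def names(self) -> list[str]:
        return list(self.table.sort_values("index")["name"])

    @property
    def region_ids(self) -> np.ndarray:
        return self.table.sort_values("index")["region_id"].to_numpy()

    def hemisphere_indices(self, hemisphere: str) -> np.ndarray:
        t = self.table
        return t.loc[t["hemisphere"] == hemisphere].sort_values("index")["index"].to_numpy()

    def name_to_index(self) -> dict[str, int]:
        return dict(zip(self.table["name"], self.table["index"]))


def default_region_table(n_per_hemisphere: int = 192) -> RegionTable:
    """Build the default homotopic region table.

    Left-hemisphere regions get ids ``1..n`` and names ``L001..``; their
    right-hemisphere homotopes get ids ``n+1..2n`` and names ``R001..``.
    Column indices put the left block first, then the right block, so index
    ``i`` and ``i + n`` are homotopes.
    """
    n = n_per_hemisphere
    rows = []
    for i in range(n):
        rows.append((i + 1, f"L{i + 1:03d}", "left", n + i + 1, i))
        rows.append((n + i + 1, f"R{i + 1:03d}", "right", i + 1, n + i))
    df = pd.DataFrame(rows, columns=["region_id", "name", "hemisphere", "homotope_id", "index"])
    return RegionTable(df.sort_values("index").reset_index(drop=True))


def synthetic_parcellation(
    regions: RegionTable, shape: tuple[int, int, int] = (48, 48, 48)
) -> nib.Nifti1Image:
    """Build a small labelled volume realizing a homotopic region table.

    Left-hemisphere regions fill the x < shape[0]/2 half as contiguous
    equal-sized blocks (in flattened voxel order); the right half mirrors
    them through the mid-sagittal plane so each region and its homotope
    occupy mirror-image voxels. This is a synthetic stand-in volume for
    exercising the extraction code path, not an anatomical atlas.
    """
    nx, ny, nz = shape
    if nx % 2:
        raise ValueError("first axis must be even to split hemispheres")
    half = nx // 2
    left_idx = regions.hemisphere_indices("left")
    ids = regions.region_ids
    left_ids = ids[left_idx]
    n_left = len(left_ids)
    n_voxels_half = half * ny * nz
    if n_voxels_half < n_left:
        raise ValueError("volume too small for the number of regions")
    # equal-size contiguous chunks over the flattened left half
    labels_half = np.repeat(left_ids, n_voxels_half // n_left)
    pad = n_voxels_half - labels_half.size
    if pad:
        labels_half = np.concatenate([labels_half, np.full(pad, left_ids[-1])])
    vol = np.zeros(shape, dtype=np.int32)
    vol[:half] = labels_half.reshape(half, ny, nz)
    # mirror: right voxel (x,y,z) gets the homotope of label at (nx-1-x,y,z)
    homotope = dict(zip(regions.table["region_id"], regions.table["homotope_id"]))
    lut = np.zeros(int(ids.max()) + 1, dtype=np.int32)
    for rid, hid in homotope.items():
        lut[rid] = hid
    vol[half:] = lut[vol[half - 1 :: -1]]
    return nib.Nifti1Image(vol, affine=np.eye(4))


def _check_same_grid(a: nib.Nifti1Image, b: nib.Nifti1Image) -> None:
    if a.shape != b.shape:
        raise ValueError(f"grid shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.affine, b.affine, atol=1e-4):
        raise ValueError("affine mismatch between mask and parcellation")


def region_damage_from_mask(
    mask: nib.Nifti1Image, parcellation: nib.Nifti1Image, regions: RegionTable
) -> np.ndarray:
    """Percent damage per region from a lesion mask.

    Entry ``r`` is ``100 * sum(mask over voxels labelled r) / n_voxels(r)``.
    Binary masks give the percentage of damaged voxels; probabilistic masks
    (voxelwise damage likelihoods in [0, 1]) give expected-damage
    percentages under the same formula.
    """
    _check_same_grid(mask, parcellation)
    mvals = np.asarray(mask.get_fdata(), dtype=float).ravel()
    labels = np.asarray(parcellation.get_fdata()).astype(np.int64).ravel()
    if mvals.min() < 0 or mvals.max() > 1:
        raise ValueError("mask values must lie in [0, 1]")
    nbins = int(labels.max()) + 1
    counts = np.bincount(labels, minlength=nbins)
    sums = np.bincount(labels, weights=mvals, minlength=nbins)
    ids = regions.region_ids
    missing = [int(r) for r in ids if r >= nbins or counts[r] == 0]
    if missing:
        raise ValueError(f"region_ids absent from parcellation volume: {missing}")
    return 100.0 * sums[ids] / counts[ids]


def vectorize_connectome(
    matrix: np.ndarray, rtol: float = 1e-6
) -> tuple[np.ndarray, dict[tuple[int, int], int]]:
    """Strict upper triangle of a symmetric connectivity matrix.

    Returns the row-major upper-triangle vector (length ``n(n-1)/2``) and a
    reversible ``(i, j) -> position`` map. Nominally symmetric inputs
    (probabilistic tractography is symmetric only up to numerics) are
    symmetrized as ``(A + A.T)/2``; asymmetry beyond ``rtol`` relative to
    the largest magnitude entry is an error. The diagonal is ignored.
    """
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {A.shape}")
    scale = max(1.0, float(np.abs(A).max()))
    asym = float(np.abs(A - A.T).max())
    if asym > rtol * scale:
        raise ValueError(f"matrix asymmetric: max |A - A.T| = {asym:g}")
    A = 0.5 * (A + A.T)
    n = A.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vec = A[iu, ju]
    index_map = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(iu, ju))}
    return vec, index_map


def devectorize_connectome(vec: np.ndarray, n_regions: int) -> np.ndarray:
    """Inverse of :func:`vectorize_connectome` (zero diagonal)."""
    vec = np.asarray(vec, dtype=float)
    expected = n_regions * (n_regions - 1) // 2
    if vec.size != expected:
        raise ValueError(f"expected {expected} edge values, got {vec.size}")
    A = np.zeros((n_regions, n_regions))
    iu, ju = np.triu_indices(n_regions, k=1)
    A[iu, ju] = vec
    A[ju, iu] = vec
    return A


def edge_labels(region_names: list[str]) -> list[str]:
    """Row-major upper-triangle edge labels ``"name_i|name_j"``."""
    n = len(region_names)
    iu, ju = np.triu_indices(n, k=1)
    return [f"{region_names[i]}|{region_names[j]}" for i, j in zip(iu, ju)]


def tiv_normalize(volumes: np.ndarray, tiv: float) -> np.ndarray:
    """Divide regional volumes by total intracranial volume (TIV)."""
    if not np.isfinite(tiv) or tiv <= 0:
        raise ValueError(f"TIV must be a positive finite scalar, got {tiv}")
    return np.asarray(volumes, dtype=float) / float(tiv)


def palf_ratio(
    roi_timeseries: np.ndarray,
    sampling_interval: float,
    band: tuple[float, float] = (0.01, 0.08),
) -> np.ndarray:
    """Partial amplitude of low-frequency fluctuations per region.

    For each region (column), the sum of discrete Fourier amplitudes over
    the frequency band divided by the sum over all positive frequencies.
    The DC component is excluded, so the ratio is invariant to positive
    rescaling and to constant offsets of the time series.
    """
    X = np.asarray(roi_timeseries, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n_t = X.shape[0]
    if n_t < 2:
        raise ValueError("need at least 2 time points")
    low, high = band
    nyquist = 0.5 / sampling_interval
    if not (0 <= low < high <= nyquist + 1e-12):
        raise ValueError(f"band {band} outside [0, Nyquist={nyquist:g}]")
    freqs = np.fft.rfftfreq(n_t, d=sampling_interval)
    amps = np.abs(np.fft.rfft(X, axis=0))
    positive = freqs > 0
    in_band = positive & (freqs >= low) & (freqs <= high)
    total = amps[positive].sum(axis=0)
    total = np.where(total == 0, np.inf, total)  # flat series -> ratio 0
    return amps[in_band].sum(axis=0) / total
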