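"""Synthetic multimodal lesion-behaviour cohorts with known ground truth.

The generator emulates the statistical structure of a chronic post-stroke
aphasia cohort at region level:

* four inter-correlated WAB-R subtest scores drawn from a clipped Gaussian
  copula calibrated so the post-clipping means, SDs and pairwise
  correlations hit the published cohort statistics (spontaneous speech
  11.4 +/- 4.9 of 20; naming 5.4 +/- 3.0; repetition 5.2 +/- 2.9; auditory
  comprehension 7.7 +/- 1.8, each of 10; correlations 0.63-0.84);
* a single latent severity factor tying lesion extent to all four scores;
* spatially clustered damage spreading through an ordered "territory" of
  contiguous left-hemisphere regions, emulating a middle-cerebral-artery
  stroke distribution;
* ten derived modalities as monotone links of regional damage (FA, CBF,
  volumetry, pALF, task fMRI decrease with damage; MD increases; structural
  and functional connectivity edges attenuate when either endpoint is
  damaged; i3mT1 is a blurred copy of proportional lesion);
* planted effects with recorded ground truth: a small set of "shared"
  territory regions whose damage degrades all four subtests, and per-subtest
  "unique" regions whose microstructural integrity perturbs exactly one
  subtest's residual, injected into several modality channels.

Every draw flows from one seeded generator, so a fixed seed reproduces the
cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .atlas import RegionTable, default_region_table, edge_labels
from .dataset import (
    SUBTESTS,
    SUBTEST_MAXIMA,
    BehaviourMatrix,
    ModalityFeatureMatrix,
)

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "aq_score",
    "generate_behaviour",
    "generate_lesions",
    "derive_modalities",
    "plant_effects",
    "generate_cohort",
]

# Published cohort calibration targets (subtest order: SS, N, R, AC).
DEFAULT_MEANS = (11.4, 5.4, 5.2, 7.7)
DEFAULT_SDS = (4.9, 3.0, 2.9, 1.8)
DEFAULT_CORRELATIONS = (
    (1.00, 0.84, 0.84, 0.68),
    (0.84, 1.00, 0.83, 0.74),
    (0.84, 0.83, 1.00, 0.63),
    (0.68, 0.74, 0.63, 1.00),
)

# Healthy-tissue baselines and full-damage fractional change per regional
# modality: value = baseline * (1 + sensitivity * damage/100) + noise.
MODALITY_BASELINES = {
    "fa": (0.45, -0.50),
    "md": (0.80, +0.60),  # 1e-3 mm^2/s
    "cbf": (50.0, -0.60),  # ml/100g/min
    "vbm_gm": (8.0e-4, -0.70),  # TIV-normalized volume
    "vbm_wm": (6.0e-4, -0.70),
    "palf": (0.55, -0.40),
    "fmri": (1.20, -0.80),  # contrast estimate, a.u.
}

# Channels carrying planted unique-region integrity deviations
# (modality -> additive change per unit deviation). Amplitudes sit well
# above each channel's noise floor so a planted region's coefficient
# stands clear of estimator noise at cohort size n=86.
# Four channels only: enough for the >= 2-modality support rule while
# keeping planted unique regions out of the (>= 6 model) shared-consensus
# core, which is count-based on VIP selections.
UNIQUE_CHANNELS = {
    "md": +0.45,
    "fa": -0.18,
    "cbf": -22.0,
    "palf": -0.16,
}


def _default_noise_sd() -> dict[str, float]:
    # fraction of each modality's healthy-baseline dynamic range
    sd = {m: 0.25 for m in ("fa", "md", "cbf", "vbm_gm", "vbm_wm", "palf", "fmri", "sc", "fc", "i3mT1")}
    sd["lesion"] = 0.10  # multiplicative texture on in-territory damage
    return sd


def _default_unique_regions() -> dict[str, tuple[int, ...]]:
    # per-subtest unique region indices, outside the territory, mixing
    # hemispheres; auditory comprehension gets the widest network
    return {
        "spontaneous_speech": (5,),
        "naming": (120, 130, 250),
        "repetition": (140, 150, 270),
        "auditory_comprehension": (160, 170, 300, 310),
    }


def _default_shared_effects() -> dict[str, float]:
    # standardized slopes of shared-region damage on each subtest; ordering
    # mirrors the observed dominance of spontaneous speech and the weak
    # loading of auditory comprehension
    return {
        "spontaneous_speech": 0.65,
        "naming": 0.50,
        "repetition": 0.50,
        "auditory_comprehension": 0.35,
    }


def _default_unique_effects() -> dict[str, float]:
    # standardized slope per planted unique region; combined with the
    # region counts (1/3/3/4) this gives auditory comprehension the
    # strongest total unique component and spontaneous speech the weakest
    return {
        "spontaneous_speech": 0.25,
        "naming": 0.40,
        "repetition": 0.40,
        "auditory_comprehension": 0.38,
    }


def _default_channel_gains() -> dict[str, float]:
    # imaging expressivity of each subtest's planted deviations: the
    # spontaneous-speech deviation is written into the imaging channels
    # at reduced amplitude, so its unique regions explain the least
    # residual variance, mirroring the weak unique substrate of speech
    # fluency relative to comprehension
    return {
        "spontaneous_speech": 0.5,
        "naming": 1.0,
        "repetition": 1.0,
        "auditory_comprehension": 1.0,
    }


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; defaults reproduce the published
    cohort statistics and region-set scales."""

    n_subjects: int = 86
    regions: RegionTable = field(default_factory=default_region_table, repr=False)
    subtest_means: tuple[float, ...] = DEFAULT_MEANS
    subtest_sds: tuple[float, ...] = DEFAULT_SDS
    subtest_correlations: tuple[tuple[float, ...], ...] = DEFAULT_CORRELATIONS
    territory: tuple[int, ...] = tuple(range(40, 100))
    shared_regions: tuple[int, ...] = (68, 69, 70, 71)
    unique_regions: dict[str, tuple[int, ...]] = field(default_factory=_default_unique_regions)
    shared_effects: dict[str, float] = field(default_factory=_default_shared_effects)
    unique_effects: dict[str, float] = field(default_factory=_default_unique_effects)
    unique_channel_gains: dict[str, float] = field(default_factory=_default_channel_gains)
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    stray_lesion_rate: float = 0.01
    severity_noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        R = np.asarray(self.subtest_correlations, dtype=float)
        if R.shape != (4, 4) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("subtest_correlations must be symmetric 4x4 with unit diagonal")
        if not self.territory:
            raise ValueError("territory must be non-empty")
        uniq_all = [r for rs in self.unique_regions.values() for r in rs]
        if set(uniq_all) & set(self.shared_regions):
            raise ValueError("shared and unique region sets must be disjoint")
        if len(set(uniq_all)) != len(uniq_all):
            raise ValueError("unique region sets overlap across subtests")
        n_reg = self.regions.n_regions
        for r in list(self.territory) + list(self.shared_regions) + uniq_all:
            if not 0 <= r < n_reg:
                raise ValueError(f"region index {r} out of range for {n_reg} regions")

    @property
    def maxima(self) -> np.ndarray:
        return np.array([SUBTEST_MAXIMA[s] for s in SUBTESTS])


@dataclass
class SyntheticCohort:
    """Generated behaviour, modalities, and the planted ground truth."""

    behaviour: BehaviourMatrix
    modalities: dict[str, ModalityFeatureMatrix]
    severity: np.ndarray = field(repr=False)
    ground_truth: dict = field(repr=False)
    spec: CohortSpec = field(repr=False)


def aq_score(ss, n, r, ac):
    """WAB Aphasia Quotient: ``AQ = 2 * (SS + N + R + AC)``, range [0, 100]."""
    ss, n, r, ac = (np.asarray(v, dtype=float) for v in (ss, n, r, ac))
    for val, name, mx in ((ss, "spontaneous_speech", 20.0), (n, "naming", 10.0),
                          (r, "repetition", 10.0), (ac, "auditory_comprehension", 10.0)):
        if ((val < 0) | (val > mx)).any():
            raise ValueError(f"{name} scores outside [0, {mx}]")
    out = 2.0 * (ss + n + r + ac)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Behaviour: clipped Gaussian copula calibrated by moment matching


def _clipped_moments(m: float, s: float, lo: float, hi: float) -> tuple[float, float]:
    """Mean and SD of clip(N(m, s^2), lo, hi), in closed form."""
    a, b = (lo - m) / s, (hi - m) / s
    Fa, Fb = stats.norm.cdf(a), stats.norm.cdf(b)
    fa, fb = stats.norm.pdf(a), stats.norm.pdf(b)
    mid = Fb - Fa
    E = lo * Fa + hi * (1 - Fb) + m * mid + s * (fa - fb)
    E2 = (lo**2 * Fa + hi**2 * (1 - Fb) + m**2 * mid
          + 2 * m * s * (fa - fb) + s**2 * (mid + a * fa - b * fb))
    return E, float(np.sqrt(max(E2 - E**2, 1e-12)))

def _calibrate_margin(tm: float, ts: float, lo: float, hi: float,
                      max_iter: int = 25, tol: float = 1e-3) -> tuple[float, float]:
    """Latent (m, s) whose clipped moments match the targets (fixed point)."""
    m, s = tm, ts
    for _ in range(max_iter):
        E, S = _clipped_moments(m, s, lo, hi)
        if abs(E - tm) < tol and abs(S - ts) < tol:
            break
        m += tm - E
        s *= ts / S
    return m, s


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(48)

def _clipped_corr(rho: float, m1, s1, hi1, m2, s2, hi2) -> float:
    """Post-clipping Pearson correlation of a bivariate latent normal,
    by 2-D Gauss-Hermite quadrature (lower bound 0, upper bounds given)."""
    z = np.sqrt(2.0) * _GH_NODES
    E1, S1 = _clipped_moments(m1, s1, 0.0, hi1)
    E2, S2 = _clipped_moments(m2, s2, 0.0, hi2)
    Z1, Z2 = z[:, None], z[None, :]
    X = np.clip(m1 + s1 * Z1, 0.0, hi1)
    Y = np.clip(m2 + s2 * (rho * Z1 + np.sqrt(1.0 - rho**2) * Z2), 0.0, hi2)
    W = (_GH_WEIGHTS[:, None] * _GH_WEIGHTS[None, :]) / np.pi
    return (float(np.sum(W * X * Y)) - E1 * E2) / (S1 * S2)


def _nearest_pd_correlation(R: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped repair to the nearest positive-definite
    correlation matrix (unit diagonal restored)."""
    w, V = np.linalg.eigh(R)
    if w.min() > eps:
        return R
    w = np.clip(w, eps, None)
    A = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(A))
    return A / np.outer(d, d)


_calibration_cache: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

def _calibrate_copula(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Latent means, SDs and correlation matrix whose clipped draws match
    the target post-clipping moments and correlations."""
    key = (spec.subtest_means, spec.subtest_sds,
           tuple(map(tuple, spec.subtest_correlations)))
    if key in _calibration_cache:
        return _calibration_cache[key]
    maxima = spec.maxima
    margins = [_calibrate_margin(m, s, 0.0, hi)
               for m, s, hi in zip(spec.subtest_means, spec.subtest_sds, maxima)]
    mu = np.array([m for m, _ in margins])
    sd = np.array([s for _, s in margins])
    R_target = np.asarray(spec.subtest_correlations, dtype=float)
    R_lat = np.eye(4)
    for i in range(4):
        for j in range(i + 1, 4):
            tgt = R_target[i, j]
            if tgt == 0.0:
                continue
            f = lambda r: _clipped_corr(r, mu[i], sd[i], maxima[i],
                                        mu[j], sd[j], maxima[j]) - tgt
            lo = max(-0.999, tgt - 0.3)
            hi = min(0.999, tgt + 0.25)
            if f(lo) * f(hi) > 0:
                raise ValueError(
                    f"cannot reach target correlation {tgt} for pair ({i},{j}); "
                    f"attainable range endpoint values: f({lo:.3f})={f(lo):.3f}, "
                    f"f({hi:.3f})={f(hi):.3f}"
                )
            R_lat[i, j] = R_lat[j, i] = brentq(f, lo, hi, xtol=1e-5)
    R_lat = _nearest_pd_correlation(R_lat)
    if np.linalg.eigvalsh(R_lat).min() <= 0:
        raise ValueError(
            f"latent correlation target not repairable; eigenvalues "
            f"{np.linalg.eigvalsh(R_lat)}"
        )
    _calibration_cache[key] = (mu, sd, R_lat)
    return mu, sd, R_lat


def generate_behaviour(
    spec: CohortSpec,
    n: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[BehaviourMatrix, np.ndarray]:
    """Draw subtest scores and the latent severity vector.

    Scores are clipped latent-Gaussian draws; the latent moments and
    correlations are pre-calibrated so the *post-clipping* sample moments
    match the targets. Severity is the (negated, probability-transformed)
    mean of the latent factors: a value in [0, 1], higher = more impaired,
    shared by all four subtests.
    """
    n = spec.n_subjects if n is None else n
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    mu, sd, R_lat = _calibrate_copula(spec)
    L = np.linalg.cholesky(R_lat)
    Z = rng.standard_normal((n, 4)) @ L.T
    scores = np.clip(mu + sd * Z, 0.0, spec.maxima)
    sd_mean = float(np.sqrt(R_lat.sum()) / 4.0)
    # lesion extent tracks impairment imperfectly: the anatomical severity
    # factor mixes the behavioural latent with an independent component
    tau = float(spec.severity_noise)
    sev_z = (-Z.mean(axis=1) / sd_mean + tau * rng.standard_normal(n)) / np.sqrt(1.0 + tau**2)
    severity = stats.norm.cdf(sev_z)
    ids = [f"sub-{i + 1:04d}" for i in range(n)]
    return BehaviourMatrix(scores, ids), severity


# ---------------------------------------------------------------------------
# Lesions and derived modalities


def generate_lesions(
    spec: CohortSpec, severity: np.ndarray, rng: np.random.Generator
) -> ModalityFeatureMatrix:
    """Spatially clustered percent-damage rows.

    Damage occupies a contiguous window of the ordered territory around a
    random seed region; window length grows with severity until it covers
    the whole territory, and the damage level approaches 100% as severity
    approaches 1 (with a bounded multiplicative texture, so at full
    severity every territory region stays above 90% when the lesion noise
    fraction is at its default or below). Outside the territory, rare
    low-grade stray damage emulates small secondary lesions.
    """
    n = len(severity)
    n_reg = spec.regions.n_regions
    terr = np.asarray(spec.territory)
    T = len(terr)
    noise = spec.noise_sd.get("lesion", 0.10)
    damage = np.zeros((n, n_reg))
    for i in range(n):
        sev = float(severity[i])
        extent = int(round(T * sev))
        if extent > 0:
            seed_pos = int(rng.integers(T))
            start = int(np.clip(seed_pos - extent // 2, 0, T - extent))
            window = terr[start : start + extent]
            level = 100.0 * sev * (1.0 - noise * rng.random(extent))
            damage[i, window] = np.clip(level, 0.0, 100.0)
        stray = rng.random(n_reg) < spec.stray_lesion_rate
        stray[terr] = False
        damage[i, stray] = np.clip(150.0 * noise * rng.random(int(stray.sum())), 0.0, 100.0)
    ids = [f"sub-{i + 1:04d}" for i in range(n)]
    return ModalityFeatureMatrix(
        "lesion", damage, "regional", spec.regions.names, ids, units="% of region voxels"
    )


def derive_modalities(
    spec: CohortSpec,
    lesion: ModalityFeatureMatrix,
    severity: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, ModalityFeatureMatrix]:
    """Derive the remaining ten modalities from regional damage.

    Regional scalars follow modality-specific monotone links of damage
    with additive Gaussian noise scaled to a fraction of each modality's
    healthy dynamic range. Pairwise modalities start from one fixed
    "healthy" connectome and attenuate each edge by a factor decreasing in
    the damage of either endpoint (emulating disconnection).
    """
    D = lesion.values / 100.0  # damage fractions, n x regions
    n, n_reg = D.shape
    ids = lesion.subject_ids
    names = spec.regions.names
    out: dict[str, ModalityFeatureMatrix] = {"lesion": lesion}

    for mod, (base, sens) in MODALITY_BASELINES.items():
        nf = spec.noise_sd.get(mod, 0.25)
        vals = base * (1.0 + sens * D)
        if nf > 0:
            vals = vals + nf * abs(sens * base) * rng.standard_normal((n, n_reg))
        if mod == "palf":
            vals = np.clip(vals, 0.0, 1.0)
        elif mod in ("fa",):
            vals = np.clip(vals, 0.0, 1.0)
        elif mod in ("md", "cbf", "vbm_gm", "vbm_wm"):
            vals = np.clip(vals, 0.0, None)
        out[mod] = ModalityFeatureMatrix(mod, vals, "regional", names, ids)

    # i3mT1: probabilistic lesion likelihood = damage fraction + blur
    nf = spec.noise_sd.get("i3mT1", 0.25)
    i3m = np.clip(D + 0.2 * nf * rng.standard_normal((n, n_reg)), 0.0, 1.0)
    out["i3mT1"] = ModalityFeatureMatrix("i3mT1", i3m, "regional", names, ids, units="probability")

    # endpoint attenuation: fully damaged endpoint leaves <= 5% of the edge
    g = 1.0 - 0.95 * D
    gg = g[:, :, None] * g[:, None, :]
    iu, ju = np.triu_indices(n_reg, k=1)
    elabels = edge_labels(names)

    base_sc = rng.lognormal(mean=3.0, sigma=1.0, size=(n_reg, n_reg))
    base_sc = 0.5 * (base_sc + base_sc.T)
    nf = spec.noise_sd.get("sc", 0.25)
    sc = base_sc[None, :, :] * gg
    if nf > 0:
        sc = sc * np.exp(nf * rng.standard_normal((n, n_reg, n_reg)))
    sc_vec = 0.5 * (sc + sc.transpose(0, 2, 1))[:, iu, ju]
    out["sc"] = ModalityFeatureMatrix("sc", sc_vec, "pairwise", elabels, ids, units="streamlines")

    base_fc = np.tanh(0.8 * rng.standard_normal((n_reg, n_reg)))
    base_fc = 0.5 * (base_fc + base_fc.T)
    nf = spec.noise_sd.get("fc", 0.25)
    fc = base_fc[None, :, :] * gg
    if nf > 0:
        fc = fc + 0.3 * nf * rng.standard_normal((n, n_reg, n_reg))
    fc = np.clip(0.5 * (fc + fc.transpose(0, 2, 1)), -1.0, 1.0)
    out["fc"] = ModalityFeatureMatrix("fc", fc[:, iu, ju], "pairwise", elabels, ids, units="correlation")
    return out


# ---------------------------------------------------------------------------
# Planted effects


def _inject(scores_col: np.ndarray, mean: float, mx: float, addition: np.ndarray) -> np.ndarray:
    """Add a planted component while approximately preserving the column's
    variance: the existing residual is shrunk so that, accounting for its
    covariance with the addition, the total variance stays at target."""
    resid = scores_col - scores_col.mean()
    v = float(resid.var())
    v_add = float(addition.var())
    c = float(np.cov(resid, addition)[0, 1])
    # solve a^2 v + 2 a c + v_add = v for the shrink factor a
    disc = c**2 - v * (v_add - v)
    a = (-c + np.sqrt(max(disc, 0.0))) / v if v > 0 else 1.0
    a = float(np.clip(a, 0.0, 1.0))
    return np.clip(mean + a * resid + addition - addition.mean(), 0.0, mx)


def plant_effects(
    spec: CohortSpec,
    behaviour: BehaviourMatrix,
    severity: np.ndarray,
    modalities: dict[str, ModalityFeatureMatrix],
    rng: np.random.Generator,
) -> SyntheticCohort:
    """Couple shared-region damage to all subtests and plant subtest-unique
    integrity effects, recording the ground truth.

    Shared regions act through their (severity-driven) lesion damage: the
    cohort-standardized mean damage of the shared set is added to every
    subtest with the per-subtest shared slope. Each unique region gets an
    independent standard-normal integrity deviation per subject that (i)
    perturbs exactly one subtest's residual with the per-region unique
    slope and (ii) is written into three modality channels (MD up, FA and
    CBF down), so the >= 2-modality recovery rule is satisfiable.
    """
    uniq_all = [r for rs in spec.unique_regions.values() for r in rs]
    if set(uniq_all) & set(spec.shared_regions):
        raise ValueError("shared and unique region sets must be disjoint")
    lesion = modalities["lesion"]
    n = lesion.n_subjects
    shared_damage = lesion.values[:, list(spec.shared_regions)].mean(axis=1)
    z_shared = (shared_damage - shared_damage.mean()) / max(shared_damage.std(), 1e-12)

    maxima = spec.maxima
    n_sub = len(SUBTESTS)

    # pass 1: shared coupling on every subtest
    shared_scores = behaviour.scores.copy()
    for j, subtest in enumerate(SUBTESTS):
        addition = -spec.shared_effects[subtest] * float(spec.subtest_sds[j]) * z_shared
        shared_scores[:, j] = _inject(
            shared_scores[:, j], float(spec.subtest_means[j]), maxima[j], addition
        )

    # pass 2: provisional unique injections with raw deviations, used only
    # to approximate the final scores each deviation must be orthogonal to
    raw_u: dict[int, np.ndarray] = {}
    provisional = shared_scores.copy()
    for j, subtest in enumerate(SUBTESTS):
        sd_j = float(spec.subtest_sds[j])
        for r in spec.unique_regions.get(subtest, ()):
            raw_u[r] = rng.standard_normal(n)
            provisional[:, j] = provisional[:, j] - spec.unique_effects[subtest] * sd_j * raw_u[r]

    # pass 3: orthogonalize each deviation (in-sample) against the other
    # subtests' provisional scores and the shared component, so it perturbs
    # exactly one subtest's residual instead of leaking through the strong
    # subtest inter-correlations, then inject for real
    scores = shared_scores.copy()
    deviations: dict[int, np.ndarray] = {}
    for j, subtest in enumerate(SUBTESTS):
        sd_j = float(spec.subtest_sds[j])
        others = [provisional[:, m] for m in range(n_sub) if m != j]
        O = np.column_stack(others + [z_shared, np.ones(n)])
        gain = spec.unique_channel_gains.get(subtest, 1.0)
        addition = np.zeros(n)
        for r in spec.unique_regions.get(subtest, ()):
            u = raw_u[r]
            u = u - O @ np.linalg.lstsq(O, u, rcond=None)[0]
            u = u / max(u.std(), 1e-12)
            deviations[r] = gain * u
            addition = addition - spec.unique_effects[subtest] * sd_j * u
        if spec.unique_regions.get(subtest):
            scores[:, j] = _inject(scores[:, j], float(spec.subtest_means[j]), maxima[j], addition)

    new_modalities = dict(modalities)
    for mod, delta in UNIQUE_CHANNELS.items():
        vals = new_modalities[mod].values.copy()
        for r, u in deviations.items():
            vals[:, r] = vals[:, r] + delta * u
        m = new_modalities[mod]
        if mod in ("md", "cbf", "vbm_gm", "vbm_wm"):
            vals = np.clip(vals, 0.0, None)
        elif mod in ("fa", "palf"):
            vals = np.clip(vals, 0.0, 1.0)
        new_modalities[mod] = ModalityFeatureMatrix(
            mod, vals, m.feature_kind, m.feature_labels, m.subject_ids, m.units,
        )

    region_names = spec.regions.names
    ground_truth = {
        "shared_regions": [region_names[r] for r in spec.shared_regions],
        "unique_regions": {
            s: [region_names[r] for r in rs] for s, rs in spec.unique_regions.items()
        },
        "severity": severity.tolist(),
    }
    new_behaviour = BehaviourMatrix(scores, behaviour.subject_ids, behaviour.subtests)
    return SyntheticCohort(new_behaviour, new_modalities, severity, ground_truth, spec)


def generate_cohort(spec: CohortSpec | None = None) -> SyntheticCohort:
    """Generate a full cohort: behaviour, lesions, derived modalities and
    planted effects, all from ``spec.seed``."""
    spec = CohortSpec() if spec is None else spec
    rng = np.random.default_rng(spec.seed)
    behaviour, severity = generate_behaviour(spec, rng=rng)
    lesion = generate_lesions(spec, severity, rng)
    modalities = derive_modalities(spec, lesion, severity, rng)
    return plant_effects(spec, behaviour, severity, modalities, rng)


def small_cohort_spec(
    n_subjects: int = 40,
    n_per_hemisphere: int = 24,
    seed: int = 0,
    **overrides,
) -> CohortSpec:
    """A reduced cohort specification for fast exercises: fewer regions, a
    shorter territory, and proportionally smaller planted region sets."""
    regions = default_region_table(n_per_hemisphere)
    defaults = dict(
        n_subjects=n_subjects,
        regions=regions,
        territory=tuple(range(4, 16)),
        shared_regions=(9, 10),
        unique_regions={
            "spontaneous_speech": (0,),
            "naming": (18, 20),
            "repetition": (22, 26),
            "auditory_comprehension": (30, 34),
        },
        seed=seed,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)
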