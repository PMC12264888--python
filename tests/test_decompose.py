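"""Shared-region consensus, unique-region calling, and the two-stage
variance decomposition."""

import numpy as np
import pandas as pd
import pytest

import lesionpls as lp
from lesionpls import (
    BehaviourMatrix,
    ModalityFeatureMatrix,
    call_unique_regions,
    consensus_shared,
    fit_plsr,
    residual_variance_analysis,
)
from lesionpls.crossval import VipSelection


def _selection(modality, retained, all_features=None):
    feats = all_features or retained
    ranking = pd.DataFrame(
        {"feature": feats, "vip": np.linspace(3, 2, len(feats)), "rank": range(1, len(feats) + 1)}
    )
    return VipSelection(modality, ranking, list(retained), n_top=30, vip_threshold=1.5)


class TestConsensus:
    def test_region_in_all_models_reaches_full_count(self):
        sels = {f"m{i}": _selection(f"m{i}", ["rA", f"r{i}"]) for i in range(11)}
        shared = consensus_shared(sels, min_models=4)
        assert shared.counts["rA"] == 11
        assert "rA" in shared.consensus()
        assert "rA" in shared.consensus(11)

    def test_threshold_above_model_count_gives_empty_set(self):
        sels = {f"m{i}": _selection(f"m{i}", ["rA"]) for i in range(11)}
        shared = consensus_shared(sels, min_models=4)
        assert shared.consensus(12) == []

    def test_consensus_shrinks_monotonically_with_threshold(self):
        rng = np.random.default_rng(0)
        regions = [f"r{i}" for i in range(20)]
        sels = {
            f"m{i}": _selection(f"m{i}", list(rng.choice(regions, size=8, replace=False)))
            for i in range(8)
        }
        shared = consensus_shared(sels, min_models=1)
        for t in range(1, 9):
            assert set(shared.consensus(t + 1)) <= set(shared.consensus(t))

    def test_edge_selections_aggregate_to_regions(self):
        sels = {
            "sc": _selection("sc", ["rA|rB", "rA|rC"]),
            "lesion": _selection("lesion", ["rA"]),
        }
        shared = consensus_shared(sels, min_models=2)
        assert shared.counts["rA"] == 2
        assert shared.counts["rB"] == 1

    def test_fewer_than_two_modalities_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            consensus_shared({"lesion": _selection("lesion", ["rA"])})


def _toy_models(seed, n=200, p=8, k=4, n_modalities=3, planted=None):
    """Small per-modality models with an optional feature driving one
    response only."""
    rng = np.random.default_rng(seed)
    models, labels = {}, {}
    names = [f"r{i}" for i in range(p)]
    for m in range(n_modalities):
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, k)) + X[:, 0:1] @ rng.standard_normal((1, k))
        if planted is not None:
            j, resp, slope = planted
            Y[:, resp] = Y[:, resp] + slope * X[:, j]
        models[f"mod{m}"] = fit_plsr(X, Y, 4)
        labels[f"mod{m}"] = names
    return models, labels, names


class TestUniqueCalling:
    subtests = ("s0", "s1", "s2", "s3")

    def test_identical_beta_maps_give_no_unique_regions(self):
        rng = np.random.default_rng(1)
        n, p = 40, 6
        X = rng.standard_normal((n, p))
        y = X @ rng.standard_normal(p) + 0.3 * rng.standard_normal(n)
        Y = np.column_stack([y, y, y, y])
        models = {"a": fit_plsr(X, Y, 3), "b": fit_plsr(X, Y, 3)}
        labels = {"a": [f"r{i}" for i in range(p)], "b": [f"r{i}" for i in range(p)]}
        out = call_unique_regions(models, labels, labels["a"], subtests=self.subtests)
        assert all(not v for v in out.assignments.values())

    def test_single_modality_support_excluded(self):
        models, labels, names = _toy_models(2, n_modalities=1, planted=(4, 2, 3.0))
        out = call_unique_regions(models, labels, names, subtests=self.subtests, min_modalities=2)
        assert all(not v for v in out.assignments.values())

    def test_planted_single_response_feature_called(self):
        models, labels, names = _toy_models(3, n_modalities=3, planted=(4, 2, 3.0))
        out = call_unique_regions(models, labels, names, subtests=self.subtests,
                                  min_modalities=2, n_components=4)
        assert "r4" in out.assignments["s2"]

    def test_invariant_to_positive_feature_rescaling(self):
        rng = np.random.default_rng(4)
        n, p = 40, 8
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, 4)) + X[:, :2] @ rng.standard_normal((2, 4))
        names = [f"r{i}" for i in range(p)]
        scale = rng.uniform(0.5, 50.0, size=p)
        m1 = {"a": fit_plsr(X, Y, 4), "b": fit_plsr(X + 0.0, Y, 4)}
        m2 = {"a": fit_plsr(X * scale, Y, 4), "b": fit_plsr(X * scale, Y, 4)}
        labels = {"a": names, "b": names}
        out1 = call_unique_regions(m1, labels, names, subtests=self.subtests)
        out2 = call_unique_regions(m2, labels, names, subtests=self.subtests)
        assert out1.assignments == out2.assignments

    def test_shared_consensus_overlap_reported_and_removed(self):
        models, labels, names = _toy_models(5, n_modalities=3, planted=(4, 2, 3.0))
        out = call_unique_regions(models, labels, names, subtests=self.subtests,
                                  min_modalities=2, n_components=4, shared_consensus=["r4"])
        assert "r4" in out.overlap_with_shared
        assert "r4" not in out.assignments["s2"]

    def test_region_unique_to_at_most_one_subtest(self, small_dataset):
        res = lp.run_all_modalities(small_dataset, n_components=8, run_cv=False)
        models = {m: r.model for m, r in res.items()}
        labels = {m: small_dataset.modalities[m].feature_labels for m in res}
        names = [mfm.feature_labels for mfm in small_dataset.modalities.values()
                 if mfm.feature_kind == "regional"][0]
        out = call_unique_regions(models, labels, names, n_components=8)
        seen = [r for regions in out.assignments.values() for r in regions]
        assert len(seen) == len(set(seen))


class TestResidualVariance:
    def _containers(self, X_lesion, X_md, Y, subtests=lp.SUBTESTS):
        n = Y.shape[0]
        ids = [f"s{i}" for i in range(n)]
        lesion = ModalityFeatureMatrix("lesion", X_lesion, "regional",
                                       [f"r{i}" for i in range(X_lesion.shape[1])], ids)
        md = ModalityFeatureMatrix("md", X_md, "regional",
                                   [f"r{i}" for i in range(X_md.shape[1])], ids)
        behaviour = BehaviourMatrix(Y, ids)
        return behaviour, lesion, md

    def test_orthogonal_unique_predictors_add_nothing(self):
        rng = np.random.default_rng(6)
        n = 86
        X_lesion = rng.uniform(0, 100, (n, 4))
        y = 10 + 0.05 * X_lesion.sum(axis=1) + rng.standard_normal(n)
        Y = np.clip(np.column_stack([y, y / 2, y / 2, y / 2]), 0, 10)
        # make MD exactly orthogonal to every stage-1 residual
        Xs = np.column_stack([np.ones(n), X_lesion])
        resid = Y - Xs @ np.linalg.lstsq(Xs, Y, rcond=None)[0]
        md_raw = rng.standard_normal((n, 2))
        Q, _ = np.linalg.qr(np.column_stack([Xs, resid]))
        X_md = md_raw - Q @ (Q.T @ md_raw)
        behaviour, lesion, md = self._containers(X_lesion, X_md, Y)
        out = residual_variance_analysis(
            behaviour, lesion, md, [f"r{i}" for i in range(4)],
            {s: ["r0", "r1"] for s in lp.SUBTESTS},
        )
        assert (out.table["unique_delta_r2"] < 0.02).all()

    def test_matches_normal_equations_oracle_on_tiny_data(self):
        rng = np.random.default_rng(7)
        n = 6
        X_lesion = rng.uniform(0, 100, (n, 2))
        X_md = rng.standard_normal((n, 1))
        Y = np.clip(rng.uniform(1, 9, (n, 4)), 0, 10)
        behaviour, lesion, md = self._containers(X_lesion, X_md, Y)
        out = residual_variance_analysis(
            behaviour, lesion, md, ["r0", "r1"], {s: ["r0"] for s in lp.SUBTESTS}
        )
        # oracle: closed-form normal equations for both stages
        for j, s in enumerate(lp.SUBTESTS):
            y = Y[:, j]
            A = np.column_stack([np.ones(n), X_lesion])
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            resid = y - A @ beta
            r2_shared = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
            B = np.column_stack([np.ones(n), X_md[:, 0]])
            gamma = np.linalg.solve(B.T @ B, B.T @ resid)
            r2u = 1 - ((resid - B @ gamma) @ (resid - B @ gamma)) / (
                (resid - resid.mean()) @ (resid - resid.mean())
            )
            row = out.table.set_index("subtest").loc[s]
            assert row["shared_r2"] == pytest.approx(r2_shared, abs=1e-10)
            assert row["unique_delta_r2"] == pytest.approx(r2u, abs=1e-10)

    def test_collinear_shared_predictors_warn(self):
        rng = np.random.default_rng(8)
        n = 20
        x = rng.uniform(0, 100, n)
        X_lesion = np.column_stack([x, x * (1 + 1e-12), rng.uniform(0, 100, n)])
        X_md = rng.standard_normal((n, 1))
        Y = np.clip(rng.uniform(1, 9, (n, 4)), 0, 10)
        behaviour, lesion, md = self._containers(X_lesion, X_md, Y)
        with pytest.warns(UserWarning, match="ill-conditioned"):
            residual_variance_analysis(behaviour, lesion, md, ["r0", "r1", "r2"],
                                       {s: ["r0"] for s in lp.SUBTESTS})

    def test_missing_shared_region_rejected(self):
        rng = np.random.default_rng(9)
        behaviour, lesion, md = self._containers(
            rng.uniform(0, 100, (6, 2)), rng.standard_normal((6, 1)),
            np.clip(rng.uniform(1, 9, (6, 4)), 0, 10),
        )
        with pytest.raises(ValueError, match="absent"):
            residual_variance_analysis(behaviour, lesion, md, ["nope"], {})
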