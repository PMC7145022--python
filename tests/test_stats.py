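"""PCA/parallel analysis, hierarchical Procrustes ANOVA, EDMA distances."""

import numpy as np
import pandas as pd
import pytest

import morphohead as mh
from conftest import random_rotation
from morphohead.geometry_io import AGE_CLASSES
from morphohead.stats import NAMED_DISTANCES


def _shape_space_from(rng, n=30, k=12, signal=None):
    base = rng.normal(scale=20, size=(k, 3))
    configs = np.stack([base + rng.normal(scale=1.0, size=(k, 3)) for _ in range(n)])
    if signal is not None:
        configs += signal
    return mh.gpa(configs)


class TestPCA:
    def test_injected_dominant_axis(self):
        """A 100:1:1 variance construction concentrates PC1 near 100/102."""
        rng = np.random.default_rng(0)
        base = rng.normal(scale=30, size=(15, 3))
        direction = rng.normal(size=(15, 3))
        direction /= np.linalg.norm(direction)
        n = 400
        coefs = rng.normal(scale=1.0, size=n)
        noise_dirs = rng.normal(size=(2, 15, 3))
        for i in range(2):
            noise_dirs[i] -= (noise_dirs[i].ravel() @ direction.ravel()) * direction
            noise_dirs[i] /= np.linalg.norm(noise_dirs[i])
        configs = np.stack([
            base + 10 * coefs[i] * direction
            + rng.normal(scale=1.0) * noise_dirs[0] + rng.normal(scale=1.0) * noise_dirs[1]
            for i in range(n)])
        res = mh.pca(mh.gpa(configs))
        assert res.variance_fractions[0] == pytest.approx(100 * 100 / 102, abs=4.0)

    def test_variance_conservation_and_reconstruction(self, rng):
        space = _shape_space_from(rng)
        res = mh.pca(space)
        x = space.tangent_coordinates()
        xc = x - x.mean(axis=0)
        total = (xc**2).sum() / (len(x) - 1)
        assert res.eigenvalues.sum() == pytest.approx(total, rel=1e-9)
        np.testing.assert_allclose(res.reconstruct(), x, atol=1e-8)
        # loadings orthonormal
        gram = res.components @ res.components.T
        assert np.abs(gram - np.eye(len(gram))).max() < 1e-8

    def test_joint_rotation_leaves_eigenvalues(self, rng):
        base = rng.normal(scale=20, size=(40, 10, 3))
        e1 = mh.pca(mh.gpa(base)).eigenvalues
        r = random_rotation(rng)
        e2 = mh.pca(mh.gpa(base @ r.T)).eigenvalues
        np.testing.assert_allclose(e1, e2, rtol=1e-6)

    def test_small_n_error(self, rng):
        with pytest.raises(ValueError):
            mh.pca(_shape_space_from(rng, n=2))


class TestParallelAnalysis:
    def test_pure_noise_retains_almost_nothing(self, rng):
        """Independent per-coordinate noise around a fixed mean retains ~0 PCs."""
        from morphohead.procrustes import ShapeSpace
        base = rng.normal(size=(8, 3))
        base -= base.mean(0)
        base /= np.linalg.norm(base)
        aligned = base + rng.normal(scale=0.01, size=(40, 8, 3))
        space = ShapeSpace(aligned, aligned.mean(0), np.ones(40),
                           [f"s{i}" for i in range(40)])
        retained = mh.parallel_analysis_retention(space, n_random=60, seed=1)
        assert retained <= 2

    def test_rank_one_signal_retained(self):
        rng = np.random.default_rng(5)
        base = rng.normal(scale=25, size=(10, 3))
        direction = rng.normal(size=(10, 3))
        direction /= np.linalg.norm(direction)
        configs = np.stack([base + 8 * rng.normal() * direction
                            + rng.normal(scale=0.15, size=(10, 3)) for _ in range(50)])
        space = mh.gpa(configs)
        retained = mh.parallel_analysis_retention(space, n_random=60, seed=2)
        assert retained == 1

    def test_rank_bound_and_warning(self, rng):
        space = _shape_space_from(rng, n=12, k=6)
        retained = mh.parallel_analysis_retention(space, n_random=30, seed=0)
        assert retained <= min(space.n_specimens - 1, 3 * 6 - 7)
        with pytest.warns(UserWarning):
            mh.parallel_analysis_retention(space, n_random=5, seed=0)


def _records(n_ind, rng, n_replicated=0):
    recs = []
    for i in range(n_ind):
        recs.append(mh.SpecimenRecord(
            f"s{i:03d}",
            ethnicity=["british", "irish"][i % 2],
            sex=["M", "F"][(i // 2) % 2],
            age_class=AGE_CLASSES[i % 5]))
    for i in range(n_replicated):
        base = recs[i]
        recs.append(mh.SpecimenRecord(f"{base.id}_r", base.ethnicity, base.sex,
                                      base.age_class, replicate_of=base.id))
    return recs


class TestProcrustesAnova:
    def test_main_effect_dfs_match_design(self, rng):
        """DF = (levels-1)(3K-7): 53/212 for 20 anchors, 1433/1493 for 480/500."""
        assert mh.main_effect_df(2, 20) == 53
        assert mh.main_effect_df(5, 20) == 212
        assert mh.main_effect_df(2, 480) == 1433
        assert mh.main_effect_df(2, 500) == 1493
        recs = _records(40, rng, n_replicated=10)
        base = rng.normal(scale=30, size=(20, 3))
        configs = np.stack([base + rng.normal(scale=1, size=(20, 3)) for _ in recs])
        tab = mh.procrustes_anova(configs, recs, 20, partition="anchors").table
        assert tab.loc["Ethnicity", "DF"] == 53
        assert tab.loc["Sex", "DF"] == 53
        assert tab.loc["Age", "DF"] == 212

    def test_variance_sums_to_100_and_ss_additive(self, rng):
        recs = _records(30, rng, n_replicated=8)
        base = rng.normal(scale=30, size=(10, 3))
        configs = np.stack([base + rng.normal(scale=1, size=(10, 3)) for _ in recs])
        tab = mh.procrustes_anova(configs, recs, 5, partition="all").table
        effects = tab.drop(index="Total")
        assert effects["variance_pct"].sum() == pytest.approx(100.0, abs=0.01)
        assert effects["SS"].sum() == pytest.approx(tab.loc["Total", "SS"], rel=1e-9)

    def test_partitions_select_landmarks(self, rng):
        recs = _records(24, rng)
        base = rng.normal(scale=30, size=(12, 3))
        configs = np.stack([base + rng.normal(scale=1, size=(12, 3)) for _ in recs])
        t_anchor = mh.procrustes_anova(configs, recs, 8, partition="anchors").table
        t_semi = mh.procrustes_anova(configs, recs, 8, partition="semilandmarks").table
        assert t_anchor.loc["Ethnicity", "DF"] == 3 * 8 - 7
        assert t_semi.loc["Ethnicity", "DF"] == 3 * 4 - 7

    def test_null_f_mean_near_one(self):
        """With no group structure the factor F ratios average ~1."""
        rng = np.random.default_rng(17)
        fvals = []
        for _ in range(200):
            recs = _records(20, rng, n_replicated=5)
            base = rng.normal(scale=30, size=(8, 3))
            configs = np.stack([base + rng.normal(scale=1, size=(8, 3)) for _ in recs])
            tab = mh.procrustes_anova(configs, recs, 8, partition="anchors").table
            fvals.append(tab.loc["Ethnicity", "F"])
        assert np.mean(fvals) == pytest.approx(1.0, abs=0.15)

    def test_recovers_injected_variance_structure(self):
        """Between-group, individual and digitization strata recovered by rank order."""
        rng = np.random.default_rng(23)
        base = rng.normal(scale=40, size=(15, 3))
        recs, configs = [], []
        for i in range(60):
            eth = ["british", "irish"][i % 2]
            sex = ["M", "F"][(i // 2) % 2]
            age = AGE_CLASSES[i % 5]
            eff = (0.6 if eth == "british" else -0.6) * np.ones((15, 3))
            indiv = rng.normal(scale=2.0, size=(15, 3))
            recs.append(mh.SpecimenRecord(f"s{i}", eth, sex, age))
            configs.append(base + eff + indiv)
            if i < 20:
                recs.append(mh.SpecimenRecord(f"s{i}_r", eth, sex, age, replicate_of=f"s{i}"))
                configs.append(configs[-1] + rng.normal(scale=0.1, size=(15, 3)))
        tab = mh.procrustes_anova(np.stack(configs), recs, 15, partition="anchors").table
        assert tab.loc["Digitizing Error", "variance_pct"] < tab.loc["Ethnicity", "variance_pct"]
        assert tab.loc["Ethnicity", "variance_pct"] < tab.loc["Individual", "variance_pct"]
        assert tab.loc["Individual", "variance_pct"] > 50

    def test_no_replicates_warns_and_omits_error(self, rng):
        recs = _records(24, rng)
        base = rng.normal(scale=30, size=(8, 3))
        configs = np.stack([base + rng.normal(scale=1, size=(8, 3)) for _ in recs])
        with pytest.warns(UserWarning, match="error stratum"):
            tab = mh.procrustes_anova(configs, recs, 8, partition="all").table
        assert "Digitizing Error" not in tab.index


class TestEDMA:
    def test_known_distance_and_log(self):
        pts = np.zeros((20, 3))
        pts[4] = [0, 0, 0]     # me
        pts[18] = [100, 0, 0]  # op
        res = mh.edma_log_distances(pts, list(mh.ANCHOR_LABELS), pairs=[("me", "op")])
        row = res.table.iloc[0]
        assert row["distance_mm"] == pytest.approx(100.0)
        assert row["log10_distance"] == pytest.approx(2.0)

    def test_all_pairs_count(self, rng):
        pts = rng.normal(scale=50, size=(20, 3))
        res = mh.edma_log_distances(pts, list(mh.ANCHOR_LABELS), pairs="all")
        assert len(res.table) == 190

    def test_named_battery_resolves_on_synthetic_mean(self, head):
        _, anchors = head
        res = mh.edma_log_distances(anchors.points, anchors.labels, pairs=NAMED_DISTANCES)
        assert len(res.table) == 12
        assert (res.table["distance_mm"] > 0).all()
        # cranial length me-op is the largest of the battery, log10 ~ 2.3 at ~200 mm
        assert res.table.set_index("pair").loc["me-op", "distance_mm"] == \
            res.table["distance_mm"].max()

    def test_unknown_label_and_scaling(self, rng):
        pts = rng.normal(scale=50, size=(20, 3))
        with pytest.raises(KeyError, match="valid"):
            mh.edma_log_distances(pts, list(mh.ANCHOR_LABELS), pairs=[("me", "nope")])
        r1 = mh.edma_log_distances(pts, list(mh.ANCHOR_LABELS), pairs=[("me", "op")])
        r2 = mh.edma_log_distances(pts * 2, list(mh.ANCHOR_LABELS), pairs=[("me", "op")])
        assert r2.table["distance_mm"][0] == pytest.approx(2 * r1.table["distance_mm"][0])

    def test_group_mean_forms_in_mm(self, rng):
        """Mean forms rescale unit shapes by mean group centroid size (pre-GPA mm)."""
        base = rng.normal(scale=40, size=(10, 3))
        configs = np.stack([base + rng.normal(scale=0.5, size=(10, 3)) for _ in range(20)])
        labels = np.array(["a"] * 10 + ["b"] * 10)
        configs[10:] *= 1.5  # group b scaled up
        space = mh.gpa(configs)
        forms = mh.group_mean_forms(space, labels)
        cs_a = mh.centroid_size(forms["a"])
        cs_b = mh.centroid_size(forms["b"])
        assert cs_b / cs_a == pytest.approx(1.5, rel=0.02)
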