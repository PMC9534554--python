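"""GLM designs, edge-wise fits, FDR, cluster filtering, concordance."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isfcpipe import inference


def toy_cohort(n=100, seed=0):
    rng = np.random.default_rng(seed)
    age = rng.integers(18, 88, size=n)
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "age": age,
        "sex": rng.integers(0, 2, size=n),
        "education_years": rng.normal(20, 3, size=n),
        "mfd": rng.uniform(0.05, 0.3, size=n),
        "brain_volume": rng.normal(1.4e6, 1e5, size=n),
        "fluid_intelligence": np.clip(43 - 0.23 * age
                                      + rng.normal(0, 5, size=n), 0, 46),
    })


class TestDesigns:
    def test_age_design_shape_and_centering(self):
        d = inference.build_design_age(toy_cohort(100))
        assert d.x.shape == (100, 7)
        assert d.columns == tuple(inference.AGE_COLUMNS)
        assert abs(d.x[:, 1].mean()) < 1e-10  # age_c centred
        assert d.age_center == pytest.approx(toy_cohort(100)["age"].mean())

    def test_linear_age_design_drops_quadratic(self):
        d = inference.build_design_age(toy_cohort(60), quadratic=False)
        assert "age_c2" not in d.columns and d.x.shape[1] == 6

    def test_constant_sex_column_raises_rank_error(self):
        cohort = toy_cohort(50)
        cohort["sex"] = 1
        with pytest.raises(ValueError, match="sex"):
            inference.build_design_age(cohort)

    def test_behavior_design_has_no_age_term(self):
        d = inference.build_design_behavior(toy_cohort(80))
        assert d.x.shape == (80, 6)
        assert "age_c" not in d.columns and "behavior" in d.columns

    def test_missing_covariates_rejected(self):
        cohort = toy_cohort(50)
        cohort.loc[3, "brain_volume"] = np.nan
        with pytest.raises(ValueError, match="brain_volume"):
            inference.build_design_age(cohort)


class TestEdgeGLM:
    def test_noiseless_slope_recovered_exactly(self):
        cohort = toy_cohort(80, seed=1)
        d = inference.build_design_age(cohort)
        z = (3.0 * d.x[:, 1])[:, None]  # z = 3 * age_c exactly
        tab = inference.fit_edge_glm(z, d, [(0, 0)])
        b1 = tab[tab.coefficient == "age_c"].iloc[0]
        assert b1.estimate == pytest.approx(3.0, abs=1e-10)
        assert b1.p < 1e-30

    def test_matches_normal_equations_and_t_oracle(self):
        rng = np.random.default_rng(2)
        cohort = toy_cohort(60, seed=2)
        d = inference.build_design_age(cohort)
        z = rng.standard_normal((60, 3))
        tab = inference.fit_edge_glm(z, d, [(0, 0), (0, 1), (1, 0)])
        x = d.x
        xtx_inv = np.linalg.inv(x.T @ x)
        for e, (k, v) in enumerate([(0, 0), (0, 1), (1, 0)]):
            beta = xtx_inv @ x.T @ z[:, e]
            resid = z[:, e] - x @ beta
            s2 = resid @ resid / (60 - 7)
            for coef, j in [("age_c", 1), ("age_c2", 2)]:
                row = tab[(tab.network == k) & (tab.voxel == v)
                          & (tab.coefficient == coef)].iloc[0]
                se = np.sqrt(s2 * xtx_inv[j, j])
                assert row.estimate == pytest.approx(beta[j], abs=1e-8)
                assert row.t == pytest.approx(beta[j] / se, abs=1e-8)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        cohort = toy_cohort(50, seed=3)
        z = rng.standard_normal((50, 2))
        perm = rng.permutation(50)
        t1 = inference.fit_edge_glm(z, inference.build_design_age(cohort),
                                    [(0, 0), (0, 1)])
        t2 = inference.fit_edge_glm(
            z[perm], inference.build_design_age(cohort.iloc[perm]),
            [(0, 0), (0, 1)])
        pd.testing.assert_frame_equal(t1, t2, atol=1e-10)

    def test_nan_subjects_dropped_pairwise(self):
        rng = np.random.default_rng(4)
        cohort = toy_cohort(60, seed=4)
        d = inference.build_design_age(cohort)
        z = rng.standard_normal((60, 2))
        z[5, 0] = np.nan
        tab = inference.fit_edge_glm(z, d, [(0, 0), (0, 1)])
        df0 = tab[(tab.voxel == 0)].iloc[0].df
        df1 = tab[(tab.voxel == 1)].iloc[0].df
        assert df0 == df1 - 1

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_ols_oracle_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(25, 60))
        cohort = toy_cohort(n, seed=seed)
        try:
            d = inference.build_design_age(cohort)
        except ValueError:
            return  # rank-deficient draw, rejected by design contract
        z = rng.standard_normal((n, 1))
        tab = inference.fit_edge_glm(z, d, [(0, 0)])
        beta = np.linalg.lstsq(d.x, z[:, 0], rcond=None)[0]
        row = tab[tab.coefficient == "age_c"].iloc[0]
        assert row.estimate == pytest.approx(beta[1], abs=1e-8)


class TestFDR:
    def test_hand_bh_example_all_rejected(self):
        qv, rej = inference.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]), 0.05)
        assert rej.all()

    def test_scope_per_network_vs_global(self):
        # one network with strong signals, one with weak: pooling changes
        # the weak network's corrected threshold
        rows = []
        for v, p in enumerate([1e-6, 1e-6, 1e-6, 1e-6]):
            rows.append((0, v, "age_c", -1.0, 0.1, -5.0, p, 50))
        for v, p in enumerate([0.012, 0.03, 0.8, 0.9]):
            rows.append((1, v, "age_c", 1.0, 0.5, 2.0, p, 50))
        tab = pd.DataFrame(rows, columns=["network", "voxel", "coefficient",
                                          "estimate", "se", "t", "p", "df"])
        per = inference.apply_fdr(tab, q=0.05, scope="per-network")
        glo = inference.apply_fdr(tab, q=0.05, scope="global")
        n1_per = per[(per.network == 1)].reject.sum()
        n1_glo = glo[(glo.network == 1)].reject.sum()
        assert n1_glo >= n1_per


def brute_flood_fill(coords_set, start, connectivity=6):
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                rank = abs(dx) + abs(dy) + abs(dz)
                if (connectivity == 6 and rank == 1) or \
                   (connectivity == 18 and rank <= 2) or connectivity == 26:
                    offsets.append((dx, dy, dz))
    seen, todo = {start}, [start]
    while todo:
        x, y, z = todo.pop()
        for dx, dy, dz in offsets:
            nb = (x + dx, y + dy, z + dz)
            if nb in coords_set and nb not in seen:
                seen.add(nb)
                todo.append(nb)
    return seen


class TestClusterFilter:
    def grid(self):
        # 10x10x4 box, C-order coordinates
        return np.argwhere(np.ones((10, 10, 4), dtype=bool))

    def test_minimum_size_boundary(self):
        coords = self.grid()
        flags = np.zeros(len(coords), dtype=bool)
        flags[:22] = True
        assert inference.cluster_filter(flags, coords, min_size=23) == []
        flags[:23] = True
        out = inference.cluster_filter(flags, coords, min_size=23)
        assert len(out) == 1 and out[0][0] == 23

    def test_empty_input(self):
        assert inference.cluster_filter(np.zeros(400, dtype=bool),
                                        self.grid()) == []

    def test_matches_brute_flood_fill(self):
        rng = np.random.default_rng(5)
        coords = self.grid()
        flags = rng.random(len(coords)) < 0.3
        for conn in (6, 18, 26):
            out = inference.cluster_filter(flags, coords, min_size=1,
                                           connectivity=conn)
            active = {tuple(c) for c in coords[flags]}
            brute_sizes = []
            left = set(active)
            while left:
                comp = brute_flood_fill(active, next(iter(left)), conn)
                comp &= left
                brute_sizes.append(len(comp))
                left -= comp
            assert sorted(s for s, _ in out) == sorted(brute_sizes)

    def test_two_components_only_large_survives(self):
        coords = self.grid()
        flags = np.zeros(len(coords), dtype=bool)
        flags[:30] = True          # one 30-voxel component
        flags[200:210] = True      # one 10-voxel component (separate slab)
        out = inference.cluster_filter(flags, coords, min_size=23)
        assert [s for s, _ in out] == [30]

    def test_signs_clustered_separately(self):
        coords = self.grid()
        rows = []
        for v in range(25):               # slab x=0: one connected block
            rows.append((0, v, "age_c", -1.0, 0.1, -5, 1e-6, 40))
        for v in range(40, 65):           # slab x=1: one connected block
            rows.append((0, v, "age_c", 1.0, 0.1, 5, 1e-6, 40))
        tab = inference.apply_fdr(pd.DataFrame(
            rows, columns=["network", "voxel", "coefficient", "estimate",
                           "se", "t", "p", "df"]))
        clusters = inference.cluster_maps(tab, coords, min_size=23)
        assert sorted(c.sign for c in clusters) == [-1, 1]
        assert all(c.size == 25 for c in clusters)


class TestReporting:
    def make_table(self):
        rows = [(0, v, "age_c", -1.0, 0.1, -5.0, 1e-6, 40) for v in range(4)]
        rows += [(1, v, "age_c", 1.0, 0.5, 1.0, 0.6, 40) for v in range(4)]
        tab = pd.DataFrame(rows, columns=["network", "voxel", "coefficient",
                                          "estimate", "se", "t", "p", "df"])
        return inference.apply_fdr(tab, q=0.05)

    def test_map_summary_counts_and_threshold(self):
        summary = inference.map_summary(self.make_table())
        by_net = {s["network"]: s for s in summary}
        assert by_net[0]["n_rejected"] == 4
        assert by_net[0]["n_negative"] == 4
        assert by_net[0]["corrected_p_threshold"] == pytest.approx(1e-6)
        assert by_net[1]["n_rejected"] == 0
        assert by_net[1]["corrected_p_threshold"] is None

    def test_tmap_nifti_export(self, tmp_path):
        import nibabel as nib

        coords = np.argwhere(np.ones((2, 2, 2), dtype=bool))
        paths = inference.export_tmaps_nifti(self.make_table(), coords,
                                             tmp_path)
        assert len(paths) == 2
        vol = np.asarray(nib.load(tmp_path / "tmap_net-0_age_c.nii.gz").dataobj)
        assert vol.shape == (2, 2, 2)
        assert np.count_nonzero(vol) == 4
        assert vol[0, 0, 0] == pytest.approx(-5.0)


class TestSignConcordance:
    def test_full_agreement(self):
        full = pd.DataFrame({"network": [0, 0], "voxel": [0, 1],
                             "coefficient": "age_c",
                             "estimate": [-1.0, 2.0],
                             "reject": [True, True]})
        half = full.assign(estimate=[-0.5, 1.5], reject=[True, False])
        frac, n = inference.sign_concordance(full, half, "age_c")
        assert frac == 1.0 and n == 2

    def test_disagreement_counted(self):
        full = pd.DataFrame({"network": [0, 0], "voxel": [0, 1],
                             "coefficient": "age_c",
                             "estimate": [-1.0, 2.0],
                             "reject": [True, True]})
        half = full.assign(estimate=[1.0, 2.0])
        frac, _ = inference.sign_concordance(full, half, "age_c")
        assert frac == 0.5

    def test_no_rejections_gives_nan(self):
        full = pd.DataFrame({"network": [0], "voxel": [0],
                             "coefficient": "age_c", "estimate": [1.0],
                             "reject": [False]})
        frac, n = inference.sign_concordance(full, full, "age_c")
        assert np.isnan(frac) and n == 0
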