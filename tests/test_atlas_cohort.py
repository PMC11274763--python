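import numpy as np
import pytest

import fconnet as fc
from fconnet.atlas import AtlasError
from fconnet.cohort import DesignError, GenerationError, check_positive_definite


class TestAtlas:
    def test_default_atlas_is_the_160_roi_six_network_partition(self):
        atlas = fc.make_atlas()
        assert atlas.n_rois == 160
        assert len(set(atlas.labels)) == 160
        for net, size in fc.DEFAULT_NETWORK_SIZES.items():
            assert len(atlas.network_indices(net)) == size
        # deterministic assignment in canonical network order
        assert atlas.networks[:18] == ("cerebellum",) * 18

    def test_non_canonical_network_name_rejected(self):
        with pytest.raises(AtlasError, match="unknown network"):
            fc.make_atlas(6, {"A": 3, "B": 3})

    def test_size_mismatch_rejected(self):
        with pytest.raises(AtlasError, match="sum to"):
            fc.make_atlas(10, {"default": 3, "sensorimotor": 3})

    def test_declared_order_is_respected(self):
        atlas = fc.make_atlas(12, {"default": 6, "sensorimotor": 6})
        assert atlas.n_rois == 12
        assert atlas.networks[:6] == ("default",) * 6
        assert atlas.networks[6:] == ("sensorimotor",) * 6

    def test_scaled_sizes_sum_and_respect_proportions(self):
        for n in (24, 40, 80, 160):
            sizes = fc.scaled_network_sizes(n)
            assert sum(sizes.values()) == n
        assert fc.scaled_network_sizes(160) == fc.DEFAULT_NETWORK_SIZES


class TestCohortGeneration:
    def test_same_seed_is_bit_identical(self, atlas24):
        design = fc.default_design(atlas24, n_subjects=3, n_timepoints=50, seed=11)
        c1 = fc.generate_cohort(atlas24, design)
        c2 = fc.generate_cohort(atlas24, design)
        assert len(c1) == len(c2) == 9
        for a, b in zip(c1, c2):
            assert a.subject_id == b.subject_id and a.group == b.group
            np.testing.assert_array_equal(a.data, b.data)

    def test_independent_design_gives_near_zero_correlations(self, atlas24):
        design = fc.CohortDesign(
            groups=(("HC", 4),),
            n_timepoints=2000,
            within_corr={"HC": {n: 0.0 for n in atlas24.network_names}},
            between_corr=0.0,
            noise_sd=0.0,
            seed=3,
        )
        cohort = fc.generate_cohort(atlas24, design)
        rs = [np.corrcoef(ts.data, rowvar=False) for ts in cohort]
        iu = np.triu_indices(atlas24.n_rois, k=1)
        offdiag = np.concatenate([r[iu] for r in rs])
        assert abs(offdiag.mean()) < 0.01
        assert np.abs(offdiag).max() < 0.15

    def test_hc_like_group_hits_its_within_network_target(self):
        """Default HC design (within 0.6, noise 0.3) at T=150: attenuated
        within-network empirical correlation stays in [0.45, 0.65]."""
        atlas = fc.make_atlas(160)
        design = fc.CohortDesign(
            groups=(("HC", 15),),
            within_corr={"HC": {n: 0.6 for n in atlas.network_names}},
            seed=5,
        )
        cohort = fc.generate_cohort(atlas, design)
        vals = []
        for ts in cohort:
            r = np.corrcoef(ts.data, rowvar=False)
            for net in atlas.network_names:
                idx = atlas.network_indices(net)
                block = r[np.ix_(idx, idx)]
                iu = np.triu_indices(len(idx), k=1)
                vals.append(block[iu].mean())
        assert 0.45 <= np.mean(vals) <= 0.65

    def test_noise_free_matrices_converge_to_target_blocks(self):
        atlas = fc.make_atlas(40)
        design = fc.default_design(atlas, n_subjects=1, n_timepoints=5000, seed=9, noise_sd=0.0)
        cohort = fc.generate_cohort(atlas, design)
        for ts in cohort:
            target = fc.target_correlation(atlas, design, ts.group)
            emp = np.corrcoef(ts.data, rowvar=False)
            iu = np.triu_indices(atlas.n_rois, k=1)
            assert np.abs(emp[iu] - target[iu]).mean() < 0.02

    def test_group_segregation_ordering_is_preserved(self):
        """Mean within-network empirical correlation ordered HC > ODN > ODP
        under the default design, across seeds."""
        atlas = fc.make_atlas(40)
        ok = 0
        n_seeds = 10
        for seed in range(n_seeds):
            design = fc.default_design(atlas, seed=seed)
            cohort = fc.generate_cohort(atlas, design)
            means = {}
            for g in ("HC", "ODN", "ODP"):
                vals = []
                for ts in cohort:
                    if ts.group != g:
                        continue
                    r = np.corrcoef(ts.data, rowvar=False)
                    for net in atlas.network_names:
                        idx = atlas.network_indices(net)
                        iu = np.triu_indices(len(idx), k=1)
                        vals.append(r[np.ix_(idx, idx)][iu].mean())
                means[g] = np.mean(vals)
            if means["HC"] > means["ODN"] > means["ODP"]:
                ok += 1
        assert ok >= n_seeds - 1

    def test_design_validation(self, atlas24):
        with pytest.raises(DesignError, match="must exceed"):
            fc.CohortDesign(
                groups=(("HC", 3),),
                within_corr={"HC": {n: 0.1 for n in atlas24.network_names}},
                between_corr=0.2,
            ).validate()
        with pytest.raises(DesignError, match="no within_corr"):
            fc.CohortDesign(groups=(("XX", 3),)).validate()
        with pytest.raises(DesignError, match="n_timepoints"):
            fc.CohortDesign(n_timepoints=2).validate()

    def test_non_positive_definite_matrix_names_offending_block(self, atlas24):
        r = fc.target_correlation(atlas24, fc.default_design(atlas24), "HC")
        idx = atlas24.network_indices("default")
        bad = r.copy()
        # make the default-network block wildly non-PD
        bad[np.ix_(idx, idx)] = -0.9
        np.fill_diagonal(bad, 1.0)
        with pytest.raises(GenerationError, match="default"):
            check_positive_definite(bad, atlas24, "HC")

    def test_matched_mean_connectivity_design(self):
        atlas = fc.make_atlas(40)
        design = fc.default_design(atlas, match_mean_connectivity=True)
        design.validate()
        # weighted mean off-diagonal target equal across groups
        means = {}
        for g, _ in design.groups:
            r = fc.target_correlation(atlas, design, g)
            iu = np.triu_indices(atlas.n_rois, k=1)
            means[g] = r[iu].mean()
        vals = list(means.values())
        assert max(vals) - min(vals) < 1e-12


class TestCohortIO:
    def test_round_trip(self, tmp_path, atlas24, micro_cohort):
        manifest = fc.write_cohort(micro_cohort, tmp_path, atlas24)
        loaded = fc.read_cohort(manifest, atlas24)
        assert len(loaded) == len(micro_cohort)
        for orig, back in zip(micro_cohort, loaded):
            assert back.subject_id == orig.subject_id
            assert back.group == orig.group
            np.testing.assert_allclose(back.data, orig.data, rtol=1e-9)

    def test_manifest_and_header(self, tmp_path, atlas24, micro_cohort):
        import pandas as pd

        manifest = fc.write_cohort(micro_cohort, tmp_path, atlas24)
        mf = pd.read_csv(manifest, sep="\t")
        assert len(mf) == len(micro_cohort)
        first = pd.read_csv(tmp_path / mf["file"].iloc[0], sep="\t", nrows=1)
        assert list(first.columns) == list(atlas24.labels)
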