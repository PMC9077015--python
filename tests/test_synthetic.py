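"""Ground-truth consistency and determinism of the synthetic generators."""

import numpy as np
import pytest

from sysmetab.nmr import BucketSpec, bucket_samples
from sysmetab.screening import records_from_table, screen_compounds
from sysmetab.synthetic import (
    SERUM_TEMPLATE,
    SyntheticConfig,
    default_effect_table,
    generate_compound_table,
    generate_spectra,
    generate_target_and_pathway_library,
    metabolite_windows,
    _template_matrix,
)


class TestCompoundTable:
    @pytest.mark.parametrize(
        "n_herbs,n_per,n_active",
        [(2, 3, 2), (2, 3, 0), (1, 1, 1), (3, 4, 12), (4, 2, 5)],
    )
    def test_screen_consistency(self, n_herbs, n_per, n_active):
        cfg = SyntheticConfig(
            seed=7, n_herbs=n_herbs, n_compounds_per_herb=n_per, n_planted_active=n_active
        )
        table, truth = generate_compound_table(cfg)
        assert len(table) == n_herbs * n_per
        kept = screen_compounds(records_from_table(table))
        assert {r.compound_id for r in kept} == truth.active_compound_ids
        assert len(kept) == n_active

    def test_determinism_and_seed_sensitivity(self):
        t1, _ = generate_compound_table(SyntheticConfig(seed=7))
        t2, _ = generate_compound_table(SyntheticConfig(seed=7))
        t3, _ = generate_compound_table(SyntheticConfig(seed=8))
        assert t1.equals(t2)
        assert not t1.equals(t3)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_herbs=0)
        with pytest.raises(ValueError):
            SyntheticConfig(n_herbs=1, n_compounds_per_herb=2, n_planted_active=5)
        with pytest.raises(ValueError):
            SyntheticConfig(noise_cv=-0.1)
        with pytest.raises(KeyError):
            SyntheticConfig(effect_table={"unobtainium": ("up", "down", 2.0)})


class TestLibrary:
    def test_overlap_pathway_carries_active_targets(self):
        cfg = SyntheticConfig(seed=3)
        _, truth0 = generate_compound_table(cfg)
        hits, lib, truth = generate_target_and_pathway_library(cfg, truth0)
        for name in cfg.planted_overlap_names:
            p = lib.by_name(name)
            assert p.proteins <= truth.target_proteins
            assert p.proteins
        retained = hits[(hits.fit_rank <= 300) & (hits.z_score >= 0.8)]
        assert set(retained.compound_id) == truth.active_compound_ids

    def test_line_graph_edge_count(self):
        cfg = SyntheticConfig(seed=3)
        _, truth0 = generate_compound_table(cfg)
        _, lib, _ = generate_target_and_pathway_library(cfg, truth0)
        for p in lib:
            assert len(p.edges) == len(p.compounds) - 1

    def test_requires_compound_truth(self):
        cfg = SyntheticConfig(seed=3)
        from sysmetab.synthetic import GroundTruth

        with pytest.raises(ValueError, match="compound table"):
            generate_target_and_pathway_library(cfg, GroundTruth())


class TestSpectra:
    def test_planted_valine_decrease_in_model_buckets(self, bucket_matrix):
        ppm = bucket_matrix.ppm
        mask = np.zeros(ppm.shape, bool)
        for lo, hi in metabolite_windows("Valine"):
            mask |= (ppm >= lo) & (ppm <= hi)
        X = bucket_matrix.X()
        groups = bucket_matrix.groups.to_numpy()
        control = X[groups == "control"][:, mask].sum(axis=1).mean()
        model = X[groups == "model"][:, mask].sum(axis=1).mean()
        assert model < control

    def test_noiseless_spectra_identical_within_group(self):
        cfg = SyntheticConfig(seed=2, noise_cv=0.0, n_per_group=3)
        spectra, _ = generate_spectra(cfg)
        by_group: dict[str, list] = {}
        for s in spectra:
            by_group.setdefault(s.group, []).append(s)
        for members in by_group.values():
            for s in members[1:]:
                np.testing.assert_array_equal(s.intensity, members[0].intensity)
                np.testing.assert_array_equal(s.ppm, members[0].ppm)

    def test_unit_concentration_line_areas_integrate_to_one(self):
        ppm = np.arange(0.2, 9.0, 0.0005)
        M, names = _template_matrix(ppm)
        integrals = np.trapezoid(M, ppm, axis=0)
        # template areas are pi-normalized Lorentzians; finite tails cost <1%
        np.testing.assert_allclose(integrals, 1.0, rtol=0.01)

    def test_fold_change_monotonicity(self):
        effects = default_effect_table()
        effects["Valine"] = ("down", "up", 2.0)
        strong = dict(effects)
        strong["Valine"] = ("down", "up", 4.0)

        def normalized_gap(eff):
            cfg = SyntheticConfig(seed=4, noise_cv=0.0, n_per_group=2, effect_table=eff)
            spectra, _ = generate_spectra(cfg)
            m = bucket_samples(spectra)
            ppm = m.ppm
            mask = np.zeros(ppm.shape, bool)
            for lo, hi in metabolite_windows("Valine"):
                mask |= (ppm >= lo) & (ppm <= hi)
            g = m.groups.to_numpy()
            X = m.X()
            return (
                X[g == "control"][:, mask].sum(axis=1).mean()
                - X[g == "model"][:, mask].sum(axis=1).mean()
            )

        assert normalized_gap(strong) > normalized_gap(effects)

    def test_raw_integral_of_unchanged_metabolite_is_stable(self):
        # only valine is perturbed: the raw (unnormalized) lactate integral
        # must be identical across groups
        effects = {name: ("none", "none", 1.0) for name in SERUM_TEMPLATE}
        effects["Valine"] = ("down", "up", 2.0)
        cfg = SyntheticConfig(seed=4, noise_cv=0.0, n_per_group=1, effect_table=effects)
        spectra, _ = generate_spectra(cfg)
        lo, hi = 1.31, 1.35
        raw = {}
        for s in spectra:
            mask = (s.ppm >= lo) & (s.ppm <= hi)
            raw[s.group] = np.trapezoid(s.intensity[::-1][mask[::-1]], s.ppm[::-1][mask[::-1]])
        assert raw["model"] == pytest.approx(raw["control"], rel=1e-12)

    def test_group_means_follow_effect_table(self, spectra_and_truth):
        _, truth = spectra_and_truth
        means = truth.group_means
        assert means.loc["Valine", "model"] == pytest.approx(
            means.loc["Valine", "control"] / 2
        )
        assert means.loc["Lipids", "model"] == pytest.approx(
            means.loc["Lipids", "control"] * 2
        )

    def test_discriminative_bucket_indices_nonempty(self, spectra_and_truth):
        _, truth = spectra_and_truth
        idx = truth.discriminative_bucket_indices(BucketSpec())
        assert idx and all(0 <= i < 1875 for i in idx)

    def test_template_covers_panel_metabolites(self):
        assert set(default_effect_table()) == set(SERUM_TEMPLATE)
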