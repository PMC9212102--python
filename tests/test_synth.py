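import itertools

import numpy as np
import pytest

from connectogcn.synth import (
    ConfigurationError,
    SynthConfig,
    draw_site_effects,
    generate_cohort,
    generate_symptoms,
    inject_site_effects,
    read_subject_table,
    write_subject_table,
)


def _corr_of(series):
    return np.corrcoef(series.values, rowvar=False)


class TestSynthConfig:
    def test_default_layout_echo(self):
        cfg = SynthConfig(seed=1)
        assert cfg.n_sites == 6
        assert sum(1 for p, _ in cfg.site_sizes if p == 0) == 1
        assert sum(p for p, _ in cfg.site_sizes) == 505
        assert sum(c for _, c in cfg.site_sizes) == 907
        assert len(cfg.signal_nodes) == 10

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"n_regions": 1}, "n_regions"),
            ({"site_sizes": ((1, 0), (0, 5)), "n_sites": 2}, "site_sizes"),
            ({"signal_nodes": (0, 95)}, "signal_nodes"),
            ({"effect_size": 1.2}, "effect_size"),
            ({"symptom_coupling": 1.5}, "symptom_coupling"),
            ({"site_sizes": ((5, 5), (4, 4)), "n_sites": 2}, "site_sizes"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            SynthConfig(**kwargs)

    def test_all_control_cohort_allowed(self):
        cfg = SynthConfig(n_sites=3, site_sizes=((0, 5), (0, 5), (0, 5)))
        records, _ = generate_cohort(cfg)
        assert all(r.diagnosis == "control" for r in records)


class TestGenerateCohort:
    def test_seeded_determinism_bitwise(self, tmp_path):
        cfg = dict(
            n_regions=12,
            n_sites=2,
            site_sizes=((0, 5), (5, 2)),
            n_timepoints=50,
            signal_nodes=(1, 4, 7),
            seed=7,
        )
        r1, s1 = generate_cohort(SynthConfig(**cfg))
        r2, s2 = generate_cohort(SynthConfig(**cfg))
        assert r1 == r2
        for a, b in zip(s1, s2):
            assert np.array_equal(a.values, b.values)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_subject_table(r1, p1)
        write_subject_table(r2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_effect_size_recovered(self):
        """Patients' signal-pair correlation is lower by ~effect_size."""
        cfg = SynthConfig(
            n_sites=2,
            site_sizes=((0, 40), (40, 2)),
            n_regions=90,
            effect_size=0.3,
            seed=3,
        )
        recs, series = generate_cohort(cfg)
        pairs = list(itertools.combinations(cfg.signal_nodes, 2))

        def group_mean(group):
            vals = [
                np.mean([_corr_of(ts)[i, j] for i, j in pairs])
                for r, ts in zip(recs, series)
                if r.diagnosis == group
            ]
            return np.mean(vals)

        diff = group_mean("patient") - group_mean("control")
        assert diff == pytest.approx(-0.3, abs=0.05)

    def test_effect_localized_to_signal_nodes(self):
        """Edges not touching signal nodes show no group difference."""
        cfg = SynthConfig(
            n_regions=30,
            n_sites=2,
            site_sizes=((0, 200), (200, 2)),
            n_timepoints=150,
            signal_nodes=(0, 1, 2, 3, 4),
            effect_size=0.4,
            seed=9,
        )
        recs, series = generate_cohort(cfg)
        out = [i for i in range(30) if i not in cfg.signal_nodes]
        pat = np.mean(
            [
                np.arctanh(np.clip(_corr_of(ts)[np.ix_(out, out)], -0.999, 0.999))
                for r, ts in zip(recs, series)
                if r.diagnosis == "patient"
            ],
            axis=0,
        )
        con = np.mean(
            [
                np.arctanh(np.clip(_corr_of(ts)[np.ix_(out, out)], -0.999, 0.999))
                for r, ts in zip(recs, series)
                if r.diagnosis == "control"
            ],
            axis=0,
        )
        delta = pat - con
        np.fill_diagonal(delta, 0)
        assert np.abs(delta).max() < 0.05

    def test_records_round_trip_csv(self, tmp_path):
        cfg = SynthConfig(
            n_regions=8, n_sites=2, site_sizes=((0, 3), (4, 2)),
            signal_nodes=(1, 3, 5), seed=2
        )
        recs, _ = generate_cohort(cfg)
        path = tmp_path / "subjects.csv"
        write_subject_table(recs, path)
        back = read_subject_table(path)
        assert [r.subject_id for r in back] == [r.subject_id for r in recs]
        assert [r.diagnosis for r in back] == [r.diagnosis for r in recs]


class TestSiteEffects:
    def test_zero_shift_zero_scale_is_identity(self):
        cfg = SynthConfig(
            n_regions=8,
            n_sites=2,
            site_sizes=((0, 3), (3, 2)),
            signal_nodes=(1, 3, 5),
            site_shift=0.0,
            site_scale=0.0,
            seed=0,
        )
        edges = np.random.default_rng(0).normal(size=(8, 28))
        sites = ["site1"] * 4 + ["site2"] * 4
        out, _ = inject_site_effects(edges, sites, cfg)
        assert np.array_equal(out, edges)

    def test_between_site_shift_matches_drawn_gamma(self):
        cfg = SynthConfig(
            n_regions=8,
            n_sites=2,
            site_sizes=((0, 3), (3, 2)),
            signal_nodes=(1, 3, 5),
            site_shift=0.5,
            site_scale=0.0,
            seed=5,
        )
        rng = np.random.default_rng(1)
        edges = np.zeros((200, 28)) + rng.normal(size=(200, 28)) * 1e-6
        sites = ["site1"] * 100 + ["site2"] * 100
        out, params = inject_site_effects(edges, sites, cfg)
        observed = out[:100].mean(axis=0) - out[100:].mean(axis=0)
        expected = params.gamma[0] - params.gamma[1]
        assert np.allclose(observed, expected, atol=1e-5)

    def test_inputs_unmodified_and_shape_checked(self):
        cfg = SynthConfig(n_regions=8, n_sites=2, site_sizes=((0, 3), (3, 2)),
                          signal_nodes=(1, 3, 5))
        edges = np.ones((4, 28))
        snapshot = edges.copy()
        inject_site_effects(edges, ["site1", "site1", "site2", "site2"], cfg)
        assert np.array_equal(edges, snapshot)
        with pytest.raises(ValueError, match="rows"):
            inject_site_effects(edges, ["site1"] * 3, cfg)

    def test_site_params_independent_of_diagnosis(self):
        # parameters are drawn per site x edge from the config seed alone
        cfg = SynthConfig(n_regions=8, n_sites=2, site_sizes=((0, 3), (3, 2)),
                          signal_nodes=(1, 3, 5))
        p1 = draw_site_effects(cfg, ["site1", "site2"], 28)
        p2 = draw_site_effects(cfg, ["site2", "site1", "site1"], 28)
        assert np.array_equal(p1.gamma, p2.gamma)
        assert np.all(p1.delta > 0)
        assert p1.delta.mean() == pytest.approx(1.0, abs=0.1)


class TestSymptoms:
    def _patients(self, coupling, n=200, seed=0):
        cfg = SynthConfig(
            n_regions=6,
            n_sites=2,
            site_sizes=((0, 2), (n, 2)),
            n_timepoints=20,
            signal_nodes=(0, 1, 2),
            symptom_coupling=coupling,
            seed=seed,
        )
        recs, _ = generate_cohort(cfg)
        pats = [r for r in recs if r.diagnosis == "patient"]
        m = np.array([r.effect_magnitude for r in pats])
        s = np.array([r.symptom_negative for r in pats])
        return m, s, recs

    def test_null_coupling(self):
        m, s, _ = self._patients(0.0)
        assert abs(np.corrcoef(m, s)[0, 1]) < 0.15

    def test_coupling_recovered(self):
        m, s, _ = self._patients(0.6)
        assert np.corrcoef(m, s)[0, 1] == pytest.approx(0.6, abs=0.1)

    def test_controls_have_no_scores_and_bounds_hold(self):
        _, s, recs = self._patients(0.6)
        assert all(
            r.symptom_negative is None
            for r in recs
            if r.diagnosis == "control"
        )
        assert s.min() >= 7.0 and s.max() <= 49.0

    def test_constant_magnitudes_give_no_explained_variance(self):
        cfg = SynthConfig(
            n_regions=6,
            n_sites=2,
            site_sizes=((0, 2), (50, 2)),
            signal_nodes=(0, 1),
            symptom_coupling=0.9,
            seed=1,
        )
        recs, _ = generate_cohort(cfg)
        pats = [r for r in recs if r.diagnosis == "patient"]
        mags = np.full(len(pats), 1.0)
        generate_symptoms(recs, mags, cfg)
        scores = np.array([r.symptom_negative for r in pats])
        # constant predictor: correlation (hence explained variance) is zero
        assert np.std(mags) == 0 and np.std(scores) > 0

    def test_invalid_coupling_rejected(self):
        cfg = SynthConfig(n_regions=6, n_sites=2, site_sizes=((0, 2), (2, 2)),
                          signal_nodes=(0, 2))
        object.__setattr__(cfg, "symptom_coupling", 2.0)
        with pytest.raises(ConfigurationError, match="symptom_coupling"):
            generate_symptoms([], np.array([]), cfg)
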