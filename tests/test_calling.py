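"""Genotype calling: polar transform, cluster fitting, primary calls and
zCall-style recalling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pidarray import calling, simulate


class TestPolarTransform:
    @pytest.mark.parametrize("x, y, expected", [
        (3.0, 3.0, 0.5),            # symmetric channels
        (5.0, 0.0, 0.0),            # pure A signal
        (0.0, 5.0, 1.0),            # pure B signal
        (1.0, np.sqrt(3.0), 2 / 3),  # arctan(sqrt(3)) = pi/3
    ])
    def test_known_angles(self, x, y, expected):
        angle, total = calling.polar_transform(x, y)
        assert angle == pytest.approx(expected)
        assert total == pytest.approx(x + y)

    def test_unmeasured_point_is_nan(self):
        angle, total = calling.polar_transform(0.0, 0.0)
        assert np.isnan(angle) and total == 0.0

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            calling.polar_transform(-1.0, 2.0)

    @given(st.floats(1e-3, 1e6), st.floats(1e-3, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_angle_in_unit_interval_and_monotone_in_ratio(self, x, y):
        angle, _ = calling.polar_transform(x, y)
        assert 0.0 <= angle <= 1.0
        angle2, _ = calling.polar_transform(x, y * 2)
        assert angle2 >= angle


def synth_probe(n_aa=30, n_ab=10, n_bb=8, noise=0.02, total=1000.0, seed=0):
    """Channel matrices for one probe with known cluster membership."""
    rng = np.random.default_rng(seed)
    angles = np.concatenate([
        rng.normal(0.05, noise, n_aa),
        rng.normal(0.5, noise, n_ab),
        rng.normal(0.95, noise, n_bb)]).clip(0, 1)
    half = np.pi / 2
    c, s = np.cos(angles * half), np.sin(angles * half)
    x = total * c / (c + s)
    y = total * s / (c + s)
    return x[:, None], y[:, None]


class TestFitClusters:
    def test_recovers_well_separated_centers(self):
        x, y = synth_probe()
        model = calling.fit_clusters(x, y, ["p"])
        assert model.centers[0] == pytest.approx([0.05, 0.5, 0.95], abs=0.03)
        assert model.counts[0].tolist() == [30, 10, 8]
        assert not model.imputed[0].any()

    def test_monomorphic_probe_imputes_two_clusters(self):
        x, y = synth_probe(n_aa=40, n_ab=0, n_bb=0)
        model = calling.fit_clusters(x, y, ["p"])
        assert model.imputed[0].tolist() == [False, True, True]
        assert model.centers[0][1] == pytest.approx(0.5)
        assert model.centers[0][2] == pytest.approx(0.95)

    def test_too_few_samples_flagged_uncallable(self):
        x, y = synth_probe(n_aa=5, n_ab=0, n_bb=0)
        model = calling.fit_clusters(x, y, ["p"])
        assert not model.callable[0]

    def test_noise_widens_spreads_not_occupancy(self):
        tight = calling.fit_clusters(*synth_probe(noise=0.01), ["p"])
        loose = calling.fit_clusters(*synth_probe(noise=0.05), ["p"])
        assert (loose.spreads[0] > tight.spreads[0]).all()
        assert loose.counts[0].tolist() == tight.counts[0].tolist()


class TestPrimaryCall:
    def test_point_at_center_scores_high(self):
        x, y = synth_probe()
        model = calling.fit_clusters(x, y, ["p"])
        a = model.centers[0][0]
        half = np.pi / 2
        px = 1000 * np.cos(a * half) / (np.cos(a * half) + np.sin(a * half))
        py = 1000 - px
        g = calling.primary_call(model, np.array([[px]]), np.array([[py]]),
                                 ["s"])
        assert g.calls[0, 0] == 0
        assert g.scores[0, 0] > 0.9

    def test_boundary_point_is_nocall(self):
        x, y = synth_probe()
        model = calling.fit_clusters(x, y, ["p"])
        a = (model.centers[0][1] + model.centers[0][2]) / 2  # AB|BB midpoint
        half = np.pi / 2
        px = 1000 * np.cos(a * half) / (np.cos(a * half) + np.sin(a * half))
        py = 1000 - px
        g = calling.primary_call(model, np.array([[px]]), np.array([[py]]),
                                 ["s"])
        assert g.calls[0, 0] == -1
        assert np.isnan(g.scores[0, 0])

    def test_score_nan_exactly_where_nocall(self):
        x, y = synth_probe(noise=0.08)
        model = calling.fit_clusters(x, y, ["p"])
        g = calling.primary_call(model, x, y, [f"s{i}" for i in range(48)])
        assert (np.isnan(g.scores) == (g.calls == -1)).all()


def _recall_of_planted_hets(cohort, matrix):
    led = cohort.ledger.planted_snvs
    hets = led[led["genotype"] == "AB"]
    sidx = {s: i for i, s in enumerate(matrix.sample_ids)}
    pidx = {p: i for i, p in enumerate(matrix.probe_ids)}
    hits = sum(int(matrix.calls[sidx[r.sample_id], pidx[r.probe_id]] == 1)
               for r in hets.itertuples(index=False))
    return hits, len(hets)


class TestZcallRecall:
    def test_rescues_boundary_heterozygote(self):
        # tight AA cluster plus a het no-called on the AA|AB boundary
        x, y = synth_probe(n_aa=40, n_ab=0, n_bb=0, noise=0.01)
        model = calling.fit_clusters(x, y, ["p"])
        a = 0.30   # outside the no-call-free zone around the AA center
        half = np.pi / 2
        px = 1000 * np.cos(a * half) / (np.cos(a * half) + np.sin(a * half))
        py = 1000 - px
        prim = calling.primary_call(model, np.array([[px]]),
                                    np.array([[py]]), ["s"])
        assert prim.calls[0, 0] == -1
        rec = calling.zcall_recall(model, prim, np.array([[px]]),
                                   np.array([[py]]))
        assert rec.calls[0, 0] == 1
        assert rec.caller[0, 0] == calling.CALLER_RECALLED

    def test_never_alters_confident_primary_calls(self):
        cfg = simulate.SimulationConfig(
            n_patients=20, n_controls=10, n_custom_probes=120,
            n_backbone_probes=150, noise_sd=0.1, probe_failure_rate=0.0,
            sample_failure_rate=0.0, seed=42)
        c = simulate.simulate_cohort(cfg)
        run = c.run1
        model = calling.fit_clusters(run.x, run.y, run.probe_ids)
        prim = calling.primary_call(model, run.x, run.y, run.sample_ids)
        rec = calling.zcall_recall(model, prim, run.x, run.y)
        was_called = prim.calls >= 0
        assert (rec.calls[was_called] == prim.calls[was_called]).all()
        assert (rec.caller[was_called] == calling.CALLER_PRIMARY).all()

    def test_recall_rate_of_planted_hets_increases(self):
        """Paired comparison at a noise level where primary calling
        no-calls part of the rare heterozygotes."""
        gained = 0
        for rep in range(5):
            cfg = simulate.SimulationConfig(
                n_patients=25, n_controls=15, n_custom_probes=150,
                n_backbone_probes=200, noise_sd=0.13,
                probe_failure_rate=0.0, sample_failure_rate=0.0,
                rare_variant_rate=2.0, seed=900 + rep)
            c = simulate.simulate_cohort(cfg)
            run = c.run1
            model = calling.fit_clusters(run.x, run.y, run.probe_ids)
            prim = calling.primary_call(model, run.x, run.y, run.sample_ids)
            rec = calling.zcall_recall(model, prim, run.x, run.y)
            before, _ = _recall_of_planted_hets(c, prim)
            after, _ = _recall_of_planted_hets(c, rec)
            assert after >= before
            gained += after - before
        assert gained > 0


class TestNoiseMonotonicity:
    def test_concordance_non_increasing_in_noise(self):
        """Calling accuracy against truth degrades with angular noise."""
        rates = []
        for noise in (0.0, 0.05, 0.12, 0.2):
            cfg = simulate.SimulationConfig(
                n_patients=15, n_controls=15, n_custom_probes=80,
                n_backbone_probes=400, noise_sd=noise, intensity_cv=0.0,
                probe_failure_rate=0.0, sample_failure_rate=0.0,
                rare_variant_rate=0.5, seed=21)
            c = simulate.simulate_cohort(cfg)
            run = c.run1
            model = calling.fit_clusters(run.x, run.y, run.probe_ids)
            g = calling.primary_call(model, run.x, run.y, run.sample_ids)
            truth = c.truth.to_codes(list(run.sample_ids),
                                     list(run.probe_ids))
            both = (g.calls >= 0) & (truth >= 0)
            rates.append((g.calls[both] == truth[both]).mean())
        assert rates[0] == 1.0
        assert all(a >= b - 1e-9 for a, b in zip(rates, rates[1:]))
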