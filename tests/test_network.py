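"""Architecture construction: wiring audits, determinism, scaling."""

import numpy as np
import pytest

from snnpong.network import (NetworkSpec, PopulationSpec, ProjectionSpec,
                             build_network, feedforward_spec, motor_hops,
                             recurrent_spec, sample_projection,
                             validate_network)


@pytest.fixture(scope="module")
def ff_net():
    return build_network(feedforward_spec(), 7)


@pytest.fixture(scope="module")
def rec_net():
    return build_network(recurrent_spec(), 7)


class TestFeedforward:
    def test_population_sizes(self, ff_net):
        sizes = {p.name: p.size for p in ff_net.spec.populations}
        assert sizes["EV1"] == 6400
        assert all(sizes[f"EV1D{d}"] == 400 for d in
                   ("E", "NE", "N", "NW", "W", "SW", "S", "SE"))
        assert sizes["EA"] == sizes["EA2"] == 1400
        assert sizes["EMUP"] == sizes["EMDOWN"] == 300
        assert sizes["IM"] == 206 and sizes["IML"] == 94

    def test_audit_clean(self, ff_net):
        assert validate_network(ff_net).ok

    def test_ea_total_excitatory_indegree(self, ff_net):
        """Each EA neuron pools 128 location and 8x8 direction inputs."""
        total = np.zeros(1400, dtype=int)
        for proj in ff_net.spec.projections:
            if proj.post == "EA" and proj.kind == "AM2":
                total += ff_net.in_degrees(proj.name)
        assert (total == 128 + 8 * 8).all()

    def test_exact_ev1_ea_row(self, ff_net):
        deg = ff_net.in_degrees("EV1->EA:AM2")
        sl = ff_net.projection_slices["EV1->EA:AM2"]
        assert (deg == 128).all()
        assert (ff_net.s_w_init[sl] == 6.0).all()

    def test_no_feedback_edges(self, ff_net):
        posts = {"EA": {"EV1"} | {f"EV1D{d}" for d in
                                  ("E", "NE", "N", "NW", "W", "SW", "S", "SE")}}
        for proj in ff_net.spec.projections:
            if proj.post == "EA":
                assert proj.pre in posts["EA"]
            assert (proj.pre, proj.post) not in {("EA2", "EA"), ("EM", "EA"),
                                                 ("EMUP", "EA"), ("EMDOWN", "EA")}

    def test_only_motor_afferents_plastic(self, ff_net):
        plastic = {p.name for p in ff_net.spec.projections if p.plastic}
        assert plastic == {"EA->EMUP:AM2", "EA->EMDOWN:AM2",
                           "EA2->EMUP:AM2", "EA2->EMDOWN:AM2"}

    def test_motor_hops(self):
        hops = motor_hops(feedforward_spec())
        assert hops["EMUP"] == hops["EMDOWN"] == 0
        assert hops["EA"] == hops["EA2"] == 1
        assert hops["EV1"] == 2


class TestRecurrent:
    def test_population_sizes(self, rec_net):
        sizes = {p.name: p.size for p in rec_net.spec.populations}
        assert sizes == {"EV1": 6400, "EA": 600, "EA2": 300,
                         "EMUP": 300, "EMDOWN": 300, "IA": 206, "IAL": 94,
                         "IA2": 103, "IA2L": 47, "IM": 206, "IML": 94}

    def test_audit_clean(self, rec_net):
        assert validate_network(rec_net).ok

    def test_em_excitatory_indegrees(self, rec_net):
        """Motor neurons pool 30 EV1 + 100 EA + 60 EA2 + 60 EM inputs."""
        for m in ("EMUP", "EMDOWN"):
            assert (rec_net.in_degrees(f"EV1->{m}:AM2") == 30).all()
            assert (rec_net.in_degrees(f"EA->{m}:AM2") == 100).all()
            assert (rec_net.in_degrees(f"EA2->{m}:AM2") == 60).all()
            assert (rec_net.in_degrees(f"{m}->{m}:AM2") == 60).all()

    def test_reciprocal_motor_inhibition_probabilistic(self, rec_net):
        """Cross-population inhibition wired at p = 0.125 per pair."""
        sl = rec_net.projection_slices["EMUP->EMDOWN:GA"]
        n_pairs = 300 * 300
        k = sl.stop - sl.start
        p = 0.125
        sigma = np.sqrt(n_pairs * p * (1 - p))
        assert abs(k - n_pairs * p) < 4 * sigma

    def test_no_autapses(self, rec_net):
        for name in ("EA->EA:AM2", "EMUP->EMUP:AM2", "IM->IM:GA"):
            sl = rec_net.projection_slices[name]
            assert (rec_net.s_pre[sl] != rec_net.s_post[sl]).all()

    def test_noise_drives_on_association_and_motor(self, rec_net):
        pops = {d["pop"] for k, d in rec_net.drives.items()
                if k.startswith("noise:")}
        assert pops == {"EA", "IA", "IAL", "EA2", "IA2", "IA2L",
                        "EMUP", "EMDOWN", "IM", "IML"}


class TestBuildRules:
    def test_seeded_rebuild_bit_identical(self):
        spec = feedforward_spec(input_shape=(20, 20), scale=4)
        a = build_network(spec, 3)
        b = build_network(spec, 3)
        for attr in ("s_pre", "s_post", "s_kind", "s_w", "s_delay"):
            assert np.array_equal(getattr(a, attr), getattr(b, attr))
        assert a.blueprint_hash() == b.blueprint_hash()

    def test_convergence_exceeding_pool_rejected(self):
        spec = NetworkSpec(
            architecture="toy",
            populations=(PopulationSpec("A", 5, "E"),
                         PopulationSpec("B", 3, "E")),
            projections=(ProjectionSpec("A", "B", "AM2", 10, 1.0),))
        with pytest.raises(ValueError, match="convergence"):
            build_network(spec, 0)

    def test_sample_projection_exact_indegree(self):
        rng = np.random.default_rng(0)
        spec = ProjectionSpec("A", "B", "AM2", 7, 1.0)
        pres, posts = sample_projection(spec, pre_size=50, post_size=20, rng=rng)
        assert len(pres) == 7 * 20
        deg = np.bincount(posts, minlength=20)
        assert (deg == 7).all()
        for j in range(20):  # without replacement per post neuron
            assert len(set(pres[posts == j])) == 7

    def test_zero_convergence_empty(self):
        spec = NetworkSpec(
            architecture="toy",
            populations=(PopulationSpec("A", 5, "E"),
                         PopulationSpec("B", 3, "E")),
            projections=(ProjectionSpec("A", "B", "AM2", 0, 1.0),))
        net = build_network(spec, 0)
        sl = net.projection_slices["A->B:AM2"]
        assert sl.stop - sl.start == 0

    def test_deleted_synapse_reported_once(self):
        net = build_network(feedforward_spec(input_shape=(20, 20), scale=4), 5)
        sl = net.projection_slices["EA->EA2:AM2"]
        # drop one synapse from the middle of the projection
        keep = np.ones(len(net.s_pre), dtype=bool)
        keep[sl.start + 10] = False
        for attr in ("s_pre", "s_post", "s_kind", "s_w", "s_w_init",
                     "s_delay", "s_plastic"):
            setattr(net, attr, getattr(net, attr)[keep])
        shift = {}
        for name, s in net.projection_slices.items():
            a, b = s.start, s.stop
            if a > sl.start:
                a -= 1
            if b > sl.start:
                b -= 1
            shift[name] = slice(a, b)
        net.projection_slices = shift
        net._build_csr()
        report = validate_network(net, raise_on_error=False)
        in_degree_violations = [v for v in report.violations if "in-degree" in v]
        assert len(in_degree_violations) == 1

    def test_delay_classes(self, ff_net):
        for proj in ff_net.spec.projections:
            sl = ff_net.projection_slices[proj.name]
            d = ff_net.s_delay[sl]
            if proj.kind == "GA":
                assert d.min() >= 1.8 and d.max() <= 2.2
            else:
                assert d.min() >= 3.0 and d.max() <= 5.0


class TestScaling:
    def test_visual_rows_preserve_total_weight(self):
        full = feedforward_spec()
        scaled = feedforward_spec(input_shape=(20, 20), scale=4)
        for f, s in zip(full.projections, scaled.projections):
            assert (f.pre, f.post, f.kind) == (s.pre, s.post, s.kind)
            if f.pre.startswith("EV1"):
                # totals preserved within the rounding of the convergence
                assert s.convergence * s.weight == pytest.approx(
                    f.convergence * f.weight, rel=0.02)
            else:
                # deeper rows keep per-event weight and coincidence order
                assert s.weight == f.weight
                assert s.convergence <= f.convergence

    def test_scaled_weights_subthreshold(self):
        """No single scaled excitatory event can fire a resting E cell."""
        scaled = feedforward_spec(input_shape=(20, 20), scale=4)
        for p in scaled.projections:
            if p.kind == "AM2":
                assert p.weight <= 20.0 < 25.0  # E threshold gap is 25 mV
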