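"""Federated engine: partitioning, algorithm equivalences, accounting hooks."""

import math

import numpy as np
import pytest

import fedgtf.engine as engine_mod
from fedgtf import (ClientState, FactorSet, RunConfig, ServerState,
                    aggregate, compress, initialize_states, partition_tensor,
                    reassemble, run, run_fedgtf_ef, run_fedgtf_ef_pc,
                    sample_block, sample_fibers, partial_stochastic_gradient,
                    generate_instance, SynthSpec)
from fedgtf.tensor import _strides

from helpers import make_sparse


def _sorted_entries(t):
    order = np.lexsort(t.coords.T[::-1])
    return t.coords[order], t.values[order]


@pytest.fixture
def instance():
    return generate_instance(
        SynthSpec((10, 6, 6, 6), rank=3, density=0.05, num_clients=2,
                  noise=0.0, seed=3))


def _cfg(**kw):
    base = dict(algorithm="fedgtf_ef", loss="least_squares", num_clients=2,
                rank=3, sample_size=16, step_size=0.05, num_iters=40, seed=11)
    base.update(kw)
    return RunConfig(**base)


class TestPartition:
    def test_k1_is_identity(self, rng):
        t = make_sparse((7, 4, 3), 0.4, rng)
        [(rows, slab)] = partition_tensor(t, 1, rng)
        np.testing.assert_array_equal(rows, np.arange(1, 8))
        np.testing.assert_array_equal(slab.coords, t.coords)

    def test_nonzeros_conserved_and_rows_disjoint(self, rng):
        t = make_sparse((11, 4, 3), 0.5, rng)
        parts = partition_tensor(t, 3, rng)
        assert sum(s.nnz for _, s in parts) == t.nnz
        all_rows = np.concatenate([rows for rows, _ in parts])
        assert sorted(all_rows) == list(range(1, 12))

    def test_roundtrip_reassembles_original(self, rng):
        t = make_sparse((9, 5, 4), 0.4, rng)
        parts = partition_tensor(t, 4, rng)
        clients = [
            ClientState(k, rows, slab, np.zeros((len(rows), 1)), {}, rng)
            for k, (rows, slab) in enumerate(parts)
        ]
        back = reassemble(clients, t.shape)
        bc, bv = _sorted_entries(back)
        tc, tv = _sorted_entries(t)
        np.testing.assert_array_equal(bc, tc)
        np.testing.assert_array_equal(bv, tv)

    def test_too_many_clients_rejected(self, rng):
        t = make_sparse((3, 4), 0.5, rng)
        with pytest.raises(ValueError):
            partition_tensor(t, 4, rng)


class TestSampleBlock:
    def test_uniform_frequencies(self):
        server = ServerState({}, np.random.default_rng(0))
        D, n = 4, 10_000
        counts = np.bincount(
            [sample_block(server, D) for _ in range(n)], minlength=D + 1)[1:]
        assert np.all(np.abs(counts / n - 1 / D) < 0.02)

    def test_cyclic_sequences(self):
        server = ServerState({}, np.random.default_rng(0))
        assert [sample_block(server, 4, "cyclic", t) for t in range(6)] == \
            [1, 2, 3, 4, 1, 2]
        assert [sample_block(server, 4, "cyclic_shared", t) for t in range(5)] == \
            [2, 3, 4, 2, 3]

    def test_seeded_determinism(self):
        a = ServerState({}, np.random.default_rng(5))
        b = ServerState({}, np.random.default_rng(5))
        assert [sample_block(a, 3) for _ in range(50)] == \
            [sample_block(b, 3) for _ in range(50)]


class TestAggregate:
    def test_single_message_is_itself(self, rng):
        P = rng.normal(size=(2, 3))
        np.testing.assert_array_equal(aggregate([compress("identity", P)]), P)

    def test_opposite_messages_cancel(self):
        P = np.array([[1.0, -2.0]])
        msgs = [compress("identity", P), compress("identity", -P)]
        np.testing.assert_array_equal(aggregate(msgs), np.zeros((1, 2)))

    def test_identity_mean_is_exact(self, rng):
        mats = [rng.normal(size=(3, 2)) for _ in range(4)]
        msgs = [compress("identity", m) for m in mats]
        np.testing.assert_allclose(aggregate(msgs), np.mean(mats, axis=0))

    def test_shape_mismatch_rejected(self):
        msgs = [compress("identity", np.ones((2, 2))),
                compress("identity", np.ones((3, 2)))]
        with pytest.raises(ValueError):
            aggregate(msgs)


class TestConfigValidation:
    def test_tau_requires_periodic_variant(self):
        with pytest.raises(ValueError):
            _cfg(algorithm="fedgtf_ef", tau=4)

    def test_periodic_rejects_nonsmooth_reg(self):
        with pytest.raises(ValueError):
            _cfg(algorithm="fedgtf_ef_pc", tau=4, reg_name="l1", reg_weight=0.1)

    def test_unknown_algorithm(self):
        with pytest.raises(ValueError):
            _cfg(algorithm="admm")

    def test_inv_sqrt_schedule(self):
        cfg = _cfg(step_schedule="inv_sqrt_T", step_size=1.0, num_iters=99)
        assert cfg.step(0) == pytest.approx(0.1)
        assert cfg.step(50) == cfg.step(0)


class TestEquivalences:
    def test_identity_compressor_has_zero_error_memory(self, instance):
        cfg = _cfg(compressor="identity")
        clients, server = initialize_states(cfg, instance.tensor)
        run_fedgtf_ef(cfg, clients, server)
        for c in clients:
            for E in c.errors.values():
                np.testing.assert_array_equal(E, 0.0)

    def test_identity_ef_bitwise_equals_dist_brascpd(self, instance):
        f1, l1 = run(_cfg(compressor="identity"), instance.tensor)
        f2, l2 = run(_cfg(algorithm="dist_brascpd"), instance.tensor)
        for a, b in zip(f1.factors, f2.factors):
            np.testing.assert_array_equal(a, b)
        assert l1.comm.records == l2.comm.records

    @pytest.mark.parametrize("comp", ["identity", "sign"])
    def test_pc_tau1_matches_ef_to_roundoff(self, comp, instance):
        f1, _ = run(_cfg(compressor=comp, num_iters=200), instance.tensor)
        f2, _ = run(_cfg(algorithm="fedgtf_ef_pc", tau=1, compressor=comp,
                         num_iters=200), instance.tensor)
        for a, b in zip(f1.factors, f2.factors):
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_k1_identity_equals_centralized_sgd(self, instance):
        """The engine at K=1 with no compression is plain block-randomized SGD."""
        cfg = _cfg(compressor="identity", num_clients=1, num_iters=150)
        fe, _ = run(cfg, instance.tensor)

        ss = np.random.SeedSequence(cfg.seed)
        block_ss, init_ss, _, c0 = ss.spawn(4)
        init_rng = np.random.default_rng(init_ss)
        A = [init_rng.uniform(size=(I, cfg.rank)) / math.sqrt(cfg.rank)
             for I in instance.tensor.shape]
        block_rng = np.random.default_rng(block_ss)
        crng = np.random.default_rng(c0)
        D = instance.tensor.order
        for t in range(cfg.num_iters):
            d = int(block_rng.integers(1, D + 1))
            _, ncols = _strides(instance.tensor.shape, d)
            s = sample_fibers(d, instance.tensor.shape,
                              min(cfg.sample_size, ncols), crng)
            G = partial_stochastic_gradient(instance.tensor,
                                            FactorSet(tuple(A)), s, cfg.loss)
            A[d - 1] = A[d - 1] - cfg.step_size * G
        for a, b in zip(fe.factors, A):
            np.testing.assert_array_equal(a, b)

    def test_pc_identical_clients_never_diverge(self, rng):
        """Two clients with the same data and sample streams act like one."""
        slab = make_sparse((4, 5, 5), 0.2, rng)
        D, R, seed = slab.order, 2, 13

        def build(K):
            init = np.random.default_rng(seed)
            shared = {d: init.uniform(size=(slab.shape[d - 1], R))
                      for d in range(2, D + 1)}
            A1 = init.uniform(size=(slab.shape[0], R))
            clients = []
            for k in range(K):
                rows = np.arange(1, slab.shape[0] + 1) + k * slab.shape[0]
                clients.append(ClientState(
                    k, rows, slab, A1.copy(),
                    {d: np.zeros_like(shared[d]) for d in shared},
                    np.random.default_rng(99),
                    {d: shared[d].copy() for d in shared}))
            server = ServerState({d: shared[d].copy() for d in shared},
                                 np.random.default_rng(7))
            return clients, server

        cfg = RunConfig(algorithm="fedgtf_ef_pc", tau=8, compressor="identity",
                        num_clients=2, rank=R, sample_size=8, step_size=0.05,
                        num_iters=64, seed=seed)
        c2, s2 = build(2)
        run_fedgtf_ef_pc(cfg, c2, s2)
        c1, s1 = build(1)
        run_fedgtf_ef_pc(cfg, c1, s1)
        for d in s2.global_factors:
            np.testing.assert_allclose(c2[0].local_factors[d],
                                       c2[1].local_factors[d], atol=1e-14)
            np.testing.assert_allclose(s2.global_factors[d],
                                       s1.global_factors[d], atol=1e-14)
        np.testing.assert_allclose(c2[0].mode1_rows, c2[1].mode1_rows,
                                   atol=1e-14)


class TestPeriodicCommunication:
    def test_uplink_round_count_matches_log(self, instance):
        cfg = _cfg(algorithm="fedgtf_ef_pc", tau=3, num_iters=50)
        _, log = run(cfg, instance.tensor)
        expected = sum(1 for t, d in enumerate(log.blocks)
                       if d != 1 and t % 3 == 0)
        sending = {(t, c) for t, c, d, p, s in log.comm.records if p > 0}
        assert len(sending) == expected * cfg.num_clients

    def test_no_bits_between_communication_rounds(self, instance):
        cfg = _cfg(algorithm="fedgtf_ef_pc", tau=4, num_iters=40)
        _, log = run(cfg, instance.tensor)
        for t, c, d, p, s in log.comm.records:
            if t % 4 != 0 or d == 1:
                assert p == 0 and s == 0


class TestEngineContracts:
    def test_mode1_is_never_serialized(self, instance, monkeypatch):
        """Serialization audit: no message carries patient-mode content."""
        sent_blocks = []
        original = engine_mod._send

        def spy(block, P, kind):
            sent_blocks.append(block)
            return original(block, P, kind)

        monkeypatch.setattr(engine_mod, "_send", spy)
        for alg in ("fedgtf_ef", "dist_sgd_ef", "dist_sgd_ef_comp"):
            run(_cfg(algorithm=alg, num_iters=12), instance.tensor)
        cfgp = _cfg(algorithm="fedgtf_ef_pc", tau=2, num_iters=12)
        run(cfgp, instance.tensor)
        assert sent_blocks and 1 not in sent_blocks

    @pytest.mark.filterwarnings("ignore:overflow")
    def test_divergence_raises_with_diagnostic(self, instance):
        with pytest.raises(RuntimeError, match="diverged"):
            run(_cfg(step_size=50.0, num_iters=300), instance.tensor)

    def test_run_is_reproducible(self, instance):
        f1, l1 = run(_cfg(), instance.tensor)
        f2, l2 = run(_cfg(), instance.tensor)
        for a, b in zip(f1.factors, f2.factors):
            np.testing.assert_array_equal(a, b)
        assert l1.comm.records == l2.comm.records
        assert l1.evals == l2.evals

    def test_objective_decreases_from_start(self, instance):
        cfg = _cfg(num_iters=400, eval_every=100)
        _, log = run(cfg, instance.tensor)
        objs = [v for _, v, _ in log.evals]
        assert objs[-1] < objs[0]

    def test_l1_prox_variant_sparsifies(self, instance):
        """FedGTF-EF-prox drives small factor entries exactly to zero."""
        cfg = _cfg(reg_name="l1", reg_weight=0.02, num_iters=400)
        fac, _ = run(cfg, instance.tensor)
        shared = np.concatenate([m.ravel() for m in fac.factors[1:]])
        assert np.mean(shared == 0.0) > 0.05
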