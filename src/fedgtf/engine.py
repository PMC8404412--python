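"""Single-process simulation of federated generalized CP factorization.

``K`` clients hold disjoint horizontal slabs of the data tensor (disjoint
patient rows, shared feature modes).  A server coordinates block-randomized
stochastic updates of the shared factors; the patient factor (mode 1) never
leaves a client.  Two algorithms are provided:

* **FedGTF-EF** — every iteration one factor block is sampled; clients send
  their error-compensated, compressed step ``Δ = Compress(γG + E)``; the
  server broadcasts the average; error memories record ``E ← P − Δ``.
  Patient-mode rounds are plain local steps with no communication.
* **FedGTF-EF-PC** — clients take local steps on their own factor copies and
  only every ``τ``-th iteration compress-and-send the accumulated
  displacement from the server copy, again with error feedback.

The all-block ablation baselines (``dist_sgd_ef``, ``dist_sgd_ef_comp``)
update every block each iteration; the block-randomized ones
(``dist_brascpd``, ``dist_brascpd_comp``) are the identity/sign-compressed
single-block variants.  All variants are reachable purely by configuration.

Bit accounting: block-randomized runs log zero uplink bits on patient-mode
rounds.  All-block runs account the patient block at full per-client size
(dense gradient all-reduce — the baseline the closed-form reduction ratios
presuppose) although, like every variant here, they never serialize
patient-mode values into a message.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .accounting import CommLog
from .compression import CompressedMessage, WORD_BITS, compress, materialize
from .gradients import partial_stochastic_gradient, sample_fibers
from .losses import Regularizer, get_loss, objective, prox
from .tensor import FactorSet, SparseTensor, _strides

__all__ = [
    "RunConfig",
    "ClientState",
    "ServerState",
    "TrainLog",
    "ALGORITHMS",
    "partition_tensor",
    "reassemble",
    "initialize_states",
    "run_fedgtf_ef",
    "run_fedgtf_ef_pc",
    "run",
    "aggregate",
    "sample_block",
]

# algorithm -> (block-randomized?, canonical compressor)
ALGORITHMS = {
    "fedgtf_ef": (True, "sign"),
    "fedgtf_ef_pc": (True, "sign"),
    "dist_brascpd": (True, "identity"),
    "dist_brascpd_comp": (True, "sign"),
    "dist_sgd_ef": (False, "identity"),
    "dist_sgd_ef_comp": (False, "sign"),
}


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run bit-for-bit.

    ``sample_size`` is the per-client fiber budget |S| (clamped to each
    client's local fiber count per mode).  ``step_schedule`` is ``constant``
    (γ[t] = step_size) or ``inv_sqrt_T`` (γ[t] = step_size/√(T+1)).
    ``block_sampling``: ``random`` (uniform over 1..D), ``cyclic``
    (1,2,…,D,1,…), or ``cyclic_shared`` (2,…,D,2,… — shared modes only,
    used for exact communication accounting).
    """

    algorithm: str = "fedgtf_ef"
    loss: str = "least_squares"
    reg_name: str = "none"
    reg_weight: float = 0.0
    num_clients: int = 1
    rank: int = 5
    sample_size: int = 128
    step_size: float = 0.1
    step_schedule: str = "constant"
    num_iters: int = 100
    tau: int = 1
    compressor: str | None = None
    block_sampling: str = "random"
    seed: int = 0
    eval_every: int = 0
    gradient_rescale: bool = True
    trace: bool = False

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.tau > 1 and self.algorithm != "fedgtf_ef_pc":
            raise ValueError("tau > 1 is only meaningful for fedgtf_ef_pc")
        if self.step_schedule not in ("constant", "inv_sqrt_T"):
            raise ValueError(f"unknown step schedule {self.step_schedule!r}")
        if self.block_sampling not in ("random", "cyclic", "cyclic_shared"):
            raise ValueError(f"unknown block sampling {self.block_sampling!r}")
        if self.compressor not in (None, "sign", "identity"):
            raise ValueError(f"unknown compressor {self.compressor!r}")
        if self.num_clients < 1 or self.rank < 1 or self.num_iters < 0:
            raise ValueError("num_clients, rank >= 1 and num_iters >= 0 required")
        reg = self.regularizer  # validates name/weight
        if self.algorithm == "fedgtf_ef_pc" and not reg.smooth:
            raise ValueError(
                "periodic communication supports smooth regularizers only"
            )

    @property
    def regularizer(self) -> Regularizer:
        return Regularizer(self.reg_name, self.reg_weight)

    @property
    def block_randomized(self) -> bool:
        return ALGORITHMS[self.algorithm][0]

    @property
    def effective_compressor(self) -> str:
        return self.compressor or ALGORITHMS[self.algorithm][1]

    def step(self, t: int) -> float:
        if self.step_schedule == "constant":
            return self.step_size
        return self.step_size / math.sqrt(self.num_iters + 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["compressor"] = self.effective_compressor
        return d


@dataclass
class ClientState:
    """One institution: a private tensor slab and private patient rows."""

    client_id: int
    row_ids: np.ndarray                 # global 1-based mode-1 rows held here
    slab: SparseTensor                  # locally reindexed (mode-1 -> 1..I1k)
    mode1_rows: np.ndarray              # I1k x R private patient factor block
    errors: dict[int, np.ndarray]       # per shared mode, zero-initialized
    rng: np.random.Generator
    local_factors: dict[int, np.ndarray] | None = None  # PC variant only


@dataclass
class ServerState:
    """Shared-mode factors (identical on all clients after each sync)."""

    global_factors: dict[int, np.ndarray]
    block_rng: np.random.Generator
    t: int = 0


@dataclass
class TrainLog:
    """Objective trace, sampled-block trace, and the uplink bit log."""

    evals: list = field(default_factory=list)       # (iter, objective, cum_bits)
    blocks: list = field(default_factory=list)      # sampled block per iteration
    comm: CommLog = field(default_factory=CommLog)
    trace: list = field(default_factory=list)       # optional instrumentation

    def loss_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.evals, columns=["iteration", "objective", "cumulative_uplink_bits"]
        )


def partition_tensor(
    tensor: SparseTensor, K: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, SparseTensor]]:
    """Split mode-1 rows into K disjoint slabs after a seeded shuffle.

    Returns ``[(row_ids, slab), ...]`` where ``row_ids`` are the global
    1-based mode-1 rows of each slab (in local order) and each slab is
    reindexed to local mode-1 coordinates ``1..I1k``.  ``K = 1`` is the
    identity partition.
    """
    I1 = tensor.shape[0]
    if not 1 <= K <= I1:
        raise ValueError(f"need 1 <= K <= I1={I1}, got {K}")
    order = np.arange(1, I1 + 1)
    if K > 1:
        order = rng.permutation(order)
    bounds = np.linspace(0, I1, K + 1).astype(int)
    out = []
    for k in range(K):
        rows = order[bounds[k]: bounds[k + 1]]
        local_of = {int(g): i + 1 for i, g in enumerate(rows)}
        mask = np.isin(tensor.coords[:, 0], rows)
        coords = tensor.coords[mask].copy()
        coords[:, 0] = [local_of[int(g)] for g in coords[:, 0]]
        slab = SparseTensor((len(rows),) + tensor.shape[1:], coords,
                            tensor.values[mask])
        out.append((rows, slab))
    return out


def reassemble(clients: Sequence[ClientState], shape: tuple[int, ...]) -> SparseTensor:
    """Invert :func:`partition_tensor`: stitch slabs back into a global tensor."""
    coords, values = [], []
    for c in clients:
        g = c.slab.coords.copy()
        g[:, 0] = c.row_ids[g[:, 0] - 1]
        coords.append(g)
        values.append(c.slab.values)
    return SparseTensor(shape, np.concatenate(coords, axis=0),
                        np.concatenate(values))


def initialize_states(
    config: RunConfig, tensor: SparseTensor
) -> tuple[list[ClientState], ServerState]:
    """Seed-derived, reproducible client/server initialization.

    Factor entries are i.i.d. uniform(0,1)/√R, drawn once globally so the
    shared modes start identical everywhere and the patient rows a client
    receives do not depend on K.
    """
    D = tensor.order
    if D < 2:
        raise ValueError("need an order >= 2 tensor")
    K = config.num_clients
    ss = np.random.SeedSequence(config.seed)
    block_ss, init_ss, part_ss, *client_ss = ss.spawn(3 + K)

    init_rng = np.random.default_rng(init_ss)
    factors = [
        init_rng.uniform(size=(I_d, config.rank)) / math.sqrt(config.rank)
        for I_d in tensor.shape
    ]
    parts = partition_tensor(tensor, K, np.random.default_rng(part_ss))

    clients = []
    for k, (rows, slab) in enumerate(parts):
        local = None
        if config.algorithm == "fedgtf_ef_pc":
            local = {d: factors[d - 1].copy() for d in range(2, D + 1)}
        clients.append(
            ClientState(
                client_id=k,
                row_ids=rows,
                slab=slab,
                mode1_rows=factors[0][rows - 1].copy(),
                errors={d: np.zeros_like(factors[d - 1]) for d in range(2, D + 1)},
                rng=np.random.default_rng(client_ss[k]),
                local_factors=local,
            )
        )
    server = ServerState(
        global_factors={d: factors[d - 1].copy() for d in range(2, D + 1)},
        block_rng=np.random.default_rng(block_ss),
    )
    return clients, server


def sample_block(server: ServerState, D: int, scheme: str = "random",
                 t: int | None = None) -> int:
    """Next block index, shared by all clients (server-generated).

    ``random``: uniform over 1..D.  ``cyclic``: 1,2,…,D,1,….
    ``cyclic_shared``: 2,…,D,2,… (patient mode never sampled).
    """
    if scheme == "random":
        return int(server.block_rng.integers(1, D + 1))
    step = server.t if t is None else t
    if scheme == "cyclic":
        return step % D + 1
    if scheme == "cyclic_shared":
        return 2 + step % (D - 1)
    raise ValueError(f"unknown block sampling scheme {scheme!r}")


def aggregate(messages: Sequence[CompressedMessage]) -> np.ndarray:
    """Server reduction: element-wise mean of the materialized messages."""
    if not messages:
        raise ValueError("nothing to aggregate")
    shapes = {m.shape for m in messages}
    if len(shapes) != 1:
        raise ValueError(f"message shape mismatch: {shapes}")
    out = materialize(messages[0])
    for m in messages[1:]:
        out += materialize(m)
    out /= len(messages)
    return out


def _send(block: int, P: np.ndarray, kind: str) -> CompressedMessage:
    """The single serialization path.  Patient-mode data must never pass."""
    if block == 1:
        raise RuntimeError("refusing to serialize patient-mode (mode-1) data")
    return compress(kind, P)


def _client_factorset(client: ClientState, server: ServerState,
                      use_local: bool) -> FactorSet:
    D = len(server.global_factors) + 1
    src = client.local_factors if use_local else server.global_factors
    return FactorSet((client.mode1_rows, *(src[d] for d in range(2, D + 1))))


def _local_mode1_step(client: ClientState, server: ServerState,
                      config: RunConfig, gamma: float, loss, reg: Regularizer,
                      use_local: bool) -> None:
    fac = _client_factorset(client, server, use_local)
    _, ncols = _strides(client.slab.shape, 1)
    s = sample_fibers(1, client.slab.shape, min(config.sample_size, ncols),
                      client.rng)
    G = partial_stochastic_gradient(client.slab, fac, s, loss,
                                    reg if reg.smooth else None,
                                    rescale=config.gradient_rescale)
    B = client.mode1_rows - gamma * G
    client.mode1_rows = prox(reg, B, gamma) if not reg.smooth else B


def _shared_gradient(client: ClientState, server: ServerState,
                     config: RunConfig, d: int, loss, reg: Regularizer,
                     use_local: bool) -> np.ndarray:
    fac = _client_factorset(client, server, use_local)
    _, ncols = _strides(client.slab.shape, d)
    s = sample_fibers(d, client.slab.shape, min(config.sample_size, ncols),
                      client.rng)
    return partial_stochastic_gradient(client.slab, fac, s, loss,
                                       reg if reg.smooth else None,
                                       rescale=config.gradient_rescale)


def _check_finite(name: str, t: int, mat: np.ndarray) -> None:
    if not np.all(np.isfinite(mat)):
        raise RuntimeError(
            f"diverged: non-finite values in {name} at iteration {t}; "
            "reduce the step size"
        )


def _assembled_factors(clients: Sequence[ClientState], server: ServerState,
                       I1: int) -> FactorSet:
    R = clients[0].mode1_rows.shape[1]
    A1 = np.zeros((I1, R))
    for c in clients:
        A1[c.row_ids - 1] = c.mode1_rows
    D = len(server.global_factors) + 1
    return FactorSet((A1, *(server.global_factors[d].copy()
                            for d in range(2, D + 1))))


def _maybe_eval(t: int, config: RunConfig, clients, server, full_tensor,
                loss, reg: Regularizer, log: TrainLog, *, force=False) -> None:
    due = force or (config.eval_every and (t + 1) % config.eval_every == 0)
    if not due:
        return
    if force and log.evals and log.evals[-1][0] == t:
        return  # final iteration already evaluated on cadence
    fac = _assembled_factors(clients, server, full_tensor.shape[0])
    regs = [reg] * full_tensor.order
    val = objective(full_tensor, fac, loss, regs)
    log.evals.append((t, val, log.comm.total_bits(include_scale=True)))


def run_fedgtf_ef(config: RunConfig, clients: list[ClientState],
                  server: ServerState) -> tuple[FactorSet, TrainLog]:
    """Per-round compressed communication with error feedback.

    Also executes the four non-periodic ablation variants: the all-block
    baselines update every block per iteration (gradients evaluated jointly
    at the iteration's starting point), the block-randomized ones exactly one.
    """
    if config.algorithm == "fedgtf_ef_pc":
        raise ValueError("use run_fedgtf_ef_pc for the periodic variant")
    loss = get_loss(config.loss)
    reg = config.regularizer
    kind = config.effective_compressor
    D = len(server.global_factors) + 1
    full = reassemble(clients, (sum(len(c.row_ids) for c in clients),)
                      + clients[0].slab.shape[1:])
    log = TrainLog()
    log.comm.blocks_per_round = D if not config.block_randomized else 1
    log.comm.rounds = config.num_iters

    for t in range(config.num_iters):
        gamma = config.step(t)
        if config.block_randomized:
            blocks = [sample_block(server, D, config.block_sampling, t)]
        else:
            blocks = list(range(1, D + 1))
        log.blocks.append(blocks[0] if len(blocks) == 1 else 0)

        # Jacobi within an iteration: all gradients at the starting iterate.
        grads = {d: [_shared_gradient(c, server, config, d, loss, reg, False)
                     for c in clients]
                 for d in blocks if d != 1}

        for d in blocks:
            if d == 1:
                for c in clients:
                    _local_mode1_step(c, server, config, gamma, loss, reg, False)
                    bits = _mode1_accounting_bits(config, kind, full.shape[0],
                                                  c.mode1_rows.shape[1])
                    log.comm.add(t, c.client_id, 1, *bits)
                _check_finite("mode-1 factor", t, clients[0].mode1_rows)
                continue
            msgs, Ps = [], []
            for c, G in zip(clients, grads[d]):
                P = gamma * G + c.errors[d]
                msg = _send(d, P, kind)
                msgs.append(msg)
                Ps.append(P)
                log.comm.add(t, c.client_id, d, msg.payload_bits, msg.scale_bits)
            mean_delta = aggregate(msgs)
            B = server.global_factors[d] - mean_delta
            server.global_factors[d] = B if reg.smooth else prox(reg, B, gamma)
            _check_finite(f"mode-{d} factor", t, server.global_factors[d])
            for c, msg, P in zip(clients, msgs, Ps):
                c.errors[d] = P - materialize(msg)
            if config.trace:
                mean_grad = sum(grads[d]) / len(clients)
                mean_err = sum(c.errors[d] for c in clients) / len(clients)
                log.trace.append({
                    "t": t, "d": d, "gamma": gamma, "mean_grad": mean_grad,
                    "virtual": server.global_factors[d] - mean_err,
                })
        server.t = t + 1
        _maybe_eval(t, config, clients, server, full, loss, reg, log)

    _maybe_eval(config.num_iters - 1, config, clients, server, full, loss, reg,
                log, force=True)
    return _assembled_factors(clients, server, full.shape[0]), log


def run_fedgtf_ef_pc(config: RunConfig, clients: list[ClientState],
                     server: ServerState) -> tuple[FactorSet, TrainLog]:
    """Periodic communication: τ local steps per compressed synchronization.

    Clients step their own copies of the sampled shared block; at
    communication rounds (``t mod τ == 0``) they compress the accumulated
    displacement from the server copy (plus error memory), the server applies
    the average and broadcasts, and clients adopt the server copy.
    """
    loss = get_loss(config.loss)
    reg = config.regularizer
    kind = config.effective_compressor
    D = len(server.global_factors) + 1
    for c in clients:
        if c.local_factors is None:
            c.local_factors = {d: server.global_factors[d].copy()
                               for d in range(2, D + 1)}
    full = reassemble(clients, (sum(len(c.row_ids) for c in clients),)
                      + clients[0].slab.shape[1:])
    log = TrainLog()
    log.comm.rounds = config.num_iters

    for t in range(config.num_iters):
        gamma = config.step(t)
        d = sample_block(server, D, config.block_sampling, t)
        log.blocks.append(d)
        if d == 1:
            for c in clients:
                _local_mode1_step(c, server, config, gamma, loss, reg, True)
                log.comm.add(t, c.client_id, 1, 0, 0)
            _check_finite("mode-1 factor", t, clients[0].mode1_rows)
        else:
            halves = []
            for c in clients:
                G = _shared_gradient(c, server, config, d, loss, reg, True)
                halves.append(c.local_factors[d] - gamma * G)
            if t % config.tau != 0:
                for c, half in zip(clients, halves):
                    c.local_factors[d] = half
                    log.comm.add(t, c.client_id, d, 0, 0)
            else:
                msgs, Ps = [], []
                for c, half in zip(clients, halves):
                    P = (server.global_factors[d] - half) + c.errors[d]
                    msg = _send(d, P, kind)
                    msgs.append(msg)
                    Ps.append(P)
                    log.comm.add(t, c.client_id, d, msg.payload_bits,
                                 msg.scale_bits)
                server.global_factors[d] = (server.global_factors[d]
                                            - aggregate(msgs))
                for c, msg, P in zip(clients, msgs, Ps):
                    c.local_factors[d] = server.global_factors[d].copy()
                    c.errors[d] = P - materialize(msg)
            _check_finite(f"mode-{d} factor", t,
                          clients[0].local_factors[d])
        server.t = t + 1
        _maybe_eval(t, config, clients, server, full, loss, reg, log)

    _maybe_eval(config.num_iters - 1, config, clients, server, full, loss, reg,
                log, force=True)
    return _assembled_factors(clients, server, full.shape[0]), log


def _mode1_accounting_bits(config: RunConfig, kind: str, I1: int,
                           R: int) -> tuple[int, int]:
    """Uplink bits charged for the patient block.

    Block-randomized variants keep patient rounds communication-free (0
    bits).  All-block baselines are charged a full-size per-client gradient
    (dense all-reduce convention) at the compressor's element width — no
    patient values are actually serialized.
    """
    if config.block_randomized:
        return 0, 0
    n = I1 * R
    if kind == "sign":
        return n, WORD_BITS
    return n * WORD_BITS, 0


def run(config: RunConfig, tensor: SparseTensor):
    """Initialize states from ``config.seed`` and execute the configured variant."""
    clients, server = initialize_states(config, tensor)
    if config.algorithm == "fedgtf_ef_pc":
        return run_fedgtf_ef_pc(config, clients, server)
    return run_fedgtf_ef(config, clients, server)
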