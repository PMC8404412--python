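"""δ-approximate gradient compressors and their exact bit-cost model.

The sign compressor maps a matrix ``P`` with ``n`` entries to
``(‖vec(P)‖₁ / n) · sign(P)`` — one sign bit per element plus a single
32-bit scale scalar.  It is a δ-approximate compressor,
``‖C(x) − x‖² ≤ (1 − δ)‖x‖²`` with δ = ‖x‖₁² / (n‖x‖₂²) ∈ [1/n, 1], and the
inequality is tight for this compressor.  The identity compressor is the
lossless full-precision baseline at 32 bits per element.

Bit accounting is deliberately decoupled from arithmetic precision: messages
carry float64 values internally, but costs are modeled at the 32-bit word
size the reduction ratios presuppose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CompressedMessage", "compress", "materialize", "delta_of", "WORD_BITS"]

WORD_BITS = 32  # full-precision word size used by the bit model


@dataclass(frozen=True)
class CompressedMessage:
    """A compressed uplink payload: sign pattern + one scale, or raw data.

    ``payload_bits`` counts per-element content (1 bit/element for sign,
    ``WORD_BITS`` per element for identity); ``scale_bits`` counts the side
    scalar (32 for sign, 0 for identity).
    """

    kind: str
    shape: tuple[int, ...]
    signs: np.ndarray | None = None
    scale: float | None = None
    data: np.ndarray | None = None

    @property
    def n_elements(self) -> int:
        return int(np.prod(self.shape))

    @property
    def payload_bits(self) -> int:
        return self.n_elements * (1 if self.kind == "sign" else WORD_BITS)

    @property
    def scale_bits(self) -> int:
        return WORD_BITS if self.kind == "sign" else 0

    @property
    def bits(self) -> int:
        return self.payload_bits + self.scale_bits


def compress(kind: str, P: np.ndarray) -> CompressedMessage:
    """Compress matrix ``P``; ``kind`` is ``"sign"`` or ``"identity"``."""
    P = np.asarray(P, dtype=np.float64)
    if not np.all(np.isfinite(P)):
        raise ValueError("cannot compress non-finite values")
    if kind == "identity":
        return CompressedMessage("identity", P.shape, data=P.copy())
    if kind == "sign":
        n = P.size
        scale = float(np.abs(P).sum() / n) if n else 0.0
        # sign(0) = 0; the element still occupies one payload bit.
        return CompressedMessage("sign", P.shape,
                                 signs=np.sign(P).astype(np.int8), scale=scale)
    raise ValueError(f"unknown compressor kind {kind!r}")


def materialize(msg: CompressedMessage) -> np.ndarray:
    """Reconstruct the matrix a receiver would use: scale·signs, or the data."""
    if msg.kind == "identity":
        if msg.data is None or msg.data.shape != msg.shape:
            raise ValueError("corrupt identity message")
        return msg.data.copy()
    if msg.kind == "sign":
        if msg.signs is None or msg.signs.shape != msg.shape:
            raise ValueError("corrupt sign message")
        return msg.scale * msg.signs.astype(np.float64)
    raise ValueError(f"unknown compressor kind {msg.kind!r}")


def delta_of(msg: CompressedMessage, P: np.ndarray) -> float:
    """Contraction factor δ = 1 − ‖C(P) − P‖² / ‖P‖² (1 for a zero input).

    For the sign compressor this equals ‖P‖₁² / (n‖P‖₂²) and is bounded below
    by 1/n (Cauchy-Schwarz).
    """
    P = np.asarray(P, dtype=np.float64)
    denom = float(np.sum(np.square(P)))
    if denom == 0.0:
        return 1.0
    err = float(np.sum(np.square(materialize(msg) - P)))
    return 1.0 - err / denom
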