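"""Bridged pair of restricted Boltzmann machines for one gene pair.

Two single-layer RBMs — one per gene — are trained jointly on the two
genes' normalized expression vectors.  Each machine has n visible and n
hidden units, where n is the number of samples, and both weight matrices
start from one shared uniform[-1/n, 1/n] draw.  During the first epoch
each machine reconstructs its own gene from its own hidden activations;
from the second epoch onward the machines are cross-wired (the "bridge"):
each reconstructs its gene from the *partner's* forward hidden
activations.  A contrastive-divergence-style update moves each weight
matrix by the difference between the data association (gene x forward
hidden activation) and the reconstruction association.

The interaction strength of the pair is read off the final epoch: hidden
units whose activation exceeds a shared per-unit random threshold in BOTH
machines are "matched", and each gene's strength is the mean of its
activation probabilities over the matched units.  Training stops when both
reconstruction errors fall to ``error_tol``, when the two strengths drift
apart by more than ``weight_diff_break``, or at ``max_epochs``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.special import expit as sigmoid

__all__ = [
    "RBMPairConfig",
    "RBMPairState",
    "PairResult",
    "EpochTrace",
    "rbm_energy",
    "pair_seed_sequence",
    "init_pair",
    "forward_pass",
    "backward_pass",
    "associations",
    "reconstruction_error",
    "update_weights",
    "matched_strengths",
    "train_pair",
]


@dataclass(frozen=True)
class RBMPairConfig:
    """Hyperparameters of one bridged RBM pair.

    learning_rate : step size of the association update.
    max_epochs : hard cap on training epochs.
    error_tol : sum-of-squares reconstruction error at which a pair counts
        as converged (both genes must reach it).
    weight_diff_break : training stops early once the two strength values
        differ by more than this (the pair is then effectively rejected by
        any acceptance threshold below the gap).
    backward_uses_transpose : reconstruct visibles through w.T (standard
        RBM contract); ``False`` uses the literal same-orientation product.
    """

    learning_rate: float = 0.1
    max_epochs: int = 1000
    error_tol: float = 0.01
    weight_diff_break: float = 0.01
    seed: int = 0
    backward_uses_transpose: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.error_tol <= 0:
            raise ValueError("error_tol must be > 0")
        if self.weight_diff_break <= 0:
            raise ValueError("weight_diff_break must be > 0")


@dataclass
class RBMPairState:
    """Evolving weights, biases and activations of one RBM pair."""

    w1: np.ndarray
    w2: np.ndarray
    bias: np.ndarray
    epoch: int = 0
    fH1: np.ndarray | None = None
    fH2: np.ndarray | None = None
    fH1_act: np.ndarray | None = None
    fH2_act: np.ndarray | None = None
    fH1_state: np.ndarray | None = None
    fH2_state: np.ndarray | None = None
    bV1_act: np.ndarray | None = None
    bV2_act: np.ndarray | None = None
    bH1_act: np.ndarray | None = None
    bH2_act: np.ndarray | None = None


@dataclass(frozen=True)
class PairResult:
    """Outcome of training one gene pair.

    ``strength_a``/``strength_b`` are NaN when no hidden unit was active in
    both machines at the final epoch (``matched_units == 0``).
    ``converged`` records whether both reconstruction errors reached
    ``error_tol``; non-converged pairs are excluded downstream.
    """

    gene_a: str
    gene_b: str
    strength_a: float
    strength_b: float
    error_a: float
    error_b: float
    epochs_run: int
    converged: bool
    matched_units: int

    @property
    def strengths_defined(self) -> bool:
        return self.matched_units > 0

    @property
    def strength_gap(self) -> float:
        return abs(self.strength_a - self.strength_b)


class EpochTrace(NamedTuple):
    """Per-epoch record sufficient to replay training step by step."""

    thresholds: np.ndarray
    w1_before: np.ndarray
    w2_before: np.ndarray


def rbm_energy(
    v: np.ndarray,
    h: np.ndarray,
    w: np.ndarray,
    b_vis: np.ndarray,
    c_hid: np.ndarray,
) -> float:
    """Energy -v.w.h - b.v - c.h of one joint (visible, hidden) state.

    ``w`` is oriented visible x hidden, matching the propagation
    operations.  Diagnostic only — training never evaluates the energy.
    """
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    w = np.asarray(w, dtype=float)
    b_vis = np.asarray(b_vis, dtype=float)
    c_hid = np.asarray(c_hid, dtype=float)
    if w.shape != (v.size, h.size) or b_vis.size != v.size or c_hid.size != h.size:
        raise ValueError(
            f"dimension mismatch: v{v.shape}, h{h.shape}, w{w.shape}, "
            f"b{b_vis.shape}, c{c_hid.shape}"
        )
    return float(-(v @ w @ h) - b_vis @ v - c_hid @ h)


def _stable_id_hash(gene_id: str) -> int:
    digest = hashlib.sha256(gene_id.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def pair_seed_sequence(seed: int, gene_a: str, gene_b: str) -> np.random.SeedSequence:
    """Seed stream for one gene pair, independent of argument order.

    Derived from the global seed and content hashes of the two gene ids
    (sorted), so whole-matrix runs reproduce pair by pair regardless of
    iteration order, and swapping the genes reuses the same stream.
    """
    lo, hi = sorted([gene_a, gene_b])
    return np.random.SeedSequence([int(seed), _stable_id_hash(lo), _stable_id_hash(hi)])


def init_pair(
    n_units: int, seed: int | np.random.SeedSequence | np.random.Generator
) -> RBMPairState:
    """Initialize both weight matrices from one uniform[-1/n, 1/n] draw.

    The two matrices start *equal* (a single n x n draw copied), which
    forces exactly symmetric trajectories — hence exactly equal strengths —
    when the two gene vectors are identical.  Biases start at zero and are
    never updated.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bound = 1.0 / n_units
    w1 = rng.uniform(-bound, bound, size=(n_units, n_units))
    return RBMPairState(w1=w1, w2=w1.copy(), bias=np.zeros(n_units))


def forward_pass(
    g: np.ndarray, w: np.ndarray, bias: np.ndarray, thresholds: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Visible -> hidden propagation with stochastic-threshold activation.

    Returns ``(pre_act, act, state)`` where ``pre_act = bias + g.w``,
    ``act = sigmoid(pre_act)`` and ``state[i] = act[i] > thresholds[i]``.
    The threshold vector is drawn by the caller once per epoch and shared
    by both machines of a pair.
    """
    g = np.asarray(g, dtype=float)
    w = np.asarray(w, dtype=float)
    bias = np.asarray(bias, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    n = g.size
    if w.shape != (n, n) or bias.size != n or thresholds.size != n:
        raise ValueError(
            f"dimension mismatch: g has {n} units, w{w.shape}, "
            f"bias {bias.size}, thresholds {thresholds.size}"
        )
    pre_act = bias + g @ w
    act = sigmoid(pre_act)
    state = act > thresholds
    return pre_act, act, state


def backward_pass(
    h_source: np.ndarray,
    w: np.ndarray,
    bias: np.ndarray,
    use_transpose: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Hidden -> visible reconstruction, then visible -> hidden re-activation.

    ``h_source`` is the machine's own forward hidden activation at epoch 1
    and the partner's from epoch 2 onward (the bridge).  With
    ``use_transpose`` the reconstruction multiplies by ``w.T`` (standard
    RBM weight sharing); without it, by ``w`` itself.
    """
    h_source = np.asarray(h_source, dtype=float)
    w = np.asarray(w, dtype=float)
    bias = np.asarray(bias, dtype=float)
    n = h_source.size
    if w.shape != (n, n) or bias.size != n:
        raise ValueError(
            f"dimension mismatch: h has {n} units, w{w.shape}, bias {bias.size}"
        )
    recon_act = sigmoid(bias + h_source @ (w.T if use_transpose else w))
    hidden_act = sigmoid(bias + recon_act @ w)
    return recon_act, hidden_act


def associations(v: np.ndarray, h_act: np.ndarray) -> np.ndarray:
    """Outer product association matrix: result[j, i] = v[j] * h_act[i]."""
    v = np.asarray(v, dtype=float)
    h_act = np.asarray(h_act, dtype=float)
    if v.size != h_act.size:
        raise ValueError(f"length mismatch: {v.size} vs {h_act.size}")
    return np.outer(v, h_act)


def reconstruction_error(original: np.ndarray, reconstructed: np.ndarray) -> float:
    """Sum of squared differences between a gene vector and its reconstruction."""
    original = np.asarray(original, dtype=float)
    reconstructed = np.asarray(reconstructed, dtype=float)
    if original.size != reconstructed.size:
        raise ValueError(f"length mismatch: {original.size} vs {reconstructed.size}")
    return float(np.sum((original - reconstructed) ** 2))


def update_weights(
    w: np.ndarray,
    f_assoc: np.ndarray,
    b_assoc: np.ndarray,
    learning_rate: float,
    n_units: int,
) -> np.ndarray:
    """One association-difference step: w + lr * (f_assoc - b_assoc) / n."""
    w = np.asarray(w, dtype=float)
    f_assoc = np.asarray(f_assoc, dtype=float)
    b_assoc = np.asarray(b_assoc, dtype=float)
    if not (w.shape == f_assoc.shape == b_assoc.shape):
        raise ValueError(
            f"shape mismatch: w{w.shape}, f{f_assoc.shape}, b{b_assoc.shape}"
        )
    return w + learning_rate * (f_assoc - b_assoc) / n_units


def matched_strengths(
    act_a: np.ndarray,
    act_b: np.ndarray,
    state_a: np.ndarray,
    state_b: np.ndarray,
) -> tuple[float, float, int]:
    """Mean activation of each gene over hidden units active in BOTH machines.

    Returns ``(strength_a, strength_b, matched_units)``; strengths are NaN
    when no unit is active in both.
    """
    act_a = np.asarray(act_a, dtype=float)
    act_b = np.asarray(act_b, dtype=float)
    state_a = np.asarray(state_a, dtype=bool)
    state_b = np.asarray(state_b, dtype=bool)
    if not (act_a.size == act_b.size == state_a.size == state_b.size):
        raise ValueError("all four vectors must have equal length")
    matched = state_a & state_b
    count = int(matched.sum())
    if count == 0:
        return float("nan"), float("nan"), 0
    return float(act_a[matched].mean()), float(act_b[matched].mean()), count


def train_pair(
    g_a: np.ndarray,
    g_b: np.ndarray,
    config: RBMPairConfig | None = None,
    gene_a: str = "gene_a",
    gene_b: str = "gene_b",
    rng: np.random.Generator | None = None,
    return_trace: bool = False,
) -> PairResult | tuple[PairResult, list[EpochTrace]]:
    """Train one bridged RBM pair on two normalized gene vectors.

    Per epoch: one shared threshold vector is drawn; both machines run a
    forward pass; each reconstructs through its own hidden activation
    (epoch 1) or the partner's previous-epoch activation (epoch >= 2);
    forward and backward associations and squared errors are computed; both
    weight matrices take one association-difference step.  Stops on
    convergence (both errors <= ``error_tol``), on strength divergence
    (> ``weight_diff_break``), or at ``max_epochs``.  Strengths come from
    the final epoch's matched hidden units.

    ``rng`` overrides the default per-pair stream derived from
    ``(config.seed, gene_a, gene_b)``.  With ``return_trace`` the per-epoch
    thresholds and pre-update weights are also returned, enabling exact
    replay through the step operations.
    """
    config = config or RBMPairConfig()
    g_a = np.asarray(g_a, dtype=float)
    g_b = np.asarray(g_b, dtype=float)
    if g_a.size != g_b.size:
        raise ValueError(f"gene vectors differ in length: {g_a.size} vs {g_b.size}")
    n = g_a.size
    if n < 2:
        raise ValueError("gene vectors need at least 2 samples")
    for name, g in ((gene_a, g_a), (gene_b, g_b)):
        if g.min() < 0 or g.max() > 1:
            raise ValueError(
                f"{name}: values outside [0, 1]; apply maxmin normalization first"
            )
    if rng is None:
        rng = np.random.default_rng(pair_seed_sequence(config.seed, gene_a, gene_b))

    state = init_pair(n, rng)
    trace: list[EpochTrace] = []
    prev_act_a: np.ndarray | None = None
    prev_act_b: np.ndarray | None = None
    strength_a = strength_b = float("nan")
    matched = 0
    err_a = err_b = float("inf")
    converged = False
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        thresholds = rng.uniform(0.0, 1.0, size=n)
        if return_trace:
            trace.append(EpochTrace(thresholds.copy(), state.w1.copy(), state.w2.copy()))
        state.fH1, state.fH1_act, state.fH1_state = forward_pass(
            g_a, state.w1, state.bias, thresholds
        )
        state.fH2, state.fH2_act, state.fH2_state = forward_pass(
            g_b, state.w2, state.bias, thresholds
        )
        h_src_a = state.fH1_act if epoch == 1 else prev_act_b
        h_src_b = state.fH2_act if epoch == 1 else prev_act_a
        state.bV1_act, state.bH1_act = backward_pass(
            h_src_a, state.w1, state.bias, config.backward_uses_transpose
        )
        state.bV2_act, state.bH2_act = backward_pass(
            h_src_b, state.w2, state.bias, config.backward_uses_transpose
        )
        err_a = reconstruction_error(g_a, state.bV1_act)
        err_b = reconstruction_error(g_b, state.bV2_act)
        state.w1 = update_weights(
            state.w1,
            associations(g_a, state.fH1_act),
            associations(state.bV1_act, state.bH1_act),
            config.learning_rate,
            n,
        )
        state.w2 = update_weights(
            state.w2,
            associations(g_b, state.fH2_act),
            associations(state.bV2_act, state.bH2_act),
            config.learning_rate,
            n,
        )
        strength_a, strength_b, matched = matched_strengths(
            state.fH1_act, state.fH2_act, state.fH1_state, state.fH2_state
        )
        prev_act_a, prev_act_b = state.fH1_act, state.fH2_act
        state.epoch = epoch
        if err_a <= config.error_tol and err_b <= config.error_tol:
            converged = True
            break
        if matched > 0 and abs(strength_a - strength_b) > config.weight_diff_break:
            break

    result = PairResult(
        gene_a=gene_a,
        gene_b=gene_b,
        strength_a=strength_a,
        strength_b=strength_b,
        error_a=err_a,
        error_b=err_b,
        epochs_run=epoch,
        converged=converged,
        matched_units=matched,
    )
    return (result, trace) if return_trace else result
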