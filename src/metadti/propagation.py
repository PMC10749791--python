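"""Typed GCN message passing along a meta-graph.

Each state update sums the contributions of all earlier states and applies
an exact-Gaussian GELU:

    H^t = gelu( sum_{i < t} g_{t,i}(H^i, mode_{t,i}) )

where the per-slot contribution is

    g = A_hat  H^i  W_{t,i}     for a real relation (A_hat the
                                 degree-normalized adjacency),
    g = H^i                      for IDENTITY,
    g = 0                        for NULL.

The module also implements the reverse-mode passes used by the trainer:
:func:`backward` differentiates a discrete (sampled) plan with respect to
the weight matrices, while :func:`mixture_forward` /
:func:`mixture_backward_alpha` run the theta-weighted supernet -- every
slot mixing all of its candidates -- and return dense gradients for the
architecture significances.  All gradients are accumulated analytically;
there is no autodiff framework underneath.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import ndtr  # standard normal CDF, exact GELU

from .hetnet import NormalizedRelation
from .metagraph import IDENTITY, NULL, MetaGraph, all_slots

__all__ = [
    "PropagationWeights",
    "StateSequence",
    "gelu",
    "propagate_relation",
    "aggregate_state",
    "run_metagraph",
    "forward_cached",
    "backward",
    "mixture_forward",
    "mixture_backward_alpha",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


def gelu(x: np.ndarray) -> np.ndarray:
    """GELU in its exact form ``x * Phi(x)`` (no tanh approximation)."""
    return x * ndtr(x)


def gelu_grad(x: np.ndarray) -> np.ndarray:
    """d/dx [x * Phi(x)] = Phi(x) + x * phi(x)."""
    return ndtr(x) + x * np.exp(-0.5 * x * x) / _SQRT2PI


@dataclass
class PropagationWeights:
    """One d x d GCN weight matrix per real-relation slot of a meta-graph."""

    W: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    @classmethod
    def initialize(
        cls, mg: MetaGraph, d: int, rng: np.random.Generator
    ) -> "PropagationWeights":
        """Glorot-uniform initialization for every selected real relation."""
        limit = np.sqrt(6.0 / (d + d))
        return cls(
            W={
                slot: rng.uniform(-limit, limit, size=(d, d))
                for slot in mg.real_slots()
            }
        )

    @classmethod
    def initialize_full(
        cls, T: int, d: int, rng: np.random.Generator
    ) -> "PropagationWeights":
        """One weight matrix per slot regardless of selection (search phase).

        During search the selected mode changes from step to step, so every
        slot keeps its own persistent matrix.
        """
        limit = np.sqrt(6.0 / (d + d))
        return cls(
            W={
                slot: rng.uniform(-limit, limit, size=(d, d))
                for slot in all_slots(T)
            }
        )


@dataclass
class StateSequence:
    """Propagation states ``H^0 .. H^T`` over all network nodes."""

    states: list[np.ndarray]

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]


def propagate_relation(
    H_i: np.ndarray,
    mode: str,
    normalized: NormalizedRelation | None = None,
    W: np.ndarray | None = None,
) -> np.ndarray:
    """Single-slot contribution g(H^i, mode); see module docstring."""
    if mode == IDENTITY:
        if normalized is not None or W is not None:
            raise ValueError("IDENTITY takes no adjacency and no weight")
        return H_i
    if mode == NULL:
        if normalized is not None or W is not None:
            raise ValueError("NULL takes no adjacency and no weight")
        return np.zeros_like(H_i)
    if normalized is None or W is None:
        raise ValueError(f"relation {mode!r} requires adjacency and weight")
    if W.shape[0] != H_i.shape[1]:
        raise ValueError(
            f"dimension mismatch: H has d={H_i.shape[1]}, W is {W.shape}"
        )
    return normalized.normalized @ H_i @ W


def aggregate_state(contributions: list[np.ndarray]) -> np.ndarray:
    """GELU of the elementwise sum of slot contributions."""
    if not contributions:
        raise ValueError("at least one contribution required")
    total = contributions[0].copy()
    for c in contributions[1:]:
        if c.shape != total.shape:
            raise ValueError("contribution shapes differ")
        total += c
    return gelu(total)


def run_metagraph(
    H0: np.ndarray,
    mg: MetaGraph,
    weights: PropagationWeights,
    relations: Mapping[str, NormalizedRelation],
) -> StateSequence:
    """Execute a meta-graph's full propagation plan (inference path)."""
    seq, _ = forward_cached(H0, mg.selected, weights, relations, theta_mult=None)
    return seq


def forward_cached(
    H0: np.ndarray,
    selections: Mapping[tuple[int, int], str],
    weights: PropagationWeights,
    relations: Mapping[str, NormalizedRelation],
    theta_mult: Mapping[tuple[int, int], float] | None = None,
) -> tuple[StateSequence, dict]:
    """Forward pass storing the intermediates needed for the backward pass.

    ``theta_mult`` scales each slot's contribution (search phase); ``None``
    means a multiplier of 1 everywhere (final training / inference).
    """
    T = max(t for (_, t) in selections)
    states: list[np.ndarray] = [np.asarray(H0, dtype=float)]
    pre: dict[int, np.ndarray] = {}
    prod: dict[tuple[int, int], np.ndarray] = {}  # A_hat @ H^i per real slot
    contrib: dict[tuple[int, int], np.ndarray] = {}  # unscaled g per slot
    for t in range(1, T + 1):
        total = np.zeros_like(states[0])
        for i in range(t):
            slot = (i, t)
            mode = selections[slot]
            mult = 1.0 if theta_mult is None else float(theta_mult.get(slot, 1.0))
            if mode == NULL:
                continue
            if mode == IDENTITY:
                g = states[i]
            else:
                if slot not in weights.W:
                    raise ValueError(f"missing weight matrix for slot {slot}")
                if mode not in relations:
                    raise ValueError(f"unknown relation {mode!r}")
                ah = relations[mode].normalized @ states[i]
                prod[slot] = ah
                g = ah @ weights.W[slot]
            contrib[slot] = g
            total = total + mult * g
        pre[t] = total
        H_t = gelu(total)
        if not np.all(np.isfinite(H_t)):
            raise FloatingPointError(f"non-finite state at t={t}")
        states.append(H_t)
    cache = {
        "selections": dict(selections),
        "theta_mult": None if theta_mult is None else dict(theta_mult),
        "pre": pre,
        "prod": prod,
        "contrib": contrib,
        "states": states,
        "T": T,
    }
    return StateSequence(states=states), cache


def backward(
    grad_HT: np.ndarray,
    cache: dict,
    weights: PropagationWeights,
    relations: Mapping[str, NormalizedRelation],
) -> tuple[dict[tuple[int, int], np.ndarray], dict[tuple[int, int], float]]:
    """Reverse-mode pass through a cached forward execution.

    Returns gradients of the loss w.r.t. every real-relation weight matrix
    and w.r.t. every slot's theta multiplier (zero for NULL slots, which
    contribute nothing).
    """
    T = cache["T"]
    selections = cache["selections"]
    theta_mult = cache["theta_mult"]
    states = cache["states"]
    grad_states: dict[int, np.ndarray] = {T: np.asarray(grad_HT, dtype=float)}
    grad_W: dict[tuple[int, int], np.ndarray] = {}
    grad_theta: dict[tuple[int, int], float] = {}
    for t in range(T, 0, -1):
        g_state = grad_states.pop(t, None)
        if g_state is None:
            continue
        dS = g_state * gelu_grad(cache["pre"][t])
        for i in range(t):
            slot = (i, t)
            mode = selections[slot]
            if mode == NULL:
                grad_theta[slot] = 0.0
                continue
            mult = 1.0 if theta_mult is None else float(theta_mult.get(slot, 1.0))
            g_unscaled = cache["contrib"][slot]
            grad_theta[slot] = float(np.sum(dS * g_unscaled))
            dG = mult * dS  # gradient w.r.t. the unscaled contribution
            if mode == IDENTITY:
                dH_i = dG
            else:
                ah = cache["prod"][slot]
                grad_W[slot] = grad_W.get(slot, 0.0) + ah.T @ dG
                dH_i = relations[mode].normalized.T @ (dG @ weights.W[slot].T)
            if i > 0:
                if i in grad_states:
                    grad_states[i] = grad_states[i] + dH_i
                else:
                    grad_states[i] = dH_i
    return grad_W, grad_theta


def mixture_forward(
    H0: np.ndarray,
    sig,
    weights: PropagationWeights,
    relations: Mapping[str, NormalizedRelation],
) -> tuple[list[np.ndarray], dict]:
    """Supernet forward pass: every slot mixes all its candidates by theta.

    Each slot's contribution is the softmax-weighted sum over its whole
    candidate set (NULL contributing nothing), sharing the slot's single
    weight matrix across candidates.  Used to compute dense architecture
    gradients during the search; ``sig`` is a significance tensor.
    """
    T = sig.T
    states: list[np.ndarray] = [np.asarray(H0, dtype=float)]
    pre: dict[int, np.ndarray] = {}
    parts: dict[tuple[tuple[int, int], int], np.ndarray] = {}
    for t in range(1, T + 1):
        total = np.zeros_like(states[0])
        for i in range(t):
            slot = (i, t)
            theta = sig.theta(slot)
            cs = sig.candidates[slot]
            for n, mode in enumerate(cs.members):
                if mode == NULL:
                    continue
                if mode == IDENTITY:
                    g = states[i]
                else:
                    g = relations[mode].normalized @ states[i] @ weights.W[slot]
                parts[(slot, n)] = g
                total = total + theta[n] * g
        pre[t] = total
        states.append(gelu(total))
    return states, {"pre": pre, "parts": parts, "T": T}


def mixture_backward_alpha(
    grad_HT: np.ndarray,
    cache: dict,
    sig,
    weights: PropagationWeights,
    relations: Mapping[str, NormalizedRelation],
) -> dict[tuple[int, int], np.ndarray]:
    """Gradient of the loss w.r.t. every slot's alpha under mixture_forward.

    Backpropagates through the theta-weighted supernet and applies the full
    softmax Jacobian per slot:  dL/da_k = theta_k (g_k - sum_n theta_n g_n)
    where g_n = dL/dtheta_n.
    """
    T = cache["T"]
    grad_states: dict[int, np.ndarray] = {T: np.asarray(grad_HT, dtype=float)}
    grad_theta = {
        slot: np.zeros(len(sig.candidates[slot].members)) for slot in sig.alpha
    }
    for t in range(T, 0, -1):
        gs = grad_states.pop(t, None)
        if gs is None:
            continue
        dS = gs * gelu_grad(cache["pre"][t])
        for i in range(t):
            slot = (i, t)
            theta = sig.theta(slot)
            cs = sig.candidates[slot]
            for n, mode in enumerate(cs.members):
                if mode == NULL:
                    continue
                g = cache["parts"][(slot, n)]
                grad_theta[slot][n] += float(np.sum(dS * g))
                if i > 0:
                    dH = theta[n] * dS
                    if mode == IDENTITY:
                        add = dH
                    else:
                        add = relations[mode].normalized.T @ (
                            dH @ weights.W[slot].T
                        )
                    if i in grad_states:
                        grad_states[i] = grad_states[i] + add
                    else:
                        grad_states[i] = add
    grad_alpha: dict[tuple[int, int], np.ndarray] = {}
    for slot, gt in grad_theta.items():
        theta = sig.theta(slot)
        grad_alpha[slot] = theta * (gt - float(theta @ gt))
    return grad_alpha
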