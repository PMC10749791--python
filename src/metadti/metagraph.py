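"""Adaptive meta-graph search space.

A meta-graph is a DAG over propagation states ``H^0 .. H^T``: every ordered
slot ``(i, t)`` with ``i < t`` carries exactly one propagation mode chosen
from a relation catalog.  Besides the network's typed relations the catalog
holds two distinguished modes: ``IDENTITY`` (copy a previous state
unchanged) and ``NULL`` (contribute nothing).  Which modes a slot may take
depends on its position:

* ``i = t-1, t < T`` -- every mode except NULL (the chain edge must carry
  something);
* ``i < t-1, t < T`` -- every mode (skip edges may be switched off);
* ``i = t-1, t = T`` -- only role-terminating relations ``* -> role`` (the
  constraint set C');
* ``i < t-1, t = T`` -- C' plus IDENTITY and NULL.

Each candidate in each slot carries a learnable significance ``alpha``;
its softmax ``theta`` gates a stochastic selection rule: with probability
``1 - p`` pick the argmax-theta candidate, with probability ``p`` pick
uniformly at random.  The exploration probability decays linearly to zero
over the search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .hetnet import HetNet

__all__ = [
    "IDENTITY",
    "NULL",
    "RelationCatalog",
    "CandidateSet",
    "SignificanceTensor",
    "MetaGraph",
    "candidate_set",
    "normalize_significance",
    "select_relation",
    "exploration_probability",
    "derive_final_metagraph",
    "all_slots",
]

IDENTITY = "IDENTITY"
NULL = "NULL"


@dataclass(frozen=True)
class RelationCatalog:
    """Ordered propagation modes: network relations plus IDENTITY and NULL.

    ``target_types`` maps each real relation to the node type it terminates
    at, which drives the final-layer constraint set C'.
    """

    modes: tuple[str, ...]
    target_types: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if IDENTITY not in self.modes or NULL not in self.modes:
            raise ValueError("catalog must contain IDENTITY and NULL")

    @classmethod
    def from_hetnet(cls, net: HetNet) -> "RelationCatalog":
        names = net.relation_names()
        modes = tuple(names) + (IDENTITY, NULL)
        targets = {name: net.relation_typing[name][1] for name in names}
        return cls(modes=modes, target_types=targets)

    @classmethod
    def from_relations(
        cls, target_types: dict[str, str]
    ) -> "RelationCatalog":
        """Catalog from an explicit relation -> target-type mapping."""
        modes = tuple(sorted(target_types)) + (IDENTITY, NULL)
        return cls(modes=modes, target_types=dict(target_types))

    def __len__(self) -> int:
        return len(self.modes)

    def real_relations(self) -> tuple[str, ...]:
        return tuple(m for m in self.modes if m not in (IDENTITY, NULL))

    def constraint_set(self, role: str) -> tuple[str, ...]:
        """C': relations of the form ``* -> role``, in catalog order."""
        return tuple(
            m for m in self.real_relations() if self.target_types[m] == role
        )


@dataclass(frozen=True)
class CandidateSet:
    """Admissible modes for one slot ``(i, t)`` of a T-step meta-graph."""

    i: int
    t: int
    T: int
    members: tuple[str, ...]


def all_slots(T: int) -> Iterator[tuple[int, int]]:
    """Slots (i, t) with 0 <= i < t <= T, in ascending (t, i) order."""
    for t in range(1, T + 1):
        for i in range(t):
            yield (i, t)


def candidate_set(
    i: int, t: int, T: int, role: str, catalog: RelationCatalog
) -> CandidateSet:
    """Admissible propagation modes for slot ``(i, t)`` (four-case rule)."""
    if not (0 <= i < t <= T):
        raise ValueError(f"invalid slot: need 0 <= i < t <= T, got ({i}, {t}, T={T})")
    c_prime = catalog.constraint_set(role)
    if t < T:
        if i == t - 1:
            members = tuple(m for m in catalog.modes if m != NULL)
        else:
            members = catalog.modes
    else:
        if i == t - 1:
            members = c_prime
        else:
            members = c_prime + (IDENTITY, NULL)
    if not members:
        raise ValueError(
            f"no admissible modes for slot ({i},{t}): no relation targets role {role!r}"
        )
    return CandidateSet(i=i, t=t, T=T, members=members)


def normalize_significance(alpha_slot: np.ndarray) -> np.ndarray:
    """Softmax of a slot's significance vector (max-shifted for stability)."""
    alpha_slot = np.asarray(alpha_slot, dtype=float)
    if alpha_slot.size == 0:
        raise ValueError("empty significance vector")
    if not np.all(np.isfinite(alpha_slot)):
        raise ValueError("non-finite significance")
    shifted = alpha_slot - alpha_slot.max()
    e = np.exp(shifted)
    return e / e.sum()


@dataclass
class SignificanceTensor:
    """Per-slot significance vectors ``alpha`` for one search role.

    ``alpha[(i, t)]`` aligns with ``candidates[(i, t)].members``.  Values
    are initialized uniformly at random in [0, 1]; ``theta`` exposes the
    softmax-normalized twin used for selection and gradient flow.
    """

    T: int
    role: str
    candidates: dict[tuple[int, int], CandidateSet]
    alpha: dict[tuple[int, int], np.ndarray]

    @classmethod
    def initialize(
        cls, T: int, role: str, catalog: RelationCatalog, rng: np.random.Generator
    ) -> "SignificanceTensor":
        candidates = {
            slot: candidate_set(slot[0], slot[1], T, role, catalog)
            for slot in all_slots(T)
        }
        alpha = {
            slot: rng.random(len(cs.members)) for slot, cs in candidates.items()
        }
        return cls(T=T, role=role, candidates=candidates, alpha=alpha)

    def theta(self, slot: tuple[int, int]) -> np.ndarray:
        return normalize_significance(self.alpha[slot])

    def save(self, path: str | Path) -> None:
        payload = {
            "T": self.T,
            "role": self.role,
            "alpha": {
                f"{i},{t}": self.alpha[(i, t)].tolist()
                for (i, t) in sorted(self.alpha)
            },
            "members": {
                f"{i},{t}": list(self.candidates[(i, t)].members)
                for (i, t) in sorted(self.candidates)
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def select_relation(
    theta_slot: np.ndarray,
    members: CandidateSet,
    p_i: float,
    rng: np.random.Generator,
) -> str:
    """Stochastic mode selection for one slot.

    With probability ``1 - p_i`` returns the argmax-theta member (ties go
    to the lowest catalog index); with probability ``p_i`` a uniform draw
    from the candidate set.
    """
    if not (0.0 <= p_i <= 1.0):
        raise ValueError("p_i must lie in [0, 1]")
    if len(theta_slot) != len(members.members):
        raise ValueError("theta vector does not align with candidate set")
    if p_i > 0.0 and rng.random() < p_i:
        return members.members[int(rng.integers(len(members.members)))]
    return members.members[int(np.argmax(theta_slot))]


def exploration_probability(step: int, total_steps: int, p0: float = 0.1) -> float:
    """Linearly decaying exploration probability, p0 at step 0 down to 0."""
    if total_steps <= 0:
        return 0.0
    if not (0 <= step <= total_steps):
        raise ValueError("step outside [0, total_steps]")
    return p0 * (1.0 - step / total_steps)


@dataclass(frozen=True)
class MetaGraph:
    """A fully selected propagation plan: one mode per slot ``(i, t)``."""

    T: int
    role: str
    selected: dict[tuple[int, int], str]

    def __post_init__(self) -> None:
        expected = set(all_slots(self.T))
        if set(self.selected) != expected:
            raise ValueError("selected slots do not cover 0 <= i < t <= T")

    def real_slots(self) -> dict[tuple[int, int], str]:
        """Slots carrying an actual relation (not IDENTITY/NULL)."""
        return {
            slot: mode
            for slot, mode in self.selected.items()
            if mode not in (IDENTITY, NULL)
        }

    def selected_relations(self) -> tuple[str, ...]:
        """All selected modes in slot order, including IDENTITY/NULL."""
        return tuple(self.selected[s] for s in all_slots(self.T))

    def to_json(self) -> str:
        payload = {
            "T": self.T,
            "role": self.role,
            "selected": {f"{i},{t}": m for (i, t), m in sorted(self.selected.items())},
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def from_json(cls, text: str) -> "MetaGraph":
        payload = json.loads(text)
        selected = {
            tuple(int(x) for x in key.split(",")): mode
            for key, mode in payload["selected"].items()
        }
        return cls(T=payload["T"], role=payload["role"], selected=selected)

    @classmethod
    def load(cls, path: str | Path) -> "MetaGraph":
        return cls.from_json(Path(path).read_text())


def derive_final_metagraph(sig: SignificanceTensor) -> MetaGraph:
    """Deterministic argmax-theta meta-graph from a trained tensor."""
    selected: dict[tuple[int, int], str] = {}
    for slot in all_slots(sig.T):
        if slot not in sig.alpha:
            raise ValueError(f"significance tensor missing slot {slot}")
        cs = sig.candidates[slot]
        selected[slot] = cs.members[int(np.argmax(sig.theta(slot)))]
    return MetaGraph(T=sig.T, role=sig.role, selected=selected)
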