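"""Tower of Hanoi state space and problem generation (4 disks, 3 pegs).

A state assigns each of the four disks (0 = smallest ... 3 = largest) to one
of three pegs; the stacking order on a peg is implied by size, so there are
exactly 3**4 = 81 legal states.  A legal move transfers the top (smallest)
disk of one peg onto a peg whose top disk is larger, or which is empty.  The
legal-move graph is connected, and problem difficulty is the shortest-path
distance between the initial and target states.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np

N_DISKS = 4
N_PEGS = 3

#: a state is a tuple (peg of disk 0, peg of disk 1, peg of disk 2, peg of disk 3)
TOHState = tuple[int, int, int, int]


@dataclass(frozen=True)
class TOHProblem:
    initial: TOHState
    target: TOHState
    min_steps: int


def all_states() -> list[TOHState]:
    """All 81 legal 4-disk/3-peg configurations."""
    return list(itertools.product(range(N_PEGS), repeat=N_DISKS))


def legal_moves(state: TOHState) -> list[TOHState]:
    """States reachable from ``state`` in one legal move."""
    tops: dict[int, int] = {}
    for disk in range(N_DISKS - 1, -1, -1):  # end with smallest on top
        tops[state[disk]] = disk
    moves = []
    for src, disk in tops.items():
        for dst in range(N_PEGS):
            if dst == src:
                continue
            if dst not in tops or tops[dst] > disk:
                nxt = list(state)
                nxt[disk] = dst
                moves.append(tuple(nxt))
    return moves


@lru_cache(maxsize=1)
def move_graph() -> nx.Graph:
    """The undirected legal-move graph over the 81 states."""
    g = nx.Graph()
    g.add_nodes_from(all_states())
    for s in all_states():
        for t in legal_moves(s):
            g.add_edge(s, t)
    return g


def toh_min_distance(a: TOHState, b: TOHState) -> int:
    """Length of the shortest legal move sequence from ``a`` to ``b``."""
    return nx.shortest_path_length(move_graph(), tuple(a), tuple(b))


@lru_cache(maxsize=1)
def _distance_index() -> dict[int, list[tuple[TOHState, TOHState]]]:
    """Ordered state pairs grouped by shortest-path distance."""
    g = move_graph()
    by_dist: dict[int, list[tuple[TOHState, TOHState]]] = {}
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            by_dist.setdefault(d, []).append((src, dst))
    for pairs in by_dist.values():
        pairs.sort()
    return by_dist


PRACTICE_STEPS = (1, 2, 2)
EXPERIMENTAL_STEPS = tuple(s for s in range(3, 11) for _ in range(2))


def generate_toh_problem_set(
    seed: int | np.random.Generator,
) -> tuple[list[TOHProblem], list[TOHProblem]]:
    """Sample the task's problem set: 3 practice problems (1, 2, 2 steps) and
    16 experimental problems, two at each step count 3..10.

    Initial/target pairs are drawn uniformly among state pairs at the
    required distance, excluding targets already used as practice targets.
    Returns ``(practice, experimental)``; the same seed reproduces the same
    set.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    index = _distance_index()

    def draw(steps: int, banned_targets: set[TOHState]) -> TOHProblem:
        pairs = index[steps]
        while True:
            a, b = pairs[int(rng.integers(len(pairs)))]
            if b not in banned_targets:
                return TOHProblem(a, b, steps)

    practice: list[TOHProblem] = []
    for s in PRACTICE_STEPS:
        practice.append(draw(s, set()))
    banned = {p.target for p in practice}
    experimental = [draw(s, banned) for s in EXPERIMENTAL_STEPS]
    return practice, experimental
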