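"""Reads as ordered multisets, and resolution of multi-base droplet order.

A droplet run yields an ordered stream of droplets, each holding an
unordered multiset of bases (within-droplet release order is lost).  The
natural read type is therefore a :class:`SetRead`: an acquisition-ordered
list of non-empty base multisets.  Linearising a SetRead means choosing an
arrangement of every multiset and concatenating the blocks in droplet order.

Two resolutions are provided: uniform random draws over the distinct
arrangements (for the permutation-averaged identity), and a restart
hill-climbing search for the arrangement that best fits a reference (the
"order correctly chosen" upper bound), exact by exhaustive enumeration when
the joint arrangement space is small.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterator, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .align import AlignmentResult, ScoringScheme
    from .mixture import OccupancyCall

__all__ = [
    "SetRead",
    "droplets_to_read",
    "sample_orderings",
    "best_order_search",
]

EXACT_SEARCH_LIMIT = 10_000


@dataclass(frozen=True)
class SetRead:
    """Ordered list of unordered base multisets, one per occupied droplet."""

    droplets: tuple[tuple[str, ...], ...]  # each inner tuple sorted
    indices: tuple[int, ...]  # acquisition index per droplet

    def __post_init__(self) -> None:
        if len(self.droplets) != len(self.indices):
            raise ValueError("droplets and indices must have equal length")
        if any(len(d) == 0 for d in self.droplets):
            raise ValueError("SetRead may not contain empty multisets")
        object.__setattr__(
            self, "droplets", tuple(tuple(sorted(d)) for d in self.droplets)
        )
        if any(
            a >= b for a, b in zip(self.indices, self.indices[1:])
        ):
            raise ValueError("indices must be strictly increasing (acquisition order)")

    def __len__(self) -> int:
        return len(self.droplets)

    @property
    def n_bases(self) -> int:
        return sum(len(d) for d in self.droplets)

    @property
    def multi_droplets(self) -> tuple[int, ...]:
        """Positions (into ``droplets``) holding more than one base."""
        return tuple(i for i, d in enumerate(self.droplets) if len(d) > 1)

    def n_arrangements(self) -> int:
        """Number of distinct joint linearizations (product of multinomials)."""
        total = 1
        for d in self.droplets:
            perms = math.factorial(len(d))
            for b in set(d):
                perms //= math.factorial(d.count(b))
            total *= perms
        return total


def droplets_to_read(
    calls: Sequence["OccupancyCall"],
    channel_map: Mapping[str, str],
) -> SetRead:
    """Collapse per-channel occupancy calls into a SetRead.

    Each droplet contributes the multiset of bases whose mapped channels were
    called occupied; droplets with no occupied channel are skipped.
    Acquisition order is preserved.
    """
    base_of = {ch: base for base, ch in channel_map.items()}
    if len(base_of) != len(channel_map):
        raise ValueError("channel_map must be a bijection")
    droplets: list[tuple[str, ...]] = []
    indices: list[int] = []
    for call in calls:
        bases = []
        for ch, occ in sorted(call.occupied.items()):
            if ch not in base_of:
                raise ValueError(f"unknown channel {ch!r} in occupancy call")
            if occ:
                bases.append(base_of[ch])
        if bases:
            droplets.append(tuple(sorted(bases)))
            indices.append(call.index)
    return SetRead(droplets=tuple(droplets), indices=tuple(indices))


def _distinct_arrangements(multiset: tuple[str, ...]) -> list[str]:
    """All distinct orderings of one droplet's multiset, sorted."""
    return sorted({"".join(p) for p in itertools.permutations(multiset)})


def sample_orderings(read: SetRead, n_draws: int = 20, seed: int = 0) -> list[str]:
    """Uniform random linearizations of a SetRead.

    Each draw independently permutes every multiset uniformly (a uniform
    random permutation is uniform over the distinct arrangements, since every
    distinct arrangement of a multiset has the same multiplicity) and
    concatenates the blocks in acquisition order.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_draws):
        parts = []
        for d in read.droplets:
            if len(d) == 1:
                parts.append(d[0])
            else:
                order = rng.permutation(len(d))
                parts.append("".join(d[k] for k in order))
        draws.append("".join(parts))
    return draws


def _linearize(arrangements: Sequence[str]) -> str:
    return "".join(arrangements)


def _greedy_arrangements(
    read: SetRead,
    reference: str,
    offset: int,
    options: Mapping[int, Sequence[str]],
) -> list[str]:
    """Per-droplet arrangements matching the reference at cumulative offsets."""
    parts: list[str] = []
    pos = offset
    for i, d in enumerate(read.droplets):
        if len(d) == 1:
            parts.append(d[0])
        else:
            window = reference[pos : pos + len(d)]
            parts.append(
                max(options[i], key=lambda c: sum(a == b for a, b in zip(c, window)))
            )
        pos += len(d)
    return parts


def _iter_joint(read: SetRead) -> Iterator[tuple[str, ...]]:
    options = [_distinct_arrangements(d) for d in read.droplets]
    return itertools.product(*options)


def best_order_search(
    read: SetRead,
    reference: str,
    scoring: "ScoringScheme | None" = None,
    n_restarts: int = 20,
    seed: int = 0,
) -> tuple[str, "AlignmentResult"]:
    """Best-fitting resolution of multi-base droplet order against a reference.

    When the joint arrangement space has at most 10^4 elements the search is
    exact (exhaustive product over distinct per-droplet arrangements).
    Otherwise restart hill-climbing: from each of ``n_restarts`` random
    linearizations, sweep the multi-base droplets in order, trying every
    arrangement of each droplet with the others held fixed and accepting any
    strict identity improvement, until a full sweep changes nothing.  The
    result dominates every ordering it evaluated, hence also every random
    start.

    Returns the best linearized sequence and its alignment.
    """
    from .align import ScoringScheme, smith_waterman

    if not reference:
        raise ValueError("reference must be non-empty")
    if len(read) == 0:
        raise ValueError("read is empty")
    if scoring is None:
        scoring = ScoringScheme()

    def evaluate(seq: str):
        return smith_waterman(seq, reference, scoring)

    if read.n_arrangements() <= EXACT_SEARCH_LIMIT:
        best_seq, best_aln = None, None
        for joint in _iter_joint(read):
            seq = _linearize(joint)
            aln = evaluate(seq)
            if best_aln is None or aln.identity > best_aln.identity:
                best_seq, best_aln = seq, aln
        return best_seq, best_aln

    rng = np.random.default_rng(seed)
    options = {i: _distinct_arrangements(read.droplets[i]) for i in read.multi_droplets}

    def random_start() -> list[str]:
        return [
            "".join(d[k] for k in rng.permutation(len(d))) if len(d) > 1 else d[0]
            for d in read.droplets
        ]

    # reference-guided starts: arrange each droplet to match the reference
    # window at its cumulative offset (exact in the error-free limit)
    probe = evaluate(_linearize(random_start()))
    offsets = {0, max(0, probe.ref_start - probe.query_start)}
    starts: list[list[str]] = [
        _greedy_arrangements(read, reference, off, options) for off in sorted(offsets)
    ]
    starts += [random_start() for _ in range(n_restarts)]

    best_seq, best_aln = None, None
    for current in starts:
        aln = evaluate(_linearize(current))
        improved = True
        while improved:
            improved = False
            for i in read.multi_droplets:
                for cand in options[i]:
                    if cand == current[i]:
                        continue
                    trial = current.copy()
                    trial[i] = cand
                    trial_aln = evaluate(_linearize(trial))
                    if trial_aln.identity > aln.identity:
                        current, aln = trial, trial_aln
                        improved = True
        if best_aln is None or aln.identity > best_aln.identity:
            best_seq, best_aln = _linearize(current), aln
    return best_seq, best_aln
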