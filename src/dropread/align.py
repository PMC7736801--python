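"""Smith-Waterman local alignment with affine gaps, and identity summaries.

The droplet workflow's accuracy is reported as the identity of a local
alignment between a reconstructed read and its reference.  Scoring follows
the common parameter set match = +2, mismatch = -2, gap opening = -3, gap
extension = -1, with the convention that a gap of length L costs
|open| + (L-1)|extend| (the first gap symbol pays the opening penalty).
Identity is matches over alignment columns, gap columns included, within the
local alignment span.

The dynamic program is the Gotoh three-state recurrence, JIT-compiled with
numba; traceback is deterministic with tie order diagonal > up > left, and
the start cell is the first maximal cell in row-major order, so repeated runs
are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .reads import SetRead, sample_orderings

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "IdentitySummary",
    "smith_waterman",
    "score_alignment",
    "mean_identity",
    "format_alignment",
]

_ALPHABET = "ACGTN"
_ENCODE = {c: i for i, c in enumerate(_ALPHABET)}
_N_CODE = 4


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring parameters (integers)."""

    match: int = 2
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("mismatch and gap penalties must be negative")
        if self.gap_extend < self.gap_open:
            # affine convention: extending a gap is never dearer than
            # opening one (otherwise gap cost is not open + (L-1)*extend)
            raise ValueError("|gap_extend| must not exceed |gap_open|")


@dataclass(frozen=True)
class AlignmentResult:
    """A local alignment: aligned strings, coordinates, score and identity.

    Coordinates are 0-based, half-open, on the original (ungapped) sequences.
    ``columns`` counts alignment columns including gap columns; ``identity``
    is ``matches / columns`` (0 for an empty alignment).
    """

    score: int
    aligned_query: str
    aligned_reference: str
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def cigar(self) -> str:
        """SAM-style CIGAR of the local segment (M/I/D)."""
        ops = []
        for qc, rc in zip(self.aligned_query, self.aligned_reference):
            ops.append("D" if qc == "-" else "I" if rc == "-" else "M")
        out, run, prev = [], 0, ""
        for op in ops:
            if op == prev:
                run += 1
            else:
                if prev:
                    out.append(f"{run}{prev}")
                prev, run = op, 1
        if prev:
            out.append(f"{run}{prev}")
        return "".join(out) or "*"


@dataclass(frozen=True)
class IdentitySummary:
    """Identities of repeated random-order draws of a multiset read."""

    identities: tuple[float, ...]
    mean: float
    sd: float
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.identities)


def _encode(seq: str, name: str) -> np.ndarray:
    codes = np.empty(len(seq), dtype=np.int8)
    for i, c in enumerate(seq):
        code = _ENCODE.get(c)
        if code is None:
            raise ValueError(f"invalid symbol {c!r} in {name} at position {i}")
        codes[i] = code
    return codes


@njit(cache=True)
def _gotoh_matrices(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m, n = q.size, r.size
    neg = np.int64(-(10**9))
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), neg, dtype=np.int64)  # gap in query (left)
    F = np.full((m + 1, n + 1), neg, dtype=np.int64)  # gap in reference (up)
    best, bi, bj = np.int64(0), 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            f = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            if q[i - 1] == 4 or r[j - 1] == 4:  # N scores as mismatch, even vs N
                s = mismatch
            elif q[i - 1] == r[j - 1]:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            if h > best:  # first maximum in row-major order wins
                best, bi, bj = h, i, j
    return H, E, F, best, bi, bj


def smith_waterman(
    query: str, reference: str, scoring: ScoringScheme = ScoringScheme()
) -> AlignmentResult:
    """Optimal local alignment of ``query`` against ``reference``.

    Alphabet {A, C, G, T, N}; N scores as a mismatch against everything.
    An empty alignment (score 0) is returned when no positive-scoring pair
    of segments exists.
    """
    if not query or not reference:
        raise ValueError("query and reference must be non-empty")
    q = _encode(query, "query")
    r = _encode(reference, "reference")
    H, E, F, best, bi, bj = _gotoh_matrices(
        q, r, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    if best == 0:
        return AlignmentResult(0, "", "", 0, 0, 0, 0, 0, 0)

    # deterministic traceback: at an H cell prefer diagonal, then up (gap in
    # reference), then left (gap in query); inside a gap state prefer closing
    # the gap over extending it.
    aq: list[str] = []
    ar: list[str] = []
    i, j, state = bi, bj, "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            if q[i - 1] == 4 or r[j - 1] == 4:
                s = scoring.mismatch
            elif q[i - 1] == r[j - 1]:
                s = scoring.match
            else:
                s = scoring.mismatch
            if H[i - 1, j - 1] + s == h:
                aq.append(query[i - 1])
                ar.append(reference[j - 1])
                i -= 1
                j -= 1
            elif F[i, j] == h:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in reference, consume query char
            aq.append(query[i - 1])
            ar.append("-")
            if H[i - 1, j] + scoring.gap_open == F[i, j]:
                state = "H"
            i -= 1
        else:  # "E": gap in query, consume reference char
            aq.append("-")
            ar.append(reference[j - 1])
            if H[i, j - 1] + scoring.gap_open == E[i, j]:
                state = "H"
            j -= 1
    aq.reverse()
    ar.reverse()
    aligned_q, aligned_r = "".join(aq), "".join(ar)
    matches = sum(
        1 for a, b in zip(aligned_q, aligned_r) if a == b and a != "-" and a != "N"
    )
    return AlignmentResult(
        score=int(best),
        aligned_query=aligned_q,
        aligned_reference=aligned_r,
        query_start=i,
        query_end=bi,
        ref_start=j,
        ref_end=bj,
        matches=matches,
        columns=len(aligned_q),
    )


def score_alignment(
    aligned_query: str, aligned_reference: str, scoring: ScoringScheme = ScoringScheme()
) -> int:
    """Re-score a pair of aligned (gapped) strings under the scheme.

    The first symbol of each gap run costs |gap_open|, each further symbol
    |gap_extend|.  Used to check that traceback and score agree.
    """
    if len(aligned_query) != len(aligned_reference):
        raise ValueError("aligned strings must have equal length")
    score = 0
    in_gap = False
    for a, b in zip(aligned_query, aligned_reference):
        if a == "-" and b == "-":
            raise ValueError("double-gap column")
        if a == "-" or b == "-":
            score += scoring.gap_extend if in_gap else scoring.gap_open
            in_gap = True
        else:
            in_gap = False
            if a == b and a != "N":
                score += scoring.match
            else:
                score += scoring.mismatch
    return score


def mean_identity(
    read: SetRead,
    reference: str,
    scoring: ScoringScheme = ScoringScheme(),
    n_draws: int = 20,
    seed: int = 0,
) -> IdentitySummary:
    """Permutation-averaged alignment identity of a multiset read.

    Draws ``n_draws`` random resolutions of the multi-base droplet orders,
    aligns each against the reference, and summarises the identities (the
    fair headline accuracy when within-droplet order is unknown).
    """
    if len(read) == 0:
        raise ValueError("read is empty")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    seqs = sample_orderings(read, n_draws, seed)
    idents = tuple(smith_waterman(s, reference, scoring).identity for s in seqs)
    return IdentitySummary(
        identities=idents,
        mean=float(np.mean(idents)),
        sd=float(np.std(idents)),
        seed=seed,
    )


def format_alignment(result: AlignmentResult, width: int = 60) -> str:
    """Human-readable pairwise alignment block (1-based coordinates)."""
    if result.columns == 0:
        return "(empty alignment, score 0)\n"
    lines = [
        f"score={result.score} identity={result.identity:.3f} "
        f"({result.matches}/{result.columns})",
    ]
    midline = "".join(
        "|" if a == b and a != "-" and a != "N" else " "
        for a, b in zip(result.aligned_query, result.aligned_reference)
    )
    qpos, rpos = result.query_start + 1, result.ref_start + 1
    for off in range(0, result.columns, width):
        qchunk = result.aligned_query[off : off + width]
        rchunk = result.aligned_reference[off : off + width]
        mchunk = midline[off : off + width]
        lines.append(f"query {qpos:>6} {qchunk}")
        lines.append(f"      {'':>6} {mchunk}")
        lines.append(f"ref   {rpos:>6} {rchunk}")
        lines.append("")
        qpos += sum(c != "-" for c in qchunk)
        rpos += sum(c != "-" for c in rchunk)
    return "\n".join(lines)
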