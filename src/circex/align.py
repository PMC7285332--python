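"""Shared pairwise-alignment primitives.

Built on edlib for the dynamic-programming core (global and
semi-global edit-distance alignment with full paths) and on exact
k-mer seed matching for locating candidate alignment regions. Identity
is always defined as matches divided by alignment columns, counting
gap columns — the stricter of the common conventions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

from circex.kmers import _encode, _pack_kmers

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class Alignment:
    """A parsed edlib alignment between a query and a target."""

    edit_distance: int
    columns: int
    matches: int
    query_span: tuple[int, int]   # [start, end) on the query
    target_span: tuple[int, int]  # [start, end) on the target
    cigar: str

    @property
    def identity(self) -> float:
        """Percent matches over all alignment columns (gaps included)."""
        if self.columns == 0:
            return 0.0
        return 100.0 * self.matches / self.columns


def _parse_cigar(cigar: str) -> tuple[int, int, int, int]:
    """Return (columns, matches, query_consumed, target_consumed).

    edlib CIGARs are extended: '=' match, 'X' mismatch, 'I' insertion
    in the query (consumes query only), 'D' deletion (consumes target
    only).
    """
    columns = matches = q = t = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        columns += n
        if op == "=":
            matches += n
            q += n
            t += n
        elif op in ("X", "M"):
            q += n
            t += n
        elif op == "I":
            q += n
        else:  # D
            t += n
    return columns, matches, q, t


def align_global(query: str, target: str) -> Alignment:
    """Global (Needleman–Wunsch-style, edit distance) alignment."""
    res = edlib.align(query, target, mode="NW", task="path")
    columns, matches, q, t = _parse_cigar(res["cigar"])
    return Alignment(
        edit_distance=res["editDistance"],
        columns=columns,
        matches=matches,
        query_span=(0, q),
        target_span=(0, t),
        cigar=res["cigar"],
    )


def align_prefix(query: str, target: str) -> Alignment:
    """Align the whole query to a prefix of the target (free end gaps
    in the target after the query ends)."""
    res = edlib.align(query, target, mode="SHW", task="path")
    loc = res["locations"][0]
    columns, matches, q, t = _parse_cigar(res["cigar"])
    return Alignment(
        edit_distance=res["editDistance"],
        columns=columns,
        matches=matches,
        query_span=(0, q),
        target_span=(0, loc[1] + 1),
        cigar=res["cigar"],
    )


def cigar_columns(cigar: str):
    """Expand a CIGAR into a per-column op iterator."""
    for num, op in _CIGAR_RE.findall(cigar):
        for _ in range(int(num)):
            yield op


def best_local_subpath(
    query: str,
    target: str,
    match_score: float = 1.0,
    mismatch_penalty: float = 2.5,
    gap_penalty: float = 3.5,
) -> Alignment | None:
    """Best-scoring local stretch of the global alignment path.

    Globally aligns *query* to *target*, scores every column (+1
    match, -penalty otherwise) and extracts the maximum-sum run of
    columns (Kadane). This recovers a local alignment with trimmed,
    non-matching ends from a candidate window located by seeding; it is
    not a full Smith–Waterman over all paths, but on windows that
    contain one homologous segment the difference is confined to a few
    terminal columns.
    """
    res = edlib.align(query, target, mode="NW", task="path")
    ops = np.array(list(cigar_columns(res["cigar"])))
    if ops.size == 0:
        return None
    is_match = ops == "="
    is_x = ops == "X"
    is_ins = ops == "I"
    is_del = ops == "D"
    scores = np.where(
        is_match, match_score, np.where(is_x, -mismatch_penalty, -gap_penalty)
    )
    # Kadane with position tracking
    best_sum = cur_sum = 0.0
    best = None
    cur_start = 0
    for i in range(scores.size):
        if cur_sum <= 0:
            cur_sum = scores[i]
            cur_start = i
        else:
            cur_sum += scores[i]
        if cur_sum > best_sum:
            best_sum = cur_sum
            best = (cur_start, i + 1)
    if best is None:
        return None
    c0, c1 = best
    # prefix sums: sequence coordinates consumed before each column
    dq = np.concatenate([[0], np.cumsum(is_match | is_x | is_ins)])
    dt = np.concatenate([[0], np.cumsum(is_match | is_x | is_del)])
    matches = int(np.count_nonzero(is_match[c0:c1]))
    columns = c1 - c0
    return Alignment(
        edit_distance=columns - matches,
        columns=columns,
        matches=matches,
        query_span=(int(dq[c0]), int(dq[c1])),
        target_span=(int(dt[c0]), int(dt[c1])),
        cigar="",
    )


# ---------------------------------------------------------------------------
# Exact seed matching


class SeedIndex:
    """Sorted-array index of the exact k-mers of one target sequence."""

    def __init__(self, target: str, k: int = 13, max_occ: int = 20):
        self.k = k
        self.length = len(target)
        packed = _pack_kmers(_encode(target), k)
        n = len(target) - k + 1
        if packed.size != max(n, 0):
            # Ns present: recompute positions of valid k-mers
            codes = _encode(target)
            bad = codes < 0
            invalid = (
                np.convolve(bad.astype(np.int32), np.ones(k, dtype=np.int32))[
                    k - 1 : k - 1 + max(n, 0)
                ]
                > 0
            )
            positions = np.nonzero(~invalid)[0]
        else:
            positions = np.arange(max(n, 0))
        order = np.argsort(packed, kind="stable")
        self._kmers = packed[order]
        self._positions = positions[order]
        self.max_occ = max_occ

    def matches(self, query: str) -> tuple[np.ndarray, np.ndarray]:
        """Exact k-mer matches as (query_pos, target_pos) arrays."""
        qpacked = _pack_kmers(_encode(query), self.k)
        nq = len(query) - self.k + 1
        if qpacked.size != max(nq, 0):
            codes = _encode(query)
            bad = codes < 0
            invalid = (
                np.convolve(bad.astype(np.int32), np.ones(self.k, dtype=np.int32))[
                    self.k - 1 : self.k - 1 + max(nq, 0)
                ]
                > 0
            )
            qpos_all = np.nonzero(~invalid)[0]
        else:
            qpos_all = np.arange(max(nq, 0))
        if qpacked.size == 0 or self._kmers.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        left = np.searchsorted(self._kmers, qpacked, side="left")
        right = np.searchsorted(self._kmers, qpacked, side="right")
        occ = right - left
        usable = (occ > 0) & (occ <= self.max_occ)
        qp_out: list[np.ndarray] = []
        tp_out: list[np.ndarray] = []
        for qi in np.nonzero(usable)[0]:
            tpos = self._positions[left[qi] : right[qi]]
            qp_out.append(np.full(tpos.size, qpos_all[qi]))
            tp_out.append(tpos)
        if not qp_out:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        return np.concatenate(qp_out), np.concatenate(tp_out)


@dataclass
class SeedCluster:
    """A diagonal band of co-linear exact seed matches."""

    qpos: np.ndarray
    tpos: np.ndarray

    @property
    def count(self) -> int:
        return self.qpos.size

    @property
    def q_span(self) -> tuple[int, int]:
        return int(self.qpos.min()), int(self.qpos.max())

    @property
    def t_span(self) -> tuple[int, int]:
        return int(self.tpos.min()), int(self.tpos.max())


def cluster_seeds(
    qpos: np.ndarray,
    tpos: np.ndarray,
    diag_band: int = 20,
    max_gap: int = 300,
) -> list[SeedCluster]:
    """Group seed matches into co-linear clusters.

    Seeds join a cluster when their diagonals differ by at most
    *diag_band* (tolerating indel drift) and they are within *max_gap*
    of the cluster along the query. Clusters come back sorted by
    descending seed count.
    """
    if qpos.size == 0:
        return []
    diag = tpos - qpos
    order = np.lexsort((qpos, diag))
    diag_s, qpos_s, tpos_s = diag[order], qpos[order], tpos[order]
    clusters: list[SeedCluster] = []
    start = 0
    for i in range(1, diag_s.size + 1):
        if i == diag_s.size or diag_s[i] - diag_s[i - 1] > diag_band:
            block = slice(start, i)
            clusters.extend(_split_by_gap(qpos_s[block], tpos_s[block], max_gap))
            start = i
    clusters.sort(key=lambda c: (-c.count, c.q_span[0], c.t_span[0]))
    return clusters


def _split_by_gap(qpos: np.ndarray, tpos: np.ndarray, max_gap: int) -> list[SeedCluster]:
    order = np.argsort(qpos, kind="stable")
    qpos, tpos = qpos[order], tpos[order]
    out = []
    start = 0
    for i in range(1, qpos.size + 1):
        if i == qpos.size or qpos[i] - qpos[i - 1] > max_gap:
            out.append(SeedCluster(qpos=qpos[start:i], tpos=tpos[start:i]))
            start = i
    return out
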