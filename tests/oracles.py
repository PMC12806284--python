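"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's scanning code: SSR enumeration
tests every candidate (start, unit) by direct string comparison, and the
repeat oracle finds match runs on diagonals/anti-diagonals of the full
pairwise base-match matrices with numpy.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _canonical(motif: str) -> str:
    rc = "".join(_COMP[c] for c in reversed(motif))
    cands = [motif[i:] + motif[:i] for i in range(len(motif))]
    cands += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(cands)


def brute_ssrs(seq: str, thresholds: dict[int, int]
               ) -> set[tuple[str, int, int, int]]:
    """Left-anchored maximal perfect tandem repeats by direct
    string-multiplication comparison at every (start, unit) pair."""
    n = len(seq)
    hits = set()
    for u, min_units in thresholds.items():
        for s in range(n - u * min_units + 1):
            motif = seq[s:s + u]
            if "N" in motif:
                continue
            if any(u % d == 0 and motif == motif[:d] * (u // d)
                   for d in range(1, u)):
                continue  # periodic motif: belongs to a shorter unit
            # left-maximality of the per-base tandem relation
            if s > 0 and seq[s - 1] != "N" and seq[s - 1] == seq[s - 1 + u]:
                continue
            c = 1
            while seq[s:s + (c + 1) * u] == motif * (c + 1):
                c += 1
            if c >= min_units:
                hits.add((_canonical(motif), c, s, s + c * u))
    return hits


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, length)."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def brute_lsrs(seq: str, min_arm: int,
               types=("forward", "palindromic", "reverse", "complement"),
               ) -> set[tuple[str, int, int, int]]:
    """Maximal disjoint-arm repeat pairs via match-matrix runs.

    Forward/complement pairs live on diagonals of the equality /
    complement matrices; palindromic/reverse pairs on anti-diagonals.
    Arms are truncated so they never overlap, matching the detector's
    disjointness convention.
    """
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(a)
    comp = np.zeros(256, dtype=np.uint8)
    for x, y in _COMP.items():
        comp[ord(x)] = ord(y)
    not_n = a != ord("N")
    eq = (a[:, None] == a[None, :]) & not_n[:, None] & not_n[None, :]
    cm = (a[:, None] == comp[a][None, :]) & not_n[:, None] & not_n[None, :]

    hits: set[tuple[str, int, int, int]] = set()

    def parallel(matrix, name):
        for d in range(1, n):
            if n - d < min_arm:
                break
            for t0, run in _runs(np.diagonal(matrix, offset=d)):
                r = min(run, d)  # disjointness caps tandem-like runs
                if r >= min_arm:
                    hits.add((name, r, t0, t0 + d))

    def antiparallel(matrix, name):
        for s in range(2 * n - 1):
            lo = max(0, s - n + 1)
            hi = min(s, n - 1)
            if hi - lo + 1 < 2 * min_arm:
                continue
            t = np.arange(lo, hi + 1)
            vec = matrix[t, s - t]
            for off, run in _runs(vec):
                t0 = lo + off
                if 2 * t0 > s:
                    # run lies right of the anti-diagonal center; it is the
                    # mirror of a left-side run that reports the same pair
                    continue
                # disjoint arms: arm1 [t0, t0+r), arm2 [s-t0-r+1, s-t0+1)
                r = min(run, (s - 2 * t0 + 1) // 2)
                if r >= min_arm:
                    hits.add((name, r, t0, s - t0 - r + 1))

    if "forward" in types:
        parallel(eq, "forward")
    if "complement" in types:
        parallel(cm, "complement")
    if "palindromic" in types:
        antiparallel(cm, "palindromic")
    if "reverse" in types:
        antiparallel(eq, "reverse")
    return hits
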