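"""Independent brute-force oracles used to cross-check the fast scanners.

These deliberately re-derive results from first principles (exhaustive
enumeration, direct pair counting) and share no scanning logic with the
package implementations.
"""

from __future__ import annotations

from itertools import combinations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def _min_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _is_aperiodic(motif: str) -> bool:
    m = len(motif)
    return not any(
        m % p == 0 and motif == motif[:p] * (m // p) for p in range(1, m)
    )


def brute_force_ssrs(seq: str, thresholds: dict[int, int]):
    """Every maximal perfect tandem run meeting the unit thresholds,
    enumerated by direct unit-block comparison at every start position."""
    n = len(seq)
    hits = set()
    for m, thr in thresholds.items():
        for s in range(n - m + 1):
            # left-maximality: the run must not extend one character left
            if s > 0 and s + m - 1 < n and seq[s - 1] == seq[s + m - 1]:
                continue
            motif = seq[s : s + m]
            if "N" in motif or not _is_aperiodic(motif):
                continue
            u = 1
            while s + (u + 1) * m <= n and seq[s + u * m : s + (u + 1) * m] == motif:
                u += 1
            if u >= thr:
                hits.add((_min_rotation(motif), u, s, s + u * m))
    return hits


def brute_force_repeats(seq: str, min_len: int):
    """All maximal exact forward and palindromic repeat pairs by direct
    all-pairs extension, with the tandem-collapse reporting convention."""
    n = len(seq)
    raw = set()
    # forward: one maximal pair per left-maximal (i, j) anchor
    for i in range(n):
        for j in range(i + 1, n):
            if seq[i] != seq[j] or seq[i] == "N":
                continue
            if i > 0 and seq[i - 1] == seq[j - 1] != "N":
                continue  # not left-maximal
            length = 0
            while (
                j + length < n
                and seq[i + length] == seq[j + length]
                and seq[i + length] != "N"
            ):
                length += 1
            if length >= min_len:
                raw.add(("forward", i, j, length))
    # palindromic: anchor on (a_start, b_end) anti-diagonals
    for a in range(n):
        for b_end in range(n):
            if seq[a] == "N" or seq[b_end] != _COMP[seq[a]]:
                continue
            if (
                a > 0
                and b_end + 1 < n
                and seq[a - 1] != "N"
                and seq[b_end + 1] == _COMP[seq[a - 1]]
            ):
                continue  # not maximal outward
            length = 0
            while (
                a + length < n
                and b_end - length >= 0
                and seq[a + length] != "N"
                and seq[b_end - length] == _COMP[seq[a + length]]
            ):
                length += 1
            if length >= min_len:
                b = b_end - length + 1
                lo, hi = (a, b) if a <= b else (b, a)
                raw.add(("palindromic", lo, hi, length))
    return collapse(raw)


def collapse(raw):
    """Same reporting convention as the package: tandem families keep the
    smallest-spacing pair (re-stated independently here)."""
    by_key = {}
    for kind, i, j, length in raw:
        key = (kind, "tandem", i, j + length) if j < i + length else (kind, "pair", i, j, length)
        prev = by_key.get(key)
        if prev is None or (j - i) < (prev[1] - prev[0]):
            by_key[key] = (i, j, length, kind)
    return {(k, i, j, ln) for i, j, ln, k in by_key.values()}


def mean_pairwise_read_diversity(columns: list[list[str]]) -> float:
    """pi from explicit per-column read bases: average over columns of the
    fraction of read pairs that disagree."""
    vals = []
    for bases in columns:
        pairs = list(combinations(bases, 2))
        vals.append(sum(1 for a, b in pairs if a != b) / len(pairs))
    return sum(vals) / len(vals)


def smith_waterman(a: str, b: str, match=2, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Plain affine-gap local alignment returning (aligned_length, identity)
    of the best-scoring local alignment, by direct dynamic programming."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    # H: best ending in match/mismatch; E: gap in a (consume b); F: gap in b
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, best_pos = 0.0, (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best, best_pos = H[i][j], (i, j)
    if best == 0:
        return 0, 0.0
    # traceback for aligned length / identity
    i, j = best_pos
    state = "H"
    length = matches = 0
    while i > 0 and j > 0 and H[i][j] > 0:
        if state == "H":
            s = match if a[i - 1] == b[j - 1] else mismatch
            if H[i][j] == H[i - 1][j - 1] + s:
                length += 1
                matches += a[i - 1] == b[j - 1]
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            length += 1
            if E[i][j] == E[i][j - 1] + gap_extend:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:
            length += 1
            if F[i][j] == F[i - 1][j] + gap_extend:
                i -= 1
            else:
                i -= 1
                state = "H"
    return length, matches / length if length else 0.0
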