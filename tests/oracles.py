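"""Independent reference implementations used as test oracles.

Everything here is deliberately written by a different route than the
package code (recursive grammar matching instead of compiled regexes,
explicit per-position loops instead of cumulative sums, full-matrix
dynamic programming instead of banded kernels) so that agreement is
meaningful.
"""

from __future__ import annotations

import numpy as np


# --- tract-and-loop grammar (G4 / iM) ----------------------------------------

def grammar_match_end(s: str, i: int, base: str, tmin: int, tmax: int | None,
                      lmin: int, lmax: int, n_tracts: int) -> int | None:
    """Greedy-with-backtracking match of the 4-tract grammar starting at i.

    Mirrors leftmost-greedy regex semantics: each tract tries its longest
    admissible extent first, then each loop, backtracking deepest-first.
    Returns the match end or None.
    """
    run = 0
    while i + run < len(s) and s[i + run] == base:
        run += 1
    if run < tmin:
        return None
    top = run if tmax is None else min(run, tmax)
    for t in range(top, tmin - 1, -1):
        j = i + t
        if n_tracts == 1:
            return j
        for l in range(lmax, lmin - 1, -1):
            k = j + l
            if k >= len(s):
                continue
            end = grammar_match_end(s, k, base, tmin, tmax, lmin, lmax, n_tracts - 1)
            if end is not None:
                return end
    return None


def scan_grammar(s: str, base: str, tmin: int, tmax: int | None,
                 lmin: int, lmax: int, n_tracts: int = 4) -> list[tuple[int, int]]:
    """Leftmost non-overlapping matches via exhaustive per-start testing."""
    out = []
    pos = 0
    while pos < len(s):
        end = grammar_match_end(s, pos, base, tmin, tmax, lmin, lmax, n_tracts)
        if end is None:
            pos += 1
        else:
            out.append((pos, end))
            pos = end
    return out


# --- RIZ / REZ ---------------------------------------------------------------

def g_runs(s: str) -> list[tuple[int, int]]:
    runs = []
    i = 0
    while i < len(s):
        if s[i] == "G":
            j = i
            while j < len(s) and s[j] == "G":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def riz_oracle(s: str) -> list[tuple[int, int, str]]:
    """Per-anchor maximal RIZ extension, recomputed with explicit loops."""
    out = []
    runs = g_runs(s)
    for model, (tmin, cmin) in (("m1", (3, 3)), ("m2", (4, 2))):
        qual = [(a, b) for a, b in runs if b - a >= tmin]
        for idx, (a, b) in enumerate(qual):
            end = b
            count = 1
            for c, d in qual[idx + 1:]:
                if c - end > 10:
                    break
                if 2 * s[a:d].count("G") < d - a:
                    break
                end = d
                count += 1
            if count >= cmin:
                out.append((a, end, model))
    out.sort(key=lambda r: (r[0], r[2]))
    return out


def rez_oracle(s: str, riz_end: int, linker_max: int = 50,
               rez_min: int = 100, rez_max: int = 2000) -> tuple[int, int] | None:
    """Scan every (start, end) window; max end wins, ties to smallest start."""
    gsum = [0]
    for ch in s:
        gsum.append(gsum[-1] + (ch == "G"))
    best = None
    for start in range(riz_end, min(riz_end + linker_max, len(s)) + 1):
        for end in range(start + rez_min, min(start + rez_max, len(s)) + 1):
            if 5 * (gsum[end] - gsum[start]) >= 2 * (end - start):
                if best is None or end > best[1]:
                    best = (start, end)
    return best


def rlfs_oracle(s: str) -> list[tuple[int, int, str, int, int]]:
    """(record_start, record_end, model, riz_start, riz_end) per anchor/model."""
    out = []
    for a, b, model in riz_oracle(s):
        rez = rez_oracle(s, b)
        if rez is not None:
            out.append((a, rez[1], model, a, b))
    return out


# --- coverage / bins / stats -------------------------------------------------

def coverage_oracle(intervals: list[tuple[int, int]], length: int) -> np.ndarray:
    depth = np.zeros(length, dtype=int)
    for s, e in intervals:
        for p in range(s, e):
            depth[p] += 1
    return depth


def pearson_oracle(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))


# --- alignment ---------------------------------------------------------------

NEG = -(10**12)


def gotoh_full(a: str, b: str, match=2, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Full-matrix affine global alignment with M>X>Y tie-breaking.

    Returns (score, aligned_a, aligned_b).
    """
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    TM = [[0] * (m + 1) for _ in range(n + 1)]
    TX = [[0] * (m + 1) for _ in range(n + 1)]
    TY = [[0] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for j in range(1, m + 1):
        Y[0][j] = gap_open + j * gap_extend
        TY[0][j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        X[i][0] = gap_open + i * gap_extend
        TX[i][0] = 0 if i == 1 else 1
        for j in range(1, m + 1):
            # X from (i-1, j)
            cand = [M[i - 1][j] + gap_open + gap_extend,
                    X[i - 1][j] + gap_extend,
                    Y[i - 1][j] + gap_open + gap_extend]
            X[i][j] = max(cand)
            TX[i][j] = cand.index(X[i][j])
            # Y from (i, j-1)
            cand = [M[i][j - 1] + gap_open + gap_extend,
                    X[i][j - 1] + gap_open + gap_extend,
                    Y[i][j - 1] + gap_extend]
            Y[i][j] = max(cand)
            TY[i][j] = cand.index(Y[i][j])
            # M from (i-1, j-1)
            sub = match if a[i - 1] == b[j - 1] else mismatch
            cand = [M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]]
            best = max(cand)
            M[i][j] = best + sub if best > NEG else NEG
            TM[i][j] = cand.index(best)
    finals = [M[n][m], X[n][m], Y[n][m]]
    score = max(finals)
    state = finals.index(score)
    i, j = n, m
    ca, cb = [], []
    while i > 0 or j > 0:
        if state == 0:
            prev = TM[i][j]
            ca.append(a[i - 1]); cb.append(b[j - 1]); i -= 1; j -= 1
        elif state == 1:
            prev = TX[i][j]
            ca.append(a[i - 1]); cb.append("-"); i -= 1
        else:
            prev = TY[i][j]
            ca.append("-"); cb.append(b[j - 1]); j -= 1
        state = prev
    return score, "".join(reversed(ca)), "".join(reversed(cb))


def enumerate_alignments_best(a: str, b: str, match=2, mismatch=-3,
                              gap_open=-5, gap_extend=-2) -> int:
    """Best score over a complete enumeration of alignments (tiny inputs)."""

    best = [NEG]

    def rec(i, j, score, last):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, "M")
        if i < len(a):
            cost = gap_extend if last == "X" else gap_open + gap_extend
            rec(i + 1, j, score + cost, "X")
        if j < len(b):
            cost = gap_extend if last == "Y" else gap_open + gap_extend
            rec(i, j + 1, score + cost, "Y")

    rec(0, 0, 0, "M")
    return best[0]


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def mutate(rng: np.random.Generator, s: str, sub_rate: float) -> str:
    out = list(s)
    k = int(round(sub_rate * len(s)))
    for i in rng.choice(len(s), size=k, replace=False):
        out[i] = rng.choice([c for c in "ACGT" if c != out[i]])
    return "".join(out)
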