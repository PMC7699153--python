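"""Independent brute-force reference implementations used only by tests.

Each oracle is deliberately written from the definition, by direct
enumeration or closed form, without sharing code paths with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Seq import Seq

# genetic code via Biopython translation (table 11), independent of the
# package's internal tables
_CODONS = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]
_AA = {c: str(Seq(c).translate(table=11)) for c in _CODONS}


def _families():
    fams: dict[str, list[str]] = {}
    for c, aa in _AA.items():
        if aa == "*":
            continue
        fams.setdefault(aa, []).append(c)
    return fams


def enc_bruteforce(counts: dict[str, int]) -> float:
    """Wright's ENc by direct per-family summation, unclamped."""
    by_deg: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in _families().items():
        k = len(codons)
        if k == 1:
            continue
        n = sum(counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        ssq = sum((counts.get(c, 0) / n) ** 2 for c in codons)
        f = (n * ssq - 1) / (n - 1)
        if f > 0:
            by_deg[k].append(f)
    fbar = {k: sum(v) / len(v) for k, v in by_deg.items() if v}
    if 3 not in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    return 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]


def rscu_bruteforce(counts: dict[str, int], include_stops: bool = True):
    fams = _families()
    if include_stops:
        fams["*"] = [c for c, aa in _AA.items() if aa == "*"]
    out = {}
    for codons in fams.values():
        tot = sum(counts.get(c, 0) for c in codons)
        for c in codons:
            out[c] = 0.0 if tot == 0 else counts.get(c, 0) / (tot / len(codons))
    return out


def cai_bruteforce(codons: list[str], w: dict[str, float]) -> float:
    """Log-domain geometric mean over scorable codons."""
    logs = [
        math.log(w[c])
        for c in codons
        if _AA[c] not in ("*", "M", "W")
    ]
    return math.exp(np.mean(logs))


def window_pi_bruteforce(rows: list[str], start: int, end: int) -> tuple[int, float | None]:
    """(valid_sites, pi) by a double loop over pairs and columns."""
    n = len(rows)
    valid_cols = [
        c for c in range(start, end)
        if all(rows[i][c] in "ACGT" for i in range(n))
    ]
    if not valid_cols:
        return 0, None
    total = 0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            npairs += 1
            total += sum(rows[i][c] != rows[j][c] for c in valid_cols)
    return len(valid_cols), total / (npairs * len(valid_cols))


def ng86_sites_bruteforce(codon: str) -> tuple[float, float]:
    s = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if _AA[mut] != "*" and _AA[mut] == _AA[codon]:
                s += 1 / 3
    return s, 3 - s


def ng86_pair_bruteforce(seq_a: str, seq_b: str):
    """NG86 dN/dS by exhaustive pathway enumeration, from the definitions."""
    sites_s = sites_n = 0.0
    sd = nd = 0.0
    used = 0
    for i in range(0, len(seq_a), 3):
        x, y = seq_a[i : i + 3], seq_b[i : i + 3]
        if set(x + y) - set("ACGT"):
            continue
        if _AA[x] == "*" or _AA[y] == "*":
            continue
        diffs = [p for p in range(3) if x[p] != y[p]]
        paths = []
        for order in itertools.permutations(diffs):
            cur, steps, dead = x, [], False
            for p in order:
                nxt = cur[:p] + y[p] + cur[p + 1 :]
                if _AA[nxt] == "*":
                    dead = True
                    break
                steps.append((cur, nxt))
                cur = nxt
            if not dead:
                paths.append(steps)
        if diffs and not paths:
            continue
        used += 1
        for z in (x, y):
            s, n = ng86_sites_bruteforce(z)
            sites_s += s / 2
            sites_n += n / 2
        if paths:
            sd += np.mean(
                [sum(_AA[a] == _AA[b] for a, b in p) for p in paths]
            )
            nd += np.mean(
                [sum(_AA[a] != _AA[b] for a, b in p) for p in paths]
            )
    ps = sd / sites_s if sites_s else 0.0
    pn = nd / sites_n if sites_n else 0.0

    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return {
        "s_sites": sites_s, "n_sites": sites_n, "sd": sd, "nd": nd,
        "ds": jc(ps), "dn": jc(pn), "codons": used,
    }


def ols_closed_form(x, y) -> tuple[float, float, float]:
    """(slope, intercept, r2) from the normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([x, np.ones_like(x)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ beta
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return float(beta[0]), float(beta[1]), 1.0 - ss_res / ss_tot


def longest_rc_repeat_bruteforce(seq: str) -> int:
    """Length of the longest disjoint reverse-complement repeat pair.

    Dynamic programming over common substrings of the sequence and its
    reverse complement (O(L^2); for toy sequences only).
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "?"}
    rc = "".join(comp[b] for b in reversed(seq))
    L = len(seq)
    s = np.frombuffer(seq.encode(), dtype="S1")
    r = np.frombuffer(rc.encode(), dtype="S1")
    best = 0
    prev = np.zeros(L, dtype=np.int32)
    for i in range(L):
        cur = np.zeros(L, dtype=np.int32)
        match = s[i] == r
        cur[0] = match[0]
        cur[1:] = np.where(match[1:], prev[:-1] + 1, 0)
        for j in np.nonzero(cur > best)[0]:
            v = int(cur[j])
            # seq[i-v+1 : i+1] matches rc[j-v+1 : j+1] == forward
            # interval [L-1-j, L-1-j+v); count only disjoint pairs
            a0, a1 = i - v + 1, i + 1
            b0, b1 = L - 1 - j, L - 1 - j + v
            if (b0 >= a1 or a0 >= b1) and v > best:
                best = v
        prev = cur
    return best
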