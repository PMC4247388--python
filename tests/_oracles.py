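"""Independent reference implementations used as test oracles.

Each function here recomputes a quantity by the most direct route
available — exhaustive enumeration, textbook formulas, or unvectorized
definitional code — deliberately sharing no code with the package paths
it is used to check.
"""

from __future__ import annotations

import math

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def brute_force_orfs(seq: str, min_protein_len: int) -> set[tuple[int, int, int, str]]:
    """Every (start, end, frame, strand) where an ATG is paired with the next
    in-frame stop and no codon between them contains N or a stop."""
    out = set()
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            positions = range(frame, len(s) - 2, 3)
            for i in positions:
                if s[i : i + 3] != "ATG":
                    continue
                j = i + 3
                while j + 3 <= len(s):
                    codon = s[j : j + 3]
                    if "N" in codon:
                        j = None
                        break
                    if codon in STOPS:
                        break
                    j += 3
                if j is None or j + 3 > len(s):
                    continue
                if s[j : j + 3] in STOPS and (j - i) // 3 >= min_protein_len:
                    out.add((i, j + 3, frame, strand))
    return out


def gotoh_overlap_score(
    a: str,
    b: str,
    open_s: float,
    ext_s: float,
    match: float | None = None,
    mismatch: float | None = None,
    sub=None,
) -> float:
    """Affine-gap overlap alignment score with free end gaps on both
    sequences: a fresh start may skip the prefix of one sequence, the
    alignment may stop once either sequence is exhausted, and the empty
    overlap scores 0."""
    n, m = len(a), len(b)
    NEG = -1e18

    def s(x, y):
        return sub[x, y] if sub is not None else (match if x == y else mismatch)

    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            fresh = 0.0 if (i == 1 or j == 1) else NEG
            M[i, j] = s(a[i - 1], b[j - 1]) + max(
                fresh, M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]
            )
            Ix[i, j] = max(M[i - 1, j] + open_s, Ix[i - 1, j] + ext_s, Iy[i - 1, j] + open_s)
            Iy[i, j] = max(M[i, j - 1] + open_s, Iy[i, j - 1] + ext_s, Ix[i, j - 1] + open_s)
    best = 0.0
    for j in range(1, m + 1):
        best = max(best, M[n, j], Ix[n, j], Iy[n, j])
    for i in range(1, n + 1):
        best = max(best, M[i, m], Ix[i, m], Iy[i, m])
    return best


# four-class partition restated from its definition, independent of the package
ORACLE_GROUPS = {}
for aa in "ED":
    ORACLE_GROUPS[aa] = "acidic"
for aa in "KHR":
    ORACLE_GROUPS[aa] = "basic"
ORACLE_GROUPS["C"] = "cysteine"
for aa in "STYNQGAVLIFPMW":
    ORACLE_GROUPS[aa] = "other"


def column_is_unique_site(
    focal_residue: str, other_residues: list[str], min_informative: int
) -> bool:
    """Definitional per-column recheck: is the focal residue's group absent
    from all informative (standard-residue) non-focal residues?"""
    if focal_residue not in ORACLE_GROUPS:
        return False
    informative = [r for r in other_residues if r in ORACLE_GROUPS]
    if len(informative) < min_informative:
        return False
    focal_group = ORACLE_GROUPS[focal_residue]
    return all(ORACLE_GROUPS[r] != focal_group for r in informative)


def direct_tmm_factors(counts: np.ndarray, m_trim=0.30, a_trim=0.05) -> np.ndarray:
    """Unvectorized direct-formula TMM: reference by upper quartile closest
    to the mean; per sample, two-sided rank trims on M and A; factor is 2
    to the precision-weighted mean of retained M; geometric mean 1."""
    G, S = counts.shape
    libs = counts.sum(axis=0).astype(float)
    uq = [float(np.quantile(counts[:, j] / libs[j], 0.75)) for j in range(S)]
    mean_uq = sum(uq) / S
    ref = min(range(S), key=lambda j: (abs(uq[j] - mean_uq), j))
    logf = [0.0] * S
    for j in range(S):
        if j == ref:
            continue
        ms, as_, ws = [], [], []
        for g in range(G):
            x, xr = counts[g, j], counts[g, ref]
            if x == 0 or xr == 0:
                continue
            obs, expd = x / libs[j], xr / libs[ref]
            ms.append(math.log2(obs / expd))
            as_.append(0.5 * math.log2(obs * expd))
            ws.append(
                1.0 / ((libs[j] - x) / (libs[j] * x) + (libs[ref] - xr) / (libs[ref] * xr))
            )
        n = len(ms)
        order_m = sorted(range(n), key=lambda k: ms[k])
        order_a = sorted(range(n), key=lambda k: as_[k])
        rank_m, rank_a = [0] * n, [0] * n
        for r, k in enumerate(order_m, start=1):
            rank_m[k] = r
        for r, k in enumerate(order_a, start=1):
            rank_a[k] = r
        lo_m, hi_m = math.floor(n * m_trim) + 1, n - math.floor(n * m_trim)
        lo_a, hi_a = math.floor(n * a_trim) + 1, n - math.floor(n * a_trim)
        num = den = 0.0
        for k in range(n):
            if lo_m <= rank_m[k] <= hi_m and lo_a <= rank_a[k] <= hi_a:
                num += ws[k] * ms[k]
                den += ws[k]
        logf[j] = num / den
    mean_logf = sum(logf) / S
    return np.array([2.0 ** (f - mean_logf) for f in logf])


def brute_force_bh(p: list[float]) -> list[float]:
    """Step-up definition verbatim: q(i) = min over j >= i of min(1, p(j)·m/j)
    on the ascending ordering, reported in original order."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [
        min(min(1.0, p[order[j]] * m / (j + 1)) for j in range(i, m)) for i in range(m)
    ]
    out = [0.0] * m
    for pos, idx in enumerate(order):
        out[idx] = q_sorted[pos]
    return out


def hypergeom_upper_tail(a: int, list_size: int, term_size: int, bg_size: int) -> float:
    """P(X >= a) by exhaustive enumeration for X ~ Hypergeom(bg, term, list)."""
    total = 0.0
    for k in range(a, min(list_size, term_size) + 1):
        total += (
            math.comb(term_size, k)
            * math.comb(bg_size - term_size, list_size - k)
            / math.comb(bg_size, list_size)
        )
    return min(1.0, total)
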