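"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most literal route possible
(exhaustive scans, explicit projector algebra, hand loops) and share no code
with the implementation they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_merge(read1: str, read2: str, min_overlap: int, max_mismatch_frac: float):
    """Reference pair merger: exhaustive scan over all overlap offsets.

    Returns the merged sequence (quality-free: read-1 base wins mismatches)
    or None.  Orientation and tie rules mirror the documented contract:
    lowest mismatch fraction, then longest overlap, then innie before outie.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc2 = "".join(comp[c] for c in reversed(read2))
    n1, n2 = len(read1), len(rc2)
    candidates = []
    for o in range(min_overlap, min(n1, n2) + 1):
        mm = sum(1 for i in range(o) if read1[n1 - o + i] != rc2[i])
        if mm / o <= max_mismatch_frac:
            candidates.append((mm / o, -o, 0, ("innie", o)))
    for o in range(min_overlap, min(n1, n2) + 1):
        if o == n2 and n1 == n2:
            continue  # same columns as the innie full overlap
        mm = sum(1 for i in range(o) if read1[i] != rc2[n2 - o + i])
        if mm / o <= max_mismatch_frac:
            candidates.append((mm / o, -o, 1, ("outie", o)))
    if not candidates:
        return None
    _, _, _, (orient, o) = min(candidates)
    if orient == "innie":
        return read1 + rc2[o:]
    return read1


def slide_identity(query: str, reference: str) -> float:
    """Best ungapped identity of the full query at any reference offset.

    Exact for substitution-only divergence (gaps cost more than mismatches
    under the implementation's scoring), including query overhang positions,
    which count as non-matching alignment columns.
    """
    best = 0.0
    nq, nr = len(query), len(reference)
    for off in range(-(nq - 1), nr):
        matches = sum(
            1
            for i in range(nq)
            if 0 <= off + i < nr and query[i] == reference[off + i]
        )
        best = max(best, matches / nq)
    return best


def nw_glocal_score(query: str, reference: str, match=1, mismatch=-1, gap=-2) -> float:
    """Needleman-Wunsch score with free end gaps on the reference only.

    Plain O(nm) dynamic program: the reference prefix/suffix may be skipped
    for free, the query must be aligned end to end.
    """
    nq, nr = len(query), len(reference)
    prev = [0.0] * (nr + 1)  # skipping any reference prefix is free
    for i in range(1, nq + 1):
        cur = [prev[0] + gap]
        for j in range(1, nr + 1):
            diag = prev[j - 1] + (match if query[i - 1] == reference[j - 1] else mismatch)
            cur.append(max(diag, prev[j] + gap, cur[j - 1] + gap))
        prev = cur
    return max(prev)  # free reference suffix


def gower(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (d ** 2) @ J


def _design(meta, factors):
    cols = [np.ones(len(meta))]
    for f in factors:
        values = meta[f].to_numpy()
        for lv in list(dict.fromkeys(values))[1:]:
            cols.append((values == lv).astype(float))
    return np.column_stack(cols)


def brute_permanova(d: np.ndarray, meta, factors):
    """Sequential partition via explicit hat matrices and pinv projectors."""
    G = gower(d)
    n = d.shape[0]
    ss_total = np.trace(G)
    results = []
    H_prev = np.full((n, n), 1.0 / n)
    rank_prev = 1
    for k in range(1, len(factors) + 1):
        X = _design(meta, factors[:k])
        H = X @ np.linalg.pinv(X)
        rank = int(round(np.trace(H)))
        ss = np.trace((H - H_prev) @ G)
        results.append({"factor": factors[k - 1], "df": rank - rank_prev, "ss": ss})
        H_prev, rank_prev = H, rank
    ss_res = np.trace((np.eye(n) - H_prev) @ G)
    df_res = n - rank_prev
    for r in results:
        r["r2"] = r["ss"] / ss_total
        r["pseudo_f"] = (r["ss"] / r["df"]) / (ss_res / df_res) if r["df"] else np.nan
    return results, ss_res, df_res, ss_total


def exact_permutation_p(d: np.ndarray, meta, factor: str) -> float:
    """Permutation p for a one-factor model from full enumeration of sample
    orderings, with the +1 convention the sampled test uses."""
    n = d.shape[0]
    res, ss_res, df_res, _ = brute_permanova(d, meta, [factor])
    f_obs = res[0]["pseudo_f"]
    df = res[0]["df"]
    count = 0
    total = 0
    for p in itertools.permutations(range(n)):
        dp = d[np.ix_(p, p)]
        G = gower(dp)
        X = _design(meta, [factor])
        H = X @ np.linalg.pinv(X)
        H0 = np.full((n, n), 1.0 / n)
        ss = np.trace((H - H0) @ G)
        ssr = np.trace((np.eye(n) - H) @ G)
        f_p = (ss / df) / (ssr / df_res)
        count += f_p >= f_obs - 1e-12
        total += 1
    return count / total
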