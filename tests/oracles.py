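"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive (per-base sets, exhaustive window
enumeration) and share no code with the package's algorithms.
"""

from __future__ import annotations


def extended_base_union(probes, extend_bp):
    """Per-base set of all extended probe bases, keyed by chromosome."""
    bases: dict[str, set[int]] = {}
    for chrom, start, end in probes:
        s = bases.setdefault(chrom, set())
        s.update(range(max(0, start - extend_bp), end + extend_bp))
    return bases


def merge_bases_oracle(probes, extend_bp, merge_gap_lt):
    """Clusters by scanning the per-base union and joining runs with
    gap < merge_gap_lt.  Returns sorted (chrom, start, end) triples."""
    bases = extended_base_union(probes, extend_bp)
    out = []
    for chrom in sorted(bases):
        pos_sorted = sorted(bases[chrom])
        runs = []
        start = prev = pos_sorted[0]
        for p in pos_sorted[1:]:
            if p == prev + 1:
                prev = p
            else:
                runs.append((start, prev + 1))
                start = prev = p
        runs.append((start, prev + 1))
        merged = [runs[0]]
        for s, e in runs[1:]:
            if s - merged[-1][1] < merge_gap_lt:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        out.extend((chrom, s, e) for s, e in merged)
    return out


def window_enumeration_oracle(deltas, cutoff, min_cpgs):
    """Like :func:`maximal_run_dmrs_oracle` but scales to hundreds of CpGs.

    Enumerates every window with an O(1) qualification test via prefix
    counts of exceedances; a qualifying window is maximal iff neither
    one-step extension qualifies.  Still shares no logic with the
    single-pass scan in the package.
    """
    n = len(deltas)
    pref_hyper = [0]
    pref_hypo = [0]
    for d in deltas:
        pref_hyper.append(pref_hyper[-1] + (1 if d > cutoff else 0))
        pref_hypo.append(pref_hypo[-1] + (1 if d < -cutoff else 0))

    def full(pref, i, j):
        return pref[j] - pref[i] == j - i

    out = []
    for i in range(n):
        for j in range(i + min_cpgs, n + 1):
            any_full = False
            for pref, direction in ((pref_hyper, "hyper"), (pref_hypo, "hypo")):
                if not full(pref, i, j):
                    continue
                any_full = True
                left_ext = i > 0 and full(pref, i - 1, j)
                right_ext = j < n and full(pref, i, j + 1)
                if not left_ext and not right_ext:
                    out.append((i, j, direction))
            if not any_full:
                break  # a broken window never re-qualifies as j grows
    return sorted(out)


def maximal_run_dmrs_oracle(deltas, cutoff, min_cpgs):
    """All maximal sign-consistent exceedance windows in one cluster.

    Enumerates every window [i, j) of consecutive CpGs, tests the
    predicate (every delta strictly beyond the cutoff with one sign and
    length >= min_cpgs), and keeps windows not contained in any larger
    qualifying window.  Returns (start_index, end_index, direction).
    """
    n = len(deltas)

    def qualifies(i, j):
        if j - i < min_cpgs:
            return None
        if all(d > cutoff for d in deltas[i:j]):
            return "hyper"
        if all(d < -cutoff for d in deltas[i:j]):
            return "hypo"
        return None

    candidates = []
    for i in range(n):
        for j in range(i + min_cpgs, n + 1):
            direction = qualifies(i, j)
            if direction:
                candidates.append((i, j, direction))
    maximal = []
    for i, j, direction in candidates:
        contained = any(
            (i2 <= i and j <= j2) and (i2, j2) != (i, j)
            for i2, j2, d2 in candidates
            if d2 == direction
        )
        if not contained:
            maximal.append((i, j, direction))
    return sorted(maximal)
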