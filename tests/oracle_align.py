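"""Independent brute-force oracle for global affine-gap alignment scores.

Plain recursion over alignment moves with memoization on
(i, j, previous-move); shares no code with the production aligner.  A gap
of length L costs gap_open + (L - 1) * gap_extend; adjacent gaps in
opposite sequences each open their own gap.  With end_gap_policy "free",
gap columns before the first or after the last residue of the ungapped
sequence cost nothing.
"""

from functools import lru_cache

NEG_INF = float("-inf")


def brute_force_score(a: str, b: str, params) -> float:
    la, lb = len(a), len(b)
    free_ends = params.end_gap_policy == "free"

    def sub(x: str, y: str) -> float:
        if x == y and x != "N":
            return params.match_score
        return params.mismatch_score

    @lru_cache(maxsize=None)
    def go(i: int, j: int, state: str) -> float:
        if i == la and j == lb:
            return 0.0
        best = NEG_INF
        if i < la and j < lb:
            best = max(best, sub(a[i], b[j]) + go(i + 1, j + 1, "M"))
        if i < la:  # consume a residue of a against a gap in b
            if free_ends and (j == 0 or j == lb):
                cost = 0.0
            else:
                cost = params.gap_extend if state == "gb" else params.gap_open
            best = max(best, cost + go(i + 1, j, "gb"))
        if j < lb:  # consume a residue of b against a gap in a
            if free_ends and (i == 0 or i == la):
                cost = 0.0
            else:
                cost = params.gap_extend if state == "ga" else params.gap_open
            best = max(best, cost + go(i, j + 1, "ga"))
        return best

    result = go(0, 0, "M")
    go.cache_clear()
    return result
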