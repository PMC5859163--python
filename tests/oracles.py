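"""Independent brute-force oracles shared across test modules."""

import math


def oracle_sw(a, b, cfg):
    """Independent affine-gap local alignment: top-down memoised recursion."""
    import functools

    alpha = str(cfg.matrix.alphabet)
    sub = {
        (x, y): cfg.matrix[alpha.index(x), alpha.index(y)]
        for x in set(a) for y in set(b)
    }
    go, ge = -(cfg.gap_open + cfg.gap_extend), -cfg.gap_extend

    @functools.lru_cache(maxsize=None)
    def best(i, j, state):
        # best score of a local alignment ENDING at (i, j) in the given state
        if state == "M":
            if i == 0 or j == 0:
                return -math.inf
            prev = max(0.0, best(i - 1, j - 1, "M"), best(i - 1, j - 1, "X"),
                       best(i - 1, j - 1, "Y"))
            return prev + sub[(a[i - 1], b[j - 1])]
        if state == "X":  # gap in a (consumes b)
            if j == 0:
                return -math.inf
            h_prev = max(0.0, best(i, j - 1, "M"), best(i, j - 1, "X"),
                         best(i, j - 1, "Y"))
            return max(h_prev + go, best(i, j - 1, "X") + ge)
        if i == 0:
            return -math.inf
        h_prev = max(0.0, best(i - 1, j, "M"), best(i - 1, j, "X"),
                     best(i - 1, j, "Y"))
        return max(h_prev + go, best(i - 1, j, "Y") + ge)

    top = 0.0
    for i in range(len(a) + 1):
        for j in range(len(b) + 1):
            for s in "MXY":
                top = max(top, best(i, j, s))
    return top


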