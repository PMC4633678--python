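"""Independent brute-force oracles for the region metrics.

Everything here is computed straight from the definitions — explicit
enumeration over ordered pixel pairs and direct plug-in entropies — without
touching the package's contingency-table code paths, so it can serve as an
independent check of the sparse implementation on small images.
"""

import math
from collections import Counter

import numpy as np


def pair_probabilities(pred, truth, mask):
    """(P[same pred and same truth], P[same pred], P[same truth]) over all
    ordered in-mask pixel pairs (with replacement) — i.e. sum p_ij^2,
    sum s_i^2, sum t_j^2 by enumeration."""
    p = np.asarray(pred)[np.asarray(mask, dtype=bool)]
    t = np.asarray(truth)[np.asarray(mask, dtype=bool)]
    same_p = p[:, None] == p[None, :]
    same_t = t[:, None] == t[None, :]
    return (
        float((same_p & same_t).mean()),
        float(same_p.mean()),
        float(same_t.mean()),
    )


def rand_oracle(pred, truth, mask, alpha=0.5):
    """(split, merge, fscore) of the Rand family from pair enumeration.

    split is precision and merge recall in the classification of ordered
    pixel pairs as co-segmented.
    """
    both, s2, t2 = pair_probabilities(pred, truth, mask)
    return both / t2, both / s2, both / (alpha * s2 + (1.0 - alpha) * t2)


def info_quantities(pred, truth, mask, base=None):
    """(I, H_pred, H_truth) from direct plug-in sums over the joint label
    distribution of in-mask pixels."""
    p = np.asarray(pred)[np.asarray(mask, dtype=bool)]
    t = np.asarray(truth)[np.asarray(mask, dtype=bool)]
    n = len(p)
    log = math.log if base is None else (lambda x: math.log(x, base))

    def entropy(counter):
        return -sum((c / n) * log(c / n) for c in counter.values() if c)

    h_p = entropy(Counter(p.tolist()))
    h_t = entropy(Counter(t.tolist()))
    h_joint = entropy(Counter(zip(p.tolist(), t.tolist())))
    return h_p + h_t - h_joint, h_p, h_t


def info_oracle(pred, truth, mask, alpha=0.5, base=None):
    """(split, merge, fscore) of the information-theoretic family, for
    non-degenerate partitions (both entropies positive)."""
    mi, h_p, h_t = info_quantities(pred, truth, mask, base=base)
    return mi / h_p, mi / h_t, mi / ((1.0 - alpha) * h_p + alpha * h_t)
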