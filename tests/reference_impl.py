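"""Naive reference implementations, transcribed directly from the textbook
definitions of the procedures and from the set-level error definitions.

These are deliberately written as plain loops, independent of the package's
vectorized code paths, and serve as oracles in the tests.
"""

import numpy as np


def bh_reference(p, alpha):
    """Benjamini-Hochberg step-up: reject the R smallest p-values where
    R = max{k : p_(k) <= k*alpha/m}."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    R = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            R = k
    rejected = [False] * m
    for k in range(R):
        rejected[order[k]] = True
    return np.array(rejected), R


def bonferroni_reference(p, level):
    """Reject every p_j <= level / n."""
    n = len(p)
    return np.array([pj <= level / n for pj in p])


def holm_reference(p, level):
    """Holm step-down: walk the sorted p-values, stop at the first failure."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    rejected = [False] * n
    for j, idx in enumerate(order, start=1):
        if p[idx] <= level / (n + 1 - j):
            rejected[idx] = True
        else:
            break
    return np.array(rejected)


def hochberg_reference(p, level):
    """Hochberg step-up: find the largest j with p_(j) <= level/(n+1-j) and
    reject the j smallest p-values."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    r = 0
    for j in range(1, n + 1):
        if p[order[j - 1]] <= level / (n + 1 - j):
            r = j
    rejected = [False] * n
    for j in range(r):
        rejected[order[j]] = True
    return np.array(rejected)


def count_errors_reference(set_rejected, individual_rejected, direction, false_null, true_sign):
    """Literal recount of (R, V, S) from the set-level error definitions.

    A rejected set is falsely rejected (V) if any true null in it — the
    screening null included — is rejected.  A correctly rejected set is in S
    if any of its rejected false nulls carries a wrong declared direction.
    """
    R = V = S = 0
    for i in range(len(set_rejected)):
        if not set_rejected[i]:
            continue
        R += 1
        any_false_individual_null = any(false_null[i])
        true_null_rejected = any(
            individual_rejected[i][j] and not false_null[i][j]
            for j in range(len(false_null[i]))
        )
        if not any_false_individual_null or true_null_rejected:
            V += 1
            continue
        directional_error = any(
            individual_rejected[i][j]
            and false_null[i][j]
            and direction[i][j] != true_sign[i][j]
            for j in range(len(false_null[i]))
        )
        if directional_error:
            S += 1
    return R, V, S
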