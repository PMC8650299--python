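"""Independent reference implementations used only to check the package.

Each oracle is a literal, unvectorized transcription of the defining
formula, deliberately sharing no code with the implementation under test.
"""

import math

import numpy as np


def loglik_double_loop(beta, times, events, x, weights):
    """Weighted Breslow partial log-likelihood via nested loops."""
    n = len(times)
    total = 0.0
    for i in range(n):
        if events[i] == 1 and weights[i] > 0:
            denom = 0.0
            for k in range(n):
                if times[i] <= times[k]:
                    denom += weights[k] * math.exp(float(np.dot(beta, x[k])))
            total += weights[i] * (float(np.dot(beta, x[i])) - math.log(denom))
    return total


def cindex_pair_count(times, events, scores):
    """Harrell C-index by exhaustive enumeration of usable pairs.

    A pair (i, j) is usable iff patient i has an event and t_j > t_i
    strictly; concordance means the earlier-failing patient has the higher
    risk score, with score ties counting 1/2.
    """
    n = len(times)
    n_usable = 0
    concordant = 0.0
    for i in range(n):
        if events[i] != 1:
            continue
        for j in range(n):
            if times[j] > times[i]:
                n_usable += 1
                if scores[j] < scores[i]:
                    concordant += 1.0
                elif scores[j] == scores[i]:
                    concordant += 0.5
    if n_usable == 0:
        raise ValueError("no usable pairs")
    return concordant / n_usable


def auc_pair_count(labels, scores):
    """ROC AUC as the Mann-Whitney pair statistic (ties count 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    if not pos or not neg:
        raise ValueError("both classes required")
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))
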