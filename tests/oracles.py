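"""Independently coded reference implementations used to cross-check the package.

These deliberately re-derive each quantity from first principles (explicit
case analysis, exhaustive pair enumeration, literal one-vs-rest tallies)
and share no code with the implementation under test.
"""

import itertools
import math

from signflow.decision import DirectionCall


def fuse_oracle(f_ab: float, f_ba: float, epsilon: float) -> DirectionCall:
    """Literal case analysis of the score-fusion rule."""
    ab_neg = f_ab < 0
    ba_neg = f_ba < 0
    if not ab_neg and ba_neg:
        return DirectionCall.A_TO_B
    if ab_neg and not ba_neg:
        return DirectionCall.B_TO_A
    if not ab_neg and not ba_neg:
        # both non-negative
        if f_ab == f_ba:
            return DirectionCall.BIDIRECTIONAL
        diff = f_ab - f_ba
        if diff > epsilon:
            return DirectionCall.A_TO_B
        if -diff > epsilon:
            return DirectionCall.B_TO_A
        return DirectionCall.BIDIRECTIONAL
    # both negative: smaller |score| is "less incredible"
    m_ab, m_ba = -f_ab, -f_ba
    if m_ba - m_ab > epsilon:
        return DirectionCall.A_TO_B
    if m_ab - m_ba > epsilon:
        return DirectionCall.B_TO_A
    return DirectionCall.UNDETERMINED


def encode_oracle(up_domains, down_domains, vocab_domains):
    """Dense feature vector by direct application of the membership rules."""
    vec = []
    for d in vocab_domains:
        in_up = d in up_domains
        in_down = d in down_domains
        if in_up and in_down:
            vec.append(2)
        elif in_up:
            vec.append(1)
        elif in_down:
            vec.append(-1)
        else:
            vec.append(0)
    return vec


def is_null_oracle(up_domains, down_domains, vocab_domains):
    vocab = set(vocab_domains)
    return not (set(up_domains) & vocab) or not (set(down_domains) & vocab)


def confusion_oracle(y_true, scores, threshold=0.0):
    """2x2 tally, label order (+1, -1), predicted +1 iff score >= threshold."""
    m = [[0, 0], [0, 0]]
    order = {1: 0, -1: 1}
    for label, score in zip(y_true, scores):
        pred = 1 if score >= threshold else -1
        m[order[label]][order[pred]] += 1
    return m


def binary_metrics_oracle(m):
    """(per-label SP/SE/MCC dict, accuracy, MCC, F1) from a 2x2 nested list."""
    tp, fn = m[0][0], m[0][1]
    fp, tn = m[1][0], m[1][1]
    total = tp + fn + fp + tn

    def safe(num, den):
        return num / den if den else 0.0

    per_label = {}
    for label, (tp_l, fn_l, fp_l, tn_l) in {
        1: (tp, fn, fp, tn),
        -1: (tn, fp, fn, tp),
    }.items():
        se = safe(tp_l, tp_l + fn_l)
        sp = safe(tn_l, tn_l + fp_l)
        den = math.sqrt((tp_l + fp_l) * (tp_l + fn_l) * (tn_l + fp_l) * (tn_l + fn_l))
        mcc = safe(tp_l * tn_l - fp_l * fn_l, den)
        per_label[label] = {"SP": sp, "SE": se, "MCC": mcc}

    accuracy = safe(tp + tn, total)
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = safe(tp * tn - fp * fn, den)
    precision = safe(tp, tp + fp)
    recall = safe(tp, tp + fn)
    f1 = safe(2 * precision * recall, precision + recall)
    return per_label, accuracy, mcc, f1


def auc_oracle(y_true, scores):
    """Mann-Whitney: fraction of (pos, neg) pairs ordered correctly, ties 0.5."""
    pos = [s for y, s in zip(y_true, scores) if y == 1]
    neg = [s for y, s in zip(y_true, scores) if y == -1]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        if p > n:
            total += 1.0
        elif p == n:
            total += 0.5
    return total / (len(pos) * len(neg))
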