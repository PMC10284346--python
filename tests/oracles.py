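"""Independent brute-force oracles used by the tests.

Deliberately written in plain Python loops, sharing no code path with
the package: direct summation for the encoding, all-pairs counting for
auROC, naive tallies for confusion counts.
"""

import math

AA = "ACDEFGHIKLMNPQRSTVWY"


def standardize_oracle(raw_rows):
    """raw_rows: list of 20-value lists -> standardized dicts aa->value."""
    out = []
    for vals in raw_rows:
        mu = sum(vals) / 20.0
        sd = math.sqrt(sum((v - mu) ** 2 for v in vals) / 20.0)
        out.append({aa: (v - mu) / sd for aa, v in zip(AA, vals)})
    return out


def aac_oracle(seq):
    return [seq.count(aa) / len(seq) for aa in AA]


def theta_oracle(seq, tau, H):
    """H: list of dicts aa->standardized value."""
    total = 0.0
    for i in range(len(seq) - tau):
        a, b = seq[i], seq[i + tau]
        total += sum((h[b] - h[a]) ** 2 for h in H) / len(H)
    return total / (len(seq) - tau)


def pseaac_oracle(seq, lam, weight, H):
    f = aac_oracle(seq)
    thetas = [theta_oracle(seq, t, H) for t in range(1, lam + 1)]
    denom = 1.0 + weight * sum(thetas)
    return [x / denom for x in f] + [weight * t / denom for t in thetas]


def auroc_oracle(y_true, scores):
    """All-pairs Mann–Whitney count, ties = 0.5."""
    pos = [s for y, s in zip(y_true, scores) if y == 1]
    neg = [s for y, s in zip(y_true, scores) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def confusion_oracle(y_true, y_pred):
    tp = fn = fp = tn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 1 and p == 0:
            fn += 1
        elif t == 0 and p == 1:
            fp += 1
        else:
            tn += 1
    return tp, fn, fp, tn
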