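"""Independent brute-force reference implementations used only by tests.

These deliberately use plain Python loops and dict counting, sharing no
code path with the package's vectorized implementations.
"""

from itertools import product

AA = "ACDEFGHIKLMNPQRSTVWY"
GROUPS = {"G1": "GAVLMI", "G2": "FYW", "G3": "KRH", "G4": "DE", "G5": "STCPNQ"}


def naive_aac(seq):
    return [seq.count(a) / len(seq) for a in AA]


def naive_dpc(seq):
    out = []
    for r in AA:
        for s in AA:
            n = sum(1 for i in range(len(seq) - 1) if seq[i] == r and seq[i + 1] == s)
            out.append(n / (len(seq) - 1))
    return out


def _group_of(residue):
    for label, members in GROUPS.items():
        if residue in members:
            return label
    raise ValueError(residue)


def naive_cksaagp(seq, kmax=5):
    out = []
    labels = list(GROUPS)
    for k in range(kmax + 1):
        denom = len(seq) - k - 1
        for gi, gj in product(labels, labels):
            n = sum(
                1
                for p in range(len(seq) - k - 1)
                if _group_of(seq[p]) == gi and _group_of(seq[p + k + 1]) == gj
            )
            out.append(n / denom)
    return out


def naive_confusion(labels, scores, threshold=0.5):
    tp = tn = fp = fn = 0
    for y, s in zip(labels, scores):
        called_pos = s > threshold
        if y == 1 and called_pos:
            tp += 1
        elif y == 0 and not called_pos:
            tn += 1
        elif y == 0 and called_pos:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def naive_auc(labels, scores):
    """Mann-Whitney pair statistic: P(score_pos > score_neg), ties half."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    if not pos or not neg:
        return float("nan")
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
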