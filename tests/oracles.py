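"""Independent brute-force oracles used to validate the vectorized encoders
and metric implementations.  Deliberately naive: plain Python loops and
dictionaries, sharing no code with the package internals."""

from __future__ import annotations

import itertools
import math

NUCS = "ACGU"
DINUCS = [a + b for a in NUCS for b in NUCS]


def naive_knf(window: str, K: int) -> list[float]:
    L = len(window)
    counts = {"".join(p): 0 for p in itertools.product(NUCS, repeat=K)}
    for i in range(L - K + 1):
        kmer = window[i : i + K]
        if "N" not in kmer:
            counts[kmer] += 1
    return [counts["".join(p)] / (L - K + 1) for p in itertools.product(NUCS, repeat=K)]


def naive_ksnpf(window: str, K: int, denominator: str = "window") -> list[float]:
    L = len(window)
    counts = {d: 0 for d in DINUCS}
    for i in range(L - K - 1):
        a, b = window[i], window[i + K + 1]
        if a != "N" and b != "N":
            counts[a + b] += 1
    den = (L - K + 1) if denominator == "window" else (L - K - 1)
    return [counts[d] / den for d in DINUCS]


def naive_position_freqs(windows: list[str]) -> list[dict[str, float]]:
    L = len(windows[0])
    out = []
    for i in range(L):
        col = [w[i] for w in windows]
        valid = [c for c in col if c != "N"]
        freq = {n: (valid.count(n) / len(valid) if valid else 0.0) for n in NUCS}
        out.append(freq)
    return out


def naive_psnp_matrix(pos_windows: list[str], neg_windows: list[str]):
    fp = naive_position_freqs(pos_windows)
    fn = naive_position_freqs(neg_windows)
    return [[fp[i][n] - fn[i][n] for i in range(len(fp))] for n in NUCS]


def naive_gapped_freqs(windows: list[str], K: int) -> list[dict[str, float]]:
    L = len(windows[0])
    out = []
    for i in range(L - K - 1):
        pairs = [w[i] + w[i + K + 1] for w in windows]
        valid = [p for p in pairs if "N" not in p]
        out.append({d: (valid.count(d) / len(valid) if valid else 0.0) for d in DINUCS})
    return out


def naive_kspsdp_matrix(pos_windows, neg_windows, K: int):
    fp = naive_gapped_freqs(pos_windows, K)
    fn = naive_gapped_freqs(neg_windows, K)
    return [[fp[i][d] - fn[i][d] for i in range(len(fp))] for d in DINUCS]


def naive_encode_psnp(window: str, matrix) -> list[float]:
    out = []
    for i, c in enumerate(window):
        out.append(matrix[NUCS.index(c)][i] if c != "N" else 0.0)
    return out


def naive_encode_kspsdp(window: str, matrix, K: int) -> list[float]:
    out = []
    for i in range(len(window) - K - 1):
        pair = window[i] + window[i + K + 1]
        out.append(matrix[DINUCS.index(pair)][i] if "N" not in pair else 0.0)
    return out


def naive_psednc(window: str, lambda_pse: int, w: float, norm_props: dict) -> list[float]:
    """norm_props: dinucleotide -> list of 3 z-scored property values."""
    L = len(window)
    dinucs = [window[i : i + 2] for i in range(L - 1)]
    valid = [d for d in dinucs if "N" not in d]
    freqs = [(valid.count(d) / len(valid) if valid else 0.0) for d in DINUCS]
    thetas = []
    for j in range(1, lambda_pse + 1):
        terms = []
        for i in range(L - 1 - j):
            d1, d2 = dinucs[i], dinucs[i + j]
            if "N" in d1 or "N" in d2:
                continue
            p1, p2 = norm_props[d1], norm_props[d2]
            terms.append(sum((a - b) ** 2 for a, b in zip(p1, p2)) / 3.0)
        thetas.append(sum(terms) / len(terms) if terms else 0.0)
    denom = sum(freqs) + w * sum(thetas)
    if denom == 0:
        return [0.0] * (16 + lambda_pse)
    return [f / denom for f in freqs] + [w * t / denom for t in thetas]


_CHEM = {"A": (1, 1, 1), "U": (0, 0, 1), "G": (0, 1, 0), "C": (1, 0, 0), "N": (0, 0, 0)}


def naive_cpd(window: str) -> list[float]:
    out = []
    for i, c in enumerate(window, start=1):
        x, y, z = _CHEM[c]
        if c == "N":
            d = 0.0
        else:
            d = window[:i].count(c) / i
        out.extend([x, y, z, d])
    return out


def naive_confusion(scores, labels, threshold):
    tp = tn = fp = fn = 0
    for s, y in zip(scores, labels):
        if s >= threshold:
            if y == 1:
                tp += 1
            else:
                fp += 1
        else:
            if y == 1:
                fn += 1
            else:
                tn += 1
    return tp, tn, fp, fn


def naive_metrics(tp, tn, fp, fn):
    def safe(num, den):
        return num / den if den else 0.0

    return {
        "Sn": safe(tp, tp + fn),
        "Sp": safe(tn, tn + fp),
        "Pre": safe(tp, tp + fp),
        "Acc": (tp + tn) / (tp + tn + fp + fn),
        "Mcc": safe(
            tp * tn - fp * fn,
            math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)),
        ),
        "F1": safe(2 * tp, 2 * tp + fp + fn),
    }


def rank_auroc(scores, labels) -> float:
    """Tie-corrected Mann-Whitney AUROC: P(S+ > S-) + 0.5 P(S+ = S-)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def exhaustive_auprc(scores, labels) -> float:
    """Step-wise AP by sweeping every distinct score as a threshold."""
    order = sorted(set(scores), reverse=True)
    n_pos = sum(labels)
    area = 0.0
    prev_recall = 0.0
    for t in order:
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        pp = sum(1 for s in scores if s >= t)
        recall = tp / n_pos
        precision = tp / pp if pp else 0.0
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area
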