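"""Independent brute-force oracles used only by the test suite.

Each oracle is deliberately written from first principles (plain loops,
textbook formulas) so it shares no code path with the implementation it
checks.
"""

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def bs_mismatches_oracle(read: str, window: str) -> int:
    mm = 0
    for r, w in zip(read, window):
        if r == "N" or w == "N":
            mm += 1
        elif r == w:
            pass
        elif w == "C" and r == "T":
            pass
        else:
            mm += 1
    return mm


def brute_force_align(read: str, contigs: dict[str, str], max_mismatch: int):
    """Double-loop scan over every offset of both strands of every contig.

    Returns (outcome_class, locus, mismatches) where locus is
    (contig, genomic_start, strand) for unique hits.  The inner loop
    abandons a window as soon as it exceeds the mismatch ceiling, which
    cannot change the outcome (windows above the ceiling never matter).
    """
    L = len(read)
    best = max_mismatch + 1
    hits = []
    for name, seq in contigs.items():
        for o in range(len(seq) - L + 1):
            window = seq[o : o + L]
            # forward strand
            mm = 0
            for r, w in zip(read, window):
                if not (r == w or (w == "C" and r == "T")) or r == "N" or w == "N":
                    mm += 1
                    if mm > max_mismatch:
                        break
            if mm < best:
                best, hits = mm, [(name, o, "+")]
            elif mm == best:
                hits.append((name, o, "+"))
            # reverse strand: compare read against rc(window) lazily
            mm = 0
            for i in range(L):
                r = read[i]
                w = _COMP[window[L - 1 - i]]
                if not (r == w or (w == "C" and r == "T")) or r == "N" or w == "N":
                    mm += 1
                    if mm > max_mismatch:
                        break
            if mm < best:
                best, hits = mm, [(name, o, "-")]
            elif mm == best:
                hits.append((name, o, "-"))
    if best > max_mismatch:
        return ("unaligned", None, best)
    if len(hits) > 1:
        return ("ambiguous", None, best)
    return ("unique", hits[0], best)


def trim_oracle(read: str, adapter: str, stringency: int, error_rate: float,
                min_length: int):
    """Exhaustive scan over every read-suffix / adapter-prefix overlap."""
    n = len(read)
    candidates = []
    for i in range(n):
        overlap = min(n - i, len(adapter))
        if overlap < stringency:
            continue
        mm = sum(
            1 for a, b in zip(read[i : i + overlap], adapter[:overlap]) if a != b
        )
        if mm <= math.floor(error_rate * overlap):
            candidates.append(i)
    cut = min(candidates) if candidates else n
    trimmed = read[:cut]
    return trimmed if len(trimmed) >= min_length else None


def welch_oracle(a, b):
    """Textbook Welch formula computed with plain floats."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sa, sb = va / na, vb / nb
    t = (ma - mb) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    from scipy.special import stdtr  # t CDF only; not the tested code path

    p = 2.0 * stdtr(df, -abs(t))  # lower tail at -|t| avoids cancellation
    return t, df, p


def bh_oracle(pvalues):
    """Benjamini-Hochberg step-up by direct enumeration of the definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvalues[i] * m / rank)
        adj[i] = val
        prev = val
    return adj
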