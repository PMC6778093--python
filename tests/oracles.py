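"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain loops straight from the method
definitions, with no code shared with the package, so that agreement is
a genuine cross-check.  Window sums use left-to-right accumulation over
the same float64 values, which for the small windows involved matches
the package's arithmetic bit for bit on integer-valued coverage.
"""

from itertools import combinations
from math import comb


# ---------------------------------------------------------------------------
# peak caller
# ---------------------------------------------------------------------------

def _mean(v, a, b):
    """Mean of 1-based inclusive slice [a, b]."""
    total = 0.0
    for i in range(a, b + 1):
        total += float(v[i - 1])
    return total / (b - a + 1)


def brute_boundaries(values, w, s, f, eps):
    """All collapsed boundary candidates, [(position, kind, fold), ...]."""
    L = len(values)
    if L < 2 * w + s:
        return []
    raw = {"start": [], "end": []}
    for i in range(1, L + 1):
        if i - s - w >= 1 and i + w - 1 <= L:
            hi = _mean(values, i, i + w - 1)
            up = _mean(values, i - s - w, i - s - 1)
            fold = (hi + eps) / (up + eps)
            if fold >= f:
                raw["start"].append((i, fold))
        if i - w + 1 >= 1 and i + s + w <= L:
            hi = _mean(values, i - w + 1, i)
            low = _mean(values, i + s + 1, i + s + w)
            fold = (hi + eps) / (low + eps)
            if fold >= f:
                raw["end"].append((i, fold))
    out = []
    for kind, entries in raw.items():
        run = []
        for pos, fold in entries:
            if run and pos != run[-1][0] + 1:
                out.append(_pick(run, kind))
                run = []
            run.append((pos, fold))
        if run:
            out.append(_pick(run, kind))
    out.sort(key=lambda c: (c[0], 0 if c[1] == "start" else 1))
    return out


def _pick(run, kind):
    best_fold = max(fold for _, fold in run)
    if kind == "start":
        pos = next(p for p, fold in run if fold == best_fold)
    else:
        pos = next(p for p, fold in reversed(run) if fold == best_fold)
    return (pos, kind, best_fold)


def brute_pair(candidates, track_length, min_peak_len=1, close_open=False):
    intervals = []
    open_start = None
    for pos, kind, _ in candidates:
        if kind == "start":
            if open_start is None:
                open_start = pos
        elif open_start is not None and pos >= open_start:
            intervals.append((open_start, pos))
            open_start = None
    if open_start is not None and close_open:
        intervals.append((open_start, track_length))
    return [(a, b) for a, b in intervals if b - a + 1 >= min_peak_len]


def brute_call_peaks(values, companion_values_list, w=5, s=10, f=1.5, c=0.2,
                     eps=0.1, min_peak_len=1, close_open=False):
    """Full brute-force peak call: [(start, end, mean_coverage), ...]."""
    cands = brute_boundaries(values, w, s, f, eps)
    intervals = brute_pair(cands, len(values), min_peak_len, close_open)
    all_tracks = [values] + list(companion_values_list)
    total = 0.0
    n_pos = 0
    for tv in all_tracks:
        for x in tv:
            total += float(x)
        n_pos += len(tv)
    threshold = c * (total / n_pos)
    return [
        (a, b, _mean(values, a, b))
        for a, b in intervals
        if _mean(values, a, b) >= threshold
    ]


# ---------------------------------------------------------------------------
# annotation classifier
# ---------------------------------------------------------------------------

def brute_classify(peak_start, peak_end, peak_strand, features):
    """features: (feature_id, kind, strand, start, end); returns
    (category, feature_id, overlap) with 'intergenic' when nothing overlaps."""
    precedence = {"five_prime_UTR": 0, "three_prime_UTR": 1, "RNA_gene": 2, "CDS": 3}
    base = {"CDS": "CDS", "RNA_gene": "RNA",
            "five_prime_UTR": "5UTR", "three_prime_UTR": "3UTR"}
    hits = []
    for fid, kind, strand, start, end in features:
        ov = min(peak_end, end) - max(peak_start, start) + 1
        if ov > 0:
            hits.append((-ov, precedence[kind], end - start + 1, fid, kind, strand, ov))
    if not hits:
        return ("intergenic", None, 0)
    hits.sort()
    _, _, _, fid, kind, strand, ov = hits[0]
    cat = base[kind]
    if strand != peak_strand:
        cat = "as" + cat
    return (cat, fid, ov)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def hypergeom_tail_by_enumeration(N, K, n, k):
    """P[X >= k] by enumerating all C(N, n) target draws (N small)."""
    in_cat = set(range(K))
    hits = sum(
        1 for draw in combinations(range(N), n) if len(in_cat & set(draw)) >= k
    )
    return hits / comb(N, n)


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        r = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = r
        i = j + 1
    return ranks


def kw_H_direct(groups):
    """Tie-corrected Kruskal-Wallis H computed from the textbook formula."""
    pooled = [x for g in groups for x in g]
    N = len(pooled)
    ranks = _midranks(pooled)
    offset = 0
    acc = 0.0
    for g in groups:
        R = sum(ranks[offset : offset + len(g)])
        acc += R * R / len(g)
        offset += len(g)
    H = 12.0 / (N * (N + 1)) * acc - 3.0 * (N + 1)
    ties = {}
    for x in pooled:
        ties[x] = ties.get(x, 0) + 1
    tie_term = sum(t**3 - t for t in ties.values()) / (N**3 - N)
    if tie_term >= 1.0:
        return 0.0
    return H / (1.0 - tie_term)


def kw_permutation_p(group_a, group_b):
    """Exact two-group permutation p for H by enumerating all splits."""
    pooled = list(group_a) + list(group_b)
    na = len(group_a)
    H_obs = kw_H_direct([group_a, group_b])
    count = total = 0
    idx = range(len(pooled))
    for pick in combinations(idx, na):
        a = [pooled[i] for i in pick]
        b = [pooled[i] for i in idx if i not in pick]
        total += 1
        if kw_H_direct([a, b]) >= H_obs - 1e-12:
            count += 1
    return count / total
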