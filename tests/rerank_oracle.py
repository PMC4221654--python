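"""Independent step-by-step transcription of the re-ranking procedure.

Written directly from the procedure's verbal description (sort, removal
pass, addition pass, LIFO backfill with constant denominator K), with no
shared code or data structures with the package implementation: type-pair
counts are re-tallied from scratch by scanning the current top-set at every
decision.  Used as the oracle in equivalence tests.
"""


def _tally(top, a1, a2):
    key = frozenset_pair(a1, a2)
    return sum(1 for p in top if frozenset_pair(p[3], p[4]) == key)


def frozenset_pair(a1, a2):
    return (a1, a2) if a1 <= a2 else (a2, a1)


def rerank_oracle(scored, sequence, class_values, k, mode="fp"):
    """Return the final ordered (i, j) list.

    ``scored`` is a list of (i, j, score); ``class_values`` maps sorted type
    pairs to class-level f_p (or f_pn) values; missing pairs count as 0.
    """
    if mode == "fpn":
        counts = {}
        for c in sequence:
            if c != "X":
                counts[c] = counts.get(c, 0) + 1
        total = sum(counts.values())
        freq = {a: c / total for a, c in counts.items()}

    def value(jc, a1, a2):
        v = jc / k
        if mode == "fpn":
            v = v / (freq[a1] * freq[a2])
        return v

    pairs = []
    for i, j, s in scored:
        lo, hi = (i, j) if i < j else (j, i)
        pairs.append((lo, hi, s, sequence[lo - 1], sequence[hi - 1]))
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    top = pairs[:k]
    rest = pairs[k:]
    rmv = []

    # removal pass: lowest score first, counts re-tallied after every move
    for p in sorted(top, key=lambda p: (p[2], -p[0], -p[1])):
        a1, a2 = p[3], p[4]
        if "X" in (a1, a2):
            continue
        target = class_values.get(frozenset_pair(a1, a2), 0.0)
        jc_inc = _tally(top, a1, a2)  # p itself is in top
        jc_exc = jc_inc - 1
        if abs(value(jc_inc, a1, a2) - target) > abs(value(jc_exc, a1, a2) - target):
            top = [q for q in top if q is not p]
            rmv.append(p)

    # addition pass: highest score first
    for p in rest:
        if len(top) == k:
            break
        a1, a2 = p[3], p[4]
        if "X" in (a1, a2):
            continue
        target = class_values.get(frozenset_pair(a1, a2), 0.0)
        jc_exc = _tally(top, a1, a2)
        jc_inc = jc_exc + 1
        if not (
            abs(value(jc_inc, a1, a2) - target) > abs(value(jc_exc, a1, a2) - target)
        ):
            top = top + [p]

    # backfill: latest-removed first
    while len(top) < k and rmv:
        top = top + [rmv.pop()]

    return [(p[0], p[1]) for p in top]
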