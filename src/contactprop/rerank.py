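"""Propensity-guided re-ranking of per-pair contact scores.

Post-processes an externally produced score table (e.g. direct information
from direct coupling analysis) so that the composition of the K top-ranked
residue pairs better matches the pair contact frequencies (f_p, or their
normalized form f_pn) of the domain's structural class:

1. Pairs are sorted by score (descending); the best K form the *top-set*,
   the remainder the *rest-set*.
2. Removal pass — walking the top-set from the lowest score upward, a pair
   is moved to the *rmv-set* when the top-set's empirical pair frequency for
   its type pair is closer to the class value without it than with it.
3. Addition pass — walking the rest-set from the highest score downward, a
   pair is appended to the top-set when including it brings the empirical
   frequency closer to the class value; the pass stops once the top-set
   holds K pairs.
4. Backfill — if the top-set is still short of K, removed pairs return from
   the rmv-set, latest-removed first, appended at the end.

The empirical frequency always uses the constant denominator K (the final
set must again hold exactly K pairs), and pairs containing an 'X' residue
are never examined or moved.  In f_pn mode the empirical frequency is
additionally divided by the product of the two types' occurrence
frequencies *within the domain*.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .propensity import PairKey, pair_key
from .structures_io import ALLOWED_AA

KEPT = "kept"
ADDED = "added"
BACKFILLED = "backfilled"


@dataclass(frozen=True)
class ScoredPair:
    """A residue pair with its prediction score and amino-acid types."""

    i: int
    j: int
    score: float
    a1: str
    a2: str

    @property
    def types(self) -> PairKey:
        return pair_key(self.a1, self.a2)

    @property
    def has_x(self) -> bool:
        return "X" in (self.a1, self.a2)


@dataclass
class RerankResult:
    """Final ordered top-set with provenance, plus the residual sets."""

    top_set: list[ScoredPair]
    provenance: list[str]  # kept / added / backfilled, aligned with top_set
    rest_set: list[ScoredPair]
    rmv_set: list[ScoredPair]
    k: int

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [(p.i, p.j) for p in self.top_set]


def compute_domain_pair_fp(
    top_set: Sequence[ScoredPair], pair: ScoredPair, k: int, include: bool
) -> float:
    """Empirical top-set frequency Jc/K of the pair's type pair.

    ``include=True`` counts the candidate pair itself as a member of the
    top-set (whether or not it currently is one); ``include=False`` counts
    only the other members.  The denominator is always K.
    """
    if pair.has_x:
        raise ValueError("pairs containing 'X' are not evaluated")
    key = pair.types
    jc = sum(1 for p in top_set if p.types == key and p is not pair)
    if include:
        jc += 1
    return jc / k


def compute_domain_pair_fpn(
    top_set: Sequence[ScoredPair],
    pair: ScoredPair,
    k: int,
    domain_frequencies: Mapping[str, float],
    include: bool,
) -> float:
    """f_pn analogue of :func:`compute_domain_pair_fp`: (Jc/K)/(f_a1·f_a2)."""
    f1 = domain_frequencies.get(pair.a1, 0.0)
    f2 = domain_frequencies.get(pair.a2, 0.0)
    if f1 <= 0 or f2 <= 0:
        raise ValueError(
            f"zero domain frequency for pair types {pair.types}; "
            "cannot normalize"
        )
    return compute_domain_pair_fp(top_set, pair, k, include) / (f1 * f2)


def make_scored_pairs(
    scored: Sequence[tuple[int, int, float]], sequence: str
) -> list[ScoredPair]:
    """Attach amino-acid types from a 1-based sequence to (i, j, score) rows."""
    out = []
    seen: set[tuple[int, int]] = set()
    for i, j, s in scored:
        if i == j:
            raise ValueError(f"self-pair ({i},{j}) in score list")
        lo, hi = (i, j) if i < j else (j, i)
        if (lo, hi) in seen:
            raise ValueError(f"duplicate pair ({lo},{hi}) in score list")
        seen.add((lo, hi))
        if not (1 <= lo and hi <= len(sequence)):
            raise ValueError(
                f"pair ({lo},{hi}) outside sequence of length {len(sequence)}"
            )
        a1, a2 = sequence[lo - 1], sequence[hi - 1]
        if a1 not in ALLOWED_AA or a2 not in ALLOWED_AA:
            raise ValueError(f"unknown residue type in pair ({lo},{hi})")
        out.append(ScoredPair(lo, hi, float(s), a1, a2))
    return out


def domain_frequencies(sequence: str) -> dict[str, float]:
    """Occurrence frequency of each standard type within one domain sequence.

    'X' is excluded from numerator and denominator, as in the class-level
    frequencies.
    """
    counts = Counter(c for c in sequence if c != "X")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence contains no standard amino acids")
    return {a: c / total for a, c in counts.items()}


def rerank(
    scored_pairs: Sequence[tuple[int, int, float]] | Sequence[ScoredPair],
    sequence: str,
    class_table: Mapping[PairKey, float],
    mode: str = "fp",
    k: int = 200,
    frozen_removal_counts: bool = False,
) -> RerankResult:
    """Re-rank scored pairs toward a class's pair-frequency statistics.

    Parameters
    ----------
    scored_pairs
        ``(i, j, score)`` triples (1-based residue indices) or ready
        :class:`ScoredPair` objects.  Must be free of duplicates.
    sequence
        The domain's amino-acid sequence, used for pair types and, in f_pn
        mode, for the domain occurrence frequencies.
    class_table
        Class-level f_p (mode ``"fp"``) or f_pn (mode ``"fpn"``) values
        keyed by canonical unordered type pair; missing pairs read as 0.
    k
        Target top-set size; the empirical frequency denominator stays K
        even while the top-set is smaller.
    frozen_removal_counts
        Sensitivity-analysis variant: removal-pass decisions use the type
        counts frozen at the start of the pass instead of updating after
        each removal.

    Returns an ordered top-set of ``min(k, len(scored_pairs))`` pairs:
    retained pairs first in descending score order, then accepted rest-set
    pairs in acceptance order, then backfilled pairs.
    """
    if mode not in ("fp", "fpn"):
        raise ValueError(f"mode must be 'fp' or 'fpn', got {mode!r}")
    if class_table is None:
        raise ValueError("a class table is required (unassigned domains are skipped)")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if scored_pairs and isinstance(scored_pairs[0], ScoredPair):
        pairs = list(scored_pairs)  # type: ignore[arg-type]
    else:
        pairs = make_scored_pairs(scored_pairs, sequence)  # type: ignore[arg-type]

    freqs = domain_frequencies(sequence) if mode == "fpn" else None

    def empirical(jc_count: int, p: ScoredPair) -> float:
        value = jc_count / k
        if mode == "fpn":
            assert freqs is not None
            f1 = freqs.get(p.a1, 0.0)
            f2 = freqs.get(p.a2, 0.0)
            if f1 <= 0 or f2 <= 0:
                raise ValueError(
                    f"zero domain frequency for pair types {p.types}"
                )
            value /= f1 * f2
        return value

    # Partition: descending score, ties broken by (i, j) for determinism.
    order = sorted(pairs, key=lambda p: (-p.score, p.i, p.j))
    if k > len(order):
        warnings.warn(
            f"k = {k} exceeds the {len(order)} available pairs; "
            "top-set is the full input"
        )
    top: list[ScoredPair] = order[:k]
    rest: list[ScoredPair] = order[k:]
    rmv: list[ScoredPair] = []

    jc: Counter = Counter(p.types for p in top)

    # Removal pass: lowest score upward through the (initial) top-set.
    frozen = Counter(jc) if frozen_removal_counts else None
    for p in list(reversed(top)):
        if p.has_x:
            continue
        counts = frozen if frozen is not None else jc
        n_inc = counts[p.types]  # p currently counted in the top-set
        target = class_table.get(p.types, 0.0)
        if abs(empirical(n_inc, p) - target) > abs(empirical(n_inc - 1, p) - target):
            top.remove(p)
            rmv.append(p)
            jc[p.types] -= 1

    kept = set(id(p) for p in top)

    # Addition pass: highest score downward through the rest-set.
    remaining_rest: list[ScoredPair] = []
    rest_iter = iter(rest)
    for p in rest_iter:
        if len(top) >= k:
            remaining_rest.append(p)
            continue
        if p.has_x:
            remaining_rest.append(p)
            continue
        n_exc = jc[p.types]
        target = class_table.get(p.types, 0.0)
        if abs(empirical(n_exc + 1, p) - target) > abs(empirical(n_exc, p) - target):
            remaining_rest.append(p)  # leave in rest-set
        else:
            top.append(p)
            jc[p.types] += 1

    # Backfill: latest-removed pairs return until the top-set holds K pairs.
    backfilled: set[int] = set()
    while len(top) < k and rmv:
        p = rmv.pop()
        top.append(p)
        backfilled.add(id(p))
        jc[p.types] += 1

    provenance = [
        KEPT if id(p) in kept else BACKFILLED if id(p) in backfilled else ADDED
        for p in top
    ]
    return RerankResult(
        top_set=top,
        provenance=provenance,
        rest_set=remaining_rest,
        rmv_set=rmv,
        k=k,
    )
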