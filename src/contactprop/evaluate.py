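"""TP-rate evaluation of ranked contact predictions against structural truth.

The truth is a contact map at the standard evaluation definition (Cβ cutoff
8 Å, separation 10, overridable).  For one domain, tp_rate(n) is the
fraction of the first n ranked predicted pairs that are true contacts
(exact (i, j) identity); the ensemble summary is the unweighted mean of
tp_rate(n) across domains at each n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .contacts import ContactMap, ContactParams, build_contact_map
from .structures_io import Domain

#: Contact definition used to assess predictions.
TRUTH_PARAMS = ContactParams(cutoff=8.0, separation=10)


def truth_map(
    domain: Domain, cutoff: float = 8.0, separation: int = 10
) -> ContactMap:
    """Ground-truth contact map for prediction assessment (8 Å / 10 default)."""
    return build_contact_map(domain, ContactParams(cutoff, separation))


@dataclass(frozen=True)
class TPRateCurve:
    """Mean true-positive rate as a function of the number of top predictions.

    ``tp_rate[m]`` is the rate at n = ``n[m]``; ``n_domains[m]`` is how many
    domains contributed at that n (domains with fewer predictions truncate
    rather than pad with failures).
    """

    n: np.ndarray
    tp_rate: np.ndarray
    n_domains: np.ndarray

    def at(self, n: int) -> float:
        idx = np.searchsorted(self.n, n)
        if idx >= len(self.n) or self.n[idx] != n:
            raise ValueError(f"curve not defined at n = {n}")
        return float(self.tp_rate[idx])


def tp_curve(
    predicted_order: Sequence[tuple[int, int]],
    truth: ContactMap,
    n_max: int = 200,
) -> TPRateCurve:
    """Cumulative precision of a ranked pair list against a truth map.

    The curve covers n = 1..min(n_max, number of predictions); duplicate
    predictions raise ``ValueError``.
    """
    preds = [(min(i, j), max(i, j)) for i, j in predicted_order]
    if len(set(preds)) != len(preds):
        raise ValueError("predicted pair list contains duplicates")
    m = min(n_max, len(preds))
    hits = np.cumsum([1 if p in truth.pairs else 0 for p in preds[:m]])
    n = np.arange(1, m + 1)
    return TPRateCurve(
        n=n, tp_rate=hits / n, n_domains=np.ones(m, dtype=int)
    )


def mean_tp_curve(curves: Sequence[TPRateCurve]) -> TPRateCurve:
    """Unweighted mean across domains at each n.

    Truncated per-domain curves contribute only where they are defined.
    """
    if not curves:
        raise ValueError("need at least one curve")
    n_max = max(int(c.n[-1]) for c in curves if len(c.n))
    grid = np.full((len(curves), n_max), np.nan)
    for r, c in enumerate(curves):
        grid[r, c.n - 1] = c.tp_rate
    counts = np.sum(~np.isnan(grid), axis=0)
    defined = counts > 0
    mean = np.full(n_max, np.nan)
    mean[defined] = np.nanmean(grid[:, defined], axis=0)
    n = np.arange(1, n_max + 1)[defined]
    return TPRateCurve(n=n, tp_rate=mean[defined], n_domains=counts[defined])


def mean_tp_curves_by_class(
    curves: Mapping[str, Sequence[TPRateCurve]],
) -> dict[str, TPRateCurve]:
    """Per-class mean curves plus an ``"all"`` entry pooling every domain."""
    out = {label: mean_tp_curve(cs) for label, cs in curves.items() if cs}
    pooled = [c for cs in curves.values() for c in cs]
    if pooled:
        out["all"] = mean_tp_curve(pooled)
    return out
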