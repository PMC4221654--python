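"""Contact maps, contact degrees and the power-law cutoff/separation scaling.

A contact site is an unordered pair of residues whose Cβ–Cβ distance is not
greater than a *cutoff* (Å) and whose sequence separation |i − j| is no less
than a *separation* threshold; two adjacent residues have separation 1.
The *contact degree* of a residue is the number of contact sites it takes
part in.  The average contact degree of an ensemble follows a power law
y = a·x^b in either the cutoff (b > 0) or the separation (b < 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structures_io import Domain


@dataclass(frozen=True)
class ContactParams:
    """Contact-site definition: distance cutoff (Å) and minimum separation."""

    cutoff: float
    separation: int

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")
        if self.separation < 1:
            raise ValueError(f"separation must be >= 1, got {self.separation}")


@dataclass(frozen=True)
class ContactMap:
    """Set of unordered residue pairs (i < j) satisfying a contact definition."""

    domain_id: str
    params: ContactParams
    pairs: frozenset[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.pairs)

    def degree(self, i: int) -> int:
        """Contact degree: number of contact sites residue ``i`` takes part in."""
        return sum(1 for a, b in self.pairs if a == i or b == i)


def build_contact_map(
    domain: Domain,
    params: ContactParams,
    strict_separation: bool = False,
) -> ContactMap:
    """All residue pairs with Cβ distance ≤ cutoff and |i − j| ≥ separation.

    Residues without a Cβ representative are excluded from every pair.
    ``strict_separation=True`` switches the predicate to |i − j| > separation
    for comparisons with tools that use the strict convention.
    """
    coords, index = domain.cbeta_coordinates()
    if len(index) < 2:
        warnings.warn(
            f"domain {domain.domain_id!r} has fewer than 2 residues with "
            "coordinates; contact map is empty"
        )
        return ContactMap(domain.domain_id, params, frozenset())
    tree = cKDTree(coords)
    min_sep = params.separation + 1 if strict_separation else params.separation
    pairs = set()
    for a, b in tree.query_pairs(r=params.cutoff):
        i, j = int(index[a]), int(index[b])
        if abs(i - j) >= min_sep:
            pairs.add((min(i, j), max(i, j)))
    return ContactMap(domain.domain_id, params, frozenset(pairs))


def contact_degree(cmap: ContactMap, i: int) -> int:
    """Number of contact sites of residue ``i`` in ``cmap``."""
    return cmap.degree(i)


def degree_vector(domain: Domain, cmap: ContactMap) -> np.ndarray:
    """Contact degree of every residue of the domain, in sequence order."""
    index = {r.seq_index: k for k, r in enumerate(domain.residues)}
    deg = np.zeros(len(domain.residues), dtype=int)
    for a, b in cmap.pairs:
        deg[index[a]] += 1
        deg[index[b]] += 1
    return deg


@dataclass(frozen=True)
class DegreeStats:
    """Average contact degree over all residues of an ensemble.

    ``std`` is the standard deviation over residues pooled across domains;
    ``std_proteins`` is the standard deviation of per-domain mean degrees
    (both are reported because figure error bars can follow either
    convention).
    """

    mean: float
    std: float
    std_proteins: float
    n_residues: int
    n_domains: int


def average_contact_degree(
    domains: Sequence[Domain], params: ContactParams
) -> DegreeStats:
    """Mean and std of contact degree over all residues of all domains.

    Degree-0 residues (including residues without coordinates) count: the
    average is over *all* amino acids of the analyzed proteins.
    """
    if not domains:
        raise ValueError("need at least one domain")
    all_deg: list[np.ndarray] = []
    for dom in domains:
        cmap = build_contact_map(dom, params)
        all_deg.append(degree_vector(dom, cmap))
    pooled = np.concatenate(all_deg)
    per_dom = np.array([d.mean() if len(d) else 0.0 for d in all_deg])
    return DegreeStats(
        mean=float(pooled.mean()),
        std=float(pooled.std()),
        std_proteins=float(per_dom.std()),
        n_residues=int(pooled.size),
        n_domains=len(domains),
    )


def sweep_average_degree(
    domains: Sequence[Domain],
    cutoffs: Sequence[float],
    separations: Sequence[int],
) -> dict[tuple[float, int], DegreeStats]:
    """Average contact degree on a (cutoff × separation) grid.

    Distances are computed once per domain and reused across the grid.
    """
    if not domains or not cutoffs or not len(separations):
        raise ValueError("domains, cutoffs and separations must be nonempty")
    # Precompute per-domain distance and separation matrices over usable residues.
    cache = []
    for dom in domains:
        coords, index = dom.cbeta_coordinates()
        n_total = len(dom.residues)
        usable_pos = np.array(
            [k for k, r in enumerate(dom.residues) if r.cbeta is not None], dtype=int
        )
        if len(index) < 2:
            cache.append((None, usable_pos, n_total))
            continue
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        sep = np.abs(index[:, None] - index[None, :])
        cache.append(((dist, sep), usable_pos, n_total))
    out: dict[tuple[float, int], DegreeStats] = {}
    for c in cutoffs:
        for s in separations:
            pooled_parts: list[np.ndarray] = []
            per_dom: list[float] = []
            for mats, usable_pos, n_total in cache:
                deg_full = np.zeros(n_total)
                if mats is not None:
                    dist, sep = mats
                    mask = (dist <= c) & (sep >= s)  # sep >= 1 excludes diagonal
                    deg_full[usable_pos] = mask.sum(axis=1)
                pooled_parts.append(deg_full)
                per_dom.append(float(deg_full.mean()) if n_total else 0.0)
            pooled = np.concatenate(pooled_parts)
            per = np.array(per_dom)
            out[(float(c), int(s))] = DegreeStats(
                mean=float(pooled.mean()),
                std=float(pooled.std()),
                std_proteins=float(per.std()),
                n_residues=int(pooled.size),
                n_domains=len(domains),
            )
    return out


@dataclass(frozen=True)
class PowerFit:
    """Least-squares fit of y = a·x^b with R² reported on the linear scale."""

    a: float
    b: float
    r_squared: float

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.a * np.asarray(x, dtype=float) ** self.b


def fit_power_law(x: Sequence[float], y: Sequence[float]) -> PowerFit:
    """Fit y = a·x^b by ordinary least squares on log-transformed data.

    Requires at least 3 strictly positive (x, y) points.  The R² is computed
    against a·x^b on the original (linear) scale, not in log space.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive x and y")
    b, log_a = np.polyfit(np.log(x), np.log(y), 1)
    a = float(np.exp(log_a))
    yhat = a * x**b
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 and ss_res == 0 else 1.0 - ss_res / ss_tot if ss_tot > 0 else float("-inf")
    return PowerFit(a=a, b=float(b), r_squared=r2)
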