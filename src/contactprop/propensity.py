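"""Amino-acid contact-propensity statistics.

Four families of statistics describe how residue types populate contact
sites within a structural class k (alpha / beta / alpha+beta) or a topology t:

* ``W_c`` — for amino-acid type a, the per-protein fraction of type-a
  residues that form at least one contact site, averaged (unweighted) over
  the N_{a,k} proteins of the class that contain a.
* ``W_t`` — the same quantity grouped by topology instead of class.
* ``f_p`` — the fraction of all contact sites of a class formed by a given
  unordered amino-acid type pair: f_p(a1,a2) = Jc(a1,a2) / Jw.
* ``f_pn`` — f_p normalized by the occurrence frequencies of the two types:
  f_pn(a1,a2) = f_p(a1,a2) / (f_a1 · f_a2).
* ``S_t`` — the (N−1)-normalized root-mean-square deviation between a
  topology's W_t profile and its class's W_c profile, over the amino-acid
  types present in the topology ('X' excluded, maximum 20 types).

Undefined entries are NaN, never 0: a statistic is undefined when no protein
of the group contains the amino acid, or when a normalizing frequency is 0.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .contacts import ContactMap, degree_vector
from .structures_io import STANDARD_AA, Domain

PairKey = tuple[str, str]


def pair_key(a1: str, a2: str) -> PairKey:
    """Canonical unordered amino-acid type pair (alphabetical)."""
    return (a1, a2) if a1 <= a2 else (a2, a1)


@dataclass
class DomainContactSummary:
    """Per-type contact participation counts for one domain.

    ``ic[a]`` counts residues of type a forming at least one contact site;
    ``iw[a]`` counts all residues of type a (including 'X' under 'X').
    """

    domain_id: str
    ic: dict[str, int]
    iw: dict[str, int]

    def __post_init__(self) -> None:
        for a, n_contact in self.ic.items():
            if not 0 <= n_contact <= self.iw.get(a, 0):
                raise ValueError(
                    f"inconsistent counts for {a!r} in {self.domain_id!r}"
                )


def summarize_domain(domain: Domain, cmap: ContactMap) -> DomainContactSummary:
    """Count, per amino-acid type, residues with contact degree ≥ 1 and total."""
    deg = degree_vector(domain, cmap)
    ic: Counter = Counter()
    iw: Counter = Counter()
    for res, d in zip(domain.residues, deg):
        iw[res.aa_type] += 1
        if d >= 1:
            ic[res.aa_type] += 1
    return DomainContactSummary(domain.domain_id, dict(ic), dict(iw))


@dataclass
class PropensityTable:
    """Per-type contact propensity (W_c for a class or W_t for a topology).

    ``values[a]`` is the unweighted mean of per-protein ratios Ic/Iw over the
    ``n_proteins[a]`` proteins containing type a; NaN where no protein
    contains a.  ``std[a]`` is the standard deviation of those per-protein
    ratios.
    """

    label: str
    values: dict[str, float]
    std: dict[str, float]
    n_proteins: dict[str, int]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "aa": a,
                "value": self.values[a],
                "std": self.std[a],
                "n_proteins": self.n_proteins[a],
            }
            for a in sorted(self.values)
        ]
        return pd.DataFrame(rows)


def _compute_propensity(
    summaries: Sequence[DomainContactSummary], label: str
) -> PropensityTable:
    if not summaries:
        raise ValueError("need at least one domain summary")
    ratios: dict[str, list[float]] = {}
    for s in summaries:
        for a, iw in s.iw.items():
            if iw > 0:
                ratios.setdefault(a, []).append(s.ic.get(a, 0) / iw)
    types = set(STANDARD_AA) | set(ratios)
    values: dict[str, float] = {}
    std: dict[str, float] = {}
    n_prot: dict[str, int] = {}
    for a in types:
        r = ratios.get(a, [])
        n_prot[a] = len(r)
        if r:
            arr = np.asarray(r)
            values[a] = float(arr.mean())
            std[a] = float(arr.std())
        else:
            values[a] = float("nan")
            std[a] = float("nan")
    return PropensityTable(label, values, std, n_prot)


def compute_Wc(
    summaries: Sequence[DomainContactSummary], class_label: str = ""
) -> PropensityTable:
    """W_c per amino-acid type for one structural class.

    Each protein containing type a contributes its ratio Ic_a/Iw_a once;
    proteins lacking a contribute nothing.  Types absent from every protein
    are NaN (undefined), not 0.
    """
    return _compute_propensity(summaries, class_label)


def compute_Wt(
    summaries: Sequence[DomainContactSummary], topology_label: str = ""
) -> PropensityTable:
    """W_t: identical contract to :func:`compute_Wc`, grouped by topology."""
    return _compute_propensity(summaries, topology_label)


def compute_frequencies(domains: Sequence[Domain]) -> dict[str, float]:
    """Occurrence frequency of each of the 20 standard types over a class.

    'X' placeholders are excluded from both numerator and denominator; the
    returned frequencies sum to 1 over the 20 standard types.
    """
    counts: Counter = Counter()
    for dom in domains:
        for res in dom.residues:
            if res.aa_type != "X":
                counts[res.aa_type] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no standard amino acids in the domain set")
    return {a: counts.get(a, 0) / total for a in STANDARD_AA}


@dataclass
class PairFrequencyTable:
    """Pair contact frequencies f_p (and optionally f_pn) for one class.

    ``jc`` maps the canonical unordered type pair to its contact count;
    ``jw`` is the total number of contact sites counted in the denominator.
    Homotypic pairs (e.g. Cys–Cys) count once per contact; f_pn carries no
    factor-2 correction for identical types.
    """

    label: str
    jw: int
    jc: dict[PairKey, int]
    fp: dict[PairKey, float]
    fpn: Optional[dict[PairKey, float]] = None
    frequencies: Optional[dict[str, float]] = None

    def fp_value(self, a1: str, a2: str) -> float:
        return self.fp.get(pair_key(a1, a2), 0.0)

    def fpn_value(self, a1: str, a2: str) -> float:
        if self.fpn is None:
            raise ValueError("f_pn has not been computed for this table")
        return self.fpn.get(pair_key(a1, a2), 0.0)

    def to_dataframe(self) -> pd.DataFrame:
        keys = sorted(set(self.jc) | set(self.fp))
        rows = []
        for k in keys:
            row = {
                "aa1": k[0],
                "aa2": k[1],
                "jc": self.jc.get(k, 0),
                "fp": self.fp.get(k, 0.0),
            }
            if self.fpn is not None:
                row["fpn"] = self.fpn.get(k, float("nan"))
            rows.append(row)
        return pd.DataFrame(rows)


def compute_fp(
    domains_and_maps: Sequence[tuple[Domain, ContactMap]],
    class_label: str = "",
    include_x_in_total: bool = True,
) -> PairFrequencyTable:
    """f_p = Jc(a1,a2)/Jw over all contact sites of a class.

    Every contact pair is tallied once under its unordered type pair; pairs
    involving 'X' appear under their own rows.  By default Jw is the literal
    count of all contact sites (X pairs included); with
    ``include_x_in_total=False`` X-containing pairs are dropped from both Jc
    and Jw.  In either mode the defined f_p values sum to 1 when Jw > 0.
    """
    jc: Counter = Counter()
    jw = 0
    for dom, cmap in domains_and_maps:
        types = {r.seq_index: r.aa_type for r in dom.residues}
        for i, j in cmap.pairs:
            key = pair_key(types[i], types[j])
            has_x = "X" in key
            if has_x and not include_x_in_total:
                continue
            jw += 1
            jc[key] += 1
    if jw == 0:
        warnings.warn(
            f"class {class_label!r} has no contact sites; f_p undefined"
        )
        return PairFrequencyTable(class_label, 0, {}, {})
    fp = {k: v / jw for k, v in jc.items()}
    return PairFrequencyTable(class_label, jw, dict(jc), fp)


def compute_fpn(
    fp_table: PairFrequencyTable, frequencies: Mapping[str, float]
) -> PairFrequencyTable:
    """Normalize f_p by the product of the two types' occurrence frequencies.

    f_pn is NaN (undefined) for pairs involving 'X' or a type with zero /
    missing frequency and f_p = 0; a pair with f_p > 0 but a zero frequency
    is an inconsistency and raises ``ValueError``.
    """
    fpn: dict[PairKey, float] = {}
    for k, fp in fp_table.fp.items():
        f1 = frequencies.get(k[0], 0.0)
        f2 = frequencies.get(k[1], 0.0)
        if "X" in k or f1 <= 0 or f2 <= 0:
            if fp > 0 and "X" not in k:
                raise ValueError(
                    f"pair {k} has f_p = {fp} but a zero occurrence frequency"
                )
            fpn[k] = float("nan")
        else:
            fpn[k] = fp / (f1 * f2)
    return PairFrequencyTable(
        label=fp_table.label,
        jw=fp_table.jw,
        jc=dict(fp_table.jc),
        fp=dict(fp_table.fp),
        fpn=fpn,
        frequencies=dict(frequencies),
    )


def compute_St(
    topology_table: PropensityTable, class_table: PropensityTable
) -> float:
    """Divergence of a topology's W_t profile from its class's W_c profile.

    S_t = sqrt( Σ_a (W_t(a) − W_c(a))² / (N − 1) ) over the N amino-acid
    types present in the topology, excluding 'X' (maximum 20).  Returns NaN
    with a warning when fewer than 2 types are present.
    """
    present = [
        a
        for a in topology_table.values
        if a != "X" and topology_table.n_proteins.get(a, 0) > 0
    ]
    n = len(present)
    if n < 2:
        warnings.warn(
            f"topology {topology_table.label!r} has fewer than 2 amino-acid "
            "types; S_t undefined"
        )
        return float("nan")
    sq = 0.0
    for a in present:
        wc = class_table.values.get(a, float("nan"))
        sq += (topology_table.values[a] - wc) ** 2
    return math.sqrt(sq / (n - 1))
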