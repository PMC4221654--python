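"""Structural-class assignment from secondary structure.

Eight-state codes are simplified to three states (H/G/I → helix, E → sheet,
everything else → coil), short elements are dissolved (helices shorter than
five residues and strands shorter than three residues become coil), and the
Nakashima-style composition thresholds assign the domain to alpha, beta or
alpha+beta; a domain matching no rule is left unassigned and excluded from
downstream re-ranking.

All threshold inequalities are strict, exactly as the rules are stated:
helix = 15 % or sheet = 10 % satisfies none of them and falls to
``unassigned``.  Note that the alpha+beta rule as stated (< 15 % helix and
< 10 % sheet) selects structure-poor domains; ``conventional_alpha_beta=True``
swaps in the both-rich variant (> 15 % helix and > 10 % sheet) instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

HELIX_CODES = frozenset("HGI")
SHEET_CODES = frozenset("E")

ALPHA = "alpha"
BETA = "beta"
ALPHA_BETA = "alpha_beta"
UNASSIGNED = "unassigned"

MIN_HELIX_RUN = 5  # helices shorter than five residues dissolve to coil
MIN_SHEET_RUN = 3  # strands shorter than three residues dissolve to coil


@dataclass(frozen=True)
class SimplifiedSS:
    """3-state secondary structure after run-length simplification."""

    codes: str
    helix_fraction: float
    sheet_fraction: float


def _dissolve_short_runs(codes: list[str], state: str, min_run: int) -> None:
    start = 0
    n = len(codes)
    while start < n:
        if codes[start] != state:
            start += 1
            continue
        end = start
        while end < n and codes[end] == state:
            end += 1
        if end - start < min_run:
            codes[start:end] = ["C"] * (end - start)
        start = end


def simplify_ss(dssp_codes: str) -> SimplifiedSS:
    """Map 8-state codes to {H, E, C} and dissolve short elements.

    Unknown codes are treated as coil with a warning.  The operation is
    idempotent, and no surviving helix run is shorter than 5 residues nor
    sheet run shorter than 3.
    """
    if not dssp_codes:
        raise ValueError("empty secondary-structure string")
    out: list[str] = []
    unknown: set[str] = set()
    for c in dssp_codes:
        if c in HELIX_CODES:
            out.append("H")
        elif c in SHEET_CODES:
            out.append("E")
        elif c in "BTSC- ":
            out.append("C")
        else:
            unknown.add(c)
            out.append("C")
    if unknown:
        warnings.warn(
            f"unknown secondary-structure codes {sorted(unknown)} treated as coil"
        )
    _dissolve_short_runs(out, "H", MIN_HELIX_RUN)
    _dissolve_short_runs(out, "E", MIN_SHEET_RUN)
    n = len(out)
    return SimplifiedSS(
        codes="".join(out),
        helix_fraction=out.count("H") / n,
        sheet_fraction=out.count("E") / n,
    )


def assign_class(ss: SimplifiedSS, conventional_alpha_beta: bool = False) -> str:
    """Assign alpha / beta / alpha_beta / unassigned from H and E fractions.

    alpha: helix > 15 % and sheet < 10 %; beta: helix < 15 % and
    sheet > 10 %; alpha_beta: helix < 15 % and sheet < 10 % (or both-rich
    when ``conventional_alpha_beta``); anything else is unassigned.
    """
    h, e = ss.helix_fraction, ss.sheet_fraction
    if h > 0.15 and e < 0.10:
        return ALPHA
    if h < 0.15 and e > 0.10:
        return BETA
    if conventional_alpha_beta:
        if h > 0.15 and e > 0.10:
            return ALPHA_BETA
    elif h < 0.15 and e < 0.10:
        return ALPHA_BETA
    return UNASSIGNED


def classify_codes(dssp_codes: str, conventional_alpha_beta: bool = False) -> str:
    """Convenience: simplify then assign in one call."""
    return assign_class(
        simplify_ss(dssp_codes), conventional_alpha_beta=conventional_alpha_beta
    )
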