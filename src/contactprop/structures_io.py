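"""Structure, secondary-structure and table I/O.

Reads protein chains from PDB files into lightweight :class:`Domain` objects
holding one Cβ representative per residue (Cα for glycine), reads DSSP output
or plain 3-state secondary-structure strings, and reads/writes the
tab-separated tables used throughout the package (per-pair scores,
propensity tables, pair-frequency tables).

Residues are renumbered 1..n consecutively over the observed residues; the
author's PDB numbering is kept as metadata.  This keeps sequence-separation
arithmetic gap-free.  Pass ``honor_numbering_gaps=True`` to preserve author
numbering gaps in the internal indices instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from Bio.SeqUtils import seq1

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Alphabet accepted for residue types: the 20 standard codes plus 'X'.
ALLOWED_AA: frozenset[str] = frozenset(STANDARD_AA) | {"X"}

#: 8-state secondary-structure codes as emitted by DSSP (blank mapped to 'C').
DSSP_CODES: frozenset[str] = frozenset("HGIEBTSC-")


@dataclass
class Residue:
    """One amino-acid position with its Cβ contact representative.

    ``cbeta`` is ``None`` when neither a CB nor a CA atom was present; such
    residues are excluded from every contact computation (never treated as
    sitting at the origin).
    """

    seq_index: int
    aa_type: str
    cbeta: Optional[np.ndarray] = None
    author_id: Optional[tuple[int, str]] = None  # (resseq, icode) from the PDB

    def __post_init__(self) -> None:
        if self.seq_index < 1:
            raise ValueError(f"seq_index must be >= 1, got {self.seq_index}")
        if self.aa_type not in ALLOWED_AA:
            raise ValueError(f"unknown amino-acid code {self.aa_type!r}")
        if self.cbeta is not None:
            self.cbeta = np.asarray(self.cbeta, dtype=float)
            if self.cbeta.shape != (3,) or not np.all(np.isfinite(self.cbeta)):
                raise ValueError("cbeta must be a finite 3-vector")


@dataclass
class Domain:
    """An ordered chain of residues with optional class/topology labels."""

    domain_id: str
    residues: list[Residue]
    class_label: Optional[str] = None
    topology_label: Optional[str] = None
    ss_string: Optional[str] = None

    def __post_init__(self) -> None:
        idx = [r.seq_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue seq_index must be strictly increasing")
        if self.ss_string is not None and len(self.ss_string) != len(self.residues):
            raise ValueError(
                f"ss_string length {len(self.ss_string)} != "
                f"residue count {len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa_type for r in self.residues)

    def cbeta_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinates and seq indices of residues with a Cβ representative."""
        usable = [r for r in self.residues if r.cbeta is not None]
        if not usable:
            return np.empty((0, 3)), np.empty(0, dtype=int)
        coords = np.stack([r.cbeta for r in usable])
        index = np.array([r.seq_index for r in usable], dtype=int)
        return coords, index


def read_structure(
    path: str | Path,
    chain: str,
    residue_range: Optional[tuple[int, int]] = None,
    honor_numbering_gaps: bool = False,
) -> Domain:
    """Read one chain of a PDB file into a :class:`Domain`.

    The Cβ representative is the CB atom; glycine, which has no Cβ, uses CA.
    A non-glycine residue lacking CB falls back to CA with a warning; a
    residue with neither atom gets an absent representative and a warning.
    Alternate locations resolve to the highest-occupancy conformer.

    Parameters
    ----------
    residue_range
        Optional inclusive ``(start, end)`` filter in author numbering.
    honor_numbering_gaps
        When true, internal indices preserve gaps in the author numbering
        (offset so the first observed residue is 1).  Default renumbers
        observed residues consecutively.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    model = next(structure.get_models())
    if chain not in [c.id for c in model]:
        raise ValueError(
            f"chain {chain!r} not found in {path} "
            f"(available: {[c.id for c in model]})"
        )
    residues: list[Residue] = []
    first_author: Optional[int] = None
    for res in model[chain]:
        het, resseq, icode = res.id
        if het != " " or not is_aa(res, standard=False):
            continue
        if residue_range is not None and not (
            residue_range[0] <= resseq <= residue_range[1]
        ):
            continue
        aa = seq1(res.get_resname())
        if aa not in ALLOWED_AA or aa == "":
            aa = "X"
        if first_author is None:
            first_author = resseq
        if honor_numbering_gaps:
            seq_index = resseq - first_author + 1
            if residues and seq_index <= residues[-1].seq_index:
                # insertion codes / repeated numbers: fall back to consecutive
                seq_index = residues[-1].seq_index + 1
        else:
            seq_index = len(residues) + 1
        coord: Optional[np.ndarray] = None
        if "CB" in res:
            coord = res["CB"].get_coord()
        elif "CA" in res:
            coord = res["CA"].get_coord()
            if res.get_resname() != "GLY":
                warnings.warn(
                    f"{path.stem}/{chain} residue {resseq}{icode.strip()} "
                    f"({res.get_resname()}) has no CB atom; using CA"
                )
        else:
            warnings.warn(
                f"{path.stem}/{chain} residue {resseq}{icode.strip()} has "
                "neither CB nor CA; excluded from contact computation"
            )
        residues.append(
            Residue(
                seq_index=seq_index,
                aa_type=aa,
                cbeta=coord,
                author_id=(resseq, icode),
            )
        )
    return Domain(domain_id=f"{path.stem}_{chain}", residues=residues)


def _looks_like_dssp(lines: Sequence[str]) -> bool:
    head = "".join(lines[:30])
    return "DSSP" in head or head.startswith("====")


def read_secondary_structure(path: str | Path, fmt: str = "auto") -> str:
    """Read per-residue secondary-structure codes.

    Supports classic DSSP output (the 8-state code in column 17 of each
    residue row; blank becomes ``C``; chain-break ``!`` rows are skipped) and
    plain text holding one-letter 3-state (or 8-state) codes, possibly over
    several lines.  ``fmt`` may be ``"dssp"``, ``"plain"`` or ``"auto"``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if fmt == "auto":
        fmt = "dssp" if path.suffix.lower() == ".dssp" or _looks_like_dssp(lines) else "plain"
    if fmt == "dssp":
        codes: list[str] = []
        in_body = False
        for line in lines:
            if line.lstrip().startswith("#  RESIDUE"):
                in_body = True
                continue
            if not in_body or len(line) < 17:
                continue
            if line[13] == "!":  # chain break marker
                continue
            code = line[16]
            codes.append("C" if code == " " else code)
        if not codes:
            raise ValueError(f"no residue rows found in DSSP file {path}")
        out = "".join(codes)
    elif fmt == "plain":
        out = "".join(
            line.strip() for line in lines if line.strip() and not line.startswith("#")
        )
        if not out:
            raise ValueError(f"no secondary-structure codes found in {path}")
    else:
        raise ValueError(f"unknown secondary-structure format {fmt!r}")
    bad = set(out) - DSSP_CODES
    if bad:
        raise ValueError(f"unknown secondary-structure codes {sorted(bad)} in {path}")
    return out


def attach_secondary_structure(domain: Domain, codes: str) -> None:
    """Attach a code string to a domain, enforcing equal lengths."""
    if len(codes) != len(domain.residues):
        raise ValueError(
            f"secondary-structure length {len(codes)} does not match "
            f"domain {domain.domain_id!r} residue count {len(domain.residues)}"
        )
    domain.ss_string = codes


def read_score_table(path: str | Path) -> list[tuple[int, int, float]]:
    """Read a 3-column TSV of per-pair scores as ``(i, j, score)`` with i < j.

    Pairs are canonicalized to ``i < j``; a duplicate unordered pair, a
    self-pair or a non-numeric score raises ``ValueError``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] != 3:
        raise ValueError(f"score table must have 3 columns, found {df.shape[1]}")
    try:
        ii = df[0].astype(int)
        jj = df[1].astype(int)
        ss = df[2].astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric entry in score table {path}: {exc}") from exc
    out: list[tuple[int, int, float]] = []
    seen: set[tuple[int, int]] = set()
    for i, j, s in zip(ii, jj, ss):
        if i == j:
            raise ValueError(f"self-pair ({i},{j}) in score table {path}")
        key = (int(min(i, j)), int(max(i, j)))
        if key in seen:
            raise ValueError(f"duplicate unordered pair {key} in score table {path}")
        seen.add(key)
        out.append((key[0], key[1], float(s)))
    return out


def write_table(
    records: Iterable[dict] | pd.DataFrame,
    path: str | Path,
    columns: Optional[Sequence[str]] = None,
) -> None:
    """Write records as TSV with a '#'-prefixed header row.

    Column order is the order of ``columns`` if given, else the key order of
    the first record (or DataFrame column order).  An empty record list
    produces a header-only file (``columns`` then required).
    """
    if isinstance(records, pd.DataFrame):
        df = records if columns is None else records[list(columns)]
    else:
        records = list(records)
        if not records and columns is None:
            raise ValueError("empty record list requires explicit columns")
        cols = list(columns) if columns is not None else list(records[0].keys())
        df = pd.DataFrame(records, columns=cols)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(str(c) for c in df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` back into a DataFrame."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path} has no '#'-prefixed header row")
        cols = header[1:].rstrip("\n").split("\t")
        df = pd.read_csv(fh, sep="\t", header=None, names=cols)
    return df
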