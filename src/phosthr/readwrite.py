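"""Readers and writers for the formats every other module consumes.

Formats
-------
* protein sequences: FASTA (via Biopython);
* per-residue structure annotations: TSV with columns
  ``protein_id, pos, aa, ss, acc`` (``pos`` 1-based, ``ss`` in H/E/C,
  ``acc`` a non-negative accessibility in whatever units the annotation
  source uses);
* site tables: TSV with columns ``protein_id, position, label``;
* feature matrices: CSV with a header of feature names plus a ``label``
  column.

All coordinates at the I/O boundary are 1-based inclusive.  Internally,
window positions are signed offsets relative to the central threonine
(center = 0, flanks -15..+15 for a 31-mer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ConsistencyError, FormatError

log = logging.getLogger(__name__)

#: The 20 standard residues, alphabetical one-letter codes.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA20)}
#: Unknown / padding residue symbol.
UNKNOWN = "X"
#: Three-state secondary structure codes: helix, strand, coil.
SS_STATES = "HEC"

LABELS = ("positive", "negative", "unlabeled")


@dataclass
class ProteinRecord:
    """A protein sequence with optional per-residue structure annotation.

    Attributes
    ----------
    id:
        Unique identifier (FASTA header word).
    sequence:
        Uppercase amino-acid string over ``AA20`` plus ``X`` for unknown.
    ss:
        Optional secondary-structure string over ``{H, E, C}``, same
        length as ``sequence``.
    acc:
        Optional per-residue accessibility values (non-negative reals in
        the units of the annotation source), same length as ``sequence``.
    """

    id: str
    sequence: str
    ss: str | None = None
    acc: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein record with empty id")
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: zero-length sequence")
        bad = set(self.sequence) - set(AA20 + UNKNOWN)
        if bad:
            raise FormatError(
                f"record {self.id!r}: residues outside alphabet: {sorted(bad)}"
            )
        if self.ss is not None:
            if len(self.ss) != len(self.sequence):
                raise ConsistencyError(
                    f"record {self.id!r}: ss length {len(self.ss)} != "
                    f"sequence length {len(self.sequence)}"
                )
            bad_ss = set(self.ss) - set(SS_STATES)
            if bad_ss:
                raise FormatError(
                    f"record {self.id!r}: ss states outside H/E/C: {sorted(bad_ss)}"
                )
        if self.acc is not None:
            self.acc = np.asarray(self.acc, dtype=float)
            if len(self.acc) != len(self.sequence):
                raise ConsistencyError(
                    f"record {self.id!r}: acc length {len(self.acc)} != "
                    f"sequence length {len(self.sequence)}"
                )
            if np.any(self.acc < 0):
                raise FormatError(f"record {self.id!r}: negative accessibility")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SiteEntry:
    protein_id: str
    position: int  # 1-based residue index; must be a threonine
    label: str  # one of LABELS


@dataclass
class SiteTable:
    """Experimentally labeled (or generator-planted) threonine sites."""

    entries: list[SiteEntry] = field(default_factory=list)

    def positives(self) -> list[SiteEntry]:
        return [e for e in self.entries if e.label == "positive"]

    def validate(self, proteins: Sequence[ProteinRecord]) -> None:
        """Check every referenced position exists and carries a threonine."""
        by_id = {p.id: p for p in proteins}
        for e in self.entries:
            if e.protein_id not in by_id:
                raise ConsistencyError(
                    f"site table references unknown protein {e.protein_id!r}"
                )
            prot = by_id[e.protein_id]
            if not 1 <= e.position <= len(prot):
                raise ConsistencyError(
                    f"site {e.protein_id}:{e.position} outside sequence "
                    f"(length {len(prot)})"
                )
            if prot.sequence[e.position - 1] != "T":
                raise ConsistencyError(
                    f"site {e.protein_id}:{e.position} is "
                    f"{prot.sequence[e.position - 1]!r}, not threonine"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased, internal whitespace is stripped, and
    characters outside the 20-letter alphabet (plus X) are mapped to X
    with a logged warning.  Empty files, duplicate ids and zero-length
    sequences raise :class:`FormatError`.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    n_mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise FormatError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        raw = "".join(str(rec.seq).split()).upper()
        if not raw:
            raise FormatError(f"{path}: record {rid!r} has a zero-length sequence")
        chars = []
        for ch in raw:
            if ch in AA_INDEX or ch == UNKNOWN:
                chars.append(ch)
            else:
                chars.append(UNKNOWN)
                n_mapped += 1
        records.append(ProteinRecord(id=rid, sequence="".join(chars)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if n_mapped:
        log.warning("%s: mapped %d out-of-alphabet residues to X", path, n_mapped)
    return records


def write_fasta(path: str | Path, proteins: Sequence[ProteinRecord]) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Per-residue annotations
# ---------------------------------------------------------------------------

_ANN_COLUMNS = ["protein_id", "pos", "aa", "ss", "acc"]


def read_annotations(
    path: str | Path, proteins: Sequence[ProteinRecord]
) -> list[ProteinRecord]:
    """Attach secondary structure and accessibility from an annotation TSV.

    Returns new :class:`ProteinRecord` objects; the inputs are not
    mutated.  Residues without an annotation row default to coil (C) and
    accessibility 0; the total count of such residues is logged.  An
    annotation whose ``aa`` disagrees with the FASTA sequence raises
    :class:`ConsistencyError` naming the protein and position.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "aa": str, "ss": str})
    missing_cols = set(_ANN_COLUMNS) - set(df.columns)
    if missing_cols:
        raise FormatError(f"{path}: missing columns {sorted(missing_cols)}")
    if not df["ss"].isin(list(SS_STATES)).all():
        bad = sorted(set(df["ss"]) - set(SS_STATES))
        raise FormatError(f"{path}: ss states outside H/E/C: {bad}")
    if (df["acc"] < 0).any():
        raise FormatError(f"{path}: negative accessibility values")

    known = {p.id for p in proteins}
    unknown = set(df["protein_id"]) - known
    if unknown:
        raise ConsistencyError(
            f"{path}: annotations reference unknown proteins {sorted(unknown)[:5]}"
        )

    grouped = dict(tuple(df.groupby("protein_id", sort=False)))
    out: list[ProteinRecord] = []
    n_default = 0
    for p in proteins:
        ss = ["C"] * len(p)
        acc = np.zeros(len(p))
        annotated = np.zeros(len(p), dtype=bool)
        rows = grouped.get(p.id)
        if rows is not None:
            for pos, aa, s, a in zip(rows["pos"], rows["aa"], rows["ss"], rows["acc"]):
                pos = int(pos)
                if not 1 <= pos <= len(p):
                    raise ConsistencyError(
                        f"{p.id}:{pos}: annotation outside sequence (length {len(p)})"
                    )
                if p.sequence[pos - 1] != aa:
                    raise ConsistencyError(
                        f"{p.id}:{pos}: annotation residue {aa!r} does not match "
                        f"sequence residue {p.sequence[pos - 1]!r}"
                    )
                ss[pos - 1] = s
                acc[pos - 1] = float(a)
                annotated[pos - 1] = True
        n_default += int((~annotated).sum())
        out.append(ProteinRecord(id=p.id, sequence=p.sequence, ss="".join(ss), acc=acc))
    if n_default:
        log.warning(
            "%s: %d residues without annotation rows defaulted to ss=C, acc=0",
            path,
            n_default,
        )
    return out


def write_annotations(path: str | Path, proteins: Sequence[ProteinRecord]) -> None:
    rows = []
    for p in proteins:
        ss = p.ss if p.ss is not None else "C" * len(p)
        acc = p.acc if p.acc is not None else np.zeros(len(p))
        for i, (aa, s, a) in enumerate(zip(p.sequence, ss, acc), start=1):
            rows.append((p.id, i, aa, s, a))
    pd.DataFrame(rows, columns=_ANN_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Site tables
# ---------------------------------------------------------------------------

def read_site_table(
    path: str | Path, proteins: Sequence[ProteinRecord] | None = None
) -> SiteTable:
    """Read a site table TSV; validate against ``proteins`` when given."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "label": str})
    missing = {"protein_id", "position", "label"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["label"]) - set(LABELS)
    if bad:
        raise FormatError(f"{path}: unknown labels {sorted(bad)}")
    table = SiteTable(
        entries=[
            SiteEntry(protein_id=r.protein_id, position=int(r.position), label=r.label)
            for r in df.itertuples()
        ]
    )
    if proteins is not None:
        table.validate(proteins)
    return table


def write_site_table(path: str | Path, table: SiteTable) -> None:
    pd.DataFrame(
        [(e.protein_id, e.position, e.label) for e in table.entries],
        columns=["protein_id", "position", "label"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------------

def write_feature_matrix(path: str | Path, matrix) -> None:
    """Write a :class:`~phosthr.encoding.FeatureMatrix` as CSV.

    The header carries the feature names; labels go in a final ``label``
    column.  Values round-trip to full precision (shortest-repr floats).
    """
    df = pd.DataFrame(matrix.X, columns=list(matrix.names))
    df["label"] = matrix.y
    # %.17g guarantees binary round-trip for float64
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_matrix(path: str | Path):
    """Read a feature-matrix CSV back into a FeatureMatrix."""
    from .encoding import FeatureMatrix  # local import to avoid a cycle

    df = pd.read_csv(path, float_precision="round_trip")
    if "label" not in df.columns:
        raise FormatError(f"{path}: feature matrix lacks a 'label' column")
    y = df.pop("label").to_numpy()
    names = list(df.columns)
    if len(set(names)) != len(names):
        raise FormatError(f"{path}: duplicate feature names")
    return FeatureMatrix(X=df.to_numpy(dtype=float), names=names, y=y)


# ---------------------------------------------------------------------------
# Position weight matrices
# ---------------------------------------------------------------------------

def write_pwm(path: str | Path, pwm: np.ndarray, flank: int) -> None:
    """Serialize a 20 x L weight matrix as TSV (residue rows, offset columns)."""
    L = pwm.shape[1]
    if L != 2 * flank + 1:
        raise ConsistencyError(f"PWM has {L} columns, expected {2 * flank + 1}")
    offsets = [str(o) for o in range(-flank, flank + 1)]
    df = pd.DataFrame(pwm, index=list(AA20), columns=offsets)
    df.to_csv(path, sep="\t", index_label="residue")


def read_pwm(path: str | Path) -> tuple[np.ndarray, int]:
    df = pd.read_csv(path, sep="\t", index_col="residue")
    if list(df.index) != list(AA20):
        raise FormatError(f"{path}: PWM rows must be the 20 residues in order")
    L = df.shape[1]
    if L % 2 == 0:
        raise FormatError(f"{path}: PWM must have an odd number of offset columns")
    return df.to_numpy(dtype=float), L // 2
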