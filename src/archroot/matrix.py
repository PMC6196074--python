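"""Binary presence/absence character matrices and residue alignments.

Genomic signatures (e.g. SCOP protein-domain superfamilies) are coded as
two-state characters per taxon: present (1), absent (0) or unknown (?).
This module holds the in-memory containers, NEXUS/CSV/TSV matrix I/O,
alignment I/O (via Biopython), phyletic-sharing (Venn) counts and reduced
alphabet recoding.
"""

from __future__ import annotations

import io
import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PRESENT",
    "ABSENT",
    "UNKNOWN",
    "BinaryCharacterMatrix",
    "ResidueAlignment",
    "VennCounts",
    "read_binary_matrix",
    "write_binary_matrix",
    "read_group_labels",
    "sharing_partition",
    "filter_characters",
    "read_alignment",
    "write_alignment",
    "recode_alphabet",
    "SR4_SCHEME",
]

ABSENT, PRESENT, UNKNOWN = 0, 1, 2
_SYMBOL_TO_STATE = {"0": ABSENT, "1": PRESENT, "?": UNKNOWN, "-": UNKNOWN, "N": UNKNOWN, "n": UNKNOWN}
_STATE_TO_SYMBOL = {ABSENT: "0", PRESENT: "1", UNKNOWN: "?"}


class BinaryCharacterMatrix:
    """Taxa × binary characters with optional per-taxon group labels.

    States are stored as an ``int8`` array with codes 0 (absent), 1 (present)
    and 2 (unknown).  Taxon and character order are preserved from input.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        characters: Sequence[str],
        states: np.ndarray,
        groups: Optional[Mapping[str, str]] = None,
    ):
        taxa = list(taxa)
        characters = list(characters)
        states = np.asarray(states, dtype=np.int8)
        if len(taxa) < 2:
            raise ValueError("a character matrix needs at least 2 taxa")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon identifiers")
        if len(set(characters)) != len(characters):
            raise ValueError("duplicate character identifiers")
        if states.shape != (len(taxa), len(characters)):
            raise ValueError(f"state array shape {states.shape} does not match {len(taxa)}×{len(characters)}")
        if not np.isin(states, (ABSENT, PRESENT, UNKNOWN)).all():
            raise ValueError("states must be coded 0 (absent), 1 (present) or 2 (unknown)")
        if groups is not None:
            missing = [t for t in taxa if t not in groups]
            if missing:
                raise ValueError(f"group labels missing for taxa: {missing[:5]}")
            groups = {t: groups[t] for t in taxa}
        self.taxa = taxa
        self.characters = characters
        self.states = states
        self.groups = groups

    # ------------------------------------------------------------- conveniences
    @property
    def shape(self) -> tuple[int, int]:
        return self.states.shape

    def row(self, taxon: str) -> np.ndarray:
        return self.states[self.taxa.index(taxon)]

    def to_frame(self) -> pd.DataFrame:
        sym = np.array([_STATE_TO_SYMBOL[ABSENT], _STATE_TO_SYMBOL[PRESENT], _STATE_TO_SYMBOL[UNKNOWN]])
        return pd.DataFrame(sym[self.states], index=self.taxa, columns=self.characters)

    def with_groups(self, groups: Mapping[str, str]) -> "BinaryCharacterMatrix":
        return BinaryCharacterMatrix(self.taxa, self.characters, self.states.copy(), groups)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BinaryCharacterMatrix)
            and self.taxa == other.taxa
            and self.characters == other.characters
            and np.array_equal(self.states, other.states)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"BinaryCharacterMatrix({len(self.taxa)} taxa × {len(self.characters)} characters)"


@dataclass
class VennCounts:
    """Characters present in exactly each non-empty subset of group labels."""

    counts: dict[frozenset, int]
    total_observed: int  # characters present in >=1 taxon
    total_characters: int

    def in_all(self, labels: Iterable[str]) -> int:
        return self.counts.get(frozenset(labels), 0)

    def in_at_least(self, k: int) -> int:
        return sum(c for s, c in self.counts.items() if len(s) >= k)


# ----------------------------------------------------------------- matrix I/O
def _parse_states(rows: Sequence[str], taxa: Sequence[str]) -> np.ndarray:
    out = np.empty((len(rows), len(rows[0])), dtype=np.int8)
    for i, row in enumerate(rows):
        for j, sym in enumerate(row):
            try:
                out[i, j] = _SYMBOL_TO_STATE[sym]
            except KeyError:
                raise ValueError(f"unknown state symbol {sym!r} at taxon {taxa[i]!r}, column {j + 1}") from None
    return out


def read_binary_matrix(path, format: Optional[str] = None) -> BinaryCharacterMatrix:
    """Read a 0/1/? matrix from NEXUS (restriction/standard data block), CSV or TSV.

    The format is inferred from the file suffix when not given.
    """
    path = Path(path)
    if format is None:
        format = {".nex": "nexus", ".nexus": "nexus", ".csv": "csv", ".tsv": "tsv"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer matrix format from suffix of {path.name!r}")
    text = path.read_text()
    if format == "nexus":
        return _read_nexus_matrix(text)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(io.StringIO(text), sep=sep, index_col=0, dtype=str)
        taxa = [str(t) for t in df.index]
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon identifiers in matrix file")
        chars = [str(c) for c in df.columns]
        rows = ["".join(df.iloc[i].tolist()) for i in range(len(taxa))]
        return BinaryCharacterMatrix(taxa, chars, _parse_states(rows, taxa))
    raise ValueError(f"unsupported matrix format {format!r}")


_NEXUS_CHARLABELS_RE = re.compile(r"charlabels\s+(.*?);", re.IGNORECASE | re.DOTALL)


def _read_nexus_matrix(text: str) -> BinaryCharacterMatrix:
    """Parse a MrBayes-style NEXUS DATA/CHARACTERS block of 0/1/? symbols.

    dendropy does the heavy lifting (quoting, interleaving, comments); the
    optional CHARLABELS statement is recovered separately since dendropy
    does not retain it.
    """
    import dendropy

    dmat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus", preserve_underscores=True)
    taxa = [t.label for t in dmat.taxon_namespace]
    rows = ["".join(str(s.symbol) for s in dmat[t]) for t in dmat.taxon_namespace]
    if not rows:
        raise ValueError("no MATRIX statement found in NEXUS file")
    (nchar,) = {len(r) for r in rows}
    cm = _NEXUS_CHARLABELS_RE.search(text)
    if cm is not None:
        chars = cm.group(1).split()
        if len(chars) != nchar:
            raise ValueError("CHARLABELS count does not match matrix width")
    else:
        chars = [f"c{j + 1}" for j in range(nchar)]
    return BinaryCharacterMatrix(taxa, chars, _parse_states(rows, taxa))


def write_binary_matrix(matrix: BinaryCharacterMatrix, path, format: Optional[str] = None) -> None:
    """Write as NEXUS (datatype=restriction, symbols 0/1, missing ?), CSV or TSV."""
    path = Path(path)
    if format is None:
        format = {".nex": "nexus", ".nexus": "nexus", ".csv": "csv", ".tsv": "tsv"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer matrix format from suffix of {path.name!r}")
    sym = np.array(["0", "1", "?"])
    if format == "nexus":
        with open(path, "w") as fh:
            fh.write("#NEXUS\n[states: 0=absent 1=present ?=unknown (-/N accepted on read)]\n")
            fh.write("BEGIN DATA;\n")
            fh.write(f"    DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={len(matrix.characters)};\n")
            fh.write('    FORMAT DATATYPE=RESTRICTION MISSING=? GAP=- SYMBOLS="01";\n')
            fh.write("    CHARLABELS\n        " + " ".join(matrix.characters) + "\n    ;\n")
            fh.write("    MATRIX\n")
            width = max(len(t) for t in matrix.taxa) + 2
            for i, t in enumerate(matrix.taxa):
                name = f"'{t}'" if re.search(r"[\s()\[\]{}/\\,;:=*'\"`+<>-]", t) else t
                fh.write(f"        {name:<{width}} " + "".join(sym[matrix.states[i]]) + "\n")
            fh.write("    ;\nEND;\n")
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        matrix.to_frame().to_csv(path, sep=sep, index_label="taxon")
    else:
        raise ValueError(f"unsupported matrix format {format!r}")


def read_group_labels(path) -> dict[str, str]:
    """Read a sidecar two-column (taxon, label) TSV; a header line is optional."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"expected two tab-separated columns, got {line!r}")
        if parts[0].lower() == "taxon" and parts[1].lower() in ("label", "group"):
            continue
        out[parts[0]] = parts[1]
    return out


# ------------------------------------------------------------ phyletic counts
def sharing_partition(matrix: BinaryCharacterMatrix, groups: Optional[Mapping[str, str]] = None) -> VennCounts:
    """Count characters by the exact subset of groups in which they occur.

    A character counts toward a group iff at least one taxon of that group
    has state *present*; unknown never counts as present.
    """
    groups = groups if groups is not None else matrix.groups
    if groups is None:
        raise ValueError("no group labels supplied")
    unlabeled = [t for t in matrix.taxa if t not in groups]
    if unlabeled:
        raise ValueError(f"unlabeled taxa: {unlabeled[:5]}")
    labels = sorted(set(groups[t] for t in matrix.taxa))
    present = matrix.states == PRESENT  # (ntaxa, nchar)
    by_group = {
        lab: present[[i for i, t in enumerate(matrix.taxa) if groups[t] == lab]].any(axis=0) for lab in labels
    }
    counts: dict[frozenset, int] = {}
    observed = np.zeros(len(matrix.characters), dtype=bool)
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = np.logical_and.reduce([by_group[lab] for lab in combo])
            outside = np.logical_or.reduce([by_group[lab] for lab in labels if lab not in combo] or [np.zeros_like(inside)])
            exact = inside & ~outside
            counts[frozenset(combo)] = int(exact.sum())
            observed |= inside
    return VennCounts(counts=counts, total_observed=int(observed.sum()), total_characters=len(matrix.characters))


def filter_characters(matrix: BinaryCharacterMatrix, policy: str = "none") -> tuple[BinaryCharacterMatrix, list[str]]:
    """Drop characters per policy; returns (filtered matrix, dropped character IDs).

    Policies: ``none`` (identity), ``drop-all-absent`` (no observed presence),
    ``drop-constant`` (fewer than two distinct observed states).
    """
    if policy == "none":
        return matrix, []
    if policy == "drop-all-absent":
        keep = (matrix.states == PRESENT).any(axis=0)
    elif policy == "drop-constant":
        has0 = (matrix.states == ABSENT).any(axis=0)
        has1 = (matrix.states == PRESENT).any(axis=0)
        keep = has0 & has1
    else:
        raise ValueError(f"unknown filter policy {policy!r}")
    if not keep.any():
        raise ValueError(f"policy {policy!r} removes every character")
    dropped = [c for c, k in zip(matrix.characters, keep) if not k]
    sub = BinaryCharacterMatrix(
        matrix.taxa, [c for c, k in zip(matrix.characters, keep) if k], matrix.states[:, keep], matrix.groups
    )
    return sub, dropped


# ---------------------------------------------------------------- alignments
_AA = set("ACDEFGHIKLMNPQRSTVWY")
_GAPS = set("-.")
_AMBIG = set("XBZJUO*?")

SR4_SCHEME: dict[str, str] = {}
for _cls, _members in zip("ACGT", ("AGNPST", "CHWY", "DEKQR", "FILMV")):
    for _aa in _members:
        SR4_SCHEME[_aa] = _cls


class ResidueAlignment:
    """An aligned set of residue sequences over a declared alphabet."""

    def __init__(self, taxa: Sequence[str], rows: Sequence[str], alphabet: str = "amino-acid"):
        taxa = list(taxa)
        rows = [r.upper() for r in rows]
        if len(taxa) != len(rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon identifiers in alignment")
        if len({len(r) for r in rows}) > 1:
            raise ValueError("alignment rows have unequal lengths (ragged alignment)")
        self.taxa = taxa
        self.rows = rows
        self.alphabet = alphabet
        symbols = set("".join(rows))
        allowed = self._allowed_symbols()
        bad = symbols - allowed
        if bad:
            raise ValueError(f"symbols {sorted(bad)} not in alphabet {alphabet!r}")

    def _allowed_symbols(self) -> set[str]:
        if self.alphabet == "nucleotide":
            core = set("ACGTU")
            amb = set("RYSWKMBDHVN?")
        elif self.alphabet == "amino-acid":
            core = set(_AA)
            amb = _AMBIG
        elif self.alphabet.startswith("recoded-"):
            # class labels are scheme-defined; any letter is acceptable
            core = set(_AA) | set("ACGTU")
            amb = _AMBIG
        else:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        return core | amb | _GAPS

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ResidueAlignment)
            and self.taxa == other.taxa
            and self.rows == other.rows
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"ResidueAlignment({len(self.taxa)} × {self.n_columns}, {self.alphabet})"


_ALN_SCHEMAS = {"fasta": "fasta", "phylip": "phylip-relaxed", "phylip-sequential": "phylip-sequential", "nexus": "nexus"}


def read_alignment(path, format: str = "fasta", alphabet: str = "amino-acid") -> ResidueAlignment:
    """Read an alignment via Biopython (``phylip`` covers interleaved; sequential is auto-detected)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty alignment file: {path}")
    if format not in _ALN_SCHEMAS:
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        aln = AlignIO.read(str(path), _ALN_SCHEMAS[format])
    except ValueError:
        if format == "phylip":  # fall back to sequential phylip
            aln = AlignIO.read(str(path), "phylip-sequential")
        else:
            raise
    return ResidueAlignment([r.id for r in aln], [str(r.seq) for r in aln], alphabet=alphabet)


def write_alignment(alignment: ResidueAlignment, path, format: str = "fasta") -> None:
    if format not in _ALN_SCHEMAS:
        raise ValueError(f"unsupported alignment format {format!r}")
    records = [SeqRecord(Seq(r), id=t, description="") for t, r in zip(alignment.taxa, alignment.rows)]
    AlignIO.write(MultipleSeqAlignment(records), str(path), _ALN_SCHEMAS[format])


def recode_alphabet(alignment: ResidueAlignment, scheme: Optional[Mapping[str, str]] = None) -> ResidueAlignment:
    """Collapse the 20 amino acids into k classes (default SR4: AGNPST|CHWY|DEKQR|FILMV).

    Gap and ambiguity symbols map to themselves.
    """
    if alignment.alphabet != "amino-acid":
        raise ValueError("recoding requires an amino-acid alignment")
    scheme = dict(SR4_SCHEME) if scheme is None else dict(scheme)
    missing = _AA - set(scheme)
    if missing:
        raise ValueError(f"recoding scheme missing residues: {sorted(missing)}")
    k = len(set(scheme.values()))
    table = {**{s: s for s in _GAPS | _AMBIG}, **scheme}
    rows = ["".join(table[c] for c in row) for row in alignment.rows]
    alphabet = f"recoded-{k}" if k < 20 else "amino-acid"
    return ResidueAlignment(alignment.taxa, rows, alphabet=alphabet)
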