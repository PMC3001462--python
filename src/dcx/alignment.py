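"""Alignment container, I/O, sequence weighting, column profiles and coordinate maps.

Everything downstream (the contrast statistic, the rendered alignment, the
mutation overlay) works on a gapped protein multiple sequence alignment.  This
module provides the in-memory :class:`Alignment`, readers/writers for aligned
FASTA and Stockholm, Henikoff position-based sequence weighting, weighted
per-column residue profiles, and the mapping from alignment columns to the
numbering of a chosen reference sequence (e.g. pre-mature EGFR numbering,
which counts the 24-residue signal peptide).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino-acid one-letter codes, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
UNKNOWN: str = "X"

_AA_SET = frozenset(AMINO_ACIDS)


class AlignmentShapeError(ValueError):
    """Sequences in an alignment do not all have the same length."""


class AlignmentInputError(ValueError):
    """Malformed alignment input (duplicate ids, empty file, ...)."""


def _normalize(seq: str) -> str:
    """Uppercase, map '.' to '-', and map non-standard letters to 'X'."""
    out = []
    for ch in seq.upper():
        if ch == ".":
            ch = GAP
        elif ch != GAP and ch not in _AA_SET:
            ch = UNKNOWN
        out.append(ch)
    return "".join(out)


@dataclass(frozen=True)
class Alignment:
    """A gapped protein multiple sequence alignment.

    Parameters
    ----------
    records
        Ordered ``(id, gapped_sequence)`` pairs.  All sequences must have the
        same length; ids must be unique and non-empty.  Letters are the 20
        amino acids plus ``'-'`` (gap) and ``'X'`` (unknown).
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentInputError("alignment has no sequences")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"sequences have unequal lengths: {sorted(lengths)}"
            )
        if next(iter(lengths)) < 1:
            raise AlignmentShapeError("alignment has zero columns")
        ids = [i for i, _ in self.records]
        if any(not i for i in ids):
            raise AlignmentInputError("empty sequence id")
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentInputError(f"duplicate sequence ids: {dup}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        return cls(tuple((i, _normalize(s)) for i, s in pairs))

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.records)

    def sequence(self, seq_id: str) -> str:
        for i, s in self.records:
            if i == seq_id:
                return s
        raise KeyError(f"unknown sequence id: {seq_id!r}")

    def index_of(self, seq_id: str) -> int:
        for k, (i, _) in enumerate(self.records):
            if i == seq_id:
                return k
        raise KeyError(f"unknown sequence id: {seq_id!r}")

    def column(self, col: int) -> str:
        if not 0 <= col < self.n_columns:
            raise IndexError(f"column {col} out of range")
        return "".join(s[col] for _, s in self.records)

    def subset(self, seq_ids: Sequence[str]) -> "Alignment":
        """A new alignment containing only ``seq_ids``, in the given order."""
        return Alignment(tuple((i, self.sequence(i)) for i in seq_ids))

    def as_matrix(self) -> np.ndarray:
        """Character matrix of shape ``(n_records, n_columns)``."""
        return np.array([list(s) for _, s in self.records], dtype="U1")

    def codes_matrix(self) -> np.ndarray:
        """Integer codes (index into AMINO_ACIDS; -1 for gap/'X'), cached."""
        cached = self.__dict__.get("_codes")
        if cached is None:
            mat = self.as_matrix()
            cached = np.full(mat.shape, -1, dtype=np.int8)
            for k, a in enumerate(AMINO_ACIDS):
                cached[mat == a] = k
            object.__setattr__(self, "_codes", cached)
        return cached


@dataclass(frozen=True)
class WeightVector:
    """Per-sequence weights in ``(0, 1]``, aligned to ``Alignment.records``.

    ``effective_count`` (the sum of weights) is the effective number of
    sequences after down-weighting redundancy.
    """

    weights: np.ndarray
    method: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a non-empty 1-D array")
        if np.any(w <= 0) or np.any(w > 1 + 1e-12):
            raise ValueError("weights must lie in (0, 1]")

    @property
    def effective_count(self) -> float:
        return float(self.weights.sum())

    def __len__(self) -> int:
        return self.weights.size


@dataclass(frozen=True)
class ResidueFrequency:
    """Weighted residue composition of one alignment column.

    ``freqs`` maps residue letters to weighted relative frequencies among the
    non-gap (standard-residue) letters of the column; they sum to 1 unless the
    column is all-gap (then ``freqs`` is empty).  ``gap_fraction`` is the
    weighted fraction of sequences showing a gap or 'X' at the column.
    """

    column: int
    freqs: Mapping[str, float]
    gap_fraction: float

    def freq(self, residues: Iterable[str]) -> float:
        """Summed frequency of a residue set (0 for absent residues)."""
        return float(sum(self.freqs.get(r, 0.0) for r in residues))

    @property
    def consensus(self) -> str | None:
        """Most frequent residue; ties broken alphabetically; None if all-gap."""
        if not self.freqs:
            return None
        return max(sorted(self.freqs), key=lambda r: self.freqs[r])


@dataclass(frozen=True)
class ReferenceMap:
    """Alignment-column -> reference-residue-number mapping.

    ``signal_peptide_offset`` shifts mature coordinates into pre-mature
    numbering (EGFR convention: +24 for the signal peptide).  Columns where
    the reference sequence has a gap are absent from the map.
    """

    reference_id: str
    signal_peptide_offset: int
    column_to_refpos: Mapping[int, int]

    def refpos(self, column: int) -> int | None:
        return self.column_to_refpos.get(column)

    def column_for(self, refpos: int) -> int | None:
        for c, p in self.column_to_refpos.items():
            if p == refpos:
                return c
        return None


# ---------------------------------------------------------------------------
# I/O


def read_alignment(path: str | Path, format: str | None = None) -> Alignment:
    """Read an aligned FASTA or Stockholm file.

    ``format`` is ``'fasta'`` or ``'stockholm'``; when None it is guessed from
    the file suffix (``.sto``/``.stk``/``.stockholm`` -> Stockholm, else
    FASTA).  Letters are uppercased, ``'.'`` normalised to ``'-'`` and
    non-standard letters to ``'X'``.
    """
    path = Path(path)
    if format is None:
        format = (
            "stockholm"
            if path.suffix.lower() in {".sto", ".stk", ".stockholm"}
            else "fasta"
        )
    if format not in {"fasta", "stockholm"}:
        raise ValueError(f"unsupported alignment format: {format!r}")
    try:
        records = list(AlignIO.read(str(path), format))
    except ValueError as exc:
        # Biopython raises on ragged FASTA and on empty files.
        msg = str(exc)
        if "same length" in msg or "one record" in msg.lower():
            if "No records" in msg or "one record" in msg.lower():
                # Distinguish empty input from ragged rows.
                from Bio import SeqIO

                raw = list(SeqIO.parse(str(path), format))
                if not raw:
                    raise AlignmentInputError(f"empty alignment file: {path}") from exc
                return Alignment.from_pairs((r.id, str(r.seq)) for r in raw)
            raise AlignmentShapeError(msg) from exc
        raise AlignmentInputError(msg) from exc
    if not records:
        raise AlignmentInputError(f"empty alignment file: {path}")
    return Alignment.from_pairs((r.id, str(r.seq)) for r in records)


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write the alignment as aligned FASTA or Stockholm."""
    if format not in {"fasta", "stockholm"}:
        raise ValueError(f"unsupported alignment format: {format!r}")
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(s), id=i, description="") for i, s in aln.records
    )
    AlignIO.write(msa, str(path), format)


def read_partition_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of ``sequence_id<TAB>{fore|back|query}``.

    Lines starting with '#' and blank lines are skipped.  A header line with
    the literal fields is tolerated.
    """
    labels: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise AlignmentInputError(f"{path}:{ln}: expected 2 tab-separated fields")
        sid, lab = parts[0].strip(), parts[1].strip().lower()
        if ln == 1 and lab not in {"fore", "back", "query"}:
            continue  # header
        if lab not in {"fore", "back", "query"}:
            raise AlignmentInputError(f"{path}:{ln}: unknown label {lab!r}")
        if sid in labels:
            raise AlignmentInputError(f"{path}:{ln}: duplicate id {sid!r}")
        labels[sid] = lab
    if not labels:
        raise AlignmentInputError(f"no partition labels in {path}")
    return labels


def write_partition_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, lab in labels.items():
            fh.write(f"{sid}\t{lab}\n")


# ---------------------------------------------------------------------------
# Weighting and profiles


def compute_weights(aln: Alignment, method: str = "position_based") -> WeightVector:
    """Per-sequence weights down-weighting redundant sequences.

    ``position_based`` is Henikoff & Henikoff position-based weighting: at
    each column a sequence showing residue ``a`` receives ``1 / (r * s)``
    where ``r`` is the number of distinct residues in the column and ``s`` the
    number of sequences showing ``a``; gaps and 'X' contribute nothing.  Raw
    weights are summed over columns and rescaled so the maximum weight is 1.
    ``uniform`` assigns every sequence weight 1.
    """
    n = aln.n_records
    if method == "uniform":
        return WeightVector(np.ones(n), "uniform")
    if method != "position_based":
        raise ValueError(f"unknown weighting method: {method!r}")
    raw = np.zeros(n)
    mat = aln.as_matrix()
    for col in range(aln.n_columns):
        letters = mat[:, col]
        mask = np.isin(letters, list(_AA_SET))
        if not mask.any():
            continue
        uniq, inv, counts = np.unique(
            letters[mask], return_inverse=True, return_counts=True
        )
        r = uniq.size
        contrib = 1.0 / (r * counts[inv])
        raw[mask] += contrib
    if raw.max() <= 0:  # every sequence all-gap; degenerate but legal
        return WeightVector(np.ones(n), "position_based")
    # Sequences with no scored column (all-gap rows) get the minimum positive
    # raw weight so the (0, 1] invariant holds.
    positive_min = raw[raw > 0].min()
    raw[raw <= 0] = positive_min
    return WeightVector(raw / raw.max(), "position_based")


def column_profile(
    aln: Alignment,
    w: WeightVector,
    subset: Sequence[int] | None = None,
) -> list[ResidueFrequency]:
    """Weighted residue profiles for every column, over a sequence subset.

    Residue frequencies are conditional on non-gap: ``freqs[r]`` is the summed
    weight of subset sequences showing ``r`` divided by the summed weight of
    subset sequences showing any standard residue at the column.  Gaps and 'X'
    count toward ``gap_fraction`` only.  An all-gap column yields empty
    ``freqs`` and ``gap_fraction`` 1.
    """
    if len(w) != aln.n_records:
        raise ValueError("weight vector length does not match alignment")
    if subset is None:
        subset = range(aln.n_records)
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    if min(subset) < 0 or max(subset) >= aln.n_records:
        raise IndexError("subset index out of range")
    ww = w.weights[subset]
    total = ww.sum()
    mat = aln.as_matrix()[subset, :]
    out: list[ResidueFrequency] = []
    for col in range(aln.n_columns):
        letters = mat[:, col]
        mask = np.isin(letters, list(_AA_SET))
        denom = ww[mask].sum()
        if denom <= 0:
            out.append(ResidueFrequency(col, {}, 1.0))
            continue
        freqs: dict[str, float] = {}
        for r in np.unique(letters[mask]):
            freqs[str(r)] = float(ww[mask][letters[mask] == r].sum() / denom)
        gap_fraction = float((total - denom) / total)
        out.append(ResidueFrequency(col, freqs, gap_fraction))
    return out


def map_columns(
    aln: Alignment, reference_id: str, signal_peptide_offset: int = 24
) -> ReferenceMap:
    """Map alignment columns to reference residue numbers.

    The reference residue at the ``i``-th non-gap position (1-based) of the
    reference row is numbered ``i + signal_peptide_offset``; use offset 0 when
    the reference sequence is supplied already in pre-mature coordinates.
    """
    if signal_peptide_offset < 0:
        raise ValueError("signal_peptide_offset must be non-negative")
    seq = aln.sequence(reference_id)  # KeyError for unknown id
    mapping: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(seq):
        if ch != GAP:
            pos += 1
            mapping[col] = pos + signal_peptide_offset
    return ReferenceMap(reference_id, signal_peptide_offset, mapping)
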