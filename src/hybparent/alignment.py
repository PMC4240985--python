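"""Multiple sequence alignment container and FASTA input/output.

The :class:`Alignment` is the unit every statistic and tree in this package
consumes: a rectangular block of upper-case nucleotide rows over the alphabet
``{A, C, G, T, N, -}`` with unique taxon labels.  ``N`` and ``-`` are treated
as missing data throughout (the "gaps as missing" policy); a strict mode that
treats gaps as a fifth state is exposed where relevant.

FASTA reading and writing go through Biopython so that real-world files
(wrapped lines, mixed case, CR/LF) behave as users expect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_STATES = frozenset(b"ACGTN-")
#: byte codes considered missing data under the default gap/N policy
MISSING = frozenset(b"N-")


class AlignmentError(ValueError):
    """Raised for structurally invalid alignments (ragged rows, dup labels)."""


@dataclass
class Alignment:
    """Equal-length gapped nucleotide rows with unique taxon labels.

    Parameters
    ----------
    labels:
        One unique label per row.
    matrix:
        ``(n_rows, n_cols)`` array of ASCII byte values (dtype ``uint8``).
    locus:
        Identifier of the locus the alignment represents.
    genome:
        ``"nuclear"`` or ``"chloroplast"`` (or ``""`` when irrelevant).
    partitions:
        Optional list of ``(locus_id, start, end)`` half-open column ranges,
        recorded by :func:`hybparent.treekit.concatenate`.
    """

    labels: list[str]
    matrix: np.ndarray
    locus: str = ""
    genome: str = ""
    partitions: list[tuple[str, int, int]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-dimensional")
        if len(self.labels) != self.matrix.shape[0]:
            raise AlignmentError(
                f"{len(self.labels)} labels for {self.matrix.shape[0]} rows"
            )
        if len(set(self.labels)) != len(self.labels):
            dups = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise AlignmentError(f"duplicate taxon labels: {dups}")
        bad = set(np.unique(self.matrix).tobytes()) - set(VALID_STATES)
        if bad:
            raise AlignmentError(
                "invalid alignment characters: "
                + ", ".join(repr(chr(b)) for b in sorted(bad))
            )

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_seqs(
        cls,
        labels: Sequence[str],
        seqs: Sequence[str],
        locus: str = "",
        genome: str = "",
    ) -> "Alignment":
        labels = list(labels)
        seqs = [s.upper() for s in seqs]
        if not seqs:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged rows: lengths {sorted(lengths)}")
        mat = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
        return cls(labels, mat.reshape(len(seqs), -1).copy(), locus, genome)

    # -- basic views -------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def row(self, label: str) -> str:
        return self.sequence(self.labels.index(label))

    def sequence(self, i: int) -> str:
        return self.matrix[i].tobytes().decode("ascii")

    def sequences(self) -> list[str]:
        return [self.sequence(i) for i in range(self.n_rows)]

    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where a cell is ``N`` or ``-``."""
        return (self.matrix == ord("N")) | (self.matrix == ord("-"))

    def take_rows(self, indices: Iterable[int]) -> "Alignment":
        idx = list(indices)
        return Alignment(
            [self.labels[i] for i in idx], self.matrix[idx].copy(),
            self.locus, self.genome,
        )

    def take_columns(self, indices: np.ndarray) -> "Alignment":
        return Alignment(
            list(self.labels), self.matrix[:, indices].copy(),
            self.locus, self.genome,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(
            self.matrix, other.matrix
        )


# -- FASTA ----------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(label, sequence)`` pairs.

    Sequences are normalised to upper case; labels are the full description
    line (so ``SPECIES|acc``-style labels survive intact).  Duplicate labels
    raise :class:`AlignmentError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    labels = [r.description for r in records]
    if len(set(labels)) != len(labels):
        dups = sorted({l for l in labels if labels.count(l) > 1})
        raise AlignmentError(f"duplicate labels in {path}: {dups}")
    return [(r.description, str(r.seq).upper()) for r in records]


def read_alignment(
    path: str | Path, locus: str = "", genome: str = ""
) -> Alignment:
    """Read an aligned FASTA file, validating rectangularity."""
    pairs = read_fasta(path)
    if not pairs:
        raise AlignmentError(f"no sequences in {path}")
    labels, seqs = zip(*pairs)
    if not locus:
        locus = Path(path).stem
    return Alignment.from_seqs(list(labels), list(seqs), locus, genome)


def write_fasta(
    pairs: Iterable[tuple[str, str]], path: str | Path, width: int = 70
) -> None:
    records = [
        SeqRecord(Seq(seq), id=label, description="") for label, seq in pairs
    ]
    handle = io.StringIO()
    SeqIO.write(records, handle, "fasta")
    # Biopython splits description on whitespace into id; our labels have no
    # spaces so id == full label.
    Path(path).write_text(handle.getvalue())


def write_alignment(aln: Alignment, path: str | Path) -> None:
    write_fasta(zip(aln.labels, aln.sequences()), path)
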