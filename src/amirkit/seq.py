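"""Core nucleotide-sequence types and elementary operations.

Everything downstream (candidate scanning, thermodynamics, off-target
screening, scaffold assembly) works on :class:`NucSeq`, a thin identified
sequence over {A, C, G, T, U} that knows whether it is DNA or RNA.

Conventions used throughout the package:

* coordinates are 0-based half-open internally; 1-based positions appear
  only in user-facing reports,
* T and U are treated as equivalent for matching and complementation
  (comparisons canonicalize RNA to DNA),
* lowercase input is accepted and uppercased on normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class SequenceError(ValueError):
    """Raised for malformed or alphabet-violating sequence input."""


@dataclass(frozen=True)
class NucSeq:
    """An identified nucleotide sequence with an explicit alphabet.

    Parameters
    ----------
    id : str
        Record label (FASTA-style identifier).
    seq : str
        Uppercase bases over the declared alphabet.
    alphabet : str
        ``"DNA"`` or ``"RNA"``.
    """

    id: str
    seq: str
    alphabet: str = "DNA"

    def __post_init__(self) -> None:
        legal = DNA_ALPHABET if self.alphabet == "DNA" else RNA_ALPHABET
        if self.alphabet not in ("DNA", "RNA"):
            raise SequenceError(f"unknown alphabet {self.alphabet!r}")
        for i, base in enumerate(self.seq):
            if base not in legal:
                raise SequenceError(
                    f"illegal symbol {base!r} at offset {i} for {self.alphabet}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def __getitem__(self, key) -> str:
        return self.seq[key]

    def as_dna(self) -> "NucSeq":
        """Canonicalize to DNA (U -> T); identity for DNA input."""
        if self.alphabet == "DNA":
            return self
        return NucSeq(self.id, self.seq.replace("U", "T"), "DNA")

    def as_rna(self) -> "NucSeq":
        """Canonicalize to RNA (T -> U); identity for RNA input."""
        if self.alphabet == "RNA":
            return self
        return NucSeq(self.id, self.seq.replace("T", "U"), "RNA")


def normalize(raw: str, id: str = "seq") -> NucSeq:
    """Normalize raw text into a :class:`NucSeq`.

    Whitespace and digits are stripped, letters are uppercased, and the
    alphabet is auto-detected: any U present forces RNA, otherwise DNA.
    Mixed T and U, or any symbol outside {A, C, G, T, U}, is rejected with
    the offending symbol and its offset (in the cleaned sequence).
    """
    cleaned = "".join(c for c in raw if not c.isspace() and not c.isdigit())
    if not cleaned:
        raise SequenceError("empty sequence after whitespace/digit removal")
    cleaned = cleaned.upper()
    for i, base in enumerate(cleaned):
        if base not in "ACGTU":
            raise SequenceError(f"illegal symbol {base!r} at offset {i}")
    has_u = "U" in cleaned
    has_t = "T" in cleaned
    if has_u and has_t:
        raise SequenceError("sequence mixes T and U; alphabet is ambiguous")
    return NucSeq(id, cleaned, "RNA" if has_u else "DNA")


def revcomp(s: NucSeq) -> NucSeq:
    """Watson-Crick reverse complement in the same alphabet."""
    table = _DNA_COMPLEMENT if s.alphabet == "DNA" else _RNA_COMPLEMENT
    return NucSeq(s.id, s.seq.translate(table)[::-1], s.alphabet)


def gc_percent(s: NucSeq) -> float:
    """GC content as a percentage: 100 * (#G + #C) / length."""
    if len(s) == 0:
        raise SequenceError("GC content undefined for an empty sequence")
    gc = sum(1 for b in s.seq if b in "GC")
    return 100.0 * gc / len(s)


def max_homopolymer_run(s: NucSeq) -> int:
    """Length of the longest run of one identical base."""
    if len(s) == 0:
        return 0
    best = run = 1
    for prev, cur in zip(s.seq, s.seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def read_fasta(path) -> List[NucSeq]:
    """Read a multi-record FASTA file into normalized :class:`NucSeq` records.

    Duplicate IDs trigger a warning but both records are kept.
    """
    path = Path(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise SequenceError(f"malformed header in {path}")
        if rec.id in seen:
            warnings.warn(f"duplicate FASTA id {rec.id!r} in {path}; keeping both")
        seen.add(rec.id)
        records.append(normalize(str(rec.seq), id=rec.id))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[NucSeq], path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    path = Path(path)
    seq_records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)
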