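"""Assembly and parsing of miR-155-backbone artificial-miRNA constructs.

A construct embeds a 21-nt antisense (guide) sequence into the miR-155
hairpin backbone as

    5' arm - antisense(21 nt) - loop - sense(19 nt) - 3' arm

where the 19-nt sense strand is the reverse complement of the antisense
with nucleotides 10 and 11 (1-based) deleted — the deletion leaves a bulge
in the hairpin stem that biases processing toward loading the guide.

The arm sequences are defined operationally as the longest common prefix
and suffix of the three reference constructs shipped with the package
(``amirkit/data/mir155_constructs.fasta``); the backbone does not exist in
this codebase in any other form. Cloning-site content inside the arms is
treated as opaque verbatim flank sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Tuple

from .seq import NucSeq, normalize, read_fasta, revcomp

#: canonical 1-based sense-strand positions deleted during embedding
CANONICAL_DELETION: Tuple[int, int] = (10, 11)


class ScaffoldError(ValueError):
    """Raised when a construct cannot be assembled or parsed."""


def reference_constructs() -> List[NucSeq]:
    """The three reference constructs shipped with the package (normalized)."""
    with resources.as_file(
        resources.files("amirkit.data").joinpath("mir155_constructs.fasta")
    ) as path:
        return read_fasta(path)


@dataclass(frozen=True)
class ScaffoldSpec:
    """The invariant parts of the miR-155 backbone."""

    arm5: NucSeq
    loop: NucSeq
    arm3: NucSeq
    delete_positions: Tuple[int, int] = CANONICAL_DELETION

    def __post_init__(self) -> None:
        if not self.arm5.seq.endswith("TGCTG"):
            raise ScaffoldError("5' arm must end with TGCTG")
        if not self.arm3.seq.startswith("CAGGA"):
            raise ScaffoldError("3' arm must start with CAGGA")
        if len(self.loop) != 19:
            raise ScaffoldError("loop must be 19 nt")
        if not all(1 <= p <= 21 for p in self.delete_positions):
            raise ScaffoldError("delete positions must lie in 1..21")


def _common_prefix(seqs: List[str]) -> str:
    first = min(seqs, key=len)
    for i, c in enumerate(first):
        if any(s[i] != c for s in seqs):
            return first[:i]
    return first


def default_scaffold() -> ScaffoldSpec:
    """Backbone derived from the packaged reference constructs.

    arm5 = longest common prefix (73 nt), arm3 = longest common suffix
    (90 nt); the loop is the invariant 19-mer between guide and sense.
    """
    seqs = [r.seq for r in reference_constructs()]
    arm5 = _common_prefix(seqs)
    arm3 = _common_prefix([s[::-1] for s in seqs])[::-1]
    return ScaffoldSpec(
        arm5=NucSeq("miR155_5arm", arm5, "DNA"),
        loop=NucSeq("miR155_loop", "GTTTTGGCCACTGACTGAC", "DNA"),
        arm3=NucSeq("miR155_3arm", arm3, "DNA"),
    )


@dataclass(frozen=True)
class AmiRConstruct:
    """A fully assembled artificial-miRNA construct."""

    name: str
    antisense21: NucSeq
    sense19: NucSeq
    full: NucSeq


def _delete_positions(seq: str, positions: Tuple[int, ...]) -> str:
    drop = {p - 1 for p in positions}
    return "".join(b for i, b in enumerate(seq) if i not in drop)


def build(antisense21: NucSeq, spec: Optional[ScaffoldSpec] = None, name: Optional[str] = None) -> AmiRConstruct:
    """Embed a 21-nt antisense (guide) into the scaffold.

    The sense strand is revcomp(antisense) with the spec's delete positions
    (default nt 10 and 11, 1-based) removed, giving the printed
    arm5-antisense-loop-sense19-arm3 layout.
    """
    spec = spec or default_scaffold()
    antisense21 = antisense21.as_dna()
    if len(antisense21) != 21:
        raise ScaffoldError(f"antisense must be 21 nt, got {len(antisense21)}")
    sense19 = _delete_positions(revcomp(antisense21).seq, spec.delete_positions)
    name = name or antisense21.id
    full = spec.arm5.seq + antisense21.seq + spec.loop.seq + sense19 + spec.arm3.seq
    return AmiRConstruct(
        name=name,
        antisense21=NucSeq(f"{name}_antisense", antisense21.seq, "DNA"),
        sense19=NucSeq(f"{name}_sense19", sense19, "DNA"),
        full=NucSeq(name, full, "DNA"),
    )


def _find_once(haystack: str, needle: str, label: str) -> int:
    first = haystack.find(needle)
    if first < 0:
        raise ScaffoldError(f"{label} not found in construct")
    if haystack.find(needle, first + 1) >= 0:
        raise ScaffoldError(f"{label} occurs more than once in construct")
    return first


def parse(full: NucSeq, spec: Optional[ScaffoldSpec] = None) -> AmiRConstruct:
    """Inverse of :func:`build`: split a construct at the backbone landmarks.

    Requires arm5, loop and arm3 to occur exactly once each and in order;
    the segments between them are the antisense (21 nt) and the deleted
    sense (19 nt). ``parse(build(x)) == x`` for any valid guide.
    """
    spec = spec or default_scaffold()
    full = full.as_dna()
    s = full.seq
    i5 = _find_once(s, spec.arm5.seq, "5' arm")
    iloop = _find_once(s, spec.loop.seq, "loop")
    i3 = _find_once(s, spec.arm3.seq, "3' arm")
    a_start = i5 + len(spec.arm5)
    if not (a_start <= iloop and iloop + len(spec.loop) <= i3):
        raise ScaffoldError("landmarks out of order")
    antisense = s[a_start:iloop]
    sense = s[iloop + len(spec.loop) : i3]
    if len(antisense) != 21:
        raise ScaffoldError(f"antisense segment is {len(antisense)} nt, expected 21")
    if len(sense) != 19:
        raise ScaffoldError(f"sense segment is {len(sense)} nt, expected 19")
    return AmiRConstruct(
        name=full.id,
        antisense21=NucSeq(f"{full.id}_antisense", antisense, "DNA"),
        sense19=NucSeq(f"{full.id}_sense19", sense, "DNA"),
        full=full,
    )


def deletion_candidates(sense19: NucSeq, antisense21: NucSeq) -> List[Tuple[int, int]]:
    """All adjacent 1-based position pairs whose deletion from
    revcomp(antisense21) yields sense19, in increasing order."""
    if len(sense19) != 19 or len(antisense21) != 21:
        raise ScaffoldError("need a 19-nt sense and a 21-nt antisense")
    full = revcomp(antisense21.as_dna()).seq
    target = sense19.as_dna().seq
    return [
        (i + 1, i + 2)
        for i in range(20)
        if full[:i] + full[i + 2 :] == target
    ]


def infer_deletion(
    sense19: NucSeq,
    antisense21: NucSeq,
    prefer: Optional[Tuple[int, int]] = CANONICAL_DELETION,
) -> Tuple[int, ...]:
    """1-based adjacent positions deleted from the full sense strand.

    Repeats can make the deletion ambiguous (several adjacent pairs yield
    the same 19-mer). The tie-break prefers the scaffold's canonical pair
    (10, 11) when it is among the valid pairs, and otherwise returns the
    smallest valid pair. Returns an empty tuple when no adjacent deletion
    explains the sense segment.
    """
    cands = deletion_candidates(sense19, antisense21)
    if not cands:
        return ()
    if prefer is not None and tuple(prefer) in cands:
        return tuple(prefer)
    return cands[0]
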