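"""Enumerate and filter siRNA duplex candidates on a target transcript.

A candidate is a 23-nt window on the target whose sense strand satisfies a
positional duplex consensus (N2[CG]N8[AUT]N8[AUT]N2), avoids homopolymer
runs of four or more identical bases, and has a GC content inside a
configured band (default 45-50%, the only attainable G+C count for a 21-mer
being 10, i.e. 47.62%).

Where the 21-nt duplex sits inside the 23-nt window is a convention, not a
biological fact: the default places it at window offset 1 (centered), and
``sense_offset`` makes it configurable. Every filter can be toggled off
independently so designs that violate one rule can still be carried through
the downstream thermodynamic and off-target stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple
import warnings

from .seq import NucSeq, gc_percent, max_homopolymer_run, revcomp

#: consensus position -> allowed bases, 1-based within the 23-nt window.
#: [AUT] mixes RNA and DNA wording; windows are canonicalized to DNA, so
#: U collapses onto T.
DEFAULT_CONSENSUS_POSITIONS: Dict[int, str] = {3: "CG", 12: "AT", 21: "AT"}


@dataclass(frozen=True)
class ConsensusSpec:
    """Positional consensus for the 23-nt duplex window."""

    window_len: int = 23
    fixed_positions: Tuple[Tuple[int, str], ...] = tuple(
        sorted(DEFAULT_CONSENSUS_POSITIONS.items())
    )
    sense_offset: int = 1  # 0-based start of the 21-nt sense within the window

    def __post_init__(self) -> None:
        if self.window_len != 23:
            raise ValueError("consensus window length is fixed at 23 nt")
        if not 0 <= self.sense_offset <= self.window_len - 21:
            raise ValueError("sense_offset must leave a full 21-mer in the window")


@dataclass(frozen=True)
class FilterConfig:
    """Toggleable candidate filters and their bounds (GC bounds inclusive)."""

    gc_min: float = 45.0
    gc_max: float = 50.0
    max_run_allowed: int = 3
    check_consensus: bool = True
    check_gc: bool = True
    check_run: bool = True
    gc_on_full_window: bool = False  # GC over the 23-nt window instead of sense21
    regions_of_interest: Optional[Tuple[Tuple[int, int], ...]] = None

    def __post_init__(self) -> None:
        if not 0 <= self.gc_min <= self.gc_max <= 100:
            raise ValueError("need 0 <= gc_min <= gc_max <= 100")


@dataclass(frozen=True)
class DuplexCandidate:
    """A 23-nt window candidate with its 21-nt duplex and filter diagnostics."""

    target_id: str
    window_start: int  # 0-based on the target
    sense21: NucSeq
    antisense21: NucSeq
    gc: float
    max_run: int
    consensus_ok: bool
    gc_ok: bool
    run_ok: bool

    @property
    def passes(self) -> bool:
        return self.consensus_ok and self.gc_ok and self.run_ok


def _window_diagnostics(
    target_id: str,
    window: str,
    start: int,
    consensus: ConsensusSpec,
    filters: FilterConfig,
) -> DuplexCandidate:
    sense = NucSeq(
        f"{target_id}:{start}",
        window[consensus.sense_offset : consensus.sense_offset + 21],
        "DNA",
    )
    gc_seq = NucSeq("w", window, "DNA") if filters.gc_on_full_window else sense
    gc = gc_percent(gc_seq)
    run = max_homopolymer_run(NucSeq("w", window, "DNA"))
    consensus_ok = all(window[pos - 1] in allowed for pos, allowed in consensus.fixed_positions)
    gc_ok = filters.gc_min <= gc <= filters.gc_max
    run_ok = run <= filters.max_run_allowed
    if not filters.check_consensus:
        consensus_ok = True
    if not filters.check_gc:
        gc_ok = True
    if not filters.check_run:
        run_ok = True
    return DuplexCandidate(
        target_id=target_id,
        window_start=start,
        sense21=sense,
        antisense21=revcomp(sense),
        gc=gc,
        max_run=run,
        consensus_ok=consensus_ok,
        gc_ok=gc_ok,
        run_ok=run_ok,
    )


def _in_regions(start: int, window_len: int, regions) -> bool:
    if not regions:
        return True
    return any(start >= lo and start + window_len <= hi for lo, hi in regions)


def scan(
    target: NucSeq,
    consensus: ConsensusSpec = ConsensusSpec(),
    filters: FilterConfig = FilterConfig(),
) -> List[DuplexCandidate]:
    """Return every 23-nt window of ``target`` passing all enabled filters.

    Output is sorted by ``window_start`` and deterministic. Overlapping
    windows are all reported; selecting among them is the designer's job.
    A target shorter than the window yields an empty list with a warning.
    """
    target = target.as_dna()
    n = len(target)
    w = consensus.window_len
    if n < w:
        warnings.warn(f"target {target.id!r} shorter than the {w}-nt window; no candidates")
        return []
    out: List[DuplexCandidate] = []
    for start in range(n - w + 1):
        if not _in_regions(start, w, filters.regions_of_interest):
            continue
        cand = _window_diagnostics(target.id, target.seq[start : start + w], start, consensus, filters)
        if cand.passes:
            out.append(cand)
    return out


def validate_candidate(
    cand: DuplexCandidate,
    consensus: ConsensusSpec = ConsensusSpec(),
    filters: FilterConfig = FilterConfig(),
    window: Optional[str] = None,
) -> Dict[str, bool]:
    """Independently re-check one candidate, one rule at a time.

    Recomputes every rule from the candidate's sequences (or from the full
    23-nt ``window`` when provided) without reusing the stored diagnostics;
    used as the scan's oracle. Returns a per-rule verdict dict with keys
    ``consensus_ok``, ``gc_ok``, ``run_ok`` and the conjunction ``all_ok``.
    """
    report: Dict[str, bool] = {}

    if window is not None:
        consensus_ok = True
        for pos, allowed in consensus.fixed_positions:
            if window[pos - 1] not in allowed:
                consensus_ok = False
        gc_source = window if filters.gc_on_full_window else cand.sense21.seq
        run_source = window
    else:
        consensus_ok = True
        for pos, allowed in consensus.fixed_positions:
            idx = (pos - 1) - consensus.sense_offset  # window pos -> sense index
            if 0 <= idx < 21 and cand.sense21.seq[idx] not in allowed:
                consensus_ok = False
        gc_source = cand.sense21.seq
        run_source = cand.sense21.seq

    gc_count = sum(1 for b in gc_source if b in "GC")
    gc = 100.0 * gc_count / len(gc_source)
    report["consensus_ok"] = consensus_ok if filters.check_consensus else True
    report["gc_ok"] = (filters.gc_min <= gc <= filters.gc_max) if filters.check_gc else True

    longest = 0
    current = 0
    prev = ""
    for b in run_source:
        current = current + 1 if b == prev else 1
        prev = b
        longest = max(longest, current)
    report["run_ok"] = (longest <= filters.max_run_allowed) if filters.check_run else True
    report["all_ok"] = report["consensus_ok"] and report["gc_ok"] and report["run_ok"]
    return report
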