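"""Off-target screening by longest contiguous exact match, and scrambled controls.

The screen replaces a database BLAST with the quantity the selection
thresholds are actually phrased in: the longest contiguous stretch of
exact identity between a candidate and any transcript in a supplied FASTA.
Two orientations are searched by default — the candidate sequence itself
(``sense_match``) and its reverse complement, i.e. the target-site
sequence a guide could pair with (``guide_match``). Mismatches and gaps
are not modelled; this is a conservative exact-match simplification.

Candidates are discarded when their best off-target match exceeds a
threshold (default 17 nt, strict: a 17-mer survives, an 18-mer does not).
Scrambled controls are composition-preserving permutations of a guide
accepted only when their best transcriptome match stays strictly below a
second threshold (default 15 nt).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .seq import NucSeq, max_homopolymer_run, revcomp


class ScreenError(ValueError):
    """Raised when a screen has nothing to run against."""


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and exclusions for the off-target screen."""

    discard_over: int = 17       # candidates with match > this are discarded
    scr_max_match: int = 15      # scrambles must match strictly below this
    excluded_subject_ids: FrozenSet[str] = frozenset()
    check_both_orientations: bool = True

    def __post_init__(self) -> None:
        if self.discard_over < 1 or self.scr_max_match < 1:
            raise ValueError("thresholds must be >= 1")


@dataclass(frozen=True)
class OffTargetHit:
    """One maximal contiguous exact match between a query and a subject.

    ``query_start`` is 0-based within the oriented pattern that was
    searched: the query itself for ``sense_match``, its reverse complement
    (the target-site sequence) for ``guide_match``.
    """

    query_id: str
    subject_id: str
    match_len: int
    query_start: int
    subject_start: int
    orientation: str  # "sense_match" | "guide_match"


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _longest_runs(pattern: str, subject: str) -> Tuple[int, List[Tuple[int, int]]]:
    """Longest common contiguous substring of pattern (short) vs subject.

    Diagonal-run dynamic programming vectorised over the subject: row i
    holds, for every subject position j, the length of the common suffix of
    pattern[:i+1] and subject[:j+1]. Returns (max_len, [(query_start,
    subject_start), ...]) with all tied maxima reported.
    """
    p = _encode(pattern)
    s = _encode(subject)
    n = len(s)
    if n == 0 or len(p) == 0:
        return 0, []
    prev = np.zeros(n, dtype=np.int32)
    best = 0
    where: List[Tuple[int, int]] = []
    for i in range(len(p)):
        match = (s == p[i])
        cur = np.zeros(n, dtype=np.int32)
        cur[0] = 1 if match[0] else 0
        cur[1:] = np.where(match[1:], prev[:-1] + 1, 0)
        row_max = int(cur.max())
        if row_max > best:
            best = row_max
            where = [(i - best + 1, int(j) - best + 1) for j in np.flatnonzero(cur == best)]
        elif row_max == best and best > 0:
            where.extend(
                (i - best + 1, int(j) - best + 1) for j in np.flatnonzero(cur == best)
            )
        prev = cur
    return best, where


def longest_match(
    query: NucSeq,
    transcriptome: Sequence[NucSeq],
    cfg: ScreenConfig = ScreenConfig(),
) -> Tuple[int, List[OffTargetHit]]:
    """Longest contiguous exact match of ``query`` against a transcriptome.

    Searches every non-excluded subject in one or both orientations and
    returns the maximum match length together with every hit achieving it.
    All subjects excluded is an error (nothing to screen), distinct from a
    clean screen returning 0 on an empty pattern overlap.
    """
    import warnings

    if len(query) != 21:
        warnings.warn(f"query {query.id!r} is {len(query)} nt; screens are tuned for 21-mers")
    query = query.as_dna()
    subjects = [t.as_dna() for t in transcriptome if t.id not in cfg.excluded_subject_ids]
    if not subjects:
        raise ScreenError("all subjects excluded: nothing to screen")
    patterns = [("sense_match", query.seq)]
    if cfg.check_both_orientations:
        patterns.append(("guide_match", revcomp(query).seq))
    best = 0
    hits: List[OffTargetHit] = []
    for subj in subjects:
        for orientation, pattern in patterns:
            length, where = _longest_runs(pattern, subj.seq)
            if length > best:
                best = length
                hits = []
            if length == best and best > 0:
                hits.extend(
                    OffTargetHit(query.id, subj.id, length, qs, ss, orientation)
                    for qs, ss in where
                )
    return best, hits


def offtarget_filter(
    candidates: Sequence,
    transcriptome: Sequence[NucSeq],
    cfg: ScreenConfig = ScreenConfig(),
) -> List[Tuple[object, int, Optional[OffTargetHit], bool]]:
    """Screen candidates; keep those with max match <= ``discard_over``.

    Accepts :class:`~amirkit.scan.DuplexCandidate` objects (screened on
    their sense 21-mer) or bare :class:`NucSeq` queries. Returns
    ``[(candidate, max_len, best_hit_or_None, kept), ...]`` in input order.
    """
    out = []
    for cand in candidates:
        query = cand.sense21 if hasattr(cand, "sense21") else cand
        max_len, hits = longest_match(query, transcriptome, cfg)
        kept = max_len <= cfg.discard_over
        out.append((cand, max_len, hits[0] if hits else None, kept))
    return out


def make_scramble(
    guide: NucSeq,
    transcriptome: Sequence[NucSeq],
    cfg: ScreenConfig = ScreenConfig(),
    seed: int = 0,
    max_attempts: int = 1000,
    enforce_run_rule: bool = True,
    max_run_allowed: int = 3,
) -> NucSeq:
    """Generate a scrambled control for ``guide``.

    Draws seeded random permutations of the guide's bases (identical base
    multiset, hence identical GC content) until one matches the
    transcriptome strictly below ``scr_max_match`` nt and — unless
    ``enforce_run_rule`` is off — contains no homopolymer run longer than
    ``max_run_allowed``. Deterministic for a fixed seed. Raises after
    ``max_attempts`` failed draws, reporting the best attempt seen.
    """
    if len(guide) != 21:
        raise ValueError(f"guide must be 21 nt, got {len(guide)}")
    guide = guide.as_dna()
    rng = np.random.default_rng(seed)
    bases = np.array(list(guide.seq))
    best_seq, best_len = None, None
    for attempt in range(max_attempts):
        perm = "".join(rng.permutation(bases))
        cand = NucSeq(f"{guide.id}_scr", perm, "DNA")
        if enforce_run_rule and max_homopolymer_run(cand) > max_run_allowed:
            continue
        max_len, _ = longest_match(cand, transcriptome, cfg)
        if best_len is None or max_len < best_len:
            best_seq, best_len = perm, max_len
        if max_len < cfg.scr_max_match:
            return cand
    raise RuntimeError(
        f"no scramble below {cfg.scr_max_match} nt in {max_attempts} attempts; "
        f"best attempt {best_seq!r} matched {best_len} nt"
    )
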