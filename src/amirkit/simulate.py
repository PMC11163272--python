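"""Seeded synthetic inputs for both pipelines, with ground truth.

Three generators:

* :func:`make_transcriptome` — random-background transcripts with planted
  exact matches of controlled length for given guide/site sequences (the
  desk-scale stand-in for screening against a real transcriptome),
* :func:`make_target_gene` — a random target transcript carrying planted
  consensus-compliant duplex windows that the candidate scan must recover
  exactly (and nothing else),
* :func:`make_recording` — an extracellular voltage trace as a sum of
  parametric biphasic spike templates placed at generated spike times plus
  Gaussian noise, with per-unit ground-truth spike times and classes.

Every generator is a pure function of its plan: all randomness flows from
one explicit integer seed, and identical plans produce identical output.
Background base composition is uniform by default and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ephys import Recording
from .offtarget import ScreenConfig, longest_match
from .scan import ConsensusSpec, FilterConfig, scan, validate_candidate
from .seq import NucSeq, max_homopolymer_run

BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, p=None) -> str:
    return "".join(rng.choice(BASES, size=length, p=p))


# ---------------------------------------------------------------------------
# transcriptomes with planted matches

@dataclass(frozen=True)
class Plant:
    """One planted exact match: ``match_len`` nt of ``site`` inserted into
    transcript ``transcript_index`` at ``position`` (0-based)."""

    site: NucSeq
    match_len: int
    transcript_index: int
    position: int

    def __post_init__(self) -> None:
        if not 1 <= self.match_len <= len(self.site):
            raise ValueError("match_len must be in [1, len(site)]")


@dataclass(frozen=True)
class TranscriptomePlan:
    seed: int = 0
    lengths: Tuple[int, ...] = (2000,)
    plants: Tuple[Plant, ...] = ()
    base_probs: Optional[Tuple[float, float, float, float]] = None


def _other_base(rng: np.random.Generator, avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return str(rng.choice(choices))


def make_transcriptome(plan: TranscriptomePlan) -> Tuple[List[NucSeq], pd.DataFrame]:
    """Generate transcripts with planted matches and a ground-truth table.

    Each plant overwrites ``match_len`` bases with the centered substring
    of its site; the flanking bases are forced to mismatch the site's
    adjacent bases so the planted match cannot extend. Generation is
    retried with a derived sub-seed until an exact-match oracle confirms
    every plant measures exactly its planned length (guards against
    coincidental background extensions).
    """
    for plant in plan.plants:
        if plant.transcript_index >= len(plan.lengths):
            raise ValueError("plant transcript_index out of range")
        if plant.position + plant.match_len > plan.lengths[plant.transcript_index]:
            raise ValueError("plant does not fit inside its transcript")
    for retry in range(20):
        # non-zero second word keeps this stream distinct from any plain
        # default_rng(plan.seed) user (SeedSequence zero-pads entropy)
        rng = np.random.default_rng((plan.seed, 9001 + retry))
        seqs = [list(_random_seq(rng, n, plan.base_probs)) for n in plan.lengths]
        for plant in plan.plants:
            site = plant.site.as_dna().seq
            a = (len(site) - plant.match_len) // 2
            sub = site[a : a + plant.match_len]
            t = seqs[plant.transcript_index]
            p = plant.position
            t[p : p + plant.match_len] = list(sub)
            if p > 0 and a > 0:
                t[p - 1] = _other_base(rng, site[a - 1])
            if p + plant.match_len < len(t) and a + plant.match_len < len(site):
                t[p + plant.match_len] = _other_base(rng, site[a + plant.match_len])
        records = [NucSeq(f"tx{i}", "".join(s), "DNA") for i, s in enumerate(seqs)]
        ok = True
        for plant in plan.plants:
            host = records[plant.transcript_index]
            measured, _ = longest_match(
                plant.site, [host], ScreenConfig(check_both_orientations=False)
            )
            if measured != plant.match_len:
                ok = False
                break
        if ok:
            truth = pd.DataFrame(
                {
                    "site_id": [p.site.id for p in plan.plants],
                    "match_len": [p.match_len for p in plan.plants],
                    "transcript_index": [p.transcript_index for p in plan.plants],
                    "position": [p.position for p in plan.plants],
                }
            )
            return records, truth
    raise RuntimeError("could not realize exact planted match lengths in 20 retries")


# ---------------------------------------------------------------------------
# target genes with planted duplex windows

def compliant_window(rng: np.random.Generator,
                     consensus: ConsensusSpec = ConsensusSpec(),
                     filters: FilterConfig = FilterConfig()) -> str:
    """Draw a random 23-nt window passing every scan filter."""
    while True:
        window = _random_seq(rng, consensus.window_len)
        cands = scan(NucSeq("w", window, "DNA"), consensus, filters)
        if len(cands) == 1 and cands[0].window_start == 0:
            return window


def make_target_gene(
    seed: int,
    length: int = 2000,
    n_plants: int = 1,
    positions: Optional[Sequence[int]] = None,
    base_probs: Optional[Tuple[float, float, float, float]] = None,
    consensus: ConsensusSpec = ConsensusSpec(),
    filters: FilterConfig = FilterConfig(),
) -> Tuple[NucSeq, pd.DataFrame]:
    """A synthetic target transcript whose scan hits are exactly the plants.

    Compliant 23-nt windows are planted at the requested (or drawn,
    non-overlapping) positions; a deterministic repair loop then mutates
    one base inside every spurious passing window (never touching a
    planted footprint, flipping GC membership so the window's GC count
    leaves the allowed band) until the scan recovers the planted windows
    and nothing else. Overlapping plants are rejected.
    """
    w = consensus.window_len
    rng = np.random.default_rng(seed)
    if positions is None:
        positions = []
        for _ in range(1000):
            if len(positions) == n_plants:
                break
            p = int(rng.integers(0, max(1, length - w + 1)))
            if all(abs(p - q) >= w for q in positions):
                positions.append(p)
        else:
            raise RuntimeError("could not place non-overlapping plants")
    positions = sorted(int(p) for p in positions)
    if any(b - a < w for a, b in zip(positions, positions[1:])):
        raise ValueError("planted windows overlap")
    if positions and positions[-1] + w > length:
        raise ValueError("plant does not fit inside the target")

    target = list(_random_seq(rng, length, base_probs))
    planted: Dict[int, str] = {}
    for p in positions:
        window = compliant_window(rng, consensus, filters)
        target[p : p + w] = list(window)
        planted[p] = window
    footprint = set()
    for p in positions:
        footprint.update(range(p, p + w))

    for _ in range(200):
        cands = scan(NucSeq("target", "".join(target), "DNA"), consensus, filters)
        extra = [c for c in cands if c.window_start not in planted]
        if not extra:
            break
        for c in extra:
            lo = c.window_start + consensus.sense_offset
            free = [i for i in range(lo, lo + 21) if i not in footprint]
            if free:
                i = free[int(rng.integers(0, len(free)))]
                target[i] = "A" if target[i] in "GC" else "G"
            else:
                # spurious window lies inside a planted footprint (a 1-2 nt
                # shift of a plant also passes): redraw that plant's window
                p_star = next(p for p in positions if p <= lo < p + w)
                window = compliant_window(rng, consensus, filters)
                target[p_star : p_star + w] = list(window)
                planted[p_star] = window
    else:
        raise RuntimeError("repair loop did not converge")

    truth = pd.DataFrame(
        {"window_start": positions, "window": [planted[p] for p in positions]}
    )
    return NucSeq("target", "".join(target), "DNA"), truth


# ---------------------------------------------------------------------------
# extracellular recordings with planted units

@dataclass(frozen=True)
class UnitPlan:
    """One planted unit: waveform shape plus a firing model.

    ``firing`` is ``"poisson"`` (homogeneous, ``rate_hz``) or ``"bursty"``
    (burst onsets at ``burst_rate_hz``, ``spikes_per_burst`` spikes at
    ``intra_isi_ms`` spacing).
    """

    ttp_us: float
    amplitude: float
    firing: str = "poisson"
    rate_hz: float = 5.0
    burst_rate_hz: float = 2.0
    spikes_per_burst: int = 3
    intra_isi_ms: float = 3.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.firing not in ("poisson", "bursty"):
            raise ValueError("firing must be 'poisson' or 'bursty'")
        if self.intra_isi_ms < 1.0:
            raise ValueError("intra-burst ISI must respect the 1-ms refractory period")


@dataclass(frozen=True)
class RecordingPlan:
    seed: int = 0
    rate: float = 20000.0
    duration_s: float = 60.0
    noise_sd: float = 1.0
    units: Tuple[UnitPlan, ...] = ()

    def __post_init__(self) -> None:
        if self.rate < 20000:
            raise ValueError("plan rate must be >= 20 kHz")


def biphasic_template(
    ttp_us: float,
    rate: float,
    amplitude: float = 1.0,
    trough_width_us: float = 300.0,
    peak_width_us: float = 400.0,
    peak_ratio: float = 0.5,
    pre_ms: float = 0.6,
    post_ms: float = 1.0,
    shape: str = "halfsine",
) -> np.ndarray:
    """Parametric biphasic extracellular spike template.

    A negative lobe (trough, centered at t = 0) followed by a positive
    lobe centered ``ttp_us`` later; only the trough-to-peak distance and
    the amplitude matter downstream. ``shape`` picks the lobe profile:
    ``"halfsine"`` (default generator shape) or ``"parabolic"`` (lobes
    quadratic around their extrema, so parabolic sub-sample refinement
    recovers the extremum positions exactly).
    """
    if shape not in ("halfsine", "parabolic"):
        raise ValueError("shape must be 'halfsine' or 'parabolic'")
    t = (np.arange(-round(pre_ms * rate / 1000.0), round(post_ms * rate / 1000.0) + 1)
         / rate * 1e6)  # us relative to the trough

    def lobe(center: float, width: float) -> np.ndarray:
        x = (t - center) / (width / 2.0)
        inside = np.abs(x) < 1.0
        if shape == "halfsine":
            return np.where(inside, np.cos(np.pi / 2.0 * x), 0.0)
        return np.where(inside, 1.0 - x**2, 0.0)

    wave = -amplitude * lobe(0.0, trough_width_us) + peak_ratio * amplitude * lobe(
        float(ttp_us), peak_width_us
    )
    return wave


def poisson_train(rng: np.random.Generator, rate_hz: float, duration_s: float,
                  min_isi_ms: float = 1.5) -> np.ndarray:
    """Homogeneous Poisson spike times (ms) with a minimum-gap constraint."""
    times = []
    t = 0.0
    while True:
        t += rng.exponential(1000.0 / rate_hz)  # ms
        if t >= duration_s * 1000.0:
            break
        if not times or t - times[-1] >= min_isi_ms:
            times.append(t)
    return np.asarray(times)


def bursty_train(rng: np.random.Generator, burst_rate_hz: float, spikes_per_burst: int,
                 intra_isi_ms: float, duration_s: float) -> np.ndarray:
    """Burst-onset Poisson process with fixed-spacing spikes per burst (ms)."""
    burst_len = (spikes_per_burst - 1) * intra_isi_ms
    onsets = poisson_train(rng, burst_rate_hz, duration_s, min_isi_ms=burst_len + 5.0)
    times = []
    for onset in onsets:
        for j in range(spikes_per_burst):
            t = onset + j * intra_isi_ms
            if t < duration_s * 1000.0:
                times.append(t)
    return np.asarray(sorted(times))


def make_recording(plan: RecordingPlan) -> Tuple[Recording, pd.DataFrame]:
    """Synthesize a recording and its ground truth.

    Returns the Recording and a table with one row per planted spike:
    ``unit_index``, ``time_ms``, ``ttp_us``, ``unit_class`` (by the 440-us
    rule applied to the planned trough-to-peak).
    """
    rng = np.random.default_rng(plan.seed)
    n = int(round(plan.duration_s * plan.rate))
    signal = rng.normal(0.0, plan.noise_sd, size=n) if plan.noise_sd > 0 else np.zeros(n)
    rows = []
    margin_ms = 2.0  # keep waveforms clear of the trace edges
    for ui, unit in enumerate(plan.units):
        if unit.firing == "poisson":
            times = poisson_train(rng, unit.rate_hz, plan.duration_s)
        else:
            times = bursty_train(rng, unit.burst_rate_hz, unit.spikes_per_burst,
                                 unit.intra_isi_ms, plan.duration_s)
        times = times[(times > margin_ms) & (times < plan.duration_s * 1000.0 - margin_ms)]
        template = biphasic_template(unit.ttp_us, plan.rate, unit.amplitude)
        pre = int(round(0.6 * plan.rate / 1000.0))
        for t in times:
            i0 = int(round(t * plan.rate / 1000.0)) - pre
            signal[i0 : i0 + len(template)] += template
            rows.append(
                {
                    "unit_index": ui,
                    "time_ms": t,
                    "ttp_us": unit.ttp_us,
                    "unit_class": "pPYR" if unit.ttp_us > 440.0 else "pIN",
                }
            )
    truth = pd.DataFrame(rows, columns=["unit_index", "time_ms", "ttp_us", "unit_class"])
    if len(truth):
        truth = truth.sort_values("time_ms").reset_index(drop=True)
    return Recording(signal, plan.rate), truth
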