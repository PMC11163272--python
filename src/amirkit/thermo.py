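"""5'-terminal duplex free energies and the strand-asymmetry filter.

Which strand of an siRNA duplex is loaded into RISC is biased by the
relative thermodynamic stability of the two duplex ends: the strand whose
5' end sits in the *less* stable terminus is preferentially retained. The
selection rule implemented here keeps candidates whose antisense-5' end is
the more stable one (Eas < Es) with the asymmetry
``delta = Eas - Es`` inside a configured band (default [-5, -3] kcal/mol).

Energies are stack-only sums of RNA Watson-Crick nearest-neighbor
free-energy increments (Delta-G at 37 C, Xia et al. 1998 set shipped as a
packaged table) over a fixed number of terminal base-pair steps at each
duplex end. Duplex initiation and terminal-AU penalties are deliberately
omitted: the filter compares two ends of the same duplex, and these terms
either cancel or are end-composition effects the band is not calibrated
for. Units, window length and parameter set are configuration, not claims
about the original design run, which stated none of them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from functools import lru_cache
from typing import Dict, List, Sequence

from .scan import DuplexCandidate
from .seq import NucSeq, revcomp

_DEFAULT_TABLE = "nn_rna_dg37.tsv"


@lru_cache(maxsize=None)
def load_nn_table(name: str = _DEFAULT_TABLE) -> Dict[str, float]:
    """Load a nearest-neighbor stack table packaged under ``amirkit/data``.

    The table maps each RNA dinucleotide step (5'->3' on one strand of a
    perfect duplex) to its stack Delta-G at 37 C in kcal/mol.
    """
    text = resources.files("amirkit.data").joinpath(name).read_text()
    table: Dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        dinuc, value = line.split("\t")
        table[dinuc] = float(value)
    if len(table) != 16:
        raise ValueError(f"NN table {name} has {len(table)} entries, expected 16")
    return table


@dataclass(frozen=True)
class ThermoConfig:
    """Terminal-energy computation and asymmetry acceptance band."""

    terminal_window_bp: int = 5  # number of NN steps summed at each end
    nn_param_set: str = _DEFAULT_TABLE
    delta_lo: float = -5.0
    delta_hi: float = -3.0

    def __post_init__(self) -> None:
        if not 2 <= self.terminal_window_bp <= 10:
            raise ValueError("terminal_window_bp must be in [2, 10]")
        if self.delta_lo > self.delta_hi:
            raise ValueError("need delta_lo <= delta_hi")


@dataclass(frozen=True)
class DuplexEnergy:
    """Terminal energies of one duplex and the asymmetry verdict."""

    Es: float    # sense-5' terminal window energy, kcal/mol
    Eas: float   # antisense-5' terminal window energy, kcal/mol
    delta: float  # Eas - Es
    accepted: bool


def _stack_sum(strand_rna: str, n_steps: int, table: Dict[str, float]) -> float:
    return sum(table[strand_rna[i : i + 2]] for i in range(n_steps))


def end_energy(duplex_sense: NucSeq, end: str, cfg: ThermoConfig = ThermoConfig()) -> float:
    """Free energy of the terminal NN-step window at one duplex end.

    ``end`` is ``"sense5p"`` or ``"antisense5p"``. The duplex is the
    perfect hybrid of ``duplex_sense`` with its reverse complement; the
    antisense-5' end therefore sits at the sense strand's 3' end. Energies
    are computed on the RNA form of the strand whose 5' end is named.
    """
    w = cfg.terminal_window_bp
    if len(duplex_sense) < w + 1:
        raise ValueError(f"duplex of {len(duplex_sense)} bp shorter than a {w}-step window")
    table = load_nn_table(cfg.nn_param_set)
    if end == "sense5p":
        strand = duplex_sense.as_rna().seq
    elif end == "antisense5p":
        strand = revcomp(duplex_sense).as_rna().seq
    else:
        raise ValueError(f"unknown end {end!r}")
    return _stack_sum(strand, w, table)


def duplex_energy(duplex_sense: NucSeq, cfg: ThermoConfig = ThermoConfig()) -> DuplexEnergy:
    """Compute Es, Eas, delta and the acceptance verdict for one duplex."""
    es = end_energy(duplex_sense, "sense5p", cfg)
    eas = end_energy(duplex_sense, "antisense5p", cfg)
    delta = eas - es
    accepted = (eas < es) and (cfg.delta_lo <= delta <= cfg.delta_hi)
    return DuplexEnergy(Es=es, Eas=eas, delta=delta, accepted=accepted)


def asymmetry_filter(
    candidates: Sequence[DuplexCandidate],
    cfg: ThermoConfig = ThermoConfig(),
) -> List[tuple]:
    """Annotate candidates with :class:`DuplexEnergy`.

    Returns ``[(candidate, energy), ...]`` in input order; the accepted
    subset is exactly those with ``energy.accepted`` — antisense-5' end
    more stable (Eas < Es) and delta inside [delta_lo, delta_hi].
    """
    return [(c, duplex_energy(c.sense21, cfg)) for c in candidates]
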