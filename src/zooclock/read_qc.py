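"""Pair-synchronized read filtering and read-retention accounting.

A read fails if it contains an ambiguous base call ('N') or if its
arithmetic-mean PHRED score is below the threshold (default 20). A pair
is discarded when either mate fails — unpaired reads are useless for
paired-end assembly. Adapter trimming and error correction are assumed
to have happened upstream; this stage only drops whole pairs and
accounts for the loss.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import percent, round_half_away
from .io_formats import ReadPair


@dataclass(frozen=True)
class ReadRetentionStats:
    species: str
    raw_pairs: int
    kept_pairs: int
    retained_pct: float
    lost_pct: float


def _read_passes(residues: str, quality: str, min_mean_q: float,
                 drop_n: bool) -> bool:
    if drop_n and "N" in residues:
        return False
    phred = [ord(c) - 33 for c in quality]
    # fail strictly below the threshold; a mean of exactly min_mean_q passes
    return sum(phred) / len(phred) >= min_mean_q


def filter_read_pairs(pairs: list[ReadPair], min_mean_q: float = 20,
                      drop_n: bool = True, species: str = "",
                      ) -> tuple[list[ReadPair], ReadRetentionStats]:
    """Keep only pairs in which both mates pass; order preserved."""
    kept = [
        p for p in pairs
        if _read_passes(p.forward.residues, p.forward_quality, min_mean_q, drop_n)
        and _read_passes(p.reverse.residues, p.reverse_quality, min_mean_q, drop_n)
    ]
    raw = len(pairs)
    retained = percent(len(kept), raw) if raw else 100.0
    stats = ReadRetentionStats(
        species=species,
        raw_pairs=raw,
        kept_pairs=len(kept),
        retained_pct=retained,
        lost_pct=round_half_away(100.0 - retained, 1),
    )
    return kept, stats


def retention_percentage(raw: int, kept: int) -> float:
    """100*kept/raw, rounded half away from zero to one decimal."""
    if raw <= 0:
        raise ZeroDivisionError("retention undefined for raw=0")
    if not 0 <= kept <= raw:
        raise ValueError(f"kept={kept} outside [0, raw={raw}]")
    return percent(kept, raw)
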