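"""Assembly QC metrics: N50, complete-ORF fraction, and the per-species
summary table comparing initial and redundancy-reduced assemblies."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import percent, round_half_away
from .orf_reduce import Orf


@dataclass(frozen=True)
class AssemblyStats:
    species: str
    phase: str                      # "initial" or "final"
    n_transcripts: int
    n50: int
    pct_of_initial: float | None = None
    pct_complete_orfs: float | None = None
    read_support_pct: float | None = None


def compute_n50(lengths: list[int]) -> int:
    """The contig length at which the cumulative sum over the
    descending-sorted lengths first reaches half the total bases.

    Contigs of this length or greater contain >= 50% of all bases. When
    the half-total falls exactly on a boundary, the larger length is
    returned (first cumulative >= half).
    """
    if not lengths:
        raise ValueError("N50 of an empty assembly is undefined")
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for l in ordered:
        acc += l
        if acc >= half:
            return l
    raise AssertionError("unreachable")


def pct_complete_orfs(orfs: list[Orf]) -> float:
    """Percentage of predicted ORFs tagged complete (start and stop),
    one decimal."""
    if not orfs:
        raise ValueError("no ORFs: complete fraction undefined")
    return percent(sum(1 for o in orfs if o.completeness == "cmp"), len(orfs))


def summarize_assemblies(stats: pd.DataFrame) -> dict:
    """Per-phase means over a stats table with columns
    ``phase, n_transcripts, n50`` and (for the final phase)
    ``pct_of_initial``.

    N50 and transcript-count means are rounded to the nearest integer,
    percentage means to two decimals.
    """
    out: dict = {}
    for phase in ("initial", "final"):
        sub = stats[stats["phase"] == phase]
        if sub.empty:
            raise ValueError(f"no rows for phase {phase!r}")
        out[f"mean_n50_{phase}"] = int(round_half_away(sub["n50"].mean(), 0))
        out[f"mean_transcripts_{phase}"] = int(
            round_half_away(sub["n_transcripts"].mean(), 0))
    final = stats[stats["phase"] == "final"]
    if "pct_of_initial" in final.columns and final["pct_of_initial"].notna().all():
        out["mean_pct_of_initial"] = round_half_away(
            final["pct_of_initial"].mean(), 2)
    return out


def stats_table(rows: list[AssemblyStats]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


def busco_completeness(summary: pd.DataFrame) -> pd.Series:
    """Completeness = (single-copy + duplicated) / total, as a percentage
    (parsed from external BUSCO summaries, never computed here)."""
    frac = (summary["complete_single"] + summary["complete_dup"]) / summary["total"]
    return (100.0 * frac).map(lambda x: round_half_away(x, 1))
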