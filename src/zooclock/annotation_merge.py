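"""Merge homology-search (Swiss-Prot-style) and orthology/domain
(EggNOG-style) annotations into one per-sequence table, and compute
annotation-rate statistics.

No coverage cutoff is applied at this stage, so short sequences can
still receive annotations; the E-value cutoff (default 1e-5) alone
controls homolog assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from ._util import percent


@dataclass(frozen=True)
class AnnotationRateStats:
    n_sequences: int
    pct_swissprot: float
    pct_eggnog: float
    pct_either: float


def best_hit_per_query(hits: pd.DataFrame, max_evalue: float = 1e-5
                       ) -> pd.DataFrame:
    """Per query, the surviving hit with the lowest E-value.

    Hits above the cutoff are discarded first; E-value ties are broken by
    higher bitscore, then lexicographic target id. Queries with no
    surviving hit are simply absent from the result.
    """
    kept = hits[hits["evalue"] <= max_evalue]
    if kept.empty:
        return kept.copy()
    ordered = kept.sort_values(
        ["query", "evalue", "bitscore", "target"],
        ascending=[True, True, False, True], kind="mergesort",
    )
    return ordered.groupby("query", as_index=False).first()


def merge_annotations(best_hits: pd.DataFrame, eggnog: pd.DataFrame,
                      all_seq_ids: list[str]
                      ) -> tuple[pd.DataFrame, AnnotationRateStats]:
    """One record per sequence in the id universe, flagging which
    source(s) annotated it. Any non-empty EggNOG-style row counts as an
    annotation. Rows for ids outside the universe are kept with a
    warning."""
    if not all_seq_ids:
        raise ValueError("empty sequence universe")
    universe = list(dict.fromkeys(all_seq_ids))
    sp_by_id = {}
    if not best_hits.empty:
        sp_by_id = best_hits.set_index("query")[["target", "evalue", "bitscore"]] \
                            .to_dict("index")
    egg_ids = set(eggnog["seq_id"]) if "seq_id" in eggnog.columns else set()
    unknown = sorted(egg_ids - set(universe))
    if unknown:
        warnings.warn(f"EggNOG-style rows for unknown id(s): {unknown[:5]}"
                      + ("..." if len(unknown) > 5 else ""))
    rows = []
    for sid in universe:
        sp = sp_by_id.get(sid)
        has_egg = sid in egg_ids
        sources = []
        if sp is not None:
            sources.append("swissprot")
        if has_egg:
            sources.append("eggnog")
        rows.append({
            "seq_id": sid,
            "swissprot_target": sp["target"] if sp else "",
            "swissprot_evalue": sp["evalue"] if sp else None,
            "swissprot_bitscore": sp["bitscore"] if sp else None,
            "annotated_by": ",".join(sources),
        })
    # ids outside the universe are appended untouched for the audit trail
    for sid in unknown:
        rows.append({"seq_id": sid, "swissprot_target": "",
                     "swissprot_evalue": None, "swissprot_bitscore": None,
                     "annotated_by": "eggnog"})
    table = pd.DataFrame(rows)
    n = len(universe)
    n_sp = sum(1 for sid in universe if sid in sp_by_id)
    n_egg = sum(1 for sid in universe if sid in egg_ids)
    n_either = sum(1 for sid in universe if sid in sp_by_id or sid in egg_ids)
    stats = AnnotationRateStats(
        n_sequences=n,
        pct_swissprot=percent(n_sp, n),
        pct_eggnog=percent(n_egg, n),
        pct_either=percent(n_either, n),
    )
    return table, stats
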