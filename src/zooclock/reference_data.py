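"""Published reference inputs for the circadian clock ortholog workflow.

The bait catalog covers the ten metazoan clock components used to pull
candidates out of pairwise-ortholog tables: the core
transcription-translation feedback loop (CLK, CYC, PER, TIM), the
cryptochromes (light-sensitive CRY1, repressor-type CRY2), the insect
second loop (PDP1e, VRI) and its mammalian counterpart (REV-ERBa, RORa).
Baits come from Drosophila melanogaster, except CRY2 (Danaus plexippus,
since the fly lacks it) and the two nuclear receptors (Mus musculus).

``CROSS_REFERENCE_EXPECTED``/``CROSS_REFERENCE_FOUND`` encode the
workflow sensitivity check: each bait should also recover the known
clock orthologs present in the *other* reference proteomes (e.g. fly CYC
should pull mouse ARNTL and ARNTL2). The single known miss is mouse
CLOCK (O08785), orthologous to insect CLK but not recovered as a
pairwise ortholog.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

COMPONENTS = [
    "CLK", "CYC", "TIM", "PER", "CRY1", "CRY2",
    "PDP1e", "VRI", "REV-ERBa", "RORa",
]

#: component -> (source species code, UniProt accession)
BAIT_ACCESSIONS: dict[str, tuple[str, str]] = {
    "CLK": ("Dm", "O61735"),
    "CYC": ("Dm", "O61734"),
    "TIM": ("Dm", "P49021"),
    "PER": ("Dm", "P07663"),
    "CRY1": ("Dm", "O77059"),
    "CRY2": ("Dp", "A0A212FAM3"),
    "PDP1e": ("Dm", "Q8SZT1"),
    "VRI": ("Dm", "Q9VMS4"),
    "REV-ERBa": ("Mm", "Q3UV55"),
    "RORa": ("Mm", "P51448"),
}

#: component -> set of (species code, accession) clock orthologs present in
#: the unused reference proteomes (the recovery ground truth).
CROSS_REFERENCE_EXPECTED: dict[str, set[tuple[str, str]]] = {
    "CLK": {("Dp", "A0A212EGJ4"), ("Mm", "O08785")},
    "CYC": {("Dp", "A0A212EKE6"), ("Mm", "Q9WTL8"), ("Mm", "Q2VPD4")},
    "TIM": {("Dp", "A0A212ETU4")},
    "PER": {("Dp", "A0A212F9R2"), ("Mm", "O35973"), ("Mm", "O54943"),
            ("Mm", "O70361")},
    "CRY1": {("Dp", "A0A212EI23")},
    "CRY2": {("Mm", "P97784"), ("Mm", "Q9R194")},
    "PDP1e": {("Mm", "Q60925"), ("Mm", "Q8BW74"), ("Mm", "Q9JLC6")},
    "VRI": {("Mm", "O08750")},
    "REV-ERBa": {("Dm", "P13055")},
    "RORa": {("Dm", "P31396")},
}

#: What the pairwise-orthology run actually recovered: everything above
#: except mouse CLOCK.
CROSS_REFERENCE_FOUND: dict[str, set[tuple[str, str]]] = {
    comp: {pair for pair in pairs if pair != ("Mm", "O08785")}
    for comp, pairs in CROSS_REFERENCE_EXPECTED.items()
}

#: Run-comparison candidate counts between the 20-proteome and the
#: 157-proteome pairwise-orthology runs (shared / unique to expanded run /
#: unique to base run).
RUN_COMPARISON_COUNTS = {"shared": 177, "only_expanded": 34, "only_base": 24}

PHYLUM_CODES = {
    "Arthropoda": "Ar", "Annelida": "An", "Phoronida": "Ph",
    "Chordata": "Ch", "Echinodermata": "Ec", "Cnidaria": "Cn",
}


def load_published_assembly_stats() -> pd.DataFrame:
    """Published per-species read counts and assembly statistics for the
    17 zooplankton transcriptomes (raw/processed read pairs, initial and
    final transcript counts, complete-ORF percentage, N50 before/after
    redundancy reduction)."""
    ref = resources.files("zooclock.data") / "published_assembly_stats.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def published_phase_table() -> pd.DataFrame:
    """The published statistics reshaped to one row per (species, phase),
    with the retained-transcript percentage recomputed from the counts."""
    from ._util import percent

    wide = load_published_assembly_stats()
    rows = []
    for r in wide.itertuples(index=False):
        rows.append({"species": r.species, "phase": "initial",
                     "n_transcripts": r.initial_transcripts,
                     "n50": r.n50_initial, "pct_of_initial": None})
        rows.append({"species": r.species, "phase": "final",
                     "n_transcripts": r.final_transcripts,
                     "n50": r.n50_final,
                     "pct_of_initial": percent(r.final_transcripts,
                                               r.initial_transcripts)})
    return pd.DataFrame(rows)
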