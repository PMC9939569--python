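"""Bait-based circadian clock ortholog identification.

The procedure: well-characterized clock proteins from reference
proteomes are marker-tagged ("baits"), pairwise orthologs to the baits
are pulled out of an ortholog table, and the raw candidates are vetted
by a four-stage cascade:

  S1  discard candidates lacking annotations from either the family
      (PANTHER-style) or the domain (Pfam) source;
  S2  discard candidates sharing no Pfam domain with their bait;
  S3  discard candidates outside the bait's protein family;
  S4  per species and component, if any survivor shares the bait's
      subfamily, keep only those.

Swiss-Prot best-hit confirmation is a report-only flag: vetted
candidates are retained regardless, and the flag is logged for manual
review. Validation against held-out reference orthologs and
run-vs-run candidate-set comparison quantify workflow sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from ._util import percent
from .io_formats import ParseError, SeqRecord
from .reference_data import COMPONENTS

DEFAULT_MARKER = "SOIREF"

STAGES = ("S1_dual_annotation", "S2_shared_domain",
          "S3_same_family", "S4_subfamily_preference")


class ConfigError(ValueError):
    """Raised when the cascade is undefined (e.g. unannotated bait)."""


@dataclass(frozen=True)
class Bait:
    component: str
    source_species: str
    accession: str
    seq_id: str                     # marker-tagged id
    domains: frozenset[str] = frozenset()
    family: str = ""
    subfamily: str = ""


@dataclass(frozen=True)
class Candidate:
    species: str
    seq_id: str
    component: str
    completeness: str = ""
    stage_status: tuple[tuple[str, bool, str], ...] = ()
    swissprot_confirmed: bool | None = None
    retained: bool = False

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.species, self.seq_id, self.component)


@dataclass(frozen=True)
class ValidationOutcome:
    expected_pairs: frozenset
    found_pairs: frozenset
    true_positives: frozenset
    false_negatives: frozenset
    false_positives: frozenset


# ---------------------------------------------------------------------------
# Bait tagging and candidate extraction
# ---------------------------------------------------------------------------

def accession_of(seq_id: str) -> str:
    """The accession token of a UniProt-style ``sp|ACC|NAME`` id (or the
    id itself when not pipe-delimited), with any bait marker stripped."""
    parts = seq_id.split("|")
    token = parts[1] if len(parts) >= 2 else seq_id
    return token


def tag_baits(reference_proteomes: dict[str, list[SeqRecord]],
              bait_accessions: dict[str, tuple[str, str]],
              marker: str = DEFAULT_MARKER,
              ) -> tuple[dict[str, list[SeqRecord]], dict[str, Bait]]:
    """Append the marker to the FASTA id of every bait protein.

    ``bait_accessions`` maps component -> (reference species, accession).
    Every accession must occur in exactly one record of its proteome, and
    no untagged id may already contain the marker.
    """
    for species, records in reference_proteomes.items():
        clashes = [r.id for r in records if marker in r.id]
        if clashes:
            raise ConfigError(
                f"marker {marker!r} already present in untagged id(s): {clashes}")
    tagged = {sp: list(records) for sp, records in reference_proteomes.items()}
    registry: dict[str, Bait] = {}
    for component, (species, accession) in bait_accessions.items():
        if species not in tagged:
            raise ConfigError(f"no reference proteome for species {species!r}")
        matches = [i for i, r in enumerate(tagged[species])
                   if accession in r.id.split("|") or r.id == accession]
        if len(matches) != 1:
            raise ConfigError(
                f"bait accession {accession!r} for {component} matched "
                f"{len(matches)} records in proteome {species!r}")
        idx = matches[0]
        old = tagged[species][idx]
        new_id = f"{old.id}_{marker}"
        tagged[species][idx] = replace(old, id=new_id)
        registry[component] = Bait(
            component=component, source_species=species,
            accession=accession, seq_id=new_id,
        )
    return tagged, registry


def extract_bait_orthologs(pair_table: pd.DataFrame,
                           bait_registry: dict[str, Bait],
                           marker: str = DEFAULT_MARKER) -> list[Candidate]:
    """Raw candidates: every pair-table row with exactly one
    marker-tagged member yields a candidate for the untagged member's
    species. One-to-many orthology yields multiple candidates; duplicate
    (species, seq, component) triples are collapsed."""
    by_seq_id = {b.seq_id: b.component for b in bait_registry.values()}
    seen: set[tuple[str, str, str]] = set()
    out: list[Candidate] = []
    for row in pair_table.itertuples(index=False):
        a_tagged = marker in row.seq_a
        b_tagged = marker in row.seq_b
        if a_tagged == b_tagged:
            if a_tagged:
                warnings.warn(f"pair with two tagged members skipped: "
                              f"{row.seq_a} / {row.seq_b}")
            continue
        bait_id, other_sp, other_id = (
            (row.seq_a, row.species_b, row.seq_b) if a_tagged
            else (row.seq_b, row.species_a, row.seq_a))
        component = by_seq_id.get(bait_id)
        if component is None:
            warnings.warn(f"tagged id not in bait registry, skipped: {bait_id}")
            continue
        key = (other_sp, other_id, component)
        if key not in seen:
            seen.add(key)
            out.append(Candidate(species=other_sp, seq_id=other_id,
                                 component=component))
    return out


# ---------------------------------------------------------------------------
# Vetting cascade
# ---------------------------------------------------------------------------

def _pfam_domains(domain_table: pd.DataFrame) -> dict[str, frozenset[str]]:
    pfam = domain_table[domain_table["db"] == "Pfam"]
    return {sid: frozenset(sub["accession"])
            for sid, sub in pfam.groupby("seq_id")}


def _families(family_table: pd.DataFrame) -> dict[str, tuple[str, str]]:
    return {r.seq_id: (r.family_acc, getattr(r, "subfamily_acc", "") or "")
            for r in family_table.itertuples(index=False)}


def annotate_baits(bait_registry: dict[str, Bait],
                   domain_table: pd.DataFrame,
                   family_table: pd.DataFrame) -> dict[str, Bait]:
    """Attach Pfam domain sets and family/subfamily accessions to the
    bait registry from the same annotation tables used for candidates."""
    domains = _pfam_domains(domain_table)
    families = _families(family_table)
    out = {}
    for component, bait in bait_registry.items():
        if bait.seq_id not in domains or bait.seq_id not in families:
            raise ConfigError(
                f"bait {component} ({bait.seq_id}) lacks domain or family "
                f"annotation; the vetting cascade is undefined")
        fam, sub = families[bait.seq_id]
        out[component] = replace(bait, domains=domains[bait.seq_id],
                                 family=fam, subfamily=sub)
    return out


def vet_candidates(raw: list[Candidate], domain_table: pd.DataFrame,
                   family_table: pd.DataFrame,
                   bait_registry: dict[str, Bait]) -> list[Candidate]:
    """Apply the four-stage cascade; every candidate carries a per-stage
    audit trail, and failing a stage short-circuits the later ones."""
    baits = (bait_registry
             if all(b.family for b in bait_registry.values())
             else annotate_baits(bait_registry, domain_table, family_table))
    domains = _pfam_domains(domain_table)
    families = _families(family_table)

    interim: list[Candidate] = []
    for cand in raw:
        bait = baits[cand.component]
        audit: list[tuple[str, bool, str]] = []
        dset = domains.get(cand.seq_id)
        fam = families.get(cand.seq_id)
        ok = dset is not None and fam is not None
        audit.append((STAGES[0], ok,
                      "" if ok else "missing Pfam and/or family annotation"))
        if ok:
            shared = dset & bait.domains
            ok = bool(shared)
            audit.append((STAGES[1], ok,
                          f"shared: {sorted(shared)}" if ok
                          else "no Pfam domain in common with bait"))
        if ok:
            ok = fam[0] == bait.family
            audit.append((STAGES[2], ok,
                          "" if ok else f"family {fam[0]} != bait {bait.family}"))
        interim.append(replace(cand, stage_status=tuple(audit), retained=ok))

    # S4: subfamily preference within each (species, component) group
    out: list[Candidate] = []
    groups: dict[tuple[str, str], list[Candidate]] = {}
    for cand in interim:
        groups.setdefault((cand.species, cand.component), []).append(cand)
    for (species, component), members in groups.items():
        bait = baits[component]
        survivors = [c for c in members if c.retained]
        matching = [c for c in survivors
                    if bait.subfamily
                    and families.get(c.seq_id, ("", ""))[1] == bait.subfamily]
        prefer = bool(matching)
        for cand in members:
            if not cand.retained:
                out.append(cand)
                continue
            if prefer and cand not in matching:
                audit = cand.stage_status + (
                    (STAGES[3], False,
                     f"sibling(s) share bait subfamily {bait.subfamily}"),)
                out.append(replace(cand, stage_status=audit, retained=False))
            else:
                reason = ("matches bait subfamily" if prefer
                          else "no subfamily-matching sibling; all retained")
                audit = cand.stage_status + ((STAGES[3], True, reason),)
                out.append(replace(cand, stage_status=audit, retained=True))
    order = {c.key: i for i, c in enumerate(raw)}
    out.sort(key=lambda c: order[c.key])
    return out


def confirm_swissprot(candidates: list[Candidate],
                      annotation_table: pd.DataFrame,
                      whitelist: set[str]) -> list[Candidate]:
    """Flag candidates whose best Swiss-Prot-style homolog is a known
    clock protein (whitelist of accessions). Report-only: the flag never
    removes a candidate."""
    best = {}
    if not annotation_table.empty and "swissprot_target" in annotation_table:
        best = dict(zip(annotation_table["seq_id"],
                        annotation_table["swissprot_target"]))
    out = []
    for cand in candidates:
        target = best.get(cand.seq_id, "")
        confirmed = bool(target) and accession_of(target) in whitelist
        out.append(replace(cand, swissprot_confirmed=confirmed))
    return out


# ---------------------------------------------------------------------------
# Reporting, validation and run comparison
# ---------------------------------------------------------------------------

def candidate_matrix(candidates: list[Candidate],
                     species: list[str] | None = None,
                     components: list[str] | None = None) -> pd.DataFrame:
    """Species x component counts of retained candidates; cells with no
    candidate are NA."""
    components = components or COMPONENTS
    retained = [c for c in candidates if c.retained]
    if species is None:
        species = sorted({c.species for c in retained})
    mat = pd.DataFrame(index=species, columns=components, dtype="Int64")
    for c in retained:
        if c.species in mat.index and c.component in mat.columns:
            cur = mat.at[c.species, c.component]
            mat.at[c.species, c.component] = (0 if pd.isna(cur) else cur) + 1
    mat.index.name = "species"
    return mat


def write_candidate_matrix(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", na_rep="NA")


def validate_against_references(found_pairs: set, expected_pairs: set
                                ) -> ValidationOutcome:
    """Confusion outcome of found vs expected (component, accession)
    ortholog pairs."""
    found = frozenset(found_pairs)
    expected = frozenset(expected_pairs)
    return ValidationOutcome(
        expected_pairs=expected,
        found_pairs=found,
        true_positives=expected & found,
        false_negatives=expected - found,
        false_positives=found - expected,
    )


def reference_found_pairs(candidates: list[Candidate],
                          reference_species: set[str]) -> set[tuple[str, str]]:
    """(component, accession) pairs recovered within the reference
    proteomes themselves — the workflow sensitivity check."""
    return {(c.component, accession_of(c.seq_id))
            for c in candidates if c.species in reference_species}


def compare_candidate_sets(run_a: set, run_b: set) -> dict:
    """Overlap of two candidate sets keyed by (species, seq_id,
    component): counts and percentages of the union (one decimal)."""
    a, b = set(run_a), set(run_b)
    union = a | b
    if not union:
        raise ZeroDivisionError("both candidate sets are empty")
    shared, only_a, only_b = a & b, a - b, b - a
    return {
        "shared": len(shared), "only_a": len(only_a), "only_b": len(only_b),
        "shared_pct": percent(len(shared), len(union)),
        "only_a_pct": percent(len(only_a), len(union)),
        "only_b_pct": percent(len(only_b), len(union)),
    }


# ---------------------------------------------------------------------------
# Fallback searches against external assemblies
# ---------------------------------------------------------------------------

STATUS_FOUND_UPSTREAM = "-"
STATUS_YES = "YES"
STATUS_NO_HOMOLOG = "NH"
STATUS_NO_DATA = "ND"


def select_fallback_hits(hits: pd.DataFrame,
                         data_available: dict[str, bool],
                         found_upstream: set[tuple[str, str]],
                         species: list[str] | None = None,
                         components: list[str] | None = None,
                         min_cov: float = 0.20) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single best external hit per (species, component) for components
    the orthology workflow missed.

    Hits with query or target coverage below ``min_cov`` (exactly 0.20
    is retained) are excluded; the minimum-E-value survivor across all of
    a species' assemblies wins, with ties broken by higher bitscore then
    lexicographic target. Status codes: '-' already found upstream, YES
    candidate found, NH no homolog in available data, ND no data
    available.
    """
    components = components or COMPONENTS
    if species is None:
        species = sorted(set(hits["species"]) | set(data_available))
    surviving = hits[(hits["qcov"] >= min_cov) & (hits["tcov"] >= min_cov)]
    chosen_rows = []
    status = pd.DataFrame(index=species, columns=components, dtype=object)
    status.index.name = "species"
    for sp in species:
        for comp in components:
            if (sp, comp) in found_upstream:
                status.at[sp, comp] = STATUS_FOUND_UPSTREAM
                continue
            if not data_available.get(sp, False):
                status.at[sp, comp] = STATUS_NO_DATA
                continue
            sub = surviving[(surviving["species"] == sp)
                            & (surviving["component"] == comp)]
            if sub.empty:
                status.at[sp, comp] = STATUS_NO_HOMOLOG
                continue
            best = sub.sort_values(
                ["evalue", "bitscore", "target"],
                ascending=[True, False, True], kind="mergesort").iloc[0]
            chosen_rows.append(best)
            status.at[sp, comp] = STATUS_YES
    chosen = (pd.DataFrame(chosen_rows).reset_index(drop=True)
              if chosen_rows else
              pd.DataFrame(columns=list(hits.columns)))
    return chosen, status
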