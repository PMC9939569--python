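"""Assembly redundancy reduction: length filter, single-best-ORF
prediction with completeness tags, near-identical sequence clustering,
longest-isoform-per-gene selection, and final transcriptome extraction.

De novo assemblies are highly redundant (isoforms, near-identical
contigs, fragments). The reduction keeps, per Trinity gene, the isoform
with the longest predicted protein, after collapsing near-identical
transcripts (>= 98% identity by default) onto their longest
representative.

ORF completeness follows the usual four-way tagging: ``cmp`` (start and
stop codon present), ``5p`` (no start), ``3p`` (no stop), ``int``
(neither).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
from Bio.Data.CodonTable import standard_dna_table

from .io_formats import ParseError, SeqRecord, parse_trinity_id

CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)

COMPLETENESS_TAGS = ("cmp", "5p", "3p", "int")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Orf:
    """A predicted coding region. Coordinates are 0-based half-open on
    the forward strand of the transcript; minus-strand ORFs store the
    forward-strand coordinates of the reverse-complemented span. The
    stop codon, when present, is included in [start, end)."""

    transcript_id: str
    strand: str            # '+' or '-'
    frame: int             # 0..2 on the reading strand
    start: int
    end: int
    protein: str
    completeness: str      # cmp / 5p / 3p / int


@dataclass(frozen=True)
class Cluster:
    representative_id: str
    member_ids: tuple[str, ...]


def filter_min_length(records: list[SeqRecord], min_len: int = 200
                      ) -> list[SeqRecord]:
    """Drop transcripts shorter than ``min_len`` nucleotides."""
    return [r for r in records if len(r) >= min_len]


# ---------------------------------------------------------------------------
# ORF prediction
# ---------------------------------------------------------------------------

def _translate(codons: list[str]) -> str:
    return "".join(CODON_TABLE[c] for c in codons)


def _scan_frame(seq: str, frame: int) -> list[dict]:
    """Candidate ORFs in one reading frame of one strand.

    Spans are maximal codon runs delimited by stop codons, codons
    containing N (untranslatable), or the sequence edges. Each span
    yields up to two candidates: one starting at the first ATG, and —
    only for the frame's first span, which has no upstream stop — one
    starting at the in-frame edge.
    """
    n = len(seq)
    candidates: list[dict] = []
    span_start_idx = 0          # codon index where current span began
    span_codons: list[str] = []
    first_span = True
    codon_starts = range(frame, n - 2, 3)

    def flush(end_codon_idx: int, stop: bool):
        nonlocal first_span
        if span_codons:
            starts = []
            if first_span:
                starts.append((0, span_codons[0] == "ATG"))
            if "ATG" in span_codons:
                atg = span_codons.index("ATG")
                if not (first_span and atg == 0):
                    starts.append((atg, True))
            for offset, has_start in starts:
                codons = span_codons[offset:]
                start_nt = frame + 3 * (span_start_idx + offset)
                end_nt = frame + 3 * end_codon_idx + (3 if stop else 0)
                candidates.append({
                    "frame": frame, "start": start_nt, "end": end_nt,
                    "protein": _translate(codons),
                    "has_start": has_start, "has_stop": stop,
                })
        first_span = False

    idx = 0
    for pos in codon_starts:
        codon = seq[pos:pos + 3]
        if codon in STOP_CODONS:
            flush(idx, stop=True)
            span_codons.clear()
            span_start_idx = idx + 1
        elif "N" in codon:
            flush(idx, stop=False)
            span_codons.clear()
            span_start_idx = idx + 1
        else:
            span_codons.append(codon)
        idx += 1
    flush(idx, stop=False)
    return candidates


def _completeness(has_start: bool, has_stop: bool) -> str:
    if has_start and has_stop:
        return "cmp"
    if has_stop:
        return "5p"
    if has_start:
        return "3p"
    return "int"


def find_best_orf(transcript: SeqRecord, min_aa: int = 100) -> Orf | None:
    """Scan all six frames and return the ORF with the longest protein,
    or None if the best one is shorter than ``min_aa``.

    Ties are broken deterministically: plus strand first, then lowest
    frame, then smallest forward-strand start.
    """
    if transcript.alphabet != "nucleotide":
        raise ParseError(f"{transcript.id}: ORF scan requires nucleotide input")
    seq = transcript.residues.upper()
    n = len(seq)
    best: tuple | None = None
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            for c in _scan_frame(s, frame):
                if strand == "+":
                    start, end = c["start"], c["end"]
                else:
                    start, end = n - c["end"], n - c["start"]
                orf = Orf(
                    transcript_id=transcript.id, strand=strand,
                    frame=frame, start=start, end=end,
                    protein=c["protein"],
                    completeness=_completeness(c["has_start"], c["has_stop"]),
                )
                key = (-len(orf.protein), 0 if strand == "+" else 1, frame, start)
                if best is None or key < best[0]:
                    best = (key, orf)
    if best is None or len(best[1].protein) < min_aa:
        return None
    return best[1]


# ---------------------------------------------------------------------------
# Near-identical sequence clustering
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity, normalized by the longer sequence:
    1 - edit_distance / max(len). For gap-free alignments this equals the
    fraction of identical aligned columns."""
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def cluster_sequences(records: list[SeqRecord], min_identity: float = 0.98,
                      min_target_cov: float = 0.98) -> list[Cluster]:
    """Greedy incremental clustering of near-identical sequences.

    Sequences are processed in descending length (ties broken by id);
    each joins the first existing cluster whose representative it matches
    at >= ``min_identity`` global identity with length coverage
    (shorter/longer) >= ``min_target_cov``, otherwise it founds a new
    cluster. The founding — hence longest — member is the representative.

    A length-ratio prefilter skips alignments that provably cannot reach
    the identity bound (identity <= shorter/longer under the normalization
    above); it never changes the result.
    """
    alphabets = {r.alphabet for r in records}
    if len(alphabets) > 1:
        raise ParseError(f"mixed alphabets in clustering input: {sorted(alphabets)}")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    reps: list[SeqRecord] = []
    members: dict[str, list[str]] = {}
    for rec in ordered:
        home = None
        for rep in reps:
            lmax, lmin = len(rep), len(rec)  # reps are never shorter
            ratio = lmin / lmax
            if ratio < min_identity or ratio < min_target_cov:
                continue
            k = math.floor(lmax * (1.0 - min_identity))
            d = edlib.align(rec.residues, rep.residues, mode="NW",
                            task="distance", k=k)["editDistance"]
            if d < 0:  # distance exceeds k: identity below threshold
                continue
            if 1.0 - d / lmax >= min_identity:
                home = rep
                break
        if home is None:
            reps.append(rec)
            members[rec.id] = [rec.id]
        else:
            members[home.id].append(rec.id)
    return [Cluster(representative_id=r.id, member_ids=tuple(members[r.id]))
            for r in reps]


# ---------------------------------------------------------------------------
# Isoform selection and final extraction
# ---------------------------------------------------------------------------

def select_longest_isoform(proteins: list[SeqRecord]
                           ) -> tuple[list[SeqRecord], dict[str, list[str]]]:
    """Per Trinity gene, keep the longest protein isoform.

    Ties go to the smallest isoform index, then lexicographic id. Returns
    the kept records (input order) and a map kept id -> discarded ids.
    """
    parsed = {}
    bad = []
    for rec in proteins:
        try:
            parsed[rec.id] = parse_trinity_id(rec.id)
        except ParseError:
            bad.append(rec.id)
    if bad:
        raise ParseError(f"unparseable Trinity id(s): {sorted(bad)}")
    by_gene: dict[str, list[SeqRecord]] = {}
    for rec in proteins:
        by_gene.setdefault(parsed[rec.id].gene_key, []).append(rec)
    kept_ids: set[str] = set()
    selection: dict[str, list[str]] = {}
    for gene, recs in by_gene.items():
        winner = min(recs, key=lambda r: (-len(r), parsed[r.id].isoform_index, r.id))
        kept_ids.add(winner.id)
        selection[winner.id] = sorted(r.id for r in recs if r.id != winner.id)
    kept = [r for r in proteins if r.id in kept_ids]
    return kept, selection


def extract_final_transcripts(initial: list[SeqRecord],
                              kept_protein_ids: list[str]) -> list[SeqRecord]:
    """Pull the nucleotide transcript for each kept protein out of the
    initial assembly, preserving assembly order."""
    wanted = {}
    for pid in kept_protein_ids:
        tid = parse_trinity_id(pid).transcript_id
        wanted[tid] = pid
    by_id = {r.id: r for r in initial}
    missing = sorted(t for t in wanted if t not in by_id)
    if missing:
        raise ParseError(f"transcript(s) not in initial assembly: {missing}")
    return [r for r in initial if r.id in wanted]


@dataclass
class ReductionResult:
    final_transcripts: list[SeqRecord]
    proteome: list[SeqRecord]
    orfs: list[Orf]
    clusters: list[Cluster]
    selection_map: dict[str, list[str]]
    n_initial: int
    n_length_filtered: int


def reduce_assembly(transcripts: list[SeqRecord], min_len: int = 200,
                    min_aa: int = 100, min_identity: float = 0.98,
                    min_target_cov: float = 0.98) -> ReductionResult:
    """The full reduction: length filter -> near-duplicate clustering ->
    best-ORF prediction on cluster representatives -> longest isoform per
    gene -> final transcript extraction."""
    filtered = filter_min_length(transcripts, min_len)
    clusters = cluster_sequences(filtered, min_identity, min_target_cov)
    rep_ids = {c.representative_id for c in clusters}
    reps = [t for t in filtered if t.id in rep_ids]
    orfs: list[Orf] = []
    proteins: list[SeqRecord] = []
    for t in reps:
        orf = find_best_orf(t, min_aa=min_aa)
        if orf is None:
            continue
        orfs.append(orf)
        proteins.append(SeqRecord(
            id=f"{t.id}.p1", residues=orf.protein,
            description=f"type:{orf.completeness}", alphabet="protein",
        ))
    kept, selection = select_longest_isoform(proteins)
    kept_orfs = {r.id for r in kept}
    final = extract_final_transcripts(transcripts, [r.id for r in kept])
    return ReductionResult(
        final_transcripts=final,
        proteome=kept,
        orfs=[o for o in orfs if f"{o.transcript_id}.p1" in kept_orfs],
        clusters=clusters,
        selection_map=selection,
        n_initial=len(transcripts),
        n_length_filtered=len(filtered),
    )
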