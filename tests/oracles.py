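"""Independent brute-force oracles used by the property suites.

These deliberately avoid the implementation's code paths: ORF search is
an exhaustive enumeration over all start candidates in all six frames,
pairwise identity comes from Biopython's dynamic-programming aligner
(unit costs) instead of edlib, and N50 uses the direct definition
("largest length x such that contigs >= x hold half the bases").
"""

from __future__ import annotations

import random

from Bio import Align

from zooclock.io_formats import SeqRecord
from zooclock.orf_reduce import CODON_TABLE, STOP_CODONS

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def orf_oracle(seq: str, min_aa: int = 1):
    """Best ORF as (strand, frame, start, end, protein, completeness) by
    exhaustive enumeration, or None.

    Candidates: for each strand/frame, every ATG codon opens a candidate
    running to the next stop codon, N-containing codon, or the edge; the
    frame's leading edge also opens a candidate provided no stop or N
    codon precedes it (trivially true). Completeness is cmp/5p/3p/int by
    presence of the ATG start and a terminating stop.
    """
    n = len(seq)
    best = None
    for strand, s in (("+", seq), ("-", _revcomp(seq))):
        for frame in range(3):
            codons = [s[i:i + 3] for i in range(frame, n - 2, 3)]
            terminators = [i for i, c in enumerate(codons)
                           if c in STOP_CODONS or "N" in c]
            starts = [(0, True)] + [(i, False) for i, c in enumerate(codons)
                                    if c == "ATG"]
            for start_idx, is_edge in starts:
                if is_edge and terminators and terminators[0] == 0:
                    continue  # empty leading span
                if is_edge:
                    prior = [t for t in terminators if t < start_idx]
                    if prior:
                        continue
                else:
                    pass  # ATG candidates are valid anywhere
                nexts = [t for t in terminators if t >= start_idx]
                end_idx = nexts[0] if nexts else len(codons)
                body = codons[start_idx:end_idx]
                if not body:
                    continue
                has_stop = (nexts and codons[end_idx] in STOP_CODONS)
                has_start = body[0] == "ATG"
                protein = "".join(CODON_TABLE[c] for c in body)
                start_nt = frame + 3 * start_idx
                end_nt = frame + 3 * end_idx + (3 if has_stop else 0)
                if strand == "-":
                    start_nt, end_nt = n - end_nt, n - start_nt
                tag = ("cmp" if has_start and has_stop else
                       "5p" if has_stop else "3p" if has_start else "int")
                key = (-len(protein), 0 if strand == "+" else 1, frame, start_nt)
                cand = (key, (strand, frame, start_nt, end_nt, protein, tag))
                if best is None or cand[0] < best[0]:
                    best = cand
    if best is None or len(best[1][4]) < min_aa:
        return None
    return best[1]


def _unit_cost_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def identity_oracle(a: str, b: str) -> float:
    """Edit-distance identity via Biopython's DP aligner."""
    d = -_unit_cost_aligner().score(a, b)
    return 1.0 - d / max(len(a), len(b))


def cluster_oracle(records: list[SeqRecord], min_identity: float = 0.98,
                   min_target_cov: float = 0.98) -> set[frozenset[str]]:
    """Greedy join rule replayed over an all-pairs DP identity matrix;
    returns the partition as a set of member-id frozensets."""
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    ident = {}
    for i, x in enumerate(ordered):
        for y in ordered[i + 1:]:
            ident[(x.id, y.id)] = identity_oracle(x.residues, y.residues)
    reps: list[SeqRecord] = []
    members: dict[str, set[str]] = {}
    for rec in ordered:
        home = None
        for rep in reps:
            cov = min(len(rec), len(rep)) / max(len(rec), len(rep))
            if cov < min_target_cov:
                continue
            if ident[(rep.id, rec.id)] >= min_identity:
                home = rep
                break
        if home is None:
            reps.append(rec)
            members[rec.id] = {rec.id}
        else:
            members[home.id].add(rec.id)
    return {frozenset(v) for v in members.values()}


def n50_oracle(lengths: list[int]) -> int:
    """Largest contig length x such that contigs of length >= x contain
    at least half of all bases."""
    total = sum(lengths)
    return max(x for x in lengths
               if sum(l for l in lengths if l >= x) * 2 >= total)


def random_cluster_instance(seed: int, max_seqs: int = 20
                            ) -> list[SeqRecord]:
    """Random sequences plus planted near-duplicates for oracle tests."""
    rng = random.Random(seed)
    records = []
    n_base = rng.randint(3, max_seqs // 2)
    for i in range(n_base):
        length = rng.randint(120, 240)
        seq = "".join(rng.choice("ACGT") for _ in range(length))
        records.append(SeqRecord(id=f"s{seed}_{i}", residues=seq,
                                 alphabet="nucleotide"))
        if rng.random() < 0.6 and len(records) < max_seqs:
            dup = list(seq)
            for pos in rng.sample(range(length), max(1, length // 200)):
                dup[pos] = rng.choice("ACGT".replace(dup[pos], ""))
            records.append(SeqRecord(id=f"s{seed}_{i}dup",
                                     residues="".join(dup),
                                     alphabet="nucleotide"))
    return records[:max_seqs]
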