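"""Ground-truthed synthetic inputs for the full pipeline.

The generator plants, for a configurable number of species, orthologs of
the ten clock baits with component-specific domain architectures, plus
paralogs (same family, different subfamily), ORF fragments
(5'/3'/internal), transcript isoforms sharing a Trinity gene id,
near-duplicate transcripts (>= 98% identity), and decoy proteins that
carry a single bait domain inside an unrelated family. Pairwise-ortholog,
domain, family and homology-hit tables are derived from the planted
truth, with injectable false negatives (dropped true pairs) and false
positives (decoy pairs).

Everything is driven by one integer seed and is byte-deterministic.
Mutations are substitutions only, and back-translation uses one fixed
codon per amino acid, so identity and coverage arithmetic stays exact
for oracle checks. The generator records what it planted in a
:class:`TruthManifest`, the acceptance oracle for recovery tests.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .clock_id import Bait, tag_baits, DEFAULT_MARKER
from .io_formats import ReadPair, SeqRecord
from .reference_data import BAIT_ACCESSIONS, COMPONENTS

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: one fixed codon per amino acid; Leu/Ser codons reverse-complement to
#: stop codons, keeping reverse-strand open frames statistically short.
BACK_TRANSLATION = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "TTA", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCA", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}
STOP = "TGA"

#: untranslated flanks with stop codons in all three reading frames, so
#: no predicted frame can run through them
DEFAULT_UTR5 = "TAAATAAATAA"
DEFAULT_UTR3 = "TAAATAAATAA"


@dataclass(frozen=True)
class ComponentSpec:
    """Planted architecture of one clock component: protein length,
    Pfam-style domains at fixed 1-based aa coordinates, and the
    family/subfamily accession used for vetting."""
    length: int
    domains: tuple[tuple[str, str, int, int], ...]  # (acc, name, start, end)
    family: str
    subfamily: str


DEFAULT_ARCHITECTURES: dict[str, ComponentSpec] = {
    "CLK": ComponentSpec(650, (("PF00010", "bHLH", 21, 75),
                               ("PF00989", "PAS", 106, 175),
                               ("PF08447", "PAS_3", 221, 290)),
                         "PTHR10001", "PTHR10001:SF1"),
    "CYC": ComponentSpec(600, (("PF00010", "bHLH", 16, 70),
                               ("PF00989", "PAS", 96, 165),
                               ("PF08447", "PAS_3", 201, 270)),
                         "PTHR10002", "PTHR10002:SF1"),
    "TIM": ComponentSpec(1000, (("PF04821", "TIMELESS", 31, 260),
                                ("PF05029", "TIMELESS_C", 701, 880)),
                         "PTHR10003", "PTHR10003:SF1"),
    "PER": ComponentSpec(900, (("PF00989", "PAS", 161, 230),
                               ("PF08447", "PAS_3", 321, 390),
                               ("PF04454", "Period_C", 561, 680)),
                         "PTHR10004", "PTHR10004:SF1"),
    "CRY1": ComponentSpec(540, (("PF00875", "DNA_photolyase", 5, 170),
                                ("PF03441", "FAD_binding_7", 251, 480)),
                          "PTHR10005", "PTHR10005:SF1"),
    "CRY2": ComponentSpec(610, (("PF00875", "DNA_photolyase", 11, 180),
                                ("PF03441", "FAD_binding_7", 261, 490)),
                          "PTHR10006", "PTHR10006:SF1"),
    "PDP1e": ComponentSpec(360, (("PF00170", "bZIP_1", 281, 340),),
                           "PTHR10007", "PTHR10007:SF1"),
    "VRI": ComponentSpec(450, (("PF00170", "bZIP_1", 361, 420),),
                         "PTHR10008", "PTHR10008:SF1"),
    "REV-ERBa": ComponentSpec(600, (("PF00105", "zf-C4", 131, 200),
                                    ("PF00104", "Hormone_recep", 401, 570)),
                              "PTHR10009", "PTHR10009:SF1"),
    "RORa": ComponentSpec(520, (("PF00105", "zf-C4", 71, 140),
                                ("PF00104", "Hormone_recep", 301, 470)),
                          "PTHR10010", "PTHR10010:SF1"),
}

DECOY_FAMILY = "PTHR99999"


class SynthConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    n_species: int = 5
    components: tuple[str, ...] = tuple(COMPONENTS)
    architectures: dict[str, ComponentSpec] = field(
        default_factory=lambda: dict(DEFAULT_ARCHITECTURES))
    divergence_per_species: float = 0.15
    paralog_rate: float = 0.25
    fragment_rate: float = 0.2
    decoy_count: int = 3
    near_duplicate_rate: float = 0.25
    isoforms_per_gene: tuple[int, int] = (1, 3)
    subfamily_fraction: float = 0.75
    ortholog_fn_rate: float = 0.0
    ortholog_fp_rate: float = 0.0
    utr5: str = DEFAULT_UTR5
    utr3: str = DEFAULT_UTR3
    min_fragment_aa: int = 150
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "divergence_per_species": self.divergence_per_species,
            "paralog_rate": self.paralog_rate,
            "fragment_rate": self.fragment_rate,
            "near_duplicate_rate": self.near_duplicate_rate,
            "subfamily_fraction": self.subfamily_fraction,
            "ortholog_fn_rate": self.ortholog_fn_rate,
            "ortholog_fp_rate": self.ortholog_fp_rate,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise SynthConfigError(f"{name}={value} outside [0, 1]")
        if self.divergence_per_species > 0.5:
            raise SynthConfigError("divergence above 0.5 is not meaningful")
        if not self.components:
            raise SynthConfigError("no components configured")
        for comp in self.components:
            spec = self.architectures.get(comp)
            if spec is None or not spec.domains:
                raise SynthConfigError(f"missing/empty architecture for {comp}")
            for acc, name, start, end in spec.domains:
                if not (1 <= start <= end <= spec.length):
                    raise SynthConfigError(
                        f"{comp}: domain {acc} [{start},{end}] exceeds the "
                        f"{spec.length}-residue sequence budget")


@dataclass
class TruthManifest:
    """Everything the generator planted, one JSON-able record per
    entity. The downstream recovery tests treat this as ground truth."""
    entries: list[dict] = field(default_factory=list)

    def orthologs(self) -> list[dict]:
        return [e for e in self.entries if e["role"] == "ortholog"]

    def true_pairs(self) -> set[tuple[str, str, str]]:
        """(species, protein_id, component) for every planted ortholog."""
        return {(e["species"], e["protein_id"], e["component"])
                for e in self.orthologs()}

    def ids_by_role(self, role: str) -> set[str]:
        return {e["protein_id"] for e in self.entries
                if e["role"] == role and "protein_id" in e}

    def near_duplicate_pairs(self) -> list[tuple[str, str]]:
        return [(e["original_transcript_id"], e["duplicate_transcript_id"])
                for e in self.entries if e["role"] == "near_duplicate"]

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(json.dumps(e, sort_keys=True) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls([json.loads(line) for line in fh if line.strip()])


@dataclass
class SyntheticUniverse:
    config: SynthConfig
    reference_proteomes: dict[str, list[SeqRecord]]   # marker-tagged
    bait_registry: dict[str, Bait]
    bait_proteins: dict[str, str]                     # component -> residues
    species: list[str]
    proteomes: dict[str, list[SeqRecord]]
    domain_table: pd.DataFrame
    family_table: pd.DataFrame
    pair_table: pd.DataFrame
    hit_table: pd.DataFrame
    manifest: TruthManifest
    _gene_meta: dict[str, dict] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def back_translate(protein: str, utr5: str = "", utr3: str = "",
                   include_stop: bool = True) -> str:
    """Deterministic nucleotide sequence encoding ``protein`` (one fixed
    codon per amino acid), framed by the given untranslated flanks."""
    cds = "".join(BACK_TRANSLATION[a] for a in protein)
    return utr5 + cds + (STOP if include_stop else "") + utr3


def _random_protein(rng: random.Random, length: int) -> str:
    body = "".join(rng.choice(AMINO_ACIDS) for _ in range(length - 1))
    return "M" + body


def _mutate_protein(rng: random.Random, protein: str, rate: float) -> str:
    out = [protein[0]]  # keep the initiator Met
    for aa in protein[1:]:
        if rng.random() < rate:
            choices = AMINO_ACIDS.replace(aa, "")
            out.append(rng.choice(choices))
        else:
            out.append(aa)
    return "".join(out)


def _avoid_met(protein: str, pos: int) -> int:
    """Nudge a cut position so the fragment does not begin with Met
    (which would let the ORF classifier call it complete)."""
    while pos > 1 and protein[pos] == "M":
        pos -= 1
    return pos


# ---------------------------------------------------------------------------
# universe generation
# ---------------------------------------------------------------------------

def generate_universe(config: SynthConfig | None = None) -> SyntheticUniverse:
    config = config or SynthConfig()
    config.validate()
    rng = random.Random(config.seed)

    # bait proteins and reference proteomes
    bait_proteins: dict[str, str] = {}
    ref_raw: dict[str, list[SeqRecord]] = {}
    for comp in config.components:
        spec = config.architectures[comp]
        bait_proteins[comp] = _random_protein(rng, spec.length)
    for comp in config.components:
        sp_code, acc = BAIT_ACCESSIONS[comp]
        rec = SeqRecord(id=f"sp|{acc}|{comp}_{sp_code.upper()}",
                        residues=bait_proteins[comp], alphabet="protein")
        ref_raw.setdefault(sp_code, []).append(rec)
    for sp_code in list(ref_raw):
        for i in range(2):  # non-clock filler proteins
            ref_raw[sp_code].append(SeqRecord(
                id=f"sp|F{sp_code.upper()}{i:03d}|FILLER{i}_{sp_code.upper()}",
                residues=_random_protein(rng, 200 + 10 * i),
                alphabet="protein"))
    bait_accessions = {c: BAIT_ACCESSIONS[c] for c in config.components}
    tagged_refs, registry = tag_baits(ref_raw, bait_accessions,
                                      marker=DEFAULT_MARKER)

    species = [f"species{i + 1:02d}" for i in range(config.n_species)]
    manifest = TruthManifest()
    proteomes: dict[str, list[SeqRecord]] = {sp: [] for sp in species}
    domain_rows: list[dict] = []
    family_rows: list[dict] = []
    pair_rows: list[dict] = []
    hit_rows: list[dict] = []
    gene_meta: dict[str, dict] = {}

    # bait annotations (Pfam + CDD mirror for visualization stacking)
    for comp in config.components:
        spec = config.architectures[comp]
        bait = registry[comp]
        for acc, name, start, end in spec.domains:
            domain_rows.append(dict(seq_id=bait.seq_id, db="Pfam",
                                    accession=acc, name=name, start=start,
                                    end=end, evalue=1e-30))
            domain_rows.append(dict(seq_id=bait.seq_id, db="CDD",
                                    accession=f"cd{acc[2:]}", name=name,
                                    start=start, end=end, evalue=1e-20))
        family_rows.append(dict(seq_id=bait.seq_id, family_acc=spec.family,
                                subfamily_acc=spec.subfamily))
        registry[comp] = replace(
            bait, domains=frozenset(a for a, *_ in spec.domains),
            family=spec.family, subfamily=spec.subfamily)

    def new_gene(species_idx: int, counter: list[int]) -> str:
        counter[0] += 1
        return f"DN{(species_idx + 1) * 100000 + counter[0]}_c0_g1"

    def emit_protein(sp: str, gene_key: str, protein: str, tag: str,
                     kind: str) -> tuple[str, str]:
        tid = f"TRINITY_{gene_key}_i1"
        pid = f"{tid}.p1"
        proteomes[sp].append(SeqRecord(id=pid, residues=protein,
                                       description=f"type:{tag}",
                                       alphabet="protein"))
        gene_meta[pid] = dict(species=sp, gene_key=gene_key,
                              transcript_id=tid, kind=kind, tag=tag)
        return tid, pid

    for si, sp in enumerate(species):
        counter = [0]
        for comp in config.components:
            spec = config.architectures[comp]
            bait = registry[comp]
            protein = _mutate_protein(rng, bait_proteins[comp],
                                      config.divergence_per_species)
            domains = list(spec.domains)
            tag = "cmp"
            # optionally truncate into an ORF fragment, keeping all domains
            if rng.random() < config.fragment_rate:
                tag = rng.choice(["5p", "3p", "int"])
                first = min(d[2] for d in domains)
                last = max(d[3] for d in domains)
                head_max = max(0, min(first - 2,
                                      len(protein) - config.min_fragment_aa))
                tail_max = max(0, len(protein) - last - 1)
                k = m = 0
                if tag in ("5p", "int") and head_max >= 5:
                    k = _avoid_met(protein, rng.randint(5, head_max))
                if tag in ("3p", "int") and tail_max >= 5:
                    m = rng.randint(5, tail_max)
                if k == 0 and m == 0:
                    tag = "cmp"  # architecture leaves no safe margin
                else:
                    if k > 0 and m == 0 and tag == "int":
                        tag = "5p"
                    if m > 0 and k == 0 and tag == "int":
                        tag = "3p"
                    protein = protein[k:len(protein) - m]
                    domains = [(a, n, s - k, e - k) for a, n, s, e in domains]
            gene_key = new_gene(si, counter)
            tid, pid = emit_protein(sp, gene_key, protein, tag, "ortholog")
            for acc, name, start, end in domains:
                domain_rows.append(dict(seq_id=pid, db="Pfam", accession=acc,
                                        name=name, start=start, end=end,
                                        evalue=1e-20))
            subfam = (spec.subfamily
                      if rng.random() < config.subfamily_fraction else "")
            family_rows.append(dict(seq_id=pid, family_acc=spec.family,
                                    subfamily_acc=subfam))
            hit_rows.append(dict(query=pid,
                                 target=f"sp|{bait.accession}|{comp}_SP",
                                 evalue=1e-60, bitscore=800.0,
                                 qcov=0.95, tcov=0.9))
            manifest.entries.append(dict(
                role="ortholog", species=sp, component=comp, protein_id=pid,
                transcript_id=tid, gene_key=gene_key, completeness=tag))
            if rng.random() >= config.ortholog_fn_rate:
                pair_rows.append(dict(species_a=bait.source_species,
                                      seq_a=bait.seq_id, species_b=sp,
                                      seq_b=pid))
            # paralog: same family, different subfamily, never in pair table
            if rng.random() < config.paralog_rate:
                para = _mutate_protein(
                    rng, bait_proteins[comp],
                    min(0.5, 2 * config.divergence_per_species))
                pkey = new_gene(si, counter)
                _, ppid = emit_protein(sp, pkey, para, "cmp", "paralog")
                for acc, name, start, end in spec.domains:
                    domain_rows.append(dict(seq_id=ppid, db="Pfam",
                                            accession=acc, name=name,
                                            start=start, end=end,
                                            evalue=1e-15))
                family_rows.append(dict(seq_id=ppid, family_acc=spec.family,
                                        subfamily_acc=f"{spec.family}:SF2"))
                manifest.entries.append(dict(
                    role="paralog", species=sp, component=comp,
                    protein_id=ppid, gene_key=pkey, completeness="cmp"))

        # decoys: one bait domain inside an unrelated family
        for d in range(config.decoy_count):
            comp = config.components[d % len(config.components)]
            spec = config.architectures[comp]
            acc, name, dstart, dend = spec.domains[0]
            dlen = dend - dstart + 1
            body = _random_protein(rng, max(300, dlen + 120))
            insert_at = 50
            segment = bait_proteins[comp][dstart - 1:dend]
            decoy = body[:insert_at] + segment + body[insert_at + dlen:]
            gkey = new_gene(si, counter)
            _, dpid = emit_protein(sp, gkey, decoy, "cmp", "decoy")
            domain_rows.append(dict(seq_id=dpid, db="Pfam", accession=acc,
                                    name=name, start=insert_at + 1,
                                    end=insert_at + dlen, evalue=1e-12))
            family_rows.append(dict(seq_id=dpid, family_acc=DECOY_FAMILY,
                                    subfamily_acc=""))
            hit_rows.append(dict(query=dpid, target="sp|Q99999|UNREL_SP",
                                 evalue=1e-8, bitscore=80.0,
                                 qcov=0.4, tcov=0.3))
            manifest.entries.append(dict(
                role="decoy", species=sp, protein_id=dpid, gene_key=gkey,
                carried_component=comp, carried_domain=acc))
            # injectable false-positive ortholog pair
            if rng.random() < config.ortholog_fp_rate:
                bait = registry[comp]
                pair_rows.append(dict(species_a=bait.source_species,
                                      seq_a=bait.seq_id, species_b=sp,
                                      seq_b=dpid, note="FP"))

    pair_table = pd.DataFrame(
        pair_rows, columns=["species_a", "seq_a", "species_b", "seq_b", "note"]
    ).fillna({"note": ""}) if pair_rows else pd.DataFrame(
        columns=["species_a", "seq_a", "species_b", "seq_b", "note"])
    return SyntheticUniverse(
        config=config,
        reference_proteomes=tagged_refs,
        bait_registry=registry,
        bait_proteins=bait_proteins,
        species=species,
        proteomes=proteomes,
        domain_table=pd.DataFrame(domain_rows),
        family_table=pd.DataFrame(family_rows),
        pair_table=pair_table,
        hit_table=pd.DataFrame(hit_rows),
        manifest=manifest,
        _gene_meta=gene_meta,
    )


# ---------------------------------------------------------------------------
# transcript generation
# ---------------------------------------------------------------------------

def generate_transcripts(universe: SyntheticUniverse,
                         config: SynthConfig | None = None
                         ) -> tuple[dict[str, list[SeqRecord]], dict[str, str]]:
    """Nucleotide transcripts with Trinity-style ids for every planted
    protein: the i1 isoform back-translates the full protein (framed by
    UTRs according to its completeness tag), additional isoforms are
    truncations, and near-duplicate transcripts are substitution-mutated
    copies planted as separate genes. Returns per-species transcript
    lists and a protein id -> transcript id reverse map; near-duplicate
    pairs are appended to the universe manifest."""
    config = config or universe.config
    rng = random.Random(config.seed + 1)
    transcripts: dict[str, list[SeqRecord]] = {sp: [] for sp in universe.species}
    reverse_map: dict[str, str] = {}
    dup_counter: dict[str, int] = {sp: 0 for sp in universe.species}

    for sp in universe.species:
        for rec in universe.proteomes[sp]:
            meta = universe._gene_meta[rec.id]
            tag = meta["tag"]
            protein = rec.residues
            if tag == "cmp":
                nt = back_translate(protein, config.utr5, config.utr3, True)
            elif tag == "5p":
                nt = back_translate(protein, "", config.utr3, True)
            elif tag == "3p":
                nt = back_translate(protein, config.utr5, "", False)
            else:  # int
                nt = back_translate(protein, "", "", False)
            tid = meta["transcript_id"]
            main = SeqRecord(id=tid, residues=nt, alphabet="nucleotide")
            transcripts[sp].append(main)
            reverse_map[rec.id] = tid
            iso_ids = [tid]
            lo, hi = config.isoforms_per_gene
            for iso in range(2, rng.randint(lo, hi) + 1):
                frac = rng.uniform(0.4, 0.8)
                prefix = protein[:max(70, int(len(protein) * frac))]
                iso_nt = back_translate(prefix, config.utr5, "", False)
                iso_tid = f"TRINITY_{meta['gene_key']}_i{iso}"
                transcripts[sp].append(SeqRecord(id=iso_tid, residues=iso_nt,
                                                 alphabet="nucleotide"))
                iso_ids.append(iso_tid)
            if len(iso_ids) > 1:
                universe.manifest.entries.append(dict(
                    role="isoform_group", species=sp,
                    gene_key=meta["gene_key"], transcript_ids=iso_ids))
            if (meta["kind"] == "ortholog"
                    and rng.random() < config.near_duplicate_rate):
                dup_counter[sp] += 1
                si = universe.species.index(sp)
                dkey = f"DN{(si + 1) * 100000 + 50000 + dup_counter[sp]}_c0_g1"
                dup_tid = f"TRINITY_{dkey}_i1"
                dup_nt = _near_duplicate(rng, nt)
                transcripts[sp].append(SeqRecord(id=dup_tid, residues=dup_nt,
                                                 alphabet="nucleotide"))
                universe.manifest.entries.append(dict(
                    role="near_duplicate", species=sp,
                    original_transcript_id=tid,
                    duplicate_transcript_id=dup_tid))
    return transcripts, reverse_map


def _near_duplicate(rng: random.Random, nt: str) -> str:
    """Copy with < 2% substitutions, 3 nt shorter so the original always
    sorts first (and stays the cluster representative)."""
    body = list(nt[:-3])
    n_sub = max(1, len(body) // 100)
    for pos in rng.sample(range(len(body)), n_sub):
        body[pos] = rng.choice("ACGT".replace(body[pos], ""))
    return "".join(body)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorProfile:
    """Planted read defects: fraction of pairs given an ambiguous base
    and fraction given a low mean quality (both fail the QC filter)."""
    n_rate: float = 0.0
    low_quality_rate: float = 0.0
    low_quality_phred: int = 10


def generate_read_pairs(transcripts: list[SeqRecord], n_pairs: int,
                        error_profile: ErrorProfile | None = None,
                        seed: int = 0, read_len: int = 100,
                        ) -> tuple[list[ReadPair], dict[str, bool]]:
    """Uniformly sampled fixed-length windows as paired reads.

    Returns the pairs and a pass-manifest: pair id -> True when the pair
    was planted defect-free (the expected survivor set of the QC filter).
    """
    profile = error_profile or ErrorProfile()
    rng = random.Random(seed)
    pairs: list[ReadPair] = []
    passes: dict[str, bool] = {}
    if n_pairs and not transcripts:
        raise ValueError("cannot sample reads from an empty transcript set")
    for i in range(n_pairs):
        t = transcripts[rng.randrange(len(transcripts))]
        insert = min(len(t), 2 * read_len + 50)
        start = rng.randint(0, len(t) - insert)
        window = t.residues[start:start + insert]
        fwd = window[:read_len].ljust(read_len, "A")
        rev_src = window[-read_len:].rjust(read_len, "A")
        rev = rev_src.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
        fq = rq = chr(40 + 33) * read_len
        clean = True
        if rng.random() < profile.n_rate:
            clean = False
            pos = rng.randrange(read_len)
            if rng.random() < 0.5:
                fwd = fwd[:pos] + "N" + fwd[pos + 1:]
            else:
                rev = rev[:pos] + "N" + rev[pos + 1:]
        elif rng.random() < profile.low_quality_rate:
            clean = False
            bad_q = chr(profile.low_quality_phred + 33) * read_len
            if rng.random() < 0.5:
                fq = bad_q
            else:
                rq = bad_q
        pair_id = f"read{i:07d}"
        pairs.append(ReadPair(
            pair_id=pair_id,
            forward=SeqRecord(id=f"{pair_id}/1", residues=fwd),
            reverse=SeqRecord(id=f"{pair_id}/2", residues=rev),
            forward_quality=fq, reverse_quality=rq))
        passes[pair_id] = clean
    return pairs, passes
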