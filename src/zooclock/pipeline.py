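"""File-driven orchestration of the analysis stages.

Each stage reads its inputs from — and writes its artifacts into — a
run directory, and records a manifest entry (stage, config hash, input
hashes) so that re-running an unchanged stage is a no-op. The stage
DAG: simulate -> filter-reads -> reduce -> stats / annotate-merge ->
find-clock -> validate / draw-domains; compare-runs operates on two
completed runs. Structured count logging at every filter is the
pipeline's primary audit output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._util import file_sha256, percent
from . import reference_data
from .annotation_merge import best_hit_per_query, merge_annotations
from .assembly_stats import AssemblyStats, compute_n50, pct_complete_orfs, \
    stats_table, summarize_assemblies
from .clock_id import (Bait, DEFAULT_MARKER, candidate_matrix,
                       compare_candidate_sets, confirm_swissprot,
                       extract_bait_orthologs, validate_against_references,
                       vet_candidates, write_candidate_matrix)
from .domain_viz import TrackSpec, label_bait, label_candidate, \
    render_domain_diagram
from .io_formats import (read_domain_table, read_family_table, read_fasta,
                         read_fastq_pairs, read_hit_table, read_pair_table,
                         write_fasta, write_fastq_pairs, write_tsv)
from .orf_reduce import reduce_assembly
from .read_qc import filter_read_pairs
from .synthetic import (ErrorProfile, SynthConfig, TruthManifest,
                        generate_read_pairs, generate_transcripts,
                        generate_universe)

log = logging.getLogger("zooclock")

STAGE_DEPS = {
    "simulate": [],
    "filter-reads": ["simulate"],
    "reduce": ["simulate"],
    "stats": ["reduce"],
    "annotate-merge": ["reduce", "simulate"],
    "find-clock": ["reduce", "annotate-merge"],
    "validate": ["find-clock"],
    "draw-domains": ["find-clock"],
}


class DependencyError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Thresholds and synthetic-universe settings for one run."""
    outdir: str = "run"
    min_len: int = 200
    min_mean_q: float = 20.0
    cluster_identity: float = 0.98
    cluster_cov: float = 0.98
    evalue_cutoff: float = 1e-5
    fallback_min_cov: float = 0.20
    orf_min_aa: int = 100
    marker: str = DEFAULT_MARKER
    seed: int = 0
    n_species: int = 5
    n_read_pairs: int = 500
    read_n_rate: float = 0.05
    read_low_quality_rate: float = 0.05
    ortholog_fn_rate: float = 0.0
    ortholog_fp_rate: float = 0.0

    def validate(self) -> None:
        if not (0 < self.cluster_identity <= 1 and 0 < self.cluster_cov <= 1):
            raise ValueError("cluster thresholds must lie in (0, 1]")
        if self.min_len < 0 or self.orf_min_aa < 0:
            raise ValueError("length thresholds must be non-negative")
        if self.evalue_cutoff <= 0:
            raise ValueError("E-value cutoff must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    def synth_config(self) -> SynthConfig:
        return SynthConfig(n_species=self.n_species,
                           ortholog_fn_rate=self.ortholog_fn_rate,
                           ortholog_fp_rate=self.ortholog_fp_rate,
                           seed=self.seed)


class Pipeline:
    def __init__(self, config: RunConfig):
        config.validate()
        self.config = config
        self.root = Path(config.outdir)
        self.root.mkdir(parents=True, exist_ok=True)
        config.to_yaml(self.root / "config.yaml")
        self.meta_path = self.root / "runmeta.json"
        self.meta = (json.loads(self.meta_path.read_text())
                     if self.meta_path.exists() else {})

    # -- manifest bookkeeping ------------------------------------------------

    def _config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self.config), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def _record(self, stage: str, inputs: list[Path], outputs: list[Path]):
        self.meta[stage] = {
            "config_hash": self._config_hash(),
            "input_hashes": {str(p): file_sha256(p) for p in inputs},
            "outputs": [str(p) for p in outputs],
        }
        self.meta_path.write_text(json.dumps(self.meta, indent=2))

    def _up_to_date(self, stage: str, inputs: list[Path]) -> bool:
        entry = self.meta.get(stage)
        if entry is None or entry["config_hash"] != self._config_hash():
            return False
        if set(entry["input_hashes"]) != {str(p) for p in inputs}:
            return False
        for p, h in entry["input_hashes"].items():
            if not Path(p).exists() or file_sha256(p) != h:
                return False
        return all(Path(p).exists() for p in entry["outputs"])

    def _check_deps(self, stage: str):
        for dep in STAGE_DEPS.get(stage, []):
            if dep not in self.meta:
                raise DependencyError(
                    f"stage {stage!r} requires {dep!r}; run it first")

    def run_stage(self, stage: str, force: bool = False) -> bool:
        """Run one stage; returns False when skipped as up to date."""
        self._check_deps(stage)
        runner = {
            "simulate": self.simulate,
            "filter-reads": self.filter_reads,
            "reduce": self.reduce,
            "stats": self.stats,
            "annotate-merge": self.annotate_merge,
            "find-clock": self.find_clock,
            "validate": self.validate,
            "draw-domains": self.draw_domains,
        }[stage]
        inputs = self._stage_inputs(stage)
        if not force and self._up_to_date(stage, inputs):
            log.info("%s: up to date, skipping", stage)
            return False
        outputs = runner()
        self._record(stage, inputs, outputs)
        return True

    def run_all(self, force: bool = False) -> None:
        for stage in ["simulate", "filter-reads", "reduce", "stats",
                      "annotate-merge", "find-clock", "validate",
                      "draw-domains"]:
            self.run_stage(stage, force=force)

    def _stage_inputs(self, stage: str) -> list[Path]:
        d = self.root
        mapping = {
            "simulate": [],
            "filter-reads": sorted((d / "inputs").glob("*_R[12].fastq")),
            "reduce": sorted((d / "inputs").glob("*_transcripts.fasta")),
            "stats": sorted((d / "reduced").glob("*_final.fasta")),
            "annotate-merge": [d / "inputs" / "hit_table.tsv"],
            "find-clock": [d / "inputs" / "pair_table.tsv"],
            "validate": [d / "clock" / "candidates.jsonl"],
            "draw-domains": [d / "clock" / "candidates.jsonl"],
        }
        return [p for p in mapping.get(stage, []) if p.exists()]

    # -- stages --------------------------------------------------------------

    def simulate(self) -> list[Path]:
        cfg = self.config
        out = self.root / "inputs"
        out.mkdir(exist_ok=True)
        universe = generate_universe(cfg.synth_config())
        transcripts, reverse_map = generate_transcripts(universe)
        outputs = []
        for sp_code, records in universe.reference_proteomes.items():
            p = out / f"reference_{sp_code}.fasta"
            write_fasta(records, p)
            outputs.append(p)
        for sp in universe.species:
            p = out / f"{sp}_transcripts.fasta"
            write_fasta(transcripts[sp], p)
            outputs.append(p)
            pairs, passes = generate_read_pairs(
                transcripts[sp], cfg.n_read_pairs,
                ErrorProfile(cfg.read_n_rate, cfg.read_low_quality_rate),
                seed=cfg.seed + hash_species(sp))
            f1, f2 = out / f"{sp}_R1.fastq", out / f"{sp}_R2.fastq"
            write_fastq_pairs(pairs, f1, f2)
            (out / f"{sp}_read_truth.json").write_text(json.dumps(passes))
            outputs += [f1, f2]
        for name, df in [("pair_table", universe.pair_table),
                         ("domain_table", universe.domain_table),
                         ("family_table", universe.family_table),
                         ("hit_table", universe.hit_table)]:
            p = out / f"{name}.tsv"
            write_tsv(df, p)
            outputs.append(p)
        universe.manifest.to_jsonl(out / "truth_manifest.jsonl")
        registry = {c: dataclasses.asdict(b) | {"domains": sorted(b.domains)}
                    for c, b in universe.bait_registry.items()}
        (out / "bait_registry.json").write_text(json.dumps(registry, indent=2))
        (out / "species.json").write_text(json.dumps(universe.species))
        log.info("simulate: %d species, %d pair rows",
                 len(universe.species), len(universe.pair_table))
        return outputs + [out / "truth_manifest.jsonl",
                          out / "bait_registry.json", out / "species.json"]

    def filter_reads(self) -> list[Path]:
        cfg = self.config
        out = self.root / "qc"
        out.mkdir(exist_ok=True)
        rows, outputs = [], []
        for sp in self._species():
            pairs = read_fastq_pairs(self.root / "inputs" / f"{sp}_R1.fastq",
                                     self.root / "inputs" / f"{sp}_R2.fastq")
            kept, st = filter_read_pairs(pairs, cfg.min_mean_q, species=sp)
            f1, f2 = out / f"{sp}_R1.fastq", out / f"{sp}_R2.fastq"
            write_fastq_pairs(kept, f1, f2)
            outputs += [f1, f2]
            rows.append(dataclasses.asdict(st))
            log.info("filter-reads %s: %d -> %d pairs (%.1f%% retained)",
                     sp, st.raw_pairs, st.kept_pairs, st.retained_pct)
        p = out / "read_retention.tsv"
        write_tsv(pd.DataFrame(rows), p)
        return outputs + [p]

    def reduce(self) -> list[Path]:
        cfg = self.config
        out = self.root / "reduced"
        out.mkdir(exist_ok=True)
        outputs = []
        for sp in self._species():
            transcripts = read_fasta(
                self.root / "inputs" / f"{sp}_transcripts.fasta",
                alphabet="nucleotide")
            res = reduce_assembly(transcripts, cfg.min_len, cfg.orf_min_aa,
                                  cfg.cluster_identity, cfg.cluster_cov)
            pf, ff = out / f"{sp}_proteome.fasta", out / f"{sp}_final.fasta"
            write_fasta(res.proteome, pf)
            write_fasta(res.final_transcripts, ff)
            ct = out / f"{sp}_clusters.tsv"
            write_tsv(pd.DataFrame(
                [{"representative": c.representative_id,
                  "members": ",".join(c.member_ids)} for c in res.clusters]), ct)
            st = out / f"{sp}_selection.tsv"
            write_tsv(pd.DataFrame(
                [{"kept": k, "discarded": ",".join(v)}
                 for k, v in sorted(res.selection_map.items())]), st)
            ot = out / f"{sp}_orfs.tsv"
            write_tsv(pd.DataFrame([dataclasses.asdict(o) for o in res.orfs]), ot)
            outputs += [pf, ff, ct, st, ot]
            log.info("reduce %s: %d -> %d (length) -> %d clusters -> %d final",
                     sp, res.n_initial, res.n_length_filtered,
                     len(res.clusters), len(res.final_transcripts))
        return outputs

    def stats(self) -> list[Path]:
        out = self.root / "stats"
        out.mkdir(exist_ok=True)
        rows = []
        for sp in self._species():
            initial = read_fasta(self.root / "inputs" / f"{sp}_transcripts.fasta")
            final = read_fasta(self.root / "reduced" / f"{sp}_final.fasta")
            orfs_df = pd.read_csv(self.root / "reduced" / f"{sp}_orfs.tsv",
                                  sep="\t")
            n_cmp = int((orfs_df["completeness"] == "cmp").sum())
            rows.append(AssemblyStats(
                species=sp, phase="initial", n_transcripts=len(initial),
                n50=compute_n50([len(r) for r in initial])))
            rows.append(AssemblyStats(
                species=sp, phase="final", n_transcripts=len(final),
                n50=compute_n50([len(r) for r in final]),
                pct_of_initial=percent(len(final), len(initial)),
                pct_complete_orfs=percent(n_cmp, len(orfs_df))))
        table = stats_table(rows)
        p1 = out / "assembly_stats.tsv"
        write_tsv(table, p1)
        summary = summarize_assemblies(table)
        p2 = out / "summary.tsv"
        write_tsv(pd.DataFrame([summary]), p2)
        return [p1, p2]

    def annotate_merge(self) -> list[Path]:
        cfg = self.config
        out = self.root / "annotation"
        out.mkdir(exist_ok=True)
        hits = read_hit_table(self.root / "inputs" / "hit_table.tsv")
        best = best_hit_per_query(hits, cfg.evalue_cutoff)
        # family rows play the part of the orthology-annotation source
        family = read_family_table(self.root / "inputs" / "family_table.tsv")
        all_ids = []
        for sp in self._species():
            all_ids += [r.id for r in
                        read_fasta(self.root / "reduced" / f"{sp}_proteome.fasta")]
        family = family[family["seq_id"].isin(set(all_ids))]  # bait rows aside
        table, rates = merge_annotations(best, family, all_ids)
        p1 = out / "annotations.tsv"
        write_tsv(table, p1)
        p2 = out / "annotation_rates.tsv"
        write_tsv(pd.DataFrame([dataclasses.asdict(rates)]), p2)
        log.info("annotate-merge: %.1f%% swissprot / %.1f%% eggnog / "
                 "%.1f%% either", rates.pct_swissprot, rates.pct_eggnog,
                 rates.pct_either)
        return [p1, p2]

    def find_clock(self) -> list[Path]:
        out = self.root / "clock"
        out.mkdir(exist_ok=True)
        pair_table = read_pair_table(self.root / "inputs" / "pair_table.tsv")
        domain_table = read_domain_table(self.root / "inputs" / "domain_table.tsv")
        family_table = read_family_table(self.root / "inputs" / "family_table.tsv")
        registry = self._registry()
        raw = extract_bait_orthologs(pair_table, registry, self.config.marker)
        vetted = vet_candidates(raw, domain_table, family_table, registry)
        annotations = pd.read_csv(self.root / "annotation" / "annotations.tsv",
                                  sep="\t", keep_default_na=False)
        whitelist = {b.accession for b in registry.values()}
        vetted = confirm_swissprot(vetted, annotations, whitelist)
        # completeness tags from the reduced proteomes
        tags = {}
        for sp in self._species():
            for rec in read_fasta(self.root / "reduced" / f"{sp}_proteome.fasta"):
                tags[rec.id] = rec.description.replace("type:", "")
        vetted = [dataclasses.replace(c, completeness=tags.get(c.seq_id, ""))
                  for c in vetted]
        p1 = out / "candidates.jsonl"
        with open(p1, "w") as fh:
            for c in vetted:
                fh.write(json.dumps(dataclasses.asdict(c), sort_keys=True) + "\n")
        mat = candidate_matrix(vetted, species=self._species())
        p2 = out / "candidate_matrix.tsv"
        write_candidate_matrix(mat, p2)
        retained = [c for c in vetted if c.retained]
        log.info("find-clock: %d raw -> %d retained candidates",
                 len(raw), len(retained))
        return [p1, p2]

    def validate(self) -> list[Path]:
        out = self.root / "clock"
        out.mkdir(exist_ok=True)
        # planted-truth recovery
        truth = TruthManifest.from_jsonl(
            self.root / "inputs" / "truth_manifest.jsonl")
        found = {(c["species"], c["seq_id"], c["component"])
                 for c in self._candidates() if c["retained"]}
        expected = truth.true_pairs()
        outcome = validate_against_references(found, expected)
        row = {
            "n_expected": len(outcome.expected_pairs),
            "n_found": len(outcome.found_pairs),
            "true_positives": len(outcome.true_positives),
            "false_negatives": len(outcome.false_negatives),
            "false_positives": len(outcome.false_positives),
            "precision": (len(outcome.true_positives) / len(outcome.found_pairs)
                          if outcome.found_pairs else float("nan")),
            "recall": (len(outcome.true_positives) / len(outcome.expected_pairs)
                       if outcome.expected_pairs else float("nan")),
        }
        p = out / "recovery_validation.tsv"
        write_tsv(pd.DataFrame([row]), p)
        log.info("validate: precision=%.3f recall=%.3f",
                 row["precision"], row["recall"])
        return [p]

    def draw_domains(self) -> list[Path]:
        out = self.root / "figures"
        out.mkdir(exist_ok=True)
        domain_table = read_domain_table(self.root / "inputs" / "domain_table.tsv")
        registry = self._registry()
        lengths = {}
        for sp_code in ("Dm", "Dp", "Mm"):
            p = self.root / "inputs" / f"reference_{sp_code}.fasta"
            if p.exists():
                lengths.update({r.id: len(r) for r in read_fasta(p)})
        for sp in self._species():
            lengths.update(
                {r.id: len(r) for r in
                 read_fasta(self.root / "reduced" / f"{sp}_proteome.fasta")})
        by_seq = {sid: [(r.accession, r.name, int(r.start), int(r.end), r.db)
                        for r in sub.itertuples(index=False)]
                  for sid, sub in domain_table.groupby("seq_id")}
        outputs, index_rows = [], []
        for comp, bait in sorted(registry.items()):
            tracks = [TrackSpec(label=label_bait(bait.source_species, bait.seq_id),
                                length=lengths.get(bait.seq_id, 1),
                                domains=tuple(by_seq.get(bait.seq_id, [])),
                                is_bait=True)]
            for c in self._candidates():
                if c["component"] != comp or not c["retained"]:
                    continue
                if c["seq_id"] not in lengths:
                    continue
                tracks.append(TrackSpec(
                    label=label_candidate(c["species"], c["seq_id"],
                                          c["completeness"] or "int", "Ar"),
                    length=lengths[c["seq_id"]],
                    domains=tuple(by_seq.get(c["seq_id"], []))))
                index_rows.append({"component": comp, "seq_id": c["seq_id"],
                                   "figure": f"{_safe(comp)}.svg"})
            p = out / f"{_safe(comp)}.svg"
            render_domain_diagram(tracks, p)
            outputs.append(p)
        idx = out / "figure_index.tsv"
        write_tsv(pd.DataFrame(index_rows,
                               columns=["component", "seq_id", "figure"]), idx)
        return outputs + [idx]

    # -- helpers -------------------------------------------------------------

    def _species(self) -> list[str]:
        return json.loads((self.root / "inputs" / "species.json").read_text())

    def _registry(self) -> dict[str, Bait]:
        data = json.loads(
            (self.root / "inputs" / "bait_registry.json").read_text())
        return {c: Bait(component=d["component"],
                        source_species=d["source_species"],
                        accession=d["accession"], seq_id=d["seq_id"],
                        domains=frozenset(d["domains"]), family=d["family"],
                        subfamily=d["subfamily"])
                for c, d in data.items()}

    def _candidates(self) -> list[dict]:
        path = self.root / "clock" / "candidates.jsonl"
        with open(path) as fh:
            return [json.loads(line) for line in fh if line.strip()]


def compare_runs(run_a: str | Path, run_b: str | Path) -> dict:
    """Overlap statistics between the retained candidate sets of two
    completed runs."""
    def _set(root):
        path = Path(root) / "clock" / "candidates.jsonl"
        with open(path) as fh:
            return {(c["species"], c["seq_id"], c["component"])
                    for c in map(json.loads, fh) if c["retained"]}
    return compare_candidate_sets(_set(run_a), _set(run_b))


def hash_species(name: str) -> int:
    """Stable small integer from a species name (process-independent)."""
    return int(hashlib.sha256(name.encode()).hexdigest()[:6], 16)


def _safe(name: str) -> str:
    return name.replace("/", "_").replace(" ", "_")
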