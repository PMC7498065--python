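"""End-to-end pipeline: reads -> CDRH3 table -> ultralong -> clonotypes ->
knob annotation -> constructs -> mass predictions, with a machine-readable
manifest and summary report.

The pipeline either consumes an existing barcoded FASTQ or simulates one
from the synthetic repertoire module, then runs every stage in order and
records per-stage record counts, output paths and a configuration hash in
``manifest.json``.  All randomness is routed through the configured seed,
so a given configuration reproduces byte-identical outputs (timestamps
aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .clonotyping import cluster_clonotypes, clonotype_summary
from .knob_domains import (SCFC_TEMPLATE_SYNTHETIC, annotate_knob,
                           build_cdrh3_scfc, build_fab_knob_fusion,
                           tev_digest, CoreNotFoundError)
from .mass_spec import MassPrediction
from .read_processing import demultiplex, process_sample
from .synthetic_repertoire import (DEFAULT_BARCODES, GermlineSet,
                                   RepertoireConfig, builtin_germlines,
                                   emit_reads, simulate_repertoire,
                                   truth_table, write_fastq)
from .ultralong import annotate_cohort

logger = logging.getLogger("knobminer")

#: synthetic acceptor heavy-chain stub for Fab-knob fusion design; the real
#: PGT121 heavy chain can be supplied through the configuration instead
SYNTHETIC_ACCEPTOR_HEAVY = "QVQLVESGGGLVQPGGSLRLSCAAS" + "WGQGTLVTVSS"
SYNTHETIC_ACCEPTOR_INSERTION = 25


def percentage(part: int, total: int) -> float | None:
    """Share of *part* in *total* as a percentage at one decimal
    (154/3559 -> 4.3); None when the total is zero."""
    if total == 0:
        return None
    return round(100.0 * part / total, 1)


def hit_rate(hits: int, total: int) -> int | None:
    """Hit rate at integer precision (14/52 -> 27)."""
    if total == 0:
        return None
    return int(round(100.0 * hits / total))


@dataclass
class PipelineConfig:
    outdir: str = "knobminer_out"
    seed: int = 0
    reads: str | None = None            # FASTQ path; None -> simulate
    germlines: str | None = None        # FASTA path; None -> builtin set
    barcodes: tuple[str, ...] = DEFAULT_BARCODES
    # simulation (used when reads is None)
    repertoire: dict = field(default_factory=dict)
    sub_rate: float = 0.0
    indel_rate: float = 0.0
    # thresholds
    length_threshold_nt: int = 90
    identity_pct: float = 75.0
    identity_mode: str = "geq"
    max_mismatch: int = 1
    min_copies: int = 1
    knob_only: bool = False
    scfc_template: str = SCFC_TEMPLATE_SYNTHETIC
    acceptor_heavy: str = SYNTHETIC_ACCEPTOR_HEAVY
    acceptor_insertion: int = SYNTHETIC_ACCEPTOR_INSERTION

    def validate(self) -> None:
        if not 0 < self.identity_pct <= 100:
            raise ValueError("identity_pct outside (0, 100]")
        if self.identity_mode not in ("geq", "gt"):
            raise ValueError("identity_mode must be geq or gt")
        if self.length_threshold_nt < 0 or self.min_copies < 1:
            raise ValueError("invalid thresholds")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.reads is not None and not Path(self.reads).exists():
            raise FileNotFoundError(self.reads)
        if self.germlines is not None and not Path(self.germlines).exists():
            raise FileNotFoundError(self.germlines)

    # -- serialisation ------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "barcodes" in data:
            data["barcodes"] = tuple(data["barcodes"])
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        data = dataclasses.asdict(self)
        data["barcodes"] = list(data["barcodes"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def config_hash(self) -> str:
        """Hash over the semantically meaningful fields (the output
        directory does not change what is computed)."""
        data = dataclasses.asdict(self)
        data.pop("outdir")
        data["barcodes"] = list(data["barcodes"])
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def summary_report(cdrs, annotations, clusters,
                   knob_annotations: dict | None = None,
                   min_members_for_clonotype: int = 2) -> dict:
    """Machine-readable cohort summary.

    ``ultralong_pct`` is reported at one decimal, e.g. 154 ultralong of
    3,559 unique CDRH3 -> 4.3.  The cysteine-parity table profiles the
    knob domain when knob annotations are supplied (even counts are
    expected to dominate there), otherwise the whole CDRH3.
    """
    n_total = len(cdrs)
    n_ultralong = sum(a.is_ultralong for a in annotations)
    n_clonotypes, n_singletons, fraction = clonotype_summary(
        clusters, min_members_for_clonotype)
    parity = {"even": 0, "odd": 0}
    for c, a in zip(cdrs, annotations):
        if not a.is_ultralong:
            continue
        if knob_annotations and c.cdrh3_aa in knob_annotations:
            n_cys = knob_annotations[c.cdrh3_aa].knob.count("C")
        else:
            n_cys = a.cys_count
        parity["even" if n_cys % 2 == 0 else "odd"] += 1
    return {
        "n_total_unique": n_total,
        "n_ultralong": n_ultralong,
        "ultralong_pct": percentage(n_ultralong, n_total),
        "n_clonotypes": n_clonotypes,
        "n_singletons": n_singletons,
        "fraction_in_clonotypes": fraction,
        "ultralong_cys_parity": parity,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute extract -> classify -> clonotype -> knob-annotate -> design
    -> mass, returning the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    germlines = (GermlineSet.from_fasta(config.germlines)
                 if config.germlines else builtin_germlines())
    core_aa = _translate(germlines.ighd82_core.seq)
    counts: list[dict] = []
    outputs: dict[str, str] = {}

    def stage(name, n_in, n_out):
        logger.info("[%s] %d -> %d", name, n_in, n_out)
        counts.append({"stage": name, "n_in": n_in, "n_out": n_out})

    # -- stage 0: reads -----------------------------------------------------
    if config.reads is None:
        rep_conf = RepertoireConfig(seed=config.seed, **config.repertoire)
        records = simulate_repertoire(germlines, rep_conf,
                                      barcodes=config.barcodes)
        reads = emit_reads(records, config.barcodes,
                           sub_rate=config.sub_rate,
                           indel_rate=config.indel_rate, seed=config.seed)
        reads_path = outdir / "reads.fastq"
        write_fastq(reads, str(reads_path))
        truth_table(records).to_csv(outdir / "truth.tsv", sep="\t",
                                    index=False)
        outputs["reads"] = str(reads_path)
        outputs["truth"] = str(outdir / "truth.tsv")
        stage("simulate", len(records), len(reads))
    else:
        from Bio import SeqIO
        reads = list(SeqIO.parse(config.reads, "fastq"))
        outputs["reads"] = config.reads
        stage("load_reads", len(reads), len(reads))

    # -- stage 1: demultiplex + extract + dedupe ---------------------------
    bins = demultiplex(reads, list(config.barcodes), config.max_mismatch)
    n_assigned = sum(len(v) for k, v in bins.items() if k != "undetermined")
    stage("demultiplex", len(reads), n_assigned)
    cdrs = []
    for bc in config.barcodes:
        cdrs.extend(process_sample(bins[bc], bc))
    cdrs = [c for c in cdrs if c.copy_number >= config.min_copies]
    stage("extract", n_assigned, len(cdrs))
    _write_tsv(outdir / "cdrh3.tsv",
               ["sample_barcode", "cdrh3_nt", "cdrh3_aa", "frame",
                "copy_number"],
               [(c.sample_barcode, c.cdrh3_nt, c.cdrh3_aa, c.frame,
                 c.copy_number) for c in cdrs])
    outputs["cdrh3"] = str(outdir / "cdrh3.tsv")

    # -- stage 2: ultralong classification ---------------------------------
    annotations = annotate_cohort(
        cdrs, length_threshold_nt=config.length_threshold_nt,
        duplication_probe=germlines.ighv17_tail)
    ultralong = [(c, a) for c, a in zip(cdrs, annotations) if a.is_ultralong]
    stage("classify", len(cdrs), len(ultralong))
    _write_tsv(outdir / "annotated.tsv",
               ["sample_barcode", "cdrh3_aa", "length_nt", "is_ultralong",
                "duplication_found", "cys_count", "cys_pattern"],
               [(c.sample_barcode, c.cdrh3_aa, a.length_nt, a.is_ultralong,
                 a.duplication_found, a.cys_count, a.cys_pattern)
                for c, a in zip(cdrs, annotations)])
    outputs["annotated"] = str(outdir / "annotated.tsv")

    # -- stage 3: knob annotation ------------------------------------------
    knob_rows = []
    knob_by_aa = {}
    n_knob_fail = 0
    for c, _a in ultralong:
        try:
            ann = annotate_knob(c.cdrh3_aa, core_aa)
        except (CoreNotFoundError, ValueError):
            n_knob_fail += 1
            continue
        knob_by_aa[c.cdrh3_aa] = ann
        knob_rows.append((c.sample_barcode, c.cdrh3_aa, ann.knob_span[0],
                          ann.knob_span[1], ann.knob,
                          len(ann.germline_cys_indices)))
    stage("knob_annotate", len(ultralong), len(knob_rows))
    if n_knob_fail:
        logger.warning("%d ultralong CDRH3 without a locatable core",
                       n_knob_fail)
    _write_tsv(outdir / "knobs.tsv",
               ["sample_barcode", "cdrh3_aa", "knob_start", "knob_end",
                "knob_aa", "n_germline_cys"], knob_rows)
    outputs["knobs"] = str(outdir / "knobs.tsv")

    # -- stage 4: clonotyping ----------------------------------------------
    if config.knob_only:
        seqs = [knob_by_aa[c.cdrh3_aa].knob for c, _ in ultralong
                if c.cdrh3_aa in knob_by_aa]
        copies = [c.copy_number for c, _ in ultralong
                  if c.cdrh3_aa in knob_by_aa]
    else:
        seqs = [c.cdrh3_aa for c, _ in ultralong]
        copies = [c.copy_number for c, _ in ultralong]
    clusters = cluster_clonotypes(seqs, threshold_pct=config.identity_pct,
                                  mode=config.identity_mode,
                                  copy_numbers=copies)
    stage("clonotype", len(seqs), len(clusters))
    _write_tsv(outdir / "clonotypes.tsv",
               ["clonotype_id", "member", "is_representative", "size"],
               [(cl.clonotype_id, m, m == cl.representative, cl.size)
                for cl in clusters for m in cl.members])
    with open(outdir / "representatives.fasta", "w") as fh:
        for cl in clusters:
            fh.write(f">{cl.clonotype_id} size={cl.size}\n"
                     f"{cl.representative}\n")
    outputs["clonotypes"] = str(outdir / "clonotypes.tsv")

    # -- stage 5: construct design + digestion + masses --------------------
    constructs = []
    mass_rows = []
    for c, _a in ultralong:
        ann = knob_by_aa.get(c.cdrh3_aa)
        if ann is None:
            continue
        scfc = build_cdrh3_scfc(c.cdrh3_aa, config.scfc_template)
        fab = build_fab_knob_fusion(ann.knob, config.acceptor_heavy,
                                    config.acceptor_insertion)
        constructs.append((c.cdrh3_aa, scfc, fab))
        fragments = tev_digest(fab.orf_aa)
        released = next(f for f in fragments if ann.knob in f)
        pred = MassPrediction.predict(released)
        mass_rows.append((c.cdrh3_aa, released, released.count("C"),
                          pred.n_disulphides,
                          round(pred.monoisotopic_mass, 4),
                          round(dict(pred.charge_states)[4], 4)))
    stage("design", len(knob_rows), len(constructs))
    stage("mass", len(constructs), len(mass_rows))
    with open(outdir / "constructs.fasta", "w") as fh:
        for aa, scfc, fab in constructs:
            fh.write(f">scfc|{aa[:12]} insert={scfc.insert_span[0]}-"
                     f"{scfc.insert_span[1]}\n{scfc.orf_aa}\n")
            fh.write(f">fab|{aa[:12]} insert={fab.insert_span[0]}-"
                     f"{fab.insert_span[1]}\n{fab.orf_aa}\n")
    _write_tsv(outdir / "masses.tsv",
               ["cdrh3_aa", "released_peptide", "n_cys", "n_disulphides",
                "monoisotopic_mass", "mz_4plus"], mass_rows)
    outputs["constructs"] = str(outdir / "constructs.fasta")
    outputs["masses"] = str(outdir / "masses.tsv")

    summary = summary_report(cdrs, annotations, clusters,
                             knob_annotations=knob_by_aa)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    outputs["summary"] = str(outdir / "summary.json")

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "counts": counts,
        "outputs": outputs,
        "summary": summary,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _translate(nt: str) -> str:
    from Bio.Seq import Seq
    return str(Seq(nt).translate())


def _write_tsv(path, header, rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
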