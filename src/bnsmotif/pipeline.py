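"""End-to-end orchestration: simulate -> demux -> enrich -> discover, and
peaks -> extract -> scan -> annotate -> test.

A run is fully determined by its :class:`RunConfig` (seed, stage
parameters, input paths).  Every intermediate artifact is written in a
documented text format re-readable by :mod:`bnsmotif.seqio`, and a
manifest (config echo plus input checksums) is written next to the
outputs.  Stage progress is logged to standard error.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .discovery import DiscoveryConfig, discover_motifs
from .enrichment import count_kmers, demultiplex, fold_enrichment, write_enrichment_tsv
from .errors import StageError, UsageError
from .motifs import MIZM1_CONSENSUS, MIZM2_CONSENSUS, Motif, hamming
from .peaks import (
    annotate_peaks,
    class_counts,
    contingency_chi2,
    density_summary,
    extract_peak_sequences,
    proximal_fraction,
)
from .scanning import scan_sequences
from .seqio import (
    read_bed,
    read_fasta,
    read_fastq,
    read_gene_table,
    read_meme_motifs,
    reverse_complement,
    write_meme_motifs,
)
from .synthetic import (
    BnSCondition,
    SimulationConfig,
    default_selection_model,
    generate_bns_library,
    generate_synthetic_genome_and_peaks,
    write_bns_library,
    write_synthetic_genome,
)

logger = logging.getLogger("bnsmotif")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

CANONICAL_CONSENSI = {"Mizm1-like": MIZM1_CONSENSUS, "Mizm2-like": MIZM2_CONSENSUS}


@dataclass
class RunConfig:
    """Serializable description of a pipeline run."""

    seed: int = 0
    out_dir: str = "bnsmotif_out"
    inputs: dict = field(default_factory=dict)  # fastq / bed / genome / genes / motifs
    stages: dict = field(default_factory=dict)  # per-stage parameter dicts

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            seed=int(data.get("seed", 0)),
            out_dir=str(data.get("out_dir", "bnsmotif_out")),
            inputs=dict(data.get("inputs", {})),
            stages=dict(data.get("stages", {})),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {"seed": self.seed, "out_dir": self.out_dir, "inputs": self.inputs, "stages": self.stages},
            sort_keys=True,
        )

    def stage(self, name: str) -> dict:
        return dict(self.stages.get(name, {}))


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the run seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _checksum(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def _write_manifest(config: RunConfig, out_dir: Path, inputs: dict[str, Path]) -> None:
    manifest = {
        "config": yaml.safe_load(config.to_yaml()),
        "input_checksums": {k: _checksum(Path(v)) for k, v in inputs.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def classify_consensus(consensus: str, canonical: dict[str, str] | None = None) -> str:
    """Label a consensus by its nearest canonical motif.

    Distance is the minimum normalized Hamming distance over all ungapped
    full-overlap-of-the-shorter alignments, in both orientations.
    """
    canonical = canonical or CANONICAL_CONSENSI
    best_label, best_d = "unclassified", float("inf")
    for label, ref in canonical.items():
        for a, b in ((consensus, ref), (reverse_complement(consensus), ref)):
            short, long_ = (a, b) if len(a) <= len(b) else (b, a)
            for off in range(len(long_) - len(short) + 1):
                d = hamming(short, long_[off : off + len(short)]) / len(short)
                if d < best_d:
                    best_d, best_label = d, label
    return best_label if best_d <= 0.5 else "unclassified"


# ---------------------------------------------------------------------------
# Bind-n-Seq pipeline


@dataclass
class BnsReport:
    out_dir: Path
    motifs_per_condition: dict[str, list[Motif]]
    classification: dict[str, dict[str, int]]  # barcode -> label -> count
    paths: dict[str, Path]


def run_bns_pipeline(config: RunConfig) -> BnsReport:
    """simulate (optional) -> demultiplex -> per-condition enrichment and
    motif discovery -> classification tally of top hits."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs_used: dict[str, Path] = {}

    fastq = config.inputs.get("fastq")
    if fastq is not None and not Path(fastq).exists():
        raise StageError(f"configured FASTQ {fastq} does not exist")

    sim_params = config.stage("simulate")
    cond_rows = config.stage("conditions").get("rows") or sim_params.pop("conditions", None)
    if cond_rows:
        conditions = [BnSCondition(str(b), float(p), float(s)) for b, p, s in cond_rows]
    else:
        conditions = [BnSCondition("ACC", 50.0, 50.0)]

    if fastq is None:
        logger.info("stage simulate: %d conditions", len(conditions))
        model = default_selection_model(
            consensus=sim_params.pop("consensus", MIZM1_CONSENSUS),
            consensus_weight=float(sim_params.pop("consensus_weight", 0.6)),
            relative_affinity=float(sim_params.pop("relative_affinity", 1.0)),
        )
        sim = SimulationConfig(
            seed=stage_seed(config.seed, "simulate"),
            conditions=conditions,
            selection=model,
            n_background=int(sim_params.pop("n_background", 100_000)),
            n_selected=int(sim_params.pop("n_selected", 100_000)),
        )
        library = generate_bns_library(sim)
        paths = write_bns_library(library, out_dir / "library")
        fastq = paths["pooled"]
    inputs_used["fastq"] = Path(fastq)

    logger.info("stage demux: %s", fastq)
    demux_params = config.stage("demux")
    reads = list(read_fastq(fastq))
    bins, unassigned = demultiplex(reads, conditions, float(demux_params.get("min_mean_q", 20.0)))
    logger.info(
        "stage demux: %d reads, %d unassigned", len(reads), len(unassigned)
    )
    for cond in conditions:
        if not bins[cond.barcode]:
            raise StageError(f"no reads after demultiplexing for barcode {cond.barcode}")

    disc_params = config.stage("discover")
    dcfg = DiscoveryConfig(
        widths=tuple(disc_params.get("widths", (6, 8, 10))),
        cluster_size=int(disc_params.get("cluster_size", 10_000)),
        n_rounds=int(disc_params.get("rounds", 3)),
        top_n=int(disc_params.get("top_n", 5)),
    )
    enrich_k = int(config.stage("enrich").get("k", 10))

    motifs_per_condition: dict[str, list[Motif]] = {}
    classification: dict[str, dict[str, int]] = {}
    out_paths: dict[str, Path] = {}
    all_motifs = []
    for cond in conditions:
        regions = [r.region for r in bins[cond.barcode]]
        logger.info("stage enrich/discover: barcode %s (%d reads)", cond.barcode, len(regions))
        table = count_kmers(regions, enrich_k)
        records = fold_enrichment(table)
        tsv = out_dir / f"enrichment_{cond.barcode}.tsv"
        write_enrichment_tsv(records, tsv)
        out_paths[f"enrichment_{cond.barcode}"] = tsv
        motifs = discover_motifs(regions, dcfg, seed=stage_seed(config.seed, f"discover:{cond.barcode}"))
        for m in motifs:
            m.motif_id = f"{cond.barcode}_{m.motif_id}"
        motifs_per_condition[cond.barcode] = motifs
        all_motifs.extend(motifs)
        tally: dict[str, int] = {}
        for m in motifs:
            label = classify_consensus(m.consensus)
            tally[label] = tally.get(label, 0) + 1
        classification[cond.barcode] = tally

    meme_path = out_dir / "discovered_motifs.meme"
    write_meme_motifs(all_motifs, meme_path)
    out_paths["motifs"] = meme_path
    summary = out_dir / "hit_summary.tsv"
    with summary.open("w") as fh:
        fh.write("barcode\tmotif_id\tconsensus\tenrichment_score\tclassification\n")
        for barcode, motifs in motifs_per_condition.items():
            for m in motifs:
                fh.write(
                    f"{barcode}\t{m.motif_id}\t{m.consensus}\t"
                    f"{(m.enrichment_score or 0):.4g}\t{classify_consensus(m.consensus)}\n"
                )
    out_paths["summary"] = summary
    _write_manifest(config, out_dir, inputs_used)
    return BnsReport(
        out_dir=out_dir,
        motifs_per_condition=motifs_per_condition,
        classification=classification,
        paths=out_paths,
    )


# ---------------------------------------------------------------------------
# peak reanalysis pipeline


@dataclass
class PeakReport:
    out_dir: Path
    fractions_with_motif: dict[str, float]
    proximal_with: dict[str, float]
    proximal_without: dict[str, float]
    chi2_results: dict[str, object]
    paths: dict[str, Path]


def run_peak_reanalysis(config: RunConfig) -> PeakReport:
    """extract -> scan -> annotate -> proximity statistics."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if "bed" not in config.inputs:
        syn = config.stage("synthetic_genome")
        if not syn.get("enabled", False):
            raise UsageError("peak reanalysis needs bed/genome/genes/motifs inputs")
        data = generate_synthetic_genome_and_peaks(
            seed=stage_seed(config.seed, "genome"),
            n_genes=int(syn.get("n_genes", 30)),
            n_peaks=int(syn.get("n_peaks", 400)),
            motif=syn.get("consensus", MIZM1_CONSENSUS),
            frac_motif_peaks=float(syn.get("frac_motif_peaks", 0.5)),
            proximal_bias=float(syn.get("proximal_bias", 0.9)),
        )
        gpaths = write_synthetic_genome(data, out_dir / "synthetic")
        config.inputs.update(
            {"bed": str(gpaths["peaks"]), "genome": str(gpaths["genome"]), "genes": str(gpaths["genes"])}
        )
        if "motifs" not in config.inputs:
            mpath = out_dir / "synthetic" / "planted.meme"
            write_meme_motifs(
                [Motif.from_consensus(syn.get("consensus", MIZM1_CONSENSUS), p0=0.9, motif_id="planted")],
                mpath,
            )
            config.inputs["motifs"] = str(mpath)

    for key in ("bed", "genome", "genes", "motifs"):
        if key not in config.inputs:
            raise UsageError(f"peak reanalysis needs input {key!r}")
        if not Path(config.inputs[key]).exists():
            raise StageError(f"input {key} = {config.inputs[key]} does not exist")
    inputs_used = {k: Path(v) for k, v in config.inputs.items()}

    peaks = read_bed(config.inputs["bed"])
    if not peaks:
        raise UsageError("empty peak set")
    genome = dict(read_fasta(config.inputs["genome"]))
    genes = read_gene_table(config.inputs["genes"])
    motifs = read_meme_motifs(config.inputs["motifs"])
    if not motifs:
        raise UsageError("motif file contains no motifs")
    missing = sorted({p.chrom for p in peaks} - set(genome))
    if missing:
        raise StageError(f"peak chromosomes absent from genome: {missing}")

    logger.info("stage extract: %d peaks", len(peaks))
    seqs = extract_peak_sequences(peaks, genome)
    p_threshold = float(config.stage("scan").get("pvalue", 1e-4))
    window_bp = int(config.stage("annotate").get("proximal_bp", 1500))

    fractions: dict[str, float] = {}
    prox_with: dict[str, float] = {}
    prox_without: dict[str, float] = {}
    chi2_results: dict[str, object] = {}
    paths: dict[str, Path] = {}
    summary_rows = []
    for mi, motif in enumerate(motifs):
        logger.info("stage scan: motif %s (w=%d)", motif.motif_id, motif.width)
        matches = scan_sequences(seqs, motif, p_threshold=p_threshold)
        hit_ids = {m.seq_id for m in matches}
        flags = {pid: pid in hit_ids for pid, _ in seqs}
        fractions[motif.motif_id] = len(hit_ids) / len(peaks)
        annotations = annotate_peaks(peaks, genes, flags)
        with_m = [a for a in annotations if a.has_motif]
        without_m = [a for a in annotations if not a.has_motif]
        prox_with[motif.motif_id] = proximal_fraction(with_m, window_bp) if with_m else float("nan")
        prox_without[motif.motif_id] = (
            proximal_fraction(without_m, window_bp) if without_m else float("nan")
        )
        ct = contingency_chi2(annotations, window_bp)
        chi2_results[motif.motif_id] = ct
        if mi == 0:
            ann_path = out_dir / "annotations.tsv"
            with ann_path.open("w") as fh:
                fh.write("peak_id\tnearest_gene\ttss_distance\tregion_class\thas_motif\n")
                for a in annotations:
                    fh.write(
                        f"{a.peak_id}\t{a.nearest_gene}\t{a.tss_distance}\t"
                        f"{a.region_class}\t{int(a.has_motif)}\n"
                    )
            paths["annotations"] = ann_path
            for label, subset in (("with_motif", with_m), ("without_motif", without_m)):
                if not subset:
                    continue
                hist = density_summary(subset)
                hpath = out_dir / f"density_{label}.tsv"
                with hpath.open("w") as fh:
                    fh.write("bin_left\tbin_right\tcount\n")
                    for row in hist:
                        fh.write(f"{row.bin_left:.0f}\t{row.bin_right:.0f}\t{row.count}\n")
                paths[f"density_{label}"] = hpath
            cls = class_counts(annotations)
            cpath = out_dir / "region_classes.tsv"
            with cpath.open("w") as fh:
                fh.write("subset\t" + "\t".join(sorted(cls["with_motif"])) + "\n")
                for subset_name, counts in cls.items():
                    fh.write(
                        subset_name + "\t" + "\t".join(str(counts[k]) for k in sorted(counts)) + "\n"
                    )
            paths["region_classes"] = cpath
        summary_rows.append(
            {
                "motif_id": motif.motif_id,
                "fraction_with_motif": fractions[motif.motif_id],
                "proximal_fraction_with": prox_with[motif.motif_id],
                "proximal_fraction_without": prox_without[motif.motif_id],
                "chi2": ct.chi2,
                "p_value": ct.p_value,
                "degenerate": ct.degenerate,
            }
        )
    spath = out_dir / "peak_summary.tsv"
    with spath.open("w") as fh:
        cols = list(summary_rows[0])
        fh.write("\t".join(cols) + "\n")
        for row in summary_rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    paths["summary"] = spath
    _write_manifest(config, out_dir, inputs_used)
    return PeakReport(
        out_dir=out_dir,
        fractions_with_motif=fractions,
        proximal_with=prox_with,
        proximal_without=prox_without,
        chi2_results=chi2_results,
        paths=paths,
    )
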