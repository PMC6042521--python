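"""Benchmark orchestration: simulate -> quantify (both methods) -> evaluate.

``run_benchmark`` drives a full desk-scale experiment: a toy transcriptome,
titration abundances for samples A-D, triplicate read libraries, the k-mer
quantifier across a k grid and the alignment quantifier, then the titration
evaluation per quantifier, writing per-gene tables and a tidy summary with
one row per (quantifier, k, stratum). All stage seeds derive from the single
run seed; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .align import AlignmentQuantifier
from .evaluate import (
    build_fold_change_table,
    detect,
    gene_lengths,
    gene_tpm,
    gene_types,
    aggregate_to_gene,
    summarize_evaluation,
    trna_cumulative_error,
)
from .io import write_design, write_fasta
from .kmer import DEFAULT_K_GRID, KmerQuantifier
from .records import TitrationDesign
from .simulate import (
    GeneratorConfig,
    assign_ercc_design,
    build_transcriptome,
    ercc_truth,
    make_ab_abundances,
    mix_titration,
    simulate_reads,
)
from .tables import AbundanceTable, to_tpm


@dataclass
class RunConfig:
    """Everything a benchmark run needs; round-trips losslessly through JSON."""

    seed: int = 1
    outdir: str = "titrabench_out"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    z: float = 1.43
    depth: int = 30_000  # reads per library
    n_replicates: int = 3
    read_length: int = 50
    mis_rate: float = 0.0
    seq_error: float = 0.001
    dispersion: float = 0.01  # replicate-to-replicate abundance jitter (NB alpha)
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    max_mismatch: int | None = None
    write_fastq: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        d["k_grid"] = list(self.k_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["generator"] = GeneratorConfig.from_dict(d["generator"])
        d["k_grid"] = tuple(d["k_grid"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


_STAGE_LABELS = {
    "transcriptome": 11,
    "design": 13,
    "abundance": 17,
    "reads": 19,
    "select": 23,
}


def _seed_for(base: int, stage: str, extra: int = 0) -> int:
    ss = np.random.SeedSequence([base, _STAGE_LABELS[stage], extra])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_experiment(config: RunConfig) -> dict:
    """Generate transcriptome, design, abundances and read libraries."""
    transcripts = build_transcriptome(config.generator, _seed_for(config.seed, "transcriptome"))
    design = TitrationDesign(z=config.z)
    ercc = [t for t in transcripts if t.gene_type == "ERCC"]
    assignment = assign_ercc_design(ercc, design, _seed_for(config.seed, "design"))
    ab = make_ab_abundances(
        transcripts, design, assignment, _seed_for(config.seed, "abundance"), config.generator
    )
    abcd = mix_titration(ab, design)
    lengths = {t.transcript_id: t.length for t in transcripts if not t.is_decoy}
    tpm_true = to_tpm(abcd)

    libraries: dict[tuple[str, int], object] = {}
    for si, sample in enumerate(("A", "B", "C", "D")):
        for rep in range(1, config.n_replicates + 1):
            libraries[(sample, rep)] = simulate_reads(
                transcripts,
                abcd,
                sample,
                replicate=1,
                n_reads=config.depth,
                read_length=config.read_length,
                mis_rate=config.mis_rate,
                seq_error=config.seq_error,
                dispersion=config.dispersion,
                seed=_seed_for(config.seed, "reads", 100 * si + rep),
            )
    return {
        "transcripts": transcripts,
        "design": design,
        "ercc_assignment": assignment,
        "abundances": abcd,
        "tpm_true": tpm_true,
        "lengths": lengths,
        "libraries": libraries,
    }


def _library_table(per_library: dict[tuple[str, int], pd.Series], unit: str, level: str) -> AbundanceTable:
    df = pd.DataFrame(per_library)
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    df.index.name = f"{level}_id"
    return AbundanceTable(df.fillna(0.0), unit=unit, level=level)


def quantify_kmer(sim: dict, k: int, config: RunConfig) -> dict:
    """Run the k-mer quantifier over every library at one k."""
    quant = KmerQuantifier(k=k, read_length=config.read_length).fit(sim["transcripts"])
    tpm_cols = {}
    for key, reads in sim["libraries"].items():
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            tpm_cols[key] = quant.transform(reads)
    tpm = _library_table(tpm_cols, "TPM", "transcript")
    gene_scale = aggregate_to_gene(
        tpm, sim["transcripts"], library_sizes=float(config.depth), read_length=config.read_length
    )
    gtpm = gene_tpm(tpm, sim["transcripts"])
    return {"transcript_tpm": tpm, "gene_values": gene_scale, "gene_tpm": gtpm}


def quantify_align(sim: dict, config: RunConfig) -> dict:
    """Run the alignment quantifier over every library."""
    quant = AlignmentQuantifier(
        max_mismatch=config.max_mismatch,
        random_state=_seed_for(config.seed, "select"),
    ).fit(sim["transcripts"])
    count_cols = {key: quant.transform(reads) for key, reads in sim["libraries"].items()}
    counts = _library_table(count_cols, "count", "gene")
    glens = gene_lengths(sim["transcripts"]).reindex(counts.ids)
    gtpm = to_tpm(counts, lengths=glens, read_length=config.read_length)
    return {"gene_counts": counts, "gene_values": counts, "gene_tpm": gtpm}


def evaluate_quantification(
    quant_out: dict, sim: dict, config: RunConfig, normalization_roc: str = "median_of_ratios"
) -> dict:
    """Fold-change table, stratified metrics and spike-in ROC for one run."""
    transcripts = sim["transcripts"]
    design = sim["design"]
    fc = build_fold_change_table(
        quant_out["gene_values"], quant_out["gene_tpm"], transcripts, z=design.z,
        normalization="cpm",
    )
    # DESeq2-analogue p-values for the ROC: size factors from non-spike-ins
    control = [
        t.gene_id for t in transcripts if t.gene_type != "ERCC" and not t.is_decoy
    ]
    try:
        fc_sf = build_fold_change_table(
            quant_out["gene_values"], quant_out["gene_tpm"], transcripts, z=design.z,
            normalization=normalization_roc, control_genes=control,
        )
        roc_p = fc_sf["p_value_AB"]
    except ValueError:
        roc_p = fc["p_value_AB"]
    truth_t = ercc_truth(sim["ercc_assignment"], design)
    # spike-in transcripts are their own genes in the generator
    truth_g = dict(truth_t)
    summary = summarize_evaluation(fc, truth_g, roc_p)
    detection = {
        col: int(detect(quant_out["gene_tpm"].values[col]).sum())
        for col in quant_out["gene_tpm"].values.columns
    }
    summary["detected_genes_per_library"] = {f"{s}{r}": n for (s, r), n in detection.items()}
    gt = gene_types(transcripts)
    trna_ids = quant_out["gene_tpm"].values.index.intersection(gt.index[gt == "tRNA"])
    trna_detect = int(
        detect(quant_out["gene_tpm"].values.loc[trna_ids]).sum()
    )
    summary["trna_detected_total"] = trna_detect
    return {"fold_changes": fc, "summary": summary, "trna_curve": trna_cumulative_error(fc)}


def _summary_rows(label: str, k, summary: dict) -> list[dict]:
    rows = []
    base = {"quantifier": label, "k": k}
    rows.append({**base, "scheme": "overall", "stratum": "overall", **summary["overall"]})
    for scheme in ("mean_expression", "gene_length", "gene_type"):
        for name, sc in summary[scheme].items():
            rows.append({**base, "scheme": scheme, "stratum": name, **sc})
    for row in rows:
        row["auc_ercc"] = summary.get("ercc_auc", np.nan)
        row["trna_detected_total"] = summary.get("trna_detected_total", np.nan)
    return rows


def report_tables(results: dict[tuple[str, object], dict]) -> pd.DataFrame:
    """One tidy row per (quantifier, k, stratum) with R², RMSE, AUC, n."""
    rows: list[dict] = []
    for (label, k), res in results.items():
        rows.extend(_summary_rows(label, k, res["summary"]))
    df = pd.DataFrame(rows)
    return df[
        [
            "quantifier",
            "k",
            "scheme",
            "stratum",
            "r2",
            "rmse",
            "n_genes",
            "auc_ercc",
            "trna_detected_total",
        ]
    ]


def run_benchmark(config: RunConfig) -> dict:
    """Full pipeline; writes outputs under ``config.outdir`` and returns them."""
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_experiment(config)
    n_live = sum(1 for t in sim["transcripts"] if not t.is_decoy)
    for (sample, rep), lib in sim["libraries"].items():
        if len(lib) != config.depth:
            raise RuntimeError(f"stage simulate: library {sample}{rep} lost reads")

    write_fasta(sim["transcripts"], out / "transcriptome.fa")
    write_design(
        sim["design"],
        out / "design.json",
        extra={"ercc_assignment": sim["ercc_assignment"]},
    )
    sim["tpm_true"].write_tsv(out / "true_tpm.tsv")
    truth = ercc_truth(sim["ercc_assignment"], sim["design"])
    pd.Series(truth, name="is_de").rename_axis("gene_id").to_frame().assign(
        group=pd.Series(sim["ercc_assignment"])
    ).to_csv(out / "truth.tsv", sep="\t")
    if config.write_fastq:
        from .io import write_fastq

        for (sample, rep), lib in sim["libraries"].items():
            write_fastq(lib, out / f"reads_{sample}{rep}.fastq")

    results: dict[tuple[str, object], dict] = {}
    for k in config.k_grid:
        q = quantify_kmer(sim, k, config)
        q["transcript_tpm"].write_tsv(out / f"kmer_k{k}_tpm.tsv")
        res = evaluate_quantification(q, sim, config)
        res["fold_changes"].to_csv(out / f"kmer_k{k}_fold_changes.tsv", sep="\t", float_format="%.8g")
        res["trna_curve"].to_csv(out / f"kmer_k{k}_trna_curve.tsv", sep="\t", index=False, float_format="%.8g")
        results[("kmer", k)] = res

    qa = quantify_align(sim, config)
    qa["gene_counts"].write_tsv(out / "align_gene_counts.tsv")
    res = evaluate_quantification(qa, sim, config)
    res["fold_changes"].to_csv(out / "align_fold_changes.tsv", sep="\t", float_format="%.8g")
    res["trna_curve"].to_csv(out / "align_trna_curve.tsv", sep="\t", index=False, float_format="%.8g")
    results[("align", None)] = res

    report = report_tables(results)
    report.to_csv(out / "summary.tsv", sep="\t", index=False, float_format="%.6g")
    summaries = {
        f"{label}" + (f"_k{k}" if k is not None else ""): res["summary"]
        for (label, k), res in results.items()
    }
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "n_transcripts": n_live,
        "runtime_seconds": round(time.time() - t0, 2),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonable(summaries), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"sim": sim, "results": results, "report": report, "manifest": manifest}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    return obj
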