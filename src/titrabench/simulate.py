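"""Synthetic data generator: toy transcriptome, titration abundances, reads.

The generator emulates, at desk scale, the ingredients of a total RNA-seq
titration benchmark:

* a mixed transcriptome of long protein-coding genes (a few with two
  isoforms sharing sequence), 92 ERCC-like spike-ins (250-2000 nt), short
  tRNA-like transcripts (~75 nt) carrying fixed modification positions
  clustered near 20/30/50, plus snoRNA/rRNA/other ncRNA background and
  optional decoy (haplotype/patch analogue) sequences;
* reference samples A and B with per-transcript molar concentrations whose
  spike-in ratios follow the four designed groups and whose totals satisfy
  sum(A)/sum(B) = z exactly;
* samples C and D as 3:1 and 1:3 mass mixtures of A and B;
* replicate count noise (negative binomial) and single-end sense-strand
  reads carrying misincorporation errors at modification sites plus uniform
  sequencing errors.

Everything is deterministic given a seed; identical seeds give byte-identical
FASTA/FASTQ/TSV output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .records import ReadSet, SimulatedRead, TitrationDesign, TranscriptRecord
from .tables import AbundanceTable

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: anticodon pool; 20 default tRNA genes drawn from 10 anticodons, so
#: isoacceptor aggregation actually merges genes
_ANTICODONS = ("GCC", "AGC", "CAT", "ACT", "AGT", "CCG", "TTC", "GTG", "CTG", "AAC")


@dataclass
class GeneratorConfig:
    """Counts, length ranges and abundance ranges per gene type.

    ``molar_log10_ranges`` gives, per type, the log10-uniform range the
    baseline concentration is drawn from; tRNA and rRNA sit higher than
    protein-coding genes, as in real total RNA. ``trna_fixed_sites`` forces
    every tRNA to carry exactly those modification positions (the mechanism
    scenario); by default each tRNA draws 1-4 sites from Normal clusters
    centred at 20/30/50 (sd 3).
    """

    n_protein_coding: int = 60
    n_two_isoform_genes: int = 5
    n_ercc: int = 92
    n_trna: int = 20
    n_snorna: int = 10
    n_rrna: int = 2
    n_other_ncrna: int = 10
    n_decoy: int = 2
    length_ranges: dict = field(
        default_factory=lambda: {
            "protein_coding": (500, 3000),
            "ERCC": (250, 2000),
            "tRNA": (70, 80),
            "snoRNA": (60, 300),
            "rRNA": (1500, 5000),
            "other_ncRNA": (200, 1000),
        }
    )
    molar_log10_ranges: dict = field(
        default_factory=lambda: {
            "protein_coding": (0.0, 3.0),
            "ERCC": (1.0, 3.0),
            "tRNA": (2.0, 4.0),
            "snoRNA": (1.0, 3.0),
            "rRNA": (3.0, 4.0),
            "other_ncRNA": (0.0, 3.0),
        }
    )
    trna_site_centers: tuple[int, ...] = (20, 30, 50)
    trna_site_sd: float = 3.0
    trna_max_sites: int = 4
    trna_fixed_sites: tuple[int, ...] | None = None
    ratio_log2_halfwidth: float = 2.0  # non-spike-in log2(A/B) ~ U(-w, w)

    def __post_init__(self) -> None:
        for name in (
            "n_protein_coding",
            "n_ercc",
            "n_trna",
            "n_snorna",
            "n_rrna",
            "n_other_ncrna",
            "n_decoy",
            "n_two_isoform_genes",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} cannot be negative")
        if self.n_two_isoform_genes > self.n_protein_coding:
            raise ValueError("cannot have more two-isoform genes than protein-coding genes")
        for gtype, (lo, hi) in self.length_ranges.items():
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid length range for {gtype}: ({lo}, {hi})")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trna_site_centers"] = list(self.trna_site_centers)
        d["trna_fixed_sites"] = (
            list(self.trna_fixed_sites) if self.trna_fixed_sites is not None else None
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["trna_site_centers"] = tuple(d.get("trna_site_centers", (20, 30, 50)))
        if d.get("trna_fixed_sites") is not None:
            d["trna_fixed_sites"] = tuple(d["trna_fixed_sites"])
        d["length_ranges"] = {k: tuple(v) for k, v in d["length_ranges"].items()}
        d["molar_log10_ranges"] = {k: tuple(v) for k, v in d["molar_log10_ranges"].items()}
        return cls(**d)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def _draw_trna_sites(rng: np.random.Generator, length: int, config: GeneratorConfig) -> tuple[int, ...]:
    if config.trna_fixed_sites is not None:
        sites = [p for p in config.trna_fixed_sites if 1 <= p <= length]
        return tuple(sorted(set(sites)))
    n_sites = int(rng.integers(1, config.trna_max_sites + 1))
    centers = list(config.trna_site_centers)
    chosen = list(rng.permutation(centers)[: min(n_sites, len(centers))])
    while len(chosen) < n_sites:
        chosen.append(centers[int(rng.integers(0, len(centers)))])
    sites: set[int] = set()
    for c in chosen:
        for _ in range(20):  # redraw on collision/clip
            p = int(round(rng.normal(c, config.trna_site_sd)))
            p = min(max(p, 1), length)
            if p not in sites:
                sites.add(p)
                break
    return tuple(sorted(sites))


def build_transcriptome(
    config: GeneratorConfig | None = None, seed: int = 0
) -> list[TranscriptRecord]:
    """Generate the toy transcriptome; deterministic for a fixed seed."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    records: list[TranscriptRecord] = []

    # protein-coding genes; the first n_two_isoform_genes get a second
    # isoform produced by an internal deletion, so the isoforms share long
    # exact stretches (a realistic source of multi-mapping reads)
    for i in range(config.n_protein_coding):
        lo, hi = config.length_ranges["protein_coding"]
        L = int(rng.integers(lo, hi + 1))
        gid = f"GENE{i + 1:04d}"
        seq = _random_seq(rng, L)
        records.append(
            TranscriptRecord(f"{gid}.T1", gid, "protein_coding", seq)
        )
        if i < config.n_two_isoform_genes:
            a = int(rng.integers(L // 4, L // 2))
            b = int(rng.integers(a + L // 8, min(a + L // 2, L - 50)))
            records.append(
                TranscriptRecord(f"{gid}.T2", gid, "protein_coding", seq[:a] + seq[b:])
            )

    for i in range(config.n_ercc):
        lo, hi = config.length_ranges["ERCC"]
        L = int(rng.integers(lo, hi + 1))
        tid = f"ERCC-{i + 1:05d}"
        records.append(TranscriptRecord(tid, tid, "ERCC", _random_seq(rng, L)))

    for i in range(config.n_trna):
        lo, hi = config.length_ranges["tRNA"]
        L = int(rng.integers(lo, hi + 1))
        anticodon = _ANTICODONS[i % len(_ANTICODONS)]
        gid = f"tRNA-{anticodon}-{i // len(_ANTICODONS) + 1}"
        tid = f"{gid}.T1"
        sites = _draw_trna_sites(rng, L, config)
        records.append(
            TranscriptRecord(tid, gid, "tRNA", _random_seq(rng, L), sites, anticodon)
        )

    for i in range(config.n_snorna):
        lo, hi = config.length_ranges["snoRNA"]
        L = int(rng.integers(lo, hi + 1))
        gid = f"SNORD{i + 1:03d}"
        records.append(TranscriptRecord(f"{gid}.T1", gid, "snoRNA", _random_seq(rng, L)))

    for i in range(config.n_rrna):
        lo, hi = config.length_ranges["rRNA"]
        L = int(rng.integers(lo, hi + 1))
        gid = f"RNA{18 + 10 * i}S"
        records.append(TranscriptRecord(f"{gid}.T1", gid, "rRNA", _random_seq(rng, L)))

    for i in range(config.n_other_ncrna):
        lo, hi = config.length_ranges["other_ncRNA"]
        L = int(rng.integers(lo, hi + 1))
        gid = f"LINC{i + 1:04d}"
        records.append(
            TranscriptRecord(f"{gid}.T1", gid, "other_ncRNA", _random_seq(rng, L))
        )

    # decoys: mutated copies of protein-coding transcripts (haplotype/patch
    # analogue) — reference-only, no abundance, no reads
    sources = [r for r in records if r.gene_type == "protein_coding"][: config.n_decoy]
    for i, src in enumerate(sources):
        arr = np.frombuffer(src.sequence.encode(), dtype=np.uint8).copy()
        n_mut = max(1, len(arr) // 100)
        pos = rng.choice(len(arr), size=n_mut, replace=False)
        for p in pos:
            arr[p] = _BASES[(np.where(_BASES == arr[p])[0][0] + rng.integers(1, 4)) % 4]
        records.append(
            TranscriptRecord(
                f"DECOY{i + 1:03d}",
                src.gene_id,
                src.gene_type,
                arr.tobytes().decode(),
                is_decoy=True,
            )
        )

    _check_unique_ids(records)
    return records


def _check_unique_ids(records: list[TranscriptRecord]) -> None:
    seen: dict[str, str] = {}
    for r in records:
        if r.transcript_id in seen:
            raise ValueError(f"duplicate transcript_id {r.transcript_id}")
        seen[r.transcript_id] = r.gene_id


def assign_ercc_design(
    ercc_records: list[TranscriptRecord],
    design: TitrationDesign,
    seed: int = 0,
) -> dict[str, str]:
    """Randomly split spike-ins into the equal-size designed ratio groups.

    Returns transcript_id -> group label. The number of spike-ins must be
    divisible by the number of groups.
    """
    labels = sorted(design.ercc_groups)
    n, g = len(ercc_records), len(labels)
    if n % g:
        raise ValueError(
            f"{n} spike-ins do not split into {g} equal groups (remainder {n % g})"
        )
    rng = np.random.default_rng(seed)
    ids = sorted(r.transcript_id for r in ercc_records)
    order = rng.permutation(len(ids))
    per = n // g
    assignment: dict[str, str] = {}
    for j, idx in enumerate(order):
        assignment[ids[idx]] = labels[j // per]
    return assignment


def ercc_truth(assignment: dict[str, str], design: TitrationDesign) -> dict[str, bool]:
    """Transcript -> True iff its designed A:B ratio differs from 1."""
    return {tid: design.is_de_group(label) for tid, label in assignment.items()}


def make_ab_abundances(
    transcripts: list[TranscriptRecord],
    design: TitrationDesign,
    ercc_assignment: dict[str, str],
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> AbundanceTable:
    """Molar concentrations for samples A and B.

    Baselines are drawn log10-uniformly per gene type. Spike-ins are forced
    to their designed A:B ratio exactly. Non-spike-in log2 ratios are drawn
    uniformly on (-w, w) and median-centred at 0; an exponential tilt of the
    non-spike-in abundance weights (w_i = ratio_i^lambda applied to a_i and
    b_i alike, preserving every per-transcript ratio) then sets
    sum(A)/sum(B) = z exactly.
    """
    if design.z <= 0:
        raise ValueError("z must be positive")
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    live = [t for t in transcripts if not t.is_decoy]
    ids = [t.transcript_id for t in live]

    base = np.empty(len(live))
    for i, t in enumerate(live):
        lo, hi = config.molar_log10_ranges[t.gene_type]
        base[i] = 10.0 ** rng.uniform(lo, hi)

    is_ercc = np.array([t.gene_type == "ERCC" for t in live])
    log2_ratio = np.zeros(len(live))
    free = ~is_ercc
    w = config.ratio_log2_halfwidth
    draws = rng.uniform(-w, w, int(free.sum()))
    draws -= np.median(draws)  # median molar ratio exactly 1 among background genes
    log2_ratio[free] = draws

    a = base * np.exp2(log2_ratio / 2.0)
    b = base * np.exp2(-log2_ratio / 2.0)
    for i, t in enumerate(live):
        if is_ercc[i]:
            ratio = design.ercc_groups[ercc_assignment[t.transcript_id]]
            a[i] = base[i]
            b[i] = base[i] / ratio

    # exponential tilt of the background so that sum(a)/sum(b) = z exactly
    rho = a[free] / b[free]
    a_e, b_e = a[is_ercc].sum(), b[is_ercc].sum()

    def total_ratio(lam: float) -> float:
        wgt = np.exp(lam * np.log(rho))
        return (a_e + (a[free] * wgt).sum()) / (b_e + (b[free] * wgt).sum())

    if free.sum() == 0:
        if not np.isclose(total_ratio(0.0), design.z, rtol=1e-9):
            raise ValueError("cannot reach z with spike-ins only")
        lam = 0.0
    else:
        lam = brentq(lambda l: np.log(total_ratio(l)) - np.log(design.z), -80.0, 80.0)
    wgt = np.ones(len(live))
    wgt[free] = np.exp(lam * np.log(rho))
    a *= wgt
    b *= wgt
    # one exact final correction absorbs float round-off (rescales both
    # samples identically, so no ratio moves)
    b *= a.sum() / (design.z * b.sum())

    df = pd.DataFrame(
        {("A", 1): a, ("B", 1): b},
        index=pd.Index(ids, name="transcript_id"),
    )
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return AbundanceTable(df, unit="molar_per_unit_mass")


def mix_titration(ab_table: AbundanceTable, design: TitrationDesign) -> AbundanceTable:
    """Add samples C and D as mass mixtures of A and B (3:1 and 1:3)."""
    if ab_table.unit != "molar_per_unit_mass":
        raise ValueError("titration mixing requires molar_per_unit_mass units")
    for s in ("A", "B"):
        if s not in ab_table.samples:
            raise ValueError(f"sample {s} missing from table")
    vals = ab_table.values.copy()
    a, b = vals[("A", 1)], vals[("B", 1)]
    ca, cb = design.ratio_CA_CB
    da, db = design.ratio_DA_DB
    vals[("C", 1)] = ca * a + cb * b
    vals[("D", 1)] = da * a + db * b
    return AbundanceTable(vals, unit="molar_per_unit_mass", level=ab_table.level)


def simulate_replicate_counts(
    tpm_table: AbundanceTable,
    lengths: pd.Series | dict,
    depth: int,
    dispersion: float = 0.01,
    n_replicates: int = 3,
    read_length: int = 50,
    seed: int = 0,
) -> AbundanceTable:
    """Simulate replicate libraries of ``depth`` reads from a TPM table.

    Expected counts are proportional to TPM x effective length, scaled to sum
    to ``depth``. With ``dispersion`` (NB alpha) > 0, counts are independent
    negative binomials with variance mu + alpha*mu^2; alpha = 0 is the
    fixed-total multinomial (conditional Poisson) draw.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if dispersion < 0:
        raise ValueError("dispersion cannot be negative")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    lens = pd.Series(lengths).reindex(tpm_table.ids)
    eff = np.maximum(lens.to_numpy(float) - read_length + 1, 1.0)

    cols = {}
    for sample in tpm_table.samples:
        tpm = tpm_table.column(sample, 1).to_numpy(float)
        weights = tpm * eff
        p = weights / weights.sum()
        mu = depth * p
        for rep in range(1, n_replicates + 1):
            if dispersion == 0.0:
                counts = rng.multinomial(depth, p)
            else:
                n_param = 1.0 / dispersion
                counts = np.where(
                    mu > 0,
                    rng.negative_binomial(n_param, n_param / (n_param + np.maximum(mu, 1e-300))),
                    0,
                )
            cols[(sample, rep)] = counts
    df = pd.DataFrame(cols, index=tpm_table.ids)
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return AbundanceTable(df, unit="count", level=tpm_table.level)


_OFFSETS = np.array(
    [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]], dtype=np.uint8
)  # index: base code -> the three alternative base codes


def simulate_reads(
    transcripts: list[TranscriptRecord],
    table: AbundanceTable,
    sample: str,
    replicate: int = 1,
    n_reads: int = 10_000,
    read_length: int = 50,
    mis_rate: float = 0.0,
    seq_error: float = 0.0,
    dispersion: float = 0.0,
    seed: int = 0,
    fastq_path=None,
) -> ReadSet:
    """Simulate single-end sense-strand reads for one library.

    Source transcripts are drawn proportionally to molar abundance times
    effective length; starts are uniform over valid positions; reads from
    transcripts shorter than ``read_length`` span the whole transcript. At
    every modification site covered by a read the base is substituted with
    probability ``mis_rate``; independently every base flips with probability
    ``seq_error``. All events are recorded in the per-read error log.

    ``dispersion`` adds replicate-level biological noise: each transcript's
    sampling weight is jittered by a Gamma(1/alpha, alpha) factor (mean 1),
    making marginal per-transcript counts negative-binomial with variance
    mu + alpha*mu^2 rather than multinomial.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not (0.0 <= mis_rate <= 1.0 and 0.0 <= seq_error <= 1.0):
        raise ValueError("error rates must lie in [0, 1]")
    if dispersion < 0:
        raise ValueError("dispersion cannot be negative")
    rng = np.random.default_rng(seed)
    live = [t for t in transcripts if not t.is_decoy]
    values = table.column(sample, replicate)
    weights = np.array(
        [values.get(t.transcript_id, 0.0) * t.effective_length(read_length) for t in live]
    )
    if weights.sum() <= 0:
        raise ValueError(f"no positive abundance for sample {sample}")
    if dispersion > 0:
        weights = weights * rng.gamma(1.0 / dispersion, dispersion, len(weights))
    per_transcript = rng.multinomial(n_reads, weights / weights.sum())

    code = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i

    reads: list[SimulatedRead] = []
    serial = 0
    for t, c in zip(live, per_transcript):
        if c == 0:
            continue
        seq = np.frombuffer(t.sequence.encode(), dtype=np.uint8)
        span = min(read_length, t.length)
        n_pos = t.effective_length(read_length)
        starts = rng.integers(0, n_pos, c)  # 0-based
        mat = code[seq[starts[:, None] + np.arange(span)]]
        logs: list[list[tuple[int, str]]] = [[] for _ in range(c)]
        for site in t.modification_positions:
            rel = site - 1 - starts
            covered = (rel >= 0) & (rel < span)
            hit = covered & (rng.random(c) < mis_rate)
            for i in np.flatnonzero(hit):
                j = int(rel[i])
                mat[i, j] = _OFFSETS[mat[i, j], rng.integers(0, 3)]
                logs[i].append((j + 1, "modification"))
        if seq_error > 0:
            err = rng.random(mat.shape) < seq_error
            for i, j in zip(*np.nonzero(err)):
                mat[i, j] = _OFFSETS[mat[i, j], rng.integers(0, 3)]
                logs[int(i)].append((int(j) + 1, "sequencing"))
        seqs = _BASES[mat]
        for i in range(c):
            reads.append(
                SimulatedRead(
                    read_id=f"{sample}{replicate}_{serial:07d}",
                    sequence=seqs[i].tobytes().decode(),
                    true_transcript_id=t.transcript_id,
                    true_start=int(starts[i]) + 1,
                    errors=tuple(sorted(logs[i])),
                )
            )
            serial += 1

    readset = ReadSet(reads=reads, read_length=read_length)
    if fastq_path is not None:
        from .io import write_fastq

        write_fastq(readset, fastq_path)
    return readset
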