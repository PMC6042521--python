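"""Titration evaluation: fold-change model, R², RMSE, ROC, stratification.

The benchmark's yardstick is internal consistency of the titration design:
samples C and D are known mass mixtures of A and B, so each gene's measured
C/D fold change can be compared to the value predicted from its measured A/B
fold change,

    log2(C/D) = log2(k1 r + (1 - k1)) - log2(k2 r + (1 - k2)),

with r = A/B on the TPM scale, k1 = 3z/(3z+1), k2 = z/(z+3). Agreement is
scored as R² = 1 - Σ(y_i - f_i)² / Σ(y_i - ȳ)² (ȳ the mean measured value;
negative R² = worse than the mean predictor) and as RMSE per gene stratum.
Spike-in truth (which ERCC groups were designed at ratio 1) supports a
ROC/AUC on differential-expression p-values.

Differential expression is a Welch t-test on log2(normalized value + 0.5).
Two normalizations are offered: ``cpm`` (per-million scaling — the scale on
which the titration identity holds exactly) and ``median_of_ratios``
(DESeq2-style size factors, optionally from control genes only — the scale
on which the 1:1 spike-in group is genuinely null despite the A/B total
signal ratio z).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .records import TitrationDesign, TranscriptRecord
from .tables import AbundanceTable

DETECTION_TPM_THRESHOLD = 0.1

#: printed category names per gene type (report tables)
GENE_TYPE_CATEGORIES = {
    "protein_coding": "Protein coding",
    "ERCC": "ERCC",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "snoRNA": "Other sncRNA",
    "other_ncRNA": "Other ncRNA",
}


# ---------------------------------------------------------------------------
# gene-level aggregation
# ---------------------------------------------------------------------------

def gene_map(transcripts: list[TranscriptRecord]) -> pd.Series:
    return pd.Series(
        {t.transcript_id: t.gene_id for t in transcripts if not t.is_decoy},
        name="gene_id",
    )


def gene_lengths(transcripts: list[TranscriptRecord]) -> pd.Series:
    """Gene length = length of the longest transcript of the gene."""
    rows = [(t.gene_id, t.length) for t in transcripts if not t.is_decoy]
    df = pd.DataFrame(rows, columns=["gene_id", "length"])
    return df.groupby("gene_id")["length"].max()


def gene_types(transcripts: list[TranscriptRecord]) -> pd.Series:
    rows = {t.gene_id: t.gene_type for t in transcripts if not t.is_decoy}
    return pd.Series(rows, name="gene_type")


def aggregate_to_gene(
    tpm_table: AbundanceTable,
    transcripts: list[TranscriptRecord],
    library_sizes: pd.Series | dict | float = 1e6,
    read_length: int = 50,
) -> AbundanceTable:
    """Transcript TPM -> gene-level count-scale values (tximport-style).

    Gene value = sum over its transcripts of TPM x effective length,
    rescaled per column so the column totals the library size (a scalar or a
    per-(sample, replicate) mapping).
    """
    if tpm_table.unit != "TPM":
        raise ValueError("gene aggregation expects a TPM table")
    gmap = gene_map(transcripts)
    missing = tpm_table.ids.difference(gmap.index)
    if len(missing):
        raise KeyError(f"unknown transcripts in table: {list(missing)[:3]}")
    eff = pd.Series(
        {
            t.transcript_id: float(t.effective_length(read_length))
            for t in transcripts
            if not t.is_decoy
        }
    ).reindex(tpm_table.ids)
    scaled = tpm_table.values.mul(eff, axis=0)
    gene_vals = scaled.groupby(gmap.reindex(tpm_table.ids)).sum()
    sums = gene_vals.sum(axis=0)
    if isinstance(library_sizes, (int, float)):
        target = pd.Series(float(library_sizes), index=gene_vals.columns)
    else:
        target = pd.Series({tuple(k) if isinstance(k, tuple) else k: v
                            for k, v in dict(library_sizes).items()})
        target = target.reindex(gene_vals.columns)
    gene_vals = gene_vals.div(sums, axis=1).mul(target, axis=1)
    gene_vals.index.name = "gene_id"
    return AbundanceTable(gene_vals, unit="count_scale", level="gene")


def gene_tpm(tpm_table: AbundanceTable, transcripts: list[TranscriptRecord]) -> AbundanceTable:
    """Gene TPM = sum of transcript TPM over the gene's transcripts."""
    if tpm_table.unit != "TPM":
        raise ValueError("expects a TPM table")
    gmap = gene_map(transcripts).reindex(tpm_table.ids)
    vals = tpm_table.values.groupby(gmap).sum()
    vals.index.name = "gene_id"
    return AbundanceTable(vals, unit="TPM", level="gene")


# ---------------------------------------------------------------------------
# detection and differential expression
# ---------------------------------------------------------------------------

def detect(tpm):
    """Detected iff TPM strictly exceeds 0.1."""
    return np.asarray(tpm) > DETECTION_TPM_THRESHOLD if np.ndim(tpm) else tpm > DETECTION_TPM_THRESHOLD


def cpm(values: pd.DataFrame) -> pd.DataFrame:
    """Counts per million per column."""
    sums = values.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("cannot CPM-normalize an all-zero column")
    return values.div(sums, axis=1) * 1e6


def size_factors(values: pd.DataFrame, control_genes=None) -> pd.Series:
    """Median-of-ratios size factors (DESeq-style).

    The geometric-mean reference uses genes with nonzero counts everywhere,
    restricted to ``control_genes`` when given (e.g. non-spike-in genes).
    """
    v = values if control_genes is None else values.loc[values.index.intersection(control_genes)]
    v = v[(v > 0).all(axis=1)]
    if v.empty:
        raise ValueError("no strictly positive genes to compute size factors from")
    logref = np.log(v).mean(axis=1)
    sf = np.exp(np.log(v).sub(logref, axis=0).median(axis=0))
    return sf


def normalize_counts(
    values: pd.DataFrame,
    method: str = "cpm",
    control_genes=None,
) -> pd.DataFrame:
    """Normalize a count matrix to CPM scale.

    ``median_of_ratios`` divides by size factors and rescales so the grand
    mean library size is 1e6 (keeping values on a CPM-like scale).
    """
    if method == "cpm":
        return cpm(values)
    if method == "median_of_ratios":
        sf = size_factors(values, control_genes)
        norm = values.div(sf, axis=1)
        return norm * (1e6 / norm.sum(axis=0).mean())
    raise ValueError(f"unknown normalization {method!r}")


def de_test(values_x, values_y) -> tuple[float, float]:
    """Welch two-sample t-test on log2(value + 0.5); returns (log2fc, p).

    ``log2fc`` is mean(log2(x + 0.5)) - mean(log2(y + 0.5)). Degenerate
    zero-variance cases: identical means give p = 1, different means with no
    variance give p = 0.
    """
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two replicates per side")
    lx, ly = np.log2(x + 0.5), np.log2(y + 0.5)
    log2fc = float(lx.mean() - ly.mean())
    if lx.std() == 0.0 and ly.std() == 0.0:
        return log2fc, (1.0 if log2fc == 0.0 else 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(lx, ly, equal_var=False)
    return log2fc, float(p)


def de_test_table(
    norm_values: pd.DataFrame, sample_x: str, sample_y: str
) -> pd.DataFrame:
    """Vectorized per-gene Welch t-test between two samples' replicates."""
    x = np.log2(norm_values[sample_x].to_numpy(float) + 0.5)
    y = np.log2(norm_values[sample_y].to_numpy(float) + 0.5)
    if x.shape[1] < 2 or y.shape[1] < 2:
        raise ValueError("need at least two replicates per side")
    log2fc = x.mean(axis=1) - y.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
    sx = x.std(axis=1)
    sy = y.std(axis=1)
    degenerate = (sx == 0) & (sy == 0)
    p = np.where(degenerate, np.where(log2fc == 0.0, 1.0, 0.0), p)
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": p}, index=norm_values.index
    )


# ---------------------------------------------------------------------------
# the expected fold-change model and its metrics
# ---------------------------------------------------------------------------

def expected_cd_log2fc(measured_log2fc_ab, z: float):
    """Expected log2(C/D) from measured log2(A/B) under the titration model.

    Monotone increasing in r = 2**measured_log2fc_ab, bounded between
    log2((1-k1)/(1-k2)) and log2(k1/k2). Non-finite inputs propagate with a
    warning.
    """
    if z <= 0:
        raise ValueError("z must be positive")
    x = np.asarray(measured_log2fc_ab, dtype=float)
    if not np.all(np.isfinite(x)):
        warnings.warn("non-finite A/B fold changes propagate to the prediction", stacklevel=2)
    design = TitrationDesign(z=z)
    k1, k2 = design.k1, design.k2
    r = np.exp2(x)
    out = np.log2(k1 * r + (1.0 - k1)) - np.log2(k2 * r + (1.0 - k2))
    return out if out.ndim else float(out)


def r_squared(measured, expected) -> float:
    """R² = 1 - Σ(y-f)² / Σ(y-ȳ)² with ȳ the mean of the measured vector.

    At most 1, unbounded below; negative values mean the model fits worse
    than the mean predictor. Raises on constant measurements.
    """
    y = np.asarray(measured, dtype=float)
    f = np.asarray(expected, dtype=float)
    if y.shape != f.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(f))):
        raise ValueError("inputs must be finite")
    denom = np.sum((y - y.mean()) ** 2)
    if denom == 0:
        raise ValueError("constant measurements: R² undefined")
    return float(1.0 - np.sum((y - f) ** 2) / denom)


def rmse(measured, expected) -> float:
    y = np.asarray(measured, dtype=float)
    f = np.asarray(expected, dtype=float)
    if y.shape != f.shape or y.size == 0:
        raise ValueError("need two equal-length nonempty vectors")
    return float(np.sqrt(np.mean((y - f) ** 2)))


def roc_auc(p_values, truth) -> tuple[pd.DataFrame, float]:
    """ROC over p-value thresholds and its AUC against spike-in truth.

    AUC is the Mann-Whitney probability that a random true-DE gene has a
    smaller p-value than a random null gene (ties 0.5).
    """
    p = np.asarray(p_values, dtype=float)
    y = np.asarray(truth, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("truth labels must contain both classes")
    score = -p  # smaller p = stronger DE call
    fpr, tpr, thr = roc_curve(y, score)
    auc = float(roc_auc_score(y, score))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "p_threshold": -thr})
    return points, auc


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def stratify(table: pd.DataFrame, by: str, scheme: str | None = None) -> dict[str, pd.Index]:
    """Named gene subsets for stratified metrics.

    ``by="mean_expression"`` gives the overlapping sets Total RNA / top 1% /
    top 10% / top 25% / bottom 75%; ``by="gene_length"`` gives four disjoint
    quartile groups; ``by="gene_type"`` groups by printed category names.
    Quantile ties break by ascending gene identifier.
    """
    if by == "gene_type":
        out = {}
        for gtype, name in GENE_TYPE_CATEGORIES.items():
            idx = table.index[table["gene_type"] == gtype]
            if len(idx):
                out[name] = idx
        return out
    if by not in table.columns:
        raise KeyError(f"column {by!r} not in table")
    order = table.sort_values([by, table.index.name or "index"], kind="mergesort").index
    n = len(order)
    if by == "mean_expression":
        desc = order[::-1]
        k1, k10, k25 = max(1, n // 100), max(1, n // 10), max(1, n // 4)
        return {
            "Total RNA": table.index,
            "Top 1%": desc[:k1],
            "Top 10%": desc[:k10],
            "Top 25%": desc[:k25],
            "Bottom 75%": desc[k25:],
        }
    if by == "gene_length":
        quarts = np.array_split(np.asarray(order), 4)
        return {f"Length Q{i + 1}": pd.Index(q) for i, q in enumerate(quarts)}
    raise ValueError(f"unknown stratification scheme for {by!r}")


# ---------------------------------------------------------------------------
# the fold-change table and the summary
# ---------------------------------------------------------------------------

def build_fold_change_table(
    gene_values: AbundanceTable,
    gene_tpm_table: AbundanceTable,
    transcripts: list[TranscriptRecord],
    z: float,
    normalization: str = "cpm",
    control_genes=None,
) -> pd.DataFrame:
    """Per-gene measured A/B and C/D fold changes vs the titration model.

    Genes with zero values in every library are excluded before modeling
    (their ids are recorded in ``df.attrs["excluded_genes"]``).
    """
    vals = gene_values.values
    keep = vals.sum(axis=1) > 0
    excluded = list(vals.index[~keep])
    vals = vals.loc[keep]
    norm = normalize_counts(vals, method=normalization, control_genes=control_genes)
    ab = de_test_table(norm, "A", "B")
    cd = de_test_table(norm, "C", "D")
    tpm_mean = gene_tpm_table.values.mean(axis=1).reindex(vals.index)
    types = gene_types(transcripts).reindex(vals.index)
    lens = gene_lengths(transcripts).reindex(vals.index)
    df = pd.DataFrame(
        {
            "gene_type": types,
            "gene_length": lens,
            "mean_expression": tpm_mean,
            "measured_log2fc_AB": ab["log2fc"],
            "p_value_AB": ab["p_value"],
            "measured_log2fc_CD": cd["log2fc"],
            "p_value_CD": cd["p_value"],
        }
    )
    df["expected_log2fc_CD"] = expected_cd_log2fc(
        df["measured_log2fc_AB"].to_numpy(), z
    )
    df.index.name = "gene_id"
    df.attrs["excluded_genes"] = excluded
    return df


def summarize_evaluation(
    fc_table: pd.DataFrame,
    ercc_gene_truth: dict[str, bool] | None = None,
    roc_p_values: pd.Series | None = None,
) -> dict:
    """R² per stratum, RMSE per gene type, ERCC AUC.

    ``roc_p_values`` lets the caller supply p-values computed under a
    different normalization (the DESeq2-analogue route) than the fold-change
    model's; defaults to the table's own A/B p-values.
    """
    y = fc_table["measured_log2fc_CD"]
    f = fc_table["expected_log2fc_CD"]

    def _scores(idx) -> dict:
        if len(idx) < 2:
            return {"r2": np.nan, "rmse": np.nan, "n_genes": len(idx)}
        try:
            r2 = r_squared(y[idx], f[idx])
        except ValueError:
            r2 = np.nan
        return {"r2": r2, "rmse": rmse(y[idx], f[idx]), "n_genes": len(idx)}

    summary: dict = {"overall": _scores(fc_table.index)}
    for by in ("mean_expression", "gene_length", "gene_type"):
        strata = stratify(fc_table, by)
        summary[by] = {name: _scores(idx) for name, idx in strata.items()}

    if ercc_gene_truth:
        genes = [g for g in fc_table.index if g in ercc_gene_truth]
        pvals = (
            roc_p_values.reindex(genes)
            if roc_p_values is not None
            else fc_table.loc[genes, "p_value_AB"]
        )
        truth = [ercc_gene_truth[g] for g in genes]
        if len(set(truth)) == 2:
            _, auc = roc_auc(pvals.to_numpy(), truth)
            summary["ercc_auc"] = auc
            summary["ercc_n"] = len(genes)
    return summary


def trna_cumulative_error(fc_table: pd.DataFrame) -> pd.DataFrame:
    """Sorted cumulative |measured - expected| C/D error over tRNA genes."""
    sub = fc_table[fc_table["gene_type"] == "tRNA"]
    err = (sub["measured_log2fc_CD"] - sub["expected_log2fc_CD"]).abs().sort_values()
    return pd.DataFrame(
        {
            "gene_id": err.index,
            "abs_error": err.to_numpy(),
            "cumulative_error": err.cumsum().to_numpy(),
        }
    )
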