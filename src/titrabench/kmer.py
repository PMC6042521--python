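"""Alignment-free quantification: k-mer index, pseudoassignment, EM.

This is a desk-scale stand-in for the Kallisto/Salmon class of tools. A read
is assigned to the intersection of the transcript sets of all its k-mers
that are present in the index (absent k-mers are skipped, in the spirit of
pseudoalignment's robust intersection); reads whose intersection is empty,
or none of whose k-mers are indexed, are unassigned. Reads with identical
compatibility sets form equivalence classes, and transcript abundances are
the EM maximizer of the standard equivalence-class likelihood with
effective-length weighting.

The mechanism of interest lives entirely in the exact-match index: a
substitution error corrupts every overlapping k-mer, so a short read whose
errors leave no error-free k-mer is unassigned — see :mod:`titrabench.dropout`
for the combinatorics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .records import EquivalenceClassCounts, ReadSet, TranscriptRecord

DEFAULT_K_GRID = (11, 15, 21, 31)


@dataclass
class KmerIndex:
    """Exact-match k-mer -> transcript-set index (sense strand only)."""

    k: int
    table: dict[str, frozenset]
    lengths: dict[str, int]

    def lookup(self, kmer: str) -> frozenset | None:
        return self.table.get(kmer)


def build_index(transcripts: list[TranscriptRecord], k: int) -> KmerIndex:
    """Index every length-k substring of every transcript.

    Transcripts shorter than k contribute nothing (warned); each transcript
    of length L contributes exactly L - k + 1 k-mer occurrences.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    short = [t.transcript_id for t in transcripts if t.length < k]
    if short:
        warnings.warn(
            f"{len(short)} transcript(s) shorter than k={k} contribute no k-mers",
            stacklevel=2,
        )
    table: dict[str, set] = {}
    for t in transcripts:
        seq = t.sequence
        for i in range(len(seq) - k + 1):
            table.setdefault(seq[i : i + k], set()).add(t.transcript_id)
    return KmerIndex(
        k=k,
        table={kmer: frozenset(v) for kmer, v in table.items()},
        lengths={t.transcript_id: t.length for t in transcripts},
    )


def pseudomap_read(sequence: str, index: KmerIndex) -> frozenset:
    """Compatibility set of a read: intersection over its indexed k-mers.

    Returns the empty frozenset when the read is shorter than k, when no
    k-mer is present in the index, or when the intersection is empty.
    """
    k = index.k
    if len(sequence) < k:
        return frozenset()
    result: frozenset | None = None
    for i in range(len(sequence) - k + 1):
        hit = index.table.get(sequence[i : i + k])
        if hit is None:
            continue
        result = hit if result is None else (result & hit)
        if not result:
            return frozenset()
    return result if result is not None else frozenset()


def collect_equivalence_classes(
    reads: ReadSet | list, index: KmerIndex
) -> EquivalenceClassCounts:
    """Group per-read compatibility sets into counted equivalence classes."""
    counts: dict[frozenset, int] = {}
    unassigned = 0
    for read in reads:
        seq = read.sequence if hasattr(read, "sequence") else read
        compat = pseudomap_read(seq, index)
        if compat:
            counts[compat] = counts.get(compat, 0) + 1
        else:
            unassigned += 1
    return EquivalenceClassCounts(counts=counts, unassigned=unassigned)


def em_read_fractions(
    classes: EquivalenceClassCounts,
    effective_lengths: dict[str, float] | pd.Series,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> pd.Series:
    """EM estimate of the read-fraction parameter theta (sums to 1).

    This is the raw maximizer of the equivalence-class likelihood
    prod_c (sum_{t in c} theta_t/l_t)^{n_c}; use :func:`em_abundances` for
    the TPM conversion.
    """
    eff = pd.Series(effective_lengths, dtype=float)
    if (eff <= 0).any():
        raise ValueError("effective lengths must be positive")
    tids = list(eff.index)
    if not classes.counts:
        warnings.warn("no assigned reads; returning all-zero estimates", stacklevel=2)
        return pd.Series(0.0, index=tids, name="theta")

    pos = {tid: i for i, tid in enumerate(tids)}
    member_tr: list[int] = []
    member_cls: list[int] = []
    n_c = np.empty(len(classes.counts))
    for ci, (members, count) in enumerate(classes.counts.items()):
        n_c[ci] = count
        for tid in members:
            if tid not in pos:
                raise KeyError(f"class member {tid} has no effective length")
            member_tr.append(pos[tid])
            member_cls.append(ci)
    tr = np.asarray(member_tr)
    cl = np.asarray(member_cls)
    ell = eff.to_numpy()

    theta = np.full(len(tids), 1.0 / len(tids))
    for _ in range(max_iter):
        w = theta[tr] / ell[tr]
        denom = np.bincount(cl, weights=w, minlength=len(n_c))
        frac = np.zeros_like(w)
        ok = denom[cl] > 0
        frac[ok] = w[ok] * (n_c[cl][ok] / denom[cl][ok])
        new = np.bincount(tr, weights=frac, minlength=len(tids))
        new /= new.sum()
        if np.max(np.abs(new - theta)) < tol:
            theta = new
            break
        theta = new
    return pd.Series(theta, index=tids, name="theta")


def em_abundances(
    classes: EquivalenceClassCounts,
    effective_lengths: dict[str, float] | pd.Series,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> pd.Series:
    """EM abundance estimates (TPM) from equivalence-class counts.

    Iterates theta_t <- sum_c n_c (theta_t/l_t) / sum_{u in c} (theta_u/l_u)
    followed by renormalization, from a uniform start, until
    max |delta theta| < tol or ``max_iter`` iterations. theta is the
    read-fraction parameter of the equivalence-class likelihood
    prod_c (sum_{t in c} theta_t/l_t)^{n_c}; the returned TPM is the
    molar proportion 1e6 * (theta_t/l_t) / sum_u (theta_u/l_u). Transcripts
    appearing in no class get TPM 0; an empty class map yields all zeros
    with a warning.
    """
    eff = pd.Series(effective_lengths, dtype=float)
    theta = em_read_fractions(classes, eff, tol=tol, max_iter=max_iter)
    if theta.sum() == 0:
        return pd.Series(0.0, index=theta.index, name="TPM")
    molar = theta / eff.reindex(theta.index)
    molar /= molar.sum()
    return pd.Series(molar.to_numpy() * 1e6, index=theta.index, name="TPM")


class KmerQuantifier(BaseEstimator):
    """k-mer equivalence-class quantifier with EM abundance estimation.

    A scikit-learn style estimator: ``fit`` indexes a transcriptome,
    ``transform`` turns a read set into per-transcript TPM.

    Parameters
    ----------
    k : int
        k-mer size (the benchmark sweeps 11, 15, 21, 31; 31 is the common
        tool default and the one short modified RNAs break).
    read_length : int
        Nominal read length, used for effective lengths
        ``max(L - read_length + 1, 1)`` in the EM.
    tol, max_iter : float, int
        EM stopping rule.
    """

    def __init__(
        self,
        k: int = 31,
        read_length: int = 50,
        tol: float = 1e-8,
        max_iter: int = 1000,
    ):
        self.k = k
        self.read_length = read_length
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, transcripts: list[TranscriptRecord], y=None) -> "KmerQuantifier":
        if self.k < 1:
            raise ValueError("k must be >= 1")
        indexable = [t for t in transcripts if not t.is_decoy]
        self.index_ = build_index(indexable, self.k)
        self.effective_lengths_ = {
            t.transcript_id: float(t.effective_length(self.read_length))
            for t in indexable
        }
        return self

    def equivalence_classes(self, reads: ReadSet | list) -> EquivalenceClassCounts:
        self._check_fitted()
        return collect_equivalence_classes(reads, self.index_)

    def transform(self, reads: ReadSet | list) -> pd.Series:
        """Per-transcript TPM for one library of reads."""
        self._check_fitted()
        classes = self.equivalence_classes(reads)
        return em_abundances(
            classes, self.effective_lengths_, tol=self.tol, max_iter=self.max_iter
        )

    def fit_transform(self, transcripts, reads) -> pd.Series:
        return self.fit(transcripts).transform(reads)

    def _check_fitted(self) -> None:
        if not hasattr(self, "index_"):
            raise AttributeError("KmerQuantifier is not fitted; call fit(transcripts) first")
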