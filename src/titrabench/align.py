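"""Alignment-based quantification with small-RNA routing and multi-map rules.

A desk-scale analogue of an alignment pipeline specialised for libraries that
capture short structured RNAs: reads are aligned end-to-end (substitutions
only) against the transcript set; hits on tRNA/rRNA transcripts pre-empt all
others (the pre-routing that keeps modified small RNAs out of ambiguous
genome assignment); among surviving hits a single one is selected by, in
order, fewest mismatches (the single-end analogue of smallest insert size),
ribosomal locus preference, primary-over-decoy preference, then a seeded
uniform draw. Each read therefore contributes at most one count to one gene;
tRNA gene counts can be aggregated per anticodon (isoacceptor level).

The public :func:`align_read` is an exhaustive scan of every offset of every
transcript. The :class:`AlignmentQuantifier` uses a pigeonhole seed-and-verify
search that returns exactly the same hit set: with ``max_mismatch = m``, the
read is split into m+1 non-overlapping exact seeds, and any alignment with at
most m mismatches must leave at least one seed intact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .records import ReadSet, TranscriptRecord

_SMALL_RNA_TYPES = ("tRNA", "rRNA")


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    transcript_id: str
    start: int  # 1-based on the transcript
    mismatches: int
    priority_class: str  # rRNA_locus | primary | decoy

    def __post_init__(self) -> None:
        if self.start < 1 or self.mismatches < 0:
            raise ValueError("invalid hit coordinates")
        if self.priority_class not in ("rRNA_locus", "primary", "decoy"):
            raise ValueError(f"unknown priority class {self.priority_class!r}")


def default_max_mismatch(read_length: int) -> int:
    """ceil(0.15 x read length) — tolerant enough for 3-4 misincorporations."""
    return math.ceil(0.15 * read_length)


def _priority_class(t: TranscriptRecord) -> str:
    if t.is_decoy:
        return "decoy"
    if t.gene_type == "rRNA":
        return "rRNA_locus"
    return "primary"


def align_read(
    read,
    transcripts: list[TranscriptRecord],
    max_mismatch: int | None = None,
) -> list[AlignmentHit]:
    """Exhaustive end-to-end scan: all sense-strand offsets of all transcripts.

    Hits within Hamming distance ``max_mismatch`` are returned; alignments
    overhanging a transcript end are disallowed. Intended for small inputs
    and as the oracle for the indexed search.
    """
    seq = read.sequence if hasattr(read, "sequence") else read
    rid = read.read_id if hasattr(read, "read_id") else "read"
    mm = default_max_mismatch(len(seq)) if max_mismatch is None else max_mismatch
    if mm < 0:
        raise ValueError("max_mismatch cannot be negative")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    hits: list[AlignmentHit] = []
    for t in transcripts:
        if t.length < len(arr):
            continue
        tseq = np.frombuffer(t.sequence.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(tseq, len(arr))
        dist = (windows != arr).sum(axis=1)
        for off in np.flatnonzero(dist <= mm):
            hits.append(
                AlignmentHit(rid, t.transcript_id, int(off) + 1, int(dist[off]), _priority_class(t))
            )
    return hits


def route_and_select(
    hits: list[AlignmentHit],
    rng: np.random.Generator | int = 0,
    transcript_types: dict[str, str] | None = None,
) -> AlignmentHit | None:
    """Reduce a read's hits to at most one by the pipeline's rules.

    1. Small-RNA routing: if any hit lies on a tRNA or rRNA transcript, all
       other hits are discarded (requires ``transcript_types``).
    2. Fewest mismatches.
    3. rRNA locus preferred, then primary over decoy.
    4. Remaining ties broken by a seeded uniform draw.
    """
    if not hits:
        return None
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    pool = hits
    if transcript_types:
        small = [h for h in hits if transcript_types.get(h.transcript_id) in _SMALL_RNA_TYPES]
        if small:
            pool = small
    best_mm = min(h.mismatches for h in pool)
    pool = [h for h in pool if h.mismatches == best_mm]
    rank = {"rRNA_locus": 0, "primary": 1, "decoy": 2}
    best_rank = min(rank[h.priority_class] for h in pool)
    pool = [h for h in pool if rank[h.priority_class] == best_rank]
    if len(pool) == 1:
        return pool[0]
    pool = sorted(pool, key=lambda h: (h.transcript_id, h.start))
    return pool[int(rng.integers(0, len(pool)))]


def count_genes(
    selected_hits: list[AlignmentHit],
    transcripts: list[TranscriptRecord],
) -> pd.Series:
    """One count per selected read to its transcript's gene."""
    gene_of = {t.transcript_id: t.gene_id for t in transcripts}
    counts: dict[str, int] = {}
    for h in selected_hits:
        if h.transcript_id not in gene_of:
            raise KeyError(f"hit references unknown transcript {h.transcript_id}")
        g = gene_of[h.transcript_id]
        counts[g] = counts.get(g, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def aggregate_anticodon(
    gene_counts: pd.Series,
    transcripts: list[TranscriptRecord],
) -> pd.Series:
    """Sum tRNA gene counts over genes sharing an anticodon."""
    anticodon_of: dict[str, str] = {}
    for t in transcripts:
        if t.gene_type == "tRNA" and not t.is_decoy:
            if t.anticodon is None:
                raise ValueError(f"tRNA {t.transcript_id} lacks an anticodon label")
            anticodon_of[t.gene_id] = t.anticodon
    out: dict[str, int] = {}
    for gene, n in gene_counts.items():
        if gene in anticodon_of:
            ac = anticodon_of[gene]
            out[ac] = out.get(ac, 0) + int(n)
    return pd.Series(out, dtype=int).sort_index()


class _SeededSearch:
    """Pigeonhole-complete substitution-only search over a transcript set."""

    def __init__(self, transcripts: list[TranscriptRecord], seed_length: int):
        self.seed_length = seed_length
        self.transcripts = transcripts
        parts = []
        offsets = []
        pos = 0
        pad = b"\x00" * seed_length
        for t in transcripts:
            offsets.append(pos)
            parts.append(t.sequence.encode())
            parts.append(pad)
            pos += t.length + seed_length
        self.text = np.frombuffer(b"".join(parts), dtype=np.uint8)
        self.offsets = np.array(offsets)
        self.lengths = np.array([t.length for t in transcripts])
        raw = bytes(self.text)
        index: dict[bytes, list[int]] = {}
        for i in range(len(raw) - seed_length + 1):
            s = raw[i : i + seed_length]
            if b"\x00" in s:
                continue
            index.setdefault(s, []).append(i)
        self.index = {k: np.array(v) for k, v in index.items()}

    def hits(self, read_seq: str, read_id: str, mm: int) -> list[AlignmentHit]:
        rl = len(read_seq)
        arr = np.frombuffer(read_seq.encode(), dtype=np.uint8)
        s = self.seed_length
        raw = read_seq.encode()
        cands: list[np.ndarray] = []
        for i in range(mm + 1):
            seg = raw[i * s : (i + 1) * s]
            if len(seg) < s:
                break
            occ = self.index.get(seg)
            if occ is not None:
                cands.append(occ - i * s)
        if not cands:
            return []
        starts = np.concatenate(cands)
        starts = starts[(starts >= 0) & (starts + rl <= len(self.text))]
        if starts.size == 0:
            return []
        windows = self.text[starts[:, None] + np.arange(rl)]
        dist = (windows != arr).sum(axis=1)
        ok = dist <= mm
        # duplicates (several intact seeds of one locus) collapse here
        keep, first = np.unique(starts[ok], return_index=True)
        dist = dist[ok][first]
        hits = []
        for gpos, d in zip(keep, dist):
            ti = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
            local = int(gpos - self.offsets[ti])
            if local + rl > int(self.lengths[ti]):
                continue  # window ran into padding (cannot happen with d<=mm unless mm>=s)
            t = self.transcripts[ti]
            hits.append(
                AlignmentHit(read_id, t.transcript_id, local + 1, int(d), _priority_class(t))
            )
        return hits


class AlignmentQuantifier(BaseEstimator):
    """Alignment-based gene counter with small-RNA routing.

    ``fit`` takes the transcript reference (decoys included); ``transform``
    maps a read set to per-gene counts. Per-read assignments from the last
    transform are kept in ``assignments_`` for audit.

    Parameters
    ----------
    max_mismatch : int or None
        Hamming tolerance; None means ceil(0.15 x read length) per library.
    random_state : int
        Seed for multi-map tie breaking.
    """

    def __init__(self, max_mismatch: int | None = None, random_state: int = 0):
        self.max_mismatch = max_mismatch
        self.random_state = random_state

    def fit(self, transcripts: list[TranscriptRecord], y=None) -> "AlignmentQuantifier":
        self.transcripts_ = list(transcripts)
        self.types_ = {t.transcript_id: t.gene_type for t in transcripts}
        self._searchers: dict[int, _SeededSearch] = {}
        return self

    def _searcher(self, seed_length: int) -> _SeededSearch:
        if seed_length not in self._searchers:
            self._searchers[seed_length] = _SeededSearch(self.transcripts_, seed_length)
        return self._searchers[seed_length]

    def align(self, read) -> list[AlignmentHit]:
        """All hits of one read (complete within max_mismatch)."""
        self._check_fitted()
        seq = read.sequence if hasattr(read, "sequence") else read
        rid = read.read_id if hasattr(read, "read_id") else "read"
        mm = self.max_mismatch
        if mm is None:
            mm = default_max_mismatch(len(seq))
        s = len(seq) // (mm + 1)
        if s < 1:
            return align_read(seq if not hasattr(read, "sequence") else read,
                              self.transcripts_, mm)
        hits = self._searcher(s).hits(seq, rid, mm)
        return hits

    def select(self, reads: ReadSet | list) -> list[AlignmentHit]:
        """Route-and-select one hit per read; drops unalignable reads."""
        self._check_fitted()
        rng = np.random.default_rng(self.random_state)
        selected = []
        for read in reads:
            choice = route_and_select(self.align(read), rng, self.types_)
            if choice is not None:
                selected.append(choice)
        return selected

    def transform(self, reads: ReadSet | list) -> pd.Series:
        """Per-gene counts for one library; stores per-read assignments."""
        selected = self.select(reads)
        self.assignments_ = pd.DataFrame(
            [(h.read_id, h.transcript_id, h.start, h.mismatches) for h in selected],
            columns=["read_id", "transcript_id", "start", "mismatches"],
        )
        counts = count_genes(selected, self.transcripts_)
        genes = sorted({t.gene_id for t in self.transcripts_ if not t.is_decoy})
        return counts.reindex(genes, fill_value=0).astype(int)

    def fit_transform(self, transcripts, reads) -> pd.Series:
        return self.fit(transcripts).transform(reads)

    def _check_fitted(self) -> None:
        if not hasattr(self, "transcripts_"):
            raise AttributeError("AlignmentQuantifier is not fitted; call fit(transcripts) first")
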