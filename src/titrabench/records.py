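"""Core domain records: transcripts, the titration design, reads, equivalence classes.

These are the units the whole benchmark moves around: a :class:`TranscriptRecord`
is simulated, indexed and quantified; a :class:`TitrationDesign` fixes the
MAQC-style mixing scheme (samples C and D are 3:1 and 1:3 mass mixtures of
reference samples A and B) together with the spike-in ratio groups and the
total-signal ratio ``z`` from which the expected C/D fold-change model derives
its constants ``k1 = 3z/(3z+1)`` and ``k2 = z/(z+3)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GENE_TYPES = ("protein_coding", "ERCC", "tRNA", "snoRNA", "rRNA", "other_ncRNA")

_DNA = frozenset("ACGT")

#: length bounds enforced per gene type (nt)
TRNA_LENGTH_RANGE = (60, 100)
ERCC_LENGTH_RANGE = (250, 2000)


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript: sequence, gene assignment, type and modification sites.

    Parameters
    ----------
    transcript_id, gene_id : str
        A transcript belongs to exactly one gene; several transcripts may
        share a gene (isoforms).
    gene_type : str
        One of :data:`GENE_TYPES`.
    sequence : str
        Sense-strand DNA over ``{A, C, G, T}``.
    modification_positions : tuple of int
        1-based, strictly increasing positions of modified bases (tRNA
        misincorporation sites); empty for unmodified transcripts.
    anticodon : str, optional
        Only meaningful for tRNA records; used for isoacceptor aggregation.
    is_decoy : bool
        Haplotype/patch analogue: present in the alignment reference but
        carrying no abundance and emitting no reads.
    """

    transcript_id: str
    gene_id: str
    gene_type: str
    sequence: str
    modification_positions: tuple[int, ...] = ()
    anticodon: str | None = None
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if self.gene_type not in GENE_TYPES:
            raise ValueError(f"unknown gene_type {self.gene_type!r}")
        if not self.sequence or set(self.sequence) - _DNA:
            raise ValueError(
                f"{self.transcript_id}: sequence must be a nonempty string over A/C/G/T"
            )
        L = len(self.sequence)
        pos = self.modification_positions
        if any(p < 1 or p > L for p in pos):
            raise ValueError(f"{self.transcript_id}: modification position outside [1, {L}]")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"{self.transcript_id}: modification positions must strictly increase")
        if self.gene_type == "tRNA" and not self.is_decoy:
            lo, hi = TRNA_LENGTH_RANGE
            if not lo <= L <= hi:
                raise ValueError(f"{self.transcript_id}: tRNA length {L} outside [{lo}, {hi}]")
        if self.gene_type == "ERCC" and not self.is_decoy:
            lo, hi = ERCC_LENGTH_RANGE
            if not lo <= L <= hi:
                raise ValueError(f"{self.transcript_id}: ERCC length {L} outside [{lo}, {hi}]")
        if self.anticodon is not None and self.gene_type != "tRNA":
            raise ValueError(f"{self.transcript_id}: anticodon only allowed on tRNA records")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def effective_length(self, read_length: int) -> int:
        """Number of valid read start positions: ``max(L - read_length + 1, 1)``."""
        return max(self.length - read_length + 1, 1)


#: designed A:B molar ratios of the four spike-in groups (0.67:1, 1:1, 1:2, 1:4)
DEFAULT_ERCC_GROUPS: dict[str, float] = {
    "0.67:1": 2.0 / 3.0,
    "1:1": 1.0,
    "1:2": 0.5,
    "1:4": 0.25,
}


@dataclass(frozen=True)
class TitrationDesign:
    """MAQC-style titration design and the expected fold-change model constants.

    ``z`` is the total-signal ratio of sample A to sample B per unit mass.
    Samples C and D are mass mixtures of A and B with weights ``ratio_CA_CB``
    and ``ratio_DA_DB`` (3:1 and 1:3 by default), which makes the C/D fold
    change of every gene a deterministic function of its A/B fold change:

        log2(C/D) = log2(k1*r + (1-k1)) - log2(k2*r + (1-k2)),

    with r the A/B ratio on the TPM scale, k1 = 3z/(3z+1) and k2 = z/(z+3).
    """

    z: float = 1.43
    ratio_CA_CB: tuple[float, float] = (3.0, 1.0)
    ratio_DA_DB: tuple[float, float] = (1.0, 3.0)
    ercc_groups: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ERCC_GROUPS)
    )
    ercc_group_size: int = 23

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("z must be positive")
        if self.ercc_group_size < 1:
            raise ValueError("ercc_group_size must be a positive integer")
        if any(r <= 0 for r in self.ercc_groups.values()):
            raise ValueError("designed ERCC ratios must be positive")

    @property
    def k1(self) -> float:
        return 3.0 * self.z / (3.0 * self.z + 1.0)

    @property
    def k2(self) -> float:
        return self.z / (self.z + 3.0)

    def is_de_group(self, label: str) -> bool:
        """Truth label: a group is differentially expressed iff its ratio != 1."""
        return self.ercc_groups[label] != 1.0

    def to_dict(self) -> dict:
        return {
            "z": self.z,
            "ratio_CA_CB": list(self.ratio_CA_CB),
            "ratio_DA_DB": list(self.ratio_DA_DB),
            "ercc_groups": dict(self.ercc_groups),
            "ercc_group_size": self.ercc_group_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TitrationDesign":
        return cls(
            z=d["z"],
            ratio_CA_CB=tuple(d["ratio_CA_CB"]),
            ratio_DA_DB=tuple(d["ratio_DA_DB"]),
            ercc_groups=dict(d["ercc_groups"]),
            ercc_group_size=d["ercc_group_size"],
        )


@dataclass(frozen=True)
class SimulatedRead:
    """A single simulated read with its ground truth.

    ``errors`` lists (1-based position within the read, cause) pairs, cause
    being ``"modification"`` or ``"sequencing"``.
    """

    read_id: str
    sequence: str
    true_transcript_id: str
    true_start: int  # 1-based on the source transcript
    errors: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for pos, cause in self.errors:
            if not 1 <= pos <= n:
                raise ValueError(f"{self.read_id}: error position {pos} outside [1, {n}]")
            if cause not in ("modification", "sequencing"):
                raise ValueError(f"{self.read_id}: unknown error cause {cause!r}")


@dataclass
class ReadSet:
    """A simulated library: reads plus the nominal read length."""

    reads: list[SimulatedRead]
    read_length: int

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


@dataclass
class EquivalenceClassCounts:
    """Read counts grouped by transcript-compatibility set.

    Reads whose k-mer compatibility set is empty are tracked in
    ``unassigned`` rather than as a class.
    """

    counts: dict[frozenset, int] = field(default_factory=dict)
    unassigned: int = 0

    def __post_init__(self) -> None:
        for key, n in self.counts.items():
            if not key:
                raise ValueError("equivalence class keys must be nonempty transcript sets")
            if n <= 0:
                raise ValueError("equivalence class counts must be positive")
        if self.unassigned < 0:
            raise ValueError("unassigned count cannot be negative")

    @property
    def total(self) -> int:
        """Total number of reads = assigned + unassigned."""
        return sum(self.counts.values()) + self.unassigned
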