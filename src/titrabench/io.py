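"""File formats: transcriptome FASTA, simulated-read FASTQ, design JSON.

FASTA headers encode the gene map as ``transcript_id|gene_id|gene_type`` with
an optional fourth ``|anticodon`` field on tRNA records and a trailing
``|decoy`` marker on decoy records, so a transcriptome file round-trips
without a sidecar annotation.
"""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO

from .records import ReadSet, SimulatedRead, TitrationDesign, TranscriptRecord


def write_fasta(transcripts: list[TranscriptRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fields = [t.transcript_id, t.gene_id, t.gene_type]
            if t.anticodon is not None:
                fields.append(t.anticodon)
            if t.is_decoy:
                fields.append("decoy")
            header = "|".join(fields)
            if t.modification_positions:
                header += " mods=" + ",".join(str(p) for p in t.modification_positions)
            fh.write(f">{header}\n")
            for i in range(0, len(t.sequence), width):
                fh.write(t.sequence[i : i + width] + "\n")


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        if len(fields) < 3:
            raise ValueError(f"FASTA header {rec.id!r} lacks transcript|gene|type fields")
        tid, gid, gtype = fields[:3]
        rest = fields[3:]
        is_decoy = "decoy" in rest
        anticodon = next((f for f in rest if f != "decoy"), None)
        mods: tuple[int, ...] = ()
        for token in rec.description.split():
            if token.startswith("mods="):
                mods = tuple(int(p) for p in token[5:].split(","))
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=gid,
                gene_type=gtype,
                sequence=str(rec.seq).upper(),
                modification_positions=mods,
                anticodon=anticodon,
                is_decoy=is_decoy,
            )
        )
    return records


def write_fastq(reads: ReadSet, path: str | Path) -> None:
    """Phred-33 FASTQ with constant quality 'I' (Q40)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Return (read_id, sequence) pairs; ground truth is not in the file."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((rec.id, str(rec.seq).upper()))
    return out


def reads_from_fastq(path: str | Path, read_length: int | None = None) -> ReadSet:
    """Load a FASTQ as a ReadSet with unknown ground truth (for the CLI)."""
    pairs = read_fastq(path)
    rl = read_length or (max(len(s) for _, s in pairs) if pairs else 0)
    reads = [
        SimulatedRead(read_id=rid, sequence=seq, true_transcript_id="?", true_start=1)
        for rid, seq in pairs
    ]
    return ReadSet(reads=reads, read_length=rl)


def write_design(design: TitrationDesign, path: str | Path, extra: dict | None = None) -> None:
    payload = design.to_dict()
    if extra:
        payload = {**payload, **extra}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_design(path: str | Path) -> TitrationDesign:
    with open(path) as fh:
        return TitrationDesign.from_dict(json.load(fh))
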