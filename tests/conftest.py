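"""Shared fixtures: a default simulated experiment and small helpers."""

from __future__ import annotations

import numpy as np
import pytest

import titrabench as tb


@pytest.fixture(scope="session")
def default_transcripts():
    return tb.build_transcriptome(tb.GeneratorConfig(), seed=1)


@pytest.fixture(scope="session")
def design():
    return tb.TitrationDesign()


@pytest.fixture(scope="session")
def ercc_assignment(default_transcripts, design):
    ercc = [t for t in default_transcripts if t.gene_type == "ERCC"]
    return tb.assign_ercc_design(ercc, design, seed=2)


@pytest.fixture(scope="session")
def abcd_table(default_transcripts, design, ercc_assignment):
    ab = tb.make_ab_abundances(default_transcripts, design, ercc_assignment, seed=3)
    return tb.mix_titration(ab, design)


@pytest.fixture(scope="session")
def true_tpm(abcd_table):
    return tb.to_tpm(abcd_table)


def make_transcript(
    tid="T1",
    gene="G1",
    gtype="protein_coding",
    length=200,
    seed=0,
    mods=(),
    anticodon=None,
):
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
    return tb.TranscriptRecord(tid, gene, gtype, seq, tuple(mods), anticodon)
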