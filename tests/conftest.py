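"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import pandas as pd
import pytest

from phoscycle.reference_db import (
    GeneDatabase,
    MultipleAlignment,
    ProteinRecord,
    ResidueRule,
)


def make_record(seq_id, sequence, gene="pepM", genome_id=None, tax_class=""):
    return ProteinRecord(
        seq_id=seq_id,
        gene=gene,
        genome_id=genome_id or f"genome_{seq_id}",
        taxonomy=("Bacteria", "", tax_class, "", "", "", ""),
        sequence=sequence,
    )


def make_alignment(rows: dict[str, str], gene="pepM") -> MultipleAlignment:
    return MultipleAlignment(
        records=[make_record(sid, seq, gene=gene) for sid, seq in rows.items()]
    )


def make_db(rows, gene="pepM") -> GeneDatabase:
    """rows: iterable of (seq_id, sequence, genome_id)."""
    return GeneDatabase(
        gene=gene,
        records=[make_record(sid, seq, gene=gene, genome_id=gid) for sid, seq, gid in rows],
    )


def make_rule(ref_seq_id, ref_position, allowed, gene="pepM"):
    return ResidueRule(
        gene=gene, ref_seq_id=ref_seq_id, ref_position=ref_position,
        allowed=frozenset(allowed),
    )


@pytest.fixture
def toy_presence() -> pd.DataFrame:
    """Five genomes, three genes, with hand-countable overlaps."""
    return pd.DataFrame(
        {
            "pepM": [1, 1, 1, 0, 0],
            "aepY": [1, 1, 0, 1, 0],
            "phpC": [1, 0, 0, 0, 1],
        },
        index=[f"g{i}" for i in range(5)],
        dtype=bool,
    )
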