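"""Shared fixtures: tiny alignments and population maps, all generated
programmatically (no stored data files)."""
from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from phylopop import Alignment, PopulationMap


@pytest.fixture
def micro_aln() -> Alignment:
    """The four-sequence worked example (S=3, PI=1, pi=10/24)."""
    return Alignment(
        ids=("s1", "s2", "s3", "s4"),
        seqs=("AAAA", "AAAT", "AATT", "ATTT"),
    )


@pytest.fixture
def two_pop_fixed():
    """Two populations each fixed for a distinct haplotype."""
    aln = Alignment(
        ids=("a1", "a2", "a3", "b1", "b2", "b3"),
        seqs=("AAAAACCCCC", "AAAAACCCCC", "AAAAACCCCC",
              "AAAAGCCCCT", "AAAAGCCCCT", "AAAAGCCCCT"),
    )
    pm = PopulationMap(
        {s: ("A" if s.startswith("a") else "B") for s in aln.ids},
        {"A": "west", "B": "east"},
        {"A": (10.0, 100.0), "B": (20.0, 110.0)},
    )
    return aln, pm


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records: dict[str, str], name: str = "aln.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for sid, seq in records.items():
                fh.write(f">{sid}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def write_popmap(tmp_path):
    def _write(rows, name: str = "popmap.csv", delim: str = ","):
        path = tmp_path / name
        header = delim.join(["sample", "population", "region", "lat", "lon"])
        lines = [header] + [delim.join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


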