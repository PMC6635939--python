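"""Alignment / population-map input, validation, and site summaries.

All downstream statistics consume the two core containers defined here:
:class:`Alignment` (equal-length uppercase IUPAC nucleotide strings) and
:class:`PopulationMap` (sample -> population -> region assignment plus site
coordinates in decimal degrees).
"""
from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, ConsistencyError, InputError

log = logging.getLogger("phylopop.io")

#: Permitted alignment symbols: unambiguous bases, IUPAC ambiguity codes, gap.
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")
#: Unambiguous nucleotide states used by distance and site statistics.
UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class Alignment:
    """An aligned set of nucleotide sequences.

    Invariants: unique ids, all sequences the same length >= 1, alphabet
    restricted to :data:`IUPAC_ALPHABET`.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs must have the same length")
        if not self.ids:
            raise InputError("alignment is empty")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise InputError(f"duplicate sequence ids: {dupes}")
        k = len(self.seqs[0])
        if k < 1:
            raise AlignmentError("alignment length must be >= 1")
        for sid, seq in zip(self.ids, self.seqs):
            if len(seq) != k:
                raise AlignmentError(
                    f"ragged alignment: sequence {sid!r} has length "
                    f"{len(seq)}, expected {k}"
                )
            bad = set(seq) - IUPAC_ALPHABET
            if bad:
                raise AlignmentError(
                    f"sequence {sid!r} contains invalid symbols {sorted(bad)}"
                )

    @property
    def n(self) -> int:
        """Number of sequences."""
        return len(self.ids)

    @property
    def length(self) -> int:
        """Number of aligned sites (k)."""
        return len(self.seqs[0])

    def sequence(self, sample_id: str) -> str:
        try:
            return self.seqs[self.ids.index(sample_id)]
        except ValueError:
            raise KeyError(sample_id) from None

    def subset(self, ids: Iterable[str]) -> "Alignment":
        """Restrict to the given sample ids (order preserved as given)."""
        wanted = list(ids)
        index = {sid: i for i, sid in enumerate(self.ids)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise ConsistencyError(f"ids not in alignment: {missing}")
        return Alignment(
            ids=tuple(wanted),
            seqs=tuple(self.seqs[index[s]] for s in wanted),
        )

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=sid, description="")
            for sid, seq in zip(self.ids, self.seqs)
        ]
        SeqIO.write(records, str(path), "fasta")


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Sequences are uppercased. Raises :class:`InputError` on empty files or
    duplicate ids, :class:`AlignmentError` on ragged lengths or bad symbols.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    aln = Alignment(ids=ids, seqs=seqs)
    log.info("read %d sequences of length %d from %s", aln.n, aln.length, path)
    return aln


@dataclass(frozen=True)
class PopulationMap:
    """Sample -> population and population -> (region, coordinates) mapping."""

    sample_to_population: Mapping[str, str]
    population_to_region: Mapping[str, str]
    coordinates: Mapping[str, tuple[float, float]]  # population -> (lat, lon)

    def __post_init__(self) -> None:
        if not self.sample_to_population:
            raise InputError("population map has no samples")
        pops = set(self.sample_to_population.values())
        missing = pops - set(self.population_to_region)
        if missing:
            raise InputError(f"populations without region: {sorted(missing)}")
        for pop, (lat, lon) in self.coordinates.items():
            if not (-90.0 <= lat <= 90.0):
                raise InputError(f"latitude out of range for {pop}: {lat}")
            if not (-180.0 <= lon <= 180.0):
                raise InputError(f"longitude out of range for {pop}: {lon}")

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.sample_to_population)

    @property
    def populations(self) -> tuple[str, ...]:
        """Populations in order of first appearance."""
        seen: dict[str, None] = {}
        for pop in self.sample_to_population.values():
            seen.setdefault(pop)
        return tuple(seen)

    @property
    def regions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for pop in self.populations:
            seen.setdefault(self.population_to_region[pop])
        return tuple(seen)

    def population_of(self, sample: str) -> str:
        return self.sample_to_population[sample]

    def region_of(self, sample: str) -> str:
        return self.population_to_region[self.sample_to_population[sample]]

    def samples_in(self, population: str) -> tuple[str, ...]:
        return tuple(
            s for s, p in self.sample_to_population.items() if p == population
        )

    def labels_for(self, ids: Iterable[str], level: str = "population") -> list[str]:
        """Group label per sample id at ``level`` ("population" | "region")."""
        if level == "population":
            return [self.population_of(s) for s in ids]
        if level == "region":
            return [self.region_of(s) for s in ids]
        raise InputError(f"unknown level: {level!r}")

    def validate_against(self, aln: Alignment) -> None:
        missing = [s for s in aln.ids if s not in self.sample_to_population]
        if missing:
            raise ConsistencyError(
                f"{len(missing)} alignment ids missing from population map, "
                f"e.g. {missing[:5]}"
            )


def read_population_map(path: str | Path) -> PopulationMap:
    """Read a delimited population table.

    Expected header: ``sample,population,region,lat,lon``; the delimiter
    (comma or tab) is auto-detected from the header line.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    text = path.read_text()
    header = text.splitlines()[0] if text.strip() else ""
    delim = "\t" if "\t" in header else ","
    reader = csv.DictReader(text.splitlines(), delimiter=delim)
    required = {"sample", "population", "region", "lat", "lon"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise InputError(
            f"population map must have columns {sorted(required)}, "
            f"got {reader.fieldnames}"
        )
    sample_to_pop: dict[str, str] = {}
    pop_to_region: dict[str, str] = {}
    coords: dict[str, tuple[float, float]] = {}
    for row in reader:
        sample = row["sample"].strip()
        pop = row["population"].strip()
        region = row["region"].strip()
        if sample in sample_to_pop:
            raise InputError(f"duplicate sample in population map: {sample!r}")
        try:
            lat, lon = float(row["lat"]), float(row["lon"])
        except ValueError as exc:
            raise InputError(f"bad coordinates for sample {sample!r}") from exc
        if pop in pop_to_region and pop_to_region[pop] != region:
            raise InputError(f"population {pop!r} assigned to two regions")
        sample_to_pop[sample] = pop
        pop_to_region[pop] = region
        coords[pop] = (lat, lon)
    return PopulationMap(sample_to_pop, pop_to_region, coords)


@dataclass(frozen=True)
class SiteSummary:
    """Counts of polymorphic (S) and parsimony-informative (PI) sites."""

    segregating: int
    parsimony_informative: int
    variable_columns: tuple[int, ...]  # 1-based column indices

    def __post_init__(self) -> None:
        assert 0 <= self.parsimony_informative <= self.segregating

    def to_dict(self) -> dict:
        return {
            "segregating_sites": self.segregating,
            "parsimony_informative_sites": self.parsimony_informative,
            "variable_columns": list(self.variable_columns),
        }


def site_summary(aln: Alignment) -> SiteSummary:
    """Count segregating and parsimony-informative columns.

    A column is segregating when >= 2 distinct unambiguous bases occur in it;
    variation carried only by ambiguity codes or gaps does not count. It is
    parsimony informative when >= 2 distinct bases are each carried by >= 2
    sequences.
    """
    s = 0
    pi = 0
    variable: list[int] = []
    for col in range(aln.length):
        counts: dict[str, int] = {}
        for seq in aln.seqs:
            base = seq[col]
            if base in UNAMBIGUOUS:
                counts[base] = counts.get(base, 0) + 1
        if len(counts) >= 2:
            s += 1
            variable.append(col + 1)
            if sum(1 for c in counts.values() if c >= 2) >= 2:
                pi += 1
    return SiteSummary(s, pi, tuple(variable))


def write_json(obj, path: str | Path) -> None:
    """Serialize a result object (anything with ``to_dict``) as stable JSON."""
    data = obj.to_dict() if hasattr(obj, "to_dict") else obj
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
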