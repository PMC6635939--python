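"""Bundled desk-scale dataset: the published COI haplotype survey of the
Masson pine moth (Dendrolimus punctatus) across 23 Chinese populations.

Only printed summary data are stored here (per-population haplotype
frequencies, sample sizes, coordinates) - no sequences. The region split
assigns the 10 westernmost populations (by longitude) to "Western" and the
remaining 13 to "Eastern", matching the described two-refugium geography.
"""
from __future__ import annotations

from dataclasses import dataclass

from .haplotypes import HaplotypeCatalog
from .io import PopulationMap


@dataclass(frozen=True)
class PopulationRecord:
    abbr: str
    lat: float
    lon: float
    n: int
    haplotype_counts: dict[str, int]


_SURVEY: tuple[PopulationRecord, ...] = (
    PopulationRecord("GXLC", 22.19, 110.16, 6, {"H6": 2, "H11": 2, "H13": 1, "H18": 1}),
    PopulationRecord("GXNN", 22.49, 108.21, 12, {"H14": 8, "H15": 2, "H16": 1, "H17": 1}),
    PopulationRecord("GDDQ", 23.15, 111.77, 8, {"H11": 3, "H22": 2, "H23": 1, "H24": 1, "H25": 1}),
    PopulationRecord("YNWS", 23.22, 104.15, 6, {"H1": 1, "H2": 3, "H3": 1, "H4": 1}),
    PopulationRecord("GXBS", 23.53, 106.37, 10, {"H46": 1, "H47": 5, "H48": 4}),
    PopulationRecord("GDXN", 24.15, 115.73, 4, {"H2": 2, "H7": 2}),
    PopulationRecord("YNSL", 24.45, 103.16, 6, {"H2": 4, "H41": 2}),
    PopulationRecord("FJSH", 25.02, 116.25, 9, {"H38": 5, "H39": 1, "H40": 3}),
    PopulationRecord("GZXY", 25.05, 104.54, 5, {"H6": 1, "H19": 3, "H20": 1}),
    PopulationRecord("FJWP", 25.10, 116.10, 11, {"H11": 3, "H18": 2, "H22": 3, "H35": 1, "H36": 1, "H37": 1}),
    PopulationRecord("GXQZ", 25.55, 111.04, 20, {"H5": 1, "H6": 2, "H8": 8, "H9": 2, "H10": 1, "H11": 4, "H12": 1, "H13": 1}),
    PopulationRecord("YNYR", 26.03, 101.40, 12, {"H4": 3, "H5": 1, "H6": 7, "H7": 1}),
    PopulationRecord("GZGY", 26.38, 106.37, 8, {"H5": 1, "H6": 3, "H18": 1, "H19": 3}),
    PopulationRecord("GZHZ", 27.07, 104.43, 7, {"H6": 3, "H11": 3, "H21": 1}),
    PopulationRecord("JXYC", 27.47, 114.23, 12, {"H5": 1, "H6": 1, "H22": 4, "H23": 4, "H45": 2}),
    PopulationRecord("JXGA", 28.25, 115.22, 11, {"H2": 4, "H3": 1, "H41": 2, "H42": 2, "H43": 1, "H44": 1}),
    PopulationRecord("ZJJS", 28.44, 118.37, 10, {"H27": 3, "H28": 2, "H29": 4, "H30": 1}),
    PopulationRecord("ZJQX", 29.03, 119.11, 11, {"H1": 1, "H2": 6, "H3": 3, "H26": 1}),
    PopulationRecord("ZJLX", 29.12, 119.28, 9, {"H11": 2, "H18": 1, "H31": 3, "H32": 1, "H33": 1, "H34": 1}),
    PopulationRecord("SCLX", 29.15, 105.38, 4, {"H2": 4}),
    PopulationRecord("SCHY", 30.38, 106.77, 8, {"H6": 3, "H9": 1, "H22": 2, "H23": 1, "H37": 1}),
    PopulationRecord("AHQS", 30.57, 116.34, 12, {"H2": 10, "H3": 1, "H46": 1}),
    PopulationRecord("HBCD", 40.59, 118.53, 35, {"H49": 15, "H50": 8, "H51": 12}),
)

#: Number of populations assigned to the western (southwest-refugium) group.
_N_WESTERN = 10


def coi_survey() -> tuple[PopulationRecord, ...]:
    """All 23 population records (N = 236 individuals, 51 haplotypes)."""
    return _SURVEY


def region_of(abbr: str) -> str:
    """"Western" for the 10 westernmost populations, else "Eastern"."""
    western = {
        r.abbr for r in sorted(_SURVEY, key=lambda r: r.lon)[:_N_WESTERN]
    }
    return "Western" if abbr in western else "Eastern"


def coi_haplotype_catalog() -> HaplotypeCatalog:
    """Haplotype catalog built from the printed per-population counts."""
    ordered: dict[str, dict[str, int]] = {
        r.abbr: dict(r.haplotype_counts) for r in _SURVEY
    }
    cat = HaplotypeCatalog.from_counts(ordered)
    # relabel into H1..H51 numeric order for readability
    order = sorted(range(cat.n_haplotypes), key=lambda i: int(cat.labels[i][1:]))
    return HaplotypeCatalog(
        labels=tuple(cat.labels[i] for i in order),
        populations=cat.populations,
        counts=cat.counts[:, order],
    )


def coi_population_map() -> PopulationMap:
    """Population map with synthetic per-individual sample ids."""
    sample_to_pop: dict[str, str] = {}
    pop_to_region: dict[str, str] = {}
    coords: dict[str, tuple[float, float]] = {}
    for rec in _SURVEY:
        for i in range(rec.n):
            sample_to_pop[f"{rec.abbr}_{i + 1:02d}"] = rec.abbr
        pop_to_region[rec.abbr] = region_of(rec.abbr)
        coords[rec.abbr] = (rec.lat, rec.lon)
    return PopulationMap(sample_to_pop, pop_to_region, coords)
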