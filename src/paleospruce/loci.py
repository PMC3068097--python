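"""Chloroplast locus definitions for the eight-fragment spruce cpDNA panel.

The panel comprises eight short amplicons (CK, MD, B, D, TL, Li, LF, K2i)
spanning pseudogene, intergenic-spacer, microsatellite and intron regions.
Each locus carries its variable positions in two coordinate frames: 1-based
fragment-local positions and 1-based positions in the fixed-order
concatenation of all eight loci.

The concatenated frame reserves the maximal aligned width for the
length-variable microsatellite fragment B (a 196-bp invariant flank plus a
20-column repeat-block frame), so all concatenated coordinates are stable
regardless of which repeat-length allele a sample carries.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

LOCUS_ORDER = ("CK", "MD", "B", "D", "TL", "Li", "LF", "K2i")

REGION_KINDS = {"pseudogene", "intergenic_spacer", "microsatellite", "intron"}


@dataclass(frozen=True)
class LocusDef:
    """One cpDNA region of the amplicon panel.

    Parameters
    ----------
    name : locus identifier (CK, MD, B, D, TL, Li, LF or K2i for the
        default panel; user panels may add others).
    region_kind : one of ``pseudogene``, ``intergenic_spacer``,
        ``microsatellite``, ``intron``.
    expected_length_bp : approximate PCR product length in bases.
    variable_positions : strictly increasing 1-based fragment-local
        positions of the polymorphic sites (for a microsatellite this
        includes every column of the aligned repeat-block frame).
    concat_positions : the same sites in the concatenated coordinate frame.
    aligned_length : width of this locus in the gapped alignment frame
        (equals ``expected_length_bp`` except for length-variable
        microsatellites).
    repeat_region : 1-based fragment-local (start, end) of the aligned
        repeat-block frame, if any.
    """

    name: str
    region_kind: str
    expected_length_bp: int
    variable_positions: tuple[int, ...] = ()
    concat_positions: tuple[int, ...] = ()
    aligned_length: int | None = None
    repeat_region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.expected_length_bp <= 0:
            raise ValueError(f"{self.name}: expected_length_bp must be positive")
        if self.region_kind not in REGION_KINDS:
            raise ValueError(f"{self.name}: unknown region kind {self.region_kind!r}")
        if list(self.variable_positions) != sorted(set(self.variable_positions)):
            raise ValueError(f"{self.name}: variable positions must be strictly increasing")
        if self.concat_positions and len(self.concat_positions) != len(
            self.variable_positions
        ):
            raise ValueError(f"{self.name}: coordinate frames differ in length")
        # Length-variant microsatellite alleles may run past the nominal
        # product length by a few bases.
        slack = 4 if self.is_microsatellite else 0
        if self.variable_positions and self.variable_positions[-1] > self.frame_length + slack:
            raise ValueError(
                f"{self.name}: variable position {self.variable_positions[-1]} "
                f"outside fragment of length {self.frame_length}"
            )
        if self.aligned_length is None:
            object.__setattr__(self, "aligned_length", self.expected_length_bp)

    @property
    def is_microsatellite(self) -> bool:
        return self.region_kind == "microsatellite" and self.repeat_region is not None

    @property
    def frame_length(self) -> int:
        return self.aligned_length or self.expected_length_bp


def _span(start: int, end: int) -> tuple[int, ...]:
    return tuple(range(start, end + 1))


#: Default locus panel. Variable positions follow the published
#: per-fragment coordinates; concatenated coordinates are cumulative
#: offsets over the aligned frame (CK 136 | MD 200 | B 216 | D 124 |
#: TL 251 | Li 237 | LF 186 | K2i 204 = 1554 columns).
DEFAULT_LOCI: dict[str, LocusDef] = {
    "CK": LocusDef("CK", "pseudogene", 136),
    "MD": LocusDef("MD", "intergenic_spacer", 200),
    "B": LocusDef(
        "B",
        "microsatellite",
        212,
        variable_positions=(88,) + _span(107, 126),
        concat_positions=(424,) + _span(443, 462),
        aligned_length=216,
        repeat_region=(107, 126),
    ),
    "D": LocusDef(
        "D",
        "microsatellite",
        124,
        variable_positions=(77, 78, 82),
        concat_positions=(629, 630, 634),
    ),
    "TL": LocusDef(
        "TL",
        "intergenic_spacer",
        251,
        variable_positions=(168, 196, 197, 206),
        concat_positions=(844, 872, 873, 882),
    ),
    "Li": LocusDef(
        "Li",
        "intron",
        237,
        variable_positions=(154, 157),
        concat_positions=(1081, 1084),
    ),
    "LF": LocusDef(
        "LF",
        "intergenic_spacer",
        186,
        variable_positions=(115, 133),
        concat_positions=(1279, 1297),
    ),
    "K2i": LocusDef(
        "K2i",
        "intron",
        204,
        variable_positions=(114,),
        concat_positions=(1464,),
    ),
}

#: Total width of the concatenated alignment frame.
CONCAT_FRAME_LENGTH = sum(DEFAULT_LOCI[name].frame_length for name in LOCUS_ORDER)


def concat_offset(locus: str, loci: Mapping[str, LocusDef] | None = None) -> int:
    """0-based offset of a locus within the concatenated frame."""
    loci = loci or DEFAULT_LOCI
    offset = 0
    for name in LOCUS_ORDER:
        if name == locus:
            return offset
        if name in loci:
            offset += loci[name].frame_length
    raise KeyError(f"unknown locus {locus!r}")


def write_locus_table(loci: Iterable[LocusDef], path: str | Path) -> None:
    """Write locus definitions as TSV (name, kind, expected length, sites)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["name", "region_kind", "expected_length_bp", "variable_positions"])
        for locus in loci:
            w.writerow(
                [
                    locus.name,
                    locus.region_kind,
                    locus.expected_length_bp,
                    ",".join(map(str, locus.variable_positions)),
                ]
            )


def read_locus_table(path: str | Path) -> dict[str, LocusDef]:
    """Read a locus-definition TSV written by :func:`write_locus_table`."""
    out: dict[str, LocusDef] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            positions = tuple(
                int(x) for x in row["variable_positions"].split(",") if x.strip()
            )
            out[row["name"]] = LocusDef(
                row["name"],
                row["region_kind"],
                int(row["expected_length_bp"]),
                variable_positions=positions,
            )
    return out
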