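"""Packaged haplotype-table fixture for the spruce cpDNA panel.

Encodes the published haplotype table: nine extant concatenated haplotypes
(Ht1-Ht9, n = 58 individuals) over the six polymorphic loci, and the sparse
per-fragment ancient sequences recovered from an 11,000-year-old cone
(cone scales + seeds) and 10,700-year-old pollen grains.

Only the states at the variable positions are published; the invariant
backbone of each fragment is a seeded SYNTHETIC placeholder sequence (no
statistic in this package depends on invariant sites, only on their
count). Known internal inconsistencies of the published table are surfaced
in ``Table1Fixture.metadata`` rather than silently corrected.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .haplotypes import Haplotype, HaplotypeTable
from .loci import DEFAULT_LOCI, LOCUS_ORDER, LocusDef, concat_offset
from .repeats import RepeatBlock, align_repeat_blocks
from .seqio import SequenceRecord, concatenate_fragments

# Extant haplotypes: states per locus in panel order. Fragment B carries a
# point substitution at position 88 plus a length-variable repeat block;
# the remaining loci carry point substitutions only (D: 77/78/82,
# TL: 168/196/197/206, Li: 154/157, LF: 115/133, K2i: 114). CK and MD are
# monomorphic. Counts are reconstructed as round(freq x 58).
_EXTANT = [
    # id,  B88, B block,             D,     TL,     Li,   LF,   K2i, count, freq, printed length
    ("Ht1", "C", "12A + 5G", "AAC", "GTCG", "TC", "TT", "C", 6, 0.103, 1551),
    ("Ht2", "C", "11A + 6G", "AAC", "GTCG", "TC", "AT", "C", 15, 0.259, 1551),
    ("Ht3", "C", "11A + 6G", "CAC", "GTCG", "TC", "AT", "C", 6, 0.103, 1551),
    ("Ht4", "C", "10A + 6G", "AAC", "GTCG", "TA", "AT", "T", 1, 0.017, 1550),
    ("Ht5", "C", "13A + 5G", "AAC", "GTCG", "TC", "AT", "C", 2, 0.034, 1552),
    ("Ht6", "C", "12A + 5G", "CAC", "GTCG", "TC", "AT", "C", 2, 0.034, 1551),
    ("Ht7", "C", "10A + 6G", "AAC", "GTCG", "TC", "AT", "C", 1, 0.017, 1550),
    ("Ht8", "C", "12A + 5G", "AAC", "GTCG", "TC", "AT", "C", 22, 0.379, 1551),
    ("Ht9", "T", "12A + 4G + 3A + G", "ACT", "GTAG", "CC", "AG", "C", 1, 0.017, 1554),
]

# Ancient per-fragment rows. A locus mapping to "" means the fragment was
# amplified but is monomorphic (CK, MD); fragment B states are
# (position-88 base, repeat-block notation). P13's TL states are the
# OBSERVED reads (A at 168 and 206); the published table prints the
# damage-corrected states (see metadata).
_ANCIENT: list[tuple[str, str, dict, int]] = [
    ("Cone", "cone_scale", {"CK": "", "D": "CAC", "TL": "GTCG", "LF": "AT", "K2i": "C"}, 901),
    ("S3", "seed", {"D": "AAC"}, 124),
    ("S4", "seed", {"Li": "TA"}, 237),
    ("S8", "seed", {"MD": "", "D": "CAC", "TL": "GTCG"}, 575),
    ("S9", "seed", {"CK": "", "B": ("C", "10A + 7G"), "TL": "GTCG", "LF": "AT", "K2i": "C"}, 990),
    ("S10", "seed", {"MD": "", "D": "AAC", "TL": "GTAG", "Li": "TC", "K2i": "C"}, 1016),
    ("S502", "seed", {"B": ("C", "12A + 5G")}, 211),
    ("S545", "seed", {"B": ("C", "12A + 5G")}, 211),
    ("P1", "pollen", {"B": ("C", "10A + 6G")}, 212),
    ("P2", "pollen", {"D": "CAC"}, 124),
    ("P3", "pollen", {"D": "CAC"}, 124),
    *[(f"P{i}", "pollen", {"TL": "GTCG"}, 251) for i in range(4, 12)],
    ("P12", "pollen", {"TL": "GTAG"}, 251),
    ("P13", "pollen", {"TL": "AGAA"}, 251),
    ("P14", "pollen", {"CK": ""}, 136),
    ("P15", "pollen", {"CK": ""}, 136),
    ("P16", "pollen", {"MD": ""}, 200),
    ("P17", "pollen", {"MD": ""}, 200),
]

# The cone was additionally typed at Li (reconstructed: the ancient Li
# sample comprises three sequences in two classes, and a cone-vs-seed
# transversion at Li position 157 is reported). Kept out of the cone's
# fragment set so its printed concatenated length (901 bp over five
# regions) still checks out.
_CONE_LI_STATES = "TC"

_ALL_B_BLOCKS = [
    "12A + 5G", "11A + 6G", "10A + 6G", "13A + 5G", "12A + 4G + 3A + G", "10A + 7G",
]

TOTAL_N = 58


def _aligned_b_blocks() -> dict[str, str]:
    """Map block notation -> 20-column gapped alignment (fixed study frame)."""
    blocks = [RepeatBlock.from_notation(t) for t in _ALL_B_BLOCKS]
    width = DEFAULT_LOCI["B"].repeat_region[1] - DEFAULT_LOCI["B"].repeat_region[0] + 1
    aligned = align_repeat_blocks(blocks, frame_width=width)
    return dict(zip(_ALL_B_BLOCKS, aligned))


_B_ALIGNED = _aligned_b_blocks()


def _backbone(locus: LocusDef) -> str:
    """Deterministic synthetic invariant sequence for one locus frame."""
    rng = np.random.default_rng(zlib.crc32(locus.name.encode()) % 2**31)
    return "".join(rng.choice(list("ACGT"), size=locus.frame_length))


_BACKBONES = {name: _backbone(DEFAULT_LOCI[name]) for name in LOCUS_ORDER}


def build_locus_sequence(
    locus_name: str,
    site_states: Mapping[int, str] | None = None,
    block_notation: str | None = None,
) -> str:
    """Aligned fragment sequence: synthetic backbone + given variable states."""
    locus = DEFAULT_LOCI[locus_name]
    seq = list(_BACKBONES[locus_name])
    if locus.repeat_region is not None:
        if block_notation is None:
            raise ValueError(f"{locus_name}: repeat-block allele required")
        start, end = locus.repeat_region
        aligned = _B_ALIGNED.get(block_notation)
        if aligned is None:
            aligned = align_repeat_blocks(
                [RepeatBlock.from_notation(block_notation)], frame_width=end - start + 1
            )[0]
        seq[start - 1 : end] = list(aligned)
    for pos, base in (site_states or {}).items():
        seq[pos - 1] = base
    return "".join(seq)


def _fragment(sample_id, population, source, locus_name, states) -> SequenceRecord:
    locus = DEFAULT_LOCI[locus_name]
    if locus_name == "B":
        b88, block = states
        bases = build_locus_sequence("B", {88: b88}, block)
    else:
        point_positions = locus.variable_positions
        site_states = dict(zip(point_positions, states)) if states else {}
        bases = build_locus_sequence(locus_name, site_states)
    return SequenceRecord(sample_id, population, source, locus, bases)


@dataclass
class Table1Fixture:
    """The packaged haplotype-table fixture.

    Attributes
    ----------
    extant_table : published 9-haplotype table (n=58, printed frequencies).
    extant_records : 56 reconstructed extant individuals, concatenated over
        the full 8-locus frame.
    extant_by_locus : the same individuals restricted to single fragments.
    ancient_by_locus : ancient per-fragment sequence sets (observed states).
    ancient_fragments : per-sample fragment lists, as printed.
    printed_lengths : published per-row concatenated lengths.
    metadata : notes on published-table inconsistencies.
    """

    extant_table: HaplotypeTable
    extant_records: list[SequenceRecord]
    extant_by_locus: dict[str, list[SequenceRecord]]
    ancient_by_locus: dict[str, list[SequenceRecord]]
    ancient_fragments: dict[str, list[SequenceRecord]]
    printed_lengths: dict[str, int]
    metadata: dict


def load_table1_fixture() -> Table1Fixture:
    """Build the packaged extant/ancient haplotype fixture."""
    # --- extant haplotype table over concatenated coordinates -------------
    positions = tuple(
        p for name in ("B", "D", "TL", "Li", "LF", "K2i")
        for p in DEFAULT_LOCI[name].concat_positions
    )
    haplotypes = []
    for hid, b88, block, d, tl, li, lf, k2i, count, freq, _len in _EXTANT:
        states = (b88,) + tuple(_B_ALIGNED[block]) + tuple(d + tl + li + lf + k2i)
        haplotypes.append(Haplotype(hid, states, count, freq))
    extant_table = HaplotypeTable(positions, haplotypes, TOTAL_N)

    # --- expand to individual records -------------------------------------
    extant_records: list[SequenceRecord] = []
    extant_by_locus: dict[str, list[SequenceRecord]] = {n: [] for n in LOCUS_ORDER}
    printed_lengths: dict[str, int] = {}
    for hid, b88, block, d, tl, li, lf, k2i, count, _freq, plen in _EXTANT:
        printed_lengths[hid] = plen
        per_locus_states = {
            "CK": "", "MD": "", "B": (b88, block), "D": d, "TL": tl,
            "Li": li, "LF": lf, "K2i": k2i,
        }
        for i in range(count):
            sid = f"{hid}_{i + 1:02d}"
            frags = [
                _fragment(sid, "extant", "needle", name, per_locus_states[name])
                for name in LOCUS_ORDER
            ]
            for frag in frags:
                extant_by_locus[frag.locus.name].append(frag)
            extant_records.append(concatenate_fragments(frags))

    # --- ancient per-fragment records --------------------------------------
    ancient_by_locus: dict[str, list[SequenceRecord]] = {n: [] for n in LOCUS_ORDER}
    ancient_fragments: dict[str, list[SequenceRecord]] = {}
    for sid, source, locus_states, plen in _ANCIENT:
        printed_lengths.setdefault(sid, plen)
        frags = [
            _fragment(sid, "ancient", source, name, st)
            for name, st in locus_states.items()
        ]
        ancient_fragments[sid] = frags
        for frag in frags:
            ancient_by_locus[frag.locus.name].append(frag)
    # reconstructed cone Li typing participates in per-locus analyses only
    ancient_by_locus["Li"].append(
        _fragment("Cone", "ancient", "cone_scale", "Li", _CONE_LI_STATES)
    )

    metadata = {
        "total_n": TOTAL_N,
        "effective_n": sum(h.count for h in haplotypes),
        "count_discrepancy": (
            "published relative frequencies on n=58 imply integer counts "
            "summing to 56; the two untyped individuals are unidentifiable"
        ),
        "cone_li_reconstructed": (
            "the cone's Li typing (states T,C) is reconstructed from the "
            "reported three-sequence {2,1} ancient Li sample and the "
            "cone-vs-seed transversion at Li 157; it is excluded from the "
            "cone's printed 901-bp five-region concatenation"
        ),
        "cone_region_count": (
            "the published text says four cone regions but the printed row "
            "populates five (CK+D+TL+LF+K2i = 901 bp); the fixture follows "
            "the lengths"
        ),
        "p13_observed_tl": "AGAA",
        "p13_corrected_tl": "GGAG",
        "p13_note": (
            "P13 TL stores the observed reads (A at 168/206); the published "
            "table prints the damage-corrected states G at 168/206"
        ),
        "length_discrepancies": {
            "S502": (211, 213),
            "S545": (211, 213),
        },
        "length_note": (
            "S502/S545 print 211 bp although a 12A+5G fragment-B allele "
            "implies 213 bp under the 196-bp invariant flank consistent "
            "with every other printed length"
        ),
    }
    return Table1Fixture(
        extant_table,
        extant_records,
        extant_by_locus,
        ancient_by_locus,
        ancient_fragments,
        printed_lengths,
        metadata,
    )


def century_old_reference_b_records() -> list[SequenceRecord]:
    """Two century-old herbarium-era pollen reference sequences, fragment B.

    SYNTHETIC stand-ins: the originals are not deposited; they are reported
    to group with the most common extant repeat-block allele, so they carry
    the 12A + 5G block.
    """
    return [
        _fragment(f"R{i}", "herbarium", "pollen", "B", ("C", "12A + 5G"))
        for i in (1, 2)
    ]
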