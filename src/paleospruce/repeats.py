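"""Run-length ("repeat block") encoding of chloroplast microsatellite alleles.

Mononucleotide-repeat alleles are conventionally reported as run-length
blocks such as ``12A + 5G`` (twelve adenines followed by five guanines).
This module round-trips that notation and aligns length-variant blocks into
a fixed-width gapped frame so that downstream statistics can treat gaps as
fifth-state characters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

_BASES = set("ACGT")
_RUN_RE = re.compile(r"^\s*(\d+)\s*([ACGT])\s*$")


@dataclass(frozen=True)
class RepeatBlock:
    """An ordered list of (run_length, base) homopolymer runs.

    ``RepeatBlock.from_notation("12A + 5G")`` parses the conventional
    notation; ``decode()`` expands back to the raw sequence.
    """

    runs: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("repeat block must contain at least one run")
        for length, base in self.runs:
            if length < 1:
                raise ValueError(f"run length must be positive, got {length}")
            if base not in _BASES:
                raise ValueError(f"illegal base {base!r} in repeat block")

    def __len__(self) -> int:
        return sum(length for length, _ in self.runs)

    def decode(self) -> str:
        """Expand to the raw base string (e.g. 2A+1G -> 'AAG')."""
        return "".join(base * length for length, base in self.runs)

    @property
    def notation(self) -> str:
        """Human-readable block notation, e.g. ``12A + 5G``."""
        return " + ".join(
            f"{length}{base}" if length > 1 else base for length, base in self.runs
        )

    @classmethod
    def from_notation(cls, text: str) -> "RepeatBlock":
        """Parse notation like ``12A + 4G + 3A + G`` (bare base = run of 1)."""
        runs: list[tuple[int, str]] = []
        for part in text.split("+"):
            part = part.strip()
            m = _RUN_RE.match(part)
            if m:
                runs.append((int(m.group(1)), m.group(2)))
            elif part in _BASES:
                runs.append((1, part))
            else:
                raise ValueError(f"cannot parse repeat-block term {part!r}")
        return cls(tuple(runs))


def encode_repeat_block(seq: str) -> RepeatBlock:
    """Maximal run-length encoding of a gap-free A/C/G/T string.

    Raises ``ValueError`` on empty input or on gaps/ambiguity codes: a
    microsatellite block must be fully resolved before encoding.
    """
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    bad = set(seq) - _BASES
    if bad:
        raise ValueError(
            f"repeat block contains non-ACGT characters {sorted(bad)}; "
            "resolve gaps/Ns before encoding"
        )
    runs: list[tuple[int, str]] = []
    for base in seq:
        if runs and runs[-1][1] == base:
            runs[-1] = (runs[-1][0] + 1, base)
        else:
            runs.append((1, base))
    return RepeatBlock(tuple(runs))


def decode_repeat_block(block: RepeatBlock) -> str:
    return block.decode()


def align_repeat_blocks(
    blocks: Sequence[RepeatBlock], frame_width: int | None = None
) -> list[str]:
    """Align length-variant repeat blocks into a common gapped frame.

    Blocks sharing the canonical two-run structure (an A-run followed by a
    G-run, the common spruce cpDNA microsatellite motif) are aligned
    left-flush *within each homopolymer run*: every A-run is padded with
    gaps to the widest A-run, then every G-run likewise, so a one-repeat
    length change costs exactly one fifth-state difference. Blocks with any
    other run structure (rare rearranged alleles) are laid out literally,
    left-flush in the full frame.

    ``frame_width`` forces the total aligned width (padded with trailing
    gaps); by default the minimal width accommodating all blocks is used.
    """
    if not blocks:
        raise ValueError("no repeat blocks to align")
    canonical = [
        b for b in blocks if len(b.runs) == 2 and b.runs[0][1] == "A" and b.runs[1][1] == "G"
    ]
    if canonical:
        a_width = max(b.runs[0][0] for b in canonical)
        g_width = max(b.runs[1][0] for b in canonical)
    else:
        a_width = g_width = 0
    zone_width = a_width + g_width
    literal_width = max((len(b) for b in blocks if b not in canonical), default=0)
    width = max(zone_width, literal_width)
    if frame_width is not None:
        if frame_width < width:
            raise ValueError(
                f"frame width {frame_width} too narrow for blocks needing {width}"
            )
        width = frame_width

    aligned = []
    for b in blocks:
        if b in canonical:
            a_len, g_len = b.runs[0][0], b.runs[1][0]
            s = (
                "A" * a_len
                + "-" * (a_width - a_len)
                + "G" * g_len
                + "-" * (g_width - g_len)
            )
        else:
            s = b.decode()
        aligned.append(s + "-" * (width - len(s)))
    return aligned


def stepwise_distance(a: RepeatBlock, b: RepeatBlock) -> int:
    """Stepwise-mutation distance: summed |run-length difference| over runs.

    Defined for blocks with the same run structure (same bases in the same
    order); rearranged alleles fall back to the fifth-state character
    distance of their literal alignment.
    """
    if len(a.runs) == len(b.runs) and all(
        ra[1] == rb[1] for ra, rb in zip(a.runs, b.runs)
    ):
        return sum(abs(ra[0] - rb[0]) for ra, rb in zip(a.runs, b.runs))
    sa, sb = align_repeat_blocks([a, b])
    return sum(1 for x, y in zip(sa, sb) if x != y)
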