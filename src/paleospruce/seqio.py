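"""Sequence records and FASTA I/O.

Records are per-sample, per-locus aligned fragments over the alphabet
``A C G T - N`` (gap ``-`` is a fifth character state; ``N`` marks untyped
sites). FASTA headers carry the sample metadata as four pipe-delimited
fields: ``sample_id|population|source|locus``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .loci import DEFAULT_LOCI, LOCUS_ORDER, LocusDef

ALPHABET = set("ACGTN-")
POPULATIONS = {"ancient", "extant", "herbarium"}
SOURCES = {"pollen", "seed", "cone_scale", "needle"}


class FastaParseError(ValueError):
    """Malformed FASTA entry (header or body)."""


@dataclass
class SequenceRecord:
    """One aligned sequence fragment (or concatenation) for one sample.

    ``locus`` is ``None`` for multi-locus concatenations, in which case
    ``segments`` maps each constituent locus name to its 1-based inclusive
    (start, end) span within ``bases``.
    """

    sample_id: str
    population: str
    source: str
    locus: LocusDef | None
    bases: str
    segments: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(
                f"{self.sample_id}: unknown population {self.population!r} "
                f"(expected one of {sorted(POPULATIONS)})"
            )
        if self.source not in SOURCES:
            raise ValueError(
                f"{self.sample_id}: unknown source {self.source!r} "
                f"(expected one of {sorted(SOURCES)})"
            )
        for i, ch in enumerate(self.bases):
            if ch not in ALPHABET:
                raise ValueError(
                    f"{self.sample_id}: illegal character {ch!r} at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def ungapped_length(self) -> int:
        """Number of real bases (alignment gaps excluded)."""
        return len(self.bases) - self.bases.count("-")

    def states_at(self, positions: Sequence[int]) -> tuple[str, ...]:
        """States at 1-based positions."""
        return tuple(self.bases[p - 1] for p in positions)

    def covers(self, locus: LocusDef | None = None) -> bool:
        """True if every variable position of the locus is typed (non-N)."""
        locus = locus or self.locus
        if locus is None:
            raise ValueError("no locus to check coverage against")
        return all(s != "N" for s in self.states_at(locus.variable_positions))


def read_fasta(
    path: str | Path, loci: Mapping[str, LocusDef] | None = None
) -> list[SequenceRecord]:
    """Read pipe-annotated FASTA into :class:`SequenceRecord` objects.

    Headers must be exactly ``sample_id|population|source|locus``; extra
    or missing fields are rejected rather than silently dropped. The locus
    field may be ``-`` for concatenated records.
    """
    loci = loci if loci is not None else DEFAULT_LOCI
    out: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        fields = entry.description.split("|")
        if len(fields) != 4:
            raise FastaParseError(
                f"entry {entry.description!r}: expected 4 pipe-delimited header "
                f"fields (sample_id|population|source|locus), got {len(fields)}"
            )
        sample_id, population, source, locus_name = (f.strip() for f in fields)
        if locus_name == "-":
            locus = None
        elif locus_name in loci:
            locus = loci[locus_name]
        else:
            raise FastaParseError(
                f"entry {sample_id!r}: unknown locus {locus_name!r}"
            )
        try:
            out.append(
                SequenceRecord(sample_id, population, source, locus, str(entry.seq).upper())
            )
        except ValueError as exc:
            raise FastaParseError(str(exc)) from exc
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA with pipe-delimited metadata headers."""
    entries = []
    for r in records:
        name = r.locus.name if r.locus is not None else "-"
        header = f"{r.sample_id}|{r.population}|{r.source}|{name}"
        entries.append(_BioRecord(Seq(r.bases), id=header, description=""))
    SeqIO.write(entries, str(path), "fasta")


def concatenate_fragments(
    records: Sequence[SequenceRecord],
    locus_order: Sequence[str] = LOCUS_ORDER,
) -> SequenceRecord:
    """Join one sample's per-locus fragments in the fixed panel order.

    Absent loci are skipped (the concatenated length is the sum of the
    present aligned fragment lengths); the mapping back to fragment-local
    coordinates is retained in ``segments``. Two fragments for the same
    locus are a conflict, not a choice.
    """
    if not records:
        raise ValueError("empty sample: no fragments to concatenate")
    sample_ids = {r.sample_id for r in records}
    if len(sample_ids) != 1:
        raise ValueError(f"fragments from multiple samples: {sorted(sample_ids)}")
    by_locus: dict[str, SequenceRecord] = {}
    for r in records:
        if r.locus is None:
            raise ValueError(f"{r.sample_id}: cannot concatenate a concatenation")
        if r.locus.name in by_locus:
            raise ValueError(
                f"{r.sample_id}: two records for locus {r.locus.name}"
            )
        by_locus[r.locus.name] = r
    unknown = set(by_locus) - set(locus_order)
    if unknown:
        raise ValueError(f"loci not in concatenation order: {sorted(unknown)}")

    parts: list[str] = []
    segments: dict[str, tuple[int, int]] = {}
    pos = 0
    for name in locus_order:
        if name not in by_locus:
            continue
        frag = by_locus[name]
        parts.append(frag.bases)
        segments[name] = (pos + 1, pos + len(frag.bases))
        pos += len(frag.bases)
    first = records[0]
    return SequenceRecord(
        first.sample_id, first.population, first.source, None, "".join(parts), segments
    )
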