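"""Haplotype tables: collapsing aligned records into state-vector classes."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .loci import LocusDef
from .seqio import SequenceRecord


@dataclass(frozen=True)
class Haplotype:
    """One haplotype class: its state vector, count and relative frequency."""

    haplotype_id: str
    states: tuple[str, ...]
    count: int
    frequency: float


@dataclass
class HaplotypeTable:
    """Haplotype state vectors at a set of variable positions.

    ``n`` is the total sample size the frequencies refer to; counts may sum
    to less than ``n`` (missing individuals), never more.
    """

    positions: tuple[int, ...]
    haplotypes: list[Haplotype]
    n: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(h.count for h in self.haplotypes)
        if total > self.n:
            raise ValueError(f"counts sum to {total} > sample size n={self.n}")
        seen = set()
        for h in self.haplotypes:
            if h.states in seen:
                raise ValueError(f"duplicate state vector {h.states}")
            seen.add(h.states)
            if abs(h.frequency - h.count / self.n) > 1e-3:
                raise ValueError(
                    f"{h.haplotype_id}: frequency {h.frequency} inconsistent "
                    f"with count {h.count}/{self.n}"
                )

    @property
    def counts(self) -> list[int]:
        return [h.count for h in self.haplotypes]

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def __getitem__(self, haplotype_id: str) -> Haplotype:
        for h in self.haplotypes:
            if h.haplotype_id == haplotype_id:
                return h
        raise KeyError(haplotype_id)


def collapse_haplotypes(
    records: Sequence[SequenceRecord],
    positions: Sequence[int] | None = None,
    id_prefix: str = "H",
) -> HaplotypeTable:
    """Group records by identical state vectors at the variable positions.

    All records must type every position (heterogeneous coverage is an
    error listing the uncovered positions per record). When ``positions``
    is omitted, the records' shared locus supplies them; records with no
    variable positions (a monomorphic locus) collapse on the full sequence.
    Output ordering is deterministic: descending count, then lexicographic
    state vector; IDs are ``H1, H2, ...``.
    """
    if not records:
        raise ValueError("no records to collapse")
    if positions is None:
        loci = {r.locus.name if r.locus else None for r in records}
        if len(loci) != 1 or None in loci:
            raise ValueError(
                "records span multiple or concatenated loci; pass positions explicitly"
            )
        locus: LocusDef = records[0].locus  # type: ignore[assignment]
        positions = locus.variable_positions or tuple(
            range(1, min(len(r.bases) for r in records) + 1)
        )
    positions = tuple(positions)

    uncovered: dict[str, list[int]] = {}
    for r in records:
        missing = [p for p in positions if p > len(r.bases) or r.bases[p - 1] == "N"]
        if missing:
            uncovered[r.sample_id] = missing
    if uncovered:
        detail = "; ".join(f"{s}: positions {m}" for s, m in sorted(uncovered.items()))
        raise ValueError(f"records do not cover all variable positions ({detail})")

    groups: dict[tuple[str, ...], int] = {}
    for r in records:
        states = r.states_at(positions)
        groups[states] = groups.get(states, 0) + 1

    n = len(records)
    ordered = sorted(groups.items(), key=lambda kv: (-kv[1], kv[0]))
    haplotypes = [
        Haplotype(f"{id_prefix}{i + 1}", states, count, count / n)
        for i, (states, count) in enumerate(ordered)
    ]
    return HaplotypeTable(positions, haplotypes, n)


def write_haplotype_table(table: HaplotypeTable, path: str | Path) -> None:
    """TSV export: haplotype_id, one column per position, count, rel_freq."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["haplotype_id"]
            + [f"pos_{p}" for p in table.positions]
            + ["count", "rel_freq"]
        )
        for h in table.haplotypes:
            w.writerow([h.haplotype_id, *h.states, h.count, f"{h.frequency:.4f}"])


def read_haplotype_table(path: str | Path, n: int | None = None) -> HaplotypeTable:
    """Read a TSV written by :func:`write_haplotype_table`."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    header = rows[0]
    positions = tuple(int(c.removeprefix("pos_")) for c in header[1:-2])
    haplotypes = []
    total = 0
    for row in rows[1:]:
        count = int(row[-2])
        total += count
        haplotypes.append(
            Haplotype(row[0], tuple(row[1 : 1 + len(positions)]), count, float(row[-1]))
        )
    return HaplotypeTable(positions, haplotypes, n if n is not None else total)
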