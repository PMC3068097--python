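"""Post-mortem damage screening for ancient cpDNA fragments.

Cytosine deamination in degraded DNA templates produces apparent C→T (and,
read from the opposite strand, G→A) transition substitutions. Against a
reference panel of extant sequences, mismatches in ancient reads are
classified as transitions (putative damage) or transversions (accepted as
authentic); flagged sites can be reverted to the reference state, masked,
or merely annotated.

The rule is deliberately conservative and cannot distinguish an authentic
transition polymorphism from a lesion; the report therefore quantifies how
many flagged sites were transitions segregating in the reference panel
itself (candidate authentic variants) rather than hiding them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

from .haplotypes import collapse_haplotypes
from .seqio import SequenceRecord

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

Policy = Literal["revert", "mask", "keep"]


@dataclass(frozen=True)
class SubstitutionCall:
    """One compared site in an ancient read versus the panel reference."""

    sample_id: str
    locus: str
    position: int  # 1-based, fragment-local
    ref_base: str
    obs_base: str
    klass: str  # transition | transversion | match | gap_event
    verdict: str  # putative_damage | authentic | match
    action: str = "none"  # reverted | masked | none


def classify_substitution(ref_base: str, obs_base: str) -> str:
    """Classify a base pair as transition/transversion/match/gap_event."""
    allowed = PURINES | PYRIMIDINES | {"-"}
    for b in (ref_base, obs_base):
        if b not in allowed:
            raise ValueError(f"cannot classify base {b!r}")
    if ref_base == obs_base:
        return "match"
    if "-" in (ref_base, obs_base):
        return "gap_event"
    if {ref_base, obs_base} in ({"A", "G"}, {"C", "T"}):
        return "transition"
    return "transversion"


@dataclass
class DamageReport:
    """All substitution calls plus the corrected sequence set."""

    calls: list[SubstitutionCall]
    corrected: list[SequenceRecord]
    policy: Policy

    @property
    def n_corrected_sites(self) -> int:
        return sum(1 for c in self.calls if c.action in ("reverted", "masked"))

    def calls_for(self, sample_id: str) -> list[SubstitutionCall]:
        return [c for c in self.calls if c.sample_id == sample_id]

    def flagged(self) -> list[SubstitutionCall]:
        return [c for c in self.calls if c.verdict == "putative_damage"]

    def ambiguous_authentic_candidates(self) -> list[SubstitutionCall]:
        """Flagged transitions whose observed state segregates in the panel.

        The damage rule cannot tell these apart from genuine transition
        polymorphism; they are reported, never silently dropped.
        """
        return [c for c in self.calls if c.verdict == "putative_damage" and
                c.action.endswith("(panel-segregating)")]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([c.__dict__ for c in self.calls])


def panel_reference(
    panel: Sequence[SequenceRecord], positions: Sequence[int] | None = None
) -> dict[int, str]:
    """Majority reference state per position from an extant panel.

    Ties are broken toward the state of the panel's most frequent
    haplotype (itself resolved deterministically by the collapse order).
    """
    if not panel:
        raise ValueError("empty reference panel")
    if positions is None:
        positions = range(1, len(panel[0].bases) + 1)
    table = collapse_haplotypes(panel, positions=positions)
    modal = dict(zip(positions, table.haplotypes[0].states))
    ref: dict[int, str] = {}
    for pos in positions:
        counts = Counter(r.bases[pos - 1] for r in panel if r.bases[pos - 1] != "N")
        if not counts:
            raise ValueError(f"no typed panel state at position {pos}")
        top = max(counts.values())
        leaders = sorted(b for b, c in counts.items() if c == top)
        ref[pos] = modal[pos] if modal[pos] in leaders else leaders[0]
    return ref


def filter_damage(
    ancient: Sequence[SequenceRecord],
    panel_by_locus: Mapping[str, Sequence[SequenceRecord]],
    policy: Policy = "revert",
) -> DamageReport:
    """Screen ancient records for deamination-type transitions.

    Every position of each ancient record (lesions can strike any C/G
    site, not only the known variable ones) is compared with the majority
    state of the extant panel for that locus. Transitions in ancient
    records are flagged as putative damage and — depending on ``policy`` —
    reverted to the reference base, masked to ``N``, or left untouched.
    Transversions and gap events are never altered.
    """
    calls: list[SubstitutionCall] = []
    corrected: list[SequenceRecord] = []
    ref_cache: dict[str, dict[int, str]] = {}
    for rec in ancient:
        if rec.locus is None:
            raise ValueError(f"{rec.sample_id}: damage filter needs per-locus records")
        locus = rec.locus
        if locus.name not in panel_by_locus or not panel_by_locus[locus.name]:
            raise ValueError(f"no reference panel for locus {locus.name}")
        panel = list(panel_by_locus[locus.name])
        positions = tuple(range(1, len(rec.bases) + 1))
        if locus.name not in ref_cache:
            ref_cache[locus.name] = panel_reference(panel, positions)
        ref = ref_cache[locus.name]
        bases = list(rec.bases)
        for pos in positions:
            obs = rec.bases[pos - 1]
            if obs == "N":
                continue
            klass = classify_substitution(ref[pos], obs)
            if klass == "match":
                verdict, action = "match", "none"
            elif klass == "transition" and rec.population == "ancient":
                verdict = "putative_damage"
                segregating = any(
                    p.bases[pos - 1] == obs for p in panel
                )
                if policy == "revert":
                    bases[pos - 1] = ref[pos]
                    action = "reverted"
                elif policy == "mask":
                    bases[pos - 1] = "N"
                    action = "masked"
                else:
                    action = "none"
                if segregating:
                    action += " (panel-segregating)"
            else:
                verdict, action = "authentic", "none"
            if klass != "match":
                calls.append(
                    SubstitutionCall(
                        rec.sample_id, locus.name, pos, ref[pos], obs, klass,
                        verdict, action,
                    )
                )
        corrected.append(replace(rec, bases="".join(bases)))
    return DamageReport(calls, corrected, policy)


def write_damage_report(report: DamageReport, path) -> None:
    """TSV export: sample, locus, position, ref, obs, class, verdict, action."""
    report.to_frame().to_csv(path, sep="\t", index=False)


def assign_taxon(
    amplicon: SequenceRecord | str,
    references: Mapping[str, Sequence[SequenceRecord | str]],
    max_mismatch_fraction: float = 0.10,
) -> str:
    """Assign an amplicon to the taxon with the fewest mismatches.

    Fragments are short and primer-anchored, so plain Hamming distance
    after end-trimming to the shorter length is used. Returns
    ``"unassigned"`` when the best and second-best taxa tie or the best
    mismatch fraction exceeds the threshold.
    """
    seq = amplicon.bases if isinstance(amplicon, SequenceRecord) else str(amplicon)
    best: dict[str, float] = {}
    for taxon, refs in references.items():
        if not refs:
            raise ValueError(f"empty reference set for taxon {taxon}")
        fractions = []
        for ref in refs:
            rseq = ref.bases if isinstance(ref, SequenceRecord) else str(ref)
            n = min(len(seq), len(rseq))
            if n == 0:
                raise ValueError("amplicon/reference length incompatible")
            mism = sum(1 for a, b in zip(seq[:n], rseq[:n]) if a != b)
            fractions.append(mism / n)
        best[taxon] = min(fractions)
    ranked = sorted(best.items(), key=lambda kv: (kv[1], kv[0]))
    if ranked[0][1] > max_mismatch_fraction:
        return "unassigned"
    if len(ranked) > 1 and abs(ranked[0][1] - ranked[1][1]) < 1e-12:
        return "unassigned"
    return ranked[0][0]
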