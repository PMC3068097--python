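"""Synthetic-data generators with known ground truth.

Three generators give every pipeline stage a testable input: a forward
haploid Wright–Fisher simulator of chloroplast haplotypes under an
arbitrary population-size trajectory N(t) (cpDNA is paternally inherited
and non-recombining in spruce, so a haploid copy model is exact), a
sediment pollen-count simulator that inverts the PAR computation with
Poisson counting noise, and a post-mortem damage process that injects
C→T/G→A lesions with a truth ledger for filter validation.

The bundled demonstration scenario reproduces the narrative Lateglacial–
Holocene chronology: a small refugial population, a first massive
expansion beginning ~11,100 cal yr BP, bottlenecks around 9180, 7200 and
2200 cal yr BP and a second expansion from ~3900 cal yr BP.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fixtures import load_table1_fixture
from .loci import DEFAULT_LOCI, LOCUS_ORDER, LocusDef, concat_offset
from .par import AgeDepthModel, DensityCalibration, build_age_depth_model, compute_par
from .repeats import RepeatBlock, align_repeat_blocks, encode_repeat_block
from .seqio import SequenceRecord

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass
class SimulationConfig:
    """Wright–Fisher simulation settings.

    ``trajectory`` is the haploid population size per generation (index 0 =
    founding generation); rates are per generation. ``ti_tv_ratio`` is the
    transition:transversion odds for point mutations; ``delta`` the
    per-C/G-site lesion probability used by :func:`apply_damage`;
    ``generation_time_yr`` maps calendar ages onto generations.
    """

    trajectory: np.ndarray
    mu_snp: float = 1e-6
    mu_ms: float = 1e-3
    ti_tv_ratio: float = 2.0
    delta: float = 0.02
    seed: int = 0
    generation_time_yr: float = 25.0

    def __post_init__(self) -> None:
        self.trajectory = np.asarray(self.trajectory, dtype=int)
        if self.trajectory.size < 1 or np.any(self.trajectory < 2):
            raise ValueError("population size must be >= 2 at every generation")
        for name in ("mu_snp", "mu_ms", "delta"):
            rate = getattr(self, name)
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def _founder_pool() -> tuple[list[str], np.ndarray]:
    """Default founders: the nine extant concatenated haplotypes, weighted
    by their published frequencies (refugial standing variation)."""
    fixture = load_table1_fixture()
    seen: dict[str, int] = {}
    for rec in fixture.extant_records:
        seen[rec.bases] = seen.get(rec.bases, 0) + 1
    seqs = sorted(seen)
    weights = np.array([seen[s] for s in seqs], dtype=float)
    return seqs, weights / weights.sum()


def _split_block(seq: str, locus: LocusDef) -> tuple[str, RepeatBlock]:
    off = concat_offset(locus.name)
    start, end = locus.repeat_region
    lo, hi = off + start - 1, off + end
    block = encode_repeat_block(seq[lo:hi].replace("-", ""))
    return seq[:lo] + seq[hi:], block


def simulate_wright_fisher(
    config: SimulationConfig,
    sample_times: Sequence[int],
    sample_sizes: Sequence[int],
    founders: Sequence[str] | None = None,
    founder_weights: Sequence[float] | None = None,
) -> dict[int, dict[str, list[SequenceRecord]]]:
    """Forward haploid Wright–Fisher simulation over the 8-locus frame.

    Each generation every offspring copies a uniformly chosen parent; point
    mutations arrive at rate ``mu_snp`` per site (transition vs
    transversion per ``ti_tv_ratio``), and the fragment-B repeat block
    mutates one random homopolymer run by ±1 repeat with probability
    ``mu_ms`` per individual. ``founders`` are full-frame concatenated
    haplotype strings (default: the packaged extant haplotype pool);
    the founding population is drawn from them by ``founder_weights``.

    Samples (without replacement) are recorded at the requested generation
    indices and returned as per-locus aligned records; the final requested
    time is labelled ``extant``, earlier ones ``ancient``.
    """
    if len(sample_times) != len(sample_sizes):
        raise ValueError("sample_times and sample_sizes differ in length")
    n_gen = config.trajectory.size - 1
    for t, s in zip(sample_times, sample_sizes):
        if not 0 <= t <= n_gen:
            raise ValueError(f"sample time {t} outside simulated range 0..{n_gen}")
        if s > config.trajectory[t]:
            raise ValueError(
                f"sample size {s} exceeds population size {config.trajectory[t]} "
                f"at generation {t}"
            )
    rng = np.random.default_rng(config.seed)
    if founders is None:
        founders, founder_weights = _founder_pool()
    founders = list(founders)
    if founder_weights is None:
        founder_weights = np.full(len(founders), 1 / len(founders))

    b_locus = DEFAULT_LOCI["B"]
    frame_cols = len(founders[0])
    founder_sites, founder_blocks = [], []
    for seq in founders:
        if len(seq) != frame_cols:
            raise ValueError("founder haplotypes must share the aligned frame")
        sites, block = _split_block(seq, b_locus)
        founder_sites.append(np.frombuffer(sites.encode(), dtype="S1").copy())
        founder_blocks.append(block)
    site_cols = founder_sites[0].size

    alleles: list[RepeatBlock] = []
    allele_index: dict[tuple, int] = {}

    def allele_id(block: RepeatBlock) -> int:
        key = block.runs
        if key not in allele_index:
            allele_index[key] = len(alleles)
            alleles.append(block)
        return allele_index[key]

    n0 = int(config.trajectory[0])
    choice = rng.choice(len(founders), size=n0, p=np.asarray(founder_weights))
    pop_sites = np.stack([founder_sites[i] for i in choice])
    pop_block = np.array([allele_id(founder_blocks[i]) for i in choice])

    want = {int(t): int(s) for t, s in zip(sample_times, sample_sizes)}
    last_time = max(want) if want else -1
    out: dict[int, dict[str, list[SequenceRecord]]] = {}

    def mutate(n: int) -> None:
        nonlocal pop_sites, pop_block
        n_mut = rng.poisson(n * site_cols * config.mu_snp)
        for _ in range(n_mut):
            i = rng.integers(n)
            j = rng.integers(site_cols)
            cur = pop_sites[i, j].decode()
            if cur not in "ACGT":
                continue
            p_ts = config.ti_tv_ratio / (config.ti_tv_ratio + 1.0)
            if rng.random() < p_ts:
                new = _TRANSITION[cur]
            else:
                new = _TRANSVERSIONS[cur][rng.integers(2)]
            pop_sites[i, j] = new.encode()
        hits = np.flatnonzero(rng.random(n) < config.mu_ms)
        for i in hits:
            block = alleles[pop_block[i]]
            runs = list(block.runs)
            r = rng.integers(len(runs))
            step = 1 if rng.random() < 0.5 else -1
            length = max(1, runs[r][0] + step)
            runs[r] = (length, runs[r][1])
            pop_block[i] = allele_id(RepeatBlock(tuple(runs)))

    raw_samples: dict[int, tuple[np.ndarray, list[RepeatBlock]]] = {}

    def take_sample(gen: int) -> None:
        k = want[gen]
        idx = rng.choice(pop_sites.shape[0], size=k, replace=False)
        raw_samples[gen] = (
            pop_sites[idx].copy(),
            [alleles[pop_block[i]] for i in idx],
        )

    if 0 in want:
        take_sample(0)
    for gen in range(1, n_gen + 1):
        n_parent = pop_sites.shape[0]
        n_child = int(config.trajectory[gen])
        parents = rng.integers(n_parent, size=n_child)
        pop_sites = pop_sites[parents].copy()
        pop_block = pop_block[parents].copy()
        mutate(n_child)
        if gen in want:
            take_sample(gen)

    # repeat blocks are aligned jointly across all sampled time points so
    # that ancient and extant records live in one common gapped frame
    all_blocks = [b for _, blocks in raw_samples.values() for b in blocks]
    base_width = b_locus.repeat_region[1] - b_locus.repeat_region[0] + 1
    need = max(len(align_repeat_blocks([b])[0]) for b in all_blocks)
    width = max(base_width, need)
    aligned_all = iter(align_repeat_blocks(all_blocks, frame_width=width))
    aligned_by_gen = {
        gen: [next(aligned_all) for _ in blocks]
        for gen, (_, blocks) in raw_samples.items()
    }

    off = concat_offset("B")
    b_start = off + b_locus.repeat_region[0] - 1
    extra = width - base_width
    for gen, (sample_sites, _blocks) in raw_samples.items():
        population = "extant" if gen == last_time else "ancient"
        per_locus: dict[str, list[SequenceRecord]] = {}
        for rank in range(sample_sites.shape[0]):
            sites = sample_sites[rank].tobytes().decode()
            full = sites[:b_start] + aligned_by_gen[gen][rank] + sites[b_start:]
            sid = f"g{gen}_i{rank + 1}"
            pos = 0
            for name in LOCUS_ORDER:
                locus = DEFAULT_LOCI[name]
                w = locus.frame_length + (extra if name == "B" else 0)
                frag = full[pos : pos + w]
                pos += w
                per_locus.setdefault(name, []).append(
                    SequenceRecord(sid, population, "needle", locus, frag)
                )
        out[gen] = per_locus
    return out


def apply_damage(
    records: Sequence[SequenceRecord], delta: float, seed: int | None = None
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Inject post-mortem deamination lesions (C→T and G→A).

    Every C and G site independently converts with probability ``delta``.
    Returns damaged copies plus a truth ledger (sample, locus, position,
    original and lesioned base) for validating the damage filter.
    """
    if not 0 <= delta <= 1:
        raise ValueError("delta must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    damaged, rows = [], []
    for rec in records:
        bases = list(rec.bases)
        for i, b in enumerate(bases):
            if b in "CG" and rng.random() < delta:
                new = "T" if b == "C" else "A"
                bases[i] = new
                rows.append(
                    {
                        "sample_id": rec.sample_id,
                        "locus": rec.locus.name if rec.locus else "-",
                        "position": i + 1,
                        "original": b,
                        "lesion": new,
                    }
                )
        damaged.append(replace(rec, bases="".join(bases)))
    ledger = pd.DataFrame(rows, columns=["sample_id", "locus", "position", "original", "lesion"])
    return damaged, ledger


# ---------------------------------------------------------------------------
# sediment record
# ---------------------------------------------------------------------------

#: Narrative Lateglacial–Holocene PAR chronology (age cal yr BP, PAR in
#: grains cm-2 yr-1): a small lakeshore population with a moderately higher
#: interstadial plateau, a Younger Dryas dip, the first massive expansion
#: from ~11,100 cal yr BP to an early Holocene maximum, bottlenecks with
#: onsets at 9180, 7200 and 2200 cal yr BP and a second expansion from
#: ~3900 cal yr BP.
PAR_NARRATIVE_POINTS: tuple[tuple[float, float], ...] = (
    (15700, 110), (14450, 150), (13600, 160), (12900, 150), (12600, 105),
    (12400, 100), (12000, 135), (11700, 140), (11400, 120), (11250, 95),
    (11100, 95), (10800, 900), (10400, 3500), (10100, 4700), (9600, 4750),
    (9180, 5400), (8900, 3300), (8700, 2300), (8500, 2150), (8000, 2200),
    (7600, 2450), (7200, 2600), (6900, 1600), (6700, 1250), (6300, 1210),
    (5000, 1205), (3900, 1190), (3400, 2100), (2800, 3600), (2200, 5000),
    (1900, 2400), (1700, 1600), (1300, 1480), (800, 1500), (400, 1520),
    (0, 1500),
)

#: Synthetic age–depth control points (depth cm, age cal yr BP): eleven
#: dated horizons spanning a 6-m lake-sediment core, anchored so that the
#: cone horizon (545 cm) dates to 11,000 and the pollen horizon (533 cm)
#: to 10,700 cal yr BP.
AGE_DEPTH_POINTS: tuple[tuple[float, float], ...] = (
    (0, 0), (100, 1800), (200, 3800), (300, 6000), (400, 8200),
    (480, 9900), (533, 10700), (545, 11000), (560, 12500), (580, 14000),
    (600, 15700),
)


def narrative_age_depth_model() -> AgeDepthModel:
    return build_age_depth_model(list(AGE_DEPTH_POINTS))


def narrative_par_trajectory(age_step: float = 50.0) -> pd.DataFrame:
    """The noise-free narrative PAR truth sampled on a uniform age grid."""
    pts = np.array(PAR_NARRATIVE_POINTS, dtype=float)
    ages = np.arange(pts[0, 0], -1.0, -age_step)
    par = np.interp(-ages, -pts[:, 0], pts[:, 1])
    model = narrative_age_depth_model()
    depths = np.interp(ages, model.ages, model.depths)
    return pd.DataFrame({"age_calBP": ages, "depth_cm": depths, "par": par})


def simulate_sediment_record(
    true_par: pd.DataFrame,
    model: AgeDepthModel,
    counting_effort: float = 0.1,
    seed: int | None = None,
    spike_added: float = 5000.0,
    volume_cm3: float = 1.0,
) -> pd.DataFrame:
    """Poisson pollen/spike counts from a true PAR trajectory.

    The true concentration at each depth is PAR divided by the local
    sedimentation rate; counted grains are Poisson with mean concentration
    × volume × effort, and exotic-marker (spike) counts are Poisson with
    mean ``spike_added`` × effort, so the standard concentration estimate
    recovers the truth in expectation.
    """
    if counting_effort <= 0:
        raise ValueError("counting effort must be positive")
    rng = np.random.default_rng(seed)
    depths = true_par["depth_cm"].to_numpy(dtype=float)
    rate = np.atleast_1d(model.sedimentation_rate(depths))
    conc = true_par["par"].to_numpy(dtype=float) / rate
    counts = rng.poisson(conc * volume_cm3 * counting_effort)
    spikes = np.maximum(rng.poisson(spike_added * counting_effort, size=depths.size), 1)
    return pd.DataFrame(
        {
            "depth_cm": depths,
            "pollen_count": counts,
            # the spike fraction counted matches the pollen fraction, so
            # the concentration estimate needs no effort correction
            "spike_count": spikes,
            "spike_added": spike_added * counting_effort,
            "volume_cm3": volume_cm3 * counting_effort,
        }
    )


def recover_par(counts: pd.DataFrame, model: AgeDepthModel) -> pd.DataFrame:
    """Run the estimation path on a simulated (or real) count table."""
    from .par import compute_concentration

    conc = [
        compute_concentration(
            row.pollen_count, row.spike_count, row.spike_added, row.volume_cm3
        )
        for _, row in counts.iterrows()
    ]
    return compute_par(conc, counts["depth_cm"].to_numpy(), model)


# ---------------------------------------------------------------------------
# bundled demonstration scenario
# ---------------------------------------------------------------------------


@dataclass
class NarrativeScenario:
    """End-to-end demo dataset with its ground truth."""

    config: SimulationConfig
    age_depth: AgeDepthModel
    par_truth: pd.DataFrame
    counts: pd.DataFrame
    samples: dict[int, dict[str, list[SequenceRecord]]]
    sample_ages: dict[int, float]
    damage_ledger: pd.DataFrame
    true_bottleneck_onsets: tuple[float, ...] = (9180.0, 7200.0, 2200.0)
    true_expansion_onsets: tuple[float, ...] = (11100.0, 3900.0)


def trajectory_from_par(
    par: np.ndarray,
    calibration: DensityCalibration | None = None,
    area_ha: float = 2.0,
    min_n: int = 8,
) -> np.ndarray:
    """Population-size trajectory N(t) = density(PAR) × forest area."""
    calibration = calibration or DensityCalibration.from_anchors()
    n = np.maximum(np.round(calibration.density(par) * area_ha), min_n)
    return n.astype(int)


def generate_narrative_scenario(seed: int = 0, outdir: str | Path | None = None) -> NarrativeScenario:
    """Bundle the full demonstration dataset.

    PAR trajectory with the narrative event chronology, Wright–Fisher
    haplotype samples at 11,000 / 10,700 cal yr BP ("ancient") and 0 BP
    ("extant") under the PAR-derived population-size trajectory, Poisson
    sediment counts, and deamination damage on the ancient reads. Sized to
    run the whole pipeline in well under a minute.
    """
    model = narrative_age_depth_model()
    truth = narrative_par_trajectory()
    counts = simulate_sediment_record(truth, model, seed=seed)

    gen_time = 25.0
    start_age = truth["age_calBP"].iloc[0]
    gen_ages = np.arange(start_age, -1.0, -gen_time)
    par_per_gen = np.interp(
        -gen_ages, -truth["age_calBP"].to_numpy(), truth["par"].to_numpy()
    )
    config = SimulationConfig(
        trajectory=trajectory_from_par(par_per_gen),
        seed=seed,
        generation_time_yr=gen_time,
    )
    ages_wanted = {11000.0: 6, 10700.0: 10, 0.0: 58}
    gens, sizes, sample_ages = [], [], {}
    for age, size in ages_wanted.items():
        g = int(round((start_age - age) / gen_time))
        gens.append(g)
        sizes.append(size)
        sample_ages[g] = age
    samples = simulate_wright_fisher(config, gens, sizes)

    ledgers = []
    for gen, per_locus in samples.items():
        if sample_ages[gen] == 0.0:
            continue
        for name, recs in per_locus.items():
            sub_seed = zlib.crc32(f"{seed}:{gen}:{name}".encode()) % 2**31
            damaged, ledger = apply_damage(recs, config.delta, seed=sub_seed)
            per_locus[name] = damaged
            ledgers.append(ledger)
    damage_ledger = (
        pd.concat(ledgers, ignore_index=True) if ledgers else pd.DataFrame()
    )

    scenario = NarrativeScenario(
        config, model, truth, counts, samples, sample_ages, damage_ledger
    )
    if outdir is not None:
        _write_scenario(scenario, Path(outdir))
    return scenario


def _write_scenario(sc: NarrativeScenario, outdir: Path) -> None:
    from .seqio import write_fasta

    outdir.mkdir(parents=True, exist_ok=True)
    sc.par_truth.to_csv(outdir / "par_truth.csv", index=False)
    sc.counts.to_csv(outdir / "pollen_counts.csv", index=False)
    pd.DataFrame(AGE_DEPTH_POINTS, columns=["depth_cm", "age_calBP"]).to_csv(
        outdir / "age_depth.csv", index=False
    )
    for gen, per_locus in sc.samples.items():
        label = "extant" if sc.sample_ages[gen] == 0 else f"ancient_{int(sc.sample_ages[gen])}"
        records = [r for recs in per_locus.values() for r in recs]
        write_fasta(records, outdir / f"{label}.fasta")
    if len(sc.damage_ledger):
        sc.damage_ledger.to_csv(outdir / "damage_ledger.csv", index=False)
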