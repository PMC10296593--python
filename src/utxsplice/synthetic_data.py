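"""Ground-truth simulators for every pipeline stage.

Three generators stand in for the study's raw data, each emitting both the
input a downstream stage consumes and a truth table for validation:

* :func:`simulate_reads` — noisy long cDNA amplicon reads drawn from a known
  isoform mixture over the ASR of a synthetic multi-exon gene, with
  independent per-base substitution/insertion/deletion errors and random
  orientation flips (the PCR amplicon has no strand preference);
* :func:`simulate_pulldown` — GFP-vs-control protein intensity matrices with
  planted enriched interactors at chosen stoichiometries and
  intensity-dependent (left-censored) missingness;
* :func:`simulate_peaks` — two-condition peak count tables with planted fold
  changes and low-coverage background regions, Poisson counts, spike-in
  totals per condition.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .gene_model import Exon, ExonModel, parse_pattern
from .interactome import PulldownMatrix

__all__ = [
    "SimulationConfig",
    "MissingLogic",
    "synthetic_gene_model",
    "simulate_reads",
    "write_fastq",
    "simulate_pulldown",
    "simulate_peaks",
    "PEAK_CATEGORIES",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {ord(c): i for i, c in enumerate("ACGT")}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one amplicon-read simulation.

    ``mixture`` maps isoform names (Δ-nomenclature) to fractions summing to
    one.  Error rates are independent per-base probabilities; the 0.3 cap
    keeps them in the regime where exon-presence calling is meaningful.
    ``orientation_flip_prob`` is the probability a read is emitted as the
    reverse complement (0.5 by default: amplicons are double-stranded).
    """

    mixture: Mapping[str, float]
    n_reads: int = 10_000
    sub_rate: float = 0.05
    ins_rate: float = 0.015
    del_rate: float = 0.015
    orientation_flip_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = np.array(list(self.mixture.values()), dtype=float)
        if (fracs < 0).any():
            raise ValueError("mixture fractions must be non-negative")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions sum to {fracs.sum()}, expected 1")
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 0.3:
                raise ValueError(f"{name}={r} outside [0, 0.3]")
        if self.n_reads < 1:
            raise ValueError("n_reads must be positive")


def synthetic_gene_model(
    seed: int = 0,
    n_exons: int = 30,
    asr_range: tuple[int, int] = (12, 17),
    exon_length_range: tuple[int, int] = (90, 180),
    gene_id: str = "GENE",
    chrom: str = "chrSyn",
    strand: str = "+",
    intron_length: int = 200,
) -> ExonModel:
    """A random multi-exon gene model with the ASR marked.

    Defaults mirror the target gene's architecture: 30 exons with exons 12-17
    forming the alternative splicing region, exon lengths drawn uniformly
    from ``exon_length_range`` (the six ASR exons of the real gene span
    roughly 400-900 bp of amplicon).
    """
    rng = np.random.default_rng(seed)
    exons = []
    pos = 0
    for i in range(1, n_exons + 1):
        length = int(rng.integers(exon_length_range[0], exon_length_range[1] + 1))
        seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
        exons.append(Exon(number=i, start=pos, end=pos + length, sequence=seq))
        pos += length + intron_length
    return ExonModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     exons=tuple(exons), asr_range=asr_range)


def _mutate(template: str, rng: np.random.Generator,
            sub_rate: float, ins_rate: float, del_rate: float) -> str:
    """Apply independent per-base substitution/insertion/deletion errors."""
    arr = np.frombuffer(template.encode(), dtype=np.uint8)
    idx = np.array([_BASE_INDEX[b] for b in arr], dtype=np.int64)
    if del_rate > 0:
        idx = idx[rng.random(idx.size) > del_rate]
    if sub_rate > 0 and idx.size:
        hit = rng.random(idx.size) < sub_rate
        # replace with one of the three other bases, uniformly
        idx[hit] = (idx[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    if ins_rate > 0:
        slots = rng.random(idx.size + 1) < ins_rate
        if slots.any():
            positions = np.flatnonzero(slots)
            ins = rng.integers(0, 4, size=positions.size)
            idx = np.insert(idx, positions, ins)
    return _BASES[idx].tobytes().decode()


def simulate_reads(
    model: ExonModel, config: SimulationConfig
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Emit amplicon reads from a known isoform mixture, with a truth table.

    Each read is the concatenation of the included ASR exon sequences (the
    two ASR-flanking anchor exons are always present, as the PCR primers
    guarantee), mutated by the error model and optionally reverse
    complemented.  Returns ``(reads, truth)`` where ``reads`` is a list of
    ``(read_id, sequence)`` and ``truth`` has columns ``read_id``,
    ``true_isoform``, ``flipped``.
    """
    templates: dict[str, str] = {}
    for name in config.mixture:
        included = parse_pattern(name, model)  # raises on unknown names
        anchors = set(model.anchor_exons)
        templates[name] = model.isoform_sequence(included | anchors)
    rng = np.random.default_rng(config.seed)
    names = list(config.mixture)
    fracs = np.array([config.mixture[n] for n in names], dtype=float)
    fracs = fracs / fracs.sum()
    choices = rng.choice(len(names), size=config.n_reads, p=fracs)
    flips = rng.random(config.n_reads) < config.orientation_flip_prob

    reads: list[tuple[str, str]] = []
    truth_rows = []
    for i in range(config.n_reads):
        name = names[choices[i]]
        seq = _mutate(templates[name], rng, config.sub_rate, config.ins_rate, config.del_rate)
        if flips[i]:
            seq = str(Seq(seq).reverse_complement())
        read_id = f"read{i:06d}"
        reads.append((read_id, seq))
        truth_rows.append((read_id, name, bool(flips[i])))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "true_isoform", "flipped"])
    return reads, truth


def write_fastq(reads: Iterable[tuple[str, str]], stream, quality_char: str = "5") -> None:
    """Write reads as FASTQ with a constant quality (Phred+33 '5' = Q20)."""
    for read_id, seq in reads:
        stream.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# pulldown simulation


@dataclass(frozen=True)
class MissingLogic:
    """Intensity-dependent dropout: logistic in the low-intensity tail.

    P(missing | log2 intensity x) = max_rate / (1 + exp((x - midpoint) /
    steepness)).  Models left-censoring at the detection limit, which is what
    the down-shifted-Gaussian imputation assumes.
    """

    midpoint: float = 21.0
    steepness: float = 0.8
    max_rate: float = 0.9

    def dropout_probability(self, x: np.ndarray) -> np.ndarray:
        return self.max_rate / (1.0 + np.exp((np.asarray(x) - self.midpoint) / self.steepness))


def simulate_pulldown(
    n_background: int = 1000,
    planted: Mapping[str, tuple[float, float]] | None = None,
    n_reps_per_group: int = 3,
    missing_logic: MissingLogic | None = None,
    seed: int = 0,
    background_mean: float = 25.0,
    background_spread: float = 2.0,
    replicate_sd: float = 0.3,
    anchor: str = "PAXIP1",
) -> tuple[PulldownMatrix, pd.DataFrame]:
    """GFP-vs-control intensity matrix with planted interactors.

    ``planted`` maps protein id to ``(effect, ibaq_level)``: the log2 LFQ
    enrichment of the GFP group over control, and the linear iBAQ level used
    for stoichiometry (GFP group only; controls get near-zero iBAQ).  The
    default planting is the anchor subunit alone at effect 5 and iBAQ 1.0.
    Background proteins share the same group means (null).  Returns the raw
    (linear-scale) matrix plus a truth table with columns ``protein``,
    ``planted``, ``effect``, ``ibaq_level``.
    """
    if n_reps_per_group < 2:
        raise ValueError("n_reps_per_group must be >= 2")
    if planted is None:
        planted = {anchor: (5.0, 1.0)}
    rng = np.random.default_rng(seed)

    bg_names = [f"BG{i:04d}" for i in range(n_background)]
    names = bg_names + list(planted)
    n = len(names)
    reps_a = [f"GFP_{r + 1}" for r in range(n_reps_per_group)]
    reps_b = [f"control_{r + 1}" for r in range(n_reps_per_group)]

    base = rng.normal(background_mean, background_spread, size=n)
    log2 = np.empty((n, 2 * n_reps_per_group))
    log2[:, :] = base[:, None] + rng.normal(0.0, replicate_sd, size=(n, 2 * n_reps_per_group))
    effects = np.zeros(n)
    for j, (prot, (effect, _)) in enumerate(planted.items(), start=n_background):
        effects[j] = effect
    log2[:, :n_reps_per_group] += effects[:, None]

    if missing_logic is not None:
        p_miss = missing_logic.dropout_probability(log2)
        log2 = np.where(rng.random(log2.shape) < p_miss, np.nan, log2)

    lfq = pd.DataFrame(2.0 ** log2, index=names, columns=reps_a + reps_b)

    # iBAQ layer: planted proteins at their stated level (with replicate noise)
    # in the GFP pulldown, near-zero in controls; background inherits LFQ scale.
    ibaq = pd.DataFrame(
        2.0 ** (log2 - 5.0), index=names, columns=reps_a + reps_b
    )
    for prot, (_, level) in planted.items():
        ibaq.loc[prot, reps_a] = level * (1.0 + rng.normal(0.0, 0.05, size=n_reps_per_group))
        ibaq.loc[prot, reps_b] = 0.0

    flags = pd.DataFrame(
        {
            "is_contaminant": False,
            "is_reverse": False,
            "n_replicates_identified": lfq.notna().sum(axis=1),
        },
        index=names,
    )
    matrix = PulldownMatrix(lfq=lfq, ibaq=ibaq, flags=flags,
                            groups={"GFP": reps_a, "control": reps_b})
    truth = pd.DataFrame(
        {
            "protein": names,
            "planted": [nm in planted for nm in names],
            "effect": effects,
            "ibaq_level": [planted.get(nm, (0.0, np.nan))[1] for nm in names],
        }
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# peak simulation

PEAK_CATEGORIES = ("strongly_down", "mildly_down", "common", "mildly_up", "strongly_up")

# representative signed fold changes well inside each category's interval
_DEFAULT_CATEGORY_FC = {
    "strongly_down": -6.0,
    "mildly_down": -3.0,
    "common": 1.0,
    "mildly_up": 3.0,
    "strongly_up": 6.0,
}


def simulate_peaks(
    n_peaks: int | None = None,
    n_background_regions: int = 1000,
    genome_length: int = 10_000_000,
    condition_effects: Mapping[str, tuple[int, float]] | None = None,
    spikein_totals: tuple[float, float] = (1_000_000.0, 1_000_000.0),
    seed: int = 0,
    base_mean: float = 200.0,
    background_mean: float = 1.0,
    peak_length_center: int = 540,
    peak_length_halfwidth: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-condition peak count table with planted fold-change categories.

    ``condition_effects`` maps each category to ``(count, fc)`` with ``fc``
    in the signed-ratio convention (negative = lower in condition B).  Raw
    counts are Poisson around means chosen so the *spike-in normalized* means
    differ by exactly the planted fold change.  Background regions have
    ``background_mean`` normalized coverage in both conditions.  Returns
    ``(peaks, truth)``; ``peaks`` has columns chrom/start/end/count_a/count_b
    and an ``is_background`` flag, ``truth`` the planted category and fc per
    peak.
    """
    if condition_effects is None:
        condition_effects = {c: (40, _DEFAULT_CATEGORY_FC[c]) for c in PEAK_CATEGORIES}
    unknown = set(condition_effects) - set(PEAK_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown peak categories: {sorted(unknown)}")
    if n_peaks is not None and n_peaks != sum(c for c, _ in condition_effects.values()):
        raise ValueError("n_peaks inconsistent with condition_effects counts")
    rng = np.random.default_rng(seed)
    spike_a, spike_b = spikein_totals
    if spike_a <= 0 or spike_b <= 0:
        raise ValueError("spike-in totals must be positive")
    scale = float(np.sqrt(spike_a * spike_b))  # geometric mean
    factor_a = spike_a / scale
    factor_b = spike_b / scale

    rows, truth_rows = [], []
    i = 0
    for category, (count, fc) in condition_effects.items():
        for _ in range(count):
            mean_a = base_mean * float(rng.lognormal(0.0, 0.2))
            if fc >= 1:
                mean_b = mean_a * fc
            elif fc <= -1:
                mean_b = mean_a / (-fc)
            else:
                raise ValueError(f"fc {fc} invalid: signed-ratio convention needs |fc| >= 1")
            length = int(rng.integers(peak_length_center - peak_length_halfwidth,
                                      peak_length_center + peak_length_halfwidth + 1))
            start = int(rng.integers(0, genome_length - length))
            rows.append(("chrSyn", start, start + length,
                         int(rng.poisson(mean_a * factor_a)),
                         int(rng.poisson(mean_b * factor_b)), False))
            truth_rows.append((f"peak{i:05d}", category, fc))
            i += 1
    for _ in range(n_background_regions):
        length = int(rng.integers(peak_length_center - peak_length_halfwidth,
                                  peak_length_center + peak_length_halfwidth + 1))
        start = int(rng.integers(0, genome_length - length))
        rows.append(("chrSyn", start, start + length,
                     int(rng.poisson(background_mean * factor_a)),
                     int(rng.poisson(background_mean * factor_b)), True))

    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "count_a", "count_b",
                                        "is_background"])
    peaks.index = [f"peak{i:05d}" for i in range(len(peaks))]
    truth = pd.DataFrame(truth_rows, columns=["peak_id", "true_category", "true_fc"])
    return peaks, truth
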