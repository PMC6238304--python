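"""Synthetic cohorts and sequences with the structure the analysis assumes.

Three generators live here:

* ``simulate_population`` draws each sample's two alleles i.i.d. from a
  star-allele frequency vector (Hardy-Weinberg equilibrium), renders the
  assay-level record with hemizygote masking, and optionally injects
  per-locus no-calls and duplication flags.  The default frequency vector
  is the 70-sample Karen cohort estimate (*1 0.214, *2 0.329, *4 0.021,
  *5 0.029, *10 0.400, *36 0.007).
* ``reconstruct_karen_cohort`` deterministically expands the published
  11 diplotype counts (n = 70) into sample records, so every cohort-level
  statistic can be recomputed from printed inputs alone.
* ``mutate_sequence`` produces divergence-controlled mutants of a
  reference sequence for exercising the intron-2 identity classifier.

Sampling uses inverse-CDF draws from a seeded ``numpy`` Generator
(PCG64), making cohorts byte-for-byte reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alleles import AlleleTable, star_sort_key
from .caller import MISSING, SampleRecord, canonical_pair, predict_exon9, predict_genotype

__all__ = [
    "KAREN_DIPLOTYPE_COUNTS",
    "KAREN_ALLELE_FREQS",
    "SimulationConfig",
    "TruthRecord",
    "render_sample",
    "simulate_population",
    "reconstruct_karen_cohort",
    "mutate_sequence",
]

#: Published cohort composition: diplotype -> number of individuals (n = 70).
KAREN_DIPLOTYPE_COUNTS: dict[tuple[str, str], int] = {
    ("*1", "*1"): 3,
    ("*1", "*2"): 8,
    ("*1", "*4"): 3,
    ("*1", "*5"): 2,
    ("*1", "*10"): 10,
    ("*1", "*36"): 1,
    ("*2", "*2"): 7,
    ("*2", "*5"): 1,
    ("*2", "*10"): 23,
    ("*5", "*10"): 1,
    ("*10", "*10"): 11,
}

#: Allele frequencies implied by the counts above (140 allele slots).
KAREN_ALLELE_FREQS: dict[str, float] = {
    "*1": 30 / 140,
    "*2": 46 / 140,
    "*4": 3 / 140,
    "*5": 4 / 140,
    "*10": 56 / 140,
    "*36": 1 / 140,
}


@dataclass
class SimulationConfig:
    """Parameters of an HWE cohort simulation."""

    allele_freqs: Mapping[str, float] = field(default_factory=lambda: dict(KAREN_ALLELE_FREQS))
    n_samples: int = 70
    seed: int = 0
    nocall_rate: float = 0.0
    p_duplication: float = 0.0
    exon9_policy: str = "render"  # render | untested

    def __post_init__(self) -> None:
        total = sum(self.allele_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies sum to {total}, expected 1")
        if any(f < 0 for f in self.allele_freqs.values()):
            raise ValueError("allele frequencies must be non-negative")
        for rate in (self.nocall_rate, self.p_duplication):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.exon9_policy not in {"render", "untested"}:
            raise ValueError(f"unknown exon9 policy {self.exon9_policy!r}")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")


@dataclass(frozen=True)
class TruthRecord:
    """The simulated ground-truth diplotype written alongside each sample."""

    sample_id: str
    true_diplotype: tuple[str, str]


def render_sample(
    pair: Sequence[str],
    table: AlleleTable,
    exon9_policy: str = "render",
    sample_id: str = "sample",
) -> SampleRecord:
    """The assay record a given diplotype would produce, deterministically.

    Genotypes come from :func:`predict_genotype` at every informative
    locus (so hemizygote masking applies); the deletion band is set when
    the pair carries *5; exon-9 conversion evidence follows
    :func:`~cyp2d6star.caller.predict_exon9` under the ``render`` policy
    (absent / present / homozygous by conversion-allele dose) or is left
    ``untested`` under the ``untested`` policy.  A double-deletion pair
    yields the defined degenerate record: all loci missing plus the band.
    """
    names = canonical_pair(*pair)
    alleles = [table.allele(n) for n in names]
    genotypes = {locus: predict_genotype(names, locus, table) for locus in table.informative_loci}
    has_del = any("whole_gene_deletion" in a.structural for a in alleles)
    if exon9_policy == "render":
        exon9 = predict_exon9(names, table)
    elif exon9_policy == "untested":
        exon9 = "untested"
    else:
        raise ValueError(f"unknown exon9 policy {exon9_policy!r}")
    return SampleRecord(
        sample_id=sample_id,
        genotypes=genotypes,
        deletion_band=has_del,
        duplication_band=False,
        exon9_conversion=exon9,
    )


def simulate_population(
    config: SimulationConfig, table: AlleleTable
) -> tuple[list[SampleRecord], list[TruthRecord]]:
    """Draw an HWE cohort and render it at the assay level."""
    names = sorted(config.allele_freqs, key=star_sort_key)
    unknown = set(names) - set(table.allele_names)
    if unknown:
        raise KeyError(f"frequencies given for unknown alleles {sorted(unknown)}")
    freqs = np.asarray([config.allele_freqs[n] for n in names], dtype=float)
    cdf = np.cumsum(freqs)
    cdf[-1] = 1.0  # guard against rounding drift in the last bin
    rng = np.random.default_rng(config.seed)

    samples: list[SampleRecord] = []
    truths: list[TruthRecord] = []
    width = max(4, len(str(config.n_samples)))
    for i in range(config.n_samples):
        draws = rng.random(2)
        a, b = (names[int(np.searchsorted(cdf, u, side="right"))] for u in draws)
        pair = canonical_pair(a, b)
        sid = f"SIM{i + 1:0{width}d}"
        sample = render_sample(pair, table, exon9_policy=config.exon9_policy, sample_id=sid)
        if config.nocall_rate > 0:
            for locus in table.informative_loci:
                if rng.random() < config.nocall_rate:
                    sample.genotypes[locus] = MISSING
        if config.p_duplication > 0 and rng.random() < config.p_duplication:
            sample.duplication_band = True
        samples.append(sample)
        truths.append(TruthRecord(sid, pair))
    return samples, truths


def reconstruct_karen_cohort(
    table: AlleleTable,
    counts: Mapping[tuple[str, str], int] | None = None,
) -> list[SampleRecord]:
    """Deterministically expand the published diplotype counts into 70 records.

    Every record is rendered with ``exon9_policy='render'`` (the single
    conversion carrier is marked ``present``, everyone else ``absent``)
    and duplication flags false throughout: the source data do not
    identify which two individuals carried duplications, and the flag
    does not enter any frequency computation.
    """
    if counts is None:
        counts = KAREN_DIPLOTYPE_COUNTS
    total = sum(counts.values())
    if total != 70:
        raise ValueError(f"diplotype counts sum to {total}, expected 70")
    samples = []
    i = 0
    for pair, n in counts.items():
        for _ in range(n):
            i += 1
            samples.append(
                render_sample(pair, table, exon9_policy="render", sample_id=f"KAREN{i:03d}")
            )
    return samples


def mutate_sequence(reference: str, divergence: float, seed: int = 0) -> str:
    """Substitute a fixed proportion of positions, each to a different base.

    Positions are chosen uniformly without replacement;
    ``round(divergence * len)`` sites are changed, so divergence 0 returns
    the reference and divergence 1 changes every position.
    """
    if not reference:
        raise ValueError("empty reference sequence")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    seq = list(reference.upper())
    bases = "ACGT"
    rng = np.random.default_rng(seed)
    n_sub = int(round(divergence * len(seq)))
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    for pos in positions:
        alternatives = [b for b in bases if b != seq[pos]]
        seq[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(seq)
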