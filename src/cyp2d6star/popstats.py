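"""Cohort-level statistics over diplotype calls.

Counting conventions
--------------------
Every uniquely called sample contributes exactly two allele slots, so
allele counts sum to ``2n`` -- the whole-gene deletion allele *5 occupies
a slot like any other.  Derived SNP frequencies use the same ``2n``
denominator: the frequency of a substitution is the summed frequency of
the alleles carrying it, and *5 (which carries no SNPs) stays in the
denominator.  This is what makes a 70-sample cohort with 140 allele slots
report C100T at 60/140 = 0.43 when the C100T-carrying alleles *4, *10 and
*36 count 3 + 56 + 1.

Samples whose call is not ``unique`` are excluded from summaries with a
logged count, never imputed.

The Hardy-Weinberg exact test is the standard conditional test: given the
observed allele counts, the probability of each possible heterozygote
count is computed by enumeration and the two-sided p-value sums the
probabilities of all configurations no more probable than the observed
one.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alleles import AlleleTable, function_summary, star_sort_key
from .caller import ALT_ALT, MISSING, REF_ALT, REF_REF, DiplotypeCall, predict_genotype

__all__ = [
    "PopulationSummary",
    "PopulationPanel",
    "summarize_cohort",
    "reduced_function_fraction",
    "hwe_exact",
    "compare_populations",
    "load_population_panel",
    "marker_frequencies",
]

log = logging.getLogger(__name__)

#: Sentinel used in panel fixtures for frequencies a study did not determine.
ND = "ND"


@dataclass
class PopulationSummary:
    """Frequency tables and function-class burden for one cohort."""

    n_samples: int
    allele_counts: dict[str, int]
    allele_freqs: dict[str, float]
    diplotype_counts: dict[tuple[str, str], int]
    diplotype_freqs: dict[tuple[str, str], float]
    derived_snp_freqs: dict[str, float]
    function_burden: dict[str, float]
    hwe: dict[str, float]
    n_excluded: int = 0
    mean_activity_score: float = 0.0

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Presentation tables (rounding applied here only): alleles 2dp/
        SNPs 2dp, per-diplotype frequencies 3dp."""
        alleles = pd.DataFrame(
            {
                "allele": list(self.allele_counts),
                "n": list(self.allele_counts.values()),
                "frequency": [round(self.allele_freqs[a], 3) for a in self.allele_counts],
            }
        )
        diplotypes = pd.DataFrame(
            {
                "diplotype": ["/".join(p) for p in self.diplotype_counts],
                "n": list(self.diplotype_counts.values()),
                "frequency": [round(self.diplotype_freqs[p], 3) for p in self.diplotype_counts],
            }
        )
        snps = pd.DataFrame(
            {
                "variant": list(self.derived_snp_freqs),
                "frequency": [round(f, 2) for f in self.derived_snp_freqs.values()],
                "hwe_p": [round(self.hwe[v], 4) if v in self.hwe else float("nan")
                          for v in self.derived_snp_freqs],
            }
        )
        return {"alleles": alleles, "diplotypes": diplotypes, "snps": snps}


def summarize_cohort(calls: Sequence[DiplotypeCall], table: AlleleTable) -> PopulationSummary:
    """Allele/diplotype/SNP frequencies and function burden over a cohort."""
    if not calls:
        raise ValueError("empty call list")
    unique = [c for c in calls if c.is_unique and c.best_pair is not None]
    n_excluded = len(calls) - len(unique)
    if n_excluded:
        log.info("excluding %d non-unique calls from summary", n_excluded)
    if not unique:
        raise ValueError("no uniquely called samples to summarize")

    n = len(unique)
    allele_counts: Counter[str] = Counter()
    dip_counts: Counter[tuple[str, str]] = Counter()
    for c in unique:
        a, b = c.best_pair  # type: ignore[misc]
        allele_counts[a] += 1
        allele_counts[b] += 1
        dip_counts[c.best_pair] += 1
    total_slots = 2 * n
    order = [a for a in table.allele_names if a in allele_counts]
    allele_counts_o = {a: allele_counts[a] for a in order}
    allele_freqs = {a: allele_counts[a] / total_slots for a in order}
    dip_order = sorted(dip_counts, key=lambda p: (star_sort_key(p[0]), star_sort_key(p[1])))
    dip_counts_o = {p: dip_counts[p] for p in dip_order}
    dip_freqs = {p: dip_counts[p] / n for p in dip_order}

    derived = {
        vid: sum(f for a, f in allele_freqs.items() if table.allele(a).carries(vid))
        for vid in sorted(table.variants, key=lambda v: table.variants[v].position)
    }

    classes = function_summary(table)
    burden: dict[str, float] = {"normal": 0.0, "decreased": 0.0, "none": 0.0}
    for a, f in allele_freqs.items():
        burden[classes[a]] += f
    activity = sum(
        table.allele(a).activity_value + table.allele(b).activity_value
        for (a, b) in (c.best_pair for c in unique)  # type: ignore[misc]
    ) / n

    hwe: dict[str, float] = {}
    for locus in table.informative_loci:
        geno = Counter(predict_genotype(c.best_pair, locus, table) for c in unique)  # type: ignore[arg-type]
        counts = (geno[REF_REF], geno[REF_ALT], geno[ALT_ALT])
        if sum(counts) > 0:
            hwe[locus] = hwe_exact(*counts)

    return PopulationSummary(
        n_samples=n,
        allele_counts=allele_counts_o,
        allele_freqs=allele_freqs,
        diplotype_counts=dip_counts_o,
        diplotype_freqs=dip_freqs,
        derived_snp_freqs=derived,
        function_burden=burden,
        hwe=hwe,
        n_excluded=n_excluded,
        mean_activity_score=activity,
    )


def reduced_function_fraction(
    summary: PopulationSummary, classes: Iterable[str] = ("decreased", "none")
) -> float:
    """Proportion of allele slots whose function class is in ``classes``."""
    classes = set(classes)
    unknown = classes - set(summary.function_burden)
    if unknown:
        raise ValueError(f"unknown function classes {sorted(unknown)}")
    return sum(summary.function_burden[c] for c in classes)


def hwe_exact(n_ref_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Enumerates every heterozygote count compatible with the observed
    allele counts, computes each configuration's conditional probability,
    and sums the probabilities of configurations no more probable than the
    observed one.  Returns a p-value in (0, 1].
    """
    if min(n_ref_hom, n_het, n_alt_hom) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_ref_hom + n_het + n_alt_hom
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_ref = 2 * n_ref_hom + n_het
    n_alt = 2 * n_alt_hom + n_het
    if n_ref == 0 or n_alt == 0:
        return 1.0  # monomorphic: only one configuration exists
    rare = min(n_ref, n_alt)

    def logprob(h: int) -> float:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            h * math.log(2.0)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_common + 1)
        )

    hs = range(rare % 2, rare + 1, 2)
    logs = {h: logprob(h) for h in hs}
    m = max(logs.values())
    z = sum(math.exp(v - m) for v in logs.values())
    probs = {h: math.exp(v - m) / z for h, v in logs.items()}
    p_obs = probs[n_het]
    p = sum(q for q in probs.values() if q <= p_obs * (1 + 1e-12))
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Cross-population comparison
# ---------------------------------------------------------------------------

#: Columns in the bundled panel that hold frequencies.
PANEL_FREQ_COLUMNS = (
    "C100T",
    "C1039T",
    "G1661C",
    "G1846A",
    "C2850T",
    "G4180C",
    "exon9_conversion",
    "deletion",
    "duplication",
)

#: Default marker set for divergence: the columns determined by most studies.
DEFAULT_COMPARE_VARIANTS = ("C100T", "G1846A", "C2850T", "deletion")


@dataclass
class PopulationPanel:
    """Published per-population marker frequencies (one row per study).

    Marker columns follow the survey convention for this gene: columns
    named after a defining substitution (C100T, G1846A, C2850T) or
    structural event (deletion, exon9_conversion) hold the frequency of
    the corresponding star allele (*10, *4, *2, *5, *36), while plain SNP
    columns (C1039T, G1661C, G4180C) hold substitution frequencies.
    Frequencies a study did not determine are NaN (``ND`` in the TSV).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        for col in PANEL_FREQ_COLUMNS:
            if col in self.frame.columns:
                vals = self.frame[col].dropna()
                if ((vals < 0) | (vals > 1)).any():
                    raise ValueError(f"panel column {col} has frequencies outside [0, 1]")

    @property
    def populations(self) -> list[str]:
        return list(self.frame["population"])


def load_population_panel(path: str | Path | None = None) -> PopulationPanel:
    """Load the bundled (or a user-supplied) cross-population panel TSV."""
    if path is None:
        ref = resources.files("cyp2d6star.data").joinpath("population_panel.tsv")
        with ref.open() as fh:
            frame = pd.read_csv(fh, sep="\t", na_values=[ND], comment="#")
    else:
        frame = pd.read_csv(path, sep="\t", na_values=[ND], comment="#")
    return PopulationPanel(frame)


def marker_frequencies(summary: PopulationSummary, table: AlleleTable) -> dict[str, float]:
    """Panel-convention marker frequencies for a cohort summary.

    Starts from derived SNP frequencies, then overrides each marker column
    with the frequency of the allele it defines (single key variant or
    structural event), mirroring how the published panels report them.
    """
    out = dict(summary.derived_snp_freqs)
    for name in table.allele_names:
        allele = table.allele(name)
        freq = summary.allele_freqs.get(name, 0.0)
        if "whole_gene_deletion" in allele.structural:
            out["deletion"] = freq
        elif "exon9_conversion" in allele.structural:
            out["exon9_conversion"] = freq
        elif len(allele.key_variants) == 1:
            out[next(iter(allele.key_variants))] = freq
    return out


def compare_populations(
    target: PopulationSummary | Mapping[str, float],
    panel: PopulationPanel,
    variants: Sequence[str] = DEFAULT_COMPARE_VARIANTS,
    table: AlleleTable | None = None,
) -> pd.DataFrame:
    """Per-population absolute frequency differences and a scalar divergence.

    ``target`` may be a cohort summary (converted with
    :func:`marker_frequencies`; requires ``table``) or a ready mapping of
    marker -> frequency.  The divergence is the mean absolute difference
    over the requested markers a row determines; undetermined markers are
    excluded from that row's mean.  Rows are sorted by divergence, so the
    qualitative "nearest populations" ordering can be read off the top.
    """
    if isinstance(target, PopulationSummary):
        if table is None:
            raise ValueError("table is required to derive marker frequencies from a summary")
        target_freqs = marker_frequencies(target, table)
    else:
        target_freqs = dict(target)
    missing = [v for v in variants if v not in target_freqs]
    if missing:
        raise KeyError(f"target does not determine markers {missing}")
    for v in variants:
        if v not in panel.frame.columns:
            raise KeyError(f"panel does not carry marker {v!r}")

    rows = []
    for _, row in panel.frame.iterrows():
        diffs = {}
        for v in variants:
            val = row[v]
            diffs[f"d_{v}"] = abs(target_freqs[v] - val) if pd.notna(val) else float("nan")
        finite = [d for d in diffs.values() if not math.isnan(d)]
        rows.append(
            {
                "population": row["population"],
                "group": row.get("group", ""),
                **diffs,
                "n_markers": len(finite),
                "divergence": sum(finite) / len(finite) if finite else float("nan"),
            }
        )
    out = pd.DataFrame(rows).sort_values("divergence", kind="mergesort").reset_index(drop=True)
    return out
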