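"""Star-allele diplotype calling from unphased genotypes and structural flags.

The assay reports, per sample, an unphased biallelic genotype at each
informative SNP locus plus three structural observations: a deletion band
(the sample carries the whole-gene deletion allele *5 on one chromosome),
a duplication band (one or more extra gene copies, carrier unknown), and
exon-9 conversion evidence from sequencing (defines *36).

Calling is by exhaustive enumeration: every unordered pair of alleles in
the table is asked what genotype it would *appear* to produce at each
locus (``predict_genotype``), and the pairs that reproduce every observed
call survive.  The central subtlety is hemizygote masking: a deletion
carrier has a single gene copy, so the remaining haplotype's variants look
homozygous -- a pair ``(*2, *5)`` appears ``alt_alt`` at C2850T even
though only one chromosome carries the substitution.  Consequently a
heterozygous call together with a deletion band is physically impossible
and is reported as ``inconsistent`` rather than raised.

Duplication bands never filter candidate pairs: the assay cannot resolve
which allele is duplicated or the copy number, so the flag is carried as a
diagnostic note and every sample contributes exactly two allele slots to
downstream counting.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterable, Mapping, Sequence

from .alleles import AlleleTable, star_sort_key

__all__ = [
    "GENOTYPE_CALLS",
    "EXON9_STATES",
    "REF_REF",
    "REF_ALT",
    "ALT_ALT",
    "MISSING",
    "SampleRecord",
    "DiplotypeCall",
    "predict_genotype",
    "predict_exon9",
    "consistent_pairs",
    "call_diplotype",
    "call_batch",
    "canonical_pair",
]

log = logging.getLogger(__name__)

REF_REF = "ref_ref"
REF_ALT = "ref_alt"
ALT_ALT = "alt_alt"
MISSING = "missing"

GENOTYPE_CALLS = frozenset({REF_REF, REF_ALT, ALT_ALT, MISSING})

#: Exon-9 conversion evidence from sequencing.  ``present`` means the
#: conversion was seen on one chromosome (mixed traces), ``homozygous`` on
#: both (clean converted sequence); hemizygote masking applies, so a
#: deletion carrier whose surviving haplotype is converted reads
#: ``homozygous``.  ``untested`` means exon 9 was not sequenced.
EXON9_STATES = frozenset({"present", "homozygous", "absent", "untested"})

_DOSE_TO_CALL = {0: REF_REF, 1: REF_ALT, 2: ALT_ALT}


@dataclass
class SampleRecord:
    """One individual's assay output: per-locus genotype calls plus flags."""

    sample_id: str
    genotypes: dict[str, str] = field(default_factory=dict)
    deletion_band: bool = False
    duplication_band: bool = False
    exon9_conversion: str = "untested"
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, call in self.genotypes.items():
            if call not in GENOTYPE_CALLS:
                raise ValueError(f"sample {self.sample_id}: bad call {call!r} at {locus}")
        if self.exon9_conversion not in EXON9_STATES:
            raise ValueError(
                f"sample {self.sample_id}: bad exon9_conversion {self.exon9_conversion!r}"
            )

    def call_at(self, locus: str) -> str:
        return self.genotypes.get(locus, MISSING)


@dataclass
class DiplotypeCall:
    """Result of calling one sample: surviving pairs, ranked best, status."""

    sample_id: str
    consistent_pairs: list[tuple[str, str]]
    best_pair: tuple[str, str] | None
    status: str  # unique | ambiguous | inconsistent | insufficient_data
    notes: list[str] = field(default_factory=list)

    @property
    def is_unique(self) -> bool:
        return self.status == "unique"


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered pair in canonical ascending star-number order."""
    return tuple(sorted((a, b), key=star_sort_key))  # type: ignore[return-value]


def predict_genotype(pair: Sequence[str], locus: str, table: AlleleTable) -> str:
    """Apparent genotype the assay would report for ``pair`` at ``locus``.

    For two non-deletion alleles the call follows the alt-allele dose
    (0/1/2 -> ref_ref/ref_alt/alt_alt).  With one deletion allele (*5) the
    sample is hemizygous and the surviving haplotype's state appears
    homozygous; with two deletion alleles there is no template and the
    locus is ``missing``.
    """
    if locus not in table.variants:
        raise KeyError(f"unknown locus {locus!r}")
    a, b = (table.allele(name) for name in pair)
    deletions = [al for al in (a, b) if "whole_gene_deletion" in al.structural]
    if len(deletions) == 2:
        return MISSING
    if len(deletions) == 1:
        survivor = a if deletions[0] is b else b
        return ALT_ALT if survivor.carries(locus) else REF_REF
    dose = int(a.carries(locus)) + int(b.carries(locus))
    return _DOSE_TO_CALL[dose]


def predict_exon9(pair: Sequence[str], table: AlleleTable) -> str:
    """Apparent exon-9 conversion evidence a diplotype would produce.

    Follows conversion-allele dose (0/1/2 -> absent/present/homozygous)
    with hemizygote masking: a single surviving converted haplotype reads
    ``homozygous``; a double deletion leaves nothing to sequence
    (``untested``).
    """
    a, b = (table.allele(name) for name in pair)
    deletions = [al for al in (a, b) if "whole_gene_deletion" in al.structural]
    if len(deletions) == 2:
        return "untested"
    if len(deletions) == 1:
        survivor = a if deletions[0] is b else b
        return "homozygous" if "exon9_conversion" in survivor.structural else "absent"
    dose = sum("exon9_conversion" in al.structural for al in (a, b))
    return {0: "absent", 1: "present", 2: "homozygous"}[dose]


def _exon9_admits(pair: tuple[str, str], state: str, table: AlleleTable, allow_untested: bool) -> bool:
    if state == "untested":
        # By default conversion alleles are not proposed without evidence
        # (calls collapse to their SNP-identical counterpart, e.g. *10);
        # allow_untested restores the ambiguous behaviour.
        if allow_untested:
            return True
        return not any("exon9_conversion" in table.allele(n).structural for n in pair)
    return predict_exon9(pair, table) == state

def _candidate_pairs(sample: SampleRecord, table: AlleleTable) -> list[tuple[str, str]]:
    dels = set(table.deletion_alleles)
    non_del = [n for n in table.allele_names if n not in dels]
    if sample.deletion_band:
        return [canonical_pair(n, d) for d in sorted(dels, key=star_sort_key) for n in non_del]
    return [canonical_pair(a, b) for a, b in combinations_with_replacement(non_del, 2)]


def consistent_pairs(
    sample: SampleRecord,
    table: AlleleTable,
    *,
    allow_untested_exon9_ambiguity: bool = False,
) -> list[tuple[str, str]]:
    """All unordered allele pairs that reproduce the observed genotypes.

    A deletion band restricts candidates to hemizygous pairs ``(a, *5)``;
    otherwise the deletion allele is excluded.  A pair survives iff its
    predicted genotype matches every non-missing informative locus and the
    exon-9 conversion constraint holds.  The fully missing deletion-band
    sample (no amplifiable template) is the defined homozygous-deletion
    degenerate case and returns ``[(*5, *5)]``.
    """
    unknown = set(sample.genotypes) - set(table.variants)
    if unknown:
        raise KeyError(f"sample {sample.sample_id}: genotypes at unknown loci {sorted(unknown)}")
    loci = table.informative_loci
    observed = {l: sample.call_at(l) for l in loci}
    if sample.deletion_band:
        if all(c == MISSING for c in observed.values()) and table.deletion_alleles:
            d = table.deletion_alleles[0]
            return [canonical_pair(d, d)]
        if any(c == REF_ALT for c in observed.values()):
            return []  # hemizygotes cannot be heterozygous
    survivors = []
    for pair in _candidate_pairs(sample, table):
        if not _exon9_admits(pair, sample.exon9_conversion, table, allow_untested_exon9_ambiguity):
            continue
        if all(
            observed[l] == MISSING or predict_genotype(pair, l, table) == observed[l]
            for l in loci
        ):
            survivors.append(pair)
    return sorted(set(survivors), key=lambda p: (star_sort_key(p[0]), star_sort_key(p[1])))


def _rank_pairs(
    pairs: Iterable[tuple[str, str]], priors: Mapping[str, float]
) -> tuple[str, str] | None:
    """Highest prior-probability pair; ties broken by canonical star order."""
    best = None
    best_score = -1.0
    for pair in sorted(pairs, key=lambda p: (star_sort_key(p[0]), star_sort_key(p[1]))):
        a, b = pair
        score = priors.get(a, 0.0) * priors.get(b, 0.0) * (2.0 if a != b else 1.0)
        if score > best_score:
            best, best_score = pair, score
    return best


def call_diplotype(
    sample: SampleRecord,
    table: AlleleTable,
    priors: Mapping[str, float] | None = None,
    *,
    allow_untested_exon9_ambiguity: bool = False,
) -> DiplotypeCall:
    """Rank the consistent pairs of one sample into a diplotype call.

    ``priors`` are non-negative allele weights (default uniform); the best
    pair maximizes prior(a)*prior(b), doubled for heterozygous pairs, with
    lexicographic star-order tie-breaking.  Status follows the number of
    survivors: exactly one -> ``unique``; none with complete data ->
    ``inconsistent``; otherwise ``insufficient_data`` when an informative
    locus is missing, else ``ambiguous``.
    """
    if priors is None:
        priors = {name: 1.0 for name in table.allele_names}
    notes: list[str] = []
    loci = table.informative_loci
    observed = {l: sample.call_at(l) for l in loci}
    missing_any = any(c == MISSING for c in observed.values())

    if sample.duplication_band:
        notes.append("duplication_present_copy_number_unresolved")

    if sample.deletion_band and any(c == REF_ALT for c in observed.values()):
        notes.append("het_call_with_deletion_band")
        return DiplotypeCall(sample.sample_id, [], None, "inconsistent", notes)

    pairs = consistent_pairs(
        sample, table, allow_untested_exon9_ambiguity=allow_untested_exon9_ambiguity
    )
    dels = table.deletion_alleles
    if sample.deletion_band and dels and pairs == [canonical_pair(dels[0], dels[0])]:
        notes.append("homozygous_deletion_no_template")
        return DiplotypeCall(sample.sample_id, pairs, pairs[0], "unique", notes)

    best = _rank_pairs(pairs, priors) if pairs else None
    if len(pairs) == 1:
        status = "unique"
    elif not pairs:
        status = "insufficient_data" if missing_any else "inconsistent"
    else:
        status = "insufficient_data" if missing_any else "ambiguous"
    return DiplotypeCall(sample.sample_id, pairs, best, status, notes)


def call_batch(
    samples: Sequence[SampleRecord],
    table: AlleleTable,
    priors: Mapping[str, float] | None = None,
    *,
    allow_untested_exon9_ambiguity: bool = False,
) -> list[DiplotypeCall]:
    """Call every sample, isolating per-sample failures; order-preserving."""
    calls: list[DiplotypeCall] = []
    for sample in samples:
        try:
            calls.append(
                call_diplotype(
                    sample,
                    table,
                    priors,
                    allow_untested_exon9_ambiguity=allow_untested_exon9_ambiguity,
                )
            )
        except Exception as exc:  # noqa: BLE001 - isolation contract
            log.warning("sample %s failed: %s", sample.sample_id, exc)
            calls.append(
                DiplotypeCall(sample.sample_id, [], None, "inconsistent", [f"error:{exc}"])
            )
    counts = Counter(c.status for c in calls)
    log.info("called %d samples: %s", len(calls), dict(counts))
    return calls
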