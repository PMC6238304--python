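"""Variant catalog and star-allele definition table for CYP2D6.

A *star allele* is a named CYP2D6 haplotype defined by a characteristic set
of single-nucleotide substitutions and/or structural events (whole-gene
deletion, duplication, exon-9 gene conversion to CYP2D7), together with a
function class (``normal`` / ``decreased`` / ``none``) describing the
enzyme activity the haplotype confers.  Everything else in this package --
the diplotype caller, the cohort statistics, the simulator -- consumes the
:class:`AlleleTable` built here.

Coordinates are gene-local, 1-based on the CYP2D6 genomic reference
(GenBank M33388.1), matching the conventional ``C100T``-style variant
labels; no genome-build liftover is attempted.

The bundled default table (``data/cyp2d6_karen6.json``) covers the six
alleles typable by a four-SNP panel (C100T, G1846A, C2850T, G4180C) plus
deletion/duplication band flags and exon-9 conversion evidence:
*1, *2, *4, *5, *10 and *36.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping

__all__ = [
    "FUNCTION_CLASSES",
    "STRUCTURAL_EVENTS",
    "DEFAULT_ACTIVITY_SCORES",
    "VariantDef",
    "StarAllele",
    "AlleleTable",
    "AlleleTableError",
    "load_allele_table",
    "default_table",
    "function_summary",
    "star_sort_key",
]

#: Closed enumeration of structural events the assay can flag.
STRUCTURAL_EVENTS = frozenset({"whole_gene_deletion", "duplication", "exon9_conversion"})

#: Closed enumeration of allele function classes.
FUNCTION_CLASSES = frozenset({"normal", "decreased", "none"})

#: Additive activity-score convention: one fully functional gene copy
#: contributes 1.0, a reduced-function copy 0.5, a non-functional copy 0.
#: Configurable via the ``activity_scores`` block of the allele-table JSON.
DEFAULT_ACTIVITY_SCORES: Mapping[str, float] = {"normal": 1.0, "decreased": 0.5, "none": 0.0}

_VARIANT_ID_RE = re.compile(r"^([ACGT])(\d+)([ACGT])$")
_DNA = frozenset("ACGT")


class AlleleTableError(ValueError):
    """Raised when an allele-definition document fails validation."""


@dataclass(frozen=True)
class VariantDef:
    """A single-nucleotide substitution on the CYP2D6 reference.

    The ``id`` follows the ``<ref><pos><alt>`` convention (e.g. ``C100T``)
    and must agree with ``ref_base``, ``position`` and ``alt_base``.
    """

    id: str
    position: int
    ref_base: str
    alt_base: str
    rsid: str = ""
    region: str = ""
    effect: str = ""

    def __post_init__(self) -> None:
        if self.ref_base not in _DNA or self.alt_base not in _DNA:
            raise AlleleTableError(f"variant {self.id!r}: bases must be A/C/G/T")
        if self.ref_base == self.alt_base:
            raise AlleleTableError(f"variant {self.id!r}: ref and alt bases are equal")
        m = _VARIANT_ID_RE.match(self.id)
        if not m:
            raise AlleleTableError(f"variant id {self.id!r} is not of the form <ref><pos><alt>")
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if (ref, pos, alt) != (self.ref_base, self.position, self.alt_base):
            raise AlleleTableError(
                f"variant id {self.id!r} inconsistent with "
                f"ref={self.ref_base} pos={self.position} alt={self.alt_base}"
            )


@dataclass(frozen=True)
class StarAllele:
    """A named haplotype: SNP content, structural events and function class.

    ``key_variants`` are the substitutions that *define* the allele
    assignment (the panel's discriminating markers); ``all_variants`` is the
    full set of associated substitutions and always contains the key set.
    """

    name: str
    key_variants: frozenset[str] = frozenset()
    all_variants: frozenset[str] = frozenset()
    structural: frozenset[str] = frozenset()
    function_class: str = "normal"
    activity_value: float = 1.0

    def __post_init__(self) -> None:
        if not self.name.startswith("*"):
            raise AlleleTableError(f"allele name {self.name!r} must start with '*'")
        if not self.key_variants <= self.all_variants:
            raise AlleleTableError(f"allele {self.name}: key_variants not a subset of all_variants")
        unknown = self.structural - STRUCTURAL_EVENTS
        if unknown:
            raise AlleleTableError(f"allele {self.name}: unknown structural events {sorted(unknown)}")
        if self.function_class not in FUNCTION_CLASSES:
            raise AlleleTableError(f"allele {self.name}: unknown function class {self.function_class!r}")
        if self.activity_value < 0:
            raise AlleleTableError(f"allele {self.name}: negative activity value")
        if self.function_class == "none" and self.activity_value != 0:
            raise AlleleTableError(f"allele {self.name}: function class 'none' requires activity 0")

    def carries(self, variant_id: str) -> bool:
        return variant_id in self.all_variants

    @property
    def signature(self) -> tuple[frozenset[str], frozenset[str]]:
        """The (all_variants, structural) pair that must be unique per table."""
        return (self.all_variants, self.structural)


def star_sort_key(name: str) -> tuple[int, str]:
    """Sort key giving the conventional ascending star-number order (*1 < *2 < *10)."""
    m = re.match(r"^\*(\d+)", name)
    return (int(m.group(1)) if m else 10**9, name)


@dataclass(frozen=True)
class AlleleTable:
    """Validated catalog of variants plus the star alleles built from them."""

    variants: Mapping[str, VariantDef]
    alleles: Mapping[str, StarAllele]
    informative_loci: tuple[str, ...]
    activity_scores: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ACTIVITY_SCORES))

    def __post_init__(self) -> None:
        positions: dict[int, str] = {}
        for vid, v in self.variants.items():
            if vid != v.id:
                raise AlleleTableError(f"catalog key {vid!r} does not match variant id {v.id!r}")
            if v.position in positions:
                raise AlleleTableError(
                    f"variants {positions[v.position]!r} and {vid!r} share position {v.position}"
                )
            positions[v.position] = vid
        seen_sig: dict[tuple[frozenset[str], frozenset[str]], str] = {}
        for name, allele in self.alleles.items():
            if name != allele.name:
                raise AlleleTableError(f"allele key {name!r} does not match allele name {allele.name!r}")
            missing = allele.all_variants - self.variants.keys()
            if missing:
                raise AlleleTableError(f"allele {name} references unknown variants {sorted(missing)}")
            if allele.signature in seen_sig:
                raise AlleleTableError(
                    "signature collision: alleles "
                    f"{seen_sig[allele.signature]} and {name} share variant set "
                    f"{sorted(allele.all_variants)} and structural set {sorted(allele.structural)}"
                )
            seen_sig[allele.signature] = name
        for locus in self.informative_loci:
            if locus not in self.variants:
                raise AlleleTableError(f"informative locus {locus!r} not in variant catalog")

    # -- convenience ---------------------------------------------------

    def allele(self, name: str) -> StarAllele:
        try:
            return self.alleles[name]
        except KeyError:
            raise KeyError(f"unknown allele {name!r}") from None

    @property
    def allele_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.alleles, key=star_sort_key))

    @property
    def deletion_alleles(self) -> tuple[str, ...]:
        return tuple(
            n for n in self.allele_names if "whole_gene_deletion" in self.alleles[n].structural
        )

    def rsid_map(self) -> dict[str, str]:
        """Mapping dbSNP rsID -> variant id, for VCF ingestion."""
        return {v.rsid: vid for vid, v in self.variants.items() if v.rsid}

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "activity_scores": dict(self.activity_scores),
            "informative_loci": list(self.informative_loci),
            "variants": [
                {
                    "id": v.id,
                    "position": v.position,
                    "ref_base": v.ref_base,
                    "alt_base": v.alt_base,
                    "rsid": v.rsid,
                    "region": v.region,
                    "effect": v.effect,
                }
                for v in sorted(self.variants.values(), key=lambda v: v.position)
            ],
            "alleles": [
                {
                    "name": a.name,
                    "key_variants": sorted(a.key_variants),
                    "all_variants": sorted(a.all_variants),
                    "structural": sorted(a.structural),
                    "function_class": a.function_class,
                    "activity_value": a.activity_value,
                }
                for a in (self.alleles[n] for n in self.allele_names)
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _table_from_dict(doc: Mapping) -> AlleleTable:
    scores = dict(DEFAULT_ACTIVITY_SCORES)
    scores.update(doc.get("activity_scores", {}))
    variants: dict[str, VariantDef] = {}
    for vd in doc.get("variants", []):
        v = VariantDef(**vd)
        if v.id in variants:
            raise AlleleTableError(f"duplicate variant id {v.id!r}")
        variants[v.id] = v
    alleles: dict[str, StarAllele] = {}
    for ad in doc.get("alleles", []):
        function_class = ad.get("function_class", "normal")
        activity = ad.get("activity_value", scores.get(function_class, 1.0))
        a = StarAllele(
            name=ad["name"],
            key_variants=frozenset(ad.get("key_variants", [])),
            all_variants=frozenset(ad.get("all_variants", [])),
            structural=frozenset(ad.get("structural", [])),
            function_class=function_class,
            activity_value=float(activity),
        )
        if a.name in alleles:
            raise AlleleTableError(f"duplicate allele name {a.name!r}")
        alleles[a.name] = a
    return AlleleTable(
        variants=variants,
        alleles=alleles,
        informative_loci=tuple(doc.get("informative_loci", [])),
        activity_scores=scores,
    )


def load_allele_table(source: str | Path | Mapping | IO[str]) -> AlleleTable:
    """Load and validate an allele-definition document.

    ``source`` may be a path to a JSON file, an already-parsed mapping, or
    an open text stream.  Raises :class:`AlleleTableError` on duplicate
    names, references to unknown variants, or two alleles sharing the same
    (variant set, structural set) signature.
    """
    if isinstance(source, Mapping):
        return _table_from_dict(source)
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return _table_from_dict(json.load(fh))
    return _table_from_dict(json.load(source))


def default_table() -> AlleleTable:
    """The bundled six-allele CYP2D6 table used throughout the package."""
    ref = resources.files("cyp2d6star.data").joinpath("cyp2d6_karen6.json")
    with ref.open() as fh:
        return _table_from_dict(json.load(fh))


def function_summary(table: AlleleTable) -> dict[str, str]:
    """Mapping allele name -> function class, in star order."""
    return {name: table.alleles[name].function_class for name in table.allele_names}
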