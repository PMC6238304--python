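"""Assay quality-control: primer/probe metrics and pseudogene discrimination.

Two concerns live here.  First, desk-checkable oligo metrics (length, GC
content, nearest-neighbor melting temperature) for the bundled primer and
probe panel.  Second, the intron-2 identity classifier: the CYP2D locus
carries two pseudogenes (CYP2D7, CYP2D8) with >90% sequence homology to
the functional gene, so amplicons sequenced from the gene-spanning PCR
product are verified by pairwise identity -- an amplicon is accepted as
CYP2D6 only when its identity to the CYP2D6 reference exceeds a threshold
(default 95%) *and* beats every pseudogene reference.

Melting temperatures use nearest-neighbor thermodynamics under PCR-buffer
defaults (50 mM monovalent salt, 1.5 mM Mg2+, 0.6 mM dNTPs, 50 nM primer,
Owczarzy divalent correction); all parameters are keyword-configurable.
Printed reference Tm values for dual-labelled probes are not comparable
(quencher/minor-groove-binder chemistry is not modelled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align, SeqIO
from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "PrimerRecord",
    "IdentityResult",
    "gc_percent",
    "melting_temperature",
    "pairwise_identity",
    "classify_amplicon",
    "load_primer_table",
    "primer_qc_report",
    "load_int2_references",
]

_DNA = frozenset("ACGT")

PRIMER_ROLES = frozenset({"outer", "nested", "probe_wt", "probe_mut"})


@dataclass(frozen=True)
class PrimerRecord:
    """One oligo with its published reference metrics (where printed)."""

    name: str
    sequence: str
    role: str
    analysis: str = ""
    reported_length: int | None = None
    reported_gc: float | None = None
    reported_tm: float | None = None
    reported_amplicon_size: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - _DNA:
            raise ValueError(f"primer {self.name}: sequence must be non-empty A/C/G/T")
        if self.role not in PRIMER_ROLES:
            raise ValueError(f"primer {self.name}: unknown role {self.role!r}")

    @property
    def is_probe(self) -> bool:
        return self.role.startswith("probe")


@dataclass
class IdentityResult:
    """Identity of a query amplicon to each labelled reference plus its class."""

    query_id: str
    identities: dict[str, float]
    classification: str  # CYP2D6 | pseudogene | indeterminate
    threshold: float

    def __post_init__(self) -> None:
        for label, pct in self.identities.items():
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"identity to {label} outside [0, 100]: {pct}")


def _check_dna(sequence: str) -> str:
    seq = sequence.upper()
    if not seq or set(seq) - _DNA:
        raise ValueError("sequence must be a non-empty A/C/G/T string")
    return seq


def gc_percent(sequence: str) -> float:
    """GC content in percent, rounded half-up to one decimal."""
    seq = _check_dna(sequence)
    pct = 100.0 * (seq.count("G") + seq.count("C")) / len(seq)
    return float(Decimal(repr(pct)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def melting_temperature(
    sequence: str,
    *,
    Na: float = 50.0,
    Mg: float = 1.5,
    dNTPs: float = 0.6,
    dnac1: float = 50.0,
    dnac2: float = 0.0,
    saltcorr: int = 7,
    nn_table=None,
) -> float:
    """Nearest-neighbor duplex melting temperature in deg C.

    Concentrations: Na/Mg/dNTPs in mM, oligo strands (dnac1/dnac2) in nM.
    Requires length >= 8 (shorter oligos are outside the model's range).
    """
    seq = _check_dna(sequence)
    if len(seq) < 8:
        raise ValueError("sequence too short for nearest-neighbor Tm (need >= 8 nt)")
    if nn_table is None:
        nn_table = _mt.DNA_NN3
    return float(
        _mt.Tm_NN(
            seq, nn_table=nn_table, Na=Na, Mg=Mg, dNTPs=dNTPs,
            dnac1=dnac1, dnac2=dnac2, saltcorr=saltcorr,
        )
    )


# ---------------------------------------------------------------------------
# Pairwise identity / pseudogene discrimination
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(query: str, reference: str) -> float:
    """Percent identity under global alignment.

    Scoring: match +1, mismatch -1, gap open -2, gap extend -1.  Identity
    is 100 * matches / alignment columns, where the denominator includes
    gap columns (a conservative reading of "sequence similarity").
    """
    q = _check_dna(query)
    r = _check_dna(reference)
    alignment = _aligner().align(q, r)[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / columns


def classify_amplicon(
    query: str,
    references: Mapping[str, str],
    threshold: float = 95.0,
    query_id: str = "query",
    gene_label: str = "CYP2D6",
) -> IdentityResult:
    """Classify an amplicon as functional gene, pseudogene, or indeterminate.

    ``references`` maps labels to sequences and must contain ``gene_label``
    plus at least one pseudogene reference.  The query is accepted as
    CYP2D6 iff its identity to the gene reference strictly exceeds
    ``threshold`` *and* strictly exceeds the identity to every pseudogene
    reference; a pseudogene label wins symmetrically; anything else is
    indeterminate.
    """
    if gene_label not in references:
        raise ValueError(f"missing {gene_label} reference")
    if len(references) < 2:
        raise ValueError("need at least two labelled references")
    identities = {label: pairwise_identity(query, seq) for label, seq in references.items()}
    gene_id = identities[gene_label]
    pseudo_ids = {k: v for k, v in identities.items() if k != gene_label}
    best_pseudo = max(pseudo_ids.values())
    if gene_id > threshold and gene_id > best_pseudo:
        classification = "CYP2D6"
    elif best_pseudo > threshold and best_pseudo > gene_id:
        classification = "pseudogene"
    else:
        classification = "indeterminate"
    return IdentityResult(query_id, identities, classification, threshold)


# ---------------------------------------------------------------------------
# Bundled fixtures
# ---------------------------------------------------------------------------

def load_primer_table(path: str | Path | None = None) -> list[PrimerRecord]:
    """Load the bundled (or a user-supplied) primer/probe metrics TSV."""
    if path is None:
        ref = resources.files("cyp2d6star.data").joinpath("primer_panel.tsv")
        with ref.open() as fh:
            frame = pd.read_csv(fh, sep="\t", comment="#")
    else:
        frame = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for _, row in frame.iterrows():
        records.append(
            PrimerRecord(
                name=row["name"],
                sequence=row["sequence"],
                role=row["role"],
                analysis=row["analysis"],
                reported_length=int(row["length_bp"]) if pd.notna(row["length_bp"]) else None,
                reported_gc=float(row["gc_percent"]) if pd.notna(row["gc_percent"]) else None,
                reported_tm=float(row["tm_c"]) if pd.notna(row["tm_c"]) else None,
                reported_amplicon_size=(
                    int(row["amplicon_bp"]) if pd.notna(row["amplicon_bp"]) else None
                ),
            )
        )
    return records


def primer_qc_report(records: Sequence[PrimerRecord] | None = None) -> pd.DataFrame:
    """Computed length/GC/Tm per oligo alongside the reported values."""
    if records is None:
        records = load_primer_table()
    rows = []
    for r in records:
        rows.append(
            {
                "analysis": r.analysis,
                "name": r.name,
                "role": r.role,
                "sequence": r.sequence,
                "length": len(r.sequence),
                "reported_length": r.reported_length,
                "gc_percent": gc_percent(r.sequence),
                "reported_gc": r.reported_gc,
                "tm_c": round(melting_temperature(r.sequence), 1),
                "reported_tm": r.reported_tm,
                "amplicon_bp": r.reported_amplicon_size,
            }
        )
    return pd.DataFrame(rows)


def load_int2_references(path: str | Path | None = None) -> dict[str, str]:
    """Labelled intron-2 reference sequences for the identity classifier.

    The bundled file carries synthetic 1,101-base stand-ins for the
    functional gene and the pseudogene at realistic (~92%) homology; they
    are generated sequences, not GenBank records.
    """
    if path is None:
        ref = resources.files("cyp2d6star.data").joinpath("int2_references_synthetic.fasta")
        with ref.open() as fh:
            records = list(SeqIO.parse(fh, "fasta"))
    else:
        records = list(SeqIO.parse(str(path), "fasta"))
    out = {}
    for rec in records:
        label = rec.id.split("_")[0]
        out[label] = str(rec.seq).upper()
    return out
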