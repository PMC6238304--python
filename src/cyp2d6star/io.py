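"""Tabular and VCF ingestion, report writing, and run metadata.

Genotype-table dialect (TSV): one row per sample with columns
``sample_id``, one column per typed locus, and the flag columns
``deletion_band``, ``duplication_band``, ``exon9_conversion``.  Genotype
tokens are dose-agnostic letters ``R/R``, ``R/A``, ``A/A``, ``NA`` by
default; a bases dialect (``C/T`` etc.) is auto-detected against the
catalog's ref/alt bases per column.  Columns that name loci absent from
the catalog are preserved as per-sample metadata with a warning, so
sequencing-only loci ride along without being invented into the calling
model.

VCF input carries genotypes only (records are matched by the catalog's
dbSNP IDs); structural band flags must come from a sidecar TSV because a
site-level VCF has no gel-band semantics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alleles import AlleleTable
from .caller import ALT_ALT, MISSING, REF_ALT, REF_REF, DiplotypeCall, SampleRecord
from .popstats import PopulationSummary

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "read_flag_sidecar",
    "read_vcf_genotypes",
    "write_calls",
    "write_summary",
    "write_truth",
    "run_metadata",
]

log = logging.getLogger(__name__)

FLAG_COLUMNS = ("deletion_band", "duplication_band", "exon9_conversion")

_LETTER_TOKENS = {"R/R": REF_REF, "R/A": REF_ALT, "A/R": REF_ALT, "A/A": ALT_ALT}
_MISSING_TOKENS = {"NA", "N/A", ".", "./.", ""}
_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n", ""}
_CALL_TO_LETTERS = {REF_REF: "R/R", REF_ALT: "R/A", ALT_ALT: "A/A", MISSING: "NA"}


def _parse_flag(token: object, row: int, col: str) -> bool:
    s = str(token).strip().lower()
    if s in ("nan",):
        return False
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"row {row}, column {col}: bad boolean token {token!r}")


def _parse_genotype(token: object, locus: str, table: AlleleTable, row: int) -> str:
    s = str(token).strip().upper()
    if s in _MISSING_TOKENS or s == "NAN":
        return MISSING
    if s in _LETTER_TOKENS:
        return _LETTER_TOKENS[s]
    # bases dialect: match the two bases against the catalog ref/alt
    variant = table.variants[locus]
    parts = s.replace("|", "/").split("/")
    if len(parts) == 2 and all(p in {variant.ref_base, variant.alt_base} for p in parts):
        dose = sum(p == variant.alt_base for p in parts)
        return {0: REF_REF, 1: REF_ALT, 2: ALT_ALT}[dose]
    raise ValueError(f"row {row}, column {locus}: bad genotype token {token!r}")


def read_genotype_table(path: str | Path, table: AlleleTable) -> list[SampleRecord]:
    """Read the genotype-table TSV dialect into sample records."""
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "sample_id" not in frame.columns:
        raise ValueError(f"{path}: missing required column 'sample_id'")
    locus_cols = [c for c in frame.columns if c in table.variants]
    extra_cols = [
        c for c in frame.columns if c not in table.variants
        and c not in FLAG_COLUMNS and c != "sample_id"
    ]
    if extra_cols:
        log.warning(
            "%s: columns %s are not catalog loci; preserved as metadata", path, extra_cols
        )
    samples = []
    for i, row in frame.iterrows():
        rownum = int(i) + 2  # 1-based file line, after the header
        genotypes = {
            locus: _parse_genotype(row[locus], locus, table, rownum) for locus in locus_cols
        }
        exon9 = "untested"
        if "exon9_conversion" in frame.columns and pd.notna(row["exon9_conversion"]):
            exon9 = str(row["exon9_conversion"]).strip().lower()
        samples.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                genotypes=genotypes,
                deletion_band=(
                    _parse_flag(row["deletion_band"], rownum, "deletion_band")
                    if "deletion_band" in frame.columns else False
                ),
                duplication_band=(
                    _parse_flag(row["duplication_band"], rownum, "duplication_band")
                    if "duplication_band" in frame.columns else False
                ),
                exon9_conversion=exon9,
                meta={c: row[c] for c in extra_cols if pd.notna(row[c])},
            )
        )
    return samples


def write_genotype_table(
    samples: Sequence[SampleRecord], path: str | Path, table: AlleleTable
) -> None:
    """Write samples in the TSV dialect consumed by :func:`read_genotype_table`."""
    loci = list(table.informative_loci)
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id}
        for locus in loci:
            row[locus] = _CALL_TO_LETTERS[s.call_at(locus)]
        row["deletion_band"] = int(s.deletion_band)
        row["duplication_band"] = int(s.duplication_band)
        row["exon9_conversion"] = s.exon9_conversion
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_flag_sidecar(path: str | Path) -> dict[str, dict]:
    """Read a sidecar TSV of structural flags keyed by sample_id."""
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "sample_id" not in frame.columns:
        raise ValueError(f"{path}: missing required column 'sample_id'")
    out: dict[str, dict] = {}
    for i, row in frame.iterrows():
        rownum = int(i) + 2
        entry: dict = {}
        if "deletion_band" in frame.columns:
            entry["deletion_band"] = _parse_flag(row["deletion_band"], rownum, "deletion_band")
        if "duplication_band" in frame.columns:
            entry["duplication_band"] = _parse_flag(
                row["duplication_band"], rownum, "duplication_band"
            )
        if "exon9_conversion" in frame.columns and pd.notna(row["exon9_conversion"]):
            entry["exon9_conversion"] = str(row["exon9_conversion"]).strip().lower()
        out[str(row["sample_id"])] = entry
    return out


def read_vcf_genotypes(
    path: str | Path,
    table: AlleleTable,
    sidecar: str | Path | Mapping[str, dict] | None = None,
) -> list[SampleRecord]:
    """Read genotypes from a VCF, matching records by catalog rsIDs.

    Biallelic GT fields map to ref_ref / ref_alt / alt_alt; absent records
    or missing genotypes map to ``missing``.  Structural flags default to
    false/untested unless a sidecar provides them.  A multiallelic record
    at a catalog rsID is an error.
    """
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    rsid_to_locus = table.rsid_map()
    vcf = VCF(str(path))
    sample_names = list(vcf.samples)
    genotypes: dict[str, dict[str, str]] = {s: {} for s in sample_names}
    for record in vcf:
        locus = rsid_to_locus.get(record.ID or "")
        if locus is None:
            continue
        if len(record.ALT) > 1:
            raise ValueError(f"{path}: multiallelic record at {record.ID} is not supported")
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        mapping = {0: REF_REF, 1: REF_ALT, 2: MISSING, 3: ALT_ALT}
        for sample, gt in zip(sample_names, record.gt_types):
            genotypes[sample][locus] = mapping[int(gt)]
    vcf.close()

    flags: Mapping[str, dict]
    if sidecar is None:
        flags = {}
    elif isinstance(sidecar, (str, Path)):
        flags = read_flag_sidecar(sidecar)
    else:
        flags = sidecar

    samples = []
    for name in sample_names:
        extra = flags.get(name, {})
        samples.append(
            SampleRecord(
                sample_id=name,
                genotypes=genotypes[name],
                deletion_band=bool(extra.get("deletion_band", False)),
                duplication_band=bool(extra.get("duplication_band", False)),
                exon9_conversion=extra.get("exon9_conversion", "untested"),
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

def run_metadata(seed: int | None = None, config: Mapping | None = None) -> dict:
    """Reproducibility block appended to every written report."""
    from . import __version__

    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "package": "cyp2d6star",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest()[:16],
    }


def _append_metadata_comment(path: Path, meta: Mapping) -> None:
    with open(path, "a") as fh:
        fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")


def write_calls(
    calls: Sequence[DiplotypeCall],
    path: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "best_pair": "/".join(c.best_pair) if c.best_pair else "",
            "status": c.status,
            "n_consistent": len(c.consistent_pairs),
            "consistent_pairs": ";".join("/".join(p) for p in c.consistent_pairs),
            "notes": ";".join(c.notes),
        }
        for c in calls
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    _append_metadata_comment(path, run_metadata(seed, config))


def write_truth(truths: Sequence, path: str | Path) -> None:
    rows = [{"sample_id": t.sample_id, "true_diplotype": "/".join(t.true_diplotype)} for t in truths]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_summary(
    summary: PopulationSummary,
    tsv_path: str | Path | None = None,
    json_path: str | Path | None = None,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    """Write a cohort summary as stacked TSV tables and/or a JSON report."""
    meta = run_metadata(seed, config)
    if tsv_path is not None:
        tsv_path = Path(tsv_path)
        frames = summary.to_frames()
        with open(tsv_path, "w") as fh:
            fh.write(f"# n_samples={summary.n_samples}\tn_excluded={summary.n_excluded}\n")
            for label, frame in frames.items():
                fh.write(f"# [{label}]\n")
                frame.to_csv(fh, sep="\t", index=False)
        _append_metadata_comment(tsv_path, meta)
    if json_path is not None:
        doc = {
            "n_samples": summary.n_samples,
            "n_excluded": summary.n_excluded,
            "allele_counts": summary.allele_counts,
            "allele_freqs": {a: round(f, 4) for a, f in summary.allele_freqs.items()},
            "diplotype_counts": {"/".join(p): n for p, n in summary.diplotype_counts.items()},
            "diplotype_freqs": {"/".join(p): round(f, 4) for p, f in summary.diplotype_freqs.items()},
            "derived_snp_freqs": {v: round(f, 4) for v, f in summary.derived_snp_freqs.items()},
            "function_burden": {k: round(v, 4) for k, v in summary.function_burden.items()},
            "mean_activity_score": round(summary.mean_activity_score, 4),
            "hwe": {v: round(p, 6) for v, p in summary.hwe.items()},
            "run": meta,
        }
        Path(json_path).write_text(json.dumps(doc, indent=2) + "\n")
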