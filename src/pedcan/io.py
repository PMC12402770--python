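"""Readers and writers for the tabular formats the pipeline touches.

MAF (tab-separated, v2.4-style columns), SEG, BED (0-based half-open), and
plain TSV for fusions, methylation calls, histologies and expression
matrices. All readers return the domain types in :mod:`pedcan.types`; all
writers produce files their readers parse back to equal in-memory values.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .intervals import GenomeIntervals
from .types import (
    CnvSegment,
    FusionCall,
    HistologyRecord,
    MethylationCall,
    VariantCall,
)


class FormatError(ValueError):
    """A file violates its format contract (missing column, bad row)."""


MAF_COLUMNS = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "t_depth",
    "t_alt_count",
    "n_depth",
    "gnomad_af",
    "HotSpotAllele",
    "Variant_Classification",
    "HGVSp_Short",
    "Tumor_Sample_Barcode",
    "caller",
]

_MAF_REQUIRED = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Tumor_Sample_Barcode",
]


def _opt_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return int(value)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def _require_columns(df: pd.DataFrame, required, path, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} file {path} is missing required column(s): {missing}")


def read_maf(path, default_caller: str = "") -> List[VariantCall]:
    """Read a MAF-style TSV into :class:`VariantCall` records.

    Comment lines starting with ``#`` are skipped. Missing numeric fields
    parse to ``None``, never to zero. A ``caller`` column, if absent, is
    filled with *default_caller*.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    _require_columns(df, _MAF_REQUIRED, path, "MAF")
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            records.append(
                VariantCall(
                    caller=row.get("caller", "") or default_caller,
                    chrom=row["Chromosome"],
                    pos=int(row["Start_Position"]),
                    ref=row["Reference_Allele"],
                    alt=row["Tumor_Seq_Allele2"],
                    sample_id=row["Tumor_Sample_Barcode"],
                    t_depth=_opt_int(row.get("t_depth", "")),
                    t_alt_count=_opt_int(row.get("t_alt_count", "")),
                    n_depth=_opt_int(row.get("n_depth", "")),
                    gnomad_af=_opt_float(row.get("gnomad_af", "")),
                    hotspot=str(row.get("HotSpotAllele", "")).strip() in ("1", "True", "true", "Yes"),
                    variant_classification=row.get("Variant_Classification", ""),
                    hugo_symbol=row.get("Hugo_Symbol", ""),
                    hgvsp_short=row.get("HGVSp_Short", ""),
                )
            )
        except (ValueError, KeyError) as exc:
            raise FormatError(f"malformed MAF row at {path} line {idx}: {exc}") from exc
    return records


def write_maf(records, path) -> None:
    rows = []
    for v in records:
        support = getattr(v, "caller_support", None)
        caller = ";".join(sorted(support)) if support else getattr(v, "caller", "")
        rows.append(
            {
                "Hugo_Symbol": v.hugo_symbol,
                "Chromosome": v.chrom,
                "Start_Position": v.pos,
                "Reference_Allele": v.ref,
                "Tumor_Seq_Allele2": v.alt,
                "t_depth": v.t_depth if v.t_depth is not None else "",
                "t_alt_count": v.t_alt_count if v.t_alt_count is not None else "",
                "n_depth": v.n_depth if v.n_depth is not None else "",
                "gnomad_af": v.gnomad_af if v.gnomad_af is not None else "",
                "HotSpotAllele": int(bool(v.hotspot)),
                "Variant_Classification": v.variant_classification,
                "HGVSp_Short": v.hgvsp_short,
                "Tumor_Sample_Barcode": v.sample_id,
                "caller": caller,
            }
        )
    pd.DataFrame(rows, columns=MAF_COLUMNS).to_csv(path, sep="\t", index=False)


SEG_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "copy.num", "status", "caller"]


def read_seg(path, default_caller: str = "") -> List[CnvSegment]:
    """Read a SEG-style TSV; coordinates are 1-based inclusive internally."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    _require_columns(df, ["ID", "chrom", "loc.start", "loc.end"], path, "SEG")
    segments = []
    # itertuples would mangle the dotted SEG column names
    for idx, row in enumerate(df.to_dict("records"), start=2):
        try:
            segments.append(
                CnvSegment(
                    caller=row.get("caller", "") or default_caller,
                    chrom=row["chrom"],
                    start=int(row["loc.start"]),
                    end=int(row["loc.end"]),
                    sample_id=row["ID"],
                    copy_number=_opt_int(row.get("copy.num", "")),
                    status=row.get("status", "") or None,
                )
            )
        except ValueError as exc:
            raise FormatError(f"malformed SEG row at {path} line {idx}: {exc}") from exc
    return segments


def write_seg(segments, path) -> None:
    rows = []
    for s in segments:
        callers = getattr(s, "supporting_callers", None)
        caller = ";".join(sorted(callers)) if callers else getattr(s, "caller", "")
        status = getattr(s, "status", None) or getattr(s, "direction", "")
        rows.append(
            {
                "ID": s.sample_id,
                "chrom": s.chrom,
                "loc.start": s.start,
                "loc.end": s.end,
                "copy.num": s.copy_number if s.copy_number is not None else "",
                "status": status or "",
                "caller": caller,
            }
        )
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_bed(path, name: str = "") -> GenomeIntervals:
    """Read a BED file (0-based half-open) into a normalized interval set."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"BED line {lineno} in {path} has fewer than 3 fields")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"malformed BED line {lineno} in {path}: {exc}") from exc
            if start < 0 or end < 0:
                raise FormatError(f"negative coordinate at BED line {lineno} in {path}")
            intervals.append((chrom, start, end))
    return GenomeIntervals(intervals, name=name or Path(path).stem)


def write_bed(intervals: GenomeIntervals, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


FUSION_COLUMNS = ["FusionName", "Gene1A", "Gene1B", "caller", "Sample", "cancer_group", "annots"]


def read_fusions(path) -> List[FusionCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["Gene1A", "Gene1B", "caller", "Sample"], path, "fusion")
    return [
        FusionCall(
            gene5=row.Gene1A,
            gene3=row.Gene1B,
            callers=frozenset(c for c in row.caller.split(";") if c),
            sample_id=row.Sample,
            cancer_group=getattr(row, "cancer_group", ""),
            annotations=frozenset(a for a in getattr(row, "annots", "").split(";") if a),
        )
        for row in df.itertuples(index=False)
    ]


def write_fusions(fusions, path) -> None:
    rows = [
        {
            "FusionName": f.name,
            "Gene1A": f.gene5,
            "Gene1B": f.gene3,
            "caller": ";".join(sorted(f.callers)),
            "Sample": f.sample_id,
            "cancer_group": f.cancer_group,
            "annots": ";".join(sorted(f.annotations)),
        }
        for f in fusions
    ]
    pd.DataFrame(rows, columns=FUSION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_methylation(path) -> List[MethylationCall]:
    """Read classifier outputs keyed by the harmonized histology field names."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    calls: List[MethylationCall] = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        sample = row.get("Kids_First_Biospecimen_ID") or row.get("sample_id", "")
        if row.get("dkfz_v12_methylation_subclass", ""):
            calls.append(
                MethylationCall(
                    classifier="dkfz_v12",
                    subclass=row["dkfz_v12_methylation_subclass"],
                    score=float(row["dkfz_v12_methylation_subclass_score"]),
                    sample_id=sample,
                    mgmt_status=row.get("dkfz_v12_methylation_mgmt_status") or None,
                    mgmt_estimated=_opt_float(row.get("dkfz_v12_methylation_mgmt_estimated", "")),
                )
            )
        if row.get("NIH_v2_methylation_Class", ""):
            calls.append(
                MethylationCall(
                    classifier="nih_v2",
                    subclass=row["NIH_v2_methylation_Class"],
                    score=float(row["NIH_v2_methylation_Class_mean_score"]),
                    sample_id=sample,
                )
            )
    return calls


def write_methylation(calls, path) -> None:
    by_sample: Dict[str, dict] = {}
    for c in calls:
        row = by_sample.setdefault(c.sample_id, {"Kids_First_Biospecimen_ID": c.sample_id})
        if c.classifier == "dkfz_v12":
            row["dkfz_v12_methylation_subclass"] = c.subclass
            row["dkfz_v12_methylation_subclass_score"] = c.score
            if c.mgmt_status is not None:
                row["dkfz_v12_methylation_mgmt_status"] = c.mgmt_status
            if c.mgmt_estimated is not None:
                row["dkfz_v12_methylation_mgmt_estimated"] = c.mgmt_estimated
        else:
            row["NIH_v2_methylation_Class"] = c.subclass
            row["NIH_v2_methylation_Class_mean_score"] = c.score
    pd.DataFrame(list(by_sample.values())).to_csv(path, sep="\t", index=False)


HISTOLOGY_COLUMNS = [
    "Kids_First_Participant_ID",
    "Kids_First_Biospecimen_ID",
    "tumor_event_id",
    "pathology_diagnosis",
    "pathology_free_text_diagnosis",
    "age_at_diagnosis_years",
    "tumor_descriptor",
    "CNS_region",
    "experimental_strategy",
    "composition",
    "germline_pathogenic",
]


def read_histologies(path) -> List[HistologyRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(
        df, ["Kids_First_Participant_ID", "Kids_First_Biospecimen_ID"], path, "histologies"
    )
    records = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        records.append(
            HistologyRecord(
                participant_id=row["Kids_First_Participant_ID"],
                biospecimen_id=row["Kids_First_Biospecimen_ID"],
                tumor_event_id=row.get("tumor_event_id", "") or row["Kids_First_Biospecimen_ID"],
                pathology_diagnosis=row.get("pathology_diagnosis", ""),
                pathology_free_text_diagnosis=row.get("pathology_free_text_diagnosis", ""),
                age_at_diagnosis_years=_opt_float(row.get("age_at_diagnosis_years", "")),
                tumor_descriptor=row.get("tumor_descriptor", ""),
                cns_region=row.get("CNS_region", ""),
                experimental_strategy=row.get("experimental_strategy", ""),
                composition=row.get("composition", ""),
                germline_pathogenic=frozenset(
                    g for g in row.get("germline_pathogenic", "").split(";") if g
                ),
            )
        )
    return records


def write_histologies(records, path) -> None:
    rows = [
        {
            "Kids_First_Participant_ID": r.participant_id,
            "Kids_First_Biospecimen_ID": r.biospecimen_id,
            "tumor_event_id": r.tumor_event_id,
            "pathology_diagnosis": r.pathology_diagnosis,
            "pathology_free_text_diagnosis": r.pathology_free_text_diagnosis,
            "age_at_diagnosis_years": (
                r.age_at_diagnosis_years if r.age_at_diagnosis_years is not None else ""
            ),
            "tumor_descriptor": r.tumor_descriptor,
            "CNS_region": r.cns_region,
            "experimental_strategy": r.experimental_strategy,
            "composition": r.composition,
            "germline_pathogenic": ";".join(sorted(r.germline_pathogenic)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=HISTOLOGY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples expression matrix (TSV, first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.duplicated().any():
        raise FormatError(f"duplicate sample columns in expression matrix {path}")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"negative expression values in {path}")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")
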