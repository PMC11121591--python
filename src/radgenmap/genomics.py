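"""Copy-number segment tables, QC filtering, and gene-level gain/loss scores.

Segment tables follow the tab-separated export of array-based copy-number
callers: one row per contiguous segment with ``sample_id, chrom, start, end``
and either an integer ``copy_number`` or an explicit signed ``call``
(+1 gain / -1 loss / 0 neutral).  Coordinates are 1-based inclusive, as in
ChAS-style exports.

A gene panel maps each gene of interest to its interval and pathway group.
The default panel carries the nine-gene hypoxia / androgen / apoptosis set
with synthetic toy coordinates (one locus per chromosome) so that fixtures
never require a genome download; the panel file header records this.

The per-gene score of a sample is the signed count of segments overlapping
the gene: (number of gains) - (number of losses).  Samples whose array QC
call score falls below 80% are excluded before any downstream analysis.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CnvSegment",
    "GenePanel",
    "PATHWAYS",
    "default_panel",
    "read_segments",
    "write_segments",
    "read_panel",
    "write_panel",
    "read_metadata",
    "qc_filter",
    "call_state",
    "score_genes",
    "DEFAULT_QC_THRESHOLD",
]

PATHWAYS = ("hypoxia", "androgen", "apoptosis")
DEFAULT_QC_THRESHOLD = 80.0

SEGMENT_COLUMNS = ("sample_id", "chrom", "start", "end", "copy_number")


@dataclass(frozen=True)
class CnvSegment:
    """One contiguous copy-number segment (1-based inclusive coordinates)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int | None = None
    call: int | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.copy_number is None and self.call is None:
            raise ValueError("segment needs a copy_number or an explicit call")
        if self.copy_number is not None and self.copy_number < 0:
            raise ValueError(f"negative copy number {self.copy_number}")
        if self.call is not None and self.call not in (-1, 0, 1):
            raise ValueError(f"call must be in {{-1, 0, +1}}, got {self.call}")


@dataclass(frozen=True)
class PanelEntry:
    gene: str
    chrom: str
    start: int
    end: int
    pathway: str
    display_name: str


@dataclass
class GenePanel:
    """Gene name -> (interval, pathway) mapping for the panels of interest."""

    entries: dict[str, PanelEntry]
    genome_build: str = "toy-synthetic-1"

    def __post_init__(self) -> None:
        for name, e in self.entries.items():
            if e.pathway not in PATHWAYS:
                raise ValueError(f"unknown pathway {e.pathway!r} for gene {name}")

    @property
    def genes(self) -> list[str]:
        return list(self.entries)

    def pathway_genes(self, pathway: str) -> list[str]:
        return [g for g, e in self.entries.items() if e.pathway == pathway]

    def display_name(self, gene: str) -> str:
        return self.entries[gene].display_name


def default_panel() -> GenePanel:
    """The nine-gene panel: hypoxia, androgen-regulated and apoptosis groups.

    Coordinates are synthetic toy loci (50 kb per gene, one per chromosome);
    TRAIL.R2 is carried under its systematic locus name TNFRSF10B and NKX3.1
    under NKX3-1, with the familiar display names preserved for reporting.
    """
    rows = [
        # gene key, chrom, pathway, display name
        ("P4HA1", "chr10", "hypoxia", "P4HA1"),
        ("ANGPTL4", "chr19", "hypoxia", "ANGPTL4"),
        ("VEGFA", "chr6", "hypoxia", "VEGFA"),
        ("KLK2", "chr19b", "androgen", "KLK2"),
        ("KLK3", "chr19c", "androgen", "KLK3"),
        ("NKX3-1", "chr8", "androgen", "NKX3.1"),
        ("TP53BP2", "chr1", "apoptosis", "TP53BP2"),
        ("BAG3", "chr10b", "apoptosis", "BAG3"),
        ("TNFRSF10B", "chr8b", "apoptosis", "TRAIL.R2"),
    ]
    entries = {
        gene: PanelEntry(gene, chrom, 1_000_000, 1_050_000, pathway, display)
        for gene, chrom, pathway, display in rows
    }
    return GenePanel(entries)


def write_panel(panel: GenePanel, path: Path | str) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# genome_build: {panel.genome_build}\n")
        fh.write("gene\tchrom\tstart\tend\tpathway\tdisplay_name\n")
        for e in panel.entries.values():
            fh.write(
                f"{e.gene}\t{e.chrom}\t{e.start}\t{e.end}\t{e.pathway}\t{e.display_name}\n"
            )


def read_panel(path: Path | str) -> GenePanel:
    build = "unknown"
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    body_start = 0
    for ln in lines:
        if ln.startswith("#"):
            body_start += 1
            if "genome_build:" in ln:
                build = ln.split("genome_build:", 1)[1].strip()
        else:
            break
    df = pd.read_csv(io.StringIO("\n".join(lines[body_start:])), sep="\t")
    required = {"gene", "chrom", "start", "end", "pathway"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel file missing columns: {sorted(required - set(df.columns))}")
    entries = {}
    for _, row in df.iterrows():
        entries[str(row["gene"])] = PanelEntry(
            str(row["gene"]),
            str(row["chrom"]),
            int(row["start"]),
            int(row["end"]),
            str(row["pathway"]),
            str(row.get("display_name", row["gene"])),
        )
    return GenePanel(entries, genome_build=build)


def write_segments(segments: Iterable[CnvSegment], path: Path | str) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "copy_number": 2 + s.call if s.copy_number is None else s.copy_number,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=list(SEGMENT_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_segments(path: Path | str) -> list[CnvSegment]:
    """Parse and validate a segment TSV; malformed rows are reported by line.

    Accepts either a ``copy_number`` column or a signed ``call`` column.
    """
    df = pd.read_csv(path, sep="\t")
    has_cn = "copy_number" in df.columns
    has_call = "call" in df.columns
    required = {"sample_id", "chrom", "start", "end"}
    missing = sorted(required - set(df.columns))
    if missing or not (has_cn or has_call):
        missing2 = missing + ([] if has_cn or has_call else ["copy_number|call"])
        raise ValueError(f"segment table missing columns: {missing2}")
    segments = []
    for pos, (_, row) in enumerate(df.iterrows()):
        line_no = pos + 2  # 1-based, after the header line
        try:
            segments.append(
                CnvSegment(
                    sample_id=str(row["sample_id"]),
                    chrom=str(row["chrom"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    copy_number=int(row["copy_number"]) if has_cn else None,
                    call=int(row["call"]) if has_call else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"invalid segment at line {line_no}: {exc}") from exc
    return segments


def read_metadata(path: Path | str) -> pd.DataFrame:
    """Patient metadata TSV: patient_id, grade_group, qc_score."""
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "grade_group", "qc_score"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def qc_filter(
    metadata: pd.DataFrame, threshold: float = DEFAULT_QC_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain samples with QC call score >= threshold (boundary inclusive).

    Returns (retained, exclusion_report); the report lists each excluded
    sample with its score.  Order-preserving and idempotent.
    """
    if metadata["qc_score"].isna().any():
        bad = metadata.loc[metadata["qc_score"].isna(), "patient_id"].tolist()
        raise ValueError(f"samples missing a QC score: {bad}")
    keep = metadata["qc_score"] >= threshold
    retained = metadata.loc[keep].copy()
    excluded = metadata.loc[~keep, ["patient_id", "qc_score"]].copy()
    excluded["reason"] = f"qc_score < {threshold:g}"
    return retained, excluded


def call_state(segment: CnvSegment, baseline: int = 2) -> int:
    """Signed gain/loss call: copy number below/at/above ``baseline``.

    The default baseline is the autosomal diploid 2; pass ``baseline=1`` for
    haploid sex chromosomes.  Explicit calls pass through unchanged.
    """
    if segment.call is not None:
        return int(segment.call)
    cn = segment.copy_number
    if cn < 0:
        raise ValueError(f"negative copy number {cn}")
    return -1 if cn < baseline else (0 if cn == baseline else 1)


def _overlaps(seg: CnvSegment, entry: PanelEntry) -> bool:
    # 1-based inclusive intervals: any shared base
    return seg.chrom == entry.chrom and max(seg.start, entry.start) <= min(seg.end, entry.end)


def _merge_same_state(segments: list[CnvSegment]) -> list[CnvSegment]:
    """Merge overlapping or abutting segments of one sample/chrom/state.

    A copy-number event reported as several contiguous pieces is one event;
    merging first makes gene scores invariant to such splits.
    """
    keyed: dict[tuple, list[CnvSegment]] = {}
    for seg in segments:
        keyed.setdefault((seg.sample_id, seg.chrom, call_state(seg)), []).append(seg)
    merged: list[CnvSegment] = []
    for (sample, chrom, state), group in keyed.items():
        group = sorted(group, key=lambda s: (s.start, s.end))
        cur_start, cur_end = group[0].start, group[0].end
        for seg in group[1:]:
            if seg.start <= cur_end + 1:
                cur_end = max(cur_end, seg.end)
            else:
                merged.append(CnvSegment(sample, chrom, cur_start, cur_end, call=state))
                cur_start, cur_end = seg.start, seg.end
        merged.append(CnvSegment(sample, chrom, cur_start, cur_end, call=state))
    return merged


def score_genes(
    segments: Iterable[CnvSegment],
    panel: GenePanel,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Samples x genes matrix of signed gain/loss scores.

    Each cell is (number of distinct gain events) minus (number of distinct
    loss events) overlapping the gene interval; genes with no overlapping
    segment score 0.  Overlapping or abutting same-state segments of a sample
    are merged into one event first, so the score is invariant to splitting a
    segment into contiguous sub-segments.  ``sample_ids`` forces the row set
    (e.g. QC-retained samples with no segments at all still get an all-zero
    row).
    """
    segments = list(segments)
    if sample_ids is None:
        sample_ids = sorted({s.sample_id for s in segments})
    genes = panel.genes
    scores = pd.DataFrame(0, index=list(sample_ids), columns=genes, dtype=int)
    scores.index.name = "sample_id"
    sample_set = set(scores.index)
    relevant = [s for s in segments if s.sample_id in sample_set]
    for seg in _merge_same_state(relevant):
        state = call_state(seg)
        if state == 0:
            continue
        for gene in genes:
            if _overlaps(seg, panel.entries[gene]):
                scores.loc[seg.sample_id, gene] += state
    return scores
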