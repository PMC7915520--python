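"""Physical anchoring of QTL intervals and candidate-gene geometry.

Markers carry 1-based physical (bp) coordinates from an anchor table;
the 1.5-LOD support interval of a locus's strongest effect is projected
to a physical interval by taking the nearest *anchored* marker at or
outside each cM endpoint (conservative outward widening, so the true
support region is always covered).  Genes from a GFF3 annotation are
listed by coordinate overlap, and candidate genes are placed on the
genetic map by local linear interpolation of cM against bp between
their flanking anchored markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model import QTLLocus
from .qtl import as_map_frame

logger = logging.getLogger(__name__)

DEFAULT_MAX_GENES = 200


def read_anchor_table(path) -> pd.DataFrame:
    """Read a marker anchor TSV with columns ``marker, chrom, bp`` (1-based)."""
    df = pd.read_csv(path, sep="\t")
    return validate_anchors(df)


def validate_anchors(df: pd.DataFrame) -> pd.DataFrame:
    need = {"marker", "chrom", "bp"}
    if not need <= set(df.columns):
        raise ValueError(f"anchor table needs columns {sorted(need)}")
    if (df["bp"] < 1).any():
        raise ValueError("bp positions are 1-based and must be >= 1")
    if df.duplicated(["marker", "chrom"]).any():
        raise ValueError("one bp per marker per chromosome")
    return df


def read_gff3_genes(path) -> pd.DataFrame:
    """Extract ``gene`` features from a GFF3 file.

    Returns columns ``gene_id, chrom, start, end, annotation`` with
    1-based inclusive coordinates.
    """
    cols = ["seqid", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", names=cols, header=None,
                     dtype={"seqid": str})
    genes = df[df["type"] == "gene"].copy()

    def _gene_id(attrs: str) -> str:
        for part in str(attrs).split(";"):
            k, _, v = part.partition("=")
            if k.strip() == "ID":
                return v.strip()
        return str(attrs)

    genes["gene_id"] = genes["attributes"].map(_gene_id)
    out = genes.rename(columns={"seqid": "chrom"})[
        ["gene_id", "chrom", "start", "end", "attributes"]]
    out = out.rename(columns={"attributes": "annotation"})
    if (out["start"] > out["end"]).any():
        raise ValueError("gene with start > end")
    return out.reset_index(drop=True)


@dataclass
class PhysicalInterval:
    """A QTL support interval projected onto physical coordinates."""

    locus_id: str
    chrom: str
    start_bp: int
    end_bp: int
    flank_left: str
    flank_right: str
    clipped: bool = False
    gene_count: Optional[int] = None
    excluded_from_cg: bool = False

    @property
    def span_mbp(self) -> float:
        return (self.end_bp - self.start_bp) / 1e6


def _anchored_markers(map_like, anchors: pd.DataFrame, chrom: str,
                      ) -> pd.DataFrame:
    """Markers on one linkage group with both cM and bp, sorted by cM."""
    map_df = as_map_frame(map_like)
    sub = map_df[map_df["chrom"] == chrom]
    merged = sub.merge(anchors[["marker", "bp"]], on="marker", how="inner")
    return merged.sort_values("cM").reset_index(drop=True)


def qtl_physical_interval(locus: QTLLocus, map_like,
                          anchors: pd.DataFrame) -> PhysicalInterval:
    """Project the highest-LOD member's support interval to bp.

    Each cM endpoint is bounded by the nearest anchored marker at or
    outside it; endpoints beyond all anchors are clipped to the terminal
    anchor and flagged.
    """
    validate_anchors(anchors)
    anchored = _anchored_markers(map_like, anchors, locus.chrom)
    if len(anchored) < 2:
        raise ValueError(f"chromosome {locus.chrom} has fewer than 2 "
                         "anchored markers")
    lo, hi = locus.peak_member.support
    cm = anchored["cM"].to_numpy(float)
    clipped = False
    left_cands = np.flatnonzero(cm <= lo + 1e-9)
    if len(left_cands):
        left = int(left_cands[-1])
    else:
        left = 0
        clipped = True
    right_cands = np.flatnonzero(cm >= hi - 1e-9)
    if len(right_cands):
        right = int(right_cands[0])
    else:
        right = len(anchored) - 1
        clipped = True
    if clipped:
        logger.info("locus %s: support endpoint beyond terminal anchors; "
                    "clipped", locus.locus_id)
    bp_a = int(anchored.loc[left, "bp"])
    bp_b = int(anchored.loc[right, "bp"])
    return PhysicalInterval(
        locus_id=locus.locus_id, chrom=locus.chrom,
        start_bp=min(bp_a, bp_b), end_bp=max(bp_a, bp_b),
        flank_left=str(anchored.loc[left, "marker"]),
        flank_right=str(anchored.loc[right, "marker"]),
        clipped=clipped)


def genes_in_interval(interval: PhysicalInterval, genes: pd.DataFrame,
                      max_genes: int = DEFAULT_MAX_GENES) -> pd.DataFrame:
    """Genes overlapping a physical interval (inclusive coordinates).

    Fills ``interval.gene_count`` and flags intervals exceeding
    ``max_genes`` as excluded from candidate-gene analysis.
    """
    chroms = set(genes["chrom"].unique())
    if interval.chrom not in chroms:
        raise ValueError(f"chromosome {interval.chrom!r} absent from the "
                         f"annotation (has {sorted(chroms)})")
    sub = genes[(genes["chrom"] == interval.chrom)
                & (genes["end"] >= interval.start_bp)
                & (genes["start"] <= interval.end_bp)]
    sub = sub.sort_values("start").reset_index(drop=True)
    interval.gene_count = len(sub)
    interval.excluded_from_cg = len(sub) > max_genes
    if interval.excluded_from_cg:
        logger.info("locus %s: %d genes > cap %d; excluded from CG analysis",
                    interval.locus_id, len(sub), max_genes)
    return sub


def interpolate_gene_cm(gene, map_like, anchors: pd.DataFrame,
                        ) -> tuple[float, bool]:
    """Genetic position of a gene by local linear cM-vs-bp interpolation.

    ``gene`` is a mapping with ``chrom, start, end``; its midpoint bp is
    interpolated between the two flanking anchored markers.  Beyond the
    terminal anchors the position clamps to the terminal cM and the
    returned flag is True.  Locally non-monotone anchors (e.g. small
    inversions) still interpolate but emit a warning.
    """
    validate_anchors(anchors)
    chrom = gene["chrom"]
    mid = (float(gene["start"]) + float(gene["end"])) / 2.0
    anchored = _anchored_markers(map_like, anchors, chrom)
    if len(anchored) < 2:
        raise ValueError(f"chromosome {chrom} has fewer than 2 anchored "
                         "markers")
    by_bp = anchored.sort_values("bp").reset_index(drop=True)
    bp = by_bp["bp"].to_numpy(float)
    cmv = by_bp["cM"].to_numpy(float)
    if np.any(np.diff(bp) == 0):
        raise ValueError("flanking anchors with equal bp positions")
    if not (np.all(np.diff(cmv) >= 0) or np.all(np.diff(cmv) <= 0)):
        logger.warning("non-monotone anchors on %s; interpolation applied "
                       "anyway", chrom)
    if mid <= bp[0]:
        return float(cmv[0]), mid < bp[0]
    if mid >= bp[-1]:
        return float(cmv[-1]), mid > bp[-1]
    j = int(np.searchsorted(bp, mid, side="right"))
    i = j - 1
    frac = (mid - bp[i]) / (bp[j] - bp[i])
    return float(cmv[i] + frac * (cmv[j] - cmv[i])), False
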