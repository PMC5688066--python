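"""Genome-streamlining statistics.

Streamlined marine genomes pack coding sequence densely and carry little
gene redundancy.  Two summary statistics capture this: the percentage of
genome bases inside protein- or RNA-coding genes (overlapping genes counted
once, as a base is either coding or not), and COG redundancy — the mean
occurrence count per distinct COG identifier, 1.0 meaning every orthologous
group is single-copy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd


@dataclass
class GeneInterval:
    """One gene span on a contig, 0-based half-open."""

    contig_id: str
    start: int
    end: int
    kind: str = "protein"  # or "RNA"
    cog_id: str | None = None
    function: str | None = None

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig_id}"
            )


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    total, cur_start, cur_end = 0, None, None
    for start, end in sorted(intervals):
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def coding_base_pct(
    genes: Sequence[GeneInterval] | pd.DataFrame,
    genome_size: int,
    contig_lengths: Mapping[str, int] | None = None,
    mode: str = "union",
) -> float:
    """Percent of genome bases inside coding genes.

    ``mode="union"`` (default) counts overlapping bases once; ``"summed"``
    adds raw gene lengths for comparison.  With ``contig_lengths`` given,
    intervals beyond their contig raise an error.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if mode not in ("union", "summed"):
        raise ValueError("mode must be 'union' or 'summed'")
    if isinstance(genes, pd.DataFrame):
        genes = [
            GeneInterval(contig_id=str(g.contig_id), start=int(g.start),
                         end=int(g.end))
            for g in genes.itertuples(index=False)
        ]
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        if contig_lengths is not None and g.end > contig_lengths[g.contig_id]:
            raise ValueError(
                f"gene [{g.start}, {g.end}) exceeds contig {g.contig_id} "
                f"length {contig_lengths[g.contig_id]}"
            )
        by_contig.setdefault(g.contig_id, []).append((g.start, g.end))
    if mode == "summed":
        coding = sum(e - s for spans in by_contig.values() for s, e in spans)
    else:
        coding = sum(_union_length(spans) for spans in by_contig.values())
    return 100.0 * coding / genome_size


def cog_redundancy(cog_ids: Iterable[str | None]) -> float | None:
    """Mean occurrence count per distinct COG; None for an empty list.

    Genes without a COG assignment (None/empty) are excluded — only assigned
    COGs are occurrences.
    """
    counts = Counter(c for c in cog_ids if c)
    if not counts:
        return None
    return sum(counts.values()) / len(counts)


def streamlining_table(
    orfs: pd.DataFrame,
    genome_sizes: Mapping[str, int],
    group_col: str = "bin_id",
) -> pd.DataFrame:
    """Per-genome streamlining metrics from an ORF table.

    One row per group (bin/SAG id): coding_pct, cog_redundancy, n_genes.
    """
    rows = []
    for gid, sub in orfs.groupby(group_col, sort=True):
        rows.append({
            "genome_id": gid,
            "coding_pct": coding_base_pct(sub, genome_sizes[gid]),
            "cog_redundancy": cog_redundancy(sub.get("cog_id", pd.Series(dtype=object))),
            "n_genes": len(sub),
        })
    return pd.DataFrame(rows, columns=["genome_id", "coding_pct",
                                       "cog_redundancy", "n_genes"])
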