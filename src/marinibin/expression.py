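"""Expression (RPKM) computation and aggregation.

RPKM = mapped_reads * 1e9 / (gene_length_bp * total_mapped_reads) per ORF.
Per-sample RPKM values are summed over ORFs sharing a functional annotation
within a bin, and per-redox-class profiles average the per-sample sums over
*all* samples of a class (a sample with no signal still counts in the
denominator).  Near-identical gene copies within a bin are first collapsed:
single-linkage grouping at >=75% amino-acid identity.  Marker genes (e.g.
nosZ variants) are clustered by a greedy centroid pass at >=95% identity —
sequences visited in decreasing length order, each joining the first
centroid it matches, otherwise founding a new cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd


def rpkm(mapped_reads: float, gene_length_bp: float, total_mapped: float) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    if gene_length_bp <= 0 or total_mapped <= 0:
        raise ValueError("gene_length_bp and total_mapped must be positive")
    return mapped_reads * 1e9 / (gene_length_bp * total_mapped)


def add_rpkm(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorised RPKM column for a (count, gene_length, total_mapped) table."""
    for col in ("count", "gene_length", "total_mapped"):
        if col not in records.columns:
            raise ValueError(f"records lack required column {col!r}")
    if (records["gene_length"] <= 0).any() or (records["total_mapped"] <= 0).any():
        raise ValueError("gene_length and total_mapped must be positive")
    out = records.copy()
    out["rpkm"] = out["count"] * 1e9 / (out["gene_length"] * out["total_mapped"])
    return out


# ---------------------------------------------------------------------------
# pairwise identity tables


def _normalize_pairs(
    pairs: Mapping[tuple[str, str], float] | pd.DataFrame,
) -> dict[tuple[str, str], float]:
    """Canonicalise a pairwise identity table to sorted-tuple keys, rejecting
    asymmetric conflicting entries."""
    if isinstance(pairs, pd.DataFrame):
        it = ((str(r[0]), str(r[1]), float(r[2]))
              for r in pairs.itertuples(index=False))
    else:
        it = ((a, b, float(v)) for (a, b), v in pairs.items())
    table: dict[tuple[str, str], float] = {}
    for a, b, v in it:
        key = (a, b) if a <= b else (b, a)
        if key in table and abs(table[key] - v) > 1e-9:
            raise ValueError(
                f"conflicting identities for pair {key}: {table[key]} vs {v}"
            )
        table[key] = v
    return table


def _pair_identity(table: dict[tuple[str, str], float], a: str, b: str) -> float:
    key = (a, b) if a <= b else (b, a)
    if key not in table:
        raise KeyError(f"missing pairwise identity for {key}")
    return table[key]


# ---------------------------------------------------------------------------
# dereplication of within-bin gene copies


def dereplicate_copies(
    pairs: Mapping[tuple[str, str], float] | pd.DataFrame,
    threshold: float = 75.0,
    ids: Iterable[str] | None = None,
    inclusive: bool = True,
) -> list[list[str]]:
    """Single-linkage groups of gene copies at >= ``threshold``% identity.

    Groups are the connected components of the graph whose edges are pairs
    meeting the threshold; ``ids`` adds isolated genes as singletons.
    Returned groups and their members are sorted for determinism.
    """
    table = _normalize_pairs(pairs)
    g = nx.Graph()
    for (a, b) in table:
        g.add_node(a)
        g.add_node(b)
    if ids is not None:
        g.add_nodes_from(str(i) for i in ids)
    for (a, b), v in table.items():
        if (v >= threshold) if inclusive else (v > threshold):
            g.add_edge(a, b)
    groups = [sorted(c) for c in nx.connected_components(g)]
    return sorted(groups)


# ---------------------------------------------------------------------------
# aggregation


def aggregate_function_rpkm(
    records: pd.DataFrame,
    by: Sequence[str] = ("bin_id", "function", "sample_id"),
) -> pd.DataFrame:
    """Sum per-ORF RPKM within each (bin, function, sample) group."""
    if not len(records):
        return pd.DataFrame(columns=[*by, "rpkm"])
    if "rpkm" not in records.columns:
        records = add_rpkm(records)
    return (
        records.groupby(list(by), sort=True, dropna=False)["rpkm"]
        .sum()
        .reset_index()
    )


def profile_by_redox(
    per_sample: pd.Series | Mapping[str, float],
    sample_class: Mapping[str, str] | pd.Series,
) -> dict[str, float]:
    """Mean per-sample summed RPKM per redox class.

    The denominator is the number of samples of the class in
    ``sample_class``; samples absent from ``per_sample`` contribute 0 to the
    numerator but still count.  Classes with no samples are omitted (missing,
    not zero).
    """
    values = dict(per_sample.items()) if isinstance(per_sample, pd.Series) \
        else dict(per_sample)
    classes = dict(sample_class.items()) if isinstance(sample_class, pd.Series) \
        else dict(sample_class)
    unknown = set(values) - set(classes)
    if unknown:
        raise ValueError(f"sample(s) without a redox class: {sorted(unknown)[:5]}")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for sample, cls in classes.items():
        sums[cls] = sums.get(cls, 0.0) + float(values.get(sample, 0.0))
        counts[cls] = counts.get(cls, 0) + 1
    return {cls: sums[cls] / counts[cls] for cls in sums}


# ---------------------------------------------------------------------------
# greedy marker clustering


@dataclass
class MarkerCluster:
    """One greedy-centroid cluster of marker-gene sequences."""

    cluster_id: str
    centroid: str
    members: list[str] = field(default_factory=list)
    threshold: float = 95.0


def greedy_cluster_markers(
    lengths: Mapping[str, int],
    pairs: Mapping[tuple[str, str], float] | pd.DataFrame,
    threshold: float = 95.0,
    inclusive: bool = True,
) -> list[MarkerCluster]:
    """Greedy centroid clustering at >= ``threshold``% identity.

    Sequences are visited in decreasing length order (length ties broken
    lexicographically by id); each joins the earliest-founded centroid it
    matches at the threshold, otherwise founds a new cluster.  Deterministic
    given lengths and identities.
    """
    table = _normalize_pairs(pairs)
    order = sorted(lengths, key=lambda i: (-lengths[i], i))
    clusters: list[MarkerCluster] = []
    for sid in order:
        placed = False
        for cl in clusters:
            ident = _pair_identity(table, sid, cl.centroid)
            if (ident >= threshold) if inclusive else (ident > threshold):
                cl.members.append(sid)
                placed = True
                break
        if not placed:
            clusters.append(MarkerCluster(
                cluster_id=f"marker{len(clusters)}", centroid=sid,
                members=[sid], threshold=threshold,
            ))
    return clusters


def marker_profile(
    records: pd.DataFrame,
    clusters: Sequence[MarkerCluster],
    sample_class: Mapping[str, str] | pd.Series,
    orf_marker: Mapping[str, str],
) -> pd.DataFrame:
    """Per-redox-class mean summed RPKM for each marker cluster.

    ``orf_marker`` maps ORF ids to marker sequence ids; ORFs whose marker
    belongs to a cluster contribute their RPKM to that cluster's per-sample
    sum, which is then averaged per redox class.
    """
    member_cluster = {m: cl.cluster_id for cl in clusters for m in cl.members}
    recs = records.copy()
    if "rpkm" not in recs.columns:
        recs = add_rpkm(recs)
    recs["cluster_id"] = recs["orf_id"].map(
        lambda o: member_cluster.get(orf_marker.get(o, ""), None)
    )
    recs = recs.dropna(subset=["cluster_id"])
    rows = []
    for cid, sub in recs.groupby("cluster_id", sort=True):
        per_sample = sub.groupby("sample_id")["rpkm"].sum()
        for cls, mean in sorted(profile_by_redox(per_sample, sample_class).items()):
            rows.append((cid, cls, mean))
    return pd.DataFrame(rows, columns=["cluster_id", "redox_class", "mean_rpkm"])
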