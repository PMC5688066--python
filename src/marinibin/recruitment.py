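"""Fragment-recruitment biogeography.

Metagenome contigs are "recruited" to a reference taxon when an alignment
hit passes identity/length thresholds.  Two tiers are used: a permissive
phylum-level recruitment (>=70% identity over >=70% of the contig) and a
stringent clade-level recruitment (>=95% identity, alignments >=200 bp) in
which each contig is assigned to a single clade — greatest percent identity,
ties broken by greatest alignment length, residual ties by lexicographically
smallest clade id.  Clade abundance is the summed full length of assigned
contigs normalised by both the SAG assembly size and the metagenome size in
Mbp.  Samples are classed on dissolved O2: oxic (>90 umol/kg), dysoxic
(20-90), suboxic (1-20), anoxic (<1), with sulfidic/methanogenic flags
overriding O2.  A marker-gene preset (>=80% identity, >=60 bp) reuses the
clade filter for genes such as nosZ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

#: (min_identity %, min alignment length bp) presets; "phylum" pairs its
#: identity bound with a fractional query-coverage bound instead of bp.
THRESHOLD_PRESETS: dict[str, tuple[float, float]] = {
    "clade": (95.0, 200.0),
    "marker": (80.0, 60.0),
    "prefilter": (95.0, 5000.0),
}

REDOX_CLASSES = ("oxic", "dysoxic", "suboxic", "anoxic", "sulfidic",
                 "methanogenic", "unknown")


# ---------------------------------------------------------------------------
# SSU masking


def mask_regions(
    contigs: Mapping[str, str],
    intervals: Mapping[str, list[tuple[int, int]]],
) -> dict[str, str]:
    """Replace the given 0-based half-open spans with N; lengths unchanged.

    Used to mask SSU rRNA genes out of SAG sequences before recruitment so
    the conserved gene cannot cross-recruit unrelated taxa (masked spans are
    also invisible to k-mer counting, which skips N windows).
    """
    out = {}
    for cid, seq in contigs.items():
        spans = intervals.get(cid, [])
        if not spans:
            out[cid] = seq
            continue
        chars = list(seq)
        for start, end in spans:
            if not (0 <= start <= end <= len(seq)):
                raise ValueError(
                    f"interval ({start}, {end}) out of bounds for contig "
                    f"{cid!r} of length {len(seq)}"
                )
            chars[start:end] = "N" * (end - start)
        out[cid] = "".join(chars)
    return out


# ---------------------------------------------------------------------------
# recruitment filters


def recruit_phylum(
    hits: pd.DataFrame,
    total_metagenome_bp: int | None = None,
    min_identity: float = 70.0,
    min_query_coverage: float = 70.0,
    inclusive: bool = True,
) -> dict:
    """Phylum-level recruitment for one metagenome.

    A contig is recruited if any single hit reaches ``min_identity`` percent
    identity with alignment length >= ``min_query_coverage``% of the contig
    length (qlen).  Recruited bp sums the *full* lengths of recruited
    contigs; the fraction divides by the total metagenome size.
    """
    if "qlen" not in hits.columns:
        raise ValueError("phylum recruitment needs a qlen column "
                         "(query coverage is undefined without it)")
    cmp = np.greater_equal if inclusive else np.greater
    ok = cmp(hits["pident"], min_identity) & cmp(
        hits["length"], min_query_coverage / 100.0 * hits["qlen"]
    )
    recruited = hits[ok].groupby("qseqid")["qlen"].first()
    recruited_bp = int(recruited.sum())
    result = {
        "recruited_contigs": sorted(recruited.index),
        "recruited_bp": recruited_bp,
    }
    if total_metagenome_bp is not None:
        if total_metagenome_bp <= 0:
            raise ValueError("total_metagenome_bp must be positive")
        result["fraction"] = recruited_bp / total_metagenome_bp
    return result


def recruit_clades(
    hits: pd.DataFrame,
    min_identity: float = 95.0,
    min_aln_len: float = 200.0,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Stringent per-clade recruitment filter: drop hits below the identity
    or alignment-length bound (inclusive >= by default)."""
    if inclusive:
        keep = (hits["pident"] >= min_identity) & (hits["length"] >= min_aln_len)
    else:
        keep = (hits["pident"] > min_identity) & (hits["length"] > min_aln_len)
    return hits[keep].reset_index(drop=True)


def assign_clade(
    hits: pd.DataFrame,
    clade_of: Mapping[str, str] | pd.Series | None = None,
) -> pd.Series:
    """Unique clade per contig from already-filtered hits.

    Best percent identity wins; ties go to the greatest alignment length;
    residual ties to the lexicographically smallest clade id.
    """
    if not len(hits):
        return pd.Series(dtype=object, name="clade_id")
    df = hits.copy()
    if clade_of is not None:
        df["clade_id"] = df["sseqid"].map(dict(clade_of))
        if df["clade_id"].isna().any():
            missing = sorted(df.loc[df["clade_id"].isna(), "sseqid"].unique()[:5])
            raise ValueError(f"sseqid(s) without clade mapping: {missing}")
    else:
        df["clade_id"] = df["sseqid"]
    df = df.sort_values(
        ["qseqid", "pident", "length", "clade_id"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    best = df.groupby("qseqid", sort=True).first()
    out = best["clade_id"]
    out.index.name = "contig_id"
    return out


def clade_abundance(
    assignments: pd.Series | Mapping[str, str],
    contig_lengths: Mapping[str, int] | pd.Series,
    sag_sizes_mbp: Mapping[str, float],
    metagenome_size_mbp: float,
) -> dict[str, float]:
    """Normalised clade abundance for one metagenome.

    abundance(clade) = sum of assigned full contig lengths in Mbp
    / (SAG assembly Mbp * metagenome Mbp); every clade in ``sag_sizes_mbp``
    is reported, absent assignments giving 0.
    """
    if metagenome_size_mbp <= 0:
        raise ValueError("metagenome_size_mbp must be positive")
    if any(v <= 0 for v in sag_sizes_mbp.values()):
        raise ValueError("SAG sizes must be positive")
    lengths = dict(contig_lengths) if not isinstance(contig_lengths, pd.Series) \
        else contig_lengths.to_dict()
    totals: dict[str, float] = {c: 0.0 for c in sag_sizes_mbp}
    items = assignments.items() if isinstance(assignments, pd.Series) \
        else assignments.items()
    for contig, clade in items:
        totals[clade] = totals.get(clade, 0.0) + lengths[contig] / 1e6
    return {
        clade: totals.get(clade, 0.0) / (sag_sizes_mbp[clade] * metagenome_size_mbp)
        if clade in sag_sizes_mbp else totals[clade] / metagenome_size_mbp
        for clade in totals
    }


def genome_equivalents(total_recruited_bp: float,
                       avg_genome_bp: float = 1_000_000.0) -> float:
    """Recruited bp expressed as genome equivalents of the given average size."""
    if avg_genome_bp <= 0:
        raise ValueError("avg_genome_bp must be positive")
    return total_recruited_bp / avg_genome_bp


# ---------------------------------------------------------------------------
# redox classification


@dataclass
class RedoxThresholds:
    """O2 boundaries (umol/kg) of the water-column redox classes.

    oxic: o2 > oxic_min; dysoxic: dysoxic_low <= o2 <= oxic_min;
    suboxic: suboxic_low <= o2 < dysoxic_low; anoxic: o2 < suboxic_low.
    Contiguous and non-overlapping over [0, inf).
    """

    oxic_min: float = 90.0
    dysoxic_low: float = 20.0
    suboxic_low: float = 1.0

    def __post_init__(self):
        if not 0 < self.suboxic_low < self.dysoxic_low < self.oxic_min:
            raise ValueError("redox thresholds must be ordered "
                             "0 < suboxic_low < dysoxic_low < oxic_min")


def classify_redox(
    o2_umol: float | None = None,
    sulfidic: bool = False,
    methanogenic: bool = False,
    thresholds: RedoxThresholds | None = None,
) -> str:
    """Redox class of a sample from O2 concentration or overriding flags."""
    if methanogenic:
        return "methanogenic"
    if sulfidic:
        return "sulfidic"
    if o2_umol is None or (isinstance(o2_umol, float) and np.isnan(o2_umol)):
        return "unknown"
    if o2_umol < 0:
        raise ValueError("o2_umol must be >= 0")
    t = thresholds or RedoxThresholds()
    if o2_umol > t.oxic_min:
        return "oxic"
    if o2_umol >= t.dysoxic_low:
        return "dysoxic"
    if o2_umol >= t.suboxic_low:
        return "suboxic"
    return "anoxic"


def classify_samples(samples: pd.DataFrame,
                     thresholds: RedoxThresholds | None = None) -> pd.Series:
    """Redox class per row of a sample-metadata table (sample_id, o2_umol,
    optional sulfidic/methanogenic flag columns)."""
    out = {}
    for s in samples.itertuples(index=False):
        out[s.sample_id] = classify_redox(
            getattr(s, "o2_umol", None),
            sulfidic=bool(getattr(s, "sulfidic", False)),
            methanogenic=bool(getattr(s, "methanogenic", False)),
            thresholds=thresholds,
        )
    return pd.Series(out, name="redox_class")


# ---------------------------------------------------------------------------
# profile container


@dataclass
class RecruitmentProfile:
    """Per-metagenome recruitment summary."""

    metagenome_id: str
    metagenome_size_mbp: float
    phylum_fraction: float
    clade_abundance: dict[str, float]
    redox_class: str = "unknown"


def profile_metagenome(
    metagenome_id: str,
    hits: pd.DataFrame,
    total_metagenome_bp: int,
    clade_of: Mapping[str, str],
    sag_sizes_mbp: Mapping[str, float],
    o2_umol: float | None = None,
    sulfidic: bool = False,
    methanogenic: bool = False,
    clade_min_identity: float = 95.0,
    clade_min_aln_len: float = 200.0,
) -> RecruitmentProfile:
    """Phylum fraction + per-clade normalised abundance + redox class for one
    metagenome's hit table."""
    phylum = recruit_phylum(hits, total_metagenome_bp)
    filtered = recruit_clades(hits, clade_min_identity, clade_min_aln_len)
    assignments = assign_clade(filtered, clade_of)
    lengths = hits.groupby("qseqid")["qlen"].first()
    abundance = clade_abundance(
        assignments, lengths, sag_sizes_mbp, total_metagenome_bp / 1e6
    )
    return RecruitmentProfile(
        metagenome_id=metagenome_id,
        metagenome_size_mbp=total_metagenome_bp / 1e6,
        phylum_fraction=phylum["fraction"],
        clade_abundance=abundance,
        redox_class=classify_redox(o2_umol, sulfidic, methanogenic),
    )
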