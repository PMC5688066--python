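"""Synthetic data with known ground truth.

Emulates the statistical structure the downstream analysis assumes: clades
with distinct genomic composition (order-m Markov sources perturbed from a
shared base model), incomplete single-cell assemblies (SAGs), metagenome
contig mixtures over a background community, aligner-style hit tables with
controlled identity and length, ORF annotations, and over-dispersed
metatranscriptome read counts with redox-dependent induction.

Every stochastic step derives its generator from one root seed through a
labelled splitting scheme (see ``_util.split_seed``), so a fixture is a pure
function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import split_seed

BASES = np.array(list("ACGT"))

#: marker functions carried by the simulated clades; nosZ is the
#: anoxic-induced marker (nitrous oxide reductase).
FUNCTION_CATALOG = ("nosZ", "narG", "psrA", "psrB", "hybC", "housekeeping")


# ---------------------------------------------------------------------------
# clade composition models


@dataclass
class CladeModel:
    """Order-m Markov nucleotide source for one clade.

    ``transition_probs`` has shape (4**order, 4): row c is the conditional
    distribution of the next base given the length-m context with code c
    (base-4 big-endian, A=0..T=3).  ``divergence`` scales the multiplicative
    perturbation applied to the shared base model.
    """

    clade_id: str
    order: int
    transition_probs: np.ndarray
    divergence: float = 0.0

    def __post_init__(self):
        self.transition_probs = np.asarray(self.transition_probs, dtype=float)
        if self.order < 0:
            raise ValueError("order must be >= 0")
        if self.transition_probs.shape != (4**self.order, 4):
            raise ValueError("transition_probs must have shape (4**order, 4)")
        if np.any(self.transition_probs < 0) or np.any(self.transition_probs > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        rowsums = self.transition_probs.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            raise ValueError("each conditional distribution must sum to 1")


def base_model(base_gc: float, order: int = 3) -> np.ndarray:
    """Context-independent base transition table with the given GC content."""
    if not 0 < base_gc < 1:
        raise ValueError("base_gc must be in (0, 1)")
    row = np.array([(1 - base_gc) / 2, base_gc / 2, base_gc / 2, (1 - base_gc) / 2])
    return np.tile(row, (4**order, 1))


def make_clade_models(
    n_clades: int,
    base_gc: float = 0.5,
    divergence: float = 0.2,
    seed: int = 0,
    order: int = 3,
    labels: Sequence[str] | None = None,
) -> list[CladeModel]:
    """Perturb a shared base model into ``n_clades`` compositionally distinct
    sources.

    Each conditional probability is multiplied by exp(divergence * N(0,1))
    and the row renormalised, so divergence 0 returns the base model exactly
    and the expected pairwise L1 distance between tables grows with
    divergence.
    """
    if n_clades < 1:
        raise ValueError("n_clades must be >= 1")
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    base = base_model(base_gc, order)
    if labels is None:
        labels = [f"clade{chr(ord('A') + i)}" for i in range(n_clades)]
    models = []
    for i, label in enumerate(labels):
        rng = split_seed(seed, "clade_model", label)
        probs = base * np.exp(divergence * rng.normal(size=base.shape))
        probs /= probs.sum(axis=1, keepdims=True)
        models.append(
            CladeModel(clade_id=label, order=order, transition_probs=probs,
                       divergence=divergence)
        )
    return models


def mean_pairwise_l1(models: Sequence[CladeModel]) -> float:
    """Mean L1 distance between the transition tables of all model pairs."""
    d, n = 0.0, 0
    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            d += float(
                np.abs(models[i].transition_probs - models[j].transition_probs).sum()
            )
            n += 1
    return d / n if n else 0.0


def simulate_genome(model: CladeModel, length: int, seed: int = 0) -> str:
    """Draw a nucleotide sequence of exactly ``length`` bases from the model."""
    m = model.order
    if length < m + 1:
        raise ValueError("length must be >= order + 1")
    rng = split_seed(seed, "genome", model.clade_id)
    cum = np.cumsum(model.transition_probs, axis=1)
    # plain-Python inner loop: a 4-way branch per base is ~10x faster than a
    # numpy call per base at the megabase lengths used here
    rows = [(r[0], r[1], r[2]) for r in cum]
    marg = np.cumsum(model.transition_probs.mean(axis=0))
    m0, m1, m2 = marg[0], marg[1], marg[2]
    us = rng.random(length).tolist()
    out = []
    ctx = 0
    mask = 4**m
    for i in range(m):
        u = us[i]
        b = 0 if u < m0 else 1 if u < m1 else 2 if u < m2 else 3
        out.append(b)
        ctx = (ctx * 4 + b) % mask if m else 0
    for i in range(m, length):
        u = us[i]
        r0, r1, r2 = rows[ctx]
        b = 0 if u < r0 else 1 if u < r1 else 2 if u < r2 else 3
        out.append(b)
        ctx = (ctx * 4 + b) % mask if m else 0
    lookup = "ACGT"
    return "".join([lookup[b] for b in out])


# ---------------------------------------------------------------------------
# fragmentation (SAG incompleteness / metagenome contigs)


@dataclass
class Fragment:
    """One contig cut from a source genome (0-based half-open coordinates)."""

    seq: str
    start: int
    end: int


def fragment_genome(
    sequence: str,
    n_contigs: int,
    completeness: float,
    min_len: int = 1,
    seed: int = 0,
    label: str = "",
) -> list[Fragment]:
    """Cut ``n_contigs`` non-overlapping contigs covering ``completeness`` of
    the genome, every contig at least ``min_len`` bp.

    Total contig length equals round(completeness * len) exactly, well within
    the +/-2% contract.
    """
    L = len(sequence)
    if not 0 < completeness <= 1:
        raise ValueError("completeness must be in (0, 1]")
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    target = int(round(completeness * L))
    if target < min_len:
        raise ValueError(
            f"infeasible: completeness*length={target} < min_len={min_len}"
        )
    if n_contigs * min_len > target:
        raise ValueError(
            f"infeasible: {n_contigs} contigs of >= {min_len} bp exceed "
            f"target {target} bp"
        )
    rng = split_seed(seed, "fragment", label)
    extra = target - n_contigs * min_len
    props = rng.dirichlet(np.ones(n_contigs))
    extras = np.floor(props * extra).astype(int)
    for i in range(extra - int(extras.sum())):  # distribute rounding remainder
        extras[i % n_contigs] += 1
    lengths = min_len + extras
    gap_total = L - target
    gaps = rng.multinomial(gap_total, rng.dirichlet(np.ones(n_contigs + 1)))
    frags, pos = [], 0
    for i in range(n_contigs):
        pos += int(gaps[i])
        start, end = pos, pos + int(lengths[i])
        frags.append(Fragment(seq=sequence[start:end], start=start, end=end))
        pos = end
    return frags


# ---------------------------------------------------------------------------
# ground truth container


@dataclass
class SyntheticTruth:
    """Ground truth for one fixture: provenance of every contig, SAG and ORF."""

    contigs: pd.DataFrame  # contig_id, clade_id, genome_id, start, end, length
    sags: pd.DataFrame     # sag_id, clade_id, assembly_bp, n_contigs
    orfs: pd.DataFrame     # orf_id, contig_id, clade_id, start, end, gene_length,
                           # function, cog_id, base_rate, anoxic_fold

    def clade_of_contig(self) -> pd.Series:
        return self.contigs.set_index("contig_id")["clade_id"]


# ---------------------------------------------------------------------------
# alignment hits

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qlen", "slen",
]


def simulate_hits(
    truth: SyntheticTruth,
    same_clade_identity: float = 97.0,
    off_clade_identity: float = 80.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    same_aln_frac: tuple[float, float] = (0.75, 1.0),
    off_aln_frac: tuple[float, float] = (0.1, 0.4),
) -> pd.DataFrame:
    """Full cross-product hit table: every metagenome contig vs every SAG.

    Hits to the contig's true clade draw identity around
    ``same_clade_identity`` and span most of the contig; hits to other clades
    draw around ``off_clade_identity`` with short alignments.  Alignment
    length never exceeds the contig length.
    """
    for v in (same_clade_identity, off_clade_identity):
        if not 0 <= v <= 100:
            raise ValueError("identities must be in [0, 100]")
    rng = split_seed(seed, "hits")
    rows = []
    sags = truth.sags
    for contig in truth.contigs.itertuples(index=False):
        for sag in sags.itertuples(index=False):
            same = sag.clade_id == contig.clade_id
            mu = same_clade_identity if same else off_clade_identity
            pident = float(np.clip(rng.normal(mu, noise_sd) if noise_sd else mu,
                                   0.0, 100.0))
            lo, hi = same_aln_frac if same else off_aln_frac
            aln = max(1, int(round(rng.uniform(lo, hi) * contig.length)))
            aln = min(aln, contig.length)
            qstart = int(rng.integers(1, contig.length - aln + 2))
            sstart = int(rng.integers(1, max(2, sag.assembly_bp - aln + 2)))
            mismatch = int(round(aln * (1 - pident / 100)))
            rows.append((
                contig.contig_id, sag.sag_id, round(pident, 2), aln, mismatch, 0,
                qstart, qstart + aln - 1, sstart, min(sstart + aln - 1, sag.assembly_bp),
                0.0, round(2.0 * aln * pident / 100, 1), contig.length,
                sag.assembly_bp,
            ))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


# ---------------------------------------------------------------------------
# expression counts


def simulate_expression(
    orfs: pd.DataFrame,
    sample_conditions: pd.DataFrame,
    effect_map: Mapping[str, float] | None = None,
    library_sizes: Mapping[str, int] | None = None,
    dispersion: float = 0.1,
    seed: int = 0,
    anoxic_o2_max: float = 1.0,
) -> pd.DataFrame:
    """Negative-binomial read counts per (ORF, sample).

    Expected count = base_rate * gene_length * library_size, multiplied by
    ``effect_map[function]`` in samples whose O2 is below ``anoxic_o2_max``
    (anoxic induction).  ``dispersion`` is the NB alpha (var = mu + alpha
    mu^2); 0 gives Poisson counts.
    """
    effect_map = dict(effect_map or {})
    if library_sizes is None:
        library_sizes = {
            s.sample_id: int(getattr(s, "total_mapped", 1_000_000))
            for s in sample_conditions.itertuples(index=False)
        }
    if any(v <= 0 for v in library_sizes.values()):
        raise ValueError("library sizes must be positive")
    rng = split_seed(seed, "expression")
    rows = []
    for sample in sample_conditions.itertuples(index=False):
        lib = library_sizes[sample.sample_id]
        anoxic = float(sample.o2_umol) < anoxic_o2_max
        for orf in orfs.itertuples(index=False):
            fold = effect_map.get(orf.function, 1.0) if anoxic else 1.0
            mu = orf.base_rate * orf.gene_length * lib * fold
            if dispersion > 0 and mu > 0:
                n = 1.0 / dispersion
                count = int(rng.negative_binomial(n, n / (n + mu)))
            else:
                count = int(rng.poisson(mu))
            rows.append((orf.orf_id, sample.sample_id, count, lib))
    return pd.DataFrame(rows, columns=["orf_id", "sample_id", "count", "total_mapped"])


# ---------------------------------------------------------------------------
# fixture configuration and full suite


@dataclass
class FixtureConfig:
    """Study conditions for the default synthetic fixture.

    Three compositionally distinct clades (order-3 sources, divergence 0.2)
    plus a background community; four partial SAG assemblies per clade for
    training; ~50 metagenome contigs >= 5 kb per clade, mixed with unequal
    weights so that abundance recovery is non-trivial; six samples spanning
    oxic to anoxic water with a 10-fold anoxic induction of nosZ.
    """

    n_clades: int = 3
    order: int = 3
    base_gc: float = 0.5
    divergence: float = 0.2
    background_divergence: float = 0.6

    sags_per_clade: int = 4
    sag_genome_len: int = 200_000
    sag_completeness: tuple[float, float] = (0.35, 0.65)
    sag_contig_len: int = 8_000

    meta_genome_len: int = 450_000
    contigs_per_clade: int = 50
    meta_completeness: float = 0.85
    min_contig_len: int = 5_000
    clade_weights: tuple[float, ...] = (1.0, 0.8, 0.6)
    background_genome_len: int = 320_000
    background_contigs: int = 40

    same_clade_identity: float = 97.0
    off_clade_identity: float = 80.0
    hit_noise_sd: float = 1.0

    cog_reuse_prob: float = 0.1  # per-ORF chance of duplicating a clade COG
    anoxic_fold: float = 10.0
    sample_o2: tuple[float, ...] = (250.0, 120.0, 60.0, 10.0, 0.5, 0.1)
    library_size: int = 1_000_000
    dispersion: float = 0.1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "FixtureConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown fixture config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("sag_completeness", "clade_weights", "sample_o2"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class Fixture:
    """In-memory synthetic data set with ground truth."""

    config: FixtureConfig
    seed: int
    sag_contigs: dict[str, dict[str, str]]   # sag_id -> contig_id -> seq
    meta_contigs: dict[str, str]             # contig_id -> seq
    hits: pd.DataFrame
    counts: pd.DataFrame
    samples: pd.DataFrame
    truth: SyntheticTruth

    @property
    def sag_clades(self) -> pd.Series:
        return self.truth.sags.set_index("sag_id")["clade_id"]


def build_fixture(config: FixtureConfig | None = None, seed: int = 0) -> Fixture:
    """Generate the full synthetic study: SAGs, metagenome, hits, annotations
    and counts, all tied to one seed."""
    cfg = config or FixtureConfig()
    models = make_clade_models(
        cfg.n_clades, cfg.base_gc, cfg.divergence, seed=seed, order=cfg.order
    )
    background = make_clade_models(
        1, cfg.base_gc, cfg.background_divergence, seed=seed, order=cfg.order,
        labels=["background"],
    )[0]

    # --- SAGs: each SAG is an incomplete assembly of its own genome draw
    sag_contigs: dict[str, dict[str, str]] = {}
    sag_rows = []
    for model in models:
        for j in range(cfg.sags_per_clade):
            sag_id = f"{model.clade_id}_sag{j}"
            genome = simulate_genome(model, cfg.sag_genome_len,
                                     seed=_sub(seed, "sag", sag_id))
            rng = split_seed(seed, "sag_completeness", sag_id)
            comp = rng.uniform(*cfg.sag_completeness)
            n = max(2, int(comp * cfg.sag_genome_len // cfg.sag_contig_len))
            frags = fragment_genome(
                genome, n, comp, min_len=cfg.min_contig_len,
                seed=_sub(seed, "sagfrag", sag_id), label=sag_id,
            )
            contigs = {f"{sag_id}_c{i}": f.seq for i, f in enumerate(frags)}
            sag_contigs[sag_id] = contigs
            sag_rows.append(
                (sag_id, model.clade_id, sum(len(s) for s in contigs.values()),
                 len(contigs))
            )
    sags = pd.DataFrame(sag_rows, columns=["sag_id", "clade_id", "assembly_bp",
                                           "n_contigs"])

    # --- metagenome: contigs from a fresh genome per clade plus background
    weights = list(cfg.clade_weights) + [1.0] * (cfg.n_clades - len(cfg.clade_weights))
    meta_contigs: dict[str, str] = {}
    contig_rows = []
    for model, w in zip(models, weights):
        genome = simulate_genome(model, cfg.meta_genome_len,
                                 seed=_sub(seed, "meta", model.clade_id))
        n = max(2, int(round(cfg.contigs_per_clade * w)))
        # aim for ~7 kb contigs (all >= min_contig_len), capped by the genome
        comp = min(cfg.meta_completeness, n * 7_000 / cfg.meta_genome_len)
        comp = max(comp, n * (cfg.min_contig_len + 200) / cfg.meta_genome_len)
        frags = fragment_genome(
            genome, n, comp, min_len=cfg.min_contig_len,
            seed=_sub(seed, "metafrag", model.clade_id), label=model.clade_id,
        )
        for i, f in enumerate(frags):
            cid = f"{model.clade_id}_mg{i}"
            meta_contigs[cid] = f.seq
            contig_rows.append((cid, model.clade_id, f"{model.clade_id}_meta",
                                f.start, f.end, len(f.seq)))
    bg_genome = simulate_genome(background, cfg.background_genome_len,
                                seed=_sub(seed, "meta", "background"))
    bg_frags = fragment_genome(
        bg_genome, cfg.background_contigs, 0.9, min_len=cfg.min_contig_len,
        seed=_sub(seed, "metafrag", "background"), label="background",
    )
    for i, f in enumerate(bg_frags):
        cid = f"background_mg{i}"
        meta_contigs[cid] = f.seq
        contig_rows.append((cid, "background", "background_meta", f.start, f.end,
                            len(f.seq)))
    contigs = pd.DataFrame(
        contig_rows,
        columns=["contig_id", "clade_id", "genome_id", "start", "end", "length"],
    )

    # --- ORFs packed densely on clade metagenome contigs, emulating
    # streamlined genomes: high coding fraction and low COG redundancy
    # (each ORF reuses an earlier COG of its clade with prob ~0.1, giving
    # per-bin redundancy around 1.1); nosZ is the anoxic-induced marker
    orf_rows = []
    rng = split_seed(seed, "orfs")
    k = 0
    next_cog = 0
    clade_cogs: dict[str, list[str]] = {}
    for contig in contigs.itertuples(index=False):
        if contig.clade_id == "background":
            continue
        seen = clade_cogs.setdefault(contig.clade_id, [])
        pos = int(rng.integers(20, 120))
        while pos + 300 <= contig.length:
            glen = int(min(rng.integers(300, 1500), contig.length - pos))
            func = FUNCTION_CATALOG[k % len(FUNCTION_CATALOG)]
            if seen and rng.random() < cfg.cog_reuse_prob:
                cog = seen[int(rng.integers(0, len(seen)))]
            else:
                cog = f"COG{1000 + next_cog}"
                next_cog += 1
            seen.append(cog)
            fold = cfg.anoxic_fold if func == "nosZ" else 1.0
            base_rate = float(rng.uniform(0.5, 2.0)) * 1e-8
            orf_rows.append(
                (f"orf{k:05d}", contig.contig_id, contig.clade_id, pos, pos + glen,
                 glen, func, cog, base_rate, fold)
            )
            pos += glen + int(rng.integers(20, 120))
            k += 1
    orfs = pd.DataFrame(
        orf_rows,
        columns=["orf_id", "contig_id", "clade_id", "start", "end", "gene_length",
                 "function", "cog_id", "base_rate", "anoxic_fold"],
    )

    truth = SyntheticTruth(contigs=contigs, sags=sags, orfs=orfs)
    hits = simulate_hits(
        truth,
        same_clade_identity=cfg.same_clade_identity,
        off_clade_identity=cfg.off_clade_identity,
        noise_sd=cfg.hit_noise_sd,
        seed=seed,
    )

    samples = pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(len(cfg.sample_o2))],
        "o2_umol": list(cfg.sample_o2),
        "total_mapped": [cfg.library_size] * len(cfg.sample_o2),
    })
    counts = simulate_expression(
        orfs, samples,
        effect_map={"nosZ": cfg.anoxic_fold},
        library_sizes={s: cfg.library_size for s in samples["sample_id"]},
        dispersion=cfg.dispersion,
        seed=seed,
    )
    return Fixture(
        config=cfg, seed=seed, sag_contigs=sag_contigs, meta_contigs=meta_contigs,
        hits=hits, counts=counts, samples=samples, truth=truth,
    )


def _sub(seed: int, *labels) -> int:
    """Stable 31-bit child seed for helpers that take a plain integer."""
    h = hashlib.sha256(("/".join(map(str, labels)) + f"#{seed}").encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# fixture suite on disk


def write_fixture_suite(config: FixtureConfig | Mapping | None, out_dir,
                        seed: int = 0) -> dict:
    """Write the full fixture to ``out_dir`` and return a checksum manifest.

    Emits SAG and metagenome FASTA, the hit table, GFF3 ORF annotations,
    read-count and sample tables, truth tables, and the YAML config; the
    manifest lists every file with its sha256.  Same (config, seed) twice
    gives identical checksums.
    """
    from . import io as mio

    if config is None or isinstance(config, FixtureConfig):
        cfg = config or FixtureConfig()
    else:
        cfg = FixtureConfig.from_dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = build_fixture(cfg, seed=seed)

    sag_records = {}
    for sag_id in sorted(fx.sag_contigs):
        clade = fx.sag_clades[sag_id]
        for cid, seq in fx.sag_contigs[sag_id].items():
            sag_records[f"{cid} sag={sag_id} clade={clade}"] = seq
    mio.write_fasta(sag_records, out / "sags.fasta")

    clade_of = fx.truth.clade_of_contig()
    meta_records = {
        f"{cid} clade={clade_of[cid]}": seq for cid, seq in fx.meta_contigs.items()
    }
    mio.write_fasta(meta_records, out / "metagenome.fasta")

    mio.write_hits(fx.hits, out / "hits.tsv")
    mio.write_gff(fx.truth.orfs, out / "orfs.gff3")
    fx.counts.to_csv(out / "counts.tsv", sep="\t", index=False)
    fx.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    fx.truth.contigs.to_csv(out / "truth_contigs.tsv", sep="\t", index=False)
    fx.truth.sags.to_csv(out / "truth_sags.tsv", sep="\t", index=False)
    fx.truth.orfs.to_csv(out / "truth_orfs.tsv", sep="\t", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({"seed": seed, "fixture": cfg.to_dict()}, fh,
                       sort_keys=True)

    from ._util import sha256_file

    files = sorted(p.name for p in out.iterdir() if p.is_file()
                   and p.name != "manifest.json")
    manifest = {
        "seed": seed,
        "files": {name: sha256_file(out / name) for name in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
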