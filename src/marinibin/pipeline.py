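"""End-to-end pipeline: simulate -> signatures -> cluster-sags -> bin ->
recruit -> metrics -> express.

Every stage reads and writes plain-text tables under one output directory,
logs its parameters and row counts to stderr, and the run ends with a
manifest (JSON) listing the config hash and the sha256 of every artefact —
two runs with the same config and seed produce bit-identical manifests.
When ground truth is available (simulated input) an evaluation stage scores
SAG-cluster purity, per-clade bin precision/recall and abundance rank
recovery against it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import binning, expression, io as mio, metrics, recruitment, signatures
from ._util import sha256_file
from .config import PipelineConfig
from .synthio import write_fixture_suite

logger = logging.getLogger("marinibin")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all stages under ``out_dir`` and return the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {"config": config, "out": out, "counts": {}}

    stages = [
        ("simulate", _stage_simulate),
        ("signatures", _stage_signatures),
        ("cluster-sags", _stage_cluster),
        ("bin", _stage_bin),
        ("recruit", _stage_recruit),
        ("metrics", _stage_metrics),
        ("express", _stage_express),
        ("evaluate", _stage_evaluate),
    ]
    if not config.simulate:
        _validate_inputs(config)
    for name, fn in stages:
        try:
            logger.info("stage %s: start", name)
            fn(state)
            logger.info("stage %s: done %s", name, state["counts"].get(name, ""))
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    files = sorted(
        str(p.relative_to(out))
        for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stage_counts": state["counts"],
        "files": {f: sha256_file(out / f) for f in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _validate_inputs(config: PipelineConfig) -> None:
    required = ["sags_fasta", "metagenome_fasta", "hits", "orfs_gff",
                "counts", "samples"]
    missing = [k for k in required if k not in config.inputs]
    if missing:
        raise ValueError(f"simulate=False but inputs missing keys: {missing}")
    absent = [str(p) for k, p in config.inputs.items()
              if k in required and not Path(p).exists()]
    if absent:
        raise FileNotFoundError(f"input path(s) do not exist: {absent}")


# ---------------------------------------------------------------------------
# stages; each reads files written by its predecessors so every stage is also
# runnable in isolation from the CLI


def _fixture_dir(state) -> Path:
    cfg: PipelineConfig = state["config"]
    if cfg.simulate:
        return state["out"] / "fixture"
    return None  # type: ignore[return-value]


def _input_path(state, key: str, sim_name: str) -> Path:
    cfg: PipelineConfig = state["config"]
    if cfg.simulate:
        return state["out"] / "fixture" / sim_name
    return Path(cfg.inputs[key])


def _stage_simulate(state) -> None:
    cfg: PipelineConfig = state["config"]
    if not cfg.simulate:
        state["counts"]["simulate"] = {"skipped": True}
        return
    manifest = write_fixture_suite(cfg.fixture, state["out"] / "fixture",
                                   seed=cfg.seed)
    state["counts"]["simulate"] = {"files": len(manifest["files"])}


def _sag_collections(state) -> dict[str, dict[str, str]]:
    """Group SAG contigs by their SAG of origin (``sag=`` FASTA tag or, for
    plain headers, the contig-id prefix before the last ``_c``)."""
    fasta = mio.read_fasta(_input_path(state, "sags_fasta", "sags.fasta"))
    # headers were written as "<contig> sag=<sag> clade=<clade>"; read_fasta
    # keeps only the id token, so recover the SAG from the contig id
    groups: dict[str, dict[str, str]] = {}
    for cid, seq in fasta.items():
        sag_id = cid.rsplit("_c", 1)[0] if "_c" in cid else cid
        groups.setdefault(sag_id, {})[cid] = seq
    return groups


def _stage_signatures(state) -> None:
    cfg: PipelineConfig = state["config"]
    out = state["out"]
    sags = _sag_collections(state)
    mat, dropped = signatures.signature_matrix(
        sags, min_len=cfg.thresholds.min_contig_len
    )
    mat.rename_axis("sag_id").to_csv(out / "sag_signatures.tsv", sep="\t")
    n_dropped = sum(len(v) for v in dropped.values())

    # per-contig signatures for SAG training contigs
    rows, index = [], []
    for sag_id in sorted(sags):
        for cid, seq in sags[sag_id].items():
            if len(seq) >= cfg.thresholds.min_contig_len:
                rows.append(signatures.tetra_signature(seq).z)
                index.append((sag_id, cid))
    train = pd.DataFrame(rows, columns=signatures.Z_COLUMNS)
    train.insert(0, "sag_id", [i[0] for i in index])
    train.insert(1, "contig_id", [i[1] for i in index])
    train.to_csv(out / "sag_contig_signatures.tsv", sep="\t", index=False)
    state["counts"]["signatures"] = {
        "sags": len(mat), "training_contigs": len(train),
        "dropped_contigs": n_dropped,
    }


def _stage_cluster(state) -> None:
    cfg: PipelineConfig = state["config"]
    out = state["out"]
    mat = pd.read_csv(out / "sag_signatures.tsv", sep="\t", index_col="sag_id")
    res = binning.pca3(mat.to_numpy())
    clusters = binning.cluster_sags(
        res.projection, cfg.n_sag_clusters, sag_ids=list(mat.index)
    )
    rows = [(cl.cluster_id, m) for cl in clusters for m in sorted(cl.members)]
    pd.DataFrame(rows, columns=["cluster_id", "sag_id"]).to_csv(
        out / "sag_clusters.tsv", sep="\t", index=False
    )
    ev = res.explained_variance
    pd.DataFrame({
        "component": [f"PC{i + 1}" for i in range(len(ev))],
        "explained_variance": ev,
    }).to_csv(out / "pca_variance.tsv", sep="\t", index=False)
    state["counts"]["cluster-sags"] = {"clusters": len(clusters)}


def _stage_bin(state) -> None:
    cfg: PipelineConfig = state["config"]
    out = state["out"]
    th = cfg.thresholds
    hits = mio.read_hits(_input_path(state, "hits", "hits.tsv"))
    meta = mio.read_fasta(_input_path(state, "metagenome_fasta",
                                      "metagenome.fasta"))

    train = pd.read_csv(out / "sag_contig_signatures.tsv", sep="\t")
    sag2cluster = pd.read_csv(out / "sag_clusters.tsv", sep="\t").set_index(
        "sag_id")["cluster_id"]
    labels = train["sag_id"].map(sag2cluster)
    model = binning.train_lda(
        train[signatures.Z_COLUMNS].to_numpy(), labels.to_numpy(),
        reg_factor=cfg.lda_reg_factor,
    )
    model.confusion.to_csv(out / "lda_training_confusion.tsv", sep="\t")

    eligible = binning.prefilter_contigs(
        hits, min_identity=th.prefilter_identity,
        min_aln_len=th.prefilter_aln_len,
        min_contig_len=th.min_contig_len,
        inclusive=not th.strict,
    )
    short = [c for c in pd.unique(eligible["contig_id"])
             if len(meta[c]) < th.min_contig_len]
    eligible = eligible[~eligible["contig_id"].isin(short)]
    wanted = sorted(pd.unique(eligible["contig_id"]))
    contig_z = pd.DataFrame(
        [signatures.tetra_signature(meta[c]).z for c in wanted],
        index=wanted, columns=signatures.Z_COLUMNS,
    )
    bins, table = binning.assign_contigs(
        model, contig_z, eligible,
        contig_lengths={c: len(meta[c]) for c in wanted},
    )
    table.to_csv(out / "bins.tsv", sep="\t", index=False)
    state["counts"]["bin"] = {
        "eligible_contigs": len(wanted),
        "assigned": int(len(table)),
        "bins": len(bins),
    }


def _stage_recruit(state) -> None:
    cfg: PipelineConfig = state["config"]
    out = state["out"]
    th = cfg.thresholds
    hits = mio.read_hits(_input_path(state, "hits", "hits.tsv"))
    meta = mio.read_fasta(_input_path(state, "metagenome_fasta",
                                      "metagenome.fasta"))
    total_bp = sum(len(s) for s in meta.values())
    sag2cluster = pd.read_csv(out / "sag_clusters.tsv", sep="\t").set_index(
        "sag_id")["cluster_id"]
    sags = _sag_collections(state)
    cluster_sizes_mbp: dict[str, float] = {}
    for sag_id, contigs in sags.items():
        cl = sag2cluster.get(sag_id)
        if cl is not None:
            cluster_sizes_mbp[cl] = cluster_sizes_mbp.get(cl, 0.0) + sum(
                len(s) for s in contigs.values()) / 1e6

    phylum = recruitment.recruit_phylum(
        hits, total_bp, min_identity=th.phylum_identity,
        min_query_coverage=th.phylum_coverage, inclusive=not th.strict,
    )
    filtered = recruitment.recruit_clades(
        hits, min_identity=th.clade_identity, min_aln_len=th.clade_aln_len,
        inclusive=not th.strict,
    )
    assignments = recruitment.assign_clade(filtered, sag2cluster)
    lengths = {c: len(s) for c, s in meta.items()}
    abundance = recruitment.clade_abundance(
        assignments, lengths, cluster_sizes_mbp, total_bp / 1e6
    )
    prof = pd.DataFrame(
        sorted(abundance.items()), columns=["clade", "abundance"]
    )
    prof["phylum_fraction"] = phylum["recruited_bp"] / total_bp
    prof["metagenome_mbp"] = total_bp / 1e6
    prof.to_csv(out / "recruitment.tsv", sep="\t", index=False)
    assignments.rename("clade_id").to_csv(out / "clade_assignments.tsv", sep="\t")
    state["counts"]["recruit"] = {
        "phylum_recruited_bp": int(phylum["recruited_bp"]),
        "clade_assigned_contigs": int(len(assignments)),
    }


def _stage_metrics(state) -> None:
    cfg: PipelineConfig = state["config"]
    out = state["out"]
    orfs = mio.read_gff(_input_path(state, "orfs_gff", "orfs.gff3"))
    meta = mio.read_fasta(_input_path(state, "metagenome_fasta",
                                      "metagenome.fasta"))
    bin_of = pd.read_csv(out / "bins.tsv", sep="\t").set_index(
        "contig_id")["bin_id"] if (out / "bins.tsv").exists() else pd.Series(dtype=object)
    orfs = orfs.assign(assigned_bin=orfs["contig_id"].map(bin_of))
    orfs = orfs.dropna(subset=["assigned_bin"])
    genome_sizes = {
        b: int(sum(len(meta[c]) for c in pd.unique(sub["contig_id"])))
        for b, sub in orfs.groupby("assigned_bin")
    }
    table = metrics.streamlining_table(orfs, genome_sizes,
                                       group_col="assigned_bin")
    table.to_csv(out / "streamlining.tsv", sep="\t", index=False)
    state["counts"]["metrics"] = {"genomes": len(table)}


def _stage_express(state) -> None:
    cfg: PipelineConfig = state["config"]
    out = state["out"]
    counts = mio.read_counts(_input_path(state, "counts", "counts.tsv"))
    samples = mio.read_samples(_input_path(state, "samples", "samples.tsv"))
    orfs = mio.read_gff(_input_path(state, "orfs_gff", "orfs.gff3"))
    bin_of = pd.read_csv(out / "bins.tsv", sep="\t").set_index(
        "contig_id")["bin_id"]
    meta_cols = orfs.set_index("orf_id")
    recs = counts.merge(
        meta_cols[["contig_id", "gene_length", "function"]],
        left_on="orf_id", right_index=True, how="inner",
    )
    recs["bin_id"] = recs["contig_id"].map(bin_of)
    recs = recs.dropna(subset=["bin_id"])
    recs = expression.add_rpkm(recs)
    recs.to_csv(out / "expression_orfs.tsv", sep="\t", index=False)

    agg = expression.aggregate_function_rpkm(recs)
    agg.to_csv(out / "expression_function.tsv", sep="\t", index=False)

    classes = recruitment.classify_samples(samples, thresholds=cfg.redox)
    rows = []
    for (bin_id, function), sub in agg.groupby(["bin_id", "function"]):
        per_sample = sub.set_index("sample_id")["rpkm"]
        for cls, mean in sorted(
                expression.profile_by_redox(per_sample, classes).items()):
            rows.append((bin_id, function, cls, mean))
    pd.DataFrame(
        rows, columns=["bin_id", "function", "redox_class", "mean_rpkm"]
    ).to_csv(out / "expression_redox.tsv", sep="\t", index=False)
    state["counts"]["express"] = {
        "orf_records": len(recs), "function_rows": len(agg),
    }


def _stage_evaluate(state) -> None:
    """Score recovered structure against ground truth when it exists."""
    cfg: PipelineConfig = state["config"]
    out = state["out"]
    truth_path = (out / "fixture" / "truth_contigs.tsv") if cfg.simulate else None
    if truth_path is None or not truth_path.exists():
        state["counts"]["evaluate"] = {"skipped": True}
        return
    truth_contigs = pd.read_csv(truth_path, sep="\t").set_index(
        "contig_id")["clade_id"]
    truth_sags = pd.read_csv(out / "fixture" / "truth_sags.tsv",
                             sep="\t").set_index("sag_id")["clade_id"]
    clusters = pd.read_csv(out / "sag_clusters.tsv", sep="\t")
    clusters["true_clade"] = clusters["sag_id"].map(truth_sags)
    purity = (
        clusters.groupby("cluster_id")["true_clade"]
        .agg(lambda s: s.value_counts().iloc[0] / len(s))
        .min()
    )
    # majority-vote mapping cluster -> clade
    cl2clade = clusters.groupby("cluster_id")["true_clade"].agg(
        lambda s: s.value_counts().index[0])
    bins = pd.read_csv(out / "bins.tsv", sep="\t")
    bins["pred_clade"] = bins["bin_id"].map(cl2clade)
    bins["true_clade"] = bins["contig_id"].map(truth_contigs)
    rows = []
    for clade in sorted(cl2clade.unique()):
        tp = int(((bins.pred_clade == clade) & (bins.true_clade == clade)).sum())
        fp = int(((bins.pred_clade == clade) & (bins.true_clade != clade)).sum())
        fn = int(((bins.pred_clade != clade) & (bins.true_clade == clade)).sum())
        rows.append((clade, tp, fp, fn,
                     tp / (tp + fp) if tp + fp else 0.0,
                     tp / (tp + fn) if tp + fn else 0.0))
    recovery = pd.DataFrame(
        rows, columns=["clade", "tp", "fp", "fn", "precision", "recall"]
    )
    recovery.to_csv(out / "bin_recovery.tsv", sep="\t", index=False)

    # abundance rank recovery: recruited clade abundance vs true mixed bp
    rec = pd.read_csv(out / "recruitment.tsv", sep="\t")
    rec["clade_label"] = rec["clade"].map(cl2clade)
    true_bp = truth_contigs.to_frame("clade_id").join(
        pd.read_csv(truth_path, sep="\t").set_index("contig_id")["length"]
    ).groupby("clade_id")["length"].sum()
    merged = rec.dropna(subset=["clade_label"]).set_index("clade_label")
    common = [c for c in true_bp.index if c in merged.index]
    rho = float("nan")
    if len(common) >= 2:
        rho = float(spearmanr(
            merged.loc[common, "abundance"], true_bp[common]).statistic)
    report = {
        "sag_cluster_min_purity": float(purity),
        "min_bin_precision": float(recovery["precision"].min()),
        "min_bin_recall": float(recovery["recall"].min()),
        "abundance_spearman_rho": rho,
        "n_assigned_contigs": int(len(bins)),
    }
    with open(out / "evaluation.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    state["counts"]["evaluate"] = report
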