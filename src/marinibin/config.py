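"""Pipeline configuration: every threshold in one serialisable object.

YAML round-trips exactly; unknown keys are rejected fail-fast so a typo in a
config file cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .recruitment import RedoxThresholds
from .synthio import FixtureConfig

CONFIG_VERSION = 1


@dataclass
class Thresholds:
    """Identity/length bounds of every filtering stage (inclusive >= unless
    ``strict`` is set, which switches all bounds to strict >)."""

    phylum_identity: float = 70.0      # % nt identity, phylum recruitment
    phylum_coverage: float = 70.0      # % of contig length covered
    clade_identity: float = 95.0       # % nt identity, clade recruitment
    clade_aln_len: float = 200.0       # bp
    prefilter_identity: float = 95.0   # % nt identity, binning prefilter
    prefilter_aln_len: float = 5000.0  # summed bp per contig-SAG pair
    marker_identity: float = 80.0      # % nt identity, marker recruitment
    marker_aln_len: float = 60.0       # bp
    derep_identity: float = 75.0       # % aa identity, gene-copy collapse
    marker_cluster_identity: float = 95.0  # % identity, greedy clustering
    min_contig_len: int = 5000         # bp, classification input
    strict: bool = False

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if f.name == "strict":
                continue
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"threshold {f.name} must be >= 0, got {v}")
        for name in ("phylum_identity", "clade_identity", "prefilter_identity",
                     "marker_identity", "derep_identity",
                     "marker_cluster_identity"):
            if getattr(self, name) > 100:
                raise ValueError(f"{name} is a percentage, got {getattr(self, name)}")
        if self.phylum_coverage > 100:
            raise ValueError("phylum_coverage is a percentage")


@dataclass
class PipelineConfig:
    """Full configuration of one pipeline run."""

    version: int = CONFIG_VERSION
    seed: int = 0
    n_sag_clusters: int = 3    # from SSU clade metadata; no automatic cut
    simulate: bool = True      # generate the synthetic fixture as input
    fixture: FixtureConfig = field(default_factory=FixtureConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    redox: RedoxThresholds = field(default_factory=RedoxThresholds)
    lda_reg_factor: float = 1e-2
    inputs: dict = field(default_factory=dict)  # paths when simulate=False

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "n_sag_clusters": self.n_sag_clusters,
            "simulate": self.simulate,
            "fixture": self.fixture.to_dict(),
            "thresholds": dataclasses.asdict(self.thresholds),
            "redox": dataclasses.asdict(self.redox),
            "lda_reg_factor": self.lda_reg_factor,
            "inputs": dict(self.inputs),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        version = d.get("version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise ValueError(f"unsupported config version {version}")
        kwargs = dict(d)
        kwargs["fixture"] = FixtureConfig.from_dict(d.get("fixture", {}))
        tkeys = {f.name for f in dataclasses.fields(Thresholds)}
        tdict = d.get("thresholds", {})
        if set(tdict) - tkeys:
            raise ValueError(f"unknown threshold keys: {sorted(set(tdict) - tkeys)}")
        kwargs["thresholds"] = Thresholds(**tdict)
        rkeys = {f.name for f in dataclasses.fields(RedoxThresholds)}
        rdict = d.get("redox", {})
        if set(rdict) - rkeys:
            raise ValueError(f"unknown redox keys: {sorted(set(rdict) - rkeys)}")
        kwargs["redox"] = RedoxThresholds(**rdict)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()
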