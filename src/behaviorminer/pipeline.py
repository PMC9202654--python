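"""End-to-end pipeline: encode → mine → rules → filter → venn.

Stages are the library functions; this module sequences them, writes the
stage artifacts (summary, frequent itemsets, rules, rule groups, Venn
table) and a run manifest recording the configuration hash and the counts
at every stage so a run is auditable. Any stage failure aborts with a
stage-labelled message and removes partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping, Optional

import yaml

from . import __version__
from .apriori import MiningConfig, generate_rules, mine_frequent_itemsets
from .errors import BehaviorMinerError, ConfigurationError
from .io import (
    ensure_dir,
    read_behavior_spec,
    read_codebook,
    read_responses,
    write_itemsets_csv,
    write_rule_groups_csv,
    write_rules_csv,
    write_summary_csv,
    write_venn_csv,
)
from .rule_analysis import BehaviorSpec, filter_rules_by_consequent, venn_partition
from .survey_model import dataset_summary, encode_transactions

logger = logging.getLogger("behaviorminer")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    responses_csv: Path
    codebook_path: Path
    output_dir: Path
    mining: MiningConfig = dataclasses.field(default_factory=MiningConfig)
    behaviors: Optional[BehaviorSpec] = None
    behaviors_path: Optional[Path] = None
    decimals: int = 1
    timepoint: str = "T1"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        mining_raw: Mapping = raw.get("mining", {})
        mining = MiningConfig(
            min_support=float(mining_raw.get("min_support", 0.05)),
            min_confidence=float(mining_raw.get("min_confidence", 0.68)),
            max_itemset_size=mining_raw.get("max_itemset_size"),
            enforce_roles=bool(mining_raw.get("enforce_roles", True)),
        )
        behaviors = None
        if "behaviors" in raw:
            behaviors = BehaviorSpec.from_dict(raw["behaviors"])
        return cls(
            responses_csv=resolve(raw["responses"]),
            codebook_path=resolve(raw["codebook"]),
            output_dir=resolve(raw.get("output_dir", "out")),
            mining=mining,
            behaviors=behaviors,
            decimals=int(raw.get("decimals", 1)),
            timepoint=str(raw.get("timepoint", "T1")),
        )

    def config_hash(self) -> str:
        payload = {
            "responses": str(self.responses_csv),
            "codebook": str(self.codebook_path),
            "mining": dataclasses.asdict(self.mining),
            "behaviors": (
                [str(i) for i in self.behaviors.all_items] if self.behaviors else None
            ),
            "decimals": self.decimals,
            "timepoint": self.timepoint,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


ARTIFACTS = (
    "summary.csv",
    "frequent_itemsets.csv",
    "rules.csv",
    "rule_groups.csv",
    "venn.csv",
    "manifest.json",
)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    for path in (config.responses_csv, config.codebook_path):
        if not Path(path).exists():
            raise ConfigurationError(f"input path does not exist: {path}")
    out = ensure_dir(config.output_dir)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "encode"
        codebook = read_codebook(config.codebook_path)
        raw = read_responses(config.responses_csv)
        dataset = encode_transactions(raw, codebook, timepoint=config.timepoint)
        summary = dataset_summary(dataset, decimals=config.decimals)
        p = out / "summary.csv"
        write_summary_csv(summary, p)
        written.append(p)
        logger.info("encode: n=%d transactions", dataset.n)

        stage = "mine"
        frequent = mine_frequent_itemsets(dataset, config.mining)
        p = out / "frequent_itemsets.csv"
        write_itemsets_csv(frequent, p)
        written.append(p)
        logger.info("mine: %d frequent itemsets", len(frequent))

        stage = "rules"
        rules = generate_rules(frequent, dataset, config.mining)
        p = out / "rules.csv"
        write_rules_csv(rules, p)
        written.append(p)
        logger.info("rules: %d rules", len(rules))

        behaviors = config.behaviors
        if behaviors is None and config.behaviors_path is not None:
            behaviors = read_behavior_spec(config.behaviors_path)

        groups_counts = None
        venn_n = None
        if behaviors is not None:
            stage = "filter"
            groups = filter_rules_by_consequent(rules, behaviors, dataset)
            p = out / "rule_groups.csv"
            write_rule_groups_csv(groups, p)
            written.append(p)
            groups_counts = {
                "continued": len(groups.group_continued),
                "protective": len(groups.group_protective),
                "all_protective": len(groups.group_all_protective),
                "retained": groups.n_retained,
            }
            logger.info(
                "filter: %d continued, %d protective (%d all-protective)",
                groups_counts["continued"],
                groups_counts["protective"],
                groups_counts["all_protective"],
            )

            stage = "venn"
            venn = venn_partition(dataset, behaviors)
            p = out / "venn.csv"
            write_venn_csv(venn, p, decimals=config.decimals)
            written.append(p)
            venn_n = venn.n

        stage = "manifest"
        manifest = {
            "tool": "behaviorminer",
            "version": __version__,
            "config_hash": config.config_hash(),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "counts": {
                "n_transactions": dataset.n,
                "n_frequent_itemsets": len(frequent),
                "n_rules": len(rules),
                "rule_groups": groups_counts,
                "venn_n": venn_n,
            },
            "mining": dataclasses.asdict(config.mining),
        }
        p = out / "manifest.json"
        with open(p, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(p)
        return manifest
    except BehaviorMinerError as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise BehaviorMinerError(f"pipeline stage {stage!r} failed: {exc}") from exc
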