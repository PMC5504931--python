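"""End-to-end orchestration: cohort -> mining -> network -> summaries.

One :class:`PipelineConfig` (a single YAML/JSON artifact of record) drives
the whole analysis; all randomness flows from its seed, so two runs with
the same config produce byte-identical artifacts.  Every written file is
listed in the run report's manifest with its SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import claims as cc
from . import mining, network, summaries, synth

__all__ = ["PipelineConfig", "RunReport", "run", "load_config"]

log = logging.getLogger("chmnet")


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs; exactly one input source."""

    claims_path: Path | None = None
    synthetic: synth.SyntheticCohortSpec | None = None
    cohort: cc.CohortConfig = field(default_factory=cc.CohortConfig)
    mining: mining.MiningConfig = field(default_factory=mining.MiningConfig)
    top_k: int = 30
    triple_k: int = 5
    out_dir: Path = Path("chmnet_out")
    seed: int = 0
    report_precision: int = 1

    def __post_init__(self) -> None:
        if (self.claims_path is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one input source (claims_path or synthetic) is required"
            )
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        self.out_dir = Path(self.out_dir)
        if self.claims_path is not None:
            self.claims_path = Path(self.claims_path)


@dataclass
class RunReport:
    attrition: dict[str, int]
    n_transactions: int
    n_itemsets: int
    n_rules: int
    top_pairs: list[dict]
    top_triples: list[dict]
    n_clusters: int
    cluster_sizes: dict[int, int]
    cluster_cores: dict[int, str]
    global_core: str | None
    modularity: float | None
    mean_items_per_prescription: float
    manifest: dict[str, str]

    def to_dict(self) -> dict[str, Any]:
        return {
            "attrition": self.attrition,
            "n_transactions": self.n_transactions,
            "n_itemsets": self.n_itemsets,
            "n_rules": self.n_rules,
            "top_pairs": self.top_pairs,
            "top_triples": self.top_triples,
            "clusters": {
                "count": self.n_clusters,
                "sizes": {str(k): v for k, v in self.cluster_sizes.items()},
                "cores": {str(k): v for k, v in self.cluster_cores.items()},
                "global_core": self.global_core,
                "modularity": self.modularity,
            },
            "mean_items_per_prescription": self.mean_items_per_prescription,
            "manifest": self.manifest,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: PipelineConfig) -> RunReport:
    """Execute every stage in order and write the report bundle."""
    t0 = time.perf_counter()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def note(path: Path) -> Path:
        written.append(path)
        return path

    # stage 1 — input
    if config.synthetic is not None:
        spec = config.synthetic
        if spec.seed != config.seed:
            spec = synth.SyntheticCohortSpec(
                **{**spec.__dict__, "seed": config.seed}
            )
        visits, _truth = synth.generate_cohort(spec)
        log.info("generated %d synthetic visits", len(visits))
    else:
        visits = cc.read_claims(config.claims_path)
        log.info("read %d visits from %s", len(visits), config.claims_path)

    # stage 2 — cohort cascade
    eligible = cc.index_patients(visits, config.cohort)
    retained, attrition = cc.filter_cohort(visits, eligible, config.cohort)
    attrition.write_json(note(out / "attrition.json"))
    attrition.write_text(note(out / "attrition.txt"))
    cc.write_claims(retained, note(out / "retained_visits.csv"))
    transactions = cc.to_transactions(retained)
    cc.write_transactions(transactions, note(out / "transactions.tsv"))
    log.info("cohort cascade: %s", attrition.to_dict())

    empty = not transactions
    # stage 3 — rule mining
    if empty:
        itemsets, rules, pairs, triples = [], [], [], []
        supports: dict[str, float] = {}
    else:
        itemsets = mining.mine_frequent_itemsets(transactions, config.mining)
        rules = mining.derive_rules(itemsets, transactions, config.mining)
        pairs = mining.top_combinations(rules, size=2, k=config.top_k) if rules else []
        triples = (
            mining.top_combinations(rules, size=3, k=config.triple_k) if rules else []
        )
        supports = dict(mining.single_item_supports(transactions))
    _write_itemsets(itemsets, note(out / "frequent_itemsets.csv"))
    _write_rules(rules, note(out / "rules.csv"))
    pair_records = mining.combinations_to_records(pairs)
    triple_records = mining.combinations_to_records(triples)
    _write_json(pair_records, note(out / "top_pairs.json"))
    _write_json(triple_records, note(out / "top_triples.json"))
    log.info("mined %d itemsets, %d rules", len(itemsets), len(rules))

    # stage 4 — network
    if pairs:
        names = {}
        kinds = {}
        for v in retained:
            for it in v.items:
                names.setdefault(it.code, it.name)
                kinds.setdefault(it.code, it.kind)
        net = network.build_network(pairs, supports, names, kinds)
        network.detect_clusters(net)
        cores, global_core = network.identify_cores(net)
        network.export_graph(net, note(out / "network.graphml"), "graphml")
        network.export_graph(net, note(out / "network.json"), "json")
        n_clusters = net.n_clusters()
        sizes = net.cluster_sizes()
        modularity = net.modularity
    else:
        cores, global_core, n_clusters, sizes, modularity = {}, None, 0, {}, None
    log.info("network: %d clusters, global core %s", n_clusters, global_core)

    # stage 5 — utilization summaries
    if retained:
        for k in ("all", "HF", "SH"):
            frame = summaries.prevalence_to_frame(
                summaries.prevalence_table(retained, kind=k)
            )
            frame.to_csv(note(out / f"prevalence_{k.lower()}.csv"), index=False)
        dist = summaries.size_distribution(retained)
        _write_json(
            {"mean": dist.mean, "histogram": {str(k): v for k, v in dist.histogram.items()}},
            note(out / "size_distribution.json"),
        )
        mean_items = dist.mean
    else:
        mean_items = 0.0

    manifest = {p.name: _sha256(p) for p in sorted(written)}
    report = RunReport(
        attrition=attrition.to_dict(),
        n_transactions=len(transactions),
        n_itemsets=len(itemsets),
        n_rules=len(rules),
        top_pairs=pair_records,
        top_triples=triple_records,
        n_clusters=n_clusters,
        cluster_sizes=sizes,
        cluster_cores=cores,
        global_core=global_core,
        modularity=modularity,
        mean_items_per_prescription=mean_items,
        manifest=manifest,
    )
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    log.info("pipeline finished in %.1fs", time.perf_counter() - t0)
    return report


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2) + "\n")


def _write_itemsets(itemsets, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("itemset,size,count,support\n")
        for e in itemsets:
            fh.write(
                f"{'+'.join(sorted(e.items))},{len(e.items)},{e.count},{e.support!r}\n"
            )


def _write_rules(rules, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("antecedent,consequent,support,confidence,lift\n")
        for r in rules:
            fh.write(
                f"{'+'.join(sorted(r.antecedent))},{'+'.join(sorted(r.consequent))},"
                f"{r.support!r},{r.confidence!r},{r.lift!r}\n"
            )


def load_config(path: str | Path, seed: int | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML/JSON file.

    Recognised top-level keys: ``claims`` (path), ``synthetic`` (either
    the string "default" or a mapping of SyntheticCohortSpec overrides),
    ``cohort``, ``mining``, ``top_k``, ``triple_k``, ``out_dir``, ``seed``.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    seed = seed if seed is not None else int(raw.get("seed", 0))
    spec = None
    if "synthetic" in raw:
        syn = raw["synthetic"]
        if syn == "default" or syn is None:
            spec = synth.default_spec(seed)
        else:
            base = synth.default_spec(seed).__dict__ | dict(syn)
            base["seed"] = seed
            spec = synth.SyntheticCohortSpec(**base)
    cohort = cc.CohortConfig(**raw.get("cohort", {}))
    mcfg = mining.MiningConfig(**raw.get("mining", {}))
    return PipelineConfig(
        claims_path=Path(raw["claims"]) if "claims" in raw else None,
        synthetic=spec,
        cohort=cohort,
        mining=mcfg,
        top_k=int(raw.get("top_k", 30)),
        triple_k=int(raw.get("triple_k", 5)),
        out_dir=Path(raw.get("out_dir", "chmnet_out")),
        seed=seed,
    )
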