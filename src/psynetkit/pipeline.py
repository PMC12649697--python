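"""End-to-end study replica: simulate -> match -> estimate -> diagnose -> compare.

`run_study` executes the stages in order, writes every intermediate
artifact (CSV/JSON) into the output directory, and returns a
StudyReport whose numbers are reproducible bit-for-bit from the stored
seeds and settings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import resampling
from .comparison import NCTResult, nct
from .centrality import centrality_table
from .datasets import (
    ScenarioParams,
    SubscaleDataset,
    default_scenario,
    read_dataset_csv,
    read_scenario_yaml,
    write_dataset_csv,
)
from .estimation import EstimationSettings, NetworkModel, select_network
from .matching import balance_table, match_dataset

log = logging.getLogger("psynetkit")

__all__ = ["RunConfig", "StudyReport", "StageError", "run_study"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries a machine-readable stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything needed to rerun a study replica deterministically."""

    out_dir: str
    input_csv: str | None = None         # analyse an existing dataset ...
    scenario_yaml: str | None = None     # ... or a serialized scenario ...
    n_per_group: int = 766               # ... or the packaged default scenario
    seed: int = 0
    do_matching: bool = True
    caliper_sd_multiplier: float = 0.2
    estimation: EstimationSettings = field(default_factory=EstimationSettings)
    bootstrap_B: int = 1000
    case_drop_B: int = 100
    drop_grid: tuple[float, ...] = resampling.DEFAULT_DROP_GRID
    n_perm: int = 2000
    alpha_edge: float = 0.001

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        est = doc.pop("estimation", None)
        cfg = cls(**doc)
        if est is not None:
            cfg.estimation = EstimationSettings(**est)
        return cfg


@dataclass
class StudyReport:
    config: RunConfig
    balance_pre: object
    balance_post: object | None
    networks: tuple[NetworkModel, NetworkModel]   # (unexposed, exposed)
    centrality: tuple[object, object]
    cs: dict
    nct_result: NCTResult

    def summary(self) -> dict:
        """Headline numbers of the replica, rounded for display."""
        net0, net1 = self.networks
        r = self.nct_result
        out = {
            "n_edges": [net0.n_edges, net1.n_edges],
            "n_possible_edges": len(net0.node_names) * (len(net0.node_names) - 1) // 2,
            "max_predictability": [
                round(float(net.predictability.max()), 4) for net in self.networks
            ],
            "global_strength": [round(g, 4) for g in r.global_strength],
            "M": round(r.M_observed, 4),
            "p_M": round(r.p_M, 4),
            "S": round(r.S_observed, 4),
            "p_S": round(r.p_S, 4),
            "cs": {k: round(v, 4) for k, v in self.cs.items()},
            "n_significant_edges": int(len(r.significant_edges())),
        }
        return out


def _load_dataset(config: RunConfig) -> SubscaleDataset:
    from .datasets import sample_dataset

    if config.input_csv:
        return read_dataset_csv(config.input_csv)
    if config.scenario_yaml:
        params = read_scenario_yaml(config.scenario_yaml)
    else:
        params = default_scenario(n_per_group=config.n_per_group, seed=config.seed)
    return sample_dataset(params)


def run_study(config: RunConfig) -> StudyReport:
    """Run all stages in order, writing artifacts into ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    # independent child seeds per stochastic stage, logged for reproducibility
    seeds = {k: int(rng.integers(2**31)) for k in
             ("bootstrap0", "bootstrap1", "casedrop0", "casedrop1", "nct")}
    log.info("stage seeds: %s", seeds)

    def stage(name, fn, *args, **kwargs):
        log.info("running stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as err:  # noqa: BLE001 - wrapped with stage name
            raise StageError(name, err) from err

    data = stage("simulate_or_load", _load_dataset, config)
    write_dataset_csv(data, out / "dataset.csv")

    pre = stage("balance_pre", balance_table, data)
    pre.to_csv(out / "balance_pre.csv", index=False)
    post = None
    if config.do_matching:
        matched, match, _ps = stage(
            "match", match_dataset, data, config.caliper_sd_multiplier
        )
        with open(out / "match.json", "w") as fh:
            json.dump({
                "pairs": [[str(a), str(b)] for a, b in match.pairs],
                "caliper_width": match.caliper_width,
                "n_matched": match.n_matched,
                "unmatched_exposed": [str(i) for i in match.unmatched_exposed],
            }, fh, indent=1)
        post = stage("balance_post", balance_table, matched)
        post.to_csv(out / "balance_post.csv", index=False)
        analysis = matched
    else:
        analysis = data

    nets, cents = [], []
    for g in (0, 1):
        X = analysis.group_scores(bool(g))
        net = stage(f"estimate_group{g}", select_network, X,
                    settings=config.estimation)
        net.to_json(out / f"network_group{g}.json", settings=config.estimation)
        net.edge_frame().to_csv(out / f"edges_group{g}.csv", index=False)
        cent = centrality_table(
            net.weights, net.communities, net.node_names, net.predictability
        )
        cent.to_csv(out / f"centrality_group{g}.csv", index=False)
        nets.append(net)
        cents.append(cent)

    cs_values = {}
    for g in (0, 1):
        X = analysis.group_scores(bool(g))
        boot = stage(
            f"bootstrap_group{g}", resampling.bootstrap_edges, X,
            config.estimation, config.bootstrap_B, seeds[f"bootstrap{g}"],
        )
        boot.summary().to_csv(out / f"edge_ci_group{g}.csv", index=False)
        for index in ("strength", "ei"):
            drop = stage(
                f"casedrop_{index}_group{g}", resampling.case_drop_bootstrap,
                X, index, config.drop_grid, config.case_drop_B,
                seeds[f"casedrop{g}"], config.estimation,
            )
            drop.table.to_csv(out / f"casedrop_{index}_group{g}.csv", index=False)
            cs = resampling.cs_coefficient(drop)
            cs_values[f"{index}_group{g}"] = cs.value
    with open(out / "cs.json", "w") as fh:
        json.dump(cs_values, fh, indent=1)

    result = stage(
        "nct", nct, analysis.group_scores(False), analysis.group_scores(True),
        config.estimation, config.n_perm, seeds["nct"], config.alpha_edge,
    )
    result.to_json(out / "nct.json")
    result.edge_frame().to_csv(out / "nct_edges.csv", index=False)

    report = StudyReport(
        config=config,
        balance_pre=pre,
        balance_post=post,
        networks=(nets[0], nets[1]),
        centrality=(cents[0], cents[1]),
        cs=cs_values,
        nct_result=result,
    )
    with open(out / "summary.json", "w") as fh:
        json.dump(report.summary(), fh, indent=1)
    with open(out / "run_config.json", "w") as fh:
        json.dump({
            **{k: v for k, v in dataclasses.asdict(config).items()},
            "stage_seeds": seeds,
        }, fh, indent=1, default=str)
    return report
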