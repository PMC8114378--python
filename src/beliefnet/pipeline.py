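"""End-to-end analysis pipelines for the two behavior conceptualizations.

Mode ``behavior_as_node`` treats the binary behavior as one node of the
network: a single partial-correlation network is estimated over items
plus behavior, followed by centralities, shortest paths to the behavior,
sign-split analyses, communities, cliques/cycles, and bootstrap
stability. Mode ``behavior_as_emergent`` removes the behavior from the
item set, splits the sample by it, jointly estimates the two group
networks with the fused graphical lasso, and compares them with the
permutation Network Comparison Test.

Every artifact is written under ``output_dir`` together with a manifest
recording the input hash, configuration, seed and package versions, so a
re-run with the same seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .centrality import centrality_table, shortest_paths_to, split_by_sign
from .comparison import nct
from .dataset import BeliefDataset
from .estimation import EstimationConfig, correlation_matrix, ebic_select, fused_glasso
from .stability import DEFAULT_PROPORTIONS, bootstrap_edges, casedrop_bootstrap
from .topology import enumerate_cliques, enumerate_cycles, greedy_communities, within_cluster_strength

logger = logging.getLogger(__name__)

MODES = ("behavior_as_node", "behavior_as_emergent")


@dataclass
class AnalysisConfig:
    """Configuration of a full pipeline run.

    ``focal_variable`` names the behavior column: the focal node in mode
    ``behavior_as_node``, the group-defining variable in mode
    ``behavior_as_emergent``.
    """

    mode: str
    focal_variable: str = "behavior"
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    stability_B: int = 200
    stability_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    n_perm: int = 500
    seed: int = 0
    output_dir: str | Path = "beliefnet_output"
    run_stability: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


def _dataset_hash(data: BeliefDataset) -> str:
    h = hashlib.sha256()
    h.update(data.values.to_csv(index=False).encode())
    if data.group is not None:
        h.update(data.group.tobytes())
    return h.hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return str(obj)


def run_pipeline(config: AnalysisConfig, data: BeliefDataset) -> dict:
    """Run one analysis mode end to end; returns the manifest dict."""
    if config.focal_variable not in data.var_names:
        raise ValueError(f"focal variable {config.focal_variable!r} not in dataset")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    sub = {name: int(s.generate_state(1)[0] % 2**31)
           for name, s in zip(("bootstrap", "casedrop", "permutation"), ss.spawn(3))}
    t0 = time.time()
    artifacts: dict[str, str] = {}

    def save(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        artifacts[name] = str(path)

    if config.mode == "behavior_as_node":
        net = ebic_select(data, config.estimation)
        save("network.csv", net.to_matrix_csv)
        save("network_edges.csv", net.to_edgelist_csv)
        save("network.graphml", net.to_graphml)

        cent = centrality_table(net)
        save("centrality.csv", lambda p: cent.rename_axis("node").to_csv(p))

        paths = shortest_paths_to(net, config.focal_variable)
        save("shortest_paths.csv", paths.write_csv)

        pos, neg = split_by_sign(net)
        save("network_positive.csv", pos.to_matrix_csv)
        save("network_negative.csv", neg.to_matrix_csv)
        for tag, subnet in (("positive", pos), ("negative", neg)):
            sp = shortest_paths_to(subnet, config.focal_variable)
            save(f"shortest_paths_{tag}.csv", sp.write_csv)
            ct = centrality_table(subnet)
            save(f"centrality_{tag}.csv", lambda p, ct=ct: ct.rename_axis("node").to_csv(p))

        part = greedy_communities(net)
        wcs = within_cluster_strength(net, part)
        save("communities.json", lambda p: Path(p).write_text(json.dumps(
            {"assignment": part.assignment, "modularity": part.modularity,
             "merge_history": part.merge_history,
             "within_cluster_strength": wcs.to_dict()},
            indent=2, default=_json_default)))

        topo_counts = {}
        for k in (3, 4, 5):
            cliques = enumerate_cliques(net, k)
            topo_counts[f"cliques_{k}"] = len(cliques)
        tri = enumerate_cycles(net, 3)
        four = enumerate_cycles(net, 4)
        topo_counts["triangles"] = len(tri)
        topo_counts["four_cycles"] = len(four)
        topo_counts["reinforcing_triangles"] = sum(
            c == "reinforcing" for c in tri.classification
        )
        save("cycles_triangles.jsonl", lambda p: tri.to_json_lines(net, p))
        save("cycles_four.jsonl", lambda p: four.to_json_lines(net, p))
        save("topology_counts.json", lambda p: Path(p).write_text(
            json.dumps(topo_counts, indent=2)))

        results: dict = {"n_edges": net.n_edges, "topology": topo_counts,
                         "modularity": part.modularity}
        if config.run_stability:
            edge_rep = bootstrap_edges(data, config.estimation, B=config.stability_B,
                                       seed=sub["bootstrap"], net=net)
            drop_rep = casedrop_bootstrap(
                data, config.estimation, proportions=config.stability_proportions,
                B=config.stability_B, seed=sub["casedrop"])
            save("edge_ci.csv", lambda p: edge_rep.edge_ci.to_csv(p, index=False))
            drop_rep.write(outdir)
            artifacts["casedrop.csv"] = str(outdir / "casedrop.csv")
            artifacts["stability.json"] = str(outdir / "stability.json")
            results["cs_coefficient"] = drop_rep.cs
    else:
        items = data.drop_column(config.focal_variable)
        beh = data.values[config.focal_variable].to_numpy()
        if not set(np.unique(beh)) <= {0, 1}:
            raise ValueError("focal variable must be binary in emergent mode")
        grouped = BeliefDataset(items.values, dict(items.var_kinds), beh.astype(int))
        d0, d1 = data.split_by(config.focal_variable)
        assert config.focal_variable not in d0.var_names

        s0 = correlation_matrix(d0, config.estimation.correlation_method)
        s1 = correlation_matrix(d1, config.estimation.correlation_method)
        net0, net1 = fused_glasso(
            s0, s1, d0.n, d1.n,
            config.estimation.fgl_lambda1, config.estimation.fgl_lambda2,
            node_labels=d0.var_names,
        )
        assert config.focal_variable not in net0.node_labels
        save("network_group0.csv", net0.to_matrix_csv)
        save("network_group1.csv", net1.to_matrix_csv)
        for tag, net in (("group0", net0), ("group1", net1)):
            ct = centrality_table(net)
            save(f"centrality_{tag}.csv", lambda p, ct=ct: ct.rename_axis("node").to_csv(p))

        res = nct(grouped, config.estimation, n_perm=config.n_perm,
                  seed=sub["permutation"])
        save("nct.json", res.to_json)
        save("nct_report.txt", lambda p: Path(p).write_text(res.report() + "\n"))
        results = {
            "M": res.M_observed, "S": res.S_observed,
            "p_structure": res.p_structure, "p_strength": res.p_strength,
            "group_sizes": list(res.group_sizes),
            "n_edges_group0": net0.n_edges, "n_edges_group1": net1.n_edges,
        }

    manifest = {
        "mode": config.mode,
        "focal_variable": config.focal_variable,
        "seed": config.seed,
        "substream_seeds": sub,
        "input_hash": _dataset_hash(data),
        "n": data.n,
        "p": data.p,
        "results": results,
        "artifacts": sorted(artifacts),
        "versions": {"beliefnet": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "wall_time_s": round(time.time() - t0, 3),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_json_default)
    )
    return manifest
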