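"""Bootstrap stability and accuracy of estimated networks.

Two resampling schemes quantify how much of an estimated belief network
survives sampling noise:

* a nonparametric bootstrap (rows resampled with replacement, the whole
  estimation including penalty selection re-run per replicate) giving a
  percentile confidence interval per edge weight, and
* a case-dropping bootstrap: for a grid of drop proportions q, repeated
  subsamples of size round((1-q) n) are re-estimated and each centrality
  vector is correlated with the full-sample one. The
  correlation-stability (CS) coefficient is the largest q at which that
  correlation stays >= 0.7 in at least 95% of replicates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .centrality import centrality_table
from .dataset import BeliefDataset
from .estimation import EstimationConfig, ebic_select
from .network import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityReport",
    "bootstrap_edges",
    "casedrop_bootstrap",
    "cs_coefficient",
    "DEFAULT_PROPORTIONS",
]

DEFAULT_PROPORTIONS = tuple(np.round(np.arange(0.1, 0.75, 0.1), 2))
MEASURES = ("strength", "closeness", "betweenness")


@dataclass
class StabilityReport:
    """Bootstrap edge CIs and/or case-dropping stability curves.

    ``edge_ci`` has one row per node pair with the sample estimate, the
    bootstrap mean and the 2.5%/97.5% percentile bounds.
    ``casedrop_curves`` maps measure -> {drop proportion -> array of
    correlations with the full-sample centralities over replicates}.
    """

    edge_ci: pd.DataFrame | None = None
    casedrop_curves: dict[str, dict[float, np.ndarray]] | None = None
    cs: dict[str, float] | None = None
    threshold: float = 0.7
    coverage: float = 0.95
    meta: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.edge_ci is not None:
            self.edge_ci.to_csv(outdir / "edge_ci.csv", index=False)
        if self.casedrop_curves is not None:
            rows = []
            for measure, curves in self.casedrop_curves.items():
                for q, corrs in curves.items():
                    for b, r in enumerate(corrs):
                        rows.append(
                            {"measure": measure, "proportion": q, "replicate": b,
                             "correlation": r}
                        )
            pd.DataFrame(rows).to_csv(outdir / "casedrop.csv", index=False)
        summary = {"threshold": self.threshold, "coverage": self.coverage,
                   "cs": self.cs, "meta": self.meta}
        (outdir / "stability.json").write_text(json.dumps(summary, indent=2))


def _spawn_seeds(seed: int, b: int) -> list[int]:
    """One reproducible child seed per replicate from the master seed."""
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(b)]


def bootstrap_edges(
    data: BeliefDataset,
    config: EstimationConfig | None = None,
    B: int = 1000,
    seed: int = 0,
    net: WeightedNetwork | None = None,
) -> StabilityReport:
    """Percentile bootstrap CIs for every edge weight.

    Each replicate resamples the rows with replacement and repeats the
    full estimation, EBIC selection included. Replicates whose
    estimation fails are counted; more than 10% failures is an error.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    config = config or EstimationConfig()
    if net is None:
        net = ebic_select(data, config)
    p = net.p
    iu = np.triu_indices(p, k=1)
    draws = np.full((B, len(iu[0])), np.nan)
    n_failed = 0
    for b, child in enumerate(_spawn_seeds(seed, B)):
        rng = np.random.default_rng(child)
        idx = rng.integers(0, data.n, size=data.n)
        try:
            bnet = ebic_select(data.subset_rows(idx), config)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        draws[b] = bnet.weights[iu]
    if n_failed > 0.1 * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap replicates failed to estimate")
    if n_failed:
        logger.warning("%d/%d bootstrap replicates failed and were dropped", n_failed, B)
    ok = draws[~np.isnan(draws).any(axis=1)]
    rows = []
    for k, (i, j) in enumerate(zip(*iu)):
        rows.append(
            {
                "node_i": net.node_labels[i],
                "node_j": net.node_labels[j],
                "sample": net.weights[i, j],
                "boot_mean": ok[:, k].mean(),
                "ci_lower": np.quantile(ok[:, k], 0.025),
                "ci_upper": np.quantile(ok[:, k], 0.975),
            }
        )
    edge_ci = pd.DataFrame(rows)
    return StabilityReport(
        edge_ci=edge_ci,
        meta={"B": B, "n_failed": n_failed, "seed": seed, "kind": "edge_bootstrap"},
    )


def casedrop_bootstrap(
    data: BeliefDataset,
    config: EstimationConfig | None = None,
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS,
    B: int = 1000,
    seed: int = 0,
    threshold: float = 0.7,
    coverage: float = 0.95,
) -> StabilityReport:
    """Case-dropping stability curves for the three centrality measures.

    For each drop proportion q, B subsamples of size round((1-q) n) are
    drawn without replacement and fully re-estimated; each subsample's
    strength/closeness/betweenness vector is Pearson-correlated with the
    full-sample one. A constant centrality vector in either sample gives
    correlation 0 for that replicate (no stability evidence).
    """
    if not all(0 < q <= 0.95 for q in proportions):
        raise ValueError("drop proportions must lie in (0, 0.95]")
    config = config or EstimationConfig()
    full_net = ebic_select(data, config)
    full_cent = centrality_table(full_net)
    curves: dict[str, dict[float, np.ndarray]] = {m: {} for m in MEASURES}
    seeds = _spawn_seeds(seed, len(proportions) * B)
    si = 0
    for q in proportions:
        size = int(round((1 - q) * data.n))
        corrs = {m: np.zeros(B) for m in MEASURES}
        for b in range(B):
            rng = np.random.default_rng(seeds[si]); si += 1
            if size < data.p:
                logger.warning("subsample size %d < p=%d at q=%.2f", size, data.p, q)
            idx = rng.choice(data.n, size=size, replace=False)
            try:
                sub_net = ebic_select(data.subset_rows(idx), config)
                sub_cent = centrality_table(sub_net)
            except (RuntimeError, ValueError, np.linalg.LinAlgError):
                for m in MEASURES:
                    corrs[m][b] = 0.0
                continue
            for m in MEASURES:
                a = full_cent[m].to_numpy()
                c = sub_cent[m].to_numpy()
                if a.std() == 0 or c.std() == 0:
                    corrs[m][b] = 0.0
                else:
                    corrs[m][b] = float(np.corrcoef(a, c)[0, 1])
        for m in MEASURES:
            curves[m][float(q)] = corrs[m]
    report = StabilityReport(
        casedrop_curves=curves,
        threshold=threshold,
        coverage=coverage,
        meta={"B": B, "proportions": list(map(float, proportions)), "seed": seed,
              "kind": "casedrop"},
    )
    report.cs = cs_coefficient(report, threshold, coverage)
    return report


def cs_coefficient(
    report: StabilityReport, threshold: float = 0.7, coverage: float = 0.95
) -> dict[str, float]:
    """CS coefficient per centrality measure.

    The largest tested drop proportion q such that the correlation with
    the full-sample centralities is >= ``threshold`` in at least
    ``coverage`` of replicates; 0 if no tested proportion qualifies.
    """
    if report.casedrop_curves is None:
        raise ValueError("report has no case-dropping curves")
    out: dict[str, float] = {}
    for measure, curves in report.casedrop_curves.items():
        cs = 0.0
        for q in sorted(curves):
            frac = float(np.mean(curves[q] >= threshold))
            if frac >= coverage:
                cs = max(cs, q)
        out[measure] = cs
    return out
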