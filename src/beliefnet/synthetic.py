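"""Synthetic belief-questionnaire data with known network structure.

The original organ-donation questionnaire data are not publicly
deposited, so every stage of the pipeline is validated against data
generated here: a Gaussian graphical model with a known sparse precision
matrix, equal-probability quantile discretization into Likert levels,
and a binary behavior produced by a logistic threshold on accumulated
stimulation from the items.

The ground-truth precision matrix is the oracle for all recovery tests:
its implied partial correlations ``rho_ij = -kappa_ij /
sqrt(kappa_ii * kappa_jj)`` are what the estimation stage must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import BeliefDataset

__all__ = [
    "GroundTruth",
    "make_ground_truth",
    "simulate_responses",
    "simulate_behavior",
    "make_two_group",
    "study_dataset",
    "study_two_group_dataset",
]

#: Group sizes of the motivating organ-donor registration study
#: (93 registered vs. 273 not registered, n = 366).
STUDY_N_REGISTERED = 93
STUDY_N_NOT_REGISTERED = 273
STUDY_N_ITEMS = 25

# Keep row sums of off-diagonal precision entries below this fraction of the
# diagonal so the matrix is strictly diagonally dominant, hence positive
# definite, without disturbing the requested sparsity pattern.
_DOMINANCE_MARGIN = 0.95


def partial_corr_from_precision(precision: np.ndarray) -> np.ndarray:
    """rho_ij = -kappa_ij / sqrt(kappa_ii * kappa_jj); zero diagonal."""
    d = np.sqrt(np.diag(precision))
    rho = -precision / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    return rho


@dataclass
class GroundTruth:
    """Known data-generating structure for a belief network.

    ``precision_matrix`` is symmetric positive definite; ``partial_corr``
    is derived from it. ``behavior_coefs`` and ``behavior_intercept`` are
    log-odds parameters of the logistic behavior threshold.
    ``discretization_levels`` is an integer >= 2 number of Likert
    categories or the string ``"continuous"``.
    """

    precision_matrix: np.ndarray
    behavior_coefs: np.ndarray | None = None
    behavior_intercept: float = 0.0
    discretization_levels: int | str = 5
    partial_corr: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        k = np.asarray(self.precision_matrix, dtype=float)
        if not np.allclose(k, k.T, atol=1e-12):
            raise ValueError("precision matrix must be symmetric")
        eigvals = np.linalg.eigvalsh(k)
        if eigvals.min() <= 0:
            raise ValueError(
                f"precision matrix not positive definite (min eigenvalue {eigvals.min():.3g})"
            )
        self.precision_matrix = k
        self.partial_corr = partial_corr_from_precision(k)
        if self.behavior_coefs is not None:
            self.behavior_coefs = np.asarray(self.behavior_coefs, dtype=float)
            if self.behavior_coefs.shape != (k.shape[0],):
                raise ValueError("behavior_coefs must have length p")
        if self.discretization_levels != "continuous":
            if int(self.discretization_levels) < 2:
                raise ValueError("discretization_levels must be >= 2 or 'continuous'")
            self.discretization_levels = int(self.discretization_levels)

    @property
    def p(self) -> int:
        return self.precision_matrix.shape[0]

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision_matrix)


def _structure_pattern(
    p: int, structure: str, edge_density: float, rng: np.random.Generator
) -> list[tuple[int, int]]:
    if structure == "chain":
        return [(i, i + 1) for i in range(p - 1)]
    if structure == "random_sparse":
        pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
        keep = rng.random(len(pairs)) < edge_density
        return [pr for pr, k in zip(pairs, keep) if k]
    if structure == "two_block":
        half = p // 2
        edges = [(i, j) for i in range(half) for j in range(i + 1, half)]
        edges += [(i, j) for i in range(half, p) for j in range(i + 1, p)]
        return edges
    raise ValueError(f"unknown structure {structure!r}")


def make_ground_truth(
    p: int,
    structure: str = "random_sparse",
    edge_density: float = 0.2,
    weight_range: tuple[float, float] = (0.2, 0.4),
    seed: int = 0,
    negative_fraction: float = 0.3,
    levels: int | str = 5,
    behavior_coefs: np.ndarray | None = None,
    behavior_intercept: float = 0.0,
) -> GroundTruth:
    """Build a GroundTruth with the requested sparsity pattern.

    Edge magnitudes are drawn uniformly from ``weight_range`` with a
    ``negative_fraction`` share of negative signs, placed in a precision
    matrix with unit diagonal. Positive definiteness is enforced by
    scaling all off-diagonals under strict diagonal dominance, which
    preserves the sparsity pattern exactly.
    """
    if p < 3:
        raise ValueError("p must be >= 3")
    if structure == "random_sparse" and not 0 <= edge_density <= 1:
        raise ValueError("edge_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pattern = _structure_pattern(p, structure, edge_density, rng)

    k = np.eye(p)
    for i, j in pattern:
        mag = rng.uniform(*weight_range)
        sign = -1.0 if rng.random() < negative_fraction else 1.0
        # kappa_ij = -rho_ij for unit diagonal, so a positive partial
        # correlation needs a negative precision entry
        k[i, j] = k[j, i] = -sign * mag
    off_row_sums = np.abs(k).sum(axis=1) - 1.0
    max_sum = off_row_sums.max()
    if max_sum > _DOMINANCE_MARGIN:
        scale = _DOMINANCE_MARGIN / max_sum
        k = np.eye(p) + (k - np.eye(p)) * scale
    if np.linalg.eigvalsh(k).min() <= 0:
        raise RuntimeError("construction failed: precision not positive definite")
    return GroundTruth(
        k,
        behavior_coefs=behavior_coefs,
        behavior_intercept=behavior_intercept,
        discretization_levels=levels,
    )


def _discretize(z: np.ndarray, levels: int) -> np.ndarray:
    """Equal-probability normal quantile cuts -> integer codes 1..levels."""
    cuts = stats.norm.ppf(np.arange(1, levels) / levels)
    return (np.searchsorted(cuts, z) + 1).astype(float)


def simulate_responses(gt: GroundTruth, n: int, seed: int = 0) -> BeliefDataset:
    """Draw n multivariate-normal responses from ``inv(precision)``.

    Continuous draws are kept as-is; otherwise each item is standardized
    and cut at equal-probability normal quantiles into integer Likert
    codes ``1..levels``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cov = gt.covariance
    x = rng.multivariate_normal(np.zeros(gt.p), cov, size=n, method="cholesky")
    names = [f"item{i + 1:02d}" for i in range(gt.p)]
    if gt.discretization_levels == "continuous":
        frame = pd.DataFrame(x, columns=names)
        kinds = {c: "continuous" for c in names}
    else:
        z = x / np.sqrt(np.diag(cov))
        frame = pd.DataFrame(_discretize(z, gt.discretization_levels), columns=names)
        kinds = {c: "ordinal" for c in names}
    return BeliefDataset(frame, kinds)


def simulate_behavior(
    gt: GroundTruth, data: BeliefDataset, seed: int = 0, name: str = "behavior"
) -> BeliefDataset:
    """Append a binary behavior column via a logistic stimulation threshold.

    The behavior fires once the accumulated stimulation from the items
    crosses a stochastic threshold: a Bernoulli draw with
    ``logit = intercept + coefs . standardized(items)``. Marginal
    prevalence is controlled through the intercept.
    """
    if gt.behavior_coefs is None:
        coefs = np.zeros(gt.p)
    else:
        coefs = gt.behavior_coefs
    if coefs.shape != (data.p,):
        raise ValueError("behavior_coefs length does not match number of items")
    rng = np.random.default_rng(seed)
    x = data.to_numpy()
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    logit = gt.behavior_intercept + z @ coefs
    prob = 1.0 / (1.0 + np.exp(-logit))
    beh = (rng.random(len(prob)) < prob).astype(float)
    frame = data.values.copy()
    frame[name] = beh
    kinds = dict(data.var_kinds)
    kinds[name] = "binary"
    return BeliefDataset(frame, kinds, data.group)


def perturb_precision(
    gt: GroundTruth, edge_perturbation: dict[tuple[int, int], float]
) -> GroundTruth:
    """Shift selected partial correlations by the given deltas.

    Deltas are on the partial-correlation scale; the precision entry is
    adjusted as ``kappa_ij -= delta * sqrt(kappa_ii * kappa_jj)``.
    Raises if the perturbed matrix is no longer positive definite.
    """
    k = gt.precision_matrix.copy()
    d = np.sqrt(np.diag(k))
    for (i, j), delta in edge_perturbation.items():
        k[i, j] -= delta * d[i] * d[j]
        k[j, i] = k[i, j]
    if np.linalg.eigvalsh(k).min() <= 0:
        raise ValueError("perturbed precision matrix is not positive definite")
    return GroundTruth(
        k,
        behavior_coefs=gt.behavior_coefs,
        behavior_intercept=gt.behavior_intercept,
        discretization_levels=gt.discretization_levels,
    )


def make_two_group(
    gt_base: GroundTruth,
    edge_perturbation: dict[tuple[int, int], float],
    n1: int,
    n2: int,
    seed: int = 0,
) -> BeliefDataset:
    """Two-group dataset with known between-group edge differences.

    Group 0 (n1 rows) is drawn under ``gt_base``; group 1 (n2 rows) under
    the perturbed structure. An empty perturbation map yields the null:
    both groups share one distribution.
    """
    gt_alt = perturb_precision(gt_base, edge_perturbation)
    ss = np.random.SeedSequence(seed)
    s1, s2 = ss.spawn(2)
    d1 = simulate_responses(gt_base, n1, seed=s1.generate_state(1)[0] % 2**31)
    d2 = simulate_responses(gt_alt, n2, seed=s2.generate_state(1)[0] % 2**31)
    frame = pd.concat([d1.values, d2.values], ignore_index=True)
    group = np.concatenate([np.zeros(n1, dtype=int), np.ones(n2, dtype=int)])
    return BeliefDataset(frame, dict(d1.var_kinds), group)


def _study_truth(seed: int) -> GroundTruth:
    rng = np.random.default_rng(seed)
    p = STUDY_N_ITEMS
    gt = make_ground_truth(
        p,
        structure="random_sparse",
        edge_density=0.15,
        weight_range=(0.15, 0.35),
        seed=seed,
        negative_fraction=0.3,
        levels=5,
    )
    # a handful of items directly stimulate (or inhibit) registration
    coefs = np.zeros(p)
    stim = rng.choice(p, size=6, replace=False)
    coefs[stim] = rng.uniform(0.3, 0.8, size=6) * rng.choice([-1, 1, 1], size=6)
    # intercept targets the study's 93/366 marginal registration
    # prevalence; the logistic-normal correction accounts for the
    # variance the item effects add to the linear predictor
    base = float(np.log(STUDY_N_REGISTERED / STUDY_N_NOT_REGISTERED))
    intercept = base * float(np.sqrt(1.0 + 0.346 * np.sum(coefs**2)))
    return GroundTruth(
        gt.precision_matrix,
        behavior_coefs=coefs,
        behavior_intercept=intercept,
        discretization_levels=5,
    )


def study_dataset(seed: int = 0) -> tuple[BeliefDataset, GroundTruth]:
    """Emulate the study's data: 25 Likert items + binary behavior, n=366.

    Behavior prevalence targets the study's 93/273 imbalance between
    registered and non-registered respondents.
    """
    ss = np.random.SeedSequence(seed)
    s_gt, s_resp, s_beh = (s.generate_state(1)[0] % 2**31 for s in ss.spawn(3))
    gt = _study_truth(s_gt)
    n = STUDY_N_REGISTERED + STUDY_N_NOT_REGISTERED
    data = simulate_responses(gt, n, seed=s_resp)
    data = simulate_behavior(gt, data, seed=s_beh)
    return data, gt


def study_two_group_dataset(
    seed: int = 0, edge_perturbation: dict[tuple[int, int], float] | None = None
) -> tuple[BeliefDataset, GroundTruth]:
    """Two-group variant with the study's exact group sizes (93 vs 273)."""
    ss = np.random.SeedSequence(seed)
    s_gt, s_data = (s.generate_state(1)[0] % 2**31 for s in ss.spawn(2))
    gt = _study_truth(s_gt)
    data = make_two_group(
        gt,
        edge_perturbation or {},
        STUDY_N_REGISTERED,
        STUDY_N_NOT_REGISTERED,
        seed=s_data,
    )
    return data, gt
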