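"""Bootstrap surrogate edge-weight distributions and mask selection.

Under the null of no group difference, every subject's epoch networks are
exchangeable, so surrogate cohorts are built by pooling ALL epoch networks
of both groups and redrawing, for each real subject, that subject's epoch
count of networks with replacement from the pool.  Surrogate subject
templates are averaged subject-equally into surrogate group templates;
repeating R times gives, for each of the 153 edges, a bootstrap
distribution of the group-mean edge weight for each group.  Edges whose
observed group weight falls in the extreme tail (one-sided empirical
p <= p_sel, add-one convention) form the mask: ASD-low edges from the lower
tail of the surrogate-ASD distribution, control-high edges from the upper
tail of the surrogate-control distribution.

The clinical-scale setting is R = 100,000 with p_sel = 1e-5; the desk-scale
default is R = 2,000 (selection is then resolution-limited at p = 1/2001,
so planted effects in tests are sized to be detectable at that resolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channels import N_PAIRS, PAIR_UNIVERSE
from .networks import EdgeMask, EpochNetwork, TemplateNetwork, combine_masks


@dataclass
class BootstrapConfig:
    n_reps: int = 2_000
    seed: int = 0
    p_sel: float | None = None   # default: 1 / n_reps

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.p_sel is None:
            self.p_sel = 1.0 / self.n_reps
        if self.p_sel < 1.0 / self.n_reps:
            raise ValueError("p_sel below the bootstrap resolution 1/n_reps")


@dataclass
class EdgeDistributions:
    """Surrogate group-mean edge-weight distributions, (n_reps x 153) per group."""

    asd: np.ndarray
    control: np.ndarray

    @property
    def n_reps(self) -> int:
        return self.asd.shape[0]


def _pool_and_counts(subject_networks: dict[str, list[EpochNetwork]]):
    """Stack all epoch adjacencies into a pool matrix; record per-subject counts."""
    rows, counts, order = [], [], []
    for sid, nets in subject_networks.items():
        if not nets:
            raise ValueError(f"subject {sid} has no epoch networks")
        order.append(sid)
        counts.append(len(nets))
        rows.extend(n.adjacency.astype(np.float64) for n in nets)
    return np.array(rows), np.array(counts), order


def resample_surrogate_cohort(
    pool: np.ndarray, epoch_counts: np.ndarray, rng
) -> np.ndarray:
    """One surrogate cohort: per-subject templates redrawn from the pooled pool.

    Returns (n_subjects x 153) surrogate subject-template weights; subject s
    is the mean of ``epoch_counts[s]`` pool rows drawn with replacement, so
    per-subject epoch counts are preserved exactly.
    """
    if pool.size == 0:
        raise ValueError("empty epoch-network pool")
    P = pool.shape[0]
    out = np.empty((len(epoch_counts), pool.shape[1]))
    for s, m in enumerate(epoch_counts):
        counts = rng.multinomial(m, np.full(P, 1.0 / P))
        out[s] = counts @ pool / m
    return out


def bootstrap_edge_distributions(
    subject_networks: dict[str, list[EpochNetwork]],
    groups: dict[str, str],
    config: BootstrapConfig = BootstrapConfig(),
) -> EdgeDistributions:
    """Surrogate group-mean edge-weight distributions for both groups.

    ``subject_networks`` maps subject id -> epoch networks; ``groups`` maps
    subject id -> 'ASD' | 'control'.  Surrogate group templates average the
    surrogate subject templates subject-equally, exactly as the observed
    group templates are formed.
    """
    labels = {groups[sid] for sid in subject_networks}
    if labels != {"ASD", "control"}:
        raise ValueError(f"cohort must contain both groups, found {sorted(labels)}")
    pool, counts, order = _pool_and_counts(subject_networks)
    is_asd = np.array([groups[sid] == "ASD" for sid in order])
    rng = np.random.default_rng(config.seed)
    asd = np.empty((config.n_reps, N_PAIRS))
    ctrl = np.empty((config.n_reps, N_PAIRS))
    for r in range(config.n_reps):
        templates = resample_surrogate_cohort(pool, counts, rng)
        asd[r] = templates[is_asd].mean(axis=0)
        ctrl[r] = templates[~is_asd].mean(axis=0)
    return EdgeDistributions(asd=asd, control=ctrl)


def empirical_tail_pvalues(
    observed: np.ndarray, surrogate: np.ndarray, tail: str
) -> np.ndarray:
    """One-sided add-one empirical p-values per edge.

    tail='lower': p = (1 + #{surrogate <= observed}) / (1 + R);
    tail='upper': p = (1 + #{surrogate >= observed}) / (1 + R).
    """
    R = surrogate.shape[0]
    if tail == "lower":
        count = (surrogate <= observed[None, :]).sum(axis=0)
    elif tail == "upper":
        count = (surrogate >= observed[None, :]).sum(axis=0)
    else:
        raise ValueError("tail must be 'lower' or 'upper'")
    return (1 + count) / (1 + R)


def select_mask_edges(
    observed_asd: TemplateNetwork,
    observed_control: TemplateNetwork,
    distributions: EdgeDistributions,
    config: BootstrapConfig = BootstrapConfig(),
    mode: str = "union",
) -> EdgeMask:
    """Build the edge mask from the extreme tails of the surrogate distributions.

    mode: 'union' (the clinical-study mask), 'intersection', 'asd_only' or
    'control_only'.
    """
    p_low = empirical_tail_pvalues(observed_asd.weights, distributions.asd, "lower")
    p_high = empirical_tail_pvalues(
        observed_control.weights, distributions.control, "upper")
    asd_low = EdgeMask(
        name="asd_low",
        pairs=tuple(PAIR_UNIVERSE[i] for i in np.flatnonzero(p_low <= config.p_sel)),
        provenance="asd_low",
    )
    control_high = EdgeMask(
        name="control_high",
        pairs=tuple(PAIR_UNIVERSE[i] for i in np.flatnonzero(p_high <= config.p_sel)),
        provenance="control_high",
    )
    return combine_masks(asd_low, control_high, mode)
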