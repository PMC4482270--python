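"""Per-epoch binary functional networks and network statistics.

An epoch network is inferred over the 153 unordered derivation pairs of the
double-banana montage in two FDR-controlled steps: pairs whose zero-lag
correlation is significant are excluded first (volume-conduction suspects),
then the remaining pairs' max-lagged-correlation p-values are thresholded by
the Benjamini-Hochberg step-up at q (default 0.05).  Density divides the
edge count by (153 minus the number of zero-lag exclusions); mask density is
the fraction of a fixed edge mask present in the epoch (excluded mask edges
count as absent), averaged over epochs per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from . import connectivity as conn
from .channels import (
    LEFT_ELECTRODES,
    N_PAIRS,
    PAIR_INDEX,
    PAIR_UNIVERSE,
    RIGHT_ELECTRODES,
    DERIVATIONS_18,
    pair_indices,
    pair_name,
    parse_pair,
)


def bh_fdr(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg linear step-up; returns a boolean rejection array."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


@dataclass
class EpochNetwork:
    """Binary graph over the canonical 153-pair universe for one 2 s epoch."""

    adjacency: np.ndarray          # bool, length 153
    zero_lag_excluded: np.ndarray  # bool, length 153
    q: float = 0.05

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, bool)
        self.zero_lag_excluded = np.asarray(self.zero_lag_excluded, bool)
        if self.adjacency.shape != (N_PAIRS,) or self.zero_lag_excluded.shape != (N_PAIRS,):
            raise ValueError(f"networks are defined over the {N_PAIRS}-pair universe")
        if np.any(self.adjacency & self.zero_lag_excluded):
            raise ValueError("an edge cannot be both present and zero-lag-excluded")

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def edge_pairs(self) -> list[tuple[str, str]]:
        return [PAIR_UNIVERSE[i] for i in np.flatnonzero(self.adjacency)]


def infer_epoch_network(
    epoch: np.ndarray,
    fs: float,
    model: conn.SignificanceModel,
    q: float = 0.05,
    max_lag_ms: float = conn.DEFAULT_MAX_LAG_MS,
) -> EpochNetwork:
    """Infer the binary network for one variance-normalized epoch.

    Zero-lag exclusion runs its own BH step-up over the 153 zero-lag
    p-values; the surviving pairs' max-correlation p-values are then BH
    thresholded at q.  The statistics are computed on the scale the model
    expects (Bartlett-standardized for empirical models, raw correlation
    for the analytic fallback).
    """
    sc = conn.subject_connectivity(np.asarray(epoch, float)[None], fs, max_lag_ms)
    if model.empirical:
        edge_stat, zero_stat = sc.s_max[0], sc.s_zero[0]
    else:
        edge_stat, zero_stat = sc.r_max[0], sc.r_zero[0]
    return network_from_stats(edge_stat, zero_stat, model, q)


def network_from_stats(
    r_max: np.ndarray, r_zero: np.ndarray, model: conn.SignificanceModel,
    q: float = 0.05,
) -> EpochNetwork:
    excluded = bh_fdr(conn.zero_lag_pvalue(r_zero, model), q)
    adjacency = np.zeros(N_PAIRS, dtype=bool)
    keep = ~excluded
    if keep.any():
        p_edge = conn.edge_pvalue(r_max[keep], model)
        adjacency[keep] = bh_fdr(p_edge, q)
    return EpochNetwork(adjacency=adjacency, zero_lag_excluded=excluded, q=q)


def density(network: EpochNetwork) -> float:
    """Edges at non-zero lag / (153 - zero-lag exclusions)."""
    denom = N_PAIRS - int(network.zero_lag_excluded.sum())
    if denom == 0:
        raise ValueError("density undefined: every pair is zero-lag-excluded")
    return network.n_edges / denom


def degree_profile(network: EpochNetwork) -> np.ndarray:
    """Number of edges touching each of the 18 derivations."""
    deg = np.zeros(len(DERIVATIONS_18), dtype=int)
    name_to_idx = {d: i for i, d in enumerate(DERIVATIONS_18)}
    for a, b in network.edge_pairs():
        deg[name_to_idx[a]] += 1
        deg[name_to_idx[b]] += 1
    return deg


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

def _derivation_side(deriv: str) -> str:
    a, b = deriv.split("-")
    if a in LEFT_ELECTRODES and b in LEFT_ELECTRODES:
        return "left"
    if a in RIGHT_ELECTRODES and b in RIGHT_ELECTRODES:
        return "right"
    return "midline"


# Anterior/posterior assignment of derivations: anterior derivations end at
# or before the central (C) electrode row; posterior ones start at or behind
# it.  The paper does not enumerate this split; this table is the package's
# documented convention (see docs/methods.md).
ANTERIOR_DERIVATIONS = frozenset({
    "Fp1-F7", "F7-T3", "Fp1-F3", "F3-C3", "Fz-Cz", "Fp2-F4", "F4-C4",
    "Fp2-F8", "F8-T4",
})
POSTERIOR_DERIVATIONS = frozenset(DERIVATIONS_18) - ANTERIOR_DERIVATIONS


@dataclass(frozen=True)
class RegionSpec:
    """A named edge subset: within-region node sets or crossing predicates."""

    name: str
    nodes: frozenset = frozenset()
    crossing: tuple[frozenset, frozenset] | None = None

    def pair_mask(self) -> np.ndarray:
        mask = np.zeros(N_PAIRS, dtype=bool)
        for k, (a, b) in enumerate(PAIR_UNIVERSE):
            if self.crossing is not None:
                s1, s2 = self.crossing
                mask[k] = (a in s1 and b in s2) or (a in s2 and b in s1)
            else:
                mask[k] = a in self.nodes and b in self.nodes
        if not mask.any():
            raise ValueError(f"region {self.name!r} resolves to no candidate edges")
        return mask


def region(name: str) -> RegionSpec:
    left = frozenset(d for d in DERIVATIONS_18 if _derivation_side(d) == "left")
    right = frozenset(d for d in DERIVATIONS_18 if _derivation_side(d) == "right")
    table = {
        "left": RegionSpec("left", nodes=left),
        "right": RegionSpec("right", nodes=right),
        "anterior": RegionSpec("anterior", nodes=ANTERIOR_DERIVATIONS),
        "posterior": RegionSpec("posterior", nodes=POSTERIOR_DERIVATIONS),
        "all": RegionSpec("all", nodes=frozenset(DERIVATIONS_18)),
        "interhemispheric_LR": RegionSpec("interhemispheric_LR", crossing=(left, right)),
        "interhemispheric_AP": RegionSpec(
            "interhemispheric_AP", crossing=(ANTERIOR_DERIVATIONS, POSTERIOR_DERIVATIONS)
        ),
    }
    if name not in table:
        raise ValueError(f"unknown region {name!r}; choose from {sorted(table)}")
    return table[name]


def regional_density(network: EpochNetwork, spec: RegionSpec | str) -> float:
    """Density restricted to a region's candidate edge set."""
    if isinstance(spec, str):
        spec = region(spec)
    mask = spec.pair_mask()
    denom = int((mask & ~network.zero_lag_excluded).sum())
    if denom == 0:
        raise ValueError(f"region {spec.name!r} has no admissible candidate edges")
    return int((mask & network.adjacency).sum()) / denom


# ---------------------------------------------------------------------------
# Template networks and masks
# ---------------------------------------------------------------------------

@dataclass
class TemplateNetwork:
    """Weighted average network; weight = fraction of constituents with the edge."""

    weights: np.ndarray   # float in [0, 1], length 153
    level: str            # 'subject' or 'group'
    n_averaged: int

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        if self.weights.shape != (N_PAIRS,):
            raise ValueError(f"template weights must cover the {N_PAIRS}-pair universe")

    def to_edge_list(self) -> list[str]:
        return [f"{pair_name(PAIR_UNIVERSE[i])}\t{w:.6g}" for i, w in enumerate(self.weights)]


def template_network(items, level: str = "subject") -> TemplateNetwork:
    """Average epoch networks (subject level) or subject templates (group level).

    Group averaging weights subjects equally regardless of their epoch count.
    """
    items = list(items)
    if not items:
        raise ValueError("nothing to average")
    if level == "subject":
        stack = np.stack([n.adjacency.astype(float) for n in items])
    elif level == "group":
        stack = np.stack([t.weights for t in items])
    else:
        raise ValueError("level must be 'subject' or 'group'")
    return TemplateNetwork(weights=stack.mean(axis=0), level=level, n_averaged=len(items))


@dataclass(frozen=True)
class EdgeMask:
    """A named, fixed set of derivation pairs."""

    name: str
    pairs: tuple[tuple[str, str], ...]
    provenance: str = "user"

    def __post_init__(self):
        for p in self.pairs:
            if frozenset(p) not in PAIR_INDEX:
                raise ValueError(f"pair {p} is outside the derivation-pair universe")

    def __len__(self) -> int:
        return len(self.pairs)

    def indices(self) -> np.ndarray:
        return pair_indices(self.pairs)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for p in self.pairs:
                fh.write(pair_name(p) + "\n")

    @classmethod
    def from_file(cls, path, name: str | None = None, provenance: str = "user") -> "EdgeMask":
        with open(path) as fh:
            pairs = tuple(parse_pair(line) for line in fh if line.strip())
        return cls(name=name or str(path), pairs=pairs, provenance=provenance)


def mask_density(network: EpochNetwork, mask: EdgeMask) -> float:
    """Fraction of mask edges present in the epoch's adjacency.

    Zero-lag-excluded mask edges count as absent; the denominator is the
    full mask size.
    """
    if len(mask) == 0:
        raise ValueError("empty edge mask")
    idx = mask.indices()
    return int(network.adjacency[idx].sum()) / len(mask)


def subject_mask_density(networks, mask: EdgeMask) -> float:
    """Mean mask density across a subject's epoch networks."""
    vals = [mask_density(n, mask) for n in networks]
    if not vals:
        raise ValueError("no epoch networks")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Published edge masks (clinical-study Table 2 notation)
# ---------------------------------------------------------------------------

def _mask(name: str, provenance: str, text: str) -> EdgeMask:
    return EdgeMask(
        name=name,
        pairs=tuple(parse_pair(t) for t in text.split(";")),
        provenance=provenance,
    )


#: Edges whose weight in the mean ASD template fell significantly below the
#: surrogate ASD bootstrap distribution (16 edges).
ASD_LOW_MASK = _mask("asd_low", "asd_low", """
Fp1-F3/Fp1-F7; F3-C3/F7-T3; C3-P3/C4-P4; C3-P3/T3-T5; P3-O1/P4-O2;
P3-O1/T5-O1; F4-C4/F8-T4; F4-C4/T4-T6; C4-P4/P4-O2; C4-P4/T4-T6;
C4-P4/T6-O2; C4-P4/Cz-Pz; P4-O2/T5-O1; P4-O2/T6-O2; T5-O1/T6-O2;
T4-T6/Cz-Pz
""")

#: Edges whose weight in the mean control template fell significantly above
#: the surrogate control bootstrap distribution (23 edges).
CONTROL_HIGH_MASK = _mask("control_high", "control_high", """
Fp1-F3/Fp2-F4; Fp1-F3/Fp1-F7; Fp1-F3/F7-T3; Fp1-F3/Fp2-F8; Fp1-F3/F8-T4;
F3-C3/F7-T3; F3-C3/T3-T5; F3-C3/Fp2-F8; C3-P3/T3-T5; P3-O1/T5-O1;
Fp2-F4/Fp1-F7; Fp2-F4/F7-T3; Fp2-F4/Fp2-F8; Fp2-F4/F8-T4; F4-C4/C4-P4;
C4-P4/T4-T6; C4-P4/Cz-Pz; P4-O2/T6-O2; Fp1-F7/F7-T3; Fp1-F7/Fp2-F8;
Fp1-F7/F8-T4; F7-T3/Fp2-F8; Fp2-F8/F8-T4
""")


def combine_masks(asd_low: EdgeMask, control_high: EdgeMask, mode: str) -> EdgeMask:
    """Union / intersection / single-direction combination of the two masks."""
    a = {frozenset(p) for p in asd_low.pairs}
    c = {frozenset(p) for p in control_high.pairs}
    if mode == "union":
        keys = a | c
    elif mode == "intersection":
        keys = a & c
    elif mode == "asd_only":
        keys = a
    elif mode == "control_only":
        keys = c
    else:
        raise ValueError(f"unknown mask mode {mode!r}")
    idx = sorted(PAIR_INDEX[k] for k in keys)
    return EdgeMask(
        name=mode, pairs=tuple(PAIR_UNIVERSE[i] for i in idx), provenance=mode
    )


UNION_MASK = combine_masks(ASD_LOW_MASK, CONTROL_HIGH_MASK, "union")
INTERSECTION_MASK = combine_masks(ASD_LOW_MASK, CONTROL_HIGH_MASK, "intersection")
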