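"""10-20 electrode set, clinical montages, and the derivation-pair universe.

All downstream network code indexes edges against the canonical double-banana
derivation order defined here (left-lateral chain, left-parasagittal chain,
midline, right-parasagittal chain, right-lateral chain).  Keeping this order
fixed makes edge index <-> pair-name mappings stable across runs and lets
edge masks be written and read as plain text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

#: The 19 scalp electrodes of the international 10-20 system used here.
TEN_TWENTY_LABELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

# Normalized anterior->posterior coordinate per electrode row (0 = frontal
# pole, 1 = occiput).  Used by the synthetic generator's alpha-amplitude taper.
ANTERIOR_POSTERIOR_COORD: dict[str, float] = {
    "Fp1": 0.0, "Fp2": 0.0,
    "F7": 0.25, "F3": 0.25, "Fz": 0.25, "F4": 0.25, "F8": 0.25,
    "T3": 0.5, "C3": 0.5, "Cz": 0.5, "C4": 0.5, "T4": 0.5,
    "T5": 0.75, "P3": 0.75, "Pz": 0.75, "P4": 0.75, "T6": 0.75,
    "O1": 1.0, "O2": 1.0,
}

# Left / right hemisphere membership (midline electrodes in neither).
LEFT_ELECTRODES = frozenset({"Fp1", "F3", "C3", "P3", "O1", "F7", "T3", "T5"})
RIGHT_ELECTRODES = frozenset({"Fp2", "F4", "C4", "P4", "O2", "F8", "T4", "T6"})

# Canonical longitudinal-bipolar ("double banana") chains.
_DOUBLE_BANANA_CHAINS: tuple[tuple[str, ...], ...] = (
    ("Fp1", "F7", "T3", "T5", "O1"),      # left lateral
    ("Fp1", "F3", "C3", "P3", "O1"),      # left parasagittal
    ("Fz", "Cz", "Pz"),                   # midline
    ("Fp2", "F4", "C4", "P4", "O2"),      # right parasagittal
    ("Fp2", "F8", "T4", "T6", "O2"),      # right lateral
)

# Transverse (coronal) bipolar montage.  The paper-era clinical convention is
# not published in full; this is a standard left-to-right coronal chain set
# and is marked non-canonical in the docs.
_TRANSVERSE_CHAINS: tuple[tuple[str, ...], ...] = (
    ("Fp1", "Fp2"),
    ("F7", "F3", "Fz", "F4", "F8"),
    ("T3", "C3", "Cz", "C4", "T4"),
    ("T5", "P3", "Pz", "P4", "T6"),
    ("O1", "O2"),
)

# Nearest neighbours for the Hjorth-Laplacian reference (standard 10-20
# adjacency; non-canonical, see docs/methods.md).
_HJORTH_NEIGHBORS: dict[str, tuple[str, ...]] = {
    "Fp1": ("Fp2", "F3", "F7"),
    "Fp2": ("Fp1", "F4", "F8"),
    "F7": ("Fp1", "F3", "T3"),
    "F3": ("Fp1", "F7", "Fz", "C3"),
    "Fz": ("F3", "F4", "Cz"),
    "F4": ("Fp2", "F8", "Fz", "C4"),
    "F8": ("Fp2", "F4", "T4"),
    "T3": ("F7", "C3", "T5"),
    "C3": ("F3", "T3", "Cz", "P3"),
    "Cz": ("Fz", "C3", "C4", "Pz"),
    "C4": ("F4", "T4", "Cz", "P4"),
    "T4": ("F8", "C4", "T6"),
    "T5": ("T3", "P3", "O1"),
    "P3": ("C3", "T5", "Pz", "O1"),
    "Pz": ("Cz", "P3", "P4"),
    "P4": ("C4", "T6", "Pz", "O2"),
    "T6": ("T4", "P4", "O2"),
    "O1": ("T5", "P3", "O2"),
    "O2": ("T6", "P4", "O1"),
}

MONTAGE_NAMES = ("double_banana", "transverse", "hjorth_laplacian", "neck_reference")


@dataclass(frozen=True)
class Montage:
    """A re-referencing scheme mapping electrode channels to derivations.

    ``derivations`` is an ordered list of ``(name, anode, cathode_or_neighbors)``
    where the cathode entry is a single label for bipolar montages or a tuple
    of neighbour labels for the Laplacian (neighbour-mean subtraction).
    """

    name: str
    derivations: tuple[tuple[str, str, object], ...]
    channel_labels: tuple[str, ...] = TEN_TWENTY_LABELS

    @property
    def derivation_names(self) -> tuple[str, ...]:
        return tuple(d[0] for d in self.derivations)

    @property
    def n_derivations(self) -> int:
        return len(self.derivations)

    def matrix(self) -> np.ndarray:
        """Linear map ``M`` with derivation signals = channels @ M.T.

        Shape ``(n_derivations, n_channels)``; re-referencing is linear, so
        this single matrix is the whole montage.
        """
        idx = {lab: i for i, lab in enumerate(self.channel_labels)}
        M = np.zeros((len(self.derivations), len(self.channel_labels)))
        for r, (_, anode, cathode) in enumerate(self.derivations):
            M[r, idx[anode]] = 1.0
            if isinstance(cathode, str):
                M[r, idx[cathode]] -= 1.0
            else:  # Laplacian neighbour set
                for nb in cathode:
                    M[r, idx[nb]] -= 1.0 / len(cathode)
        return M

    def apply(self, samples: np.ndarray) -> np.ndarray:
        """Re-reference a (time x channel) array to (time x derivation)."""
        if samples.shape[1] != len(self.channel_labels):
            raise ValueError(
                f"expected {len(self.channel_labels)} channels, got {samples.shape[1]}"
            )
        return samples @ self.matrix().T


def _bipolar_from_chains(chains: Sequence[Sequence[str]], labels: Sequence[str]):
    derivs = []
    labset = set(labels)
    for chain in chains:
        for a, b in zip(chain[:-1], chain[1:]):
            for lab in (a, b):
                if lab not in labset:
                    raise ValueError(f"montage references missing electrode label {lab!r}")
            derivs.append((f"{a}-{b}", a, b))
    return tuple(derivs)


def build_montage(
    channel_labels: Sequence[str] = TEN_TWENTY_LABELS,
    name: str = "double_banana",
    reference_channel: str | None = None,
) -> Montage:
    """Construct a named clinical montage over the given electrode labels.

    ``double_banana`` yields the 18 longitudinal bipolar derivations in the
    canonical chain order; ``hjorth_laplacian`` subtracts the neighbour mean;
    ``neck_reference`` subtracts a designated reference channel (which must be
    supplied, since the 10-20 set carries no neck electrode).
    """
    labels = tuple(channel_labels)
    if name == "double_banana":
        if set(TEN_TWENTY_LABELS) <= set(labels):
            derivs = _bipolar_from_chains(_DOUBLE_BANANA_CHAINS, labels)
        else:
            # Toy chains (tests): consecutive bipolar pairs.
            derivs = _bipolar_from_chains([labels], labels)
        return Montage(name, derivs, labels)
    if name == "transverse":
        derivs = _bipolar_from_chains(_TRANSVERSE_CHAINS, labels)
        return Montage(name, derivs, labels)
    if name == "hjorth_laplacian":
        derivs = []
        labset = set(labels)
        for lab in labels:
            nbs = tuple(n for n in _HJORTH_NEIGHBORS.get(lab, ()) if n in labset)
            if not nbs:
                raise ValueError(f"no Laplacian neighbours available for {lab!r}")
            derivs.append((f"{lab}-avg", lab, nbs))
        return Montage(name, tuple(derivs), labels)
    if name == "neck_reference":
        if reference_channel is None or reference_channel not in labels:
            raise ValueError(
                "neck_reference requires a designated reference channel present "
                "in the recording"
            )
        derivs = tuple(
            (f"{lab}-{reference_channel}", lab, reference_channel)
            for lab in labels
            if lab != reference_channel
        )
        return Montage(name, derivs, labels)
    raise ValueError(f"unsupported montage {name!r}; choose from {MONTAGE_NAMES}")


DOUBLE_BANANA: Montage = build_montage()
DERIVATIONS_18: tuple[str, ...] = DOUBLE_BANANA.derivation_names
assert len(DERIVATIONS_18) == 18

#: All unordered derivation pairs in canonical order — the 153-edge universe.
PAIR_UNIVERSE: tuple[tuple[str, str], ...] = tuple(combinations(DERIVATIONS_18, 2))
PAIR_INDEX: dict[frozenset, int] = {
    frozenset(p): i for i, p in enumerate(PAIR_UNIVERSE)
}
N_PAIRS = len(PAIR_UNIVERSE)

#: Posterior/anterior derivation pairs used by the peak-alpha-ratio statistic,
#: in scalp order far-left, medial-left, medial-right, far-right.
RATIO_PAIRS: tuple[tuple[str, str], ...] = (
    ("T5-O1", "Fp1-F7"),
    ("P3-O1", "Fp1-F3"),
    ("P4-O2", "Fp2-F4"),
    ("T6-O2", "Fp2-F8"),
)


def pair_name(pair: tuple[str, str]) -> str:
    """Render a derivation pair in mask-file notation, e.g. 'Fp1-F3/Fp1-F7'."""
    a, b = pair
    return f"{a}/{b}"


def parse_pair(text: str) -> tuple[str, str]:
    """Parse 'derivA/derivB' into the canonically ordered pair."""
    parts = text.strip().split("/")
    if len(parts) != 2:
        raise ValueError(f"cannot parse derivation pair {text!r}")
    a, b = (p.strip() for p in parts)
    key = frozenset((a, b))
    if key not in PAIR_INDEX:
        raise ValueError(f"unknown derivation pair {text!r}")
    return PAIR_UNIVERSE[PAIR_INDEX[key]]


def pair_indices(pairs) -> np.ndarray:
    """Map an iterable of derivation pairs to canonical edge indices."""
    return np.array(sorted(PAIR_INDEX[frozenset(p)] for p in pairs), dtype=int)
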