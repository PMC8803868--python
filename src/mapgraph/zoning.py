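"""Structural vs functional zoning of map columns and their correspondence.

Structural zones are the anatomical zebrin bands containing each column.
Functional zones derive from the graph-module partition, either as maximal
spatially contiguous runs of a module label (α1, β1, α2, …) or as the bare
module labels with contiguity dropped (α, β, …).  Correspondence between the
two labelings is measured by mutual information normalised by the larger of
the two label entropies, so 1 means perfect overlap; chance levels come from
permuting the structural labels across columns.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .zebrin import ZebrinGeometry, BAND_NAMES
from .graphs import ModulePartition

#: default structural template: the seven printed zebrin bands
TEMPLATE_7 = tuple(BAND_NAMES)

#: eight-zone template: ipsilateral P1− split into medial and lateral halves
TEMPLATE_8 = (
    "P2-_contra",
    "P2+_contra",
    "P1-_contra",
    "P1+",
    "P1-_ipsi_medial",
    "P1-_ipsi_lateral",
    "P2+_ipsi",
    "P2-_ipsi",
)

_GREEK = "αβγδεζηθικλμνξοπρστυφχψω"


@dataclass
class ZoneLabeling:
    """Per-column zone labels of one kind."""

    labels: np.ndarray               # (n_columns,) strings
    kind: str                        # structural | functional_contiguous | functional_modulewise

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class MIResult:
    """Mutual information between two labelings, with entropies and chance."""

    mi: float                        # nats
    h_x: float
    h_y: float
    nmi: float                       # mi / max(h_x, h_y); 0 when both entropies are 0
    chance: np.ndarray | None = None
    chance_ci: tuple[float, float] | None = None


def structural_zones(
    positions_um: Sequence[float],
    geometry: ZebrinGeometry,
    template: Sequence[str] = TEMPLATE_7,
) -> ZoneLabeling:
    """Label each column by the zebrin band containing its centre.

    With the 8-zone template the ipsilateral P1− band is split at its
    midpoint into medial and lateral halves.  Positions outside the tiled
    extent are clamped to the outermost band; boundary positions go to the
    band on their ipsilateral side.
    """
    template = tuple(template)
    if template not in (TEMPLATE_7, TEMPLATE_8):
        raise ValueError("unknown structural zone template")
    labels = []
    edges = geometry.band_edges
    for pos in np.asarray(positions_um, dtype=float):
        band = geometry.band_at(pos)
        if template == TEMPLATE_8 and band == "P1-_ipsi":
            mid = (edges[4] + edges[5]) / 2.0
            band = "P1-_ipsi_medial" if pos < mid else "P1-_ipsi_lateral"
        labels.append(band)
    return ZoneLabeling(labels=np.array(labels, dtype=object), kind="structural")


def functional_zones(
    partition: ModulePartition,
    definition: str = "contiguous",
) -> ZoneLabeling:
    """Derive functional zone labels from the graph-module partition.

    ``contiguous``: maximal runs of one module become separate zones (α1, β1,
    α2, …) so every zone is a spatially connected range, like an anatomical
    band.  ``modulewise``: the module label itself is the zone (α, β, …),
    allowing spatially disconnected zones.
    """
    mods = partition.labels
    if definition == "modulewise":
        labels = [_GREEK[m % len(_GREEK)] for m in mods]
        return ZoneLabeling(np.array(labels, dtype=object), kind="functional_modulewise")
    if definition != "contiguous":
        raise ValueError(f"unknown functional-zone definition {definition!r}")
    labels = []
    run_counts: dict[int, int] = {}
    prev = None
    for m in mods:
        if m != prev:
            run_counts[m] = run_counts.get(m, 0) + 1
            prev = m
        labels.append(f"{_GREEK[m % len(_GREEK)]}{run_counts[m]}")
    return ZoneLabeling(np.array(labels, dtype=object), kind="functional_contiguous")


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels.astype(str), return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def _mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    xs = x.astype(str)
    ys = y.astype(str)
    n = len(xs)
    mi = 0.0
    for xv in np.unique(xs):
        for yv in np.unique(ys):
            pxy = np.sum((xs == xv) & (ys == yv)) / n
            if pxy == 0:
                continue
            px = np.sum(xs == xv) / n
            py = np.sum(ys == yv) / n
            mi += pxy * math.log(pxy / (px * py))
    return float(max(mi, 0.0))


def normalized_mi(x: ZoneLabeling, y: ZoneLabeling) -> MIResult:
    """Plug-in mutual information normalised by the larger label entropy.

    Natural logarithms; the normalisation makes the headline value
    base-free, with 1 denoting perfect overlap (identity up to relabeling)
    and 0 independence.
    """
    if len(x) != len(y):
        raise ValueError("labelings must cover the same columns")
    mi = _mutual_information(x.labels, y.labels)
    hx, hy = _entropy(x.labels), _entropy(y.labels)
    h = max(hx, hy)
    nmi = mi / h if h > 0 else 0.0
    return MIResult(mi=mi, h_x=hx, h_y=hy, nmi=float(np.clip(nmi, 0.0, 1.0)))


def mi_chance(
    x: ZoneLabeling,
    y: ZoneLabeling,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    block_preserving: bool = False,
) -> MIResult:
    """Chance level of the normalised MI by permuting structural labels.

    The default shuffles labels per column (destroying spatial contiguity);
    ``block_preserving`` instead rotates the label string by a random offset,
    keeping zone blocks intact.  Returns the actual MI result with the
    permutation distribution and its 95% percentile interval attached.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    result = normalized_mi(x, y)
    chance = np.empty(n_perm)
    labels = x.labels.copy()
    n = len(labels)
    for i in range(n_perm):
        if block_preserving:
            shift = int(rng.integers(0, n))
            perm = np.roll(labels, shift)
        else:
            perm = labels[rng.permutation(n)]
        chance[i] = normalized_mi(
            ZoneLabeling(perm, kind=x.kind), y
        ).nmi
    result.chance = chance
    result.chance_ci = (
        float(np.percentile(chance, 2.5)),
        float(np.percentile(chance, 97.5)),
    )
    return result
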