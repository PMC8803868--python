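"""Zebrin-band geometry: the anatomical coordinate frame of the maps.

Purkinje cells in the anterior vermis are organised into parasagittal
zebrin(aldolase-C) bands.  Seven bands tile the mediolateral axis around the
midline — P2−, P2+, P1− on the contralateral side, P1+ straddling the midline,
then P1−, P2+, P2− ipsilaterally.  All map positions are expressed relative to
this frame: the origin sits at the centre of the P1+ band, ipsilateral
positions are positive, and positions are normalised to the width of the
ipsilateral P1− band for cross-animal alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: band labels in mediolateral order, contralateral → ipsilateral
BAND_NAMES = (
    "P2-_contra",
    "P2+_contra",
    "P1-_contra",
    "P1+",
    "P1-_ipsi",
    "P2+_ipsi",
    "P2-_ipsi",
)

#: adult lobule III/IV/V band widths, mean and SD in µm (n = 100 bands)
BAND_WIDTH_MEANS = np.array([416.6, 71.56, 320.516, 34.63, 320.46, 69.75, 438.04])
BAND_WIDTH_SDS = np.array([70.72, 24.59, 62.94, 16.18, 60.54, 22.53, 64.25])

#: recorded-PC distance from midline, µm (mean, SD) and the recording criterion cap
PC_POSITION_MEAN = 52.42
PC_POSITION_SD = 29.8
PC_POSITION_MAX = 130.0

_MIN_WIDTH = 5.0  # positive floor for truncated sampling, µm


@dataclass(frozen=True)
class ZebrinGeometry:
    """Widths of the seven zebrin bands plus the recorded-PC position.

    The coordinate origin (``midline_position``) is the centre of the P1+
    band; ipsilateral positions are positive.
    """

    band_widths: tuple[float, ...]
    pc_position: float = 0.0
    midline_position: float = 0.0

    def __post_init__(self) -> None:
        if len(self.band_widths) != 7:
            raise ValueError("expected 7 band widths")
        if any(w <= 0 for w in self.band_widths):
            raise ValueError("band widths must be positive")
        if abs(self.pc_position) > PC_POSITION_MAX:
            raise ValueError(
                f"pc_position {self.pc_position} outside ±{PC_POSITION_MAX} µm"
            )

    @property
    def band_edges(self) -> np.ndarray:
        """Band boundary positions (µm), length 8, strictly increasing.

        ``edges[i]:edges[i+1]`` is the extent of band ``BAND_NAMES[i]``.
        """
        w = np.asarray(self.band_widths, dtype=float)
        left = self.midline_position - w[3] / 2.0 - w[:3].sum()
        return left + np.concatenate([[0.0], np.cumsum(w)])

    @property
    def p1m_ipsi_width(self) -> float:
        """Width of the ipsilateral P1− band (µm), the normalisation unit."""
        return float(self.band_widths[4])

    @property
    def extent(self) -> tuple[float, float]:
        e = self.band_edges
        return float(e[0]), float(e[-1])

    def band_at(self, position: float) -> str:
        """Band containing a mediolateral position (µm).

        Positions exactly on a boundary are assigned to the band on the
        ipsilateral side of the boundary; positions outside the tiled extent
        are clamped to the outermost band.
        """
        edges = self.band_edges
        # side="right" puts a boundary position into the band starting there,
        # i.e. the ipsilateral neighbour, matching the tie rule
        idx = int(np.searchsorted(edges, position, side="right")) - 1
        return BAND_NAMES[int(np.clip(idx, 0, 6))]

    def normalize(self, positions_um):
        """Map positions in µm to % of the ipsilateral P1− band width.

        Sign is preserved (contralateral negative).
        """
        w = self.p1m_ipsi_width
        if w <= 0:
            raise ValueError("ipsilateral P1- width must be positive")
        return 100.0 * (np.asarray(positions_um, dtype=float) - self.midline_position) / w

    def to_dict(self) -> dict:
        return {
            "band_widths": list(map(float, self.band_widths)),
            "pc_position": float(self.pc_position),
            "midline_position": float(self.midline_position),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZebrinGeometry":
        return cls(
            band_widths=tuple(d["band_widths"]),
            pc_position=float(d.get("pc_position", 0.0)),
            midline_position=float(d.get("midline_position", 0.0)),
        )


def mean_geometry(pc_position: float = PC_POSITION_MEAN) -> ZebrinGeometry:
    """Geometry built from the printed adult mean band widths."""
    return ZebrinGeometry(tuple(BAND_WIDTH_MEANS), pc_position=pc_position)


def generate_zebrin_geometry(
    seed: int | np.random.Generator,
    truncate: bool = True,
    width_means=BAND_WIDTH_MEANS,
    width_sds=BAND_WIDTH_SDS,
) -> ZebrinGeometry:
    """Sample a geometry from the printed band-width statistics.

    Each width is drawn Normal(mean, sd); with ``truncate`` the draw is
    redrawn (then floored) to stay above a small positive width.  The PC
    position is drawn Normal(52.42, 29.8) µm clipped to [0, 130] µm, the
    recording inclusion criterion.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    means = np.asarray(width_means, dtype=float)
    sds = np.asarray(width_sds, dtype=float)
    widths = rng.normal(means, sds)
    if truncate:
        for _ in range(20):
            bad = widths < _MIN_WIDTH
            if not bad.any():
                break
            widths[bad] = rng.normal(means[bad], sds[bad])
        widths = np.maximum(widths, _MIN_WIDTH)
    pc = float(np.clip(rng.normal(PC_POSITION_MEAN, PC_POSITION_SD), 0.0, PC_POSITION_MAX))
    return ZebrinGeometry(tuple(widths), pc_position=pc)
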