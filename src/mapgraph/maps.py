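"""Processing of granule-cell → Purkinje-cell connectivity maps.

A connectivity map is a rectangular grid of mean evoked EPSC amplitudes
(magnitudes, pA) over photostimulation sites in the granule-cell layer:
rows span depth, columns span the mediolateral axis.  Sites are scored
against the recording's synaptic-noise distribution,

    z = (A − X) / σ,

with ``A`` the mean evoked amplitude at the site and ``X``, ``σ`` the mean
and SD of the map-wide noise distribution; sites with z ≥ 3 are "active"
(statistically above background).  Per-column maxima of z (or of the
significant amplitudes) give a 1-D synaptic profile along the mediolateral
axis, which supports group medians, cumulative-strength curves and the graph
construction downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .zebrin import ZebrinGeometry

#: z threshold above which a site counts as synaptically connected
Z_THRESHOLD = 3.0

#: triangular smoothing kernel half-widths (µm) by site size
KERNEL_HALF_WIDTH = {20: 9.0, 40: 18.0}

#: averaging bin widths (µm equivalents) by site size
AVERAGE_BIN_WIDTH = {20: 30.0, 40: 60.0}

#: granule-cell density in the adult granular layer, cells per mm³
GC_DENSITY_PER_MM3 = 1.92e6


@dataclass
class ConnectivityMap:
    """Grid of mean EPSC amplitude magnitudes with spatial coordinates."""

    amplitudes: np.ndarray           # (rows, cols), pA, >= 0
    site_size: int                   # µm, 20 or 40
    column_positions: np.ndarray     # (cols,) µm column centres, ipsi positive
    geometry: ZebrinGeometry
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.column_positions = np.asarray(self.column_positions, dtype=float)
        if self.amplitudes.ndim != 2:
            raise ValueError("amplitudes must be 2-D (rows x columns)")
        if self.site_size not in (20, 40):
            raise ValueError("site_size must be 20 or 40 µm")
        if self.amplitudes.shape[1] != self.column_positions.size:
            raise ValueError("column_positions length must match column count")
        if np.any(np.diff(self.column_positions) <= 0):
            raise ValueError("column positions must be strictly increasing")
        if not np.all(np.isfinite(self.amplitudes)) or np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be finite and non-negative")

    @property
    def n_rows(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_columns(self) -> int:
        return self.amplitudes.shape[1]

    @property
    def normalized_positions(self) -> np.ndarray:
        """Column centres in % of the ipsilateral P1− band width."""
        return self.geometry.normalize(self.column_positions)


@dataclass
class TrialSet:
    """Repeated-trial evoked amplitudes and noise draws for every site."""

    evoked: np.ndarray    # (n_trials, rows, cols), pA
    noise: np.ndarray     # (n_trials, rows, cols), pA

    def __post_init__(self) -> None:
        self.evoked = np.asarray(self.evoked, dtype=float)
        self.noise = np.asarray(self.noise, dtype=float)
        if self.evoked.shape != self.noise.shape:
            raise ValueError("evoked and noise trial arrays must share a shape")
        if self.evoked.shape[0] < 5:
            raise ValueError("at least 5 trials per site are required")
        if not (np.all(np.isfinite(self.evoked)) and np.all(np.isfinite(self.noise))):
            raise ValueError("trial amplitudes must be finite")

    @property
    def n_trials(self) -> int:
        return self.evoked.shape[0]

    def mean_evoked(self) -> np.ndarray:
        return self.evoked.mean(axis=0)


@dataclass
class ZScoreMap:
    """Per-site z scores against the map-wide synaptic-noise distribution."""

    z: np.ndarray
    noise_mean: float
    noise_sd: float
    threshold: float = Z_THRESHOLD

    @property
    def active(self) -> np.ndarray:
        """Boolean mask of sites at or above the z threshold."""
        return self.z >= self.threshold


@dataclass
class SynapticProfile:
    """Per-column projection of a map's maximal significant response."""

    values: np.ndarray               # per-column max z or max amplitude
    connected: np.ndarray            # per-column bool, any site with z >= threshold
    positions_um: np.ndarray
    positions_norm: np.ndarray       # % of ipsilateral P1− width
    mode: str = "max_z"              # "max_z" or "max_weight"
    site_size: int = 20

    def __post_init__(self) -> None:
        n = len(self.values)
        if not (len(self.connected) == len(self.positions_um) == len(self.positions_norm) == n):
            raise ValueError("profile fields must have equal length")


@dataclass
class MedianProfile:
    """Pointwise median ± MAD of aligned, smoothed profiles."""

    positions_norm: np.ndarray
    median: np.ndarray
    mad: np.ndarray
    n_maps: int


@dataclass
class AveragedMap:
    """Row-wise binned average of spatially aligned maps.

    Empty bins are NaN (missing), never zero.
    """

    values: np.ndarray               # (rows, n_bins)
    bin_centers_norm: np.ndarray
    bin_width_norm: float
    n_maps: int


def compute_zscore_map(
    trials: TrialSet | None = None,
    *,
    amplitudes: np.ndarray | None = None,
    noise_mean: float | None = None,
    noise_sd: float | None = None,
    threshold: float = Z_THRESHOLD,
) -> ZScoreMap:
    """z-score a map against its pooled synaptic-noise distribution.

    Either pass a :class:`TrialSet` (noise statistics are pooled over every
    site's noise draws) or the per-site mean amplitudes plus explicit noise
    mean/SD.
    """
    if trials is not None:
        a = trials.mean_evoked()
        pooled = trials.noise.ravel()
        if pooled.size < 2:
            raise ValueError("need at least 2 noise samples")
        x = float(pooled.mean())
        sd = float(pooled.std(ddof=1))
    else:
        if amplitudes is None or noise_mean is None or noise_sd is None:
            raise ValueError("provide trials, or amplitudes with noise stats")
        a = np.asarray(amplitudes, dtype=float)
        x, sd = float(noise_mean), float(noise_sd)
    if sd <= 0:
        raise ValueError("noise SD must be positive (degenerate noise distribution)")
    return ZScoreMap(z=(a - x) / sd, noise_mean=x, noise_sd=sd, threshold=threshold)


def project_profile(
    cmap: ConnectivityMap, zmap: ZScoreMap, mode: str = "max_z"
) -> SynapticProfile:
    """Project a map onto the mediolateral axis by per-column maxima.

    ``max_z`` takes the column-wise maximum z score; ``max_weight`` takes the
    maximum amplitude among significant (z ≥ threshold) sites, masked to 0
    where a column has none.  A column is "connected" iff it contains at
    least one significant site.
    """
    if zmap.z.shape != cmap.amplitudes.shape:
        raise ValueError("z map and amplitude grid shapes differ")
    connected = (zmap.z >= zmap.threshold).any(axis=0)
    if mode == "max_z":
        values = zmap.z.max(axis=0)
    elif mode == "max_weight":
        sig = np.where(zmap.z >= zmap.threshold, cmap.amplitudes, 0.0)
        values = sig.max(axis=0)
    else:
        raise ValueError(f"unknown profile mode {mode!r}")
    return SynapticProfile(
        values=values,
        connected=connected,
        positions_um=cmap.column_positions.copy(),
        positions_norm=cmap.normalized_positions,
        mode=mode,
        site_size=cmap.site_size,
    )


def align_to_zebrin(positions_um, geometry: ZebrinGeometry) -> np.ndarray:
    """Normalise µm positions to % of the ipsilateral P1− band width."""
    return geometry.normalize(positions_um)


def _triangular_kernel(half_width_um: float, step_um: float) -> np.ndarray:
    """Unit-area triangular kernel sampled at ``step_um``."""
    n = max(int(round(half_width_um / step_um)), 1)
    x = np.arange(-n, n + 1, dtype=float) * step_um
    k = np.maximum(1.0 - np.abs(x) / half_width_um, 0.0)
    return k / k.sum()


def smooth_profile(profile: SynapticProfile, step_um: float = 1.0):
    """Interpolate a profile to a fine µm grid and apply triangular smoothing.

    Returns ``(positions_norm, smoothed_values)`` on a ``step_um`` grid.
    The kernel half-width follows the map resolution (9 µm at 20 µm sites,
    18 µm at 40 µm sites) and has unit area, so constant profiles pass
    through unchanged.
    """
    half_width = KERNEL_HALF_WIDTH[profile.site_size]
    pos = profile.positions_um
    fine = np.arange(pos[0], pos[-1] + step_um / 2, step_um)
    vals = np.interp(fine, pos, profile.values)
    kernel = _triangular_kernel(half_width, step_um)
    # edge-pad so the unit-area kernel preserves constants at the boundaries
    pad = len(kernel) // 2
    padded = np.concatenate([np.full(pad, vals[0]), vals, np.full(pad, vals[-1])])
    smoothed = np.convolve(padded, kernel, mode="valid")
    # per-map normalisation: µm → % of this map's P1− ipsi width
    scale = profile.positions_norm[-1] - profile.positions_norm[0]
    span = pos[-1] - pos[0]
    norm = profile.positions_norm[0] + (fine - pos[0]) * scale / span
    return norm, smoothed


def median_profile(
    profiles: Sequence[SynapticProfile], step_norm: float = 0.3125
) -> MedianProfile:
    """Median ± MAD of smoothed profiles on a common normalised axis.

    Each profile is interpolated to a 1-µm grid, convolved with the
    resolution-matched unit-area triangular kernel, mapped to normalised
    (% P1−) coordinates and re-interpolated onto a shared axis.  The median
    is reported only where at least half the maps overlap spatially.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    sizes = {p.site_size for p in profiles}
    if len(sizes) > 1:
        raise ValueError("profiles mix map resolutions")
    aligned = [smooth_profile(p) for p in profiles]
    lo = min(a[0][0] for a in aligned)
    hi = max(a[0][-1] for a in aligned)
    axis = np.arange(lo, hi + step_norm / 2, step_norm)
    stack = np.full((len(aligned), axis.size), np.nan)
    for i, (norm, vals) in enumerate(aligned):
        inside = (axis >= norm[0]) & (axis <= norm[-1])
        stack[i, inside] = np.interp(axis[inside], norm, vals)
    counts = np.sum(~np.isnan(stack), axis=0)
    ok = counts >= max(int(np.ceil(len(aligned) / 2)), 2)
    med = np.full(axis.size, np.nan)
    mad = np.full(axis.size, np.nan)
    med[ok] = np.nanmedian(stack[:, ok], axis=0)
    mad[ok] = np.nanmedian(np.abs(stack[:, ok] - med[ok]), axis=0)
    return MedianProfile(
        positions_norm=axis[ok], median=med[ok], mad=mad[ok], n_maps=len(aligned)
    )


def average_map(maps: Sequence[ConnectivityMap], bin_width_um: float | None = None) -> AveragedMap:
    """Bin-average spatially aligned maps row by row.

    Site values from all maps are pooled with their normalised positions,
    sorted along the mediolateral axis and averaged in bins of 30 µm
    (high resolution) or 60 µm (low resolution) equivalents on the
    normalised axis.  Bins with no sites are NaN.
    """
    if len(maps) < 1:
        raise ValueError("need at least 1 map")
    sizes = {m.site_size for m in maps}
    if len(sizes) > 1:
        raise ValueError("maps mix resolutions")
    site_size = sizes.pop()
    rows = {m.n_rows for m in maps}
    if len(rows) > 1:
        raise ValueError("maps mix row counts")
    n_rows = rows.pop()
    if bin_width_um is None:
        bin_width_um = AVERAGE_BIN_WIDTH[site_size]
    # convert the µm bin width to normalised units per map, use the mean scale
    scale = np.mean([100.0 / m.geometry.p1m_ipsi_width for m in maps])
    bw = bin_width_um * scale
    pos = np.concatenate([m.normalized_positions for m in maps])
    lo, hi = pos.min(), pos.max()
    n_bins = int(np.floor((hi - lo) / bw + 1e-9)) + 1
    # shave a relative epsilon off the edges so sites sitting exactly on a
    # boundary land in the upper bin regardless of float rounding
    edges = lo + bw * (np.arange(n_bins + 1) - 1e-6)
    out = np.full((n_rows, n_bins), np.nan)
    for r in range(n_rows):
        vals = np.concatenate([m.amplitudes[r] for m in maps])
        idx = np.clip(np.searchsorted(edges, pos, side="right") - 1, 0, n_bins - 1)
        for b in range(n_bins):
            sel = idx == b
            if sel.any():
                out[r, b] = vals[sel].mean()
    centers = (edges[:-1] + edges[1:]) / 2
    return AveragedMap(values=out, bin_centers_norm=centers, bin_width_norm=bw, n_maps=len(maps))


def cumulative_strength(profile: SynapticProfile) -> np.ndarray:
    """Running sum of significant column weights, contralateral → ipsilateral.

    Input must be a ``max_weight`` profile (pA); output is in nA.
    Non-connected columns contribute zero, so the curve is non-decreasing.
    """
    if profile.mode != "max_weight":
        raise ValueError("cumulative strength requires a max_weight profile")
    contrib = np.where(profile.connected, profile.values, 0.0)
    return np.cumsum(contrib) / 1000.0


def downsample_map(cmap: ConnectivityMap) -> ConnectivityMap:
    """Downsample a 20 µm map to 40 µm by 2×2 block averaging.

    Odd row/column counts are edge-replicated to even before blocking; column
    positions are merged pairwise.
    """
    if cmap.site_size != 20:
        raise ValueError("downsampling expects a 20 µm (high-resolution) map")
    a = cmap.amplitudes
    pos = cmap.column_positions
    if a.shape[0] % 2:
        a = np.vstack([a, a[-1:]])
    if a.shape[1] % 2:
        a = np.hstack([a, a[:, -1:]])
        pos = np.concatenate([pos, [pos[-1] + 20.0]])
    blocked = (a[0::2, 0::2] + a[0::2, 1::2] + a[1::2, 0::2] + a[1::2, 1::2]) / 4.0
    new_pos = (pos[0::2] + pos[1::2]) / 2.0
    meta = dict(cmap.metadata)
    meta["downsampled_from"] = 20
    return ConnectivityMap(
        amplitudes=blocked,
        site_size=40,
        column_positions=new_pos,
        geometry=cmap.geometry,
        metadata=meta,
    )


def bootstrap_profile_ci(
    profiles: Sequence[SynapticProfile],
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    step_norm: float = 0.3125,
):
    """Percentile bootstrap CI of the group median profile.

    Maps (profiles) are resampled with replacement ``n_boot`` times; the
    pointwise median is recomputed on each resample and the ``alpha``-level
    percentile interval returned.  A position counts as connected at the
    group level when the CI lower bound exceeds zero.

    Returns ``(positions_norm, lower, upper, group_connected)``.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles to bootstrap")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    base = median_profile(profiles, step_norm=step_norm)
    axis = base.positions_norm
    aligned = [smooth_profile(p) for p in profiles]
    stack = np.full((len(aligned), axis.size), np.nan)
    for i, (norm, vals) in enumerate(aligned):
        inside = (axis >= norm[0]) & (axis <= norm[-1])
        stack[i, inside] = np.interp(axis[inside], norm, vals)
    n = len(aligned)
    meds = np.empty((n_boot, axis.size))
    for b in range(n_boot):
        take = rng.integers(0, n, size=n)
        meds[b] = np.nanmedian(stack[take], axis=0)
    lower = np.nanquantile(meds, alpha / 2, axis=0)
    upper = np.nanquantile(meds, 1 - alpha / 2, axis=0)
    if alpha >= 1.0:  # degenerate request: interval collapses to the estimate
        lower = upper = np.nanmedian(stack, axis=0)
    return axis, lower, upper, lower > 0


#: effective stimulated volumes per site size (mm³): 4 × 10⁻⁵ for 20 µm
#: sites and 2 × 10⁻⁴ for 40 µm sites
STIMULATED_VOLUME_MM3 = {20: 4e-5, 40: 2e-4}


def estimate_activated_gc_count(
    site_side_um: float,
    depth_um: float | None = None,
    density_per_mm3: float = GC_DENSITY_PER_MM3,
) -> float:
    """Expected number of granule cells activated by one photostimulation.

    The stimulated volume times the adult granular-layer density of
    1.92 × 10⁶ cells/mm³.  Without an explicit ``depth_um`` the effective
    stimulated volumes for the two standard site sizes are used
    (4 × 10⁻⁵ mm³ at 20 µm, 2 × 10⁻⁴ mm³ at 40 µm, light penetrating
    < 100 µm into the slice), giving 76.8 and 384 cells; with a depth the
    volume is ``site_side² × depth``.
    """
    if site_side_um < 0 or density_per_mm3 < 0:
        raise ValueError("arguments must be non-negative")
    if depth_um is None:
        if int(site_side_um) not in STIMULATED_VOLUME_MM3:
            raise ValueError("depth required for non-standard site sizes")
        volume_mm3 = STIMULATED_VOLUME_MM3[int(site_side_um)]
    else:
        if depth_um < 0:
            raise ValueError("arguments must be non-negative")
        volume_mm3 = (site_side_um ** 2 * depth_um) * 1e-9
    return volume_mm3 * density_per_mm3


def active_site_stats(zmap: ZScoreMap, cmap: ConnectivityMap) -> dict:
    """Fraction of active sites, their amplitudes and the ipsi/contra split."""
    if zmap.z.shape != cmap.amplitudes.shape:
        raise ValueError("z map and amplitude grid shapes differ")
    mask = zmap.active
    total = mask.size
    frac = mask.sum() / total
    amps = cmap.amplitudes[mask]
    col_ipsi = cmap.column_positions >= 0
    ipsi_mask = mask & col_ipsi[None, :]
    contra_mask = mask & ~col_ipsi[None, :]
    return {
        "fraction_active": float(frac),
        "active_amplitudes": amps,
        "n_active": int(mask.sum()),
        "n_sites": int(total),
        "fraction_active_ipsi": float(ipsi_mask.sum() / max(col_ipsi.sum() * cmap.n_rows, 1)),
        "fraction_active_contra": float(contra_mask.sum() / max((~col_ipsi).sum() * cmap.n_rows, 1)),
        "active_amplitudes_ipsi": cmap.amplitudes[ipsi_mask],
        "active_amplitudes_contra": cmap.amplitudes[contra_mask],
    }
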