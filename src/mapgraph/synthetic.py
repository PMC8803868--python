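"""Synthetic cohorts of connectivity maps, trials, and coupled behavior.

The generator emulates the statistical structure the analysis assumes:
rectangular photostimulation grids (6 rows × 20 µm sites at high resolution,
4 rows × 40 µm at low resolution, up to 1280 µm wide), patches of functional
sites surrounded by silent ones, right-skewed (lognormal) significant-site
amplitude distributions with condition-specific means (e.g. 72.3 ± 50 pA in
controls), zebrin geometries drawn from the printed band-width statistics,
and behavioral records coupled to each map's graph features through a
planted linear model with a group-interaction term,

    Y_i = β0 + Σ_j β_j G_ji + Σ_j γ_j T_i G_ji + ε_i,   T_i ∈ {+1, −1}.

Everything is driven by one :class:`CohortConfig` and a seed; identical
config + seed reproduces the cohort exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .zebrin import ZebrinGeometry, generate_zebrin_geometry
from .maps import ConnectivityMap, TrialSet, Z_THRESHOLD

#: the seven locomotor conditions of the high-resolution dataset
CONDITIONS = (
    "control",
    "short_training",
    "long_training",
    "early_sham",
    "early_cuff",
    "adapted_sham",
    "adapted_cuff",
)

#: per-condition map counts of the high-resolution dataset (105 maps total)
DEFAULT_COUNTS = {
    "control": 14,
    "short_training": 13,
    "long_training": 11,
    "early_sham": 11,
    "early_cuff": 25,
    "adapted_sham": 14,
    "adapted_cuff": 17,
}

#: per-condition mean ± SD of significant synaptic weights (pA)
DEFAULT_AMPLITUDE_STATS = {
    "control": (72.3, 50.0),
    "short_training": (89.8, 71.0),
    "long_training": (86.7, 48.3),
    "early_sham": (91.9, 60.0),
    "early_cuff": (78.7, 62.0),
    "adapted_sham": (116.2, 69.0),
    "adapted_cuff": (88.8, 59.0),
}

#: per-condition mean fraction of active (z ≥ 3) sites
DEFAULT_ACTIVE_FRACTIONS = {
    "control": 0.124,
    "short_training": 0.116,
    "long_training": 0.099,
    "early_sham": 0.142,
    "early_cuff": 0.165,
    "adapted_sham": 0.133,
    "adapted_cuff": 0.153,
}

#: default patch-centre prior: Gaussian mixture components (mean µm, SD µm).
#: The first component is the recurrent hotspot ~500 µm ipsilateral of the
#: midline (mid P2− ipsi); the others spread patches over both sides.
DEFAULT_PATCH_PRIOR = ((500.0, 120.0), (-350.0, 150.0), (120.0, 100.0))


@dataclass
class NoiseModel:
    """Synaptic-noise model: i.i.d. Normal per site on the magnitude scale.

    Defaults put the z = 3 significance threshold at ≈ 15 pA
    (mean + 3 SD = 4.5 + 3·3.5), the amplitude the threshold corresponds to
    in the recordings.
    """

    mean: float = 4.5
    sd: float = 3.5
    trial_sd: float = 8.0     # trial-to-trial spread of evoked amplitudes (pA)


@dataclass
class CohortConfig:
    """Everything needed to generate one synthetic cohort."""

    counts: dict = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    resolution: int = 20                     # µm site size, 20 or 40
    amplitude_stats: dict = field(default_factory=lambda: dict(DEFAULT_AMPLITUDE_STATS))
    active_fractions: dict = field(default_factory=lambda: dict(DEFAULT_ACTIVE_FRACTIONS))
    patch_prior: tuple = DEFAULT_PATCH_PRIOR
    noise: NoiseModel = field(default_factory=NoiseModel)
    map_width_um: float = 1280.0
    n_trials: int = 7
    glm_beta0: float = 10.0
    glm_beta: tuple = (4.0, -6.0, 5.0, -3.0)
    glm_gamma: tuple = (2.0, 0.0, -2.0, 1.0)
    behavior_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution not in (20, 40):
            raise ValueError("resolution must be 20 or 40 µm")
        if not (5 <= self.n_trials <= 10):
            raise ValueError("n_trials must be between 5 and 10")
        for c, n in self.counts.items():
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r}")
            if n < 1:
                raise ValueError("per-condition counts must be >= 1")

    @property
    def n_rows(self) -> int:
        # 96 sites / 320 µm field at 20 µm, 32 sites / 320 µm at 40 µm
        return 6 if self.resolution == 20 else 4

    @property
    def n_columns(self) -> int:
        return int(round(self.map_width_um / self.resolution))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["patch_prior"] = [list(c) for c in self.patch_prior]
        d["amplitude_stats"] = {k: list(v) for k, v in self.amplitude_stats.items()}
        d["glm_beta"] = list(self.glm_beta)
        d["glm_gamma"] = list(self.glm_gamma)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseModel(**d["noise"])
        if "patch_prior" in d:
            d["patch_prior"] = tuple(tuple(c) for c in d["patch_prior"])
        if "amplitude_stats" in d:
            d["amplitude_stats"] = {k: tuple(v) for k, v in d["amplitude_stats"].items()}
        for k in ("glm_beta", "glm_gamma"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class Cohort:
    """A self-consistent synthetic dataset: maps, trials, behavior, labels."""

    maps: list
    trials: list                    # TrialSet per map, or empty
    labels: list                    # condition per map
    behavior: list                  # dict of behavioral features per map
    features: np.ndarray            # planted per-map feature matrix
    group_codes: np.ndarray         # ±1 per map
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.maps)


def _lognormal_params(mean: float, sd: float, floor: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal whose mean above ``floor`` equals ``mean``.

    sigma is set from the untruncated coefficient of variation; mu is then
    solved so that the left-truncated mean matches the target, because the
    configured statistics describe significant (above-threshold) sites.
    """
    sigma = math.sqrt(math.log(1.0 + (sd / mean) ** 2))
    log_floor = math.log(floor)

    def truncated_mean(mu: float) -> float:
        alpha = (log_floor - mu) / sigma
        tail = norm.sf(alpha)
        if tail <= 0:
            return float("inf")
        return math.exp(mu + sigma ** 2 / 2) * norm.sf(alpha - sigma) / tail

    target = math.log(mean) - sigma ** 2 / 2
    lo, hi = target - 2.0, target + 1.0
    try:
        mu = brentq(lambda m: truncated_mean(m) - mean, lo, hi)
    except ValueError:
        mu = target
    return mu, sigma


def _draw_active_amplitudes(
    rng: np.random.Generator, n: int, mean: float, sd: float, floor: float
) -> np.ndarray:
    """Left-truncated lognormal draws with truncated mean = ``mean``."""
    mu, sigma = _lognormal_params(mean, sd, floor)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=max(2 * (n - filled), 16))
        draw = draw[draw >= floor]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def generate_map(
    condition: str,
    geometry: ZebrinGeometry,
    config: CohortConfig,
    seed: int | np.random.Generator,
) -> ConnectivityMap:
    """One synthetic connectivity map: noise background plus active patches.

    Patch centres are drawn from the configured Gaussian-mixture prior along
    the mediolateral axis (hotspot ~500 µm ipsilateral by default); elliptical
    patches are added until the target active fraction for the condition is
    reached, and active-site amplitudes are drawn from a left-truncated
    lognormal whose mean matches the condition's significant-weight mean.
    """
    if condition not in config.counts and condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if condition not in config.amplitude_stats:
        raise ValueError(f"no amplitude statistics for condition {condition!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows, cols = config.n_rows, config.n_columns
    site = config.resolution
    positions = (np.arange(cols) - cols / 2 + 0.5) * site
    nm = config.noise
    # silent-site mean evoked amplitude fluctuates at the SEM of the noise
    background = np.clip(
        rng.normal(nm.mean, nm.sd / math.sqrt(config.n_trials), size=(rows, cols)), 0.0, None
    )
    target_frac = config.active_fractions.get(condition, 0.13)
    target_sites = int(round(target_frac * rows * cols))
    mask = np.zeros((rows, cols), dtype=bool)
    comps = config.patch_prior
    guard = 0
    while mask.sum() < target_sites and guard < 50:
        guard += 1
        cx, csd = comps[int(rng.integers(0, len(comps)))]
        center_x = rng.normal(cx, csd)
        center_r = rng.uniform(0, rows - 1)
        half_w = rng.uniform(2.0, 4.5) * site       # mediolateral half-extent, µm
        half_h = rng.uniform(1.0, 2.2)              # rows
        dx = (positions - center_x) / half_w
        dr = (np.arange(rows) - center_r) / half_h
        patch = (dr[:, None] ** 2 + dx[None, :] ** 2) <= 1.0
        mask |= patch
    amplitudes = background.copy()
    n_active = int(mask.sum())
    if n_active:
        mean, sd = config.amplitude_stats[condition]
        floor = nm.mean + Z_THRESHOLD * nm.sd
        amplitudes[mask] = _draw_active_amplitudes(rng, n_active, mean, sd, floor)
    return ConnectivityMap(
        amplitudes=amplitudes,
        site_size=site,
        column_positions=positions,
        geometry=geometry,
        metadata={"condition": condition},
    )


def generate_trials(
    cmap: ConnectivityMap,
    n_trials: int,
    noise: NoiseModel,
    seed: int | np.random.Generator,
) -> TrialSet:
    """Repeated-trial evoked and noise draws around a map's site means."""
    if not (5 <= n_trials <= 10):
        raise ValueError("n_trials must be between 5 and 10")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    shape = (n_trials,) + cmap.amplitudes.shape
    evoked = rng.normal(cmap.amplitudes[None], noise.trial_sd, size=shape)
    noise_draws = rng.normal(noise.mean, noise.sd, size=shape)
    return TrialSet(evoked=evoked, noise=noise_draws)


def generate_behavior(
    features: np.ndarray,
    beta0: float,
    beta: Sequence[float],
    gamma: Sequence[float],
    group_codes: Sequence[int],
    noise_sd: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Behavioral targets from the planted interaction linear model.

    Y_i = β0 + Σ_j β_j G_ji + Σ_j γ_j T_i G_ji + ε_i with Gaussian ε.
    """
    g = np.asarray(features, dtype=float)
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    t = np.asarray(group_codes, dtype=float)
    if g.shape[0] != t.size:
        raise ValueError("features and group codes differ in length")
    if g.shape[1] != beta.size or g.shape[1] != gamma.size:
        raise ValueError("coefficient length does not match feature dimension")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    eps = rng.normal(0.0, noise_sd, size=t.size) if noise_sd > 0 else np.zeros(t.size)
    return beta0 + g @ beta + t * (g @ gamma) + eps


def _planted_features(cmap: ConnectivityMap, config: CohortConfig) -> np.ndarray:
    """Map summaries used as the planted behavioral predictors.

    Four cheap, deterministic map statistics (active fraction, mean
    amplitude, ipsilateral share of total weight, mediolateral amplitude
    spread) stand in for fitted graph features when planting the
    map→behavior coupling; the analysis pipeline later recovers the coupling
    from whichever features it assembles.
    """
    a = cmap.amplitudes
    thresh = config.noise.mean + Z_THRESHOLD * config.noise.sd
    active = a >= thresh
    frac = active.mean()
    mean_amp = a[active].mean() / 100.0 if active.any() else 0.0
    ipsi = cmap.column_positions >= 0
    total = a.sum()
    ipsi_share = a[:, ipsi].sum() / total if total > 0 else 0.5
    col_profile = a.max(axis=0)
    spread = float(np.std(cmap.normalized_positions[col_profile >= thresh])) / 100.0 \
        if (col_profile >= thresh).any() else 0.0
    return np.array([frac, mean_amp, ipsi_share, spread])


def generate_cohort(config: CohortConfig | None = None, with_trials: bool = True) -> Cohort:
    """A full cohort: per-condition maps, trials, planted behavior, labels."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    maps, trials, labels = [], [], []
    for condition in CONDITIONS:
        n = config.counts.get(condition, 0)
        for i in range(n):
            geom = generate_zebrin_geometry(rng)
            m = generate_map(condition, geom, config, rng)
            m.metadata.update({"map_id": f"{condition}_{i:02d}", "subject": f"m_{condition}_{i:02d}"})
            maps.append(m)
            labels.append(condition)
            if with_trials:
                trials.append(generate_trials(m, config.n_trials, config.noise, rng))
    feats = np.stack([_planted_features(m, config) for m in maps])
    group_codes = np.array([1 if ("cuff" in c or c == "long_training") else -1 for c in labels])
    targets = generate_behavior(
        feats, config.glm_beta0, config.glm_beta, config.glm_gamma,
        group_codes, config.behavior_noise_sd, rng,
    )
    behavior = [
        {"target": float(y), "condition": c, "map_id": m.metadata["map_id"]}
        for y, c, m in zip(targets, labels, maps)
    ]
    return Cohort(
        maps=maps,
        trials=trials,
        labels=labels,
        behavior=behavior,
        features=feats,
        group_codes=group_codes,
        config=config,
    )
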