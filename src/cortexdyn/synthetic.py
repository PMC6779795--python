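"""Synthetic cortical cohorts with known memory-dynamics ground truth.

Real cohorts of this kind (multi-location, two-laminar-compartment,
multi-week IEG imaging) are not publicly deposited, so every pipeline
stage is validated on generated cohorts whose generative structure is
known exactly.  The generator realizes the three qualitative dynamics
regimes the analysis is designed to separate:

``shared_recency``
    every location's activity is driven by the same recency-weighted
    kernel over the last few scans (the superficial-layer II/III
    phenotype: recent history dominates, identically everywhere);
``location_specific_lag``
    each location is driven by its own one or two dominant historical
    scans (the deep-layer V phenotype: information stored at different
    past time points in different places);
``independent``
    days are mutually independent noise (the no-signal null used to
    calibrate the shuffle control).

On top of the history term, each scan day adds an environment-specific
population pattern whose reactivation fidelity decays linearly with the
time since that environment was last experienced — the substrate for
the environment-repeat interval analysis.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_model import (
    AREA_TYPES,
    ActivityPanel,
    EnvironmentSchedule,
)

REGIMES = ("shared_recency", "location_specific_lag", "independent")

#: default recency kernel: exponentially decaying weight over scan lags 1-3
_RECENCY_KERNEL = {1: 0.665, 2: 0.245, 3: 0.090}

_AREA_CYCLE = sorted(AREA_TYPES)


def _stable_hash(*parts: object) -> int:
    """Deterministic 32-bit hash of a tuple of printable parts."""
    return zlib.crc32("|".join(str(p) for p in parts).encode())


@dataclass
class DynamicsSpec:
    """Generative regime of one laminar compartment.

    Parameters
    ----------
    regime
        One of ``shared_recency``, ``location_specific_lag``,
        ``independent``.
    lag_weights
        Scan-lag -> weight map.  For ``shared_recency`` one map shared
        by all locations (default: exponential decay over lags 1-3).
        For ``location_specific_lag`` either a per-location mapping
        ``{location_id: {lag: weight}}`` or None, in which case each
        location is assigned its own dominant lag deterministically
        (location i gets lag ``(i mod max_lag) + 1``).
    env_effect_scale
        Amplitude of the additive environment-specific population
        pattern (0 disables environment structure).
    env_decay_rate
        Per-day linear loss of reactivation fidelity of an
        environment's pattern since its last occurrence.
    noise_sd
        SD of the per-cell Gaussian innovation.
    link
        ``piecewise`` (default; thresholded-linear, so tree learners
        have structure a global linear fit underuses) or ``linear``.
    kink
        Knot of the piecewise link.
    max_lag
        Largest scan lag available for deterministic location-specific
        assignment.
    """

    regime: str
    lag_weights: Mapping[int, float] | Mapping[str, Mapping[int, float]] | None = None
    env_effect_scale: float = 0.5
    env_decay_rate: float = 0.0
    noise_sd: float = 0.3
    link: str = "piecewise"
    kink: float = 1.5
    max_lag: int = 6

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.env_effect_scale < 0 or self.env_decay_rate < 0:
            raise ValueError("environment parameters must be non-negative")
        if self.link not in ("piecewise", "linear"):
            raise ValueError(f"unknown link {self.link!r}")

    def realized_lag_weights(
        self, location_ids: Sequence[str], n_scans: int
    ) -> dict[str, dict[int, float]]:
        """Per-location lag kernels implied by this spec.

        Structural assignments depend only on the dynamics spec and location
        order, never on the noise seed, so cohorts drawn with different
        seeds share identical ground-truth structure.
        """
        if self.regime == "independent":
            return {loc: {} for loc in location_ids}
        if self.regime == "shared_recency":
            shared = dict(self.lag_weights) if self.lag_weights else dict(_RECENCY_KERNEL)
            if any(w < 0 for w in shared.values()):
                raise ValueError("lag weights must be non-negative")
            return {loc: dict(shared) for loc in location_ids}
        # location_specific_lag
        if self.lag_weights is not None:
            out = {}
            for loc in location_ids:
                if loc not in self.lag_weights:
                    raise ValueError(f"no lag weights given for location {loc}")
                out[loc] = dict(self.lag_weights[loc])  # type: ignore[index]
            return out
        max_lag = max(1, min(self.max_lag, n_scans - 2))
        return {
            loc: {(i % max_lag) + 1: 1.0} for i, loc in enumerate(location_ids)
        }


@dataclass
class PanelTruth:
    """Realized generative parameters of one (location, compartment)."""

    lag_weights: dict[int, float]
    env_patterns: dict[str, np.ndarray]
    env_effect_scale: float
    env_decay_rate: float
    regime: str


@dataclass
class GroundTruth:
    """Everything needed to recompute the expected predictive structure."""

    seed: int
    panels: dict[tuple[str, str], PanelTruth] = field(default_factory=dict)

    def dominant_lag(self, location_id: str, compartment: str) -> int:
        w = self.panels[(location_id, compartment)].lag_weights
        if not w:
            raise ValueError("independent regime has no dominant lag")
        return max(w, key=lambda k: w[k])


def _env_pattern(
    location_id: str, compartment: str, environment: str, n_neurons: int
) -> np.ndarray:
    """Environment-specific population pattern; a structural parameter,
    so it is derived from labels only (seed-independent)."""
    rng = np.random.default_rng(
        [_stable_hash(location_id), _stable_hash(compartment), _stable_hash(environment)]
    )
    return rng.normal(0.0, 1.0, n_neurons)


def _apply_link(x: np.ndarray, link: str, kink: float) -> np.ndarray:
    if link == "linear":
        return x
    # continuous thresholded-linear: identity above the knot, strongly
    # compressed below it
    return np.where(x >= kink, x, kink + 0.3 * (x - kink))


def generate_cohort(
    n_locations: int,
    n_neurons_per_panel: int,
    schedule: EnvironmentSchedule,
    spec_by_compartment: Mapping[str, DynamicsSpec],
    seed: int,
) -> tuple[list[ActivityPanel], GroundTruth]:
    """Simulate one mouse's panels under the given dynamics regimes.

    Activity on scan t is ``link(sum_d w_d * a[t-d])`` plus the current
    environment's pattern (scaled by ``env_effect_scale`` and attenuated
    by ``env_decay_rate`` x days since that environment last occurred)
    plus Gaussian noise, clipped at zero.  Lags that would reach before
    Day 0 are dropped (burn-in).  Bit-identical given the seed.
    """
    if n_locations < 2:
        raise ValueError("need at least 2 locations")
    if len(schedule.entries) < 6:
        raise ValueError("schedule must have at least 6 scan days")
    if n_neurons_per_panel < 200:
        raise ValueError("need at least 200 neurons per panel")

    location_ids = [f"L{i + 1}" for i in range(n_locations)]
    n_scans = len(schedule.entries)
    days = schedule.days
    envs = schedule.environments

    rng = np.random.default_rng(seed)
    truth = GroundTruth(seed=seed)
    panels: list[ActivityPanel] = []

    for comp, spec in spec_by_compartment.items():
        lag_maps = spec.realized_lag_weights(location_ids, n_scans)
        for li, loc in enumerate(location_ids):
            weights = lag_maps[loc]
            patterns = {
                env: _env_pattern(loc, comp, env, n_neurons_per_panel)
                for env in sorted(set(envs))
            }
            act = np.zeros((n_neurons_per_panel, n_scans))
            last_seen: dict[str, int] = {}
            for t in range(n_scans):
                if spec.regime == "independent" or t == 0 or not weights:
                    base = rng.gamma(2.0, 1.0, n_neurons_per_panel)
                else:
                    hist = np.zeros(n_neurons_per_panel)
                    for lag, w in weights.items():
                        if t - lag >= 0:
                            hist += w * act[:, t - lag]
                    base = _apply_link(hist, spec.link, spec.kink)
                env = envs[t]
                if spec.env_effect_scale > 0:
                    if env in last_seen:
                        gap = days[t] - days[last_seen[env]]
                        fidelity = max(0.0, 1.0 - spec.env_decay_rate * gap)
                    else:
                        fidelity = 1.0
                    base = base + spec.env_effect_scale * fidelity * patterns[env]
                last_seen[env] = t
                noise = rng.normal(0.0, spec.noise_sd, n_neurons_per_panel)
                act[:, t] = np.clip(base + noise, 0.0, None)

            panels.append(
                ActivityPanel(
                    mouse_id=schedule.mouse_id,
                    location_id=loc,
                    area_type=_AREA_CYCLE[li % len(_AREA_CYCLE)],
                    hemisphere="L" if li % 2 == 0 else "R",
                    compartment=comp,
                    neuron_ids=[f"{loc}_{comp}_n{k}" for k in range(n_neurons_per_panel)],
                    scan_days=days.copy(),
                    activity=act,
                )
            )
            truth.panels[(loc, comp)] = PanelTruth(
                lag_weights=dict(weights),
                env_patterns=patterns,
                env_effect_scale=spec.env_effect_scale,
                env_decay_rate=spec.env_decay_rate,
                regime=spec.regime,
            )
    return panels, truth


@dataclass
class MissingnessLog:
    """Audit record of injected detection gaps."""

    light_neurons: dict[str, list[int]]  # neuron id -> missing scan days (1-3 days)
    heavy_neurons: dict[str, list[int]]  # neuron id -> missing scan days (4+ days)


def inject_missingness(
    panel: ActivityPanel, frac_light: float, frac_heavy: float, seed: int
) -> tuple[ActivityPanel, MissingnessLog]:
    """Mark random neurons as undetected to exercise the QC policy.

    ``frac_light`` of neurons lose 1-3 random scan days (they survive
    QC, gaps imputed); ``frac_heavy`` lose 4 or more (QC removes them).
    Returns the masked panel and a log of exactly what was injected.
    """
    if not (0 <= frac_light < 1 and 0 <= frac_heavy < 1):
        raise ValueError("fractions must be in [0, 1)")
    if frac_light + frac_heavy >= 1:
        raise ValueError("frac_light + frac_heavy must be < 1")

    rng = np.random.default_rng(seed)
    n, n_days = panel.n_neurons, panel.n_days
    n_light = int(round(frac_light * n))
    n_heavy = int(round(frac_heavy * n))
    chosen = rng.choice(n, size=n_light + n_heavy, replace=False)
    light_rows, heavy_rows = chosen[:n_light], chosen[n_light:]

    mask = panel.missing_mask.copy()
    log = MissingnessLog(light_neurons={}, heavy_neurons={})
    for row in light_rows:
        k = int(rng.integers(1, 4))
        cols = rng.choice(n_days, size=k, replace=False)
        mask[row, cols] = True
        log.light_neurons[panel.neuron_ids[row]] = sorted(
            int(panel.scan_days[c]) for c in cols
        )
    hi = min(n_days - 1, 7)
    if n_heavy and hi < 4:
        raise ValueError("panel too short to inject >3-day missingness")
    for row in heavy_rows:
        k = int(rng.integers(4, hi + 1))
        cols = rng.choice(n_days, size=k, replace=False)
        mask[row, cols] = True
        log.heavy_neurons[panel.neuron_ids[row]] = sorted(
            int(panel.scan_days[c]) for c in cols
        )

    import dataclasses

    return dataclasses.replace(panel, missing_mask=mask), log


def demo_schedule(
    mouse_id: str = "Syn", n_scans: int = 12, spacing: int | None = None
) -> EnvironmentSchedule:
    """A compact environment schedule with training/retrieval structure
    and environment repeats, loosely shaped like the real cohorts'
    protocols (home-cage days interleaved with context exposures).

    With the default non-uniform spacing, inter-scan gaps grow over the
    protocol so that environment repeats span several distinct
    intervals (needed by the repeat-interval regression); passing
    ``spacing`` forces a uniform gap instead.
    """
    cycle = ["H", "CA", "TA", "RA", "H", "RA", "EE", "RA", "CB", "EE", "RA", "H",
             "EE", "RB", "RA", "TU", "EE", "RA", "CB", "H"]
    if n_scans > len(cycle):
        reps = -(-n_scans // len(cycle))
        cycle = (cycle * reps)[:n_scans]
    envs = cycle[:n_scans]
    if spacing is not None:
        days = [spacing * k for k in range(n_scans)]
    else:
        days, d = [0], 0
        for k in range(1, n_scans):
            d += min(2 + (k - 1) // 2, 7)
            days.append(d)
    return EnvironmentSchedule.from_environments(mouse_id, days, envs)
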