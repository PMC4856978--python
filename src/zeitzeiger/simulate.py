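"""Synthetic oscillatory datasets with known ground truth.

Emulates the statistical structure of multi-organ circadian expression
after batch correction: a small set of periodic "signal" features with
varying amplitude and phase, many non-periodic noise features, Gaussian
residual noise, grouped batches standing in for organs (with small residual
per-group baseline offsets), and optional missing entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import TimeStampedMatrix


@dataclass
class SimulationConfig:
    """Generative settings for one synthetic dataset.

    Signal feature j in group g at time t takes the value
    ``baseline_{g,j} + A_j * waveform(t - phi_j) + N(0, noise_sd^2)``;
    noise features omit the oscillatory term. Baselines are drawn
    N(0, group_shift_sd^2) per (group, feature).
    """

    n_signal_features: int = 20
    n_noise_features: int = 480
    n_timepoints_per_cycle: int = 12
    n_replicates: int = 2
    n_groups: int = 3
    amplitudes: np.ndarray | float = 1.0  # scalar, or vector of length n_signal
    phases: np.ndarray | str = "uniform"  # vector in [0,1), or "uniform"
    noise_sd: float = 0.5
    group_shift_sd: float = 0.0
    waveform: str = "cosine"  # "cosine" | "spline-perturbed"
    group_amplitude_scaling_sd: float = 0.0  # optional multiplicative stress test
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_signal_features", "n_noise_features", "n_timepoints_per_cycle",
                     "n_replicates", "n_groups"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.group_shift_sd < 0:
            raise ValueError("group_shift_sd must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.waveform not in ("cosine", "spline-perturbed"):
            raise ValueError("waveform must be 'cosine' or 'spline-perturbed'")


@dataclass
class SyntheticDataset:
    data: TimeStampedMatrix
    groups: np.ndarray
    truth: dict = field(default_factory=dict)


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Draw one dataset from the configured generative model (fully seeded)."""
    rng = np.random.default_rng(config.seed)
    n_sig, n_noise = config.n_signal_features, config.n_noise_features
    p = n_sig + n_noise
    tp = np.arange(config.n_timepoints_per_cycle) / config.n_timepoints_per_cycle
    times_per_group = np.tile(tp, config.n_replicates)
    n_per_group = times_per_group.size
    n = n_per_group * config.n_groups

    amps = np.broadcast_to(
        np.asarray(config.amplitudes, dtype=float), (n_sig,)
    ).copy()
    if isinstance(config.phases, str):
        if config.phases != "uniform":
            raise ValueError("phases must be a vector or 'uniform'")
        phases = rng.uniform(0.0, 1.0, size=n_sig)
    else:
        phases = np.mod(np.asarray(config.phases, dtype=float), 1.0)
        if phases.shape != (n_sig,):
            raise ValueError("phases vector must have length n_signal_features")

    # second-harmonic perturbation so non-sinusoidal waveforms are testable
    if config.waveform == "spline-perturbed":
        h2a = rng.normal(0.0, 0.15, size=n_sig)
        h2b = rng.normal(0.0, 0.15, size=n_sig)
    else:
        h2a = h2b = np.zeros(n_sig)

    baselines = rng.normal(0.0, config.group_shift_sd, size=(config.n_groups, p))
    amp_scale = (
        np.exp(rng.normal(0.0, config.group_amplitude_scaling_sd, size=(config.n_groups, n_sig)))
        if config.group_amplitude_scaling_sd > 0
        else np.ones((config.n_groups, n_sig))
    )

    values = np.empty((n, p))
    times = np.empty(n)
    groups = np.empty(n, dtype=object)
    for g in range(config.n_groups):
        sl = slice(g * n_per_group, (g + 1) * n_per_group)
        t = times_per_group
        ph = 2.0 * np.pi * (t[:, None] - phases[None, :])
        wave = np.cos(ph) + h2a[None, :] * np.cos(2 * ph) + h2b[None, :] * np.sin(2 * ph)
        signal = (amps[None, :] * amp_scale[g][None, :]) * wave
        block = np.concatenate(
            [signal, np.zeros((n_per_group, n_noise))], axis=1
        )
        values[sl] = baselines[g][None, :] + block + rng.normal(
            0.0, config.noise_sd, size=(n_per_group, p)
        )
        times[sl] = t
        groups[sl] = f"group_{g}"

    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values[mask] = np.nan

    feature_ids = [f"signal_{j:03d}" for j in range(n_sig)] + [
        f"noise_{j:03d}" for j in range(n_noise)
    ]
    observation_ids = [
        f"group_{g}_rep{r}_t{i:02d}"
        for g in range(config.n_groups)
        for r in range(config.n_replicates)
        for i in range(config.n_timepoints_per_cycle)
    ]
    data = TimeStampedMatrix(
        values=values, times=times, feature_ids=feature_ids, observation_ids=observation_ids
    )
    truth = {
        "signal_features": feature_ids[:n_sig],
        "amplitude": dict(zip(feature_ids[:n_sig], amps.tolist())),
        "phase": dict(zip(feature_ids[:n_sig], phases.tolist())),
        "noise_sd": config.noise_sd,
    }
    return SyntheticDataset(data=data, groups=np.asarray(groups, dtype=str), truth=truth)


def default_benchmark(seed: int = 0) -> SyntheticDataset:
    """The canonical benchmark: 20 signal features with phases spread over
    the cycle and amplitudes 1-3, 480 noise features, 12 time-points x 2
    replicates x 3 groups (72 observations x 500 features), noise SD 0.5,
    small residual group baselines."""
    config = SimulationConfig(
        n_signal_features=20,
        n_noise_features=480,
        n_timepoints_per_cycle=12,
        n_replicates=2,
        n_groups=3,
        amplitudes=np.linspace(1.0, 3.0, 20),
        phases=np.arange(20) / 20,
        noise_sd=0.5,
        group_shift_sd=0.1,
        waveform="cosine",
        missing_rate=0.0,
        seed=seed,
    )
    return simulate(config)
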