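"""Seeded synthetic scanpath generator with planted group structure.

Archetypes emulate the ambient/focal contrast of viewing behavior: a focal
viewer makes long fixations and short saccades inside a compact region,
an ambient viewer short fixations and long exploratory saccades. Fixation
durations and saccade amplitudes are lognormal (positive, right-skewed,
as in real gaze recordings); fixation positions follow a per-axis
skew-normal spatial model, optionally widened by a heavy-tail scale
mixture to raise kurtosis.

Positions and amplitudes are reconciled by a target-pursuit walk: every
saccade aims at a fresh independent draw from the spatial model and
travels min(drawn amplitude, distance to target). With generous amplitudes
fixations land on iid spatial samples, so the spatial moments are
controlled; with short amplitudes the walk creeps, producing the short
saccades of focal viewing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import Dataset, FixationRecord, Scanpath


@dataclass(frozen=True)
class ArchetypeConfig:
    """Generator parameters for one planted participant group."""

    label: str
    n_participants: int = 10
    n_stimuli: int = 5
    fixation_count_mean: float = 30.0
    fixation_count_sd: float = 5.0
    # lognormal parameters of fixation duration (ms)
    duration_mu: float = np.log(250.0)
    duration_sigma: float = 0.3
    # lognormal parameters of saccade amplitude (px)
    amplitude_mu: float = np.log(150.0)
    amplitude_sigma: float = 0.4
    center: tuple[float, float] = (960.0, 540.0)
    spread: tuple[float, float] = (250.0, 180.0)
    skew: float = 0.0  # skew-normal shape parameter, per axis
    heavy_tail: bool = False  # scale mixture that raises kurtosis
    saccade_gap_mean: float = 40.0  # ms between fixation end and next start

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_stimuli < 1:
            raise ValueError("participant and stimulus counts must be >= 1")
        if self.fixation_count_sd < 0 or min(self.spread) <= 0:
            raise ValueError("spreads must be positive, count sd non-negative")


def _spatial_sample(rng: np.random.Generator, cfg: ArchetypeConfig, n: int) -> np.ndarray:
    """n iid fixation targets from the archetype's spatial model."""
    out = np.empty((n, 2))
    for axis in range(2):
        z = stats.skewnorm.rvs(a=cfg.skew, size=n, random_state=rng)
        if cfg.heavy_tail:
            inflate = rng.random(n) < 0.15
            z = np.where(inflate, z * 3.0, z)
        out[:, axis] = cfg.center[axis] + cfg.spread[axis] * z
    return out


def _scanpath(rng: np.random.Generator, cfg: ArchetypeConfig, pid: str, sid: str) -> Scanpath:
    n = max(2, int(round(rng.normal(cfg.fixation_count_mean, cfg.fixation_count_sd))))
    targets = _spatial_sample(rng, cfg, n)
    amplitudes = rng.lognormal(cfg.amplitude_mu, cfg.amplitude_sigma, size=n - 1)
    durations = rng.lognormal(cfg.duration_mu, cfg.duration_sigma, size=n)
    gaps = rng.exponential(cfg.saccade_gap_mean, size=n - 1) + 1.0

    pos = np.empty((n, 2))
    pos[0] = targets[0]
    for i in range(n - 1):
        delta = targets[i + 1] - pos[i]
        dist = float(np.hypot(*delta))
        if dist <= amplitudes[i] or dist == 0.0:
            pos[i + 1] = targets[i + 1]
        else:
            pos[i + 1] = pos[i] + delta * (amplitudes[i] / dist)

    fixes = []
    t = 0.0
    for i in range(n):
        fixes.append(FixationRecord(pid, sid, float(pos[i, 0]), float(pos[i, 1]), t, float(durations[i])))
        if i < n - 1:
            t += durations[i] + gaps[i]
    sp = Scanpath(pid, sid, fixes)
    sp.validate()
    return sp


def generate_dataset(
    configs: list[ArchetypeConfig], seed: int
) -> tuple[Dataset, dict[str, str]]:
    """Generate a dataset from archetype configs; returns (data, true labels).

    Deterministic for a fixed seed. Every participant gets an independent
    substream spawned from the global seed, so removing one participant
    never changes another's scanpaths.
    """
    if not configs:
        raise ValueError("need at least one archetype config")
    labels = {c.label for c in configs}
    if len(labels) != len(configs):
        raise ValueError("archetype labels must be unique")
    root = np.random.SeedSequence(seed)
    truth: dict[str, str] = {}
    ds = Dataset()
    streams = root.spawn(sum(c.n_participants for c in configs))
    idx = 0
    for cfg in sorted(configs, key=lambda c: c.label):
        for j in range(cfg.n_participants):
            pid = f"{cfg.label}{j:02d}"
            truth[pid] = cfg.label
            rng = np.random.default_rng(streams[idx])
            idx += 1
            for s in range(cfg.n_stimuli):
                ds.add(_scanpath(rng, cfg, pid, f"S{s:02d}"))
    return ds, truth


#: Archetypes of the default recovery benchmark: a focal group (long
#: fixations, short saccades, compact spatial footprint) versus an ambient
#: group (short fixations, long saccades, wide footprint).
FOCAL = ArchetypeConfig(
    label="focal",
    duration_mu=np.log(400.0),
    duration_sigma=0.25,
    amplitude_mu=np.log(40.0),
    amplitude_sigma=0.35,
    spread=(120.0, 90.0),
)
AMBIENT = ArchetypeConfig(
    label="ambient",
    duration_mu=np.log(150.0),
    duration_sigma=0.25,
    amplitude_mu=np.log(350.0),
    amplitude_sigma=0.35,
    spread=(350.0, 260.0),
)


def default_recovery_benchmark(seed: int) -> tuple[Dataset, dict[str, str]]:
    """2 archetypes × 10 participants × 5 stimuli with well-separated groups."""
    return generate_dataset([FOCAL, AMBIENT], seed)
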