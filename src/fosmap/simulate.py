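"""Synthetic cohorts with planted activation effects and factor covariance.

The generator emulates the study design the analysis assumes: four
groups (home cage, ISO, saline, KET; n = 6/6/8/6), log-normal per-region
baseline densities, multiplicative treatment effects on chosen region
sets, and a subject-level latent-factor model that induces ground-truth
correlation modules and, optionally, a cross-module connector hub.
Counts are Poisson around density x area, so zero counts (and the zero
control SDs they can cause downstream) arise naturally.

Model per subject s and region r:

    log density = mu_r + log f(group, r) + sum_k lambda_k(r) F_k(s) + eps,
    eps ~ Normal(0, sigma_r^2),  F ~ Normal(0, C),
    count ~ Poisson(density * area)

where C has unit diagonal and off-diagonal ``factor_corr``.  A hub
region loads on several factors at once; note that with independent
factors its correlation with members of any single module is bounded by
1/sqrt(K), which is why connector-hub scenarios use ``factor_corr > 0``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import validate_counts

__all__ = [
    "Effect",
    "Factor",
    "HubSpec",
    "EEGConfig",
    "SynthConfig",
    "GroundTruth",
    "generate_counts",
    "generate_eeg",
]

DEFAULT_GROUP_SIZES = {"homecage": 6, "ISO": 6, "saline": 8, "KET": 6}


@dataclass(frozen=True)
class Effect:
    """Multiplicative treatment effect: densities of *regions* in *group*
    are scaled by *fold* (>= 0; fold 0 silences the region)."""

    group: str
    regions: tuple[str, ...]
    fold: float

    def __post_init__(self) -> None:
        if self.fold < 0:
            raise ValueError("fold must be >= 0")


@dataclass(frozen=True)
class Factor:
    """Latent factor: every region in *regions* gains ``loading * F``
    on the log scale, F ~ Normal(0, sd^2) per subject."""

    regions: tuple[str, ...]
    loading: float
    sd: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.loading):
            raise ValueError("loading must be finite")
        if self.sd <= 0:
            raise ValueError("factor sd must be > 0")


@dataclass(frozen=True)
class HubSpec:
    """A region loading on several factors (default: all of them)."""

    region: str
    factors: tuple[int, ...] | None = None
    loading: float | None = None


@dataclass(frozen=True)
class EEGConfig:
    """Synthetic EEG/EMG: a sum of sinusoids plus white noise."""

    sampling_rate: float = 200.0
    duration: float = 60.0
    components: tuple[tuple[float, float], ...] = ((2.0, 1.0),)  # (center Hz, amplitude)
    noise_sd: float = 0.0
    emg_sd: float = 1.0


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    regions: int | Sequence[str] = 53
    baseline_log_mean: float | Mapping[str, float] | None = None  # None -> U(3, 5) per region
    baseline_log_sd: float = 0.3
    area: float = 1.0
    effects: tuple[Effect, ...] = ()
    factors: tuple[Factor, ...] = ()
    factor_corr: float = 0.0
    hub: HubSpec | None = None
    eeg: EEGConfig = field(default_factory=EEGConfig)

    def region_names(self) -> list[str]:
        if isinstance(self.regions, int):
            if self.regions < 1:
                raise ValueError("need at least one region")
            width = len(str(self.regions))
            return [f"R{i + 1:0{width}d}" for i in range(self.regions)]
        return list(self.regions)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SynthConfig":
        d = dict(d)
        if "effects" in d:
            d["effects"] = tuple(
                Effect(e["group"], tuple(e["regions"]), float(e["fold"])) for e in d["effects"]
            )
        if "factors" in d:
            d["factors"] = tuple(
                Factor(tuple(f["regions"]), float(f["loading"]), float(f.get("sd", 1.0)))
                for f in d["factors"]
            )
        if d.get("hub") is not None:
            h = d["hub"]
            d["hub"] = HubSpec(
                h["region"],
                tuple(h["factors"]) if h.get("factors") is not None else None,
                h.get("loading"),
            )
        if "eeg" in d and d["eeg"] is not None and not isinstance(d["eeg"], EEGConfig):
            e = dict(d["eeg"])
            if "components" in e:
                e["components"] = tuple((float(f), float(a)) for f, a in e["components"])
            d["eeg"] = EEGConfig(**e)
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: per-group activated region sets, the module
    partition implied by the factor sets, and the hub region."""

    activated: Mapping[str, frozenset[str]]
    modules: Mapping[str, int]
    hub: str | None


def _subject_ids(group_sizes: Mapping[str, int]) -> list[tuple[str, str]]:
    out = []
    for group, n in group_sizes.items():
        if n < 1:
            raise ValueError(f"group {group!r} is empty")
        out.extend((f"{group}_{i + 1:02d}", group) for i in range(n))
    return out


def generate_counts(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one cohort. The seed fully determines the output."""
    rng = np.random.default_rng(config.seed)
    regions = config.region_names()
    region_index = {r: i for i, r in enumerate(regions)}
    subjects = _subject_ids(config.group_sizes)
    n_subj, n_reg = len(subjects), len(regions)

    for eff in config.effects:
        unknown = set(eff.regions) - set(regions)
        if unknown:
            raise ValueError(f"effect regions not in panel: {sorted(unknown)}")
    for fac in config.factors:
        unknown = set(fac.regions) - set(regions)
        if unknown:
            raise ValueError(f"factor regions not in panel: {sorted(unknown)}")
    if config.hub is not None and config.hub.region not in region_index:
        raise ValueError(f"hub region {config.hub.region!r} not in panel")

    if config.baseline_log_mean is None:
        mu = rng.uniform(3.0, 5.0, size=n_reg)
    elif isinstance(config.baseline_log_mean, Mapping):
        mu = np.array([float(config.baseline_log_mean[r]) for r in regions])
    else:
        mu = np.full(n_reg, float(config.baseline_log_mean))

    logd = np.tile(mu, (n_subj, 1))

    with np.errstate(divide="ignore"):
        for eff in config.effects:
            log_fold = np.log(eff.fold)
            rows = [i for i, (_, g) in enumerate(subjects) if g == eff.group]
            cols = [region_index[r] for r in eff.regions]
            logd[np.ix_(rows, cols)] += log_fold

    n_fac = len(config.factors)
    if n_fac:
        C = np.full((n_fac, n_fac), config.factor_corr)
        np.fill_diagonal(C, 1.0)
        F = rng.multivariate_normal(np.zeros(n_fac), C, size=n_subj, method="cholesky")
        for k, fac in enumerate(config.factors):
            cols = [region_index[r] for r in fac.regions]
            logd[:, cols] += fac.loading * fac.sd * F[:, [k]]
        if config.hub is not None:
            which = config.hub.factors if config.hub.factors is not None else tuple(range(n_fac))
            col = region_index[config.hub.region]
            for k in which:
                fac = config.factors[k]
                loading = config.hub.loading if config.hub.loading is not None else fac.loading
                logd[:, col] += loading * fac.sd * F[:, k]

    logd += rng.normal(0.0, config.baseline_log_sd, size=(n_subj, n_reg))
    counts = rng.poisson(np.exp(logd) * config.area)

    sids = np.repeat([s for s, _ in subjects], n_reg)
    groups = np.repeat([g for _, g in subjects], n_reg)
    df = pd.DataFrame(
        {
            "subject_id": sids,
            "group": groups,
            "region_acronym": np.tile(regions, n_subj),
            "cell_count": counts.ravel(),
            "area": config.area,
        }
    )
    df = validate_counts(df)

    activated = {}
    for eff in config.effects:
        if eff.fold != 1.0:
            cur = activated.setdefault(eff.group, set())
            cur.update(eff.regions)
    modules: dict[str, int] = {}
    for k, fac in enumerate(config.factors):
        for r in fac.regions:
            if r in modules:  # region in several factor sets belongs to none
                modules.pop(r)
            else:
                modules[r] = k
    truth = GroundTruth(
        activated={g: frozenset(s) for g, s in activated.items()},
        modules=modules,
        hub=config.hub.region if config.hub is not None else None,
    )
    return df, truth


def generate_eeg(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize (eeg, emg) series per ``config.eeg``; seeded."""
    e = config.eeg
    fs = e.sampling_rate
    if e.components:
        top = max(f for f, _ in e.components)
        if fs <= 2 * top:
            raise ValueError(f"sampling rate {fs} Hz violates Nyquist for {top} Hz component")
    rng = np.random.default_rng([config.seed, 0x5EE6])
    n = int(round(e.duration * fs))
    t = np.arange(n) / fs
    eeg = np.zeros(n)
    for freq, amp in e.components:
        eeg += amp * np.sin(2 * np.pi * freq * t)
    if e.noise_sd > 0:
        eeg += rng.normal(0.0, e.noise_sd, size=n)
    emg = rng.normal(0.0, e.emg_sd, size=n)
    return eeg, emg
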