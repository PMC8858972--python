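"""Synthetic cohorts of IgG-subclass glycan profiles.

The generator emulates the statistical structure the downstream analysis
assumes: a three-group liver-fibrosis cohort (no fibrosis / early-moderate /
advanced-cirrhosis) of compositional glycan profiles measured on five
antibody capture channels (IgG, IgG1-IgG4).  Per sample and channel,
log-abundances are drawn as

    log a = baseline + group shift (planted features only) + N(0, sigma)

and closed to percentiles summing to 100 per channel (a logistic-normal
composition).  The logistic-normal is used rather than a Dirichlet so that
per-feature mean shifts and between-feature correlations can be controlled
independently — the feature-elimination stage needs correlated feature
pairs, which "decoy twin" features provide by sharing a planted feature's
noise deviations.

Planted features carry a timing class mirroring how fibrosis-associated
glycans behave: ``early`` features shift at the group 1 -> 2 transition and
then plateau, ``late`` only at 2 -> 3, and ``both`` at both transitions.
The default planted panel is the seven-glycan fibrosis signature (A2G2F and
A2BG0F on IgG, A2G1F and A2G2S1 on IgG1, A2G1F and A2G0F on IgG2, A2BG1F on
IgG3), with agalactosylated/bisected glycans rising and galactosylated or
sialylated glycans falling as fibrosis advances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path


import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable, GROUP_STAGES
from .glycans import GlycanPanel, build_panel
from .spectra import SpotSpectrum

__all__ = [
    "PlantedFeature",
    "DecoyTwin",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_spot_spectra",
    "default_config",
    "DEFAULT_CHANNEL_GLYCANS",
    "DEFAULT_BASELINE_PERCENTILES",
]

#: Glycans simulated on every capture channel (>=10 per channel).
DEFAULT_CHANNEL_GLYCANS: tuple[str, ...] = (
    "A2BG0",
    "A2G0",
    "A2G0F",
    "A2G1",
    "A2G1F",
    "A2G2",
    "A2G2F",
    "A2G2S1",
    "A2BG0F",
    "A2BG1F",
    "A2BG2F",
)

#: Baseline mean profile (percent of channel total), loosely shaped like a
#: healthy IgG Fc glycan profile: dominated by core-fucosylated bi-antennary
#: glycans with 0-2 galactoses, minor bisected and sialylated species.
DEFAULT_BASELINE_PERCENTILES: dict[str, float] = {
    "A2BG0": 1.0,
    "A2G0": 3.0,
    "A2G0F": 20.0,
    "A2G1": 4.0,
    "A2G1F": 33.0,
    "A2G2": 2.0,
    "A2G2F": 15.0,
    "A2G2S1": 8.0,
    "A2BG0F": 4.0,
    "A2BG1F": 4.0,
    "A2BG2F": 2.0,
}

TIMING_CLASSES = ("early", "late", "both")


@dataclass(frozen=True)
class PlantedFeature:
    """A glycan feature given a group-dependent mean shift.

    ``direction`` is +1 (rises with fibrosis) or -1 (falls); ``effect`` is
    the log-abundance shift per affected transition.  The timing class sets
    which transitions shift: ``early`` -> groups 2 and 3 shifted by one
    effect unit; ``late`` -> group 3 only; ``both`` -> group 2 by one unit,
    group 3 by two.
    """

    channel: str
    glycan: str
    timing: str
    direction: int
    effect: float = 1.0

    def __post_init__(self) -> None:
        if self.timing not in TIMING_CLASSES:
            raise ValueError(f"unknown timing class {self.timing!r}")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")

    @property
    def label(self) -> str:
        return f"{self.channel}.{self.glycan}"

    def group_shifts(self) -> np.ndarray:
        """Log-scale mean shift for groups (1, 2, 3)."""
        d = self.direction * self.effect
        if self.timing == "early":
            return np.array([0.0, d, d])
        if self.timing == "late":
            return np.array([0.0, 0.0, d])
        return np.array([0.0, d, 2 * d])


@dataclass(frozen=True)
class DecoyTwin:
    """A feature generated as a noisy near-duplicate of a planted partner.

    The decoy shares the partner's per-sample noise deviation (plus its own
    noise of scale ``extra_sd``) and an attenuated fraction
    (``shift_fraction``) of the partner's group shift: strong enough to pass
    the univariate screen, weaker than the partner — so the pair-elimination
    path sees a highly dependent pair whose less informative member is the
    decoy.
    """

    channel: str
    glycan: str
    partner_channel: str
    partner_glycan: str
    extra_sd: float = 0.25
    shift_fraction: float = 0.6

    @property
    def label(self) -> str:
        return f"{self.channel}.{self.glycan}"

    @property
    def partner_label(self) -> str:
        return f"{self.partner_channel}.{self.partner_glycan}"


def _default_planted(effect: float) -> tuple[PlantedFeature, ...]:
    return (
        PlantedFeature("IgG", "A2G2F", "early", -1, effect),
        PlantedFeature("IgG", "A2BG0F", "both", +1, effect),
        PlantedFeature("IgG1", "A2G1F", "early", -1, effect),
        PlantedFeature("IgG1", "A2G2S1", "early", -1, effect),
        PlantedFeature("IgG2", "A2G1F", "early", -1, effect),
        PlantedFeature("IgG2", "A2G0F", "early", +1, effect),
        PlantedFeature("IgG3", "A2BG1F", "late", -1, effect),
    )


_DEFAULT_DECOYS = (
    DecoyTwin("IgG", "A2BG2F", "IgG", "A2BG0F"),
    DecoyTwin("IgG1", "A2G2", "IgG1", "A2G1F"),
)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic three-group cohort."""

    group_sizes: tuple[int, int, int] = (41, 28, 43)
    channels: tuple[str, ...] = ("IgG", "IgG1", "IgG2", "IgG3", "IgG4")
    channel_glycans: tuple[str, ...] = DEFAULT_CHANNEL_GLYCANS
    baseline_percentiles: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_PERCENTILES)
    )
    planted: tuple[PlantedFeature, ...] | None = None  # None -> default panel
    decoys: tuple[DecoyTwin, ...] = _DEFAULT_DECOYS
    effect: float = 1.0
    noise_sd: float = 0.5
    pixels: int = 50
    snr: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("each group needs at least 2 samples")
        if any(v <= 0 for v in self.baseline_percentiles.values()):
            raise ValueError("baseline percentiles must be positive")
        missing = set(self.channel_glycans) - set(self.baseline_percentiles)
        if missing:
            raise ValueError(f"no baseline for glycans {sorted(missing)}")
        if self.planted is None:
            self.planted = _default_planted(self.effect)
        self.planted = tuple(self.planted)
        self.decoys = tuple(self.decoys)
        labels = {f"{ch}.{g}" for ch in self.channels for g in self.channel_glycans}
        for p in self.planted:
            if p.label not in labels:
                raise ValueError(f"planted feature {p.label} not in channel panels")
        for d in self.decoys:
            if d.label not in labels or d.partner_label not in labels:
                raise ValueError(f"decoy {d.label} or its partner not in panels")
            if d.label == d.partner_label:
                raise ValueError("decoy cannot twin itself")

    @property
    def feature_labels(self) -> list[str]:
        return [f"{ch}.{g}" for ch in self.channels for g in self.channel_glycans]

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["planted"] = [asdict(p) for p in self.planted]
        doc["decoys"] = [asdict(d) for d in self.decoys]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if "planted" in doc:
            doc["planted"] = tuple(PlantedFeature(**p) for p in doc["planted"])
        if "decoys" in doc:
            doc["decoys"] = tuple(DecoyTwin(**d) for d in doc["decoys"])
        for key in ("group_sizes", "channels", "channel_glycans"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


def default_config(**overrides) -> SyntheticConfig:
    """The default study-scale configuration (groups of 41/28/43, 55
    features over five channels, the seven-glycan planted panel plus two
    decoy twins)."""
    return SyntheticConfig(**overrides)


def all_oxford_names(max_antennae: int = 4) -> list[str]:
    """Every composition the Oxford grammar admits up to ``max_antennae``
    antennae (A >= G >= S, optional B and core F), in sorted order."""
    names = []
    for a in range(1, max_antennae + 1):
        for g in range(0, a + 1):
            for s in range(0, g + 1):
                for b in ("", "B"):
                    for f in ("", "F"):
                        names.append(
                            f"A{a}{b}G{g}" + (f"S{s}" if s else "") + f
                        )
    return sorted(set(names))


def null_config(
    n_features: int = 200, group_sizes: tuple[int, int, int] = (41, 28, 43), **overrides
) -> SyntheticConfig:
    """A global-null cohort configuration: ``n_features`` glycan features
    spread evenly over the five channels, equal baselines, no planted
    effects and no decoys — for type-I-error calibration of the screen and
    null behavior of downstream classifiers."""
    channels = ("IgG", "IgG1", "IgG2", "IgG3", "IgG4")
    per_channel = -(-n_features // len(channels))
    names = all_oxford_names()
    if per_channel > len(names):
        raise ValueError(f"cannot build {per_channel} glycans per channel")
    glycans = tuple(names[:per_channel])
    return SyntheticConfig(
        group_sizes=group_sizes,
        channels=channels,
        channel_glycans=glycans,
        baseline_percentiles={g: 1.0 for g in glycans},
        planted=(),
        decoys=(),
        **overrides,
    )


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside every generated cohort."""

    planted: tuple[PlantedFeature, ...]
    decoys: tuple[DecoyTwin, ...]
    group_mean_percentiles: pd.DataFrame  # groups 1..3 x feature labels
    seed: int

    @property
    def planted_labels(self) -> list[str]:
        return [p.label for p in self.planted]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "planted": [asdict(p) for p in self.planted],
            "decoys": [asdict(d) for d in self.decoys],
            "group_mean_percentiles": {
                str(g): row.to_dict()
                for g, row in self.group_mean_percentiles.iterrows()
            },
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(doc, indent=2))


def _assign_stages(group: int, n: int) -> list[str]:
    """Distribute METAVIR stages within a group in the cohort's proportions
    (group 1: mostly healthy plus a few stage 0; group 2: stages 1-2;
    group 3: a few stage 3, mostly stage 4)."""
    weights = {1: (38, 3), 2: (10, 18), 3: (6, 37)}[group]
    stages = GROUP_STAGES[group]
    n_first = int(round(n * weights[0] / sum(weights)))
    return [stages[0]] * n_first + [stages[1]] * (n - n_first)


def _expected_percentiles(cfg: SyntheticConfig) -> pd.DataFrame:
    """Noise-free per-group mean percentiles from the closed mean logs."""
    base_log = {g: np.log(cfg.baseline_percentiles[g]) for g in cfg.channel_glycans}
    shifts = {p.label: p.group_shifts() for p in cfg.planted}
    for d in cfg.decoys:
        shifts[d.label] = d.shift_fraction * shifts.get(d.partner_label, np.zeros(3))
    rows = {}
    for gi, group in enumerate((1, 2, 3)):
        row = {}
        for ch in cfg.channels:
            logs = np.array(
                [
                    base_log[g] + shifts.get(f"{ch}.{g}", np.zeros(3))[gi]
                    for g in cfg.channel_glycans
                ]
            )
            props = np.exp(logs)
            props = 100.0 * props / props.sum()
            for g, v in zip(cfg.channel_glycans, props):
                row[f"{ch}.{g}"] = v
        rows[group] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def generate_cohort(
    cfg: SyntheticConfig, seed: int | None = None
) -> tuple[CohortTable, SyntheticTruth]:
    """Draw one synthetic cohort; deterministic given the seed.

    Returns the cohort table (per-channel percentiles closed to 100) and
    the ground truth used to generate it.
    """
    used_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    labels = cfg.feature_labels
    decoy_partners = {d.label: d for d in cfg.decoys}
    shifts = {p.label: p.group_shifts() for p in cfg.planted}
    base_log = {
        f"{ch}.{g}": np.log(cfg.baseline_percentiles[g])
        for ch in cfg.channels
        for g in cfg.channel_glycans
    }

    records, groups, stages, sample_ids = [], [], [], []
    counter = 0
    for gi, (group, size) in enumerate(zip((1, 2, 3), cfg.group_sizes)):
        stage_list = _assign_stages(group, size)
        for k in range(size):
            counter += 1
            sample_ids.append(f"S{counter:03d}")
            groups.append(group)
            stages.append(stage_list[k])
            noise = {lab: rng.normal(0.0, cfg.noise_sd) for lab in labels}
            logs = {}
            for lab in labels:
                if lab in decoy_partners:
                    continue
                logs[lab] = (
                    base_log[lab]
                    + shifts.get(lab, np.zeros(3))[gi]
                    + noise[lab]
                )
            for lab, decoy in decoy_partners.items():
                # share the partner's noise deviation and a damped group shift
                partner_shift = shifts.get(decoy.partner_label, np.zeros(3))[gi]
                logs[lab] = (
                    base_log[lab]
                    + decoy.shift_fraction * partner_shift
                    + noise[decoy.partner_label]
                    + rng.normal(0.0, decoy.extra_sd)
                )
            row = {}
            for ch in cfg.channels:
                ch_labels = [f"{ch}.{g}" for g in cfg.channel_glycans]
                props = np.exp([logs[lab] for lab in ch_labels])
                props = 100.0 * props / props.sum()
                row.update(dict(zip(ch_labels, props)))
            records.append(row)

    df = pd.DataFrame(records, index=pd.Index(sample_ids, name="sample_id"))
    df.insert(0, "group", groups)
    df.insert(1, "stage", stages)
    table = CohortTable(df)
    truth = SyntheticTruth(
        planted=cfg.planted,
        decoys=cfg.decoys,
        group_mean_percentiles=_expected_percentiles(cfg),
        seed=used_seed,
    )
    return table, truth


def cohort_panel(cfg: SyntheticConfig) -> GlycanPanel:
    """Theoretical-peak panel matching the synthetic channel glycan sets."""
    return build_panel({ch: cfg.channel_glycans for ch in cfg.channels})


def generate_spot_spectra(
    profile: pd.Series,
    panel: GlycanPanel,
    pixels: int = 50,
    snr: float = 20.0,
    seed: int = 0,
    peak_sigma_ppm: float = 3.0,
    points_per_peak: int = 9,
    noise_points: int = 200,
    spot_id: str = "spot",
) -> list[SpotSpectrum]:
    """Generate centroided pixel spectra for one capture spot.

    Each panel glycan becomes a cluster of ``points_per_peak`` centroids
    with Gaussian-shaped intensities around its theoretical m/z (width
    ``peak_sigma_ppm``), total height proportional to the profile value
    times a lognormal per-pixel factor and a per-peak lognormal noise of
    scale ``1/snr``.  A sparse uniform baseline of low-intensity noise
    points is added.  ``snr=inf`` gives a noiseless spectrum.

    ``profile`` must be indexed by the panel's labels (any nonnegative
    scale; only ratios matter downstream).
    """
    if pixels < 1:
        raise ValueError("pixels must be >= 1")
    if not snr > 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    entries = list(panel.entries)
    channels = {e.channel for e in entries}
    if len(channels) != 1:
        raise ValueError("spot spectra require a single-channel panel")
    (channel,) = channels
    heights = np.array([float(profile[e.label]) for e in entries])
    if np.any(heights < 0):
        raise ValueError("profile values must be nonnegative")
    offsets = np.linspace(-2.0, 2.0, points_per_peak)  # in sigma units
    shape = np.exp(-0.5 * offsets**2)
    shape /= shape.sum()
    mz_lo = min(e.theoretical_mz for e in entries) - 50.0
    mz_hi = max(e.theoretical_mz for e in entries) + 50.0
    noiseless = not np.isfinite(snr)

    out = []
    for _ in range(pixels):
        pixel_factor = 1.0 if noiseless else rng.lognormal(0.0, 0.2)
        mzs, intens = [], []
        for e, h in zip(entries, heights):
            if h == 0:
                continue
            eps = 0.0 if noiseless else rng.normal(0.0, 1.0 / snr)
            total = h * pixel_factor * np.exp(eps)
            sigma = e.theoretical_mz * peak_sigma_ppm * 1e-6
            mzs.append(e.theoretical_mz + offsets * sigma)
            intens.append(total * shape)
        if not noiseless and noise_points:
            peak_scale = heights.max() if heights.any() else 1.0
            mzs.append(rng.uniform(mz_lo, mz_hi, size=noise_points))
            intens.append(rng.uniform(0.0, peak_scale / snr, size=noise_points))
        mz = np.concatenate(mzs) if mzs else np.array([])
        inten = np.concatenate(intens) if intens else np.array([])
        order = np.argsort(mz)
        mz, inten = mz[order], inten[order]
        # merge coincident centroids so the m/z axis is strictly increasing
        uniq, inverse = np.unique(mz, return_inverse=True)
        merged = np.zeros_like(uniq)
        np.add.at(merged, inverse, inten)
        out.append(SpotSpectrum(mz=uniq, intensity=merged, spot_id=spot_id, channel=channel))
    return out
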