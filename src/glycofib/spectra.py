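"""Spot-array spectrum quantification.

Converts per-pixel MALDI imaging spectra of antibody capture spots into
per-sample glycan feature vectors: each pixel spectrum is normalized to its
total ion current, the area under each panel glycan's monoisotopic peak is
summed within a ppm window around the theoretical m/z, pixel areas are
averaged per spot, and each glycan is finally expressed as a relative
percentile of the spot's total glycan profile.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .glycans import GlycanPanel

logger = logging.getLogger(__name__)

__all__ = [
    "SpotSpectrum",
    "tic_normalize",
    "extract_peak_area",
    "quantify_spot",
    "relative_percentile",
    "build_cohort_table",
    "check_window_collisions",
    "read_spot_json",
    "write_spot_json",
    "read_imzml_spots",
    "DEFAULT_TOL_PPM",
]

#: Default peak-matching half-window (ppm), consistent with FT-ICR-grade
#: mass accuracy.
DEFAULT_TOL_PPM = 10.0


@dataclass(frozen=True)
class SpotSpectrum:
    """One pixel's centroided spectrum, tagged with its capture spot."""

    mz: np.ndarray
    intensity: np.ndarray
    spot_id: str
    channel: str

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and np.any(np.diff(mz) <= 0):
            raise ValueError("mz array must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be nonnegative")


def tic_normalize(spec: SpotSpectrum) -> SpotSpectrum:
    """Scale intensities so the total ion current (their sum) equals 1."""
    total = float(spec.intensity.sum())
    if total <= 0:
        raise ValueError(f"empty spectrum (all-zero TIC) for spot {spec.spot_id}")
    return replace(spec, intensity=spec.intensity / total)


def extract_peak_area(spec: SpotSpectrum, mz0: float, tol_ppm: float = DEFAULT_TOL_PPM) -> float:
    """Area under the monoisotopic peak: summed centroid intensity within
    ``mz0 * (1 +/- tol_ppm * 1e-6)``.  Returns 0 when no point falls inside."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    tol = mz0 * tol_ppm * 1e-6
    lo = np.searchsorted(spec.mz, mz0 - tol, side="left")
    hi = np.searchsorted(spec.mz, mz0 + tol, side="right")
    if lo == hi:
        logger.debug("no points within %.1f ppm of m/z %.4f in spot %s",
                     tol_ppm, mz0, spec.spot_id)
        return 0.0
    return float(spec.intensity[lo:hi].sum())


def check_window_collisions(panel: GlycanPanel, tol_ppm: float = DEFAULT_TOL_PPM) -> list[tuple[str, str]]:
    """Report same-channel panel entry pairs whose ppm windows overlap
    (shared points are counted for both entries).  Entries on different
    capture channels never collide: each spot is quantified against its own
    channel's sub-panel."""
    collisions = []
    by_channel: dict[str | None, list] = {}
    for e in panel.entries:
        by_channel.setdefault(e.channel, []).append(e)
    for entries in by_channel.values():
        entries = sorted(entries, key=lambda e: e.theoretical_mz)
        for a, b in zip(entries, entries[1:]):
            if b.theoretical_mz * (1 - tol_ppm * 1e-6) < a.theoretical_mz * (1 + tol_ppm * 1e-6):
                collisions.append((a.label, b.label))
                warnings.warn(
                    f"panel windows overlap at {tol_ppm} ppm: {a.label} "
                    f"({a.theoretical_mz:.4f}) and {b.label} ({b.theoretical_mz:.4f})",
                    stacklevel=2,
                )
    return collisions


def quantify_spot(
    pixels: Sequence[SpotSpectrum],
    panel: GlycanPanel,
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> pd.Series:
    """Mean per-pixel peak area for each panel glycan of one capture spot.

    Each pixel is TIC-normalized before extraction, then areas are averaged
    across pixels, mirroring image normalization followed by per-region mean
    peak quantification.
    """
    if not pixels:
        raise ValueError("empty pixel list")
    spot_ids = {p.spot_id for p in pixels}
    channels = {p.channel for p in pixels}
    if len(spot_ids) > 1 or len(channels) > 1:
        raise ValueError(
            f"pixels span multiple spots/channels: {spot_ids}, {channels}"
        )
    (channel,) = channels
    sub = panel.for_channel(channel)
    if not len(sub):
        raise ValueError(f"panel has no entries for channel {channel}")
    areas = np.zeros(len(sub))
    for pix in pixels:
        norm = tic_normalize(pix)
        areas += [extract_peak_area(norm, e.theoretical_mz, tol_ppm) for e in sub]
    return pd.Series(areas / len(pixels), index=sub.labels, name=next(iter(spot_ids)))


def relative_percentile(raw: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Express raw glycan quantities as percent of their total (0-100).

    An all-zero vector is returned unchanged with a warning (a no-signal
    spot); negative entries are rejected.
    """
    values = np.asarray(raw, dtype=float)
    if np.any(values < 0):
        raise ValueError("negative entry in raw glycan vector")
    total = values.sum()
    if total == 0:
        warnings.warn("all-zero glycan vector: no signal in spot", stacklevel=2)
        out = values.copy()
    else:
        out = values * 100.0 / total
    if isinstance(raw, pd.Series):
        return pd.Series(out, index=raw.index, name=raw.name)
    return out


def build_cohort_table(
    samples: Mapping[str, Mapping[str, Sequence[SpotSpectrum]]],
    panel: GlycanPanel,
    tol_ppm: float = DEFAULT_TOL_PPM,
    groups: Mapping[str, int] | None = None,
    stages: Mapping[str, str] | None = None,
) -> CohortTable:
    """Quantify every sample's capture spots into one cohort feature table.

    Parameters
    ----------
    samples
        ``{sample_id: {channel: [pixel spectra...]}}``.  A channel missing
        for some sample yields missing values in that channel's columns.
    groups, stages
        Optional per-sample fibrosis group (1/2/3) and METAVIR stage labels;
        absent entries are stored as missing.
    """
    ids = list(samples)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample IDs")
    check_window_collisions(panel, tol_ppm)
    rows = {}
    for sample_id, by_channel in samples.items():
        parts = []
        for channel, pixels in by_channel.items():
            raw = quantify_spot(list(pixels), panel, tol_ppm)
            parts.append(relative_percentile(raw))
        rows[sample_id] = pd.concat(parts) if parts else pd.Series(dtype=float)
    df = pd.DataFrame.from_dict(rows, orient="index")
    missing = df.isna().any(axis=1)
    if missing.any():
        logger.info("samples with missing channels: %s", list(df.index[missing]))
    df.insert(0, "group", pd.Series(groups) if groups else pd.NA)
    df.insert(1, "stage", pd.Series(stages, dtype=object) if stages else pd.NA)
    df.index.name = "sample_id"
    return CohortTable(df)


# -- simple spot dialect: one JSON document per capture spot ----------------

def write_spot_json(path: str | Path, pixels: Sequence[SpotSpectrum]) -> None:
    """Write one spot's pixel spectra as JSON:
    ``{"spot_id", "channel", "pixels": [{"mz": [...], "intensity": [...]}]}``."""
    if not pixels:
        raise ValueError("empty pixel list")
    doc = {
        "spot_id": pixels[0].spot_id,
        "channel": pixels[0].channel,
        "pixels": [
            {"mz": p.mz.tolist(), "intensity": p.intensity.tolist()} for p in pixels
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_spot_json(path: str | Path) -> list[SpotSpectrum]:
    doc = json.loads(Path(path).read_text())
    return [
        SpotSpectrum(
            mz=np.asarray(p["mz"], dtype=float),
            intensity=np.asarray(p["intensity"], dtype=float),
            spot_id=doc["spot_id"],
            channel=doc["channel"],
        )
        for p in doc["pixels"]
    ]


def read_imzml_spots(
    imzml_path: str | Path,
    region_map_path: str | Path,
) -> dict[str, dict[str, list[SpotSpectrum]]]:
    """Read an imzML image and assign pixels to capture spots via a region
    map TSV with columns ``x, y, spot_id, channel, sample_id``.

    Returns the ``{sample_id: {channel: [pixels...]}}`` structure consumed
    by `build_cohort_table`.  Pixels absent from the region map are ignored.
    """
    from pyimzml.ImzMLParser import ImzMLParser  # deferred: optional extra

    regions = pd.read_csv(region_map_path, sep="\t", dtype={"spot_id": str, "sample_id": str})
    required = {"x", "y", "spot_id", "channel", "sample_id"}
    if missing := required - set(regions.columns):
        raise ValueError(f"region map missing columns {sorted(missing)}")
    lookup = {
        (int(r.x), int(r.y)): (r.sample_id, r.channel, r.spot_id)
        for r in regions.itertuples(index=False)
    }
    out: dict[str, dict[str, list[SpotSpectrum]]] = {}
    parser = ImzMLParser(str(imzml_path))
    for idx, (x, y, _z) in enumerate(parser.coordinates):
        key = lookup.get((int(x), int(y)))
        if key is None:
            continue
        sample_id, channel, spot_id = key
        mz, intensity = parser.getspectrum(idx)
        order = np.argsort(mz)
        out.setdefault(sample_id, {}).setdefault(channel, []).append(
            SpotSpectrum(
                mz=np.asarray(mz)[order],
                intensity=np.asarray(intensity)[order],
                spot_id=spot_id,
                channel=channel,
            )
        )
    return out
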