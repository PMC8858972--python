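"""Oxford-nomenclature N-glycan compositions and theoretical masses.

IgG Fc N-glycans share a constant trimannosyl-chitobiose core: two core
GlcNAc residues plus three mannoses.  Oxford notation builds names on top of
that core:

* ``Ax`` — x antennary GlcNAc residues on the core,
* ``B``  — a bisecting GlcNAc on the core beta-mannose,
* ``Gx`` — x galactoses capping antennae,
* ``Sx`` — x sialic acids (NeuAc) on galactoses,
* ``F``  — a core fucose on the innermost GlcNAc.

So ``A2BG1F`` is a bi-antennary glycan with a bisecting GlcNAc, one
galactose and a core fucose.  This module parses such names (optionally
prefixed with an IgG capture-channel tag, e.g. ``G4.A2BG0F`` for IgG4) into
monosaccharide compositions, computes monoisotopic neutral masses by residue
summation, and derives singly charged positive-mode adduct m/z values for
building peak panels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GlycanComposition",
    "ChannelFeature",
    "GlycanPanel",
    "PanelEntry",
    "GlycanParseError",
    "parse_oxford",
    "format_oxford",
    "parse_channel_feature",
    "format_channel_feature",
    "neutral_mass",
    "adduct_mz",
    "build_panel",
    "default_adduct",
    "RESIDUE_MASSES",
    "ADDUCT_SHIFTS",
    "CHANNELS",
]

# Monoisotopic residue masses (Da): monosaccharide minus one water, i.e. the
# mass added per glycosidic bond.  One water is restored for the free
# reducing end of a released glycan.
RESIDUE_MASSES = {
    "hexnac": 203.079373,  # HexNAc (GlcNAc), C8H13NO5
    "hex": 162.052824,     # hexose (Man/Gal), C6H10O5
    "fuc": 146.057909,     # deoxyhexose (Fuc), C6H10O4
    "neuac": 291.095417,   # N-acetylneuraminic acid, C11H17NO8
}
WATER = 18.010565

# Singly charged positive-mode adduct shifts (cation mass minus electron
# bookkeeping, as conventionally tabulated).
ADDUCT_SHIFTS = {
    "M+H": 1.007276,
    "M+Na": 22.989218,
    "M+2Na-H": 44.971160,
}

#: Capture channels of the antibody spot array, keyed by label prefix.
CHANNEL_PREFIXES = {
    "G": "IgG",
    "G1": "IgG1",
    "G2": "IgG2",
    "G3": "IgG3",
    "G4": "IgG4",
}
CHANNELS = tuple(CHANNEL_PREFIXES.values())
_CHANNEL_TO_PREFIX = {v: k for k, v in CHANNEL_PREFIXES.items()}


class GlycanParseError(ValueError):
    """Raised when a glycan or feature label cannot be parsed."""


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide counts of an N-glycan over the trimannosyl core.

    ``hexnac`` includes the two core GlcNAcs, the antennary GlcNAcs and the
    bisecting GlcNAc when present; ``hexose`` includes the three core
    mannoses plus antennal galactoses.
    """

    hexnac: int
    hexose: int
    fuc: int
    neuac: int
    bisecting: bool = False
    antennae: int = 0

    def __post_init__(self) -> None:
        for name in ("hexnac", "hexose", "fuc", "neuac", "antennae"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name} count")
        if self.hexnac != 2 + self.antennae + int(self.bisecting):
            raise ValueError(
                "hexnac count must equal 2 core + antennae + bisecting "
                f"(got hexnac={self.hexnac}, antennae={self.antennae}, "
                f"bisecting={self.bisecting})"
            )
        if self.hexose < 3:
            raise ValueError("hexose count below the 3 core mannoses")
        if not (self.antennae >= self.galactose >= self.neuac):
            raise ValueError(
                "require antennae >= galactoses >= sialic acids "
                f"(A{self.antennae} G{self.galactose} S{self.neuac})"
            )

    @property
    def galactose(self) -> int:
        """Galactose count: hexoses beyond the three core mannoses."""
        return self.hexose - 3


_OXFORD_RE = re.compile(
    r"^A(?P<ant>\d)(?P<bis>B)?G(?P<gal>\d)"
    r"(?:(?P<f_pre>F)?(?:S(?P<sia>\d))?(?P<f_post>F)?)$"
)


def parse_oxford(name: str) -> GlycanComposition:
    """Parse an Oxford-notation glycan name into a composition.

    The grammar is ``A<d>[B]G<d>[S<d>][F]``; the core-fucose ``F`` is
    accepted either before or after the sialic-acid block.

    >>> parse_oxford("A2BG0F")
    GlycanComposition(hexnac=5, hexose=3, fuc=1, neuac=0, bisecting=True, antennae=2)
    """
    token = name.strip()
    m = _OXFORD_RE.match(token)
    if m is None:
        raise GlycanParseError(f"malformed Oxford glycan name: {name!r}")
    if m.group("f_pre") and m.group("f_post"):
        raise GlycanParseError(f"duplicated fucose token 'F' in {name!r}")
    antennae = int(m.group("ant"))
    gal = int(m.group("gal"))
    sia = int(m.group("sia") or 0)
    bisecting = m.group("bis") is not None
    fuc = 1 if (m.group("f_pre") or m.group("f_post")) else 0
    if gal > antennae:
        raise GlycanParseError(
            f"{name!r}: galactose count G{gal} exceeds antenna count A{antennae}"
        )
    if sia > gal:
        raise GlycanParseError(
            f"{name!r}: sialic acid count S{sia} exceeds galactose count G{gal}"
        )
    return GlycanComposition(
        hexnac=2 + antennae + int(bisecting),
        hexose=3 + gal,
        fuc=fuc,
        neuac=sia,
        bisecting=bisecting,
        antennae=antennae,
    )


def format_oxford(comp: GlycanComposition) -> str:
    """Canonical Oxford name; ``S`` omitted when zero, ``F`` always last."""
    out = f"A{comp.antennae}"
    if comp.bisecting:
        out += "B"
    out += f"G{comp.galactose}"
    if comp.neuac:
        out += f"S{comp.neuac}"
    if comp.fuc:
        out += "F"
    return out


@dataclass(frozen=True)
class ChannelFeature:
    """A glycan feature tied to one capture-antibody channel."""

    channel: str
    glycan: str

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise GlycanParseError(f"unknown capture channel {self.channel!r}")
        parse_oxford(self.glycan)  # validates

    @property
    def label(self) -> str:
        return f"{self.channel}.{self.glycan}"


def parse_channel_feature(label: str) -> ChannelFeature:
    """Parse a channel-prefixed label such as ``G4.A2BG0F`` or ``IgG1.A2G1F``.

    Short prefixes map ``G -> IgG``, ``G1 -> IgG1``, ... ``G4 -> IgG4``;
    full ``IgG*`` prefixes are accepted as-is.  Whitespace after the dot is
    tolerated.
    """
    if "." not in label:
        raise GlycanParseError(f"feature label {label!r} lacks a '.' separator")
    prefix, _, rest = label.partition(".")
    prefix = prefix.strip()
    if prefix in CHANNEL_PREFIXES:
        channel = CHANNEL_PREFIXES[prefix]
    elif prefix in CHANNELS:
        channel = prefix
    else:
        raise GlycanParseError(f"unknown capture channel prefix {prefix!r} in {label!r}")
    glycan = rest.strip()
    try:
        comp = parse_oxford(glycan)
    except GlycanParseError as exc:
        raise GlycanParseError(f"invalid glycan part of {label!r}: {exc}") from exc
    return ChannelFeature(channel=channel, glycan=format_oxford(comp))


def format_channel_feature(feat: ChannelFeature, short: bool = False) -> str:
    prefix = _CHANNEL_TO_PREFIX[feat.channel] if short else feat.channel
    return f"{prefix}.{feat.glycan}"


def neutral_mass(comp: GlycanComposition) -> float:
    """Monoisotopic neutral mass (Da): residue summation plus one water."""
    return (
        comp.hexnac * RESIDUE_MASSES["hexnac"]
        + comp.hexose * RESIDUE_MASSES["hex"]
        + comp.fuc * RESIDUE_MASSES["fuc"]
        + comp.neuac * RESIDUE_MASSES["neuac"]
        + WATER
    )


def adduct_mz(mass: float, adduct: str) -> float:
    """m/z of a singly charged adduct of a neutral mass."""
    if mass <= 0:
        raise ValueError("neutral mass must be positive")
    try:
        return mass + ADDUCT_SHIFTS[adduct]
    except KeyError:
        raise ValueError(
            f"unknown adduct {adduct!r}; expected one of {sorted(ADDUCT_SHIFTS)}"
        ) from None


def default_adduct(comp: GlycanComposition) -> str:
    """Default positive-mode MALDI adduct: sodiated; sialylated glycans as
    the disodiated [M+2Na-H]+ salt."""
    return "M+2Na-H" if comp.neuac > 0 else "M+Na"


@dataclass(frozen=True)
class PanelEntry:
    """One theoretical peak of a quantification panel."""

    label: str
    channel: str | None
    glycan: str
    composition: GlycanComposition
    neutral_mass: float
    adduct: str
    theoretical_mz: float


@dataclass
class GlycanPanel:
    """An ordered set of theoretical glycan peaks, unique per
    (channel, glycan, adduct)."""

    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            if e.theoretical_mz <= 0:
                raise ValueError(f"non-positive theoretical m/z for {e.label}")
            key = (e.channel, e.glycan, e.adduct)
            if key in seen:
                raise ValueError(f"duplicate panel entry {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def for_channel(self, channel: str) -> "GlycanPanel":
        """Sub-panel of entries assigned to one capture channel (entries
        without a channel apply to every channel)."""
        return GlycanPanel(
            [e for e in self.entries if e.channel in (None, channel)]
        )

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    @property
    def mz_values(self) -> list[float]:
        return [e.theoretical_mz for e in self.entries]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "label": [e.label for e in self.entries],
                "channel": [e.channel or "" for e in self.entries],
                "glycan": [e.glycan for e in self.entries],
                "adduct": [e.adduct for e in self.entries],
                "theoretical_mz": [e.theoretical_mz for e in self.entries],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, mz_tol: float = 5e-4) -> "GlycanPanel":
        """Load a panel TSV, re-deriving each m/z from the glycan name and
        adduct and refusing entries whose stated m/z disagrees."""
        df = pd.read_csv(path, sep="\t", dtype={"channel": str}, keep_default_na=False)
        required = {"label", "channel", "glycan", "adduct", "theoretical_mz"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"panel file {path} missing columns {sorted(missing)}")
        entries = []
        for row in df.itertuples(index=False):
            comp = parse_oxford(row.glycan)
            channel = row.channel or None
            if channel is not None and channel not in CHANNELS:
                raise GlycanParseError(f"unknown channel {channel!r} in panel file")
            mass = neutral_mass(comp)
            mz = adduct_mz(mass, row.adduct)
            if abs(mz - float(row.theoretical_mz)) > mz_tol:
                raise ValueError(
                    f"panel entry {row.label}: stated m/z {row.theoretical_mz} "
                    f"disagrees with computed {mz:.6f}"
                )
            entries.append(
                PanelEntry(
                    label=row.label,
                    channel=channel,
                    glycan=format_oxford(comp),
                    composition=comp,
                    neutral_mass=mass,
                    adduct=row.adduct,
                    theoretical_mz=mz,
                )
            )
        return cls(entries)


def build_panel(
    glycans: Sequence[str] | dict[str, Iterable[str]],
    adducts: dict[str, str] | None = None,
) -> GlycanPanel:
    """Construct a panel from glycan names.

    Parameters
    ----------
    glycans
        Either a flat sequence of Oxford names (channel-free panel) or a
        mapping ``{channel: [names...]}``.
    adducts
        Optional per-glycan adduct override; otherwise `default_adduct`.
    """
    adducts = adducts or {}
    if isinstance(glycans, dict):
        items = [(ch, g) for ch, names in glycans.items() for g in names]
    else:
        items = [(None, g) for g in glycans]
    entries = []
    for channel, name in items:
        comp = parse_oxford(name)
        canonical = format_oxford(comp)
        adduct = adducts.get(canonical, adducts.get(name, default_adduct(comp)))
        mass = neutral_mass(comp)
        label = f"{channel}.{canonical}" if channel else canonical
        entries.append(
            PanelEntry(
                label=label,
                channel=channel,
                glycan=canonical,
                composition=comp,
                neutral_mass=mass,
                adduct=adduct,
                theoretical_mz=adduct_mz(mass, adduct),
            )
        )
    return GlycanPanel(entries)
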