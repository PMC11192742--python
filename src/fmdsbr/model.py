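"""Core domain types for multiplexed DSB-repair reporter cytometry.

The assay transfects two plasmid cocktails in parallel: a *damaged* cocktail
whose fluorescent reporters only express after the cell repairs a defined
double-strand break (one reporter per pathway: NHEJ, HR, MMEJ), and an
*undamaged* cocktail of the matching wild-type plasmids. Both cocktails carry
the same intact transfection-control plasmid (AmCyan by default) and inert
carrier DNA. Per-sample fluorescence is read on a small panel of detector
channels, one primary channel per fluorophore.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Repair pathways and structural roles a cocktail plasmid can play.
PATHWAYS = ("NHEJ", "HR", "MMEJ")
ROLES = PATHWAYS + ("TRANSFECTION_CONTROL", "CARRIER")

#: Cocktail designations an event table can carry.
COCKTAIL_KINDS = ("damaged", "undamaged", "negative", "none")


class PanelValidationError(ValueError):
    """A panel/cocktail configuration violates a structural invariant."""


@dataclass(frozen=True)
class ChannelDef:
    """One detector channel: name, excitation laser (nm), emission bandpass."""

    name: str
    excitation_nm: float
    filter: str


@dataclass(frozen=True)
class ReporterDef:
    """One plasmid in a cocktail.

    ``pathway`` is the scored repair pathway for reporter plasmids, or the
    structural role TRANSFECTION_CONTROL / CARRIER. Carrier DNA bears no
    fluorophore. ``damaged`` marks plasmids whose expression requires repair.
    """

    reporter_name: str
    pathway: str
    mass_ng: float
    fluorophore: str | None = None
    channel: str | None = None
    damaged: bool = False

    def __post_init__(self) -> None:
        if self.pathway not in ROLES:
            raise PanelValidationError(
                f"unknown pathway/role {self.pathway!r} for {self.reporter_name!r}"
            )
        if not (self.mass_ng > 0 and math.isfinite(self.mass_ng)):
            raise PanelValidationError(
                f"mass_ng must be positive and finite, got {self.mass_ng!r}"
            )
        if self.pathway == "CARRIER":
            if self.fluorophore is not None:
                raise PanelValidationError("carrier DNA must not carry a fluorophore")
        else:
            if self.fluorophore is None or self.channel is None:
                raise PanelValidationError(
                    f"{self.reporter_name!r}: non-carrier plasmids need a "
                    "fluorophore and a detector channel"
                )


@dataclass(frozen=True)
class PanelSpec:
    """Detector panel plus the damaged and undamaged cocktail definitions."""

    channels: tuple[ChannelDef, ...]
    damaged_cocktail: tuple[ReporterDef, ...]
    undamaged_cocktail: tuple[ReporterDef, ...]
    control_fluorophore: str

    def __post_init__(self) -> None:
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise PanelValidationError(f"duplicate channel names in panel: {names}")
        fl2ch: dict[str, str] = {}
        for cocktail in (self.damaged_cocktail, self.undamaged_cocktail):
            n_ctrl = sum(r.pathway == "TRANSFECTION_CONTROL" for r in cocktail)
            if n_ctrl != 1:
                raise PanelValidationError(
                    f"cocktail must contain exactly one TRANSFECTION_CONTROL "
                    f"plasmid, found {n_ctrl}"
                )
            for r in cocktail:
                if r.fluorophore is None:
                    continue
                if r.channel not in names:
                    raise PanelValidationError(
                        f"{r.reporter_name!r} references unknown channel {r.channel!r}"
                    )
                prev = fl2ch.setdefault(r.fluorophore, r.channel)
                if prev != r.channel:
                    raise PanelValidationError(
                        f"fluorophore {r.fluorophore!r} mapped to two channels "
                        f"({prev!r}, {r.channel!r})"
                    )
        if self.control_fluorophore not in fl2ch:
            raise PanelValidationError(
                f"control fluorophore {self.control_fluorophore!r} missing from cocktails"
            )
        dam = {r.fluorophore for r in self.damaged_cocktail if r.pathway in PATHWAYS}
        und = {r.fluorophore for r in self.undamaged_cocktail if r.pathway in PATHWAYS}
        if dam != und:
            raise PanelValidationError(
                f"damaged and undamaged cocktails score different fluorophores: "
                f"{sorted(dam)} vs {sorted(und)}"
            )

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def fluorophore_channels(self) -> dict[str, str]:
        """Fluorophore -> primary detector channel, over both cocktails."""
        out: dict[str, str] = {}
        for cocktail in (self.damaged_cocktail, self.undamaged_cocktail):
            for r in cocktail:
                if r.fluorophore is not None:
                    out[r.fluorophore] = r.channel  # type: ignore[assignment]
        return out

    @property
    def scored_pathways(self) -> list[str]:
        """Pathways with a damaged reporter in the damaged cocktail."""
        return [r.pathway for r in self.damaged_cocktail if r.pathway in PATHWAYS]

    def pathway_fluorophore(self, pathway: str, cocktail: str = "damaged") -> str:
        recs = self.damaged_cocktail if cocktail == "damaged" else self.undamaged_cocktail
        for r in recs:
            if r.pathway == pathway and r.fluorophore is not None:
                return r.fluorophore
        raise KeyError(f"no fluorophore for pathway {pathway!r} in {cocktail} cocktail")

    def control_channel(self) -> str:
        return self.fluorophore_channels[self.control_fluorophore]


@dataclass
class EventTable:
    """Per-cell fluorescence intensities on named detector channels.

    Rows are events (cells), columns are detector channels, in acquisition
    units on the linear scale. Negative values only arise after compensation.
    """

    data: pd.DataFrame
    sample_id: str = ""
    cocktail: str = "none"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if len(self.data.columns) == 0:
            raise ValueError("event table needs at least one channel column")
        vals = self.data.to_numpy(dtype=float, copy=False)
        if vals.size and not np.isfinite(vals).all():
            raise ValueError(f"non-finite intensities in sample {self.sample_id!r}")
        if not (
            self.cocktail in COCKTAIL_KINDS or self.cocktail.startswith("single_color:")
        ):
            raise ValueError(f"unknown cocktail designation {self.cocktail!r}")

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    def channel_values(self, channel: str) -> np.ndarray:
        return self.data[channel].to_numpy(dtype=float)


@dataclass(frozen=True)
class GateSet:
    """Per-channel positive/negative cutoffs and where each came from."""

    thresholds: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, t in self.thresholds.items():
            if not (math.isfinite(t) and t >= 0):
                raise ValueError(f"threshold for {ch!r} must be finite and >= 0, got {t}")

    def __getitem__(self, channel: str) -> float:
        return self.thresholds[channel]


@dataclass(frozen=True)
class ReporterScore:
    """The %Reporter Expression statistic for one pathway in one sample pair.

    ``x_value`` is the damaged-cocktail ratio
    (reporter count x MFI) / (control count x MFI); ``y_value`` is the same
    ratio in the undamaged cocktail; percent_expression = 100 * X / Y.
    ``counts_and_mfi`` stores the four (count, MFI) pairs keyed by
    ``{reporter,control} x {damaged,undamaged}``.
    """

    pathway: str
    percent_expression: float
    x_value: float
    y_value: float
    counts_and_mfi: dict[str, tuple[int, float]]
    sample_id: str = ""

    @property
    def defined(self) -> bool:
        return math.isfinite(self.percent_expression)


@dataclass(frozen=True)
class NormalizedScore:
    """Treated-over-control fold change of mean %Reporter Expression."""

    pathway: str
    fold_change: float
    treated_label: str = ""
    control_label: str = ""


@dataclass(frozen=True)
class MarkerFractions:
    """Marker-positive proportions, overall and per cell-cycle phase."""

    overall_fraction: float
    per_phase: dict[str, float]
    counts: dict[str, tuple[int, int]]  # phase -> (positive, total)
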