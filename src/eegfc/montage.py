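"""The 19-channel 10-20 scalp montage and its five-region partition."""

from __future__ import annotations

from dataclasses import dataclass, field

from eegfc.errors import ConfigurationError

#: Channel order of the clinical 10-20 recording montage (19 scalp electrodes).
MONTAGE_19: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Electrode-location partition used for regional graph metrics.
DEFAULT_REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "Fp2", "F3", "F4", "Fz"),
    "temporal": ("T3", "T4", "T5", "T6", "F7", "F8"),
    "parietal": ("P3", "Pz", "P4"),
    "occipital": ("O1", "O2"),
    "central": ("C3", "Cz", "C4"),
}


@dataclass(frozen=True)
class RegionScheme:
    """Maps each channel label to exactly one scalp region.

    Labels are matched case-insensitively.  The default partitions the
    19-channel montage into frontal / temporal / parietal / occipital /
    central groups by electrode location.
    """

    regions: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for region, chans in self.regions.items():
            for ch in chans:
                key = ch.lower()
                if key in seen:
                    raise ConfigurationError(
                        f"channel {ch!r} assigned to both {seen[key]!r} and {region!r}"
                    )
                seen[key] = region

    def region_of(self, channel: str) -> str:
        for region, chans in self.regions.items():
            if channel.lower() in (c.lower() for c in chans):
                return region
        raise ConfigurationError(f"channel {channel!r} missing from region scheme")

    def members(self, region: str, channel_labels: list[str] | tuple[str, ...]) -> list[int]:
        """Indices of ``channel_labels`` belonging to ``region``."""
        if region not in self.regions:
            raise ConfigurationError(f"unknown region {region!r}")
        wanted = {c.lower() for c in self.regions[region]}
        return [i for i, ch in enumerate(channel_labels) if ch.lower() in wanted]
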