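"""Electrode montage for the 31-channel 10–20 recording layout."""

from __future__ import annotations

from dataclasses import dataclass, field

#: Default 31-channel montage. The original acquisition montage listed C4
#: twice; the second occurrence is read as P4 (the parietal site symmetric
#: to P3), which restores a standard left/right-balanced 10–20 layout.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "AF3", "AF4", "F3", "F4", "F7", "F8",
    "Fc1", "Fc2", "Fc5", "Fc6", "Fz", "C3", "C4", "Cp1",
    "Cp2", "Cp5", "Cp6", "Cz", "P3", "P4", "PO3", "PO4",
    "Pz", "T3", "T4", "T5", "T6", "O1", "O2",
)


@dataclass(frozen=True)
class ChannelMontage:
    """Ordered set of scalp electrode labels (10–20 system)."""

    names: tuple[str, ...] = field(default=DEFAULT_CHANNELS)

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if list(names).count(n) > 1})
            raise ValueError(f"montage labels must be unique; duplicated: {dupes}")
        if not names:
            raise ValueError("montage must contain at least one channel")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, label: str) -> bool:
        return label in self.names

    def index(self, label: str) -> int:
        """Position of *label* in the montage; raises ``KeyError`` if absent."""
        try:
            return self.names.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None
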