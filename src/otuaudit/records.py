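"""Per-member distance records shared by the distance and audit layers."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InputError


@dataclass(frozen=True)
class DistanceRecord:
    """Distances from one OTU member to its representative.

    Any of the three metrics may be absent (``None``); at least one must be
    present. MSD and PSD are p-distances in [0, 1]; BLD is a patristic
    distance in expected substitutions per site, unbounded above.
    """

    otu_id: str
    member_id: str
    msd: float | None = None
    bld: float | None = None
    psd: float | None = None

    def __post_init__(self) -> None:
        if self.msd is None and self.bld is None and self.psd is None:
            raise InputError(
                f"record ({self.otu_id}, {self.member_id}): at least one metric required"
            )
        for name in ("msd", "psd"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise InputError(f"record ({self.otu_id}, {self.member_id}): {name}={v} outside [0,1]")
        if self.bld is not None and self.bld < 0:
            raise InputError(f"record ({self.otu_id}, {self.member_id}): bld={self.bld} negative")
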