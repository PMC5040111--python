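"""Two-source carbon-isotope mixing model.

The fraction of soil carbon derived from C4 plants is the linear mixing
coefficient implied by the bulk-soil delta-13C and the two plant
end-members. Out-of-range fractions are flagged, never clamped, so that
end-member misspecification stays visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class IsotopeEndmembers:
    """delta-13C values (per mil) of C3 tissue, C4 tissue, and bulk soil."""

    delta_c3: float
    delta_c4: float
    delta_soil: float

    def __post_init__(self):
        if self.delta_c3 == self.delta_c4:
            raise ValueError(
                "C3 and C4 end-members are equal; mixing fraction undefined"
            )


@dataclass(frozen=True)
class MixingResult:
    fraction: float
    in_range: bool  # False when the fraction falls outside [0, 1]


def fraction_c4(e: IsotopeEndmembers) -> MixingResult:
    """Fraction of soil C from C4 sources: (soil - c3) / (c4 - c3)."""
    f = (e.delta_soil - e.delta_c3) / (e.delta_c4 - e.delta_c3)
    return MixingResult(fraction=float(f), in_range=0.0 <= f <= 1.0)


def fraction_c4_table(
    samples: pd.DataFrame, delta_c3: float, delta_c4: float
) -> pd.DataFrame:
    """Vector version over a (sample_id, delta_soil) table."""
    missing = {"sample_id", "delta_soil"} - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    out = samples[["sample_id", "delta_soil"]].copy()
    results = [
        fraction_c4(IsotopeEndmembers(delta_c3, delta_c4, d))
        for d in out["delta_soil"]
    ]
    out["fraction_c4"] = [r.fraction for r in results]
    out["in_range"] = [r.in_range for r in results]
    return out
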