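"""The paired-factorial design shared by all analysis stages.

Treatment cells are coded ``UU`` (unclipped-unwarmed control), ``UW``
(warmed only), ``CU`` (clipped only), and ``CW`` (clipped and warmed):
first letter clipping status, second letter warming status.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Treatment cells in canonical order.
TREATMENTS: tuple[str, ...] = ("UU", "UW", "CU", "CW")

#: (warmed, clipped) indicator flags per treatment cell.
TREATMENT_FLAGS: dict[str, tuple[int, int]] = {
    "UU": (0, 0),
    "UW": (1, 0),
    "CU": (0, 1),
    "CW": (1, 1),
}


def treatment_code(warmed: int, clipped: int) -> str:
    """Map binary (warmed, clipped) flags to the treatment cell label."""
    return ("C" if clipped else "U") + ("W" if warmed else "U")


@dataclass(frozen=True)
class FactorialDesign:
    """A complete block design: every block holds one plot per treatment cell."""

    n_blocks: int = 6

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError(f"n_blocks must be positive, got {self.n_blocks}")

    @property
    def blocks(self) -> list[str]:
        return [f"B{i + 1}" for i in range(self.n_blocks)]

    def sample_id(self, block: str, treatment: str) -> str:
        if treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {treatment!r}")
        return f"{block}_{treatment}"

    def sample_table(self) -> pd.DataFrame:
        """One row per plot: sample_id, block, treatment, warmed, clipped."""
        rows = []
        for block in self.blocks:
            for trt in TREATMENTS:
                warmed, clipped = TREATMENT_FLAGS[trt]
                rows.append(
                    {
                        "sample_id": self.sample_id(block, trt),
                        "block": block,
                        "treatment": trt,
                        "warmed": warmed,
                        "clipped": clipped,
                    }
                )
        return pd.DataFrame(rows)
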